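"""Benchmark construction: eligibility filtering, temporal and random splits.

QSAR benchmarks are built per target from aggregated pairs.  A target is
worth modelling only if it has enough signal on both sides of the activity
threshold and enough dynamic range; targets below the bar are disregarded
with the reason recorded.

Two split schemes are provided.  The *temporal* split holds out everything
first published in or after the cut year (default 2013) — a harder, more
honest estimate of prospective performance than a random split, since
congeneric series published together stay together.  The *random* split is
seeded and optionally stratified on the activity class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SplitConfig",
    "Eligibility",
    "qsar_eligible",
    "temporal_split",
    "random_split",
    "cv_folds",
]


@dataclass(frozen=True)
class SplitConfig:
    scheme: str = "temporal"
    split_year: int = 2013
    test_fraction: float = 0.2
    seed: int = 1234
    activity_threshold: float = 6.5
    min_class_count: int = 30
    min_range: float = 2.0
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("random", "temporal"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.min_class_count < 1:
            raise ValueError("min_class_count must be >= 1")


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: str = ""
    n_active: int = 0
    n_inactive: int = 0
    value_range: float = 0.0


def _means(records) -> list[float]:
    means = [r.pchembl_mean for r in records if r.pchembl_mean is not None]
    return means


def qsar_eligible(
    target_records: Sequence, cfg: SplitConfig = SplitConfig()
) -> Eligibility:
    """Decide whether one target has enough data to model.

    Requires at least ``min_class_count`` actives *and* inactives at
    ``activity_threshold`` (a pair is active when its mean pChEMBL is at or
    above the threshold) and a pChEMBL spread of at least ``min_range`` log
    units; both bounds are inclusive, so 30/30 compounds spanning exactly
    2.0 logs pass.
    """
    means = _means(target_records)
    n_active = sum(v >= cfg.activity_threshold for v in means)
    n_inactive = len(means) - n_active
    value_range = (max(means) - min(means)) if means else 0.0
    if n_active < cfg.min_class_count or n_inactive < cfg.min_class_count:
        return Eligibility(
            False,
            f"class count: {n_active} active / {n_inactive} inactive, "
            f"need >= {cfg.min_class_count} of each",
            n_active,
            n_inactive,
            value_range,
        )
    if value_range < cfg.min_range:
        return Eligibility(
            False,
            f"range: values span {value_range:.2f} < {cfg.min_range} log units",
            n_active,
            n_inactive,
            value_range,
        )
    return Eligibility(True, "", n_active, n_inactive, value_range)


def temporal_split(
    records: Sequence, cfg: SplitConfig = SplitConfig()
) -> tuple[list, list] | None:
    """Partition by first-publication year: ``year >= split_year`` is test.

    The year of an aggregated pair is the earliest contributing document
    year (a pair known early belongs to the past); records with no year are
    assigned to train.  Returns ``None`` — the target is disregarded — when
    either side would be empty.
    """
    train, test = [], []
    for r in records:
        year = getattr(r, "year_first", None)
        if year is None:
            year = getattr(r, "year", None)
        if year is not None and year >= cfg.split_year:
            test.append(r)
        else:
            train.append(r)
    if not train or not test:
        return None
    return train, test


def random_split(
    records: Sequence, cfg: SplitConfig = SplitConfig()
) -> tuple[list, list]:
    """Seeded disjoint partition with ``round(n * test_fraction)`` test records.

    With ``cfg.stratify`` the split is drawn per activity class (at
    ``activity_threshold`` on the mean pChEMBL), keeping the test class
    balance within one record of the dataset's.
    """
    records = list(records)
    rng = np.random.default_rng(cfg.seed)
    if not cfg.stratify:
        return _draw(records, cfg.test_fraction, rng)

    active = [r for r in records if (r.pchembl_mean or 0.0) >= cfg.activity_threshold]
    inactive = [r for r in records if (r.pchembl_mean or 0.0) < cfg.activity_threshold]
    # largest-remainder allocation of the overall test size across classes
    n_test = int(round(len(records) * cfg.test_fraction))
    n_test_active = int(round(len(active) * cfg.test_fraction))
    n_test_active = min(n_test_active, n_test)
    train_a, test_a = _draw_n(active, n_test_active, rng)
    train_i, test_i = _draw_n(inactive, n_test - n_test_active, rng)
    return train_a + train_i, test_a + test_i


def _draw(records: list, fraction: float, rng: np.random.Generator):
    return _draw_n(records, int(round(len(records) * fraction)), rng)


def _draw_n(records: list, n_test: int, rng: np.random.Generator):
    n_test = min(n_test, len(records))
    idx = rng.permutation(len(records))
    test_idx = set(idx[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def cv_folds(
    n_records: int, n_folds: int = 5, seed: int = 1234
) -> list[np.ndarray]:
    """Seeded fold assignment for k-fold cross-validation: a list of index
    arrays, sizes differing by at most one, pairwise disjoint and covering
    ``range(n_records)``."""
    if n_folds < 2 or n_folds > n_records:
        raise ValueError("need 2 <= n_folds <= n_records")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_records)
    return [np.sort(part) for part in np.array_split(idx, n_folds)]
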