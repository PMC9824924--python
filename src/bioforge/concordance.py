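"""High-reproducibility subset via cross-assay concordance filtering.

IC50 and EC50 values depend strongly on assay design (substrate
concentration, incubation time, readout), so the same compound-target pair
measured in different assays can disagree by orders of magnitude, while Ki
and KD are comparatively assay-independent.  The filter therefore:

1. leaves Ki and KD evidence intact;
2. for IC50 and EC50 separately, takes every pair measured in at least two
   assays, computes the median over its measurements, and removes points
   whose absolute distance to that median exceeds ``max_median_distance``
   (default 0.5 log units) — those are *non-concordant*;
3. scores every assay by the fraction of its multi-assay measurements that
   survived (its *concordance*); an assay is *reproducible* when that
   fraction is at least ``min_assay_concordance`` (default 0.75);
4. keeps a single-assay IC50/EC50 point only if its assay was deemed
   reproducible.  An assay with no multi-assay comparisons cannot
   demonstrate reproducibility, so its singletons are excluded.

The pass is single-shot: survivors are not re-scored against the new
median.  The output is always a subset of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .quality import AnnotatedActivity

__all__ = [
    "PlusFilterConfig",
    "AssayScore",
    "concordance_filter",
    "score_assays",
    "build_concordant_set",
]


@dataclass(frozen=True)
class PlusFilterConfig:
    """Numeric rules of the concordance filter.

    ``max_median_distance``: removal bound, strict inequality (a point
    exactly 0.5 log units from the median stays).  ``min_assay_concordance``:
    inclusive reproducibility threshold on the concordant fraction.
    ``exempt_types`` pass unfiltered.
    """

    max_median_distance: float = 0.5
    min_assay_concordance: float = 0.75
    exempt_types: frozenset[str] = frozenset({"Ki", "KD"})
    filtered_types: tuple[str, ...] = ("IC50", "EC50")

    def __post_init__(self) -> None:
        if not self.max_median_distance > 0:
            raise ValueError("max_median_distance must be positive")
        if not 0 <= self.min_assay_concordance <= 1:
            raise ValueError("min_assay_concordance must be a fraction")


@dataclass(frozen=True)
class AssayScore:
    """Concordance record of one assay over multi-assay pairs."""

    assay_id: str
    n_comparisons: int
    n_concordant: int
    reproducible: bool

    @property
    def concordance(self) -> float | None:
        if self.n_comparisons == 0:
            return None
        return self.n_concordant / self.n_comparisons


def concordance_filter(
    pair_values: Sequence[tuple[str, float]],
    cfg: PlusFilterConfig = PlusFilterConfig(),
) -> tuple[list[int], list[int]]:
    """Split one multi-assay pair's measurements into kept/removed indices.

    The median is taken over all measurements of the pair (not per-assay
    means); index ``i`` is removed iff ``|value_i - median| >
    cfg.max_median_distance`` (strictly).  ``kept + removed`` is always a
    permutation of the input indices.
    """
    if len(pair_values) < 2:
        raise ValueError("concordance filter needs >= 2 measurements")
    values = np.asarray([v for _, v in pair_values], dtype=float)
    median = float(np.median(values))
    kept, removed = [], []
    for i, v in enumerate(values):
        (removed if abs(v - median) > cfg.max_median_distance else kept).append(i)
    return kept, removed


def _pair_key(r: AnnotatedActivity, compounds: Mapping | None) -> tuple[str, str]:
    ref = r.measurement.molecule_ref
    if compounds is not None and ref in compounds:
        ref = compounds[ref].connectivity_key
    return (ref, r.target_accession)


def score_assays(
    multi_assay_pairs: Mapping[tuple, Sequence[tuple[str, float]]],
    cfg: PlusFilterConfig = PlusFilterConfig(),
) -> dict[str, AssayScore]:
    """Score every assay appearing in the given multi-assay pairs.

    ``multi_assay_pairs`` maps a pair key to its ``(assay_id, pchembl)``
    measurements (>= 2 measurements from >= 2 assays).  Each measurement —
    not each pair — counts as one comparison for its assay.  Assays absent
    from every multi-assay pair get no score here and are treated as not
    reproducible downstream.
    """
    n_comp: dict[str, int] = {}
    n_conc: dict[str, int] = {}
    for values in multi_assay_pairs.values():
        kept, _ = concordance_filter(values, cfg)
        kept_set = set(kept)
        for i, (assay_id, _v) in enumerate(values):
            n_comp[assay_id] = n_comp.get(assay_id, 0) + 1
            if i in kept_set:
                n_conc[assay_id] = n_conc.get(assay_id, 0) + 1
    return {
        a: AssayScore(
            assay_id=a,
            n_comparisons=n_comp[a],
            n_concordant=n_conc.get(a, 0),
            reproducible=(n_conc.get(a, 0) / n_comp[a]) >= cfg.min_assay_concordance,
        )
        for a in sorted(n_comp)
    }


@dataclass
class ConcordanceResult:
    """Outcome of the filter at measurement level, before re-aggregation."""

    kept: list[AnnotatedActivity]
    removed: list[AnnotatedActivity]
    #: activity type -> assay id -> score (assays are scored per type)
    assay_scores: dict[str, dict[str, AssayScore]] = field(default_factory=dict)


def build_concordant_set(
    records: Iterable[AnnotatedActivity],
    cfg: PlusFilterConfig = PlusFilterConfig(),
    *,
    compounds: Mapping | None = None,
) -> ConcordanceResult:
    """Apply the full concordance filter to annotated exact measurements.

    Exempt types (Ki/KD) pass untouched.  For each filtered type
    separately, multi-assay pairs keep their concordant points and
    singleton points survive only in reproducible assays.  Censored and
    binary records of filtered types are outside the filter's remit and are
    excluded from the high-reproducibility subset.
    """
    records = list(records)
    kept: list[AnnotatedActivity] = []
    removed: list[AnnotatedActivity] = []
    scores: dict[str, dict[str, AssayScore]] = {}

    by_type: dict[str, list[AnnotatedActivity]] = {}
    for r in records:
        t = r.normalised.activity_type
        if t in cfg.exempt_types:
            kept.append(r)
        elif t in cfg.filtered_types and not r.normalised.censored and not r.normalised.is_binary:
            by_type.setdefault(t, []).append(r)
        else:
            removed.append(r)

    for t in cfg.filtered_types:
        type_records = by_type.get(t, [])
        pairs: dict[tuple, list[AnnotatedActivity]] = {}
        for r in type_records:
            pairs.setdefault(_pair_key(r, compounds), []).append(r)

        multi: dict[tuple, list[AnnotatedActivity]] = {}
        single: dict[tuple, list[AnnotatedActivity]] = {}
        for key, group in pairs.items():
            assays = {r.measurement.assay_id for r in group}
            (multi if len(assays) > 1 else single)[key] = group

        pair_values = {
            key: [(r.measurement.assay_id, r.pchembl) for r in group]
            for key, group in multi.items()
        }
        type_scores = score_assays(pair_values, cfg)
        scores[t] = type_scores

        for key, group in multi.items():
            kept_idx, removed_idx = concordance_filter(pair_values[key], cfg)
            kept.extend(group[i] for i in kept_idx)
            removed.extend(group[i] for i in removed_idx)
        for group in single.values():
            for r in group:
                score = type_scores.get(r.measurement.assay_id)
                if score is not None and score.reproducible:
                    kept.append(r)
                else:
                    removed.append(r)

    return ConcordanceResult(kept=kept, removed=removed, assay_scores=scores)
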