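"""Sphere-exclusion diversity (SE_Div) of molecule sets.

SE_Div is the fraction of a molecule set picked as cluster centres by the
leader algorithm — a single-pass sphere-exclusion clustering: scan the set
in order, and a molecule founds a new centre exactly when its Tanimoto
distance to every existing centre strictly exceeds the sphere radius,
otherwise it joins an existing sphere.  At the default radius of 0.65
(Tanimoto similarity 0.35 or above belongs to a sphere) the fraction of
centres approximates the minimum fraction of the set needed to cover its
chemical diversity.

Because SE_Div grows with set size, sets of different sizes are compared
through repeated fixed-size subsampling: draw ``subsample_size`` molecules
without replacement, shuffle the scan order, compute SE_Div, and repeat.
The scan order is randomised per repeat — the leader algorithm is
order-dependent, and a fixed order would bias the statistic by input
sorting.

Fingerprints are folded Morgan (circular) fingerprints, radius 3 /
1024 bits by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "DiversityConfig",
    "SEDivResult",
    "fingerprints",
    "leader_pick",
    "se_div",
    "subsampled_se_div",
]


@dataclass(frozen=True)
class DiversityConfig:
    fp_radius: int = 3
    fp_bits: int = 1024
    distance_threshold: float = 0.65
    subsample_size: int = 228
    n_repeats: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.distance_threshold < 1:
            raise ValueError("distance_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SEDivResult:
    per_repeat: tuple[float, ...]
    mean: float
    sd: float


def fingerprints(
    smiles: Sequence[str], cfg: DiversityConfig = DiversityConfig()
) -> list:
    """Folded Morgan fingerprints (bond radius ``fp_radius``, ``fp_bits``
    bits) for a list of SMILES; unparseable entries raise."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.fp_radius, fpSize=cfg.fp_bits
    )
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def leader_pick(fps: Sequence, threshold: float = 0.65) -> list[int]:
    """Centre indices of the leader algorithm at the given distance radius.

    Single pass in the given order: element ``i`` becomes a centre iff its
    Tanimoto distance (1 - similarity) to every existing centre is strictly
    greater than ``threshold``.  The first element is always a centre.
    """
    if len(fps) == 0:
        raise ValueError("leader_pick needs a non-empty fingerprint list")
    centres: list[int] = [0]
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], [fps[c] for c in centres])
        if all(1.0 - s > threshold for s in sims):
            centres.append(i)
    return centres


def se_div(fps: Sequence, cfg: DiversityConfig = DiversityConfig()) -> float:
    """SE_Div of one set: |centres| / |set| at ``cfg.distance_threshold``."""
    return len(leader_pick(fps, cfg.distance_threshold)) / len(fps)


def subsampled_se_div(
    fps: Sequence, cfg: DiversityConfig = DiversityConfig()
) -> SEDivResult:
    """Size-normalised SE_Div: mean over repeated fixed-size subsamples.

    Each repeat draws ``subsample_size`` fingerprints uniformly without
    replacement (independently across repeats) and scans them in a fresh
    random order; all randomness flows from ``cfg.seed``.  The dataset is
    put into a canonical order (by fingerprint bit string) before sampling,
    so two datasets identical up to record order give identical results for
    the same seed.
    """
    n = len(fps)
    if n < cfg.subsample_size:
        raise ValueError(
            f"dataset of {n} smaller than subsample_size {cfg.subsample_size}"
        )
    order = sorted(range(n), key=lambda i: fps[i].ToBitString())
    fps = [fps[i] for i in order]
    rng = np.random.default_rng(cfg.seed)
    values = []
    for _ in range(cfg.n_repeats):
        idx = rng.choice(n, size=cfg.subsample_size, replace=False)
        subset = [fps[i] for i in idx]
        values.append(se_div(subset, cfg))
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SEDivResult(
        per_repeat=tuple(values), mean=float(arr.mean()), sd=sd
    )
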