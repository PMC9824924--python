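"""Cross-source deduplication and per-pair pooling of pChEMBL evidence.

Aggregated public sources repackage one another (a kinase collection may
embed an older ChEMBL release wholesale), so identical measurements recur
across sources.  Deduplication uses a declared *lineage*: a mapping from
each source to the upstream sources it repackages.  A record is dropped
when an identical record exists in a source it repackages — the upstream
copy is the one kept — while genuinely independent equal values survive, as
repeated measurements legitimately agree.  Composite scores derived from
several activity types (declared via ``derived_types``) are never deduped
against their inputs; they pass through flagged ``derived``.

Surviving exact values are pooled per (compound connectivity, target
accession, activity type) into mean / sample std / median pChEMBL.
Censored values are counted but never enter the statistics; activity types
are pooled separately by default since Ki, KD, IC50 and EC50 answer
different experimental questions (``pool_types=True`` collapses them for
use cases that want one number per pair regardless).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .quality import AnnotatedActivity
from .standardize import StandardisedCompound

__all__ = [
    "AggregatedActivity",
    "deduplicate_sources",
    "aggregate_pair",
    "aggregate_all",
]

_TIER_ORDER = {"high": 0, "medium": 1, "low": 2}


@dataclass(frozen=True)
class AggregatedActivity:
    """Pooled evidence for one compound-target pair and activity type."""

    connectivity_key: str
    target_accession: str
    activity_type: str
    inchikey: str = ""
    inchi: str = ""
    smiles: str = ""
    organism: str = ""
    relation: str = "="
    pchembl_mean: float | None = None
    pchembl_std: float | None = None
    pchembl_median: float | None = None
    n_exact: int = 0
    n_censored: int = 0
    quality: str = "low"
    year_first: int | None = None
    year_last: int | None = None
    sources: tuple[str, ...] = ()
    assays: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_exact == 0 and self.n_censored == 0:
            raise ValueError("aggregated pair needs exact or censored evidence")
        if self.n_exact == 1 and self.pchembl_std not in (0.0, None):
            raise ValueError("single exact value must have std 0")


# ---------------------------------------------------------------------------
# Source deduplication


def _ancestors(lineage: Mapping[str, Sequence[str]]) -> dict[str, frozenset[str]]:
    """Transitive closure of "repackages"; raises on a circular declaration."""
    closure: dict[str, frozenset[str]] = {}

    def visit(src: str, stack: tuple[str, ...]) -> frozenset[str]:
        if src in stack:
            cycle = " -> ".join(stack[stack.index(src):] + (src,))
            raise ValueError(f"circular source lineage: {cycle}")
        if src in closure:
            return closure[src]
        acc: set[str] = set()
        for parent in lineage.get(src, ()):
            acc.add(parent)
            acc |= visit(parent, stack + (src,))
        closure[src] = frozenset(acc)
        return closure[src]

    for src in lineage:
        visit(src, ())
    return closure


def _content_key(m, key_func) -> tuple:
    return (
        key_func(m),
        m.target_accession,
        m.assay_id,
        m.activity_type,
        m.relation,
        m.value,
        m.unit,
        m.is_binary,
    )


def deduplicate_sources(
    records: Sequence[AnnotatedActivity],
    lineage: Mapping[str, Sequence[str]] | None = None,
    *,
    derived_types: frozenset[str] = frozenset(),
    key_func=None,
) -> tuple[list[AnnotatedActivity], list[AnnotatedActivity]]:
    """Drop repackaged copies; return ``(kept, dropped)``.

    ``lineage`` maps a source id to the upstream source ids it repackages
    (transitively expanded; a cycle is a hard error).  ``key_func`` extracts
    the molecule identity from a raw measurement — pass one based on
    connectivity keys so that salt/stereo variants of one repackaged record
    still collapse; the default uses the verbatim ``molecule_ref``.
    """
    lineage = lineage or {}
    ancestors = _ancestors(lineage)
    if key_func is None:
        key_func = lambda m: m.molecule_ref  # noqa: E731

    kept: list[AnnotatedActivity] = []
    dropped: list[AnnotatedActivity] = []
    groups: dict[tuple, list[AnnotatedActivity]] = {}
    for r in records:
        m = r.measurement
        if m.activity_type in derived_types:
            kept.append(
                replace(
                    r,
                    normalised=replace(
                        r.normalised,
                        flags=r.normalised.flags | {"derived"},
                    ),
                )
            )
            continue
        groups.setdefault(_content_key(m, key_func), []).append(r)

    for group in groups.values():
        present = {r.measurement.source_id for r in group}
        seen_in_source: set[str] = set()
        for r in group:
            src = r.measurement.source_id
            repackaged = any(
                a in present for a in ancestors.get(src, frozenset())
            )
            if repackaged or src in seen_in_source:
                dropped.append(r)
            else:
                kept.append(r)
                seen_in_source.add(src)
    return kept, dropped


# ---------------------------------------------------------------------------
# Per-pair pooling


def aggregate_pair(
    records: Sequence[AnnotatedActivity],
    *,
    compound: StandardisedCompound | None = None,
    organism: str = "",
    activity_type: str | None = None,
) -> AggregatedActivity:
    """Pool one (compound, target, type) group of annotated records.

    Statistics are over exact values only (sample std, ddof 1, defined as 0
    for a single value); censored bounds are counted in ``n_censored``.  The
    pooled quality is the worst tier among the contributing records — a pair
    is only as reliable as its weakest included point.  Permutation
    invariant in record order.
    """
    if not records:
        raise ValueError("aggregate_pair needs at least one record")
    first = records[0]
    exact = sorted(
        r.pchembl for r in records if not r.normalised.censored and not r.normalised.is_binary
    )
    censored = [r for r in records if r.normalised.censored]
    if len(exact) + len(censored) != len(records):
        raise ValueError("binary records cannot be pooled into pChEMBL statistics")

    if exact:
        arr = np.asarray(exact, dtype=float)
        mean = float(arr.mean())
        std = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
        median = float(np.median(arr))
        relation = "="
    else:
        mean = std = median = None
        relation = ";".join(sorted({r.normalised.relation for r in censored}))

    years = [r.measurement.year for r in records if r.measurement.year is not None]
    quality = max((r.quality for r in records), key=_TIER_ORDER.__getitem__)
    compound = compound if compound is not None else None
    return AggregatedActivity(
        connectivity_key=compound.connectivity_key if compound else "",
        inchikey=compound.inchikey if compound else "",
        inchi=compound.inchi if compound else "",
        smiles=compound.smiles if compound else "",
        target_accession=first.target_accession,
        organism=organism,
        activity_type=activity_type or first.normalised.activity_type,
        relation=relation,
        pchembl_mean=mean,
        pchembl_std=std,
        pchembl_median=median,
        n_exact=len(exact),
        n_censored=len(censored),
        quality=quality,
        year_first=min(years) if years else None,
        year_last=max(years) if years else None,
        sources=tuple(sorted({r.measurement.source_id for r in records})),
        assays=tuple(sorted({r.measurement.assay_id for r in records})),
    )


def aggregate_all(
    records: Iterable[AnnotatedActivity],
    compounds: Mapping[str, StandardisedCompound],
    organisms: Mapping[str, str] | None = None,
    *,
    pool_types: bool = False,
) -> list[AggregatedActivity]:
    """Group annotated records by (connectivity, accession, type) and pool.

    ``compounds`` maps each measurement's ``molecule_ref`` to its
    standardised structure; records of rejected structures and binary
    activity classes are excluded from pooling (the latter stay available
    for measurement-level reports).  Output is sorted deterministically.
    """
    organisms = organisms or {}
    groups: dict[tuple[str, str, str], list[AnnotatedActivity]] = {}
    for r in records:
        if r.normalised.is_binary:
            continue
        comp = compounds.get(r.measurement.molecule_ref)
        if comp is None or comp.rejected:
            continue
        atype = "pooled" if pool_types else r.normalised.activity_type
        groups.setdefault(
            (comp.connectivity_key, r.target_accession, atype), []
        ).append(r)

    out = []
    for (ckey, acc, atype), group in sorted(groups.items()):
        comp = compounds[group[0].measurement.molecule_ref]
        out.append(
            aggregate_pair(
                group,
                compound=comp,
                organism=organisms.get(acc, ""),
                activity_type=atype,
            )
        )
    return out
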