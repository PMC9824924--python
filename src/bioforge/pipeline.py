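"""End-to-end curation: raw measurements in, aggregated activity set out.

The stage order is fixed: standardise structures, normalise activities to
pChEMBL, annotate quality, deduplicate repackaged sources, aggregate per
(compound connectivity, target, activity type).  Each stage's intermediate
product stays available on the result object for reporting and for the
concordance filter, which operates on annotated measurements and re-uses
the aggregation step on its survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .aggregate import AggregatedActivity, aggregate_all, deduplicate_sources
from .concordance import ConcordanceResult, PlusFilterConfig, build_concordant_set
from .io import Measurement, ProteinRecord
from .normalize import NormalisedActivity, normalise_all
from .quality import AnnotatedActivity, annotate_all
from .standardize import StandardisedCompound, standardize_molecule

__all__ = ["CurationResult", "curate", "concordant_subset"]


@dataclass
class CurationResult:
    """All products of one curation run, from structures to pooled pairs."""

    compounds: dict[str, StandardisedCompound]
    normalised: list[NormalisedActivity]
    annotated: list[AnnotatedActivity]
    deduplicated: list[AnnotatedActivity]
    dropped_duplicates: list[AnnotatedActivity]
    aggregated: list[AggregatedActivity]
    inadmissible: list[NormalisedActivity] = field(default_factory=list)


def curate(
    measurements: Sequence[Measurement],
    proteins: Mapping[str, ProteinRecord] | None = None,
    lineage: Mapping[str, Sequence[str]] | None = None,
    *,
    derived_types: frozenset[str] = frozenset(),
    pool_types: bool = False,
    keep_stereo: bool = False,
) -> CurationResult:
    """Run the full curation pipeline over raw measurements.

    ``proteins`` supplies organisms for the curated table (records whose
    accession is unknown keep an empty organism); ``lineage`` declares which
    sources repackage which (see :func:`~bioforge.aggregate.deduplicate_sources`).
    """
    proteins = proteins or {}
    compounds: dict[str, StandardisedCompound] = {}
    for m in measurements:
        if m.molecule_ref not in compounds:
            compounds[m.molecule_ref] = standardize_molecule(
                m.molecule_ref, keep_stereo=keep_stereo
            )

    normalised = normalise_all(measurements)
    inadmissible = [n for n in normalised if not n.admissible]
    annotated = annotate_all(normalised)

    def mol_key(m: Measurement) -> str:
        comp = compounds.get(m.molecule_ref)
        if comp is not None and not comp.rejected:
            return comp.connectivity_key
        return m.molecule_ref

    deduplicated, dropped = deduplicate_sources(
        annotated, lineage, derived_types=derived_types, key_func=mol_key
    )

    organisms = {acc: p.organism for acc, p in proteins.items()}
    aggregated = aggregate_all(
        deduplicated, compounds, organisms, pool_types=pool_types
    )
    return CurationResult(
        compounds=compounds,
        normalised=normalised,
        annotated=annotated,
        deduplicated=deduplicated,
        dropped_duplicates=dropped,
        aggregated=aggregated,
        inadmissible=inadmissible,
    )


def concordant_subset(
    result: CurationResult,
    cfg: PlusFilterConfig = PlusFilterConfig(),
    *,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> tuple[list[AggregatedActivity], ConcordanceResult]:
    """High-reproducibility subset of a curation run.

    Applies the assay-concordance filter to the deduplicated measurements
    and re-aggregates the survivors; returns the filtered aggregated set
    together with the measurement-level filter outcome (kept / removed /
    per-assay scores).
    """
    filtered = build_concordant_set(
        result.deduplicated, cfg, compounds=result.compounds
    )
    organisms = {
        acc: p.organism for acc, p in (proteins or {}).items()
    }
    aggregated = aggregate_all(filtered.kept, result.compounds, organisms)
    return aggregated, filtered
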