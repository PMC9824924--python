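"""Quality tiers for normalised measurements.

Each admissible record is placed in exactly one of three tiers describing
what kind of model it can support:

* **high** — an exact value measured on an unambiguous target (a single
  protein or a complex subunit): regression-grade evidence;
* **medium** — an exact value whose target is ambiguous (possibly several
  proteins, or a single protein identified only by homology);
* **low** — exact values on multiply-homologous targets or homologous
  complex subunits, plus all censored values and binary activity classes:
  classification-grade evidence at best.

The tier is a pure function of (evidence kind, target mapping), so the
tiers are mutually exclusive and exhaustive, and degrading the target
mapping can never raise the tier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .normalize import NormalisedActivity

__all__ = ["QualityTier", "assign_quality", "annotate_all", "AnnotatedActivity"]

_RATIONALE_TO_TIER = {
    "exact_single": "high",
    "exact_multi_maybe": "medium",
    "exact_homolog_single": "medium",
    "exact_multi_homolog": "low",
    "homolog_complex": "low",
    "censored": "low",
    "binary": "low",
}

#: mapping value -> rationale for an *exact* record
_EXACT_RATIONALE = {
    "single": "exact_single",
    "complex_subunit": "exact_single",
    "multi": "exact_multi_maybe",
    "single_homolog": "exact_homolog_single",
    "multi_homolog": "exact_multi_homolog",
    "homolog_complex_subunit": "homolog_complex",
}


@dataclass(frozen=True)
class QualityTier:
    tier: str
    rationale: str

    def __post_init__(self) -> None:
        if _RATIONALE_TO_TIER.get(self.rationale) != self.tier:
            raise ValueError(
                f"tier {self.tier!r} inconsistent with rationale {self.rationale!r}"
            )


def assign_quality(n: NormalisedActivity) -> QualityTier:
    """Tier one admissible record by the decision table above.

    Censored and binary evidence is low regardless of target mapping; exact
    evidence is graded by how ambiguously the assay target maps to the
    protein accession.
    """
    if not n.admissible:
        raise ValueError(f"cannot tier inadmissible record: {n.reason}")
    if n.is_binary:
        rationale = "binary"
    elif n.censored:
        rationale = "censored"
    else:
        mapping = n.measurement.target_mapping
        try:
            rationale = _EXACT_RATIONALE[mapping]
        except KeyError:
            raise ValueError(f"unknown target mapping {mapping!r}") from None
    return QualityTier(tier=_RATIONALE_TO_TIER[rationale], rationale=rationale)


@dataclass(frozen=True)
class AnnotatedActivity:
    """A normalised record with its quality tier, as consumed by reporting,
    aggregation and the concordance filter."""

    normalised: NormalisedActivity
    quality: str
    rationale: str

    # convenience pass-throughs used throughout the pipeline
    @property
    def measurement(self):
        return self.normalised.measurement

    @property
    def target_accession(self) -> str:
        return self.normalised.measurement.target_accession

    @property
    def pchembl(self) -> float | None:
        return self.normalised.pchembl


def annotate_all(normalised) -> list[AnnotatedActivity]:
    """Tier every admissible record; inadmissible records are dropped here
    (they were already reported at normalisation)."""
    out = []
    for n in normalised:
        if not n.admissible:
            continue
        q = assign_quality(n)
        out.append(AnnotatedActivity(normalised=n, quality=q.tier, rationale=q.rationale))
    return out
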