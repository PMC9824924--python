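"""Activity-type admission and pChEMBL normalisation.

Only equilibrium/potency measures with a molar interpretation are pooled:
Ki, KD, IC50, EC50 and their negative-log transforms (pKi, pKD, pIC50,
pEC50).  Exact molar values are converted to pChEMBL = -log10(value in
mol/L); already-log values are admitted verbatim (no unit check is possible
for them, so they are flagged ``assumed_p_scale``).  Everything else —
percent inhibition, doses in mg/kg, free-text readouts — is inadmissible,
with the reason recorded: inadmissibility is data, not failure.

Censored values keep their bound through the transform; because -log10 is
decreasing, a concentration bound flips orientation on the p-scale
("IC50 > 1 uM" becomes "pIC50 < 6").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import Measurement

__all__ = [
    "NormalisedActivity",
    "UNIT_TO_MOLAR",
    "to_molar",
    "compute_pchembl",
    "admit_activity_type",
    "InadmissibleUnit",
]

#: unit alias -> factor to mol/L; keys compared case-insensitively after
#: micro-sign folding, so "uM", "um", "µM" and "μM" are all micromolar.
UNIT_TO_MOLAR: dict[str, float] = {
    "m": 1.0,
    "mol/l": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}

#: exact-scale type -> canonical name
_EXACT_TYPES = {"ki": "Ki", "kd": "KD", "ic50": "IC50", "ec50": "EC50"}
#: log-scale alias -> canonical exact type it transforms
_LOG_TYPES = {
    "pki": "Ki",
    "pkd": "KD",
    "pic50": "IC50",
    "pec50": "EC50",
    "log ki": "Ki",
    "log kd": "KD",
    "log ic50": "IC50",
    "log ec50": "EC50",
    "-log ki": "Ki",
    "-log kd": "KD",
    "-log ic50": "IC50",
    "-log ec50": "EC50",
}

_FLIP = {"<": ">", ">": "<", "<=": ">=", ">=": "<=", "=": "="}


class InadmissibleUnit(ValueError):
    """Raised by :func:`to_molar` for units without a molar interpretation."""


@dataclass(frozen=True)
class NormalisedActivity:
    """A measurement on the common pChEMBL scale, or the reason it is not.

    ``pchembl`` is defined iff the record is admissible and not binary;
    ``censored`` iff the (p-scale) relation is a bound.  The original
    measurement is retained for lineage, quality annotation and
    aggregation provenance.
    """

    measurement: Measurement
    activity_type: str = ""
    pchembl: float | None = None
    relation: str = "="
    censored: bool = False
    admissible: bool = False
    reason: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_binary(self) -> bool:
        return self.measurement.is_binary

    def __post_init__(self) -> None:
        if self.admissible and not self.is_binary and self.pchembl is None:
            raise ValueError("admissible exact/censored record needs a pchembl")
        if not self.admissible and self.pchembl is not None:
            raise ValueError("inadmissible record cannot carry a pchembl")
        if self.censored != (self.relation not in ("=",)) and self.admissible:
            raise ValueError("censored flag must mirror a non-'=' relation")


def _canonical_unit(unit: str) -> str:
    return unit.replace("µ", "u").replace("μ", "u").strip().lower()


def to_molar(value: float, unit: str) -> float:
    """Scale ``value`` in ``unit`` to mol/L.

    Accepted units are the molar-concentration family (M, mM, uM/µM, nM,
    pM), case-insensitively.  Anything else raises :class:`InadmissibleUnit`
    — percent inhibition or mg/kg doses cannot be placed on the pChEMBL
    scale.
    """
    factor = UNIT_TO_MOLAR.get(_canonical_unit(unit))
    if factor is None:
        raise InadmissibleUnit(f"non-molar unit {unit!r}")
    return value * factor


def compute_pchembl(molar: float) -> float:
    """pChEMBL of a molar activity: -log10(mol/L), full precision.

    Strictly decreasing in the concentration; 1 nM -> 9.0, 1 uM -> 6.0.
    Zero or negative concentrations have no logarithm and raise.
    """
    if molar <= 0:
        raise ValueError(f"non-positive molar value {molar!r}")
    return -math.log10(molar)


def admit_activity_type(m: Measurement) -> NormalisedActivity:
    """Decide admissibility of one measurement and normalise it to pChEMBL.

    Decision ladder:

    * binary activity classes of an admitted type: admissible, no pchembl;
    * Ki/KD/IC50/EC50 with a molar unit: converted, bound relations flipped
      on the p-scale;
    * pKi/pIC50/... : value taken verbatim as pchembl (``assumed_p_scale``
      flag), relation kept as is — it already points the p-scale way;
    * everything else: inadmissible with the reason recorded.
    """
    raw = m.activity_type.strip()
    key = raw.lower().replace("_", "")
    flags: set[str] = set()

    if m.is_binary:
        # binary activity classes carry no value to convert; the label type
        # is kept for bookkeeping but does not gate admission
        canonical = _LOG_TYPES.get(key) or _EXACT_TYPES.get(key) or raw
        return NormalisedActivity(
            measurement=m,
            activity_type=canonical,
            admissible=True,
            relation="=",
            censored=False,
        )

    if key in _LOG_TYPES:
        canonical = _LOG_TYPES[key]
        is_log = True
    elif key in _EXACT_TYPES:
        canonical = _EXACT_TYPES[key]
        is_log = False
    else:
        return _inadmissible(m, f"activity type {raw!r} not admitted")

    assert m.value is not None
    if is_log:
        flags.add("assumed_p_scale")
        pchembl = float(m.value)
        relation = m.relation
    else:
        assert m.unit is not None
        try:
            molar = to_molar(m.value, m.unit)
            pchembl = compute_pchembl(molar)
        except (InadmissibleUnit, ValueError) as exc:
            return _inadmissible(m, str(exc))
        relation = _FLIP[m.relation]

    return NormalisedActivity(
        measurement=m,
        activity_type=canonical,
        pchembl=pchembl,
        relation=relation,
        censored=relation != "=",
        admissible=True,
        flags=frozenset(flags),
    )


def _inadmissible(m: Measurement, reason: str) -> NormalisedActivity:
    return NormalisedActivity(measurement=m, admissible=False, reason=reason)


def normalise_all(measurements) -> list[NormalisedActivity]:
    """Admit/normalise a batch, keeping inadmissible records for reporting."""
    return [admit_activity_type(m) for m in measurements]
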