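"""pChEMBL normalisation: units, closed forms, censoring sign flips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioforge import admit_activity_type, compute_pchembl, to_molar
from bioforge.normalize import UNIT_TO_MOLAR, InadmissibleUnit

from conftest import make_measurement


class TestToMolar:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (10, "nM", 1e-8),
            (1, "µM", 1e-6),
            (1, "uM", 1e-6),
            (1, "um", 1e-6),
            (2.5, "mM", 2.5e-3),
            (3, "M", 3.0),
            (7, "pM", 7e-12),
            (1, "NM", 1e-9),
        ],
    )
    def test_concentration_units_scale_to_mol_per_litre(self, value, unit, expected):
        assert to_molar(value, unit) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("unit", ["%", "mg/kg", "ug.mL-1", "", "furlongs"])
    def test_non_molar_units_are_inadmissible(self, unit):
        with pytest.raises(InadmissibleUnit):
            to_molar(50, unit)

    @given(
        value=st.floats(1e-6, 1e6),
        unit=st.sampled_from(sorted(UNIT_TO_MOLAR)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverse_round_trip(self, value, unit):
        molar = to_molar(value, unit)
        assert molar / UNIT_TO_MOLAR[unit] == pytest.approx(value, rel=1e-12)


class TestComputePchembl:
    @pytest.mark.parametrize(
        "molar,expected", [(1e-9, 9.0), (1.0, 0.0), (3.162e-7, 6.50)]
    )
    def test_closed_forms(self, molar, expected):
        assert compute_pchembl(molar) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("molar", [0.0, -1e-9])
    def test_non_positive_rejected(self, molar):
        with pytest.raises(ValueError):
            compute_pchembl(molar)

    @given(
        a=st.floats(1e-12, 1e-1),
        factor=st.floats(1.0 + 1e-6, 1e6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, a, factor):
        assert compute_pchembl(a) > compute_pchembl(a * factor)


class TestAdmitActivityType:
    def test_exact_ic50_converted(self):
        n = admit_activity_type(make_measurement(value=100.0, unit="nM"))
        assert n.admissible and not n.censored
        assert n.pchembl == pytest.approx(7.0)
        assert n.activity_type == "IC50"

    def test_censored_bound_flips_on_p_scale(self):
        # "IC50 > 1 uM" means weaker than pIC50 6, so pchembl < 6
        n = admit_activity_type(
            make_measurement(relation=">", value=1.0, unit="µM")
        )
        assert n.censored and n.relation == "<"
        assert n.pchembl == pytest.approx(6.0)

    def test_percent_inhibition_inadmissible(self):
        n = admit_activity_type(
            make_measurement(activity_type="percent inhibition", value=45.0, unit="%")
        )
        assert not n.admissible and "not admitted" in n.reason

    @pytest.mark.parametrize("log_type", ["pKi", "pIC50", "pEC50", "pKD"])
    def test_log_types_taken_verbatim_and_flagged(self, log_type):
        n = admit_activity_type(
            make_measurement(activity_type=log_type, value=7.5, unit="log units")
        )
        assert n.admissible and n.pchembl == 7.5
        assert "assumed_p_scale" in n.flags

    def test_log_type_relation_not_flipped(self):
        # a bound already on the p-scale keeps its orientation
        n = admit_activity_type(
            make_measurement(activity_type="pIC50", relation=">", value=6.0, unit="-")
        )
        assert n.relation == ">" and n.censored

    def test_binary_record_admitted_without_pchembl(self):
        n = admit_activity_type(
            make_measurement(
                value=None, unit=None, is_binary=True, active_label=True
            )
        )
        assert n.admissible and n.pchembl is None and n.is_binary

    def test_non_molar_unit_on_admitted_type_inadmissible(self):
        n = admit_activity_type(make_measurement(value=50.0, unit="%"))
        assert not n.admissible and "non-molar" in n.reason

    @given(
        pchembl=st.floats(2.0, 12.0),
        relation=st.sampled_from(["<", ">", "<=", ">="]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_p_scale_interval_is_the_transformed_original(self, pchembl, relation):
        """The censored interval on the p-scale contains exactly the image
        of the concentration interval: conc < c maps to pchembl > -log10(c)."""
        conc_nm = 10 ** (9 - pchembl)
        n = admit_activity_type(
            make_measurement(relation=relation, value=conc_nm, unit="nM")
        )
        flipped = {"<": ">", ">": "<", "<=": ">=", ">=": "<="}[relation]
        assert n.relation == flipped
        assert n.pchembl == pytest.approx(pchembl, abs=1e-9)
        # pick a concentration strictly inside the original interval and
        # check its image lies inside the transformed interval
        inside = conc_nm * (0.5 if "<" in relation else 2.0)
        image = -math.log10(inside * 1e-9)
        if "<" in flipped:
            assert image < n.pchembl
        else:
            assert image > n.pchembl
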