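"""Assay-concordance filter: median rule, assay scoring, subset building."""

import pytest

from bioforge import (
    PlusFilterConfig,
    annotate_all,
    build_concordant_set,
    concordance_filter,
    normalise_all,
    score_assays,
    simulate,
)
from bioforge.simulate import SimConfig

from conftest import make_measurement


def _values(pairs):
    return [(assay, v) for assay, v in pairs]


class TestConcordanceFilter:
    def test_outlier_beyond_half_log_removed(self):
        kept, removed = concordance_filter(
            _values([("A", 7.0), ("B", 7.2), ("C", 9.0)])
        )
        assert kept == [0, 1] and removed == [2]

    def test_identical_values_all_kept(self):
        kept, removed = concordance_filter(_values([("A", 7.0), ("B", 7.0)]))
        assert kept == [0, 1] and not removed

    def test_exactly_half_log_from_median_is_kept(self):
        # [6, 7]: median 6.5, both at distance exactly 0.5 -> strict rule keeps
        kept, removed = concordance_filter(_values([("A", 6.0), ("B", 7.0)]))
        assert kept == [0, 1] and not removed

    def test_singleton_is_an_error(self):
        with pytest.raises(ValueError):
            concordance_filter(_values([("A", 7.0)]))

    def test_kept_plus_removed_partition_input(self):
        vals = _values([("A", 5.0), ("B", 6.0), ("C", 6.1), ("D", 9.9)])
        kept, removed = concordance_filter(vals)
        assert sorted(kept + removed) == list(range(len(vals)))


class TestScoreAssays:
    def test_fully_concordant_assay_reproducible(self):
        pairs = {
            i: _values([("X", 7.0), ("Y", 7.1)]) for i in range(5)
        }
        scores = score_assays(pairs)
        assert scores["X"].concordance == 1.0 and scores["X"].reproducible

    def test_three_of_four_meets_inclusive_threshold(self):
        pairs = {
            0: _values([("X", 7.0), ("Y", 7.0)]),
            1: _values([("X", 7.0), ("Y", 7.0)]),
            2: _values([("X", 7.0), ("Y", 7.0)]),
            3: _values([("X", 9.0), ("Y", 7.0), ("Z", 7.0)]),
        }
        scores = score_assays(pairs)
        assert scores["X"].n_comparisons == 4
        assert scores["X"].n_concordant == 3
        assert scores["X"].concordance == pytest.approx(0.75)
        assert scores["X"].reproducible  # >= 0.75, inclusive

    def test_unscored_assay_absent(self):
        scores = score_assays({0: _values([("X", 7.0), ("Y", 7.0)])})
        assert "Z" not in scores


def _ic50(value_p, assay, mol="CCO", acc="P00001", source="S1"):
    return make_measurement(
        source_id=source,
        molecule_ref=mol,
        target_accession=acc,
        assay_id=assay,
        value=10 ** (9 - value_p),
        unit="nM",
    )


def _ki(value_p, assay, mol="CCO", acc="P00001"):
    m = _ic50(value_p, assay, mol=mol, acc=acc)
    return make_measurement(
        source_id=m.source_id,
        molecule_ref=m.molecule_ref,
        target_accession=m.target_accession,
        assay_id=m.assay_id,
        activity_type="Ki",
        value=m.value,
        unit=m.unit,
    )


def _annotated(ms):
    return annotate_all(normalise_all(ms))


class TestBuildConcordantSet:
    def test_ki_far_from_pair_median_is_exempt(self):
        records = _annotated(
            [_ki(9.0, "A1"), _ki(7.0, "A2"), _ki(7.0, "A3")]
        )
        result = build_concordant_set(records)
        assert len(result.kept) == 3 and not result.removed

    def test_singleton_kept_only_in_reproducible_assay(self):
        # assay GOOD is concordant on 4/5 shared pairs (0.8); assay BAD on
        # 0 of its 2; each then has one singleton pair
        records = []
        for i in range(5):
            off = 3.0 if i == 4 else 0.0
            records.append(_ic50(7.0 + off, "GOOD", mol=f"{'C' * (i + 2)}O"))
            records.append(_ic50(7.0, "REF1", mol=f"{'C' * (i + 2)}O"))
            records.append(_ic50(7.0, "REF2", mol=f"{'C' * (i + 2)}O"))
        for i in range(2):
            records.append(_ic50(9.0, "BAD", mol=f"{'C' * (i + 2)}N"))
            records.append(_ic50(7.0, "REF1", mol=f"{'C' * (i + 2)}N"))
            records.append(_ic50(7.0, "REF2", mol=f"{'C' * (i + 2)}N"))
        records.append(_ic50(7.0, "GOOD", mol="CCCCCCCCO"))  # singleton
        records.append(_ic50(7.0, "BAD", mol="CCCCCCCCN"))  # singleton
        result = build_concordant_set(_annotated(records))
        scores = result.assay_scores["IC50"]
        assert scores["GOOD"].reproducible and not scores["BAD"].reproducible
        kept_singletons = {
            r.measurement.molecule_ref
            for r in result.kept
            if r.measurement.molecule_ref in ("CCCCCCCCO", "CCCCCCCCN")
        }
        assert kept_singletons == {"CCCCCCCCO"}

    def test_singleton_of_uncompared_assay_excluded(self):
        records = _annotated([_ic50(7.0, "LONE", mol="CCO")])
        result = build_concordant_set(records)
        assert not result.kept and len(result.removed) == 1

    def test_output_is_subset_and_conserves_measurements(self):
        cfg = SimConfig(
            activity_types=("IC50", "Ki"),
            censored_fraction=0.0,
            binary_fraction=0.0,
            variant_fraction=0.0,
            source_overlap=0.0,
            seed=21,
        )
        data = simulate(cfg)
        records = _annotated([m for s in data.sources.values() for m in s])
        result = build_concordant_set(records)
        assert len(result.kept) + len(result.removed) == len(records)
        ids = {id(r) for r in records}
        assert all(id(r) in ids for r in result.kept)
        ki = [r for r in records if r.normalised.activity_type == "Ki"]
        kept_ki = [r for r in result.kept if r.normalised.activity_type == "Ki"]
        assert len(kept_ki) == len(ki)

    def test_idempotent_on_simulated_fixture(self):
        cfg = SimConfig(
            activity_types=("IC50",),
            censored_fraction=0.0,
            binary_fraction=0.0,
            variant_fraction=0.0,
            source_overlap=0.0,
            planted_biases={"A001": 1.0},
            seed=13,
        )
        data = simulate(cfg)
        records = _annotated([m for s in data.sources.values() for m in s])
        once = build_concordant_set(records)
        twice = build_concordant_set(once.kept)
        assert {id(r) for r in twice.kept} == {id(r) for r in once.kept}

    def test_planted_bias_recovered(self):
        """An assay with a +1.0 log bias over shared pairs at sigma=0.1 is
        flagged non-reproducible; unbiased assays are not."""
        cfg = SimConfig(
            n_molecules=10,
            n_targets=6,
            n_assays=6,
            pair_fraction=1.0,
            measurements_per_pair=3,
            noise_sd=0.1,
            assay_bias_sd=0.0,
            planted_biases={"A001": 1.0},
            censored_fraction=0.0,
            binary_fraction=0.0,
            variant_fraction=0.0,
            homolog_fraction=0.0,
            source_overlap=0.0,
            activity_types=("IC50",),
            seed=99,
        )
        data = simulate(cfg)
        records = _annotated([m for s in data.sources.values() for m in s])
        scores = build_concordant_set(records).assay_scores["IC50"]
        assert not scores["A001"].reproducible
        for assay, score in scores.items():
            if assay != "A001":
                assert score.reproducible


class TestPlusFilterConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlusFilterConfig(max_median_distance=0.0)
        with pytest.raises(ValueError):
            PlusFilterConfig(min_assay_concordance=1.5)
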