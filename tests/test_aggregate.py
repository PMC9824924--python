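"""Deduplication lineage rules and per-pair pooling statistics."""

import random

import numpy as np
import pytest

from bioforge import (
    aggregate_pair,
    annotate_all,
    deduplicate_sources,
    normalise_all,
)

from conftest import make_measurement


def _annotated(measurements):
    return annotate_all(normalise_all(measurements))


def _exact(values, **kw):
    """Annotated exact IC50 records with the given pChEMBL values (in nM)."""
    ms = [
        make_measurement(value=10 ** (9 - v), unit="nM", assay_id=f"A{i}", **kw)
        for i, v in enumerate(values)
    ]
    return _annotated(ms)


class TestDeduplicateSources:
    def _pair_in(self, source, value=100.0, assay="A1", ref="CCO"):
        return make_measurement(
            source_id=source, molecule_ref=ref, value=value, assay_id=assay
        )

    def test_repackaged_copy_dropped_upstream_kept(self):
        records = _annotated([self._pair_in("A"), self._pair_in("B")])
        kept, dropped = deduplicate_sources(records, {"B": ["A"]})
        assert len(kept) == 1 and len(dropped) == 1
        assert kept[0].measurement.source_id == "A"
        assert dropped[0].measurement.source_id == "B"

    def test_identical_duplicate_within_one_source_collapses(self):
        records = _annotated([self._pair_in("A"), self._pair_in("A")])
        kept, dropped = deduplicate_sources(records, {})
        assert len(kept) == 1 and len(dropped) == 1

    def test_independent_equal_values_both_kept(self):
        records = _annotated([self._pair_in("A"), self._pair_in("B")])
        kept, dropped = deduplicate_sources(records, {})  # no lineage
        assert len(kept) == 2 and not dropped

    def test_lineage_is_transitive(self):
        records = _annotated(
            [self._pair_in("A"), self._pair_in("C")]
        )
        kept, dropped = deduplicate_sources(records, {"B": ["A"], "C": ["B"]})
        assert [r.measurement.source_id for r in kept] == ["A"]

    def test_circular_lineage_is_an_error(self):
        with pytest.raises(ValueError, match="circular"):
            deduplicate_sources([], {"A": ["B"], "B": ["A"]})

    def test_derived_scores_pass_through_flagged(self):
        records = _annotated(
            [
                make_measurement(activity_type="Ki", source_id="B"),
                self._pair_in("A"),
            ]
        )
        kept, dropped = deduplicate_sources(
            records, {"B": ["A"]}, derived_types=frozenset({"Ki"})
        )
        assert len(kept) == 2 and not dropped
        derived = [r for r in kept if r.measurement.source_id == "B"]
        assert "derived" in derived[0].normalised.flags

    def test_lineage_graph_oracle_on_random_fixture(self):
        """Against a brute-force oracle over a random lineage DAG."""
        rng = random.Random(5)
        sources = ["S1", "S2", "S3", "S4"]
        lineage = {"S3": ["S1"], "S4": ["S2", "S3"]}
        ancestors = {"S1": set(), "S2": set(), "S3": {"S1"}, "S4": {"S2", "S3", "S1"}}
        ms = [
            make_measurement(
                source_id=rng.choice(sources),
                molecule_ref=rng.choice(["CCO", "CCN"]),
                value=rng.choice([10.0, 100.0]),
                assay_id=rng.choice(["A1", "A2"]),
            )
            for _ in range(40)
        ]
        records = _annotated(ms)
        kept, dropped = deduplicate_sources(records, lineage)

        def content(r):
            m = r.measurement
            return (m.molecule_ref, m.target_accession, m.assay_id, m.value)

        expected_dropped = 0
        groups = {}
        for r in records:
            groups.setdefault(content(r), []).append(r)
        for group in groups.values():
            present = {r.measurement.source_id for r in group}
            seen = set()
            for r in group:
                src = r.measurement.source_id
                if ancestors[src] & present or src in seen:
                    expected_dropped += 1
                else:
                    seen.add(src)
        assert len(dropped) == expected_dropped
        assert len(kept) + len(dropped) == len(records)


class TestAggregatePair:
    def test_two_exact_values(self):
        agg = aggregate_pair(_exact([7.0, 8.0]))
        assert agg.pchembl_mean == pytest.approx(7.5)
        assert agg.pchembl_median == pytest.approx(7.5)
        assert agg.n_exact == 2 and agg.n_censored == 0

    def test_single_value_has_zero_std(self):
        agg = aggregate_pair(_exact([6.0]))
        assert agg.pchembl_mean == pytest.approx(6.0)
        assert agg.pchembl_std == 0.0 and agg.n_exact == 1

    def test_censored_bound_counted_but_excluded_from_statistics(self):
        records = _exact([7.0]) + _annotated(
            [
                make_measurement(
                    relation=">", value=5.0, unit="µM", assay_id="A9"
                )
            ]
        )
        agg = aggregate_pair(records)
        assert agg.pchembl_mean == pytest.approx(7.0)
        assert agg.n_exact == 1 and agg.n_censored == 1

    def test_sample_std_uses_ddof_1(self):
        agg = aggregate_pair(_exact([6.0, 7.0, 8.0]))
        assert agg.pchembl_std == pytest.approx(np.std([6, 7, 8], ddof=1))

    def test_even_sized_median_is_midpoint(self):
        agg = aggregate_pair(_exact([5.0, 6.0, 8.0, 9.0]))
        assert agg.pchembl_median == pytest.approx(7.0)

    def test_quality_is_worst_of_evidence(self):
        good = _annotated([make_measurement(target_mapping="single")])
        shaky = _annotated(
            [make_measurement(target_mapping="single_homolog", assay_id="A2")]
        )
        agg = aggregate_pair(good + shaky)
        assert agg.quality == "medium"

    def test_years_span_and_provenance(self):
        ms = [
            make_measurement(year=2011, source_id="S1", assay_id="A1"),
            make_measurement(year=2007, source_id="S2", assay_id="A2", value=50.0),
        ]
        agg = aggregate_pair(_annotated(ms))
        assert (agg.year_first, agg.year_last) == (2007, 2011)
        assert agg.sources == ("S1", "S2") and agg.assays == ("A1", "A2")

    def test_permutation_invariant(self):
        records = _exact([5.5, 6.5, 7.0, 9.0])
        shuffled = records[::-1]
        a, b = aggregate_pair(records), aggregate_pair(shuffled)
        assert (a.pchembl_mean, a.pchembl_std, a.pchembl_median) == (
            b.pchembl_mean,
            b.pchembl_std,
            b.pchembl_median,
        )

    def test_median_between_min_and_max(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(4, 10, size=rng.integers(1, 8)).tolist()
            agg = aggregate_pair(_exact(vals))
            assert min(vals) - 1e-9 <= agg.pchembl_median <= max(vals) + 1e-9

    def test_pooling_disjoint_sets_equals_pooling_union(self):
        left, right = _exact([5.0, 6.0]), _exact([7.0, 8.0], source_id="S2")
        union = aggregate_pair(left + right)
        assert union.pchembl_mean == pytest.approx(6.5)
        assert union.n_exact == 4
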