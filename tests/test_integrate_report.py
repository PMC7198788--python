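import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maglink.integrate_report import (
    crosstab,
    fpkm,
    merge_signals,
    overlap_sets,
    relative_abundance,
    retained,
)
from maglink.io_core import SourceClass
from maglink.nt_signals import Method, PredictionSignal


def sig(v, h, m=Method.CRISPR, score=0.0):
    return PredictionSignal(v, h, m, score)


class TestMergeSignals:
    def test_grouping(self):
        signals = [
            sig("v1", "h1"),
            sig("v1", "h2", Method.BLASTN),
            sig("v2", "h1", Method.TRNA),
            sig("v2", "h1", Method.TRNA),
            sig("v3", "h3", Method.ONF),
        ]
        reports = merge_signals(signals)
        assert len(reports) == 3
        r1 = reports[0]
        assert r1.viral_id == "v1"
        assert r1.methods == {"crispr", "blastn"} and r1.host_ids == {"h1", "h2"}

    def test_exclusion_arithmetic(self):
        signals = [sig(f"v{i:02d}", "h") for i in range(35)]
        reports = merge_signals(signals, [("v03", "known SAR11 virus"), ("v07", "archaeal virus")])
        assert len(reports) == 35
        assert len(retained(reports)) == 33
        excluded = [r for r in reports if r.excluded]
        assert {r.viral_id for r in excluded} == {"v03", "v07"}
        assert excluded[0].reason

    def test_empty(self):
        assert merge_signals([]) == []

    def test_idempotent(self):
        signals = [sig("v1", "h1"), sig("v1", "h2", Method.ONF), sig("v2", "h1")]
        once = merge_signals(signals)
        again = merge_signals(
            [
                sig(r.viral_id, h, Method(m))
                for r in once
                for m in r.methods
                for h in r.host_ids
            ]
        )
        assert {(r.viral_id, r.methods, r.host_ids) for r in again} >= {
            (r.viral_id, r.methods, r.host_ids) for r in once
        }


class TestCrosstab:
    def test_per_class_totals(self):
        source_of = {"rs": SourceClass.HOST_REFSEQ, "mag": SourceClass.HOST_MAG}
        signals = (
            [sig(f"a{i}", "rs", Method.CRISPR) for i in range(3)]
            + [sig(f"b{i}", "rs", Method.BLASTN) for i in range(16)]
            + [sig(f"c{i}", "mag", Method.CRISPR) for i in range(1)]
            + [sig(f"d{i}", "mag", Method.TRNA) for i in range(14)]
            + [sig(f"e{i}", "mag", Method.BLASTN) for i in range(18)]
            + [sig(f"f{i}", "mag", Method.ONF) for i in range(5)]
        )
        t = crosstab(signals, source_of)
        assert t.loc["host_refseq", "total"] == 19
        assert t.loc["host_mag", "total"] == 38
        assert t.loc["total", "total"] == 57

    def test_empty(self):
        t = crosstab([], {})
        assert t.loc["total", "total"] == 0

    def test_unknown_host_rejected(self):
        with pytest.raises(KeyError):
            crosstab([sig("v", "mystery")], {})

    def test_totals_are_cell_sums_randomized(self):
        rng = np.random.default_rng(0)
        source_of = {"h1": SourceClass.HOST_REFSEQ, "h2": SourceClass.HOST_MAG}
        methods = list(Method)
        for _ in range(20):
            signals = [
                sig(f"v{i}", ["h1", "h2"][int(rng.integers(2))], methods[int(rng.integers(len(methods)))])
                for i in range(int(rng.integers(1, 40)))
            ]
            t = crosstab(signals, source_of)
            body = t.drop(index="total", columns="total")
            assert t.loc["total", "total"] == body.values.sum() == len(signals)
            assert (t.loc["total"].drop("total") == body.sum(axis=0)).all()
            assert (t["total"].drop("total") == body.sum(axis=1)).all()


class TestOverlap:
    def test_worked_example(self):
        r = overlap_sets({"1", "2", "3"}, {"3", "4"})
        assert r.counts == {"only_a": 2, "only_b": 1, "both": 1, "union": 4}

    def test_equal_sets(self):
        r = overlap_sets({"x"}, {"x"})
        assert r.counts["only_a"] == r.counts["only_b"] == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.sets(st.text(max_size=3)), st.sets(st.text(max_size=3)))
    def test_partition_identity(self, a, b):
        r = overlap_sets(a, b)
        assert len(r.union) == len(r.only_a) + len(r.only_b) + len(r.both)
        assert r.only_a | r.only_b | r.both == r.union


class TestFpkm:
    def test_worked_example(self):
        t = fpkm({("s1", "g1"): 100}, {"g1": 10_000}, {"s1": 1_000_000})
        assert t.loc["g1", "s1"] == pytest.approx(10.0)

    def test_depth_invariance(self):
        t1 = fpkm({("s1", "g1"): 100}, {"g1": 5000}, {"s1": 2_000_000})
        t2 = fpkm({("s1", "g1"): 200}, {"g1": 5000}, {"s1": 4_000_000})
        assert t1.loc["g1", "s1"] == pytest.approx(t2.loc["g1", "s1"])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm({("s1", "g1"): 1}, {"g1": 0}, {"s1": 100})
        with pytest.raises(ValueError):
            fpkm({("s1", "g1"): 1}, {"g1": 100}, {"s1": 0})

    def test_relative_abundance_full_set_is_one(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [5, 0, 15]}, index=["g1", "g2", "g3"]
        )
        t = fpkm(counts, {"g1": 1000, "g2": 2000, "g3": 500}, {"s1": 1e6, "s2": 2e6})
        ra = relative_abundance(t, ["g1", "g2", "g3"])
        assert ra.tolist() == pytest.approx([1.0, 1.0])

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(1)
        genomes = [f"g{i}" for i in range(6)]
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(6, 3)), index=genomes, columns=["s1", "s2", "s3"]
        )
        t = fpkm(counts, {g: int(rng.integers(500, 5000)) for g in genomes}, {s: 1e6 for s in ["s1", "s2", "s3"]})
        total = sum(
            relative_abundance(t, part)
            for part in (genomes[:2], genomes[2:4], genomes[4:])
        )
        assert total.tolist() == pytest.approx([1.0, 1.0, 1.0])
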