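import warnings

import numpy as np
import pytest

from maglink.homolog_profile import (
    CalibrationWarning,
    HomologProfile,
    Thresholds,
    attribute_provirus_origin,
    build_homolog_profile,
    calibrate_thresholds,
    classify_viral_genome,
    read_profiles,
    read_thresholds,
    write_profiles,
    write_thresholds,
)
from maglink.io_core import (
    DomainClass,
    GeneRecord,
    HomologyHit,
    IntervalAnnotation,
    TaxonAssignment,
    TaxonomyMap,
)

from .oracles import profile_recount_oracle

TARGET = "Bacteroidetes"

TAX = TaxonomyMap(
    [
        TaxonAssignment("tgt1", DomainClass.CELLULAR, TARGET),
        TaxonAssignment("tgt2", DomainClass.CELLULAR, TARGET),
        TaxonAssignment("oth1", DomainClass.CELLULAR, "Proteobacteria"),
        TaxonAssignment("oth2", DomainClass.CELLULAR, "Firmicutes"),
        TaxonAssignment("vir1", DomainClass.VIRAL, "unknown"),
    ]
)


def genes(vid, n):
    return [
        GeneRecord(f"{vid}_g{i}", vid, vid, i * 300 + 1, i * 300 + 200) for i in range(n)
    ]


def hit(q, s, bs=100.0, ident=50.0, ev=1e-20, length=100):
    return HomologyHit(q, s, ident, length, ev, bs)


class TestBuildProfile:
    def test_worked_arithmetic(self):
        """10 genes; 6 cellular best hits of which 3 to the target phylum."""
        g = genes("v", 10)
        hits = []
        for i in range(3):
            hits.append(hit(f"v_g{i}", "tgt1"))
        for i in range(3, 6):
            hits.append(hit(f"v_g{i}", "oth1"))
        p = build_homolog_profile("v", g, hits, TAX, TARGET, "refseq")
        assert (p.n_genes, p.n_cellular, p.n_target) == (10, 6, 3)
        assert p.prop_of_genes == pytest.approx(0.30)
        assert p.prop_of_cellular == pytest.approx(0.50)

    def test_no_hits(self):
        p = build_homolog_profile("v", genes("v", 5), [], TAX, TARGET, "refseq")
        assert (p.n_cellular, p.n_target, p.prop_of_genes, p.prop_of_cellular) == (0, 0, 0, 0)

    def test_viral_subject_does_not_mask_cellular(self):
        g = genes("v", 2)
        hits = [hit("v_g0", "vir1", bs=500), hit("v_g0", "tgt1", bs=100)]
        p = build_homolog_profile("v", g, hits, TAX, TARGET, "refseq")
        assert (p.n_cellular, p.n_target) == (1, 1)
        # overall-best-hit mode: the viral hit masks the cellular one
        p2 = build_homolog_profile("v", g, hits, TAX, TARGET, "refseq", cellular_only=False)
        assert (p2.n_cellular, p2.n_target) == (0, 0)

    def test_subthreshold_hits_ignored(self):
        g = genes("v", 3)
        hits = [
            hit("v_g0", "tgt1", ev=1e-5),
            hit("v_g1", "tgt1", ident=25.0),
            hit("v_g2", "tgt1", bs=45.0),
        ]
        p = build_homolog_profile("v", g, hits, TAX, TARGET, "refseq")
        assert p.n_cellular == 0

    def test_foreign_gene_rejected(self):
        with pytest.raises(ValueError, match="belongs to"):
            build_homolog_profile("v", genes("w", 2), [], TAX, TARGET, "refseq")

    def test_agrees_with_recount_oracle(self):
        tax_dict = {
            "tgt1": ("cellular", TARGET),
            "tgt2": ("cellular", TARGET),
            "oth1": ("cellular", "Proteobacteria"),
            "oth2": ("cellular", "Firmicutes"),
            "vir1": ("viral", "unknown"),
        }
        subjects = list(tax_dict)
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 31))
            g = genes("v", n)
            raw = []
            for _ in range(int(rng.integers(0, 4 * n))):
                raw.append(
                    hit(
                        f"v_g{rng.integers(n)}",
                        subjects[int(rng.integers(len(subjects)))],
                        bs=float(rng.integers(20, 300)),
                        ident=float(rng.integers(10, 100)),
                        ev=float(10.0 ** -rng.integers(0, 60)),
                    )
                )
            p = build_homolog_profile("v", g, raw, TAX, TARGET, "refseq")
            o = profile_recount_oracle(
                [x.gene_id for x in g],
                [(h.query_id, h.subject_id, h.pct_identity, h.evalue, h.bitscore) for h in raw],
                tax_dict,
                TARGET,
            )
            assert (p.n_genes, p.n_cellular, p.n_target) == o


class TestProvirusAttribution:
    SUBJ = {
        "tgt1": GeneRecord("tgt1", "H", "c1", 100, 400),
        "tgt2": GeneRecord("tgt2", "H", "c1", 4900, 5100),
    }
    IV = [IntervalAnnotation("c1", 50, 5000, 5)]

    def _profile(self, subject):
        g = genes("v", 4)
        return build_homolog_profile("v", g, [hit("v_g0", subject)], TAX, TARGET, "refseq")

    def test_contained_subject_counted(self):
        p = attribute_provirus_origin(self._profile("tgt1"), TAX, TARGET, self.IV, self.SUBJ)
        assert p.n_provirus_origin == 1

    def test_straddling_subject_not_contained(self):
        p = attribute_provirus_origin(self._profile("tgt2"), TAX, TARGET, self.IV, self.SUBJ)
        assert p.n_provirus_origin == 0
        p2 = attribute_provirus_origin(
            self._profile("tgt2"), TAX, TARGET, self.IV, self.SUBJ, mode="overlap"
        )
        assert p2.n_provirus_origin == 1

    def test_no_intervals(self):
        p = attribute_provirus_origin(self._profile("tgt1"), TAX, TARGET, [], self.SUBJ)
        assert p.n_provirus_origin == 0

    def test_non_target_homolog_ignored(self):
        p = attribute_provirus_origin(
            self._profile("oth1"), TAX, TARGET, self.IV, self.SUBJ
        )
        assert p.n_provirus_origin == 0


def prof(vid, pg, pc, nt, db="refseq", n_genes=100):
    # construct a consistent profile carrying the requested statistics
    n_cell = max(nt, round(nt / pc) if pc else nt)
    return HomologProfile(
        viral_id=vid,
        database_label=db,
        n_genes=max(n_genes, n_cell),
        n_cellular=n_cell,
        n_target=nt,
        prop_of_genes=pg,
        prop_of_cellular=pc,
    )


class TestCalibration:
    def test_max_of_list(self):
        t = calibrate_thresholds(
            [prof("n1", 0.03, 0.1, 2), prof("n2", 0.079, 0.05, 1)]
        )
        assert t.min_prop_of_genes == pytest.approx(0.079)
        assert t.min_prop_of_cellular == pytest.approx(0.1)
        assert t.min_count == 2

    def test_single_negative_warns_and_equals_stats(self):
        with pytest.warns(CalibrationWarning):
            t = calibrate_thresholds([prof("n1", 0.05, 0.2, 3)])
        assert (t.min_prop_of_genes, t.min_prop_of_cellular, t.min_count) == (0.05, 0.2, 3)

    def test_all_zero_negatives_floor(self):
        # the count floor of 1 keeps all-zero negatives from self-classifying
        t = calibrate_thresholds([prof("n1", 0.0, 0.0, 0), prof("n2", 0.0, 0.0, 0)])
        assert (t.min_prop_of_genes, t.min_prop_of_cellular, t.min_count) == (0.0, 0.0, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([])

    def test_mixed_databases_rejected(self):
        with pytest.raises(ValueError, match="databases"):
            calibrate_thresholds([prof("a", 0.1, 0.1, 1), prof("b", 0.1, 0.1, 1, db="mag")])

    def test_separation_property(self):
        """Distinct per-criterion maxima imply zero self-positive negatives."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(200):
            negs = [
                prof(
                    f"n{i}",
                    float(rng.uniform(0, 0.2)),
                    float(rng.uniform(0, 0.5)),
                    int(rng.integers(0, 8)),
                )
                for i in range(int(rng.integers(2, 10)))
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("error", CalibrationWarning)
                try:
                    t = calibrate_thresholds(negs)
                except CalibrationWarning:
                    continue  # a negative attains all maxima: documented edge case
            checked += 1
            for n in negs:
                assert not classify_viral_genome(
                    {"refseq": n}, {"refseq": t}
                ).verdict
        assert checked > 100


REFSEQ_T = Thresholds("refseq", 0.079, 0.188, 5)
MAG_T = Thresholds("mag", 0.042, 0.389, 3)


class TestClassifier:
    def test_passing_profile(self):
        res = classify_viral_genome({"refseq": prof("v", 0.10, 0.40, 6)}, {"refseq": REFSEQ_T})
        assert res.verdict and res.passing_databases == ("refseq",)

    def test_fails_first_criterion(self):
        res = classify_viral_genome({"refseq": prof("v", 0.078, 0.40, 6)}, {"refseq": REFSEQ_T})
        assert not res.verdict

    def test_inclusive_at_exact_thresholds(self):
        res = classify_viral_genome({"refseq": prof("v", 0.079, 0.188, 5)}, {"refseq": REFSEQ_T})
        assert res.verdict  # "at least" comparisons are inclusive

    def test_union_across_databases(self):
        res = classify_viral_genome(
            {"refseq": prof("v", 0.01, 0.0, 0), "mag": prof("v", 0.042, 0.389, 3, db="mag")},
            {"refseq": REFSEQ_T, "mag": MAG_T},
        )
        assert res.verdict and res.passing_databases == ("mag",)

    def test_missing_thresholds_rejected(self):
        with pytest.raises(KeyError):
            classify_viral_genome({"refseq": prof("v", 0.1, 0.4, 6)}, {})

    def test_monotonicity(self):
        """Raising any statistic never flips a positive verdict to negative."""
        base = prof("v", 0.10, 0.40, 6)
        assert classify_viral_genome({"refseq": base}, {"refseq": REFSEQ_T}).verdict
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = prof(
                "v",
                min(1.0, 0.10 + float(rng.uniform(0, 0.5))),
                min(1.0, 0.40 + float(rng.uniform(0, 0.5))),
                6 + int(rng.integers(0, 20)),
            )
            assert classify_viral_genome({"refseq": p}, {"refseq": REFSEQ_T}).verdict


def test_profile_and_threshold_tsv_round_trip(tmp_path):
    ps = [prof("v1", 0.1, 0.25, 4), prof("v2", 0.0, 0.0, 0, db="mag")]
    write_profiles(tmp_path / "p.tsv", ps)
    assert read_profiles(tmp_path / "p.tsv") == ps
    ts = [REFSEQ_T, MAG_T]
    write_thresholds(tmp_path / "t.tsv", ts)
    assert read_thresholds(tmp_path / "t.tsv") == {"refseq": REFSEQ_T, "mag": MAG_T}
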