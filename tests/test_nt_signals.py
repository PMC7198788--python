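import numpy as np
import pytest

from maglink.io_core import GenomeRecord, HomologyHit
from maglink.nt_signals import (
    Method,
    SpacerRecord,
    TRNARecord,
    filter_blastn_signals,
    match_spacers,
    match_trnas,
    read_signals,
    revcomp,
    write_signals,
)

from .oracles import spacer_scan_oracle

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(seq, pos, rng):
    new = BASES[(BASES.index(seq[pos]) + 1 + int(rng.integers(3))) % 4]
    return seq[:pos] + new + seq[pos + 1 :]


def _genome(seq, circular=False):
    return GenomeRecord.single("V", seq, circular=circular)


def _signal_positions(signals):
    out = set()
    for s in signals:
        d = dict(kv.split("=") for kv in s.detail.split(";"))
        out.add((int(d["start"]), d["strand"], int(s.score)))
    return out


class TestMatchSpacers:
    def test_exact_substring_detected(self):
        rng = np.random.default_rng(0)
        g = _random_seq(rng, 2000)
        spacer = SpacerRecord("sp", "H", g[700:732])
        sig = match_spacers([spacer], [_genome(g)])
        assert (701, "+", 0) in _signal_positions(sig)
        assert all(s.method is Method.CRISPR and s.host_id == "H" for s in sig)

    def test_single_5prime_mismatch_allowed(self):
        rng = np.random.default_rng(1)
        g = _random_seq(rng, 2000)
        proto = g[500:532]
        spacer = SpacerRecord("sp", "H", _mutate(proto, 0, rng))
        sig = match_spacers([spacer], [_genome(g)])
        assert (501, "+", 1) in _signal_positions(sig)

    def test_internal_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        g = _random_seq(rng, 2000)
        proto = g[500:532]
        spacer = SpacerRecord("sp", "H", _mutate(proto, 15, rng))
        assert match_spacers([spacer], [_genome(g)]) == []

    def test_two_5prime_snps_need_length_40(self):
        # 2 mismatches fail 95% identity at L=32 (30/32) but pass at L=40
        rng = np.random.default_rng(3)
        g = _random_seq(rng, 2000)
        for L, expect in ((32, 0), (40, 1)):
            proto = g[500 : 500 + L]
            sp = _mutate(_mutate(proto, 0, rng), 1, rng)
            sig = match_spacers([SpacerRecord("sp", "H", sp)], [_genome(g)])
            assert len([s for s in sig if s.score == 2]) == expect

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        g = _random_seq(rng, 1500)
        spacer = SpacerRecord("sp", "H", g[300:332])
        plus = _signal_positions(match_spacers([spacer], [_genome(g)]))
        minus = _signal_positions(
            match_spacers([SpacerRecord("sp", "H", revcomp(spacer.sequence))], [_genome(g)])
        )
        assert {(p, "-" if st == "+" else "+", m) for p, st, m in plus} == minus

    def test_circular_junction_protospacer(self):
        rng = np.random.default_rng(5)
        g = _random_seq(rng, 800)
        junction = g[-16:] + g[:16]
        sig = match_spacers([SpacerRecord("sp", "H", junction)], [_genome(g, circular=True)])
        assert (len(g) - 15, "+", 0) in _signal_positions(sig)
        # linear scan misses it
        assert match_spacers([SpacerRecord("sp", "H", junction)], [_genome(g)]) == []

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            match_spacers([SpacerRecord("sp", "H", "ACGTACGTACGT")], [])

    @pytest.mark.parametrize("seed", range(30))
    def test_equivalent_to_sliding_window_oracle(self, seed):
        """Planted + random instances agree with the exhaustive scan."""
        rng = np.random.default_rng(seed)
        glen = int(rng.integers(200, 4000))
        g = _random_seq(rng, glen)
        circular = bool(rng.integers(2))
        L = int(rng.integers(20, 41))
        if rng.random() < 0.8:  # plant a (possibly mutated) protospacer
            pos = int(rng.integers(0, glen - L))
            proto = g[pos : pos + L]
            for _ in range(int(rng.integers(0, 3))):
                proto = _mutate(proto, int(rng.integers(0, min(4, L))), rng)
            spacer = proto if rng.random() < 0.5 else revcomp(proto)
        else:
            spacer = _random_seq(rng, L)
        got = _signal_positions(
            match_spacers([SpacerRecord("sp", "H", spacer)], [_genome(g, circular)])
        )
        assert got == spacer_scan_oracle(spacer, g, circular)


class TestMatchTrnas:
    T = "ACGT" * 18 + "ACG"  # 75 nt

    def test_identical_pair_detected(self):
        h = TRNARecord("h1", "HOST", self.T)
        v = TRNARecord("v1", "VIR", self.T)
        (s,) = match_trnas([h], [v])
        assert (s.viral_id, s.host_id, s.method) == ("VIR", "HOST", Method.TRNA)

    def test_one_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        h = TRNARecord("h1", "HOST", self.T)
        v = TRNARecord("v1", "VIR", _mutate(self.T, 10, rng))
        assert match_trnas([h], [v]) == []

    def test_empty_host_list(self):
        assert match_trnas([], [TRNARecord("v1", "VIR", self.T)]) == []

    def test_symmetry_up_to_orientation(self):
        h = TRNARecord("h1", "A", self.T)
        v = TRNARecord("v1", "B", self.T)
        fwd = match_trnas([h], [v])
        rev = match_trnas([v], [h])
        assert [(s.viral_id, s.host_id) for s in fwd] == [("B", "A")]
        assert [(s.viral_id, s.host_id) for s in rev] == [("A", "B")]


def _nt_hit(q="v1", s="h1", ident=85.0, length=1500, bs=300.0, ev=1e-50):
    return HomologyHit(q, s, ident, length, ev, bs)


class TestFilterBlastn:
    def test_qualifying_best_hit(self):
        (s,) = filter_blastn_signals([_nt_hit()])
        assert (s.viral_id, s.host_id, s.score) == ("v1", "h1", 85.0)
        assert s.method is Method.BLASTN

    def test_length_999_rejected(self):
        assert filter_blastn_signals([_nt_hit(length=999)]) == []

    def test_identity_exactly_70_rejected(self):
        assert filter_blastn_signals([_nt_hit(ident=70.0)]) == []

    def test_best_hit_first_semantics(self):
        # top-bitscore hit fails identity: no signal even though a weaker hit passes
        hits = [_nt_hit(ident=65.0, bs=300), _nt_hit(ident=90.0, bs=200)]
        assert filter_blastn_signals(hits) == []

    def test_per_pair_best_hits(self):
        hits = [_nt_hit(s="h1"), _nt_hit(s="h2", ident=75.0)]
        sig = filter_blastn_signals(hits)
        assert {(s.viral_id, s.host_id) for s in sig} == {("v1", "h1"), ("v1", "h2")}

    def test_id_mapping(self):
        sig = filter_blastn_signals(
            [_nt_hit(q="contig_9", s="ctg_3")],
            query_genome={"contig_9": "VIR"},
            subject_genome={"ctg_3": "MAG"},
        )
        assert [(s.viral_id, s.host_id) for s in sig] == [("VIR", "MAG")]


def test_signal_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    g = _random_seq(rng, 1000)
    sig = match_spacers([SpacerRecord("sp", "H", g[100:132])], [_genome(g)])
    sig += match_trnas(
        [TRNARecord("h", "H", g[:75])], [TRNARecord("v", "V", g[:75])]
    )
    p = tmp_path / "signals.tsv"
    write_signals(p, sig)
    assert read_signals(p) == sig
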