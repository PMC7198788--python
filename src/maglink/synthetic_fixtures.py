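"""Seeded synthetic fixtures with planted ground-truth virus-host links.

Every stage of the toolkit is testable offline against a small generated
dataset: host genomes (each drawn from its own order-4 Markov model, so each
has a distinctive oligonucleotide composition), viral genomes (positives
share their host's composition and carry planted protospacers, tRNAs and
>= 1 kb homologous segments; negatives come from unrelated models), protein
hit tables realising exact per-class homolog counts for the calibrated
classifier (positives above the calibration maxima by a margin, negatives
below), provirus intervals covering a stated fraction of target-homolog
subjects, viral-like contamination on one MAG, and a read-count table.

A single integer seed drives one named pseudo-random stream per file type,
so adding a generator does not perturb existing fixtures, and regeneration
from (seed, params) is byte-identical.  The default fixture is small
(14 genomes, < 100 kb of sequence) so the full suite runs quickly.

The blast-style nucleotide hit table is produced by :func:`naive_hit_search`,
a seed-and-extend exact-segment finder for toy data.  It is a synthetic hit
generator, not an aligner: real analyses consume externally produced
blast-tabular files, and the toolkit itself never runs a search tool.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    DomainClass,
    GeneRecord,
    GenomeRecord,
    HomologyHit,
    IntervalAnnotation,
    SourceClass,
    TaxonAssignment,
    TaxonomyMap,
    write_fasta,
    write_genes,
    write_hits,
    write_intervals,
    write_taxonomy,
)
from .nt_signals import (
    Method,
    SpacerRecord,
    TRNARecord,
    revcomp,
    write_spacers,
    write_trnas,
)

__all__ = [
    "FixtureParams",
    "PlantedLink",
    "FixtureManifest",
    "Fixture",
    "generate_fixture",
    "scramble_control",
    "naive_hit_search",
]

TARGET_PHYLUM = "Bacteroidetes"
_OTHER_PHYLA = ("Proteobacteria", "Firmicutes", "Actinobacteria")

# fixed stream ids per file type; append-only so fixtures stay stable
_STREAMS = {
    "hosts": 1,
    "viruses": 2,
    "spacers": 3,
    "trnas": 4,
    "homology": 5,
    "protein_hits": 6,
    "reads": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class FixtureParams:
    """All generation knobs.  Defaults define the standard test conditions."""

    n_target_hosts: int = 4  # first half refseq isolates, second half MAGs
    n_decoy_hosts: int = 2
    host_length: int = 9000
    n_positive: int = 4
    n_negative: int = 4
    virus_length: int = 5000
    spacer_length: int = 32
    trna_length: int = 75
    homology_segment: int = 1200
    genes_per_virus: int = 20
    gene_length: int = 200
    provirus_fraction: float = 0.5
    n_samples: int = 3
    databases: tuple[str, ...] = ("refseq", "mag")
    # per database: (n_target, n_cellular) best-hit genes for every positive
    pos_design: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"refseq": (8, 14), "mag": (6, 12)}
    )
    # per database: (n_target, n_cellular) per negative, cycled; chosen so
    # the per-criterion maxima fall on distinct negatives and no negative
    # attains all three
    neg_design: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {
            "refseq": ((3, 18), (1, 3), (0, 6), (1, 12)),
            "mag": ((2, 16), (0, 5), (1, 3), (0, 8)),
        }
    )

    def validate(self) -> None:
        if min(self.host_length, self.virus_length) <= 0:
            raise ValueError("genome lengths must be positive")
        if not (0.0 <= self.provirus_fraction <= 1.0):
            raise ValueError("provirus_fraction must be in [0, 1]")
        if self.homology_segment >= self.virus_length:
            raise ValueError("homology segment must fit inside a viral genome")
        if self.spacer_length >= self.virus_length:
            raise ValueError("spacer must fit inside a viral genome")
        for db in self.databases:
            designs = [self.pos_design[db], *self.neg_design[db]]
            for t, c in designs:
                if not (0 <= t <= c):
                    raise ValueError(f"{db}: need 0 <= n_target <= n_cellular")
                if c + 2 > self.genes_per_virus:
                    raise ValueError(
                        f"{db}: design ({t},{c}) needs {c + 2} genes but only "
                        f"{self.genes_per_virus} are generated"
                    )


@dataclass(frozen=True)
class PlantedLink:
    viral_id: str
    host_id: str
    method: Method
    expected_detection: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))


@dataclass(frozen=True)
class FixtureManifest:
    seed: int
    planted_links: tuple[PlantedLink, ...]
    params: FixtureParams

    def links(self, method: Method | str, expected: bool | None = None) -> list[PlantedLink]:
        m = Method(method)
        return [
            l
            for l in self.planted_links
            if l.method is m and (expected is None or l.expected_detection is expected)
        ]


@dataclass
class Fixture:
    """In-memory fixture bundle; :meth:`write` serialises it to plain files."""

    manifest: FixtureManifest
    hosts: list[GenomeRecord]
    viruses: list[GenomeRecord]
    spacers: list[SpacerRecord]
    host_trnas: list[TRNARecord]
    viral_trnas: list[TRNARecord]
    nucleotide_hits: list[HomologyHit]
    protein_hits: dict[str, list[HomologyHit]]
    viral_genes: dict[str, list[GeneRecord]]
    subject_genes: dict[str, dict[str, GeneRecord]]
    taxonomy: TaxonomyMap
    provirus_intervals: list[IntervalAnnotation]
    viral_like_intervals: list[IntervalAnnotation]
    read_counts: pd.DataFrame  # genomes x samples
    library_sizes: dict[str, float]
    target_phylum: str = TARGET_PHYLUM

    @property
    def positive_ids(self) -> list[str]:
        return [v.genome_id for v in self.viruses if v.genome_id.startswith("VPOS")]

    @property
    def negative_ids(self) -> list[str]:
        return [v.genome_id for v in self.viruses if v.genome_id.startswith("VNEG")]

    @property
    def host_source(self) -> dict[str, SourceClass]:
        return {h.genome_id: h.source_class for h in self.hosts}

    def decontaminated_hosts(self) -> list[GenomeRecord]:
        from .taxonomy_validation import drop_viral_like_contigs

        return [drop_viral_like_contigs(h, self.viral_like_intervals) for h in self.hosts]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "viruses.fasta", self.viruses)
        write_fasta(out / "hosts.fasta", self.hosts)
        write_spacers(out / "spacers.fasta", self.spacers)
        write_trnas(out / "host_trnas.fasta", self.host_trnas)
        write_trnas(out / "viral_trnas.fasta", self.viral_trnas)
        write_hits(out / "nucleotide_hits.tsv", self.nucleotide_hits)
        for db, hits in self.protein_hits.items():
            write_hits(out / f"protein_hits_{db}.tsv", hits)
            write_genes(
                out / f"subject_genes_{db}.tsv",
                [self.subject_genes[db][sid] for sid in sorted(self.subject_genes[db])],
            )
        write_genes(
            out / "viral_genes.tsv",
            [g for vid in sorted(self.viral_genes) for g in self.viral_genes[vid]],
        )
        write_taxonomy(out / "taxonomy.tsv", self.taxonomy)
        write_intervals(out / "provirus_intervals.tsv", self.provirus_intervals)
        write_intervals(out / "viral_like_intervals.tsv", self.viral_like_intervals)
        self.read_counts.to_csv(out / "read_counts.tsv", sep="\t")
        pd.Series(self.library_sizes).to_csv(
            out / "library_sizes.tsv", sep="\t", header=["mapped_fragments"]
        )
        with open(out / "manifest.tsv", "w") as fh:
            fh.write("viral_id\thost_id\tmethod\texpected_detection\n")
            for l in self.manifest.planted_links:
                fh.write(
                    f"{l.viral_id}\t{l.host_id}\t{l.method.value}\t"
                    f"{int(l.expected_detection)}\n"
                )
        with open(out / "params.json", "w") as fh:
            d = asdict(self.manifest.params)
            d["seed"] = self.manifest.seed
            json.dump(d, fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequence models
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_MARKOV_ORDER = 4


def _make_model(rng: np.random.Generator, base_weights) -> tuple[np.ndarray, np.ndarray]:
    """An order-4 Markov model: base composition + per-context transitions."""
    base = rng.dirichlet(np.asarray(base_weights, dtype=float) * 10.0)
    base = np.clip(base, 0.02, None)
    base /= base.sum()
    trans = rng.dirichlet(base * 25.0, size=4**_MARKOV_ORDER)
    return base, trans


def _sample_sequence(
    rng: np.random.Generator, length: int, model: tuple[np.ndarray, np.ndarray]
) -> str:
    base, trans = model
    cum = np.cumsum(trans, axis=1)
    codes = list(rng.choice(4, size=_MARKOV_ORDER, p=base))
    ctx = 0
    for c in codes:
        ctx = (ctx * 4 + int(c)) % (4**_MARKOV_ORDER)
    u = rng.random(max(length - _MARKOV_ORDER, 0))
    for i in range(length - _MARKOV_ORDER):
        nxt = int(np.searchsorted(cum[ctx], u[i], side="right"))
        nxt = min(nxt, 3)
        codes.append(nxt)
        ctx = (ctx * 4 + nxt) % (4**_MARKOV_ORDER)
    return "".join(_BASES[c] for c in codes[:length])


def _mutate(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = seq[pos]
    new = _BASES[(_BASES.index(old) + 1 + int(rng.integers(3))) % 4]
    return seq[:pos] + new + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# scramble control
# ---------------------------------------------------------------------------

def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle: exact dinucleotide (hence mononucleotide)
    counts, first and last characters preserved, long-range order destroyed."""
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # pick one "last out-edge" per vertex forming an arborescence into `last`
    while True:
        tree = {}
        for v in vertices:
            if v == last:
                continue
            tree[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in tree:
            seen = set()
            u = v
            while u != last and u not in seen:
                seen.add(u)
                u = tree.get(u, None)
                if u is None:
                    break
            if u != last:
                ok = False
                break
        if ok:
            break
    adj: dict[str, list[str]] = {}
    for v in vertices:
        lst = list(edges[v])
        if v in tree:
            lst.remove(tree[v])
        order = rng.permutation(len(lst))
        shuffled = [lst[i] for i in order]
        if v in tree:
            shuffled.append(tree[v])
        adj[v] = shuffled
    ptr = {v: 0 for v in vertices}
    out = [seq[0]]
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = adj[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def scramble_control(genome: GenomeRecord, seed: int) -> GenomeRecord:
    """Dinucleotide-preserving shuffle of each contig of a genome.

    The scrambled control keeps length and (di)nucleotide composition
    exactly, but destroys long-range homology, protospacers and tRNAs, so
    alignment-based detectors must go silent on it while composition-based
    statistics barely move.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    contigs = {
        cid: _dinucleotide_shuffle(s, rng) for cid, s in genome.contigs.items()
    }
    return GenomeRecord(
        genome_id=f"{genome.genome_id}_scrambled",
        contigs=contigs,
        source_class=genome.source_class,
        circular=genome.circular,
    )


# ---------------------------------------------------------------------------
# synthetic nucleotide hit generation (seed-and-extend, exact segments)
# ---------------------------------------------------------------------------

def naive_hit_search(
    query: GenomeRecord,
    subject: GenomeRecord,
    seed_len: int = 24,
    min_report_length: int = 100,
) -> list[HomologyHit]:
    """Find maximal shared exact forward-strand segments between two genomes.

    A synthetic stand-in for an external nucleotide search on toy data:
    seeds of ``seed_len`` are extended to maximal exact runs and reported as
    100%-identity hits with bitscore 2*length.  Suitable only for fixtures
    whose homology was planted as exact copies.
    """
    hits: list[HomologyHit] = []
    for scid, sseq in subject.contigs.items():
        index: dict[str, list[int]] = {}
        for j in range(len(sseq) - seed_len + 1):
            index.setdefault(sseq[j : j + seed_len], []).append(j)
        for qcid, qseq in query.contigs.items():
            covered: dict[int, int] = {}  # diagonal -> end of reported run
            for i in range(len(qseq) - seed_len + 1):
                for j in index.get(qseq[i : i + seed_len], ()):
                    diag = i - j
                    if covered.get(diag, -1) >= i + seed_len:
                        continue
                    a, b = i, j
                    while a > 0 and b > 0 and qseq[a - 1] == sseq[b - 1]:
                        a -= 1
                        b -= 1
                    e1, e2 = i + seed_len, j + seed_len
                    while e1 < len(qseq) and e2 < len(sseq) and qseq[e1] == sseq[e2]:
                        e1 += 1
                        e2 += 1
                    covered[diag] = e1
                    run = e1 - a
                    if run >= min_report_length:
                        hits.append(
                            HomologyHit(
                                query_id=qcid,
                                subject_id=scid,
                                pct_identity=100.0,
                                aln_length=run,
                                evalue=max(4.0**-run, 1e-180),
                                bitscore=2.0 * run,
                                extras=(
                                    "0",
                                    "0",
                                    str(a + 1),
                                    str(e1),
                                    str(b + 1),
                                    str(e2),
                                ),
                            )
                        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id, h.extras))
    return hits


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_fixture(
    seed: int,
    params: FixtureParams | None = None,
    out_dir: str | Path | None = None,
) -> Fixture:
    """Generate the full fixture for ``(seed, params)``; optionally write it.

    Regeneration with the same arguments is byte-identical.  See the module
    docstring for what is planted; the manifest lists every planted link
    with the method expected to recover it.
    """
    params = params or FixtureParams()
    params.validate()
    links: list[PlantedLink] = []

    # --- hosts -----------------------------------------------------------
    host_rng = _rng(seed, "hosts")
    n_refseq = params.n_target_hosts - params.n_target_hosts // 2
    target_ids = [
        (f"RS_H{i + 1}", SourceClass.HOST_REFSEQ)
        if i < n_refseq
        else (f"MAG_H{i - n_refseq + 1}", SourceClass.HOST_MAG)
        for i in range(params.n_target_hosts)
    ]
    hosts: list[GenomeRecord] = []
    host_models: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gid, src in target_ids:
        model = _make_model(host_rng, [3.0, 2.0, 2.0, 3.0])  # AT-leaning targets
        host_models[gid] = model
        seq = _sample_sequence(host_rng, params.host_length, model)
        if gid == "MAG_H1":
            half = len(seq) // 2
            contigs = {f"{gid}_c1": seq[:half], f"{gid}_c2": seq[half:]}
        else:
            contigs = {gid: seq}
        hosts.append(GenomeRecord(gid, contigs, src))
    decoy_models = {}
    for j in range(params.n_decoy_hosts):
        gid = f"DEC_{j + 1}"
        model = _make_model(host_rng, [1.5, 3.5, 3.5, 1.5])  # GC-leaning decoys
        decoy_models[gid] = model
        seq = _sample_sequence(host_rng, params.host_length, model)
        hosts.append(GenomeRecord(gid, {gid: seq}, SourceClass.HOST_REFSEQ))

    # --- viruses ---------------------------------------------------------
    virus_rng = _rng(seed, "viruses")
    viruses: list[GenomeRecord] = []
    virus_host: dict[str, str] = {}
    for i in range(params.n_positive):
        vid = f"VPOS_{i + 1}"
        hid = target_ids[i % params.n_target_hosts][0]
        virus_host[vid] = hid
        seq = _sample_sequence(virus_rng, params.virus_length, host_models[hid])
        viruses.append(GenomeRecord.single(vid, seq, SourceClass.VIRAL, circular=True))
        links.append(PlantedLink(vid, hid, Method.ONF, True))
    for i in range(params.n_negative):
        vid = f"VNEG_{i + 1}"
        model = _make_model(virus_rng, [2.5, 2.5, 2.5, 2.5])
        seq = _sample_sequence(virus_rng, params.virus_length, model)
        viruses.append(GenomeRecord.single(vid, seq, SourceClass.VIRAL, circular=True))

    # --- planted nucleotide homology (>= 1 kb exact segments) ------------
    hom_rng = _rng(seed, "homology")
    seg = params.homology_segment

    def _paste(target_seq: str, donor_seq: str) -> tuple[str, str]:
        q = int(hom_rng.integers(0, len(donor_seq) - seg + 1))
        p = int(hom_rng.integers(0, len(target_seq) - seg + 1))
        piece = donor_seq[q : q + seg]
        return target_seq[:p] + piece + target_seq[p + seg :], piece

    for i, virus in enumerate(v for v in viruses if v.genome_id.startswith("VPOS")):
        vid = virus.genome_id
        hid = virus_host[vid]
        donor_contig = hosts[[h.genome_id for h in hosts].index(hid)].contig_ids[0]
        donor_seq = hosts[[h.genome_id for h in hosts].index(hid)].contigs[donor_contig]
        new_seq, _ = _paste(virus.sequence, donor_seq)
        viruses[viruses.index(virus)] = GenomeRecord.single(
            vid, new_seq, SourceClass.VIRAL, circular=True
        )
        links.append(PlantedLink(vid, hid, Method.BLASTN, True))

    # a viral-like contaminant contig on MAG_H1 sharing homology with a
    # negative virus; decontamination must silence this link
    vneg1 = next(v for v in viruses if v.genome_id == "VNEG_1")
    mag_h1_idx = next(i for i, h in enumerate(hosts) if h.genome_id == "MAG_H1")
    q = int(hom_rng.integers(0, len(vneg1.sequence) - seg + 1))
    contaminant = _sample_sequence(
        hom_rng, max(seg + 300, 1500), decoy_models["DEC_1"]
    )
    contaminant = contaminant[:150] + vneg1.sequence[q : q + seg] + contaminant[150 + seg :]
    mag_h1 = hosts[mag_h1_idx]
    hosts[mag_h1_idx] = GenomeRecord(
        "MAG_H1",
        {**mag_h1.contigs, "MAG_H1_c3": contaminant},
        SourceClass.HOST_MAG,
    )
    viral_like_intervals = [
        IntervalAnnotation("MAG_H1_c3", 1, len(contaminant), 2)
    ]
    links.append(PlantedLink("VNEG_1", "MAG_H1", Method.BLASTN, False))

    # --- planted CRISPR spacers ------------------------------------------
    spacer_rng = _rng(seed, "spacers")
    spacers: list[SpacerRecord] = []
    sl = params.spacer_length
    for i, vid in enumerate(sorted(virus_host)):
        hid = virus_host[vid]
        vseq = next(v for v in viruses if v.genome_id == vid).sequence
        pos = int(spacer_rng.integers(0, len(vseq) - sl))
        proto = vseq[pos : pos + sl]
        exact = proto if i % 2 == 0 else revcomp(proto)
        spacers.append(SpacerRecord(f"SP_{vid}_exact", hid, exact))
        pos2 = int(spacer_rng.integers(0, len(vseq) - sl))
        mutated = _mutate(vseq[pos2 : pos2 + sl], 0, spacer_rng)
        spacers.append(SpacerRecord(f"SP_{vid}_5prime_snp", hid, mutated))
        links.append(PlantedLink(vid, hid, Method.CRISPR, True))
    # junction-spanning protospacer on the first (circular) positive virus
    v1 = next(v for v in viruses if v.genome_id == "VPOS_1")
    junction = v1.sequence[-(sl // 2) :] + v1.sequence[: sl - sl // 2]
    spacers.append(SpacerRecord("SP_VPOS_1_junction", virus_host["VPOS_1"], junction))
    # decoy spacers drawn from decoy-host models: no virus carries them
    for j, (gid, model) in enumerate(sorted(decoy_models.items())):
        rand = _sample_sequence(spacer_rng, sl, model)
        spacers.append(SpacerRecord(f"SP_{gid}_random", gid, rand))
        links.append(PlantedLink(f"VNEG_{j % params.n_negative + 1}", gid, Method.CRISPR, False))

    # --- planted tRNAs ----------------------------------------------------
    trna_rng = _rng(seed, "trnas")
    host_trnas: list[TRNARecord] = []
    viral_trnas: list[TRNARecord] = []
    tl = params.trna_length
    for vid in sorted(virus_host):
        hid = virus_host[vid]
        hseq = next(h for h in hosts if h.genome_id == hid).sequence
        pos = int(trna_rng.integers(0, len(hseq) - tl))
        shared = hseq[pos : pos + tl]
        host_trnas.append(TRNARecord(f"tRNA_{hid}_{vid}", hid, shared))
        viral_trnas.append(TRNARecord(f"tRNA_{vid}", vid, shared))
        links.append(PlantedLink(vid, hid, Method.TRNA, True))
    for gid, model in sorted(decoy_models.items()):
        host_trnas.append(
            TRNARecord(f"tRNA_{gid}_solo", gid, _sample_sequence(trna_rng, tl, model))
        )
    for i in range(params.n_negative):
        vid = f"VNEG_{i + 1}"
        model = _make_model(trna_rng, [2.5, 2.5, 2.5, 2.5])
        viral_trnas.append(
            TRNARecord(f"tRNA_{vid}", vid, _sample_sequence(trna_rng, tl, model))
        )
    links.append(PlantedLink("VNEG_1", "DEC_1", Method.TRNA, False))

    # --- synthetic nucleotide hit table ----------------------------------
    nucleotide_hits: list[HomologyHit] = []
    for virus in viruses:
        for host in hosts:
            nucleotide_hits.extend(naive_hit_search(virus, host))

    # --- protein hit tables, genes, taxonomy, provirus intervals ---------
    ph_rng = _rng(seed, "protein_hits")
    viral_genes: dict[str, list[GeneRecord]] = {}
    for virus in viruses:
        vid = virus.genome_id
        genes = []
        for gi in range(params.genes_per_virus):
            start = gi * (params.gene_length + 50) + 1
            genes.append(
                GeneRecord(
                    gene_id=f"{vid}_g{gi:02d}",
                    genome_id=vid,
                    contig_id=vid,
                    start=start,
                    end=start + params.gene_length - 1,
                    strand="+" if gi % 2 == 0 else "-",
                )
            )
        viral_genes[vid] = genes

    assignments: list[TaxonAssignment] = []
    subject_genes: dict[str, dict[str, GeneRecord]] = {}
    provirus_intervals: list[IntervalAnnotation] = []
    protein_hits: dict[str, list[HomologyHit]] = {}

    n_tgt_subjects = 10
    n_oth_subjects = 6
    n_vir_subjects = 4

    for db in params.databases:
        db_src = SourceClass.HOST_REFSEQ if db == "refseq" else SourceClass.HOST_MAG
        db_host_contigs = [
            (h.genome_id, cid)
            for h in hosts
            if h.source_class is db_src and h.genome_id.startswith(("RS_", "MAG_"))
            for cid in h.contig_ids
            if cid != "MAG_H1_c3"
        ]
        sgenes: dict[str, GeneRecord] = {}
        n_covered = round(params.provirus_fraction * n_tgt_subjects)
        for j in range(n_tgt_subjects):
            sid = f"TGT_{db}_{j}"
            gid, cid = db_host_contigs[j % len(db_host_contigs)]
            start = 200 + (j // len(db_host_contigs)) * 1500
            end = start + 399
            sgenes[sid] = GeneRecord(sid, gid, cid, start, end, "+")
            assignments.append(TaxonAssignment(sid, DomainClass.CELLULAR, TARGET_PHYLUM))
            if j < n_covered:
                provirus_intervals.append(
                    IntervalAnnotation(cid, max(1, start - 50), end + 50, 5)
                )
            elif j == n_covered and n_covered < n_tgt_subjects:
                # straddles its provirus boundary: overlap but not containment
                provirus_intervals.append(
                    IntervalAnnotation(cid, max(1, start - 50), start + 199, 6)
                )
        for j in range(n_oth_subjects):
            sid = f"OTH_{db}_{j}"
            assignments.append(
                TaxonAssignment(sid, DomainClass.CELLULAR, _OTHER_PHYLA[j % len(_OTHER_PHYLA)])
            )
        for j in range(n_vir_subjects):
            assignments.append(
                TaxonAssignment(f"VIR_{db}_{j}", DomainClass.VIRAL, "unknown")
            )
        subject_genes[db] = sgenes

        hits: list[HomologyHit] = []
        neg_cycle = params.neg_design[db]
        for virus in viruses:
            vid = virus.genome_id
            if vid.startswith("VPOS"):
                t, c = params.pos_design[db]
            else:
                idx = int(vid.split("_")[1]) - 1
                t, c = neg_cycle[idx % len(neg_cycle)]
            genes = viral_genes[vid]
            for gi, gene in enumerate(genes):
                qid = gene.gene_id

                def _hit(sid, bs, ident=None, ev=None):
                    return HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        pct_identity=float(
                            ident if ident is not None else ph_rng.uniform(35, 95)
                        ),
                        aln_length=int(ph_rng.integers(80, 300)),
                        evalue=float(
                            ev if ev is not None else 10.0 ** -ph_rng.uniform(15, 80)
                        ),
                        bitscore=float(bs),
                    )

                if gi < t:
                    bs = float(ph_rng.uniform(120, 300))
                    hits.append(_hit(f"TGT_{db}_{gi % n_tgt_subjects}", bs))
                    if gi % 2 == 0:  # lower-scoring off-target decoy
                        hits.append(_hit(f"OTH_{db}_{gi % n_oth_subjects}", bs - 30))
                    if gi < 2:  # higher-scoring viral hit must not mask it
                        hits.append(_hit(f"VIR_{db}_{gi % n_vir_subjects}", bs + 80))
                elif gi < c:
                    bs = float(ph_rng.uniform(100, 250))
                    hits.append(_hit(f"OTH_{db}_{gi % n_oth_subjects}", bs))
                elif gi == c:  # viral-only homolog: no cellular best hit
                    hits.append(_hit(f"VIR_{db}_{gi % n_vir_subjects}", ph_rng.uniform(80, 200)))
                elif gi == c + 1:  # sub-threshold junk, all must be filtered
                    hits.append(_hit(f"OTH_{db}_0", 120, ev=1e-5))
                    hits.append(_hit(f"OTH_{db}_1", 120, ident=25.0))
                    hits.append(_hit(f"OTH_{db}_2", 45))
        protein_hits[db] = hits

    for vid in sorted(virus_host):
        links.append(PlantedLink(vid, TARGET_PHYLUM, Method.HOMOLOG, True))
    for i in range(params.n_negative):
        links.append(PlantedLink(f"VNEG_{i + 1}", TARGET_PHYLUM, Method.HOMOLOG, False))

    taxonomy = TaxonomyMap(assignments)

    # --- read counts ------------------------------------------------------
    read_rng = _rng(seed, "reads")
    samples = [f"S{i + 1}" for i in range(params.n_samples)]
    all_genomes = sorted([g.genome_id for g in viruses] + [h.genome_id for h in hosts])
    lengths = {g.genome_id: len(g) for g in [*viruses, *hosts]}
    data = {}
    for s in samples:
        depth = read_rng.uniform(0.5, 2.0)
        data[s] = {
            gid: int(read_rng.poisson(depth * lengths[gid] / 1000 * read_rng.uniform(20, 80)))
            for gid in all_genomes
        }
    read_counts = pd.DataFrame(data).loc[all_genomes]
    library_sizes = {s: float(read_counts[s].sum()) for s in samples}

    manifest = FixtureManifest(seed=seed, planted_links=tuple(links), params=params)
    fixture = Fixture(
        manifest=manifest,
        hosts=hosts,
        viruses=viruses,
        spacers=spacers,
        host_trnas=host_trnas,
        viral_trnas=viral_trnas,
        nucleotide_hits=nucleotide_hits,
        protein_hits=protein_hits,
        viral_genes=viral_genes,
        subject_genes=subject_genes,
        taxonomy=taxonomy,
        provirus_intervals=provirus_intervals,
        viral_like_intervals=viral_like_intervals,
        read_counts=read_counts,
        library_sizes=library_sizes,
    )
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture
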