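"""Domain types and file I/O shared by every stage of the toolkit.

The toolkit links uncultured viral genomes to candidate host genomes (RefSeq
isolates or metagenome-assembled genomes).  Everything it consumes arrives as
plain files: FASTA sequences, 12-column blast-tabular hit files produced by an
external search, and small TSV tables (taxonomy map, gene coordinates,
viral-likeness / provirus intervals).  This module defines the in-memory
records for those files and the readers/writers.

Conventions
-----------
* All coordinates are 1-based inclusive, matching blast-tabular output.
* DNA alphabet is restricted to ``A C G T N`` after uppercasing; other
  ambiguity codes are rejected rather than silently remapped.
* Hit files are the integration boundary: the toolkit never invokes an
  aligner, it only consumes and filters their tabular output.
"""

from __future__ import annotations

import csv
import enum
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "UnknownSubjectError",
    "SourceClass",
    "DomainClass",
    "GenomeRecord",
    "GeneRecord",
    "HomologyHit",
    "TaxonAssignment",
    "TaxonomyMap",
    "IntervalAnnotation",
    "read_fasta",
    "write_fasta",
    "read_genes",
    "write_genes",
    "read_hits",
    "write_hits",
    "read_taxonomy",
    "write_taxonomy",
    "read_intervals",
    "write_intervals",
]

_DNA_ALPHABET = frozenset("ACGTN")
_STRICT_DNA = frozenset("ACGT")

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class ParseError(ValueError):
    """A file did not conform to its expected tabular/FASTA layout."""


class UnknownSubjectError(KeyError):
    """A scored hit references a subject absent from the taxonomy map."""


class SourceClass(str, enum.Enum):
    """Provenance of a genome: viral query, RefSeq host, or host MAG."""

    VIRAL = "viral"
    HOST_REFSEQ = "host_refseq"
    HOST_MAG = "host_mag"


class DomainClass(str, enum.Enum):
    """Coarse classification of a hit subject: cellular organism or virus."""

    CELLULAR = "cellular"
    VIRAL = "viral"


def _validate_dna(seq: str, *, what: str, strict: bool = False) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what}: sequence is empty")
    alphabet = _STRICT_DNA if strict else _DNA_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(
            f"{what}: illegal character(s) {sorted(bad)!r}; "
            f"allowed alphabet is {''.join(sorted(alphabet))}"
        )
    return seq


@dataclass(frozen=True, eq=True)
class GenomeRecord:
    """A viral genome or a (possibly multi-contig) host genome/MAG.

    ``contigs`` maps contig id to uppercase sequence; insertion order is
    preserved.  Single-contig genomes (all viral genomes here; the study
    corpus consists of circularly assembled complete genomes) use the genome
    id as the sole contig id.  A genome may end up with zero contigs after
    decontamination; individual contig sequences are never empty.
    """

    genome_id: str
    contigs: Mapping[str, str]
    source_class: SourceClass = SourceClass.VIRAL
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        cleaned: dict[str, str] = {}
        for cid, seq in self.contigs.items():
            cleaned[cid] = _validate_dna(
                seq, what=f"genome {self.genome_id!r} contig {cid!r}"
            )
        object.__setattr__(self, "contigs", cleaned)
        object.__setattr__(self, "source_class", SourceClass(self.source_class))

    @classmethod
    def single(
        cls,
        genome_id: str,
        sequence: str,
        source_class: SourceClass = SourceClass.VIRAL,
        circular: bool = False,
    ) -> "GenomeRecord":
        return cls(genome_id, {genome_id: sequence}, source_class, circular)

    @property
    def contig_ids(self) -> list[str]:
        return list(self.contigs)

    @property
    def sequence(self) -> str:
        """Concatenation of all contig sequences (in stored order)."""
        return "".join(self.contigs.values())

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class GeneRecord:
    """A predicted gene/ORF on a contig; coordinates 1-based inclusive."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    protein: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column blast-tabular similarity search.

    Only the fields the pipeline filters on are parsed; the remaining six
    columns (mismatch, gapopen, qstart, qend, sstart, send) are retained
    verbatim in ``extras`` so files round-trip.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    extras: tuple[str, ...] = ("0", "0", "0", "0", "0", "0")

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} must be >= 1")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} must be non-negative")
        if self.bitscore < 0:
            raise ValueError(f"bitscore {self.bitscore} must be non-negative")


@dataclass(frozen=True)
class TaxonAssignment:
    subject_id: str
    domain_class: DomainClass
    phylum: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_class", DomainClass(self.domain_class))


UNKNOWN_PHYLUM = "unknown"


class TaxonomyMap:
    """Resolves hit subjects to (cellular|viral, phylum) assignments.

    Every subject referenced by a scored hit must resolve to exactly one
    assignment.  With ``allow_unknown=True`` unresolvable subjects fall back
    to ``(cellular, "unknown")``; otherwise resolution raises
    :class:`UnknownSubjectError`.
    """

    def __init__(
        self,
        assignments: Iterable[TaxonAssignment],
        allow_unknown: bool = False,
    ) -> None:
        self.allow_unknown = allow_unknown
        self._by_id: dict[str, TaxonAssignment] = {}
        for a in assignments:
            prev = self._by_id.get(a.subject_id)
            if prev is not None and prev != a:
                raise ValueError(
                    f"conflicting taxonomy for subject {a.subject_id!r}: "
                    f"{prev} vs {a}"
                )
            self._by_id[a.subject_id] = a

    def resolve(self, subject_id: str) -> TaxonAssignment:
        try:
            return self._by_id[subject_id]
        except KeyError:
            if self.allow_unknown:
                return TaxonAssignment(subject_id, DomainClass.CELLULAR, UNKNOWN_PHYLUM)
            raise UnknownSubjectError(
                f"subject {subject_id!r} has no taxonomy assignment "
                "(use allow_unknown=True to map it to cellular/unknown)"
            ) from None

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())


@dataclass(frozen=True)
class IntervalAnnotation:
    """A per-contig annotation interval with a category label 1-6.

    Categories 1-3 flag whole contigs as viral-like (dropped during MAG
    decontamination); categories 4-6 delimit predicted provirus regions
    (used to attribute shared homologs to an integrated virus).
    """

    contig_id: str
    start: int
    end: int
    category: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval on {self.contig_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"interval on {self.contig_id!r}: start must be >= 1")
        if not (1 <= self.category <= 6):
            raise ValueError(
                f"interval on {self.contig_id!r}: category {self.category} "
                "outside 1-6"
            )

    @property
    def is_viral_like(self) -> bool:
        return self.category in (1, 2, 3)

    @property
    def is_provirus(self) -> bool:
        return self.category in (4, 5, 6)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    source_class: SourceClass = SourceClass.VIRAL,
    circular: bool = False,
) -> list[GenomeRecord]:
    """Read a FASTA file into one single-contig :class:`GenomeRecord` per entry.

    Sequences are uppercased; duplicate ids and characters outside ACGTN are
    rejected.  An empty file yields an empty list.  Use a grouping step (e.g.
    :func:`group_contigs`) to assemble multi-contig MAGs from contig records.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            return []
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty FASTA header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(
                GenomeRecord.single(rec.id, str(rec.seq), source_class, circular)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(path: str | Path, genomes: Iterable[GenomeRecord]) -> None:
    """Write genomes as FASTA, one entry per contig."""
    seqrecs = []
    for g in genomes:
        for cid, seq in g.contigs.items():
            seqrecs.append(SeqRecord(Seq(seq), id=cid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def group_contigs(
    contig_records: Iterable[GenomeRecord],
    genome_of: Mapping[str, str],
    source_class: SourceClass = SourceClass.HOST_MAG,
) -> list[GenomeRecord]:
    """Assemble single-contig records into multi-contig genomes.

    ``genome_of`` maps contig id -> genome id; contigs missing from the map
    are treated as single-contig genomes of their own.
    """
    grouped: dict[str, dict[str, str]] = {}
    for rec in contig_records:
        cid = rec.genome_id
        gid = genome_of.get(cid, cid)
        grouped.setdefault(gid, {})[cid] = rec.sequence
    return [
        GenomeRecord(gid, contigs, source_class) for gid, contigs in grouped.items()
    ]


# ---------------------------------------------------------------------------
# blast-tabular hits
# ---------------------------------------------------------------------------

def read_hits(path: str | Path, dialect: str = "blast6") -> list[HomologyHit]:
    """Read a 12-column blast-tabular (``-outfmt 6``) hit file.

    Columns 1, 2, 3, 4, 11, 12 populate the typed fields of
    :class:`HomologyHit`; columns 5-10 are kept verbatim in ``extras``.
    A row with a different column count raises :class:`ParseError` naming
    the row.
    """
    if dialect != "blast6":
        raise ValueError(f"unsupported hit-file dialect {dialect!r}")
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path, newline="") as fh:
        for rowno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 12:
                raise ParseError(
                    f"{path}: row {rowno}: expected 12 columns, got {len(row)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=row[0],
                        subject_id=row[1],
                        pct_identity=float(row[2]),
                        aln_length=int(row[3]),
                        evalue=float(row[10]),
                        bitscore=float(row[11]),
                        extras=tuple(row[4:10]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return hits


def write_hits(path: str | Path, hits: Iterable[HomologyHit]) -> None:
    """Write hits back out as 12-column blast-tabular (no header row)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    _fmt_float(h.pct_identity),
                    h.aln_length,
                    *h.extras,
                    _fmt_float(h.evalue),
                    _fmt_float(h.bitscore),
                ]
            )


def _fmt_float(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# small TSV tables (header row on output; tolerated on input)
# ---------------------------------------------------------------------------

def _tsv_rows(path: Path, n_cols: int, header_first_field: str):
    with open(path, newline="") as fh:
        for rowno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if rowno == 1 and row[0] == header_first_field:
                continue
            if len(row) != n_cols:
                raise ParseError(
                    f"{path}: row {rowno}: expected {n_cols} columns, got {len(row)}"
                )
            yield rowno, row


def read_taxonomy(path: str | Path, allow_unknown: bool = False) -> TaxonomyMap:
    """Read a subject-taxonomy TSV: subject_id, domain_class, phylum."""
    path = Path(path)
    assignments = []
    for rowno, row in _tsv_rows(path, 3, "subject_id"):
        try:
            assignments.append(TaxonAssignment(row[0], DomainClass(row[1]), row[2]))
        except ValueError as exc:
            raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return TaxonomyMap(assignments, allow_unknown=allow_unknown)


def write_taxonomy(path: str | Path, taxonomy: TaxonomyMap) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["subject_id", "domain_class", "phylum"])
        for a in taxonomy:
            w.writerow([a.subject_id, a.domain_class.value, a.phylum])


def read_intervals(path: str | Path) -> list[IntervalAnnotation]:
    """Read an interval TSV: contig_id, start, end, category (1-6)."""
    path = Path(path)
    intervals = []
    for rowno, row in _tsv_rows(path, 4, "contig_id"):
        try:
            intervals.append(
                IntervalAnnotation(row[0], int(row[1]), int(row[2]), int(row[3]))
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return intervals


def write_intervals(path: str | Path, intervals: Iterable[IntervalAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "start", "end", "category"])
        for iv in intervals:
            w.writerow([iv.contig_id, iv.start, iv.end, iv.category])


def read_genes(path: str | Path, protein_fasta: str | Path | None = None) -> list[GeneRecord]:
    """Read a gene-coordinate TSV (gene_id, genome_id, contig_id, start, end,
    strand), optionally attaching protein sequences from a FASTA keyed by
    gene id."""
    path = Path(path)
    proteins: dict[str, str] = {}
    if protein_fasta is not None:
        for rec in SeqIO.parse(str(protein_fasta), "fasta"):
            proteins[rec.id] = str(rec.seq)
    genes = []
    for rowno, row in _tsv_rows(path, 6, "gene_id"):
        try:
            genes.append(
                GeneRecord(
                    gene_id=row[0],
                    genome_id=row[1],
                    contig_id=row[2],
                    start=int(row[3]),
                    end=int(row[4]),
                    strand=row[5],
                    protein=proteins.get(row[0]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return genes


def write_genes(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "genome_id", "contig_id", "start", "end", "strand"])
        for g in genes:
            w.writerow([g.gene_id, g.genome_id, g.contig_id, g.start, g.end, g.strand])
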