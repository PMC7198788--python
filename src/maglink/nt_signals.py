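"""Nucleotide-level virus-host detectors.

Three of the four classical nucleotide-similarity host-prediction strategies
live here:

* CRISPR spacer matching — a host spacer aligning (ungapped, either strand)
  over its whole length to a viral genome records a past infection.  The
  match must reach 95% overall identity and any mismatches must sit in the
  first couple of positions at the spacer's 5' end (default window 2 nt, at
  most 2 SNPs), the stricter reading of the tolerance applied in practice.
* tRNA matching — viruses frequently carry host-derived tRNAs; only a
  perfect match (100% length and 100% identity) counts as evidence.
* Filtered nucleotide homology — the best blast-style hit per virus-host
  genome pair counts when it exceeds 70% identity over >= 1000 bp.

The fourth strategy (alignment-free oligonucleotide-frequency dissimilarity)
is in :mod:`maglink.onf`.  All detectors are deterministic and independent of
input order; each emitted :class:`PredictionSignal` carries method
provenance and a method-specific score.
"""

from __future__ import annotations

import csv
import enum
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_core import GenomeRecord, HomologyHit, ParseError, _validate_dna

__all__ = [
    "Method",
    "PredictionSignal",
    "SpacerRecord",
    "TRNARecord",
    "match_spacers",
    "match_trnas",
    "filter_blastn_signals",
    "read_signals",
    "write_signals",
    "read_spacers",
    "write_spacers",
    "read_trnas",
    "write_trnas",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map ACGTN to int8 codes 0-3 (N -> -1, never matches anything)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


class Method(str, enum.Enum):
    CRISPR = "crispr"
    TRNA = "trna"
    BLASTN = "blastn"
    ONF = "onf"
    HOMOLOG = "homolog_profile"


@dataclass(frozen=True)
class PredictionSignal:
    """One virus-host evidence link with method provenance.

    ``score`` semantics depend on ``method``: mismatch count for crispr,
    matched length for trna, percent identity for blastn, dissimilarity for
    onf, and passing-database count for homolog_profile.
    """

    viral_id: str
    host_id: str
    method: Method
    score: float
    detail: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))


@dataclass(frozen=True)
class SpacerRecord:
    """A CRISPR spacer extracted from a host genome (prediction upstream)."""

    spacer_id: str
    host_genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sequence",
            _validate_dna(self.sequence, what=f"spacer {self.spacer_id!r}", strict=True),
        )


@dataclass(frozen=True)
class TRNARecord:
    """A tRNA sequence recovered from a host or viral genome."""

    record_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sequence",
            _validate_dna(self.sequence, what=f"tRNA {self.record_id!r}", strict=True),
        )


# ---------------------------------------------------------------------------
# (i) CRISPR spacer matching
# ---------------------------------------------------------------------------

def _scan_windows(
    gcodes: np.ndarray,
    pattern: np.ndarray,
    *,
    max_snps: int,
    min_identity: float,
    window: int,
    five_prime_at_start: bool,
) -> list[tuple[int, int]]:
    """Return (0-based offset, mismatch count) for qualifying ungapped matches.

    ``five_prime_at_start`` is True when the pattern is the spacer itself
    (its 5' end is the window start) and False when the pattern is the
    spacer's reverse complement (the spacer's 5' end is the window *end*).
    """
    L = len(pattern)
    n = len(gcodes) - L + 1
    if n <= 0:
        return []
    mm = sliding_window_view(gcodes, L) != pattern
    counts = mm.sum(axis=1)
    ok = (counts <= max_snps) & ((L - counts) / L >= min_identity)
    if window < L:
        if five_prime_at_start:
            ok &= ~mm[:, window:].any(axis=1)
        else:
            ok &= ~mm[:, : L - window].any(axis=1)
    return [(int(i), int(counts[i])) for i in np.nonzero(ok)[0]]


def match_spacers(
    spacers: Iterable[SpacerRecord],
    viral_genomes: Iterable[GenomeRecord],
    min_identity: float = 0.95,
    max_5prime_snps: int = 2,
    five_prime_window: int = 2,
    min_spacer_length: int = 18,
) -> list[PredictionSignal]:
    """Scan viral genomes for protospacers matching host CRISPR spacers.

    A signal is emitted when a spacer aligns ungapped over its whole length
    to a viral contig (either strand) with overall identity >=
    ``min_identity``, every mismatch within the first ``five_prime_window``
    positions of the spacer's 5' end, and at most ``max_5prime_snps``
    mismatches.  One signal per (spacer, genome, position, strand); the
    score is the mismatch count.  Circular contigs are scanned with a
    wraparound suffix so junction-spanning protospacers are found.
    """
    spacers = list(spacers)
    for sp in spacers:
        if len(sp.sequence) < min_spacer_length:
            raise ValueError(
                f"spacer {sp.spacer_id!r} is {len(sp.sequence)} nt, below the "
                f"configured floor of {min_spacer_length}"
            )
    signals: list[PredictionSignal] = []
    for genome in viral_genomes:
        for contig_id, contig_seq in genome.contigs.items():
            clen = len(contig_seq)
            for sp in spacers:
                L = len(sp.sequence)
                seq = contig_seq
                if genome.circular and clen > L:
                    seq = contig_seq + contig_seq[: L - 1]
                gcodes = _encode(seq)
                for strand, pattern, at_start in (
                    ("+", _encode(sp.sequence), True),
                    ("-", _encode(revcomp(sp.sequence)), False),
                ):
                    for off, nmm in _scan_windows(
                        gcodes,
                        pattern,
                        max_snps=max_5prime_snps,
                        min_identity=min_identity,
                        window=five_prime_window,
                        five_prime_at_start=at_start,
                    ):
                        pos = off % clen + 1  # 1-based, wraps on circular contigs
                        signals.append(
                            PredictionSignal(
                                viral_id=genome.genome_id,
                                host_id=sp.host_genome_id,
                                method=Method.CRISPR,
                                score=float(nmm),
                                detail=(
                                    f"spacer={sp.spacer_id};contig={contig_id};"
                                    f"start={pos};strand={strand};mismatches={nmm}"
                                ),
                            )
                        )
    signals.sort(key=lambda s: (s.viral_id, s.host_id, s.detail))
    return signals


# ---------------------------------------------------------------------------
# (ii) tRNA perfect match
# ---------------------------------------------------------------------------

def match_trnas(
    host_trnas: Iterable[TRNARecord],
    viral_trnas: Iterable[TRNARecord],
) -> list[PredictionSignal]:
    """Emit one signal per host/viral tRNA pair with identical sequences.

    Only a perfect match — 100% length and 100% sequence identity, forward
    strand as given — is considered indicative of a virus-host pair.
    """
    by_seq: dict[str, list[TRNARecord]] = {}
    for vt in viral_trnas:
        by_seq.setdefault(vt.sequence, []).append(vt)
    signals = []
    for ht in host_trnas:
        for vt in by_seq.get(ht.sequence, ()):
            signals.append(
                PredictionSignal(
                    viral_id=vt.genome_id,
                    host_id=ht.genome_id,
                    method=Method.TRNA,
                    score=float(len(vt.sequence)),
                    detail=f"viral_trna={vt.record_id};host_trna={ht.record_id}",
                )
            )
    signals.sort(key=lambda s: (s.viral_id, s.host_id, s.detail))
    return signals


# ---------------------------------------------------------------------------
# (iii) filtered nucleotide homology
# ---------------------------------------------------------------------------

def _hit_rank(h: HomologyHit) -> tuple:
    # best first: highest bitscore, then lowest evalue, then smallest subject
    return (-h.bitscore, h.evalue, h.subject_id)


def filter_blastn_signals(
    hits: Iterable[HomologyHit],
    min_identity: float = 70.0,
    min_length: int = 1000,
    query_genome: Callable[[str], str] | Mapping[str, str] | None = None,
    subject_genome: Callable[[str], str] | Mapping[str, str] | None = None,
) -> list[PredictionSignal]:
    """Filter viral-vs-host nucleotide hits down to indicative best hits.

    Per (viral genome, host genome) pair only the top-bitscore hit is kept
    (so a virus may still be linked to several candidate hosts); it yields a
    signal iff identity > ``min_identity`` (strict) and alignment length >=
    ``min_length``.  ``query_genome``/``subject_genome`` optionally map hit
    ids (e.g. contig ids) to genome ids; default is the identity mapping.
    """
    q_of = _as_mapper(query_genome)
    s_of = _as_mapper(subject_genome)
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (q_of(h.query_id), s_of(h.subject_id))
        prev = best.get(key)
        if prev is None or _hit_rank(h) < _hit_rank(prev):
            best[key] = h
    signals = []
    for (viral_id, host_id), h in best.items():
        if h.pct_identity > min_identity and h.aln_length >= min_length:
            signals.append(
                PredictionSignal(
                    viral_id=viral_id,
                    host_id=host_id,
                    method=Method.BLASTN,
                    score=h.pct_identity,
                    detail=(
                        f"query={h.query_id};subject={h.subject_id};"
                        f"length={h.aln_length};bitscore={h.bitscore:g}"
                    ),
                )
            )
    signals.sort(key=lambda s: (s.viral_id, s.host_id, s.detail))
    return signals


def _as_mapper(m) -> Callable[[str], str]:
    if m is None:
        return lambda x: x
    if callable(m):
        return m
    return lambda x: m.get(x, x)


# ---------------------------------------------------------------------------
# spacer / tRNA FASTA round-trip (header: "<record_id> <genome_id>")
# ---------------------------------------------------------------------------

def write_spacers(path: str | Path, spacers: Iterable[SpacerRecord]) -> None:
    SeqIO.write(
        (
            SeqRecord(Seq(s.sequence), id=s.spacer_id, description=s.host_genome_id)
            for s in spacers
        ),
        str(path),
        "fasta",
    )


def read_spacers(path: str | Path) -> list[SpacerRecord]:
    """Read spacers from FASTA; the description's second word is the host id."""
    spacers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        words = rec.description.split()
        if len(words) < 2:
            raise ParseError(
                f"{path}: spacer {rec.id!r}: header must be '<spacer_id> <host_genome_id>'"
            )
        spacers.append(SpacerRecord(rec.id, words[1], str(rec.seq)))
    return spacers


def write_trnas(path: str | Path, trnas: Iterable[TRNARecord]) -> None:
    SeqIO.write(
        (
            SeqRecord(Seq(t.sequence), id=t.record_id, description=t.genome_id)
            for t in trnas
        ),
        str(path),
        "fasta",
    )


def read_trnas(path: str | Path) -> list[TRNARecord]:
    """Read tRNAs from FASTA; the description's second word is the genome id."""
    trnas = []
    for rec in SeqIO.parse(str(path), "fasta"):
        words = rec.description.split()
        if len(words) < 2:
            raise ParseError(
                f"{path}: tRNA {rec.id!r}: header must be '<record_id> <genome_id>'"
            )
        trnas.append(TRNARecord(rec.id, words[1], str(rec.seq)))
    return trnas


# ---------------------------------------------------------------------------
# signal TSV round-trip
# ---------------------------------------------------------------------------

def write_signals(path: str | Path, signals: Iterable[PredictionSignal]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["viral_id", "host_id", "method", "score", "detail"])
        for s in signals:
            w.writerow([s.viral_id, s.host_id, s.method.value, repr(s.score), s.detail])


def read_signals(path: str | Path) -> list[PredictionSignal]:
    path = Path(path)
    signals = []
    with open(path, newline="") as fh:
        for rowno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if rowno == 1 and row[0] == "viral_id":
                continue
            if len(row) != 5:
                raise ParseError(
                    f"{path}: row {rowno}: expected 5 columns, got {len(row)}"
                )
            try:
                signals.append(
                    PredictionSignal(row[0], row[1], Method(row[2]), float(row[3]), row[4])
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return signals
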