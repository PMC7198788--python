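"""Contig-level taxonomy validation and MAG decontamination bookkeeping.

MAGs binned from metagenomes can carry contigs from other taxa or from
viruses.  Before a MAG contig is trusted as evidence of a virus-host link,
its genes are searched against a reference protein database and the summed
bit scores of the best hits are examined: if more than 80% of the total bit
score is consistently assigned to the target phylum, the contig is accepted
as deriving from that phylum; otherwise it is treated as a contaminant.
Contigs flagged as viral-like upstream (interval categories 1-3) are dropped
outright.

All inequality thresholds here are strict (evalue < 1e-10, identity > 30,
bit score > 50, fraction > 0.8); boundary values are excluded.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, replace

from .io_core import (
    DomainClass,
    GenomeRecord,
    HomologyHit,
    IntervalAnnotation,
    TaxonomyMap,
)

__all__ = [
    "Verdict",
    "ContigVerdict",
    "filter_protein_hits",
    "best_hit_per_query",
    "classify_contig",
    "drop_viral_like_contigs",
]

logger = logging.getLogger(__name__)


class Verdict(str, enum.Enum):
    TARGET_PHYLUM = "target_phylum"
    CONTAMINANT = "contaminant"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ContigVerdict:
    """Outcome of the summed best-hit bit-score vote for one contig."""

    contig_id: str
    total_bitscore: float
    target_bitscore: float
    fraction: float
    verdict: Verdict

    def __post_init__(self) -> None:
        object.__setattr__(self, "verdict", Verdict(self.verdict))


def filter_protein_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float = 1e-10,
    min_identity: float = 30.0,
    min_bitscore: float = 50.0,
) -> list[HomologyHit]:
    """Keep protein hits with evalue < max_evalue, identity > min_identity
    and bit score > min_bitscore (all strict)."""
    return [
        h
        for h in hits
        if h.evalue < max_evalue
        and h.pct_identity > min_identity
        and h.bitscore > min_bitscore
    ]


def best_hit_per_query(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """Select the single best hit per query.

    Best = highest bit score; ties broken by lower e-value, then by
    lexicographically smallest subject id, so the result is deterministic
    and independent of input order.  Hits are expected to be pre-filtered.
    """
    best: dict[str, HomologyHit] = {}
    for h in hits:
        prev = best.get(h.query_id)
        if prev is None or _rank(h) < _rank(prev):
            best[h.query_id] = h
    return best


def _rank(h: HomologyHit) -> tuple:
    return (-h.bitscore, h.evalue, h.subject_id)


def classify_contig(
    contig_id: str,
    best_hits: Mapping[str, HomologyHit],
    taxonomy: TaxonomyMap,
    target_phylum: str,
    min_fraction: float = 0.8,
    exclude_viral: bool = True,
) -> ContigVerdict:
    """Vote on a contig's phylum from its genes' best-hit bit scores.

    ``best_hits`` maps gene id -> best qualifying hit for the genes of this
    contig (genes without qualifying hits simply do not appear and
    contribute nothing).  The contig is called ``target_phylum`` iff the
    target's share of the summed bit score strictly exceeds
    ``min_fraction``; ``unassigned`` when no gene contributes.  Genes whose
    best hit is a viral subject are excluded from the vote by default (the
    procedure targets cellular assignment).
    """
    total = 0.0
    target = 0.0
    for hit in best_hits.values():
        assignment = taxonomy.resolve(hit.subject_id)
        if exclude_viral and assignment.domain_class is DomainClass.VIRAL:
            continue
        total += hit.bitscore
        if assignment.phylum == target_phylum:
            target += hit.bitscore
    if total <= 0.0:
        return ContigVerdict(contig_id, 0.0, 0.0, 0.0, Verdict.UNASSIGNED)
    fraction = target / total
    verdict = Verdict.TARGET_PHYLUM if fraction > min_fraction else Verdict.CONTAMINANT
    return ContigVerdict(contig_id, total, target, fraction, verdict)


def drop_viral_like_contigs(
    mag: GenomeRecord,
    annotations: Iterable[IntervalAnnotation],
) -> GenomeRecord:
    """Remove contigs flagged viral-like (category 1-3) from a MAG.

    Provirus annotations (categories 4-6) mark regions within otherwise
    cellular contigs and do not cause removal.  Removal counts are logged.
    """
    flagged = {a.contig_id for a in annotations if a.is_viral_like}
    keep = {cid: seq for cid, seq in mag.contigs.items() if cid not in flagged}
    n_dropped = len(mag.contigs) - len(keep)
    if n_dropped:
        logger.info(
            "MAG %s: dropped %d viral-like contig(s) of %d, %d retained",
            mag.genome_id,
            n_dropped,
            len(mag.contigs),
            len(keep),
        )
    return replace(mag, contigs=keep)
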