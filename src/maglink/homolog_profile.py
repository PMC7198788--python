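"""Homolog-proportion host classification with negative-control calibration.

The central idea: viruses accumulate genes from the taxa they infect, so the
share of a viral genome's proteins whose closest cellular homolog belongs to
a given phylum is a host-range signal.  For each viral genome and each
reference protein collection (e.g. "refseq" isolates and "mag" genomes) a
:class:`HomologProfile` records three statistics over the best qualifying
hits of its predicted genes:

* the proportion of all genes whose best cellular hit is in the target
  phylum (``prop_of_genes``),
* the proportion of genes *with* a cellular best hit that hit the target
  phylum (``prop_of_cellular``), and
* the absolute count of target-phylum homolog genes (``n_target``).

Thresholds for a three-criterion classifier are calibrated on negative
controls — viruses known not to infect the target phylum — as the maximum of
each statistic over the negatives.  A viral genome is called a putative
target-phylum virus when all three statistics reach their thresholds
(inclusive, "at least") for at least one reference collection.

Homologs shared because the reference genome carries an integrated provirus
are flagged by interval containment against provirus annotations
(categories 4-6); the same containment operator serves auxiliary-metabolic-
gene attribution given a user-supplied AMG gene list.
"""

from __future__ import annotations

import csv
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

from .io_core import (
    DomainClass,
    GeneRecord,
    HomologyHit,
    IntervalAnnotation,
    TaxonomyMap,
)
from .taxonomy_validation import best_hit_per_query, filter_protein_hits

__all__ = [
    "HomologProfile",
    "Thresholds",
    "ClassificationResult",
    "CalibrationWarning",
    "best_cellular_hits",
    "build_homolog_profile",
    "attribute_provirus_origin",
    "calibrate_thresholds",
    "classify_viral_genome",
    "read_profiles",
    "write_profiles",
    "read_thresholds",
    "write_thresholds",
]


class CalibrationWarning(UserWarning):
    """A single negative control attains every per-criterion maximum, so it
    would classify itself positive under the inclusive rule."""


@dataclass(frozen=True)
class HomologProfile:
    """Per-viral-genome homolog statistics against one reference collection."""

    viral_id: str
    database_label: str
    n_genes: int
    n_cellular: int
    n_target: int
    prop_of_genes: float
    prop_of_cellular: float
    n_provirus_origin: int = 0
    # best cellular hit per gene, kept for provenance/attribution; not
    # part of equality or serialisation.
    best_hits: Mapping[str, HomologyHit] | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if not (0 <= self.n_target <= self.n_cellular <= self.n_genes):
            raise ValueError(
                f"{self.viral_id}: need 0 <= n_target <= n_cellular <= n_genes, "
                f"got {self.n_target}/{self.n_cellular}/{self.n_genes}"
            )
        for name in ("prop_of_genes", "prop_of_cellular"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.viral_id}: {name}={v} outside [0, 1]")
        if not (0 <= self.n_provirus_origin <= self.n_target):
            raise ValueError(
                f"{self.viral_id}: n_provirus_origin={self.n_provirus_origin} "
                f"exceeds n_target={self.n_target}"
            )


@dataclass(frozen=True)
class Thresholds:
    """Calibrated cutoffs for the three-criterion classifier (one database)."""

    database_label: str
    min_prop_of_genes: float
    min_prop_of_cellular: float
    min_count: int

    def __post_init__(self) -> None:
        if self.min_prop_of_genes < 0 or self.min_prop_of_cellular < 0:
            raise ValueError("threshold proportions must be non-negative")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class ClassificationResult:
    verdict: bool
    passing_databases: tuple[str, ...]


def best_cellular_hits(
    genes: Iterable[GeneRecord],
    hits: Iterable[HomologyHit],
    taxonomy: TaxonomyMap,
    max_evalue: float = 1e-10,
    min_identity: float = 30.0,
    min_bitscore: float = 50.0,
    cellular_only: bool = True,
) -> dict[str, HomologyHit]:
    """Best qualifying hit per gene, restricted to the given genes.

    Hits are filtered with the strict protein thresholds, then (by default)
    hits to viral subjects are discarded *before* best-hit selection, so a
    viral subject can never mask a cellular homolog — proportions are taken
    among the most closely matched cellular homologs.  With
    ``cellular_only=False`` the overall best hit is selected first and genes
    whose best hit is viral drop out of the cellular tally.
    """
    gene_ids = {g.gene_id for g in genes}
    kept = [
        h
        for h in filter_protein_hits(hits, max_evalue, min_identity, min_bitscore)
        if h.query_id in gene_ids
    ]
    if cellular_only:
        kept = [
            h
            for h in kept
            if taxonomy.resolve(h.subject_id).domain_class is DomainClass.CELLULAR
        ]
        return best_hit_per_query(kept)
    best = best_hit_per_query(kept)
    return {
        g: h
        for g, h in best.items()
        if taxonomy.resolve(h.subject_id).domain_class is DomainClass.CELLULAR
    }


def build_homolog_profile(
    viral_id: str,
    viral_genes: Iterable[GeneRecord],
    hits: Iterable[HomologyHit],
    taxonomy: TaxonomyMap,
    target_phylum: str,
    database_label: str,
    max_evalue: float = 1e-10,
    min_identity: float = 30.0,
    min_bitscore: float = 50.0,
    cellular_only: bool = True,
) -> HomologProfile:
    """Tabulate target-phylum homolog statistics for one viral genome.

    ``viral_genes`` are the genome's predicted genes; ``hits`` the protein
    search of those genes against one reference collection (queries are gene
    ids).  Proportions are 0 when their denominator is 0.
    """
    genes = list(viral_genes)
    for g in genes:
        if g.genome_id != viral_id:
            raise ValueError(
                f"gene {g.gene_id!r} belongs to {g.genome_id!r}, not {viral_id!r}"
            )
    best = best_cellular_hits(
        genes, hits, taxonomy, max_evalue, min_identity, min_bitscore, cellular_only
    )
    n_genes = len(genes)
    n_cellular = len(best)
    n_target = sum(
        1 for h in best.values() if taxonomy.resolve(h.subject_id).phylum == target_phylum
    )
    return HomologProfile(
        viral_id=viral_id,
        database_label=database_label,
        n_genes=n_genes,
        n_cellular=n_cellular,
        n_target=n_target,
        prop_of_genes=n_target / n_genes if n_genes else 0.0,
        prop_of_cellular=n_target / n_cellular if n_cellular else 0.0,
        best_hits=best,
    )


def _contained(gene: GeneRecord, iv: IntervalAnnotation, mode: str) -> bool:
    if gene.contig_id != iv.contig_id:
        return False
    if mode == "containment":
        return gene.start >= iv.start and gene.end <= iv.end
    if mode == "overlap":
        return gene.start <= iv.end and gene.end >= iv.start
    raise ValueError(f"unknown attribution mode {mode!r}")


def attribute_provirus_origin(
    profile: HomologProfile,
    taxonomy: TaxonomyMap,
    target_phylum: str,
    provirus_intervals: Iterable[IntervalAnnotation],
    subject_genes: Mapping[str, GeneRecord],
    mode: str = "containment",
) -> HomologProfile:
    """Count target-phylum homologs whose reference gene lies in a provirus.

    A homolog is provirus-origin when its best-hit subject gene is fully
    contained in any category-4/5/6 interval on the same contig (or merely
    overlapping one, with ``mode="overlap"``).  Subjects without coordinates
    are left unattributed.  Returns an updated profile.
    """
    if profile.best_hits is None:
        raise ValueError(
            f"profile {profile.viral_id!r} carries no best-hit provenance; "
            "build it with build_homolog_profile"
        )
    provirus = [iv for iv in provirus_intervals if iv.is_provirus]
    n = 0
    for hit in profile.best_hits.values():
        if taxonomy.resolve(hit.subject_id).phylum != target_phylum:
            continue
        gene = subject_genes.get(hit.subject_id)
        if gene is None:
            continue
        if any(_contained(gene, iv, mode) for iv in provirus):
            n += 1
    return replace(profile, n_provirus_origin=n)


def calibrate_thresholds(
    negative_profiles: Iterable[HomologProfile],
) -> Thresholds:
    """Set each classifier threshold to its maximum over negative controls.

    The count threshold is floored at 1.  If one negative simultaneously
    attains all three maxima it would classify itself positive under the
    inclusive rule; this is surfaced as a :class:`CalibrationWarning`.
    """
    negatives = list(negative_profiles)
    if not negatives:
        raise ValueError("calibration requires at least one negative profile")
    labels = {p.database_label for p in negatives}
    if len(labels) > 1:
        raise ValueError(
            f"negative profiles span multiple databases: {sorted(labels)}"
        )
    t = Thresholds(
        database_label=negatives[0].database_label,
        min_prop_of_genes=max(p.prop_of_genes for p in negatives),
        min_prop_of_cellular=max(p.prop_of_cellular for p in negatives),
        min_count=max(max(p.n_target for p in negatives), 1),
    )
    offenders = [p.viral_id for p in negatives if _passes(p, t)]
    if offenders:
        warnings.warn(
            "negative control(s) attain all three per-criterion maxima and "
            f"would self-classify positive: {offenders}",
            CalibrationWarning,
            stacklevel=2,
        )
    return t


def _passes(p: HomologProfile, t: Thresholds) -> bool:
    return (
        p.prop_of_genes >= t.min_prop_of_genes
        and p.prop_of_cellular >= t.min_prop_of_cellular
        and p.n_target >= t.min_count
    )


def classify_viral_genome(
    profiles: Mapping[str, HomologProfile],
    thresholds: Mapping[str, Thresholds],
) -> ClassificationResult:
    """Apply the three-criterion rule per database and combine by union.

    A database passes iff all three statistics reach their thresholds
    (inclusive); the overall verdict is positive when any supplied database
    passes, since detections specific to a single reference collection are
    real detections.
    """
    passing = []
    for label, profile in profiles.items():
        if label not in thresholds:
            raise KeyError(f"no thresholds supplied for database {label!r}")
        if _passes(profile, thresholds[label]):
            passing.append(label)
    return ClassificationResult(verdict=bool(passing), passing_databases=tuple(sorted(passing)))


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_PROFILE_COLS = [
    "viral_id",
    "database_label",
    "n_genes",
    "n_cellular",
    "n_target",
    "prop_of_genes",
    "prop_of_cellular",
    "n_provirus_origin",
]


def write_profiles(path: str | Path, profiles: Iterable[HomologProfile]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PROFILE_COLS)
        for p in profiles:
            w.writerow(
                [
                    p.viral_id,
                    p.database_label,
                    p.n_genes,
                    p.n_cellular,
                    p.n_target,
                    repr(p.prop_of_genes),
                    repr(p.prop_of_cellular),
                    p.n_provirus_origin,
                ]
            )


def read_profiles(path: str | Path) -> list[HomologProfile]:
    profiles = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            profiles.append(
                HomologProfile(
                    viral_id=row["viral_id"],
                    database_label=row["database_label"],
                    n_genes=int(row["n_genes"]),
                    n_cellular=int(row["n_cellular"]),
                    n_target=int(row["n_target"]),
                    prop_of_genes=float(row["prop_of_genes"]),
                    prop_of_cellular=float(row["prop_of_cellular"]),
                    n_provirus_origin=int(row["n_provirus_origin"]),
                )
            )
    return profiles


def write_thresholds(path: str | Path, thresholds: Iterable[Thresholds]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["database_label", "min_prop_of_genes", "min_prop_of_cellular", "min_count"])
        for t in thresholds:
            w.writerow(
                [
                    t.database_label,
                    repr(t.min_prop_of_genes),
                    repr(t.min_prop_of_cellular),
                    t.min_count,
                ]
            )


def read_thresholds(path: str | Path) -> dict[str, Thresholds]:
    out: dict[str, Thresholds] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            t = Thresholds(
                database_label=row["database_label"],
                min_prop_of_genes=float(row["min_prop_of_genes"]),
                min_prop_of_cellular=float(row["min_prop_of_cellular"]),
                min_count=int(row["min_count"]),
            )
            out[t.database_label] = t
    return out
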