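"""Signal integration, redundancy removal, cross-tabulation and abundance.

A viral genome flagged by several detectors, or paired with several
candidate hosts, is still one prediction: :func:`merge_signals` collapses a
signal list to one report per viral genome, applies an explicit exclusion
list (expert-curated false positives are an input, not a computation), and
keeps per-pair detail available.  :func:`crosstab` reproduces the standard
method-by-reference-collection count table; :func:`overlap_sets` is the set
algebra used to compare detection strategies; :func:`fpkm` is the
fragments-per-kilobase-per-million read-recruitment normalisation used for
abundance summaries.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .io_core import SourceClass
from .nt_signals import PredictionSignal

__all__ = [
    "PredictionReport",
    "OverlapResult",
    "merge_signals",
    "retained",
    "crosstab",
    "overlap_sets",
    "fpkm",
    "relative_abundance",
]

TOTAL = "total"


@dataclass(frozen=True)
class PredictionReport:
    """One row per viral genome after redundancy removal."""

    viral_id: str
    methods: frozenset[str]
    host_ids: frozenset[str]
    excluded: bool = False
    reason: str = ""


def merge_signals(
    signals: Iterable[PredictionSignal],
    exclusion: Iterable[tuple[str, str]] = (),
) -> list[PredictionReport]:
    """Group signals by viral genome and flag excluded ids.

    Returns one report per viral genome, sorted by id.  Genomes on the
    exclusion list are flagged ``excluded`` with their reason and are not
    part of the positive set (see :func:`retained`); excluded ids without
    any signal still yield a (flagged) report row so the bookkeeping is
    visible.  Idempotent: merging the merge output's signals changes
    nothing.
    """
    excluded_by_id = {vid: reason for vid, reason in exclusion}
    grouped: dict[str, tuple[set[str], set[str]]] = {}
    for s in signals:
        methods, hosts = grouped.setdefault(s.viral_id, (set(), set()))
        methods.add(s.method.value)
        hosts.add(s.host_id)
    reports = []
    for vid in sorted(set(grouped) | set(excluded_by_id)):
        methods, hosts = grouped.get(vid, (set(), set()))
        reports.append(
            PredictionReport(
                viral_id=vid,
                methods=frozenset(methods),
                host_ids=frozenset(hosts),
                excluded=vid in excluded_by_id,
                reason=excluded_by_id.get(vid, ""),
            )
        )
    return reports


def retained(reports: Iterable[PredictionReport]) -> list[PredictionReport]:
    """The positive set: reports not flagged as excluded."""
    return [r for r in reports if not r.excluded]


def crosstab(
    signals: Iterable[PredictionSignal],
    source_of: Mapping[str, SourceClass],
) -> pd.DataFrame:
    """Count signals per (reference source class, method), with totals.

    Rows are host source classes (e.g. host_refseq / host_mag), columns are
    detection methods, plus a ``total`` row and column; every host id in the
    signal list must resolve through ``source_of``.
    """
    rows = []
    for s in signals:
        try:
            src = SourceClass(source_of[s.host_id])
        except KeyError:
            raise KeyError(
                f"host {s.host_id!r} has no source-class assignment"
            ) from None
        rows.append((src.value, s.method.value))
    if not rows:
        return pd.DataFrame({TOTAL: [0]}, index=pd.Index([TOTAL], name="source_class"))
    df = pd.DataFrame(rows, columns=["source_class", "method"])
    table = pd.crosstab(
        df["source_class"], df["method"], margins=True, margins_name=TOTAL
    )
    table.index.name = "source_class"
    return table


@dataclass(frozen=True)
class OverlapResult:
    only_a: frozenset[str]
    only_b: frozenset[str]
    both: frozenset[str]
    union: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "both": len(self.both),
            "union": len(self.union),
        }


def overlap_sets(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapResult:
    """Exact set algebra between two collections of viral ids."""
    a, b = frozenset(set_a), frozenset(set_b)
    return OverlapResult(
        only_a=a - b,
        only_b=b - a,
        both=a & b,
        union=a | b,
    )


def fpkm(
    read_counts: Mapping[tuple[str, str], float] | pd.DataFrame,
    genome_lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
) -> pd.DataFrame:
    """Fragments per kilobase of genome per million mapped fragments.

    ``read_counts`` is either a DataFrame (genomes x samples) or a mapping
    (sample, genome) -> fragment count.  FPKM = count / ((length/1e3) *
    (library_size/1e6)).  Zero or negative lengths/library sizes are
    rejected.
    """
    if isinstance(read_counts, pd.DataFrame):
        counts = read_counts.astype(float)
    else:
        records: dict[str, dict[str, float]] = {}
        for (sample, genome), c in read_counts.items():
            records.setdefault(genome, {})[sample] = float(c)
        counts = pd.DataFrame(records).T.fillna(0.0).sort_index()
        counts = counts[sorted(counts.columns)]
    lengths = pd.Series({g: genome_lengths[g] for g in counts.index}, dtype=float)
    libs = pd.Series({s: library_sizes[s] for s in counts.columns}, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def relative_abundance(fpkm_table: pd.DataFrame, genome_ids: Iterable[str]) -> pd.Series:
    """Per-sample share of total FPKM contributed by a genome set."""
    ids = [g for g in fpkm_table.index if g in set(genome_ids)]
    totals = fpkm_table.sum(axis=0)
    return fpkm_table.loc[ids].sum(axis=0) / totals
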