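"""Alignment-free host matching by oligonucleotide-frequency dissimilarity.

Viruses tend to mimic the nucleotide composition of their hosts, so a low
k-mer-composition distance between a viral genome and a candidate host is a
host-range signal even with no alignable homology.  The measure implemented
here is the d2* statistic: k-mer counts are centred by their expectation
under an order-r Markov model fitted to the same sequence, and the
normalised inner product of the centred count vectors is mapped to a
dissimilarity in [0, 1] (0 = identical composition, ~0.5 = unrelated).
Pairs below a screening threshold (default 0.13) are reported as candidate
virus-host links.

Counting is double-stranded (each word and its reverse complement), so the
dissimilarity is invariant to reverse-complementing either genome.  Words
containing N are skipped; multi-contig hosts pool counts across contigs with
no word spanning a junction; circular contigs are counted with a wraparound
suffix.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenomeRecord
from .nt_signals import Method, PredictionSignal, _encode

__all__ = [
    "ONFProfile",
    "build_profile",
    "d2star_dissimilarity",
    "dissimilarity_matrix",
    "onf_screen",
]


@dataclass
class ONFProfile:
    """Double-stranded k-mer counts and Markov-expected counts for a genome."""

    genome_id: str
    k: int
    markov_order: int
    counts: np.ndarray  # observed word counts, length 4**k
    expected: np.ndarray  # expected counts under the fitted Markov model

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.counts.shape != (4**self.k,) or self.expected.shape != (4**self.k,):
            raise ValueError("counts/expected must have length 4**k")


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes >= 0, 3 - codes, codes)
    return out[::-1]


def _word_counts(codes: np.ndarray, m: int, circular: bool) -> np.ndarray:
    """Count m-mers (single strand) in an integer-coded sequence.

    Words containing N (code -1) are skipped.  For circular sequences the
    first m-1 codes are appended so junction-spanning words are counted.
    """
    if circular and len(codes) >= m:
        codes = np.concatenate([codes, codes[: m - 1]])
    n = len(codes) - m + 1
    counts = np.zeros(4**m, dtype=np.int64)
    if n <= 0:
        return counts
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(m):
        c = codes[j : j + n]
        valid &= c >= 0
        idx = idx * 4 + np.where(c >= 0, c, 0)
    return np.bincount(idx[valid], minlength=4**m)


def _count_both_strands(genome: GenomeRecord, m: int) -> np.ndarray:
    counts = np.zeros(4**m, dtype=np.int64)
    for seq in genome.contigs.values():
        codes = _encode(seq)
        counts += _word_counts(codes, m, genome.circular)
        counts += _word_counts(_revcomp_codes(codes), m, genome.circular)
    return counts


DEFAULT_MARKOV_ORDER = 2


def build_profile(
    genome: GenomeRecord,
    k: int = 6,
    markov_order: int | None = None,
    pseudocount: float = 1.0,
) -> ONFProfile:
    """Build the k-mer profile and its order-r Markov expectations.

    The Markov model is fitted to the same genome: (r+1)-mer counts (both
    strands, pseudocount added to every word so no expectation is zero)
    define the transition probabilities, and their marginals define the
    context distribution.  The expected count of word w_1..w_k is
    M * P(w_1..w_r) * prod_{i>r} P(w_i | w_{i-r}..w_{i-1}), where M is the
    total number of counted word positions.

    The default order is 2: a null of order r absorbs all compositional
    structure up to order r, so d2* can only expose similarity in structure
    *above* the null order, and r = 2 with k = 6 is the configuration the
    alignment-free host-prediction literature found most discriminative.
    Any r in [0, k-1] is accepted.
    """
    if markov_order is None:
        markov_order = max(0, min(DEFAULT_MARKOV_ORDER, k - 2))
    r = markov_order
    if not (0 <= r <= k - 1):
        raise ValueError(f"markov_order must be in [0, {k - 1}], got {r}")
    max_len = max((len(s) for s in genome.contigs.values()), default=0)
    if max_len < k:
        raise ValueError(
            f"genome {genome.genome_id!r}: no contig reaches word length k={k}"
        )

    counts = _count_both_strands(genome, k).astype(float)
    M = counts.sum()

    # order-r model from (r+1)-mer counts; marginalising keeps conditionals
    # exactly normalised.
    c_sub = _count_both_strands(genome, r + 1).astype(float) + pseudocount
    c_ctx = c_sub.reshape(4**r, 4).sum(axis=1)  # context counts
    trans = c_sub / np.repeat(c_ctx, 4)  # P(next | context), flat over 4**(r+1)
    ctx_prob = c_ctx / c_ctx.sum()  # P(context), flat over 4**r

    idx = np.arange(4**k, dtype=np.int64)
    prefix = idx >> (2 * (k - r))
    prob = ctx_prob[prefix].copy()
    gram_mask = 4 ** (r + 1) - 1
    for t in range(k - r):
        gram = (idx >> (2 * (k - 1 - (t + r)))) & gram_mask
        prob *= trans[gram]
    expected = M * prob
    return ONFProfile(genome.genome_id, k, r, counts, expected)


def d2star_dissimilarity(p: ONFProfile, q: ONFProfile) -> float:
    """d2*-based dissimilarity between two profiles, in [0, 1].

    With centred counts X~ = X - EX and Y~ = Y - EY,
    D2* = sum_w X~_w Y~_w / sqrt(EX_w EY_w) and the dissimilarity is
    (1 - D2* / (||X~/sqrt(EX)|| * ||Y~/sqrt(EY)||)) / 2.  Words with zero
    expected count in either profile are skipped (with pseudocounted models
    this does not occur).  Degenerate profiles with no centred signal map
    to 0.5 (no compositional information either way).
    """
    if p.k != q.k:
        raise ValueError(f"profile k mismatch: {p.k} vs {q.k}")
    mask = (p.expected > 0) & (q.expected > 0)
    xc = p.counts[mask] - p.expected[mask]
    yc = q.counts[mask] - q.expected[mask]
    ex = p.expected[mask]
    ey = q.expected[mask]
    num = float(np.sum(xc * yc / np.sqrt(ex * ey)))
    nx = float(np.sqrt(np.sum(xc * xc / ex)))
    ny = float(np.sqrt(np.sum(yc * yc / ey)))
    if nx == 0.0 or ny == 0.0:
        return 0.5
    d = 0.5 * (1.0 - num / (nx * ny))
    return float(min(1.0, max(0.0, d)))


def dissimilarity_matrix(
    viral_profiles: Iterable[ONFProfile],
    host_profiles: Iterable[ONFProfile],
) -> pd.DataFrame:
    """Full d2* dissimilarity matrix, viral genomes as rows, hosts as columns."""
    vps = list(viral_profiles)
    hps = list(host_profiles)
    data = [[d2star_dissimilarity(v, h) for h in hps] for v in vps]
    return pd.DataFrame(
        data,
        index=[v.genome_id for v in vps],
        columns=[h.genome_id for h in hps],
    )


def onf_screen(
    viral_profiles: Iterable[ONFProfile],
    host_profiles: Iterable[ONFProfile],
    max_dissimilarity: float = 0.13,
) -> list[PredictionSignal]:
    """Report virus-host pairs with dissimilarity strictly below threshold."""
    signals = []
    for v in viral_profiles:
        for h in host_profiles:
            d = d2star_dissimilarity(v, h)
            if d < max_dissimilarity:
                signals.append(
                    PredictionSignal(
                        viral_id=v.genome_id,
                        host_id=h.genome_id,
                        method=Method.ONF,
                        score=d,
                        detail=f"k={v.k};markov_order={v.markov_order}",
                    )
                )
    signals.sort(key=lambda s: (s.viral_id, s.host_id))
    return signals
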