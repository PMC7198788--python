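"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-offset string comparison,
dict-based word counting, explicit tabulation — and shares no code with the
library paths it validates.
"""

from __future__ import annotations

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def spacer_scan_oracle(
    spacer: str,
    genome_seq: str,
    circular: bool,
    min_identity: float = 0.95,
    max_snps: int = 2,
    window: int = 2,
) -> set[tuple[int, str, int]]:
    """Exhaustive sliding-window protospacer scan.

    Returns {(1-based start on forward strand, strand, n_mismatches)} for
    every qualifying ungapped full-length placement: overall identity >=
    min_identity, every mismatch within the first `window` positions of the
    spacer's 5' end, and at most max_snps mismatches.
    """
    L = len(spacer)
    clen = len(genome_seq)
    ext = genome_seq + (genome_seq[: L - 1] if circular and clen > L else "")
    found: set[tuple[int, str, int]] = set()
    for strand, pat in (("+", spacer), ("-", rc(spacer))):
        for off in range(len(ext) - L + 1):
            mm = 0
            ok = True
            for i in range(L):
                if ext[off + i] != pat[i]:
                    spacer_pos = i if strand == "+" else L - 1 - i
                    if spacer_pos >= window:
                        ok = False
                        break
                    mm += 1
                    if mm > max_snps:
                        ok = False
                        break
            if ok and (L - mm) / L >= min_identity:
                found.add((off % clen + 1, strand, mm))
    return found


def markov_expected_oracle(
    seq: str,
    k: int,
    r: int,
    circular: bool = False,
    pseudocount: float = 1.0,
) -> tuple[dict[str, float], dict[str, int]]:
    """Dict-based double-stranded word counts and order-r expected counts."""

    def words(s: str, m: int) -> list[str]:
        s2 = s + s[: m - 1] if circular and len(s) >= m else s
        return [
            s2[i : i + m]
            for i in range(len(s2) - m + 1)
            if "N" not in s2[i : i + m]
        ]

    def count_both(m: int) -> dict[str, int]:
        c = {"".join(w): 0 for w in product("ACGT", repeat=m)}
        for w in words(seq, m) + words(rc(seq), m):
            c[w] += 1
        return c

    kcounts = count_both(k)
    sub = {w: n + pseudocount for w, n in count_both(r + 1).items()}
    ctx = {"".join(w): 0.0 for w in product("ACGT", repeat=r)}
    for w, n in sub.items():
        ctx[w[:r]] += n
    total_ctx = sum(ctx.values())
    M = sum(kcounts.values())
    expected = {}
    for w in kcounts:
        p = ctx[w[:r]] / total_ctx if r > 0 else 1.0
        if r == 0:
            total1 = sum(sub.values())
            for i in range(k):
                p *= sub[w[i]] / total1
        else:
            for i in range(r, k):
                p *= sub[w[i - r : i + 1]] / ctx[w[i - r : i]]
        expected[w] = M * p
    return expected, kcounts


def profile_recount_oracle(
    gene_ids: list[str],
    hits: list[tuple[str, str, float, float, float]],
    taxonomy: dict[str, tuple[str, str]],
    target_phylum: str,
    max_evalue: float = 1e-10,
    min_identity: float = 30.0,
    min_bitscore: float = 50.0,
) -> tuple[int, int, int]:
    """Explicit recount of (n_genes, n_cellular, n_target).

    hits: (query, subject, identity, evalue, bitscore);
    taxonomy: subject -> (domain, phylum).  Restricted to cellular subjects
    before best-hit selection (bitscore desc, evalue asc, subject asc).
    """
    per_gene: dict[str, list[tuple[str, float, float]]] = {}
    for q, s, ident, ev, bs in hits:
        if q not in gene_ids:
            continue
        if not (ev < max_evalue and ident > min_identity and bs > min_bitscore):
            continue
        if taxonomy[s][0] != "cellular":
            continue
        per_gene.setdefault(q, []).append((s, ev, bs))
    n_cellular = 0
    n_target = 0
    for q, cand in per_gene.items():
        cand.sort(key=lambda t: (-t[2], t[1], t[0]))
        best_subject = cand[0][0]
        n_cellular += 1
        if taxonomy[best_subject][1] == target_phylum:
            n_target += 1
    return len(gene_ids), n_cellular, n_target


def contig_vote_oracle(
    best_hits: dict[str, tuple[str, float]],
    taxonomy: dict[str, tuple[str, str]],
    target_phylum: str,
    min_fraction: float = 0.8,
) -> tuple[float, float, str]:
    """Explicit bit-score tabulation: best_hits maps gene -> (subject, bs)."""
    total = 0.0
    target = 0.0
    for subject, bs in best_hits.values():
        domain, phylum = taxonomy[subject]
        if domain == "viral":
            continue
        total += bs
        if phylum == target_phylum:
            target += bs
    if total <= 0:
        return 0.0, 0.0, "unassigned"
    frac = target / total
    return total, target, ("target_phylum" if frac > min_fraction else "contaminant")
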