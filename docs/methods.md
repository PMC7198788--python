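# Methods

This note documents the models and procedures implemented in `maglink`, the
defaults and why they were chosen, what the synthetic fixture does and does
not emulate, and the numerical corner cases.

## Scope and data model

The toolkit links viral genomes to candidate host genomes from two kinds of
reference collection: isolate genomes ("refseq") and metagenome-assembled
genomes ("mag"). All sequence input is FASTA restricted to `ACGTN` after
uppercasing — other ambiguity codes are rejected rather than silently
remapped, because every downstream statistic treats `N` as
matches-nothing/count-nothing and a silent remap would bias identities.
All coordinates are 1-based inclusive, the blast-tabular convention.
Similarity searches are consumed, never executed: the 12-column
blast-tabular file is the integration boundary, so any aligner
(or none) can sit upstream.

## Nucleotide detectors

**CRISPR spacers.** A signal requires an ungapped full-length placement of
the spacer on either strand with (a) overall identity ≥ `min_identity`
(default 0.95), (b) every mismatch within the first `five_prime_window`
(default 2) positions of the spacer's 5′ end, and (c) at most
`max_5prime_snps` (default 2) mismatches. The published tolerance ("1–2
SNPs at the 5′ end") is ambiguous about whether additional mismatches are
allowed elsewhere; we implement the stricter reading (no mismatch outside
the 5′ window) and expose the window and counts as parameters. Matching is
ungapped because protospacers are contiguous samples of the viral genome.
Circular genomes are scanned with a wraparound suffix of length
spacer−1 so junction-spanning protospacers are found; reported start
positions are taken modulo the contig length. The detector is vectorised
(numpy sliding windows); an exhaustive per-offset scan serves as its
oracle in the tests and never shares code with it.

**tRNAs.** Only exact string equality of full sequences counts, as given
(no reverse-complement folding): upstream tRNA callers emit the coding
orientation, and requiring identity makes orientation handling moot for
true matches.

**Nucleotide homology.** Best hit is selected per (virus, host) *pair* —
not per virus overall — so one virus can be linked to several candidate
hosts; the pair's top-bitscore hit must exceed 70% identity (strict) over
at least 1000 bp (inclusive). Ties are broken by lower E-value, then
lexicographically smallest subject, everywhere in the toolkit, so results
are independent of input order.

## d2\* dissimilarity (alignment-free)

Counts are double-stranded: each k-mer and its reverse complement are
accumulated for every contig (no word spans a contig junction; circular
contigs wrap around), words containing `N` are skipped. The null model is
an order-r Markov chain fitted to the same genome from its (r+1)-mer
counts with a pseudocount of 1 on every word, which keeps all expected
counts positive on short sequences; context counts are obtained by
marginalising the (r+1)-mer table so the conditional distributions are
exactly normalised. Expected counts are M·P(w) with M the number of
counted word positions and P(w) the chain probability of the word. The
dissimilarity maps the normalised centred inner product to [0, 1]; 0 for
identical composition, 0.5 for unrelated sequences (verified: two i.i.d.
uniform 50-kb sequences average 0.499 over 20 pairs).

**Defaults: k = 6, r = 2.** The choice of r is not free: deviations from
an order-r null carry information only about structure of order > r, so a
null at the maximal r = k−2 explains away nearly everything the statistic
could use and leaves estimation noise (we measured virus–host vs
virus–decoy separations of 0.46 vs 0.48 at r = 4 on the fixture, against
0.31 vs 0.49 at r = 2). k = 6 with a low-order null is also the
configuration the alignment-free host-prediction literature found most
discriminative. Both parameters are configurable and recorded in each
signal's detail field so runs are self-describing.

The absolute screening threshold (default 0.13) is meaningful for
real-scale genomes (tens of kb to Mb); on the fixture's 5–9 kb toys the
same-model dissimilarity floor is ≈ 0.26–0.31, so fixture tests assert
*ranking* (true host nearest) rather than the absolute screen.

## Taxonomy validation and decontamination

Contigs flagged viral-like (interval categories 1–3) are removed from MAGs
before any evidence is drawn from them; provirus annotations (categories
4–6) mark regions, not whole contigs, and do not cause removal. For the
remaining contigs, genes' best protein hits (E-value < 10⁻¹⁰, identity
> 30%, bit score > 50 — all strict, matching the "<"/">" wording of the
thresholds) vote by bit score: the contig is accepted as target-phylum only
when the target's share of the summed best-hit bit score strictly exceeds
0.8. Genes without qualifying hits contribute nothing to the denominator
(the rule is defined over best-hit bit scores, not over genes); genes whose
best hit is viral are excluded from the vote by default since the
procedure targets cellular assignment (configurable).

## Homolog-proportion classifier

Per viral genome and reference collection, hits are filtered with the same
strict protein thresholds, hits to viral subjects are discarded *before*
best-hit selection (the statistic is defined among the most closely
matched **cellular** homologs, so a viral subject may not mask a cellular
one; an overall-best-hit mode exists but is off by default), and the best
cellular hit per gene yields three statistics: T/N (target homologs per
gene), T/C (target homologs per cellular homolog, 0 when C = 0) and T
itself. Criterion (iii) counts genes, not distinct subjects: each gene
contributes its single best hit.

**Calibration** sets each threshold to the maximum of the corresponding
statistic over negative-control profiles, with the count floored at 1.
Criteria are applied inclusively ("at least"), which creates one edge
case: a negative that simultaneously attains all three maxima would
classify itself positive. This is surfaced as a `CalibrationWarning`
rather than silently adjusted, because the remedy (a better negative set)
is a study-design decision. Databases are evaluated separately and
combined by union — a virus detected in only one reference collection is a
real detection, and collection-specific thresholds would be invalid for a
pooled statistic.

**Provirus / AMG attribution.** A target-phylum homolog is attributed to a
provirus when its reference gene is fully contained (start and end inside;
`mode="overlap"` relaxes this to any overlap) in a category-4/5/6 interval
on the same contig. The same containment operator against a user-supplied
gene list serves auxiliary-metabolic-gene attribution; no AMG detection is
performed.

## Integration and abundance

A virus predicted by several methods or paired with several hosts is one
prediction; per-pair detail stays in the signal list. The exclusion list is
an explicit input (curated false positives are expert judgment, not a
computation); excluded ids remain visible as flagged report rows.
FPKM = count / ((length/10³)·(library/10⁶)); relative abundance of a
genome set is its FPKM share of the total, so abundances over a partition
sum to 1.

## Synthetic fixture

One integer seed drives a named pseudo-random stream per file type, so
adding a generator never perturbs existing outputs and regeneration is
byte-identical. The default community is 6 hosts (4 target-phylum — two
"refseq" isolates, two MAGs, one of them multi-contig with a planted
viral-like contaminant contig — plus 2 compositionally distinct decoys)
and 8 viruses (4 positives, 4 negatives), ≈ 95 kb of sequence in total,
small enough that the full suite runs in seconds. Each host has its own
order-4 Markov model (AT-leaning targets, GC-leaning decoys, Dirichlet
transition rows around the base composition); positives are sampled from
their host's model, negatives from unrelated models.

Planted ground truth per detector: exact, 5′-SNP, minus-strand and
junction-spanning protospacers; identical 75-nt host/virus tRNA pairs;
1.2-kb exact homologous segments (one per positive, plus one between a
negative virus and the contaminant contig, which decontamination must
silence); protein hit tables realising exact per-class (target, cellular)
best-hit counts — positives above the calibration maxima by a margin
> 1/N, negatives below with the per-criterion maxima attained by distinct
negatives — including sub-threshold junk hits, lower-scoring decoy hits
and higher-scoring viral hits that must not mask cellular homologs;
provirus intervals covering half the target subjects plus one
boundary-straddling subject; and Poisson read counts with per-sample
totals as library sizes.

The nucleotide hit table is produced by an in-package seed-and-extend
finder for exact forward-strand segments (`naive_hit_search`) — a
synthetic hit generator for toy data, not an aligner; real analyses
consume externally produced hit files. The scramble control is an exact
dinucleotide-preserving (Altschul–Erikson) shuffle: same length and
(di)nucleotide counts, destroyed long-range homology, so alignment-based
detectors must go silent on scrambled genomes.

**What the fixture does not emulate** — and hence what passing tests do
not show about real data: gene content and genome architecture of real
phages, sequencing/assembly error, strain-level variation within spacers
beyond the planted SNPs, gapped homology, uneven MAG completeness, and
realistic E-value distributions. The fixture establishes correctness of
the decision rules and detectors under known ground truth, not field
performance.

## Problem sizes in the checks

The oracle-equivalence checks run the spacer scanner against an exhaustive
per-offset scan on randomized instances with genomes up to 10 kb (1,000
instances in the test suite, 300 in the acceptance script), the homolog
tabulation against an explicit recount on instances up to 50 genes, and
the Markov expected counts against dict-based enumeration on 200-nt
sequences; ONF host recovery uses 20 regenerated fixture replicates.

## Known limitations

Spacer scanning is exact-window based and does not model gapped or
truncated protospacer matches; tRNA matching has no tolerance at all (by
design); d2\* profiles hold dense 4^k vectors, fine for k ≤ 8; the
classifier inherits any taxonomic error in the subject-to-phylum map; and
negative-control calibration is only as good as the negative set — a
single negative yields degenerate thresholds equal to its own statistics
(warned).
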