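# maglink

**In silico virus–host linkage for uncultured viral genomes, using isolate
references and metagenome-assembled genomes (MAGs).**

Most environmental viruses assembled from viromes have no cultured relative,
so which microbe they infect must be inferred from genomic signals left by
the infection itself. `maglink` implements the standard nucleotide-level
detectors plus a calibrated protein-homology classifier for linking complete
environmental viral genomes (EVGs) to candidate host genomes — either
isolate genomes or MAGs binned from co-sampled metagenomes — with the
bookkeeping that makes MAG-based prediction trustworthy (viral-contig
removal and bit-score taxonomy validation of every implicated contig).

## What it computes

Four nucleotide-similarity detectors, each emitting `PredictionSignal`
records with method provenance:

1. **CRISPR spacer matching** — a host spacer aligning ungapped over its
   whole length to a viral genome (either strand, circular junctions
   included) with identity ≥ 95% and at most 2 SNPs confined to the
   spacer's 5′ end.
2. **tRNA matching** — only a perfect match (100% length, 100% identity)
   between a host and a viral tRNA counts.
3. **Filtered nucleotide homology** — per virus–host pair, the top-bitscore
   hit of an externally produced blast-tabular file, kept when identity
   > 70% over ≥ 1000 bp. The toolkit never runs an aligner; hit files are
   the integration boundary.
4. **Oligonucleotide-frequency (ONF) dissimilarity** — the alignment-free
   d2\* statistic on double-stranded k-mer counts X centred by an order-r
   Markov expectation fitted to the same genome:

   D₂\* = Σ_w X̃_w Ỹ_w / √(EX_w EY_w),  d = ½ (1 − D₂\*/(‖X̃/√EX‖·‖Ỹ/√EY‖))

   with k = 6, r = 2 by default; pairs with d < 0.13 are screened in.

The package's centrepiece is the **homolog-proportion classifier**: for a
viral genome with N genes, let C be the number whose best qualifying
protein hit (E-value < 10⁻¹⁰, identity > 30%, bit score > 50, viral
subjects excluded) is to a cellular organism, and T the number whose best
cellular hit is in the target phylum. The three statistics T/N, T/C and T
are thresholded by **negative-control calibration** — each cutoff is the
maximum observed among viruses known not to infect the target — and a
virus passing all three criteria (inclusive, "at least") in at least one
reference collection is called a putative target-phylum virus. Shared
homologs located inside annotated provirus intervals of the reference
genome are attributed to integrated viruses.

Around these: MAG decontamination (drop viral-like contigs, categories
1–3; accept a contig as target-phylum only when > 80% of its genes'
summed best-hit bit score votes for the target), signal merging and
cross-tabulation, exclusion lists, and FPKM abundance summaries.

A first-class synthetic-fixture generator (`maglink.synthetic_fixtures`)
builds a seeded toy community with planted ground-truth links for every
detector, so the entire stack is testable offline.

## Worked example

```bash
python examples/homolog_classifier.py
```

```
refseq: calibrated thresholds  prop_of_genes>=0.150  prop_of_cellular>=0.333  count>=3
mag: calibrated thresholds  prop_of_genes>=0.100  prop_of_cellular>=0.333  count>=2

verdicts (three inclusive criteria, union across reference collections):
  VPOS_1: genes=20 cellular=14 target=8 -> Bacteroidetes virus ['mag', 'refseq']
  ...
  VNEG_1: genes=20 cellular=18 target=3 -> not called []

VPOS_1: 5 of 8 target-phylum homologs map inside annotated provirus regions ...
```

The thresholds are the maxima over the four negative-control viruses; every
planted Bacteroidetes virus clears all three criteria in both reference
collections and every negative fails at least one. Other examples cover the
spacer screen (`crispr_spacer_screen.py`), alignment-free matching
(`onf_host_matching.py`, where each planted virus's lowest d2\* lands on its
true host at d ≈ 0.26–0.31 while unrelated pairs sit near 0.5), MAG
decontamination (`mag_decontamination.py`) and signal integration with
FPKM abundance (`integrate_and_abundance.py`).

A thin CLI mirrors the library: `maglink crispr|trna|blastn-filter|onf|
validate-contigs|profile|calibrate|call|report|make-fixture` (see
`maglink --help`).

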