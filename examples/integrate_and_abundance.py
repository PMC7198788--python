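"""Merge detector signals, cross-tabulate them and summarise abundance.

Runs all three alignment-based detectors on the synthetic community,
collapses signals to one prediction per virus, tabulates signal counts by
method and reference class, and computes FPKM-normalised relative
abundance of the predicted virus set from the read-count table.
"""

from maglink import (
    crosstab,
    filter_blastn_signals,
    fpkm,
    match_spacers,
    match_trnas,
    merge_signals,
    relative_abundance,
    retained,
)
from maglink.synthetic_fixtures import generate_fixture

fx = generate_fixture(seed=7)
contig_of = {cid: h.genome_id for h in fx.hosts for cid in h.contig_ids}
kept = {cid for h in fx.decontaminated_hosts() for cid in h.contig_ids}

signals = (
    match_spacers(fx.spacers, fx.viruses)
    + match_trnas(fx.host_trnas, fx.viral_trnas)
    + filter_blastn_signals(
        [h for h in fx.nucleotide_hits if h.subject_id in kept],
        subject_genome=contig_of,
    )
)

table = crosstab(signals, fx.host_source)
print("signals by reference class and method:")
print(table.to_string())

reports = retained(merge_signals(signals))
print(f"\n{len(signals)} signals collapse to {len(reports)} predicted viruses:")
for r in reports:
    print(f"  {r.viral_id}: methods={sorted(r.methods)} hosts={sorted(r.host_ids)}")

lengths = {g.genome_id: len(g) for g in [*fx.viruses, *fx.hosts]}
table_fpkm = fpkm(fx.read_counts, lengths, fx.library_sizes)
ra = relative_abundance(table_fpkm, [r.viral_id for r in reports])
print("\nrelative abundance of the predicted virus set per virome sample:")
for sample, frac in ra.items():
    print(f"  {sample}: {100 * frac:.1f}%")
print(
    "\nFPKM normalises read counts by genome length and sequencing depth, so "
    "these percentages are depth-independent shares of the whole community."
)
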