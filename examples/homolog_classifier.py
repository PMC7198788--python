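"""Calibrated homolog-proportion host classification.

The share of a viral genome's proteins whose closest cellular homolog
belongs to a phylum is a host signal.  Thresholds are calibrated as the
maximum of each statistic over negative-control viruses (known not to
infect the target), then every virus passing all three criteria —
proportion of genes, proportion of cellular homologs, absolute homolog
count — in at least one reference collection is called a putative
target-phylum virus.
"""

from maglink import (
    attribute_provirus_origin,
    build_homolog_profile,
    calibrate_thresholds,
    classify_viral_genome,
)
from maglink.synthetic_fixtures import generate_fixture

fx = generate_fixture(seed=7)

profiles, thresholds = {}, {}
for db in fx.manifest.params.databases:
    profiles[db] = {
        v.genome_id: build_homolog_profile(
            v.genome_id, fx.viral_genes[v.genome_id], fx.protein_hits[db],
            fx.taxonomy, fx.target_phylum, db,
        )
        for v in fx.viruses
    }
    thresholds[db] = calibrate_thresholds([profiles[db][n] for n in fx.negative_ids])
    t = thresholds[db]
    print(
        f"{db}: calibrated thresholds  prop_of_genes>={t.min_prop_of_genes:.3f}  "
        f"prop_of_cellular>={t.min_prop_of_cellular:.3f}  count>={t.min_count}"
    )

print("\nverdicts (three inclusive criteria, union across reference collections):")
for vid in fx.positive_ids + fx.negative_ids:
    res = classify_viral_genome({db: profiles[db][vid] for db in profiles}, thresholds)
    p = profiles["refseq"][vid]
    print(
        f"  {vid}: genes={p.n_genes} cellular={p.n_cellular} target={p.n_target} "
        f"-> {'Bacteroidetes virus' if res.verdict else 'not called'} "
        f"{list(res.passing_databases)}"
    )

p = attribute_provirus_origin(
    profiles["refseq"]["VPOS_1"], fx.taxonomy, fx.target_phylum,
    fx.provirus_intervals, fx.subject_genes["refseq"],
)
print(
    f"\nVPOS_1: {p.n_provirus_origin} of {p.n_target} target-phylum homologs map "
    "inside annotated provirus regions of the reference genomes — shared genes "
    "that most likely entered the host genome as an integrated virus."
)
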