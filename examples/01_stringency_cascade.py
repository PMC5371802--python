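"""Run the full stringency cascade on a simulated triplicate amplicon table.

Builds a mock community, simulates three PCR replicates with singleton
artefacts and terrestrial contaminants, and prints phylotype/read retention
at every level from no filter (T0) to ten-copies-in-all-replicates (T10-R2).
"""

from phylofilt import (
    CommunitySpec,
    NoiseSpec,
    retention_report,
    run_cascade,
    sample_community,
    simulate_otu_tables,
)

community = sample_community(CommunitySpec(n_taxa=100, seed=7))
table, truth = simulate_otu_tables(community, NoiseSpec(depth=20_000, seed=7))

print(f"simulated OTU table: {len(table)} OTUs over {table.n_replicates} replicates")
print(f"  true taxa: {len(truth.true_otu_ids)}, artefacts: {len(truth.artefact_otu_ids)}, "
      f"contaminants: {len(truth.contaminant_otu_ids)}\n")

report = retention_report(run_cascade(table))
print(report.as_frame().to_string())
print(
    "\nPhylotype counts fall steeply across the cascade while read totals "
    "barely move: the filters remove many rare (mostly artefactual) "
    "phylotypes that carry almost no read mass."
)
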