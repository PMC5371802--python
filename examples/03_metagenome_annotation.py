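"""Annotate a simulated metagenome fraction by BLAST top hit.

Simulates a tabular hit file with a bacterial-dominated superkingdom
mixture, gates hits at e-value 1e-5, selects the top hit per query and
prints the resulting superkingdom profile plus a Krona text export.
"""

import io

from phylofilt import (
    CommunitySpec,
    MetagenomeSpec,
    annotate,
    parse_blast_tabular,
    sample_community,
    simulate_metagenome_hits,
    superkingdom_profile,
    top_hit_per_query,
    write_krona_text,
)

community = sample_community(CommunitySpec(n_taxa=80, seed=21))
hits_text, taxmap, _truth = simulate_metagenome_hits(
    community, MetagenomeSpec(n_queries=3000, seed=21)
)

gated = parse_blast_tabular(io.StringIO(hits_text), max_evalue=1e-5)
print(f"hits retained: {len(gated.hits)}  discarded by e-value gate: {gated.n_discarded}")

annotation = annotate(top_hit_per_query(gated.hits), taxmap)
profile = superkingdom_profile(annotation)
print("superkingdom profile (% of annotated queries):")
for category, pct in profile.items():
    print(f"  {category:<10} {pct:6.2f}")

krona = write_krona_text(
    [(1, lin) for lin in annotation.lineages().values()][:5]
)
print("\nfirst Krona lines:\n" + krona)
print(
    "The profile mirrors the configured mixture: mostly Bacteria with a "
    "sizeable 'unknown' slice from subjects absent from the taxonomy map."
)
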