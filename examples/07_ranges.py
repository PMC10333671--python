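"""Distributional ranges and partner-limitation screening.

Measures each species' and phylogroup's range as the maximum great-circle
distance between occupied forests, regresses species range on regional
partner richness, and flags candidate partner-limited distributions.
"""

from symbiospec import CommunityConfig, build_table, generate_community
from symbiospec.pipeline import delimit_alignment, relabel_records
from symbiospec.ranges import partner_limitation, range_table, richness_vs_range_lm

community = generate_community(CommunityConfig(seed=1))
_, _, partition = delimit_alignment(community.alignment)
records = relabel_records(community.records, partition.assignments)
table = build_table(records)
coords = {f.forest: (f.latitude, f.longitude) for f in community.forests}

ranges = range_table(table, coords)
species = ranges[ranges["entity_type"] == "species"]
phylo = ranges[ranges["entity_type"] == "phylogroup"]
lm = richness_vs_range_lm(table, coords, min_regional=10)
flags = partner_limitation(table, coords)

print(f"species ranges:    {species['range_km'].min():.0f} - "
      f"{species['range_km'].max():.0f} km")
print(f"phylogroup ranges: {phylo['range_km'].min():.0f} - "
      f"{phylo['range_km'].max():.0f} km")
print(f"range ~ partner richness: R2 = {lm['r_squared']:.3f}, "
      f"p = {lm['p_value']:.3f} (n = {lm['n']})")
print(f"potentially partner-limited species: "
      f"{int(flags['potentially_limited'].sum())}")
print(f"reciprocal exclusive pairs: {int(flags['reciprocal_match'].sum())}")
# A weak regression means wide-ranging lichens get there either by using
# many partners or by using a few widely distributed ones.
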