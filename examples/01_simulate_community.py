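"""Simulate a small SAG community and inspect its ground truth.

Each SAG is a partial assembly of one (or, for planted co-sorts, two)
synthetic genomes; the truth record is what downstream detectors are
later scored against.
"""

from sagkit import simulate_community

community = simulate_community(n_taxa=8, n_sags=24, cosort_rate=0.1, seed=9)

print(f"{len(community.taxa)} taxa, {len(community.sags)} SAGs")
for g in community.taxa[:4]:
    p = g.profile
    print(f"  {p.taxon_id}: code {p.genetic_code}, "
          f"target density {p.target_coding_density:.2f}, "
          f"ETC complexes {sorted(p.etc_complement) or 'none'}")

n_cosort = sum(s.truth["admixture"] for s in community.sags)
comps = [s.truth["completeness"][0] for s in community.sags]
print(f"planted co-sorts: {n_cosort}/{len(community.sags)}")
print(f"mean completeness: {sum(comps)/len(comps):.2f}")
# A co-sort is a sorting well that received two cells: its assembly mixes
# two genomes, which the marker and 16S detectors should later flag.
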