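"""Profile respiratory coding potential of contrasting genomes.

Counts accepted KO hits per electron-transport complex (score >= 50% of
the family threshold), detects oxygen-reductase homologs by local
alignment with an e-value cutoff of 1e-10, and reports the EC-class-1
(oxidoreductase) fraction of all proteins.
"""

from sagkit import genome_energy_profile, make_taxon_profile
from sagkit.community import synthesize_genome

for phylum, style in [("Other-Bacteria", "standard"),
                      ("Patescibacteria", "patesci_like"),
                      ("DPANN", "dpann_like")]:
    g = synthesize_genome(make_taxon_profile(phylum, style, 11), 11)
    ep = genome_energy_profile(g.annotations, g.aa_seqs,
                               genome_id=g.profile.taxon_id)
    print(f"{g.profile.taxon_id}:")
    print(f"  complexes {dict(ep.complex_counts)} "
          f"complete ETC: {ep.complete_etc}")
    print(f"  oxygen reductases: "
          f"{[(h.family, h.affinity) for h in ep.o2red_hits]}")
    print(f"  EC1 fraction: {ep.ec1_fraction:.2f}%")
# Candidate-phyla genomes carry no ETC complexes and no oxygen
# reductases, and their oxidoreductase fraction is several-fold lower -
# the coding signature of a fermentative, non-respiring lifestyle.
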