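"""Select the genetic code of a genome by comparing total CDS length.

A genome that reads TGA as sense (translation table 25, as in
Gracilibacteria/SR1) fragments badly when called with the standard table
11, so its table-25 total CDS is much larger; a standard genome shows
only the caller's small systematic table-25 excess.
"""

import dataclasses

from sagkit import coding_density, make_taxon_profile, synthesize_genome

for code in (11, 25):
    prof = make_taxon_profile("Patescibacteria", "patesci_like", seed=5)
    prof = dataclasses.replace(prof, genetic_code=code, genome_length=120_000)
    genome = synthesize_genome(prof, seed=6)
    res = coding_density({"g": genome.sequence})
    ratio = res.total_cds_25 / res.total_cds_11
    print(f"true code {code}: total_cds_11={res.total_cds_11:,} "
          f"total_cds_25={res.total_cds_25:,} ratio={ratio:.2f} "
          f"-> chosen table {res.chosen_table}")
# The ratio stays below 1.5 for standard-code genomes and jumps to ~2-3
# for genuine table-25 genomes, which is what the selection rule keys on.
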