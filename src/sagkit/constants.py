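"""Shared controlled vocabularies for the SAG analysis toolkit.

These are the fixed label sets the rest of the package assumes: the 25
COG functional categories, a 56-protein universal single-copy marker set,
translation-table stop/start codons, and a small default map from KEGG
orthology identifiers to respiratory-chain complexes.
"""

from __future__ import annotations

# The 25 COG functional category letters, in conventional display order.
COG_CATEGORIES: tuple[str, ...] = (
    "J", "A", "K", "L", "B", "D", "Y", "V", "T", "M", "N", "Z", "W",
    "U", "O", "C", "G", "E", "F", "H", "I", "P", "Q", "R", "S",
)

# Universal single-copy marker protein set used for completeness /
# contamination estimation. 56 labels, mirroring the size of the standard
# concatenated-phylogeny marker panel; synthetic stand-in identifiers.
MARKER_SET: tuple[str, ...] = tuple(f"SCP{i:03d}" for i in range(1, 57))

# Stop-codon sets per translation table. Code 11 is the standard
# bacterial/archaeal table; code 25 reassigns TGA from stop to sense
# (glycine), as in Gracilibacteria/SR1.
STOP_CODONS: dict[int, frozenset[str]] = {
    11: frozenset({"TAA", "TAG", "TGA"}),
    25: frozenset({"TAA", "TAG"}),
}
START_CODON = "ATG"

ETC_COMPLEXES: tuple[str, ...] = ("I", "II", "III", "IV")

# Default KO -> respiratory complex map. A deliberately small, clearly
# labeled configuration default (subunits of NADH dehydrogenase, succinate
# dehydrogenase, cytochrome bc1, and terminal oxidases); callers may pass
# their own map.
DEFAULT_COMPLEX_MAP: dict[str, str] = {
    # Complex I: NADH:quinone oxidoreductase subunits (nuoA-N)
    "K00330": "I", "K00331": "I", "K00332": "I", "K00333": "I",
    "K00334": "I", "K00335": "I", "K00336": "I", "K00337": "I",
    "K00338": "I", "K00339": "I", "K00340": "I", "K00341": "I",
    "K00342": "I", "K00343": "I",
    # Complex II: succinate dehydrogenase (sdhABCD)
    "K00234": "II", "K00235": "II", "K00236": "II", "K00237": "II",
    # Complex III: cytochrome bc1 (Rieske, cyt b, cyt c1)
    "K00411": "III", "K00412": "III", "K00413": "III",
    # Complex IV: terminal reductases (cytochrome c oxidase, bd oxidase)
    "K02274": "IV", "K02275": "IV", "K02276": "IV",
    "K00425": "IV", "K00426": "IV",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_PHYLA: tuple[str, ...] = (
    "Patescibacteria", "DPANN", "Other-Bacteria", "Other-Archaea",
)
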