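"""Synthetic single-amplified-genome (SAG) community generator.

Real SAG surveys sequence thousands of individually sorted, whole-genome
amplified cells; each assembly recovers a partial genome, and occasionally
a sorting well receives two cells ("co-sort"), producing a chimeric
assembly. This module generates communities with known ground truth so
every downstream stage — ORF calling and genetic-code selection, 16S
detection/classification, co-sort flagging, respiratory-gene census, and
COG ordination — can be validated end to end:

* taxa with a phylum label, a genetic code (11 or 25), a target coding
  density, a 56-marker complement, a divergent 16S gene, COG/EC/KO gene
  complements, and electron-transport-chain / oxygen-reductase content;
* genomes realizing those complements as ATG-initiated ORFs separated by
  random intergenic sequence;
* SAG assemblies sampled from one or two genomes at a chosen completeness,
  with annotation tables subset to fully retained genes and a truth record
  per SAG.

All randomness flows from one integer seed, hierarchically split per
taxon/SAG, so any subset regenerates identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .constants import (
    AMINO_ACIDS,
    COG_CATEGORIES,
    DEFAULT_COMPLEX_MAP,
    DEFAULT_PHYLA,
    MARKER_SET,
    STOP_CODONS,
)

__all__ = [
    "TaxonProfile",
    "GeneFeature",
    "SyntheticGenome",
    "SagAssembly",
    "Community",
    "child_seed",
    "evolve_ssu",
    "make_reference_taxonomy",
    "make_taxon_profile",
    "synthesize_genome",
    "sample_sag",
    "simulate_community",
]

_BASES = np.array(list("ACGT"))

STYLES = ("patesci_like", "dpann_like", "standard", "symbiont_like")


def child_seed(seed: int, *tokens) -> int:
    """Derive a stable sub-stream seed from a parent seed and tokens."""
    h = hashlib.blake2b(repr((int(seed),) + tokens).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def _rng(seed, *tokens) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(child_seed(seed, *tokens))


# ---------------------------------------------------------------------------
# profiles

@dataclass
class TaxonProfile:
    """Generative ground truth for one taxon."""

    taxon_id: str
    domain: str                      # Bacteria | Archaea
    phylum: str
    genetic_code: int                # 11 | 25
    target_coding_density: float
    genome_length: int
    marker_complement: tuple[str, ...]
    ssu_ref: str
    cog_distribution: np.ndarray     # probability over the 25 COG categories
    ec1_rate: float
    etc_complement: dict[str, tuple[str, ...]]  # complex -> subunit KO ids
    o2red_genes: tuple[dict, ...]    # {family, affinity}
    style: str = "standard"
    diameter_median_um: float = 0.8

    def __post_init__(self):
        if self.genetic_code not in (11, 25):
            raise ValueError("genetic_code must be 11 or 25")
        if not 0.0 <= self.ec1_rate <= 1.0:
            raise ValueError("ec1_rate outside [0, 1]")
        if not 0.5 <= self.target_coding_density <= 1.0:
            raise ValueError("target_coding_density outside [0.5, 1.0]")
        if len(self.ssu_ref) < 1200:
            raise ValueError("ssu_ref shorter than 1,200 nt")
        s = float(np.sum(self.cog_distribution))
        if abs(s - 1.0) > 1e-9:
            raise ValueError("cog_distribution must sum to 1")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def evolve_ssu(ref: str, divergence: float, seed) -> str:
    """Mutate a 16S reference by i.i.d. per-site substitution.

    Each site independently substitutes to one of the three other bases
    with probability ``divergence`` (single-hit model, no indels), so the
    expected observed difference fraction equals ``divergence``.
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence outside [0, 0.3]")
    if divergence == 0.0:
        return ref
    rng = _rng(seed, "ssu", len(ref))
    arr = np.array(list(ref))
    hit = rng.random(arr.size) < divergence
    idx = np.flatnonzero(hit)
    if idx.size:
        cur = arr[idx]
        # pick uniformly among the three non-identical bases
        offs = rng.integers(1, 4, size=idx.size)
        base_idx = np.searchsorted(_BASES, cur)
        arr[idx] = _BASES[(base_idx + offs) % 4]
    return "".join(arr)


def make_reference_taxonomy(
    phyla=DEFAULT_PHYLA, seed: int = 0, length: int = 1500,
    radiation: float = 0.12,
) -> dict[str, str]:
    """Build one 16S reference per phylum, mutually divergent.

    Each phylum reference evolves independently from a common root at
    ``radiation`` substitutions/site, giving expected pairwise divergence
    of roughly twice that.
    """
    root = random_sequence(length, _rng(seed, "ssu-root"))
    return {
        p: evolve_ssu(root, radiation, child_seed(seed, "phylum-ref", p))
        for p in phyla
    }


_DEF_REF_CACHE: dict = {}


def default_reference_taxonomy(phyla=DEFAULT_PHYLA) -> dict[str, str]:
    """The packaged synthetic phylum-level 16S reference panel."""
    key = tuple(phyla)
    if key not in _DEF_REF_CACHE:
        _DEF_REF_CACHE[key] = make_reference_taxonomy(phyla, seed=0)
    return _DEF_REF_CACHE[key]


# baseline COG category weights (loosely typical prokaryote proportions)
_BASE_COG_W = {
    "J": 6, "A": 0.3, "K": 6, "L": 6, "B": 0.3, "D": 1.5, "Y": 0.1,
    "V": 1.5, "T": 4, "M": 5, "N": 1.5, "Z": 0.1, "W": 0.3, "U": 2,
    "O": 4, "C": 6, "G": 6, "E": 8, "F": 2.5, "H": 4.5, "I": 3.5,
    "P": 5, "Q": 2, "R": 10, "S": 9,
}

_STYLE_CONF = {
    # cog_shift multiplies baseline weights before normalization
    "patesci_like": dict(
        density=0.90, ec1=0.01, etc=(), o2red=(), diameter=0.2,
        genome_length=150_000,
        cog_shift={"C": 0.25, "E": 0.3, "H": 0.3, "P": 0.3, "D": 2.0, "O": 1.6},
    ),
    "dpann_like": dict(
        density=0.90, ec1=0.01, etc=(), o2red=(), diameter=0.2,
        genome_length=150_000,
        cog_shift={"C": 0.25, "E": 0.3, "H": 0.3, "P": 0.3, "B": 3.0,
                   "K": 1.5, "S": 1.4},
    ),
    "standard": dict(
        density=0.90, ec1=0.05, etc=("I", "II", "III", "IV"),
        o2red=(
            {"family": "HCO_A", "affinity": "low"},
            {"family": "bd", "affinity": "high"},
        ),
        diameter=0.8, genome_length=300_000, cog_shift={},
    ),
    "symbiont_like": dict(
        density=0.75, ec1=0.03, etc=("IV",),
        o2red=({"family": "bd", "affinity": "high"},),
        diameter=0.6, genome_length=200_000,
        cog_shift={"C": 0.6, "E": 0.6},
    ),
}


def _complex_subunits() -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    for ko, cx in DEFAULT_COMPLEX_MAP.items():
        out.setdefault(cx, []).append(ko)
    return {cx: tuple(sorted(kos)) for cx, kos in out.items()}


def make_taxon_profile(
    phylum: str,
    style: str,
    seed: int,
    taxon_id: str | None = None,
    phylum_refs: dict[str, str] | None = None,
) -> TaxonProfile:
    """Draw a taxon profile for a phylum under a style preset.

    Styles encode the contrasts the downstream analyses look for:
    ``patesci_like``/``dpann_like`` deplete COG categories C/E/H/P, carry
    no electron-transport complexes or oxygen reductases, and have small
    cells; ``patesci_like`` taxa use translation table 25 half the time.
    ``symbiont_like`` lowers coding density (recent gene loss leaves
    pseudogenized intergenic DNA). Deterministic for (phylum, style, seed).
    """
    if style not in _STYLE_CONF:
        raise ValueError(f"unknown style {style!r}; expected one of {STYLES}")
    conf = _STYLE_CONF[style]
    rng = _rng(seed, "profile", phylum, style)
    if taxon_id is None:
        taxon_id = f"{phylum}_{style}_{seed}"
    if phylum_refs is None:
        phyla = DEFAULT_PHYLA if phylum in DEFAULT_PHYLA else DEFAULT_PHYLA + (phylum,)
        phylum_refs = default_reference_taxonomy(phyla)
    domain = "Archaea" if phylum in ("DPANN", "Other-Archaea") else "Bacteria"
    if style == "patesci_like":
        code = 25 if rng.random() < 0.5 else 11
    else:
        code = 11
    density = float(np.clip(rng.normal(conf["density"], 0.015), 0.55, 0.97))
    w = np.array([_BASE_COG_W[c] * conf["cog_shift"].get(c, 1.0)
                  for c in COG_CATEGORIES])
    w = w / w.sum()
    cog = rng.dirichlet(w * 400.0)
    cog = cog / cog.sum()
    subunits = _complex_subunits()
    etc = {cx: subunits[cx] for cx in conf["etc"]}
    ssu = evolve_ssu(phylum_refs[phylum], 0.02, _rng(seed, "taxon-ssu", taxon_id))
    return TaxonProfile(
        taxon_id=taxon_id,
        domain=domain,
        phylum=phylum,
        genetic_code=code,
        target_coding_density=density,
        genome_length=conf["genome_length"],
        marker_complement=MARKER_SET,
        ssu_ref=ssu,
        cog_distribution=cog,
        ec1_rate=float(np.clip(rng.normal(conf["ec1"], conf["ec1"] * 0.2),
                               0.0, 1.0)),
        etc_complement=etc,
        o2red_genes=tuple(dict(g) for g in conf["o2red"]),
        style=style,
        diameter_median_um=conf["diameter"],
    )


# ---------------------------------------------------------------------------
# genome synthesis

@dataclass(frozen=True)
class GeneFeature:
    """One placed feature in genome (later: contig) coordinates."""

    protein_id: str
    kind: str            # marker | etc | o2red | filler | ssu
    start: int
    end: int             # half-open, includes the stop codon for CDS
    strand: str
    contig_id: str = ""


@dataclass
class SyntheticGenome:
    profile: TaxonProfile
    sequence: str
    annotations: list[dict]          # AnnotationTable rows (truth)
    gene_map: list[GeneFeature]
    aa_seqs: dict[str, str] = field(default_factory=dict)


_CODON_STRS = np.array(
    ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
)
_FWD11 = CodonTable.unambiguous_dna_by_id[11].forward_table
_BACK: dict[str, list[str]] = {}
for _codon, _aa in _FWD11.items():
    _BACK.setdefault(_aa, []).append(_codon)


def _sense_codon_ids(table: int, allow_tga: bool) -> np.ndarray:
    banned = set(STOP_CODONS[table]) | {"ATG"}
    if table == 25 and not allow_tga:
        banned.add("TGA")
    return np.array([i for i, c in enumerate(_CODON_STRS) if c not in banned])


def _random_cds(n_codons: int, table: int, rng, use_tga: bool = False) -> str:
    """Random CDS: ATG + (n_codons-2) sense codons + stop, no internal stop.

    For a table-25 gene with ``use_tga``, TGA is included in the sense
    pool at elevated frequency and at least one TGA is guaranteed.
    """
    body_n = n_codons - 2
    pool = _sense_codon_ids(table, allow_tga=False)
    ids = pool[rng.integers(0, pool.size, size=body_n)]
    if table == 25 and use_tga:
        tga = int(np.flatnonzero(_CODON_STRS == "TGA")[0])
        hit = rng.random(body_n) < 0.04
        if not hit.any():
            hit[rng.integers(0, body_n)] = True
        ids[hit] = tga
    stops = sorted(STOP_CODONS[table])
    stop = stops[rng.integers(0, len(stops))]
    return "ATG" + "".join(_CODON_STRS[ids]) + stop


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def translate(nt: str, table: int) -> str:
    """Translate a CDS (ATG..stop) to a peptide; TGA is Gly under code 25."""
    aa = []
    stops = STOP_CODONS[table]
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in stops:
            break
        if codon == "TGA":      # table 25 sense reassignment
            aa.append("G")
        else:
            aa.append(_FWD11.get(codon, "X"))
    return "".join(aa)


def _backtranslate(aa: str, rng, table: int) -> str:
    """Back-translate a peptide (without leading M) to ATG + codons + stop."""
    codons = ["ATG"] + [
        _BACK[a][int(rng.integers(0, len(_BACK[a])))] for a in aa
    ]
    stops = sorted(STOP_CODONS[table])
    return "".join(codons) + stops[int(rng.integers(0, len(stops)))]


def random_peptide(length: int, rng) -> str:
    aa = np.array(list(AMINO_ACIDS))
    return "".join(aa[rng.integers(0, 20, size=length)])


def mutate_peptide(ref: str, rate: float, rng) -> str:
    aa = np.array(list(ref))
    hit = rng.random(aa.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        alphabet = np.array(list(AMINO_ACIDS))
        aa[idx] = alphabet[rng.integers(0, 20, size=idx.size)]
    return "".join(aa)


def _draw_gene_len(rng, mean_codons: int = 300, min_codons: int = 100) -> int:
    n = int(rng.lognormal(np.log(mean_codons), 0.35))
    return max(min_codons, n)


def synthesize_genome(profile: TaxonProfile, seed: int) -> SyntheticGenome:
    """Realize a profile as a genome with truth annotations and gene map.

    Genes are ATG-initiated ORFs terminated by the stop set of the
    taxon's genetic code; for table-25 genomes ~60% of CDS carry at least
    one in-frame TGA, so standard-table calling fragments them. One copy
    of each marker, each ETC subunit KO, and each oxygen-reductase gene is
    embedded, plus filler CDS up to the target coding density, separated
    by uniform-random intergenic sequence. The embedded 16S equals the
    profile's reference (non-coding). Raises if the genome length cannot
    fit the requested complements.
    """
    from .energy import reference_o2red_db  # local import to avoid cycle

    rng = _rng(seed, "genome", profile.taxon_id)
    code = profile.genetic_code
    L = profile.genome_length

    plan: list[tuple[str, str, str | None, str | None]] = []
    # (kind, protein_id, marker_id, ko_id)
    for m in profile.marker_complement:
        plan.append(("marker", f"{profile.taxon_id}|{m}", m, None))
    for cx, kos in sorted(profile.etc_complement.items()):
        for ko in kos:
            plan.append(("etc", f"{profile.taxon_id}|{ko}", None, ko))
    o2refs = reference_o2red_db()
    o2_picks = []
    for i, g in enumerate(profile.o2red_genes):
        fam = [r for r in o2refs if r.family == g["family"]]
        ref = fam[rng.integers(0, len(fam))]
        o2_picks.append((g, ref))
        plan.append(("o2red", f"{profile.taxon_id}|o2red{i}", None, None))

    pieces: dict[str, str] = {}
    aa_seqs: dict[str, str] = {}
    o2_i = 0
    for kind, pid, marker, ko in plan:
        if kind == "o2red":
            g, ref = o2_picks[o2_i]
            o2_i += 1
            # keep the initial Met; diverge the rest at ~10% of residues
            pep = "M" + mutate_peptide(ref.sequence[1:], 0.10, rng)
            nt = _backtranslate(pep[1:], rng, code)
        else:
            n = _draw_gene_len(rng, 300 if kind == "marker" else 310)
            use_tga = code == 25 and rng.random() < 0.6
            nt = _random_cds(n, code, rng, use_tga=use_tga)
        pieces[pid] = nt
    required = sum(len(s) for s in pieces.values())
    target_coding = int(profile.target_coding_density * L)
    ssu_len = len(profile.ssu_ref)
    if required + ssu_len + 200 > L:
        raise ValueError(
            f"genome_length {L} too small for requested complements "
            f"({required + ssu_len} nt required)"
        )
    fillers: list[tuple[str, str, str | None, str | None]] = []
    i = 0
    while required < target_coding - 450:
        n = _draw_gene_len(rng)
        if required + 3 * n > target_coding:
            n = max(100, (target_coding - required) // 3)
        pid = f"{profile.taxon_id}|g{i:05d}"
        use_tga = code == 25 and rng.random() < 0.6
        nt = _random_cds(n, code, rng, use_tga=use_tga)
        pieces[pid] = nt
        fillers.append(("filler", pid, None, None))
        required += len(nt)
        i += 1
    plan += fillers

    order = rng.permutation(len(plan))
    laid = [plan[j] for j in order]
    # insert the 16S at a random slot
    ssu_slot = int(rng.integers(0, len(laid) + 1))

    intergenic_total = L - required - ssu_len
    n_gaps = len(laid) + 2
    gap_sizes = rng.multinomial(intergenic_total, np.ones(n_gaps) / n_gaps)

    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    items: list[tuple] = []
    for j, item in enumerate(laid):
        if j == ssu_slot:
            items.append(("ssu",))
        items.append(item)
    if ssu_slot == len(laid):
        items.append(("ssu",))
    for j, item in enumerate(items):
        gap = int(gap_sizes[j])
        seq_parts.append(random_sequence(gap, rng))
        pos += gap
        if item[0] == "ssu":
            strand = "+" if rng.random() < 0.5 else "-"
            s = profile.ssu_ref if strand == "+" else _revcomp(profile.ssu_ref)
            seq_parts.append(s)
            features.append(GeneFeature(
                f"{profile.taxon_id}|ssu", "ssu", pos, pos + len(s), strand))
            pos += len(s)
            continue
        kind, pid, marker, ko = item
        nt = pieces[pid]
        strand = "+" if rng.random() < 0.5 else "-"
        placed = nt if strand == "+" else _revcomp(nt)
        seq_parts.append(placed)
        features.append(GeneFeature(pid, kind, pos, pos + len(nt), strand))
        aa_seqs[pid] = translate(nt, code)
        pos += len(nt)
    seq_parts.append(random_sequence(int(gap_sizes[-1]), rng))
    genome = "".join(seq_parts)
    assert len(genome) == L, (len(genome), L)

    annotations = _truth_annotations(profile, items, rng)
    return SyntheticGenome(profile, genome, annotations, features, aa_seqs)


_ALL_KOS = sorted(DEFAULT_COMPLEX_MAP)


def _truth_annotations(profile: TaxonProfile, items, rng) -> list[dict]:
    rows = []
    cog_idx = np.arange(len(COG_CATEGORIES))
    for item in items:
        if item[0] == "ssu":
            continue
        kind, pid, marker, ko = item
        cat = COG_CATEGORIES[rng.choice(cog_idx, p=profile.cog_distribution)]
        u = rng.random()
        if u < profile.ec1_rate:
            ec = 1
        elif u < profile.ec1_rate + 0.25:
            ec = int(rng.integers(2, 8))
        else:
            ec = None
        ko_id, score, thr = None, None, None
        if kind == "etc":
            ko_id = ko
            thr = float(rng.uniform(100, 400))
            score = float(thr * rng.uniform(0.6, 1.5))
        elif kind == "filler" and rng.random() < 0.03:
            # sub-threshold decoy KO annotation
            ko_id = _ALL_KOS[rng.integers(0, len(_ALL_KOS))]
            thr = float(rng.uniform(100, 400))
            score = float(thr * rng.uniform(0.05, 0.45))
        rows.append(dict(
            genome_id=profile.taxon_id,
            protein_id=pid,
            cog_category=cat,
            ec_top_class=ec,
            ko_id=ko_id,
            ko_score=score,
            ko_threshold=thr,
            marker_id=marker,
        ))
    return rows


# ---------------------------------------------------------------------------
# SAG sampling

@dataclass
class SagAssembly:
    sag_id: str
    plate_id: str
    contigs: dict[str, str]
    diameter_um: float
    truth: dict
    annotations: list[dict] = field(default_factory=list)
    gene_map: list[GeneFeature] = field(default_factory=list)
    aa_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def assembly_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def _sample_intervals(L, completeness, n_fragments, min_len, rng):
    retained = int(round(completeness * L))
    n = max(1, min(n_fragments, retained // min_len if retained >= min_len else 1))
    # fragment sizes: Dirichlet jitter around an even split, floored at
    # min_len by taking the deficit from the largest fragments
    w = rng.dirichlet(np.full(n, 8.0))
    sizes = np.floor(w * retained).astype(int)
    sizes[0] += retained - sizes.sum()
    for i in range(n):
        if sizes[i] < min_len:
            need = min(min_len, retained) - sizes[i]
            j = int(np.argmax(sizes))
            sizes[j] -= need
            sizes[i] += need
    if n > 1 and sizes.min() < min_len:
        sizes = np.full(n, retained // n)
        sizes[0] += retained - sizes.sum()
    gap_total = L - int(sizes.sum())
    gaps = rng.multinomial(gap_total, np.ones(n + 1) / (n + 1))
    ivals = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        ivals.append((pos, pos + int(sizes[i])))
        pos += int(sizes[i])
    return ivals


def sample_sag(
    genomes: list[SyntheticGenome],
    completeness,
    n_fragments: int,
    plate_id: str,
    seed: int,
    sag_id: str | None = None,
    min_contig_len: int = 2000,
) -> SagAssembly:
    """Sample a SAG assembly from one or two source genomes.

    ``completeness`` is a fraction per source genome (scalar or sequence).
    Contigs are non-overlapping sub-intervals of each source covering
    approximately that fraction; annotation rows and gene-map features are
    kept only for genes fully inside a retained interval, with coordinates
    remapped to the contig. Two sources mark the SAG as an admixture
    (planted co-sort).
    """
    if not 1 <= len(genomes) <= 2:
        raise ValueError("sample_sag takes 1 or 2 source genomes")
    comps = np.atleast_1d(np.asarray(completeness, dtype=float))
    if comps.size == 1 and len(genomes) == 2:
        comps = np.repeat(comps, 2)
    if comps.size != len(genomes):
        raise ValueError("one completeness per source genome")
    if np.any(comps <= 0) or np.any(comps > 1):
        raise ValueError("completeness must be in (0, 1]")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if sag_id is None:
        sag_id = f"SAG_{child_seed(seed, 'id', plate_id):08d}"
    rng = _rng(seed, "sag", sag_id)

    contigs: dict[str, str] = {}
    annotations: list[dict] = []
    gene_map: list[GeneFeature] = []
    aa_seqs: dict[str, str] = {}
    ci = 0
    for g, comp in zip(genomes, comps):
        L = len(g.sequence)
        ivals = _sample_intervals(L, float(comp), n_fragments, min_contig_len, rng)
        feats = sorted(g.gene_map, key=lambda f: f.start)
        ann_by_pid = {r["protein_id"]: r for r in g.annotations}
        for s, e in ivals:
            cid = f"{sag_id}_c{ci:03d}"
            ci += 1
            contigs[cid] = g.sequence[s:e]
            for f in feats:
                if f.start >= s and f.end <= e:
                    gene_map.append(GeneFeature(
                        f.protein_id, f.kind, f.start - s, f.end - s,
                        f.strand, contig_id=cid))
                    if f.kind != "ssu":
                        row = dict(ann_by_pid[f.protein_id])
                        row["genome_id"] = sag_id
                        annotations.append(row)
                        if f.protein_id in g.aa_seqs:
                            aa_seqs[f.protein_id] = g.aa_seqs[f.protein_id]
    diam = 0.0
    for g in genomes:
        d = float(rng.lognormal(np.log(g.profile.diameter_median_um), 0.30))
        diam = max(diam, d)
    if len(genomes) == 2:
        diam *= 1.3     # aggregates present larger than single cells
    truth = dict(
        source_taxa=tuple(g.profile.taxon_id for g in genomes),
        source_phyla=tuple(g.profile.phylum for g in genomes),
        completeness=tuple(float(c) for c in comps),
        admixture=len(genomes) == 2,
        fragments=len(contigs),
    )
    return SagAssembly(
        sag_id=sag_id, plate_id=plate_id, contigs=contigs,
        diameter_um=round(diam, 3), truth=truth,
        annotations=annotations, gene_map=gene_map, aa_seqs=aa_seqs,
    )


# ---------------------------------------------------------------------------
# community simulation

@dataclass
class Community:
    taxa: list[SyntheticGenome]
    sags: list[SagAssembly]
    phylum_refs: dict[str, str]
    config: dict

    def taxon(self, taxon_id: str) -> SyntheticGenome:
        return next(g for g in self.taxa if g.profile.taxon_id == taxon_id)


# study-like phylum composition: candidate superphyla are a modest
# minority of sorted cells, most wells receive ordinary bacteria/archaea
DEFAULT_COMPOSITION = {
    "Patescibacteria": 0.16,
    "DPANN": 0.04,
    "Other-Bacteria": 0.60,
    "Other-Archaea": 0.20,
}

_PHYLUM_STYLE = {
    "Patescibacteria": "patesci_like",
    "DPANN": "dpann_like",
    "Other-Bacteria": "standard",
    "Other-Archaea": "standard",
}


def simulate_community(
    n_taxa: int = 12,
    n_sags: int = 96,
    cosort_rate: float = 0.02,
    completeness_range: tuple[float, float] = (0.05, 0.61),
    seed: int = 0,
    composition: dict[str, float] | None = None,
    symbiont_fraction: float = 0.15,
    plate_size: int = 96,
) -> Community:
    """Simulate a SAG survey: taxa, genomes, and sampled SAG assemblies.

    Each SAG draws a source taxon from the phylum composition and a
    completeness uniform over ``completeness_range`` (default mean 0.33,
    matching partial single-cell assemblies); with probability
    ``cosort_rate`` a second, distinct taxon is co-sorted into the same
    well. Plates fill round-robin with ``plate_size`` wells.
    """
    comp = dict(composition or DEFAULT_COMPOSITION)
    phyla = sorted(comp)
    weights = np.array([comp[p] for p in phyla], dtype=float)
    weights = weights / weights.sum()
    rng = _rng(seed, "community")

    taxa: list[SyntheticGenome] = []
    taxon_phyla = [phyla[i] for i in rng.choice(len(phyla), size=n_taxa, p=weights)]
    # guarantee at least one taxon per phylum with nonzero weight
    for j, p in enumerate([p for p in phyla if comp[p] > 0][: n_taxa]):
        taxon_phyla[j] = p
    refs = default_reference_taxonomy(tuple(phyla))
    for i, p in enumerate(taxon_phyla):
        style = _PHYLUM_STYLE.get(p, "standard")
        if style == "standard" and rng.random() < symbiont_fraction:
            style = "symbiont_like"
        prof = make_taxon_profile(
            p, style, child_seed(seed, "taxon", i), taxon_id=f"T{i:03d}_{p}",
            phylum_refs=refs,
        )
        taxa.append(synthesize_genome(prof, child_seed(seed, "syn", i)))

    by_phylum: dict[str, list[int]] = {}
    for i, g in enumerate(taxa):
        by_phylum.setdefault(g.profile.phylum, []).append(i)
    lo, hi = completeness_range
    # restrict SAG source draws to phyla actually realized as taxa
    avail = [p for p in phyla if p in by_phylum]
    aw = np.array([comp[p] for p in avail], dtype=float)
    aw = aw / aw.sum()
    sags: list[SagAssembly] = []
    for s in range(n_sags):
        p = avail[rng.choice(len(avail), p=aw)]
        i1 = by_phylum[p][rng.integers(0, len(by_phylum[p]))]
        sources = [taxa[i1]]
        if rng.random() < cosort_rate and n_taxa > 1:
            i2 = i1
            while i2 == i1:
                i2 = int(rng.integers(0, n_taxa))
            sources.append(taxa[i2])
        comps = [float(rng.uniform(lo, hi)) for _ in sources]
        nf = int(rng.integers(3, 13))
        plate = f"AG-{s // plate_size + 1:03d}"
        sags.append(sample_sag(
            sources, comps, nf, plate, child_seed(seed, "sag", s),
            sag_id=f"SAG{s:05d}",
        ))
    config = dict(
        n_taxa=n_taxa, n_sags=n_sags, cosort_rate=cosort_rate,
        completeness_range=list(completeness_range), seed=seed,
        composition=comp, symbiont_fraction=symbiont_fraction,
        plate_size=plate_size,
    )
    return Community(taxa=taxa, sags=sags, phylum_refs=refs, config=config)
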