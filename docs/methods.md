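# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic data does and does not emulate, and the design
decisions taken where the design was genuinely open.

## Synthetic community model

A community is a set of taxa, each a `TaxonProfile`: phylum, domain,
genetic code (11 or 25), target coding density, genome length, a
56-marker complement, a 16S reference, a probability vector over the 25
COG categories, an EC1 annotation rate, per-complex ETC subunit KO lists,
and oxygen-reductase genes. Four style presets encode the biological
contrasts the analyses look for:

| style | coding density | EC1 rate | ETC | O₂ reductases | code | diameter (µm) | genome (kb) |
|---|---|---|---|---|---|---|---|
| `standard` | N(0.90, 0.015) | 0.05 | I–IV | HCO_A (low aff.) + bd (high aff.) | 11 | 0.8 | 300 |
| `patesci_like` | N(0.90, 0.015) | 0.01 | none | none | 11 or 25 (p=0.5) | 0.2 | 150 |
| `dpann_like` | N(0.90, 0.015) | 0.01 | none | none | 11 | 0.2 | 150 |
| `symbiont_like` | N(0.75, 0.02) | 0.03 | IV only | bd | 11 | 0.6 | 200 |

COG distributions are Dirichlet draws (concentration 400) around a
typical prokaryote baseline; the candidate-phyla styles multiply
categories C/E/H/P by 0.25–0.3 (depletion of energy, amino-acid,
coenzyme and ion metabolism) and enrich D/O (patesci-like) or B/K/S
(dpann-like, the archaeal signature). Genome lengths are deliberate
desk-scale stand-ins for 1–2 Mb genomes, chosen so whole test cohorts
synthesize in seconds; every rule tested is length-invariant.

Genome synthesis lays out one copy of each marker, each ETC subunit KO,
each oxygen-reductase gene (a peptide diverged ~10% from the packaged
reference, back-translated), one 16S (non-coding), and filler CDS up to
the target coding density, separated by i.i.d. uniform intergenic
sequence, on random strands in random order. CDS are ATG + random sense
codons + a stop from the genome's code; in table-25 genomes ~60% of CDS
carry in-frame TGA (rate 0.04/codon, at least one forced), giving the
code-selection rule its signal. Realized coding density lands within
0.03 of target (verified from the gene map).

SAG sampling retains `completeness × L` nucleotides in `n_fragments`
non-overlapping intervals (Dirichlet-jittered sizes, floored at the 2 kb
minimum contig length), keeps only genes fully inside retained intervals,
and remaps annotations to contig coordinates. Co-sorts concatenate
fragments of two genomes. Cell diameters are lognormal around the style
median (σ=0.3); co-sorts take the larger draw × 1.3, mimicking
aggregates sorting as larger particles.

Defaults not fixed by any published value, chosen once as field-realistic:
co-sort rate 2% (the in-situ rate is unknown), completeness U(0.05, 0.61)
(mean 0.33, so a 492-SAG cohort carries ~162 genome equivalents), phylum
composition {Patescibacteria 0.16, DPANN 0.04, other bacteria 0.60, other
archaea 0.20}, 15% of "other" taxa symbiont-like. One global integer
seed is hierarchically split (BLAKE2 hash of seed + tokens) per
taxon/SAG, so any subset regenerates identically and two runs from one
config+seed are byte-identical.

What the generator does **not** emulate: amplification (MDA) coverage
bias, read-level errors or assembly chimerism, rRNA secondary structure
and introns, GC/codon-usage structure in intergenic DNA, lineage-specific
marker sets, and real 16S phylogenetic structure (the taxonomy is a
star-like radiation from a random root). Passing tests therefore show
the *rules* are implemented correctly and have the claimed operating
characteristics under clean partial-sampling noise — not that they would
achieve the same sensitivity on real amplification artifacts.

## ORF calling and genetic-code selection

The caller is deterministic: on both strands and all frames, one ORF per
in-frame stop, from the first ATG after the previous stop through the
stop codon (stop set {TAA,TAG,TGA} for table 11, {TAA,TAG} for table
25), minimum length 90 nt, N-containing codons treated as sense. Total
CDS is the *sum* of call lengths — overlapping calls across frames can
push density above 1, which is flagged, never clipped.

Code selection compares the two totals. Because table 25's stop set is a
subset of table 11's, each frame's per-stop longest-ORF total under 25 is
provably ≥ the table-11 total, so a raw comparison would select table 25
for every input: spurious ORFs in non-coding frames (reverse strands of
genes, off-frame sequence, intergenic DNA) are systematically longer
when one stop codon is removed. Measured on synthetic genomes, this
baseline excess gives t25/t11 ratios of 1.25–1.40 for genomes that truly
use table 11 (across styles, lengths and densities), whereas genuine
table-25 genomes — whose genes fragment at internal TGAs under table
11 — show ratios of 1.7–3.3. Selection therefore uses a relative margin:
table 25 is chosen only when t25 > (1 + margin) × t11, with margin 0.5
sitting in the measured gap; margin 0 recovers the raw comparison, and
exact ties still resolve to table 11. Further caller simplifications
relative to a trained gene finder: ATG-only starts, no partial/edge
genes, no start scoring.

## 16S detection and classification

Detection slides a 200 nt window over each strand and marks windows
where ≥ 35% of 16-mer starts occur in the reference panel; passing
windows are merged (gap ≤ 300), trimmed to the outermost matching
k-mers, and filtered at the length threshold. Two thresholds exist by
design: >1,000 nt for co-sort screening, ≥1,200 nt for
ordination/phylogeny eligibility. The false-positive rate on random 10 kb
contigs is <1%.

Classification is the standard word-based naive Bayes: the likelihood of
an 8-mer under a phylum is (references containing it + 0.5)/(references
+ 1); the winner maximizes the summed log likelihood over the query's
distinct words; confidence is the percentage of 100 bootstrap subsamples
(⌈W/8⌉ of the W words, with replacement, seeded) agreeing with the
full-set winner. Self-classification of any reference gives confidence
100; queries 2% diverged from a reference classify to its phylum with
confidence ≥ 80 when phyla are ≥ 10% mutually divergent. No chimera or
intron handling.

## Co-sort detection and the chi-square decomposition

Marker census: completeness = distinct markers found / 56, contamination
= extra copies / 56 — a single-set simplification of lineage-specific
collocated marker sets, keeping the 10% flagging threshold semantics.
The 16S detector requires two confident (≥ 80 bootstrap) hits above the
length threshold with different phylum labels.

The chi-square uses expected counts E = row×col/N, X² = Σ(O−E)²/E, df =
(r−1)(c−1), upper-tail p from the continuous chi-square distribution, no
continuity correction. Pearson residuals (O−E)/√E are squared and
normalized by X² into percent contributions (summing to 100 when X² >
0). Zero margins are an error rather than a silent 0/0. Under equal
co-sort rates across groups (rate 0.05, group sizes 400/300/300 — large
enough for the asymptotic approximation to hold) the test rejects at
α=0.05 in 5% ± 2% of null cohorts.

## Energy metabolism

Smith–Waterman uses affine gaps (BLOSUM62, open 11, extend 1: the first
gapped column costs 11, each further one 1); alignment length is the
column count of an optimal traceback, ties broken toward the longest.
The kernel is numba-compiled when available (identical function, python
fallback). E-values follow the Karlin–Altschul form E = K·m·n·e^(−λS)
with gapped BLOSUM62 constants λ=0.267, K=0.041 (configurable); a shared
5-mer prefilter (≥3 words) skips hopeless alignments, as a seeded search
would. A protein is an oxygen-reductase hit when its best reference
e-value ≤ 1e-10 (family and affinity inherited from the best reference;
ties on e-value → higher score → lexicographic id); the tree-eligible
subset additionally requires >400 aa. The packaged reference panel is
synthetic (two families with the real panel's structure: HCO_A/low
affinity ~560 aa, bd/high affinity ~470 aa) — carrying no biological
motif content, it tests the detection machinery, not real homology.

The KO rule accepts a protein when score ≥ 0.5 × the family threshold
(scale-invariant by construction); accepted hits are rolled up by a
configurable KO→complex map (the shipped default covers nuo, sdh, bc1
and terminal-oxidase subunits and is configuration, not ground truth).
EC1 fraction = 100 × EC-class-1 proteins / all proteins.

## COG ordination and group tests

Rows are percentages of assigned COGs per category (zero-assignment
genomes excluded); genomes need ≥ 30% completeness and a ≥ 1,200 nt 16S
to enter. Ordination is classical scaling of Euclidean distances on the
raw percentages — implemented literally as eigen-decomposition of the
centered Gram matrix, which for Euclidean distances equals PCA (verified
against an SVD-based PCA in tests; a Hellinger transform is available
but off by default, matching the percent-input convention). Axes are
ordered by eigenvalue; signs follow "first nonzero loading positive";
negative eigenvalues (numerical noise) are clipped to zero; full-rank
coordinates reproduce the input distances to 1e-6 (Gower's identity).

The Wilcoxon rank-sum test enumerates the exact null distribution of the
midrank sum when both groups have ≤ 8 members (two-sided p = probability
of a rank-sum at least as far from its null mean); larger samples use
the tie-corrected normal approximation without continuity correction.
Singleton groups are skipped with a warning.

## Cohort reporting

Percentages round half away from zero (banker's rounding deliberately
rejected so printed rates like 0.53% reproduce). Box statistics use
type-7 (linear-interpolation) quartiles and Q1−1.5·IQR / Q3+1.5·IQR
whiskers. Plate abundances subsample without replacement (seeded;
default no subsampling). Effective complete genomes = Σ completeness /
100, reported to one decimal.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the package's
own defaults: 120–300 kb genomes, cohorts of 10–100 SAGs, 100-genome
code-selection panels, 200-SAG detector panels, 1,000-cohort
calibrations, 100-cohort power runs. All headline rules are
size-invariant; sizes only set Monte-Carlo resolution.

## Known limitations

The caller's sum-of-lengths density overestimates true coding density
(spurious multi-frame calls), so absolute density values are not
comparable to trained-gene-finder output — only the table comparison
and the flagged >1 densities are meaningful. The marker detector cannot
see co-sorts of near-identical strains (overlapping markers are the
signal). The 16S detector's k-mer windows cannot find 16S genes more
diverged than the panel (~30%+). The classifier assigns phylum only.
The synthetic taxonomy's star topology makes classification easier than
real reference databases; the reported confidences should not be read as
field performance.
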