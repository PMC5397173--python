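# Methods

This note documents the models, parameters and design choices behind
`sdbiasscan`. The package analyses translation-initiation signals in
prokaryotic genomes: which genes carry a Shine–Dalgarno (SD) sequence, what
positional nucleotide biases surround the initiation codons of genes that do
not, how those bias patterns compare across species, and whether non-SD
genes show relaxed mRNA secondary structure or start-codon-proximal
16S-rRNA-tail interactions.

## SD / non-SD classification

The anti-SD sequence — the 3′ tail of the species' 16S rRNA, supplied as a
13-nt input written 5′→3′ — is slid without gaps along the SD region of each
gene (upstream positions −20..−5, with −1 adjacent to the start codon). At
every offset, including partial overlaps of at least two positions, the
hybridization free energy ΔG37 of the gapless antiparallel duplex is
computed from a nearest-neighbor stack model, and the minimum over offsets
represents the interaction. A gene is non-SD iff this minimum is weaker
(greater) than the threshold of −0.8924 kcal/mol; a gene exactly at the
threshold is SD.

The energy model: every maximal run of ≥ 2 consecutive complementary pairs
contributes the sum of its stack free energies; one duplex-initiation term
(+4.09 kcal/mol) is charged per duplex containing at least one such run; a
terminal penalty (+0.45 kcal/mol) applies to each run end closed by an A·U
(or G·U) pair. Isolated single pairs contribute nothing because
nearest-neighbor energies are defined on stacks, and a duplex whose total
would be positive is reported as ΔG = 0 (no interaction) — this also makes
the scan minimum well-defined and ≤ 0 on every input. Watson–Crick stack
energies are the INN-HB ΔG37 values (Xia et al. 1998); G·U-containing
stacks, off by default for hybridization and on for folding, use Turner-2004
values. The table ships as `data/rna_stack_dg37.tsv` and is validated for
completeness and two-fold rotational symmetry on load.

The −0.8924 kcal/mol cutoff is the documented mean of the three-base
SD/anti-SD duplex energies (GGA, GAG, AGG cores). With the shipped table
that mean evaluates to −0.7367 kcal/mol
(`threshold_from_three_base_duplexes`); the historical parameter set that
yields exactly −0.8924 is not recoverable, so the threshold is kept as a
configured constant, decoupled from the table. Note the constant is only
meaningful with the initiation term included: without it, three-base
matches sit near −5 kcal/mol and the cutoff would classify nearly every
gene as SD.

Genes whose available SD-region slice is shorter than 2 nt, or contains
ambiguity codes, are labelled non-SD by convention and carry a note; every
record receives exactly one label.

## Positional G-statistics

Genes are aligned at their initiation codons without gaps; position +1 is
the first base of the start codon, −1 the base just upstream, and position
0 does not exist. At each position i,

    G(i) = 2 Σ_n O_n(i) ln(O_n(i) / E_n(i)),   n ∈ {A, U, G, C},

with 0·ln 0 ≡ 0, referred to χ² with 3 degrees of freedom. Expected counts
come from four per-species categories — upstream (all bases of the ≤100-nt
upstream windows) and codon positions 1/2/3 pooled over full CDSs including
start and stop codons — because base composition differs sharply between
these classes. Each signed term G_n(i) measures one nucleotide's bias
(positive = over-represented), and g_n(i) = G_n(i)/N(i) removes the
dependence on gene count N so species are comparable. Positions +1..+3 are
computed but flagged: their "bias" is start-codon identity. Positions no
gene covers are omitted rather than reported as zero; E_n = 0 with O_n > 0
marks a position invalid.

By default expectations are estimated from the same gene subset being
profiled (e.g. the non-SD subset): subset-matched expectations avoid
leaking the SD genes' composition into non-SD profiles. A flag switches to
all-gene expectations.

## Cross-species comparison

Each species is summarized by the 160-value vector of g_n over upstream
positions −40..−1 × 4 nucleotides. Pairwise similarity is the standard
Pearson correlation r over these 160 paired values, centering each species
by one grand mean across all positions and nucleotides; the dissimilarity
is D = 1 − r (0 for identical patterns, 2 for perfectly anticorrelated
ones). Species are clustered by group-average (UPGMA) agglomeration on D
(scipy), whose merge heights are monotone, and ordinated by PCA of the
same vectors — centered but not scaled, since all 160 variables share
units. PCA signs are fixed by making each component's largest-magnitude
loading positive, for reproducibility.

## mRNA folding around the start codon

The folding window spans positions −20..+20: the 20 upstream bases adjacent
to the start codon plus the first 20 CDS bases, start codon included at
+1..+3 (40 nt). The window must be "around the initiation codon" for the
downstream comparisons to bear on initiation, so the codon sits inside it;
both half-window lengths are configurable.

The default engine is a self-contained simplified Zuker-style dynamic
program: stack energies from the shipped table (Watson–Crick plus G·U),
hairpin/bulge/internal-loop length penalties from `data/loop_dg37.tsv`
(Turner-2004 initiation terms), bulge and internal loops capped at 30
unpaired bases, minimum hairpin loop 3, hairpins beyond the table
extrapolated with the Jacobson–Stockmayer term, and a linear multiloop
model (a = 3.4, b = 0.4 per branch, c = 0 per unpaired base). No dangles,
no coaxial stacking, no terminal-AU penalties. Every downstream use is
comparative — observed vs randomized, SD vs non-SD with the same engine —
so a consistent simplified energy function preserves the analysis logic
even though its absolute ΔG values differ from full Turner-model folders.
An adapter exposes ViennaRNA's RNAfold as an external engine for users who
want full parameters; an unavailable engine raises an error rather than
silently falling back. The inner loop is numba-compiled; an exhaustive
structure-enumeration scorer over the identical energy rules serves as the
test oracle for sequences ≤ 12 nt, and every returned structure re-scores
exactly to its reported MFE.

## Randomization null and folding tests

The null model preserves per-position nucleotide composition of the
observed −20..+20 windows while destroying within-sequence dependence:
position j of each output is drawn independently from the empirical
multinomial of column j, and 100 null sequences are generated per observed
gene (configurable). Observed and null ΔG samples are compared with a
two-sided Wilcoxon rank-sum (Mann–Whitney) test, normal approximation with
tie correction; "observed weaker" means observed ΔG is less negative.
SD-vs-non-SD folding uses the same rank-sum machinery on the two groups'
ΔG samples. In cohort runs every per-species p-value is Bonferroni
corrected with m = the number of species, and a direction is reported only
when the corrected p clears the α level (0.05 and 0.01 are both flagged).
All randomness flows from named numpy PCG64 generators seeded from the
run configuration; per-species seeds are derived deterministically from
the base seed and the species id.

## 16S-tail interaction profiles

For anchors i across −100..+100 (configurable), ΔG(i) is the energy of the
full-overlap gapless duplex whose 5′-most mRNA base sits at position i,
computed with the classifier's energy function. Assigning the energy to
the alignment's 5′-most base makes the characteristic dip fall at +1 when
the tail pairs the region that includes the initiation codon. Only
full-overlap alignments enter the profile; partial overlaps are a scan
concern. Because the SD-region scan does admit partial overlaps and its
windows are confined to the −20..−5 slice while profile windows extend
past it, the scan minimum equals the profile minimum only when the best
alignment is a full overlap inside the slice; in general the scan bounds
the profile values from below, which is what the tests assert.

Group profiles are position-wise means over SD and non-SD genes. The +1
difference is tested two ways: per species, a rank-sum test over per-gene
+1 energies (Bonferroni across species); across species, a paired
signed-rank test on the per-species arithmetic mean +1 energies of the two
groups (minimum attainable two-sided p with 6 species is 1/32).

## Synthetic species generator

The generator emits a complete one-contig species — genome FASTA, 5-column
annotation TSV, 16S tail — that round-trips exactly through the loaders,
with per-gene ground truth. Genes are placed non-overlapping with 100-nt
upstream windows and 20-nt spacers; an option mirrors a fraction of genes
to the − strand to exercise strand handling. Start codons follow a
configurable usage distribution (default dominated by AUG, then GUG/UUG);
CDS lengths are uniform over a codon-count range (default 50–200);
internal stop codons are redrawn.

Planted features, all tunable:

* **SD motifs** (default GGAGG) are planted in a configurable fraction of
  genes at a start position drawn from −13..−11 (motif centered near −10,
  inside the −20..−5 SD region), by per-base probabilistic reweighting with
  strength 1.0 by default — soft planting mirrors the soft positional
  biases the G-statistic measures.
* **Leaderless-style upstream profiles**: archaeal (U/A-enrichment at
  −27..−23, A at −31..−29, G/C at −37..−33) or bacterial (A/U-rich
  TATAAT-like enrichment across −20..−10), mixed into the background with a
  strength parameter (default 0.6).
* **Relaxed structure** around the start codon: with probability equal to
  the bias strength, a gene draws its −10..+10 region (sparing start-codon
  identity and the stop codon) from a single coherent A/U-skewed pool —
  purines {A: 0.8, G: 0.2} or pyrimidines {U: 0.8, C: 0.2}, chosen per
  gene. A one-alphabet region cannot base-pair with itself, while the
  per-column composition across genes stays mixed, so observed windows
  fold weaker than their column-shuffle null. This is the within-sequence
  property the randomization test is designed to detect; note that
  position-wise independent A/U enrichment, however strong, is
  *indistinguishable from its own shuffle null* because the null preserves
  column composition by construction — and A/U-rich sequences still pair
  internally. By default the bias applies to genes without a planted SD
  motif, matching the hypothesis that structure avoidance compensates for
  the missing SD interaction; a flag applies it to all genes.
* **+1 interaction sites**: the tail's reverse complement planted at
  +1..+13 (in all genes or only non-SD genes). This requires a tail whose
  reverse complement begins with a legal start codon and plants no
  in-frame stop; the generator validates both at configuration time.

What the generator does *not* emulate: operonic structure and genes whose
upstream windows overlap neighbouring CDSs, codon-usage and amino-acid
composition beyond per-position base frequencies, rRNA sequence variation,
GC-skew along the replichore, and annotation errors. Passing tests
therefore demonstrate that the pipeline recovers planted signals of
realistic effect size from data satisfying its assumptions, not that real
genomes satisfy them.

Backgrounds used in the shipped analyses were chosen a priori from the
energetics: false SD calls arise from G-rich upstream trigrams that pair
the C-rich anti-SD tail, so the parameter-recovery fixtures use AU-rich,
G-depleted backgrounds (G = 0.10 for the 80%-SD species, G = 0.02 for the
0%-SD species) emulating the AT-rich intergenic regions where G-rich
SD-like trigrams are rare; the relaxed-structure fixtures use a GC-rich
background (G = C = 0.35) so that unbiased genes have pairing partners.

## Numerical and procedural choices

* Ambiguity codes are tolerated on read; genes keep them, but windows
  containing them are excluded from energy and folding computations while
  G-statistics simply skip the ambiguous bases at affected positions.
* Scan ties across offsets break toward the smallest offset; the UPGMA
  tie behaviour is scipy's, deterministic for a fixed species order.
* Rank-sum tests are two-sided with the direction read off group medians;
  the tests' sidedness is part of the reproducibility contract.
* Problem sizes in the test-suite and acceptance analyses — 500-gene
  recovery species, 250-gene cohort species, 300 genes × 100-fold
  randomization, 200-replicate null calibration on 20-nt windows — were
  chosen as the smallest sizes at which the planted effects and the
  calibration bands are comfortably resolved.
* Chi-square calibration of the G-test (df = 3) is validated under the
  null at N = 500 genes across 10,000 simulated positions for α = 0.05
  and 0.01 within three standard errors.

## Known limitations

* The simplified folder's absolute ΔG values are not comparable to
  hybrid-ss-min or RNAfold outputs; only within-engine comparisons are
  meaningful. The ViennaRNA adapter exists for users who need full
  parameters end to end.
* The hybridization model has no dangling ends, no accessibility
  correction, and G·U pairing in the SD scan is off by default; species
  whose anti-SD pairing relies heavily on wobble pairs will have SD genes
  misclassified as non-SD unless `allow_gu` is enabled.
* The classifier's false-positive rate depends strongly on background GC
  content; on G-rich genomes a sizeable fraction of genes without a
  biological SD site still exceeds the energy threshold, exactly as with
  the original energy-threshold definition.
* Bonferroni correction with m = #species is conservative for the small
  cohorts typical of synthetic studies.
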