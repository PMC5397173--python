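# sdbiasscan

Comparative analysis of translation-initiation signals in prokaryotic
genomes. In bacteria and archaea, the canonical route into translation is
base-pairing between the 3′ tail of 16S rRNA and a Shine–Dalgarno (SD)
sequence (consensus GGAGG) ~10 nt upstream of the start codon — but in many
species a large fraction of genes lacks an SD site. This package implements
the genomic analyses used to characterize how such **non-SD genes** are
initiated: leaderless-mRNA-style promoter signals immediately upstream of
the start codon, relaxed mRNA secondary structure around it, and direct
16S-tail interactions at the initiation codon itself. It is written for
computational microbiologists who want to run these analyses on their own
(or synthetic benchmark) genomes.

## What it computes

* **SD / non-SD classification.** The anti-SD tail (13-nt 3′ end of 16S
  rRNA) is slid gaplessly over the SD region (upstream positions −20..−5);
  hybridization ΔG37 comes from a nearest-neighbor stack model (INN-HB
  Watson–Crick stacks, +4.09 kcal/mol duplex initiation, +0.45 terminal
  A·U). A gene is non-SD iff min ΔG > −0.8924 kcal/mol.
* **Positional bias profiles.** Genes aligned at their start codons;
  per-position likelihood-ratio statistic
  `G(i) = 2 Σₙ Oₙ ln(Oₙ/Eₙ)` (χ², df = 3) with expectations estimated per
  species in four categories (upstream, codon positions 1/2/3); the signed
  per-nucleotide terms divided by gene count, `gₙ = Gₙ/N`, are comparable
  across species.
* **Cross-species comparison.** Dissimilarity `D = 1 − r` where r is the
  Pearson correlation of two species' 160-value gₙ vectors (positions
  −40..−1 × A,U,G,C); group-average (UPGMA) clustering and centered PCA.
* **Folding tests.** Minimum-free-energy ΔG of the −20..+20 window around
  the start codon (simplified Zuker-style folder, pluggable ViennaRNA
  engine), compared against a column-shuffle null (100 randomized
  sequences per gene, per-position composition preserved) and between SD
  and non-SD genes, with Wilcoxon rank-sum tests and Bonferroni correction
  across species.
* **16S-tail interaction profiles.** Positional hybridization-energy
  profiles across −100..+100 with the characteristic dip at +1, and paired
  signed-rank tests of the SD vs non-SD difference at +1.
* **Synthetic species generator.** Complete benchmark genomes with known
  planted SD fractions, leaderless-style upstream motifs, relaxed-structure
  genes and +1 interaction sites, so every stage can be validated against
  ground truth.

See `docs/methods.md` for models, parameters and design decisions.

## Worked example

```python
from sdbiasscan import (GeneratorConfig, generate_species, extract_gene_records,
                        classify_genes, RandomizationConfig, folding_vs_random_test)
from sdbiasscan.hybridization import split_by_label

cfg = GeneratorConfig(
    species_id="demo", seed=11, n_genes=300, sd_fraction=0.6,
    background={"A": 0.35, "C": 0.20, "G": 0.10, "U": 0.35},
    symmetric_bias_strength=0.8,          # non-SD genes avoid structure
)
species, truth = generate_species(cfg)
records = extract_gene_records(species).records
calls = classify_genes(records, species.anti_sd_tail)
n_sd = sum(c.label == "SD" for c in calls)
print(f"{n_sd}/{len(calls)} genes classified SD "
      f"(planted fraction {truth.realized_sd_fraction:.2f})")

sd, nonsd = split_by_label(records, calls)
out = folding_vs_random_test(nonsd, RandomizationConfig(multiplier=100, seed=1),
                             species_id="demo")
print(f"non-SD folding vs column-shuffle null: median dG "
      f"{out.extra['median_obs']:.2f} vs {out.extra['median_null']:.2f} kcal/mol, "
      f"p = {out.raw_p:.2e} ({out.direction})")
```

prints

```
208/300 genes classified SD (planted fraction 0.62)
non-SD folding vs column-shuffle null: median dG -0.20 vs -1.92 kcal/mol, p = 2.90e-13 (observed_weaker)
```

The classifier recovers the planted SD fraction (208/300 = 0.69 vs 0.62
planted — the excess is background sequence that genuinely pairs the tail),
and the planted structure avoidance in non-SD genes shows up as observed
folding energies significantly *weaker* (less negative) than the
composition-matched randomized null.

## Command line

A thin CLI wraps the library:

```bash
sdbiasscan synth    --config species.yaml --out fixtures/
sdbiasscan extract  --genome G.fa --annot A.gff3 --tail tail.fa --out records.tsv
sdbiasscan classify --records records.tsv --tail tail.fa --out calls.tsv
sdbiasscan gstats   --records records.tsv --window -100:99 --out profile.tsv
sdbiasscan fold     --seq GGGAAAACCC
sdbiasscan report   --genome G.fa --annot A.tsv --tail tail.fa --out out/
sdbiasscan compare  --species-dir fixtures/sp1 --species-dir fixtures/sp2 --out out/
```

Annotations may be GFF3 (CDS features) or a 5-column TSV
(`contig  strand  start  end  gene_id`, 1-based inclusive).

## Analysis scripts

`analysis/01…06` are narrative drivers that run the full study on the
synthetic cohort — fixture generation, SD classification and parameter
recovery, bias profiles, cross-species clustering/PCA, folding
randomization tests, and the +1 interaction analysis — writing their tables
under `results/`.

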