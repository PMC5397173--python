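#!/usr/bin/env python
"""16S-tail interaction profiles across -40..+40 and the +1 paired test.

Planting a tail-complementary site at the start codon of non-SD genes only,
across six species, produces the characteristic +1 dip in the positional
energy profile and a significant paired signed-rank difference between
groups.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))

from sdbiasscan.hybridization import classify_genes, revcomp_rna, split_by_label  # noqa: E402
from sdbiasscan.interaction_profile import group_profiles, plus_one_tests  # noqa: E402
from sdbiasscan.sequence_io import extract_gene_records  # noqa: E402
from sdbiasscan.synthetic_data import GeneratorConfig, generate_species  # noqa: E402

OUT = Path(__file__).parent.parent / "results"

MOTIF = "AUGGCUGGUCCGA"  # planted +1 site; its reverse complement is the tail
TAIL = revcomp_rna(MOTIF)


def main() -> None:
    per_species, tails, frames = [], {}, []
    for i in range(6):
        cfg = GeneratorConfig(
            species_id=f"s{i}", seed=200 + i, n_genes=150, sd_fraction=0.5,
            background={"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3},
            tail=TAIL, plus_one_scope="non_sd",
        )
        sp, _ = generate_species(cfg)
        recs = extract_gene_records(sp).records
        sd, nonsd = split_by_label(recs, classify_genes(recs, TAIL))
        per_species.append((cfg.species_id, sd, nonsd))
        tails[cfg.species_id] = TAIL
        prof = group_profiles(sd, nonsd, TAIL, span=(-40, 40))
        prof.insert(0, "species_id", cfg.species_id)
        frames.append(prof)
    paired, per = plus_one_tests(per_species, tails)

    OUT.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "interaction_profiles.tsv", sep="\t", index=False
    )
    prof0 = frames[0]
    for group in ("SD", "non-SD"):
        sub = prof0[prof0.group == group]
        best = sub.loc[sub.mean_dG.idxmin()]
        print(
            f"s0 {group}: profile minimum at position {int(best.position)} "
            f"({best.mean_dG:.2f} kcal/mol)"
        )
    print(
        f"\npaired signed-rank over 6 species at +1: p = {paired.raw_p:.4f} "
        f"({paired.direction})"
    )
    for o in per:
        print(
            f"  {o.species_id}: per-gene rank-sum p = {o.raw_p:.2e}, "
            f"Bonferroni-corrected {o.corrected_p:.2e} ({o.direction})"
        )


if __name__ == "__main__":
    main()
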