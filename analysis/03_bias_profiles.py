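#!/usr/bin/env python
"""Positional G-statistic bias profiles of non-SD genes per species.

Aligns genes at their start codons, computes per-position signed nucleotide
bias terms g_n against category-matched expectations, and reports where the
planted archaeal (U/A at -25, A at -30, G/C at -35) and bacterial
(A/U at -20..-10) upstream signals surface.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import cohort_configs  # noqa: E402

from sdbiasscan.gstats import expected_frequencies, g_profile  # noqa: E402
from sdbiasscan.hybridization import classify_genes, split_by_label  # noqa: E402
from sdbiasscan.sequence_io import extract_gene_records  # noqa: E402
from sdbiasscan.synthetic_data import generate_species  # noqa: E402

OUT = Path(__file__).parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = []
    checks = []
    for cfg in cohort_configs():
        sp, _ = generate_species(cfg)
        recs = extract_gene_records(sp).records
        _, nonsd = split_by_label(recs, classify_genes(recs, sp.anti_sd_tail))
        prof = g_profile(nonsd, expected_frequencies(nonsd), (-60, 30))
        df = prof.to_frame()
        df.insert(0, "species_id", cfg.species_id)
        frames.append(df)
        checks.append(
            {
                "species_id": cfg.species_id,
                "profile": cfg.leaderless_profile,
                "gAU_at_-25": prof.gn_at(-25, "A") + prof.gn_at(-25, "U"),
                "gGC_at_-35": prof.gn_at(-35, "G") + prof.gn_at(-35, "C"),
                "gAU_at_-15": prof.gn_at(-15, "A") + prof.gn_at(-15, "U"),
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "g_profiles_nonsd.tsv", sep="\t", index=False
    )
    summary = pd.DataFrame(checks)
    summary.to_csv(OUT / "g_profile_signals.tsv", sep="\t", index=False)
    print(summary.to_string(index=False, float_format="%.3f"))
    print(
        "\nArchaeal-style species show positive U/A bias at -25 and G/C at "
        "-35; bacterial-style species show the A/U (Pribnow-like) bias "
        "inside -20..-10 instead."
    )


if __name__ == "__main__":
    main()
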