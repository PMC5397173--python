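"""Shared study cohort for the analysis scripts.

Eight synthetic species in two planted groups (archaeal-style vs
bacterial-style upstream signals), plus two parameter-recovery species and
one relaxed-structure species. Deterministic under the seeds below.
"""

from sdbiasscan.synthetic_data import GeneratorConfig

BG = {"A": 0.30, "C": 0.25, "G": 0.15, "U": 0.30}
AU_RICH_BG = {"A": 0.35, "C": 0.20, "G": 0.10, "U": 0.35}
G_DEPLETED_BG = {"A": 0.34, "C": 0.30, "G": 0.02, "U": 0.34}
GC_RICH_BG = {"A": 0.15, "C": 0.35, "G": 0.35, "U": 0.15}


def cohort_configs() -> list[GeneratorConfig]:
    out = []
    for i in range(8):
        profile = "archaeal" if i < 4 else "bacterial"
        out.append(
            GeneratorConfig(
                species_id=f"{profile[:3]}{i}", seed=100 + i, n_genes=250,
                sd_fraction=0.3, background=BG,
                leaderless_profile=profile, leaderless_strength=0.6,
                symmetric_bias_strength=0.5,
            )
        )
    return out


def recovery_configs() -> list[GeneratorConfig]:
    return [
        GeneratorConfig(species_id="sd80", seed=42, n_genes=500,
                        sd_fraction=0.8, background=AU_RICH_BG),
        GeneratorConfig(species_id="sd0", seed=7, n_genes=500,
                        sd_fraction=0.0, background=G_DEPLETED_BG),
    ]


def relaxed_config() -> GeneratorConfig:
    return GeneratorConfig(
        species_id="relaxed", seed=5, n_genes=300, sd_fraction=0.0,
        background=GC_RICH_BG, symmetric_bias_strength=0.9,
        symmetric_bias_scope="all",
    )
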