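"""Shared fixtures: small hand-built genes and cached synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from sdbiasscan.hybridization import NNParameterTable
from sdbiasscan.sequence_io import GeneRecord, extract_gene_records
from sdbiasscan.synthetic_data import GeneratorConfig, generate_species

#: AU-rich, G-depleted background: SD-like (G-rich) trigrams are rare, so
#: planted SD motifs dominate the classifier signal.
AU_RICH_BG = {"A": 0.35, "C": 0.20, "G": 0.10, "U": 0.35}

#: Strongly G-depleted background for zero-SD fixtures (false SD calls are
#: driven by mRNA G pairing the C-rich anti-SD tail).
G_DEPLETED_BG = {"A": 0.34, "C": 0.30, "G": 0.02, "U": 0.34}


def make_record(
    gene_id: str = "g1",
    upstream: str = "A" * 100,
    n_codons: int = 30,
    start: str = "AUG",
    cds_body: str | None = None,
) -> GeneRecord:
    """A valid GeneRecord with a harmless default CDS."""
    if cds_body is None:
        cds_body = "GCU" * n_codons
    return GeneRecord(gene_id=gene_id, upstream=upstream, cds=start + cds_body + "UAA")


@pytest.fixture(scope="session")
def params() -> NNParameterTable:
    return NNParameterTable.default()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231101)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), n))


@pytest.fixture(scope="session")
def sd80_species():
    """Species with 80% planted SD genes on an AU-rich background."""
    cfg = GeneratorConfig(
        species_id="sd80", seed=42, n_genes=500, sd_fraction=0.8,
        background=AU_RICH_BG,
    )
    sp, truth = generate_species(cfg)
    return sp, truth, extract_gene_records(sp).records


@pytest.fixture(scope="session")
def sd0_species():
    """Species with no planted SD genes on a G-depleted background."""
    cfg = GeneratorConfig(
        species_id="sd0", seed=7, n_genes=500, sd_fraction=0.0,
        background=G_DEPLETED_BG,
    )
    sp, truth = generate_species(cfg)
    return sp, truth, extract_gene_records(sp).records


def two_group_cohort(n_per_group: int = 4, n_genes: int = 250):
    """Archaeal-style vs bacterial-style species with planted upstream motifs."""
    bg = {"A": 0.30, "C": 0.25, "G": 0.15, "U": 0.30}
    out = []
    for i in range(2 * n_per_group):
        profile = "archaeal" if i < n_per_group else "bacterial"
        cfg = GeneratorConfig(
            species_id=f"{profile[:3]}{i}", seed=100 + i, n_genes=n_genes,
            sd_fraction=0.3, background=bg,
            leaderless_profile=profile, leaderless_strength=0.6,
        )
        out.append((generate_species(cfg), profile))
    return out


@pytest.fixture(scope="session")
def planted_cohort():
    return two_group_cohort()
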