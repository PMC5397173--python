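"""Synthetic prokaryotic species with known translation-initiation signals.

The generator emits a complete species -- one-contig genome, CDS annotation
table and 16S rRNA 3' tail -- with parameterized ground truth:

* a controllable fraction of genes carrying an SD motif (default GGAGG)
  placed ~10 nt upstream of the start codon, planted by per-base
  probabilistic reweighting so signal strength is tunable;
* optional leaderless-style upstream promoter profiles (archaeal: U/A near
  -25, A near -30, G/C near -35; bacterial: TATAAT-like A/U enrichment at
  -20..-10);
* an optional per-gene symmetric "relaxed-structure" bias around the start
  codon (sparing start-codon identity). A relaxed gene draws its center
  region from a single-strand-coherent A/U-skewed pool -- purines
  ({A: 0.8, G: 0.2}) or pyrimidines ({U: 0.8, C: 0.2}), chosen per gene --
  so the region cannot base-pair with itself, while the per-column
  composition across genes stays mixed. This within-sequence avoidance of
  complementarity is exactly what column-shuffle randomization detects;
  per-position independent A/U enrichment would be indistinguishable from
  its own shuffle null, which preserves column composition by design;
* an optional planted tail-complementary 13-mer at position +1 (the
  start-codon-proximal 16S-tail interaction).

Everything is deterministic under the configured seed, and generated files
round-trip exactly through :mod:`sdbiasscan.sequence_io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .hybridization import revcomp_rna
from .sequence_io import (
    ALLOWED_START_CODONS,
    STOP_CODONS,
    Annotation,
    SpeciesInput,
)

_NTS = ("A", "C", "G", "U")
_STOPS = tuple(sorted(STOP_CODONS))

DEFAULT_TAIL = "GAUCACCUCCUUA"  # 13-nt anti-SD tail, 3' end of 16S rRNA

DEFAULT_START_USAGE = {
    "AUG": 0.80,
    "GUG": 0.12,
    "UUG": 0.06,
    "AUA": 0.01,
    "AUU": 0.005,
    "AUC": 0.005,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic species.

    ``background`` maps nucleotide -> fraction (must sum to 1); upstream
    positions are numbered -100..-1 as elsewhere in the package. Motif
    planting positions give the 5'-most base of the motif.
    """

    species_id: str = "synthetic"
    seed: int = 0
    n_genes: int = 300
    background: dict[str, float] = field(
        default_factory=lambda: {n: 0.25 for n in _NTS}
    )
    sd_fraction: float = 0.5
    sd_motif: str = "GGAGG"
    sd_motif_strength: float = 1.0
    sd_placement: tuple[int, int] = (-13, -11)
    leaderless_profile: str = "none"  # none | archaeal | bacterial
    leaderless_strength: float = 0.6
    symmetric_bias_strength: float = 0.0
    symmetric_bias_region: tuple[int, int] = (-10, 10)
    symmetric_bias_scope: str = "non_sd"  # non_sd | all
    plus_one_scope: str = "none"  # none | all | non_sd
    start_codon_usage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_START_USAGE)
    )
    cds_codons: tuple[int, int] = (50, 200)
    tail: str = DEFAULT_TAIL
    minus_strand_fraction: float = 0.0
    upstream_length: int = 100
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InputError("n_genes must be >= 1")
        if abs(sum(self.background.values()) - 1.0) > 1e-9:
            raise InputError("background fractions must sum to 1")
        if not 0.0 <= self.sd_fraction <= 1.0:
            raise InputError("sd_fraction must be in [0, 1]")
        lo, hi = self.sd_placement
        if not (-self.upstream_length <= lo <= hi <= -len(self.sd_motif)):
            raise InputError("sd_placement must keep the motif within the upstream window")
        if self.leaderless_profile not in ("none", "archaeal", "bacterial"):
            raise InputError(f"unknown leaderless_profile {self.leaderless_profile!r}")
        if self.symmetric_bias_scope not in ("non_sd", "all"):
            raise InputError(f"unknown symmetric_bias_scope {self.symmetric_bias_scope!r}")
        if self.plus_one_scope not in ("none", "all", "non_sd"):
            raise InputError(f"unknown plus_one_scope {self.plus_one_scope!r}")
        if self.plus_one_scope != "none":
            motif = revcomp_rna(self.tail)
            if motif[:3] not in ALLOWED_START_CODONS:
                raise InputError(
                    "plus_one planting requires a tail whose reverse complement "
                    f"starts with an allowed start codon, got {motif[:3]!r}"
                )
            for c in range(1, 4):
                codon = motif[3 * c : 3 * c + 3]
                if len(codon) == 3 and codon in STOP_CODONS:
                    raise InputError(
                        "tail reverse complement would plant an in-frame stop codon"
                    )

    @property
    def background_array(self) -> np.ndarray:
        return np.array([self.background[n] for n in _NTS])


@dataclass
class GroundTruth:
    """Per-gene planted features and species-level summaries."""

    genes: pd.DataFrame  # gene_id, planted_sd, sd_motif_start, start_codon, ...
    realized_sd_fraction: float
    config: GeneratorConfig


def _mix(base: np.ndarray, target: dict[str, float], strength: float) -> np.ndarray:
    t = np.array([target.get(n, 0.0) for n in _NTS])
    return (1.0 - strength) * base + strength * t


def _upstream_profile(cfg: GeneratorConfig) -> np.ndarray:
    """(upstream_length, 4) per-position probabilities before per-gene effects.

    Row k corresponds to position k - upstream_length (i.e. row 0 is -100,
    row 99 is -1).
    """
    P = np.tile(cfg.background_array, (cfg.upstream_length, 1))

    def rows(lo: int, hi: int) -> slice:
        return slice(cfg.upstream_length + lo, cfg.upstream_length + hi + 1)

    s = cfg.leaderless_strength
    if cfg.leaderless_profile == "archaeal":
        P[rows(-27, -23)] = _mix(cfg.background_array, {"U": 0.5, "A": 0.5}, s)
        P[rows(-31, -29)] = _mix(cfg.background_array, {"A": 1.0}, s)
        P[rows(-37, -33)] = _mix(cfg.background_array, {"G": 0.5, "C": 0.5}, s)
    elif cfg.leaderless_profile == "bacterial":
        P[rows(-20, -10)] = _mix(cfg.background_array, {"A": 0.55, "U": 0.45}, s)
    return P


def _draw(rng: np.random.Generator, probs: np.ndarray, size: int) -> list[str]:
    """``size`` iid bases from one probability vector (inverse-CDF sampling)."""
    cum = np.cumsum(probs / probs.sum())
    idx = np.searchsorted(cum, rng.random(size), side="right")
    return [_NTS[min(i, 3)] for i in idx]


def _draw_rows(rng: np.random.Generator, profile: np.ndarray) -> list[str]:
    """One base per row of a (L, 4) per-position probability matrix."""
    cum = np.cumsum(profile / profile.sum(axis=1, keepdims=True), axis=1)
    u = rng.random(profile.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return [_NTS[min(i, 3)] for i in idx]


def _draw_codon(rng: np.random.Generator, bg: np.ndarray) -> str:
    while True:
        codon = "".join(_draw(rng, bg, 3))
        if codon not in STOP_CODONS:
            return codon


@dataclass
class _Gene:
    gene_id: str
    upstream: str
    cds: str
    planted_sd: bool
    sd_motif_start: int | None
    relaxed: bool
    plus_one: bool
    strand: str = "+"


def _make_gene(cfg: GeneratorConfig, rng: np.random.Generator, idx: int,
               profile: np.ndarray) -> _Gene:
    planted_sd = bool(rng.random() < cfg.sd_fraction)
    in_non_sd_scope = not planted_sd
    relaxed = False
    if cfg.symmetric_bias_strength > 0 and (
        cfg.symmetric_bias_scope == "all" or in_non_sd_scope
    ):
        relaxed = bool(rng.random() < cfg.symmetric_bias_strength)
    plus_one = cfg.plus_one_scope == "all" or (
        cfg.plus_one_scope == "non_sd" and in_non_sd_scope
    )

    # relaxed genes: one coherent, self-unpairable A/U-skewed pool per gene
    relaxed_pool: tuple[tuple[str, str], tuple[float, float]] | None = None
    if relaxed:
        if rng.random() < 0.5:
            relaxed_pool = (("A", "G"), (0.8, 0.2))
        else:
            relaxed_pool = (("U", "C"), (0.8, 0.2))

    def pool_base() -> str:
        letters, probs = relaxed_pool
        return letters[0] if rng.random() < probs[0] else letters[1]

    # upstream, position by position
    up = _draw_rows(rng, profile)
    blo, bhi = cfg.symmetric_bias_region
    if relaxed and blo < 0:
        for pos in range(blo, min(bhi, -1) + 1):
            up[cfg.upstream_length + pos] = pool_base()
    sd_start: int | None = None
    if planted_sd:
        lo, hi = cfg.sd_placement
        sd_start = int(rng.integers(lo, hi + 1))
        for off, base in enumerate(cfg.sd_motif):
            if rng.random() < cfg.sd_motif_strength:
                up[cfg.upstream_length + sd_start + off] = base
    upstream = "".join(up)

    # CDS: start codon + internal codons + stop
    starts = list(cfg.start_codon_usage)
    weights = np.array([cfg.start_codon_usage[s] for s in starts])
    start_codon = starts[rng.choice(len(starts), p=weights / weights.sum())]
    n_internal = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    bg = cfg.background_array
    internal = _draw(rng, bg, 3 * n_internal)
    codons = [start_codon]
    for c in range(n_internal):
        codon = "".join(internal[3 * c : 3 * c + 3])
        if codon in STOP_CODONS:
            codon = _draw_codon(rng, bg)
        codons.append(codon)
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    cds = list("".join(codons))

    if relaxed and bhi >= 4:
        # rewrite CDS positions +4..bhi from the gene's pool, keeping the
        # reading frame free of premature stops (pool codons cannot be stops,
        # but codons straddling the region boundary are rechecked)
        for pos in range(max(blo, 4), bhi + 1):
            if pos - 1 < len(cds) - 3:  # never touch the stop codon
                cds[pos - 1] = pool_base()
        c = 1
        while 3 * c + 3 <= len(cds) - 3 and 3 * c < bhi + 3:
            while "".join(cds[3 * c : 3 * c + 3]) in STOP_CODONS:
                for k in range(3 * c, 3 * c + 3):
                    if 4 <= k + 1 <= bhi:
                        cds[k] = pool_base()
                    else:
                        cds[k] = _draw(rng, bg, 1)[0]
            c += 1
    if plus_one:
        motif = revcomp_rna(cfg.tail)
        for k, base in enumerate(motif):
            cds[k] = base
        # codon straddling the motif end could have become a stop
        c = len(motif) // 3
        while 3 * c + 3 <= len(cds) - 3:
            if "".join(cds[3 * c : 3 * c + 3]) not in STOP_CODONS:
                break
            for k in range(3 * c, 3 * c + 3):
                if k >= len(motif):
                    cds[k] = _draw(rng, bg, 1)[0]
        start_codon = motif[:3]

    return _Gene(
        gene_id=f"{cfg.species_id}_g{idx + 1:04d}",
        upstream=upstream,
        cds="".join(cds),
        planted_sd=planted_sd,
        sd_motif_start=sd_start,
        relaxed=relaxed,
        plus_one=plus_one,
    )


def generate_species(cfg: GeneratorConfig) -> tuple[SpeciesInput, GroundTruth]:
    """Generate one synthetic species (in memory) with its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    profile = _upstream_profile(cfg)
    genes = [_make_gene(cfg, rng, i, profile) for i in range(cfg.n_genes)]
    for g in genes:
        if rng.random() < cfg.minus_strand_fraction:
            g.strand = "-"

    contig_parts: list[str] = []
    annotations: list[Annotation] = []
    offset = 0  # 0-based length so far

    def spacer() -> str:
        return "".join(_draw(rng, cfg.background_array, cfg.spacer_length))

    contig_parts.append(spacer())
    offset += cfg.spacer_length
    for g in genes:
        block = g.upstream + g.cds
        if g.strand == "+":
            start = offset + len(g.upstream) + 1
            end = offset + len(block)
        else:
            block = revcomp_rna(block)
            start = offset + 1
            end = offset + len(g.cds)
        contig_parts.append(block)
        annotations.append(("contig1", g.strand, start, end, g.gene_id))
        offset += len(block)
        contig_parts.append(spacer())
        offset += cfg.spacer_length
    contig_dna = "".join(contig_parts).replace("U", "T")

    sp = SpeciesInput(
        species_id=cfg.species_id,
        genome={"contig1": contig_dna},
        annotations=annotations,
        anti_sd_tail=cfg.tail,
    )
    truth_df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "planted_sd": g.planted_sd,
                "sd_motif_start": g.sd_motif_start,
                "start_codon": g.cds[:3],
                "relaxed": g.relaxed,
                "plus_one": g.plus_one,
                "strand": g.strand,
            }
            for g in genes
        ]
    )
    truth = GroundTruth(
        genes=truth_df,
        realized_sd_fraction=float(truth_df["planted_sd"].mean()),
        config=cfg,
    )
    return sp, truth


def write_species(
    sp: SpeciesInput, truth: GroundTruth | None, out_dir: str | Path
) -> dict[str, Path]:
    """Write genome FASTA, annotation TSV, tail FASTA (and truth TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / f"{sp.species_id}.fa",
        "annotation": out / f"{sp.species_id}.annotation.tsv",
        "tail": out / f"{sp.species_id}.tail.fa",
    }
    with open(paths["genome"], "w") as fh:
        for contig, seq in sp.genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["annotation"], "w") as fh:
        fh.write("# contig\tstrand\tstart\tend\tgene_id\n")
        for contig, strand, start, end, gene_id in sp.annotations:
            fh.write(f"{contig}\t{strand}\t{start}\t{end}\t{gene_id}\n")
    with open(paths["tail"], "w") as fh:
        fh.write(f">{sp.species_id}_16S_tail\n{sp.anti_sd_tail}\n")
    if truth is not None:
        paths["truth"] = out / f"{sp.species_id}.truth.tsv"
        truth.genes.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def generate_cohort(
    configs: list[GeneratorConfig], out_dir: str | Path | None = None
) -> dict[str, tuple[SpeciesInput, GroundTruth]]:
    """Generate a multi-species fixture set, optionally writing files."""
    if len(configs) < 2:
        raise InputError("a cohort needs >= 2 species configs")
    ids = [c.species_id for c in configs]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate species ids in cohort: {ids}")
    cohort = {}
    for cfg in configs:
        sp, truth = generate_species(cfg)
        if out_dir is not None:
            write_species(sp, truth, Path(out_dir) / cfg.species_id)
        cohort[cfg.species_id] = (sp, truth)
    return cohort


def config_variants(base: GeneratorConfig, **overrides) -> GeneratorConfig:
    """A copy of ``base`` with field overrides (seeds, profiles, ...)."""
    return dataclasses.replace(base, **overrides)
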