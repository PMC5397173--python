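"""Per-species and cross-species orchestration of all analysis stages.

``run_species`` composes extract -> classify -> G-statistics (SD and non-SD
subsets) -> folding randomization tests -> 16S-tail interaction profile for
one species; ``run_cohort`` adds the cross-species stages (bias-vector
similarity, UPGMA clustering, PCA, paired +1 interaction test) with
Bonferroni correction across species, and emits a per-species summary
table. All fixed constants of the method (SD region -20..-5, threshold
-0.8924 kcal/mol, bias window -40..-1, fold window -20..+20, 100x
randomization, chi-square df = 3) live in :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DegenerateInputError
from .gstats import GProfile, expected_frequencies, g_profile
from .hybridization import (
    DEFAULT_SD_REGION,
    DEFAULT_THRESHOLD,
    NNParameterTable,
    classify_genes,
    split_by_label,
)
from .interaction_profile import (
    group_profiles,
    plus_one_paired_test,
    plus_one_species_test,
)
from .randomization_tests import (
    RandomizationConfig,
    TestOutcome,
    apply_bonferroni,
    folding_vs_random_test,
    sd_vs_nonsd_folding_test,
)
from .sequence_io import SpeciesInput, extract_gene_records
from .similarity import (
    DEFAULT_BIAS_WINDOW,
    BiasVector,
    Dendrogram,
    PCAResult,
    SimilarityMatrix,
    cluster,
    pca,
    similarity_matrix,
)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one place; CLI flags override fields."""

    sd_region: tuple[int, int] = DEFAULT_SD_REGION
    threshold: float = DEFAULT_THRESHOLD
    gstats_window: tuple[int, int] = (-100, 99)
    bias_window: tuple[int, int] = DEFAULT_BIAS_WINDOW
    fold_window: tuple[int, int] = (20, 20)
    multiplier: int = 100
    seed: int = 0
    alphas: tuple[float, ...] = (0.05, 0.01)
    expectations: str = "subset"  # subset | all
    interaction_span: tuple[int, int] = (-40, 40)
    pca_components: int = 3
    allow_gu: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def species_seed(base_seed: int, species_id: str) -> int:
    """Deterministic per-species RNG seed below 2^31."""
    return (base_seed * 100003 + zlib.crc32(species_id.encode())) % (2**31)


@dataclass
class SpeciesReport:
    """Per-species summary: counts, test outcomes and skip reasons."""

    species_id: str
    n_annotations: int
    n_records: int
    n_dropped: int
    n_sd: int
    n_nonsd: int
    outcomes: dict[str, TestOutcome] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def sd_fraction(self) -> float:
        return self.n_sd / self.n_records if self.n_records else float("nan")

    def flag(self, test_name: str, alpha: float) -> str:
        out = self.outcomes.get(test_name)
        if out is None or out.corrected_p >= alpha:
            return ""
        return out.extra.get("trend", out.direction)


@dataclass
class SpeciesResult:
    """Full artifact bundle for one species."""

    report: SpeciesReport
    classifications: pd.DataFrame
    profiles: dict[str, GProfile]
    interaction: pd.DataFrame | None


def run_species(
    sp: SpeciesInput,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SpeciesResult:
    """Run every per-species stage; artifacts optionally written as TSVs."""
    if config is None:
        config = PipelineConfig()
    params = NNParameterTable.default().with_gu(config.allow_gu)
    extraction = extract_gene_records(sp)
    records = extraction.records
    classifications = classify_genes(
        records, sp.anti_sd_tail, params, config.threshold, config.sd_region
    )
    sd_records, nonsd_records = split_by_label(records, classifications)
    report = SpeciesReport(
        species_id=sp.species_id,
        n_annotations=len(sp.annotations),
        n_records=len(records),
        n_dropped=extraction.n_dropped,
        n_sd=len(sd_records),
        n_nonsd=len(nonsd_records),
    )

    profiles: dict[str, GProfile] = {}
    for label, subset in (("SD", sd_records), ("non-SD", nonsd_records)):
        if not subset:
            report.skipped[f"gstats_{label}"] = "empty gene group"
            continue
        expected = expected_frequencies(
            records if config.expectations == "all" else subset
        )
        profiles[label] = g_profile(subset, expected, config.gstats_window)

    rand_cfg = RandomizationConfig(
        multiplier=config.multiplier,
        seed=species_seed(config.seed, sp.species_id),
        window=config.fold_window,
        alphas=config.alphas,
    )
    try:
        report.outcomes["folding_vs_random"] = folding_vs_random_test(
            nonsd_records, rand_cfg, species_id=sp.species_id
        )
    except DegenerateInputError as exc:
        report.skipped["folding_vs_random"] = str(exc)
    try:
        report.outcomes["sd_vs_nonsd_folding"] = sd_vs_nonsd_folding_test(
            sd_records, nonsd_records, rand_cfg, species_id=sp.species_id
        )
    except DegenerateInputError as exc:
        report.skipped["sd_vs_nonsd_folding"] = str(exc)

    interaction: pd.DataFrame | None = None
    if sd_records and nonsd_records:
        interaction = group_profiles(
            sd_records, nonsd_records, sp.anti_sd_tail, params,
            span=config.interaction_span,
        )
        try:
            report.outcomes["plus_one_interaction"] = plus_one_species_test(
                sd_records, nonsd_records, sp.anti_sd_tail, params,
                species_id=sp.species_id, alpha=max(config.alphas),
            )
        except DegenerateInputError as exc:
            report.skipped["plus_one_interaction"] = str(exc)
    else:
        report.skipped["interaction_profile"] = "one gene group is empty"

    result = SpeciesResult(
        report=report,
        classifications=pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "sd_region_dG": c.sd_region_dG,
                    "best_offset": c.best_offset,
                    "label": c.label,
                    "note": c.note,
                }
                for c in classifications
            ]
        ),
        profiles=profiles,
        interaction=interaction,
    )
    if out_dir is not None:
        _write_species_artifacts(result, sp, config, Path(out_dir))
    return result


def _write_species_artifacts(
    result: SpeciesResult, sp: SpeciesInput, config: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.classifications.to_csv(out / "classifications.tsv", sep="\t", index=False)
    for label, profile in result.profiles.items():
        safe = label.replace("-", "").lower()
        profile.to_frame().to_csv(out / f"gprofile_{safe}.tsv", sep="\t", index=False)
    if result.interaction is not None:
        result.interaction.to_csv(out / "interaction_profile.tsv", sep="\t", index=False)
    outcome_frame(result.report).to_csv(out / "test_outcomes.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "species_id": sp.species_id,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "species_seed": species_seed(config.seed, sp.species_id),
        "rng": "numpy PCG64",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def outcome_frame(report: SpeciesReport) -> pd.DataFrame:
    rows = []
    for name, o in report.outcomes.items():
        rows.append(
            {
                "species_id": report.species_id,
                "test_name": name,
                "statistic": o.statistic,
                "raw_p": o.raw_p,
                "corrected_p": o.corrected_p,
                "direction": o.direction,
                "n_obs": o.n_obs,
                "n_null": o.n_null,
            }
        )
    for name, reason in report.skipped.items():
        rows.append({"species_id": report.species_id, "test_name": name,
                     "direction": f"skipped: {reason}"})
    return pd.DataFrame(rows)


@dataclass
class CohortResult:
    """Cross-species artifact bundle."""

    species_results: dict[str, SpeciesResult]
    similarity: SimilarityMatrix
    dendrogram: Dendrogram
    pca: PCAResult
    paired_plus_one: TestOutcome | None
    summary: pd.DataFrame


def run_cohort(
    inputs: list[SpeciesInput],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    group_labels: dict[str, str] | None = None,
) -> CohortResult:
    """Run the full pipeline on >= 2 species and compare them.

    Bias vectors are built from each species' non-SD G-profile over the
    configured window; Bonferroni factors use the number of species in the
    run. ``group_labels`` optionally assigns display groups (e.g. phyla) in
    the summary table.
    """
    if config is None:
        config = PipelineConfig()
    if len(inputs) < 2:
        raise DegenerateInputError("a cohort run needs >= 2 species")
    species_results: dict[str, SpeciesResult] = {}
    for sp in inputs:
        sp_dir = None if out_dir is None else Path(out_dir) / sp.species_id
        species_results[sp.species_id] = run_species(sp, config, sp_dir)

    vectors = []
    for sid, res in species_results.items():
        if "non-SD" not in res.profiles:
            raise DegenerateInputError(
                f"species {sid!r} has no non-SD genes; cannot build a bias vector"
            )
        vectors.append(
            BiasVector.from_profile(sid, res.profiles["non-SD"], config.bias_window)
        )
    sim = similarity_matrix(vectors)
    dendro = cluster(sim)
    k = min(config.pca_components, len(vectors) - 1, len(vectors[0].values))
    pca_res = pca(vectors, k)

    m = len(inputs)
    for name in ("folding_vs_random", "sd_vs_nonsd_folding", "plus_one_interaction"):
        outs = [
            r.report.outcomes[name]
            for r in species_results.values()
            if name in r.report.outcomes
        ]
        apply_bonferroni(outs, m)

    rows = []
    for sid, res in species_results.items():
        o = res.report.outcomes.get("plus_one_interaction")
        if o is not None:
            rows.append(
                {"species_id": sid, "mean_sd": o.extra["mean_sd"],
                 "mean_nonsd": o.extra["mean_nonsd"]}
            )
    paired = None
    if len(rows) >= 2:
        paired = plus_one_paired_test(pd.DataFrame(rows), alpha=max(config.alphas))

    summary = cohort_summary(species_results, config, group_labels)
    result = CohortResult(
        species_results=species_results,
        similarity=sim,
        dendrogram=dendro,
        pca=pca_res,
        paired_plus_one=paired,
        summary=summary,
    )
    if out_dir is not None:
        _write_cohort_artifacts(result, config, Path(out_dir))
    return result


def cohort_summary(
    species_results: dict[str, SpeciesResult],
    config: PipelineConfig,
    group_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species summary table (counts, fractions, test flags)."""
    a_loose, a_strict = max(config.alphas), min(config.alphas)
    rows = []
    for sid, res in species_results.items():
        rep = res.report
        row = {
            "species_id": sid,
            "group": (group_labels or {}).get(sid, ""),
            "n_genes": rep.n_records,
            "n_SD": rep.n_sd,
            "n_nonSD": rep.n_nonsd,
            "sd_fraction": rep.sd_fraction,
        }
        for name, short in (
            ("folding_vs_random", "rand"),
            ("sd_vs_nonsd_folding", "sdcmp"),
            ("plus_one_interaction", "plus1"),
        ):
            o = rep.outcomes.get(name)
            row[f"{short}_p"] = o.corrected_p if o else np.nan
            row[f"{short}_{a_loose}"] = rep.flag(name, a_loose)
            row[f"{short}_{a_strict}"] = rep.flag(name, a_strict)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_cohort_artifacts(
    result: CohortResult, config: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    result.similarity.D.to_csv(out / "similarity_D.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
    result.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    result.pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    if result.paired_plus_one is not None:
        o = result.paired_plus_one
        pd.DataFrame(
            [
                {
                    "test_name": o.test_name,
                    "statistic": o.statistic,
                    "raw_p": o.raw_p,
                    "direction": o.direction,
                    "n_species": o.n_obs,
                }
            ]
        ).to_csv(out / "paired_plus_one.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "species": list(result.species_results),
        "pca_variance_ratio": [float(v) for v in result.pca.variance_ratio],
        "rng": "numpy PCG64",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
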