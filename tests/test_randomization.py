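"""Column-shuffle null model and the folding comparison tests."""

import numpy as np
import pytest
from scipy import stats

from sdbiasscan.errors import DegenerateInputError, InputError
from sdbiasscan.randomization_tests import (
    RandomizationConfig,
    bonferroni,
    column_shuffle,
    folding_vs_random_test,
    rank_sum_compare,
    sd_vs_nonsd_folding_test,
)
from sdbiasscan.sequence_io import extract_gene_records
from sdbiasscan.synthetic_data import GeneratorConfig, generate_species

from conftest import random_rna


class TestColumnShuffle:
    def test_identical_inputs_reproduced_exactly(self):
        windows = ["ACGUACGU"] * 5
        out = column_shuffle(windows, RandomizationConfig(multiplier=10, seed=1))
        assert len(out) == 50
        assert set(out) == {"ACGUACGU"}

    def test_output_count_is_multiplier_fold(self, rng):
        windows = [random_rna(rng, 12) for _ in range(37)]
        out = column_shuffle(windows, RandomizationConfig(multiplier=100, seed=2))
        assert len(out) == 3700

    def test_column_compositions_preserved_within_sampling_error(self, rng):
        windows = [random_rna(rng, 10) for _ in range(100)]
        out = column_shuffle(windows, RandomizationConfig(multiplier=100, seed=3))
        assert len(out) == 10_000
        for j in range(10):
            obs_col = [w[j] for w in windows]
            null_col = [w[j] for w in out]
            exp_frac = np.array([obs_col.count(n) / len(obs_col) for n in "ACGU"])
            got = np.array([null_col.count(n) for n in "ACGU"])
            keep = exp_frac > 0
            chi = stats.chisquare(got[keep], exp_frac[keep] * len(out))
            assert chi.pvalue > 1e-5
            assert np.all(got[~keep] == 0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            column_shuffle(["ACGU", "ACG"], RandomizationConfig(seed=0))

    def test_same_seed_same_output(self, rng):
        windows = [random_rna(rng, 8) for _ in range(5)]
        cfg = RandomizationConfig(multiplier=3, seed=99)
        assert column_shuffle(windows, cfg) == column_shuffle(windows, cfg)


class TestBonferroni:
    def test_arithmetic_cap_and_identity(self):
        assert bonferroni([0.001], 10) == [pytest.approx(0.01)]
        assert bonferroni([0.5], 260) == [1.0]
        assert bonferroni([0.37], 1) == [0.37]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(InputError):
            bonferroni([1.5], 2)


class TestFoldingVsRandom:
    def test_identical_samples_give_p_one(self):
        out = rank_sum_compare([1.0, 1.0, 1.0], [1.0, 1.0], "s", "t")
        assert out.raw_p == 1.0
        assert out.direction == "none"

    def test_self_null_calibration(self):
        """Observed data drawn from the shuffle model itself rejects at ~alpha.

        200 seeded replicates, each testing a column-shuffle draw against its
        own shuffle null; short windows keep the folding cheap without
        changing the statistical machinery under test.
        """
        base_cfg = GeneratorConfig(species_id="cal", seed=77, n_genes=40)
        sp, _ = generate_species(base_cfg)
        recs = extract_gene_records(sp).records
        alpha = 0.05
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            cfg = RandomizationConfig(multiplier=20, seed=1000 + rep,
                                      window=(10, 10))
            from sdbiasscan.folding import fold_windows

            windows, _, _ = fold_windows(recs, cfg.window)
            observed = column_shuffle(windows, RandomizationConfig(
                multiplier=1, seed=5000 + rep, window=cfg.window))
            from sdbiasscan.folding import mfe_energies

            null = column_shuffle(observed, cfg)
            out = rank_sum_compare(
                mfe_energies(observed), mfe_energies(null), "cal", "self_null"
            )
            if out.raw_p < alpha:
                rejections += 1
        rate = rejections / n_reps
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) < 3 * se

    def test_planted_relaxed_structure_detected(self):
        """Per-gene coherent A/U-skewed centers fold weaker than their null."""
        cfg = GeneratorConfig(
            species_id="rel", seed=5, n_genes=300, sd_fraction=0.0,
            background={"A": 0.15, "C": 0.35, "G": 0.35, "U": 0.15},
            symmetric_bias_strength=0.9, symmetric_bias_scope="all",
        )
        sp, truth = generate_species(cfg)
        recs = extract_gene_records(sp).records
        out = folding_vs_random_test(
            recs, RandomizationConfig(multiplier=100, seed=11), species_id="rel"
        )
        assert out.n_null == 100 * out.n_obs
        assert out.corrected_p < 0.01
        assert out.direction == "observed_weaker"

    def test_too_few_records_rejected(self):
        with pytest.raises(DegenerateInputError):
            folding_vs_random_test([], RandomizationConfig(seed=1))


class TestSdVsNonsd:
    def test_identical_groups_give_p_one(self):
        cfg = GeneratorConfig(species_id="e", seed=8, n_genes=10)
        recs = extract_gene_records(generate_species(cfg)[0]).records
        out = sd_vs_nonsd_folding_test(recs, recs, species_id="e")
        assert out.raw_p == 1.0
        assert out.direction == "none"

    def test_planted_group_difference_detected(self):
        """Relaxed non-SD genes vs structured SD genes at n=200/200."""
        cfg = GeneratorConfig(
            species_id="mix", seed=6, n_genes=400, sd_fraction=0.5,
            background={"A": 0.15, "C": 0.35, "G": 0.35, "U": 0.15},
            symmetric_bias_strength=0.9, symmetric_bias_scope="non_sd",
        )
        sp, truth = generate_species(cfg)
        recs = extract_gene_records(sp).records
        planted = set(truth.genes.loc[truth.genes.planted_sd, "gene_id"])
        sd = [r for r in recs if r.gene_id in planted]
        nonsd = [r for r in recs if r.gene_id not in planted]
        out = sd_vs_nonsd_folding_test(sd, nonsd, species_id="mix")
        assert out.corrected_p < 0.01
        assert out.direction == "nonsd_weaker"

    def test_bonferroni_across_species(self):
        from sdbiasscan.randomization_tests import TestOutcome, apply_bonferroni

        outs = [
            TestOutcome("s1", "t", 0.0, 0.004, 0.004, "none", 5, 5,
                        extra={"trend": "nonsd_weaker"}),
            TestOutcome("s2", "t", 0.0, 0.5, 0.5, "none", 5, 5,
                        extra={"trend": "sd_weaker"}),
        ]
        apply_bonferroni(outs, m=10)
        assert outs[0].corrected_p == pytest.approx(0.04)
        assert outs[0].direction == "nonsd_weaker"
        assert outs[1].corrected_p == 1.0
        assert outs[1].direction == "none"
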