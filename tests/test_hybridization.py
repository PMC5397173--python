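"""Nearest-neighbor duplex energies, the anti-SD scan and SD classification."""

import numpy as np
import pytest

from sdbiasscan.errors import AlphabetError, InputError
from sdbiasscan.hybridization import (
    DEFAULT_SD_REGION,
    DEFAULT_THRESHOLD,
    NNParameterTable,
    classify_genes,
    duplex_energy,
    revcomp_rna,
    scan_min_energy,
    threshold_from_three_base_duplexes,
)
from sdbiasscan.synthetic_data import DEFAULT_TAIL

from conftest import make_record, random_rna


class TestDuplexEnergy:
    def test_three_pair_duplex_hand_sum(self, params):
        # G.C, G.C, A.U pairs: stacks GG/CC (-3.26) + GA/CU (-2.35),
        # +4.09 initiation, +0.45 terminal A.U
        assert duplex_energy("GGA", "UCC", params) == pytest.approx(-1.07)

    def test_no_complementary_pairs_scores_zero(self, params):
        assert duplex_energy("AAA", "CCC", params) == 0.0

    def test_isolated_single_pair_contributes_nothing(self, params):
        # middle A.U pair flanked by mismatches: no stack, no initiation
        assert duplex_energy("CAC", "CUC", params) == 0.0

    def test_endergonic_duplex_reported_as_no_interaction(self, params):
        # lone A.U/A.U stack: -0.93 + 4.09 + 2*0.45 > 0 -> floored to 0
        assert duplex_energy("AA", "UU", params) == 0.0

    def test_three_base_sd_duplex_mean_near_documented_cutoff(self, params):
        mean = threshold_from_three_base_duplexes(params)
        assert mean == pytest.approx(-0.7367, abs=1e-3)
        # the published constant is nearby but not identical
        assert abs(mean - DEFAULT_THRESHOLD) < 0.2

    def test_unequal_lengths_rejected(self, params):
        with pytest.raises(InputError):
            duplex_energy("GGAA", "UCC", params)

    def test_non_rna_characters_rejected(self, params):
        with pytest.raises(AlphabetError):
            duplex_energy("GGN", "UCC", params)

    def test_strand_role_swap_symmetry(self, params, rng):
        for _ in range(50):
            x = random_rna(rng, int(rng.integers(4, 12)))
            y = revcomp_rna(x)
            assert duplex_energy(x, y, params) == pytest.approx(
                duplex_energy(y, x, params)
            )

    def test_gu_wobble_only_when_enabled(self, params):
        # GGG vs CCU pairs G.U,G.C,G.C; the G.U stack exists only with wobble
        assert duplex_energy("GGG", "CCU", params) == 0.0
        assert duplex_energy("GGG", "CCU", params.with_gu()) < 0.0


def brute_force_scan(region: str, tail: str, params) -> float:
    """Independent all-offset enumeration using direct slicing."""
    rt = tail[::-1]
    best = 0.0
    for k in range(-(len(rt) - 2), len(region) - 1):
        j0, j1 = max(0, -k), min(len(rt) - 1, len(region) - 1 - k)
        if j1 - j0 + 1 < 2:
            continue
        sub_region = region[k + j0 : k + j1 + 1]
        sub_tail = tail[len(tail) - 1 - j1 : len(tail) - j0]
        best = min(best, duplex_energy(sub_region, sub_tail, params))
    return best


class TestScan:
    def test_planted_full_complement_found_at_its_offset(self, params):
        tail = DEFAULT_TAIL
        motif = revcomp_rna(tail)
        region = "AAAAA" + motif + "AAAAA"
        full = duplex_energy(motif, tail, params)
        res = scan_min_energy(region, tail, params)
        assert res.min_dG == pytest.approx(full)
        assert res.best_offset == 5
        assert res.min_dG == min(res.per_offset_dG.values())

    def test_matches_brute_force_enumeration(self, params, rng):
        for _ in range(300):
            region = random_rna(rng, 16)
            tail = random_rna(rng, 13)
            res = scan_min_energy(region, tail, params)
            assert res.min_dG == pytest.approx(brute_force_scan(region, tail, params))

    def test_minimum_bounds_every_offset(self, params, rng):
        region, tail = random_rna(rng, 30), DEFAULT_TAIL
        res = scan_min_energy(region, tail, params)
        assert all(res.min_dG <= e for e in res.per_offset_dG.values())

    def test_appending_bases_never_weakens_minimum(self, params, rng):
        for _ in range(30):
            region = random_rna(rng, 15)
            ext = region + random_rna(rng, 5)
            assert (
                scan_min_energy(ext, DEFAULT_TAIL, params).min_dG
                <= scan_min_energy(region, DEFAULT_TAIL, params).min_dG + 1e-12
            )

    def test_too_short_region_rejected(self, params):
        with pytest.raises(InputError):
            scan_min_energy("A", DEFAULT_TAIL, params)


class TestClassification:
    def test_planted_ggagg_is_sd(self, params):
        up = "A" * 88 + "GGAGG" + "A" * 7  # motif at -12..-8
        rec = make_record(upstream=up)
        (c,) = classify_genes([rec], DEFAULT_TAIL, params)
        assert c.label == "SD"
        assert c.sd_region_dG < DEFAULT_THRESHOLD

    def test_poly_a_upstream_is_non_sd(self, params):
        (c,) = classify_genes([make_record(upstream="A" * 100)], DEFAULT_TAIL, params)
        assert c.sd_region_dG == 0.0
        assert c.label == "non-SD"

    def test_default_constants(self):
        assert DEFAULT_THRESHOLD == -0.8924
        assert DEFAULT_SD_REGION == (-20, -5)

    def test_energy_exactly_at_threshold_is_sd(self, params):
        up = "A" * 88 + "GGAGG" + "A" * 7
        rec = make_record(upstream=up)
        (c,) = classify_genes([rec], DEFAULT_TAIL, params)
        (c2,) = classify_genes([rec], DEFAULT_TAIL, params,
                               threshold=c.sd_region_dG)
        assert c2.label == "SD"

    def test_short_upstream_defaults_to_non_sd(self, params):
        rec = make_record(upstream="AC")  # covers only -2..-1, outside -20..-5
        (c,) = classify_genes([rec], DEFAULT_TAIL, params)
        assert c.label == "non-SD"
        assert c.note == "sd_region_too_short"

    def test_every_record_gets_exactly_one_label(self, params, rng):
        recs = [make_record(gene_id=f"g{i}", upstream=random_rna(rng, 100))
                for i in range(60)]
        cls = classify_genes(recs, DEFAULT_TAIL, params)
        assert len(cls) == len(recs)
        n_sd = sum(c.label == "SD" for c in cls)
        n_non = sum(c.label == "non-SD" for c in cls)
        assert n_sd + n_non == len(recs)


def test_parameter_table_symmetry_validated():
    table = dict(NNParameterTable.default().stack_energy)
    table["GG/CC"] = -1.0  # breaks two-fold symmetry with CC/GG
    with pytest.raises(InputError):
        NNParameterTable(stack_energy=table)
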