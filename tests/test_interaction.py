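"""Positional 16S-tail interaction profiles and the +1 tests."""

import numpy as np
import pytest

from sdbiasscan.hybridization import (
    classify_genes,
    duplex_energy,
    revcomp_rna,
    split_by_label,
)
from sdbiasscan.interaction_profile import (
    group_profiles,
    plus_one_paired_test,
    plus_one_tests,
    positional_energy,
)
from sdbiasscan.sequence_io import GeneRecord, extract_gene_records
from sdbiasscan.synthetic_data import GeneratorConfig, generate_species

from conftest import make_record, random_rna

# tail whose reverse complement starts with AUG, so a full-complement site
# can legally sit at +1
MOTIF = "AUGGCUGGUCCGA"
TAIL = revcomp_rna(MOTIF)


class TestPositionalEnergy:
    def test_planted_complement_at_plus_one_is_profile_minimum(self, params):
        rec = GeneRecord("g", upstream="A" * 100, cds=MOTIF + "GCU" * 5 + "UAA")
        prof = positional_energy(rec, TAIL, params, span=(-40, 10))
        assert min(prof, key=prof.get) == 1
        assert prof[1] == pytest.approx(duplex_energy(MOTIF, TAIL, params))

    def test_poly_a_mrna_gives_flat_zero_profile(self, params):
        rec = make_record(upstream="A" * 100, cds_body="AAA" * 20, start="AUA")
        prof = positional_energy(rec, "CCGCCGCCGCCGC", params, span=(-40, 10))
        assert prof
        assert all(v == 0.0 for v in prof.values())

    def test_each_anchor_matches_direct_duplex_energy(self, params, rng):
        rec = make_record(upstream=random_rna(rng, 100), n_codons=30)
        seq = rec.upstream + rec.cds
        tail = random_rna(rng, 13)
        prof = positional_energy(rec, tail, params, span=(-100, 100))
        for pos, dg in prof.items():
            idx = 100 + pos if pos < 0 else 100 + pos - 1
            assert dg == pytest.approx(duplex_energy(seq[idx : idx + 13], tail, params))
        # anchors too close to the 3' end are absent
        assert max(prof) == len(rec.cds) - 13 + 1

    def test_short_record_yields_empty_profile(self, params):
        rec = GeneRecord("g", upstream="", cds="AUGUAA")
        assert positional_energy(rec, TAIL, params) == {}


class TestProfileConsistency:
    def test_planted_sd_match_equals_classifier_energy(self, params):
        # full tail complement inside -20..-8: scan optimum is a full overlap
        up = "A" * 80 + revcomp_rna("GAUCACCUCCUUA") + "A" * 7
        rec = make_record(upstream=up)
        (c,) = classify_genes([rec], "GAUCACCUCCUUA", params)
        prof = positional_energy(rec, "GAUCACCUCCUUA", params, span=(-20, -5))
        assert min(prof.values()) == pytest.approx(c.sd_region_dG)

    def test_scan_bounds_full_overlap_anchors_inside_region(self, params, rng):
        for _ in range(20):
            rec = make_record(upstream=random_rna(rng, 100))
            (c,) = classify_genes([rec], "GAUCACCUCCUUA", params)
            prof = positional_energy(rec, "GAUCACCUCCUUA", params, span=(-20, -17))
            # windows for anchors -20..-17 lie inside the scanned -20..-5 slice
            assert c.sd_region_dG <= min(prof.values()) + 1e-12


class TestGroupProfiles:
    def test_single_gene_group_profile_equals_its_energies(self, params):
        rec = make_record(upstream="ACGU" * 25, n_codons=30)
        other = make_record(gene_id="g2", upstream="UGCA" * 25, n_codons=30)
        df = group_profiles([rec], [other], TAIL, params, span=(-10, 10))
        sd = df[df.group == "SD"].set_index("position")
        prof = positional_energy(rec, TAIL, params, span=(-10, 10))
        for pos, dg in prof.items():
            assert sd.loc[pos, "mean_dG"] == pytest.approx(dg)
            assert sd.loc[pos, "n"] == 1

    def test_pooled_groups_give_count_weighted_mean(self, params, rng):
        recs = [make_record(gene_id=f"g{i}", upstream=random_rna(rng, 100))
                for i in range(6)]
        a, b = recs[:2], recs[2:]
        df_a = group_profiles(a, [], TAIL, params, span=(-5, 5))
        df_all = group_profiles(recs, [], TAIL, params, span=(-5, 5))
        pos = 1
        mean_a = df_a[df_a.position == pos].mean_dG.iloc[0]
        prof_b = [positional_energy(r, TAIL, params, span=(pos, pos))[pos] for r in b]
        expected = (mean_a * len(a) + sum(prof_b)) / len(recs)
        got = df_all[df_all.position == pos].mean_dG.iloc[0]
        assert got == pytest.approx(expected)


class TestPlusOneTests:
    def test_identical_group_means_give_p_one(self):
        import pandas as pd

        df = pd.DataFrame(
            {"species_id": list("abcd"), "mean_sd": [1.0, 2.0, 3.0, 4.0],
             "mean_nonsd": [1.0, 2.0, 3.0, 4.0]}
        )
        out = plus_one_paired_test(df)
        assert out.raw_p == 1.0
        assert out.direction == "none"

    def test_planting_in_nonsd_genes_only_detected_across_species(self):
        per_species, tails = [], {}
        bg = {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}
        for i in range(6):
            cfg = GeneratorConfig(
                species_id=f"s{i}", seed=200 + i, n_genes=150, sd_fraction=0.5,
                background=bg, tail=TAIL, plus_one_scope="non_sd",
            )
            sp, _ = generate_species(cfg)
            recs = extract_gene_records(sp).records
            cls = classify_genes(recs, sp.anti_sd_tail)
            sd, nonsd = split_by_label(recs, cls)
            per_species.append((cfg.species_id, sd, nonsd))
            tails[cfg.species_id] = TAIL
        paired, per = plus_one_tests(per_species, tails)
        assert paired.raw_p < 0.05
        assert paired.direction == "nonsd_stronger"
        # per-species corrected p uses m = number of species
        for o in per:
            assert o.corrected_p == pytest.approx(min(1.0, o.raw_p * 6))

    def test_profile_dips_at_plus_one_in_both_groups(self):
        cfg = GeneratorConfig(
            species_id="pp", seed=9, n_genes=60, sd_fraction=0.5,
            background={"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3},
            tail=TAIL, plus_one_scope="all",
        )
        sp, _ = generate_species(cfg)
        recs = extract_gene_records(sp).records
        cls = classify_genes(recs, sp.anti_sd_tail)
        sd, nonsd = split_by_label(recs, cls)
        df = group_profiles(sd, nonsd, TAIL, span=(-40, 40))
        for group in ("SD", "non-SD"):
            sub = df[df.group == group]
            assert sub.loc[sub.mean_dG.idxmin(), "position"] == 1
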