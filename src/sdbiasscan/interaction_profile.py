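"""Positional 16S-tail / mRNA hybridization-energy profiles.

For every anchor position i across -100..+100 the hybridization free energy
of the gapless duplex whose 5'-most mRNA base sits at i is computed with the
same nearest-neighbor model used for SD classification (full-overlap
alignments only). Averaging per position over the SD and non-SD gene groups
gives the two group profiles; the characteristic dip at +1 reflects pairing
between the tail and the region that includes the initiation codon. The +1
difference between groups is tested per species (rank-sum over genes,
Bonferroni across species) and across species (paired signed-rank on
per-species group means).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .hybridization import NNParameterTable, duplex_energy
from .randomization_tests import TestOutcome, bonferroni, rank_sum_compare
from .sequence_io import GeneRecord

DEFAULT_SPAN = (-100, 100)


def _position_index(record: GeneRecord, position: int) -> int:
    """0-based index of a gene-relative position in upstream + cds."""
    if position == 0:
        raise ValueError("position 0 does not exist")
    if position < 0:
        return len(record.upstream) + position
    return len(record.upstream) + position - 1


def positional_energy(
    record: GeneRecord,
    tail: str,
    params: NNParameterTable | None = None,
    span: tuple[int, int] = DEFAULT_SPAN,
) -> dict[int, float]:
    """Anchor-position -> duplex dG map over ``span``.

    dG(i) is the energy of the full-overlap gapless alignment whose 5'-most
    mRNA base sits at position i (the tail extending 3' of i along the
    mRNA). Anchors whose window leaves the gene's covered sequence, or spans
    ambiguity codes, are omitted.
    """
    if params is None:
        params = NNParameterTable.default()
    seq = record.upstream + record.cds
    T = len(tail)
    out: dict[int, float] = {}
    lo, hi = span
    for i in range(lo, hi + 1):
        if i == 0:
            continue
        a = _position_index(record, i)
        if a < 0 or a + T > len(seq):
            continue
        window = seq[a : a + T]
        if set(window) - set("ACGU"):
            continue
        out[i] = duplex_energy(window, tail, params)
    return out


def group_profiles(
    sd_records: Sequence[GeneRecord],
    nonsd_records: Sequence[GeneRecord],
    tail: str,
    params: NNParameterTable | None = None,
    span: tuple[int, int] = DEFAULT_SPAN,
) -> pd.DataFrame:
    """Position-wise mean dG per group as a tidy DataFrame.

    Columns: position, group ('SD'/'non-SD'), mean_dG, n. Groups that are
    empty are omitted.
    """
    frames = []
    for group, records in (("SD", sd_records), ("non-SD", nonsd_records)):
        if not records:
            continue
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for rec in records:
            for pos, dg in positional_energy(rec, tail, params, span).items():
                sums[pos] = sums.get(pos, 0.0) + dg
                counts[pos] = counts.get(pos, 0) + 1
        frames.append(
            pd.DataFrame(
                {
                    "position": sorted(sums),
                    "group": group,
                    "mean_dG": [sums[p] / counts[p] for p in sorted(sums)],
                    "n": [counts[p] for p in sorted(sums)],
                }
            )
        )
    if not frames:
        raise DegenerateInputError("both gene groups are empty")
    return pd.concat(frames, ignore_index=True)


def plus_one_energies(
    records: Sequence[GeneRecord],
    tail: str,
    params: NNParameterTable | None = None,
) -> np.ndarray:
    """Per-gene dG of the duplex anchored at position +1."""
    vals = []
    for rec in records:
        e = positional_energy(rec, tail, params, span=(1, 1))
        if 1 in e:
            vals.append(e[1])
    return np.array(vals)


def plus_one_species_test(
    sd_records: Sequence[GeneRecord],
    nonsd_records: Sequence[GeneRecord],
    tail: str,
    params: NNParameterTable | None = None,
    species_id: str = "species",
    m: int = 1,
    alpha: float = 0.05,
) -> TestOutcome:
    """Per-species rank-sum test of +1 interaction energies, SD vs non-SD.

    Direction ``nonsd_stronger`` means non-SD genes show more negative +1
    energies (a stronger tail/start-codon interaction) than SD genes.
    """
    sd_e = plus_one_energies(sd_records, tail, params)
    nonsd_e = plus_one_energies(nonsd_records, tail, params)
    if len(sd_e) < 2 or len(nonsd_e) < 2:
        raise DegenerateInputError(
            f"{species_id}: need >= 2 genes with a +1 window in each group"
        )
    out = rank_sum_compare(
        nonsd_e, sd_e, species_id, "plus_one_interaction",
        weaker_means=("nonsd_weaker", "nonsd_stronger"), m=m, alpha=alpha,
    )
    out.extra["mean_nonsd"] = float(np.mean(nonsd_e))
    out.extra["mean_sd"] = float(np.mean(sd_e))
    return out


def plus_one_paired_test(
    species_means: pd.DataFrame, alpha: float = 0.05
) -> TestOutcome:
    """Across-species paired signed-rank test of mean +1 energies.

    ``species_means`` needs columns ``species_id``, ``mean_sd``,
    ``mean_nonsd`` (per-species arithmetic means of per-gene +1 energies).
    Direction ``nonsd_stronger`` means non-SD means are systematically more
    negative.
    """
    if len(species_means) < 2:
        raise DegenerateInputError("paired test needs >= 2 species")
    diffs = species_means["mean_nonsd"].to_numpy() - species_means["mean_sd"].to_numpy()
    if np.all(diffs == 0):
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(diffs, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    trend = "nonsd_stronger" if np.mean(diffs) < 0 else "nonsd_weaker"
    return TestOutcome(
        species_id="(all)",
        test_name="plus_one_paired_signed_rank",
        statistic=stat,
        raw_p=p,
        corrected_p=p,
        direction=trend if p < alpha else "none",
        n_obs=len(diffs),
        n_null=len(diffs),
        alpha=alpha,
        extra={"trend": trend, "mean_diff": float(np.mean(diffs))},
    )


def plus_one_tests(
    per_species: Sequence[tuple[str, Sequence[GeneRecord], Sequence[GeneRecord]]],
    tail_by_species: dict[str, str],
    params: NNParameterTable | None = None,
    alpha: float = 0.05,
) -> tuple[TestOutcome, list[TestOutcome]]:
    """Across-species paired test plus Bonferroni-corrected per-species tests.

    ``per_species`` holds ``(species_id, sd_records, nonsd_records)`` triples.
    """
    m = len(per_species)
    per: list[TestOutcome] = []
    rows = []
    for species_id, sd_records, nonsd_records in per_species:
        tail = tail_by_species[species_id]
        out = plus_one_species_test(
            sd_records, nonsd_records, tail, params, species_id, m=m, alpha=alpha
        )
        per.append(out)
        rows.append(
            {
                "species_id": species_id,
                "mean_sd": out.extra["mean_sd"],
                "mean_nonsd": out.extra["mean_nonsd"],
            }
        )
    corrected = bonferroni([o.raw_p for o in per], m)
    for o, cp in zip(per, corrected):
        o.corrected_p = cp
        o.direction = o.extra["trend"] if cp < o.alpha else "none"
    paired = plus_one_paired_test(pd.DataFrame(rows), alpha=alpha)
    return paired, per
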