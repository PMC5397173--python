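"""Column-shuffle randomization null and folding-energy comparisons.

The null model for folding energies preserves the per-position nucleotide
composition of the observed -20..+20 windows while making positions
independent: each output sequence draws position j from the empirical
multinomial of column j. One hundred null sequences are generated per
observed gene by default. Folding energies of observed vs null (and SD vs
non-SD) sets are compared with two-sided Wilcoxon rank-sum (Mann-Whitney)
tests, Bonferroni-corrected across the species of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError
from .folding import DEFAULT_FOLD_WINDOW, fold_windows, mfe_energies
from .sequence_io import GeneRecord

_DECODE = np.array(list("ACGU"))
_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class RandomizationConfig:
    """Parameters of the randomization null and its tests."""

    multiplier: int = 100
    seed: int = 0
    window: tuple[int, int] = DEFAULT_FOLD_WINDOW
    alphas: tuple[float, ...] = (0.05, 0.01)
    rng_name: str = "numpy PCG64"

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise InputError("multiplier must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TestOutcome:
    """Result of one per-species statistical comparison."""

    species_id: str
    test_name: str
    statistic: float
    raw_p: float
    corrected_p: float
    direction: str  # observed_weaker | observed_stronger | none
    n_obs: int
    n_null: int
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)


def column_shuffle(
    windows: Sequence[str],
    cfg: RandomizationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Randomized sequences preserving per-column nucleotide composition.

    Emits ``multiplier * len(windows)`` sequences; position j of every output
    is drawn independently from the empirical nucleotide distribution of
    position j across the input windows.
    """
    if cfg is None:
        cfg = RandomizationConfig()
    if not windows:
        raise DegenerateInputError("column_shuffle needs at least one window")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise InputError(f"windows have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()
    if rng is None:
        rng = cfg.rng()
    enc = np.array([[_ENCODE[b] for b in w] for w in windows], dtype=np.int8)
    n_out = cfg.multiplier * len(windows)
    out = np.empty((n_out, L), dtype=np.int8)
    for j in range(L):
        counts = np.bincount(enc[:, j], minlength=4).astype(float)
        out[:, j] = rng.choice(4, size=n_out, p=counts / counts.sum())
    return ["".join(row) for row in _DECODE[out]]


def rank_sum_compare(
    x: Sequence[float],
    y: Sequence[float],
    species_id: str,
    test_name: str,
    weaker_means: tuple[str, str] = ("observed_weaker", "observed_stronger"),
    m: int = 1,
    alpha: float = 0.05,
) -> TestOutcome:
    """Two-sided Mann-Whitney comparison of two dG samples.

    ``weaker_means`` gives the direction labels when the first sample is
    stochastically greater (weaker folding, less negative dG) respectively
    smaller than the second. Direction is reported only when the
    Bonferroni-corrected p (factor ``m``) is below ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateInputError(f"{test_name}: both samples need >= 2 values")
    if np.ptp(np.concatenate([x, y])) == 0:
        stat, raw_p = 0.0, 1.0
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, raw_p = float(res.statistic), float(res.pvalue)
    corrected = min(1.0, raw_p * m)
    trend = weaker_means[0] if np.median(x) > np.median(y) else weaker_means[1]
    direction = trend if corrected < alpha else "none"
    return TestOutcome(
        species_id=species_id,
        test_name=test_name,
        statistic=stat,
        raw_p=raw_p,
        corrected_p=corrected,
        direction=direction,
        n_obs=len(x),
        n_null=len(y),
        alpha=alpha,
        extra={"trend": trend},
    )


def folding_vs_random_test(
    records: Sequence[GeneRecord],
    cfg: RandomizationConfig | None = None,
    species_id: str = "species",
    m: int = 1,
) -> TestOutcome:
    """Compare observed fold energies against the column-shuffle null.

    Folds the observed -20..+20 windows and ``multiplier`` times as many
    randomized windows with the same (builtin) engine, then applies a
    two-sided rank-sum test. ``observed_weaker`` means observed dG values are
    less negative than the null's.
    """
    if cfg is None:
        cfg = RandomizationConfig()
    windows, _, _ = fold_windows(records, cfg.window)
    if len(windows) < 2:
        raise DegenerateInputError(
            f"{species_id}: need >= 2 foldable genes for the randomization test"
        )
    null_windows = column_shuffle(windows, cfg)
    obs_dg = mfe_energies(windows)
    null_dg = mfe_energies(null_windows)
    out = rank_sum_compare(
        obs_dg, null_dg, species_id, "folding_vs_random", m=m,
        alpha=max(cfg.alphas),
    )
    out.extra["median_obs"] = float(np.median(obs_dg))
    out.extra["median_null"] = float(np.median(null_dg))
    return out


def sd_vs_nonsd_folding_test(
    sd_records: Sequence[GeneRecord],
    nonsd_records: Sequence[GeneRecord],
    cfg: RandomizationConfig | None = None,
    species_id: str = "species",
    m: int = 1,
) -> TestOutcome:
    """Rank-sum comparison of fold energies between SD and non-SD genes.

    Direction ``nonsd_weaker`` flags relaxed structures in non-SD genes
    (their dG median less negative), ``sd_weaker`` the opposite.
    """
    if cfg is None:
        cfg = RandomizationConfig()
    sd_w, _, _ = fold_windows(sd_records, cfg.window)
    nonsd_w, _, _ = fold_windows(nonsd_records, cfg.window)
    if len(sd_w) < 2 or len(nonsd_w) < 2:
        raise DegenerateInputError(
            f"{species_id}: both SD and non-SD groups need >= 2 foldable genes"
        )
    sd_dg = mfe_energies(sd_w)
    nonsd_dg = mfe_energies(nonsd_w)
    out = rank_sum_compare(
        nonsd_dg, sd_dg, species_id, "sd_vs_nonsd_folding",
        weaker_means=("nonsd_weaker", "sd_weaker"), m=m, alpha=max(cfg.alphas),
    )
    out.n_obs, out.n_null = len(nonsd_dg), len(sd_dg)
    out.extra["median_nonsd"] = float(np.median(nonsd_dg))
    out.extra["median_sd"] = float(np.median(sd_dg))
    return out


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: min(1, p * m) elementwise.

    ``m`` defaults to the number of p-values (one test per species).
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise InputError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in ps]


def apply_bonferroni(outcomes: Sequence[TestOutcome], m: int | None = None) -> None:
    """Recorrect a set of per-species outcomes in place with factor ``m``."""
    if m is None:
        m = len(outcomes)
    corrected = bonferroni([o.raw_p for o in outcomes], m)
    for o, cp in zip(outcomes, corrected):
        o.corrected_p = cp
        o.direction = o.extra.get("trend", o.direction) if cp < o.alpha else "none"
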