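"""Positional nucleotide frequency bias around initiation codons (G-statistic).

Genes are aligned at their initiation codons without gaps. At each aligned
position i the observed nucleotide counts O_n(i) are compared with expected
counts E_n(i) via the likelihood-ratio goodness-of-fit statistic

    G(i) = 2 * sum_n O_n(i) * ln(O_n(i) / E_n(i)),

referred to a chi-square distribution with 3 degrees of freedom. Each signed
term G_n(i) = 2 O_n ln(O_n/E_n) measures the bias of one nucleotide (positive
when over-represented), and g_n(i) = G_n(i) / N(i) removes the dependence on
the number of genes so that species are comparable.

Expected frequencies are estimated per species in four separate categories --
the 100 nt upstream of the initiation codon, and the first, second and third
codon positions across coding sequences -- because base composition differs
sharply between these sequence classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .sequence_io import GeneRecord

#: Nucleotide ordering used in every count/bias array.
NUCLEOTIDES = ("A", "U", "G", "C")

_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

CATEGORIES = ("upstream", "codon1", "codon2", "codon3")


@dataclass(frozen=True)
class ExpectedFreqs:
    """Expected nucleotide fractions for one sequence category."""

    category: str
    freq: dict[str, float]
    source_count: int

    def as_array(self) -> np.ndarray:
        return np.array([self.freq[n] for n in NUCLEOTIDES])


def expected_frequencies(
    records: Sequence[GeneRecord],
) -> dict[str, ExpectedFreqs]:
    """Pooled expected nucleotide fractions in the four positional categories.

    The upstream category pools every base of every gene's upstream window;
    codon1/2/3 pool the bases at those codon positions over each gene's full
    CDS (start and stop codons included). Ambiguity codes are skipped.
    """
    if not records:
        raise DegenerateInputError("cannot estimate expected frequencies: no genes")
    counts = {c: np.zeros(4) for c in CATEGORIES}
    for rec in records:
        for base in rec.upstream:
            i = _NT_INDEX.get(base)
            if i is not None:
                counts["upstream"][i] += 1
        for frame, cat in enumerate(("codon1", "codon2", "codon3")):
            for base in rec.cds[frame::3]:
                i = _NT_INDEX.get(base)
                if i is not None:
                    counts[cat][i] += 1
    out = {}
    for cat, c in counts.items():
        total = c.sum()
        if total == 0:
            raise DegenerateInputError(f"no countable bases in category {cat!r}")
        out[cat] = ExpectedFreqs(
            category=cat,
            freq={n: c[i] / total for i, n in enumerate(NUCLEOTIDES)},
            source_count=int(total),
        )
    return out


def position_category(position: int) -> str:
    """The expectation category an aligned position belongs to."""
    if position == 0:
        raise ValueError("position 0 does not exist")
    if position < 0:
        return "upstream"
    return f"codon{(position - 1) % 3 + 1}"


def g_test_counts(
    observed: np.ndarray, expected: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized G-test terms for rows of nucleotide counts.

    ``observed`` and ``expected`` are (..., 4) arrays with matching row sums.
    Returns ``(G_n, G, p)`` where ``G_n`` holds the signed per-nucleotide
    terms 2 O ln(O/E) (0 where O = 0), ``G`` their sum and ``p`` the
    upper-tail chi-square probability with 3 degrees of freedom.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(observed > 0, observed / expected, 1.0)
        gn = 2.0 * observed * np.log(ratio)
    gn = np.where(observed == 0, 0.0, gn)
    g = gn.sum(axis=-1)
    p = stats.chi2.sf(g, df=3)
    return gn, g, p


@dataclass
class GProfile:
    """Per-position G-test decomposition for a gene set.

    Arrays are aligned with ``positions``; the nucleotide axis follows
    :data:`NUCLEOTIDES`. ``start_codon_flag`` marks positions +1..+3, whose
    biases reflect start-codon identity rather than context and are normally
    masked in displays. ``valid`` is False where E_n = 0 < O_n for some
    nucleotide (the G-test is undefined there).
    """

    positions: np.ndarray  # (P,)
    N: np.ndarray  # genes contributing per position
    observed: np.ndarray  # (P, 4)
    expected: np.ndarray  # (P, 4)
    Gn: np.ndarray  # (P, 4) signed bias terms
    gn: np.ndarray  # (P, 4) Gn / N
    G: np.ndarray  # (P,)
    p: np.ndarray  # (P,)
    valid: np.ndarray  # (P,) bool
    start_codon_flag: np.ndarray  # (P,) bool

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"position": self.positions, "N": self.N}
        for i, n in enumerate(NUCLEOTIDES):
            cols[f"O_{n}"] = self.observed[:, i]
        for i, n in enumerate(NUCLEOTIDES):
            cols[f"E_{n}"] = self.expected[:, i]
        for i, n in enumerate(NUCLEOTIDES):
            cols[f"G_{n}"] = self.Gn[:, i]
        for i, n in enumerate(NUCLEOTIDES):
            cols[f"g_{n}"] = self.gn[:, i]
        cols["G"] = self.G
        cols["p"] = self.p
        cols["valid"] = self.valid
        cols["start_codon"] = self.start_codon_flag
        return pd.DataFrame(cols)

    def gn_at(self, position: int, nucleotide: str) -> float:
        idx = np.nonzero(self.positions == position)[0]
        if len(idx) == 0:
            raise KeyError(f"position {position} not in profile")
        return float(self.gn[idx[0], _NT_INDEX[nucleotide]])


def g_profile(
    records: Sequence[GeneRecord],
    expected: dict[str, ExpectedFreqs] | None = None,
    window: tuple[int, int] = (-100, 99),
) -> GProfile:
    """G-statistic profile of a gene set over aligned positions.

    ``window`` is inclusive and may span negative (upstream) and positive
    (CDS) positions; position 0 is skipped. A gene contributes to position i
    only if its sequence covers i with an unambiguous base; positions with
    N = 0 are omitted from the profile. ``expected`` defaults to category
    frequencies estimated from ``records`` themselves (subset-matched
    expectations).
    """
    if not records:
        raise DegenerateInputError("cannot profile an empty gene set")
    if expected is None:
        expected = expected_frequencies(records)
    lo, hi = window
    if lo > hi:
        raise ValueError("window start must be <= end")
    positions = [i for i in range(lo, hi + 1) if i != 0]
    obs = np.zeros((len(positions), 4))
    pos_index = {p: k for k, p in enumerate(positions)}
    for rec in records:
        up, cds = rec.upstream, rec.cds
        n_up = len(up)
        for k, i in enumerate(positions):
            if i < 0:
                if -i > n_up:
                    continue
                base = up[n_up + i]
            else:
                if i > len(cds):
                    continue
                base = cds[i - 1]
            j = _NT_INDEX.get(base)
            if j is not None:
                obs[k, j] += 1
    keep = obs.sum(axis=1) > 0
    positions_arr = np.array(positions)[keep]
    obs = obs[keep]
    N = obs.sum(axis=1)
    exp_frac = np.vstack(
        [expected[position_category(i)].as_array() for i in positions_arr]
    )
    exp = exp_frac * N[:, None]
    gn, g, p = g_test_counts(obs, exp)
    valid = ~np.any((exp == 0) & (obs > 0), axis=1)
    return GProfile(
        positions=positions_arr,
        N=N,
        observed=obs,
        expected=exp,
        Gn=gn,
        gn=gn / N[:, None],
        G=g,
        p=p,
        valid=valid,
        start_codon_flag=(positions_arr >= 1) & (positions_arr <= 3),
    )


def profile_table(records: Iterable[GeneRecord], **kwargs) -> pd.DataFrame:
    """Convenience: :func:`g_profile` rendered as a DataFrame."""
    return g_profile(list(records), **kwargs).to_frame()
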