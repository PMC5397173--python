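"""Dynamic-programming kernel for the simplified MFE folder (numba-compiled).

Sequences are encoded A=0, C=1, G=2, U=3. Energy model (all dG37 kcal/mol):
stack free energies for Watson-Crick and G.U pairs; hairpin / bulge /
internal loops penalized by length via shipped initiation tables; internal
and bulge loops capped at ``maxloop`` unpaired bases; hairpin loops of at
least 3 bases, with lengths beyond the table extrapolated by the
Jacobson-Stockmayer term; multiloops scored linearly
(a + b * branches + c * unpaired). No dangles, no coaxial stacking.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e9

#: Gas constant x 310.15 K, kcal/mol (Jacobson-Stockmayer extrapolation).
RT37 = 0.0019872 * 310.15


@njit(cache=True)
def fill_matrices(
    seq: np.ndarray,
    pair_ok: np.ndarray,
    stack: np.ndarray,
    hairpin: np.ndarray,
    bulge: np.ndarray,
    internal: np.ndarray,
    ml_a: float,
    ml_b: float,
    ml_c: float,
    maxloop: int,
):
    """Fill V (pair-closed), WM (multiloop component) and W (exterior) tables."""
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V: minimum energy of a structure closed by pair (i, j)
            if pair_ok[seq[i], seq[j]] and span >= 4:
                best = hairpin[j - i - 1]
                for k in range(i + 1, j - 1):
                    b1 = k - i - 1
                    if b1 > maxloop:
                        break
                    for l in range(j - 1, k, -1):
                        b2 = j - 1 - l
                        size = b1 + b2
                        if size > maxloop:
                            break
                        if V[k, l] >= INF / 2:
                            continue
                        if size == 0:
                            e = stack[seq[i], seq[k], seq[j], seq[l]] + V[k, l]
                        elif b1 == 0 or b2 == 0:
                            e = bulge[size] + V[k, l]
                        else:
                            e = internal[size] + V[k, l]
                        if e < best:
                            best = e
                for m in range(i + 1, j - 1):
                    if WM[i + 1, m] < INF / 2 and WM[m + 1, j - 1] < INF / 2:
                        e = ml_a + ml_b + WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # --- WM: >= 1 multiloop branch somewhere in i..j
            wm = INF
            if V[i, j] < INF / 2:
                wm = V[i, j] + ml_b
            if WM[i + 1, j] + ml_c < wm:
                wm = WM[i + 1, j] + ml_c
            if WM[i, j - 1] + ml_c < wm:
                wm = WM[i, j - 1] + ml_c
            for m in range(i, j):
                if WM[i, m] < INF / 2 and WM[m + 1, j] < INF / 2:
                    e = WM[i, m] + WM[m + 1, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm
    W = np.zeros(n)
    for j in range(n):
        w = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            if V[i, j] < INF / 2:
                left = W[i - 1] if i > 0 else 0.0
                if left + V[i, j] < w:
                    w = left + V[i, j]
        if j > 0 and V[0, j] < INF / 2 and V[0, j] < w:
            w = V[0, j]
        W[j] = w
    return V, WM, W


@njit(cache=True)
def mfe_only(
    seq: np.ndarray,
    pair_ok: np.ndarray,
    stack: np.ndarray,
    hairpin: np.ndarray,
    bulge: np.ndarray,
    internal: np.ndarray,
    ml_a: float,
    ml_b: float,
    ml_c: float,
    maxloop: int,
) -> float:
    """Minimum free energy only (no traceback matrices kept)."""
    _, _, W = fill_matrices(
        seq, pair_ok, stack, hairpin, bulge, internal, ml_a, ml_b, ml_c, maxloop
    )
    n = seq.shape[0]
    e = W[n - 1]
    if e > 0.0:
        e = 0.0
    return e


@njit(cache=True)
def mfe_batch(
    seqs: np.ndarray,
    lengths: np.ndarray,
    pair_ok: np.ndarray,
    stack: np.ndarray,
    hairpin: np.ndarray,
    bulge: np.ndarray,
    internal: np.ndarray,
    ml_a: float,
    ml_b: float,
    ml_c: float,
    maxloop: int,
) -> np.ndarray:
    """MFE for each row of an encoded (padded) sequence matrix."""
    m = seqs.shape[0]
    out = np.empty(m)
    for r in range(m):
        out[r] = mfe_only(
            seqs[r, : lengths[r]],
            pair_ok,
            stack,
            hairpin,
            bulge,
            internal,
            ml_a,
            ml_b,
            ml_c,
            maxloop,
        )
    return out
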