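"""Minimum-free-energy secondary structure of the window around start codons.

The analysis window spans positions -20..+20: the 20 upstream bases adjacent
to the start codon followed by the first 20 CDS bases (start codon at
+1..+3), 40 nt in total. Folding is comparative throughout the package
(observed vs column-shuffled, SD vs non-SD), so the default engine is a
self-contained simplified Zuker-style dynamic program (see
:mod:`sdbiasscan._zuker` for the energy model); an adapter for the ViennaRNA
thermodynamic engine is provided for users wanting full Turner parameters.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from . import _zuker
from .errors import AlphabetError, DegenerateInputError, EngineUnavailableError
from .hybridization import NNParameterTable
from .sequence_io import GeneRecord

#: Default half-windows around the start codon (upstream bases, CDS bases).
DEFAULT_FOLD_WINDOW = (20, 20)

#: Largest bulge/internal loop considered, unpaired bases.
MAXLOOP = 30

#: Minimum hairpin loop size.
MIN_HAIRPIN = 3

#: Linear multiloop model: a + b * branches + c * unpaired.
ML_A, ML_B, ML_C = 3.4, 0.4, 0.0

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_DECODE = "ACGU"


@dataclass(frozen=True)
class FoldResult:
    """MFE fold of one RNA window."""

    sequence: str
    min_dG: float
    structure: str
    engine: str


@functools.cache
def _loop_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hairpin, bulge, internal) dG37 penalty arrays indexed by loop size."""
    text = resources.files("sdbiasscan.data").joinpath("loop_dg37.tsv").read_text()
    hairpin = np.full(31, _zuker.INF)
    bulge = np.full(31, _zuker.INF)
    internal = np.full(31, _zuker.INF)
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("size\t"):
            continue
        size_s, h, b, i = line.split("\t")
        size = int(size_s)
        if h:
            hairpin[size] = float(h)
        bulge[size] = float(b)
        if i:
            internal[size] = float(i)
    return hairpin, bulge, internal


def hairpin_penalty(size: int) -> float:
    """Hairpin initiation dG37 for a loop of ``size`` unpaired bases.

    Sizes beyond the table (30) use the Jacobson-Stockmayer extrapolation
    ``H(30) + 1.75 * RT * ln(size / 30)``.
    """
    if size < MIN_HAIRPIN:
        return _zuker.INF
    hairpin, _, _ = _loop_tables()
    if size <= 30:
        return float(hairpin[size])
    return float(hairpin[30] + 1.75 * _zuker.RT37 * np.log(size / 30.0))


def loop_penalty(kind: str, size: int) -> float:
    """Bulge or internal loop initiation dG37 (capped at MAXLOOP)."""
    _, bulge, internal = _loop_tables()
    if size < 1 or size > MAXLOOP:
        return _zuker.INF
    if kind == "bulge":
        return float(bulge[size])
    if kind == "internal":
        return float(internal[size]) if size >= 2 else _zuker.INF
    raise ValueError(f"unknown loop kind {kind!r}")


@functools.cache
def _energy_arrays(allow_gu: bool = True):
    """Numba-ready (pair_ok, stack) arrays from the shipped stack table."""
    params = NNParameterTable.default().with_gu(allow_gu)
    pair_ok = np.zeros((4, 4), dtype=np.bool_)
    for x in _DECODE:
        for y in _DECODE:
            pair_ok[_ENCODE[x], _ENCODE[y]] = params.is_pair(x, y)
    stack = np.full((4, 4, 4, 4), _zuker.INF)
    for key, e in params.stack_energy.items():
        (a, b), (c, d) = key.split("/")
        if params.is_pair(a, c) and params.is_pair(b, d):
            stack[_ENCODE[a], _ENCODE[b], _ENCODE[c], _ENCODE[d]] = e
    return pair_ok, stack


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(f"non-ACGU character {exc.args[0]!r} in sequence") from exc


def _hairpin_array(n: int) -> np.ndarray:
    out = np.full(max(31, n), _zuker.INF)
    for s in range(MIN_HAIRPIN, len(out)):
        out[s] = hairpin_penalty(s)
    return out


def mfe_fold(seq: str, engine: str = "builtin", allow_gu: bool = True) -> FoldResult:
    """Minimum-free-energy fold of an RNA sequence.

    ``engine`` is ``"builtin"`` (the simplified Zuker dynamic program) or
    ``"vienna"`` (ViennaRNA's RNAfold via its Python bindings; full Turner
    parameters, returned unchanged). A missing external engine raises
    :class:`EngineUnavailableError`, never a silent fallback.
    """
    if not seq:
        raise AlphabetError("cannot fold an empty sequence")
    if engine == "vienna":
        return _fold_vienna(seq)
    if engine != "builtin":
        raise EngineUnavailableError(f"unknown folding engine {engine!r}")
    enc = encode(seq)
    n = len(enc)
    if n < MIN_HAIRPIN + 2:
        return FoldResult(sequence=seq, min_dG=0.0, structure="." * n, engine="builtin")
    pair_ok, stack = _energy_arrays(allow_gu)
    hairpin = _hairpin_array(n)
    _, bulge, internal = _loop_tables()
    V, WM, W = _zuker.fill_matrices(
        enc, pair_ok, stack, hairpin, bulge, internal, ML_A, ML_B, ML_C, MAXLOOP
    )
    mfe = min(0.0, float(W[n - 1]))
    pairs = _traceback(enc, V, WM, W, pair_ok, stack, hairpin, bulge, internal)
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult(
        sequence=seq, min_dG=mfe, structure="".join(structure), engine="builtin"
    )


def mfe_energy(seq: str, allow_gu: bool = True) -> float:
    """Builtin-engine MFE without structure traceback."""
    enc = encode(seq)
    n = len(enc)
    if n < MIN_HAIRPIN + 2:
        return 0.0
    pair_ok, stack = _energy_arrays(allow_gu)
    _, bulge, internal = _loop_tables()
    return float(
        _zuker.mfe_only(
            enc, pair_ok, stack, _hairpin_array(n), bulge, internal,
            ML_A, ML_B, ML_C, MAXLOOP,
        )
    )


def mfe_energies(windows: Sequence[str], allow_gu: bool = True) -> np.ndarray:
    """Builtin-engine MFE for many windows (batched numba path)."""
    if not windows:
        return np.zeros(0)
    n_max = max(len(w) for w in windows)
    mat = np.zeros((len(windows), n_max), dtype=np.int8)
    lengths = np.empty(len(windows), dtype=np.int64)
    for r, w in enumerate(windows):
        e = encode(w)
        mat[r, : len(e)] = e
        lengths[r] = len(e)
    pair_ok, stack = _energy_arrays(allow_gu)
    _, bulge, internal = _loop_tables()
    return _zuker.mfe_batch(
        mat, lengths, pair_ok, stack, _hairpin_array(n_max), bulge, internal,
        ML_A, ML_B, ML_C, MAXLOOP,
    )


def _fold_vienna(seq: str) -> FoldResult:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise EngineUnavailableError(
            "ViennaRNA Python bindings are not installed; "
            "install the 'viennarna' package or use engine='builtin'"
        ) from exc
    structure, mfe = RNA.fold(seq)
    return FoldResult(sequence=seq, min_dG=float(mfe), structure=structure, engine="vienna")


# ---------------------------------------------------------------------------
# structure scoring and traceback


def score_structure(
    seq: str, pairs: Iterable[tuple[int, int]], allow_gu: bool = True
) -> float:
    """Energy of a given secondary structure under the builtin model.

    Decomposes the structure into loops and sums their energies with the
    same tables the dynamic program uses; used both to verify returned
    structures and as an independent scorer for exhaustive enumeration.
    Returns +inf for structures the model disallows (non-pairable bases,
    hairpins < 3, oversized internal loops, crossing pairs).
    """
    enc = encode(seq)
    n = len(enc)
    params = NNParameterTable.default().with_gu(allow_gu)
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    seen: set[int] = set()
    for i, j in plist:
        if i == j or not (0 <= i < j < n):
            return _zuker.INF
        if i in seen or j in seen:
            return _zuker.INF
        seen.update((i, j))
        if not params.is_pair(seq[i], seq[j]):
            return _zuker.INF
    for (i1, j1) in plist:  # no pseudoknots
        for (i2, j2) in plist:
            if i1 < i2 < j1 < j2:
                return _zuker.INF
    total = 0.0
    for (i, j) in plist:
        children = _direct_children(plist, i, j)
        if not children:
            size = j - i - 1
            if size < MIN_HAIRPIN:
                return _zuker.INF
            total += hairpin_penalty(size)
        elif len(children) == 1:
            k, l = children[0]
            b1, b2 = k - i - 1, j - l - 1
            size = b1 + b2
            if size == 0:
                total += params.stack(seq[i], seq[k], seq[j], seq[l])
            elif size > MAXLOOP:
                return _zuker.INF
            elif b1 == 0 or b2 == 0:
                total += loop_penalty("bulge", size)
            else:
                total += loop_penalty("internal", size)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += ML_A + ML_B * (1 + len(children)) + ML_C * unpaired
    return total


def _direct_children(
    plist: list[tuple[int, int]], i: int, j: int
) -> list[tuple[int, int]]:
    children = []
    for (k, l) in plist:
        if i < k < l < j:
            if any(k2 < k and l < l2 and i < k2 for (k2, l2) in plist if (k2, l2) != (i, j)):
                continue
            children.append((k, l))
    return sorted(children)


def enumerate_structures(seq: str, allow_gu: bool = True):
    """Yield every nested structure (as a pair list) the model allows.

    Intended for small sequences (<= ~14 nt) as a brute-force oracle.
    """
    enc = seq
    params = NNParameterTable.default().with_gu(allow_gu)
    n = len(seq)

    @functools.lru_cache(maxsize=None)
    def structures(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i + 1 < 2:
            return [()]
        out = list(structures(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if params.is_pair(enc[i], enc[k]):
                for inner in structures(i + 1, k - 1):
                    for rest in structures(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return out

    if n == 0:
        return
    for s in structures(0, n - 1):
        yield list(s)


def brute_force_mfe(seq: str, allow_gu: bool = True) -> float:
    """Exhaustive-enumeration MFE under the builtin energy model."""
    best = 0.0
    for pairs in enumerate_structures(seq, allow_gu):
        e = score_structure(seq, pairs, allow_gu)
        if e < best:
            best = e
    return best


def _traceback(enc, V, WM, W, pair_ok, stack, hairpin, bulge, internal):
    """Recover one MFE structure from the filled matrices."""
    n = len(enc)
    eps = 1e-6
    pairs: list[tuple[int, int]] = []

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        e = V[i, j]
        if abs(e - hairpin[j - i - 1]) < eps:
            return
        for k in range(i + 1, j - 1):
            b1 = k - i - 1
            if b1 > MAXLOOP:
                break
            for l in range(j - 1, k, -1):
                b2 = j - 1 - l
                size = b1 + b2
                if size > MAXLOOP:
                    break
                if V[k, l] >= _zuker.INF / 2:
                    continue
                if size == 0:
                    cand = stack[enc[i], enc[k], enc[j], enc[l]] + V[k, l]
                elif b1 == 0 or b2 == 0:
                    cand = bulge[size] + V[k, l]
                else:
                    cand = internal[size] + V[k, l]
                if abs(e - cand) < eps:
                    trace_V(k, l)
                    return
        for m in range(i + 1, j - 1):
            if WM[i + 1, m] < _zuker.INF / 2 and WM[m + 1, j - 1] < _zuker.INF / 2:
                if abs(e - (ML_A + ML_B + WM[i + 1, m] + WM[m + 1, j - 1])) < eps:
                    trace_WM(i + 1, m)
                    trace_WM(m + 1, j - 1)
                    return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_WM(i: int, j: int) -> None:
        e = WM[i, j]
        if V[i, j] < _zuker.INF / 2 and abs(e - (V[i, j] + ML_B)) < eps:
            trace_V(i, j)
            return
        if i + 1 <= j and abs(e - (WM[i + 1, j] + ML_C)) < eps:
            trace_WM(i + 1, j)
            return
        if i <= j - 1 and abs(e - (WM[i, j - 1] + ML_C)) < eps:
            trace_WM(i, j - 1)
            return
        for m in range(i, j):
            if WM[i, m] < _zuker.INF / 2 and WM[m + 1, j] < _zuker.INF / 2:
                if abs(e - (WM[i, m] + WM[m + 1, j])) < eps:
                    trace_WM(i, m)
                    trace_WM(m + 1, j)
                    return
        raise AssertionError("traceback failed in WM")  # pragma: no cover

    def trace_W(j: int) -> None:
        while j > 0:
            if abs(W[j] - W[j - 1]) < eps:
                j -= 1
                continue
            for i in range(0, j + 1):
                if V[i, j] < _zuker.INF / 2:
                    left = W[i - 1] if i > 0 else 0.0
                    if abs(W[j] - (left + V[i, j])) < eps:
                        trace_V(i, j)
                        j = i - 1
                        break
            else:  # pragma: no cover
                raise AssertionError("traceback failed in W")

    if W[n - 1] < -eps:
        trace_W(n - 1)
    return pairs


# ---------------------------------------------------------------------------
# window extraction


def extract_fold_window(
    record: GeneRecord, window: tuple[int, int] = DEFAULT_FOLD_WINDOW
) -> str:
    """The -20..+20 RNA window around a gene's start codon.

    ``window = (n_up, n_down)``: the last ``n_up`` upstream bases followed by
    the first ``n_down`` CDS bases (the start codon is included at +1..+3).
    Raises :class:`DegenerateInputError` when the gene does not cover the
    window.
    """
    n_up, n_down = window
    if len(record.upstream) < n_up or len(record.cds) < n_down:
        raise DegenerateInputError(
            f"gene {record.gene_id!r} does not cover the -{n_up}..+{n_down} window"
        )
    return record.upstream[-n_up:] + record.cds[:n_down]


def fold_windows(
    records: Iterable[GeneRecord], window: tuple[int, int] = DEFAULT_FOLD_WINDOW
) -> tuple[list[str], list[GeneRecord], int]:
    """Fold windows for every record that covers them without ambiguity.

    Returns (windows, contributing records, number dropped).
    """
    windows: list[str] = []
    kept: list[GeneRecord] = []
    dropped = 0
    for rec in records:
        try:
            w = extract_fold_window(rec, window)
        except DegenerateInputError:
            dropped += 1
            continue
        if set(w) - set("ACGU"):
            dropped += 1
            continue
        windows.append(w)
        kept.append(rec)
    return windows, kept, dropped
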