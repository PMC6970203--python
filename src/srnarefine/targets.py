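"""Prediction of sRNA->mRNA interactions.

Two routes produce per-candidate target lists with binding energies:

* a built-in nearest-neighbour-free hybridization scorer — a deliberately
  simple local duplex model (per-pair stacking-free energies plus affine
  interior-loop penalties, no accessibility/unfolding term) whose job in the
  pipeline is only to impose a reproducible total order of binding strength
  over gene windows;
* an adapter that ingests a tabular energy file produced by a dedicated
  RNA-RNA interaction predictor (e.g. IntaRNA CSV output), for runs where
  thermodynamic fidelity matters.

Energies are in kcal/mol and negative for favourable interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genome import TargetWindow

logger = logging.getLogger(__name__)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, 4) for c in seq], dtype=np.uint8)


@njit(cache=True)
def _duplex_core(s, t, pair_matrix, loop_open, loop_extend):  # pragma: no cover
    """Two-state local hybridization DP over encoded sequences.

    Returns (best_score, i_best, j_best, pair_count, j_first_pair); score is
    -energy, maximized.  State M: s[i] pairs t[j]; state L: inside a loop.
    """
    n, m = len(s), len(t)
    M = np.full((n, m), -np.inf)
    L = np.full((n, m), -np.inf)
    cM = np.zeros((n, m), dtype=np.int64)
    cL = np.zeros((n, m), dtype=np.int64)
    jM0 = np.zeros((n, m), dtype=np.int64)
    jL0 = np.zeros((n, m), dtype=np.int64)
    open_ext = loop_open + loop_extend
    for i in range(n):
        si = s[i]
        for j in range(m):
            best = -np.inf
            cnt = 0
            j0 = 0
            if i > 0:
                v = M[i - 1, j] - open_ext
                if v > best:
                    best, cnt, j0 = v, cM[i - 1, j], jM0[i - 1, j]
                v = L[i - 1, j] - loop_extend
                if v > best:
                    best, cnt, j0 = v, cL[i - 1, j], jL0[i - 1, j]
            if j > 0:
                v = M[i, j - 1] - open_ext
                if v > best:
                    best, cnt, j0 = v, cM[i, j - 1], jM0[i, j - 1]
                v = L[i, j - 1] - loop_extend
                if v > best:
                    best, cnt, j0 = v, cL[i, j - 1], jL0[i, j - 1]
            L[i, j] = best
            cL[i, j] = cnt
            jL0[i, j] = j0

            e = pair_matrix[si, t[j]] if si < 4 and t[j] < 4 else 0.0
            if e >= 0.0:
                continue
            best = 0.0
            cnt = 0
            j0 = j
            if i > 0 and j > 0:
                if M[i - 1, j - 1] > best:
                    best, cnt, j0 = M[i - 1, j - 1], cM[i - 1, j - 1], jM0[i - 1, j - 1]
                if L[i - 1, j - 1] > best:
                    best, cnt, j0 = L[i - 1, j - 1], cL[i - 1, j - 1], jL0[i - 1, j - 1]
            M[i, j] = best - e
            cM[i, j] = cnt + 1
            jM0[i, j] = j0
    best_score = -np.inf
    i_best = 0
    j_best = 0
    for i in range(n):
        for j in range(m):
            if M[i, j] > best_score or (
                M[i, j] == best_score and cM[i, j] > cM[i_best, j_best]
            ):
                best_score = M[i, j]
                i_best, j_best = i, j
    return best_score, i_best, j_best, cM[i_best, j_best], jM0[i_best, j_best]


@dataclass(frozen=True)
class HybridizationParams:
    """Built-in duplex model parameters (kcal/mol; penalties positive)."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    loop_open: float = 4.0
    loop_extend: float = 0.5  # per unpaired nt, either strand
    min_duplex_len: int = 6  # minimum base pairs for a reported interaction
    gu_wobble: bool = True

    def __post_init__(self) -> None:
        if not (self.gc < 0 and self.au < 0 and self.gu < 0):
            raise ValueError("pair energies must be negative")
        if self.loop_open <= 0 or self.loop_extend <= 0:
            raise ValueError("loop penalties must be positive")
        if self.min_duplex_len < 1:
            raise ValueError("min_duplex_len must be >= 1")

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of an antiparallel base pair a:b, or None if unpaired."""
        pair = frozenset((a, b))
        if pair == frozenset("GC"):
            return self.gc
        if pair == frozenset("AT"):
            return self.au
        if self.gu_wobble and pair == frozenset("GT"):
            return self.gu
        return None

    def pair_matrix(self) -> np.ndarray:
        """4x4 pair-energy lookup over codes A,C,G,T; 0 marks 'no pair'."""
        mat = np.zeros((4, 4))
        a, c, g, t = 0, 1, 2, 3
        mat[g, c] = mat[c, g] = self.gc
        mat[a, t] = mat[t, a] = self.au
        if self.gu_wobble:
            mat[g, t] = mat[t, g] = self.gu
        return mat


@dataclass(frozen=True)
class TargetPrediction:
    srna_id: str
    gene_id: str
    energy: float  # kcal/mol, <= 0
    span: tuple[int, int]  # half-open offsets on the window (paired extent)
    source: str = "builtin"


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def duplex_energy(
    srna_seq: str, window_seq: str, params: HybridizationParams | None = None
) -> tuple[float, tuple[int, int]] | None:
    """Minimum-energy local antiparallel hybridization of an sRNA with a
    target window.

    Dynamic program over the sRNA (5'->3') and the reversed window, with two
    states per cell: last position paired, or inside an interior loop/bulge.
    Each loop is charged ``loop_open`` once plus ``loop_extend`` per unpaired
    nucleotide on either strand.  Returns ``(energy, (window_start,
    window_end))`` for the best structure, or ``None`` when no structure has
    at least ``min_duplex_len`` pairs and negative energy.
    """
    if params is None:
        params = HybridizationParams()
    s = _encode(_normalize_seq(srna_seq))
    t = _encode(_normalize_seq(window_seq))[::-1].copy()  # antiparallel: 3'->5'
    m = len(t)
    if len(s) == 0 or m == 0:
        return None
    best_score, _i_best, j_best, n_pairs, j_first = _duplex_core(
        s, t, params.pair_matrix(), params.loop_open, params.loop_extend
    )
    if best_score <= 0 or n_pairs < params.min_duplex_len:
        return None
    # map reversed-window indices back to forward window coordinates;
    # j_first is the structure's first pair (largest forward index)
    w_hi = m - int(j_first)
    w_lo = m - 1 - int(j_best)
    return -float(best_score), (w_lo, w_hi)


def predict_targets_builtin(
    srna_id: str,
    srna_seq: str,
    windows: list[TargetWindow],
    params: HybridizationParams | None = None,
    k: int = 50,
) -> list[TargetPrediction]:
    """Score an sRNA against every gene window and keep the ``k`` most
    favourable interactions (energy ascending, ties by gene id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits: list[TargetPrediction] = []
    for w in windows:
        result = duplex_energy(srna_seq, w.sequence, params)
        if result is None:
            continue
        energy, span = result
        if energy >= 0:
            continue
        hits.append(TargetPrediction(srna_id, w.gene_id, energy, span, source="builtin"))
    hits.sort(key=lambda h: (h.energy, h.gene_id))
    return hits[:k]


def read_external_targets(
    path,
    query_col: str = "id1",
    target_col: str = "id2",
    energy_col: str = "E",
    sep: str | None = None,
) -> list[TargetPrediction]:
    """Adapter for external interaction-predictor output (CSV/TSV).

    Rows with positive energy are dropped with a warning; required columns
    missing raise a ValueError naming the column.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else None
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in (query_col, target_col, energy_col):
        if col not in df.columns:
            raise ValueError(f"external target table missing column {col!r}")
    predictions: list[TargetPrediction] = []
    for row in df.itertuples(index=False):
        energy = float(getattr(row, energy_col))
        if energy > 0:
            warnings.warn(
                f"dropping external prediction {getattr(row, query_col)}->"
                f"{getattr(row, target_col)} with positive energy {energy}"
            )
            continue
        predictions.append(
            TargetPrediction(
                str(getattr(row, query_col)),
                str(getattr(row, target_col)),
                energy,
                (0, 0),
                source="external",
            )
        )
    return predictions


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA (to drive an external predictor)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for off in range(0, len(seq), 70):
                fh.write(seq[off : off + 70] + "\n")
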