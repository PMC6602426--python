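"""RNA accessibility: per-nucleotide unpaired probabilities in sliding windows.

Cas13 guides work poorly in highly structured transcript regions, so each
guide is scored by the mean probability of structure over the positions it
targets. Folding is done in 70-nt windows (the default); each position's
unpaired probability is averaged over all windows covering it.

The default folding engine is a fully specified reference partition
function: nested structures only, allowed pairs {AU, UA, GC, CG, GU, UG},
minimum hairpin loop of 3 nt, and a single-parameter energy model of -1
unit per base pair at kT = 1 (Boltzmann weight e per pair). Pair
probabilities come from exact inside/outside recursions in O(n^3). Any
engine implementing :class:`FoldingEngine` (e.g. a thermodynamic package)
can be plugged in instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .enumeration import GuideCandidate
from .errors import ContractError, CoordinateError
from .sequence_io import normalize_sequence

#: Watson-Crick plus G:U wobble, in DNA-alphabet encoding (U stored as T).
CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

#: Minimum number of unpaired bases enclosed by any pair.
MIN_HAIRPIN = 3

#: Boltzmann weight of one base pair (energy -1, kT = 1).
PAIR_WEIGHT = math.e


class FoldingEngine(Protocol):
    """Contract for pluggable secondary-structure engines."""

    name: str

    def pair_probabilities(self, seq: str) -> np.ndarray:
        """Upper-triangular matrix P with P[i, j] = prob. bases i<j pair."""
        ...


@dataclass(frozen=True)
class AccessibilityProfile:
    tx_id: str
    unpaired: tuple[float, ...]  # one probability per transcript position
    window_len: int
    engine_name: str

    def __post_init__(self) -> None:
        if any(not -1e-9 <= u <= 1 + 1e-9 for u in self.unpaired):
            raise ContractError("unpaired probabilities outside [0, 1]")


def _pairable_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if (seq[i], seq[j]) in CANONICAL_PAIRS:
                ok[i, j] = True
    return ok


class ReferencePartitionEngine:
    """Exact partition function under the reference energy model.

    O(n^3) inside/outside recursions; sequences are capped at ``max_len``
    (windows are short, and float64 comfortably holds the ensemble weights
    at this scale).
    """

    name = "reference"

    def __init__(self, max_len: int = 200):
        self.max_len = max_len

    def pair_probabilities(self, seq: str) -> np.ndarray:
        seq = normalize_sequence(seq)
        n = len(seq)
        if n > self.max_len:
            raise ContractError(
                f"sequence length {n} exceeds engine cap {self.max_len}"
            )
        P = np.zeros((n, n))
        if n == 0:
            return P
        w = PAIR_WEIGHT
        can = _pairable_matrix(seq)

        # Z[i, j]: partition function of the half-open slice seq[i:j].
        Z = np.ones((n + 1, n + 1))
        # Zb[i, j]: partition of seq[i..j] (closed) given (i, j) paired.
        Zb = np.zeros((n, n))
        for j in range(1, n + 1):  # half-open end; base j-1 is the last one
            kmax = j - MIN_HAIRPIN - 1  # pairs (k, j-1) need k < kmax
            if kmax > 0:
                ks = np.flatnonzero(can[:kmax, j - 1])
                Zb[ks, j - 1] = w * Z[ks + 1, j - 1]
            zb_col = Zb[:max(kmax, 0), j - 1]
            for i in range(j - 1, -1, -1):
                paired = float(np.dot(Z[i, i:kmax], zb_col[i:])) if i < kmax else 0.0
                Z[i, j] = Z[i, j - 1] + paired
        Ztot = Z[0, n]

        # Zout[p, q]: ensemble weight of everything outside pair (p, q),
        # excluding the pair's own weight and its inside.
        Zout = np.zeros((n, n))
        # L[p, b] = sum over finalized enclosing pairs (a, b), a < p, of
        #           w * Zout[a, b] * Z[a + 1, p]
        Lacc = np.zeros((n, n))
        for span in range(n - 1, MIN_HAIRPIN, -1):  # q - p, descending
            new_pairs = []
            for p in range(0, n - span):
                q = p + span
                if not can[p, q]:
                    continue
                ext = Z[0, p] * Z[q + 1, n]
                if q + 1 < n:
                    # sum over enclosing pairs (a, b): b ranges q+1 .. n-1;
                    # Z[q+1, b] is the gap strictly between q and b
                    enclosed = float(np.dot(Lacc[p, q + 1 :], Z[q + 1, q + 1 : n]))
                else:
                    enclosed = 0.0
                Zout[p, q] = ext + enclosed
                new_pairs.append((p, q))
            # fold the just-finalized pairs into Lacc for smaller spans
            for a, b in new_pairs:
                if a + 1 < n:
                    # rows p = a+1 .. n-1; Z[a+1, p] is the gap between a and p
                    Lacc[a + 1 :, b] += w * Zout[a, b] * Z[a + 1, a + 1 : n]

        for p in range(n):
            for q in range(p + MIN_HAIRPIN + 1, n):
                if can[p, q]:
                    P[p, q] = Zb[p, q] * Zout[p, q] / Ztot
        return P


def unpaired_from_pairs(P: np.ndarray) -> np.ndarray:
    """Per-position unpaired probability u_i = 1 - sum_j P[i, j]."""
    return 1.0 - (P.sum(axis=0) + P.sum(axis=1))


def windowed_unpaired_profile(
    tx_seq: str,
    engine: FoldingEngine | None = None,
    window_len: int = 70,
    step: int = 1,
    *,
    tx_id: str = "tx",
) -> AccessibilityProfile:
    """Fold sliding windows and average per-position unpaired probabilities.

    Transcripts shorter than the window are folded whole. With step > 1 a
    final window anchored at the 3' end is added so every position is
    covered. Positions in several windows take the arithmetic mean.
    """
    if window_len < 10:
        raise ContractError("window_len must be >= 10")
    if step < 1:
        raise ContractError("step must be >= 1")
    if engine is None:
        engine = ReferencePartitionEngine()
    seq = normalize_sequence(tx_seq, name=tx_id)
    n = len(seq)
    if n <= window_len:
        starts = [0]
        window_len_eff = n
    else:
        starts = list(range(0, n - window_len + 1, step))
        if starts[-1] != n - window_len:
            starts.append(n - window_len)
        window_len_eff = window_len
    sums = np.zeros(n)
    counts = np.zeros(n)
    for s in starts:
        u = unpaired_from_pairs(engine.pair_probabilities(seq[s : s + window_len_eff]))
        sums[s : s + window_len_eff] += u
        counts[s : s + window_len_eff] += 1
    prof = np.clip(sums / counts, 0.0, 1.0)
    return AccessibilityProfile(
        tx_id=tx_id,
        unpaired=tuple(float(x) for x in prof),
        window_len=window_len,
        engine_name=engine.name,
    )


def guide_accessibility(
    profile: AccessibilityProfile, cand: GuideCandidate
) -> tuple[float, float]:
    """(mean unpaired, mean structure) over the guide's target positions."""
    L = len(cand.target_seq)
    if cand.start < 0 or cand.start + L > len(profile.unpaired):
        raise CoordinateError(
            f"guide [{cand.start},{cand.start + L}) outside transcript "
            f"{profile.tx_id} (length {len(profile.unpaired)})"
        )
    u = float(np.mean(profile.unpaired[cand.start : cand.start + L]))
    return u, 1.0 - u
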