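"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by the most direct method
available (exhaustive enumeration, position-by-position scanning) without
sharing code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMPL[c] for c in reversed(seq))


# --------------------------------------------------------------------------
# enumeration oracle

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def motif_matches(motif: str, window: str) -> bool:
    return len(motif) == len(window) and all(
        w in IUPAC_SETS[m] for m, w in zip(motif, window)
    )


def count_sites(seq: str, spacer_len: int, motif: str, side: str,
                both_strands: bool) -> int:
    """Position-by-position count of valid target sites."""
    n_found = 0
    strands = [seq, rc(seq)] if both_strands else [seq]
    for s in strands:
        for i in range(len(s) - spacer_len - len(motif) + 1):
            if side == "3prime":
                target = s[i : i + spacer_len]
                mot = s[i + spacer_len : i + spacer_len + len(motif)]
            else:
                mot = s[i : i + len(motif)]
                target = s[i + len(motif) : i + len(motif) + spacer_len]
            if "N" not in target and motif_matches(motif, mot):
                n_found += 1
    return n_found


# --------------------------------------------------------------------------
# self-complementarity oracle


def selfcomp_oracle(spacer: str, backbones=(), min_stem: int = 4) -> int:
    """Exhaustive substring-pair enumeration of maximal stems."""

    def is_stem(a: int, b: int, k: int) -> bool:
        # spacer[a:a+k] == rc(spacer[b:b+k]) with non-overlap a+k <= b
        return a + k <= b and spacer[a : a + k] == rc(spacer[b : b + k])

    count = 0
    n = len(spacer)
    for a in range(n):
        for b in range(a, n):
            for k in range(min_stem, n + 1):
                if a + k > n or b + k > n or not is_stem(a, b, k):
                    continue
                # maximal: not extendable by stacking one more pair on the
                # outer end (a-1 with b+k) or the inner end (a+k with b-1);
                # a register-shifted duplex (a, b, k+1) is a different stem
                ext = (
                    (a > 0 and is_stem(a - 1, b, k + 1))
                    or (b > 0 and is_stem(a, b - 1, k + 1))
                )
                if not ext:
                    count += 1
    for bb in backbones:
        m = len(bb)
        for a in range(n):
            for b in range(m):
                for k in range(min_stem, min(n, m) + 1):
                    if a + k > n or b + k > m:
                        continue
                    if spacer[a : a + k] != rc(bb[b : b + k]):
                        continue

                    def bext(a2, b2, k2):
                        return (
                            0 <= a2
                            and 0 <= b2
                            and a2 + k2 <= n
                            and b2 + k2 <= m
                            and spacer[a2 : a2 + k2] == rc(bb[b2 : b2 + k2])
                        )

                    if not (bext(a - 1, b, k + 1) or bext(a, b - 1, k + 1)):
                        count += 1
    return count


# --------------------------------------------------------------------------
# off-target oracle (pure python, windows + mismatch count)


def offtarget_oracle(target: str, sequences: dict, motif: str, side: str,
                     max_mm: int, both_strands: bool):
    """Set of (contig, start, strand, mismatches) by direct scanning."""
    L, m = len(target), len(motif)
    hits = set()
    for name, seq in sequences.items():
        reps = [("+", seq)]
        if both_strands:
            reps.append(("-", rc(seq)))
        for strand, s in reps:
            for i in range(len(s) - L - m + 1):
                if side == "3prime":
                    window, mot = s[i : i + L], s[i + L : i + L + m]
                    t_start = i
                else:
                    mot, window = s[i : i + m], s[i + m : i + m + L]
                    t_start = i + m
                if not motif_matches(motif, mot):
                    continue
                mm = sum(1 for a, b in zip(target, window) if a != b)
                if mm <= max_mm:
                    fwd = t_start if strand == "+" else len(s) - (t_start + L)
                    hits.add((name, fwd, strand, mm))
    return hits


# --------------------------------------------------------------------------
# structure-ensemble oracle

RNA_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_structures(seq: str) -> list[frozenset]:
    """All nested structures with min hairpin 3 over the allowed pairs."""

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i + 1 <= 0:
            return [frozenset()]
        out = list(rec(i, j - 1))  # base j unpaired
        for k in range(i, j - 3):
            if (seq[k], seq[j]) in RNA_PAIRS:
                for left in rec(i, k - 1):
                    for inside in rec(k + 1, j - 1):
                        out.append(left | inside | {(k, j)})
        return out

    return rec(0, len(seq) - 1)


def pair_prob_oracle(seq: str) -> np.ndarray:
    """Exact pair probabilities with weight e per pair, by enumeration."""
    n = len(seq)
    structs = enumerate_structures(seq)
    weights = [math.e ** len(s) for s in structs]
    Z = sum(weights)
    P = np.zeros((n, n))
    for st, w in zip(structs, weights):
        for i, j in st:
            P[i, j] += w
    return P / Z


# --------------------------------------------------------------------------
# microhomology oracle


def microhomology_oracle(seq: str, cut: int, window: int = 30,
                         mh_min: int = 2, lam: float = 20.0):
    """Exhaustive enumeration of maximal straddling substring pairs.

    Returns (frameshift_fraction, set of (i, D, k) patterns, fallback).
    """
    lo = max(0, cut - window)
    hi = min(len(seq), cut + window)

    def valid(i: int, j: int, k: int) -> bool:
        return (
            lo <= i
            and i + k <= cut
            and cut <= j
            and j + k <= hi
            and seq[i : i + k] == seq[j : j + k]
        )

    pats = set()
    for i in range(lo, cut):
        for j in range(cut, hi):
            for k in range(mh_min, hi - lo + 1):
                if not valid(i, j, k):
                    continue
                if (
                    valid(i - 1, j - 1, k + 1)
                    or valid(i, j, k + 1)
                ):
                    continue
                pats.add((i, j - i, k))
    if not pats:
        return 2.0 / 3.0, pats, True
    weights = {p: p[2] * math.exp(-p[1] / lam) for p in pats}
    total = sum(weights.values())
    shifted = sum(w for (i, D, k), w in weights.items() if D % 3 != 0)
    return shifted / total, pats, False
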