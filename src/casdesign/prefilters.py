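"""Cheap pre-filters applied before scoring: GC content and self-complementarity.

Both filters exist to shrink the candidate set before the expensive
off-target and folding steps. GC bounds default to the 10-90% window; the
self-complementarity filter rejects any spacer that can form a
reverse-complementary stem of at least ``min_stem`` bp, either internally
or against a configured scaffold/backbone sequence, since such folding can
inactivate the guide.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .enumeration import GuideCandidate
from .errors import ContractError
from .sequence_io import normalize_sequence

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}


@dataclass(frozen=True)
class PrefilterConfig:
    gc_min: float = 10.0
    gc_max: float = 90.0
    selfcomp_enabled: bool = True
    min_stem: int = 4
    backbone_seqs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min <= self.gc_max <= 100:
            raise ContractError("need 0 <= gc_min <= gc_max <= 100")
        if self.min_stem < 3:
            raise ContractError("min_stem must be >= 3")


def gc_percent(seq: str) -> Fraction:
    """GC content as an exact percentage (Fraction) in [0, 100]."""
    if not seq:
        raise ContractError("gc_percent of empty sequence")
    seq = normalize_sequence(seq)
    gc = sum(1 for c in seq if c in "GC")
    return Fraction(100 * gc, len(seq))


def _antidiagonal_stems(
    row_seq: str, col_seq: str, min_stem: int, *, self_mode: bool
) -> int:
    """Count maximal complementary runs along anti-diagonals.

    A stem pairs row_seq[i] with col_seq[j] where i+j is constant along the
    stem. In self mode (row_seq is col_seq) only cells with i < j are legal,
    which enforces that the two substrings of the pair are non-overlapping
    and the second one lies 3' of the first.
    """
    n, m = len(row_seq), len(col_seq)
    count = 0
    for d in range(n + m - 1):
        run = 0
        i_lo = max(0, d - m + 1)
        i_hi = min(n - 1, d)
        for i in range(i_lo, i_hi + 1):
            j = d - i
            legal = (not self_mode) or (i < j)
            if legal and _COMPL[row_seq[i]] == col_seq[j]:
                run += 1
            else:
                if run >= min_stem:
                    count += 1
                run = 0
        if run >= min_stem:
            count += 1
    return count


def selfcomp_count(
    spacer: str,
    backbones: Sequence[str] = (),
    min_stem: int = 4,
) -> int:
    """Number of maximal stems of length >= min_stem the spacer can form.

    Counts (a) internal stems — a spacer substring base-paired with the
    reverse complement of a later, non-overlapping spacer substring — and
    (b) stems against any backbone substring. Maximal means not extendable
    on either end. G:U wobble is not counted (DNA-style complement).
    """
    spacer = normalize_sequence(spacer)
    if len(spacer) < min_stem:
        raise ContractError("spacer shorter than min_stem")
    total = _antidiagonal_stems(spacer, spacer, min_stem, self_mode=True)
    for bb in backbones:
        bb = normalize_sequence(bb)
        total += _antidiagonal_stems(spacer, bb, min_stem, self_mode=False)
    return total


def apply_prefilters(
    cands: Sequence[GuideCandidate],
    cfg: PrefilterConfig = PrefilterConfig(),
) -> tuple[list[GuideCandidate], list[tuple[GuideCandidate, list[str]]]]:
    """Split candidates into (kept, rejected-with-reasons).

    GC bounds are inclusive (a guide at exactly 10% or 90% is kept); the GC
    comparison is done in exact rational arithmetic. With selfcomp enabled,
    any guide with at least one stem is rejected.
    """
    lo = Fraction(cfg.gc_min).limit_denominator(10**6)
    hi = Fraction(cfg.gc_max).limit_denominator(10**6)
    kept: list[GuideCandidate] = []
    rejected: list[tuple[GuideCandidate, list[str]]] = []
    for cand in cands:
        reasons: list[str] = []
        gc = gc_percent(cand.spacer_seq)
        if gc < lo:
            reasons.append("gc_low")
        elif gc > hi:
            reasons.append("gc_high")
        if cfg.selfcomp_enabled:
            if selfcomp_count(cand.spacer_seq, cfg.backbone_seqs, cfg.min_stem) > 0:
                reasons.append("self_complementarity")
        if reasons:
            rejected.append((cand, reasons))
        else:
            kept.append(cand)
    return kept, rejected
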