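"""Guide scoring: pluggable efficiency scorers, frameshift prediction, ranking.

Efficiency models trained on large screens are exposed through a scorer
contract (register any callable model by name); the shipped default is a
uniform scorer that satisfies the contract without pretending to be a
trained model. Frameshift probability after a double-strand break is
estimated with a microhomology surrogate: short identical sequences
flanking the cut template deletion-forming repair, and deletions whose
length is not a multiple of three shift the reading frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .enumeration import GuideCandidate
from .errors import ContractError, CoordinateError
from .offtargets import OffTargetSummary

# --------------------------------------------------------------------------
# efficiency scorer contract

#: Context geometry for 3'-motif DNA effectors: bases upstream of the
#: protospacer, and downstream of the motif, in the scorer's input window.
CONTEXT_UP = 4
CONTEXT_DOWN = 3


class UniformScorer:
    """Test double satisfying the EfficiencyScorer contract: constant 0.5.

    A truncated context (sequence edge) yields None — "not available" is
    never silently reported as a score of 0.
    """

    name = "uniform"

    def __init__(self, expected_len: int | None = None):
        self.expected_len = expected_len

    def score(self, context: str | None) -> float | None:
        if context is None:
            return None
        if self.expected_len is not None and len(context) != self.expected_len:
            return None
        return 0.5


SCORER_REGISTRY: dict[str, Callable[[], object]] = {
    "uniform": UniformScorer,
}


def register_scorer(name: str, factory: Callable[[], object]) -> None:
    """Register an external efficiency scorer under *name*."""
    SCORER_REGISTRY[name] = factory


def get_scorer(name: str):
    try:
        return SCORER_REGISTRY[name]()
    except KeyError:
        raise ContractError(f"unknown efficiency scorer {name!r}") from None


# --------------------------------------------------------------------------
# microhomology frameshift surrogate


@dataclass(frozen=True)
class FrameshiftPrediction:
    frameshift_fraction: float
    #: (deletion_start, deletion_len, microhomology_len, weight)
    patterns: tuple[tuple[int, int, int, float], ...]
    fallback_used: bool


def microhomology_frameshift(
    local_seq: str,
    cut_index: int,
    window: int = 30,
    mh_min: int = 2,
    lambda_decay: float = 20.0,
) -> FrameshiftPrediction:
    """Frameshift probability from microhomology-mediated deletion patterns.

    All maximal pairs of identical substrings of length >= ``mh_min`` with
    one copy ending at or before the cut and the other starting at or after
    it, within ``window`` nt of the cut on each side, are enumerated. A pair
    whose copies start D nt apart implies a deletion of length D with weight
    ``k * exp(-D / lambda_decay)`` (k = microhomology length). The
    frameshift fraction is the weight share of deletions with D % 3 != 0.
    With no microhomology at all, a uniform prior over deletion length mod 3
    gives 2/3 (``fallback_used`` is set).
    """
    n = len(local_seq)
    if not 0 <= cut_index <= n:
        raise CoordinateError(f"cut_index {cut_index} outside sequence of length {n}")
    left_lo = max(0, cut_index - window)
    right_hi = min(n, cut_index + window)
    seq = local_seq.upper()
    patterns: list[tuple[int, int, int, float]] = []
    for i in range(left_lo, cut_index):
        for j in range(cut_index, right_hi):
            if seq[i] != seq[j]:
                continue
            # skip non-maximal pairs: extendable one step to the left
            if i > left_lo and j - 1 >= cut_index and seq[i - 1] == seq[j - 1]:
                continue
            k = 0
            while (
                i + k < cut_index  # left copy must end at or before the cut
                and j + k < right_hi
                and seq[i + k] == seq[j + k]
            ):
                k += 1
            if k >= mh_min:
                D = j - i
                w = k * math.exp(-D / lambda_decay)
                patterns.append((i, D, k, w))
    if not patterns:
        return FrameshiftPrediction(2.0 / 3.0, (), True)
    total = sum(p[3] for p in patterns)
    shifted = sum(p[3] for p in patterns if p[1] % 3 != 0)
    return FrameshiftPrediction(shifted / total, tuple(patterns), False)


# --------------------------------------------------------------------------
# ranking


@dataclass
class ScoredGuide:
    """A guide candidate with all annotations a design mode attaches."""

    candidate: GuideCandidate
    mode: str
    gc: float = float("nan")
    selfcomp: int = 0
    offtargets: OffTargetSummary = field(default_factory=OffTargetSummary)
    efficiency: float | None = None
    frameshift: FrameshiftPrediction | None = None
    mean_unpaired: float | None = None
    mean_structure: float | None = None
    constitutive: bool | None = None
    cds_overlap: bool | None = None
    cut: int | None = None
    rank: int | None = None

    @property
    def frameshift_fraction(self) -> float | None:
        return self.frameshift.frameshift_fraction if self.frameshift else None


def _eff_key(g: ScoredGuide) -> tuple:
    # higher efficiency first; not-available sorts after any real score
    return (1, 0.0) if g.efficiency is None else (0, -g.efficiency)


def _pos_key(g: ScoredGuide) -> tuple:
    c = g.candidate
    return (c.contig_or_tx, c.start, c.strand)


def _knockout_key(g: ScoredGuide) -> tuple:
    ff = g.frameshift_fraction
    return (
        g.offtargets.mm0,
        g.offtargets.mm1,
        _eff_key(g),
        -(ff if ff is not None else 0.0),
        _pos_key(g),
    )


def _knockdown_key(g: ScoredGuide) -> tuple:
    u = g.mean_unpaired if g.mean_unpaired is not None else 0.0
    return (g.offtargets.mm0, -u, g.offtargets.mm1, _pos_key(g))


def _generic_key(g: ScoredGuide) -> tuple:
    return (g.offtargets.mm0, g.offtargets.mm1, _eff_key(g), _pos_key(g))


RANKING_KEYS: dict[str, Callable[[ScoredGuide], tuple]] = {
    "knockout": _knockout_key,
    "knockin": _knockout_key,
    "knockdown": _knockdown_key,
    "activate": _generic_key,
    "repress": _generic_key,
    "nanopore": _generic_key,
    "raw": _generic_key,
}


def rank_guides(
    scored: Sequence[ScoredGuide],
    mode: str,
    key: Callable[[ScoredGuide], tuple] | None = None,
) -> list[ScoredGuide]:
    """Deterministic lexicographic ranking; ties fall back to 5'-most position.

    All guides must carry the same mode tag. The returned list is a new
    ordering with 1-based ``rank`` filled in; it is invariant under
    permutation of the input.
    """
    modes = {g.mode for g in scored}
    if len(modes) > 1:
        raise ContractError(f"mixed modes in rank_guides: {sorted(modes)}")
    if key is None:
        key = RANKING_KEYS.get(mode, _generic_key)
    ordered = sorted(scored, key=key)
    for i, g in enumerate(ordered, start=1):
        g.rank = i
    return ordered
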