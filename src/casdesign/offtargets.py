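"""Mismatch off-target search, genome-wide (DNA) or transcriptome-wide (RNA).

An off-target is a motif-valid site (the PAM/PFS must match at the hit)
whose target window differs from the guide's target sequence at no more
than ``max_mm`` positions; indels are not modelled. Two routes are provided:
a vectorised brute-force scan of every window, and a pigeonhole
seed-and-extend search over a flat k-mer table. They are contract-equal and
cross-checked against each other in the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .enumeration import IUPAC, GuideCandidate, PatternSpec, iupac_match
from .errors import ContractError, ControlExhaustionError, StaleIndexError
from .sequence_io import GenomeIndex, normalize_sequence, revcomp


@dataclass(frozen=True)
class OffTargetHit:
    space: str  # 'genomic' or 'transcript'
    contig_or_tx: str
    start: int  # 0-based start of the target window, forward coordinates
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]  # spacer-relative (target 5'->3')


@dataclass(frozen=True)
class OffTargetSummary:
    """MM0-MM3 bin counts; the on-target locus is excluded from mm0."""

    mm0: int = 0
    mm1: int = 0
    mm2: int = 0
    mm3: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.mm0, self.mm1, self.mm2, self.mm3)


def _sequences_of(genome_or_tx) -> Mapping[str, str]:
    if isinstance(genome_or_tx, GenomeIndex):
        return genome_or_tx.contigs
    return genome_or_tx


def _target_of(spacer: str, spec: PatternSpec) -> str:
    """Sense (target-strand) representation of the guide's protospacer."""
    spacer = normalize_sequence(spacer, name="spacer")
    if len(spacer) != spec.spacer_len:
        raise ContractError(
            f"spacer length {len(spacer)} != spec.spacer_len {spec.spacer_len}"
        )
    return revcomp(spacer) if spec.target_class == "RNA" else spacer


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _motif_start_mask(arr: np.ndarray, motif: str) -> np.ndarray:
    """Boolean mask over start positions where the IUPAC motif matches."""
    n, m = len(arr), len(motif)
    if n < m:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n - m + 1, dtype=bool)
    for t, code in enumerate(motif):
        allowed = _encode("".join(sorted(IUPAC[code])))
        ok &= np.isin(arr[t : n - m + 1 + t], allowed)
    return ok


def _scan_one(
    seq: str, target: str, spec: PatternSpec, max_mm: int
) -> list[tuple[int, int, tuple[int, ...]]]:
    """(target_start, mismatches, positions) for plus-orientation sites."""
    L, m = len(target), len(spec.motif)
    if len(seq) < L + m:
        return []
    arr = _encode(seq)
    t_arr = _encode(target)
    wins = sliding_window_view(arr, L)
    mism = (wins != t_arr).sum(axis=1)
    motif_ok = _motif_start_mask(arr, spec.motif)
    out = []
    if spec.motif_side == "3prime":
        # target at p, motif at p + L; p ranges over [0, n - L - m]
        valid = np.flatnonzero(
            (mism[: len(arr) - L - m + 1] <= max_mm) & motif_ok[L:]
        )
        starts = valid
    else:
        # motif at q, target at q + m
        valid = np.flatnonzero(
            motif_ok[: len(arr) - m - L + 1] & (mism[m:] <= max_mm)
        )
        starts = valid + m
    for p in starts:
        diffs = tuple(int(x) for x in np.flatnonzero(wins[p] != t_arr))
        out.append((int(p), len(diffs), diffs))
    return out


def brute_force_offtargets(
    spacer: str,
    genome_or_tx,
    spec: PatternSpec,
    max_mm: int = 3,
) -> list[OffTargetHit]:
    """Scan every motif-valid window for targets within *max_mm* mismatches.

    DNA effectors scan both strands of every contig; RNA effectors scan only
    the sense strand of each transcript. N in a window counts as a mismatch.
    """
    if not 0 <= max_mm <= 5:
        raise ContractError("max_mm must be in [0, 5]")
    target = _target_of(spacer, spec)
    space = "transcript" if spec.target_class == "RNA" else "genomic"
    L = len(target)
    hits: list[OffTargetHit] = []
    for name, seq in _sequences_of(genome_or_tx).items():
        for p, mm, diffs in _scan_one(seq, target, spec, max_mm):
            hits.append(OffTargetHit(space, name, p, "+", mm, diffs))
        if spec.target_class == "DNA":
            rc = revcomp(seq)
            n = len(seq)
            for p, mm, diffs in _scan_one(rc, target, spec, max_mm):
                hits.append(
                    OffTargetHit(space, name, n - (p + L), "-", mm, diffs)
                )
    hits.sort(key=lambda h: (h.contig_or_tx, h.start, h.strand))
    return hits


class KmerIndex:
    """Flat exact k-mer location table over the forward strands.

    Persisted as a plain-text file whose header carries a digest of the
    indexed sequences; loading against different sequences raises
    :class:`StaleIndexError`.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 5):
        if k < 3:
            raise ContractError("k must be >= 3")
        self.k = k
        self.sequences = {n: normalize_sequence(s, name=n) for n, s in sequences.items()}
        self.digest = self._digest(self.sequences)
        table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append((name, i))
        self.table = table

    @staticmethod
    def _digest(sequences: Mapping[str, str]) -> str:
        h = hashlib.sha256()
        for name in sorted(sequences):
            h.update(name.encode())
            h.update(b"\x00")
            h.update(sequences[name].encode())
            h.update(b"\x00")
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#casdesign-kmer-index\tk={self.k}\tdigest={self.digest}\n")
            for kmer in sorted(self.table):
                locs = ",".join(f"{n}:{p}" for n, p in self.table[kmer])
                fh.write(f"{kmer}\t{locs}\n")

    @classmethod
    def load(cls, path: str | Path, sequences: Mapping[str, str]) -> "KmerIndex":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "#casdesign-kmer-index":
                raise StaleIndexError(f"{path} is not a k-mer index file")
            meta = dict(kv.split("=", 1) for kv in header[1:])
            norm = {n: normalize_sequence(s, name=n) for n, s in sequences.items()}
            if meta["digest"] != cls._digest(norm):
                raise StaleIndexError(
                    "index digest does not match the supplied sequences"
                )
            idx = cls.__new__(cls)
            idx.k = int(meta["k"])
            idx.sequences = norm
            idx.digest = meta["digest"]
            table: dict[str, list[tuple[str, int]]] = {}
            for line in fh:
                kmer, locs = line.rstrip("\n").split("\t")
                table[kmer] = [
                    (n, int(p))
                    for n, p in (loc.rsplit(":", 1) for loc in locs.split(","))
                ]
            idx.table = table
            return idx


def _site_layout(spec: PatternSpec, strand: str, L: int):
    """Forward-strand layout of a site on the given strand.

    Returns (rep, motif_rel, motif_check) where ``rep`` is the target
    sequence as it appears on the forward strand, ``motif_rel`` the offset
    of the motif window relative to the forward target start, and
    ``motif_check`` a callable validating the observed forward motif window.
    """
    m = len(spec.motif)
    if strand == "+":
        rel = L if spec.motif_side == "3prime" else -m
        return rel, lambda w: iupac_match(spec.motif, w)
    rel = -m if spec.motif_side == "3prime" else L
    return rel, lambda w: iupac_match(spec.motif, revcomp(w))


def indexed_offtargets(
    spacer: str,
    index: KmerIndex,
    spec: PatternSpec,
    max_mm: int = 3,
) -> list[OffTargetHit]:
    """Seed-and-extend search; set-equal to :func:`brute_force_offtargets`.

    The target is split into ``max_mm + 1`` chunks; by pigeonhole any hit
    with at most ``max_mm`` mismatches contains at least one exact chunk,
    whose first k bases are looked up in the index and extended/verified.
    """
    if not 0 <= max_mm <= 5:
        raise ContractError("max_mm must be in [0, 5]")
    target = _target_of(spacer, spec)
    L = len(target)
    n_chunks = max_mm + 1
    if L // n_chunks < index.k:
        raise ContractError(
            f"spacer too short for k={index.k} seeds with max_mm={max_mm}"
        )
    space = "transcript" if spec.target_class == "RNA" else "genomic"
    strands = ["+"] if spec.target_class == "RNA" else ["+", "-"]
    seen: dict[tuple, OffTargetHit] = {}
    for strand in strands:
        rep = target if strand == "+" else revcomp(target)
        motif_rel, motif_check = _site_layout(spec, strand, L)
        # chunk boundaries over the forward representation
        bounds = [round(i * L / n_chunks) for i in range(n_chunks + 1)]
        for ci in range(n_chunks):
            off = bounds[ci]
            seed = rep[off : off + index.k]
            for name, pos in index.table.get(seed, ()):  # candidate sites
                fstart = pos - off
                seq = index.sequences[name]
                if fstart < 0 or fstart + L > len(seq):
                    continue
                window = seq[fstart : fstart + L]
                # mismatches counted in target 5'->3' orientation
                obs = window if strand == "+" else revcomp(window)
                diffs = tuple(
                    i for i, (a, b) in enumerate(zip(target, obs)) if a != b
                )
                if len(diffs) > max_mm:
                    continue
                ms = fstart + motif_rel
                if ms < 0 or ms + len(spec.motif) > len(seq):
                    continue
                if not motif_check(seq[ms : ms + len(spec.motif)]):
                    continue
                key = (name, fstart, strand)
                seen.setdefault(
                    key,
                    OffTargetHit(space, name, fstart, strand, len(diffs), diffs),
                )
    hits = sorted(seen.values(), key=lambda h: (h.contig_or_tx, h.start, h.strand))
    return hits


def summarize(
    hits: list[OffTargetHit], on_target: GuideCandidate | None = None
) -> OffTargetSummary:
    """Bin hits by mismatch count 0-3, excluding the on-target locus itself.

    Exclusion is by coordinate identity (space, contig, start, strand);
    shifted tandem copies still count. Hits with more than 3 mismatches are
    ignored.
    """
    bins = [0, 0, 0, 0]
    on_key = None
    if on_target is not None:
        on_key = (on_target.space, on_target.contig_or_tx, on_target.start, on_target.strand)
    for h in hits:
        if on_key is not None and (h.space, h.contig_or_tx, h.start, h.strand) == on_key:
            continue
        if h.mismatches <= 3:
            bins[h.mismatches] += 1
    return OffTargetSummary(*bins)


def control_guides(
    genome_or_tx,
    spec: PatternSpec,
    n: int = 1,
    min_mm: int = 4,
    rng_seed: int = 0,
    max_attempts: int | None = None,
) -> list[str]:
    """Design *n* spacers with no genome/transcriptome match.

    "No match" means the brute-force search at up to ``min_mm - 1``
    mismatches returns nothing. Candidates are seeded uniform random spacers
    filtered by the verifier; deterministic for a fixed seed.
    """
    if n < 1 or min_mm < 1:
        raise ContractError("need n >= 1 and min_mm >= 1")
    rng = np.random.default_rng(rng_seed)
    budget = max_attempts if max_attempts is not None else 1000 * n
    bases = np.array(list("ACGT"))
    controls: list[str] = []
    attempts = 0
    while len(controls) < n:
        if attempts >= budget:
            raise ControlExhaustionError(
                f"found {len(controls)}/{n} control guides in {attempts} attempts"
            )
        attempts += 1
        spacer = "".join(rng.choice(bases, size=spec.spacer_len))
        if spacer in controls:
            continue
        if not brute_force_offtargets(spacer, genome_or_tx, spec, min_mm - 1):
            controls.append(spacer)
    return controls
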