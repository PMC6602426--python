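"""Candidate target-site enumeration for DNA- and RNA-targeting effectors.

An effector is described by a :class:`PatternSpec`: spacer length, the
IUPAC motif the protein requires next to the target (PAM on DNA, PFS on
RNA), which side of the target the motif sits on, and whether the target is
DNA or RNA. DNA effectors are enumerated on both strands; RNA effectors only
on the sense strand of a transcript, and their spacer is the reverse
complement of the target site. The motif is never part of the spacer.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ContractError
from .sequence_io import normalize_sequence, revcomp

#: Full 15-letter IUPAC nucleotide code -> set of matching bases.
IUPAC: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
        "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
        "N": "ACGT",
    }.items()
}


@dataclass(frozen=True)
class PatternSpec:
    """Effector definition.

    ``cut_offset`` is the distance in nt from the motif-proximal boundary of
    the protospacer to the (blunt-collapsed) cut: 3 for Cas9-like 3'-motif
    effectors, 18 by default for 5'-motif effectors such as Cas12a.
    """

    effector_name: str
    spacer_len: int
    motif: str
    motif_side: str  # '5prime' or '3prime', relative to the target site
    target_class: str  # 'DNA' or 'RNA'
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if self.spacer_len < 10:
            raise ContractError("spacer_len must be >= 10")
        if not self.motif or any(c not in IUPAC for c in self.motif.upper()):
            raise ContractError(f"motif {self.motif!r} is not IUPAC")
        object.__setattr__(self, "motif", self.motif.upper().replace("U", "T"))
        if self.motif_side not in ("5prime", "3prime"):
            raise ContractError(f"bad motif_side {self.motif_side!r}")
        if self.target_class not in ("DNA", "RNA"):
            raise ContractError(f"bad target_class {self.target_class!r}")


def builtin_effectors() -> dict[str, PatternSpec]:
    """Effector definitions shipped with the package (data/effectors.yaml)."""
    text = resources.files("casdesign").joinpath("data/effectors.yaml").read_text()
    return _parse_effectors(yaml.safe_load(text))


def load_effectors(path: str | Path) -> dict[str, PatternSpec]:
    """Built-in effectors overlaid with user definitions from a YAML file."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    effectors = builtin_effectors()
    effectors.update(_parse_effectors(user))
    return effectors


def _parse_effectors(raw: dict) -> dict[str, PatternSpec]:
    out = {}
    for name, cfg in raw.items():
        out[name.lower()] = PatternSpec(
            effector_name=name.lower(),
            spacer_len=int(cfg["spacer_len"]),
            motif=str(cfg["motif"]),
            motif_side=str(cfg["motif_side"]),
            target_class=str(cfg["target_class"]).upper(),
            cut_offset=cfg.get("cut_offset"),
        )
    return out


@dataclass(frozen=True)
class GuideCandidate:
    """One enumerated target site.

    ``start`` is the 0-based start of the target site itself (motif
    excluded) on the forward strand of ``contig_or_tx``. ``target_seq`` is
    the protospacer read 5'->3' on the target strand; ``spacer_seq`` is what
    goes into the guide RNA (identical to the target for DNA effectors,
    reverse complement of it for RNA effectors) and never includes the motif.
    """

    id: str
    space: str  # 'genomic' or 'transcript'
    contig_or_tx: str
    start: int
    strand: str
    target_seq: str
    motif_seq: str
    spacer_seq: str
    context_seq: str = ""

    @property
    def end(self) -> int:
        return self.start + len(self.target_seq)


def iupac_match(motif: str, window: str) -> bool:
    """True iff each base of *window* is in the IUPAC set of *motif*.

    N in the window matches nothing (not even motif N): an undefined genome
    base cannot satisfy a motif requirement.
    """
    if len(motif) != len(window):
        raise ContractError(
            f"motif length {len(motif)} != window length {len(window)}"
        )
    return all(w in IUPAC[m] for m, w in zip(motif, window))


def _scan_forward(seq: str, spec: PatternSpec) -> list[tuple[int, str, str]]:
    """Yield (target_start, target, motif) for plus-orientation sites."""
    L, m = spec.spacer_len, len(spec.motif)
    out = []
    for i in range(len(seq) - (L + m) + 1):
        if spec.motif_side == "3prime":
            t_start, target, motif_obs = i, seq[i : i + L], seq[i + L : i + L + m]
        else:
            t_start, target, motif_obs = i + m, seq[i + m : i + m + L], seq[i : i + m]
        if "N" in target:
            continue
        if iupac_match(spec.motif, motif_obs):
            out.append((t_start, target, motif_obs))
    return out


def enumerate_guides(
    seq: str,
    spec: PatternSpec,
    both_strands: bool = True,
    *,
    space: str = "genomic",
    name: str = "seq",
    start_offset: int = 0,
) -> list[GuideCandidate]:
    """Enumerate all candidate target sites of *spec* in *seq*.

    RNA effectors are restricted to the sense strand regardless of
    *both_strands*. Target windows containing N are skipped. Candidates are
    sorted by (start, strand) and deduplicated on (space, contig, start,
    strand). ``start_offset`` shifts reported coordinates when *seq* is a
    slice of a larger contig.
    """
    seq = normalize_sequence(seq, name=name)
    L = spec.spacer_len
    if spec.target_class == "RNA":
        both_strands = False
    n = len(seq)
    found: dict[tuple, GuideCandidate] = {}

    def add(t_start: int, strand: str, target: str, motif_obs: str, scanned: str, scan_start: int) -> None:
        spacer = revcomp(target) if spec.target_class == "RNA" else target
        ctx = scanned[max(0, scan_start - 10) : scan_start + L + 10]
        gstart = t_start + start_offset
        key = (space, name, gstart, strand)
        if key in found:
            return
        found[key] = GuideCandidate(
            id=f"{spec.effector_name}_{name}_{gstart}{strand}",
            space=space,
            contig_or_tx=name,
            start=gstart,
            strand=strand,
            target_seq=target,
            motif_seq=motif_obs,
            spacer_seq=spacer,
            context_seq=ctx,
        )

    for t_start, target, motif_obs in _scan_forward(seq, spec):
        add(t_start, "+", target, motif_obs, seq, t_start)
    if both_strands:
        rc = revcomp(seq)
        for rc_start, target, motif_obs in _scan_forward(rc, spec):
            fwd_start = n - (rc_start + L)
            cand = GuideCandidate(
                id=f"{spec.effector_name}_{name}_{fwd_start + start_offset}-",
                space=space,
                contig_or_tx=name,
                start=fwd_start + start_offset,
                strand="-",
                target_seq=target,
                motif_seq=motif_obs,
                spacer_seq=target,
                context_seq=rc[max(0, rc_start - 10) : rc_start + L + 10],
            )
            found.setdefault((space, name, cand.start, "-"), cand)
    return sorted(found.values(), key=lambda c: (c.start, c.strand))


#: Sentinel returned by cut_site for effectors that do not cut DNA.
NO_DNA_CUT = None


def cut_site(c: GuideCandidate, spec: PatternSpec) -> int | None:
    """Between-base cut index in forward coordinates, or None for RNA.

    Cas9-like 3'-motif effectors cut bluntly 3 nt motif-proximal; 5'-motif
    effectors use ``spec.cut_offset`` nt downstream of the motif end
    (default 18, a single-index collapse of the staggered Cas12a cut).
    """
    if spec.target_class == "RNA":
        return NO_DNA_CUT
    L = spec.spacer_len
    if spec.motif_side == "3prime":
        offset = spec.cut_offset if spec.cut_offset is not None else 3
        return c.start + L - offset if c.strand == "+" else c.start + offset
    offset = spec.cut_offset if spec.cut_offset is not None else 18
    return c.start + offset if c.strand == "+" else c.start + L - offset
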