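"""The five experiment modes: knockout, knockdown, knock-in, activation/
repression, and nanopore enrichment, plus isoform resolution.

Every mode runs the same backbone — enumerate candidate sites, prefilter,
summarize off-targets, score, rank — and differs in where candidates come
from (gene exons, transcript sequence, promoter window, region flanks) and
which annotations matter for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import _intervals
from .accessibility import (
    AccessibilityProfile,
    FoldingEngine,
    guide_accessibility,
    windowed_unpaired_profile,
)
from .enumeration import GuideCandidate, PatternSpec, cut_site, enumerate_guides
from .errors import ContractError, CoordinateError
from .offtargets import brute_force_offtargets, summarize
from .prefilters import PrefilterConfig, apply_prefilters, gc_percent, selfcomp_count
from .scoring import (
    ScoredGuide,
    get_scorer,
    microhomology_frameshift,
    rank_guides,
)
from .sequence_io import GeneModel, GenomeIndex, Transcript, transcript_sequence

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class DesignConfig:
    """Knobs shared by the design modes; defaults are the documented ones."""

    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    max_mm: int = 3
    scorer: str = "uniform"
    isoform_mode: str = "intersection"  # or 'union'
    require_cds_overlap: bool = True
    # microhomology surrogate
    mh_window: int = 30
    mh_min: int = 2
    mh_lambda: float = 20.0
    # accessibility
    window_len: int = 70
    window_step: int = 1
    # knock-in
    arm_cap: int = 2000
    # activation / repression promoter windows, relative to the TSS
    activate_window: Interval = (-400, -50)
    repress_window: Interval = (-50, 300)
    tss_choice: str = "5prime_most"  # or 'per_isoform'
    # nanopore enrichment
    span_max: int = 40_000
    flank_width: int = 1000
    min_efficiency: float = 0.3
    boundary_slop: int = 0


@dataclass(frozen=True)
class IsoformResolution:
    mode: str
    intersection: tuple[Interval, ...]
    union: tuple[Interval, ...]

    @property
    def target_intervals(self) -> tuple[Interval, ...]:
        return self.intersection if self.mode == "intersection" else self.union

    def is_constitutive(self, start: int, end: int) -> bool:
        return _intervals.contains(self.intersection, start, end)


@dataclass(frozen=True)
class HomologyArms:
    left_seq: str
    right_seq: str
    cut_site: int
    contig: str

    @property
    def left_len(self) -> int:
        return len(self.left_seq)

    @property
    def right_len(self) -> int:
        return len(self.right_seq)


@dataclass(frozen=True)
class GuidePair:
    left: ScoredGuide
    right: ScoredGuide
    span: int  # nt between the two cut sites
    region: Interval


@dataclass(frozen=True)
class PromoterWindow:
    purpose: str  # 'activate' or 'repress'
    relative: Interval  # [upstream_offset, downstream_offset) w.r.t. TSS
    genomic: Interval
    contig: str
    tss: int


@dataclass
class DesignResult:
    mode: str
    guides: list[ScoredGuide] = field(default_factory=list)
    pairs: list[GuidePair] = field(default_factory=list)
    arms: list[HomologyArms] = field(default_factory=list)
    rejected: list[tuple[GuideCandidate, list[str]]] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)
    resolution: IsoformResolution | None = None


# --------------------------------------------------------------------------
# isoform resolution


def resolve_isoforms(gene: GeneModel, mode: str = "intersection") -> IsoformResolution:
    """Exonic coverage shared by every isoform vs present in any isoform."""
    if mode not in ("intersection", "union"):
        raise ContractError(f"unknown isoform mode {mode!r}")
    exon_sets = [t.exons for t in gene.transcripts]
    return IsoformResolution(
        mode=mode,
        intersection=tuple(_intervals.intersect_all(exon_sets)),
        union=tuple(_intervals.union_all(exon_sets)),
    )


# --------------------------------------------------------------------------
# shared annotation pipeline


def _annotate(
    cand: GuideCandidate,
    spec: PatternSpec,
    cfg: DesignConfig,
    mode: str,
    *,
    search_space,
    genome: GenomeIndex | None = None,
    scorer=None,
) -> ScoredGuide:
    g = ScoredGuide(candidate=cand, mode=mode)
    g.gc = float(gc_percent(cand.spacer_seq))
    g.selfcomp = selfcomp_count(
        cand.spacer_seq, cfg.prefilter.backbone_seqs, cfg.prefilter.min_stem
    )
    hits = brute_force_offtargets(cand.spacer_seq, search_space, spec, cfg.max_mm)
    g.offtargets = summarize(hits, cand)
    scorer = scorer or get_scorer(cfg.scorer)
    g.efficiency = scorer.score(_scoring_context(cand, spec, genome))
    if genome is not None and spec.target_class == "DNA":
        g.cut = cut_site(cand, spec)
        if g.cut is not None:
            contig_seq = genome.contigs[cand.contig_or_tx]
            g.frameshift = microhomology_frameshift(
                contig_seq, g.cut, cfg.mh_window, cfg.mh_min, cfg.mh_lambda
            )
    return g


def _scoring_context(
    cand: GuideCandidate, spec: PatternSpec, genome: GenomeIndex | None
) -> str | None:
    """Target + motif with a 4 nt / 3 nt flank, oriented 5'->3'; None at edges."""
    if genome is None or cand.space != "genomic":
        return None
    L, m = len(cand.target_seq), len(cand.motif_seq)
    contig = genome.contigs[cand.contig_or_tx]
    if cand.strand == "+":
        lo = cand.start - 4 if spec.motif_side == "3prime" else cand.start - m - 4
        hi = lo + 4 + L + m + 3
        if lo < 0 or hi > len(contig):
            return None
        return contig[lo:hi]
    from .sequence_io import revcomp

    hi = cand.end + 4 if spec.motif_side == "3prime" else cand.end + m + 4
    lo = hi - (4 + L + m + 3)
    if lo < 0 or hi > len(contig):
        return None
    return revcomp(contig[lo:hi])


# --------------------------------------------------------------------------
# knockout


def design_knockout(
    gene: GeneModel,
    genome: GenomeIndex,
    spec: PatternSpec,
    cfg: DesignConfig = DesignConfig(),
) -> DesignResult:
    """Rank guides over the resolved exonic intervals of a gene."""
    if spec.target_class != "DNA":
        raise ContractError("knockout requires a DNA-targeting effector")
    res = resolve_isoforms(gene, cfg.isoform_mode)
    result = DesignResult(mode="knockout", resolution=res)
    if not res.target_intervals:
        result.notices.append(
            f"{gene.gene_id}: isoform {cfg.isoform_mode} is empty; no region to search"
        )
        return result
    cands = _enumerate_in_intervals(genome, gene.contig, res.target_intervals, spec)
    kept, rejected = apply_prefilters(cands, cfg.prefilter)
    result.rejected.extend(rejected)

    cds_cov = _intervals.merge(
        iv for t in gene.transcripts if t.cds for iv in t.cds
    )
    final: list[ScoredGuide] = []
    for cand in kept:
        in_cds = _intervals.overlaps(cds_cov, cand.start, cand.end)
        if cfg.require_cds_overlap and not in_cds:
            result.rejected.append((cand, ["non_coding"]))
            continue
        g = _annotate(cand, spec, cfg, "knockout", search_space=genome, genome=genome)
        g.cds_overlap = in_cds
        g.constitutive = res.is_constitutive(cand.start, cand.end)
        final.append(g)
    result.guides = rank_guides(final, "knockout")
    return result


def _enumerate_in_intervals(
    genome: GenomeIndex,
    contig: str,
    intervals: Sequence[Interval],
    spec: PatternSpec,
) -> list[GuideCandidate]:
    """Candidates whose target site lies inside one of the intervals.

    The motif may extend past the interval edge (it exists in the genome
    either way); enumeration therefore scans a margin around each interval.
    """
    margin = spec.spacer_len + len(spec.motif)
    seq = genome.contigs[contig]
    out: dict[tuple, GuideCandidate] = {}
    for s, e in _intervals.merge(intervals):
        lo, hi = max(0, s - margin), min(len(seq), e + margin)
        for cand in enumerate_guides(
            seq[lo:hi], spec, both_strands=True, name=contig, start_offset=lo
        ):
            if s <= cand.start and cand.end <= e:
                out.setdefault((cand.start, cand.strand), cand)
    return sorted(out.values(), key=lambda c: (c.start, c.strand))


# --------------------------------------------------------------------------
# knockdown (RNA)


def design_knockdown(
    gene: GeneModel,
    genome: GenomeIndex,
    spec: PatternSpec,
    cfg: DesignConfig = DesignConfig(),
    transcriptome: Mapping[str, str] | None = None,
    engine: FoldingEngine | None = None,
) -> DesignResult:
    """Cas13-style design on spliced transcripts with accessibility scoring.

    ``transcriptome`` is the off-target search space (tx id -> sequence);
    it defaults to the transcripts of this gene. Guides sharing an identical
    genomic footprint across isoforms are reported once.
    """
    if spec.target_class != "RNA":
        raise ContractError("knockdown requires an RNA-targeting effector")
    res = resolve_isoforms(gene, cfg.isoform_mode)
    result = DesignResult(mode="knockdown", resolution=res)
    tx_seqs = {t.id: transcript_sequence(t, genome) for t in gene.transcripts}
    search_space = dict(transcriptome) if transcriptome else dict(tx_seqs)
    scorer = get_scorer(cfg.scorer)

    seen_footprints: set[tuple] = set()
    final: list[ScoredGuide] = []
    for t in gene.transcripts:
        seq = tx_seqs[t.id]
        if len(seq) < spec.spacer_len + len(spec.motif):
            continue
        profile = windowed_unpaired_profile(
            seq, engine, cfg.window_len, cfg.window_step, tx_id=t.id
        )
        cands = enumerate_guides(seq, spec, both_strands=False, space="transcript", name=t.id)
        gpos = t.genomic_positions()
        kept, rejected = apply_prefilters(cands, cfg.prefilter)
        result.rejected.extend(rejected)
        for cand in kept:
            footprint = tuple(sorted(gpos[cand.start : cand.end]))
            fp_ivs = _positions_to_intervals(footprint)
            constitutive = all(
                _intervals.contains(res.intersection, s, e) for s, e in fp_ivs
            )
            if cfg.isoform_mode == "intersection" and not constitutive:
                result.rejected.append((cand, ["not_in_every_isoform"]))
                continue
            if footprint in seen_footprints:
                continue
            seen_footprints.add(footprint)
            g = _annotate(
                cand, spec, cfg, "knockdown",
                search_space=search_space, genome=None, scorer=scorer,
            )
            g.efficiency = scorer.score(cand.context_seq or None)
            g.mean_unpaired, g.mean_structure = guide_accessibility(profile, cand)
            g.constitutive = constitutive
            final.append(g)
    if not final and cfg.isoform_mode == "intersection":
        result.notices.append(
            f"{gene.gene_id}: no guide lies in every isoform (intersection mode)"
        )
    result.guides = rank_guides(final, "knockdown")
    return result


def _positions_to_intervals(positions: Sequence[int]) -> list[Interval]:
    if not positions:
        return []
    out = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        out.append((start, prev + 1))
        start = prev = p
    out.append((start, prev + 1))
    return out


# --------------------------------------------------------------------------
# knock-in


def design_knockin_arms(
    cut: int,
    genome: GenomeIndex,
    contig: str,
    arm_len_requested: int,
    cap: int = 2000,
) -> HomologyArms:
    """Homology arms abutting the cut, clamped to the 2 kb cap and the contig."""
    if arm_len_requested <= 0:
        raise ContractError("arm_len_requested must be positive")
    seq = genome.contigs.get(contig)
    if seq is None or not 0 <= cut <= len(seq):
        raise CoordinateError(f"cut site {cut} outside contig {contig!r}")
    if arm_len_requested > cap:
        logger.warning(
            "requested arm length %d clamped to cap %d", arm_len_requested, cap
        )
    want = min(arm_len_requested, cap)
    left = seq[max(0, cut - want) : cut]
    right = seq[cut : min(len(seq), cut + want)]
    return HomologyArms(left_seq=left, right_seq=right, cut_site=cut, contig=contig)


def design_knockin(
    gene: GeneModel,
    genome: GenomeIndex,
    spec: PatternSpec,
    cfg: DesignConfig = DesignConfig(),
    arm_len_requested: int = 2000,
) -> DesignResult:
    """Same guides as knockout, plus homology arms around each cut site."""
    result = design_knockout(gene, genome, spec, cfg)
    result.mode = "knockin"
    for g in result.guides:
        g.mode = "knockin"
        if g.cut is not None:
            result.arms.append(
                design_knockin_arms(
                    g.cut, genome, g.candidate.contig_or_tx,
                    arm_len_requested, cfg.arm_cap,
                )
            )
    return result


# --------------------------------------------------------------------------
# activation / repression


def promoter_window(
    gene: GeneModel,
    purpose: str,
    cfg: DesignConfig = DesignConfig(),
    genome: GenomeIndex | None = None,
) -> PromoterWindow:
    """Strand-aware promoter interval anchored at the gene's TSS.

    The TSS is the 5'-most TSS among isoforms. Windows falling off the
    contig are clipped with a warning.
    """
    if purpose not in ("activate", "repress"):
        raise ContractError(f"unknown purpose {purpose!r}")
    rel = cfg.activate_window if purpose == "activate" else cfg.repress_window
    strand = gene.strand
    tsss = [t.tss for t in gene.transcripts]
    tss = min(tsss) if strand == "+" else max(tsss)
    a, b = rel
    if strand == "+":
        gs, ge = tss + a, tss + b
    else:
        gs, ge = tss - b, tss - a
    if genome is not None:
        length = len(genome.contigs[gene.contig])
        cs, ce = max(0, gs), min(length, ge)
        if (cs, ce) != (gs, ge):
            logger.warning(
                "promoter window [%d,%d) clipped to [%d,%d)", gs, ge, cs, ce
            )
        gs, ge = cs, ce
    if gs >= ge:
        raise ContractError("promoter window is empty after clipping")
    return PromoterWindow(
        purpose=purpose, relative=rel, genomic=(gs, ge), contig=gene.contig, tss=tss
    )


def design_promoter_targeting(
    gene: GeneModel,
    genome: GenomeIndex,
    spec: PatternSpec,
    purpose: str,
    cfg: DesignConfig = DesignConfig(),
) -> DesignResult:
    """CRISPRa/CRISPRi design inside the promoter window."""
    if spec.target_class != "DNA":
        raise ContractError("activation/repression requires a DNA effector")
    win = promoter_window(gene, purpose, cfg, genome)
    result = DesignResult(mode=purpose)
    cands = _enumerate_in_intervals(genome, win.contig, [win.genomic], spec)
    kept, rejected = apply_prefilters(cands, cfg.prefilter)
    result.rejected.extend(rejected)
    final = [
        _annotate(c, spec, cfg, purpose, search_space=genome, genome=genome)
        for c in kept
    ]
    result.guides = rank_guides(final, purpose)
    result.notices.append(
        f"promoter window {win.genomic} ({purpose}) anchored at TSS {win.tss}"
    )
    return result


# --------------------------------------------------------------------------
# nanopore enrichment


def design_nanopore_pairs(
    region: Interval,
    genome: GenomeIndex,
    contig: str,
    spec: PatternSpec,
    cfg: DesignConfig = DesignConfig(),
) -> DesignResult:
    """Guide pairs whose cuts flank *region* for Cas9-mediated enrichment.

    Self-complementary guides are removed unconditionally (they inhibit
    multiplexed Cas9 activity), low-efficiency guides are removed, both
    cuts must fall outside the region (up to ``boundary_slop``), and the
    cut-to-cut span may not exceed 40 kb. Pairs are ranked by their worse
    member, then by smaller span overhang.
    """
    if spec.target_class != "DNA":
        raise ContractError("nanopore enrichment requires a DNA effector")
    start, end = region
    if not 0 <= start < end <= len(genome.contigs[contig]):
        raise CoordinateError(f"region {region} outside contig {contig!r}")
    result = DesignResult(mode="nanopore")
    if end - start > cfg.span_max:
        result.notices.append(
            f"region length {end - start} exceeds the {cfg.span_max} nt span cap"
        )
        return result

    def flank_guides(lo: int, hi: int) -> list[ScoredGuide]:
        cands = _enumerate_in_intervals(genome, contig, [(lo, hi)], spec)
        out = []
        for cand in cands:
            if selfcomp_count(
                cand.spacer_seq, cfg.prefilter.backbone_seqs, cfg.prefilter.min_stem
            ) > 0:
                result.rejected.append((cand, ["self_complementarity"]))
                continue
            kept, rejected = apply_prefilters([cand], cfg.prefilter)
            if rejected:
                result.rejected.extend(rejected)
                continue
            g = _annotate(cand, spec, cfg, "nanopore", search_space=genome, genome=genome)
            if g.efficiency is not None and g.efficiency < cfg.min_efficiency:
                result.rejected.append((cand, ["low_efficiency"]))
                continue
            out.append(g)
        return out

    left = flank_guides(max(0, start - cfg.flank_width), start + cfg.boundary_slop)
    right = flank_guides(end - cfg.boundary_slop, min(len(genome.contigs[contig]), end + cfg.flank_width))
    left = [g for g in left if g.cut is not None and g.cut < start + cfg.boundary_slop]
    right = [g for g in right if g.cut is not None and g.cut > end - cfg.boundary_slop]
    left = rank_guides(left, "nanopore")
    right = rank_guides(right, "nanopore")
    result.guides = left + right

    pairs = []
    for gl in left:
        for gr in right:
            span = gr.cut - gl.cut
            if span <= cfg.span_max:
                pairs.append(GuidePair(left=gl, right=gr, span=span, region=region))
    pairs.sort(
        key=lambda p: (
            max(p.left.rank, p.right.rank),
            p.span - (end - start),
            p.left.cut,
            p.right.cut,
        )
    )
    result.pairs = pairs
    if not pairs:
        result.notices.append("no guide pair satisfies the span and flank constraints")
    return result


# --------------------------------------------------------------------------
# downstream in-frame ATGs


def downstream_atgs(
    transcript: Transcript,
    genome: GenomeIndex,
    position: int,
) -> list[int]:
    """CDS-relative offsets of in-frame ATGs 3' of a genomic guide position.

    Offsets are measured from the annotated start codon (offset 0) and are
    multiples of 3. A transcript without CDS yields an empty list.
    """
    if transcript.cds is None:
        logger.info("%s has no CDS; no downstream ATGs", transcript.id)
        return []
    from .sequence_io import revcomp

    contig_seq = genome.contigs[transcript.contig]
    cds_pos = transcript.cds_genomic_positions()
    if transcript.strand == "+":
        cds_seq = "".join(contig_seq[p] for p in cds_pos)
    else:
        cds_seq = "".join(revcomp(contig_seq[p]) for p in cds_pos)
    # index of the first CDS base strictly 3' of the guide position
    if transcript.strand == "+":
        after = [i for i, p in enumerate(cds_pos) if p > position]
    else:
        after = [i for i, p in enumerate(cds_pos) if p < position]
    guide_idx = after[0] if after else len(cds_pos)
    return [
        o
        for o in range(0, len(cds_seq) - 2, 3)
        if o >= guide_idx and cds_seq[o : o + 3] == "ATG"
    ]
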