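"""Deterministic synthetic genomes, annotations and spiked guide scenarios.

Every test and worked example in this package runs on fixtures produced
here: a seeded random genome with target sites (target + concrete motif)
planted at recorded positions with exact mismatch counts, and multi-isoform
gene models with known intersection/union exon sets, CDS and planted
in-frame downstream ATGs. The manifest returned alongside each fixture is
the ground truth the integration tests compare against. Identical
FixtureSpec (including seed) => byte-identical FASTA/GFF3 output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CapacityError, ContractError
from .sequence_io import GeneModel, GenomeIndex, Transcript, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """A target site to spike into the genome.

    ``motif`` is a concrete motif realization appended on ``motif_side`` of
    each planted copy (empty string to plant the bare target). ``mismatches``
    substitutions are introduced into the target portion of every copy.
    """

    spacer: str
    n_copies: int = 1
    mismatches: int = 0
    motif: str = ""
    motif_side: str = "3prime"
    strand: str = "+"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_contigs: int = 1
    contig_len: int = 10_000
    gc_fraction: float = 0.5
    n_genes: int = 1
    isoforms_per_gene: int = 2
    planted_sites: tuple[PlantedSite, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ContractError("gc_fraction must be in (0, 1)")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> tuple[str, list[int]]:
    """Introduce exactly n_mut substitutions at distinct random positions."""
    if n_mut > len(seq):
        raise ContractError("more mismatches than positions")
    positions = sorted(rng.choice(len(seq), size=n_mut, replace=False).tolist())
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars), positions


def make_genome(spec: FixtureSpec) -> tuple[GenomeIndex, dict]:
    """Seeded random genome with planted sites; returns (genome, manifest).

    Planted copies are inserted at non-overlapping recorded positions.
    Raises :class:`CapacityError` when a site cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, list[str]] = {}
    for i in range(spec.n_contigs):
        contigs[f"c{i + 1}"] = list(
            _random_seq(rng, spec.contig_len, spec.gc_fraction)
        )
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in contigs}
    manifest: dict = {"planted": [], "seed": spec.seed}
    names = list(contigs)
    for site in spec.planted_sites:
        full_len = len(site.spacer) + len(site.motif)
        for _ in range(site.n_copies):
            placed = False
            for _attempt in range(200):
                contig = names[rng.integers(len(names))]
                if spec.contig_len < full_len:
                    break
                pos = int(rng.integers(0, spec.contig_len - full_len + 1))
                if any(
                    pos < e and pos + full_len > s for s, e in occupied[contig]
                ):
                    continue
                target, mutated = _mutate(rng, site.spacer.upper(), site.mismatches)
                if site.motif_side == "3prime":
                    insert = target + site.motif.upper()
                    t_pos = pos
                else:
                    insert = site.motif.upper() + target
                    t_pos = pos + len(site.motif)
                if site.strand == "-":
                    insert = revcomp(insert)
                    t_pos = pos + (len(site.motif) if site.motif_side == "3prime" else 0)
                contigs[contig][pos : pos + full_len] = list(insert)
                occupied[contig].append((pos, pos + full_len))
                manifest["planted"].append(
                    {
                        "spacer": site.spacer.upper(),
                        "contig": contig,
                        "target_start": t_pos,
                        "strand": site.strand,
                        "mismatches": site.mismatches,
                        "mutated_positions": mutated,
                    }
                )
                placed = True
                break
            if not placed:
                raise CapacityError(
                    f"could not place a copy of {site.spacer} ({full_len} nt)"
                )
    genome = GenomeIndex({n: "".join(chars) for n, chars in contigs.items()})
    return genome, manifest


# --------------------------------------------------------------------------
# annotation fixtures

#: Codons free of ATG and of stop codons, used to build CDS filler.
_SAFE_CODONS = ("GCT", "GAA", "CTT", "GGA", "TCA", "CCA", "GTT", "AAA")


def _design_cds(rng: np.random.Generator, n_codons: int, atg_codon: int) -> str:
    """Start codon + filler codons + one planted in-frame ATG + stop."""
    if not 1 <= atg_codon <= n_codons - 2:
        raise ContractError("planted ATG codon out of range")
    codons = ["ATG"]
    for c in range(1, n_codons - 1):
        if c == atg_codon:
            codons.append("ATG")
        else:
            codons.append(_SAFE_CODONS[rng.integers(len(_SAFE_CODONS))])
    codons.append("TAA")
    return "".join(codons)


def _write_through_intervals(
    chars: list[str], intervals: Sequence[tuple[int, int]], strand: str, seq: str
) -> None:
    """Write a transcript-space sequence into genomic interval slices."""
    total = sum(e - s for s, e in intervals)
    if total != len(seq):
        raise ContractError("sequence length != interval coverage")
    genomic = seq if strand == "+" else revcomp(seq)
    off = 0
    for s, e in sorted(intervals):
        chars[s:e] = list(genomic[off : off + (e - s)])
        off += e - s


def make_annotation(
    genome: GenomeIndex, spec: FixtureSpec
) -> tuple[GenomeIndex, list[GeneModel], dict]:
    """Multi-isoform genes with shared + unique exons and designed CDS.

    Gene g occupies its own window on contig 1: two shared exons A1, A2
    (constitutive) and, with >= 2 isoforms, a cassette exon B present only
    in the second isoform. The CDS lives in A1+A2, is shared by all
    isoforms, and contains exactly one planted in-frame downstream ATG.
    Returns the genome with the designed CDS written in, the gene models,
    and a ground-truth manifest.
    """
    rng = np.random.default_rng(spec.seed + 1)
    contig = "c1"
    chars = list(genome.contigs[contig])
    gene_span = 1600
    lead = 600  # room upstream of the first TSS for promoter windows
    if lead + spec.n_genes * gene_span > len(chars):
        raise CapacityError(
            f"{spec.n_genes} genes x {gene_span} nt (+{lead} nt lead) do not "
            f"fit contig of {len(chars)} nt"
        )
    genes: list[GeneModel] = []
    manifest: dict = {"genes": []}
    for gi in range(spec.n_genes):
        base = lead + gi * gene_span
        strand = "+" if gi % 2 == 0 else "-"
        a1 = (base, base + 240)
        cassette = (base + 300, base + 360)
        a2 = (base + 420, base + 720)
        # CDS: inside A1 and A2, total length divisible by 3
        cds1 = (a1[0] + 30, a1[1])  # 210 nt
        cds2 = (a2[0], a2[1] - 30)  # 270 nt -> 480 nt = 160 codons
        n_codons = ((cds1[1] - cds1[0]) + (cds2[1] - cds2[0])) // 3
        atg_codon = 3 + int(rng.integers(0, n_codons - 6))
        cds_seq = _design_cds(rng, n_codons, atg_codon)
        cds_intervals = (cds1, cds2)
        _write_through_intervals(chars, cds_intervals, strand, cds_seq)

        tx_list = []
        exon_sets = []
        for ti in range(max(1, spec.isoforms_per_gene)):
            exons = [a1, a2]
            if ti == 1:
                exons = [a1, cassette, a2]
            elif ti >= 2:
                # further isoforms reuse the cassette plus a 3' extension
                exons = [a1, cassette, (a2[0], a2[1] + 40 * (ti - 1))]
            tx_list.append(
                Transcript(
                    id=f"g{gi + 1}.t{ti + 1}",
                    gene_id=f"g{gi + 1}",
                    contig=contig,
                    strand=strand,
                    exons=tuple(exons),
                    cds=cds_intervals,
                )
            )
            exon_sets.append(exons)
        gene = GeneModel(f"g{gi + 1}", tuple(tx_list))
        genes.append(gene)

        from . import _intervals

        inframe_atgs = [
            o for o in range(3, len(cds_seq) - 2, 3) if cds_seq[o : o + 3] == "ATG"
        ]
        manifest["genes"].append(
            {
                "gene_id": gene.gene_id,
                "contig": contig,
                "strand": strand,
                "isoforms": {
                    t.id: [list(iv) for iv in t.exons] for t in tx_list
                },
                "intersection": [list(iv) for iv in _intervals.intersect_all(exon_sets)],
                "union": [list(iv) for iv in _intervals.union_all(exon_sets)],
                "cds": [list(iv) for iv in cds_intervals],
                "cds_seq": cds_seq,
                "inframe_atg_offsets": inframe_atgs,
                "tss": tx_list[0].tss,
            }
        )
    new_genome = GenomeIndex({**genome.contigs, contig: "".join(chars)})
    return new_genome, genes, manifest


@dataclass(frozen=True)
class Fixture:
    genome: GenomeIndex
    genes: tuple[GeneModel, ...]
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit FASTA + GFF3 + JSON manifest; deterministic bytes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .sequence_io import write_fasta

        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "annotation.gff3",
            "manifest": out / "manifest.json",
        }
        write_fasta(self.genome.contigs, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Genome + annotation + combined manifest in one call."""
    genome, genome_manifest = make_genome(spec)
    genome, genes, anno_manifest = make_annotation(genome, spec)
    manifest = {**genome_manifest, **anno_manifest}
    return Fixture(genome=genome, genes=tuple(genes), manifest=manifest)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Minimal deterministic GFF3 writer (gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            g_start = min(t.exons[0][0] for t in gene.transcripts)
            g_end = max(t.exons[-1][1] for t in gene.transcripts)
            fh.write(
                f"{gene.contig}\tcasdesign\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for t in gene.transcripts:
                fh.write(
                    f"{t.contig}\tcasdesign\tmRNA\t{t.exons[0][0] + 1}\t"
                    f"{t.exons[-1][1]}\t.\t{t.strand}\t.\t"
                    f"ID={t.id};Parent={t.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.contig}\tcasdesign\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\tParent={t.id}\n"
                    )
                for s, e in t.cds or ():
                    fh.write(
                        f"{t.contig}\tcasdesign\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t0\tParent={t.id}\n"
                    )
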