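# Methods

This note defines every algorithm and convention in `casdesign` precisely
enough to reimplement it. All coordinates are 0-based, half-open, on the
forward strand of the named contig or transcript; GFF3 input (1-based,
closed) is converted at the parsing boundary and BED output is emitted
0-based half-open. Sequences are uppercased, `U` is converted to `T`, and
characters outside `ACGTN` are rejected with the offending position.

## Effector model and candidate enumeration

An effector is a `PatternSpec`: spacer length, an IUPAC motif (PAM for DNA
effectors, protospacer-flanking site for RNA effectors), the side of the
target the motif sits on (`5prime`/`3prime`), the target class
(`DNA`/`RNA`), and a cut offset. Shipped definitions:

| effector | spacer | motif | side | class | cut offset |
|----------|--------|-------|------|-------|------------|
| cas9     | 20     | NGG   | 3'   | DNA   | 3          |
| cas12a   | 23     | TTTV  | 5'   | DNA   | 18         |
| casx     | 20     | TTCN  | 5'   | DNA   | 18         |
| cas13a   | 28     | H     | 3'   | RNA   | —          |

Enumeration slides over the sequence and reports every window of
`spacer_len` whose adjacent motif window matches the IUPAC pattern. An `N`
in the genome matches no motif letter (an undefined base cannot satisfy a
requirement), and target windows containing `N` are skipped. DNA effectors
are enumerated on both strands; minus-strand sites are reported at their
forward-strand coordinates (`start = n - (rc_start + L)`). RNA effectors
are enumerated on the sense strand of the spliced transcript only, and the
spacer is the reverse complement of the target site. The motif is never
part of the spacer.

The cut site is a between-base index on the forward strand. For 3'-motif
DNA effectors the blunt cut is `cut_offset` (3) nt motif-proximal:
`start + L - 3` on `+`, `start + 3` on `-`. For 5'-motif effectors the
staggered cut is collapsed to a single index `cut_offset` (18) nt
downstream of the motif-proximal protospacer boundary. RNA effectors have
no DNA cut.

## Prefilters

- **GC content**: percentage computed in exact rational arithmetic;
  guides outside the inclusive band [10 %, 90 %] are rejected
  (`gc_low` / `gc_high`).
- **Self-complementarity**: a stem is a run of Watson–Crick pairs (DNA
  complement, no wobble) between one spacer substring and the reverse
  complement of a later, non-overlapping spacer substring, or of any
  backbone/scaffold substring. Stems are counted along anti-diagonals of
  the complementarity matrix; a stem is maximal if it cannot be extended by
  stacking one more pair on either end (register-shifted duplexes are
  separate stems). Any maximal stem of ≥ 4 bp rejects the guide
  (`self_complementarity`).

## Off-target search

An off-target is a motif-valid site whose target window differs from the
guide's target sequence at ≤ `max_mm` positions (default 3); indels are not
modelled, and `N` counts as a mismatch. DNA effectors search both strands
of every contig; RNA effectors search the sense strand of every transcript
in the supplied transcriptome. Two implementations are contract-equal and
cross-checked: a vectorised brute-force scan of every window, and a
pigeonhole seed-and-extend search (the target is split into `max_mm + 1`
chunks; any hit with ≤ `max_mm` mismatches contains one exact chunk, whose
first k bases are looked up in a flat k-mer table, k = 5). The persisted
index carries a SHA-256 digest of the indexed sequences and refuses to load
against different ones.

Hits are binned MM0–MM3. The on-target locus — identified by coordinate
(space, contig, start, strand), not by sequence — is excluded from MM0;
identical copies elsewhere still count. Negative-control spacers are drawn
uniformly at random (seeded) and accepted only if a brute-force search at
`min_mm - 1` mismatches returns nothing.

## Accessibility (RNA targets)

Secondary structure is computed by a fully specified reference partition
function: nested structures only; allowed pairs AU, UA, GC, CG, GU, UG;
minimum hairpin loop 3 nt; energy −1 per pair at kT = 1, i.e. Boltzmann
weight e per pair. Inside recursion:

    Z[i, j]  = Z[i, j-1] + Σ_k Z[i, k] · Zb[k, j-1]
    Zb[k, j] = e · Z[k+1, j]        if (k, j) can pair

with `Z[i, j]` the ensemble weight of the half-open slice `seq[i:j]`. An
outside recursion yields `Zout[p, q]` (weight of everything outside pair
(p, q)), and `P[p, q] = Zb[p, q] · Zout[p, q] / Z[0, n]`. The per-position
unpaired probability is `u_i = 1 − Σ_j P[i, j]`. The whole computation is
O(n³) and is verified against exhaustive structure enumeration.

Transcripts are folded in 70-nt windows sliding by 1; positions covered by
several windows take the arithmetic mean of their unpaired probabilities.
A guide's accessibility is the mean unpaired probability over its target
positions (`mean_structure = 1 − mean_unpaired`). Any engine implementing
`pair_probabilities(seq) -> matrix` (e.g. a thermodynamic package) can be
substituted for the reference engine.

## Efficiency scoring and frameshift surrogate

Efficiency models are pluggable through a registry; the shipped default is
a uniform scorer (constant 0.5) that satisfies the contract without
pretending to be a trained model. The scorer receives a 5'→3' context
window (4 nt upstream + protospacer + motif + 3 nt downstream); when the
window is truncated by a sequence edge the score is `None` ("not
available"), never silently 0.

Frameshift probability after a double-strand break uses a microhomology
surrogate. Within ±30 nt of the cut, all maximal pairs of identical
substrings of length k ≥ 2 with one copy ending at or before the cut and
the other starting at or after it are enumerated ("maximal" = not
extendable one step left or right under the same straddle constraint).
A pair whose copies start D nt apart templates a deletion of length D with
weight `k · exp(−D / 20)`. The frameshift fraction is the weight share of
patterns with `D mod 3 ≠ 0`; with no pattern at all a uniform prior over
deletion length mod 3 gives 2/3 (flagged `fallback_used`).

## Isoform handling

Exonic coverage is resolved by interval algebra: the **intersection**
(regions present in every isoform) and **union** (any isoform). A guide is
*constitutive* if its genomic footprint — for spliced RNA guides, the set
of genomic positions it covers, as intervals — lies entirely inside the
intersection. Knockdown in intersection mode rejects non-constitutive
guides (`not_in_every_isoform`); guides with identical genomic footprints
across isoforms are reported once.

## Design modes

All modes share one backbone — enumerate, prefilter, summarise off-targets,
score, rank — and differ in candidate origin and ranking key. Ranking is a
deterministic lexicographic sort with 5'-most position as the final
tie-break, so output order is invariant under input permutation.

- **knockout**: candidates inside the resolved exonic intervals of the
  gene; guides not overlapping any isoform's CDS are rejected
  (`non_coding`) unless disabled. Key: (MM0, MM1, −efficiency,
  −frameshift, position).
- **knockdown**: RNA effector on each spliced isoform, accessibility
  attached. Key: (MM0, −mean unpaired, MM1, position).
- **knock-in**: knockout guides plus homology arms abutting each cut,
  clamped to ≤ 2000 nt per side and to the contig.
- **activate / repress**: candidates in a strand-aware promoter window
  anchored at the 5'-most TSS: activation [−400, −50), repression
  [−50, +300) relative to the TSS (for `−` genes the window is mirrored).
  Windows falling off the contig are clipped with a warning; an empty
  window is an error.
- **nanopore enrichment**: for a region of ≤ 40 kb, guide pairs whose cuts
  fall strictly outside the region within 1000-nt flanks.
  Self-complementary guides are removed unconditionally and guides with
  efficiency < 0.3 are dropped. Pairs are ranked by their worse member,
  then smaller span overhang, then cut positions. Longer regions are
  refused with a notice.
- Reinitiation risk after knockout is reported as the CDS-relative offsets
  of in-frame ATGs 3' of the guide position.

## Synthetic fixtures

All tests and examples run on seeded synthetic data: random genomes with
target sites planted at recorded positions with exact mismatch counts, and
multi-isoform gene models (two shared exons, a cassette exon in the second
isoform, a CDS with exactly one planted in-frame downstream ATG). The
manifest emitted with each fixture is the ground truth the integration
tests compare against; identical spec (including seed) produces
byte-identical FASTA/GFF3/JSON.

## Output contract

Each run writes `results.tsv` (frozen, versioned column order; `NA` for
unavailable values; booleans as `yes`/`no`), `results.bed` (BED6, score = 1000 · 1/rank, so rank 1 maps
to 1000), optional `pairs.tsv` and
`homology_arms.fa`, and `summary.json` (version, full configuration and
its SHA-256 digest, counts, rejection reasons, notices). Exit codes:
0 success, 1 data error, 2 usage error.
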