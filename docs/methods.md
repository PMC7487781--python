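# Methods

## Locus model and coordinates

All coordinates are 0-based.  The Cas9 blunt cut is an *inter-base* index
`cut_index`: the cut lies between reference bases `cut_index − 1` and
`cut_index`, 3 nt 5′ of the PAM on the protospacer strand.  `locate_guide`
scans both strands for the unique placement of the 20-nt protospacer
immediately followed by a PAM (IUPAC pattern, default `NGG`) and fails loudly
on zero or multiple placements — amplicon references are short enough that
ambiguity indicates a mis-specified guide.

The indel-attribution window of half-width `w` (default 3 bp) is the base set
`{cut−w, …, cut+w−1}` for deletions and the inter-base anchor set
`{cut−w, …, cut+w}` for insertions.  Independently of `w`, an indel that
touches the cut itself (a deletion removing base `cut−1` or `cut`, or an
insertion anchored exactly at `cut`) always counts as overlapping the cut
site; for `w ≥ 1` the window subsumes this clause, and it keeps the
degenerate `w = 0` window meaningful.  Window membership is monotone in `w`.

Donors are substitution-only in this version: the donor is placed on the
reference by the same global aligner with free end gaps, any internal gap is
rejected, and each mismatch column becomes an edit position.  Exactly one
edit is primary — by default the edit nearest the cut (distance from base
`p` to the inter-base cut is `|p + 0.5 − cut|`; ties to the left), because
the intended biological edit normally sits closest to the cut while
PAM-blocking silent edits sit in or past the PAM.  An explicit coordinate
overrides this.  Donors with programmed indels are out of scope.

## Read preparation

Adapter trimming removes the longest read 3′ suffix matching a prefix of the
expected read-through sequence with mismatch fraction ≤ 0.1 and length ≥ 3.
The packaged defaults are ~120-nt TruSeq-style read-through strings (adapter,
index, post-adapter tail) shared with the simulator.  Merging reverse-
complements mate 2 and chooses, over all overlap lengths ≥ 10 with mismatch
fraction ≤ 0.1, the one maximising matched bases (ties prefer the longer
overlap).  At discordant overlap columns the base with higher Phred quality
wins, its quality is kept, and quality ties go to read 1; at concordant
columns the higher quality is kept.  Unmergeable pairs are counted and
excluded from all rate denominators — they are not analysed single-ended.

## Alignment

`global_align` is a three-state Gotoh dynamic program (match/substitution,
gap-in-read, gap-in-reference).  Defaults follow EMBOSS `needle` for DNA:
match +5, mismatch −4, gap open 10, gap extend 0.5, with a gap of length *L*
charged `open + extend·L` and end gaps penalised (the merged read spans the
amplicon, so a true global alignment is appropriate); free end gaps are
available as an option and are used for donor placement and donor-score
diagnostics.  Rows are vectorised in numpy; the within-row (horizontal) gap
state uses the running-maximum identity
`Iy[i][j] = max_{k<j}( max(M, Ix)[i][k] + e·k ) − o − e·j`.
Traceback tie-breaking is fixed — prefer match/substitution, then deletion,
then insertion — which makes outputs bit-reproducible and places indels at
their leftmost equivalent position.  All default scores are dyadic, so float
arithmetic in the DP is exact.  A deliberately naive exhaustive-recursion
scorer is included as a reference implementation for validating the DP on
short sequences; tests additionally cross-check scores against Biopython's
`PairwiseAligner`.

Event extraction walks the alignment columns, coalescing adjacent gap
columns into single insertion/deletion events with reference coordinates
(insertions get the inter-base anchor between their flanking reference
columns) and reporting substitutions as `(ref_coord, read_base)` pairs.

## Classification

Per merged read, against the reference alignment only (window coordinates
are reference-frame quantities; the read-versus-donor score is recorded
purely as a diagnostic):

1. **DISCARD** if gap-excluded identity < `min_identity` (default 0.60) or
   the read's aligned reference span does not cover the donor footprint.
   Note that under affine scoring even unrelated sequences reach ~0.75
   gap-excluded identity (gaps absorb mismatch runs), so the identity gate
   only rejects grossly corrupt reads; the footprint-span check is what
   removes truncated molecules.
2. **NHEJ** if any indel event hits the cut window (rule above).  This is
   unconditional: reads that both convert the edit site and carry a window
   indel are counted once, as NHEJ, with `primary_converted` flagged so the
   overlap class can be re-tabulated if desired.
3. **HDR** if the read base at the primary edit position equals the donor
   base.  Auxiliary-edit conversion is counted but not required.
4. **UNMODIFIED** otherwise.  Substitutions never count toward NHEJ, which
   makes calls robust to per-base sequencing error.

Rates are fractions of `n_total = n_HDR + n_NHEJ + n_UNMODIFIED`; discarded
and unmerged reads are excluded from the denominator.  The HDR/NHEJ ratio is
flagged undefined when a sample has zero NHEJ reads and such samples are
excluded (with a reported count) from group means rather than imputed.
Identical read sequences are classified once and the call reused, so results
are independent of read order.

## Group statistics

Groups are summarised as mean ± sample SD (n−1; flagged undefined for
n = 1).  Comparisons use the unpaired two-tailed Student *t* test with
pooled variance — the classic default of the point-and-click statistics
packages this replaces — with Welch available as an option; fold change is
the ratio of group means, undefined-flagged for a non-positive denominator.
Significance tiers are reported at 0.05 / 0.01 / 0.001.  No multiple-testing
correction is applied (comparisons are reported per pair); outputs carry
both fraction and percentage scales, since *t* and *p* are scale-invariant.

## Single-cell QC and cell-cycle calling

QC keeps cells with **more than** 200 detected genes and **less than** 6%
of counts on genes matching the mitochondrial name pattern (default prefix
`MT-`); both inequalities are strict, and a per-cell report records the
failure reasons.

Counts are library-size normalised to 10,000 per cell and log1p-transformed.
Each cell receives two module scores — 43 G1/S genes and 55 G2/M genes by
default — computed as the mean normalised expression over the markers minus
the mean over an expression-matched control set: genes are ranked by
population mean expression into `n_bins = 24` equal-occupancy bins and, for
every bin containing a marker, up to `n_ctrl = 100` non-marker genes are
sampled without replacement (seeded; pools are name-sorted, and ranking ties
break on gene name, so scores are invariant to gene order).  If the total
non-marker pool is smaller than `n_ctrl` the scoring errors out; a per-bin
shortfall falls back to the whole bin.  Fewer than 5 matched markers is an
error; missing markers are otherwise scored over the intersection.  An
all-zero cell scores exactly 0 on both modules.

A cell is **G0** when both scores are ≤ 0 (it expresses neither program),
otherwise **G2M** when the G2/M score strictly exceeds the G1/S score, else
**G1S** (ties above threshold go to G1S).  Phase fractions are reported per
condition with counts and sum to 1.

The shipped marker lists are a reconstruction of the standard human G1/S and
G2/M module symbols at the published sizes (43 + 55); the exact lists used in
any given study are rarely printed, so both are user-overridable, and exact
reproduction of someone else's calls requires their lists.

## Simulators

**Amplicon reads.**  Defaults mirror the assay being emulated: 300 bp
paired-end reads, 10,000 pairs per sample, per-base substitution error
1×10⁻³, over a 240-bp synthetic amplicon.  Category counts are drawn once
from a multinomial (default mixture 25% HDR / 40% NHEJ / 35% unmodified —
the depth-and-mixture condition used throughout the tests); each molecule is
the reference, the reference with donor conversions (auxiliary edits
co-convert with probability 1 by default), or the reference with one indel.
Indel sizes are geometric (p = 0.3) truncated at 25 bp with a 2:1
deletion:insertion ratio — a plausible Cas9 spectrum; none of the outcome
statistics depend on these specifics, only on the recorded truth labels.
Indels are anchored uniformly over the cut window (strict-inside mode) with
an optional strictly-outside contaminant class placed at a ≥ 10 bp safety
margin.  Two conventions make truth labels exact rather than approximate:
indel coordinates are recorded *left-normalised* (the aligner's own leftmost
placement), with placements re-sampled if normalisation would move them out
of (or into) the window against the requested mode; and the toy locus is
redrawn from its seed until the ±35 bp around the cut contains no
homopolymer run ≥ 4, so optimal alignments cannot relocate a simulated
indel.  Reads longer than the fragment run through into the fixed TruSeq-
like read-through sequence, exercising adapter trimming; qualities come from
a two-state (Q37/Q12) model, sufficient to exercise quality-weighted
merging.  Identical seeds give byte-identical FASTQ output (fixed gzip
mtime).

What the simulator does **not** model: PCR chimeras and jackpot duplicates,
indel-type sequencing errors, quality-correlated errors, position-dependent
error profiles, large structural variants, or donor integration artefacts.
Passing the closed-loop tests therefore demonstrates correctness of the
trimming/merging/alignment/rule machinery under the stated error model, not
robustness to every real-world artefact.

**Single-cell counts.**  Cells are gamma-Poisson (negative-binomial-like,
dispersion 0.3) draws over ~3,000 genes with log-normal library sizes
(median 5,000 counts) and a fixed mitochondrial fraction (3%; a high-mito
class at 15% and a low-depth class exist for QC testing).  Cell-cycle marker
genes sit at 0.2× a typical gene's baseline — quiescent cells are defined by
lacking both marker programs, and cycle genes are largely silent outside the
cycle — and each cycling phase multiplies its module by the configured fold
change (default 10).  The generator does not model doublets, ambient RNA,
batch effects, or the continuous gradation of real cell-cycle states, so
phase-call accuracies near 100% on it are an upper bound, not an estimate
for real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at the assay's stated depth where the
quantity depends on it (10,000 pairs for rate recovery) and at 1,500–4,000
pairs for properties that do not (monotonicity sweeps, determinism,
replicate-level ratio comparisons at 3 replicates per condition), with
recovery tolerances computed from binomial/delta-method sampling variances
of the configured truth rather than fixed percentages.  Alignment scores are
compared exactly (dyadic arithmetic); statistical closed forms to 1×10⁻⁶.
Degenerate inputs fail loudly and early: empty sequences, zero classifiable
reads, empty groups, all-undefined ratios, absent markers, and no-cells-pass
QC all raise with specific messages rather than propagating NaNs.
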