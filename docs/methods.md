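# Methods

This note documents the models, rules and numerical choices behind
`mitoedit`, and what the synthetic-data tests do and do not establish.

## Coordinate frame and reference model

All sites live in 1-based nucleotide coordinates within the CDS of a
sense-strand ORF; codon index `ceil(p/3)` and codon position
`((p−1) mod 3) + 1`. Inputs are DNA-alphabet FASTA; `U` appears only in
rendered output (edited-codon tallies). Reference FASTA entries may
carry symmetric flanks of `flank_len` nucleotides (default 100), added
upstream to stabilise read coverage at CDS ends; the loader trims them
and the caller discards any count rows at flank coordinates. Reverse
strands are not handled: CDS extraction is assumed done upstream, so a
C-to-U edit is always a reference C. Pseudogenes are annotated in their
nominal reading frame and flagged. Trailing partial codons (CDS length
not a multiple of 3) are tolerated at load time, but any codon
operation touching one raises instead of guessing.

## Detection rules

**RNA-seq channel.** At a C reference position the editing level is
`T/(A+C+G+T)` over the merged samples (counts are summed per position,
equivalent to merging alignments, so the pooled level is
depth-weighted). A candidate requires level ≥ `threshold` (default
0.10, inclusive) and depth ≥ `min_depth` (default 1 — organellar
coverage varies over two orders of magnitude and no depth cutoff is
imposed by default). The threshold is inclusive on both channels; the
two natural phrasings ("above 10%" vs "at least 10%") differ only on
the boundary and a single inclusive rule is used, exposed in
configuration.

**Sanger channel.** The per-replicate level is `T/(C+T)` from peak
heights; a site is called when ≥ `min_pass_replicates` (default 2) of
the replicates (default 3) reach the threshold. The reported level is
the mean over replicates with data; using a single representative
replicate instead would change reported levels by at most the
inter-replicate spread and is not offered.

**Reconciliation.** Sanger evidence is primary. A Sanger-called site is
accepted when its RNA-seq level is ≥ `threshold − rnaseq_tolerance`
(default tolerance 0.02, admitting sites whose RNA-seq estimate lands
around 9%) or when RNA-seq gives no coverage at the position. This
tolerance formalises an outcome-level practice (borderline
cross-method sites are retained when the discrepancy is small) as an
explicit, configurable rule; the tolerance applied is recorded in the
run log and echoed configuration. RNA-seq-only candidates are emitted
with status `rejected_rnaseq_only` (set `require_sanger: false` to
accept them). Sanger-called sites with deeply discordant RNA-seq
levels become `rejected_below_threshold`.

**Categories.** L [10–30%), M [30–60%), H [60–90%), EH [90–100%].
Bin edges are half-open on the left; verbal range descriptions
("60–90%") leave the boundaries ambiguous, so one convention is fixed
and exposed (`category_bounds`). The category of an accepted site comes
from its Sanger level when present, else its RNA-seq level. A site can
be accepted with a level marginally below the lowest edge (a passing
2-of-3 vote whose mean is dragged down by one weak replicate, or the
reconciliation tolerance); such sites are classed L rather than
erroring, since acceptance already vouches for them.

## Consequence annotation

Edits sharing a codon are applied simultaneously; one consequence
record per edited codon. Effects: `start_gain` for ACG→ATG (reported at
any codon index — organellar editing can create initiation codons away
from the annotated start, so no positional restriction is imposed),
`stop_gain` when the edited codon is a terminator, otherwise
synonymous/nonsynonymous by the standard genetic code (plant
mitochondria use it). Start/stop gains take precedence in the single
`effect` field; a separate `is_nonsynonymous` flag records whether the
amino acid changed, so syn/nonsyn tallies over codons count stop gains
as nonsynonymous (and the stop-gain rows are flagged rather than
silently folded in). Hydropathy transitions use the positive
Kyte–Doolittle set {A, C, F, I, L, M, V} as "hydrophobic"; the set is
an argument (`hydrophobic_aa` in the run configuration) because
published classifications vary, and the choice is consistent with
treating Ser→Leu, Pro→Leu and Ser→Phe as hydrophilic→hydrophobic.

## Summary statistics

Percentages are stored unrounded and displayed with half-up rounding to
two decimals. Per-gene edited-C percentage = 100 × distinct edited C
positions / C count of the CDS (genes with zero Cs report n/a).
Pearson correlations (edited Cs vs total Cs, edited Cs vs CDS length)
are computed by the product-moment formula with a two-sided p from
`t = r·√(n−2)/√(1−r²)` on n−2 degrees of freedom, over the genes that
carry at least one accepted site — the natural per-gene sample for an
editing survey; genes without sites would add structural zeros. The
implementation is cross-checked against `scipy.stats.pearsonr` in the
test suite. The alignment-column report maps an ungapped reference
position to its alignment column by counting non-gap characters and
reports the identity fraction over non-gap residues (gapped rows leave
the denominator).

## Synthetic data

The generator emulates an organellar ORF editing study end to end:

* **Panels**: `n_orfs` (default 10) random ORFs of 300–1500 nt at 44%
  GC (typical organellar coding GC), ATG start, stop-free interior
  (also after applying every planted edit, so consequence annotation is
  well defined), TAA terminator, plus 100 nt random flanks. The
  interior base composition is solved by bisection so that realized GC
  matches the target despite stop-codon exclusion (which would
  otherwise enrich GC by ~1.4 points).
* **Sites**: by default each C position independently carries a "real"
  site with probability `site_rate` = 0.05, giving the strong per-gene
  count variability real catalogues show (an exact `sites_per_orf` is
  available for controlled experiments). Real levels are uniform on
  [0.10, 1.0]. Three decoy classes exercise every reconciliation
  branch: sub-threshold sites ([0.01, 0.09], both channels),
  RNA-seq-visible/Sanger-absent sites, and borderline sites
  (Sanger ~[0.11, 0.15] with RNA-seq ~[0.085, 0.095]).
* **RNA-seq counts**: per-position depth is gamma-Poisson around
  `mean_coverage` (default 500, split over 2 samples; real coverage
  spans ~74–9500), and base counts are multinomial: a fraction `level`
  of molecules carry T, every molecule is misread with probability
  `sequencing_error_rate` (default 0.002) uniformly into the three
  other bases. Flank positions are emitted at coordinates ≤ 0 and
  > length so trimming is exercised.
* **Sanger peaks**: ideal heights `100·(1−level)` / `100·level` per
  replicate, each scaled by `max(0, 1 + N(0, 0.05))`; channel-invisible
  sites emit level 0.

Counts are generated directly rather than via simulated reads plus
alignment: read mapping is external tooling and the caller's contract
is the count table, so the test surface stays on the computation this
package owns. All outputs are byte-reproducible under a fixed seed
(independent substreams per generator stage).

What passing synthetic tests do **not** show about real data: alignment
artifacts (duplicates, soft clips, mapping bias near paralogs/NUMTs),
strand- or context-dependent error profiles, correlated replicate
noise, tissue-specific editing, and the real clustering of edits at
codon positions 1–2 (the simulator plants sites uniformly over Cs).
Recall/false-positive results transfer only to the extent that the
binomial error model approximates post-filtering read errors.

## Problem sizes and numerical choices

The default test suite runs panels of 3–10 ORFs at coverage 200–500;
the parameter-recovery study uses 10 seeds × 500 sites at depth 500 and
error 0.002, levels 0.12–0.95, chosen so the per-site binomial miss
probability at the 10% threshold is negligible except in the lowest
sliver of the level range. Oracle-equivalence tests on noise-free runs
compare against an expected set recomputed independently from the raw
count and truth tables; sites planted adjacent to the acceptance
boundary (the borderline class) are resolved by the observed binomial
draw, so the oracle uses observed T fractions rather than planted
parameters. Degenerate inputs are defined errors, not guesses: zero
total peak height, zero variance in a correlation, positions in
trailing partial codons, non-C "editing" sites, conflicting reference
bases across samples.

## Known limitations

* Only C-to-U events on the sense strand are modelled; U-to-C, indels,
  and edits in introns/UTRs/tRNA/rRNA are out of scope.
* No quality-score-aware counting or strand-bias filtering; the count
  table is trusted as delivered.
* The annotation linter searches only ±1 nt and the claimed codon's
  other C positions; grossly misplaced claims are reported as
  unexplainable rather than relocated.
* GFF3 export models each site as a zero-length-span feature on the ORF
  sequence, not on genome coordinates.
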