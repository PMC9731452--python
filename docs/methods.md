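# Methods

## The construct model and coordinates

All read processing shares one coordinate system: 0-based positions on the
mRNA-sense construct, promoter → randomized cassette → constant downstream
5′ UTR. The first cassette base is the transcript's +1 nucleotide
(`expected_tss_index = len(promoter_seq)`); human-readable output adds 1 to
recover the +1/+2/+3 convention. The internal alphabet is DNA; U is accepted
on input and stored as T, because all sequencing inputs are DNA-space. The
cassette is represented by an N-run in template FASTA files and is treated
as per-molecule unknown everywhere. The default construct uses the standard
promoter tail `…GAACCGTC`, a 7-nt cassette, a downstream region beginning
`GCCGCAGCCGCCGCC` (containing the anchoring seed `AGCCGCCGCC`), and the
printed spike-in mRNA whose 5′ end mimics a TOP-like `CTCTTCC` library
transcript but carries a private `CATG` insert, so spike-in removal must be
(and is) sequence-specific beyond 7 nt.

## Read classification

Reverse transcriptases often append a non-templated cytidine opposite the
cap, which appears as an extra 5′ G. Classification therefore reasons about
*origins*: pairs (start coordinate, number of leading artifact Gs). After
anchoring a read by the first exact seed occurrence within the first 60 nt
(the seed lies in a constant region; a mismatch-tolerant scan exists but
defaults to exact), the alignment of the non-artifact portion is fixed, and
each candidate artifact count g in 0..cap (cap = 2 by default, matching the
two splint-adapter variants used in the protocol; configurable) is checked
for consistency: leftover run Gs must sit on cassette positions or templated
Gs, and all other bases must match the template at known positions.

- exactly one consistent (start, 7-mer) interpretation → a definitive call:
  `cassette_start` (start = +1, non-G first base; the next 7 nt are the
  7-mer), `upstream_start`, or `downstream_start`;
- two or more interpretations differing in start or 7-mer →
  `ambiguous_plus1G`. This covers the classic case (5′-GAACCTT… is either a
  +1 `GAACCTT` molecule or a +2 `AACCTT…` molecule plus an artifact G) and
  every other unresolvable leading-G geometry, including a leading G over a
  templated promoter G adjacent to an alternative placement;
- a unique interpretation whose first base is a G inside the cassette is
  also excluded as `ambiguous_plus1G`: +1 G counts are unreliable as a
  class, so they never enter a count table;
- reads without the seed, or inconsistent with every origin, are `no_seed`;
  seed-anchored reads too short to span the cassette are tallied
  `truncated`; spike-ins are matched first (15-nt 5′ prefix, artifact Gs
  allowed) and removed.

Equivalence with a brute-force enumerator that tries every (start, g) origin
by direct string comparison — no seed logic, no stripping — is asserted
exhaustively in the test suite (all 16,384 7-mers × offsets −3..+3 × 0–2
artifact Gs; zero disagreements).

One deliberate, documented artifact of seed anchoring: a molecule whose
cassette is exactly `AGCCGCC` creates a spurious earlier seed occurrence
(cassette + the downstream `GCC…`), and such reads are dropped as `no_seed`
— the same behavior a first-occurrence seed search has on real data. This
costs one 7-mer out of 16,384; it is excluded by the detection filter rather
than mis-counted.

G-variants sharing a base sequence collapse into one count
(`collapse_calls`), category tallies preserve read conservation exactly, and
the start-position distribution is computed over definitive calls only.
Because in-cassette starts with a 5′ G are necessarily ambiguous, the
recovered distribution estimates the *retention-conditioned* multinomial,
not the raw start probabilities; recovery tests compare against that
conditional expectation in closed form.

## Expression, regulation, motif and CAGE statistics

*Expression.* Per sample, counts become reads-per-million of assigned reads;
normalized expression is mean reporter RPM over replicates divided by
plasmid RPM. The plasmid division is also the composition-bias correction:
the cassette synthesis has a mild T/G excess, which propagates into the
mRNA pool and cancels in the ratio; no additional positional correction is
applied. Detection requires count > threshold (default 50; plasmid rule 20)
in every replicate, restricted to +1 A/C/T. The fold range defaults to
max/min over detected entries ("spanned"); quantile knobs give robust
variants. Replicates aggregate by arithmetic mean (geometric mean
available). The top-expressed fraction for logo matrices defaults to 5%
(the alternative 10% convention is a parameter).

*Regulation.* The log2 estimator is a pseudocount ratio of normalized
abundances: l2fc = log₂((a+α)/(b+α)) per replicate pair, α = 0.5 RPM,
averaged over replicates. This replaces shrinkage-based differential
testing deliberately — it is self-contained and fully specified; externally
computed fold changes can be read in and compared by rank agreement only.
P/SP ratios use spike-in scaling by default (equal spike-in mass is added to
each fraction, making fractions comparable despite different RNA content;
RPM mode exists because protocols differ). Decay ratios *must* use spike-in
scaling: the spike-in does not decay, so it anchors the absolute
ActD+/ActD− scale that within-sample RPM would cancel. Stratum contrasts
(e.g. AG vs CU starts) use two-sided Welch tests without multiplicity
correction, matching figure-level planned contrasts; a Benjamini–Hochberg
helper exists for exploratory scans. The regulation table contains only
7-mers passing detection in all contributing samples.

*Motifs.* Patterns are +1-anchored IUPAC strings in DNA space. Class value
tests compare members against the all-sequence background (the dashed-line
convention). Y-run groups are disjoint — run length k means k leading
pyrimidines then a purine (k = 7 unterminated), with +1 C required for
k ≥ 1 (TOP semantics) and the k = 0 purine-start group as comparator; a
nested variant is a flag. Substitution scans force one pattern position to
one nucleotide and subtract the unmodified-background mean, so the identity
substitution is exactly 0 and empty cells are NaN. The hybrid ranking uses
Pareto dominance plus a rank product rather than an arbitrary weighted sum,
because joint optimality does not define a scalar score.

*CAGE.* Input is tag-level (chrom, 0-based 5′ position, strand, count) —
CTSS text or single-base BED6 — keeping the analysis alignment-agnostic; an
optional BAM collapser takes the aligned 5′ end (soft clips, e.g. removed
non-templated Gs, never shift the tag). "A 1 kb window surrounding the TSS"
is implemented symmetrically and half-open: |pos − tss| < window/2. A tag in
several windows counts once globally and per gene locally. k-mers at tag 5′
ends are read in transcript orientation (reverse-complemented on −), +1 G
tags are excluded by default (exclusion provably preserves ratios among
retained k-mers), and frequencies are count-weighted (position-collapsed is
a flag). The library-vs-endogenous comparison is computed on log10 values
floored at the smallest positive observation, over the 48 +1 A/C/T 3-mers.

## The synthetic study

The generator emulates the study design; every number below is a design
choice fixed before the recovery tests were run, and all randomness flows
from one seed through per-purpose child seeds (CRC-derived, process
independent).

- **Start positions**: 48% at the expected +1; the remainder spread over
  −3..+3 (4/7/12/—/14/9/6%). **Artifact Gs**: 0/1/2 with probabilities
  0.30/0.60/0.10 — the true per-read artifact distribution is not published,
  so these are explicit, configurable assumptions consistent with a protocol
  that provisions a dedicated G-adapter at a 4:1 ratio. Artifact count is
  capped at 2 (the dominant behavior; configurable).
- **Plasmid bias**: per-nucleotide weights A/C 0.23, T/G 0.27. mRNA
  abundance is plasmid copy number × per-copy transcription rate, so the
  bias propagates into reads and is removed by the plasmid division — the
  pipeline's correction is thereby actually exercised.
- **Transcription truth** (bimodal, >200-fold): log₁₀ rate = 1.3 for +1 A,
  −1.0 for +1 T, 0 for +1 G; +1 C uniform on (−1.0, 0.8) plus 0.4 for a
  +2 T; plus N(0, 0.25) everywhere.
- **Translation truth**: control log₂(P/SP) = +0.5 (+1 A), −0.3 (+1 T),
  0 otherwise, plus N(0, 0.45). Torin subtracts 4·strength where
  strength = [+1 C]·(min(Y-run, 5)/5)·(0.3 + 0.7·[+3 ∈ C/T]) — chosen so
  repression grows with the pyrimidine run, saturates at 5 nt, and depends
  more on +3 than +2. A pure run-length rule cannot reproduce the +3 > +2
  asymmetry, and a pure position-weight rule cannot keep the Y-run profile
  monotone; the product form yields both.
- **Decay truth**: basal half-life 2^(2 + N(0, 0.35)) h — a deliberately
  narrow (~2-fold) basal spread; Torin multiplies half-life by
  (1 + 2·strength) (TOP stabilization) and by 0.7 for +1 A
  (destabilization).
- **Depths**: 5×10⁶ reporter reads split over 2 replicates; 3×10⁷ per
  fraction/decay count sample; 2×10⁷ for the plasmid library; 2% spike-in.
  Count-table depths were set by a pre-run power analysis: at 3×10⁷ the
  per-7-mer log2-ratio sampling error (~0.05–0.08) is small against the
  designed biological spreads, so recovery correlations are dominated by
  truth, not noise. The plasmid depth reflects that plasmid DNA libraries
  are cheaply sequenced deeply, and keeps the normalization denominator
  from being the noise bottleneck.
- **CAGE toy study**: 150 genes on a 160 kb genome, alternating strands,
  spacing ≥ window; each gene's expression follows the library rate of its
  planted start 3-mer times 10^N(0, 0.4) gene noise; 90% of a gene's tags at
  the annotated TSS (sharp promoters; off-TSS tags read arbitrary genomic
  3-mers, a realistic dilution); 15% of genes are "RP"-class with TOP/TCT
  hybrid starts and a 10^N(0.7, 0.2) expression boost.

What the generator does **not** emulate: sequencing errors, PCR duplicates,
quality-score structure, replicate batch effects, dispersed/multi-modal
endogenous promoters, and any +1-G-specific biology (the pipeline excludes
+1 G by construction). Passing recovery tests therefore demonstrates the
correctness of the analysis machinery under the stated generative
assumptions, not robustness to real-data artifacts outside them.

## Problem sizes and numerical choices

The default "acceptance-scale" study (5×10⁶ reads plus deep count tables)
runs in about a minute on one CPU; module tests use smaller depths with
thresholds scaled accordingly, and statistical assertions use closed-form
standard errors (3 SE) or chi-square goodness of fit. At the default scale
the detection filter passes ~4.5k of 12,288 7-mers (the synthetic depth is
well below the original deep-sequencing scale, so low-expressed 7-mers fall
under threshold; recovery statistics are defined over the detection-passing
set, which is also how the regulation table is scoped). Probability maps
must sum to 1 within 1e-9; rates and half-lives are strictly positive;
frequency matrices renormalize rows after any correction; Pareto dominance
uses ≥/> with ties kept on the front; the Y-run comparator is "purine at +1,
any continuation" (the all-purine alternative is a flag).

## Known limitations

- +1 G regulation is invisible by design, mirroring the assay's limitation.
- The pseudocount ratio estimator is biased toward 0 for very low counts;
  the detection filter bounds this, and rank-based comparisons are used
  against external shrinkage estimates.
- Seed anchoring loses the single cassette `AGCCGCC` (see above).
- Only the two-timepoint (0/2 h) shutoff design is modeled; no multi-point
  half-life fitting.
- The CAGE module consumes pre-aligned tags; alignment itself is out of
  scope.
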