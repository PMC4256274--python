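# Methods

## The model

A gene is "interrupted" when its annotated reading frame contains a premature
stop codon. Transcriptional slippage at a homopolymeric adenosine tract lets
RNA polymerase insert (or delete) a net number k of untemplated As, producing
a heterogeneous mRNA population. Transcripts with a frame-shifting k are
translated in a downstream frame past the premature stop, so two (or more)
protein length variants coexist, and the fraction f of frame-restoring
transcripts is the frameshift frequency. `slipscan` treats four linked
sub-problems: finding candidate sites, predicting the variant catalog,
predicting/assigning amplicon mass ladders, and estimating f from
quantitative readouts.

### Coordinates and the stop-position convention

All coordinates are 1-based, inclusive, on the coding strand, counted from
the start codon. A "stop at position p" is interpreted so that a protein of
L residues has 3L coding nucleotides before its stop: p = 3L names the last
nucleotide of the final sense codon and the stop codon occupies p+1 .. p+3.
This is the only reading under which a stop "at 2,421" coexists with an
807-residue product and a 2,424-nt ORF (807 × 3 = 2,421), and it is the
convention used everywhere here. U and T are interchangeable for codon lookup
(NCBI translation table 11) and run scanning; the declared alphabet is kept
for output.

### Site calling

A *run* is a maximal stretch of identical A (or T) bases with length at least
`min_run_length` (default 8 — comfortably below the two characterised sites
of 9 and 11 As, and long enough that random sequence rarely qualifies:
the per-position chance of an 8-mer homorun is 4^-8). The *distance* between
a run and a premature stop counts nucleotides strictly between the run's last
base and the stop's first base; the one measured natural spacing is 28 nt,
and the search window default is 60 nt (double, for recall). For each
candidate k in `k_set` (default {−2, −1, +1, +2}) the k-edited transcript is
translated; k is *restoring* iff translation proceeds past the (shifted)
parent stop, i.e. 3L + 1 > p + k on the edited transcript. This single
membership test is shared by the scanner's `restoring_edits` and the variant
catalog's `full_length_restored`, so the two modules can never disagree. Note
the test is literal: a −1 edit whose new frame happens to run a few codons
past p also counts as restoring, even when the product is barely longer than
the truncated form. Sites are ordered by distance, then by run length
descending, so output is deterministic when several runs flank one stop.

Runs are scanned on the coding strand only; T-runs are reported as potential
template-strand slippage without strand inference. The family screen flags a
member as abnormal-length when its CDS is shorter than 0.8× the family median
(configurable), and requires at least 3 members for the median to mean
anything.

### Edits and the variant catalog

Insertions within a homopolymer are indistinguishable at the sequence level,
so edits are canonically placed at the run's 3′ end: +k appends k copies of
the run base after the run, −k removes them from the 3′ end (at most
run length − 1). Each edited transcript is translated from nt 1 to its first
stop. Protein masses are average masses from the Expasy residue table
(sum of residues + one water), reported in kDa to 3 decimals; display
rounding to whole kDa mirrors how blot sizes are usually quoted. Epitope tags
(N-terminal FLAG, C-terminal 6×His) are not included by default; a flag adds
their residue masses, since tagged constructs are the common experimental
reality.

### Mass ladders

PCR products are modeled as two independent neutral single strands (the two
strand series are what deconvoluted electrospray spectra show). Strand masses
are average masses computed as nucleoside-monophosphate residues minus one
water per phosphodiester bond — numerically identical to "residue masses plus
one terminal water" with residue masses of 313.21 (dA), 289.18 (dC), 329.21
(dG) and 304.19 (dT) Da. The default 5′ end is hydroxyl (unphosphorylated
primers); a 5′-phosphate adds one HPO3 (79.98 Da). Amplicon bounds are
user-specified coordinates bracketing the run (primer sequences are an
experimental detail, not an input here) and default to the full template —
e.g. the printed 56-nt window around the natural run. Peak assignment is
nearest-predicted-mass per peak, independent across peaks (hence
permutation-invariant), with a default tolerance of 0.02% beyond which a peak
is flagged rather than dropped; instrument precision varies, so the tolerance
is a parameter.

### Frequency estimators

*Western:* each variant carries a single N-terminal epitope, so band signal
is taken proportional to molecule count and no length correction is applied.
f = I_slip / (I_slip + I_other), where the slippage product is declared per
locus (the long product when slippage restores the full-length frame, the
short product when slippage truncates). The ratio reported is other:slip and
always equals (1 − f)/f.

*GFP three-construct scheme:* a negative control with the in-frame stop
(no fusion made), a +1 reporter (fusion made only upon slippage), and a 100%
reference in which the frame is restored constitutively.
f = (f_test − f_neg)/(f_max − f_neg), which is invariant under any affine
transformation of the three values. Raw plate measurements are normalized as
(fluorescence − blank fluorescence)/(OD600 − blank OD600); subtracting the
blank from both numerator and denominator before dividing is a deliberate,
tested choice where the verbal protocol is ambiguous. Estimates outside
[0, 1] (possible under reporter noise) are clamped with a flag rather than
rejected. Replicate estimates are aggregated as mean ± standard error
(sample SD, ddof 1, over √n).

## The synthetic-data generator

`design_gene` builds genes with the natural architecture: ATG + upstream
codons, a poly-A run, a spacer, a premature amber stop (TAG), and a
downstream region that is an open reading frame in the restored (+1) frame
ending in a designed terminal stop. Defaults reproduce the natural geometry:
794 upstream codons, an 11-A run, a 28-nt spacer (truncated product 807 aa,
ORF 2,424 nt) and 320 restored-frame codons past the stop (full-length
product 1,129 aa). `run_length + spacer_nt` must be a multiple of 3 so the
designed stop is in frame. With `plus1_orf_codons = 0` a restored-frame stop
is planted inside the spacer, so a +1 edit terminates before the parent stop;
a short frame-0 tail still follows the designed stop so it remains premature.
Construction is rejection sampling — sense codons drawn avoiding unintended
A/T runs, then whole-gene verification through the scanner itself (stop
placement, exactly one run, exactly one site, the intended +1 behaviour) —
with a bounded retry count; generation is deterministic given the design
seed.

`simulate_transcription` draws one net edit k per transcript from a
user-supplied distribution p(k) (default p(+1) = 0.25, remainder on k = 0,
matching the frequency scale estimated for the natural loci; default support
within −1…+4 spans the observed 10–15 A species around an 11-A run). Drawing
a single net k per transcript, rather than modeling per-step polymerase
kinetics, is a deliberate simplification: it reproduces the observed mRNA
species support and keeps the model identifiable, but says nothing about
slippage mechanism or processivity. `simulate_western` multiplies the two
dominant variant counts by lognormal noise exp(N(0, σ²)) (default σ 0.05);
`simulate_reporters` places f_neg at a background (default 50 A.U.), f_max at
background + span (default span 1,000 A.U.) and f_test at the true fraction
of the span, with additive Gaussian noise per replicate (default 10 A.U.,
3 replicates). Background and span are arbitrary units chosen for realistic
signal-to-background, not quantitative claims. The real per-k species
distribution is unknown, so simulation probabilities are inputs, never
claimed estimates.

What the generator does *not* emulate: sequencing error, transcript decay
or length-dependent transfer efficiency on blots, promoter/induction
variability, and any per-step slippage kinetics. Passing tests therefore
demonstrate the estimators' correctness and calibration under the stated
noise models, not robustness to every artefact of real gels and reporters.

## Numerical choices and degenerate inputs

- Translation ignores a trailing partial codon; a sequence whose only stop
  occupies its final full codon has no *premature* stop.
- A sequence with no stop at all returns "no stop" with a warning rather
  than an error.
- Empty proteins have mass 0 (with a warning); empty oligos are rejected.
- Tie-breaks: sites sort by (distance, −run length); peak assignment breaks
  exact mass ties by strand name for determinism.
- Estimators reject all-zero band pairs and f_max ≤ f_neg as undefined
  rather than returning NaN.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces every output byte for byte.

## Problem sizes

Tests exercise the full-size geometry (2.4–3.4 kb genes) where the printed
arithmetic matters, and compact designs (~100–200 nt upstream) for oracle
sweeps across hundreds of seeds; simulations use 10,000 transcripts, the
scale at which binomial standard errors (≤ 0.5 percentage points at
f = 0.25) are far below the tolerances being checked. The whole suite runs
in a few seconds.

## Known limitations

- The scanner targets user-supplied CDS sets; it is not a genome-wide
  screen, and it does not model translational (ribosomal) frameshifting
  signals such as Shine–Dalgarno-like elements or RNA structure.
- Restoration is judged purely by reading past the parent stop; biological
  functionality of the extended product is out of scope.
- Mass prediction covers neutral average masses of clean single strands; raw
  spectrum processing, charge-state deconvolution and isotope structure are
  assumed handled upstream.
- The western estimator's proportionality assumption (signal ∝ molecule
  count) ignores variant-specific transfer or antibody effects.
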