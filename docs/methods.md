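# Methods

This note documents the models, estimators, defaults and known
limitations behind `fracsynth`. It is written for users who want to know
what the numbers mean and what the tests do and do not establish.

## Isotope model

All isotope math runs on a fixed, versioned constants table
(`src/fracsynth/data/isotopes.tsv`: ¹³C 0.0107, ¹⁵N 0.003642, ²H
0.000115, ¹⁷O/¹⁸O, ³³S/³⁴S/³⁶S, ²⁹Si/³⁰Si) so results do not depend on
the environment. Isotopologues are indexed by nominal neutron shift
("low-resolution" pooling): at survey-scan resolving powers the ¹³C and
¹⁵N isotopologues of peptide-sized ions are not separated, so a single
axis of +1 Th/z peaks is the right abstraction. Peaks are sought at
mz₀ + i·1.00335/z (the ¹³C spacing); the ¹⁵N spacing difference
(0.99703) stays inside the default ±10 ppm tolerance for i ≤ 6. Both the
spacing constant and the tolerance are arguments, as is the retention-
time half-window (default ±0.5 min around the identification apex; the
underlying acquisition does not dictate one).

Natural distributions are exact multinomial convolutions per element
(binary exponentiation with truncation), not Gaussian approximations.
The envelope width is chosen per peptide and per condition:
n_labelable + n_nat + 1 peaks, where n_nat is the number of peaks the
natural distribution of the non-nitrogen atoms needs to reach a 0.999
cumulative mass. Conditions with more enriched pools therefore get wider
windows for the same peptide.

## NIA correction and the enrichment estimator

The correction matrix column j is the envelope of a molecule with j
deliberately labelled N atoms: the natural distribution of the formula
minus j nitrogens, shifted by j, thinned binomially by the tracer purity
(default 0.99 — each deliberately labelled atom is heavy with that
probability). Deconvolution is non-negative least squares, not matrix
inversion: truncated envelopes make the system non-square and noise
makes unconstrained solutions go negative. Fractions are renormalized to
sum 1; the fit residual is kept as a quality statistic.

Two enrichment statistics are computed. The primary one is the mean
isotopic enrichment E = Σ j·x_j / n_label (the labelled-peptide
fraction, LPF); 1 − x₀ is also reported as `labelled_fraction` since
"fraction of molecules carrying any label" is a defensible alternative
reading. n_label counts only *labelable* atoms — residues whose soluble
pool shows non-zero tracer enrichment; the same convention defines E_max,
so LPF/E_max is internally consistent and, in the exact forward model,
equals the fraction-new identically.

**Non-negativity bias and pooling.** With x ≥ 0, noise can only inflate
the mass assigned to high-j columns, so per-sample enrichments of weakly
labelled (and especially unlabelled) analytes are biased upward; the
bias scales with the noise variance entering the fit. The pipeline
therefore deconvolves the envelope *summed over labelled biological
replicates* for the reported LPF point estimate (at 5% multiplicative
noise this cuts the bias in the recovered fraction-new from ≈0.013 to
≈0.004), while per-replicate enrichments still feed the replicate-level
significance test. The same principle drives the pool side: fragment
selection statistics (control baselines, reported means) come from
summed-envelope estimates, which is what keeps truly unlabelled control
fragments below the null threshold.

## Soluble pools

Each amino acid is measured through several derivatized GC–MS fragments
(the synthetic fragment model appends TMS-like C₃H₉Si units to the free
amino acid; real fragment formulas are taken from the input table).
Fragment QC follows three gates:

1. fragments are cross-checked by Pearson correlation of their
   *summed-isotopologue* abundances across samples (monoisotopic
   abundances are not comparable under labelling); pairs below r = 0.8
   are flagged;
2. fragments with control enrichment above a null threshold (default
   0.002 — the value is a package choice, surfaced in the API, since no
   published number exists) are discarded; when *every* fragment is
   biased the analyte is treated as technically biased instead: the mean
   control "enrichment" is subtracted from the labelled samples and
   minimal-control-variance fragments are retained;
3. among survivors the fragment with the lowest relative standard
   deviation wins, with technical replicates pooled within biological
   replicates before the RSD is taken.

Negative post-subtraction enrichments are clipped to zero and flagged
(enrichment is a physical fraction); values below the null threshold are
reported as zero with a flag, since they are indistinguishable from an
unlabelled pool. Histidine and arginine — below the GC–MS detection
limit in the motivating experiment — are simply absent from the table
and contribute no labelable atoms (a configurable override exists).
Pyroglutamate is aliased to glutamine, which it derives from during
extraction/derivatization.

Cross-treatment comparisons use one-way ANOVA with Tukey HSD at 95%
confidence and a compact letter display (insert-and-absorb); groups with
zero variance everywhere are flagged degenerate and lettered by exact
ties.

## Growth normalization

RGR_t = dW_t/(W_f·dt) with the initial root mass taken as zero, so dW_t
is the measurement at time t. This is a fraction-of-final-weight rate,
deliberately not the slope of log W: germinating-root weight series are
far from log-linear, and a test documents that the two definitions
disagree for exponential input. Averaging is replicate-first (mean
within each sampling day, then an unweighted mean across the days inside
the labelling window); t = 0 is excluded because dt = 0 leaves the rate
undefined there. W_f is the mean over final-day replicates per condition
— weighing is destructive, so per-replicate pairing across days does not
exist, and for the same reason Ks uses the condition-average RGR rather
than a per-replicate one. The dry-weight RGR is the normalizer for Ks
(protein synthesis is a dominant contributor to dry-weight gain).

## Filters and statistics

A peptide × condition observation passes when: a one-sided Welch t-test
of the labelled replicate enrichments against the non-labelled controls
(or against zero if no controls exist / the control mean is ≤ 0) gives
BH-adjusted q < 0.05; at least two labelled replicates exist; the mean
NNLS residual is ≤ 0.1 (sum-normalized scale); and envelope completeness
is ≥ 80%. Completeness counts a peak as "expected" only when the fitted
forward model predicts ≥ 1% of the maximum predicted peak there — a
vanishing theoretical tail is not "missing data". Every gate's counts
are emitted as a funnel table. BH families are per analysis table
(peptides; protein contrasts; LFQ differential), each adjusted
separately.

Protein aggregation uses medians over unique peptides; shared peptides
are discarded (razor assignment off) because paralogue-specific
synthesis must not be mixed — the motivating application is exactly
differential synthesis of ribosomal-protein paralogues. A protein is
"synthesized" with ≥ 1 passing peptide (configurable). Differential
synthesis between conditions is a two-sided Welch test on per-replicate
protein-level corrected LPFs with stars at q < 0.1/0.05/0.01.

## Complex-ome statistics

Substoichiometry divides each r-protein's LFQ intensity by its own
subunit-class sum per sample (40S for SSU, 60S for LSU), removing the
difference in assembled-subunit numbers between samples; within-class
values sum to exactly 1. Differential abundance runs on log2 intensities
with a pseudo-intensity floor at the 1st percentile (variance
stabilization), pairwise-complete, with no imputation at protein level.
Group calls cross "accumulated" (member-wise significant, direction-aware
differential abundance — a complex can never be accumulation-positive in
both conditions) with "synthesized" (members passing the labelling
filter in that condition). Member flags aggregate to the complex by
majority of detected members by default (`any`/`majority`/`all`
configurable — no published aggregation rule exists); the positive
member subsets are always reported so a minority subset can be read the
way nested complex annotations are.

## The synthetic data generator

`simulate` emulates: old/new molecule mixtures (each labelable N atom of
a new molecule heavy with probability e_a·purity + (1−e_a)·p_nat,
convolved with the natural isotopes of everything else — built from
per-atom Bernoulli convolutions, *independently* of the correction-matrix
code, so round trips are genuine two-route checks); Lys-C digestion
(cleavage after K only); 2 conditions × 3 biological replicates ×
labelled/non-labelled, with technical triplicates on the GC–MS side;
pool enrichments defaulting to Ser/Gly 0.15 with weaker spread
(0.03–0.05) into Gln/Glu/Asn/Pro/Val/Asp/Phe/Ile in the cold and
Ser/Gly ≈ 0.04 in the control; tracer purity 0.99; 5% multiplicative
intensity noise (an additive detector-noise floor is available, default
off); dry-weight RGRs 0.017 (cold, transiently peaked near 72 h) and
0.008 h⁻¹ (control) over a 120 h window, constructed so the
window-averaged fraction-of-final-weight RGR equals the configured truth
exactly in the noiseless limit; and LFQ matrices with configurable
fold changes. Default proteome: 50 random proteins × 10 Lys-C peptides
(6–16 residues + K) over an alphabet without internal K and without
His/Arg.

What it does **not** emulate: chromatographic peak shapes and retention
drift, co-isolation/interference, charge-state envelopes beyond a single
state, intensity-dependent (shot-noise) error structure, missingness
mechanisms in LFQ, or real fragment chemistries. Passing recovery tests
therefore demonstrates correctness of the *computations* under the
stated noise model, not robustness to every artefact of real
acquisitions.

## Numerical choices and degenerate inputs

All-zero envelopes are rejected explicitly (distinct from "not found",
which yields a flagged zero envelope). NNLS solutions with zero total
mass fall back to "fully unlabelled". Enrichment with n_label = 0 is
undefined and excluded with a reason, never reported as 0. Corrected
LPF > 1 is reported with a "pool underestimate" flag, not truncated.
Tukey letters are deterministic (columns ordered by first member).
Seeded simulations are byte-identical across runs.

## Problem sizes in the test and acceptance runs

The shipped tests and `scripts/acceptance.py` use 200 random peptides
for round-trip and stochastic-recovery checks, a 5-protein grid study
for the end-to-end identity, the full default pool panel (15 analytes ×
3 fragments × 36 samples), and 200 replicate studies of 20 proteins for
the null calibration — sizes at which every property they assert is
stable while a complete run stays in the single-minute range.

## Known limitations

* Degradation rates (Kd) and turnover are out of scope by design: the
  method targets synthesis under non-steady-state transitions, where
  tracer-dilution-based degradation estimates are not identifiable.
* The per-analyte pool enrichment rests on a single selected fragment;
  with 1-N TMS fragments at 5% intensity noise a single estimate carries
  ≈0.005 SD (large natural C/Si M+1 background), so per-analyte errors
  up to ≈0.02 occur even though the table-wide recovery is unbiased with
  RMSE ≈ 0.005. The strongly enriched tracer targets (Ser/Gly) are
  individually accurate well within 0.01.
* E_max assumes the soluble pool is a faithful proxy for aminoacyl-tRNA
  charging; where that fails, corrected LPFs inherit the discrepancy
  (flagged when they exceed 1).
* Fine-structure (resolving ¹³C vs ¹⁵N) and variable modifications are
  not modelled; the only fixed modification is carbamidomethyl-C.
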