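# Methods

This note documents the models, parameter choices, numerical policies, and
known limitations behind each module.

## Spectral-count enrichment (`synsurf.enrichment`)

The pipeline compares two groups of synaptosome samples — sorted mossy-fiber
("MF") and crude reference ("P2") — with three replicates per group by
default. Stages, in order:

1. **Detection filter.** A protein is kept when its peptide identifications
   summed over *all* samples of both groups reach `min_peptides` (default 3,
   inclusive). The sum is across samples, not per sample.
2. **NSAF.** Per sample, NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j). Each
   sample column therefore sums to 1 over its detected proteins; a sample
   with no identifications yields an all-zero column and a warning rather
   than an error.
3. **Zero imputation.** NSAF is forced to exactly 0 wherever SpC = 0, so
   exclusively detected proteins contribute (0,0,0) vectors to the test.
4. **log₂ fold change** of group mean NSAFs. P2 mean 0 with MF mean > 0
   gives +∞ (serialized as the literal string `Inf` for lossless
   round-trips); both means 0 gives NaN.
5. **t test.** Two-sided equal-variance Student t on the NSAF replicate
   values, zeros included. Welch (`--welch`) and a log₂(NSAF + ε) variant
   (`--log-transform`, ε one decade below the smallest nonzero NSAF) are
   provided because the literature is split on both choices; the defaults
   are the plain Student t on raw NSAF. Degenerate rows where both groups
   are constant get p = 1 when the constants agree and p = 0 when they
   differ — the latter keeps exclusively detected proteins testable
   (a (0,0,0) vs constant-positive row is unambiguous evidence at face
   value, and the class is flagged separately as MF-exclusive).
6. **Benjamini–Hochberg.** q-values via the standard step-up procedure
   (statsmodels `fdr_bh`); the "cutoff rank" is the deepest rank in the
   ascending-p ordering with q ≤ α (α default 0.05, inclusive). Both the
   p and q thresholds are inclusive (≤) and configurable.

Significance flags are independent: `significant` is p ≤ α,
`high_confidence` is membership in the BH α-FDR set.

### Power at 3 replicates, and NSAF compositionality

Two properties of this design are worth knowing when interpreting recovery
tests on synthetic data:

* With 3-vs-3 replicates the t test has df = 4, so even clean 8-fold
  effects rarely produce p below ~10⁻⁴. After BH correction across
  hundreds of proteins, the q ≤ 0.05 set recovers ~50% of 8-fold planted
  effects at realistic count noise, and ≥80% only for stronger effects
  (the suite exercises the 5%-FDR set at a 32-fold planted effect and the
  p ≤ 0.05 positive-fold set at 8-fold). This mirrors real label-free
  experiments, where the FDR-controlled set is conservative.
* NSAF is compositional: planting strong MF signal deflates every other
  protein's MF NSAF, inducing genuine small *negative* shifts in null
  proteins. False-discovery accounting in the recovery tests is therefore
  done on the positive-direction discovery set (flag AND log₂FC > 0),
  matching how an enrichment analysis is read in practice.

## Screen calling (`synsurf.interactome`)

* **Background** is estimated per experiment (per plate) as the arithmetic
  mean of its blank wells; fewer than 30 blanks is an error.
* **Promiscuity rejection.** A prey is rejected for an experiment when it
  exceeds the FOB threshold in every bait column including the AP-only
  control (`sticky_fraction` default 1.0 — the literal "present in every
  bait" — exposed as a configurable fraction), or when it exceeds the
  threshold against the AP-only control alone. Control-column wells never
  become pair calls.
* **Thresholds are strict**: FOB must exceed 5.0; a well at exactly 5.0 is
  negative.
* **Merging.** Detection events are unique (experiment, orientation)
  tuples; duplicated wells within a plate cannot double-count. A
  heterophilic pair can accumulate up to 2 × n_experiments events, a
  homophilic pair (single diagonal well per plate) up to n_experiments;
  the ≥2 rule applies unchanged to both, and two orientations within a
  single experiment suffice — the literal "detected at least twice
  independent of orientation" reading, with `min_detections` configurable.
* **Ordering.** Pair lists and network output are sorted lexicographically
  by (min-id, max-id) for reproducible files.
* A caveat on threshold monotonicity: because the promiscuity rule is
  threshold-relative, raising the FOB threshold can in principle *un-flag*
  a prey whose whole row sat above the lower threshold, admitting new
  calls on pathological matrices. On plates matching the screen model
  (near-background wells plus sparse strong positives) raising the
  threshold only shrinks the accepted set, which is what the property test
  checks.

## Pull-down filters (`synsurf.pulldown`)

Both filters apply their bait clause per experiment (AND across bait
columns) and their control clause across every control column; "absent in
Fc controls" means strictly zero. Any number of control columns is
accepted. Hits are ranked by summed bait counts descending, ties broken by
protein identifier, so output files are deterministic.

## BLI affinity fitting (`synsurf.bli`)

Steady-state analysis only: the package consumes extracted equilibrium
responses per concentration, not kinetic traces, because the K_D of
interest is read from response-vs-concentration. The fit is unweighted
nonlinear least squares (scipy `curve_fit`, TRF with positivity bounds) on
R(C) = R_max·C/(K_D + C), initialized at R_max⁰ = max response and
K_D⁰ = the concentration nearest half-maximum. Options: a linear drift
term in the dilution index (instrument drift is a known artifact of the
assay), and a soft-L1 robust loss. Replicate response columns in input
files are averaged before fitting. Non-convergence sets `converged=False`
with the solver message instead of raising; a K_D outside the tested
concentration range raises an extrapolation warning and clears the
`bracketed` flag. On noise-free model data the fit recovers parameters to
machine precision (RSS ≤ 1e-8 is asserted).

## Synthetic data (`synsurf.simulate`)

The generators define the study conditions the analysis stages are tested
under; all are deterministic given their config, and all return ground
truth alongside the data.

* **Spectral counts.** Negative-binomial counts (mean μ, size k; variance
  μ + μ²/k). Per-protein abundance is lognormal around `baseline_mean`
  (σ = 0.5), matching the wide dynamic range of spectral counts. The
  dispersion default k = 10 (replicate CV floor 1/√10 ≈ 0.32) models
  pooled-sample biological replicates: noisier than technical LC–MS/MS
  repeats, far less dispersed than single-animal RNA-seq-style counts.
  Enriched proteins scale the MF mean by `enrichment_fold`; exclusive
  proteins have P2 forced to zero and at least one nonzero MF replicate.
  Peptide counts are ceil(SpC/2), floored at 1 when detected — only the
  summed-peptide filter consumes them, so their exact distribution is
  immaterial. Dropout (`detect_dropout`) is off by default.
* **ELISA plates.** 73 constructs and 3 experiments by default (73 × 73 =
  5329 test wells per experiment plus an AP-only control column).
  Background wells and the 100 blank wells draw from Normal(0.07, 0.027)
  clipped at 0, the stated plate background; blanks are kept as a value
  list ("contiguous" placement is not modeled since only the mean is
  used). True-pair wells receive uniform FOB in [6, 50] × background,
  independently per (experiment, orientation) with probability
  `detection_prob` — the Bernoulli independence lets tests exercise the
  ≥2-detection rule at every event count. Sticky preys receive the same
  signal range against every bait including the control.
* **Pull-downs.** Planted hits: ≥2 counts per bait experiment, ≤1 in the
  Fc control; contaminants: counts in bait and control; background
  proteins: sparse Poisson(0.5) counts.
* **BLI.** The default ladder is nine twofold dilutions from 34 µM
  (ending at 34/2⁸ ≈ 0.133 µM) plus a buffer-only zero point; responses
  follow the one-site model with additive Gaussian noise (default SD
  0.02 nm) and optional linear drift.

### What the generators do not emulate

Raw spectra and database search, peptide-to-protein inference, plate
spatial effects (edge wells, gradients), partial-promiscuity preys,
expression-level variation among constructs, and kinetic BLI sensorgrams.
Passing recovery tests therefore demonstrates correctness of the calling
logic under the stated statistical model, not robustness to every artifact
of real plates or LC–MS/MS runs.

## Problem sizes used in tests and the acceptance script

Enrichment recovery and null-control simulations use 100–1000 proteins over
20 seeds; screen recovery uses 15–20 constructs over 10–20 seeds (the full
73-construct design is exercised for its combinatorics and background);
K_D recovery uses 50 seeded series. These sizes give stable pooled
estimates while keeping the whole suite fast on a single CPU.
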