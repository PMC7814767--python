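# Methods

This note records the models, conventions and design choices behind
`envconn`, in the order the pipeline runs.

## Connectome and bands

The shipped atlas (`envconn/data/atlas32.tsv`) is a reconstruction of a
32-node, six-network resting-state parcellation: node labels, network
memberships and hemispheres were assembled from published figure labels of
the study design this package reimplements and completed from the upstream
42-node atlas it was adapted from (visual network reduced to bilateral V1;
subcortical nodes dropped).  MNI coordinates are not part of the
reconstruction and are left empty — they would only serve plotting.  The
left inferior temporal gyrus node is stored with its original DMN
membership plus an `alias_network = LAN` column, because the literature
supports both attributions; the alias never affects matrix indexing.
Node order in the file is the indexing contract: flat (node, band) indices
are node-major, band-minor.

Bands default to δ 1–4, θ 4–8, α 8–12, β_L 12–21, β_H 21–30 Hz.  All
filters are 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), i.e. zero-phase with squared magnitude response.

## Envelope connectomics

Per subject and band the pipeline computes, for every ordered node pair
(i, j):

1. **Orthogonalization** (leakage control): node j's band signal is
   replaced by its residual against node i's signal in the *same* band,
   `y⊥ = y − (⟨x,y⟩/⟨x,x⟩)x`.  Leakage from source reconstruction is
   instantaneous and band-preserving, so cross-frequency entries
   orthogonalize within each node's own band.  Residuals with variance
   below 1e−12 of the original flag the connection undefined
   (collinearity guard).
2. **Slow envelope**: magnitude of the analytic signal, decimated by
   average-pooling to ≈10× the low-pass cutoff, then zero-phase low-passed
   at 1 Hz.  One filter length (1/cutoff s) is trimmed from both ends
   before correlating, removing Hilbert/filter transients.  The decimation
   is an efficiency device: envelope content above the cutoff is discarded
   by the low-pass anyway, and `slow_envelope` provides the exact
   full-rate counterpart for single signals.  The analytic transform runs
   in single precision (relative error ~1e−7, orders of magnitude below
   the statistical noise of any correlation); exact primitives
   (`orthogonalize_static`, OLS, Welch t, R²) stay in double precision.
3. **Correlation and symmetrization**: the entry ((i, a), (j, b)) is the
   average of corr(env(x_i,a), env(y⊥_j,b)) over both orthogonalization
   directions — static pairwise orthogonalization is asymmetric and one
   value per pair is reported.
4. Same-node entries (all band pairs) are undefined throughout: they are
   confounded by shared broadband amplitude.  Envelopes are correlated
   raw — no log transform or Fisher z.

Mean-network matrices average defined multi-layer entries over
within-network node pairs (diagonal blocks) or all inter-network pairs
(off-diagonal); for same-network cross-band entries both orientations of
each node pair contribute.  Power is the temporal variance per node and
band, divided by a supplied noise variance (1 for synthetic data), and is
averaged within networks alongside.

A note on what orthogonalization can and cannot remove: with reciprocal
instantaneous mixing, the residual necessarily retains a sign-flipped copy
of the other node's signal at the mixing amplitude ε.  Zero-lag *carrier*
correlation is removed exactly (verified by simulation: mixing 0.25
between amplitude-stationary carriers inflates raw envelope correlation
to ≈0.13 while the orthogonalized estimate is statistically
indistinguishable from 0).  Leaked *amplitude-envelope* content, however,
is sign-blind and survives at order ε² (≈0.06 at ε = 0.1 with realistic
amplitude modulation).  No pairwise zero-lag correction can remove that
component; tests therefore assert exact removal on the carrier component
and treat the ε² envelope term as a documented limitation.

## Synthetic cohort generator

Each (node, band) entry k gets `x_k(t) = c_k(t)·e_k(t)`:

* Carriers `c_k`: unit-variance Gaussian noise with the band's zero-phase
  band-pass spectrum, synthesized in the frequency domain (white complex
  coefficients shaped by |H|²) — statistically the same as filtering white
  noise.
* Envelopes `e_k = exp(σ·z_k)` with σ = 0.7 by default (realistic envelope
  coefficient of variation ≈ 0.8); the `z_k` are unit-variance Gaussian
  processes low-passed at 0.5 Hz, generated at a low rate and linearly
  interpolated, and correlated across entries through the Cholesky factor
  of a latent matrix.  Exponentiation guarantees strictly positive
  envelopes; sharing latent factors across bands is what makes
  cross-frequency envelope coupling plantable.

`target_corr` is specified on the scale the analysis measures — Pearson
correlation of slow envelopes.  Two known attenuations separate that from
the latent Gaussian scale, and the generator inverts both in closed form:
lognormal compression (`r = (e^{sρ}−1)/(e^s−1)`, s = σ²) and carrier
dilution (the measured envelope is, to first order, the planted envelope
times the slow residue of the carrier's Rayleigh envelope, an independent
multiplicative noise whose CV² is estimated once per band by pushing a
long noise realization through the analysis envelope chain with a fixed
internal seed).  The combined inversion is
`ρ = log(1 + r·(e^s(1+c)−1))/s`; targets beyond the feasibility limit
(ρ = 1) are clipped and reported in the ground-truth record.  With this
calibration a planted within-band correlation of 0.6 is recovered by the
full pipeline to within ±0.02 in the mean (Monte-Carlo SE ≈ 0.01 over 50
replicates of 300 s).

Group effects add deltas to the patient group's target matrix (validated
for range and positive semidefiniteness).  Behavioral couplings draw each
coupled connection's true value per subject (Gaussian jitter, SD 0.15,
clipped to ±0.85, eigenvalue-clipped back to a valid correlation matrix)
and build scores as weighted sums of those true values plus optional
confound and structural-marker contributions plus Gaussian noise.  The
battery mirrors a clinical MS study: seven neuropsychological scores plus
depression for everyone, EDSS and disease duration for patients only.
Confound distributions (age ~ N(48, 10) years, education ~ N(14, 3)
years, binary sex/scanner/benzodiazepine) are placeholder conventions, not
claims about any cohort; lesion load is gamma-distributed (patients ≈ 10
ml, controls ≈ 0.3 ml) and normalized thalamic volume Gaussian (patients
lower), with optional couplings into the scores.

What the generator does **not** emulate: 1/f broadband spectra, phase
coupling, nonstationary dynamics, realistic sensor noise or field spread
beyond a user-supplied instantaneous mixing matrix.  Passing tests
demonstrate the pipeline's statistical behavior under its stated model,
not performance on real MEG.

## Permutation statistics

* Welch's unequal-variance t with Welch–Satterthwaite degrees of freedom
  everywhere a two-group comparison occurs (robust to the unbalanced
  designs this pipeline targets).
* Confound regression for the group contrast subtracts the fitted
  contribution of the *centered* regressors (`keep_mean`), so each
  sample's mean survives while confound variance is removed — full
  residualization would center both groups exactly and erase the
  contrast.  The default scheme fits the shared confounds (two endpoint
  powers, age, sex, education, scanner type) in one pooled,
  label-independent model and removes benzodiazepine within the patient
  group, where it varies.  Separate per-group fits
  (`scheme="within_group"`) are available but leave group-specific
  confound-mean offsets that label permutations cannot reproduce; at 20+20
  subjects this measurably inflates the family-wise error, while the
  pooled scheme is calibrated (FWER ≈ 5%, permutation p of the maximum
  uniform by KS test across 200 null cohorts).  Pooling a patients-only
  indicator instead would absorb part of the group contrast itself (it is
  collinear with the group label), which is why it is removed within
  patients.
* Score-regression β maps use the Frisch–Waugh identity: values and score
  are residualized on the confounds, and the simple slope of residual on
  residual equals the score's coefficient in the joint multiple
  regression (verified against statsmodels to 1e−10).
* Permutation schemes: group-label shuffles for t and Δβ contrasts,
  subject-order shuffles against the score for β maps — always applied to
  the already-residualized matrices.  Null distributions collect the
  maximum absolute statistic over all defined entries; the corrected
  threshold is the (1 − α/family)th percentile with linear interpolation;
  p-values use the add-one estimator (1 + #{null ≥ obs})/(n_perm + 1),
  which never returns 0.  Bonferroni families are computed from the
  registered analysis plan (38 = (1 contrast + 10 patient scores + 8
  control scores) × 2 levels; 8 behavioral tests), never hard-coded, so
  desk-scale designs scale down automatically.
* The effect-size ratio compares mean/SD of a mean-network value against
  the average mean/SD of its contributing connections; independent
  same-mean connections approach a √k gain, redundant ones stay at 1.

## Structuro-functional model comparison

Structural model: score ~ intercept + lesion load + thalamic volume.
Functional features (by default the mean-network values flagged by the
group contrast) are orthogonalized column-wise against [intercept,
structural markers] — a reparametrization that leaves R² unchanged
(asserted to 1e−10) but isolates their independent contribution.  The
null distribution of the full-model R² comes from jointly shuffling the
rows of the orthogonalized feature block (structural markers and score
fixed), which preserves the features' internal correlation and, in
expectation, their orthogonality to the structural block; 10⁴ samples by
default, computed by batched normal equations (the feature Gram matrix is
shuffle-invariant) and verified against per-permutation OLS refits to
1e−10.  Reported quantities: structural R², adjusted structural R² (the
null mean — what the augmented model explains by chance), full-model R²,
and the add-one permutation p.  An empty feature block degenerates to
identical R² and p = 1.

## Problem sizes and tolerances

Desk-scale defaults — 10 nodes, 2 bands (α, β_L), 20+20 subjects, 60 s at
250 Hz, 1,000 permutations — keep a full 200-cohort null-calibration
study at roughly ten minutes on one CPU; the 32-node, 5-band design runs
through the same code paths.  Key tolerances: collinearity guard 1e−12
(relative residual variance); exact-oracle agreement 1e−10; planted-
correlation recovery ±0.1 at 300 s; envelope decimation keeps ≥10 samples
per low-pass period.  Degenerate inputs (all-zero signals, rank-deficient
designs, single-subject groups, empty feature blocks, single-node
networks) raise typed errors or produce flagged-undefined entries rather
than silent numbers.
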