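# Methods

This note documents the models, conventions and numerical choices behind
`nirsnet`, in the order the pipeline applies them, followed by the
generative model of the synthetic cohort and what validation against it
does and does not establish.

## Signal path

**Stage order.** Artifact screen → discard of the first 120 s → zero-phase
band-pass of the *optical density* series → modified Beer-Lambert inversion
→ total-Hb. Filtering before conversion is fixed by design (not a config
switch); since both operations are linear the order cannot change results
beyond float noise — a property the test suite asserts.

**Band-pass.** Butterworth of order 2 per band edge, applied
forward–backward (`scipy.signal.sosfiltfilt`), pass band 0.009–0.08 Hz.
Zero-phase filtering preserves the relative timing on which channel-wise
correlation depends; the effective roll-off is ≈ 24 dB/octave, which
attenuates a 1 Hz cardiac tone by > 90 dB while passing 0.03 Hz within
0.001 dB (both measured in the acceptance script). The design and
coefficients are fully determined by `FilterSpec`, so runs are bit
reproducible.

**Beer-Lambert conversion.** Per sample the 2×2 system
ΔOD(λ) = [ε_HbO(λ)·Δ[HbO] + ε_HbR(λ)·Δ[HbR]] · DPF(λ) · d
is solved with d = 3.2 cm (source–detector separation) and DPF = 6 at both
wavelengths. Extinction coefficients default to the Gratzer/Kollias
compiled hemoglobin spectra at 690/830 nm (0.276/2.052 and 0.974/0.693
mM⁻¹cm⁻¹) and are overridable; the matrix condition number is exposed.
Units: concentrations come out in mM under these defaults. Because Pearson
correlation is scale invariant, neither the unit convention nor the
DPF × separation factorisation can affect any network quantity — asserted
by a test that rescales channels and compares binary networks.

**Artifact screen.** The visual inspection used in practice is replaced by
a deterministic proxy: a channel is motion-flagged when the robust z-score
(median/MAD) of its first differences exceeds 5 anywhere, and low-SNR
flagged when its variance falls below 1e−12 (absolute) or 1e−4 × the
cohort-median channel variance. Flags are reported in a QC record; data are
never mutated. The thresholds are config.

## Networks and metrics

**Thresholding.** Binary networks keep the K = round(S·N(N−1)/2) edges with
the largest |r| (negative correlations count by magnitude; a positive-only
switch exists but is off). Rounding to nearest minimises
|realized − requested| sparsity; the realised cutoff T and the size of any
tie group at rank K are recorded (ties are broken lexicographically on the
channel pair, so runs are reproducible; they are measure-zero for
continuous data). Edge sets are nested along the grid by construction.

**Conventions fixed across all metrics.**

- L_p is the mean shortest-path length over *connected* pairs only; the
  disconnected-pair fraction is reported beside it at every sparsity.
  Efficiencies handle disconnection natively (zero inverse distance).
- Nodes of degree < 2 contribute 0 to the C_p and E_loc averages rather
  than being excluded, keeping denominators at N across the sweep.
- Betweenness is exact Brandes fractional counting, normalised by
  (N−1)(N−2)/2.
- The hierarchy fit C(k) ∝ k^−β bins nodes by degree (mean C per k), drops
  k < 2 and C = 0, and reports β, R² and the point count; fewer than two
  usable degrees yields an undefined flag, not an exception. Mean clustering
  is *not* monotone in S on nested graphs (an added edge can dilute a
  clustered node's neighbourhood); only global efficiency is.
- Modularity: Q = Σ_m [e_mm − a_m²]. The deterministic greedy agglomerative
  optimizer (Clauset–Newman–Moore) is the metrics-level default and is used
  for metric curves and null replicates on both sides of every comparison;
  the Model layer reads out the reference-sparsity partition with seeded
  multistart Louvain (10 restarts, best Q, all restart Qs retained) because
  the analysis reports the maximum-modularity decomposition. Reported Q is
  always recomputed from the returned labels.

**Null models.** Degree-preserving double-edge swaps: swap_factor × K
attempted swaps per replicate (default 10, unstated in the source
literature; edge overlap vs swap_factor is a tested, decreasing trend),
self-loops and multi-edges rejected, degree sequence asserted per
replicate. Ensemble statistics use the population (n) standard deviation by
default (switchable to n−1). z = (x − μ)/σ with two-tailed significance at
|z| > 1.96; σ = 0 is flagged rather than returned as an infinite z. For
dense graphs σ of L_p and E_glob becomes tiny and |z| explodes — σ is
therefore always reported next to z. Per-sparsity ensembles are built
independently rather than rewired once and rethresholded.

**Hubs.** AUC over the sparsity grid (trapezoid; flagged-degenerate points
dropped with width renormalisation), hub rule auc ≥ mean + 1 SD with the
*sample* SD (ddof = 1, switchable) and "≥" at the boundary. Per-metric
sets, the "any one metric" union, and the three-metric consensus are all
reported rather than choosing one definition.

**Reproducibility.** By-subject splits are seeded balanced randomisations
(7 + 8 for 15 subjects); by-time splits cut each post-discard series into
two contiguous 6000-sample halves. Matrix similarity is the Pearson r of
the unique off-diagonal entries. Nodal-profile correlation is computed
across nodes at every sparsity; the summary mean ± SD is taken over
0.1 ≤ S ≤ 0.5 by default — below 0.1 the networks fragment and above ≈ 0.9
degrees saturate toward N−1, so across-node variance (and hence r) becomes
noise; the full-grid summary remains available. The contrast comparison is
a one-way repeated-measures ANOVA (uncorrected F by default,
Greenhouse–Geisser available) on per-subject AUCs with two-sided paired
t-tests for the three contrast pairs; raw p-values are primary, Bonferroni
and Benjamini–Hochberg columns are reported alongside.

## The synthetic cohort

**What it emulates.** 15 subjects × 46 channels × 600 s at 25 Hz — the
acquisition geometry of a whole-head two-wavelength probe — with a planted
connectivity structure carrying the three hallmarks the analysis is meant
to detect: five modules (13/12/8/8/5 channels), one connector hub, and a
small-world topology.

**Planted structure.** The ground truth is a *blueprint network* at 10%
density (104 edges): each module's members joined by a ring plus random
chords (budgets proportional to module size; every node keeps ≥ 2
within-module edges), a hub linked to 33 channels spread round-robin over
all modules, and 5 distributed between-module bridges. Blueprint pairs
receive correlation targets N(0.6, 0.03²) — hub pairs N(0.5, 0.03²) —
and all other pairs a continuous background
N(0.16 + b_i + b_j + 0.06·[same module], 0.05²), where b_i ~ N(0, 0.05²)
are per-channel coupling strengths. The matrix is then projected to the
nearest unit-diagonal PSD correlation matrix.

Three aspects of this design are forced by correlation geometry rather
than taste. (1) A uniform block matrix (r_within inside modules, r_between
elsewhere) thresholds into five disconnected cliques at sparse S — no
between-module edges, hence no small-world pattern to detect; real group
matrices avoid this because their correlations form a continuous spectrum,
which the background tail reproduces. (2) A hub cannot couple at 0.6 to
dozens of channels that mutually correlate ≈ 0.2 — the PSD cone caps
uniform coupling near √r̄ ≈ 0.4 — so the planted hub strength is 0.5 with
the projection absorbing the remainder; this is why `r_hub` sits below
`r_within`. (3) Per-channel background strengths exist because without
them all non-hub channels are statistically exchangeable, nodal-metric
profiles carry no stable signal, and split-half profile correlations
measure pure noise — unlike any real cohort.

**Subjects and signals.** Each subject's covariance is the group target
plus symmetric Gaussian jitter (sd 0.10), re-projected to PSD. The 0.10 is
calibrated so that the two split-half reliabilities separate the way real
resting-state cohorts separate (by-time ≈ 0.88 > by-subject ≈ 0.84 here):
band-limited signals carry only ~2·B·T ≈ 68 effective samples per 8-min
series, so a much smaller jitter would leave both splits dominated by
sampling noise and their ordering a coin flip. Oxy-Hb signals are
Cholesky-mixed band-limited Gaussian noise synthesised inside 0.01–0.08 Hz
— so the analysis band-pass transmits them essentially unchanged,
separating filter validation from signal generation; deoxy-Hb is
−κ·oxy + √(1−κ²)·independent noise (κ = 0.5), giving corr(oxy, deoxy) = −κ
with equal variances. Nuisance terms are added in concentration space:
slow drift (< 0.005 Hz sinusoid mixture, relative amplitude 1.0), cardiac
≈ 1 Hz and respiratory ≈ 0.3 Hz tones with per-channel phase and ±2%
frequency jitter (amplitude 0.5), optional motion spikes (Poisson,
1-s exponential decay, amplitude 5, rate 0 by default). The hemodynamic
scale is 1 µM (0.001 mM), a typical resting fluctuation amplitude. The
forward Beer-Lambert model then maps concentrations to two-wavelength
optical densities. Everything derives from one seed via SeedSequence
spawning; generation is bit-reproducible.

**What it does not emulate.** Photon transport and partial-volume effects;
scalp/systemic physiology coupled across channels; spatial geometry (the
probe layout is symbolic — channels have no coordinates); non-Gaussian and
non-stationary dynamics; real spectra outside the analysis band (spectra
are stipulated, not fitted — no resting fNIRS spectrum was available to
fit). Consequently, passing the planted-recovery tests shows the pipeline
correctly extracts modular, hub-like, small-world structure *when it is
present at realistic correlation levels and cohort sizes*; it does not
certify preprocessing against real-world systemic confounds, which would
require short-separation channels the underlying protocol lacks.

**Estimation-noise floor.** With B ≈ 0.07 Hz of signal bandwidth, a single
8-min recording supports correlation estimates with sd ≈ 0.1; cohort-mean
matrices reach ≈ 0.026. Convergence of the cohort mean to the target is
therefore tested as a decreasing trend over durations with a mean-absolute
deviation bound, not as a per-pair maximum.

## Problem sizes in the validation suite

The test suite and acceptance script run the study-scale cohort
(15 × 46 × 12000 samples) end to end, but use reduced ensemble sizes where
the module default (1000 replicates) is not itself the quantity under
test: 40–100 replicates per ensemble for calibration and small-world
checks, the full 1000 for the degree-sequence invariant. Metric
correctness is established against brute-force enumeration on 50 random
graphs with n ≤ 12 and exhaustive partition search at n ≤ 8, where
enumeration is exact and fast. The z-score calibration study (40 ER graphs
× 6 metrics) checks the pooled two-tailed exceedance rate against its 5%
nominal level; a joint all-six-within-bounds-per-run criterion would be
expected to fail ~15% of runs for a perfectly calibrated procedure (six
correlated 5%-level tests) and is reported but not asserted.

## Known limitations

- The disconnected-pair convention for L_p (mean over connected pairs) is
  one of several in use; results at very sparse thresholds depend on it,
  which is why the disconnection fraction is carried in every output row.
- The greedy modularity optimizer under-resolves occasionally; multistart
  Louvain is the readout default, and both are exposed.
- β (hierarchy) is a two-parameter fit on few points at sparse thresholds;
  its R² and point count should be inspected before interpretation.
- Repeated-measures ANOVA assumes sphericity unless the
  Greenhouse–Geisser option is enabled.
- SNIRF I/O is not implemented; recordings are delimited text
  (samples × channels with a channel-ID header row).
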