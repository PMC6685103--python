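# Methods

This note documents the models, estimators, defaults, and design
decisions behind `dtfconn`, and what the synthetic-data validation does
and does not establish.

## EEG signal model and conditioning

Recordings are channels × samples matrices in µV with 10–20-system
labels. Conditioning applies, in order: a zero-phase order-4 Butterworth
low-pass (default 100 Hz), a zero-phase order-2 Butterworth band-stop
notch (default 49–51 Hz for 50 Hz mains), and per-channel polynomial
baseline removal (default order 3, via projection onto an orthonormal
Legendre basis). Zero-phase (forward–backward) filtering matters here:
a causal filter's group delay would distort the lagged cross-channel
structure that the autoregressive model estimates.

Artifact handling is a deliberately simple amplitude criterion: epochs
containing any sample beyond ±100 µV (configurable) are dropped and
logged. High-amplitude transients are the common signature of ocular
and muscle artifacts; ICA-style decomposition is out of scope, and the
validation data are clean by construction.

Signal-to-noise is reported per channel as the variance ratio
`SNR_i = σ²_signal(i) / σ²_noise(i)`, with the noise SD taken from a
designated "pre" interval. For a resting recording no event-locked pre
interval exists, so the default is the first second of the recording —
a declared convention, configurable. A channel gate
(`gate_channels`, default pass-band [7, 10] in the clinical usage this
mirrors) can restrict analysis to channels in a trusted SNR range.

Epochs are non-overlapping, default 2 s: long enough for a stable MVAR
fit per epoch, short enough that tens of within-subject replicates come
out of a one-minute recording. Epoch length is a logged config entry.

## MVAR estimation and order selection

The model `X(t) = Σ_{n=1..p} A_n X(t−n) + E(t)` is estimated by
ordinary least squares on the lagged regression. Epoched recordings are
fitted by pooling regression rows across epochs with lag windows that
never cross an epoch boundary, so discontinuities created by artifact
rejection cannot masquerade as dynamics; a per-epoch (non-pooled) mode
is also provided, and the two agree exactly on a single epoch. The
innovation covariance uses the small-sample divisor `rows − N·p − 1`.
Rank-deficient designs raise an error that names zero-variance or
collinear channels.

Order selection minimises SBC (default) or log-FPE over a candidate
range (library default [1, 20]); all candidate orders are fitted on the
same rows (the first `p_max` samples of each epoch serve only as lags)
so criterion values are comparable. The criterion formulas follow the
ARfit definitions:

```
sbc(p) = logdp/N − log(ne)·(ne − Np)/ne
fpe(p) = logdp/N − log(ne·(ne − Np)/(ne + Np))
```

with `logdp` the log-determinant of the residual cross-product matrix
and `ne` the row count. Behavioural checks stand in for a formula-level
oracle: the true order of strongly coupled simulated systems is
recovered (≥ 9/10 seeds at n = 20,000 for p ∈ {1, 2, 3}), and on white
noise the penalty makes `p_min` the minimiser. Single-epoch fits agree
with statsmodels' VAR to machine precision, which cross-checks the OLS
core without replacing it.

## DTF and band summaries

`A(f) = Σ_{i=0..p} A_i e^{−j2πfiΔt}` with `A_0 = −I` (the overall sign
vanishes after squaring); `H(f) = A(f)^{-1}`, checked by the
`H·A = I` invariant; `γ_ij(f)² = |H_ij|² / Σ_m |H_im|²`. Singularity of
`A(f)` is tested by condition number (> 1e12), not determinant
magnitude, which scales with dimension. Rows of `γ²` sum to 1 to 1e−10
by construction — verified over random stable models up to N = 8,
p = 5.

The default analysis grid is 1–45 Hz in 0.5 Hz steps; the gamma band is
defined as 30–45 Hz, keeping its upper edge below the 49–51 Hz notch.
Both are config entries recorded in every report. The scalar summary
`DTF_mean` averages the band-mean matrix **off-diagonal only** by
default: self-inflow `γ_ii²` dominates every row (typically > 0.8) and
would swamp a whole-matrix mean; a flag restores the full-matrix mean
for comparability with conventions that include it.

Note the DTF's semantics: it measures directed *inflow shares*,
including cascade (indirect) paths, and each row is normalised to 1.
Two consequences show up in validation: significant links appear along
indirect routes (truthfully — the transfer matrix mixes them in), and
removing one source's inflow re-inflates the shares of the remaining
sources of that row.

## Surrogate significance testing

The null distribution for each directed link is built by permuting each
channel's samples independently (within each epoch, so surrogates keep
the observed epoch structure), refitting the MVAR at the observed-data
order, and recording band-mean `γ²` — default 1,000 shuffles, α = 0.05.
Holding the order fixed keeps order-selection variability out of the
null. P-values are add-one empirical, `p = (1 + #{null ≥ obs})/(1 + S)`,
so they can never be zero; a link is kept iff `p ≤ α`. Decisions are
per link with no multiplicity correction by default (an optional
Benjamini–Hochberg flag exists). Under exchangeability (white-noise
observed data), the procedure's realised level at S = 200 is
`⌈α(S+1)⌉/(S+1) ≈ 0.0497`, and the measured per-link rejection rate
over 200 independent datasets lands in [0.03, 0.07].

The surrogate loop solves the fixed-order pooled normal equations by
Cholesky factorisation (refitting thousands of times); a numerically
singular permutation is retried with a fresh one and counted.

## Electrode profiles and group comparison

A pruned band matrix collapses to one scalar per electrode: mean
off-diagonal inflow (its row), outflow (its column), or their average
("total", the library default; the replica configuration uses inflow —
see below). Pruned links count as zero.

Comparing one subject against a control group needs a unit of
replication on both sides. The subject contributes per-epoch profiles
(its only within-subject replicates). Each control is summarised by the
**mean of its per-epoch profiles**, not by its pooled-fit profile:
pooled and per-epoch DTF estimators carry different finite-sample
inflation (per-epoch fits sit on a higher noise floor), and mixing the
two estimators biases the test — in measurement, enough to wash out a
10× true attenuation. Per electrode, a Welch t-test is used when both
samples pass Shapiro–Wilk normality at 0.05, otherwise Wilcoxon's
rank-sum ("auto"); electrodes with `p ≤ α` are reported with the
direction of the difference. No multiplicity correction by default,
with an optional BH flag.

## Synthetic EEG generator

`simulate_mvar` runs the MVAR recursion with Gaussian i.i.d. per-channel
innovations (the distribution is a free choice given only "zero-mean
uncorrelated white noise"; Gaussian enables closed-form checks) and
discards a 1,000-sample burn-in so the returned segment is effectively
stationary. Stability is enforced at construction: the companion-matrix
spectral radius must be < 1, and the error reports the radius.
`random_stable_network` scales lag matrix `A_k` by `s^k`, which scales
every companion eigenvalue by exactly `s`, to hit a target radius.

The control-like scalp network (`control_network`) gives each of 32
montage electrodes a lag-1 self term and couplings from its three
nearest montage neighbours, rescaled to spectral radius 0.92 — a
minimal stand-in for the spatially smooth sensor-level correlation of
real EEG. The patient variant attenuates the **inflow** couplings
(matrix rows) of the 15 posterior electrodes by a factor of 0.2.
Row-only attenuation is a validation-design choice: it leaves every
non-posterior electrode's direct inflow exactly at control values, so
"affected" and "untouched" electrode sets are unambiguous ground truth.
Attenuating rows and columns (`direction="both"`, also provided) is
equally plausible physiology but genuinely reduces boundary electrodes'
inflow-from-posterior, making them true positives that a
confined-effect scorecard would miscount.

What the generator does *not* emulate: oscillatory rhythms, 1/f
spectra, volume conduction, non-stationarity, or realistic artifacts.
Passing tests establish that the estimator chain recovers known linear
directed structure at realistic sample sizes — not that it is robust to
everything real EEG contains.

## Study replica

`run_replica` reproduces the study shape on synthetic data: 8 controls
and one patient (pre = attenuated network, post = intact network),
60 s at 250 Hz each, 2-s epochs, 200 shuffles, electrode selection at
α = 0.001 (the study's electrode-selection threshold), inflow profiles.
The order search is capped at p = 2 in this configuration as an
identifiability constraint: per-epoch fits must estimate `N·p`
regressors per channel from ~500-sample epochs, and beyond p = 2 (64
regressors, ≈ 8 samples per parameter) the per-epoch DTF noise floor
(measured ≈ 0.016 per link) exceeds the true per-link signal (≈ 0.01),
destroying the comparison's power regardless of the real effect size.
At these conditions the comparison flags all 15 attenuated electrodes
as reduced with 0–1 false flags among the 17 untouched ones, and the
pre-vs-post comparison flags the posterior electrodes as increased.
The full run takes well under five minutes on one CPU.

## fMRI branch

`simulate_fmri_blocks` builds each in-mask voxel's series as
`√b·g + √(w−b)·c_k + √(1−w)·e_v` (global factor, community factor,
voxel noise), giving exact target correlations `w` within and `b`
between communities; `w = b` degenerates to a single shared factor and
`w = b = 0` to independent noise. GBC computes Pearson correlations on
per-voxel linearly detrended series and averages raw r (the plain
reading of "correlation … then averaged"); a Fisher-z averaging flag is
provided. Zero-variance voxels get NaN and are excluded from every
average. For the two-community model the expected mean GBC is
`(w(k−1) + bk)/(2k−1)` for community size k; a single 500-timepoint
volume's community mean fluctuates around this with sd ≈ 0.014 (the
shared factor's realised variance moves all pairs together), which the
validation accounts for. `compare_gbc` is descriptive only — voxelwise
and region-level differences with no inferential claim, matching the
qualitative use of the pre/post fMRI contrast.

DMN/ECN masks are inputs (binary NIfTI volumes); deriving them from an
atlas, and all fMRI preprocessing before the mask-aligned 4-D volume,
are out of scope.

## Numerical and I/O choices

- OLS via LAPACK `gelsd` with a condition-number guard (limit 1e12);
  surrogate refits via Cholesky normal equations.
- All randomness flows through `numpy.random.default_rng`; the pipeline
  expands one global seed into per-stage seeds by CRC-keyed
  `SeedSequence`, and any run is byte-identical under the same config
  and seed (checked in the suite). Every results directory carries a
  manifest with the config, seed, library versions, and SHA-256 of each
  output.
- EDF is read through MNE. Writing uses a minimal plain-EDF writer
  (1-s records, int16, per-channel physical scaling; quantisation step
  (max−min)/65535), round-trip tested against MNE's reader. CSV
  recordings carry the sampling rate in a `# fs=` header line. NIfTI
  goes through nibabel with an identity affine for synthetic volumes.

## Known limitations

- The DTF inherits MVAR linearity and stationarity assumptions; epochs
  are assumed individually stationary.
- Per-epoch profiles at many channels are noisy; comparisons lean on
  the matched-estimator design above and degrade if epochs are too
  short for the selected order.
- The amplitude-threshold artifact stand-in will not catch low-amplitude
  ocular/muscle contamination.
- Sampling rate and montage reference of the emulated recordings are
  free parameters (250 Hz and the built-in 32-channel montage by
  default); nothing in the validation pins them.
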