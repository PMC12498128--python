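# Methods

## Signal model of the synthetic cohort

Each subject's EEG is synthesized per epoch (1100 ms at 500 Hz, 19
channels) as a sum of independent components, in microvolts:

1. **1/f background.** White Gaussian noise is shaped in the frequency
   domain by $f^{-\beta/2}$ (power slope $\beta$, default 1), band-limited
   to the 1–100 Hz acquisition band and scaled to a target broadband RMS
   (default 5 µV). Realizations are independent across epochs and channels.
2. **Band oscillators.** One sinusoid per band at the band's centre
   frequency — theta 6 Hz, alpha 10 Hz, beta 20 Hz, gamma 60 Hz — with a
   fresh uniform phase every epoch, a per-band scalp gain profile, and a
   per-group amplitude (defaults, µV: NC theta 3.0 / alpha 4.0 / beta 1.2 /
   gamma 0.9; SZ theta 4.2 / beta 1.5, others equal). A single line per
   band suffices because the 4 Hz multitaper half-bandwidth spreads it
   across ≈ ±4 Hz of the PSD grid, producing band-wide spectral elevations
   and hence band-wide clusters.
3. **40 Hz steady-state component** (task state only), gated over 0–500 ms
   post-onset, amplitude 3 µV × a fronto-central, slightly right-weighted
   profile. Its per-epoch phase is von Mises with group concentration
   κ (defaults NC 0.8, SZ 0.55) — the ground truth that PLF estimation must
   recover via $E[\mathrm{PLF}] \approx I_1(\kappa)/I_0(\kappa)$, diluted
   by background noise at the coefficient level. Mean directions are equal
   across groups, so phase-angle contrasts are null by construction.
4. **State effects.** Task-state alpha amplitude is multiplied by the
   suppression factor (defaults NC 0.7, SZ 0.95 — the patients' attenuated
   rest–task shift); task-state gamma is boosted ×1.35 in patients
   (elevated induced gamma).
5. **Artifacts.** With probability `artifact_rate` (default 0.08) an epoch
   receives a rectangular 250 µV, 100 ms excursion in one random channel,
   deterministically exercising the >200 µV peak-to-peak rejection rule.

All scalp profiles are centred to zero mean across the 19 channels and
scaled to max |gain| = 1. Centring makes each source dipolar (a polarity
reversal exists on the scalp), which is physically realistic and makes the
profiles exactly invariant under the common-average reference; without it,
re-referencing would cancel most of a spatially coherent source.

Between-subject dispersion comes from a lognormal global amplitude factor
(σ = 0.12) and lognormal κ jitter (σ = 0.15); within-subject dispersion
from a lognormal per-state band-amplitude drift (σ = 0.10) modelling
arousal differences between the two recordings, which keeps mixed-ANOVA F
statistics in a realistic range instead of the near-infinite values a
noise-free within-subject contrast would give. An optional latent factor
(`panss_eeg_corr`) couples these subject-level deviations to the synthetic
five-factor symptom scores for exercising PLSC; it defaults to 0.

Default group effects are sized so that the qualitative case–control
pattern (phase-locking cluster, low-frequency induced/resting clusters,
alpha-band group × state interaction) is reliably recoverable at the
30 + 30 cohort sizes the test suite runs: cluster-level Cohen's d ≈ 1.2–1.5,
larger than typical published effects (d ≈ 0.6–0.75), because a d ≈ 0.7
effect cannot pass a p < 0.001 cluster-forming threshold at n = 30/30. The
generator emulates the spectral, phase-locking and state structure the
analysis consumes — it does not model anatomy-based volume conduction,
ocular/cardiac artifact morphology, non-stationarity within a recording, or
realistic epoch-to-epoch amplitude dynamics, so passing tests certify the
estimators and inference machinery, not performance on real recordings.

## Preprocessing

Zero-phase filtering (forward–backward 4th-order Butterworth 1–100 Hz
band-pass plus a Q = 30 notch at 60 Hz; the two-pass magnitude response is
the squared design response, giving ≥ 40 dB at 0.3 Hz and at 60 Hz and a
ripple-free passband), common average reference, rejection of epochs whose
peak-to-peak amplitude exceeds 200 µV on any channel (strictly greater:
exactly 200 µV is retained), and random subsampling without replacement to
exactly 120 epochs per state (order-preserving, PCG64 generator seeded per
subject and state) so epoch counts cannot bias comparisons. Resting
recordings are segmented into contiguous non-overlapping 1100 ms epochs,
dropping the trailing partial segment. Independent-component artifact
removal is upstream cleaning of real data and is not re-implemented; a
pass-through hook accepts externally cleaned epochs at that point.

## Time–frequency decomposition

Analytic Morlet wavelet $w(t) = g(t)\,e^{2\pi i f t}$ with Gaussian
envelope SD $\sigma_t = n_c/(2\pi f)$, truncated at ±3σ, applied by FFT
convolution. Cycle counts default to $n_c(f) = \max(2, f/4)$ (≈250 ms
windows above 8 Hz); the 38–42 Hz analysis band is insensitive to the
low-frequency choice, and the value is recorded in every run config.
Kernels are amplitude-calibrated (a unit sinusoid at the centre frequency
gives |coefficient| = 1). Bins whose wavelet support extends beyond the
epoch are flagged in an edge mask rather than silently truncated; the
100–500 ms × 38–42 Hz analysis window contains no flagged bins at the
defaults, and window reductions refuse flagged bins. Zero-magnitude
coefficients are treated as missing trials at that bin during PLF
unit-normalization (denominator adjusted), avoiding 0/0 while preserving
PLF ∈ [0, 1]. Angles are reduced by circular mean (argument of summed unit
vectors) over the window *before* subtracting the control-group reference,
and the reference is reduced the same way; PLA uses the single 40 Hz bin,
with the band exposed as an option. Wrapped differences live in (−π, π].

## Spectral estimation

Multitaper PSD with 4 Hz half-bandwidth on 1.1 s epochs: ⌊2·4·1.1⌋ − 1 = 7
Slepian tapers, eigenvalue-weighted (no adaptive weighting), one-sided
V²/Hz normalization (integrating over 0–Nyquist recovers the variance).
The native 0.909 Hz FFT grid is linearly interpolated onto the integer
4–100 Hz bins so spectra align with the time–frequency grid for
clustering. The full 1100 ms task epoch (including prestimulus) enters the
induced PSD, mirroring the epoch definition; a `post_stimulus_only` option
restricts to t ≥ 0. Logs are natural (putting scalp EEG near −20…−27
ln V²/Hz) and guarded at 10⁻³⁰ V²/Hz; floored values are flagged, not
errors. Evoked power, being baseline-subtracted and therefore signed, is
log-compressed at the statistics stage with a signed log1p on the
10⁻¹² V² scale.

## Cluster-based permutation inference

Per-bin two-sided t statistics (pooled-variance two-sample t for group
contrasts, df = n₁+n₂−2; one-sample t on within-subject differences for the
state contrast, df = n−1; zero-variance bins are excluded from forming and
logged). Bins with uncorrected p < 0.001 (two-sided t critical value at the
design's df) are clustered by connected components over the adjacency
graph, positive and negative t separately. The 19-channel spatial adjacency
is a frozen Delaunay-triangulation neighbour table on idealized 10–20
positions, version-controlled in source; electrode × frequency adjacency is
the tensor product (spatial neighbour at the same frequency, or the same
electrode at ±1 Hz — no diagonal links). Cluster significance compares each
observed $T_{sum}$ with the permutation distribution of the largest
$|T_{sum}|$ of either sign (1000 relabelings by default; group labels
shuffled for unpaired designs, within-subject sign flips for paired), with
the add-one convention p = (1 + #{surrogate ≥ observed})/(1 + B), which
keeps the test valid and p > 0. Designs whose permutation space is no
larger than the requested count are enumerated exactly (and then p is the
exact proportion). Partitions are sampled without uniqueness enforcement,
matching common practice. By the exchangeability argument the family-wise
error rate is exact at the cluster-level α; the calibration module measures
it empirically on spatially smoothed Gaussian nulls (unit per-bin variance,
positive neighbour correlation).

## Scalar statistics

Welch t (with Welch–Satterthwaite df) and Pearson chi-square (no continuity
correction, which is what reproduces published 2-d.p. table statistics)
accept raw samples or (n, mean, SD) summaries and go through scipy.
Cohen's d uses the (n−1)-weighted pooled SD; d for phase angles first
z-scores both groups by the control mean/SD of the wrapped angles. The
Watson-Williams test uses the classical F with the 1 + 3/(8κ̂) correction,
κ̂ estimated from the pooled mean resultant length; a resultant length
below 0.45 triggers a warning, not an error. Spearman uses average-rank
ties with Bonferroni-adjusted significance levels (family sizes 5 for
dose–EEG screens, 2 for the phase-locking–gamma screens, fixed at 4 for the
interaction post hocs). The 2×2 mixed ANOVA decomposes sums of squares with
group tested against subjects-within-groups and state/interaction against
the state × subjects error; with two within-subject levels there is no
sphericity to correct, and df₂ = n − 2 for all three effects.

## PLSC

Both blocks are column z-scored; R = XᵀY/(n−1) is the cross-correlation
matrix and R = USVᵀ its SVD, with sign indeterminacy resolved by making the
largest-|element| of each U column positive. Loadings are correlations of
the original variables with the opposite block's latent scores. Permutation
p-values shuffle rows of Y and compare singular values by rank order
(surrogate s_k vs observed s_k), which keeps the leading-component null
uniform; aligning surrogate axes to the observed saliences instead mixes
singular values and was measured to be strongly anti-conservative, so it is
not used. Bootstrap ratios resample subjects with replacement, Procrustes-
rotate each resample's (U, V) onto the original solution (the standard
remedy for axis rotation/reflection across resamples), and divide each
loading's bootstrap mean by its bootstrap SD; |ratio| > 1.96 flags
stability. Degenerate resamples (a single repeated subject or a constant
column) are redrawn. The feature order in the study pipeline is evoked
power per electrode (19), PLF per electrode (19), induced then resting
power per electrode × frequency bin (2 × 1843), with names exported so
loadings are traceable.

## Pipeline and reproducibility

`run_study` executes: the four group cluster tests (evoked power and PLF
over electrodes; induced and resting log-power over electrode × frequency),
cluster-level summaries and Cohen's d ranking (subject values averaged over
cluster members), Watson-Williams + angle effect sizes for PLF-significant
clusters, the paired rest–task-shift cluster test on resting − induced
(positive = task suppression), a mixed ANOVA with Bonferroni post hocs per
shift cluster, the Spearman screens, and PLSC on patients with complete
symptom scores. Every stage is a pure function of (inputs, config, seed):
all randomness flows from `numpy.random.default_rng` seeded hierarchically
from the run seed, and the StudyReport JSON is byte-identical across
reruns. The windowed 40 Hz measures are computed on a wavelet grid
restricted to 38–42 Hz (the only band they consume), keeping a 60-subject
study around a minute; full-grid maps remain available through
`timefreq.subject_tfr_maps`. Figures (topographies, spectra) are
conveniences; no numeric result depends on them.

On-disk formats: a `.npz` + JSON-sidecar array container for epochs and
evoked responses, tidy TSV exports of windowed measures and spectra, and
EDF. EDF reading goes through MNE; writing uses a minimal 16-bit EDF+
writer (one data record per epoch, per-channel physical scaling), round-trip
verified against MNE's reader in the tests.

## Simulation sizes in the test suite

The suite runs scaled-down replicates chosen to keep the default test run
short while leaving every decision threshold untouched: FWER calibration
uses 60 null datasets × 300 permutations in the test (the acceptance script
runs the full 200 × 500 study); power/localization uses 12 replicates of
the 1.5 SD planted patch at n = 30/30; the end-to-end pattern check runs
one 30 + 30 cohort with 500 permutations; byte-identical determinism is
checked on a miniature cohort; PLSC null calibration uses 60 replicate
cohort tables with the generator's subject-level ground-truth parameters
(κ, amplitude factor) as the EEG block — valid because permutation
calibration depends only on row exchangeability of Y, not on the EEG
block's structure.

## Known limitations

- The generator's oscillators are stationary sinusoids with epoch-wise
  random phase; real EEG bands are bursty and broadband.
- The κ → PLF mapping at an electrode is diluted by background noise in the
  wavelet coefficient, so estimated PLF sits below the Bessel-ratio value
  unless the steady-state amplitude dominates (tests that assert the
  Bessel band use high-SNR configurations).
- Spatial structure is a fixed gain profile, not a forward model; channel
  covariance of the background is diagonal.
- The EDF writer targets the plain 16-bit EDF+ continuous layout and does
  not write annotations.
- PLSC loadings' bootstrap ratios are optimistic for components that are
  not themselves significant (loadings are correlations with overfit latent
  scores); component-level permutation p is the gatekeeper.
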