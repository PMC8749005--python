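# Methods

This note documents the models and procedures implemented in
`neurotraj`, the choices made where the design was genuinely open, and —
importantly — what the validation experiments do and do not show.

## Task model

An n-back session consists of runs of fixed component arithmetic:
initial fixation (3 s) + task blocks (60 s each) interleaved with rest
blocks + final fixation. Two variants are supported: *short* (two
blocks/run, 25-s rests, 7-s final fixation; 155-s runs) and *long*
(three blocks/run, 30-s rests, 10-s final fixation; 253 s by the same
arithmetic — the component sum, which is what the generator uses). Each
block opens with a 2-s cue followed by 13 trials: a 0.5-s picture and a
jittered inter-trial fixation in [1.5, 10] s. Load conditions (1-back /
2-back) alternate across blocks within a run, and the starting condition
alternates across runs, so any session with an even block count is
exactly balanced — six blocks per condition gives the canonical 78
trials per condition per session.

**Jitter squeeze.** Thirteen 0.5-s trials with mean-5.75-s uniform
jitters cannot fit a 60-s block; the printed constraints are mutually
inconsistent. The generator samples jitters uniformly on [1.5, 10] and,
when a block's sampled sum would overflow the block window, linearly
compresses the jitters toward the 1.5-s minimum (compression factor
capped at 1). Every ITI stays inside [1.5, 10]; the marginal
distribution is right-shortened rather than exactly uniform.

**Targets.** Each block receives 2–4 repeat (target) trials, placed
uniformly among positions where an n-back repeat is legal, never
adjacent; stimulus identities are drawn from a 120-picture pool with
targets forced to match and non-targets forced to differ from the item
n trials back.

## Hemodynamic response model

The canonical HRF is the double-gamma
h(t) = g(t; 6, 1) − g(t; 16, 1)/6 (gamma densities; shape, scale),
normalized to unit peak, sampled on [0, 32] s at dt = 0.1 s. The
informed basis set adds two finite-difference partial derivatives: a
1-s onset-shift (delay) derivative and a 0.01 dispersion derivative,
both normalized by the canonical peak.

The GLM is beta-series style: every trial contributes three regressors
(stick at onset convolved with each basis function on the dt grid, then
read off at scan times), runs are convolved independently, and each run
adds an intercept. Ordinary least squares per region gives three
coefficients per trial; the trial's evoked response is the
coefficient-weighted basis evaluated at t = TR, 2·TR, …, 9 s.

Two numerical choices deserve note. First, the response window starts at
the first TR *after* onset: all three basis functions vanish identically
at t = 0, so sampling at onset would make every trial's first response
row the exact zero vector — hundreds of coincident points that the
adaptive-bandwidth kernel rightly rejects. Second, if the joint design's
condition number exceeds 1e6 (pathologically short ITIs), the fit falls
back to least-squares-separate (one GLM per trial with the remaining
trials collapsed per condition); on the generated schedules the joint
design stays near condition 1e4 and the primary path is used.

## Synthetic ground truth

Each simulated session draws a smooth 3-D latent trajectory (cubic
spline through 8 random control points, centered on its centroid,
unit mean radius) and assigns one anchor per trial in onset order.
2-back anchors are the same base anchors radially scaled by
`expansion_factor` about the centroid, so planted condition
trajectory lengths are in exactly that ratio; incorrect-trial anchors
shrink by `accuracy_shrink` (default 0.4), planting the
correct > incorrect ordering. Every trial contributes an impulse of its
anchor vector at stimulus onset; latent courses are HRF-convolved,
mapped through a random full-column-rank loading matrix
(regions × 3, entries N(0, 1/√n_regions)), and corrupted with AR(1)
Gaussian noise (coefficient 0.4 — the simplest autocorrelated model of
BOLD noise). The noise level is calibrated to a **trial-level SNR**:
RMS of the noiseless evoked region signal divided by the noise standard
deviation (default 2).

What the generator does **not** emulate: spatially correlated noise,
motion artifacts, biophysical (balloon-model) hemodynamics,
participant-specific HRFs, or behavioral reaction times. Passing tests
therefore demonstrate algorithmic correctness and the statistical
behavior of the chain under idealized noise, not performance on real
fMRI.

## Embedding

The diffusion-potential recipe is implemented from first principles:

1. pairwise Euclidean distances between response samples (features =
   regions);
2. α-decay kernel with adaptive bandwidths ε_i = distance to the
   k-th nearest neighbor (α = 35, k = 10 by default), symmetrized as the
   mean of the two one-sided kernels; duplicate-point bandwidth
   collapse is an error instructing deduplication;
3. row normalization into the diffusion operator P; the spectrum of the
   symmetric conjugate D^{1/2} P D^{-1/2} is cached, giving exact matrix
   powers and the von Neumann entropy curve cheaply;
4. diffusion time t selected at the knee of H(t) (maximum perpendicular
   distance from the chord between t = 1 and t_max = 100) — chosen among
   elbow rules because it is deterministic and parameter-free; a fixed
   t can be supplied instead;
5. potential distances between log-transformed diffusion profiles with
   a γ = 1e-12 floor; a disconnected affinity graph is an error by
   default (components named), while the full recipe runs with the γ
   regularization since α = 35 underflows to exact zeros between
   separated structures;
6. metric MDS: classical scaling initialization refined by SMACOF
   majorization (deterministic, stress non-increasing), dimensions
   ordered by variance. Variance fractions are computed over the five
   embedded coordinates.

Per-region **spatial weights** are the Pearson correlations between each
region's concatenated response course and each embedding coordinate —
the simplest projection consistent with "relative weight" brain maps; it
is a reconstruction, not a published formula.

## What the embedding preserves — measured limits

The validation experiments revealed sharp, reproducible limits on what
trajectory-length ratios survive this class of embedding. These are
properties of the method, not implementation defects; each was isolated
with controlled experiments:

* **Scale normalization.** The adaptive bandwidth makes the kernel
  nearly scale-free: dilating one condition's trajectory rescales its
  bandwidths identically, so a planted radial ratio of 7 embeds at ≈ 1
  on noiseless concentric curves.
* **Log saturation.** Potential distances between well-separated
  structures saturate near √n·|log γ|, bounding any global ratio.
* **Noise ruler.** Summed consecutive-step length over noisy points has
  an additive noise floor; at trial-level SNR 2 the floor exceeds the
  low-load condition's per-step signal, compressing ratios toward 1.
* **Hemodynamic low-pass.** With equal trial counts and fixed session
  duration, traversing more latent arc per unit time pushes the signal
  above the HRF passband; speed-coded expansion beyond ≈ 1.5× is
  attenuated regardless of the embedding.
* Even for two interleaved same-density paths with an exact E-fold arc
  ratio and mild noise (no GLM, no HRF), the full recipe recovers
  roughly √E (measured 1.31 / 1.80 / 3.55 for E = 1.5 / 3 / 7).

Consequently the full pipeline's estimated expansion ratios respond to
the planted factor monotonically but sublinearly and with high seed
variance; `scripts/acceptance.py` reports the measured transfer at the
study conditions rather than asserting linearity. Large published
expansion ratios on real data are, under this analysis, empirical
properties of the data's structure in potential space rather than
linearly preserved latent arc lengths.

## Trajectory statistics and inference

Lengths use the top three embedding dimensions; expansion ratios require
both trajectories to come from the same embedding space (enforced via an
embedding fingerprint). Group-vs-individual distances are index-matched
sums over the shared trial grid, with linear resampling (logged) when
counts differ. Load scaling regresses 2-back distances on 1-back
distances across participants; trajectory–behavior association is a
Pearson correlation of lengths with 2-back accuracy.

Paired t, one- and two-way within-subject ANOVA (no sphericity
correction by default), and Pearson r are implemented directly from
their sums-of-squares / moment formulas — vectorizable for the
10,000-rep null calibrations — and are cross-checked in the test suite
against scipy and statsmodels. The comparison of dependent
non-overlapping correlations uses the Dunn–Clark z with the
Pearson–Filon covariance of the Fisher-transformed estimates; its type-I
error calibrates to 0.05 within Monte-Carlo error at n = 17.
Benjamini–Hochberg adjustment delegates to statsmodels.

## Spectral-kurtosis QC

Convolved stimulus series are screened for sharp edges with short-time
spectral kurtosis: Hann-tapered frames (64 samples, 50 % overlap; both
config-exposed), SK(f) = ⟨|X|⁴⟩/⟨|X|²⟩² − 2 over interior frequency bins
(DC and Nyquist excluded — their coefficients are real, so the
complex-Gaussian null does not apply). A frame is flagged when its mean
normalized power excess exceeds 3·√(4/M) (three asymptotic null SDs of
SK for M frames); the per-session report is the flagged-frame
percentage with a < 7 % pass mark. The estimator settings are this
package's reconstruction — no published settings exist for the original
QC step — so the per-session percentages are comparable only in kind,
not digit-for-digit. On short series the window is halved until at least
four frames fit, and with few frames the percentage is necessarily
coarse (one frame in eight reads as 12.5 %).

## Problem sizes

Tests and the acceptance script run at desk scale: short-variant
sessions (two runs, 26 trials per condition, 468-point embeddings),
17-participant cohorts, 3 cohort seeds per planted factor, 10,000-rep
statistical nulls, 1,000-rep QC nulls. The pipeline defaults remain the
full study conditions (long variant, 78 trials per condition, 17
participants, three sessions with planted ratios 1.3 / 1.5 / 7.3).

## Known limitations

* The parameter-recovery experiment does not reach ±20 % fidelity for
  planted factors of 3–7; see "measured limits" above for the mechanism.
* The robustness sweep over α ∈ {35…50} × k ∈ {6, 8, 10} shows large
  (> 2×) variation in estimated ratios on single-session fixtures — the
  same instability, reported rather than hidden.
* Group embeddings of full 17-participant concatenations (≈ 24k points)
  are outside the dense-eigendecomposition budget; the shared-space
  group analysis runs when the pooled point count is at most
  `max_embed_points` (default 6000) and is skipped, with a log message,
  otherwise.
* fMRI preprocessing (motion correction, nuisance regression,
  parcellation from voxel images) is out of scope; inputs are already
  parcellated matrices.
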