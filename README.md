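# neurotraj

Low-dimensional trajectories of task-evoked brain activity: trial-locked
hemodynamic response estimation, a from-scratch diffusion-potential
manifold embedding, trajectory geometry statistics, spectral-kurtosis QC,
and the matching inferential battery — exercised end-to-end on synthetic
parcellated BOLD cohorts with planted ground truth.

## The scientific problem

Working-memory fMRI experiments (the n-back task: respond whether the
current picture matches the one *n* trials back) evoke distributed
activity across hundreds of cortical parcels, yet that activity is
largely confined to a low-dimensional manifold. A useful summary of a
task condition is the **state-space trajectory**: the time-ordered path
of embedded brain states during its trials. Its **length**, and the
**expansion ratio** between conditions (2-back / 1-back), quantify how
the system reconfigures under cognitive load — and how that
reconfiguration changes when local neural activity is perturbed
(e.g. by theta-burst TMS over a task-relevant region).

This package implements the full analysis chain for parcellated BOLD
time series (333 cortical regions, TR = 1 s by default):

1. **Task design** (`task_design`): block-structured n-back session
   schedules (13 trials per 60-s block, 0.5-s stimuli, jittered 1.5–10-s
   ITIs; 78 trials per load condition per session), BIDS-style events
   TSV round-tripping.
2. **Response estimation** (`response_estimation`): beta-series GLM with
   the informed basis set — canonical double-gamma HRF
   h(t) = g(t; 6, 1) − g(t; 16, 1)/6 (unit peak) plus its partial
   derivatives w.r.t. onset delay and dispersion; per trial, the evoked
   response over the first 9 s is reconstructed from the three fitted
   coefficients and concatenated by condition × accuracy cell.
3. **Embedding** (`phate_embed`): diffusion-potential embedding built
   from first principles — α-decay kernel
   K_ij = ½e^−(d_ij/ε_i)^α + ½e^−(d_ij/ε_j)^α with adaptive bandwidths
   ε_i (distance to the k-th neighbor; α = 35, k = 10), row-stochastic
   diffusion operator, diffusion time t from the knee of the von Neumann
   entropy of the operator spectrum, potential distances
   U_ij = ‖log(P^t_i + γ) − log(P^t_j + γ)‖₂, and metric MDS
   (classical-scaling initialization + SMACOF stress majorization) into
   5 dimensions, the top 3 carrying the trajectories.
4. **Trajectory geometry** (`trajectory_metrics`): path lengths
   Σ‖x_{i+1} − x_i‖₂ in the top three dimensions, expansion ratios,
   group-vs-individual summed Euclidean distances, load scaling,
   trajectory–behavior correlations.
5. **Inference** (`stats_infer`): two-sided paired t, within-subject
   (repeated-measures) ANOVA, Pearson r, the Dunn–Clark z for dependent
   non-overlapping correlations, Benjamini–Hochberg FDR.
6. **QC** (`qc_spectral`): spectral-kurtosis detection of sharp edges in
   the HRF-convolved stimulus series, with a < 7 % pass criterion.
7. **Synthetic cohorts** (`synthetic_data`): sessions with a *planted*
   low-dimensional ground truth — a smooth 3-D latent trajectory whose
   2-back segment is radially expanded by a chosen factor — so the whole
   chain can be scored against known answers.

`pipeline_cli` orchestrates everything (`neurotraj run`), writes tidy
CSV/JSON artifacts plus a reproducibility manifest, and summarizes
per-region embedding weights over the four Gordon-parcellation network
communities (Sensory, Associative, Default, Non-hub).

## Worked example

```python
import neurotraj as nt

cfg = nt.PipelineConfig(
    participants=10, sessions=("baseline", "S1", "iPS"),
    expansion=(1.3, 1.5, 7.3),       # planted 2-back/1-back ratios
    variant="short", n_runs=2,       # 26 trials per condition per session
    n_regions=333, seed=1, output_dir="demo_run",
)
result = nt.run_pipeline(cfg)
for s in cfg.sessions:
    print(s, round(result.session_ratio(s), 3))
```

prints (seed 1):

```
baseline: median expansion ratio 0.874
S1: median expansion ratio 1.618
iPS: median expansion ratio 1.093
 session  flagged_pct  passed
baseline         12.5   False
      S1         12.5   False
     iPS         12.5   False
rm_anova:load_diff_by_session: stat=0.449 p=0.645
paired_t:baseline:2b_gt_1b: stat=-0.611 p=0.557 p_FDR=0.742
...
dunn_clark:baseline_vs_iPS: stat=-1.230 p=0.219 p_FDR=0.51
```

Reading this output: the per-session medians are the cohort's estimated
2-back/1-back trajectory-length ratios for correct trials. They are
*not* close to the planted factors — the adaptive-bandwidth embedding
largely normalizes planted length ratios away (measured and analyzed in
`docs/methods.md`; the estimates respond to the planted factor only
sublinearly and noisily). The QC block flags sharp-edge frames in each
session's convolved stimulus series (on this short two-run series only
8 STFT frames exist, so one flagged frame already reads as 12.5 %; the
standard four-run series passes well under the 7 % criterion). The
statistics block reports the paired load contrasts, the session ANOVA on
load differences, per-session trajectory–behavior correlations, and the
Dunn–Clark comparison of the baseline and iPS correlations, all BH-FDR
adjusted within their family.

A command-line surface mirrors the library:

```bash
neurotraj make-schedule --variant long --seed 7 --out events.tsv
neurotraj simulate --participants 2 --sessions baseline,iPS --expansion 1.3,7.3 --out data/
neurotraj estimate --ts data/sub-00_baseline.ts.tsv --events data/sub-00_baseline.events.tsv --out resp.tsv
neurotraj embed --responses resp.tsv --alpha 35 --knn 10 --out embed.csv
neurotraj metrics --embedding embed.csv --out lengths.csv
neurotraj run --participants 4 --seed 1 --out run_out/
```

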