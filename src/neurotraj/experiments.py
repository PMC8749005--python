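"""Validation experiments: parameter-recovery, statistical calibration, QC.

These are the package's own end-to-end checks, runnable at configurable
problem sizes: they generate synthetic cohorts with planted ground truth,
run the full estimation -> embedding -> geometry pipeline, and report how
faithfully planted quantities are recovered; and they calibrate the
inferential battery under its null hypotheses by vectorized Monte Carlo.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .phate_embed import PhateParams, phate
from .qc_spectral import spectral_kurtosis
from .response_estimation import build_design_matrix, build_hrf_basis, fit_trial_responses
from .synthetic_data import TruthParams, simulate_session
from .task_design import TaskConfig, generate_schedule
from .trajectory_metrics import expansion_ratio, trajectory_from_embedding

__all__ = [
    "participant_expansion_ratio",
    "cohort_median_ratio",
    "expansion_recovery",
    "session_ordering_fraction",
    "paired_t_type_one_error",
    "rm_anova_type_one_error",
    "dependent_corr_type_one_error",
    "qc_null_false_flag_rate",
    "qc_flagged_percent",
    "convolved_stimulus_series",
]


def _child_seed(*keys) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# parameter recovery through the full pipeline
# --------------------------------------------------------------------------

def participant_expansion_ratio(config: TaskConfig, truth: TruthParams, seed: int,
                                phate_params: PhateParams | None = None) -> float:
    """Simulate one participant-session and push it through estimation,
    embedding and trajectory geometry; return the estimated correct-trial
    2-back / 1-back length ratio."""
    phate_params = phate_params or PhateParams()
    sim = simulate_session(config, truth, seed=seed)
    basis = build_hrf_basis(dt=0.1)
    design = build_design_matrix(sim.schedule, basis, n_scans=sim.ts.n_time, tr=sim.ts.tr)
    responses = fit_trial_responses(sim.ts, design, basis)
    emb = phate(responses.values, phate_params)
    t2 = trajectory_from_embedding(emb, responses.sample_labels,
                                   condition="2back", accuracy="correct")
    t1 = trajectory_from_embedding(emb, responses.sample_labels,
                                   condition="1back", accuracy="correct")
    return expansion_ratio(t2, t1)


def cohort_median_ratio(expansion: float, seed: int, participants: int = 17,
                        config: TaskConfig | None = None, snr: float = 2.0) -> float:
    """Median estimated expansion ratio across a synthetic cohort."""
    config = config or TaskConfig.for_variant("short", n_runs=2)
    truth = TruthParams(expansion_factor=expansion, snr=snr)
    ratios = [
        participant_expansion_ratio(config, truth, seed=_child_seed(seed, p))
        for p in range(participants)
    ]
    return float(np.median(ratios))


def expansion_recovery(expansions=(1.5, 3.0, 7.0), n_seeds: int = 3,
                       participants: int = 17, config: TaskConfig | None = None,
                       snr: float = 2.0, base_seed: int = 0) -> dict:
    """Planted-vs-recovered expansion factors (median over seeds of the
    cohort-median estimated ratio)."""
    out = {}
    for E in expansions:
        meds = [
            cohort_median_ratio(E, seed=_child_seed(base_seed, k, int(E * 10)),
                                participants=participants, config=config, snr=snr)
            for k in range(n_seeds)
        ]
        out[E] = float(np.median(meds))
    return out


def session_ordering_fraction(expansions=(1.3, 1.5, 7.3), n_seeds: int = 3,
                              participants: int = 17,
                              config: TaskConfig | None = None,
                              snr: float = 2.0, base_seed: int = 1000) -> float:
    """Fraction of seeds in which the session ordering of cohort-median
    estimated ratios matches the planted ordering."""
    hits = 0
    for k in range(n_seeds):
        meds = [
            cohort_median_ratio(E, seed=_child_seed(base_seed, k, s_idx),
                                participants=participants, config=config, snr=snr)
            for s_idx, E in enumerate(expansions)
        ]
        if all(meds[i] < meds[i + 1] for i in range(len(meds) - 1)):
            hits += 1
    return hits / n_seeds


# --------------------------------------------------------------------------
# null calibration of the inferential battery (vectorized Monte Carlo)
# --------------------------------------------------------------------------

def paired_t_type_one_error(n: int = 17, reps: int = 10_000, alpha: float = 0.05,
                            seed: int = 0) -> float:
    """Empirical rejection rate of the paired t-test under its null."""
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((reps, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    return float(np.mean(p < alpha))


def rm_anova_type_one_error(n: int = 17, k: int = 3, reps: int = 10_000,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical rejection rate of the one-way within-subject ANOVA under
    an exchangeable null (i.i.d. Gaussian cells plus subject effects)."""
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((reps, n, k)) + rng.standard_normal((reps, n, 1))
    grand = Y.mean(axis=(1, 2), keepdims=True)
    ss_subj = k * ((Y.mean(axis=2, keepdims=True) - grand) ** 2).sum(axis=(1, 2))
    ss_cond = n * ((Y.mean(axis=1, keepdims=True) - grand) ** 2).sum(axis=(1, 2))
    ss_total = ((Y - grand) ** 2).sum(axis=(1, 2))
    ss_err = ss_total - ss_subj - ss_cond
    F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    p = sps.f.sf(F, k - 1, (n - 1) * (k - 1))
    return float(np.mean(p < alpha))


def dependent_corr_type_one_error(n: int = 17, reps: int = 10_000, rho: float = 0.3,
                                  alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical rejection rate of the Dunn-Clark z under a null where both
    non-overlapping correlations are truly equal (block-diagonal Gaussian
    cohort: corr(x1,x2) = corr(x3,x4) = rho, blocks independent)."""
    rng = np.random.default_rng(seed)
    cov = np.eye(4)
    cov[0, 1] = cov[1, 0] = rho
    cov[2, 3] = cov[3, 2] = rho
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((reps, n, 4)) @ L.T
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    def corr(i, j):
        return (Xc[:, :, i] * Xc[:, :, j]).mean(axis=1) / (sd[:, i] * sd[:, j])
    r12, r34 = corr(0, 1), corr(2, 3)
    r13, r14, r23, r24 = corr(0, 2), corr(0, 3), corr(1, 2), corr(1, 3)
    psi = (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24 + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r34 * r13 * r23 + r34 * r14 * r24)
    )
    c = np.clip(psi / ((1 - r12**2) * (1 - r34**2)), -0.999999, 0.999999)
    z = (np.arctanh(np.clip(r12, -0.999999, 0.999999))
         - np.arctanh(np.clip(r34, -0.999999, 0.999999))) * np.sqrt((n - 3) / (2 - 2 * c))
    p = 2.0 * sps.norm.sf(np.abs(z))
    return float(np.mean(p < alpha))


# --------------------------------------------------------------------------
# spectral-kurtosis QC behavior
# --------------------------------------------------------------------------

def qc_null_false_flag_rate(reps: int = 1000, n_samples: int = 1024,
                            window_len: int = 64, overlap: float = 0.5,
                            seed: int = 0) -> float:
    """Fraction of frames flagged on pure white-Gaussian-noise series."""
    rng = np.random.default_rng(seed)
    flagged = 0
    total = 0
    for _ in range(reps):
        res = spectral_kurtosis(rng.standard_normal(n_samples), window_len, overlap)
        flagged += int(res.flagged.sum())
        total += res.n_frames
    return flagged / total


def convolved_stimulus_series(config: TaskConfig | None = None, seed: int = 0) -> np.ndarray:
    """Canonical-HRF-convolved stimulus train of a generated schedule — the
    series whose sharp-edge content the QC step audits."""
    config = config or TaskConfig.for_variant("long", seed=seed)
    schedule = generate_schedule(config)
    basis = build_hrf_basis(dt=0.1)
    n_scans = int(np.round(schedule.total_duration_s))
    design = build_design_matrix(schedule, basis, n_scans=n_scans, tr=1.0)
    cols = [i for i, lab in enumerate(design.column_labels)
            if lab[0] == "trial" and lab[2] == "canonical"]
    return design.X[:, cols].sum(axis=1)


def qc_flagged_percent(x: np.ndarray, window_len: int = 64, overlap: float = 0.5) -> float:
    return 100.0 * spectral_kurtosis(np.asarray(x, float), window_len, overlap).flagged_fraction
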