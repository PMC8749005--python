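"""Trial-locked BOLD response estimation with an informed HRF basis set.

Each stimulus onset is convolved with the canonical double-gamma HRF plus
its partial derivatives with respect to onset delay and dispersion, giving
three regressors per trial (beta-series style: every trial gets its own
regressor triplet inside one per-session GLM).  After ordinary least
squares, the evoked response of a trial in a region is the basis functions
weighted by that trial's three coefficients, evaluated over the first 9 s
after onset at the TR; trial responses are concatenated by condition x
accuracy cell to form the input of the manifold embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .containers import ResponseMatrix, TimeSeriesMatrix
from .exceptions import ConfigurationError, ContractError
from .task_design import TaskSchedule

__all__ = [
    "HRFBasis",
    "DesignMatrix",
    "build_hrf_basis",
    "build_design_matrix",
    "fit_trial_responses",
    "concatenate_group",
]

logger = logging.getLogger(__name__)

BASIS_NAMES = ("canonical", "delay", "dispersion")


@dataclass
class HRFBasis:
    """Canonical double-gamma HRF and its delay/dispersion derivatives,
    sampled on a regular grid [0, duration_s] with step ``dt``."""

    dt: float
    t: np.ndarray
    canonical: np.ndarray
    delay_derivative: np.ndarray
    dispersion_derivative: np.ndarray
    duration_s: float = 32.0

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.canonical, self.delay_derivative, self.dispersion_derivative])

    def sample_window(self, tr: float, window_s: float) -> np.ndarray:
        """Basis functions at t = tr, 2*tr, ..., window_s (rows x 3).

        The grid starts at the first TR after onset rather than at onset
        itself: all three basis functions vanish identically at t = 0, so
        an onset sample would make every trial's first response point the
        exact zero vector (a degenerate duplicate for the embedding).
        """
        n = int(np.floor(window_s / tr))
        idx = np.round((np.arange(1, n + 1)) * tr / self.dt).astype(int)
        return self.as_matrix()[idx]


def _double_gamma(t: np.ndarray, peak_delay=6.0, undershoot_delay=16.0,
                  peak_disp=1.0, undershoot_disp=1.0, ratio=6.0) -> np.ndarray:
    """Unnormalized canonical HRF: gamma-density peak minus scaled undershoot."""
    h = gamma_dist.pdf(t, peak_delay, scale=peak_disp) - gamma_dist.pdf(
        t, undershoot_delay, scale=undershoot_disp
    ) / ratio
    return np.where(t >= 0, h, 0.0)


def build_hrf_basis(dt: float = 0.1, duration_s: float = 32.0,
                    delay_step: float = 1.0, dispersion_step: float = 0.01) -> HRFBasis:
    """Construct the informed basis set on a fine time grid.

    The canonical response is normalized to unit peak; the delay derivative
    is a finite difference under a ``delay_step`` onset shift, and the
    dispersion derivative a finite difference under a ``dispersion_step``
    change of the peak dispersion (both normalized by the canonical peak so
    the three functions share one scale).
    """
    if dt <= 0:
        raise ConfigurationError(f"dt: must be positive, got {dt}")
    t = np.arange(0.0, duration_s + dt / 2, dt)
    h_raw = _double_gamma(t)
    peak = h_raw.max()
    h = h_raw / peak
    h_shift = _double_gamma(t - delay_step) / peak
    delay = (h - h_shift) / delay_step
    h_disp = _double_gamma(t, peak_disp=1.0 + dispersion_step) / peak
    dispersion = (h - h_disp) / dispersion_step
    return HRFBasis(
        dt=dt,
        t=t,
        canonical=h,
        delay_derivative=delay,
        dispersion_derivative=dispersion,
        duration_s=duration_s,
    )


@dataclass
class DesignMatrix:
    """GLM design: three basis regressors per modeled trial plus one
    intercept per run, sampled at the TR."""

    X: np.ndarray
    column_labels: list[tuple]
    n_scans: int
    tr: float
    trial_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self) -> int:
        return len(self.trial_table)

    def trial_columns(self, trial_idx: int) -> list[int]:
        return [
            i for i, lab in enumerate(self.column_labels)
            if lab[0] == "trial" and lab[1] == trial_idx
        ]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.X))


def build_design_matrix(schedule: TaskSchedule, basis: HRFBasis, n_scans: int,
                        tr: float = 1.0) -> DesignMatrix:
    """Convolve trial onsets with the basis set, per run, and resample at TR.

    Convolution happens on the basis' fine ``dt`` grid so jittered onsets
    are represented exactly (to dt resolution), then columns are read off
    at scan times.  Runs are modeled independently (no convolution bleed
    across run boundaries) and each run contributes an intercept column.
    """
    trials = schedule.trials
    run_durations = np.asarray(schedule.run_duration_s, dtype=float)
    n_runs = len(run_durations)
    run_offsets = np.concatenate([[0.0], np.cumsum(run_durations)])
    total_duration = n_scans * tr
    abs_onsets = schedule.absolute_onsets()
    late = np.nonzero(abs_onsets + basis.dt > total_duration)[0]
    if late.size:
        raise ContractError(
            f"events beyond scan end ({total_duration}s): trial indices {late.tolist()}"
        )

    dt = basis.dt
    B = basis.as_matrix()
    n_trials = len(trials)
    X = np.zeros((n_scans, 3 * n_trials + n_runs))
    scan_times = np.arange(n_scans) * tr
    labels: list[tuple] = []
    for i in range(n_trials):
        labels.extend(("trial", i, name) for name in BASIS_NAMES)

    for run in range(n_runs):
        run_start = run_offsets[run]
        run_end = min(run_offsets[run + 1], total_duration)
        n_fine = int(np.round((run_end - run_start) / dt))
        in_run = np.nonzero(trials["run"].to_numpy() == run)[0]
        scan_mask = (scan_times >= run_start - 1e-9) & (scan_times < run_end - 1e-9)
        scan_idx = np.nonzero(scan_mask)[0]
        fine_idx = np.round((scan_times[scan_idx] - run_start) / dt).astype(int)
        for i in in_run:
            onset_in_run = float(trials["onset"].iloc[i])
            stick = np.zeros(n_fine)
            k = int(np.round(onset_in_run / dt))
            if k >= n_fine:
                raise ContractError(f"event beyond run end: trial index {int(i)}")
            stick[k] = 1.0
            for b in range(3):
                conv = np.convolve(stick, B[:, b])[:n_fine]
                X[scan_idx, 3 * i + b] = conv[fine_idx]
        X[scan_idx, 3 * n_trials + run] = 1.0
    for run in range(n_runs):
        labels.append(("intercept", run))

    nonzero = np.abs(X).sum(axis=0) > 0
    if not np.all(nonzero):
        bad = [labels[i] for i in np.nonzero(~nonzero)[0]]
        raise ContractError(f"all-zero design columns: {bad}")
    return DesignMatrix(
        X=X,
        column_labels=labels,
        n_scans=n_scans,
        tr=tr,
        trial_table=trials.copy(),
    )


def fit_trial_responses(ts: TimeSeriesMatrix, design: DesignMatrix, basis: HRFBasis,
                        window_s: float = 9.0,
                        max_condition_number: float = 1e6) -> ResponseMatrix:
    """OLS beta-series fit and per-trial evoked-response reconstruction.

    Returns trial responses evaluated on [0, window_s) at the TR,
    concatenated in onset order within each condition x accuracy cell
    (cells ordered by condition then accuracy).  If the joint design is
    ill-conditioned beyond ``max_condition_number``, falls back to a
    least-squares-separate fit (one GLM per trial, remaining trials
    collapsed into per-condition regressors).
    """
    if ts.n_time != design.n_scans:
        raise ContractError(
            f"time-series length {ts.n_time} != design n_scans {design.n_scans}"
        )
    X = design.X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.column_labels)
        raise ContractError(f"rank-deficient design matrix; collinear columns: {bad}")
    Y = ts.data.T  # scans x regions
    cond = design.condition_number()
    if cond > max_condition_number:
        logger.warning(
            "design condition number %.3g > %.3g; using least-squares-separate fits",
            cond, max_condition_number,
        )
        betas = _fit_lss(X, Y, design)
    else:
        betas, *_ = np.linalg.lstsq(X, Y, rcond=None)

    B_win = basis.sample_window(design.tr, window_s)  # samples_per_trial x 3
    n_win = B_win.shape[0]
    trials = design.trial_table
    order = _cell_order(trials)
    blocks = []
    label_rows = []
    for i in order:
        cols = design.trial_columns(i)
        resp = B_win @ betas[cols]  # n_win x regions
        blocks.append(resp)
        for t_idx in range(n_win):
            label_rows.append(
                {
                    "trial": int(i),
                    "condition": trials["trial_type"].iloc[i],
                    "accuracy": trials["accuracy"].iloc[i],
                    "session": ts.session,
                    "participant": ts.participant,
                    "t_index": t_idx,
                }
            )
    values = np.vstack(blocks) if blocks else np.empty((0, ts.n_regions))
    return ResponseMatrix(
        values=values,
        sample_labels=pd.DataFrame(label_rows),
        tr=design.tr,
        window_s=window_s,
        region_names=list(ts.region_names),
        meta={"design_condition_number": cond, "fit": "lss" if cond > max_condition_number else "ols"},
    )


def _cell_order(trials: pd.DataFrame) -> list[int]:
    """Trial indices grouped by (condition, accuracy), onset order within."""
    order: list[int] = []
    conditions = sorted(trials["trial_type"].unique())
    accuracies = [a for a in ("correct", "incorrect", "unset") if a in set(trials["accuracy"])]
    abs_pos = np.lexsort((trials["onset"].to_numpy(), trials["run"].to_numpy()))
    for cond in conditions:
        for acc in accuracies:
            for i in abs_pos:
                if trials["trial_type"].iloc[i] == cond and trials["accuracy"].iloc[i] == acc:
                    order.append(int(i))
    return order


def _collinear_columns(X: np.ndarray, labels: list) -> list:
    """Name columns involved in exact linear dependence via QR pivoting."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    return [labels[i] for i in piv[rank:]]


def _fit_lss(X: np.ndarray, Y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Least-squares-separate: per trial, keep its three columns and collapse
    all other trials of each condition into summed regressors."""
    trials = design.trial_table
    n_cols = X.shape[1]
    betas = np.zeros((n_cols, Y.shape[1]))
    intercept_cols = [i for i, lab in enumerate(design.column_labels) if lab[0] == "intercept"]
    conditions = sorted(trials["trial_type"].unique())
    for i in range(len(trials)):
        own = design.trial_columns(i)
        others = []
        for cond in conditions:
            idxs = [
                j for j in range(len(trials))
                if j != i and trials["trial_type"].iloc[j] == cond
            ]
            if idxs:
                cols = np.concatenate([design.trial_columns(j) for j in idxs])
                collapsed = X[:, cols].reshape(X.shape[0], -1, 3).sum(axis=1)
                others.append(collapsed)
        X_i = np.column_stack([X[:, own]] + others + [X[:, intercept_cols]])
        beta_i, *_ = np.linalg.lstsq(X_i, Y, rcond=None)
        betas[own] = beta_i[:3]
    return betas


def concatenate_group(responses: list[ResponseMatrix], mode: str = "per_session") -> ResponseMatrix:
    """Row-wise concatenation of response matrices (same regions and TR).

    ``per_session`` tags the result as a within-session group matrix;
    ``shared`` marks data pooled across sessions for a common embedding
    space.  Both concatenate identically — the mode is recorded so
    downstream trajectory comparisons can verify the embedding space.
    """
    if mode not in ("per_session", "shared"):
        raise ConfigurationError(f"mode: must be 'per_session' or 'shared', got {mode!r}")
    if not responses:
        raise ContractError("no response matrices to concatenate")
    first = responses[0]
    for r in responses[1:]:
        if r.region_names != first.region_names:
            raise ContractError("region sets differ across response matrices")
        if not np.isclose(r.tr, first.tr):
            raise ContractError("TR differs across response matrices")
    values = np.vstack([r.values for r in responses])
    labels = pd.concat([r.sample_labels for r in responses], ignore_index=True)
    return ResponseMatrix(
        values=values,
        sample_labels=labels,
        tr=first.tr,
        window_s=first.window_s,
        region_names=list(first.region_names),
        meta={"mode": mode, "n_inputs": len(responses)},
    )
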