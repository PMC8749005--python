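"""Synthetic parcellated BOLD sessions with known low-dimensional structure.

The generator plants an analytic ground truth so every downstream stage of
the pipeline can be scored against it:

* a smooth 3-D latent trajectory (cubic spline through random control
  points, centered on its centroid) supplies one latent anchor per trial,
  in onset order within each load condition;
* high-load (2-back) anchors are the low-load anchors radially scaled by
  ``expansion_factor`` about the trajectory centroid, so the planted
  trajectory length ratio between conditions is the factor (exactly, for
  matched accuracy patterns; up to the accuracy subsetting otherwise);
* incorrect-trial anchors shrink by ``accuracy_shrink`` (< 1), planting
  the correct > incorrect length ordering;
* each trial contributes an impulse of its anchor vector at stimulus
  onset; latent courses map to regions through a full-column-rank loading
  matrix, are convolved with the canonical HRF, and receive AR(1)
  Gaussian noise calibrated to a trial-level SNR (RMS of the noiseless
  evoked signal over the noise standard deviation).

Toy manifolds (noisy curve, Gaussian blobs, two separated clusters) back
the embedding tests with simple known geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import TimeSeriesMatrix
from .exceptions import ConfigurationError, ContractError
from .response_estimation import build_hrf_basis
from .task_design import TaskConfig, TaskSchedule, generate_schedule, label_accuracy

__all__ = [
    "TruthParams",
    "GroundTruth",
    "SimulatedSession",
    "simulate_session",
    "make_toy_manifold",
]


@dataclass(frozen=True)
class TruthParams:
    """Knobs of the planted ground truth.

    ``snr`` is the trial-level signal-to-noise ratio: RMS of the noiseless
    evoked region signal over the noise standard deviation.  If
    ``noise_sd`` is given it overrides ``snr``.
    """

    n_regions: int = 333
    latent_dim: int = 3
    expansion_factor: float = 1.3
    accuracy_shrink: float = 0.4
    accuracy_rate: float = 0.85
    snr: float = 2.0
    noise_sd: float | None = None
    ar1_coef: float = 0.4

    def validate(self) -> None:
        if self.expansion_factor <= 0:
            raise ConfigurationError(f"expansion_factor: must be > 0, got {self.expansion_factor}")
        if not 0 <= abs(self.ar1_coef) < 1:
            raise ConfigurationError(f"ar1_coef: must satisfy |phi| < 1, got {self.ar1_coef}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.noise_sd is None and self.snr <= 0:
            raise ConfigurationError(f"snr: must be > 0, got {self.snr}")
        if self.n_regions < self.latent_dim:
            raise ConfigurationError(
                f"n_regions: must be >= latent_dim, got {self.n_regions} < {self.latent_dim}"
            )
        if self.accuracy_shrink <= 0:
            raise ConfigurationError(f"accuracy_shrink: must be > 0, got {self.accuracy_shrink}")


@dataclass
class GroundTruth:
    """Planted latent structure of one simulated session."""

    latent_dim: int
    expansion_factor: float
    loading_matrix: np.ndarray  # regions x latent_dim
    noise_sd: float
    ar1_coef: float
    accuracy_shrink: float
    seed: int
    # (condition, accuracy) -> ordered latent anchor points, one per trial
    latent_trajectories: dict = field(default_factory=dict)
    latent_courses: np.ndarray | None = None  # n_scans x latent_dim, noiseless

    def analytic_length(self, condition: str, accuracy: str = "correct") -> float:
        """Chord-sum arc length of the planted anchor path for one cell."""
        pts = self.latent_trajectories[(condition, accuracy)]
        if len(pts) < 2:
            raise ContractError("need >= 2 anchors for a length")
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def analytic_expansion_ratio(self, accuracy: str = "correct") -> float:
        return self.analytic_length("2back", accuracy) / self.analytic_length("1back", accuracy)


@dataclass
class SimulatedSession:
    ts: TimeSeriesMatrix
    schedule: TaskSchedule
    truth: GroundTruth


def _smooth_base_curve(n_points: int, rng: np.random.Generator, n_ctrl: int = 8) -> np.ndarray:
    """Smooth random 3-D curve through ``n_ctrl`` control points, centered
    on its centroid and scaled to unit mean radius."""
    ctrl = rng.standard_normal((n_ctrl, 3)).cumsum(axis=0)
    spline = CubicSpline(np.linspace(0.0, 1.0, n_ctrl), ctrl, axis=0)
    pts = spline(np.linspace(0.0, 1.0, n_points))
    pts -= pts.mean(axis=0)
    scale = np.mean(np.linalg.norm(pts, axis=1))
    return pts / scale


def simulate_session(config: TaskConfig, truth_params: TruthParams = TruthParams(),
                     seed: int = 0, session_label: str = "baseline",
                     participant: str = "sub-00") -> SimulatedSession:
    """Simulate one participant-session of parcellated BOLD data.

    Region signals are the HRF-convolved latent anchor impulses mapped
    through the loading matrix, plus AR(1) Gaussian noise; the returned
    :class:`GroundTruth` carries the planted anchors and their analytic
    lengths.  Bit-reproducible for fixed seeds.
    """
    truth_params.validate()
    rng = np.random.default_rng(seed)
    cfg = TaskConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
    schedule = generate_schedule(cfg, session_label=session_label)
    schedule = label_accuracy(schedule, truth_params.accuracy_rate, seed=int(rng.integers(2**31)))

    trials = schedule.trials
    tr = 1.0
    n_scans = int(np.round(schedule.total_duration_s / tr))

    loading = rng.standard_normal((truth_params.n_regions, truth_params.latent_dim))
    loading /= np.sqrt(truth_params.n_regions)
    if np.linalg.matrix_rank(loading) < truth_params.latent_dim:
        raise ContractError("degenerate loading matrix (rank-deficient)")

    # one latent anchor per trial of each condition: the same base curve for
    # both conditions (centered, so radial scaling about the centroid equals
    # scaling about the origin), expanded for 2-back, shrunk for errors
    latent_trajectories: dict = {}
    anchors = np.zeros((len(trials), truth_params.latent_dim))
    cond_order = np.argsort(schedule.absolute_onsets()) if len(trials) else np.array([], int)
    counts = trials["trial_type"].value_counts() if len(trials) else {}
    max_count = int(max(counts.values)) if len(trials) else 0
    base_curve = _smooth_base_curve(max(max_count, 4), rng) if max_count else None
    for condition in ("1back", "2back"):
        idx = [i for i in cond_order if trials["trial_type"].iloc[i] == condition]
        if not idx:
            continue
        scale = 1.0 if condition == "1back" else truth_params.expansion_factor
        cond_anchors = base_curve[: len(idx)] * scale
        for j, i in enumerate(idx):
            a = cond_anchors[j]
            if trials["accuracy"].iloc[i] == "incorrect":
                a = a * truth_params.accuracy_shrink
            anchors[i] = a
        for accuracy in ("correct", "incorrect", "unset"):
            sel = [j for j, i in enumerate(idx) if trials["accuracy"].iloc[i] == accuracy]
            if len(sel) >= 2:
                shrink = truth_params.accuracy_shrink if accuracy == "incorrect" else 1.0
                latent_trajectories[(condition, accuracy)] = cond_anchors[sel] * shrink
        latent_trajectories[(condition, "all")] = np.array([anchors[i] for i in idx])

    # latent impulse course convolved with the canonical HRF on a fine grid
    dt = 0.1
    basis = build_hrf_basis(dt=dt)
    n_fine = int(np.round(schedule.total_duration_s / dt))
    latent_fine = np.zeros((n_fine, truth_params.latent_dim))
    abs_onsets = schedule.absolute_onsets()
    for i in range(len(trials)):
        k = int(np.round(abs_onsets[i] / dt))
        if k < n_fine:
            latent_fine[k] += anchors[i]
    for d in range(truth_params.latent_dim):
        latent_fine[:, d] = np.convolve(latent_fine[:, d], basis.canonical)[:n_fine]
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    latent_courses = latent_fine[scan_idx]

    clean = latent_courses @ loading.T  # scans x regions
    rms = float(np.sqrt(np.mean(clean**2))) if clean.size else 0.0
    if truth_params.noise_sd is not None:
        noise_sd = truth_params.noise_sd
    else:
        noise_sd = rms / truth_params.snr if rms > 0 else 0.0

    noise = np.zeros_like(clean)
    if noise_sd > 0:
        phi = truth_params.ar1_coef
        innov_sd = noise_sd * np.sqrt(1.0 - phi**2)
        w = rng.normal(0.0, innov_sd, size=clean.shape)
        noise[0] = rng.normal(0.0, noise_sd, size=clean.shape[1])
        for t in range(1, clean.shape[0]):
            noise[t] = phi * noise[t - 1] + w[t]

    ts = TimeSeriesMatrix(
        data=(clean + noise).T,
        tr=tr,
        session=session_label,
        participant=participant,
        meta={"seed": seed, "noise_sd": noise_sd, "snr": truth_params.snr},
    )
    truth = GroundTruth(
        latent_dim=truth_params.latent_dim,
        expansion_factor=truth_params.expansion_factor,
        loading_matrix=loading,
        noise_sd=noise_sd,
        ar1_coef=truth_params.ar1_coef,
        accuracy_shrink=truth_params.accuracy_shrink,
        seed=seed,
        latent_trajectories=latent_trajectories,
        latent_courses=latent_courses,
    )
    return SimulatedSession(ts=ts, schedule=schedule, truth=truth)


def make_toy_manifold(kind: str, n_points: int = 200, ambient_dim: int = 10,
                      noise_sd: float = 0.1, seed: int = 0):
    """Toy point clouds with known structure for embedding tests.

    ``noisy_curve``  -> (X, ordering): points along a smooth 1-D curve,
    returned in curve order.
    ``gaussian_blobs`` -> (X, labels): three isotropic blobs (one blob if
    n_points < 30).
    ``two_clusters`` -> (X, labels): two tight clusters whose separation is
    at least 10x the intra-cluster spread.
    """
    if n_points < 10:
        raise ConfigurationError(f"n_points: must be >= 10, got {n_points}")
    if ambient_dim < 3:
        raise ConfigurationError(f"ambient_dim: must be >= 3, got {ambient_dim}")
    rng = np.random.default_rng(seed)
    if kind == "noisy_curve":
        s = np.linspace(0.0, 1.0, n_points)
        curve3 = np.column_stack(
            [np.cos(1.5 * np.pi * s), np.sin(1.5 * np.pi * s), 2.0 * s]
        )
        X = np.zeros((n_points, ambient_dim))
        X[:, :3] = curve3
        Q, _ = np.linalg.qr(rng.standard_normal((ambient_dim, ambient_dim)))
        X = X @ Q.T + noise_sd * rng.standard_normal((n_points, ambient_dim))
        return X, np.arange(n_points)
    if kind == "gaussian_blobs":
        n_blobs = 3 if n_points >= 30 else 1
        centers = 8.0 * rng.standard_normal((n_blobs, ambient_dim))
        labels = np.repeat(np.arange(n_blobs), int(np.ceil(n_points / n_blobs)))[:n_points]
        X = centers[labels] + rng.standard_normal((n_points, ambient_dim))
        return X, labels
    if kind == "two_clusters":
        spread = max(noise_sd, 1e-6)
        direction = rng.standard_normal(ambient_dim)
        direction /= np.linalg.norm(direction)
        gap = 20.0 * spread
        labels = (np.arange(n_points) % 2).astype(int)
        X = np.outer(labels, gap * direction) + spread * rng.standard_normal(
            (n_points, ambient_dim)
        )
        return X, labels
    raise ConfigurationError(f"kind: unknown toy manifold {kind!r}")
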