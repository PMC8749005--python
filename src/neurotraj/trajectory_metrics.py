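"""Geometry of embedded state-space trajectories.

A trajectory is the ordered path of embedded brain-activity points for one
condition x accuracy x session cell (per participant or group).  The core
statistics: path length in the top three embedding dimensions, condition
expansion ratios (the 2-back / 1-back length ratio), total summed
Euclidean distance between index-matched group and individual
trajectories, load-induced scaling across participants, and
trajectory-behavior correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import ContractError
from .phate_embed import Embedding

__all__ = [
    "Trajectory",
    "trajectory_from_embedding",
    "trajectory_length",
    "expansion_ratio",
    "group_individual_distance",
    "load_scaling",
    "behavior_association",
]

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Ordered embedded points with their cell labels."""

    points: np.ndarray
    labels: dict = field(default_factory=dict)
    embedding_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ContractError("a trajectory needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ContractError("trajectory contains non-finite coordinates")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def trajectory_from_embedding(embedding: Embedding, sample_labels, **criteria) -> Trajectory:
    """Slice one cell's ordered points out of an embedding.

    ``sample_labels`` is the DataFrame aligned 1:1 with embedding rows;
    ``criteria`` are label equalities (condition=..., accuracy=...).
    """
    mask = np.ones(len(sample_labels), dtype=bool)
    for key, val in criteria.items():
        mask &= (sample_labels[key] == val).to_numpy()
    if mask.sum() < 2:
        raise ContractError(f"fewer than 2 embedding samples match {criteria}")
    return Trajectory(
        points=embedding.coords[mask],
        labels=dict(criteria),
        embedding_id=embedding.embedding_id,
    )


def trajectory_length(traj: Trajectory, dims: int = 3) -> float:
    """Total path length: sum of Euclidean steps between consecutive points
    in the first ``dims`` embedding dimensions."""
    if dims > traj.points.shape[1]:
        raise ContractError(
            f"dims={dims} exceeds embedding dimensionality {traj.points.shape[1]}"
        )
    pts = traj.points[:, :dims]
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _check_same_space(a: Trajectory, b: Trajectory) -> None:
    if a.embedding_id is not None and b.embedding_id is not None:
        if a.embedding_id != b.embedding_id:
            raise ContractError(
                "trajectories come from different embedding spaces "
                f"({a.embedding_id} vs {b.embedding_id}); geometry is not comparable"
            )


def expansion_ratio(numerator: Trajectory, denominator: Trajectory, dims: int = 3) -> float:
    """Length ratio between two trajectories of one embedding space."""
    _check_same_space(numerator, denominator)
    den = trajectory_length(denominator, dims)
    if den == 0:
        raise ContractError("denominator trajectory has zero length")
    return trajectory_length(numerator, dims) / den


def group_individual_distance(group: Trajectory, individual: Trajectory,
                              dims: int = 3, resample: bool = True) -> float:
    """Total summed Euclidean distance between index-matched points of the
    group trajectory and one participant's trajectory.

    Trajectories built on the same trial grid match by construction; with
    unequal point counts the individual is linearly resampled onto the
    group's index grid (logged), unless ``resample`` is disabled.
    """
    _check_same_space(group, individual)
    g = group.points[:, :dims]
    p = individual.points[:, :dims]
    if len(g) != len(p):
        if not resample:
            raise ContractError(
                f"point counts differ ({len(g)} vs {len(p)}) and resampling is disabled"
            )
        logger.info(
            "resampling individual trajectory from %d to %d points", len(p), len(g)
        )
        src = np.linspace(0.0, 1.0, len(p))
        dst = np.linspace(0.0, 1.0, len(g))
        p = np.column_stack([np.interp(dst, src, p[:, d]) for d in range(dims)])
    return float(np.sum(np.linalg.norm(g - p, axis=1)))


def load_scaling(distances_1back: np.ndarray, distances_2back: np.ndarray):
    """Across-participant regression of high-load trajectory distances on
    low-load distances: returns (slope, r, p)."""
    x = np.asarray(distances_1back, dtype=float)
    y = np.asarray(distances_2back, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("distance vectors must be 1-D and equal length")
    if len(x) < 3:
        raise ContractError(f"need >= 3 participants, got {len(x)}")
    if np.ptp(x) == 0:
        raise ContractError("zero variance in predictor distances")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.rvalue), float(fit.pvalue)


def behavior_association(lengths: np.ndarray, accuracy: np.ndarray):
    """Pearson correlation between per-participant trajectory lengths and
    task accuracy: returns (r, p)."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(accuracy, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("inputs must be 1-D and equal length")
    if len(x) < 4:
        raise ContractError(f"need >= 4 participants, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ContractError("non-finite values in inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ContractError("constant input vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
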