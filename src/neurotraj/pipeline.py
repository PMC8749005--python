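"""End-to-end pipeline: simulate (or ingest) -> estimate -> embed ->
trajectory metrics -> inference -> QC -> report.

One :class:`PipelineConfig` fully determines a run; the manifest written
alongside the outputs (parameters, derived seeds, library versions, output
checksums) suffices to reproduce every artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, ContractError
from .phate_embed import PhateParams, phate, spatial_weights
from .qc_spectral import edge_fraction_report
from .response_estimation import (
    build_design_matrix,
    build_hrf_basis,
    concatenate_group,
    fit_trial_responses,
)
from .stats_infer import (
    StatResult,
    adjust_family,
    compare_dependent_correlations,
    paired_t,
    pearson,
    rm_anova,
)
from .synthetic_data import TruthParams, simulate_session
from .task_design import TaskConfig
from .trajectory_metrics import (
    Trajectory,
    expansion_ratio,
    group_individual_distance,
    load_scaling,
    trajectory_from_embedding,
    trajectory_length,
)

__all__ = [
    "PipelineConfig",
    "CommunityTable",
    "PipelineResult",
    "run_pipeline",
    "community_summary",
]

logger = logging.getLogger(__name__)

COMMUNITIES = ("Sensory", "Associative", "Default", "Non-hub")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs; serializes to/from YAML."""

    participants: int = 17
    sessions: tuple = ("baseline", "S1", "iPS")
    expansion: tuple = (1.3, 1.5, 7.3)
    variant: str = "long"
    n_runs: int | None = None
    n_regions: int = 333
    latent_dim: int = 3
    accuracy_rate: float = 0.85
    accuracy_sd: float = 0.07
    accuracy_shrink: float = 0.4
    snr: float = 2.0
    ar1_coef: float = 0.4
    window_s: float = 9.0
    alpha: float = 35.0
    knn: int = 10
    t: int | str = "auto"
    n_dims: int = 5
    qc_window: int = 64
    qc_overlap: float = 0.5
    group_mode: str = "none"  # none | shared
    max_embed_points: int = 6000
    community_table_path: str | None = None
    community_summary_requested: bool = False
    save_embeddings: bool = False
    output_dir: str = "neurotraj_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.participants < 1:
            raise ConfigurationError(f"participants: must be >= 1, got {self.participants}")
        if len(self.sessions) != len(self.expansion):
            raise ConfigurationError(
                "expansion: needs one planted factor per session "
                f"({len(self.sessions)} sessions, {len(self.expansion)} factors)"
            )
        if self.group_mode not in ("none", "shared"):
            raise ConfigurationError(f"group_mode: must be 'none' or 'shared', got {self.group_mode!r}")
        if self.community_summary_requested and not self.community_table_path:
            raise ConfigurationError(
                "community_table_path: required when a community summary is requested"
            )
        if self.community_table_path and not Path(self.community_table_path).exists():
            raise ConfigurationError(
                f"community_table_path: file not found: {self.community_table_path}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sessions", "expansion"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sessions"] = list(d["sessions"])
        d["expansion"] = list(d["expansion"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def task_config(self, seed: int = 0) -> TaskConfig:
        return TaskConfig.for_variant(self.variant, n_runs=self.n_runs, seed=seed)

    def phate_params(self) -> PhateParams:
        return PhateParams(
            n_dims=self.n_dims, alpha=self.alpha, knn=self.knn, t=self.t, seed=self.seed
        )


@dataclass
class CommunityTable:
    """Region -> network-community lookup (four communities: Sensory,
    Associative, Default, Non-hub)."""

    mapping: dict

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in COMMUNITIES}
        if bad:
            raise ConfigurationError(f"unknown communities {sorted(bad)}; expected {COMMUNITIES}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CommunityTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["region", "community"])
        if df["region"].duplicated().any():
            dupes = df.loc[df["region"].duplicated(), "region"].tolist()
            raise ConfigurationError(f"regions mapped more than once: {dupes[:10]}")
        return cls(mapping=dict(zip(df["region"].astype(str), df["community"])))

    def communities_for(self, region_names: list[str]) -> np.ndarray:
        missing = [r for r in region_names if r not in self.mapping]
        if missing:
            raise ContractError(f"regions missing from community table: {missing[:10]}")
        return np.array([self.mapping[r] for r in region_names])


def community_summary(weights: np.ndarray, table: CommunityTable,
                      region_names: list[str]) -> pd.DataFrame:
    """Mean absolute spatial weight per community per embedding dimension."""
    weights = np.asarray(weights, dtype=float)
    comms = table.communities_for(region_names)
    rows = []
    for community in sorted(set(comms)):
        mask = comms == community
        mean_abs = np.abs(weights[mask]).mean(axis=0)
        row = {"community": community, "n_regions": int(mask.sum())}
        row.update({f"dim{d + 1}": float(v) for d, v in enumerate(mean_abs)})
        rows.append(row)
    return pd.DataFrame(rows).sort_values("community").reset_index(drop=True)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    stats: list
    qc: pd.DataFrame
    community: pd.DataFrame | None
    manifest: dict
    output_dir: Path
    embeddings: dict = field(default_factory=dict)

    def session_ratio(self, session: str, statistic=np.median) -> float:
        """Summary 2-back/1-back correct-trial expansion ratio for a session."""
        sub = self.metrics[self.metrics["session"] == session]
        return float(statistic(sub["expansion_ratio"].to_numpy()))


def _child_seed(*keys) -> int:
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic-cohort analysis defined by ``config``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: %d participants x %s", config.participants, config.sessions)

    rng = np.random.default_rng(_child_seed(config.seed, 999))
    participant_rates = np.clip(
        rng.normal(config.accuracy_rate, config.accuracy_sd, size=config.participants),
        0.55, 0.98,
    )

    basis = build_hrf_basis(dt=0.1)
    phate_params = config.phate_params()
    metrics_rows = []
    behavior: dict = {s: {"length": [], "accuracy": []} for s in config.sessions}
    lengths_by_session: dict = {s: {"1back": [], "2back": []} for s in config.sessions}
    stimulus_series: dict = {}
    embeddings: dict = {}
    weights_accum: list = []
    session_responses: dict = {s: [] for s in config.sessions}
    derived_seeds: dict = {}

    for p_idx in range(config.participants):
        participant = f"sub-{p_idx:02d}"
        for s_idx, session in enumerate(config.sessions):
            seed_ps = _child_seed(config.seed, p_idx, s_idx)
            derived_seeds[f"{participant}/{session}"] = seed_ps
            truth_params = TruthParams(
                n_regions=config.n_regions,
                latent_dim=config.latent_dim,
                expansion_factor=float(config.expansion[s_idx]),
                accuracy_shrink=config.accuracy_shrink,
                accuracy_rate=float(participant_rates[p_idx]),
                snr=config.snr,
                ar1_coef=config.ar1_coef,
            )
            logger.info("stage simulate: %s %s (seed %d)", participant, session, seed_ps)
            sim = simulate_session(
                config.task_config(), truth_params, seed=seed_ps,
                session_label=session, participant=participant,
            )
            n_scans = sim.ts.n_time
            design = build_design_matrix(sim.schedule, basis, n_scans, tr=sim.ts.tr)
            responses = fit_trial_responses(sim.ts, design, basis, window_s=config.window_s)
            session_responses[session].append(responses)

            if p_idx == 0:
                canonical_cols = [
                    i for i, lab in enumerate(design.column_labels)
                    if lab[0] == "trial" and lab[2] == "canonical"
                ]
                stimulus_series[session] = design.X[:, canonical_cols].sum(axis=1)

            logger.info("stage embed: %s %s (%d points)", participant, session, responses.n_samples)
            emb = phate(responses.values, phate_params)
            emb.spatial_weights = spatial_weights(responses, emb.coords[:, :3])
            if config.save_embeddings or (config.participants * responses.n_samples
                                          <= config.max_embed_points):
                embeddings[f"{participant}/{session}"] = emb
            if session == config.sessions[0]:
                weights_accum.append(emb.spatial_weights)

            cell_lengths = {}
            for condition in ("1back", "2back"):
                for accuracy in ("correct", "incorrect"):
                    try:
                        traj = trajectory_from_embedding(
                            emb, responses.sample_labels,
                            condition=condition, accuracy=accuracy,
                        )
                        cell_lengths[(condition, accuracy)] = trajectory_length(traj)
                    except ContractError:
                        cell_lengths[(condition, accuracy)] = np.nan
            ratio = (
                cell_lengths[("2back", "correct")] / cell_lengths[("1back", "correct")]
                if cell_lengths[("1back", "correct")] else np.nan
            )
            acc_2b = float(
                (sim.schedule.trials.query("trial_type == '2back'")["accuracy"] == "correct").mean()
            )
            metrics_rows.append(
                {
                    "participant": participant,
                    "session": session,
                    "len_1back_correct": cell_lengths[("1back", "correct")],
                    "len_2back_correct": cell_lengths[("2back", "correct")],
                    "len_1back_incorrect": cell_lengths[("1back", "incorrect")],
                    "len_2back_incorrect": cell_lengths[("2back", "incorrect")],
                    "expansion_ratio": ratio,
                    "planted_expansion": float(config.expansion[s_idx]),
                    "accuracy_2back": acc_2b,
                    "t_selected": emb.t_selected,
                    "var_dim1": float(emb.variance_fraction[0]),
                }
            )
            lengths_by_session[session]["1back"].append(cell_lengths[("1back", "correct")])
            lengths_by_session[session]["2back"].append(cell_lengths[("2back", "correct")])
            behavior[session]["length"].append(cell_lengths[("2back", "correct")])
            behavior[session]["accuracy"].append(acc_2b)

    metrics = pd.DataFrame(metrics_rows)

    # ---- inference across participants -------------------------------------
    stats_results: list[StatResult] = []
    family: list[StatResult] = []
    for session in config.sessions:
        l1 = np.asarray(lengths_by_session[session]["1back"], float)
        l2 = np.asarray(lengths_by_session[session]["2back"], float)
        if len(l1) >= 2 and np.isfinite(l1).all() and np.isfinite(l2).all():
            res = paired_t(l2, l1, name=f"paired_t:{session}:2b_gt_1b")
            family.append(res)
    if config.participants >= 2 and len(config.sessions) >= 2:
        diffs = np.column_stack(
            [
                np.asarray(lengths_by_session[s]["2back"], float)
                - np.asarray(lengths_by_session[s]["1back"], float)
                for s in config.sessions
            ]
        )
        if np.isfinite(diffs).all():
            stats_results.append(rm_anova(diffs, name="rm_anova:load_diff_by_session"))
    corr_by_session = {}
    for session in config.sessions:
        lens = np.asarray(behavior[session]["length"], float)
        accs = np.asarray(behavior[session]["accuracy"], float)
        if len(lens) >= 4 and np.ptp(lens) > 0 and np.ptp(accs) > 0:
            res = pearson(lens, accs, name=f"pearson:len_vs_acc:{session}")
            corr_by_session[session] = (lens, accs, res)
            family.append(res)
    if len(corr_by_session) >= 2 and config.participants >= 10:
        names = list(corr_by_session)
        s_a, s_b = names[0], names[-1]
        la, aa, res_a = corr_by_session[s_a]
        lb, ab, res_b = corr_by_session[s_b]
        cross = {
            "r13": float(np.corrcoef(la, lb)[0, 1]),
            "r14": float(np.corrcoef(la, ab)[0, 1]),
            "r23": float(np.corrcoef(aa, lb)[0, 1]),
            "r24": float(np.corrcoef(aa, ab)[0, 1]),
        }
        family.append(
            compare_dependent_correlations(
                res_a.statistic, res_b.statistic, cross, n=config.participants,
                name=f"dunn_clark:{s_a}_vs_{s_b}",
            )
        )
    if family:
        adjust_family(family, family_id="trajectory_tests")
        stats_results.extend(family)

    # ---- optional shared-space group analysis ------------------------------
    group_rows = []
    if config.group_mode == "shared":
        for session in config.sessions:
            n_points = sum(r.n_samples for r in session_responses[session])
            if n_points > config.max_embed_points:
                logger.warning(
                    "group embedding skipped for %s: %d points > max_embed_points=%d",
                    session, n_points, config.max_embed_points,
                )
                continue
            pooled = concatenate_group(session_responses[session], mode="per_session")
            emb = phate(pooled.values, phate_params)
            labels = pooled.sample_labels
            for condition in ("1back", "2back"):
                mask = (
                    (labels["condition"] == condition)
                    & (labels["accuracy"] == "correct")
                ).to_numpy()
                if mask.sum() < 2:
                    continue
                pts = emb.coords[mask][:, :3]
                parts = labels.loc[mask, "participant"].to_numpy()
                tcourse = labels.loc[mask].groupby("participant").cumcount().to_numpy()
                grid = np.unique(tcourse)
                group_pts = np.vstack(
                    [pts[tcourse == g].mean(axis=0) for g in grid]
                )
                group_traj = Trajectory(group_pts, labels={"condition": condition},
                                        embedding_id=emb.embedding_id)
                for participant in np.unique(parts):
                    sel = parts == participant
                    indiv = Trajectory(pts[sel], labels={"condition": condition},
                                       embedding_id=emb.embedding_id)
                    dist = group_individual_distance(group_traj, indiv)
                    group_rows.append(
                        {
                            "session": session,
                            "condition": condition,
                            "participant": participant,
                            "group_distance": dist,
                        }
                    )
        if group_rows:
            gdf = pd.DataFrame(group_rows)
            for session in gdf["session"].unique():
                try:
                    d1 = gdf.query("session == @session and condition == '1back'")
                    d2 = gdf.query("session == @session and condition == '2back'")
                    merged = d1.merge(d2, on="participant", suffixes=("_1b", "_2b"))
                    slope, r, p = load_scaling(
                        merged["group_distance_1b"].to_numpy(),
                        merged["group_distance_2b"].to_numpy(),
                    )
                    stats_results.append(
                        StatResult(
                            name=f"load_scaling:{session}", statistic=slope,
                            df=float(len(merged) - 2), p=p, extra={"r": r},
                        )
                    )
                except ContractError as exc:
                    logger.warning("load scaling failed for %s: %s", session, exc)

    # ---- QC -----------------------------------------------------------------
    shortest = min(len(s) for s in stimulus_series.values())
    qc_window = config.qc_window
    while qc_window > 16 and shortest < 4 * qc_window:
        qc_window //= 2
    if qc_window != config.qc_window:
        logger.info("qc window reduced to %d samples for %d-sample series",
                    qc_window, shortest)
    qc = edge_fraction_report(stimulus_series, qc_window, config.qc_overlap)

    # ---- community summary --------------------------------------------------
    community = None
    if config.community_table_path:
        table = CommunityTable.from_tsv(config.community_table_path)
        mean_weights = np.mean(np.stack(weights_accum), axis=0)
        region_names = [f"region{i:03d}" for i in range(config.n_regions)]
        community = community_summary(mean_weights, table, region_names)

    # ---- artifacts ----------------------------------------------------------
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.10g")
    stats_payload = [r.to_dict() for r in stats_results]
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=1, sort_keys=True))
    qc_path = out / "qc.json"
    qc_path.write_text(qc.to_json(orient="records", indent=1))
    if group_rows:
        pd.DataFrame(group_rows).to_csv(out / "group_distances.csv", index=False,
                                        float_format="%.10g")
    if community is not None:
        community.to_csv(out / "community_summary.csv", index=False, float_format="%.10g")
    if config.save_embeddings:
        for key, emb in embeddings.items():
            safe = key.replace("/", "_")
            pd.DataFrame(
                emb.coords, columns=[f"dim{i + 1}" for i in range(emb.coords.shape[1])]
            ).to_csv(out / f"embedding_{safe}.csv", index=False, float_format="%.10g")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "derived_seeds": derived_seeds,
        "outputs": {
            "metrics.csv": _sha256(metrics_path),
            "qc.json": _sha256(qc_path),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    logger.info("pipeline done: %s", out)
    return PipelineResult(
        metrics=metrics,
        stats=stats_payload,
        qc=qc,
        community=community,
        manifest=manifest,
        output_dir=out,
        embeddings=embeddings,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
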