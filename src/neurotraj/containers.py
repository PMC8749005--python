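"""In-memory containers for parcellated BOLD data and estimated responses.

Matrices travel as plain delimited text (TSV) with a JSON sidecar holding
metadata (TR, region names, session/participant labels), so every artifact
of a run is human-readable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractError, ParseError

__all__ = ["TimeSeriesMatrix", "ResponseMatrix"]


@dataclass
class TimeSeriesMatrix:
    """Parcellated BOLD time series, shape (n_regions, n_time), TR in seconds."""

    data: np.ndarray
    tr: float = 1.0
    region_names: list[str] | None = None
    session: str = "baseline"
    participant: str = "sub-00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ContractError("TimeSeriesMatrix.data must be 2-D (regions x time)")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("TimeSeriesMatrix.data contains non-finite values")
        if self.tr <= 0:
            raise ContractError("tr must be positive")
        if self.region_names is None:
            self.region_names = [f"region{i:03d}" for i in range(self.data.shape[0])]
        if len(self.region_names) != self.data.shape[0]:
            raise ContractError("region_names length must match number of rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.data, index=self.region_names)
        df.to_csv(path, sep="\t", header=False, float_format="%.10g")
        sidecar = {
            "tr": self.tr,
            "session": self.session,
            "participant": self.participant,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TimeSeriesMatrix":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"could not parse time-series matrix {path}: {exc}") from exc
        sidecar_path = path.with_suffix(path.suffix + ".json")
        sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return cls(
            data=df.to_numpy(dtype=float),
            tr=float(sidecar.get("tr", 1.0)),
            region_names=[str(r) for r in df.index],
            session=sidecar.get("session", "baseline"),
            participant=sidecar.get("participant", "sub-00"),
            meta=sidecar.get("meta", {}),
        )


@dataclass
class ResponseMatrix:
    """Concatenated trial-locked estimated responses.

    ``values`` is (n_samples, n_regions): each modeled trial contributes
    ``floor(window_s / tr)`` consecutive rows (its estimated evoked response
    sampled at the TR), and ``sample_labels`` carries one row per sample with
    columns trial / condition / accuracy / session / participant / t_index.
    """

    values: np.ndarray
    sample_labels: pd.DataFrame
    tr: float = 1.0
    window_s: float = 9.0
    region_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ContractError("ResponseMatrix.values must be 2-D (samples x regions)")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("ResponseMatrix.values contains non-finite values")
        if len(self.sample_labels) != self.values.shape[0]:
            raise ContractError("sample_labels must have one row per sample")
        if self.region_names is None:
            self.region_names = [f"region{i:03d}" for i in range(self.values.shape[1])]
        if len(self.region_names) != self.values.shape[1]:
            raise ContractError("region_names length must match number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def samples_per_trial(self) -> int:
        return int(np.floor(self.window_s / self.tr))

    def select(self, **criteria) -> "ResponseMatrix":
        """Subset samples by label equality, e.g. ``select(condition="2back")``."""
        mask = np.ones(self.n_samples, dtype=bool)
        for key, val in criteria.items():
            if key not in self.sample_labels.columns:
                raise ContractError(f"unknown sample label {key!r}")
            mask &= (self.sample_labels[key] == val).to_numpy()
        return ResponseMatrix(
            values=self.values[mask],
            sample_labels=self.sample_labels.loc[mask].reset_index(drop=True),
            tr=self.tr,
            window_s=self.window_s,
            region_names=self.region_names,
            meta=dict(self.meta),
        )

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, columns=self.region_names).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        self.sample_labels.to_csv(
            path.with_suffix(".labels.tsv"), sep="\t", index=False
        )
        sidecar = {"tr": self.tr, "window_s": self.window_s, "meta": _jsonable(self.meta)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResponseMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        labels = pd.read_csv(path.with_suffix(".labels.tsv"), sep="\t")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return cls(
            values=df.to_numpy(dtype=float),
            sample_labels=labels,
            tr=float(sidecar.get("tr", 1.0)),
            window_s=float(sidecar.get("window_s", 9.0)),
            region_names=list(df.columns),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    """Best-effort conversion of metadata values to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
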