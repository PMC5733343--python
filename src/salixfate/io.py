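"""Feature tables, sample designs, pipeline configuration and text I/O.

The central in-memory object is :class:`FeatureTable`: a matrix of peak
areas (features x samples) carried together with per-feature m/z and
retention time and a sample design describing, for every sample column,
its incubation channel, willow-bark-extract concentration, sampling time
and replicate number.

Not-detected cells are stored as ``NaN`` and are distinct from a measured
area of zero.  On disk a table is a directory of three tab-separated
files (``features.tsv``, ``areas.tsv``, ``design.tsv``); not-detected
cells are written as empty fields, which round-trips exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Channel",
    "TIME_POINTS",
    "TIME_LABELS",
    "PipelineConfig",
    "FeatureTable",
    "make_design",
    "sample_id",
    "read_feature_table",
    "write_feature_table",
]


class Channel(str, enum.Enum):
    """Incubation channel of the experiment.

    HFS_WBE: human fecal suspension plus willow bark extract (2 or 10 mg/ml);
    HFS_VEHICLE: fecal suspension plus ethanol/buffer vehicle only;
    HFS_PBS: fecal suspension plus plain buffer;
    EXTRACT_CONTROL: extract in buffer without fecal microbes.
    """

    HFS_WBE = "HFS_WBE"
    HFS_VEHICLE = "HFS_VEHICLE"
    HFS_PBS = "HFS_PBS"
    EXTRACT_CONTROL = "EXTRACT_CONTROL"


#: Sampling times in hours (t0, t4, t24 labels of the incubation design).
TIME_POINTS: tuple[float, ...] = (0.5, 4.0, 24.0)
TIME_LABELS: dict[str, float] = {"t0": 0.5, "t4": 4.0, "t24": 24.0}

_DESIGN_COLUMNS = ["channel", "wbe_concentration", "time_h", "replicate"]


def sample_id(channel: Channel, conc: float, time_h: float, replicate: int) -> str:
    return f"{Channel(channel).value}-c{conc:g}-t{time_h:g}-r{replicate}"


def make_design(
    concentrations: Sequence[float] = (2.0, 10.0),
    times: Sequence[float] = TIME_POINTS,
    replicates: int = 3,
) -> pd.DataFrame:
    """Full factorial sample design of the incubation experiment.

    One series per WBE concentration in fecal suspension, a vehicle and a
    plain-buffer control (concentration 0) and an extract-in-buffer control
    at the high concentration, each sampled at every time point in
    triplicate (or ``replicates``).
    """
    series: list[tuple[Channel, float]] = [
        (Channel.HFS_WBE, float(c)) for c in concentrations
    ]
    series += [
        (Channel.HFS_VEHICLE, 0.0),
        (Channel.HFS_PBS, 0.0),
        (Channel.EXTRACT_CONTROL, float(max(concentrations))),
    ]
    rows = []
    for channel, conc in series:
        for t in times:
            for r in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": sample_id(channel, conc, t, r),
                        "channel": channel.value,
                        "wbe_concentration": conc,
                        "time_h": float(t),
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in _DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns {missing}")
    if design.index.duplicated().any():
        dupes = design.index[design.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in design: {dupes}")
    for sid, row in design.iterrows():
        channel = Channel(row["channel"])
        conc = float(row["wbe_concentration"])
        if channel in (Channel.HFS_VEHICLE, Channel.HFS_PBS) and conc != 0.0:
            raise ValueError(f"sample {sid}: {channel.value} must have concentration 0")
        if channel is Channel.EXTRACT_CONTROL and conc <= 0.0:
            raise ValueError(f"sample {sid}: extract control needs a positive concentration")


@dataclass
class FeatureTable:
    """Peak areas per feature and sample, tied to a sample design.

    features: DataFrame indexed by feature id with columns ``mz`` and ``rt``.
    areas: DataFrame indexed by feature id, one column per sample id;
        ``NaN`` marks a not-detected cell.
    design: DataFrame indexed by sample id with columns ``channel``,
        ``wbe_concentration``, ``time_h`` and ``replicate``.
    """

    features: pd.DataFrame
    areas: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.features.index.name = "feature_id"
        self.areas.index.name = "feature_id"
        self.areas.columns.name = "sample_id"
        self.design.index.name = "sample_id"
        if self.features.index.duplicated().any():
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        for col in ("mz", "rt"):
            if col not in self.features.columns:
                raise ValueError(f"features table is missing column {col!r}")
        _validate_design(self.design)
        unknown = [c for c in self.areas.columns if c not in self.design.index]
        if unknown:
            raise ValueError(f"area columns not covered by the design: {unknown}")
        missing = [s for s in self.design.index if s not in self.areas.columns]
        if missing:
            raise ValueError(f"design samples missing from the area table: {missing}")
        if not self.areas.index.equals(self.features.index):
            raise ValueError("area rows and feature rows disagree")
        values = self.areas.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            bad = self.areas.index[(self.areas < 0).any(axis=1)].tolist()
            raise ValueError(f"negative peak areas for features {bad}")

    @property
    def feature_ids(self) -> list:
        return list(self.features.index)

    def concentrations(self) -> list[float]:
        """WBE concentrations incubated with fecal suspension, ascending."""
        mask = self.design["channel"] == Channel.HFS_WBE.value
        return sorted(set(self.design.loc[mask, "wbe_concentration"].astype(float)))

    def cell_samples(self, channel: Channel, conc: float, time_h: float) -> list[str]:
        """Sample ids of one (channel, concentration, time) design cell."""
        d = self.design
        mask = (
            (d["channel"] == Channel(channel).value)
            & (d["wbe_concentration"].astype(float) == float(conc))
            & (d["time_h"].astype(float) == float(time_h))
        )
        samples = d.index[mask].tolist()
        if not samples:
            raise KeyError(
                f"no samples for cell ({Channel(channel).value}, {conc} mg/ml, {time_h} h)"
            )
        return samples

    def cell_areas(self, feature_id, channel: Channel, conc: float, time_h: float) -> np.ndarray:
        """Replicate areas of one feature in one design cell (NaN = not detected)."""
        return self.areas.loc[feature_id, self.cell_samples(channel, conc, time_h)].to_numpy(
            dtype=float
        )


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as a directory of three TSV files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table.features.to_csv(path / "features.tsv", sep="\t", index_label="feature_id")
    table.areas.to_csv(path / "areas.tsv", sep="\t", index_label="feature_id", na_rep="")
    table.design.to_csv(path / "design.tsv", sep="\t", index_label="sample_id")
    return path


def read_feature_table(path: str | Path, design_path: str | Path | None = None) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    ``path`` is the table directory; a design stored elsewhere can be
    supplied via ``design_path``.  Validation errors (unknown sample
    columns, duplicate ids, negative areas) name the offending rows.
    """
    path = Path(path)
    features = pd.read_csv(path / "features.tsv", sep="\t", index_col="feature_id")
    areas = pd.read_csv(path / "areas.tsv", sep="\t", index_col="feature_id")
    design_file = Path(design_path) if design_path is not None else path / "design.tsv"
    design = pd.read_csv(design_file, sep="\t", index_col="sample_id")
    return FeatureTable(features=features, areas=areas, design=design)


@dataclass
class PipelineConfig:
    """Thresholds and paths steering the full pipeline.

    The fate thresholds are the published triage rules: a feature increases
    if its t24/t0 ratio exceeds ``up`` at ``alpha``, decreases below
    ``down``, and is an intermediate if t4/t0 exceeds ``up`` (significant)
    while t4/t24 exceeds ``inter``.
    """

    up: float = 2.0
    down: float = 0.5
    inter: float = 1.25
    alpha: float = 0.05
    ppm_tol: float = 5.0
    rt_tol: float | None = None
    lod: float = 100.0
    min_detected: int = 2
    welch: bool = False
    sigma: float = 0.2
    seed: int | None = None
    table_path: str | None = None
    out_dir: str = "salixfate_out"

    def __post_init__(self) -> None:
        if not self.up > 1:
            raise ValueError("up threshold must exceed 1")
        if not 0 < self.down < 1:
            raise ValueError("down threshold must lie in (0, 1)")
        if not self.inter > 1:
            raise ValueError("intermediate threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.ppm_tol <= 0:
            raise ValueError("ppm tolerance must be positive")
        if self.lod < 0 or self.sigma < 0:
            raise ValueError("lod and sigma must be non-negative")
        if self.min_detected < 1:
            raise ValueError("min_detected must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def header_lines(self) -> list[str]:
        """Config echoed as '# key=value' lines for report provenance."""
        return [f"# {f.name}={getattr(self, f.name)}" for f in fields(self)]
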