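"""Metabolic-fate classification of time-course LC-MS features.

For every feature and extract concentration the stage computes group
ratios between sampling times (t4 vs t0, t24 vs t0, t4 vs t24) on replicate
mean areas, assesses them with an unpaired two-tailed Student's t-test,
and assigns one fate label:

* INCREASING  - t24/t0 ratio > 2 with p < 0.05;
* DECREASING  - t24/t0 ratio < 0.5 with p < 0.05;
* INTERMEDIATE - t4/t0 ratio > 2 (p < 0.05) plus t4/t24 ratio > 1.25
  (rise then fall; evaluated before the monotone rules since such a
  feature can satisfy several of them);
* UNCHANGED   - none of the above;
* MATRIX      - present in a fecal channel without added extract, hence a
  fecal-background peak, excluded from extract-derived reports;
* FAST_METABOLIZED - present in the microbe-free extract control but never
  detected in any fecal incubation with extract (turned over before the
  first sampling);
* INSUFFICIENT_DATA - never reliably detected in the concentration series.

Not-detected replicates enter group means as zero area (they are below
the detection limit) while a feature counts as *present* in a design cell
only when at least ``min_detected`` of its replicates were detected.
Every fate is additionally crosschecked against the extract control: a
same-direction significant change there means the trend is not caused by
the microbes and the feature is flagged abiotic.

No multiple-testing correction is applied: the procedure deliberately
uses raw p < alpha per feature, as in the published triage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TIME_POINTS, Channel, FeatureTable

__all__ = [
    "FateLabel",
    "GroupStats",
    "RatioTest",
    "FateRecord",
    "group_stats",
    "fold_test",
    "classify_fate",
    "matrix_filter",
    "detect_fast_metabolized",
    "crosscheck_abiotic",
    "run_triage",
    "fates_to_frame",
]


class FateLabel(str, enum.Enum):
    INCREASING = "INCREASING"
    DECREASING = "DECREASING"
    INTERMEDIATE = "INTERMEDIATE"
    UNCHANGED = "UNCHANGED"
    FAST_METABOLIZED = "FAST_METABOLIZED"
    MATRIX = "MATRIX"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class GroupStats:
    """Replicate summary of one feature in one design cell (ND counted as 0)."""

    mean: float
    sd: float
    n_total: int
    n_detected: int

    def present(self, min_detected: int = 2) -> bool:
        return self.n_detected >= min_detected


@dataclass(frozen=True)
class RatioTest:
    """Group-mean ratio plus the two-sample t-test behind it.

    ``ratio`` is mean(b)/mean(a); ``undefined`` is set when both means are
    zero (no information).  A zero denominator with a non-zero numerator
    yields an infinite ratio (newly formed compound).
    """

    ratio: float
    t_statistic: float
    p_value: float
    df: int
    undefined: bool = False
    insufficient: bool = False


_INSUFFICIENT = RatioTest(
    ratio=math.nan, t_statistic=math.nan, p_value=math.nan, df=0, undefined=True, insufficient=True
)


@dataclass
class FateRecord:
    """Triage outcome for one feature at one extract concentration."""

    feature_id: object
    concentration: float
    label: FateLabel
    abiotic_flag: bool = False
    control_label: FateLabel | None = None
    tests: Dict[str, RatioTest] = field(default_factory=dict)


def _clean(values: Iterable[float]) -> np.ndarray:
    """Replicate areas with not-detected (NaN) mapped to zero."""
    arr = np.asarray(list(values), dtype=float)
    return np.nan_to_num(arr, nan=0.0)


def group_stats(table: FeatureTable, feature_id, channel: Channel, conc: float, time_h: float) -> GroupStats:
    """Mean, sd and detection counts of one feature in one design cell."""
    raw = table.cell_areas(feature_id, channel, conc, time_h)
    detected = int(np.sum(~np.isnan(raw)))
    areas = np.nan_to_num(raw, nan=0.0)
    sd = float(np.std(areas, ddof=1)) if areas.size > 1 else 0.0
    return GroupStats(mean=float(np.mean(areas)), sd=sd, n_total=int(raw.size), n_detected=detected)


def fold_test(a: Sequence[float], b: Sequence[float], welch: bool = False) -> RatioTest:
    """Ratio mean(b)/mean(a) with an unpaired two-tailed Student's t-test.

    The classical pooled-variance statistic with df = n_a + n_b - 2 is
    used (Welch's unequal-variance form behind the ``welch`` switch).
    Two degenerate regimes keep the test total on noise-free data: when
    both groups have zero variance, p is 0 if the means differ and 1 if
    they are equal.  Fewer than two values in either group yields an
    insufficient-data result rather than an error.
    """
    a = _clean(a)
    b = _clean(b)
    if a.size < 2 or b.size < 2:
        return _INSUFFICIENT
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if mean_a > 0:
        ratio, undefined = mean_b / mean_a, False
    elif mean_b > 0:
        ratio, undefined = math.inf, False
    else:
        ratio, undefined = math.nan, True
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    n_a, n_b = a.size, b.size
    if welch:
        se = math.sqrt(var_a / n_a + var_b / n_b)
        if se > 0:
            t = (mean_b - mean_a) / se
            df_w = (var_a / n_a + var_b / n_b) ** 2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
            p = 2.0 * float(stats.t.sf(abs(t), df_w))
            return RatioTest(ratio, t, p, int(round(df_w)), undefined)
        t, p = _degenerate_t(mean_a, mean_b)
        return RatioTest(ratio, t, p, n_a + n_b - 2, undefined)
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    if se > 0:
        t = (mean_b - mean_a) / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        t, p = _degenerate_t(mean_a, mean_b)
    return RatioTest(ratio, t, p, df, undefined)


def _degenerate_t(mean_a: float, mean_b: float) -> tuple[float, float]:
    # Zero pooled variance: limit behavior of the t-test.
    if mean_a == mean_b:
        return 0.0, 1.0
    return math.copysign(math.inf, mean_b - mean_a), 0.0


def classify_fate(
    tests: Mapping[str, RatioTest],
    presence: Mapping[str, bool],
    alpha: float = 0.05,
    up: float = 2.0,
    down: float = 0.5,
    inter: float = 1.25,
) -> FateLabel:
    """Apply the published ratio/significance rules to one feature.

    ``tests`` holds the RatioTests keyed ``t4_vs_t0``, ``t24_vs_t0`` and
    ``t4_vs_t24``; ``presence`` says whether the feature was reliably
    detected at each time point (keys ``t0``, ``t4``, ``t24``).  Presence
    gates the direction claims: an increase must be present at the end
    point it allegedly rose to, a decrease at the start point it fell
    from, an intermediate at its transient peak.
    """
    t4_t0 = tests.get("t4_vs_t0", _INSUFFICIENT)
    t24_t0 = tests.get("t24_vs_t0", _INSUFFICIENT)
    t4_t24 = tests.get("t4_vs_t24", _INSUFFICIENT)
    if all(t.insufficient for t in (t4_t0, t24_t0, t4_t24)):
        return FateLabel.INSUFFICIENT_DATA

    def significant(test: RatioTest) -> bool:
        return not test.insufficient and not math.isnan(test.p_value) and test.p_value < alpha

    if (
        presence.get("t4", False)
        and not t4_t0.undefined
        and t4_t0.ratio > up
        and significant(t4_t0)
        and not t4_t24.undefined
        and t4_t24.ratio > inter
    ):
        return FateLabel.INTERMEDIATE
    if (
        presence.get("t24", False)
        and not t24_t0.undefined
        and t24_t0.ratio > up
        and significant(t24_t0)
    ):
        return FateLabel.INCREASING
    if (
        presence.get("t0", False)
        and not t24_t0.undefined
        and t24_t0.ratio < down
        and significant(t24_t0)
    ):
        return FateLabel.DECREASING
    return FateLabel.UNCHANGED


def matrix_filter(table: FeatureTable, feature_id, min_detected: int = 2) -> bool:
    """True if the feature occurs in a fecal channel without added extract.

    Presence (>= ``min_detected`` of the replicates detected) in the
    vehicle or plain-buffer fecal series at any time point marks the
    feature as fecal background rather than extract-derived.
    """
    channels = set(table.design["channel"])
    controls = [
        c
        for c in (Channel.HFS_VEHICLE, Channel.HFS_PBS)
        if c.value in channels
    ]
    if not controls:
        raise ValueError("no extract-free fecal control channels in the design")
    times = sorted(set(table.design["time_h"].astype(float)))
    for channel in controls:
        for t in times:
            gs = group_stats(table, feature_id, channel, 0.0, t)
            if gs.present(min_detected):
                return True
    return False


def detect_fast_metabolized(table: FeatureTable, feature_id, min_detected: int = 2) -> bool:
    """True if present in the extract control at t0 but never in fecal+extract.

    Such features were turned over before the first sampling: they exist
    in the unmetabolized extract yet are undetectable at every time point
    of both fecal incubation series.
    """
    channels = set(table.design["channel"])
    if Channel.EXTRACT_CONTROL.value not in channels:
        return False
    times = sorted(set(table.design["time_h"].astype(float)))
    ec_conc = float(
        table.design.loc[
            table.design["channel"] == Channel.EXTRACT_CONTROL.value, "wbe_concentration"
        ].iloc[0]
    )
    t0 = min(times)
    if not group_stats(table, feature_id, Channel.EXTRACT_CONTROL, ec_conc, t0).present(min_detected):
        return False
    for conc in table.concentrations():
        for t in times:
            if group_stats(table, feature_id, Channel.HFS_WBE, conc, t).present(min_detected):
                return False
    return True


def crosscheck_abiotic(fate_hfs: FateRecord, fate_extract_control: FateRecord) -> bool:
    """Flag trends that the microbe-free extract control also shows.

    A feature significantly increasing (or decreasing) both in the fecal
    incubation and in the extract control changed for reasons other than
    microbial metabolism; such features are excluded from microbial
    substrate/metabolite reports.
    """
    same_direction = (
        (FateLabel.INCREASING, FateLabel.INCREASING),
        (FateLabel.DECREASING, FateLabel.DECREASING),
    )
    return (fate_hfs.label, fate_extract_control.label) in same_direction


def _time_tests(
    table: FeatureTable,
    feature_id,
    channel: Channel,
    conc: float,
    times: Sequence[float],
    welch: bool,
) -> tuple[Dict[str, RatioTest], Dict[str, bool]]:
    t0, t4, t24 = times
    cells = {
        label: table.cell_areas(feature_id, channel, conc, t)
        for label, t in (("t0", t0), ("t4", t4), ("t24", t24))
    }
    tests = {
        "t4_vs_t0": fold_test(cells["t0"], cells["t4"], welch),
        "t24_vs_t0": fold_test(cells["t0"], cells["t24"], welch),
        "t4_vs_t24": fold_test(cells["t24"], cells["t4"], welch),
    }
    presence = {
        label: int(np.sum(~np.isnan(areas))) for label, areas in cells.items()
    }
    return tests, presence


def run_triage(
    table: FeatureTable,
    alpha: float = 0.05,
    up: float = 2.0,
    down: float = 0.5,
    inter: float = 1.25,
    min_detected: int = 2,
    welch: bool = False,
) -> list[FateRecord]:
    """Classify every feature at every extract concentration.

    Returns one :class:`FateRecord` per (feature, concentration) with the
    label precedence MATRIX > FAST_METABOLIZED > INSUFFICIENT_DATA >
    INTERMEDIATE > INCREASING > DECREASING > UNCHANGED, each crosschecked
    against the extract control for abiotic trends.  Deterministic: the
    output depends only on the table.
    """
    times = sorted(set(table.design["time_h"].astype(float)))
    if len(times) != 3:
        raise ValueError(f"triage expects three time points, found {times}")
    concentrations = table.concentrations()
    channels = set(table.design["channel"])
    has_ec = Channel.EXTRACT_CONTROL.value in channels
    if has_ec:
        ec_conc = float(
            table.design.loc[
                table.design["channel"] == Channel.EXTRACT_CONTROL.value,
                "wbe_concentration",
            ].iloc[0]
        )
    records: list[FateRecord] = []
    for fid in table.feature_ids:
        is_matrix = matrix_filter(table, fid, min_detected)
        is_fast = (not is_matrix) and has_ec and detect_fast_metabolized(table, fid, min_detected)
        control_record: FateRecord | None = None
        if has_ec:
            ec_tests, ec_counts = _time_tests(
                table, fid, Channel.EXTRACT_CONTROL, ec_conc, times, welch
            )
            ec_presence = {k: v >= min_detected for k, v in ec_counts.items()}
            ec_label = (
                classify_fate(ec_tests, ec_presence, alpha, up, down, inter)
                if any(ec_presence.values())
                else FateLabel.INSUFFICIENT_DATA
            )
            control_record = FateRecord(
                feature_id=fid, concentration=ec_conc, label=ec_label, tests=ec_tests
            )
        for conc in concentrations:
            tests, counts = _time_tests(table, fid, Channel.HFS_WBE, conc, times, welch)
            presence = {k: v >= min_detected for k, v in counts.items()}
            if is_matrix:
                label = FateLabel.MATRIX
            elif is_fast:
                label = FateLabel.FAST_METABOLIZED
            elif not any(presence.values()):
                label = FateLabel.INSUFFICIENT_DATA
            else:
                label = classify_fate(tests, presence, alpha, up, down, inter)
            record = FateRecord(
                feature_id=fid,
                concentration=conc,
                label=label,
                control_label=control_record.label if control_record else None,
                tests=tests,
            )
            if control_record is not None:
                record.abiotic_flag = crosscheck_abiotic(record, control_record)
            records.append(record)
    return records


def fates_to_frame(records: Sequence[FateRecord]) -> pd.DataFrame:
    """Fate records as a flat table with a stable column order."""
    rows = []
    for r in records:
        row = {
            "feature_id": r.feature_id,
            "concentration": r.concentration,
            "label": r.label.value,
            "abiotic_flag": r.abiotic_flag,
            "control_label": r.control_label.value if r.control_label else "",
        }
        for key in ("t4_vs_t0", "t24_vs_t0", "t4_vs_t24"):
            test = r.tests.get(key, _INSUFFICIENT)
            row[f"ratio_{key}"] = test.ratio
            row[f"t_{key}"] = test.t_statistic
            row[f"p_{key}"] = test.p_value
        rows.append(row)
    columns = [
        "feature_id",
        "concentration",
        "label",
        "abiotic_flag",
        "control_label",
        "ratio_t4_vs_t0",
        "t_t4_vs_t0",
        "p_t4_vs_t0",
        "ratio_t24_vs_t0",
        "t_t24_vs_t0",
        "p_t24_vs_t0",
        "ratio_t4_vs_t24",
        "t_t4_vs_t24",
        "p_t4_vs_t24",
    ]
    return pd.DataFrame(rows, columns=columns)
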