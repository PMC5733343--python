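"""Independent, deliberately naive re-application of the fate rules.

Used as the oracle for triage-equivalence tests: straight-line code that
re-reads the written classification rules feature by feature, sharing
nothing with the implementation except scipy's t distribution.
"""

import numpy as np
from scipy import stats


def _cell(table, fid, channel, conc, time):
    d = table.design
    cols = d.index[
        (d["channel"] == channel)
        & (d["wbe_concentration"].astype(float) == conc)
        & (d["time_h"].astype(float) == time)
    ]
    return table.areas.loc[fid, cols].to_numpy(dtype=float)


def _ttest_p(a, b):
    a = np.where(np.isnan(a), 0.0, a)
    b = np.where(np.isnan(b), 0.0, b)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _ratio(num, den):
    num = np.where(np.isnan(num), 0.0, num).mean()
    den = np.where(np.isnan(den), 0.0, den).mean()
    if den > 0:
        return num / den
    return np.inf if num > 0 else np.nan


def brute_force_labels(table, alpha=0.05, up=2.0, down=0.5, inter=1.25, min_detected=2):
    """Label per (feature, concentration) by literal rule application."""
    times = sorted(set(table.design["time_h"].astype(float)))
    t0, t4, t24 = times
    concs = sorted(
        set(
            table.design.loc[
                table.design["channel"] == "HFS_WBE", "wbe_concentration"
            ].astype(float)
        )
    )
    ec_conc = float(
        table.design.loc[
            table.design["channel"] == "EXTRACT_CONTROL", "wbe_concentration"
        ].iloc[0]
    )
    labels = {}
    flags = {}
    for fid in table.features.index:

        def present(vals):
            return int(np.sum(~np.isnan(vals))) >= min_detected

        matrix = any(
            present(_cell(table, fid, ch, 0.0, t))
            for ch in ("HFS_VEHICLE", "HFS_PBS")
            for t in times
        )
        fast = present(_cell(table, fid, "EXTRACT_CONTROL", ec_conc, t0)) and not any(
            present(_cell(table, fid, "HFS_WBE", c, t)) for c in concs for t in times
        )

        def classify(channel, conc):
            a0 = _cell(table, fid, channel, conc, t0)
            a4 = _cell(table, fid, channel, conc, t4)
            a24 = _cell(table, fid, channel, conc, t24)
            if not (present(a0) or present(a4) or present(a24)):
                return "INSUFFICIENT_DATA"
            r_4_0, p_4_0 = _ratio(a4, a0), _ttest_p(a0, a4)
            r_24_0, p_24_0 = _ratio(a24, a0), _ttest_p(a0, a24)
            r_4_24 = _ratio(a4, a24)
            if (
                present(a4)
                and not np.isnan(r_4_0)
                and r_4_0 > up
                and p_4_0 < alpha
                and not np.isnan(r_4_24)
                and r_4_24 > inter
            ):
                return "INTERMEDIATE"
            if present(a24) and not np.isnan(r_24_0) and r_24_0 > up and p_24_0 < alpha:
                return "INCREASING"
            if present(a0) and not np.isnan(r_24_0) and r_24_0 < down and p_24_0 < alpha:
                return "DECREASING"
            return "UNCHANGED"

        ec_a0 = _cell(table, fid, "EXTRACT_CONTROL", ec_conc, t0)
        ec_a4 = _cell(table, fid, "EXTRACT_CONTROL", ec_conc, t4)
        ec_a24 = _cell(table, fid, "EXTRACT_CONTROL", ec_conc, t24)
        if present(ec_a0) or present(ec_a4) or present(ec_a24):
            ec_label = classify("EXTRACT_CONTROL", ec_conc)
        else:
            ec_label = "INSUFFICIENT_DATA"
        for conc in concs:
            if matrix:
                label = "MATRIX"
            elif fast:
                label = "FAST_METABOLIZED"
            else:
                label = classify("HFS_WBE", conc)
            labels[(fid, conc)] = label
            flags[(fid, conc)] = (label, ec_label) in (
                ("INCREASING", "INCREASING"),
                ("DECREASING", "DECREASING"),
            )
    return labels, flags
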