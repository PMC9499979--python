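"""Noise-condition assembly and nonparametric group comparison.

Every recorded hour is labelled with one of eight noise conditions — the
presence/absence combinations of ultrasonic antifouling (UA) signals,
echosounders, and vessel engine noise — and hourly beaked-whale detection
sums (minutes per hour with clicks) are compared across conditions with a
Kruskal–Wallis test followed by Dunn-type mean-rank z tests under
Bonferroni correction, with mean-rank comparison intervals for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Condition codes: 1 = all absent … 8 = all present.
CONDITION_NAMES = {
    1: "quiet",
    2: "vessel",
    3: "echosounder",
    4: "vessel+echosounder",
    5: "UA",
    6: "UA+vessel",
    7: "UA+echosounder",
    8: "UA+echosounder+vessel",
}

_ECHO_CLASSES = {"echosounder", "echosounder_28", "echosounder_50"}


def condition_code(ua: bool, echo: bool, vessel: bool) -> int:
    """Map the three presence flags onto the 1–8 condition enumeration."""
    return 1 + int(vessel) + 2 * int(echo) + 4 * int(ua)


def _merge_class_intervals(log: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping encounters within each signal class (with warning)."""
    out = []
    for cls, grp in log.groupby("signal_class"):
        grp = grp.sort_values("start_utc")
        merged: list[list] = []
        overlapped = False
        for _, row in grp.iterrows():
            if merged and row["start_utc"] < merged[-1][1]:
                overlapped = True
                merged[-1][1] = max(merged[-1][1], row["end_utc"])
            else:
                merged.append([row["start_utc"], row["end_utc"]])
        if overlapped:
            warnings.warn(f"overlapping {cls} encounters merged", stacklevel=3)
        for a, b in merged:
            out.append({"signal_class": cls, "start_utc": a, "end_utc": b})
    return pd.DataFrame(out, columns=["signal_class", "start_utc", "end_utc"])


def _overlaps_hour(log: pd.DataFrame, hour: pd.Timestamp) -> bool:
    end = hour + pd.Timedelta(hours=1)
    return bool(((log["start_utc"] < end) & (log["end_utc"] > hour)).any())


def hourly_assemble(
    bw_log: pd.DataFrame,
    anthro_log: pd.DataFrame,
    coverage: list[tuple] | None = None,
) -> pd.DataFrame:
    """Build hourly records with minute sums, presence flags and condition.

    ``coverage`` lists (start_utc, end_utc) recording-effort intervals;
    hours with no effort are excluded.  An hour's class flag is true if any
    encounter of that class overlaps it (any-overlap semantics), and
    ``bw_minutes`` counts the distinct UTC minute bins within the hour that
    any beaked-whale encounter touches.
    """
    bw_log = _merge_class_intervals(bw_log) if len(bw_log) else bw_log
    anthro_log = _merge_class_intervals(anthro_log) if len(anthro_log) else anthro_log
    if coverage is None:
        stamps = pd.concat(
            [df[col] for df in (bw_log, anthro_log) for col in ("start_utc", "end_utc") if len(df)]
        )
        if stamps.empty:
            raise ValueError("no coverage intervals and no encounters to infer them from")
        coverage = [(stamps.min(), stamps.max())]
    hours: set[pd.Timestamp] = set()
    for a, b in coverage:
        a, b = pd.Timestamp(a), pd.Timestamp(b)
        last = (b - pd.Timedelta(nanoseconds=1)).floor("h")
        hours.update(pd.date_range(a.floor("h"), last, freq="h"))

    ua_log = anthro_log[anthro_log["signal_class"] == "ua"] if len(anthro_log) else anthro_log
    echo_log = (
        anthro_log[anthro_log["signal_class"].isin(_ECHO_CLASSES)]
        if len(anthro_log)
        else anthro_log
    )
    vessel_log = (
        anthro_log[anthro_log["signal_class"] == "vessel"] if len(anthro_log) else anthro_log
    )

    rows = []
    for hour in sorted(hours):
        end = hour + pd.Timedelta(hours=1)
        minutes = 0
        if len(bw_log):
            sel = bw_log[(bw_log["start_utc"] < end) & (bw_log["end_utc"] > hour)]
            bins: set[pd.Timestamp] = set()
            for _, row in sel.iterrows():
                a = max(row["start_utc"], hour).floor("min")
                b = (min(row["end_utc"], end) - pd.Timedelta(nanoseconds=1)).floor("min")
                bins.update(pd.date_range(a, b, freq="min"))
            minutes = len(bins)
        ua = _overlaps_hour(ua_log, hour) if len(ua_log) else False
        echo = _overlaps_hour(echo_log, hour) if len(echo_log) else False
        vessel = _overlaps_hour(vessel_log, hour) if len(vessel_log) else False
        rows.append(
            {
                "hour_utc": hour,
                "bw_minutes": minutes,
                "ua_present": ua,
                "echo_present": echo,
                "vessel_present": vessel,
                "condition": condition_code(ua, echo, vessel),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class KWResult:
    chi2: float
    df: int
    p: float
    group_sizes: dict
    mean_ranks: dict
    pairwise: pd.DataFrame | None = None
    intervals: pd.DataFrame | None = None


def kruskal_wallis(
    records: pd.DataFrame,
    value_col: str = "bw_minutes",
    group_col: str = "condition",
) -> KWResult:
    """Tie-corrected Kruskal–Wallis H across the non-empty groups."""
    groups = {g: d[value_col].to_numpy() for g, d in records.groupby(group_col) if len(d)}
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs at least two non-empty groups")
    h, p = sps.kruskal(*groups.values())
    pooled = records[[group_col, value_col]].copy()
    pooled["rank"] = sps.rankdata(pooled[value_col])
    mean_ranks = pooled.groupby(group_col)["rank"].mean().to_dict()
    return KWResult(
        chi2=float(h),
        df=len(groups) - 1,
        p=float(p),
        group_sizes={g: len(v) for g, v in groups.items()},
        mean_ranks=mean_ranks,
    )


def posthoc_pairwise(
    records: pd.DataFrame,
    value_col: str = "bw_minutes",
    group_col: str = "condition",
    alpha: float = 0.05,
) -> KWResult:
    """Dunn-type mean-rank z tests with Bonferroni correction.

    All k·(k−1)/2 pairs of non-empty groups are tested on pooled-rank
    means with the tie-corrected rank variance; adjusted p is
    min(1, raw·n_pairs).  Per-group "comparison intervals" (mean rank ±
    z_crit·sqrt(S²/(2n)) with z_crit at the Bonferroni-adjusted level) are
    returned for the familiar mean-rank interval plot: for equal group
    sizes, non-overlap corresponds to pairwise significance.
    """
    result = kruskal_wallis(records, value_col, group_col)
    values = records[value_col].to_numpy()
    labels = records[group_col].to_numpy()
    n = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_sum = np.sum(tie_counts**3 - tie_counts)
    s2 = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    groups = sorted(result.group_sizes)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for gi, gj in combinations(groups, 2):
        ri, rj = result.mean_ranks[gi], result.mean_ranks[gj]
        ni, nj = result.group_sizes[gi], result.group_sizes[gj]
        se = np.sqrt(s2 * (1.0 / ni + 1.0 / nj))
        z = (ri - rj) / se
        raw_p = 2.0 * sps.norm.sf(abs(z))
        adj_p = min(1.0, raw_p * n_pairs)
        rows.append(
            {
                "group_i": gi,
                "group_j": gj,
                "mean_rank_i": ri,
                "mean_rank_j": rj,
                "z": z,
                "raw_p": raw_p,
                "adjusted_p": adj_p,
                "significant": adj_p < alpha,
            }
        )
    z_crit = sps.norm.ppf(1.0 - alpha / (2.0 * n_pairs))
    intervals = pd.DataFrame(
        {
            "group": groups,
            "name": [CONDITION_NAMES.get(g, str(g)) for g in groups],
            "n": [result.group_sizes[g] for g in groups],
            "mean_rank": [result.mean_ranks[g] for g in groups],
            "halfwidth": [
                z_crit * np.sqrt(s2 / (2.0 * result.group_sizes[g])) for g in groups
            ],
        }
    )
    intervals["lower"] = intervals["mean_rank"] - intervals["halfwidth"]
    intervals["upper"] = intervals["mean_rank"] + intervals["halfwidth"]
    result.pairwise = pd.DataFrame(rows)
    result.intervals = intervals
    return result
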