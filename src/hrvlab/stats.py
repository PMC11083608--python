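"""Device-validation and cohort-comparison statistics.

Provides the mean-squared error and relative-error measures used to compare
two interval series (e.g. two recording devices), Welch two-sample t-tests of
a reference group against each other group, a one-way ANOVA across all
groups, and a cohort pipeline that runs every HRV method on every record and
aggregates per-parameter group means +/- sd with the test p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .frequency import WelchConfig, spectral_analysis
from .io import RrSeries, register_report
from .poincare import poincare
from .recurrence import RqaConfig, rqa_from_rr
from .time_domain import time_domain

__all__ = [
    "GroupComparison",
    "mse",
    "relative_error",
    "compare_groups",
    "cohort_pipeline",
    "comparisons_to_frame",
]

log = logging.getLogger(__name__)


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error (1/N) * sum((x_i - y_i)^2); units are input units squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("series must be equal-length 1-D with N >= 1")
    return float(np.mean((x - y) ** 2))


def relative_error(x: np.ndarray, y: np.ndarray) -> float:
    """Relative error of means, in percent: 100*|mean(x) - mean(y)|/mean(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx = float(x.mean())
    if mx == 0:
        raise ValidationError("reference series has zero mean")
    return float(100.0 * abs(mx - y.mean()) / mx)


@register_report
@dataclass
class GroupComparison:
    """Per-parameter cross-group summary (Welch t vs reference; one-way ANOVA)."""

    parameter: str
    group_names: list
    group_means: list
    group_sds: list
    group_ns: list
    p_t: dict = field(default_factory=dict)  # other-group name -> p-value
    p_anova: float | None = None


def compare_groups(values: dict[str, np.ndarray], reference: str,
                   parameter: str = "", equal_var: bool = False
                   ) -> GroupComparison:
    """Compare one parameter across groups.

    Two-sided t-test (Welch by default) of ``reference`` against each other
    group, plus a one-way ANOVA across all groups.  ANOVA is None (with a
    warning) when every group has zero within-group variance.
    """
    if len(values) < 2:
        raise ValidationError("need at least 2 groups")
    if reference not in values:
        raise ValidationError(f"reference group {reference!r} not present")
    arrays = {g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
              for g, v in values.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
    names = list(arrays)
    ref = arrays[reference]
    p_t: dict[str, float] = {}
    for g in names:
        if g == reference:
            continue
        if ref.std(ddof=1) == 0 and arrays[g].std(ddof=1) == 0:
            p_t[g] = 1.0 if ref.mean() == arrays[g].mean() else 0.0
            continue
        res = sps.ttest_ind(ref, arrays[g], equal_var=equal_var)
        p_t[g] = float(res.pvalue)
    if all(v.std(ddof=1) == 0 for v in arrays.values()):
        warnings.warn("zero within-group variance everywhere; ANOVA undefined",
                      stacklevel=2)
        p_anova = None
    else:
        p_anova = float(sps.f_oneway(*arrays.values()).pvalue)
    return GroupComparison(
        parameter=parameter,
        group_names=names,
        group_means=[float(arrays[g].mean()) for g in names],
        group_sds=[float(arrays[g].std(ddof=1)) for g in names],
        group_ns=[int(arrays[g].size) for g in names],
        p_t=p_t,
        p_anova=p_anova,
    )


# Parameters emitted per record by the cohort pipeline.
_PIPELINE_PARAMS = [
    "mean_rr", "sdnn", "sdann", "rmssd", "sdnn_index", "pnn50", "hrv_ti",
    "tinn", "vlf_power", "lf_power", "hf_power", "lf_nu", "hf_nu", "lf_hf",
    "sd1", "sd2", "sd1_sd2", "rec", "det", "lam", "entr",
]


def analyze_record(rr: RrSeries, welch_cfg: WelchConfig | None = None,
                   rqa_cfg: RqaConfig | None = None) -> dict[str, float | None]:
    """All scalar HRV parameters of one NN series, as a flat dict."""
    out: dict[str, float | None] = {}
    t = time_domain(rr)
    for name in ("mean_rr", "sdnn", "sdann", "rmssd", "sdnn_index", "pnn50",
                 "hrv_ti", "tinn"):
        out[name] = getattr(t, name)
    s = spectral_analysis(rr, welch_cfg)
    for name in ("vlf_power", "lf_power", "hf_power", "lf_nu", "hf_nu",
                 "lf_hf"):
        out[name] = getattr(s, name)
    p = poincare(rr)
    out["sd1"], out["sd2"], out["sd1_sd2"] = p.sd1, p.sd2, p.ratio
    r = rqa_from_rr(rr, rqa_cfg)
    out["rec"], out["det"], out["lam"], out["entr"] = r.rec, r.det, r.lam, r.entr
    return out


def cohort_pipeline(records: list[tuple[RrSeries, str]], reference: str,
                    welch_cfg: WelchConfig | None = None,
                    rqa_cfg: RqaConfig | None = None,
                    ) -> tuple[list[GroupComparison], int]:
    """Run every HRV method per record and compare the groups per parameter.

    ``records`` is a list of (NN series, group label) pairs.  Per-record
    failures are logged and excluded; the failure count is returned alongside
    the comparisons.  With a single group the t/ANOVA columns stay empty.
    """
    per_group: dict[str, list[dict]] = {}
    failures = 0
    for rr, group in records:
        try:
            per_group.setdefault(group, []).append(
                analyze_record(rr, welch_cfg, rqa_cfg))
        except Exception as exc:  # noqa: BLE001 — per-record isolation
            failures += 1
            log.warning("record %r in group %r failed: %s", rr.label, group, exc)
    per_group = {g: rows for g, rows in per_group.items() if len(rows) >= 2}
    if not per_group:
        raise ValidationError("no group retained at least 2 records")
    comparisons: list[GroupComparison] = []
    single = len(per_group) < 2
    for param in _PIPELINE_PARAMS:
        values = {
            g: np.asarray([row[param] for row in rows
                           if row[param] is not None], dtype=float)
            for g, rows in per_group.items()
        }
        values = {g: v for g, v in values.items() if v.size >= 2}
        if not values:
            continue
        if single or len(values) < 2 or reference not in values:
            names = list(values)
            comparisons.append(GroupComparison(
                parameter=param, group_names=names,
                group_means=[float(values[g].mean()) for g in names],
                group_sds=[float(values[g].std(ddof=1)) for g in names],
                group_ns=[int(values[g].size) for g in names],
                p_t={}, p_anova=None,
            ))
        else:
            comparisons.append(
                compare_groups(values, reference=reference, parameter=param))
    return comparisons, failures


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular (one row per parameter) view of a comparison list."""
    rows = []
    for c in comparisons:
        row: dict = {"parameter": c.parameter}
        for g, mean, sd, n in zip(c.group_names, c.group_means, c.group_sds,
                                  c.group_ns):
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
            row[f"{g}_n"] = n
        for g, p in c.p_t.items():
            row[f"p_t_{g}"] = p
        row["p_anova"] = c.p_anova
        rows.append(row)
    return pd.DataFrame(rows)
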