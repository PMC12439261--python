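"""Statistical layer: Pearson correlation with linear fit, one-way ANOVA
with Tukey's post-hoc test, and node-level report assembly.

p-values are reported but never drive automated decisions, and no
multiple-testing correction is applied across the report table; the table
carries the number of tests so a reader can adjust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    SampleSizeError,
    UndefinedCorrelationError,
)


@dataclass
class CorrelationResult:
    r: float
    p: float
    r_squared: float
    slope: float
    intercept: float
    n: int


@dataclass
class AnovaResult:
    f: float
    p: float
    group_means: list
    tukey: list  # (i, j, mean_diff, adjusted p) for every unordered pair


def pearson_fit(x, y) -> CorrelationResult:
    """Pearson r with two-sided p (t transform, n−2 df), R² and OLS line."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise SampleSizeError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise SampleSizeError(f"need n >= 3 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    fit = sps.linregress(x, y)
    r = float(fit.rvalue)
    return CorrelationResult(
        r=r,
        p=float(fit.pvalue),
        r_squared=r * r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=n,
    )


def anova_tukey(groups, post_hoc: bool = True) -> AnovaResult:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    F = MS_between / MS_within; Tukey adjusted p-values come from the
    studentized-range distribution at the pooled degrees of freedom.
    ``post_hoc=False`` skips the pairwise comparisons (e.g. in
    calibration loops that only need the omnibus test).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise SampleSizeError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise SampleSizeError("every group needs at least 2 values")
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        raise DegenerateVarianceError("zero pooled within-group variance")
    f, p = sps.f_oneway(*groups)
    pairs = []
    if post_hoc:
        hsd = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairs.append(
                    (
                        i,
                        j,
                        float(groups[i].mean() - groups[j].mean()),
                        float(hsd.pvalue[i, j]),
                    )
                )
    return AnovaResult(
        f=float(f),
        p=float(p),
        group_means=[float(g.mean()) for g in groups],
        tukey=pairs,
    )


PARAM_NAMES = (
    "n_tracks",
    "vessel_area_px",
    "vessel_density_pct",
    "mean_flow_speed_mm_s",
    "sum_mb_flow_count",
)
SCOPES = ("whole", "type1", "type2", "type3")


def build_report(nodes: list[dict]) -> pd.DataFrame:
    """Correlate every vascular parameter × scope against lymphatic density.

    Parameters
    ----------
    nodes : list of dicts, one per node, with keys
        ``lvd_pct`` (float) and ``params`` — a mapping from scope name
        ("whole", "type1", "type2", "type3") to a VascularParams (or a
        plain dict of the five parameters).  A node missing a scope is
        excluded from that scope's rows with a warning (it still
        contributes to the scopes it has).

    Returns
    -------
    DataFrame with columns parameter, scope, r, p, R2, slope, intercept, n,
    n_tests.
    """
    if len(nodes) < 3:
        raise SampleSizeError("need at least 3 nodes with complete measurements")
    rows = []
    for scope in SCOPES:
        have = [nd for nd in nodes if scope in nd["params"] and nd["params"][scope] is not None]
        missing = len(nodes) - len(have)
        if missing:
            warnings.warn(
                f"scope {scope!r}: {missing} node(s) missing and excluded",
                stacklevel=2,
            )
        if len(have) < 3:
            continue
        lvd = np.array([nd["lvd_pct"] for nd in have], dtype=np.float64)
        for name in PARAM_NAMES:
            vals = []
            for nd in have:
                p = nd["params"][scope]
                vals.append(p[name] if isinstance(p, dict) else getattr(p, name))
            vals = np.asarray(vals, dtype=np.float64)
            try:
                res = pearson_fit(vals, lvd)
            except UndefinedCorrelationError:
                continue
            rows.append(
                {
                    "parameter": name,
                    "scope": scope,
                    "r": res.r,
                    "p": res.p,
                    "R2": res.r_squared,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "n": res.n,
                }
            )
    df = pd.DataFrame(rows, columns=["parameter", "scope", "r", "p", "R2", "slope", "intercept", "n"])
    df["n_tests"] = len(df)
    return df


def report_markdown(df: pd.DataFrame) -> str:
    """Human-readable summary of a correlation report table."""
    lines = ["| parameter | scope | r | R² | P | n |", "|---|---|---|---|---|---|"]
    for _, row in df.iterrows():
        lines.append(
            f"| {row.parameter} | {row.scope} | {row.r:+.3f} | {row.R2:.3f} "
            f"| {row.p:.2e} | {int(row.n)} |"
        )
    lines.append(f"\n{len(df)} correlations computed (no multiplicity adjustment).")
    return "\n".join(lines)
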