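"""Group statistics: t-tests, chi-square, AUC summaries, FDR, and
metric-cognition correlation.

Per-sparsity metric values are compared between groups with pooled-variance
(Student) two-sample two-tailed t-tests; the sign convention throughout is
patient minus control, so a positive t means the metric is higher in
patients. Because per-sparsity tests are threshold-dependent, each
subject's metric curve is also summarised by the area under the curve
(AUC, trapezoid rule) over a stated sparsity range and tested once.
Multiple comparisons are corrected by Benjamini-Hochberg FDR within each
metric family. Group summaries printed as mean +/- SD can be tested
directly from the summary triples (``summary_ttest``), which is exactly
equivalent to the raw-data pooled t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryStatsGroup",
    "TTestResult",
    "MetricCurve",
    "two_sample_ttest",
    "summary_ttest",
    "chi_square_2x2",
    "curve_auc",
    "bh_fdr",
    "auc_table",
    "compare_groups_over_grid",
    "metric_cognition_correlation",
]


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class SummaryStatsGroup:
    """A printed group summary: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise StatsError("sd must be >= 0")
        if self.n < 2:
            raise StatsError("n must be >= 2")


@dataclass
class MetricCurve:
    """One subject's metric across the sparsity grid, with AUC summaries."""

    subject_id: str
    metric: str
    sparsities: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sparsities.shape != self.values.shape:
            raise StatsError("sparsities and values must align")

    def auc(self, lo: float | None = None, hi: float | None = None) -> float:
        lo = self.sparsities[0] if lo is None else lo
        hi = self.sparsities[-1] if hi is None else hi
        return curve_auc(self.sparsities, self.values, lo, hi)


def two_sample_ttest(x: Sequence[float], y: Sequence[float], equal_var: bool = True) -> TTestResult:
    """Two-sample two-tailed t-test; pooled-variance (Student) by default.

    ``equal_var=False`` gives the Welch variant. Order matters for the
    sign: t > 0 means mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise StatsError("zero pooled variance: t-test undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = len(x) + len(y) - 2 if equal_var else float(res.df)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def summary_ttest(a: SummaryStatsGroup, b: SummaryStatsGroup, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test from printed (mean, SD, n) triples.

    Identical to ``two_sample_ttest`` on any raw data realising exactly
    those summaries.
    """
    if a.sd == 0 and b.sd == 0:
        raise StatsError("zero pooled variance: t-test undefined")
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def chi_square_2x2(table, method: str = "pearson"):
    """Association test for a 2x2 count table.

    ``method='pearson'`` (default): Pearson chi-square without continuity
    correction, df = 1; ``'yates'``: with continuity correction;
    ``'fisher'``: Fisher's exact test (returns statistic = odds ratio).
    Returns ``(statistic, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if (t < 0).any():
        raise StatsError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("zero marginal: test undefined")
    if method == "fisher":
        res = sps.fisher_exact(t)
        return float(res.statistic), float(res.pvalue)
    if method not in ("pearson", "yates"):
        raise StatsError(f"unknown method {method!r}")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected <= 0).any():
        raise StatsError("zero expected count: test undefined")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=(method == "yates"))
    return float(chi2), float(p)


def curve_auc(sparsities, values, lo: float, hi: float) -> float:
    """Trapezoid-rule integral of a metric curve over [lo, hi].

    Endpoints must be grid points of the curve.
    """
    s = np.asarray(sparsities, dtype=float)
    v = np.asarray(values, dtype=float)
    i0 = np.flatnonzero(np.isclose(s, lo, atol=1e-9))
    i1 = np.flatnonzero(np.isclose(s, hi, atol=1e-9))
    if len(i0) == 0 or len(i1) == 0 or i1[0] < i0[0]:
        raise StatsError(f"AUC range [{lo}, {hi}] endpoints not on the curve's grid")
    sl = slice(i0[0], i1[0] + 1)
    if i1[0] == i0[0]:
        return 0.0
    return float(np.trapezoid(v[sl], s[sl]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _group_vectors(df: pd.DataFrame, groups: pd.Series, value_col: str):
    g = df["subject"].map(groups)
    x = df.loc[g == "patient", value_col].to_numpy(dtype=float)
    y = df.loc[g == "control", value_col].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError(
            f"need >= 2 subjects per group, got {len(x)} patients / {len(y)} controls"
        )
    return x, y


def auc_table(
    global_curves: pd.DataFrame,
    auc_range: tuple[float, float],
    metrics: Sequence[str] = ("Cp", "Lp", "Eglob", "Eloc"),
) -> pd.DataFrame:
    """Per-subject AUC of each global metric over ``auc_range`` (long format)."""
    rows = []
    for sid, sub in global_curves.groupby("subject", sort=True):
        sub = sub.sort_values("sparsity")
        for m in metrics:
            rows.append(
                dict(
                    subject=sid,
                    metric=m,
                    auc=curve_auc(sub["sparsity"], sub[m], *auc_range),
                )
            )
    return pd.DataFrame(rows)


def compare_groups_over_grid(
    global_curves: pd.DataFrame,
    groups: pd.Series,
    grid,
    nodal_curves: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
    report_sparsity: float = 0.18,
    auc_range: tuple[float, float] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Group comparison of metric curves: per-sparsity, AUC, and nodal tests.

    Parameters
    ----------
    global_curves : DataFrame
        Per-subject rows (subject, sparsity, Cp, Lp, Eglob, Eloc).
    groups : Series
        subject_id -> 'patient' / 'control'.
    grid : SparsityGrid
    nodal_curves : DataFrame, optional
        Long format (subject, region, metric, sparsity, value); when given,
        per-region tests are run at ``report_sparsity`` for each nodal
        metric, BH-corrected across the regions within each metric family.
    auc_range : (lo, hi), optional
        Defaults to the full grid span.

    Returns a tidy DataFrame with columns metric, scope, region, sparsity,
    t, df, p, q, direction, significant — the sign convention is patient
    minus control. Per-sparsity and AUC global tests are BH-corrected
    within each (metric, scope) family.
    """
    if auc_range is None:
        auc_range = (float(grid.values[0]), float(grid.values[-1]))
    results = []

    metrics_present = [m for m in ("Cp", "Lp", "Eglob", "Eloc") if m in global_curves.columns]
    for m in metrics_present:
        fam = []
        for s in grid.values:
            sub = global_curves[np.isclose(global_curves["sparsity"], float(s))]
            x, y = _group_vectors(sub, groups, m)
            t, df, p = two_sample_ttest(x, y, equal_var=equal_var)
            fam.append(dict(metric=m, scope="global", region="", sparsity=float(s),
                            t=t, df=df, p=p))
        q = bh_fdr([r["p"] for r in fam])
        for r, qv in zip(fam, q):
            r["q"] = float(qv)
        results.extend(fam)

    if len(grid.values) > 1:
        aucs = auc_table(global_curves, auc_range, metrics=metrics_present)
        fam = []
        for m in metrics_present:
            sub = aucs[aucs["metric"] == m]
            x, y = _group_vectors(sub, groups, "auc")
            t, df, p = two_sample_ttest(x, y, equal_var=equal_var)
            fam.append(dict(metric=m, scope="global_auc", region="", sparsity=np.nan,
                            t=t, df=df, p=p))
        q = bh_fdr([r["p"] for r in fam])
        for r, qv in zip(fam, q):
            r["q"] = float(qv)
        results.extend(fam)

    if nodal_curves is not None:
        at_s = nodal_curves[np.isclose(nodal_curves["sparsity"], report_sparsity)]
        if len(at_s) == 0:
            raise StatsError(f"report sparsity {report_sparsity} not present in nodal curves")
        for m, mdf in at_s.groupby("metric", sort=True):
            if m == "degree":
                continue
            fam = []
            for region, rdf in mdf.groupby("region", sort=True):
                x, y = _group_vectors(rdf, groups, "value")
                if (x.var(ddof=1) == 0 and y.var(ddof=1) == 0) or (
                    np.isnan(x).any() or np.isnan(y).any()
                ):
                    continue
                t, df, p = two_sample_ttest(x, y, equal_var=equal_var)
                fam.append(dict(metric=m, scope="nodal", region=region,
                                sparsity=report_sparsity, t=t, df=df, p=p))
            if fam:
                q = bh_fdr([r["p"] for r in fam])
                for r, qv in zip(fam, q):
                    r["q"] = float(qv)
                results.extend(fam)

    out = pd.DataFrame(results)
    out["direction"] = np.sign(out["t"]).astype(int)
    out["significant"] = out["q"] < fdr_q
    return out


def metric_cognition_correlation(
    global_curves: pd.DataFrame,
    scores: pd.DataFrame,
    auc_range: tuple[float, float] = (0.08, 0.31),
    nodal_curves: pd.DataFrame | None = None,
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation between per-subject metric AUCs and cognitive scores.

    ``scores`` is indexed by subject_id, one column per score. Correlations
    are computed for every global metric (and, when ``nodal_curves`` is
    given, for every region's nodal metrics, BH-corrected across regions
    within each metric-score family). ``subjects`` restricts the analysis
    (e.g. to the patient group, as when probing cognition-connectome
    coupling within patients).
    """
    gc = global_curves
    if subjects is not None:
        gc = gc[gc["subject"].isin(subjects)]
    have = sorted(gc["subject"].unique())
    missing = [s for s in have if s not in scores.index]
    if missing:
        raise StatsError(f"no cognitive scores for subject(s) {missing[:3]}")
    metrics_present = [m for m in ("Cp", "Lp", "Eglob", "Eloc") if m in gc.columns]
    aucs = auc_table(gc, auc_range, metrics=metrics_present).pivot(
        index="subject", columns="metric", values="auc"
    )
    rows = []
    for score_name in scores.columns:
        svec = scores.loc[aucs.index, score_name].to_numpy(dtype=float)
        if np.std(svec) == 0:
            raise StatsError(f"score {score_name!r} is constant: correlation undefined")
        for m in metrics_present:
            r, p = sps.pearsonr(aucs[m].to_numpy(dtype=float), svec)
            rows.append(dict(metric=m, scope="global", region="", score=score_name,
                             r=float(r), p=float(p), q=float(p), n=len(svec)))
    if nodal_curves is not None:
        nc = nodal_curves
        if subjects is not None:
            nc = nc[nc["subject"].isin(subjects)]
        lo, hi = auc_range
        nc = nc[(nc["sparsity"] >= lo - 1e-9) & (nc["sparsity"] <= hi + 1e-9)]
        for score_name in scores.columns:
            for m, mdf in nc.groupby("metric", sort=True):
                if m == "degree":
                    continue
                fam = []
                for region, rdf in mdf.groupby("region", sort=True):
                    piv = rdf.pivot(index="subject", columns="sparsity", values="value")
                    piv = piv.sort_index()
                    if piv.isna().any().any():
                        continue
                    s_vals = piv.columns.to_numpy(dtype=float)
                    auc = np.trapezoid(piv.to_numpy(dtype=float), s_vals, axis=1)
                    svec = scores.loc[piv.index, score_name].to_numpy(dtype=float)
                    if np.std(auc) == 0:
                        continue
                    r, p = sps.pearsonr(auc, svec)
                    fam.append(dict(metric=m, scope="nodal", region=region,
                                    score=score_name, r=float(r), p=float(p),
                                    n=len(svec)))
                if fam:
                    q = bh_fdr([d["p"] for d in fam])
                    for d, qv in zip(fam, q):
                        d["q"] = float(qv)
                    rows.extend(fam)
    return pd.DataFrame(rows)
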