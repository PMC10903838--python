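"""Cohort statistics: paired t, Welch t, one-way ANOVA, Spearman correlation.

Matches the analysis plan of a prone-vs-supine cohort study: paired t-tests
for position-related volume changes, independent (Welch) t for the <30% vs
>=30% fibrosis dichotomy, one-way ANOVA for three-level groupings, Spearman
for FVC/fibrosis correlations. All P values are two-sided and reported raw
(no multiple-testing correction, with an optional Holm adjustment helper).
Computation is delegated to scipy.stats behind this module surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError


@dataclass
class StatsResult:
    test_name: str
    n: int
    statistic: float
    dof: float
    p_two_sided: float
    estimate: float | None = None  # mean difference / correlation
    ci95: tuple | None = None
    group_ns: tuple | None = None

    def __post_init__(self):
        if not (np.isnan(self.p_two_sided) or 0.0 <= self.p_two_sided <= 1.0):
            raise ValidationError("p value outside [0, 1]")


@dataclass(frozen=True)
class GroupingRule:
    """How to split a cohort: fibrosis dichotomy at 30%, three fibrosis
    levels (none = 0%, mild < threshold, severe >= threshold), or the three
    CT pattern groups. A subject at exactly the threshold is severe."""

    kind: str = "fibrosis_dichotomy_30"
    threshold: float = 30.0

    _KINDS = ("fibrosis_dichotomy_30", "fibrosis_three_level", "pattern_three_level")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown grouping kind {self.kind!r}")

    def assign(self, record) -> str:
        if self.kind == "fibrosis_dichotomy_30":
            return "severe" if record.fibrosis_extent >= self.threshold else "mild"
        if self.kind == "fibrosis_three_level":
            if record.fibrosis_extent == 0:
                return "none"
            return "severe" if record.fibrosis_extent >= self.threshold else "mild"
        return record.pattern_group

    def group_names(self) -> tuple:
        if self.kind == "fibrosis_dichotomy_30":
            return ("mild", "severe")
        if self.kind == "fibrosis_three_level":
            return ("none", "mild", "severe")
        return ("normal", "UIP_or_probable", "indeterminate_or_alternative")


def paired_t(deltas) -> StatsResult:
    """One-sample t on paired differences; 95% CI of the mean difference."""
    d = np.asarray(deltas, dtype=np.float64)
    if d.size < 2:
        raise ValidationError("paired t requires n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("paired differences have zero variance")
    n = d.size
    res = sps.ttest_1samp(d, 0.0)
    se = sd / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    mean = float(d.mean())
    return StatsResult(
        "paired_t", n, float(res.statistic), float(n - 1), float(res.pvalue),
        estimate=mean, ci95=(mean - tcrit * se, mean + tcrit * se),
    )


def welch_t(group_a, group_b) -> StatsResult:
    """Welch's unequal-variance independent t with Welch-Satterthwaite dof."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch t requires n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return StatsResult("welch_t", a.size + b.size, 0.0, float(a.size + b.size - 2), 1.0,
                               estimate=0.0, ci95=(0.0, 0.0), group_ns=(a.size, b.size))
        raise DegenerateInputError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    dof = float(res.df)
    est = float(a.mean() - b.mean())
    se = float(np.sqrt(va / a.size + vb / b.size))
    tcrit = sps.t.ppf(0.975, dof)
    return StatsResult(
        "welch_t", a.size + b.size, float(res.statistic), dof, float(res.pvalue),
        estimate=est, ci95=(est - tcrit * se, est + tcrit * se), group_ns=(a.size, b.size),
    )


def oneway_anova(groups) -> StatsResult:
    """Classical one-way ANOVA F test over k >= 3 groups."""
    gs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(gs) < 3:
        raise ValidationError("one-way ANOVA requires >= 3 groups; use welch_t for two")
    if any(g.size < 2 for g in gs):
        raise ValidationError("one-way ANOVA requires n >= 2 per group")
    res = sps.f_oneway(*gs)
    k = len(gs)
    N = sum(g.size for g in gs)
    return StatsResult(
        "oneway_anova", N, float(res.statistic), float(k - 1), float(res.pvalue),
        group_ns=tuple(g.size for g in gs),
    )


def spearman(x, y) -> StatsResult:
    """Tie-corrected (average-rank) Spearman rho; p via the t approximation.

    Missing values are dropped pairwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValidationError("spearman requires paired samples")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("spearman requires n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman is undefined for a constant variable")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    n = x.size
    if abs(rho) < 1 and n > 3:
        z = np.arctanh(rho)
        hw = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = None
    return StatsResult("spearman", n, rho, float(n - 2), float(res.pvalue), estimate=rho, ci95=ci)


def holm_adjust(pvalues) -> list:
    """Holm step-down adjustment (optional; raw P values are the default)."""
    p = np.asarray(pvalues, dtype=np.float64)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

_MOVEMENT_METRICS = (
    ("max_3d_cm", "3D plane (cm)"),
    ("max_abs_x_cm", "X-axis (cm)"),
    ("max_abs_y_cm", "Y-axis (cm)"),
    ("max_abs_z_cm", "Z-axis (cm)"),
)


def _safe_paired(deltas):
    try:
        return paired_t(deltas), ""
    except DegenerateInputError:
        return None, "degenerate (zero variance)"
    except ValidationError as exc:
        return None, str(exc)


def cohort_tables(results, subjects, rules=None, include_failed: bool = False) -> dict:
    """Build the cohort report tables from per-subject results and metadata.

    Returns a dict of DataFrames: per-region paired-t volume changes, one
    movement comparison per grouping rule, and Spearman correlations of FVC
    and fibrosis with the key outcomes. QC-failed subjects are excluded by
    default (they are in the denominator of the run manifest instead).
    """
    rules = rules if rules is not None else [
        GroupingRule("fibrosis_dichotomy_30"),
        GroupingRule("fibrosis_three_level"),
        GroupingRule("pattern_three_level"),
    ]
    meta = {s.subject_id: s for s in subjects}
    kept = [r for r in results if (r.qc_passed or include_failed) and r.subject_id in meta]

    tables = {}

    # Volume-change table (per-region paired t on prone - supine deltas)
    vol_rows = []
    regions = []
    for r in kept:
        if r.volume_report is not None:
            regions = [reg for reg in r.volume_report.delta_ml]
            break
    for region in regions:
        deltas = [
            r.volume_report.delta_ml[region]
            for r in kept
            if r.volume_report is not None and region in r.volume_report.delta_ml
        ]
        res, flag = _safe_paired(deltas) if len(deltas) >= 2 else (None, "n < 2")
        vol_rows.append(
            {
                "region": region,
                "n": len(deltas),
                "mean_delta_ml": float(np.mean(deltas)) if deltas else np.nan,
                "sd_ml": float(np.std(deltas, ddof=1)) if len(deltas) > 1 else np.nan,
                "ci95_low_ml": res.ci95[0] if res else np.nan,
                "ci95_high_ml": res.ci95[1] if res else np.nan,
                "p_value": res.p_two_sided if res else np.nan,
                "flag": flag,
            }
        )
    tables["volume_changes"] = pd.DataFrame(vol_rows)

    # Movement comparisons per grouping rule
    moved = [r for r in kept if r.movement is not None]
    for rule in rules:
        rows = []
        names = rule.group_names()
        for attr, label in _MOVEMENT_METRICS:
            groups = {name: [] for name in names}
            for r in moved:
                groups[rule.assign(meta[r.subject_id])].append(getattr(r.movement, attr))
            row = {"metric": label}
            for name in names:
                vals = groups[name]
                row[f"{name}_n"] = len(vals)
                row[f"{name}_mean"] = float(np.mean(vals)) if vals else np.nan
                row[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            try:
                filled = [groups[name] for name in names if len(groups[name]) >= 2]
                if len(filled) == 2:
                    row["p_value"] = welch_t(filled[0], filled[1]).p_two_sided
                elif len(filled) >= 3:
                    row["p_value"] = oneway_anova(filled).p_two_sided
                else:
                    row["p_value"] = np.nan
            except (DegenerateInputError, ValidationError):
                row["p_value"] = np.nan
            rows.append(row)
        tables[f"movement_by_{rule.kind}"] = pd.DataFrame(rows)

    # Correlations
    corr_rows = []

    def corr(label, xs, ys):
        try:
            res = spearman(xs, ys)
            corr_rows.append(
                {"pair": label, "n": res.n, "rho": res.estimate, "p_value": res.p_two_sided}
            )
        except (ValidationError, DegenerateInputError):
            corr_rows.append({"pair": label, "n": len(xs), "rho": np.nan, "p_value": np.nan})

    fvc = [meta[r.subject_id].fvc_l if meta[r.subject_id].fvc_l is not None else np.nan for r in kept]
    fib = [meta[r.subject_id].fibrosis_extent for r in kept]
    lll = [
        r.volume_report.delta_ml.get("LLL", np.nan) if r.volume_report else np.nan for r in kept
    ]
    corr("FVC vs LLL volume change", fvc, lll)
    corr("fibrosis extent vs LLL volume change", fib, lll)
    for attr, label in _MOVEMENT_METRICS:
        vals = [getattr(r.movement, attr) if r.movement else np.nan for r in kept]
        corr(f"FVC vs {label}", fvc, vals)
    tables["correlations"] = pd.DataFrame(corr_rows)
    return tables
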