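"""The statistical battery and the structured report.

Two-group comparisons use an unpaired two-tailed t-test, with an F-test on
the variance ratio (α = 0.05) deciding between the pooled-variance and
Welch forms. Multi-group comparisons are screened per group for normality
(Shapiro–Wilk, α = 0.05) and routed to one-way ANOVA with Tukey/Dunnett
post-hocs, or to Kruskal–Wallis with Dunn's pairwise tests under Šidák
adjustment. Every result records which branch fired. Data summaries are
mean ± SEM; significance stars follow *p<0.05, **p<0.01, ***p<0.001,
****p<0.0001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))
VARIANCE_ALPHA = 0.05
NORMALITY_ALPHA = 0.05


def star_code(p: float) -> str:
    """Significance stars as a pure function of p and the declared thresholds."""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    groups: tuple = ()
    adjustment: str = "none"
    detail: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return star_code(self.pvalue)

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "pvalue": self.pvalue,
            "groups": list(self.groups), "adjustment": self.adjustment,
            "stars": self.stars, **self.detail,
        }


@dataclass
class GroupedMeasurements:
    """One parameter measured across cohort groups (e.g. N.CTX, Ki67-10...)."""

    parameter: str
    units: str
    groups: dict          # label -> list of values

    def summary(self) -> dict:
        out = {}
        for label, vals in self.groups.items():
            v = np.asarray(vals, float)
            out[label] = {
                "n": int(v.size),
                "mean": float(v.mean()) if v.size else float("nan"),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
            }
        return out


def compare_two(group_a, group_b) -> TestResult:
    """Unpaired two-tailed t-test; the F-test on the variance ratio selects
    pooled-variance vs Welch."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        logger.info("compare_two: zero variance in both groups; p set by convention")
        return TestResult("t", 0.0 if p == 1.0 else float("inf"), p,
                          detail={"branch": "degenerate"})
    if va >= vb:
        F, dfn, dfd = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p_f = min(1.0, 2.0 * sps.f.sf(F, dfn, dfd)) if np.isfinite(F) else 0.0
    equal_var = p_f >= VARIANCE_ALPHA
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        "student_t" if equal_var else "welch_t", float(t), float(p),
        detail={"branch": "pooled" if equal_var else "welch",
                "f_statistic": float(F), "f_pvalue": float(p_f)},
    )


def _dunn_sidak(groups: dict) -> list[TestResult]:
    """Dunn's rank-based pairwise tests with Šidák multiplicity adjustment."""
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n_total ** 3 - n_total) if n_total > 1 else 1.0
    var_base = n_total * (n_total + 1) / 12.0 * tie
    mean_rank, sizes = {}, {}
    i = 0
    for k in labels:
        n = len(groups[k])
        mean_rank[k] = ranks[i:i + n].mean()
        sizes[k] = n
        i += n
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for ka, kb in combinations(labels, 2):
        se = np.sqrt(var_base * (1 / sizes[ka] + 1 / sizes[kb]))
        z = (mean_rank[ka] - mean_rank[kb]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        p_adj = float(min(1.0, 1.0 - (1.0 - p) ** m))
        out.append(TestResult("dunn", float(z), p_adj, groups=(ka, kb),
                              adjustment="sidak", detail={"p_unadjusted": float(p)}))
    return out


def compare_many(groups: dict, posthoc: str = "tukey") -> list[TestResult]:
    """Omnibus + pairwise comparisons across ≥3 groups.

    A Shapiro–Wilk screen (α = 0.05 per group) routes to one-way ANOVA with
    the requested parametric post-hoc ("tukey" or "dunnett_vs_control",
    control = first group) or to Kruskal–Wallis with Dunn–Šidák pairwise
    tests. The omnibus result is returned first, pairwise results follow.
    """
    if len(groups) < 3:
        raise ValueError("compare_many needs >= 3 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    normal = all(
        v.size < 3 or np.ptp(v) == 0 or sps.shapiro(v).pvalue >= NORMALITY_ALPHA
        for v in arrays.values()
    )
    labels = list(arrays)
    results: list[TestResult] = []
    if normal:
        F, p = sps.f_oneway(*arrays.values())
        results.append(TestResult("anova", float(F), float(p), groups=tuple(labels),
                                  detail={"branch": "parametric"}))
        if posthoc == "tukey":
            hsd = sps.tukey_hsd(*arrays.values())
            for i, j in combinations(range(len(labels)), 2):
                results.append(TestResult(
                    "tukey_hsd", float(hsd.statistic[i, j]), float(hsd.pvalue[i, j]),
                    groups=(labels[i], labels[j]), adjustment="tukey",
                ))
        elif posthoc == "dunnett_vs_control":
            control = arrays[labels[0]]
            rest = [arrays[k] for k in labels[1:]]
            dn = sps.dunnett(*rest, control=control)
            for idx, k in enumerate(labels[1:]):
                results.append(TestResult(
                    "dunnett", float(dn.statistic[idx]), float(dn.pvalue[idx]),
                    groups=(labels[0], k), adjustment="dunnett",
                ))
        elif posthoc == "dunn_sidak":
            results.extend(_dunn_sidak(arrays))
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
    else:
        H, p = sps.kruskal(*arrays.values())
        results.append(TestResult("kruskal_wallis", float(H), float(p),
                                  groups=tuple(labels), detail={"branch": "nonparametric"}))
        results.extend(_dunn_sidak(arrays))
    return results


def correlation_matrix(parameter_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations across parameter columns.

    Missing values are dropped pairwise; a constant column yields an
    undefined r which is flagged (NaN) rather than silently reported as 0.
    Returns a long-form table (parameter_a, parameter_b, r, pvalue, n, flag).
    """
    cols = list(parameter_table.columns)
    rows = []
    for a, b in combinations(cols, 2):
        pair = parameter_table[[a, b]].dropna()
        n = len(pair)
        if n < 3:
            rows.append((a, b, np.nan, np.nan, n, "insufficient_n"))
            continue
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((a, b, np.nan, np.nan, n, "constant_column"))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((a, b, float(r), float(p), n, ""))
    return pd.DataFrame(rows, columns=["parameter_a", "parameter_b", "r", "pvalue", "n", "flag"])


def build_report(
    stage_outputs: dict,
    config: dict | None = None,
    seed: int | None = None,
    grouped: list[GroupedMeasurements] | None = None,
) -> dict:
    """Assemble one structured, deterministic report from stage outputs.

    Missing stages are marked absent rather than failing; provenance records
    the config, seed and software version (no timestamps, so equal inputs
    give byte-identical serialized reports).
    """
    from . import __version__

    if not stage_outputs:
        raise ValueError("at least one stage output is required")
    known_stages = ("simulate", "restore", "segment", "vessels", "walls",
                    "overlap", "tcells", "myeloid", "stats")
    stages = {
        name: (stage_outputs[name] if name in stage_outputs else {"status": "absent"})
        for name in known_stages
    }
    for name in stage_outputs:
        if name not in known_stages:
            stages[name] = stage_outputs[name]
    report = {
        "schema": "gliovasc-report-1",
        "provenance": {
            "software": "gliovasc",
            "version": __version__,
            "seed": seed,
            "config": config or {},
        },
        "stages": stages,
    }
    if grouped:
        report["group_summaries"] = {
            g.parameter: {"units": g.units, "groups": g.summary()} for g in grouped
        }
    return report
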