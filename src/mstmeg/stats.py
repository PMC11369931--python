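"""Statistics relating tree topology to the plasma biomarker.

The battery mirrors a cohort analysis in which, per frequency band, the
epoch-averaged tree metrics (leaf fraction, normalized diameter, tree
hierarchy) are correlated with a plasma biomarker:

* Pearson correlations across the whole sample — one family of
  bands x metrics tests under Benjamini-Hochberg FDR at q = 0.1;
* the same correlations within each risk group, FDR-corrected as a single
  pooled family across both groups;
* a one-tailed two-sample Fisher r-to-z comparison of the two group
  correlations per cell;
* a follow-up TH-LF correlation within a group, computed only where that
  group's TH test was significant (TH is non-monotone in topology, so its
  direction is read off the co-moving leaf fraction);
* demographic screens (biomarker vs age/education, sex differences), kept
  outside the FDR families.

Group t-tests are pooled-variance Student; the 2x2 chi-square carries no
continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_Q = 0.1
DEFAULT_METRICS = ("lf", "diameter", "th")
DEFAULT_BAND_NAMES = ("theta", "alpha", "beta")


@dataclass
class StatResult:
    """One test: estimate, raw p, and (when in an FDR family) adjusted q."""

    estimate: float
    stat: str                      # "rho", "t", "chi2" or "z"
    p_raw: float
    q_adj: float | None = None
    significant: bool | None = None
    n: int | None = None
    n1: int | None = None
    n2: int | None = None


@dataclass
class FdrResult:
    """Benjamini-Hochberg step-up outcome for one family of p-values."""

    q_adj: np.ndarray
    significant: np.ndarray
    threshold: float               # largest raw p in the rejection set (0 if none)
    q: float


def pearson_corr(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Pearson correlation with a two-tailed t-distribution p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = sps.pearsonr(x, y)
    return StatResult(estimate=float(r), stat="rho", p_raw=float(p), n=n)


def bh_fdr(pvals: np.ndarray, q: float = DEFAULT_Q) -> FdrResult:
    """Benjamini-Hochberg step-up over one family of raw p-values.

    Adjusted values are the usual step-up q-values (monotone, capped at 1);
    the rejection set is every p at or below p_(k), where k is the largest
    rank with p_(k) <= k q / M; the reported threshold is p_(k) itself
    (0 when nothing is rejected).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return FdrResult(q_adj=q_adj, significant=reject, threshold=threshold, q=q)


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> StatResult:
    """Pooled-variance Student t from group summaries, two-tailed."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=True)
    return StatResult(estimate=float(t), stat="t", p_raw=float(p),
                      n1=n1, n2=n2)


def two_sample_t_from_samples(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Pooled-variance Student t from raw samples, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return StatResult(estimate=float(t), stat="t", p_raw=float(p),
                      n1=a.size, n2=b.size)


def chi_square_2x2(counts) -> StatResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2):
        raise ValueError(f"counts must be 2x2, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(c.sum(axis=0) <= 0) or np.any(c.sum(axis=1) <= 0):
        raise ValueError("both margins must be positive")
    res = sps.chi2_contingency(c, correction=False)
    return StatResult(estimate=float(res.statistic), stat="chi2",
                      p_raw=float(res.pvalue), n=int(c.sum()))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> StatResult:
    """One-tailed two-sample Fisher r-to-z comparison of two correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with
    p = 1 - Phi(|z|).  Symmetric under swapping the two groups.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    if n1 < 4 or n2 < 4:
        raise ValueError("both groups need n >= 4")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 1.0 - sps.norm.cdf(abs(z))
    return StatResult(estimate=float(z), stat="z", p_raw=float(p),
                      n1=n1, n2=n2)


def _require_columns(table: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")


def metric_column(band: str, metric: str) -> str:
    return f"{band}_{metric}"


def run_association_battery(table: pd.DataFrame,
                            bands: tuple[str, ...] = DEFAULT_BAND_NAMES,
                            metrics: tuple[str, ...] = DEFAULT_METRICS,
                            q: float = DEFAULT_Q) -> pd.DataFrame:
    """The full battery over a cohort table; returns one tidy frame.

    Expects columns ``biomarker``, ``group`` and ``{band}_{metric}`` for
    every requested band and metric; ``age``, ``education`` and ``sex`` are
    screened when present.  Output columns: family, band, metric, group,
    stat, estimate, n, p_raw, q_adj, significant, fdr_threshold.
    """
    cells = list(product(bands, metrics))
    needed = ["biomarker", "group"] + [metric_column(b, m) for b, m in cells]
    _require_columns(table, needed)
    groups = [g for g in ("FH+", "FH-") if (table["group"] == g).any()]
    for g in groups:
        n_g = int((table["group"] == g).sum())
        if n_g < 4:
            raise ValueError(
                f"group {g!r} has {n_g} subjects; every analyzed group "
                "needs at least 4")
    rows: list[dict] = []

    def add(family, band, metric, group, res: StatResult, extra=None):
        rows.append({
            "family": family, "band": band, "metric": metric, "group": group,
            "stat": res.stat, "estimate": res.estimate,
            "n": res.n if res.n is not None else None,
            "p_raw": res.p_raw, "q_adj": res.q_adj,
            "significant": res.significant,
            **(extra or {}),
        })

    # (a) whole-sample correlations, one 9-test FDR family
    whole_idx = []
    for band, metric in cells:
        res = pearson_corr(table["biomarker"].to_numpy(),
                           table[metric_column(band, metric)].to_numpy())
        whole_idx.append(len(rows))
        add("whole_sample", band, metric, "all", res)
    _apply_fdr(rows, whole_idx, q)

    # (b) per-group correlations, one pooled FDR family over both groups
    sub_idx = []
    for group in groups:
        sub = table[table["group"] == group]
        for band, metric in cells:
            res = pearson_corr(sub["biomarker"].to_numpy(),
                               sub[metric_column(band, metric)].to_numpy())
            sub_idx.append(len(rows))
            add("subgroup", band, metric, group, res)
    if sub_idx:
        _apply_fdr(rows, sub_idx, q)

    # (c) between-group comparison of correlations, per cell (raw p, no FDR)
    if len(groups) == 2:
        by_cell = {(r["band"], r["metric"], r["group"]): r
                   for i, r in enumerate(rows) if r["family"] == "subgroup"}
        for band, metric in cells:
            r1 = by_cell[(band, metric, groups[0])]
            r2 = by_cell[(band, metric, groups[1])]
            res = compare_correlations(r1["estimate"], r1["n"],
                                       r2["estimate"], r2["n"])
            add("group_comparison", band, metric,
                f"{groups[0]} vs {groups[1]}", res)

    # (d) TH-LF follow-up within groups whose TH test was significant
    for r in [r for r in rows if r["family"] == "subgroup"
              and r["metric"] == "th" and r["significant"]]:
        sub = table[table["group"] == r["group"]]
        res = pearson_corr(sub[metric_column(r["band"], "th")].to_numpy(),
                           sub[metric_column(r["band"], "lf")].to_numpy())
        add("th_lf", r["band"], "th_vs_lf", r["group"], res)

    # (e) demographic screens, outside the FDR families
    if "age" in table.columns:
        add("demographics", None, "age", "all",
            pearson_corr(table["biomarker"].to_numpy(),
                         table["age"].to_numpy()))
    if "education" in table.columns:
        add("demographics", None, "education", "all",
            pearson_corr(table["biomarker"].to_numpy(),
                         table["education"].to_numpy()))
    if "sex" in table.columns:
        sexes = table["sex"].unique()
        if len(sexes) == 2:
            a = table.loc[table["sex"] == sexes[0], "biomarker"].to_numpy()
            b = table.loc[table["sex"] == sexes[1], "biomarker"].to_numpy()
            add("demographics", None, "biomarker_by_sex", "all",
                two_sample_t_from_samples(a, b))
            if len(groups) == 2:
                counts = [
                    [int(((table["sex"] == s) & (table["group"] == g)).sum())
                     for s in sexes] for g in groups]
                add("demographics", None, "sex_by_group", "all",
                    chi_square_2x2(counts))

    return pd.DataFrame(rows)


def _apply_fdr(rows: list[dict], idx: list[int], q: float) -> None:
    fam = bh_fdr(np.array([rows[i]["p_raw"] for i in idx]), q=q)
    for k, i in enumerate(idx):
        rows[i]["q_adj"] = float(fam.q_adj[k])
        rows[i]["significant"] = bool(fam.significant[k])
        rows[i]["fdr_threshold"] = fam.threshold
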