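"""Statistics for germplasm trait tables and 2D-3D method comparison.

Works on long-format trait tables with columns
``sample_id, variety, organ, method, trait, value`` (``method`` is '2D' or
'3D').  Provides per-group descriptive statistics, Pearson concordance
between measurement methods, trait-trait correlation matrices with
pairwise-complete observations, one-way ANOVA across varieties, and
Fisher's protected LSD test with a compact letter display.

Conventions: SD uses the n-1 denominator; quartiles use linear
interpolation; correlation matrices use pairwise-complete deletion; LSD is
protected (pairs tested only after a significant ANOVA) by default; raw
p-values are reported (no multiple-testing correction) unless an
adjustment is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DataError

TABLE_COLUMNS = ["sample_id", "variety", "organ", "method", "trait", "value"]


def make_trait_table(records) -> pd.DataFrame:
    """Build and validate a long-format trait table.

    Enforces uniqueness of (sample_id, method, trait) and finite values.
    """
    table = pd.DataFrame(records)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"trait table missing columns: {missing}")
    if not np.all(np.isfinite(table["value"].to_numpy(float))):
        raise DataError("trait table contains non-finite values")
    dup = table.duplicated(subset=["sample_id", "method", "trait"])
    if dup.any():
        raise DataError(f"{int(dup.sum())} duplicate (sample_id, method, trait) records")
    return table[TABLE_COLUMNS].copy()


def descriptive_stats(table: pd.DataFrame, by=("organ", "trait")) -> pd.DataFrame:
    """Per-group n, mean, SD, min, quartiles, max.

    SD uses the n-1 denominator and is NaN for singleton groups (not 0);
    quartiles use the linear-interpolation convention.
    """
    if len(table) == 0:
        raise DataError("empty trait table")
    grouped = table.groupby(list(by))["value"]
    out = grouped.agg(
        n="count",
        mean="mean",
        sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
        min="min",
        q25=lambda v: v.quantile(0.25),
        median="median",
        q75=lambda v: v.quantile(0.75),
        max="max",
    )
    return out.reset_index()


@dataclass
class ConcordanceResult:
    """Pearson agreement between two measurement methods for one trait."""

    trait: str
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float


def pearson(x, y, trait: str = "") -> ConcordanceResult:
    """Product-moment correlation with two-sided p (t transform, n-2 df),
    plus the least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise DataError("need at least 3 pairs for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError(f"undefined correlation: zero variance in {trait or 'input'}")
    res = _stats.pearsonr(x, y)
    fit = _stats.linregress(x, y)
    return ConcordanceResult(
        trait=trait,
        n=len(x),
        pearson_r=float(res.statistic),
        p_value=float(res.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def correlation_matrix(
    table: pd.DataFrame, traits: list[str], method: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise trait-trait Pearson matrix for one measurement method.

    Uses pairwise-complete observations, so n can differ per cell; returns
    (r, p, n) DataFrames.  The r matrix is symmetric with unit diagonal.
    """
    sub = table[table["method"] == method]
    for t in traits:
        if t not in set(sub["trait"]):
            raise KeyError(f"trait {t!r} absent from table for method {method!r}")
    wide = sub.pivot(index="sample_id", columns="trait", values="value")[traits]
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n, wide.notna().sum().to_numpy())
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                raise DataError(
                    f"fewer than 3 complete cases for {traits[i]!r} vs {traits[j]!r}"
                )
            res = pearson(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.pearson_r
            p[i, j] = p[j, i] = res.p_value
            n[i, j] = n[j, i] = res.n
    idx = pd.Index(traits, name="trait")
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


@dataclass
class AnovaResult:
    """Textbook one-way decomposition: F = MSB / MSE."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    mse: float
    group_means: pd.Series
    group_sizes: pd.Series


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA across named groups.

    Requires >= 2 groups each with >= 2 observations.  When every group is
    a constant (MSE = 0) F is reported as 0 with a missing p-value.
    """
    if len(groups) < 2:
        raise DataError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise DataError(f"group {k!r} has fewer than 2 observations")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    dfb = len(arrays) - 1
    dfw = len(all_values) - len(arrays)
    mse = ssw / dfw
    if mse <= 0:
        f = 0.0 if ssb <= 1e-30 else np.inf
        p = np.nan
    else:
        f = (ssb / dfb) / mse
        p = float(_stats.f.sf(f, dfb, dfw))
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_between=dfb,
        df_within=dfw,
        ss_between=float(ssb),
        ss_within=float(ssw),
        mse=float(mse),
        group_means=pd.Series({k: v.mean() for k, v in arrays.items()}),
        group_sizes=pd.Series({k: len(v) for k, v in arrays.items()}),
    )


@dataclass
class AnovaLsdResult:
    """ANOVA plus Fisher's LSD pairwise verdicts and letter display."""

    anova: AnovaResult
    alpha: float
    protected: bool
    lsd_value: float  # for the balanced case (equal n); NaN if unbalanced
    significant: pd.DataFrame  # boolean, symmetric, False diagonal
    letters: pd.Series  # compact letter display, indexed by group


def _compact_letters(names: list[str], means: pd.Series, sig: pd.DataFrame) -> pd.Series:
    """Compact letter display via the insert-and-absorb procedure.

    Starts from one column holding every group; each significantly
    different pair splits the columns containing both; absorbed (subset)
    columns are removed.  Letters are assigned to columns in order of the
    best mean they contain.
    """
    ordered = sorted(names, key=lambda g: -means[g])
    columns: list[set] = [set(ordered)]
    for i, gi in enumerate(ordered):
        for gj in ordered[i + 1 :]:
            if not sig.loc[gi, gj]:
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                for drop in (gi, gj):
                    new = col - {drop}
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(ordered.index(g) for g in c))
    letters = {g: "" for g in names}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li) if li < 26 else f"z{li}"
        for g in col:
            letters[g] += ch
    return pd.Series({g: "".join(sorted(letters[g])) for g in names})


def lsd_test(
    groups: dict[str, np.ndarray], alpha: float = 0.05, protected: bool = True
) -> AnovaLsdResult:
    """Fisher's least significant difference test.

    LSD(i, j) = t(1 - alpha/2, df_within) * sqrt(MSE * (1/n_i + 1/n_j));
    a pair differs when |mean_i - mean_j| > LSD(i, j).  When ``protected``
    the pairwise stage runs only if the ANOVA p <= alpha; otherwise no
    pair is declared different.
    """
    anova = one_way_anova(groups)
    names = list(anova.group_means.index)
    k = len(names)
    tcrit = float(_stats.t.ppf(1 - alpha / 2, anova.df_within))
    sizes = anova.group_sizes
    gate = (not protected) or (np.isfinite(anova.p_value) and anova.p_value <= alpha)
    sig = pd.DataFrame(False, index=names, columns=names)
    if gate and anova.mse > 0:
        for i in range(k):
            for j in range(i + 1, k):
                gi, gj = names[i], names[j]
                lsd_ij = tcrit * np.sqrt(anova.mse * (1 / sizes[gi] + 1 / sizes[gj]))
                differ = abs(anova.group_means[gi] - anova.group_means[gj]) > lsd_ij
                sig.loc[gi, gj] = sig.loc[gj, gi] = bool(differ)
    if sizes.nunique() == 1:
        n0 = int(sizes.iloc[0])
        lsd_value = tcrit * np.sqrt(anova.mse * 2.0 / n0)
    else:
        lsd_value = float("nan")
    letters = _compact_letters(names, anova.group_means, sig)
    return AnovaLsdResult(
        anova=anova,
        alpha=alpha,
        protected=protected,
        lsd_value=float(lsd_value),
        significant=sig,
        letters=letters,
    )


def concordance_report(
    table2d: pd.DataFrame, table3d: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Per-trait 2D-vs-3D Pearson concordance, ordered by descending r.

    Joins the two tables on (sample_id, trait); raises if no samples
    overlap.  Output columns: trait, n, pearson_r, p_value, slope,
    intercept (slope/intercept of 3D regressed on 2D).
    """
    merged = table2d.merge(
        table3d, on=["sample_id", "trait"], suffixes=("_2d", "_3d"), how="inner"
    )
    if len(merged) == 0:
        raise DataError("no overlapping (sample_id, trait) records between methods")
    if traits is None:
        traits = sorted(merged["trait"].unique())
    rows = []
    for trait in traits:
        sub = merged[merged["trait"] == trait]
        if len(sub) < 3:
            raise DataError(f"fewer than 3 paired samples for trait {trait!r}")
        res = pearson(sub["value_2d"], sub["value_3d"], trait=trait)
        rows.append(
            {
                "trait": trait,
                "n": res.n,
                "pearson_r": res.pearson_r,
                "p_value": res.p_value,
                "slope": res.slope,
                "intercept": res.intercept,
            }
        )
    report = pd.DataFrame(rows).sort_values("pearson_r", ascending=False, kind="stable")
    return report.reset_index(drop=True)


def adjust_pvalues(p: np.ndarray, method: str = "none") -> np.ndarray:
    """Optional multiple-testing adjustment ('none', 'bonferroni', 'fdr_bh')."""
    p = np.asarray(p, dtype=float)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise DataError(f"unknown adjustment method {method!r}")
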