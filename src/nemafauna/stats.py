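"""Inferential statistics: two-way ANOVA, paired t-tests, and RDA.

The study design is a balanced two-factor layout: treatment (decomposition-
impacted vs control) crossed with sampling day (categorical), six replicate
sites per cell.  Community-level ordination uses redundancy analysis (RDA)
on Euclidean distances, i.e. a constrained PCA of the community matrix on a
group-membership design, with decay-stage centroids and per-group standard
deviations for ellipse radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaTable",
    "PairedTestResult",
    "RdaResult",
    "two_way_anova",
    "paired_t",
    "rda",
]

_SS_TOL = 1e-12


@dataclass
class AnovaTable:
    """Fixed-effects crossed ANOVA with interaction (Type II sums of squares).

    For the balanced designs this analysis targets, Type II coincides with
    Type I/III; the choice is documented so unbalanced user data behaves
    predictably.  ``flags`` records degenerate regimes ('perfect_fit' when
    the residual SS vanishes, 'degenerate' when the total SS vanishes).
    """

    table: pd.DataFrame  # index: C(A), C(B), C(A):C(B), Residual; cols: sum_sq, df, F, PR(>F)
    flags: list[str] = field(default_factory=list)

    @property
    def total_ss(self) -> float:
        return float(self.table["sum_sq"].sum())

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def two_way_anova(
    response: np.ndarray | pd.Series,
    factor_a: np.ndarray | pd.Series,
    factor_b: np.ndarray | pd.Series,
) -> AnovaTable:
    """Two-way crossed ANOVA of ``response`` on two categorical factors.

    Factor A is typically treatment, factor B the sampling day (treated as
    categorical).  Requires >= 2 levels per factor and no empty cells for
    the interaction term.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "A": pd.Categorical(np.asarray(factor_a)),
            "B": pd.Categorical(np.asarray(factor_b)),
        }
    )
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = pd.crosstab(df["A"], df["B"])
    if (cells == 0).any().any():
        raise ValueError(
            "design has empty cells; the interaction term is inestimable "
            "(consider an additive model)"
        )
    total_ss = float(((df["y"] - df["y"].mean()) ** 2).sum())
    flags: list[str] = []
    if total_ss < _SS_TOL:
        # constant response: zero SS everywhere, F defined as 0 by convention
        index = ["C(A)", "C(B)", "C(A):C(B)", "Residual"]
        n = len(df)
        a, b = df["A"].nunique(), df["B"].nunique()
        dfs = [a - 1, b - 1, (a - 1) * (b - 1), n - a * b]
        table = pd.DataFrame(
            {
                "sum_sq": [0.0] * 4,
                "df": [float(d) for d in dfs],
                "F": [0.0, 0.0, 0.0, np.nan],
                "PR(>F)": [1.0, 1.0, 1.0, np.nan],
            },
            index=index,
        )
        return AnovaTable(table=table, flags=["degenerate"])
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = float(table.loc["Residual", "df"])
    if resid_df <= 0 or resid_ss < _SS_TOL * total_ss:
        # saturated / perfect fit: effects with positive SS get p -> 0
        flags.append("perfect_fit")
        for term in table.index:
            if term == "Residual":
                continue
            has_effect = table.loc[term, "sum_sq"] > _SS_TOL * total_ss
            table.loc[term, "F"] = np.inf if has_effect else 0.0
            table.loc[term, "PR(>F)"] = 0.0 if has_effect else 1.0
    return AnovaTable(table=table, flags=flags)


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test at one sampling day: impacted minus control per site."""

    mean_difference: float
    t: float
    df: int
    p: float
    degenerate: bool = False
    day: int | None = None


def paired_t(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    day: int | None = None,
) -> PairedTestResult:
    """Two-sided paired t-test, t = mean(d) / (sd(d)/sqrt(n)) with d = x - y.

    Zero-variance differences are flagged degenerate: p = 0 if the mean
    difference is nonzero (every pair moved identically) else p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs (df = n - 1 >= 1)")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(0.0, 0.0, n - 1, 1.0, degenerate=True, day=day)
        t = np.inf if mean_d > 0 else -np.inf
        return PairedTestResult(mean_d, t, n - 1, 0.0, degenerate=True, day=day)
    res = scipy.stats.ttest_rel(x, y)
    return PairedTestResult(
        mean_difference=mean_d,
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        day=day,
    )


def paired_t_by_day(
    wide: pd.DataFrame, response: str, holm: bool = False
) -> pd.DataFrame:
    """Per-day paired impacted-vs-control t-tests on a per-sample table.

    ``wide`` needs columns site, treatment, study_day, and ``response``.
    Sites present in only one arm at a day are dropped (pairing by site).
    No multiple-testing correction is applied by default; ``holm=True``
    adds Holm-adjusted p-values.
    """
    rows = []
    for day, grp in wide.groupby("study_day"):
        piv = grp.pivot_table(index="site", columns="treatment", values=response)
        piv = piv.dropna()
        if len(piv) < 2 or not {"impacted", "control"} <= set(piv.columns):
            continue
        res = paired_t(piv["impacted"].values, piv["control"].values, day=int(day))
        rows.append(
            {
                "study_day": int(day),
                "n_pairs": len(piv),
                "mean_difference": res.mean_difference,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p"].values, method="holm")[1]
    return out


@dataclass
class RdaResult:
    """Redundancy analysis of a community matrix on a grouping factor.

    ``site_scores`` are weighted-average scores (centered community matrix
    projected on the canonical axes); ``lc_scores`` are the fitted-value
    (linear-combination) scores.  Centroids and per-group standard
    deviations along each axis parameterize the stage ellipses.
    """

    eigenvalues: np.ndarray
    proportion_explained: np.ndarray  # per canonical axis, of total variance
    constrained_proportion: float
    site_scores: pd.DataFrame
    lc_scores: pd.DataFrame
    loadings: pd.DataFrame  # taxa x axes
    centroids: pd.DataFrame  # group x axes
    group_sd: pd.DataFrame  # group x axes


def rda(
    community: pd.DataFrame,
    groups,
    transform=None,
) -> RdaResult:
    """RDA on Euclidean distances of ``community`` (samples x taxa).

    The community matrix is column-centered (no standardization or chord/
    Hellinger pre-transformation, matching a Euclidean-distance analysis;
    pass ``transform`` to pre-transform abundances, e.g. ``np.sqrt``), then
    projected onto the group-membership design by least squares.  Canonical
    axes come from the spectral decomposition of the fitted values; axis
    signs are fixed so the first nonzero taxon loading is positive.
    """
    if not isinstance(community, pd.DataFrame):
        community = pd.DataFrame(np.asarray(community, dtype=float))
    groups = np.asarray(groups)
    n, p = community.shape
    if groups.shape[0] != n:
        raise ValueError("groups must have one label per sample")
    if n < 2:
        raise ValueError("RDA needs at least 2 samples")
    levels, codes = np.unique(groups, return_inverse=True)
    g = levels.size
    if g > n:
        raise ValueError("more groups than samples")
    Y = community.to_numpy(dtype=float)
    if transform is not None:
        Y = transform(Y)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    total_ss = float((Yc**2).sum())
    # fitted values under the group-membership design = per-group means
    group_mean = np.zeros((g, p))
    for k in range(g):
        group_mean[k] = Yc[codes == k].mean(axis=0)
    Yhat = group_mean[codes]
    fitted_ss = float((Yhat**2).sum())
    max_axes = min(g - 1, p)
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    keep = S > 1e-10 * max(S[0], 1.0) if S.size else np.array([], dtype=bool)
    n_axes = min(int(keep.sum()), max_axes)
    V = Vt[:n_axes].T  # taxa x axes
    # deterministic sign: first nonzero loading positive on each axis
    for j in range(n_axes):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    eigenvalues = (S[:n_axes] ** 2) / (n - 1)
    total_var = total_ss / (n - 1)
    proportion = eigenvalues / total_var if total_var > 0 else np.zeros(n_axes)
    axes = [f"RDA{j + 1}" for j in range(n_axes)]
    wa = pd.DataFrame(Yc @ V, index=community.index, columns=axes)
    lc = pd.DataFrame(Yhat @ V, index=community.index, columns=axes)
    cent = wa.groupby(pd.Series(groups, index=wa.index)).mean()
    sd = wa.groupby(pd.Series(groups, index=wa.index)).std(ddof=1)
    return RdaResult(
        eigenvalues=eigenvalues,
        proportion_explained=proportion,
        constrained_proportion=(fitted_ss / total_ss if total_ss > 0 else 0.0),
        site_scores=wa,
        lc_scores=lc,
        loadings=pd.DataFrame(V, index=community.columns, columns=axes),
        centroids=cent,
        group_sd=sd,
    )
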