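"""Treatment statistics: the assumption-gated repeated-measures decision tree.

The experimental unit is the individual: trials are averaged per individual
x treatment before any inference (pseudoreplication guard).  For a metric
measured under the three incline treatments the pipeline then:

1. tests normality per treatment group (Shapiro-Wilk) and variance
   homogeneity across groups (Levene), both at alpha = 0.05;
2. if either gate fails, applies the decadic logarithm (optionally after a
   fixed positive offset, used for the landing angle where raw values can
   be negative) and retests;
3. if the transformed data still fail, falls back to a Kruskal-Wallis test
   (the rank test is invariant to the monotone transform, so raw values
   are used), with Dunn's test as the post hoc when the omnibus test is
   significant;
4. on the parametric branch, fits a mixed model with a random individual
   intercept; if the random effect is not supported by a likelihood-ratio
   test the individual term is dropped and a one-way ANOVA used, otherwise
   a repeated-measures ANOVA; pairwise contrasts (paired or independent t,
   Bonferroni-adjusted) follow a significant omnibus test.

Every report records which gate failed, which transform was applied and
which branch was taken, so the routing is fully auditable; identical input
gives identical routing and p-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "TestReport",
    "average_trials",
    "group_summary",
    "compare_inclines",
    "regress",
    "dunn_test",
]

ALPHA = 0.05
_REQUIRED = ("individual_id", "treatment_deg", "value")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"metric table lacks column(s): {missing}")
    return table


def average_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean per individual x treatment (one row each).

    Raises if any individual x treatment cell is empty, listing the gaps.
    """
    table = _check_table(table)
    out = (
        table.groupby(["individual_id", "treatment_deg"], as_index=False)["value"]
        .mean()
    )
    individuals = sorted(table["individual_id"].unique())
    treatments = sorted(table["treatment_deg"].unique())
    have = set(zip(out["individual_id"], out["treatment_deg"]))
    gaps = [
        (i, t)
        for i in individuals
        for t in treatments
        if (i, t) not in have
    ]
    if gaps:
        raise ValueError(f"missing individual x treatment cell(s): {gaps}")
    return out


def group_summary(averaged: pd.DataFrame) -> pd.DataFrame:
    """Group mean and standard error per treatment (reported as mean +/- SE)."""
    g = averaged.groupby("treatment_deg")["value"]
    return pd.DataFrame(
        {"mean": g.mean(), "se": g.sem(ddof=1), "n": g.size()}
    ).reset_index()


@dataclass
class TestReport:
    """Auditable record of one metric's journey through the decision tree."""

    metric: str
    transform: str  # "none" | "offset+log10" | "log10"
    normality_p: dict  # stage -> {treatment: p}
    levene_p: dict  # stage -> p
    chosen_test: str  # "rm_anova" | "anova" | "kruskal"
    omnibus_p: float
    posthoc: dict | None  # pair -> p, only when omnibus significant
    individual_effect: dict = field(default_factory=dict)
    group_means: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.omnibus_p < ALPHA


def _gate(averaged: pd.DataFrame) -> tuple[dict, float, bool]:
    groups = [g["value"].to_numpy() for _, g in averaged.groupby("treatment_deg")]
    normality = {}
    ok = True
    for (tr, g) in averaged.groupby("treatment_deg"):
        vals = g["value"].to_numpy()
        if len(vals) < 3 or np.ptp(vals) == 0:
            p = 0.0  # cannot support normality
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(sps.shapiro(vals).pvalue)
        normality[tr] = p
        ok &= p >= ALPHA
    lev = float(sps.levene(*groups, center="median").pvalue)
    ok &= lev >= ALPHA
    return normality, lev, ok


def _random_effect_lrt(averaged: pd.DataFrame) -> dict:
    """Likelihood-ratio test of the random individual intercept.

    Compares a mixed model (random intercept per individual) against plain
    OLS on a chi-squared(1) reference; conservative at the boundary.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = averaged.rename(
        columns={"individual_id": "ind", "treatment_deg": "treat"}
    ).copy()
    df["treat"] = df["treat"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = smf.ols("value ~ C(treat)", data=df).fit()
        try:
            mixed = smf.mixedlm("value ~ C(treat)", data=df, groups=df["ind"]).fit(
                reml=False, method="lbfgs", maxiter=200
            )
            lr = 2.0 * (mixed.llf - ols.llf)
        except Exception:  # singular fits on degenerate data
            lr = 0.0
    lr = max(lr, 0.0)
    p = float(sps.chi2.sf(lr, df=1))
    return {"test": "lrt_random_intercept", "statistic": lr, "p": p,
            "retained": p < ALPHA}


def _parametric(averaged: pd.DataFrame, keep_individual: bool) -> tuple[str, float, dict | None]:
    df = averaged.rename(
        columns={"individual_id": "ind", "treatment_deg": "treat"}
    ).copy()
    df["treat"] = df["treat"].astype(str)
    treatments = sorted(df["treat"].unique())
    if keep_individual:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(data=df, dv="value", within="treat", subject="ind")
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        omnibus = float(aov[pcol].iloc[0])
        name = "rm_anova"
    else:
        groups = [df.loc[df["treat"] == t, "value"].to_numpy() for t in treatments]
        omnibus = float(sps.f_oneway(*groups).pvalue)
        name = "anova"
    posthoc = None
    if omnibus < ALPHA:
        pairs = list(itertools.combinations(treatments, 2))
        m = len(pairs)
        posthoc = {}
        for a, b in pairs:
            if keep_individual:
                wide = df.pivot(index="ind", columns="treat", values="value")
                p = float(sps.ttest_rel(wide[a], wide[b]).pvalue)
            else:
                p = float(
                    sps.ttest_ind(
                        df.loc[df["treat"] == a, "value"],
                        df.loc[df["treat"] == b, "value"],
                    ).pvalue
                )
            posthoc[f"{a} vs {b}"] = min(1.0, p * m)  # Bonferroni, single-step
    return name, omnibus, posthoc


def dunn_test(
    values: np.ndarray, groups: np.ndarray, adjust: str = "none"
) -> dict[str, float]:
    """Dunn's rank-sum post hoc for a Kruskal-Wallis design.

    Pairwise z statistics from mean ranks with the standard tie
    correction; two-sided p-values, unadjusted by default (``adjust`` may
    be "bonferroni").
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    labels = sorted(pd.unique(groups).tolist())
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    pairs = list(itertools.combinations(labels, 2))
    out = {}
    for a, b in pairs:
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        out[f"{a} vs {b}"] = float(p)
    return out


def compare_inclines(
    table: pd.DataFrame,
    metric: str = "metric",
    log_offset: float = 0.0,
    dunn_adjust: str = "none",
    pre_averaged: bool = False,
) -> TestReport:
    """Run the full decision tree for one metric.

    ``table`` holds trial-level rows (individual_id, treatment_deg, value);
    trials are averaged per individual x treatment first unless
    ``pre_averaged``.  ``log_offset`` is added before the decadic log on
    the transform branch (3.0 for the landing angle, which can be
    negative).
    """
    table = _check_table(table)
    averaged = table.copy() if pre_averaged else average_trials(table)
    if averaged["individual_id"].nunique() < 2:
        raise ValueError("repeated-measures design needs at least 2 individuals")
    if averaged["treatment_deg"].nunique() < 2:
        raise ValueError("need at least 2 treatments to compare")

    normality: dict = {}
    levene: dict = {}
    norm_raw, lev_raw, ok = _gate(averaged)
    normality["raw"], levene["raw"] = norm_raw, lev_raw
    transform = "none"
    work = averaged

    if not ok:
        shifted = averaged["value"] + log_offset
        if (shifted > 0).all():
            trans = averaged.copy()
            trans["value"] = np.log10(shifted)
            norm_t, lev_t, ok_t = _gate(trans)
            transform = "offset+log10" if log_offset else "log10"
            normality[transform], levene[transform] = norm_t, lev_t
            if ok_t:
                work, ok = trans, True
            else:
                transform = "none"

    if ok:
        ind = _random_effect_lrt(work)
        chosen, omnibus, posthoc = _parametric(work, keep_individual=ind["retained"])
    else:
        vals = averaged["value"].to_numpy()
        treats = averaged["treatment_deg"].to_numpy()
        omnibus = float(
            sps.kruskal(
                *[vals[treats == t] for t in np.unique(treats)]
            ).pvalue
        )
        inds = averaged["individual_id"].to_numpy()
        ind_p = float(
            sps.kruskal(*[vals[inds == i] for i in np.unique(inds)]).pvalue
        )
        ind = {"test": "kruskal_individual", "p": ind_p, "retained": ind_p < ALPHA}
        chosen = "kruskal"
        posthoc = (
            dunn_test(vals, treats.astype(str), adjust=dunn_adjust)
            if omnibus < ALPHA
            else None
        )

    return TestReport(
        metric=metric,
        transform=transform if ok else "none",
        normality_p=normality,
        levene_p=levene,
        chosen_test=chosen,
        omnibus_p=omnibus,
        posthoc=posthoc,
        individual_effect=ind,
        group_means=group_summary(averaged),
    )


def regress(y: np.ndarray, x: np.ndarray) -> dict[str, float]:
    """Ordinary least squares y ~ x: slope, intercept, r^2 and the slope's
    two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("regression needs >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": len(x),
    }
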