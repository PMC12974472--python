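"""Normalizations and statistical contracts for the cell-based assays.

Viability (CellTiter-Glo ATP signal) is expressed as a percentage of the
untreated control of the same biological replicate, after averaging
technical replicates; summaries (mean ± SD) are over biological replicates
only.  Mutation frequencies are expressed relative to the per-replicate
0 µM baseline.  Dose x group designs are analysed with a conventional
fixed-effects two-way ANOVA with interaction (type-II sums of squares,
balanced designs required) plus Tukey-adjusted pairwise comparisons.
Relative qPCR expression uses 2^-ddCt with dCt referenced to the geometric
mean of three housekeeping genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .repeat_instability import significance_tier

__all__ = [
    "normalize_viability",
    "relative_mf",
    "two_way_anova",
    "ddct_fold_change",
]


def normalize_viability(
    plate: pd.DataFrame,
    value_col: str = "signal",
    group_cols: tuple = ("group",),
    dose_col: str = "dose_uM",
    recovery_col: str = "recovery_h",
    replicate_col: str = "replicate",
) -> dict:
    """Percent viability relative to the untreated control.

    Technical replicates are averaged first (any ``technical`` column is
    collapsed); each biological replicate is then expressed as a percentage
    of its own untreated (dose 0) mean within the same (group, recovery)
    stratum.  Returns ``{"replicates": ..., "summary": ...}`` where
    ``replicates`` holds one row per biological replicate x condition and
    ``summary`` the mean ± SD over biological replicates.
    """
    keys = [*group_cols, recovery_col, dose_col, replicate_col]
    tech_mean = plate.groupby(keys, as_index=False)[value_col].mean()

    strata = [*group_cols, recovery_col]
    rows = []
    for stratum, sub in tech_mean.groupby(strata):
        untreated = sub[sub[dose_col] == 0]
        if untreated.empty:
            raise ValueError(f"no untreated (dose 0) wells in stratum {stratum}")
        base_by_rep = untreated.set_index(replicate_col)[value_col]
        for _, r in sub.iterrows():
            rep = r[replicate_col]
            if rep not in base_by_rep.index:
                raise ValueError(
                    f"replicate {rep} lacks an untreated well in stratum {stratum}")
            rows.append({**{c: r[c] for c in keys},
                         "percent_viability": 100.0 * r[value_col] / base_by_rep[rep]})
    replicates = pd.DataFrame(rows)
    summary = (replicates
               .groupby([*strata, dose_col], as_index=False)["percent_viability"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                    n="count"))
    return {"replicates": replicates, "summary": summary}


def relative_mf(
    mf: pd.DataFrame,
    value_col: str = "mf",
    group_col: str = "group",
    dose_col: str = "dose_uM",
    replicate_col: str = "replicate",
) -> dict:
    """Mutation frequency as a percentage of the per-replicate 0 µM baseline.

    Each biological replicate is normalised to its own baseline and
    summaries are taken afterwards (mean ± SD over replicates).
    """
    rows = []
    for (group,), sub in mf.groupby([group_col]):
        baseline = sub[sub[dose_col] == 0].set_index(replicate_col)[value_col]
        if baseline.empty:
            raise ValueError(f"no baseline (dose 0) rows for group {group!r}")
        if (baseline <= 0).any():
            raise ValueError(f"zero baseline MF for group {group!r}")
        for _, r in sub.iterrows():
            rep = r[replicate_col]
            if rep not in baseline.index:
                raise ValueError(f"replicate {rep} of group {group!r} lacks a baseline")
            rows.append({group_col: group, dose_col: r[dose_col],
                         replicate_col: rep,
                         "percent_mf": 100.0 * r[value_col] / baseline[rep]})
    replicates = pd.DataFrame(rows)
    summary = (replicates
               .groupby([group_col, dose_col], as_index=False)["percent_mf"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                    n="count"))
    return {"replicates": replicates, "summary": summary}


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "dose_uM",
    factor_b: str = "group",
) -> dict:
    """Fixed-effects two-way ANOVA with interaction and Tukey comparisons.

    Requires at least two levels per factor and at least two observations
    per cell; empty cells raise an explicit unbalanced-design error rather
    than silently changing the model.  Returns the ANOVA table (F and p for
    both main effects and the interaction), Tukey-adjusted pairwise
    comparisons over the cell combinations, and significance tiers.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    d = data[[response, factor_a, factor_b]].copy()
    counts = d.groupby([factor_a, factor_b], observed=True)[response].count()
    n_a = d[factor_a].nunique()
    n_b = d[factor_b].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs >= 2 levels")
    if len(counts) < n_a * n_b or (counts < 2).any():
        raise ValueError("unbalanced design: every cell needs >= 2 observations")

    d = d.rename(columns={response: "y", factor_a: "A", factor_b: "B"})
    model = smf.ols("y ~ C(A) * C(B)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)

    effects = {}
    for label, key in (("C(A)", factor_a), ("C(B)", factor_b),
                       ("C(A):C(B)", f"{factor_a}:{factor_b}")):
        f = float(table.loc[label, "F"])
        p = float(table.loc[label, "PR(>F)"])
        effects[key] = {"F": f, "p": p, "tier": significance_tier(p)}

    cells = (d["A"].astype(str) + " / " + d["B"].astype(str)).to_numpy()
    tukey = pairwise_tukeyhsd(d["y"].to_numpy(), cells)
    pairwise = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    pairwise["tier"] = [significance_tier(float(p)) for p in pairwise["p-adj"]]
    return {"anova": table, "effects": effects, "pairwise": pairwise}


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    housekeeping: tuple,
    control_group: str,
    sample_col: str = "sample",
    group_col: str = "group",
    gene_col: str = "gene",
    ct_col: str = "ct",
    reference_mean: str = "geometric",
) -> pd.DataFrame:
    """Relative expression 2^-ddCt against three housekeeping genes.

    Per sample, dCt is the target Ct minus the geometric mean of the three
    housekeeping Ct values; ddCt subtracts the control group's mean dCt.
    The control mean is geometric by default (matching the stated
    procedure; requires positive control dCt values) with an arithmetic
    alternative for data where dCt can cross zero.
    """
    if len(housekeeping) != 3:
        raise ValueError("exactly three housekeeping genes are expected")
    if reference_mean not in ("geometric", "arithmetic"):
        raise ValueError("reference_mean must be 'geometric' or 'arithmetic'")

    dct_rows = []
    for (sample,), sub in ct.groupby([sample_col]):
        genes = sub.set_index(gene_col)[ct_col]
        missing = [g for g in (*housekeeping, target) if g not in genes.index]
        if missing:
            raise ValueError(f"sample {sample!r} is missing Ct for genes {missing}")
        hk = stats.gmean([genes[g] for g in housekeeping])
        dct_rows.append({sample_col: sample,
                         group_col: sub[group_col].iloc[0],
                         "dct": float(genes[target] - hk)})
    dct = pd.DataFrame(dct_rows)

    control = dct[dct[group_col] == control_group]["dct"]
    if control.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    if reference_mean == "geometric":
        if (control < 0).any():
            raise ValueError(
                "geometric reference mean requires non-negative control dCt "
                "values; use reference_mean='arithmetic'")
        ref = float(stats.gmean(control)) if (control > 0).all() else 0.0
    else:
        ref = float(control.mean())

    dct["ddct"] = dct["dct"] - ref
    dct["fold_change"] = np.power(2.0, -dct["ddct"])
    return dct
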