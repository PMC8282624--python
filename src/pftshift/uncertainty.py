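"""ANOVA variance partitioning of projection uncertainty.

Per grid cell (and species), projected suitability varies with four crossed
factors: the algorithm, the training replicate, the emission scenario (RCP)
and the climate model (GCM). A main-effects analysis of variance attributes
a fraction of the total sum of squares to each factor; the residual absorbs
interactions. On a balanced design the main-effect sums of squares are
computed directly from group means; unbalanced layouts fall back to
sequential (type I) sums of squares in the canonical factor order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FACTORS", "VariancePartition", "anova_partition", "rank_factors"]

FACTORS = ("algorithm", "replicate", "rcp", "gcm")


@dataclass
class VariancePartition:
    fractions: dict[str, float]  # per-factor variance fraction
    residual: float
    n_obs: int
    degenerate: bool = False


def _is_balanced(df: pd.DataFrame, factors: list[str]) -> bool:
    counts = df.groupby(factors, observed=True).size()
    full = np.prod([df[f].nunique() for f in factors])
    return len(counts) == full and counts.nunique() == 1


def anova_partition(values: pd.DataFrame, factors: tuple[str, ...] = FACTORS) -> VariancePartition:
    """Partition the variance of ``values['value']`` across the given factors.

    Requires at least two observations and at least one factor with two or
    more levels. Zero total variance yields a degenerate partition with all
    fractions zero.
    """
    df = values
    missing = [f for f in factors if f not in df.columns]
    if missing:
        raise KeyError(f"missing factor column(s): {missing}")
    if "value" not in df.columns:
        raise KeyError("missing 'value' column")
    n = len(df)
    if n < 2:
        raise ValueError("need at least two observations")
    used = [f for f in factors if df[f].nunique() >= 2]
    if not used:
        raise ValueError("need at least one factor with >= 2 levels")

    y = df["value"].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0:
        return VariancePartition(
            fractions={f: 0.0 for f in factors}, residual=0.0, n_obs=n, degenerate=True
        )

    if _is_balanced(df, used):
        grand = y.mean()
        ss = {}
        for f in factors:
            if f not in used:
                ss[f] = 0.0
                continue
            g = df.groupby(f, observed=True)["value"]
            ss[f] = float((g.size() * (g.mean() - grand) ** 2).sum())
    else:
        # sequential (type I) SS in canonical order via OLS
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = df[list(used) + ["value"]].copy()
        formula = "value ~ " + " + ".join(f"C({f})" for f in used)
        fit = smf.ols(formula, data=d).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        ss = {f: 0.0 for f in factors}
        for f in used:
            ss[f] = float(table.loc[f"C({f})", "sum_sq"])

    fractions = {f: ss[f] / ss_total for f in factors}
    residual = 1.0 - sum(fractions.values())
    # numeric guard: tiny negatives from float round-off
    residual = 0.0 if abs(residual) < 1e-12 else residual
    return VariancePartition(fractions=fractions, residual=residual, n_obs=n)


def rank_factors(
    partitions: list[VariancePartition], factors: tuple[str, ...] = FACTORS
) -> pd.DataFrame:
    """Median variance fraction per factor across cells, sorted descending.

    Ties keep the canonical factor order (stable sort).
    """
    if not partitions:
        raise ValueError("need at least one partition")
    med = {
        f: float(np.median([p.fractions[f] for p in partitions])) for f in factors
    }
    out = pd.DataFrame(
        {"factor": list(factors), "median_fraction": [med[f] for f in factors]}
    )
    return out.sort_values(
        "median_fraction", ascending=False, kind="stable"
    ).reset_index(drop=True)
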