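"""Group summaries, trait ranges, stress percent-changes, correlations.

These operate on genotype-level tables (BLUPs or means) with a ``group``
column for the germplasm classes.  Reporting convention: concentrations to
1 decimal, yields to whole kg/L per hectare, percent changes to the nearest
integer, correlations to 3 decimals — full precision is always retained
internally and rounding is applied only by the callers that print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TraitRange:
    trait: str
    min_genotype: str
    min_value: float
    max_genotype: str
    max_value: float


def group_summary(
    table: pd.DataFrame, traits: list[str], group_col: str = "group"
) -> pd.DataFrame:
    """Per group x trait: n, mean, sample SD (n-1 denominator).

    SD is reported as NaN for single-member groups; empty groups are
    omitted with a warning.  An ``_overall`` row per trait pools all rows.
    """
    if group_col not in table.columns:
        raise ValueError(f"table has no {group_col!r} column")
    rows = []
    groups = list(pd.unique(table[group_col]))
    for trait in traits:
        for grp in groups + ["_overall"]:
            sub = table if grp == "_overall" else table[table[group_col] == grp]
            vals = sub[trait].dropna()
            if vals.empty:
                warnings.warn(f"group {grp!r} empty for trait {trait!r}; omitted")
                continue
            rows.append(
                {
                    "group": grp,
                    "trait": trait,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def trait_range(table: pd.DataFrame, trait: str) -> TraitRange:
    """Extremes of a trait with the genotypes attaining them.

    Ties are broken by table order (first occurrence wins).
    """
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    vals = table[trait].dropna()
    if vals.empty:
        raise ValueError(f"no values for trait {trait!r}")
    geno_col = "genotype" if "genotype" in table.columns else "genotype_id"
    imin, imax = vals.idxmin(), vals.idxmax()
    return TraitRange(
        trait=trait,
        min_genotype=str(table.loc[imin, geno_col]),
        min_value=float(vals.loc[imin]),
        max_genotype=str(table.loc[imax, geno_col]),
        max_value=float(vals.loc[imax]),
    )


def percent_change(value_irri: float, value_dry: float) -> float:
    """Stress-induced percent reduction, 100*(irri - dry)/irri.

    Positive means the trait decreased under water stress; a negative
    result is an increase (callers may negate when reporting increases).
    """
    if value_irri == 0:
        raise ZeroDivisionError("well-watered baseline is zero")
    return 100.0 * (value_irri - value_dry) / value_irri


def pearson_matrix(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pairwise Pearson r with two-sided p-values (t transform, n-2 df).

    Long-format result: one row per unordered trait pair with columns
    ``trait_a, trait_b, r, p_value, n``.  Pairs with fewer than 3 complete
    rows or a zero-variance column get NaN r with a warning.
    """
    rows = []
    for a, b in combinations(traits, 2):
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            warnings.warn(f"pair ({a}, {b}): fewer than 3 complete rows")
            r, p = np.nan, np.nan
        elif sub[a].nunique() == 1 or sub[b].nunique() == 1:
            warnings.warn(f"pair ({a}, {b}): zero variance, r undefined")
            r, p = np.nan, np.nan
        else:
            res = stats.pearsonr(sub[a], sub[b])
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({"trait_a": a, "trait_b": b, "r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows)


def correlation_square(long: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pivot :func:`pearson_matrix` output to a symmetric matrix with unit diagonal."""
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for row in long.itertuples():
        mat.loc[row.trait_a, row.trait_b] = row.r
        mat.loc[row.trait_b, row.trait_a] = row.r
    return mat
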