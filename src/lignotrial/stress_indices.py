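"""Drought stress/stability indices from per-environment genotype yields.

Eight indices summarise how a genotype's yield y_C under well-watered
conditions relates to its yield y_D under water stress, relative to the
population means Y_C and Y_D over the genotype set:

    STI = (y_C * y_D) / Y_C^2        stress tolerance index
    YI  = y_D / Y_D                  yield index
    YSI = y_D / y_C                  yield stability index
    TOL = y_C - y_D                  tolerance (trait units)
    RSI = (y_C / y_D) / (Y_C / Y_D)  relative stress index
    STE = 100 * y_D / y_C            stress tolerance efficiency (%)
    GMP = sqrt(y_C * y_D)            geometric mean productivity
    HM  = 2 y_C y_D / (y_C + y_D)    harmonic mean

RSI is implemented exactly in this orientation (some literature uses its
reciprocal).  The indices obey hard algebraic identities — STE = 100*YSI,
GMP^2 = y_C*y_D, HM*(y_C+y_D) = 2*y_C*y_D, RSI*YSI = Y_D/Y_C, and
STI*YSI/YI^2 = (Y_D/Y_C)^2 identical for every genotype of a set — which
:func:`consistency_check` verifies; this is how published index tables can
be validated when the underlying yields are unavailable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PopulationMeans:
    """Means of y_C and y_D over the genotype set the indices refer to."""

    Y_C: float
    Y_D: float

    def __post_init__(self) -> None:
        if self.Y_C <= 0 or self.Y_D <= 0:
            raise ValueError("population means must be > 0")


@dataclass(frozen=True)
class StressIndexRecord:
    genotype_id: str
    trait: str
    y_C: float
    y_D: float
    STI: float
    YI: float
    YSI: float
    TOL: float
    RSI: float  # nan when y_D == 0
    STE: float
    GMP: float
    HM: float


def compute_indices(
    y_C: float,
    y_D: float,
    means: PopulationMeans,
    genotype_id: str = "",
    trait: str = "",
) -> StressIndexRecord:
    """All eight indices for one genotype.  Requires y_C > 0 and y_D >= 0.

    With y_D = 0, RSI involves division by zero and is reported as NaN with
    a warning; the remaining indices are still defined.
    """
    if y_C <= 0:
        raise ValueError(f"y_C must be > 0 (genotype {genotype_id!r})")
    if y_D < 0:
        raise ValueError(f"y_D must be >= 0 (genotype {genotype_id!r})")
    if y_D == 0:
        warnings.warn(
            f"y_D = 0 for genotype {genotype_id!r}: RSI undefined, reported as NaN",
            stacklevel=2,
        )
        rsi = math.nan
    else:
        rsi = (y_C / y_D) / (means.Y_C / means.Y_D)
    return StressIndexRecord(
        genotype_id=genotype_id,
        trait=trait,
        y_C=y_C,
        y_D=y_D,
        STI=(y_C * y_D) / means.Y_C**2,
        YI=y_D / means.Y_D,
        YSI=y_D / y_C,
        TOL=y_C - y_D,
        RSI=rsi,
        STE=100.0 * y_D / y_C,
        GMP=math.sqrt(y_C * y_D),
        HM=2.0 * y_C * y_D / (y_C + y_D) if (y_C + y_D) > 0 else 0.0,
    )


def index_table(
    per_env: pd.DataFrame,
    traits: list[str] | None = None,
    env_watered: str = "IRRI",
    env_stressed: str = "DRY",
) -> pd.DataFrame:
    """Indices for every genotype x trait of a per-environment value table.

    ``per_env`` is long-format with columns ``genotype``, ``trait`` and the
    two environment columns (default ``IRRI``/``DRY``).  Population means
    are taken per trait over exactly the genotypes supplied.  Returns one
    row per genotype x trait with the eight index columns plus the inputs.
    """
    for col in ("genotype", "trait", env_watered, env_stressed):
        if col not in per_env.columns:
            raise ValueError(f"per-environment table missing column {col!r}")
    if traits is None:
        traits = list(pd.unique(per_env["trait"]))
    records = []
    for trait in traits:
        sub = per_env[per_env["trait"] == trait]
        if sub.empty:
            raise ValueError(f"no rows for trait {trait!r}")
        if sub[[env_watered, env_stressed]].isna().any().any():
            raise ValueError(f"missing y_C/y_D values for trait {trait!r}")
        means = PopulationMeans(
            Y_C=float(sub[env_watered].mean()), Y_D=float(sub[env_stressed].mean())
        )
        for row in sub.itertuples():
            records.append(
                compute_indices(
                    float(getattr(row, env_watered)),
                    float(getattr(row, env_stressed)),
                    means,
                    genotype_id=str(row.genotype),
                    trait=trait,
                )
            )
    return pd.DataFrame([vars(r) for r in records])


def consistency_check(records: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Verify the algebraic identities on an index table; report violations.

    Runs every identity whose columns are present, so it applies both to
    full tables from :func:`index_table` and to published tables carrying
    only YSI/YI/STI (where only the constancy of STI*YSI/YI^2 can be
    tested).  Relative deviations beyond ``tol`` are returned as rows
    ``(identity, trait, genotype_id, deviation)``; an empty frame means all
    identities hold.
    """
    cols = set(records.columns)
    out = []

    def flag(identity, trait, geno, dev):
        out.append(
            {"identity": identity, "trait": trait, "genotype_id": geno, "deviation": dev}
        )

    for _, r in records.iterrows():
        trait = r.get("trait", "")
        geno = r.get("genotype_id", "")
        if {"STE", "YSI"} <= cols:
            dev = abs(r["STE"] - 100.0 * r["YSI"]) / max(1.0, abs(r["STE"]))
            if dev > tol:
                flag("STE=100*YSI", trait, geno, dev)
        if {"GMP", "y_C", "y_D"} <= cols:
            dev = abs(r["GMP"] ** 2 - r["y_C"] * r["y_D"]) / max(1.0, r["y_C"] * r["y_D"])
            if dev > tol:
                flag("GMP^2=yC*yD", trait, geno, dev)
        if {"HM", "y_C", "y_D"} <= cols:
            dev = abs(r["HM"] * (r["y_C"] + r["y_D"]) - 2 * r["y_C"] * r["y_D"]) / max(
                1.0, 2 * r["y_C"] * r["y_D"]
            )
            if dev > tol:
                flag("HM*(yC+yD)=2*yC*yD", trait, geno, dev)

    if {"RSI", "YSI", "y_C", "y_D"} <= cols:
        for trait, sub in records.groupby("trait"):
            ratio = sub["y_D"].mean() / sub["y_C"].mean()
            prod = (sub["RSI"] * sub["YSI"]).dropna()
            for idx, val in prod.items():
                dev = abs(val - ratio)
                if dev > tol:
                    flag("RSI*YSI=YD/YC", trait, records.loc[idx, "genotype_id"], dev)

    if {"STI", "YSI", "YI"} <= cols:
        group_key = "trait" if "trait" in cols else None
        grouped = records.groupby(group_key) if group_key else [("", records)]
        for trait, sub in grouped:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (sub["STI"] * sub["YSI"] / sub["YI"] ** 2).to_numpy()
            finite = ratio[np.isfinite(ratio)]
            if finite.size == 0:
                continue
            center = float(np.median(finite))
            for idx, val in zip(sub.index, ratio):
                if not np.isfinite(val):
                    continue
                dev = abs(val - center)
                if dev > tol:
                    flag(
                        "STI*YSI/YI^2 constant",
                        trait,
                        sub.loc[idx].get("genotype_id", sub.loc[idx].get("genotype", "")),
                        dev,
                    )
    return pd.DataFrame(out, columns=["identity", "trait", "genotype_id", "deviation"])
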