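"""EM-REML variance components and Henderson-equation BLUPs for trial data.

The trial model treats every design factor as random, with the grand mean
the only fixed effect:

    y = 1*mu + Z_E u_E + Z_B u_B(E) + Z_G u_G + Z_CE u_CE + Z_GE u_GE + eps

where E is irrigation environment, B(E) block nested in environment, G
genotype, CE the check-by-environment interaction (nonzero only on check
plots), and GE genotype-by-environment.  Each u_i ~ N(0, sigma2_i I) and
eps ~ N(0, sigma2_e I).  Augmented block designs are inherently unbalanced
(test entries unreplicated, checks replicated in every block), so the
solver never assumes balance; only the method-of-moments oracle does.

Variance components are estimated by EM-REML: the classic fixed-point
iteration on the residual projection matrix P, which keeps every component
non-negative and never decreases the restricted likelihood.  BLUPs then
come from Henderson's mixed-model equations at the estimated components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from lignotrial.trial_data import plots_to_frame

#: canonical factor order for reporting
FACTORS = ("environment", "block_within_env", "genotype", "check_by_env", "gxe")


@dataclass(frozen=True)
class ModelSpec:
    """Which random factors enter the model for a given response trait.

    The genotype factor is always present; the others can be switched off
    for reduced models (e.g. a one-way genotype layout for oracle checks).
    """

    trait: str
    include_environment: bool = True
    include_block: bool = True
    include_check_by_env: bool = True
    include_gxe: bool = True

    def included(self) -> list[str]:
        out = []
        if self.include_environment:
            out.append("environment")
        if self.include_block:
            out.append("block_within_env")
        out.append("genotype")
        if self.include_check_by_env:
            out.append("check_by_env")
        if self.include_gxe:
            out.append("gxe")
        return out


@dataclass
class VarianceComponents:
    """Estimated sigma^2 per random factor plus convergence metadata."""

    sigma2: dict[str, float]
    n_iter: int
    converged: bool
    final_change: float
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_obs: int = 0
    n_dropped: int = 0

    def __getitem__(self, factor: str) -> float:
        return self.sigma2[factor]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"factor": list(self.sigma2), "sigma2": list(self.sigma2.values())}
        )


@dataclass
class BlupTable:
    """Predicted genotype values: overall and, optionally, per environment."""

    grand_mean: float
    overall: pd.Series  # index genotype -> mu + u_G
    by_env: pd.DataFrame | None = None  # index genotype, one column per environment

    def to_frame(self) -> pd.DataFrame:
        out = self.overall.rename("overall").to_frame()
        if self.by_env is not None:
            out = out.join(self.by_env)
        return out.reset_index(names="genotype")


def _as_frame(plots) -> pd.DataFrame:
    if isinstance(plots, pd.DataFrame):
        return plots.copy()
    return plots_to_frame(plots)


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.shape[0], n_levels))
    mask = codes >= 0  # negative code = level not applicable (non-check plots)
    Z[np.nonzero(mask)[0], codes[mask]] = 1.0
    return Z


def design_matrices(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, pd.Index]]:
    """Response vector, indicator matrix per included factor, and level labels."""
    if spec.trait not in frame.columns:
        raise KeyError(f"response trait {spec.trait!r} not in table")
    frame = frame.reset_index(drop=True)
    y = frame[spec.trait].to_numpy(dtype=float)

    Zs: dict[str, np.ndarray] = {}
    levels: dict[str, pd.Index] = {}

    def add(name: str, keys: pd.Series, applicable: pd.Series | None = None):
        codes, lev = pd.factorize(keys, sort=True)
        if applicable is not None:
            codes = np.where(applicable.to_numpy(), codes, -1)
        Zs[name] = _indicator(codes, len(lev))
        levels[name] = pd.Index(lev)

    geno = frame["genotype_id"].astype(str)
    needs_env = (
        spec.include_environment
        or spec.include_block
        or spec.include_check_by_env
        or spec.include_gxe
    )
    env = frame["environment"].astype(str) if needs_env else None
    if spec.include_environment:
        add("environment", env)
    if spec.include_block:
        add("block_within_env", env + ":" + frame["block"].astype(str))
    add("genotype", geno)
    if spec.include_check_by_env:
        is_check = frame["is_check"].astype(bool)
        add("check_by_env", geno + ":" + env, applicable=is_check)
    if spec.include_gxe:
        add("gxe", geno + ":" + env)

    for name in list(Zs):
        if Zs[name].shape[1] < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
    return y, Zs, levels


def fit_varcomp(
    plots,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 5000,
    init: Mapping[str, float] | None = None,
    accelerate: bool = True,
) -> VarianceComponents:
    """Estimate variance components by EM-REML.

    ``plots`` is a plot DataFrame (or iterable of :class:`PlotObservation`)
    that already carries the response trait column.  Rows with a missing
    response are dropped with a count recorded on the result.

    The update is the classic EM fixed-point sweep on the REML projection
    matrix; with ``accelerate=True`` (default) sweeps are extrapolated by a
    safeguarded SQUAREM step that shares the EM fixed point and falls back
    to the plain sweep whenever extrapolation would decrease the restricted
    likelihood, so monotonicity is preserved while boundary-adjacent
    components converge orders of magnitude faster.

    Convergence is declared when the largest component change in one plain
    sweep falls below ``tol`` times max(1, total variance), so the
    criterion is meaningful for traits measured in percent (variance ~ 10)
    and in kg/ha (variance ~ 1e6) alike.  A component whose update falls
    below 1e-12 on that same scale is pinned to exactly zero — the EM
    boundary estimate.  Non-convergence is reported on the result, never
    silenced.  ``n_iter`` counts EM sweeps (likelihood evaluations).
    """
    frame = _as_frame(plots)
    n_total = len(frame)
    frame = frame.dropna(subset=[spec.trait])
    n_dropped = n_total - len(frame)
    y, Zs, _ = design_matrices(frame, spec)
    n = y.size
    names = list(Zs)
    k = len(names)
    Zmats = [Zs[name] for name in names]
    qs = np.array([Z.shape[1] for Z in Zmats], dtype=float)

    scale = max(1.0, float(np.var(y)))
    pin = 1e-12 * scale
    if init is None:
        start = float(np.var(y)) / (k + 1) or 1.0
        theta = np.full(k + 1, start)  # components..., residual last
    else:
        theta = np.array([float(init[name]) for name in names] + [float(init["residual"])])

    ones = np.ones(n)
    eye = np.eye(n)

    def em_step(th: np.ndarray) -> tuple[np.ndarray, float]:
        """One EM sweep; returns the update and the loglik at ``th``."""
        V = th[-1] * eye
        for i in range(k):
            if th[i] > 0:
                V += th[i] * (Zmats[i] @ Zmats[i].T)
        try:
            cho = linalg.cho_factor(V)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(f"V not positive definite: {exc}") from exc
        Vinv = linalg.cho_solve(cho, eye)
        a = Vinv @ ones
        s = float(a.sum())
        Py = Vinv @ y - a * (float(a @ y) / s)
        P = Vinv - np.outer(a, a) / s
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ll = -0.5 * (logdet_V + np.log(s) + float(y @ Py))

        new = np.empty_like(th)
        for i in range(k):
            if th[i] <= 0:
                new[i] = 0.0
                continue
            Z = Zmats[i]
            u = Z.T @ Py
            tr = float(np.sum(Z * (P @ Z)))
            val = th[i] + th[i] ** 2 * (float(u @ u) - tr) / qs[i]
            new[i] = 0.0 if val < pin else val
        # residual is floored, not pinned, so V stays invertible in the
        # noiseless limit; the floor is far below any reportable tolerance
        val_e = th[-1] + th[-1] ** 2 * (float(Py @ Py) - float(np.trace(P))) / n
        new[-1] = max(val_e, pin)
        return new, ll

    def project(th: np.ndarray) -> np.ndarray:
        out = np.where(th < pin, 0.0, th)
        out[-1] = max(th[-1], pin)
        return out

    loglik_trace: list[float] = []
    converged = False
    delta = np.inf
    sweeps = 0
    while sweeps < max_iter and not converged:
        theta1, ll0 = em_step(theta)
        sweeps += 1
        loglik_trace.append(ll0)
        delta = float(np.max(np.abs(theta1 - theta)))
        if delta < tol * scale:
            theta = theta1
            converged = True
            break
        if not accelerate or sweeps >= max_iter:
            theta = theta1
            continue

        theta2, ll1 = em_step(theta1)
        sweeps += 1
        loglik_trace.append(ll1)
        delta = float(np.max(np.abs(theta2 - theta1)))
        if delta < tol * scale:
            theta = theta2
            converged = True
            break

        r = theta1 - theta
        v = (theta2 - theta1) - r
        vnorm = float(np.linalg.norm(v))
        if vnorm < 1e-300:
            theta = theta2
            continue
        alpha = min(-1.0, -float(np.linalg.norm(r)) / vnorm)
        cand = project(theta - 2.0 * alpha * r + alpha**2 * v)
        theta3, ll_cand = em_step(cand)
        sweeps += 1
        if ll_cand >= ll1:  # safeguard: keep the likelihood monotone
            loglik_trace.append(ll_cand)
            delta = float(np.max(np.abs(theta3 - cand)))
            theta = theta3
            if delta < tol * scale:
                converged = True
        else:
            theta = theta2

    sigma2 = {name: float(theta[i]) for i, name in enumerate(names)}
    sigma2["residual"] = float(theta[-1])
    return VarianceComponents(
        sigma2=sigma2,
        n_iter=sweeps,
        converged=converged,
        final_change=delta,
        loglik=loglik_trace[-1] if loglik_trace else np.nan,
        loglik_trace=loglik_trace,
        n_obs=n,
        n_dropped=n_dropped,
    )


def blup(
    plots,
    spec: ModelSpec,
    vc: VarianceComponents | Mapping[str, float],
    scope: str = "overall",
) -> BlupTable:
    """Solve Henderson's mixed-model equations at the given components.

    ``scope='overall'`` returns mu + u_G per genotype.  With
    ``scope='per_environment'`` each genotype additionally gets an
    environment-specific prediction mu + u_E + u_G + u_GE — the y_C / y_D
    values the stress indices consume.

    Random terms whose component is zero are dropped (their BLUPs are
    identically zero).  A numerically singular coefficient matrix raises
    ``numpy.linalg.LinAlgError`` carrying the condition number.
    """
    if scope not in ("overall", "per_environment"):
        raise ValueError("scope must be 'overall' or 'per_environment'")
    sigma2 = vc.sigma2 if isinstance(vc, VarianceComponents) else dict(vc)
    frame = _as_frame(plots).dropna(subset=[spec.trait])
    y, Zs, levels = design_matrices(frame, spec)
    n = y.size
    sigma2_e = sigma2["residual"]
    if sigma2_e <= 0:
        raise ValueError("residual variance must be > 0 to form the equations")

    # zero-variance factors drop out of the equations: their BLUPs are 0
    active = [f for f in Zs if sigma2.get(f, 0.0) > 0]

    X = np.ones((n, 1))
    Z = np.hstack([Zs[f] for f in active]) if active else np.zeros((n, 0))
    lam = (
        np.concatenate(
            [np.full(Zs[f].shape[1], sigma2_e / sigma2[f]) for f in active]
        )
        if active
        else np.zeros(0)
    )

    W = np.hstack([X, Z])
    C = W.T @ W
    C[1:, 1:] += np.diag(lam)
    rhs = W.T @ y
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"mixed-model equations numerically singular (cond={cond:.3g})"
        )
    sol = np.linalg.solve(C, rhs)
    mu = float(sol[0])
    effects: dict[str, pd.Series] = {}
    offset = 1
    for f in active:
        k = Zs[f].shape[1]
        effects[f] = pd.Series(sol[offset : offset + k], index=levels[f])
        offset += k

    genos = levels["genotype"]
    u_g = effects.get("genotype", pd.Series(0.0, index=genos))
    overall = (mu + u_g).rename_axis("genotype")
    table = BlupTable(grand_mean=mu, overall=overall)

    if scope == "per_environment":
        envs = list(levels.get("environment", pd.Index(frame["environment"].unique())))
        u_e = effects.get("environment", pd.Series(0.0, index=pd.Index(envs)))
        cols = {}
        for env in envs:
            vals = []
            for g in genos:
                ge = 0.0
                if "gxe" in effects:
                    key = f"{g}:{env}"
                    if key in effects["gxe"].index:
                        ge = float(effects["gxe"][key])
                vals.append(mu + float(u_e.get(env, 0.0)) + float(u_g[g]) + ge)
            cols[env] = vals
        table.by_env = pd.DataFrame(cols, index=genos).rename_axis("genotype")
    return table


def anova_moments_oracle(
    plots, trait: str, two_way: bool = False
) -> VarianceComponents:
    """Method-of-moments variance components from expected mean squares.

    Independent of the REML path: classical ANOVA estimators on *balanced*
    layouts only (equal replication in every cell); refuses anything else.

    One-way (default): genotype with r replicates.
        sigma2_e = MS_within,  sigma2_G = (MS_G - MS_within)/r.
    Two-way crossed random model (``two_way=True``): genotype x environment
    with r replicates per cell.
        sigma2_e  = MS_err
        sigma2_GE = (MS_GE - MS_err)/r
        sigma2_G  = (MS_G - MS_GE)/(r*e),  sigma2_E = (MS_E - MS_GE)/(r*g).
    Estimates are truncated at zero.
    """
    frame = _as_frame(plots).dropna(subset=[trait])
    y = frame[trait].to_numpy(dtype=float)
    geno = frame["genotype_id"].astype(str)

    if not two_way:
        counts = geno.value_counts()
        if counts.nunique() != 1:
            raise ValueError("unbalanced layout: unequal replication per genotype")
        r = int(counts.iloc[0])
        if r < 2:
            raise ValueError("need >= 2 replicates per genotype")
        g = counts.size
        means = frame.groupby(geno)[trait].mean()
        grand = y.mean()
        ss_g = r * float(((means - grand) ** 2).sum())
        ss_w = float(((frame[trait] - means.loc[geno].to_numpy()) ** 2).sum())
        ms_g = ss_g / (g - 1)
        ms_w = ss_w / (g * (r - 1))
        sigma2 = {
            "genotype": max(0.0, (ms_g - ms_w) / r),
            "residual": max(0.0, ms_w),
        }
    else:
        env = frame["environment"].astype(str)
        cell = frame.groupby([geno, env])[trait]
        counts = cell.count()
        if counts.nunique() != 1:
            raise ValueError("unbalanced layout: unequal replication per cell")
        r = int(counts.iloc[0])
        if r < 2:
            raise ValueError("need >= 2 replicates per cell")
        g = geno.nunique()
        e = env.nunique()
        grand = y.mean()
        gm = frame.groupby(geno)[trait].mean()
        em = frame.groupby(env)[trait].mean()
        cm = cell.mean()
        ss_g = r * e * float(((gm - grand) ** 2).sum())
        ss_e = r * g * float(((em - grand) ** 2).sum())
        inter = cm - gm.reindex(cm.index.get_level_values(0)).to_numpy() - em.reindex(
            cm.index.get_level_values(1)
        ).to_numpy() + grand
        ss_ge = r * float((inter**2).sum())
        fitted = cm.loc[list(zip(geno, env))].to_numpy()
        ss_err = float(((y - fitted) ** 2).sum())
        ms_g = ss_g / (g - 1)
        ms_e = ss_e / (e - 1)
        ms_ge = ss_ge / ((g - 1) * (e - 1))
        ms_err = ss_err / (g * e * (r - 1))
        sigma2 = {
            "environment": max(0.0, (ms_e - ms_ge) / (r * g)),
            "genotype": max(0.0, (ms_g - ms_ge) / (r * e)),
            "gxe": max(0.0, (ms_ge - ms_err) / r),
            "residual": max(0.0, ms_err),
        }
    return VarianceComponents(
        sigma2=sigma2,
        n_iter=0,
        converged=True,
        final_change=0.0,
        loglik=np.nan,
        n_obs=y.size,
    )
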