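"""Entry-mean broad-sense heritability from variance components.

Two denominators are offered.  The compact form divides the genetic
variance by itself plus the genotype-by-environment variance averaged over
environments,

    h2 = sigma2_G / (sigma2_G + sigma2_GxE / e),

and the fuller entry-mean form additionally carries the plot residual
divided by the effective number of replicates per environment,

    h2 = sigma2_G / (sigma2_G + sigma2_GxE / e + sigma2_eps / (e * r_bar)).

The fuller form is the default: in multi-environment trials the residual
term matters whenever plots are noisy, and omitting it inflates h2.  For an
augmented design r_bar is not a design constant (checks are replicated,
test entries are not); the harmonic-mean number of plots per genotype is a
reasonable choice and the parameter is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from lignotrial.varcomp_blup import VarianceComponents


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    variant: str
    e: int
    r_bar: float | None = None


def entry_mean_h2(
    vc: VarianceComponents | Mapping[str, float],
    e: int,
    variant: str = "with_residual",
    r_bar: float | None = None,
) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability.

    Parameters
    ----------
    vc : variance components (needs ``genotype``, ``gxe``; ``residual``
        for the ``with_residual`` variant; absent components count as 0)
    e : number of environments (>= 1)
    variant : ``"compact"`` for the compact denominator,
        ``"with_residual"`` (default) for the full entry-mean denominator
    r_bar : effective replicates per environment; required by
        ``with_residual``
    """
    sigma2 = vc.sigma2 if isinstance(vc, VarianceComponents) else dict(vc)
    if e < 1:
        raise ValueError("e must be >= 1")
    s_g = float(sigma2.get("genotype", 0.0))
    s_ge = float(sigma2.get("gxe", 0.0))
    if s_g < 0 or s_ge < 0:
        raise ValueError("variance components must be >= 0")

    if variant == "compact":
        denom = s_g + s_ge / e
    elif variant == "with_residual":
        if r_bar is None or r_bar <= 0:
            raise ValueError("with_residual variant requires r_bar > 0")
        s_e = float(sigma2.get("residual", 0.0))
        if s_e < 0:
            raise ValueError("variance components must be >= 0")
        denom = s_g + s_ge / e + s_e / (e * r_bar)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if denom <= 0:
        raise ZeroDivisionError(
            "heritability undefined: all variance components are zero"
        )
    return HeritabilityEstimate(h2=s_g / denom, variant=variant, e=e, r_bar=r_bar)
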