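"""Detergent-fiber arithmetic: lignocellulose concentrations, yields, ethanol.

Sequential detergent fiber analysis partitions cell-wall dry matter so that

* lignin        = ADL
* cellulose     = ADF - ADL
* hemicellulose = NDF - ADF

hence the three components sum exactly to NDF.  Component yields scale the
concentration by plot dry biomass, and theoretical ethanol converts the
structural carbohydrate yield through the stoichiometric chain

    ethanol [L/ha] = (cellulose + hemicellulose) [kg/ha]
                     x 1.11 (hydrolysis mass gain to monomer sugars)
                     x 0.51 (Gay-Lussac fermentation yield, kg ethanol/kg sugar)
                     x efficiency / 0.79 (ethanol density, kg/L)

All constants are configurable via :class:`EthanolConstants`; a separate
pentosan hydrolysis factor (1.136 instead of 1.11) can be enabled for the
hemicellulose stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EthanolConstants:
    """Stoichiometric constants of the theoretical ethanol conversion."""

    hydrolysis_factor: float = 1.11  # hexan -> glucose mass gain
    fermentation_yield: float = 0.51  # kg ethanol per kg monomer sugar
    ethanol_density: float = 0.79  # kg per litre
    process_efficiency: float = 1.0  # unitless, <= 1
    #: optional distinct hydrolysis gain for the pentosan (hemicellulose)
    #: stream; ``None`` applies ``hydrolysis_factor`` to both streams.
    pentosan_hydrolysis_factor: float | None = None

    def __post_init__(self) -> None:
        for name in ("hydrolysis_factor", "fermentation_yield", "ethanol_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.process_efficiency <= 1:
            raise ValueError("process_efficiency must be in (0, 1]")
        if self.pentosan_hydrolysis_factor is not None and self.pentosan_hydrolysis_factor <= 0:
            raise ValueError("pentosan_hydrolysis_factor must be > 0")


def derive_composition(ndf_pct, adf_pct, adl_pct):
    """Lignin, hemicellulose, cellulose (% of DM) from NDF/ADF/ADL fractions.

    Accepts scalars or array-likes.  Requires 0 <= ADL <= ADF <= NDF.
    Returns ``(lignin_pct, hemicellulose_pct, cellulose_pct)``.
    """
    ndf = np.asarray(ndf_pct, dtype=float)
    adf = np.asarray(adf_pct, dtype=float)
    adl = np.asarray(adl_pct, dtype=float)
    if np.any(adl < 0) or np.any(adf < adl) or np.any(ndf < adf):
        raise ValueError("fiber ordering violated: need 0 <= ADL <= ADF <= NDF")
    lignin = adl
    cellulose = adf - adl
    hemicellulose = ndf - adf
    if np.ndim(ndf_pct) == 0 and np.ndim(adf_pct) == 0 and np.ndim(adl_pct) == 0:
        return float(lignin), float(hemicellulose), float(cellulose)
    return lignin, hemicellulose, cellulose


def component_yield(concentration_pct, dry_biomass_kg_ha):
    """Per-hectare component yield: concentration/100 x dry biomass."""
    conc = np.asarray(concentration_pct, dtype=float)
    biomass = np.asarray(dry_biomass_kg_ha, dtype=float)
    if np.any(conc < 0) or np.any(biomass < 0):
        raise ValueError("concentration and biomass must be >= 0")
    out = conc / 100.0 * biomass
    return float(out) if out.ndim == 0 else out


def theoretical_ethanol(
    cellulose_yield,
    hemicellulose_yield,
    constants: EthanolConstants = EthanolConstants(),
):
    """Theoretical ethanol yield (L ha^-1) from structural carbohydrate yields."""
    cel = np.asarray(cellulose_yield, dtype=float)
    hem = np.asarray(hemicellulose_yield, dtype=float)
    if np.any(cel < 0) or np.any(hem < 0):
        raise ValueError("carbohydrate yields must be >= 0")
    pent = constants.pentosan_hydrolysis_factor
    if pent is None:
        pent = constants.hydrolysis_factor
    sugar = cel * constants.hydrolysis_factor + hem * pent
    out = (
        sugar
        * constants.fermentation_yield
        * constants.process_efficiency
        / constants.ethanol_density
    )
    return float(out) if out.ndim == 0 else out


def composition_table(
    plots: pd.DataFrame, constants: EthanolConstants = EthanolConstants()
) -> pd.DataFrame:
    """Derive the seven composition/yield traits for every row of a plot table.

    Input columns: ``ndf_pct, adf_pct, adl_pct, dry_biomass_kg_ha`` (the plot
    CSV schema).  Returns a copy with the trait columns appended.
    """
    out = plots.copy()
    lig, hemi, cel = derive_composition(
        out["ndf_pct"].to_numpy(),
        out["adf_pct"].to_numpy(),
        out["adl_pct"].to_numpy(),
    )
    biomass = out["dry_biomass_kg_ha"].to_numpy()
    out["lignin_pct"] = lig
    out["hemicellulose_pct"] = hemi
    out["cellulose_pct"] = cel
    out["lignin_yield"] = component_yield(lig, biomass)
    out["hemicellulose_yield"] = component_yield(hemi, biomass)
    out["cellulose_yield"] = component_yield(cel, biomass)
    out["ethanol_yield"] = theoretical_ethanol(
        out["cellulose_yield"].to_numpy(),
        out["hemicellulose_yield"].to_numpy(),
        constants,
    )
    return out
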