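"""Simulate plot-level data from a two-environment augmented block design.

The generator mirrors the evaluation trial the package targets: 51
unreplicated test entries plus 6 replicated checks, laid out in 4 blocks per
environment under two irrigation regimes (well-watered ``IRRI`` vs.
water-stressed ``DRY``), with every random factor of the trial model drawn
i.i.d. Gaussian at a configured variance:

    y = mu + E + B(E) + G + CE*is_check + GE + eps

Each of the three cell-wall concentration traits (lignin, hemicellulose,
cellulose, % of dry matter) is simulated on this model with its own
independent effect draws; the plot's NDF/ADF/ADL fractions are then emitted
so that detergent-fiber arithmetic recovers the simulated concentrations
exactly (ADL = lignin, ADF = lignin + cellulose, NDF = ADF + hemicellulose).
Dry biomass has its own genotype and residual variances and a multiplicative
reduction under DRY, so component yields inherit a genuine genotype-by-
environment structure.

Because all known effects are returned in :class:`SimulationTruth`, the
estimation stages (EM-REML, BLUP, heritability) can be tested by parameter
recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from lignotrial.trial_data import PlotObservation

_CONC_TRAITS = ("lignin_pct", "hemicellulose_pct", "cellulose_pct")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated trial.

    Defaults reproduce the target trial's layout (51 test entries, 6 checks,
    4 blocks per environment, 2 environments) with variances on the scale of
    the cellulose concentration trait and a water-stress biomass reduction
    to roughly 30% of the well-watered level.
    """

    n_test_entries: int = 51
    n_checks: int = 6
    n_blocks_per_env: int = 4
    trait_means: dict[str, float] = field(
        default_factory=lambda: {
            "lignin_pct": 16.3,
            "hemicellulose_pct": 15.5,
            "cellulose_pct": 22.5,
        }
    )
    var_env: float = 1.75
    var_block: float = 0.5
    var_genotype: float = 15.52
    var_checkxenv: float = 0.25
    var_gxe: float = 0.94
    var_residual: float = 4.0
    biomass_mean: float = 25000.0
    biomass_var_genotype: float = 2.5e7
    biomass_var_residual: float = 6.25e6
    stress_effect: float = 0.3  # DRY biomass multiplier, in (0, 1]
    seed: int = 0
    max_redraws: int = 50

    def __post_init__(self) -> None:
        for name in (
            "var_env",
            "var_block",
            "var_genotype",
            "var_checkxenv",
            "var_gxe",
            "var_residual",
            "biomass_var_genotype",
            "biomass_var_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_test_entries", "n_checks", "n_blocks_per_env"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.stress_effect <= 1:
            raise ValueError("stress_effect must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Realised effect draws of one simulated trial, for recovery checks."""

    genotype_effects: pd.DataFrame  # index genotype, columns traits + biomass
    env_effects: pd.DataFrame  # index environment, columns traits
    block_effects: pd.DataFrame  # index (environment, block), columns traits
    checkxenv_effects: pd.DataFrame  # index (genotype, environment), columns traits
    gxe_effects: pd.DataFrame  # index (genotype, environment), columns traits
    config: SimulationConfig


def _layout(config: SimulationConfig) -> pd.DataFrame:
    """Field book: every check in every block, test entries round-robin."""
    checks = [f"CHK-{i + 1}" for i in range(config.n_checks)]
    entries = [f"ENT-{i + 1:02d}" for i in range(config.n_test_entries)]
    rows = []
    for env in ("IRRI", "DRY"):
        for block in range(1, config.n_blocks_per_env + 1):
            for chk in checks:
                rows.append((env, block, chk, True))
        for i, ent in enumerate(entries):
            block = i % config.n_blocks_per_env + 1
            rows.append((env, block, ent, False))
    return pd.DataFrame(rows, columns=["environment", "block", "genotype_id", "is_check"])


def generate_trial(
    config: SimulationConfig,
) -> tuple[list[PlotObservation], SimulationTruth]:
    """Draw one trial from the configured augmented design.

    Same config (including its seed) always yields identical output: the
    seed feeds one ``SeedSequence`` whose children give each random factor
    its own deterministic stream.

    Negative concentration draws (possible when residual noise is large
    relative to the mean) are handled by redrawing that plot's residuals up
    to ``config.max_redraws`` times and clipping at zero afterwards, which
    preserves the fiber ordering 0 <= ADL <= ADF <= NDF.
    """
    traits = list(_CONC_TRAITS)
    for t in traits:
        if t not in config.trait_means:
            raise ValueError(f"trait_means missing {t!r}")
    book = _layout(config)
    envs = ["IRRI", "DRY"]
    genotypes = list(dict.fromkeys(book["genotype_id"]))
    checks = [g for g in genotypes if g.startswith("CHK-")]
    blocks = [(e, b) for e in envs for b in range(1, config.n_blocks_per_env + 1)]

    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("env", "block", "genotype", "checkxenv", "gxe", "residual", "biomass"),
            ss.spawn(7),
        )
    }

    def draws(rng, var, shape):
        return rng.normal(0.0, np.sqrt(var), size=shape)

    env_eff = pd.DataFrame(
        draws(streams["env"], config.var_env, (2, len(traits))),
        index=pd.Index(envs, name="environment"),
        columns=traits,
    )
    block_eff = pd.DataFrame(
        draws(streams["block"], config.var_block, (len(blocks), len(traits))),
        index=pd.MultiIndex.from_tuples(blocks, names=["environment", "block"]),
        columns=traits,
    )
    geno_eff = pd.DataFrame(
        draws(streams["genotype"], config.var_genotype, (len(genotypes), len(traits))),
        index=pd.Index(genotypes, name="genotype"),
        columns=traits,
    )
    geno_eff["biomass"] = draws(
        streams["biomass"], config.biomass_var_genotype, len(genotypes)
    )
    ce_index = pd.MultiIndex.from_product(
        [checks, envs], names=["genotype", "environment"]
    )
    ce_eff = pd.DataFrame(
        draws(streams["checkxenv"], config.var_checkxenv, (len(ce_index), len(traits))),
        index=ce_index,
        columns=traits,
    )
    ge_index = pd.MultiIndex.from_product(
        [genotypes, envs], names=["genotype", "environment"]
    )
    ge_eff = pd.DataFrame(
        draws(streams["gxe"], config.var_gxe, (len(ge_index), len(traits))),
        index=ge_index,
        columns=traits,
    )

    resid_rng = streams["residual"]
    biomass_rng = streams["biomass"]
    observations: list[PlotObservation] = []
    for row in book.itertuples():
        base = {}
        for t in traits:
            mu = config.trait_means[t]
            val = (
                mu
                + env_eff.at[row.environment, t]
                + block_eff.at[(row.environment, row.block), t]
                + geno_eff.at[row.genotype_id, t]
                + ge_eff.at[(row.genotype_id, row.environment), t]
            )
            if row.is_check:
                val += ce_eff.at[(row.genotype_id, row.environment), t]
            base[t] = val
        conc = None
        for _ in range(config.max_redraws + 1):
            eps = draws(resid_rng, config.var_residual, len(traits))
            trial = {t: base[t] + e for t, e in zip(traits, eps)}
            if all(v >= 0 for v in trial.values()):
                conc = trial
                break
        if conc is None:  # bounded retries exhausted: clip at zero
            conc = {t: max(0.0, v) for t, v in trial.items()}

        mean_biomass = config.biomass_mean + geno_eff.at[row.genotype_id, "biomass"]
        biomass = None
        for _ in range(config.max_redraws + 1):
            cand = mean_biomass + biomass_rng.normal(
                0.0, np.sqrt(config.biomass_var_residual)
            )
            if cand >= 0:
                biomass = cand
                break
        if biomass is None:
            biomass = max(0.0, cand)
        if row.environment == "DRY":
            biomass *= config.stress_effect

        adl = conc["lignin_pct"]
        adf = adl + conc["cellulose_pct"]
        ndf = adf + conc["hemicellulose_pct"]
        observations.append(
            PlotObservation(
                environment=row.environment,
                block=int(row.block),
                genotype_id=row.genotype_id,
                is_check=bool(row.is_check),
                ndf_pct=ndf,
                adf_pct=adf,
                adl_pct=adl,
                dry_biomass_kg_ha=biomass,
            )
        )

    truth = SimulationTruth(
        genotype_effects=geno_eff,
        env_effects=env_eff,
        block_effects=block_eff,
        checkxenv_effects=ce_eff,
        gxe_effects=ge_eff,
        config=config,
    )
    return observations, truth
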