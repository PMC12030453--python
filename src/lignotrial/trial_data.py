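"""Plot-level data model, CSV readers/writers, and bundled reference tables.

The plot CSV schema is::

    environment,block,genotype_id,is_check,ndf_pct,adf_pct,adl_pct,dry_biomass_kg_ha

with ``environment`` in {IRRI, DRY} (well-watered vs. water-stressed),
integer block numbers, and fiber fractions as percent of dry matter on the
0-100 scale.  The detergent-fiber fractions are nested
(ADL <= ADF <= NDF <= 100), which every reader enforces.

Four genotype-level reference tables for the 51-entry USDA guayule/mariola
collection ship with the package and are accessed through
:func:`load_fixture`: variance components (``table1``), per-genotype BLUPs
for the seven composition/yield traits (``table2``), group-by-environment
mean BLUPs (``table3``), and YSI/YI/STI stress indices (``table4``).
Genotype labels are normalised at transcription: thousands separators inside
accession numbers are dropped ("PI 478,657" becomes "PI 478657").
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: The seven genotype-level traits, in canonical order.  Concentrations are
#: percent of dry matter, component yields kg ha^-1, ethanol yield L ha^-1.
TRAITS: tuple[str, ...] = (
    "lignin_pct",
    "hemicellulose_pct",
    "cellulose_pct",
    "lignin_yield",
    "hemicellulose_yield",
    "cellulose_yield",
    "ethanol_yield",
)

#: Germplasm groups used throughout the reference tables.
GROUPS: tuple[str, ...] = ("mariola", "guayule_hybrid", "guayule")

ENVIRONMENTS: tuple[str, ...] = ("IRRI", "DRY")

PLOT_COLUMNS: tuple[str, ...] = (
    "environment",
    "block",
    "genotype_id",
    "is_check",
    "ndf_pct",
    "adf_pct",
    "adl_pct",
    "dry_biomass_kg_ha",
)

_FIXTURE_FILES = {
    "table1": "table1_varcomp.csv",
    "table2": "table2_blups.csv",
    "table3": "table3_group_env_means.csv",
    "table4": "table4_stress_indices.csv",
}


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable header."""


class ValidationError(ValueError):
    """Row contents violate a design or measurement invariant."""


@dataclass(frozen=True)
class GenotypeRecord:
    """One entry of the trial: accession label, germplasm group, check status."""

    id: str
    is_check: bool = False
    group: str | None = None


@dataclass(frozen=True)
class PlotObservation:
    """Raw measurements from one field plot with its design coordinates."""

    environment: str
    block: int
    genotype_id: str
    is_check: bool
    ndf_pct: float
    adf_pct: float
    adl_pct: float
    dry_biomass_kg_ha: float


def normalize_genotype_id(raw: str) -> str:
    """Normalise an accession label: collapse whitespace, drop thousands commas."""
    return " ".join(raw.replace(",", "").split())


def _check_fiber_ordering(row: pd.Series, line: int) -> None:
    ndf, adf, adl = row["ndf_pct"], row["adf_pct"], row["adl_pct"]
    if not 0 <= adl:
        raise ValidationError(f"line {line}: ADL must be >= 0 (got {adl})")
    if adl > adf:
        raise ValidationError(f"line {line}: ADF >= ADL violated (ADF={adf}, ADL={adl})")
    if adf > ndf:
        raise ValidationError(f"line {line}: NDF >= ADF violated (NDF={ndf}, ADF={adf})")
    if ndf > 100:
        raise ValidationError(f"line {line}: NDF must be <= 100 (got {ndf})")
    if row["dry_biomass_kg_ha"] < 0:
        raise ValidationError(f"line {line}: dry biomass must be >= 0")


def validate_plot_frame(frame: pd.DataFrame) -> None:
    """Validate design invariants on a plot table already in memory.

    Checks must appear in every block of every environment; unreplicated
    test entries at most once per environment.
    """
    for env, env_rows in frame.groupby("environment", observed=True):
        blocks = set(env_rows["block"].unique())
        checks = env_rows[env_rows["is_check"]]
        for geno, geno_rows in checks.groupby("genotype_id", observed=True):
            missing = blocks - set(geno_rows["block"])
            if missing:
                raise ValidationError(
                    f"check {geno!r} missing from block(s) {sorted(missing)} in {env}"
                )
        tests = env_rows[~env_rows["is_check"]]
        counts = tests["genotype_id"].value_counts()
        dupes = counts[counts > 1]
        if len(dupes):
            raise ValidationError(
                f"test entries replicated within {env}: {sorted(dupes.index)}"
            )


def read_plot_table(
    path: str | Path, validate_design: bool = True
) -> tuple[list[PlotObservation], list[GenotypeRecord]]:
    """Read a plot CSV and return observations plus the genotype roster.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for rows violating the fiber ordering or the
    augmented-design layout, naming the offending CSV line.
    """
    frame = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    frame["genotype_id"] = frame["genotype_id"].map(normalize_genotype_id)
    frame["is_check"] = frame["is_check"].astype(bool)
    frame["block"] = frame["block"].astype(int)
    for env in frame["environment"].unique():
        if env not in ENVIRONMENTS:
            raise ValidationError(f"{path}: unknown environment {env!r}")
    # header is line 1, first data row line 2
    for idx, row in frame.iterrows():
        _check_fiber_ordering(row, line=int(idx) + 2)
    if validate_design:
        validate_plot_frame(frame)
    observations = [
        PlotObservation(
            environment=r.environment,
            block=int(r.block),
            genotype_id=r.genotype_id,
            is_check=bool(r.is_check),
            ndf_pct=float(r.ndf_pct),
            adf_pct=float(r.adf_pct),
            adl_pct=float(r.adl_pct),
            dry_biomass_kg_ha=float(r.dry_biomass_kg_ha),
        )
        for r in frame.itertuples()
    ]
    roster = {}
    for obs in observations:
        roster.setdefault(obs.genotype_id, obs.is_check)
    genotypes = [GenotypeRecord(id=g, is_check=c) for g, c in roster.items()]
    return observations, genotypes


def write_plot_table(observations: Iterable[PlotObservation], path: str | Path) -> None:
    """Write observations to the plot CSV schema (lossless round-trip)."""
    plots_to_frame(observations).to_csv(path, index=False)


def plots_to_frame(observations: Iterable[PlotObservation]) -> pd.DataFrame:
    """Convert observations to a DataFrame in plot-schema column order."""
    frame = pd.DataFrame([vars(o) for o in observations])
    return frame.loc[:, list(PLOT_COLUMNS)]


def frame_to_plots(frame: pd.DataFrame) -> list[PlotObservation]:
    """Inverse of :func:`plots_to_frame`."""
    return [
        PlotObservation(
            environment=r.environment,
            block=int(r.block),
            genotype_id=r.genotype_id,
            is_check=bool(r.is_check),
            ndf_pct=float(r.ndf_pct),
            adf_pct=float(r.adf_pct),
            adl_pct=float(r.adl_pct),
            dry_biomass_kg_ha=float(r.dry_biomass_kg_ha),
        )
        for r in frame.itertuples()
    ]


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the bundled reference tables (``table1`` .. ``table4``).

    ``table1``: variance components per trait (rows environment/genotype/gxe).
    ``table2``: 51 genotype-level BLUPs for the seven traits, with group.
    ``table3``: group x environment mean BLUPs.
    ``table4``: YSI/YI/STI stress indices per genotype for the four yield traits.
    """
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        ) from None
    with resources.files("lignotrial.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh)


def genotype_records_from_table(table: pd.DataFrame) -> list[GenotypeRecord]:
    """Build the genotype roster (with groups) from a genotype-level table."""
    return [
        GenotypeRecord(id=r.genotype, group=r.group)
        for r in table.itertuples()
    ]


def fixture_checksums() -> dict[str, int]:
    """Row counts of the bundled tables, for quick integrity checks."""
    return {name: len(load_fixture(name)) for name in _FIXTURE_FILES}
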