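"""Leaf-level measurements to species-level trait profiles.

Three leaf traits drive the CSR ordination: leaf area (LA, mm²), leaf dry
matter content (LDMC, %) and specific leaf area (SLA, mm²/mg). Raw
measurements per leaf are LA plus water-saturated fresh mass (LFM, mg) and
dry mass (LDM, mg). Raw quantities are averaged hierarchically — leaves
within individual, then individuals within species, each level unweighted —
and the derived ratios SLA = LA/LDM and LDMC = 100·LDM/LFM are computed
from the species-level averages (ratio of means, not mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LeafMeasurement:
    """One leaf: area (mm²), water-saturated fresh mass and dry mass (mg)."""

    species_id: str
    individual_id: str
    plot_id: str
    leaf_id: str
    la_mm2: float
    lfm_mg: float
    ldm_mg: float

    def __post_init__(self):
        if self.la_mm2 <= 0:
            raise ValueError(f"leaf {self.leaf_id}: LA must be positive")
        if self.ldm_mg <= 0:
            raise ValueError(f"leaf {self.leaf_id}: LDM must be positive")
        if self.lfm_mg < self.ldm_mg:
            raise ValueError(f"leaf {self.leaf_id}: dry mass exceeds fresh mass")


@dataclass(frozen=True)
class SpeciesTraitProfile:
    """Species-level LA/LDMC/SLA with origin label and collection counts."""

    species_id: str
    origin: str
    la_mm2: float
    ldmc_pct: float
    sla_mm2_mg: float
    n_individuals: int
    n_leaves: int


def compute_sla(la_mm2: float, ldm_mg: float) -> float:
    """Specific leaf area: leaf area per unit dry mass (mm²/mg)."""
    if ldm_mg <= 0:
        raise ValueError("LDM must be positive")
    if la_mm2 <= 0:
        raise ValueError("LA must be positive")
    return la_mm2 / ldm_mg


def compute_ldmc(ldm_mg: float, lfm_mg: float) -> float:
    """Leaf dry matter content: dry mass as a percentage of fresh mass."""
    if ldm_mg <= 0:
        raise ValueError("LDM must be positive")
    if ldm_mg > lfm_mg:
        raise ValueError("dry mass exceeds fresh mass")
    return 100.0 * ldm_mg / lfm_mg


def validate_leaf_table(leaves: pd.DataFrame) -> None:
    """Check the per-leaf physical invariants; raise on the first violation."""
    if (leaves["la_mm2"] <= 0).any():
        bad = leaves.loc[leaves["la_mm2"] <= 0].iloc[0]
        raise ValueError(f"leaf {bad['leaf_id']} of {bad['species_id']}: LA must be positive")
    if (leaves["ldm_mg"] <= 0).any():
        bad = leaves.loc[leaves["ldm_mg"] <= 0].iloc[0]
        raise ValueError(f"leaf {bad['leaf_id']} of {bad['species_id']}: LDM must be positive")
    if (leaves["lfm_mg"] < leaves["ldm_mg"]).any():
        bad = leaves.loc[leaves["lfm_mg"] < leaves["ldm_mg"]].iloc[0]
        raise ValueError(
            f"leaf {bad['leaf_id']} of {bad['species_id']}: dry mass exceeds fresh mass")


def aggregate_to_species(leaves: pd.DataFrame, origins: dict[str, str]) -> pd.DataFrame:
    """Two-level averaging of the leaf table into species trait profiles.

    LA, LFM and LDM are averaged per individual (over its leaves) and then
    per species (unweighted over individual means, so individuals with
    fewer leaves are not down-weighted); SLA and LDMC are derived from the
    species-level averages. Species with incomplete collections (fewer than
    the nominal 4 individuals × 5 leaves) are retained with the available
    material; the counts are recorded in the profile.

    Parameters
    ----------
    leaves
        Columns species_id, individual_id, plot_id, leaf_id, la_mm2,
        lfm_mg, ldm_mg; one row per leaf.
    origins
        Mapping species_id -> 'native' | 'alien'.
    """
    validate_leaf_table(leaves)
    if leaves.empty:
        logger.warning("empty leaf table: no species profiles produced")
        return pd.DataFrame(columns=[
            "species_id", "origin", "la_mm2", "ldmc_pct", "sla_mm2_mg",
            "n_individuals", "n_leaves"])

    indiv = (leaves.groupby(["species_id", "individual_id"], sort=True)
             .agg(la=("la_mm2", "mean"), lfm=("lfm_mg", "mean"),
                  ldm=("ldm_mg", "mean"), n_leaves=("leaf_id", "size"))
             .reset_index())
    sp = (indiv.groupby("species_id", sort=True)
          .agg(la=("la", "mean"), lfm=("lfm", "mean"), ldm=("ldm", "mean"),
               n_individuals=("individual_id", "size"), n_leaves=("n_leaves", "sum"))
          .reset_index())

    sp["sla_mm2_mg"] = sp["la"] / sp["ldm"]
    sp["ldmc_pct"] = 100.0 * sp["ldm"] / sp["lfm"]
    saturated = sp["ldmc_pct"] >= 100.0 - 1e-12
    for sid in sp.loc[saturated, "species_id"]:
        logger.warning("species %s: LFM equals LDM (LDMC = 100%%), at the physical boundary", sid)

    sp["origin"] = [origins.get(s, "native") for s in sp["species_id"]]
    missing = [s for s in sp["species_id"] if s not in origins]
    if missing:
        logger.warning("species without an origin label treated as native: %s", missing)
    out = sp.rename(columns={"la": "la_mm2"})[
        ["species_id", "origin", "la_mm2", "ldmc_pct", "sla_mm2_mg",
         "n_individuals", "n_leaves"]]
    return out.reset_index(drop=True)


def profiles_from_frame(df: pd.DataFrame) -> list[SpeciesTraitProfile]:
    return [SpeciesTraitProfile(r.species_id, r.origin, float(r.la_mm2),
                                float(r.ldmc_pct), float(r.sla_mm2_mg),
                                int(r.n_individuals), int(r.n_leaves))
            for r in df.itertuples(index=False)]
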