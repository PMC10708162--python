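"""Plot-level stand structure and community-level CSR aggregation.

A plot is a 100 m² census of all woody stems with DBH ≥ 1 cm. Stand
structure (basal area G, tree and stem densities, mean DBH/height, origin
fractions) is summarised per plot, and species CSR scores are aggregated
to the community level under four weighting schemes: unweighted (each
species present counts once), abundance (trees per species), stem density
(stems per species) and basal area (summed stem basal area per species).
Compositional similarity between paired plots uses the Sørensen index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMES = ("unweighted", "abundance", "stem_density", "basal_area")
SORENSEN_SIMILAR_THRESHOLD = 0.70


@dataclass(frozen=True)
class StemRecord:
    plot_id: str
    tree_id: str
    stem_id: str
    species_id: str
    dbh_cm: float
    height_m: float

    def __post_init__(self):
        if self.dbh_cm < 1.0:
            raise ValueError(f"stem {self.stem_id}: DBH below the 1 cm census rule")
        if self.height_m <= 0:
            raise ValueError(f"stem {self.stem_id}: height must be positive")


@dataclass
class PlotInventory:
    plot_id: str
    elevation_m: float
    trail_position: str  # 'near' | 'off'
    stems: list[StemRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.elevation_m < 0:
            raise ValueError("elevation must be non-negative")
        if self.trail_position not in ("near", "off"):
            raise ValueError(f"trail_position must be 'near' or 'off', got {self.trail_position!r}")
        for s in self.stems:
            if s.plot_id != self.plot_id:
                raise ValueError(f"stem {s.stem_id} belongs to plot {s.plot_id}, not {self.plot_id}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.plot_id, self.elevation_m, self.trail_position,
              s.tree_id, s.stem_id, s.species_id, s.dbh_cm, s.height_m)
             for s in self.stems],
            columns=["plot_id", "elevation_m", "trail_position", "tree_id",
                     "stem_id", "species_id", "dbh_cm", "height_m"])

    @property
    def species(self) -> set[str]:
        return {s.species_id for s in self.stems}


def inventories_from_frame(df: pd.DataFrame) -> list[PlotInventory]:
    out = []
    for plot_id, grp in df.groupby("plot_id", sort=True):
        stems = [StemRecord(plot_id, str(r.tree_id), str(r.stem_id), r.species_id,
                            float(r.dbh_cm), float(r.height_m))
                 for r in grp.itertuples(index=False)]
        out.append(PlotInventory(plot_id, float(grp["elevation_m"].iloc[0]),
                                 str(grp["trail_position"].iloc[0]), stems))
    return out


def stem_basal_area(dbh_cm: float) -> float:
    """Cross-sectional area (m²) at breast height of one stem: π(DBH/200)²."""
    if dbh_cm <= 0:
        raise ValueError("DBH must be positive")
    return math.pi * (dbh_cm / 200.0) ** 2


def plot_basal_area(inventory: PlotInventory) -> float:
    """Basal area G (m² per 100 m² plot): sum over every stem in the plot.

    Multi-stemmed trees contribute one term per stem.
    """
    if not inventory.stems:
        logger.warning("plot %s has no stems; G = 0", inventory.plot_id)
        return 0.0
    return sum(stem_basal_area(s.dbh_cm) for s in inventory.stems)


@dataclass(frozen=True)
class StructureSummary:
    plot_id: str
    elevation_m: float
    trail_position: str
    richness: int
    tree_density: int
    stem_density: int
    mean_dbh_cm: float
    mean_height_m: float
    basal_area_m2: float
    alien_species_fraction: float
    alien_individual_fraction: float


def structure_summary(inventory: PlotInventory, origins: dict[str, str]) -> StructureSummary:
    """Per-plot stand structure.

    Mean DBH is taken over stems, mean height over trees (one height per
    tree); alien fractions are over species and over trees.
    """
    df = inventory.to_frame()
    if df.empty:
        logger.warning("plot %s has no stems", inventory.plot_id)
        return StructureSummary(inventory.plot_id, inventory.elevation_m,
                                inventory.trail_position, 0, 0, 0,
                                float("nan"), float("nan"), 0.0,
                                float("nan"), float("nan"))
    trees = df.drop_duplicates("tree_id")
    species = sorted(df["species_id"].unique())
    alien_sp = [s for s in species if origins.get(s) == "alien"]
    alien_trees = trees["species_id"].map(lambda s: origins.get(s) == "alien")
    return StructureSummary(
        plot_id=inventory.plot_id,
        elevation_m=inventory.elevation_m,
        trail_position=inventory.trail_position,
        richness=len(species),
        tree_density=len(trees),
        stem_density=len(df),
        mean_dbh_cm=float(df["dbh_cm"].mean()),
        mean_height_m=float(trees["height_m"].mean()),
        basal_area_m2=plot_basal_area(inventory),
        alien_species_fraction=len(alien_sp) / len(species),
        alien_individual_fraction=float(alien_trees.mean()),
    )


@dataclass(frozen=True)
class CommunityCSRProfile:
    plot_id: str
    scheme: str
    c: float
    s: float
    r: float


def _species_weights(inventory: PlotInventory, scheme: str) -> dict[str, float]:
    if scheme == "unweighted":
        return {sp: 1.0 for sp in inventory.species}
    df = inventory.to_frame()
    if scheme == "abundance":
        w = df.drop_duplicates("tree_id").groupby("species_id").size()
    elif scheme == "stem_density":
        w = df.groupby("species_id").size()
    elif scheme == "basal_area":
        w = df.assign(ba=[stem_basal_area(d) for d in df["dbh_cm"]]) \
              .groupby("species_id")["ba"].sum()
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return w.to_dict()


def community_csr(inventory: PlotInventory, species_scores: dict[str, tuple[float, float, float]],
                  scheme: str) -> CommunityCSRProfile:
    """Weighted mean of the species CSR scores present in the plot.

    ``species_scores`` maps species_id -> (c, s, r). Weights are normalised
    to sum to one and the output is re-closed to sum to 100.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    present = sorted(inventory.species)
    if not present:
        raise ValueError(f"plot {inventory.plot_id} has no stems")
    missing = [sp for sp in present if sp not in species_scores]
    if missing:
        raise KeyError(f"species lacking a CSR score: {missing}")
    weights = _species_weights(inventory, scheme)
    w = np.array([weights[sp] for sp in present], dtype=float)
    w = w / w.sum()
    scores = np.array([species_scores[sp] for sp in present], dtype=float)
    mean = w @ scores
    mean = 100.0 * mean / mean.sum()
    return CommunityCSRProfile(inventory.plot_id, scheme, *mean)


def community_csr_table(inventories: list[PlotInventory], scores: pd.DataFrame,
                        schemes: tuple[str, ...] = SCHEMES) -> pd.DataFrame:
    """One row per plot × scheme; ``scores`` has species_id, c, s, r columns."""
    mapping = {r.species_id: (r.c, r.s, r.r) for r in scores.itertuples(index=False)}
    rows = []
    for inv in inventories:
        for scheme in schemes:
            prof = community_csr(inv, mapping, scheme)
            rows.append((inv.plot_id, inv.elevation_m, inv.trail_position,
                         scheme, prof.c, prof.s, prof.r))
    return pd.DataFrame(rows, columns=["plot_id", "elevation_m", "trail_position",
                                       "scheme", "c", "s", "r"])


def structure_table(inventories: list[PlotInventory], origins: dict[str, str]) -> pd.DataFrame:
    rows = [structure_summary(inv, origins).__dict__ for inv in inventories]
    return pd.DataFrame(rows)


def sorensen(species_a: set[str], species_b: set[str]) -> float:
    """Sørensen similarity 2|A∩B| / (|A|+|B|) between two species sets."""
    if not species_a and not species_b:
        raise ValueError("Sørensen index undefined for two empty sets")
    return 2.0 * len(set(species_a) & set(species_b)) / (len(set(species_a)) + len(set(species_b)))


def sorensen_is_similar(value: float) -> bool:
    """Communities above 0.70 are conventionally called similar."""
    return value > SORENSEN_SIMILAR_THRESHOLD


def paired_sorensen(inventories: list[PlotInventory]) -> pd.DataFrame:
    """Sørensen index between the near- and off-trail plot at each elevation."""
    by_elev: dict[float, dict[str, PlotInventory]] = {}
    for inv in inventories:
        by_elev.setdefault(inv.elevation_m, {})[inv.trail_position] = inv
    rows = []
    for elev in sorted(by_elev):
        pair = by_elev[elev]
        if {"near", "off"} <= set(pair):
            s = sorensen(pair["near"].species, pair["off"].species)
            rows.append((elev, s, sorensen_is_similar(s)))
    return pd.DataFrame(rows, columns=["elevation_m", "sorensen", "similar"])
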