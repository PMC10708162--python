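"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a stratified elevational plot network: plots in
pairs (near-trail / off-trail) every ``elevation_step`` metres, woody
stems ≥ 1 cm DBH censused per 100 m² plot, and a leaf-trait collection
of up to 4 individuals × 5 leaves per species. Species occupy contiguous
elevational windows; community structure (richness, tree and stem
density humped at mid-elevation, mean DBH lowest there, height declining
with elevation) and two trait–environment effects are injected: species
leaf dry matter content (logit scale) increases with the species'
elevational optimum, and leaf area (log scale) increases with stand
crowding. Alien species are confined to elevations at or below a
ceiling. A Yule phylogeny over all species, rescaled to unit depth,
supports the Brownian-motion null of the origin comparison.

All randomness flows from one seed, split hierarchically by purpose
(tree / species traits / abundances / per-species leaves) so that edits
to one part of the configuration do not shift unrelated draws.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io
from .community import PlotInventory, StemRecord
from .phylo import Phylogeny, write_newick, yule_tree


class ConfigurationError(ValueError):
    """An invalid SyntheticConfig field (the message names the field)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters; defaults are the reference study conditions."""

    seed: int = 0
    n_elevations: int = 8
    elevation_step: float = 300.0
    n_species: int = 80
    alien_fraction: float = 0.125
    alien_elevation_ceiling: float = 900.0
    ldmc_elevation_slope: float = 0.6      # logit-LDMC units per km of optimum
    la_basal_area_slope: float = 1.5       # log-LA units per (m²/100 m²) crowding
    leaf_noise_cv: float = 0.10            # multiplicative lognormal CV per leaf
    max_individuals_per_species: int = 4
    max_leaves_per_individual: int = 5
    yule_birth_rate: float = 1.0

    def __post_init__(self):
        if self.n_elevations < 2:
            raise ConfigurationError("n_elevations must be at least 2")
        if not (0 < self.alien_fraction < 1):
            raise ConfigurationError("alien_fraction must lie strictly between 0 and 1")
        if self.leaf_noise_cv < 0:
            raise ConfigurationError("leaf_noise_cv must be non-negative")
        for name in ("elevation_step", "n_species", "max_individuals_per_species",
                     "max_leaves_per_individual", "yule_birth_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.alien_elevation_ceiling < 0:
            raise ConfigurationError("alien_elevation_ceiling must be non-negative")

    @property
    def elevations(self) -> np.ndarray:
        return np.arange(self.n_elevations) * self.elevation_step

    @property
    def max_elevation(self) -> float:
        return float((self.n_elevations - 1) * self.elevation_step)


@dataclass
class SyntheticDataset:
    leaf_table: pd.DataFrame
    inventories: list[PlotInventory]
    origins: dict[str, str]
    tree: Phylogeny
    truth: dict

    def inventory_frame(self) -> pd.DataFrame:
        return pd.concat([inv.to_frame() for inv in self.inventories], ignore_index=True)


def _plot_label(i: int, position: str) -> str:
    letter = string.ascii_uppercase[i] if i < 26 else f"Z{i}"
    return f"{letter}{1 if position == 'near' else 2}"


def _bump(e: np.ndarray | float, emax: float):
    """Hump factor in [0, 1] peaking at mid-elevation."""
    u = np.asarray(e, dtype=float) / emax
    return 4.0 * u * (1.0 - u)


def _crowding(e, emax: float):
    """Expected stand crowding (basal-area-like index) vs elevation.

    High through low and mid elevations, collapsing towards the
    gradient's top where stands open out into shrubland.
    """
    u = np.asarray(e, dtype=float) / emax
    return 0.9 - 0.6 * u ** 2


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def _species_truth(config: SyntheticConfig, streams) -> pd.DataFrame:
    emax = config.max_elevation
    n_alien = max(1, round(config.alien_fraction * config.n_species))
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"sp{i + 1:03d}"
        alien = i < n_alien
        ceiling = min(config.alien_elevation_ceiling, emax)
        if alien:
            optimum = rng.uniform(0.0, ceiling)
        else:
            optimum = emax * rng.beta(2.0, 2.0)
        halfwidth = rng.uniform(300.0, 900.0)
        lo = max(0.0, optimum - halfwidth)
        hi = min(emax, optimum + halfwidth)
        if alien:
            hi = min(hi, ceiling)
        logit_ldmc = logit(0.27) + config.ldmc_elevation_slope * (optimum / 1000.0) \
            + rng.normal(0.0, 0.3)
        log_la = np.log(800.0) + config.la_basal_area_slope * (float(_crowding(optimum, emax)) - 0.7) \
            + rng.normal(0.0, 0.5)
        log_sla = np.log(15.0) - 0.5 * (logit_ldmc - logit(0.35)) + rng.normal(0.0, 0.25)
        ldmc = 100.0 * expit(logit_ldmc)
        la = float(np.exp(log_la))
        sla = float(np.exp(log_sla))
        ldm = la / sla
        lfm = ldm / (ldmc / 100.0)
        rows.append((sid, "alien" if alien else "native", optimum, lo, hi,
                     la, ldmc, sla, ldm, lfm))
    return pd.DataFrame(rows, columns=[
        "species_id", "origin", "optimum_m", "window_lo_m", "window_hi_m",
        "la_mm2", "ldmc_pct", "sla_mm2_mg", "ldm_mg", "lfm_mg"])


def _build_inventories(config: SyntheticConfig, species: pd.DataFrame,
                       rng: np.random.Generator) -> list[PlotInventory]:
    emax = config.max_elevation
    inventories = []
    for i, e in enumerate(config.elevations):
        in_window = (species["window_lo_m"] <= e) & (e <= species["window_hi_m"])
        pool = species.loc[in_window, "species_id"].tolist()
        if not pool:
            natives = species[species["origin"] == "native"]
            nearest = natives.iloc[(natives["optimum_m"] - e).abs().argmin()]
            pool = [nearest["species_id"]]
        bump = float(_bump(e, emax))
        crowd = float(_crowding(e, emax))
        for position in ("near", "off"):
            plot_id = _plot_label(i, position)
            # density humped at mid-elevation, damped where stands open out
            lam = (15.0 + 45.0 * bump) * (crowd / 0.7)
            n_trees = max(1, int(rng.poisson(lam)))
            weights = rng.dirichlet(np.full(len(pool), 0.8))
            counts = rng.multinomial(n_trees, weights)
            # mean DBH lowest at mid-elevation, but with a heavier tail there
            # so that basal area still tracks the crowding index
            dbh_median = 2.0 + 5.0 * (1.0 - bump)
            dbh_sigma = 0.4 + 0.35 * bump
            h_mean = 6.0 - 2.0 * (e / emax)
            stems, tree_no = [], 0
            for sp, k in zip(pool, counts):
                for _ in range(int(k)):
                    tree_no += 1
                    tree_id = f"{plot_id}-t{tree_no:03d}"
                    n_stems = 1 + rng.poisson(0.2)
                    dbh_tree = 1.0 + dbh_median * float(rng.lognormal(0.0, dbh_sigma))
                    height = max(1.0, h_mean * (dbh_tree / 5.0) ** 0.3
                                 * float(rng.lognormal(0.0, 0.2)))
                    for j in range(n_stems):
                        dbh = dbh_tree if j == 0 else \
                            1.0 + 0.6 * dbh_median * float(rng.lognormal(0.0, dbh_sigma))
                        stems.append(StemRecord(plot_id, tree_id, f"{tree_id}-s{j + 1}",
                                                sp, dbh, height))
            inventories.append(PlotInventory(plot_id, float(e), position, stems))
    return inventories


def _build_leaves(config: SyntheticConfig, species: pd.DataFrame,
                  inventories: list[PlotInventory], leaf_streams) -> pd.DataFrame:
    occupancy: dict[str, list[str]] = {}
    for inv in inventories:
        for sp in inv.species:
            occupancy.setdefault(sp, []).append(inv.plot_id)
    plot_by_elev = {inv.plot_id: inv.elevation_m for inv in inventories}
    rows = []
    for (row, ss) in zip(species.itertuples(index=False), leaf_streams):
        rng = np.random.default_rng(ss)
        sid = row.species_id
        plots = sorted(set(occupancy.get(sid, [])))
        if not plots:
            # never drawn into a plot: collect near the species' optimum
            plots = [min(plot_by_elev, key=lambda p: abs(plot_by_elev[p] - row.optimum_m))]
        n_ind = config.max_individuals_per_species
        if rng.random() < 0.15 and n_ind > 1:  # incomplete collections happen
            n_ind = int(rng.integers(1, n_ind))
        for ind in range(1, n_ind + 1):
            plot_id = plots[int(rng.integers(len(plots)))]
            n_leaves = config.max_leaves_per_individual
            if rng.random() < 0.15 and n_leaves > 1:
                n_leaves = int(rng.integers(1, n_leaves))
            f_la = _lognormal_factor(rng, config.leaf_noise_cv, n_leaves)
            f_ldm = _lognormal_factor(rng, config.leaf_noise_cv, n_leaves)
            f_w = _lognormal_factor(rng, config.leaf_noise_cv, n_leaves)
            water = row.lfm_mg - row.ldm_mg
            for k in range(n_leaves):
                ldm = row.ldm_mg * f_ldm[k]
                lfm = ldm + water * f_w[k]  # water modelled separately keeps LFM ≥ LDM
                rows.append((sid, f"{sid}-i{ind}", plot_id, f"{sid}-i{ind}-l{k + 1}",
                             row.la_mm2 * f_la[k], lfm, ldm))
    return pd.DataFrame(rows, columns=io.LEAF_COLUMNS)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one complete dataset; identical configs give identical data."""
    root = np.random.SeedSequence(config.seed)
    tree_ss, species_ss, abund_ss, leaf_ss = root.spawn(4)

    species_streams = species_ss.spawn(config.n_species)
    species = _species_truth(config, species_streams)

    labels = species["species_id"].tolist()
    tree_seed = int(tree_ss.generate_state(1)[0] % (2 ** 31 - 1))
    tree = yule_tree(config.n_species, labels, config.yule_birth_rate, seed=tree_seed)

    inventories = _build_inventories(config, species, np.random.default_rng(abund_ss))
    leaves = _build_leaves(config, species, inventories, leaf_ss.spawn(config.n_species))

    origins = dict(zip(species["species_id"], species["origin"]))
    truth = {
        "config": asdict(config),
        "species": species.to_dict(orient="records"),
    }
    return SyntheticDataset(leaves, inventories, origins, tree, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  seed: int | None = None) -> dict[str, Path]:
    """Serialise a dataset to leaf/inventory/origins CSVs, Newick and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "leaves": io.write_csv(dataset.leaf_table, outdir / "leaves.csv", seed=seed),
        "inventory": io.write_csv(dataset.inventory_frame(), outdir / "inventory.csv", seed=seed),
        "origins": io.write_csv(
            pd.DataFrame(sorted(dataset.origins.items()), columns=io.ORIGIN_COLUMNS),
            outdir / "origins.csv", seed=seed),
        "tree": write_newick(dataset.tree, outdir / "phylogeny.nwk"),
        "truth": io.write_json(dataset.truth, outdir / "truth.json", seed=seed),
    }
    return paths


def _mini_dataset(inventories: list[PlotInventory], species_rows: list[tuple],
                  origins: dict[str, str]) -> SyntheticDataset:
    leaves = pd.DataFrame(species_rows, columns=io.LEAF_COLUMNS)
    labels = sorted(origins)
    if len(labels) == 1:
        newick = f"({labels[0]}:1.0):0.0;"
    else:
        newick = "(" + ",".join(f"{s}:1.0" for s in labels) + "):0.0;"
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return SyntheticDataset(leaves, inventories, origins, tree, {"fixture": True})


def degenerate_fixtures() -> dict[str, SyntheticDataset]:
    """Hand-built edge-case datasets for exercising downstream boundaries."""

    def leaf(sp, ind, plot, k, la, lfm, ldm):
        return (sp, f"{sp}-i{ind}", plot, f"{sp}-i{ind}-l{k}", la, lfm, ldm)

    def stem(plot, t, s, sp, dbh=5.0, h=4.0):
        return StemRecord(plot, f"{plot}-t{t}", f"{plot}-t{t}-s{s}", sp, dbh, h)

    fixtures = {}

    inv = PlotInventory("P1", 300.0, "near",
                        [stem("P1", 1, 1, "solo"), stem("P1", 2, 1, "solo", dbh=8.0)])
    fixtures["single_species_plot"] = _mini_dataset(
        [inv], [leaf("solo", 1, "P1", k, 300.0, 100.0, 30.0) for k in range(1, 4)],
        {"solo": "native"})

    inv = PlotInventory("P1", 0.0, "off", [stem("P1", 1, 1, "one", dbh=10.0)])
    fixtures["single_stem_plot"] = _mini_dataset(
        [inv], [leaf("one", 1, "P1", 1, 500.0, 120.0, 40.0),
                leaf("one", 1, "P1", 2, 520.0, 118.0, 41.0)],
        {"one": "alien"})

    inv = PlotInventory("P1", 600.0, "near", [stem("P1", 1, 1, "mono")])
    fixtures["single_leaf_species"] = _mini_dataset(
        [inv], [leaf("mono", 1, "P1", 1, 250.0, 90.0, 45.0)], {"mono": "native"})

    shared = ["spA", "spB", "spC"]
    invs = []
    for plot, pos in (("Q1", "near"), ("Q2", "off")):
        invs.append(PlotInventory(plot, 900.0, pos,
                                  [stem(plot, i + 1, 1, sp) for i, sp in enumerate(shared)]))
    fixtures["identical_pair"] = _mini_dataset(
        invs, [leaf(sp, 1, "Q1", 1, 200.0, 80.0, 24.0) for sp in shared],
        {sp: "native" for sp in shared})

    invs = [PlotInventory("R1", 1200.0, "near", [stem("R1", 1, 1, "spA"), stem("R1", 2, 1, "spB")]),
            PlotInventory("R2", 1200.0, "off", [stem("R2", 1, 1, "spC"), stem("R2", 2, 1, "spD")])]
    sp4 = ["spA", "spB", "spC", "spD"]
    fixtures["disjoint_pair"] = _mini_dataset(
        invs, [leaf(sp, 1, "R1" if sp in ("spA", "spB") else "R2", 1, 150.0, 70.0, 21.0)
               for sp in sp4],
        {sp: "native" for sp in sp4})

    return fixtures
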