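"""Native vs alien comparison controlling for phylogeny.

Each CSR score (C, S, R) and each raw trait (LA, LDMC, SLA) is compared
between native and alien species with a one-way F statistic whose null
distribution is built by simulating Brownian-motion (BM) trait evolution
on the species phylogeny: under BM, related species are correlated, so
the ordinary F null is too liberal; simulating the trait on the tree and
recomputing F with the same group labels yields a null that carries the
phylogenetic covariance. The simulation p-value is (b+1)/(n_sim+1) where
b counts simulated F at or above the observed one. p-values are
Bonferroni-adjusted within each three-variable family (scores; traits).

R scores, LA and SLA are natural-log transformed before testing; zero R
scores are handled by applying ln(R+1) uniformly to the R variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csr import CSRScore
from .phylo import Phylogeny, prune_to, tip_labels

SCORE_FAMILY = ("C", "S", "R")
TRAIT_FAMILY = ("LA", "LDMC", "SLA")
LOG_TRANSFORMED = ("R", "LA", "SLA")


def _edge_structure(tree: Phylogeny):
    """Tip labels, edge lengths, and the tip × edge incidence matrix.

    Tip i's value under BM is the sum of the per-edge normal increments
    along its root path, so tips = increments @ incidence.T.
    """
    labels = []
    edges = []
    paths = []  # per tip: list of edge indices on the root path
    edge_index = {}

    def walk(node, path):
        e = node.edge
        if e.tail_node is not None:  # skip the root's stem edge
            idx = edge_index.setdefault(id(e), len(edges))
            if idx == len(edges):
                edges.append(e.length if e.length is not None else 0.0)
            path = path + [idx]
        children = node.child_nodes()
        if not children:
            labels.append(node.taxon.label)
            paths.append(path)
        for ch in children:
            walk(ch, path)

    walk(tree.seed_node, [])
    lengths = np.array(edges, dtype=float)
    if np.any(lengths < 0):
        raise ValueError("negative branch length")
    incidence = np.zeros((len(labels), len(edges)))
    for i, path in enumerate(paths):
        incidence[i, path] = 1.0
    return labels, lengths, incidence


def simulate_bm(tree: Phylogeny, sigma2: float, seed=None, size: int | None = None):
    """Brownian-motion trait simulation on a phylogeny.

    The root value is 0 and each branch adds an independent normal
    increment with variance ``sigma2`` × branch length.

    Parameters
    ----------
    seed
        Integer seed or ``numpy.random.Generator``.
    size
        If None, return a dict tip label -> value (one replicate);
        otherwise return ``(values, labels)`` with ``values`` of shape
        (size, n_tips).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels, lengths, incidence = _edge_structure(tree)
    rng = np.random.default_rng(seed)
    m = 1 if size is None else size
    z = rng.standard_normal((m, lengths.size)) * np.sqrt(sigma2 * lengths)
    values = z @ incidence.T
    if size is None:
        return dict(zip(labels, values[0]))
    return values, labels


def f_oneway_statistic(values: np.ndarray, group_codes: np.ndarray) -> np.ndarray:
    """One-way ANOVA F, vectorised over rows of a (m, n) value matrix."""
    values = np.atleast_2d(values)
    n = values.shape[1]
    codes = np.asarray(group_codes)
    ks = np.unique(codes)
    k = ks.size
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in ks:
        sel = values[:, codes == g]
        mu = sel.mean(axis=1, keepdims=True)
        ssb += sel.shape[1] * ((mu - grand) ** 2)[:, 0]
        ssw += ((sel - mu) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return f


@dataclass(frozen=True)
class PhyloANOVAResult:
    variable: str
    f_obs: float
    p_sim: float
    p_adjusted: float
    n_sim: int
    seed: int | None
    transform_applied: str  # 'none' | 'log'


def phylo_anova(values: dict[str, float], groups: dict[str, str], tree: Phylogeny,
                n_sim: int = 10000, seed=None, variable: str = "",
                transform_applied: str = "none") -> PhyloANOVAResult:
    """Simulation-based phylogenetic ANOVA.

    ``values`` and ``groups`` map tip labels to trait values and group
    labels; both must cover the same tips and every group needs at least
    two members. The BM rate is fixed at 1: F is invariant to affine
    transformation of the values, so the unknown rate cannot affect p.
    """
    if set(values) != set(groups):
        raise ValueError("values and groups must cover the same tips")
    tips = set(tip_labels(tree))
    if not set(values) <= tips:
        raise ValueError(f"tips missing from tree: {sorted(set(values) - tips)}")
    if len(values) < len(tips):
        tree = prune_to(tree, set(values))
    labels_order = None
    counts = pd.Series(list(groups.values())).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least two groups with at least two tips each")

    sims, labels_order = simulate_bm(tree, 1.0, seed=seed, size=n_sim)
    obs = np.array([values[t] for t in labels_order])
    codes = np.array([groups[t] for t in labels_order])
    f_obs = float(f_oneway_statistic(obs[None, :], codes)[0])
    f_sim = f_oneway_statistic(sims, codes)
    b = int(np.count_nonzero(f_sim >= f_obs))
    p_sim = (b + 1) / (n_sim + 1)
    return PhyloANOVAResult(variable, f_obs, p_sim, p_sim, n_sim,
                            seed if isinstance(seed, (int, np.integer)) else None,
                            transform_applied)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, m·p)."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, m * p)


def prepare_variables(profiles: pd.DataFrame, scores: pd.DataFrame) -> dict[str, pd.Series]:
    """The six tested variables, log-transformed where appropriate.

    C, S and LDMC pass through; LA and SLA are ln-transformed; R is
    ln(R+1)-transformed (R = 0 occurs for strongly CS species).
    Returns a dict variable name -> Series indexed by species_id.
    """
    prof = profiles.set_index("species_id")
    sc = scores.set_index("species_id")
    return {
        "C": sc["c"].astype(float),
        "S": sc["s"].astype(float),
        "R": np.log1p(sc["r"].astype(float)),
        "LA": np.log(prof["la_mm2"].astype(float)),
        "LDMC": prof["ldmc_pct"].astype(float),
        "SLA": np.log(prof["sla_mm2_mg"].astype(float)),
    }


def run_comparison(profiles: pd.DataFrame, scores: pd.DataFrame, tree: Phylogeny,
                   origins: dict[str, str], n_sim: int = 10000,
                   seed: int | None = None) -> pd.DataFrame:
    """Phylogenetic ANOVA of all six variables, Bonferroni per family (m=3).

    Species absent from the tree (e.g. tree ferns on a seed-plant
    phylogeny) are excluded from this comparison only.
    """
    variables = prepare_variables(profiles, scores)
    tips = set(tip_labels(tree))
    rng = np.random.default_rng(seed)
    rows = []
    for name, series in variables.items():
        keep = [s for s in series.index if s in tips]
        vals = {s: float(series[s]) for s in keep}
        grp = {s: origins[s] for s in keep}
        sub_seed = int(rng.integers(2 ** 31 - 1))
        res = phylo_anova(vals, grp, tree, n_sim=n_sim, seed=sub_seed,
                          variable=name,
                          transform_applied="log" if name in LOG_TRANSFORMED else "none")
        rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["p_adjusted"] = [bonferroni(p, 3) for p in df["p_sim"]]
    df["family"] = ["scores" if v in SCORE_FAMILY else "traits" for v in df["variable"]]
    return df


def balance_sensitivity(values: dict[str, float], groups: dict[str, str], tree: Phylogeny,
                        n_resamples: int, seed=None, n_sim: int = 1000) -> np.ndarray:
    """p_sim distribution under subsampling the larger group to balance.

    Each resample draws without replacement from the larger group to
    match the smaller group's size, prunes the tree to the retained tips
    and reruns the phylogenetic ANOVA. Checks that an unbalanced design
    (e.g. 70 natives vs 10 aliens) is not driving the p-value.
    """
    rng = np.random.default_rng(seed)
    counts = pd.Series(list(groups.values())).value_counts()
    small, large = counts.idxmin(), counts.idxmax()
    small_tips = [t for t, g in groups.items() if g == small]
    large_tips = [t for t, g in groups.items() if g == large]
    if n_resamples == 0:
        return np.array([])
    if len(large_tips) == len(small_tips):
        # already balanced: nothing to drop, every resample is the full analysis
        res = phylo_anova(values, groups, tree, n_sim=n_sim,
                          seed=int(rng.integers(2 ** 31 - 1)))
        return np.full(n_resamples, res.p_sim)
    ps = []
    for _ in range(n_resamples):
        kept = list(rng.choice(large_tips, size=len(small_tips), replace=False))
        tipset = set(small_tips) | set(kept)
        sub_vals = {t: values[t] for t in tipset}
        sub_grp = {t: groups[t] for t in tipset}
        res = phylo_anova(sub_vals, sub_grp, tree, n_sim=n_sim,
                          seed=int(rng.integers(2 ** 31 - 1)))
        ps.append(res.p_sim)
    return np.array(ps)


def group_summary(scores: pd.DataFrame, origins: dict[str, str]) -> dict[str, CSRScore]:
    """Componentwise median CSR per origin group, re-closed to sum 100."""
    df = scores.copy()
    df["origin"] = [origins[s] for s in df["species_id"]]
    out = {}
    for origin, grp in df.groupby("origin"):
        if grp.empty:
            raise ValueError(f"empty group {origin}")
        med = grp[["c", "s", "r"]].median().to_numpy(dtype=float)
        med = 100.0 * med / med.sum()
        out[origin] = CSRScore(*med)
    return out
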