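"""Simulation-based phylogenetic ANOVA with a Brownian-motion null.

Species are not independent samples: closely related species share most
of their evolutionary history, so an ordinary ANOVA across species
inflates type-I error whenever the grouping factor is phylogenetically
clustered.  The simulation-based phylogenetic ANOVA keeps the familiar
F statistic but replaces its parametric null with the distribution of F
computed on traits evolved under Brownian motion (BM) along the tree:
``p = (1 + #{F_sim >= F_obs}) / (nsim + 1)``.

Under BM the tip covariance is ``sigma^2 * C`` where ``C[i, j]`` is the
shared root-to-tip path length of tips i and j.  F is invariant to
affine transforms of the trait, so the null is simulated at unit rate.

Post hoc pairwise comparisons use pooled-variance t statistics whose
null values come from the same BM simulations; their two-tailed
p-values are Holm-Bonferroni adjusted.  Effect sizes are eta squared,
SSB / (SSB + SSW).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phylogeny container

class Phylogeny:
    """A rooted tree with branch lengths plus its BM covariance scaffold.

    Thin wrapper over a :class:`dendropy.Tree` caching tip labels, tip
    depths and the phylogenetic variance-covariance (VCV) matrix whose
    entry (i, j) is the shared root-to-tip path length of tips i and j.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges with missing branch lengths")
            if edge.length < 0:
                raise ValueError("tree has negative branch lengths")
        self.tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        self._vcv: np.ndarray | None = None
        self._depths: dict[str, float] | None = None

    # -- geometry -----------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        if self._depths is None:
            self.tree.calc_node_root_distances(return_leaf_distances_only=False)
            self._depths = {
                leaf.taxon.label: float(leaf.root_distance)
                for leaf in self.tree.leaf_node_iter()
            }
        return self._depths

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        """All root-to-tip distances equal within relative tolerance."""
        d = np.array(list(self.tip_depths().values()))
        depth = d.max()
        if depth == 0:
            return True
        return bool((d.max() - d.min()) / depth <= tol)

    def require_ultrametric(self, tol: float = 1e-6) -> None:
        if not self.is_ultrametric(tol):
            depths = self.tip_depths()
            lo = min(depths, key=depths.get)
            hi = max(depths, key=depths.get)
            raise ValueError(
                "tree is not ultrametric within tolerance "
                f"{tol}: tip '{hi}' has depth {depths[hi]:.6g} but tip "
                f"'{lo}' has depth {depths[lo]:.6g}"
            )

    def vcv(self) -> tuple[list[str], np.ndarray]:
        """Tip labels and the shared-path-length (BM covariance) matrix."""
        if self._vcv is None:
            self.tree.calc_node_root_distances(return_leaf_distances_only=False)
            index = {label: i for i, label in enumerate(self.tip_labels)}
            n = len(self.tip_labels)
            C = np.zeros((n, n))
            # postorder: collect tip indices per subtree; tips meeting at a
            # node (across different children) share that node's depth
            tips_below: dict[int, list[int]] = {}
            for node in self.tree.postorder_node_iter():
                if node.is_leaf():
                    i = index[node.taxon.label]
                    C[i, i] = float(node.root_distance)
                    tips_below[id(node)] = [i]
                    continue
                child_sets = [tips_below.pop(id(ch)) for ch in node.child_nodes()]
                depth = float(node.root_distance or 0.0)
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        ia = np.asarray(child_sets[a])
                        ib = np.asarray(child_sets[b])
                        C[np.ix_(ia, ib)] = depth
                        C[np.ix_(ib, ia)] = depth
                tips_below[id(node)] = [i for s in child_sets for i in s]
            self._vcv = C
        return list(self.tip_labels), self._vcv

    def vcv_for(self, species: list[str]) -> np.ndarray:
        """VCV submatrix for a subset of tips, in the given order."""
        labels, C = self.vcv()
        index = {s: i for i, s in enumerate(labels)}
        missing = [s for s in species if s not in index]
        if missing:
            raise ValueError(f"species absent from tree: {missing}")
        idx = [index[s] for s in species]
        return C[np.ix_(idx, idx)]

    # -- serialisation ------------------------------------------------------

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def __len__(self) -> int:
        return len(self.tip_labels)


def read_newick(source: str) -> Phylogeny:
    """Parse a Newick string (or file-like) into a :class:`Phylogeny`."""
    if hasattr(source, "read"):
        source = source.read()
    tree = dendropy.Tree.get(
        data=source, schema="newick", suppress_internal_node_taxa=True
    )
    return Phylogeny(tree)


def validate_ultrametric(tree: Phylogeny, tol: float = 1e-6) -> bool:
    return tree.is_ultrametric(tol)


# ---------------------------------------------------------------------------
# Grouping factors

@dataclass
class GroupFactor:
    """Ecological grouping of species (e.g. anti-predator strategy)."""

    name: str
    mapping: dict[str, str]  # species -> level; missing species simply absent

    def __post_init__(self) -> None:
        self.mapping = {
            sp: lvl for sp, lvl in self.mapping.items()
            if lvl is not None and not (isinstance(lvl, float) and np.isnan(lvl))
        }

    @property
    def levels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def validate(self, min_per_level: int = 2) -> None:
        counts = pd.Series(list(self.mapping.values())).value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor '{self.name}' has fewer than 2 levels")
        thin = counts[counts < min_per_level]
        if not thin.empty:
            raise ValueError(
                f"factor '{self.name}' levels with < {min_per_level} species: "
                f"{dict(thin)}"
            )


# ---------------------------------------------------------------------------
# ANOVA machinery

@dataclass
class AnovaStats:
    F: float
    SSB: float
    SSW: float
    degenerate: bool = False  # constant trait: F is 0/0, reported as 0

    def __iter__(self):
        return iter((self.F, self.SSB, self.SSW))


def _group_codes(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(groups.tolist()))
    code = {lvl: k for k, lvl in enumerate(levels)}
    return np.array([code[g] for g in groups]), levels


def _f_stats(Y: np.ndarray, codes: np.ndarray, k: int) -> tuple[np.ndarray, ...]:
    """Vectorised one-way ANOVA over rows of Y (each row one dataset).

    Returns (F, SSB, SSW, group_means, MSW) with F set to 0 where the
    response is constant (0/0) and +inf where SSW is 0 but SSB > 0.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    n = Y.shape[1]
    counts = np.bincount(codes, minlength=k).astype(float)
    ind = np.zeros((n, k))
    ind[np.arange(n), codes] = 1.0
    sums = Y @ ind
    means = sums / counts
    grand = Y.mean(axis=1, keepdims=True)
    SST = ((Y - grand) ** 2).sum(axis=1)
    SSB = (counts * (means - grand) ** 2).sum(axis=1)
    # a constant response leaves ~eps-level rounding residue in the sums of
    # squares; treat relative variance below 1e-20 as exactly zero
    tiny = n * (Y**2).mean(axis=1) * 1e-20
    const = SST <= tiny
    SST = np.where(const, 0.0, SST)
    SSB = np.where(const, 0.0, SSB)
    SSW = np.maximum(SST - SSB, 0.0)
    dfb, dfw = k - 1, n - k
    MSW = SSW / dfw
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (SSB / dfb) / MSW
    F = np.where(SSW == 0.0, np.where(SSB == 0.0, 0.0, np.inf), F)
    return F, SSB, SSW, means, MSW


def anova_F(values, groups) -> AnovaStats:
    """Standard one-way ANOVA: F = [SSB/(k-1)] / [SSW/(n-k)].

    ``values`` and ``groups`` are parallel sequences; groups must have
    at least two levels and every level at least one member.  A constant
    response yields F = 0 with the ``degenerate`` flag.
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have the same length")
    codes, levels = _group_codes(g)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if y.size <= k:
        raise ValueError("need more observations than groups")
    counts = np.bincount(codes, minlength=k)
    empty = [levels[i] for i in range(k) if counts[i] == 0]
    if empty:
        raise ValueError(f"groups with no members: {empty}")
    F, SSB, SSW, _, _ = _f_stats(y[None, :], codes, k)
    degenerate = bool(SSW[0] == 0.0 and SSB[0] == 0.0)
    return AnovaStats(float(F[0]), float(SSB[0]), float(SSW[0]), degenerate)


def eta_squared(SSB: float, SSW: float) -> float:
    """Effect size SSB / (SSB + SSW); NaN when both sums are zero."""
    if SSB < 0 or SSW < 0:
        raise ValueError("sums of squares must be non-negative")
    total = SSB + SSW
    if total == 0:
        return float("nan")
    return float(SSB / total)


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce a
    running maximum so adjusted values are monotone in the raw order,
    cap at 1, and restore the input order.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA

@dataclass
class PhyloANOVAResult:
    F_obs: float
    p_phylo: float
    eta2: float
    SSB: float
    SSW: float
    nsim: int
    seed: int | None
    n_species: int
    n_dropped: int = 0
    degenerate: bool = False
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


def simulate_bm_tips(
    C: np.ndarray, sigma2: float, nreps: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``nreps`` BM tip vectors ~ MVN(0, sigma2 * C); shape (nreps, n)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    n = C.shape[0]
    if sigma2 == 0:
        return np.zeros((nreps, n))
    # tiny jitter guards against exactly singular VCVs (e.g. zero-length tips)
    L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.trace(C) / n * np.eye(n))
    return (L @ rng.standard_normal((n, nreps))).T


def phyl_anova(
    tree: Phylogeny,
    factor: GroupFactor,
    trait: dict[str, float],
    nsim: int = 1000,
    seed: int | None = None,
    posthoc: bool = True,
    ultrametric_tol: float = 1e-6,
) -> PhyloANOVAResult:
    """Simulation-based phylogenetic ANOVA of a species trait.

    The observed one-way F is compared against F statistics of ``nsim``
    unit-rate BM simulations on the tree with the same group labels
    (F is affine-invariant, so the BM rate is irrelevant).  Species
    missing a factor level are dropped with a logged count; species in
    the trait table but absent from the tree are an error.  Post hoc
    pooled-variance t statistics draw their two-tailed null from the
    same simulations and are Holm-adjusted.
    """
    import warnings as _warnings

    if nsim < 100:
        _warnings.warn(
            f"nsim={nsim} is small; the p-value resolution is 1/{nsim + 1}",
            UserWarning, stacklevel=2,
        )
    tree.require_ultrametric(ultrametric_tol)

    trait_species = list(trait)
    species = [s for s in trait_species if s in factor.mapping]
    n_dropped = len(trait_species) - len(species)
    if n_dropped:
        logger.info(
            "factor '%s': dropped %d species without a level", factor.name, n_dropped
        )
    missing = [s for s in species if s not in set(tree.tip_labels)]
    if missing:
        raise ValueError(f"trait species absent from tree tips: {missing}")
    unused_tips = len(tree.tip_labels) - len(species)
    if unused_tips:
        logger.info("pruning %d tree tips without trait/factor data", unused_tips)

    y = np.array([trait[s] for s in species], float)
    if not np.isfinite(y).all():
        raise ValueError("trait contains non-finite values")
    g = np.array([factor.mapping[s] for s in species])
    codes, levels = _group_codes(g)
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor '{factor.name}' has < 2 levels among trait species")
    counts = np.bincount(codes, minlength=k)
    if (counts == 0).any():
        empty = [levels[i] for i in range(k) if counts[i] == 0]
        raise ValueError(f"groups with no species after matching: {empty}")

    F_vec, SSB, SSW, means_obs, MSW_obs = _f_stats(y[None, :], codes, k)
    F_obs = float(F_vec[0])
    degenerate = bool(SSW[0] == 0.0 and SSB[0] == 0.0)

    C = tree.vcv_for(species)
    rng = np.random.default_rng(seed)
    sims = simulate_bm_tips(C, 1.0, nsim, rng)
    F_sim, _, _, means_sim, MSW_sim = _f_stats(sims, codes, k)

    p_phylo = float((1 + np.count_nonzero(F_sim >= F_obs)) / (nsim + 1))
    eta2 = eta_squared(float(SSB[0]), float(SSW[0]))

    posthoc_df = None
    if posthoc and k >= 2:
        rows = []
        raw_ps = []
        with np.errstate(divide="ignore", invalid="ignore"):
            for a in range(k):
                for b in range(a + 1, k):
                    se_fac = 1.0 / counts[a] + 1.0 / counts[b]
                    t_obs = (means_obs[0, a] - means_obs[0, b]) / np.sqrt(
                        MSW_obs[0] * se_fac
                    )
                    t_sim = (means_sim[:, a] - means_sim[:, b]) / np.sqrt(
                        MSW_sim * se_fac
                    )
                    t_obs = 0.0 if not np.isfinite(t_obs) else float(t_obs)
                    p = float(
                        (1 + np.count_nonzero(np.abs(t_sim) >= abs(t_obs)))
                        / (nsim + 1)
                    )
                    rows.append((levels[a], levels[b], t_obs, p))
                    raw_ps.append(p)
        p_holm = holm_adjust(raw_ps)
        posthoc_df = pd.DataFrame(
            [(la, lb, t, p, ph) for (la, lb, t, p), ph in zip(rows, p_holm)],
            columns=["level_a", "level_b", "t", "p", "p_holm"],
        )

    return PhyloANOVAResult(
        F_obs=F_obs,
        p_phylo=p_phylo,
        eta2=eta2,
        SSB=float(SSB[0]),
        SSW=float(SSW[0]),
        nsim=nsim,
        seed=seed,
        n_species=len(species),
        n_dropped=n_dropped,
        degenerate=degenerate,
        posthoc=posthoc_df,
    )
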