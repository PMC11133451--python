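"""Tree handling, Brownian covariance, phylogenetic signal and ancestral states.

All statistics in this module assume a rooted tree with branch lengths in
arbitrary (typically time) units and a continuous trait observed at the tips.
The Brownian-motion expectation is encoded by the phylogenetic
variance-covariance matrix C, whose (i, j) entry is the root-to-MRCA path
length shared by tips i and j.  Pagel's lambda rescales the off-diagonal of C,
interpolating between a star phylogeny (lambda = 0, independent tips) and full
Brownian covariance (lambda = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import linalg, optimize

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "SignalStats",
    "AncestralReconstruction",
    "TreeError",
    "SingularCovarianceError",
    "read_newick",
    "vcv_matrix",
    "pagel_transform",
    "gls_mean",
    "blomberg_k",
    "pagel_lambda_ml",
    "ancestral_states",
    "prune",
    "simulate_bm",
]

EIG_FLOOR = 1e-12


class TreeError(ValueError):
    """Malformed or unusable phylogeny."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Phylogenetic covariance is numerically singular.

    Usually caused by duplicated tips or zero-length pendant edges; jitter
    terminal branch lengths or check the tree.
    """


class PhyloTree:
    """Rooted phylogeny with branch lengths; thin wrapper over dendropy.

    Tip labels must be unique and every non-root edge must carry a
    non-negative branch length.  Multifurcations are allowed and treated as
    hard polytomies.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction / serialisation ------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(dtree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                who = node.taxon.label if node.taxon else "internal node"
                raise TreeError(f"missing branch length above {who!r}")
            if node.edge.length < 0:
                who = node.taxon.label if node.taxon else "internal node"
                raise TreeError(f"negative branch length above {who!r}")

    # -- basic queries ----------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in tree (Newick) order."""
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node is not self._tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))


@dataclass
class PhyloCovariance:
    """Brownian trait covariance implied by a tree: shared root-to-MRCA paths."""

    C: np.ndarray
    tip_order: list[str]

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.tip_order), len(self.tip_order)):
            raise ValueError("covariance shape does not match tip order")

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def reorder(self, tip_order: list[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in tip_order]
        return PhyloCovariance(self.C[np.ix_(idx, idx)], list(tip_order))


@dataclass
class SignalStats:
    K: float
    lam: float
    logL: float


@dataclass
class AncestralReconstruction:
    node_states: np.ndarray  # per internal node, preorder
    root_state: float


def read_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def vcv_matrix(tree: PhyloTree) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix under Brownian motion.

    C[i, j] is the path length from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip depths.
    """
    tips = tree.tips
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    root = tree._tree.seed_node

    # node depth from root (root edge, if any, ignored)
    depth: dict = {root: 0.0}
    for node in tree._tree.preorder_node_iter():
        if node is root:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length

    # postorder: tip sets per subtree; cross-child pairs share this node's depth
    tipset: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[node]
            tipset[node] = [i]
        else:
            children = [tipset.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tipset[node] = [i for ch in children for i in ch]
    return PhyloCovariance(C, tips)


def pagel_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariance by Pagel's lambda (diagonal untouched)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(C, list(cov.tip_order))


def _floored_eigh(C: np.ndarray, floor: float = EIG_FLOOR):
    w, U = np.linalg.eigh(C)
    return np.maximum(w, floor), U


def inv_matrix(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse with eigenvalue floor; robust on near-ultrametric trees."""
    w, U = _floored_eigh(C)
    return (U / w) @ U.T


def inv_sqrt_matrix(C: np.ndarray) -> np.ndarray:
    w, U = _floored_eigh(C)
    return (U / np.sqrt(w)) @ U.T


def _check_invertible(C: np.ndarray) -> None:
    w = np.linalg.eigvalsh(C)
    if w[0] < 1e-10 * max(w[-1], 1.0):
        raise SingularCovarianceError(
            "phylogenetic covariance is singular (duplicated tips or "
            "zero-length pendant edges?); jitter branch lengths or check the tree"
        )


def gls_mean(y: np.ndarray, cov: PhyloCovariance) -> float:
    """GLS estimate of the trait mean, (1'C^-1 1)^-1 1'C^-1 y (the BM root state)."""
    y = np.asarray(y, dtype=float)
    if y.shape != (cov.n,):
        raise ValueError("trait vector length does not match covariance")
    _check_invertible(cov.C)
    Cinv = inv_matrix(cov.C)
    one = np.ones(cov.n)
    return float(one @ Cinv @ y / (one @ Cinv @ one))


def blomberg_k(y: np.ndarray, tree: PhyloTree) -> float:
    """Blomberg's K: observed vs Brownian-expected partitioning of variance.

    K = [MSE0 / MSE] / [(tr C - n / (1'C^-1 1)) / (n - 1)], with MSE0 the mean
    squared deviation from the GLS mean in the original space and MSE the
    phylogenetically corrected mean square.  K = 1 is the Brownian
    expectation; K > 1 means trait similarity is more phylogenetically
    clustered than Brownian motion predicts.
    """
    y = np.asarray(y, dtype=float)
    if tree.n_tips < 3:
        raise TreeError("Blomberg's K needs at least 3 tips")
    if np.var(y) <= 0:
        raise ValueError("trait has zero variance")
    cov = vcv_matrix(tree)
    n = cov.n
    _check_invertible(cov.C)
    Cinv = inv_matrix(cov.C)
    one = np.ones(n)
    denom_1C1 = one @ Cinv @ one
    a = (one @ Cinv @ y) / denom_1C1
    r = y - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    expected = (np.trace(cov.C) - n / denom_1C1) / (n - 1)
    return float((mse0 / mse) / expected)


def _lambda_profile_loglik(lam: float, cov: PhyloCovariance, y: np.ndarray) -> float:
    """Profile log-likelihood of lambda (mean and sigma^2 profiled out)."""
    n = cov.n
    V = pagel_transform(cov, lam).C
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        w, U = _floored_eigh(V)
        logdet = float(np.sum(np.log(w)))
        Vinv = (U / w) @ U.T
        one = np.ones(n)
        a = (one @ Vinv @ y) / (one @ Vinv @ one)
        r = y - a
        s2 = (r @ Vinv @ r) / n
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    one = np.ones(n)
    Vinv_y = linalg.cho_solve(cf, y, check_finite=False)
    Vinv_1 = linalg.cho_solve(cf, one, check_finite=False)
    a = (one @ Vinv_y) / (one @ Vinv_1)
    r = y - a
    s2 = (r @ linalg.cho_solve(cf, r, check_finite=False)) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagel_lambda_ml(y: np.ndarray, tree: PhyloTree, xatol: float = 1e-5) -> SignalStats:
    """ML estimate of Pagel's lambda constrained to [0, 1], with Blomberg's K.

    The multivariate-normal likelihood of the trait under covariance
    sigma^2 * pagel_transform(C, lambda) is profiled over sigma^2 and the mean
    and maximised over lambda by bounded scalar search; the boundary values
    lambda = 0 and 1 are always evaluated and kept if better.
    """
    y = np.asarray(y, dtype=float)
    if tree.n_tips < 3:
        raise TreeError("lambda estimation needs at least 3 tips")
    cov = vcv_matrix(tree)

    def neg(lam):
        return -_lambda_profile_loglik(lam, cov, y)

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"lambda optimiser failed to converge: {res}")
    cands = [(res.x, -res.fun)]
    for lam in (0.0, 1.0):
        cands.append((lam, _lambda_profile_loglik(lam, cov, y)))
    lam_hat, logL = max(cands, key=lambda t: t[1])
    return SignalStats(K=blomberg_k(y, tree), lam=float(lam_hat), logL=float(logL))


def ancestral_states(y: np.ndarray, tree: PhyloTree) -> AncestralReconstruction:
    """GLS/ML ancestral state estimates at internal nodes under Brownian motion.

    Each internal node estimate is the best linear unbiased prediction
    a_hat + c_k' C^-1 (y - a_hat), where c_k[i] is the shared root path of
    node k and tip i and a_hat is the GLS root estimate.
    """
    y = np.asarray(y, dtype=float)
    if tree.n_tips < 3:
        raise TreeError("ancestral reconstruction needs at least 3 tips")
    cov = vcv_matrix(tree)
    _check_invertible(cov.C)
    index = {t: i for i, t in enumerate(cov.tip_order)}
    Cinv = inv_matrix(cov.C)
    one = np.ones(cov.n)
    a = (one @ Cinv @ y) / (one @ Cinv @ one)
    w = Cinv @ (y - a)

    root = tree._tree.seed_node
    depth: dict = {root: 0.0}
    tipsets: dict = {}
    for node in tree._tree.preorder_node_iter():
        if node is not root:
            depth[node] = depth[node.parent_node] + node.edge.length
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = {index[node.taxon.label]}
        else:
            tipsets[node] = set().union(*(tipsets[ch] for ch in node.child_nodes()))

    states = []
    for node in tree._tree.preorder_internal_node_iter():
        c_k = np.empty(cov.n)
        # shared path of node k with tip i = depth of the deepest ancestor of
        # k (inclusive) whose subtree contains tip i
        anc_chain = []
        nd = node
        while nd is not None:
            anc_chain.append(nd)
            nd = nd.parent_node
        for i in range(cov.n):
            c_k[i] = 0.0
            for anc in anc_chain:  # node itself first (deepest)
                if i in tipsets[anc]:
                    c_k[i] = depth[anc]
                    break
        states.append(a + c_k @ w)
    return AncestralReconstruction(node_states=np.asarray(states), root_state=float(a))


def prune(tree: PhyloTree, keep) -> PhyloTree:
    """Induced subtree on `keep`; path lengths between retained tips preserved."""
    keep = set(keep)
    unknown = keep - set(tree.tips)
    if unknown:
        raise TreeError(f"species not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to prune to")
    if keep == set(tree.tips):
        return tree.clone()
    sub = tree._tree.extract_tree_with_taxa_labels(keep)
    return PhyloTree(sub)


def simulate_bm(
    cov: PhyloCovariance,
    rng: np.random.Generator,
    sigma2: float = 1.0,
    mean: float = 0.0,
    size: int = 1,
) -> np.ndarray:
    """Draw Brownian trait vectors ~ N(mean, sigma2 * C); shape (size, n)."""
    w, U = _floored_eigh(cov.C)
    L = U * np.sqrt(w)
    z = rng.standard_normal((size, cov.n))
    return mean + np.sqrt(sigma2) * z @ L.T
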