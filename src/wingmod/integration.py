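"""Phylogenetic two-block partial least squares with permutation effect sizes.

Trait blocks are first transformed to the phylogenetically independent space
E = C^(-1/2) (Y - 1 a'), where a is the per-column GLS mean: under Brownian
motion the rows of E are exchangeable, so a permutation null for the
cross-block association is obtained by shuffling the row assignment of the
second transformed block.  The association statistic r_PLS is the Pearson
correlation of the paired first singular scores of the cross-block
covariance; the effect size Z standardises the observed r_PLS against its
permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import PhyloCovariance, inv_matrix, inv_sqrt_matrix

__all__ = [
    "IntegrationRecord",
    "phylo_transform",
    "two_block_pls",
    "permutation_effect_size",
    "normalize_effect",
]


@dataclass
class IntegrationRecord:
    pair: tuple[str, str]
    r_pls: float
    Z: float
    p_perm: float
    n: int

    @property
    def z_norm(self) -> float:
        return normalize_effect(self.Z, self.n)


def phylo_transform(Y: np.ndarray, cov: PhyloCovariance) -> np.ndarray:
    """Project a trait block into the phylogenetically exchangeable space."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and cov.n != 1:
        Y = Y.T
    if Y.shape[0] != cov.n:
        raise ValueError(
            f"block has {Y.shape[0]} rows but covariance is for {cov.n} tips"
        )
    Cinv = inv_matrix(cov.C)
    one = np.ones(cov.n)
    denom = one @ Cinv @ one
    a = (one @ Cinv @ Y) / denom  # per-column GLS mean
    return inv_sqrt_matrix(cov.C) @ (Y - a)


def two_block_pls(E1: np.ndarray, E2: np.ndarray):
    """First singular pair of the cross-block covariance and its score correlation.

    Returns (r_pls, left_axis, right_axis).  For univariate blocks r_pls
    reduces to the absolute Pearson correlation of the two vectors.
    """
    E1 = np.atleast_2d(np.asarray(E1, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    if E1.shape[0] == 1:
        E1 = E1.T
    if E2.shape[0] == 1:
        E2 = E2.T
    n = E1.shape[0]
    if E2.shape[0] != n:
        raise ValueError("blocks have different numbers of rows")
    if n < 3:
        raise ValueError("two-block PLS needs at least 3 rows")
    E1c = E1 - E1.mean(axis=0)
    E2c = E2 - E2.mean(axis=0)
    if np.allclose(E1c, 0) or np.allclose(E2c, 0):
        raise ValueError("zero-variance block")
    S12 = E1c.T @ E2c / (n - 1)
    U, _, Vt = np.linalg.svd(S12)
    u, v = U[:, 0], Vt[0]
    s1 = E1c @ u
    s2 = E2c @ v
    r = np.corrcoef(s1, s2)[0, 1]
    if r < 0:  # singular axes are sign-indeterminate
        v = -v
        r = -r
    return float(min(r, 1.0)), u, v


def permutation_effect_size(
    Y1: np.ndarray,
    Y2: np.ndarray,
    cov: PhyloCovariance,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> IntegrationRecord:
    """Permutation p-value and effect size Z for phylogenetic 2B-PLS.

    The null is built by permuting the row assignment of the transformed
    second block (RRPP-style; exchangeability holds after the phylogenetic
    transform, so blocks are not re-transformed per permutation).
    """
    n = cov.n
    if n < 5:
        raise ValueError("permutation test needs at least 5 tips")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    E1 = phylo_transform(Y1, cov)
    E2 = phylo_transform(Y2, cov)
    r_obs, _, _ = two_block_pls(E1, E2)
    r_null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        r_null[k], _, _ = two_block_pls(E1, E2[perm])
    sd = r_null.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("degenerate permutation null (sd < 1e-12)")
    p = (1 + np.sum(r_null >= r_obs)) / (n_perm + 1)
    Z = (r_obs - r_null.mean()) / sd
    return IntegrationRecord(pair=("block1", "block2"), r_pls=r_obs, Z=float(Z), p_perm=float(p), n=n)


def normalize_effect(Z_mean: float, n: int) -> float:
    """Z / sqrt(n), truncated below at zero (Z scales with sqrt(sample size))."""
    if n <= 0:
        raise ValueError("n must be positive")
    return max(0.0, Z_mean / np.sqrt(n))
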