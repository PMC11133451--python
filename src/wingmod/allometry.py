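"""PGLS allometric models and the running variance profile.

Each skeletal element's log10 centroid size is regressed on log10 body mass
by generalized least squares whose error covariance follows the tree under a
Pagel-lambda correlation structure (lambda ML-optimised per element).  The
residuals are the allometrically corrected relative sizes (log10 rCsize) used
by both downstream methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .phylo import (
    PhyloCovariance,
    PhyloTree,
    _floored_eigh,
    pagel_transform,
    vcv_matrix,
)

__all__ = [
    "CANONICAL_ELEMENTS",
    "MODULE_MAP",
    "MODULES",
    "AllometricFit",
    "VarianceProfile",
    "validate_trait_table",
    "mass_sorted_species",
    "fit_pgls_allometry",
    "residual_matrix",
    "running_iqr",
]

CANONICAL_ELEMENTS = (
    "cranium",
    "mandible",
    "scapula",
    "coracoid",
    "sternum",
    "synsacrum",
    "humerus",
    "ulna",
    "radius",
    "carpometacarpus",
    "femur",
    "tibiotarsus",
    "tarsometatarsus",
)

# anatomical modules of the avian body plan
MODULE_MAP = {
    "cranium": "head",
    "mandible": "head",
    "scapula": "trunk",
    "coracoid": "trunk",
    "sternum": "trunk",
    "synsacrum": "trunk",
    "humerus": "wing",
    "ulna": "wing",
    "radius": "wing",
    "carpometacarpus": "wing",
    "femur": "leg",
    "tibiotarsus": "leg",
    "tarsometatarsus": "leg",
}

MODULES = ("head", "wing", "trunk", "leg")


@dataclass
class AllometricFit:
    element: str
    slope: float
    intercept: float
    lambda_hat: float
    logL: float
    residuals: pd.Series  # indexed by species, tip order


@dataclass
class VarianceProfile:
    element: str
    species: list[str]  # mass-sorted
    log_mass: np.ndarray
    iqr: np.ndarray
    window: int


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the species x trait table contract; returns the table unchanged."""
    required = {"log_mass", *CANONICAL_ELEMENTS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate species rows: {dup}")
    block = table[["log_mass", *CANONICAL_ELEMENTS]]
    bad = ~np.isfinite(block.to_numpy(dtype=float))
    if bad.any():
        rows, cols = np.nonzero(bad)
        where = [(block.index[r], block.columns[c]) for r, c in zip(rows, cols)]
        raise ValueError(f"non-finite trait values at {where[:10]}")
    return table


def mass_sorted_species(table: pd.DataFrame) -> list[str]:
    """Species ordered by log mass, ties broken by name for determinism."""
    order = sorted(table.index, key=lambda s: (table.at[s, "log_mass"], s))
    return order


def _gls_fit(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS coefficients, residuals, profiled sigma^2 and log-likelihood."""
    n = len(y)
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        solve = lambda b: linalg.cho_solve(cf, b, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    except linalg.LinAlgError:
        w, U = _floored_eigh(V)
        Vinv = (U / w) @ U.T
        solve = lambda b: Vinv @ b
        logdet = float(np.sum(np.log(w)))
    VX = solve(X)
    XtVX = X.T @ VX
    beta = np.linalg.solve(XtVX, VX.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ solve(resid)) / n
    if s2 <= 0:
        return beta, resid, s2, -np.inf
    logL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return beta, resid, s2, logL


def _fit_one(
    X: np.ndarray,
    y: np.ndarray,
    cov: PhyloCovariance,
    lam: float | None,
    xatol: float,
):
    """lambda-profiled PGLS on prepared arrays (hot path for replicate refits)."""
    if lam is not None:
        beta, resid, _, logL = _gls_fit(X, y, pagel_transform(cov, lam).C)
        return beta, resid, float(lam), logL

    def neg(l):
        return -_gls_fit(X, y, pagel_transform(cov, l).C)[3]

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
    )
    cands = [(float(res.x), -float(res.fun)), (0.0, -neg(0.0)), (1.0, -neg(1.0))]
    lam_hat, _ = max(cands, key=lambda t: t[1])
    beta, resid, _, logL = _gls_fit(X, y, pagel_transform(cov, lam_hat).C)
    return beta, resid, lam_hat, logL


def fit_pgls_allometry(
    table: pd.DataFrame,
    element: str,
    tree: PhyloTree,
    cov: PhyloCovariance | None = None,
    lam: float | None = None,
    xatol: float = 1e-4,
) -> AllometricFit:
    """PGLS fit of log_size ~ 1 + log_mass with a Pagel-lambda error structure.

    lambda is profiled by ML over the whole [0, 1] interval (bounded search
    with explicit boundary checks); pass `lam` to fix it, e.g. ``lam=0`` for
    ordinary least squares.  Residuals are returned in tip order of the
    covariance.
    """
    if element not in CANONICAL_ELEMENTS:
        raise ValueError(f"unknown element {element!r}")
    if cov is None:
        cov = vcv_matrix(tree)
    species = cov.tip_order
    if len(species) < 10:
        raise ValueError("PGLS allometry needs at least 10 species")
    missing = set(species) - set(table.index)
    if missing:
        raise ValueError(f"species missing from trait table: {sorted(missing)}")
    y = table.loc[species, element].to_numpy(dtype=float)
    x = table.loc[species, "log_mass"].to_numpy(dtype=float)
    if np.ptp(x) < 1e-12:
        raise np.linalg.LinAlgError("singular design: log_mass is constant")
    X = np.column_stack([np.ones(len(x)), x])
    beta, resid, lam_hat, logL = _fit_one(X, y, cov, lam, xatol)
    return AllometricFit(
        element=element,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        lambda_hat=lam_hat,
        logL=float(logL),
        residuals=pd.Series(resid, index=species, name=element),
    )


def residual_matrix(
    table: pd.DataFrame,
    tree: PhyloTree,
    elements=CANONICAL_ELEMENTS,
    cov: PhyloCovariance | None = None,
    lam: float | None = None,
    xatol: float = 1e-4,
) -> pd.DataFrame:
    """Species x element matrix of allometrically corrected sizes (log10 rCsize)."""
    if cov is None:
        cov = vcv_matrix(tree)
    species = cov.tip_order
    if len(species) < 10:
        raise ValueError("PGLS allometry needs at least 10 species")
    x = table.loc[species, "log_mass"].to_numpy(dtype=float)
    if np.ptp(x) < 1e-12:
        raise np.linalg.LinAlgError("singular design: log_mass is constant")
    X = np.column_stack([np.ones(len(x)), x])
    Y = table.loc[species, list(elements)].to_numpy(dtype=float)
    out = np.empty_like(Y)
    for j in range(Y.shape[1]):
        _, resid, _, _ = _fit_one(X, Y[:, j], cov, lam, xatol)
        out[:, j] = resid
    return pd.DataFrame(out, index=species, columns=list(elements))


def running_iqr(
    values: pd.Series, log_mass: pd.Series, window: int = 30
) -> VarianceProfile:
    """Running inter-quartile range of a trait over a mass-ordered window.

    Species are sorted by mass (ties by name); at each rank the IQR
    (Q3 - Q1, linear-interpolation quantiles) of the surrounding `window`
    species is returned.  Near the edges the window is truncated at the
    boundary, so the profile covers all n ranks.
    """
    if len(values) < window:
        raise ValueError(f"need at least window={window} species, got {len(values)}")
    order = sorted(values.index, key=lambda s: (log_mass[s], s))
    v = values.loc[order].to_numpy(dtype=float)
    n = len(v)
    half_lo = window // 2
    half_hi = window - half_lo
    iqr = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi)
        q1, q3 = np.percentile(v[lo:hi], [25, 75])
        iqr[i] = q3 - q1
    return VarianceProfile(
        element=str(values.name),
        species=order,
        log_mass=log_mass.loc[order].to_numpy(dtype=float),
        iqr=iqr,
        window=window,
    )
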