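"""Method 2: dispersion from the major axis of trait covariance.

For a chosen pair of allometrically corrected element sizes, each species
gets a signed score D_m: its component orthogonal to the leading principal
axis of the bivariate residual cloud (the second PC score).  The dispersion
of D_m is inversely related to integration strength, so mass-dependent
integration shows up as heteroskedasticity of D_m with respect to log mass.
Because body masses are right-skewed, significance is judged on Gaussian
mass-stratified resamples: one-tailed Breusch-Pagan p-values from 100
resamples of the real data are compared against the same procedure run on a
mass-permuted null ('flame plots'); no multiple-testing correction is
applied, which is why the paired null distribution is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from ._seeds import child_rng
from .allometry import residual_matrix, validate_trait_table
from .phylo import PhyloTree

__all__ = [
    "DispersionRecord",
    "FlameResult",
    "Method2Config",
    "Method2Result",
    "major_axis_distance",
    "running_ribbon",
    "gaussian_mass_resample",
    "bp_test_one_tailed",
    "flame_analysis",
    "run_method2",
]

# (elementA, elementB) -> expected direction of D_m heteroskedasticity in mass
DEFAULT_PAIRS: dict[tuple[str, str], str] = {
    ("humerus", "carpometacarpus"): "decreasing",
    ("scapula", "sternum"): "increasing",
    ("carpometacarpus", "sternum"): "increasing",
    ("cranium", "mandible"): "both",  # control pair, run both one-tailed directions
}


@dataclass
class DispersionRecord:
    pair: tuple[str, str]
    major_axis: np.ndarray  # unit vector in the (elementA, elementB) plane
    D_m: pd.Series  # signed per-species score, indexed by species
    log_mass: pd.Series


@dataclass
class FlameResult:
    pair: tuple[str, str]
    direction: str
    real_p: np.ndarray
    null_p: np.ndarray
    exceedance: float  # fraction of real p below the null 5th percentile


@dataclass
class Method2Config:
    pairs: dict = field(default_factory=lambda: dict(DEFAULT_PAIRS))
    n_iter: int = 100
    n_breaks: int = 10
    max_per_bin: int = 10
    window: int = 30
    master_seed: int = 0


@dataclass
class Method2Result:
    records: dict  # pair -> DispersionRecord
    ribbons: dict  # pair -> ribbon DataFrame
    flames: list  # FlameResult per (pair, direction)
    outliers: pd.DataFrame
    config: Method2Config = field(repr=False, default_factory=Method2Config)


def major_axis_distance(
    x: pd.Series | np.ndarray, y: pd.Series | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Major axis of the bivariate cloud and signed orthogonal scores.

    Returns (m, D_m): the unit leading eigenvector of the 2x2 sample
    covariance of the centred data and the signed scalar projections onto
    the orthogonal (minor) direction -- the second PC scores.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 points")
    P = np.column_stack([x - x.mean(), y - y.mean()])
    S = P.T @ P / (len(x) - 1)
    w, U = np.linalg.eigh(S)  # ascending eigenvalues
    if w[1] <= 0:
        raise ValueError("zero variance in the residual plane")
    if w[1] - w[0] < 1e-12:
        raise ValueError("isotropic covariance: major axis is ambiguous")
    m = U[:, 1]
    ortho = U[:, 0]
    # orient deterministically: positive first nonzero component of m
    if m[0] < 0 or (m[0] == 0 and m[1] < 0):
        m = -m
    if ortho[1] < 0 or (ortho[1] == 0 and ortho[0] < 0):
        ortho = -ortho
    return m, P @ ortho


def dispersion_record(
    residuals: pd.DataFrame, log_mass: pd.Series, pair: tuple[str, str]
) -> DispersionRecord:
    a, b = pair
    m, d = major_axis_distance(residuals[a], residuals[b])
    idx = residuals.index
    return DispersionRecord(
        pair=pair,
        major_axis=m,
        D_m=pd.Series(d, index=idx, name="D_m"),
        log_mass=log_mass.loc[idx],
    )


def running_ribbon(
    D_m: pd.Series, log_mass: pd.Series, window: int = 30
) -> pd.DataFrame:
    """1-sigma / 2-sigma running percentile bands of D_m along the mass order."""
    if len(D_m) < window:
        raise ValueError(f"need at least window={window} species")
    order = sorted(D_m.index, key=lambda s: (log_mass[s], s))
    d = D_m.loc[order].to_numpy(dtype=float)
    n = len(d)
    half_lo = window // 2
    half_hi = window - half_lo
    rows = np.empty((n, 4))
    for i in range(n):
        seg = d[max(0, i - half_lo) : min(n, i + half_hi)]
        rows[i] = np.percentile(seg, [2.275, 15.865, 84.135, 97.725])
    return pd.DataFrame(
        rows,
        index=pd.Index(order, name="species"),
        columns=["lo2", "lo1", "hi1", "hi2"],
    ).assign(log_mass=log_mass.loc[order].to_numpy(dtype=float))


def gaussian_mass_resample(
    species: list[str],
    log_mass: pd.Series,
    n_breaks: int = 10,
    max_per_bin: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Mass-stratified subsample converging on a Gaussian mass distribution.

    The log-mass range is split into `n_breaks` equal-width intervals; within
    each non-empty interval a count is drawn uniformly from
    1..min(max_per_bin, available) and that many species are sampled without
    replacement.  Subsample sizes therefore vary between draws.
    """
    if len(species) < n_breaks:
        raise ValueError("fewer species than mass breaks")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    species = sorted(species)
    m = log_mass.loc[species].to_numpy(dtype=float)
    edges = np.linspace(m.min(), m.max(), n_breaks + 1)
    which = np.clip(np.searchsorted(edges, m, side="right") - 1, 0, n_breaks - 1)
    out: list[str] = []
    for k in range(n_breaks):
        members = [s for s, w in zip(species, which) if w == k]
        if not members:
            continue
        take = int(rng.integers(1, min(max_per_bin, len(members)) + 1))
        out.extend(rng.choice(members, size=take, replace=False))
    return sorted(out)


def bp_test_one_tailed(
    D_m: np.ndarray, log_mass: np.ndarray, direction: str = "increasing"
) -> float:
    """One-tailed Breusch-Pagan test of D_m dispersion against log mass.

    D_m is regressed on log mass by OLS; the studentised score statistic
    (n R^2 of the squared residuals on log mass, chi2 with 1 df) gives the
    two-sided p, halved towards the tail whose auxiliary slope sign matches
    `direction` ('increasing' = dispersion grows with mass).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"direction must be increasing/decreasing, got {direction!r}")
    d = np.asarray(D_m, dtype=float)
    m = np.asarray(log_mass, dtype=float)
    if len(d) < 10:
        raise ValueError("need at least 10 species")
    if np.ptp(m) < 1e-12:
        raise ValueError("log mass is constant")
    X = sm.add_constant(m)
    resid = sm.OLS(d, X).fit().resid
    _, p_two, _, _ = het_breuschpagan(resid, X, robust=True)
    aux_slope = np.polyfit(m, resid**2, 1)[0]
    matches = (aux_slope > 0) == (direction == "increasing")
    return float(p_two / 2 if matches else 1 - p_two / 2)


def flame_analysis(
    residuals: pd.DataFrame,
    log_mass: pd.Series,
    pair: tuple[str, str],
    direction: str,
    n_iter: int = 100,
    n_breaks: int = 10,
    max_per_bin: int = 10,
    master_seed: int = 0,
) -> FlameResult:
    """Resampled one-tailed heteroskedasticity p-values vs a permuted null.

    Real arm: per iteration, a Gaussian-mass subsample of the (global) pair
    residuals is drawn, the major axis and D_m recomputed on the subsample,
    and the one-tailed test applied.  Null arm: identical, except the mass
    vector is randomly reassigned to the residual rows each iteration,
    breaking any trait-mass linkage.
    """
    a, b = pair
    species = list(residuals.index)
    x = residuals[a]
    y = residuals[b]
    real_p = np.empty(n_iter)
    null_p = np.empty(n_iter)
    for it in range(n_iter):
        rng = child_rng(master_seed, "flame", a, b, direction, it)
        sub = gaussian_mass_resample(
            species, log_mass, n_breaks=n_breaks, max_per_bin=max_per_bin, seed=rng
        )
        _, d = major_axis_distance(x.loc[sub], y.loc[sub])
        real_p[it] = bp_test_one_tailed(
            d, log_mass.loc[sub].to_numpy(), direction=direction
        )

        perm = rng.permutation(len(species))
        shuffled = pd.Series(
            log_mass.loc[species].to_numpy()[perm], index=species
        )
        sub0 = gaussian_mass_resample(
            species, shuffled, n_breaks=n_breaks, max_per_bin=max_per_bin, seed=rng
        )
        _, d0 = major_axis_distance(x.loc[sub0], y.loc[sub0])
        null_p[it] = bp_test_one_tailed(
            d0, shuffled.loc[sub0].to_numpy(), direction=direction
        )
    exceed = float(np.mean(real_p < np.percentile(null_p, 5)))
    return FlameResult(
        pair=pair, direction=direction, real_p=real_p, null_p=null_p, exceedance=exceed
    )


def run_method2(
    table: pd.DataFrame, tree: PhyloTree, config: Method2Config | None = None
) -> Method2Result:
    """Full dispersion pipeline on a common (all-species) allometric model."""
    config = config or Method2Config()
    validate_trait_table(table)
    elements = sorted({e for p in config.pairs for e in p})
    R = residual_matrix(table, tree, elements=elements)
    log_mass = table["log_mass"]

    records, ribbons, flames = {}, {}, []
    outlier_rows = []
    for pair, direction in config.pairs.items():
        rec = dispersion_record(R, log_mass, pair)
        records[pair] = rec
        rib = running_ribbon(rec.D_m, rec.log_mass, window=config.window)
        ribbons[pair] = rib
        d = rec.D_m.loc[rib.index]
        outside = (d < rib["lo2"]) | (d > rib["hi2"])
        for sp in rib.index[outside]:
            outlier_rows.append(
                {
                    "pair": f"{pair[0]}|{pair[1]}",
                    "species": sp,
                    "D_m": d[sp],
                    "log_mass": log_mass[sp],
                }
            )
        directions = (
            ["increasing", "decreasing"] if direction == "both" else [direction]
        )
        for dr in directions:
            flames.append(
                flame_analysis(
                    R,
                    log_mass,
                    pair,
                    dr,
                    n_iter=config.n_iter,
                    n_breaks=config.n_breaks,
                    max_per_bin=config.max_per_bin,
                    master_seed=config.master_seed,
                )
            )
    outliers = pd.DataFrame(
        outlier_rows, columns=["pair", "species", "D_m", "log_mass"]
    )
    return Method2Result(
        records=records,
        ribbons=ribbons,
        flames=flames,
        outliers=outliers,
        config=config,
    )
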