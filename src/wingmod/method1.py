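"""Method 1: integration of skeletal proportions across overlapping mass bins.

Species are ranked by body mass and grouped into overlapping bins of 40 taxa
(20 bins by default, stepping 9 or 10 ranks).  Within each bin, replicates of
30 taxa are drawn, the per-element allometry is refit inside the replicate
(so allometric scaling may vary across the mass range), and phylogenetic
2B-PLS permutation effect sizes Z are computed for all 78 element pairs.
Replicate-mean Z is normalised by sqrt(subsample), truncated below at zero,
and averaged within / between anatomical modules; bootstrap envelopes and
per-pair OLS trend slopes against bin mean log mass summarise how modular
integration changes with body size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .allometry import (
    CANONICAL_ELEMENTS,
    MODULE_MAP,
    MODULES,
    mass_sorted_species,
    residual_matrix,
    validate_trait_table,
)
from .integration import phylo_transform
from .phylo import PhyloTree, prune, vcv_matrix

__all__ = [
    "PAIRS",
    "MODULE_TARGETS",
    "BinScheme",
    "Method1Config",
    "Method1Result",
    "make_bins",
    "replicate_integration",
    "aggregate_modules",
    "bootstrap_envelope",
    "trend_slopes",
    "run_method1",
]

PAIRS: list[tuple[str, str]] = list(itertools.combinations(CANONICAL_ELEMENTS, 2))

# 4 within-module targets + 6 cross-module targets, in a fixed order
MODULE_TARGETS: list[str] = list(MODULES) + [
    f"{a}-{b}" for a, b in itertools.combinations(MODULES, 2)
]

# percentile levels of the 1-sigma and 2-sigma normal tail masses
_LEVELS = {"1": (15.865, 84.135), "2": (2.275, 97.725)}


def _pair_target(a: str, b: str) -> str:
    ma, mb = MODULE_MAP[a], MODULE_MAP[b]
    if ma == mb:
        return ma
    i, j = sorted((MODULES.index(ma), MODULES.index(mb)))
    return f"{MODULES[i]}-{MODULES[j]}"


PAIR_TARGETS: list[str] = [_pair_target(a, b) for a, b in PAIRS]

# row-normalised indicator matrix mapping the 78 pairs onto the 10 targets
_GROUP = np.array(
    [[1.0 if t == pt else 0.0 for pt in PAIR_TARGETS] for t in MODULE_TARGETS]
)
_GROUP /= _GROUP.sum(axis=1, keepdims=True)


@dataclass
class BinScheme:
    window: int
    bins: list[tuple[int, int]]  # 1-based inclusive rank ranges

    @property
    def count(self) -> int:
        return len(self.bins)


@dataclass
class Method1Config:
    window: int = 40
    n_bins: int = 20
    n_rep: int = 30
    subsample: int = 30
    n_perm: int = 999
    bootstrap_B: int = 1000
    master_seed: int = 0


@dataclass
class Method1Result:
    scheme: BinScheme
    bin_log_mass: np.ndarray  # per-bin mean log10 mass of the bin's taxa
    pair_z: pd.DataFrame  # bins x 78 pairs, truncated Z/sqrt(n)
    module_trends: pd.DataFrame  # per (bin, target): mean + envelopes
    pair_slopes: pd.DataFrame  # 78 rows: OLS slope of z_norm vs log_mass
    module_slopes: pd.Series  # per module target
    config: Method1Config = field(repr=False, default_factory=Method1Config)


def make_bins(n: int, window: int = 40, count: int = 20) -> BinScheme:
    """Overlapping mass-rank bins: first covers ranks 1..window, last ends at n.

    Consecutive bin starts differ by 9 or 10 ranks; steps are chosen as 10
    wherever possible with the minimum number of 9s, 10s first, so the scheme
    is deterministic.
    """
    if n < window:
        raise ValueError(f"need at least window={window} species, got {n}")
    span = n - window
    if count == 1:
        if span != 0:
            raise ValueError(f"count=1 requires n == window, got n={n}")
        return BinScheme(window=window, bins=[(1, window)])
    n_steps = count - 1
    nines = 10 * n_steps - span
    tens = n_steps - nines
    if not (0 <= nines <= n_steps):
        feasible = [
            c
            for c in range(2, span + 2)
            if 9 * (c - 1) <= span <= 10 * (c - 1)
        ]
        raise ValueError(
            f"no composition of {n_steps} steps of 9 or 10 sums to {span}; "
            f"feasible bin counts for n={n}: {feasible or 'none'}"
        )
    steps = [10] * tens + [9] * nines
    bins = []
    start = 1
    bins.append((start, window))
    for s in steps:
        start += s
        bins.append((start, start + window - 1))
    assert bins[-1][1] == n
    return BinScheme(window=window, bins=bins)


def _replicate_z(
    species: list[str],
    table: pd.DataFrame,
    tree: PhyloTree,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation effect sizes Z for all 78 pairs in one subsample."""
    sub = prune(tree, species)
    cov = vcv_matrix(sub)
    n = cov.n
    R = residual_matrix(table, sub, cov=cov, xatol=1e-3)
    E = phylo_transform(R.to_numpy(), cov)
    Ec = E - E.mean(axis=0)
    norms = np.linalg.norm(Ec, axis=0)
    if np.any(norms < 1e-12):
        raise ValueError("zero-variance transformed element within replicate")
    Es = Ec / norms
    corr = Es.T @ Es

    a_idx = np.array([CANONICAL_ELEMENTS.index(a) for a, _ in PAIRS])
    b_idx = np.array([CANONICAL_ELEMENTS.index(b) for _, b in PAIRS])
    r_obs = np.abs(corr[a_idx, b_idx])

    # shared permutation block: one (n_perm, n) index array per pair
    base = np.broadcast_to(np.arange(n), (len(PAIRS) * n_perm, n)).copy()
    perms = rng.permuted(base, axis=1).reshape(len(PAIRS), n_perm, n)
    Z = np.empty(len(PAIRS))
    for k in range(len(PAIRS)):
        xb = Es[:, b_idx[k]][perms[k]]  # (n_perm, n)
        r_null = np.abs(xb @ Es[:, a_idx[k]])
        sd = r_null.std(ddof=1)
        if sd < 1e-12:
            raise ValueError("degenerate permutation null (sd < 1e-12)")
        Z[k] = (r_obs[k] - r_null.mean()) / sd
    return Z


def replicate_integration(
    bin_species: list[str],
    table: pd.DataFrame,
    tree: PhyloTree,
    n_rep: int = 30,
    subsample: int = 30,
    n_perm: int = 999,
    master_seed: int = 0,
    bin_id: int = 0,
) -> np.ndarray:
    """Z matrix (78 pairs x n_rep replicates) for one mass bin.

    Each replicate draws `subsample` taxa without replacement, prunes the
    tree, refits the per-element PGLS allometry inside the replicate, and
    runs the permutation test for every element pair.  A replicate whose
    PGLS fit fails is redrawn once before the error propagates.
    """
    if len(bin_species) < subsample:
        raise ValueError(
            f"bin has {len(bin_species)} taxa, fewer than subsample={subsample}"
        )
    pool = sorted(bin_species)
    Z = np.empty((len(PAIRS), n_rep))
    for rep in range(n_rep):
        rng = child_rng(master_seed, "method1", bin_id, rep)
        chosen = list(rng.choice(pool, size=subsample, replace=False))
        try:
            Z[:, rep] = _replicate_z(chosen, table, tree, n_perm, rng)
        except (ValueError, np.linalg.LinAlgError):
            chosen = list(rng.choice(pool, size=subsample, replace=False))
            Z[:, rep] = _replicate_z(chosen, table, tree, n_perm, rng)
    return Z


def aggregate_modules(z_by_pair: np.ndarray) -> dict[str, float]:
    """Mean z over pairs within each module and spanning each module pair."""
    z = np.asarray(z_by_pair, dtype=float)
    if z.shape != (len(PAIRS),):
        raise ValueError(f"expected one value per pair ({len(PAIRS)}), got {z.shape}")
    out = {}
    targets = np.array(PAIR_TARGETS)
    for t in MODULE_TARGETS:
        out[t] = float(z[targets == t].mean())
    return out


def bootstrap_envelope(
    values: np.ndarray, B: int = 1000, seed: int | np.random.Generator = 0
) -> dict[str, tuple[float, float]]:
    """Percentile 1-sigma / 2-sigma intervals of the bootstrapped mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    return {
        sig: tuple(np.percentile(means, lv)) for sig, lv in _LEVELS.items()
    }


def trend_slopes(per_bin_values: np.ndarray, bin_log_mass: np.ndarray) -> np.ndarray:
    """OLS slope of each column against per-bin mean log mass."""
    V = np.atleast_2d(np.asarray(per_bin_values, dtype=float))
    x = np.asarray(bin_log_mass, dtype=float)
    if V.shape[0] != len(x):
        raise ValueError("row count must match number of bins")
    if len(x) < 3:
        raise ValueError("need at least 3 bins to fit a trend")
    if np.ptp(x) < 1e-12:
        raise ValueError("bin mass means are constant")
    xc = x - x.mean()
    return (xc @ (V - V.mean(axis=0))) / (xc @ xc)


def _chain_aggregate(Z: np.ndarray, subsample: int) -> tuple[np.ndarray, dict]:
    """Replicate-mean Z -> Z/sqrt(n) -> truncate at 0 -> module aggregates."""
    z_norm = np.maximum(Z.mean(axis=1) / np.sqrt(subsample), 0.0)
    return z_norm, aggregate_modules(z_norm)


def run_method1(
    table: pd.DataFrame, tree: PhyloTree, config: Method1Config | None = None
) -> Method1Result:
    """Full mass-binned integration pipeline."""
    config = config or Method1Config()
    validate_trait_table(table)
    order = mass_sorted_species(table)
    n = len(order)
    scheme = make_bins(n, window=config.window, count=config.n_bins)

    bin_mass = np.empty(scheme.count)
    pair_z = np.empty((scheme.count, len(PAIRS)))
    trend_rows = []
    for b, (lo, hi) in enumerate(scheme.bins):
        species = order[lo - 1 : hi]
        bin_mass[b] = table.loc[species, "log_mass"].mean()
        Z = replicate_integration(
            species,
            table,
            tree,
            n_rep=config.n_rep,
            subsample=config.subsample,
            n_perm=config.n_perm,
            master_seed=config.master_seed,
            bin_id=b,
        )
        z_norm, aggs = _chain_aggregate(Z, config.subsample)
        pair_z[b] = z_norm

        # bootstrap over replicates, re-running the normalise/truncate/aggregate chain
        rng = child_rng(config.master_seed, "method1", b, "bootstrap")
        idx = rng.integers(0, config.n_rep, size=(config.bootstrap_B, config.n_rep))
        boot_z = np.maximum(
            Z[:, idx].mean(axis=2) / np.sqrt(config.subsample), 0.0
        )  # (78, B)
        boot = (_GROUP @ boot_z).T  # (B, targets)
        for j, t in enumerate(MODULE_TARGETS):
            lo1, hi1 = np.percentile(boot[:, j], _LEVELS["1"])
            lo2, hi2 = np.percentile(boot[:, j], _LEVELS["2"])
            trend_rows.append(
                {
                    "bin": b,
                    "target": t,
                    "mean_log_mass": bin_mass[b],
                    "z_norm": aggs[t],
                    "lo1": lo1,
                    "hi1": hi1,
                    "lo2": lo2,
                    "hi2": hi2,
                }
            )

    slopes = trend_slopes(pair_z, bin_mass)
    pair_slopes = pd.DataFrame(
        {
            "element_a": [a for a, _ in PAIRS],
            "element_b": [b for _, b in PAIRS],
            "target": PAIR_TARGETS,
            "slope": slopes,
        }
    )
    module_trends = pd.DataFrame(trend_rows)
    module_agg = module_trends.pivot(index="bin", columns="target", values="z_norm")
    module_slopes = pd.Series(
        trend_slopes(module_agg[MODULE_TARGETS].to_numpy(), bin_mass),
        index=MODULE_TARGETS,
        name="slope",
    )
    return Method1Result(
        scheme=scheme,
        bin_log_mass=bin_mass,
        pair_z=pd.DataFrame(
            pair_z, columns=[f"{a}|{b}" for a, b in PAIRS]
        ),
        module_trends=module_trends,
        pair_slopes=pair_slopes,
        module_slopes=module_slopes,
        config=config,
    )
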