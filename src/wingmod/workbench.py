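"""Pipeline orchestration: validation, full runs, serialisation, reporting.

`run_all` ties together the phylogenetic-signal appraisal, the variance
profile, and both analysis methods, and writes every result as CSV/JSON plus
a manifest so a run is fully re-derivable from (inputs, config, master seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import CANONICAL_ELEMENTS, running_iqr, validate_trait_table
from .method1 import Method1Config, Method1Result, run_method1
from .method2 import Method2Config, Method2Result, run_method2
from .phylo import PhyloTree, ancestral_states, pagel_lambda_ml

__all__ = [
    "RunConfig",
    "ArtifactBundle",
    "ValidationError",
    "validate_inputs",
    "read_inputs",
    "run_all",
    "report",
]


class ValidationError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("input validation failed:\n" + "\n".join(problems))


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the published settings."""

    master_seed: int = 0
    window: int = 40
    n_bins: int = 20
    n_rep: int = 30
    subsample: int = 30
    n_perm: int = 999
    bootstrap_B: int = 1000
    iqr_window: int = 30
    flame_n_iter: int = 100
    n_breaks: int = 10
    max_per_bin: int = 10

    def method1(self) -> Method1Config:
        return Method1Config(
            window=self.window,
            n_bins=self.n_bins,
            n_rep=self.n_rep,
            subsample=self.subsample,
            n_perm=self.n_perm,
            bootstrap_B=self.bootstrap_B,
            master_seed=self.master_seed,
        )

    def method2(self) -> Method2Config:
        return Method2Config(
            n_iter=self.flame_n_iter,
            n_breaks=self.n_breaks,
            max_per_bin=self.max_per_bin,
            window=self.iqr_window,
            master_seed=self.master_seed,
        )


@dataclass
class ArtifactBundle:
    signal: dict
    variance_profiles: pd.DataFrame
    method1: Method1Result
    method2: Method2Result
    config: RunConfig
    files: list[str] = field(default_factory=list)


def validate_inputs(tree: PhyloTree, table: pd.DataFrame) -> list[str]:
    """Structural checks; returns the (possibly empty) list of problems."""
    problems: list[str] = []
    tips = set(tree.tips)
    rows = set(table.index)
    for sp in sorted(tips - rows):
        problems.append(f"species {sp!r} is in the tree but not the trait table")
    for sp in sorted(rows - tips):
        problems.append(f"species {sp!r} is in the trait table but not the tree")
    missing = {"log_mass", *CANONICAL_ELEMENTS} - set(table.columns)
    for col in sorted(missing):
        problems.append(f"trait table is missing column {col!r}")
    if not missing:
        block = table[["log_mass", *CANONICAL_ELEMENTS]].to_numpy(dtype=float)
        bad = ~np.isfinite(block)
        for r, c in zip(*np.nonzero(bad)):
            problems.append(
                f"non-finite value at species {table.index[r]!r}, "
                f"column {(['log_mass', *CANONICAL_ELEMENTS])[c]!r}"
            )
    return problems


def read_inputs(tree_path: str | Path, traits_path: str | Path):
    tree = PhyloTree.from_newick(Path(tree_path).read_text())
    table = pd.read_csv(traits_path, index_col="species")
    problems = validate_inputs(tree, table)
    if problems:
        raise ValidationError(problems)
    return tree, table


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def signal_stage(table: pd.DataFrame, tree: PhyloTree) -> dict:
    """Phylogenetic signal of log mass and its Brownian root estimate."""
    y = table.loc[tree.tips, "log_mass"].to_numpy(dtype=float)
    stats = pagel_lambda_ml(y, tree)
    anc = ancestral_states(y, tree)
    return {
        "K": stats.K,
        "lambda": stats.lam,
        "logL": stats.logL,
        "root_log10_mass": anc.root_state,
        "root_mass_g": float(10.0**anc.root_state),
    }


def variance_stage(
    table: pd.DataFrame, tree: PhyloTree, window: int = 30
) -> pd.DataFrame:
    """Running IQR of allometrically corrected sizes, long format."""
    from .allometry import residual_matrix

    R = residual_matrix(table, tree)
    rows = []
    for element in CANONICAL_ELEMENTS:
        prof = running_iqr(R[element], table["log_mass"], window=window)
        for rank, (sp, lm, iqr) in enumerate(
            zip(prof.species, prof.log_mass, prof.iqr), start=1
        ):
            rows.append(
                {
                    "element": element,
                    "rank": rank,
                    "species": sp,
                    "log_mass": lm,
                    "iqr": iqr,
                }
            )
    return pd.DataFrame(rows)


def run_all(
    table: pd.DataFrame,
    tree: PhyloTree,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> ArtifactBundle:
    config = config or RunConfig()
    validate_trait_table(table)
    problems = validate_inputs(tree, table)
    if problems:
        raise ValidationError(problems)

    signal = signal_stage(table, tree)
    profiles = variance_stage(table, tree, window=config.iqr_window)
    m1 = run_method1(table, tree, config.method1())
    m2 = run_method2(table, tree, config.method2())
    bundle = ArtifactBundle(
        signal=signal,
        variance_profiles=profiles,
        method1=m1,
        method2=m2,
        config=config,
    )
    if outdir is not None:
        bundle.files = write_bundle(bundle, Path(outdir))
    return bundle


def write_bundle(bundle: ArtifactBundle, outdir: Path) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit_csv(name: str, df: pd.DataFrame, **kw) -> None:
        (outdir / name).parent.mkdir(exist_ok=True, parents=True)
        df.to_csv(outdir / name, **kw)
        files.append(name)

    _write_json(outdir / "signal.json", bundle.signal)
    files.append("signal.json")
    emit_csv("variance_profiles.csv", bundle.variance_profiles, index=False)

    m1 = bundle.method1
    emit_csv("method1_module_trends.csv", m1.module_trends, index=False)
    slopes = m1.pair_slopes.copy()
    emit_csv("method1_pair_slopes.csv", slopes, index=False)
    _write_json(
        outdir / "method1_bin_matrices.json",
        {
            "bins": [list(b) for b in m1.scheme.bins],
            "bin_log_mass": list(m1.bin_log_mass),
            "pairs": list(m1.pair_z.columns),
            "z_norm": [list(row) for row in m1.pair_z.to_numpy()],
            "module_slopes": dict(m1.module_slopes),
        },
    )
    files.append("method1_bin_matrices.json")

    m2 = bundle.method2
    for pair, rec in m2.records.items():
        tag = f"{pair[0]}_{pair[1]}"
        df = pd.DataFrame(
            {
                "D_m": rec.D_m,
                "log_mass": rec.log_mass,
            }
        ).join(m2.ribbons[pair][["lo2", "lo1", "hi1", "hi2"]])
        df.index.name = "species"
        emit_csv(f"method2_dm_{tag}.csv", df)
    for fl in m2.flames:
        tag = f"{fl.pair[0]}_{fl.pair[1]}_{fl.direction}"
        _write_json(
            outdir / f"method2_flame_{tag}.json",
            {
                "pair": list(fl.pair),
                "direction": fl.direction,
                "real_p": list(fl.real_p),
                "null_p": list(fl.null_p),
                "exceedance": fl.exceedance,
            },
        )
        files.append(f"method2_flame_{tag}.json")
    emit_csv("method2_outliers.csv", m2.outliers, index=False)

    manifest = {
        "wingmod_version": __version__,
        "config": asdict(bundle.config),
        "files": sorted(files),
    }
    _write_json(outdir / "manifest.json", manifest)
    files.append("manifest.json")
    return sorted(files)


def report(bundle: ArtifactBundle) -> str:
    """Human-readable markdown summary of a completed run."""
    if bundle.method1 is None or bundle.method2 is None:
        raise ValueError("bundle is incomplete")
    s = bundle.signal
    lines = [
        "# wingmod run summary",
        "",
        "## Phylogenetic signal of log10 body mass",
        f"- Blomberg's K: {s['K']:.3f}",
        f"- Pagel's lambda: {s['lambda']:.3f}",
        f"- Brownian root estimate: {s['root_log10_mass']:.3f} "
        f"(~{s['root_mass_g']:.0f} g)",
        "",
        "## Method 1: module integration trends (slope of Z/sqrt(n) vs log10 mass)",
    ]
    for target, slope in bundle.method1.module_slopes.items():
        lines.append(f"- {target}: {slope:+.4f}")
    lines += ["", "## Method 2: flame-plot separation (one-tailed Breusch-Pagan)"]
    any_sep = False
    for fl in bundle.method2.flames:
        sep = fl.exceedance > 0.5
        any_sep = any_sep or sep
        lines.append(
            f"- {fl.pair[0]}-{fl.pair[1]} ({fl.direction}): "
            f"median real p = {np.median(fl.real_p):.4f}, "
            f"median null p = {np.median(fl.null_p):.4f}, "
            f"exceedance = {fl.exceedance:.2f}"
            + (" [separated]" if sep else " [overlapping]")
        )
    if not any_sep:
        lines.append("- no flame pair shows real/null separation")
    lines += [
        "",
        f"Outliers beyond the 2-sigma ribbon: {len(bundle.method2.outliers)}",
        "",
    ]
    return "\n".join(lines)
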