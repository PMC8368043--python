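"""End-to-end orchestration: simulate -> qmp -> diversity -> mix -> flux ->
modules -> gpfit, with input validation and a reproducibility manifest.

Stages exchange plain-text tables (TSV/CSV/JSON) in a working directory so
every intermediate is inspectable and reusable from other languages; the
sample identifier is the join key throughout.  A run manifest records the
configuration, per-stage row counts and SHA-256 hashes of every output, which
is sufficient to verify byte-identical reproduction of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import flux as flx
from .gp import GpConfig, SymbolicRegression
from .mixing import fractions_table
from .network import CoabundanceNetwork, NetworkConfig
from .qmp import CalibrationSpec, SpikeSpec, qmp_auto
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "DependencyError", "validate_inputs", "run_pipeline"]

log = logging.getLogger("wapflux")

ALL_STAGES = ("simulate", "qmp", "diversity", "mix", "flux", "modules", "gpfit")

#: physical-driver metadata columns fed to the NCP regression
GP_PHYSICAL_FEATURES = (
    "mld", "par", "par_mld", "salinity", "sst", "f_sim", "f_met", "x_grid", "y_grid",
)


class DependencyError(RuntimeError):
    """A stage's upstream output is missing."""


@dataclass
class PipelineConfig:
    workdir: str | Path = "wapflux_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    gp: GpConfig = field(default_factory=GpConfig)
    spike: SpikeSpec = field(default_factory=SpikeSpec)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    rarefaction_depth: int | None = None  # None = minimum retained total
    k_coef: float = flx.DEFAULT_K_COEF
    window_days: int = 30
    network_edge_threshold: float = 0.1

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw.pop("simulation"))
        if "network" in raw:
            kwargs["network"] = NetworkConfig(**raw.pop("network"))
        if "gp" in raw:
            kwargs["gp"] = GpConfig(**raw.pop("gp"))
        if "stages" in raw:
            kwargs["stages"] = tuple(raw.pop("stages"))
        kwargs.update(raw)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(
    counts: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    underway: pd.DataFrame | None = None,
) -> dict:
    """Cross-table consistency and unit-range sanity checks.

    Returns a machine-readable report: a list of issues each with severity
    ("error" or "warning"), a code, and a message, plus summary counts.
    Never raises; callers decide what severity aborts.
    """
    issues = []

    def add(severity, code, message):
        issues.append({"severity": severity, "code": code, "message": message})

    if counts is not None:
        neg = np.argwhere(counts.to_numpy() < 0)
        for i, j in neg[:20]:
            add(
                "error",
                "negative_count",
                f"negative count at sample {counts.index[i]!r}, ASV {counts.columns[j]!r}",
            )
        if not counts.select_dtypes(exclude=[np.number]).empty:
            add("error", "non_numeric_counts", "count table has non-numeric columns")
    if counts is not None and metadata is not None:
        missing = counts.index.difference(metadata.index)
        for s in missing[:20]:
            add("error", "sample_missing_metadata", f"sample {s!r} absent from metadata")
    if counts is not None and underway is not None and "sample_id" in underway.columns:
        missing = counts.index.difference(pd.Index(underway["sample_id"]))
        for s in missing[:20]:
            add("error", "sample_missing_underway", f"sample {s!r} absent from underway")
    if metadata is not None:
        if "sst" in metadata.columns:
            bad = metadata.index[(metadata["sst"] < -5) | (metadata["sst"] > 30)]
            for s in bad[:20]:
                add("error", "sst_out_of_range", f"SST outside [-5, 30] degC for {s!r}")
        if "salinity" in metadata.columns:
            bad = metadata.index[(metadata["salinity"] < 0) | (metadata["salinity"] > 42)]
            for s in bad[:20]:
                add("error", "salinity_out_of_range", f"salinity outside [0, 42] for {s!r}")
        if "mld" in metadata.columns:
            bad = metadata.index[metadata["mld"] <= 0]
            for s in bad[:20]:
                add("error", "mld_not_positive", f"MLD not positive for {s!r}")
    return {
        "n_errors": sum(1 for i in issues if i["severity"] == "error"),
        "n_warnings": sum(1 for i in issues if i["severity"] == "warning"),
        "issues": issues,
    }


def _require(workdir: Path, filename: str, needed_by: str) -> Path:
    path = workdir / filename
    if not path.exists():
        raise DependencyError(
            f"stage {needed_by!r} requires {filename!r}, which was not produced "
            "(upstream stage disabled or failed)"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "versions": _versions()}
    stages = [s for s in ALL_STAGES if s in config.stages]

    for stage in stages:
        t0 = time.monotonic()
        log.info("stage %s: starting", stage)
        try:
            outputs, n_rows = _STAGE_FUNCS[stage](config, workdir)
        except DependencyError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest["stages"][stage] = {
            "rows": n_rows,
            "seconds": round(time.monotonic() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        log.info("stage %s: done (%d rows)", stage, n_rows)

    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "wapflux": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


# --- stage implementations -------------------------------------------------


def _read_counts(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _read_metadata(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _stage_simulate(config: PipelineConfig, workdir: Path):
    from dataclasses import replace

    sim = replace(config.simulation, seed=config.seed)
    ds = simulate_dataset(sim)
    paths = ds.write(workdir)
    report = validate_inputs(ds.counts, ds.metadata, ds.underway)
    if report["n_errors"]:
        raise RuntimeError(f"simulated data failed validation: {report}")
    return list(paths.values()), len(ds.counts)


def _stage_qmp(config: PipelineConfig, workdir: Path):
    counts = _read_counts(_require(workdir, "counts.tsv", "qmp"))
    meta = _read_metadata(_require(workdir, "metadata.csv", "qmp"))
    tax = pd.read_csv(_require(workdir, "taxonomy.tsv", "qmp"), sep="\t", index_col=0)[
        "taxonomy"
    ]
    spike = config.spike
    if "spike_ng" in meta.columns:
        from dataclasses import replace

        spike = replace(spike, gdna_ng=float(meta["spike_ng"].iloc[0]))
    qmp, report = qmp_auto(counts, meta, spike, config.calibration, tax)
    qmp.to_csv(workdir / "qmp.tsv", sep="\t")
    report.to_csv(workdir / "qmp_report.csv")
    return [workdir / "qmp.tsv", workdir / "qmp_report.csv"], len(qmp)


def _stage_diversity(config: PipelineConfig, workdir: Path):
    counts = _read_counts(_require(workdir, "counts.tsv", "diversity"))
    meta = _read_metadata(_require(workdir, "metadata.csv", "diversity"))
    spike_col = config.spike.spike_asv
    if spike_col in counts.columns:
        counts = counts.drop(columns=[spike_col])
    rare = div.rarefy(counts, depth=config.rarefaction_depth, seed=config.seed)
    alpha = div.alpha_diversity(rare)
    alpha.to_csv(workdir / "alpha.csv")
    sst = meta["sst"].reindex(alpha.index)
    trend = {
        name: div.diversity_sst_trend(alpha[name], sst).to_dict()
        for name in ("chao1", "shannon", "pielou")
    }
    (workdir / "trend.json").write_text(json.dumps(trend, indent=2))
    return [workdir / "alpha.csv", workdir / "trend.json"], len(alpha)


def _stage_mix(config: PipelineConfig, workdir: Path):
    meta = _read_metadata(_require(workdir, "metadata.csv", "mix"))
    frac = fractions_table(meta, endmembers=config.simulation.endmembers)
    frac.to_csv(workdir / "fractions.csv")
    return [workdir / "fractions.csv"], len(frac)


def _stage_flux(config: PipelineConfig, workdir: Path):
    underway = pd.read_csv(_require(workdir, "underway.csv", "flux"))
    ncp = flx.ncp_table(underway, k_coef=config.k_coef, window_days=config.window_days)
    ncp.to_csv(workdir / "ncp.csv", index=False)
    return [workdir / "ncp.csv"], len(ncp)


def _stage_modules(config: PipelineConfig, workdir: Path):
    qmp = pd.read_csv(_require(workdir, "qmp.tsv", "modules"), sep="\t", index_col=0)
    meta = _read_metadata(_require(workdir, "metadata.csv", "modules"))
    res = CoabundanceNetwork(qmp, config.network).fit()
    res.modules_table().rename_axis("asv").to_csv(workdir / "modules.tsv", sep="\t")
    res.eigenvalues.to_csv(workdir / "eigenvalues.csv")
    traits = meta.select_dtypes(include=[np.number])
    res.trait_correlations(traits).to_csv(workdir / "module_trait.csv", index=False)
    edges, _nodes = res.export_network(config.network_edge_threshold)
    edges.to_csv(workdir / "network_edges.tsv", sep="\t", index=False)
    outputs = [
        workdir / "modules.tsv",
        workdir / "eigenvalues.csv",
        workdir / "module_trait.csv",
        workdir / "network_edges.tsv",
    ]
    return outputs, len(res.labels)


def _stage_gpfit(config: PipelineConfig, workdir: Path):
    from dataclasses import replace

    eig = pd.read_csv(_require(workdir, "eigenvalues.csv", "gpfit"), index_col=0)
    meta = _read_metadata(_require(workdir, "metadata.csv", "gpfit"))
    ncp = pd.read_csv(_require(workdir, "ncp.csv", "gpfit"))
    ncp = ncp.set_index("sample_id") if "sample_id" in ncp.columns else ncp
    physical = meta[[c for c in GP_PHYSICAL_FEATURES if c in meta.columns]]
    target = ncp["ncp_volumetric"].rename("ncp_volumetric")
    model = SymbolicRegression.from_tables(
        eig, physical, target,
        replace(config.gp, split_seed=config.seed, run_seed=config.seed),
    )
    results = model.fit()
    (workdir / "solutions.json").write_text(results.to_json())
    results.report().to_csv(workdir / "solutions.tsv", sep="\t", index=False)
    return [workdir / "solutions.json", workdir / "solutions.tsv"], len(results.ranked)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qmp": _stage_qmp,
    "diversity": _stage_diversity,
    "mix": _stage_mix,
    "flux": _stage_flux,
    "modules": _stage_modules,
    "gpfit": _stage_gpfit,
}
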