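"""Synthetic WAP-like survey generator with a recorded ground truth.

Emulates a summer underway survey of ~112 samples and a few hundred 18S ASVs
so the whole analysis chain — spike-in QMP normalisation, diversity,
water-mass mixing, O2/Ar NCP fluxes, co-abundance modules and symbolic NCP
regression — can be exercised and verified without any external data.

What is planted, and how it can be recovered:

* **Environment** — SST, MLD, PAR (mast, sub-surface and mixed-layer mean)
  and grid coordinates; freshwater fractions are drawn on the simplex with
  CDW dominant and mapped to salinity/d18O through the *forward* three-end-
  member mixing rule, so the mixing inversion can be round-trip tested.
* **Community** — a configurable set of co-abundance blocks.  Each block has
  a latent factor tied to an environmental driver (default: a large
  diatom-like block driven by cold SST, a cryptophyte block by warm SST, a
  heterotroph block by deep MLD, mirroring the canonical ice / warm-water /
  deep-mixing assemblages); member ASVs share the factor plus independent
  noise scaled to reach a requested within-block correlation.  Log-abundances
  become counts by multinomial sampling at a lognormal per-sample depth, with
  one designated spike-in ASV ("S.pombe_spike") whose read fraction is drawn
  from the observed usable range (0.7-5.7% by default).
* **NCP** — a known expression over the latent module factors and the
  environment gives the true volumetric NCP; the emitted underway track's
  delta(O2/Ar) is computed by *inverting* the NCP flux equation given
  generated wind histories and solubility, so the forward flux pipeline must
  reproduce the planted NCP exactly.

Everything is driven by a single seed: identical configuration implies
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flux
from .mixing import DEFAULT_END_MEMBERS, EndMemberSet, forward_mix
from .qmp import SpikeSpec

__all__ = [
    "ModuleBlock",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_environment",
    "simulate_community",
    "simulate_ncp",
    "simulate_dataset",
]

_FORMULA_FUNCS = {
    "exp": np.exp, "log": np.log, "sqrt": np.sqrt, "abs": np.abs,
    "sin": np.sin, "cos": np.cos, "tanh": np.tanh, "minimum": np.minimum,
    "maximum": np.maximum,
}


@dataclass(frozen=True)
class ModuleBlock:
    """One planted co-abundance block: (id, size, driver, sign, correlation)."""

    module_id: str
    n_asvs: int
    driver: str
    driver_sign: int
    within_block_correlation: float

    def __post_init__(self):
        if not 0 <= self.within_block_correlation <= 1:
            raise ValueError("within_block_correlation must be in [0, 1]")
        if self.driver_sign not in (-1, 1):
            raise ValueError("driver_sign must be -1 or +1")


DEFAULT_MODULES = (
    ModuleBlock("MET", 60, "sst", -1, 0.7),
    ModuleBlock("MER", 30, "sst", +1, 0.7),
    ModuleBlock("MEG", 20, "mld", +1, 0.7),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic survey."""

    n_samples: int = 112
    n_asvs: int = 300
    module_spec: tuple[ModuleBlock, ...] = DEFAULT_MODULES
    driver_correlation: float = 0.5
    ncp_formula: str = "(50 + 20*MET - 0.3*MLD) / MLD"
    noise_sd: float = 0.05
    depth_range: tuple[int, int] = (30_000, 100_000)
    spike_fraction_range: tuple[float, float] = (0.007, 0.057)
    spike: SpikeSpec = field(default_factory=SpikeSpec)
    endmembers: EndMemberSet = field(default_factory=lambda: DEFAULT_END_MEMBERS)
    cdw_dirichlet_alpha: tuple[float, float, float] = (1.5, 1.5, 40.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10")
        planted = sum(b.n_asvs for b in self.module_spec)
        if planted > self.n_asvs:
            raise ValueError(
                f"module ASV counts ({planted}) exceed n_asvs ({self.n_asvs})"
            )
        lo, hi = self.spike_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("spike_fraction_range must lie within [0, 1]")


@dataclass
class GroundTruth:
    """Recorded latent state of one simulated dataset."""

    fractions: pd.DataFrame  # samples x (f_sim, f_met, f_cdw)
    factors: pd.DataFrame  # samples x modules, latent module factors
    module_labels: pd.Series  # asv -> module id or "noise"
    true_qmp: pd.DataFrame  # samples x asvs, copies per liter
    spike_fractions: pd.Series
    true_ncp_volumetric: pd.Series
    true_ncp_areal: pd.Series
    ncp_formula: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "ncp_formula": self.ncp_formula,
                "fractions": self.fractions.round(12).to_dict(orient="index"),
                "factors": self.factors.round(12).to_dict(orient="index"),
                "module_labels": self.module_labels.to_dict(),
                "spike_fractions": self.spike_fractions.round(12).to_dict(),
                "true_ncp_volumetric": self.true_ncp_volumetric.round(12).to_dict(),
                "true_ncp_areal": self.true_ncp_areal.round(12).to_dict(),
            }
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def simulate_environment(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample environment table and true end-member fractions.

    Fractions are drawn from a Dirichlet with a dominant CDW component and
    mapped through the forward mixing rule, so ``salinity`` and ``d18o`` in
    the returned table are exactly consistent with the returned fractions.
    """
    rng = _rng(config, 0)
    n = config.n_samples
    idx = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample")

    sst = np.clip(rng.normal(0.8, 1.5, n), -1.8, 6.0)
    mld = np.clip(rng.lognormal(np.log(30.0), 0.45, n), 5.0, 120.0)
    mast_par = rng.uniform(15.0, 60.0, n)  # mol photons m-2 d-1
    kd = rng.uniform(0.08, 0.20, n)  # m-1
    par0 = flux.par_subsurface(mast_par)
    parmld = flux.par_mld(par0, kd, mld)
    x_grid = rng.uniform(0.0, 220.0, n)
    y_grid = rng.uniform(0.0, 900.0, n)

    frac = rng.dirichlet(config.cdw_dirichlet_alpha, size=n)
    salinity, d18o = forward_mix(frac, config.endmembers)

    env = pd.DataFrame(
        {
            "sst": sst,
            "mld": mld,
            "par": mast_par,
            "par0": par0,
            "par_mld": parmld,
            "kd": kd,
            "salinity": salinity,
            "d18o": d18o,
            "x_grid": x_grid,
            "y_grid": y_grid,
        },
        index=idx,
    )
    fractions = pd.DataFrame(frac, index=idx, columns=["f_sim", "f_met", "f_cdw"])
    return env, fractions


@dataclass
class CommunityResult:
    """Output of :func:`simulate_community` including its truth channel."""

    counts: pd.DataFrame  # includes the spike-in column; rows sum to depth
    taxonomy: pd.Series
    factors: pd.DataFrame  # samples x modules, latent module factors
    labels: pd.Series  # asv -> module id, "noise" or "spike"
    true_qmp: pd.DataFrame  # samples x asvs, true copies per liter
    spike_fractions: pd.Series  # expected spike read fraction per sample
    volume_l: pd.Series  # filtration volume per sample
    total_copies_per_l: pd.Series  # true community 18S copies per liter


def simulate_community(
    environment: pd.DataFrame, config: SimulationConfig
) -> CommunityResult:
    """Planted-block community counts with a spike-in internal standard.

    The planted structure lives in *absolute* abundances (copies per liter),
    the quantity QMP normalisation recovers: each ASV's log abundance is
    loading x (module factor + noise) plus a baseline.  The per-sample total
    is therefore emergent — blooms raise it — and, together with the fixed
    spike mass and the recorded filtration volume, determines each sample's
    expected spike read fraction phi = C / (C + total x volume).  Totals are
    clipped just enough to keep phi inside ``config.spike_fraction_range``.
    Read counts are a multinomial draw over (spike, community) at a lognormal
    sequencing depth, so counts are compositional while the truth channel is
    not — recovering the planted correlations downstream requires undoing
    compositionality, which is the point of the spike-in design.
    """
    rng = _rng(config, 1)
    n = len(environment)
    if n != config.n_samples:
        raise ValueError("environment rows must equal n_samples")

    factors = {}
    log_abund = {}
    labels = {}
    taxonomy = {}
    c = config.driver_correlation
    asv_counter = 0

    tax_by_module = {
        "MET": "Eukaryota;Stramenopiles;Bacillariophyta;Thalassiosira",
        "MER": "Eukaryota;Cryptophyta;Geminigera",
        "MEG": "Eukaryota;Picozoa;Picomonas",
    }

    for block in config.module_spec:
        if block.driver not in environment.columns:
            raise ValueError(f"unknown driver {block.driver!r}")
        z = environment[block.driver].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        # orthogonalize the factor noise against the driver so the planted
        # factor-driver correlation is exact, not just exact in expectation
        e = rng.normal(size=n)
        e = e - (e @ z / n) * z
        e = (e - e.mean()) / e.std()
        f = block.driver_sign * c * z + np.sqrt(max(1 - c**2, 0.0)) * e
        factors[block.module_id] = f
        rho = block.within_block_correlation
        noise_scale = np.sqrt(1.0 / rho - 1.0) if rho > 0 else np.inf
        for _ in range(block.n_asvs):
            asv_counter += 1
            asv = f"ASV{asv_counter:04d}"
            loading = rng.uniform(0.6, 1.4)
            mu = rng.normal(0.0, 1.0)
            if rho == 0:
                x = rng.normal(size=n)
            elif rho == 1:
                x = f.copy()
            else:
                x = f + noise_scale * rng.normal(size=n)
            log_abund[asv] = mu + loading * x
            labels[asv] = block.module_id
            taxonomy[asv] = tax_by_module.get(
                block.module_id, f"Eukaryota;module_{block.module_id}"
            )

    noise_taxa = (
        "Eukaryota;Dinoflagellata;Gyrodinium",
        "Eukaryota;Haptophyta;Phaeocystis",
        "Eukaryota;Ciliophora;Strombidium",
        "Eukaryota;Chlorophyta;Micromonas",
    )
    while asv_counter < config.n_asvs:
        asv_counter += 1
        asv = f"ASV{asv_counter:04d}"
        mu = rng.normal(0.0, 1.0)
        log_abund[asv] = mu + rng.normal(size=n)
        labels[asv] = "noise"
        taxonomy[asv] = noise_taxa[asv_counter % len(noise_taxa)]

    asvs = list(log_abund)
    lam = np.column_stack([log_abund[a] for a in asvs])  # log abundance, unscaled

    # scale absolute abundances so the emergent totals put the expected spike
    # fraction phi = C / (C + T*V) inside the configured range
    volume = np.round(rng.uniform(2.0, 4.0, n), 2)
    c_added = config.spike.copies_added
    lo, hi = config.spike_fraction_range
    phi_mid = np.sqrt(lo * hi)
    t_mid = c_added * (1 - phi_mid) / (phi_mid * 3.0)
    abs_copies = np.exp(lam)
    total = abs_copies.sum(axis=1)
    abs_copies *= t_mid / np.median(total)
    total = abs_copies.sum(axis=1)
    t_lo = c_added * (1 - hi) / (hi * volume)
    t_hi = c_added * (1 - lo) / (lo * volume)
    clip_factor = np.clip(total, t_lo, t_hi) / total
    abs_copies *= clip_factor[:, None]
    total *= clip_factor
    spike_frac = c_added / (c_added + total * volume)

    lo_d, hi_d = config.depth_range
    depths = np.clip(
        rng.lognormal(np.log(np.sqrt(lo_d * hi_d)), 0.25, n), lo_d, hi_d
    ).astype(np.int64)

    rel = abs_copies / total[:, None]
    spike_name = config.spike.spike_asv
    probs = np.column_stack([rel * (1 - spike_frac)[:, None], spike_frac])
    counts = np.vstack(
        [rng.multinomial(depths[i], probs[i] / probs[i].sum()) for i in range(n)]
    )
    cols = asvs + [spike_name]
    counts = pd.DataFrame(counts, index=environment.index, columns=cols)
    taxonomy[spike_name] = "Fungi;Ascomycota;Schizosaccharomyces"
    labels[spike_name] = "spike"

    return CommunityResult(
        counts=counts,
        taxonomy=pd.Series(taxonomy, name="taxonomy"),
        factors=pd.DataFrame(factors, index=environment.index),
        labels=pd.Series(labels, name="module"),
        true_qmp=pd.DataFrame(abs_copies, index=environment.index, columns=asvs),
        spike_fractions=pd.Series(
            spike_frac, index=environment.index, name="spike_fraction"
        ),
        volume_l=pd.Series(volume, index=environment.index, name="volume_l"),
        total_copies_per_l=pd.Series(
            total, index=environment.index, name="total_copies_per_l"
        ),
    )


def evaluate_formula(formula: str, namespace: dict) -> np.ndarray:
    """Evaluate an NCP expression over named arrays (restricted namespace)."""
    ns = dict(_FORMULA_FUNCS)
    ns.update(namespace)
    try:
        out = eval(formula, {"__builtins__": {}}, ns)  # noqa: S307 - no builtins
    except NameError as e:
        raise ValueError(f"ncp_formula references an unknown symbol: {e}") from e
    return np.asarray(out, dtype=float)


def _formula_namespace(environment: pd.DataFrame, factors: pd.DataFrame, fractions):
    ns = {m: factors[m].to_numpy() for m in factors.columns}
    ns.update(
        {
            "SST": environment["sst"].to_numpy(),
            "MLD": environment["mld"].to_numpy(),
            "PAR": environment["par"].to_numpy(),
            "PAR_mld": environment["par_mld"].to_numpy(),
            "Salinity": environment["salinity"].to_numpy(),
            "X": environment["x_grid"].to_numpy(),
            "Y": environment["y_grid"].to_numpy(),
        }
    )
    if fractions is not None:
        ns["f_sim"] = fractions["f_sim"].to_numpy()
        ns["f_met"] = fractions["f_met"].to_numpy()
    return ns


def simulate_ncp(
    environment: pd.DataFrame,
    factors: pd.DataFrame,
    config: SimulationConfig,
    fractions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True and observed NCP plus a synthetic underway O2/Ar track.

    The underway record's O2/Ar ratio is obtained by inverting
    NCP = k [O2]_sat delta(O2/Ar) with a ventilation-weighted k over a
    generated 30-day wind history, so running the forward flux pipeline on
    the track recovers the planted areal NCP to solver precision.
    """
    rng = _rng(config, 2)
    n = len(environment)
    true_vol = pd.Series(
        evaluate_formula(
            config.ncp_formula, _formula_namespace(environment, factors, fractions)
        ),
        index=environment.index,
        name="true_ncp_volumetric",
    )
    observed = true_vol + rng.normal(0.0, config.noise_sd, n)
    mld = environment["mld"].to_numpy()
    areal = true_vol.to_numpy() * mld

    winds = rng.weibull(2.0, size=(n, 30)) * 9.0
    ages = np.arange(30, dtype=float)
    o2sat = flux.o2_equilibrium_concentration(
        environment["sst"].to_numpy(), environment["salinity"].to_numpy()
    )
    k = np.array(
        [
            flux.weighted_gas_transfer(
                np.column_stack([ages, winds[i]]),
                mld[i],
                environment["sst"].iloc[i],
                environment["salinity"].iloc[i],
            )
            for i in range(n)
        ]
    )
    delta_pct = 100.0 * areal / (k * o2sat)
    o2ar_sample = 1.0 + delta_pct / 100.0
    if np.any(o2ar_sample <= 0):
        raise ValueError("planted NCP implies a non-positive O2/Ar ratio")

    ncp = pd.DataFrame(
        {
            "true_ncp_volumetric": true_vol,
            "observed_ncp_volumetric": observed,
            "true_ncp_areal": areal,
            "delta_o2ar_pct": delta_pct,
            "k_m_d": k,
            "o2sat_mmol_m3": o2sat,
        },
        index=environment.index,
    )
    underway = pd.DataFrame(
        {
            "sample_id": environment.index,
            "timestamp": pd.date_range("2016-01-05", periods=n, freq="2h"),
            "latitude": -64.0 - environment["y_grid"].to_numpy() / 300.0,
            "longitude": -64.0 - environment["x_grid"].to_numpy() / 100.0,
            "o2ar_sample": o2ar_sample,
            "o2ar_sat": np.ones(n),
            "sst": environment["sst"].to_numpy(),
            "salinity": environment["salinity"].to_numpy(),
            "mld": mld,
        },
        index=environment.index,
    )
    for j in range(30):
        underway[f"wind_{j:02d}"] = winds[:, j]
    return ncp, underway


@dataclass
class SyntheticDataset:
    """A complete simulated survey plus its ground truth."""

    config: SimulationConfig
    environment: pd.DataFrame
    metadata: pd.DataFrame
    counts: pd.DataFrame
    taxonomy: pd.Series
    underway: pd.DataFrame
    ncp: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the plain-text interchange files; sample id is the join key."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "metadata": outdir / "metadata.csv",
            "underway": outdir / "underway.csv",
            "truth": outdir / "truth.json",
        }
        self.counts.to_csv(paths["counts"], sep="\t")
        self.taxonomy.rename_axis("asv").to_csv(paths["taxonomy"], sep="\t")
        self.metadata.to_csv(paths["metadata"])
        self.underway.to_csv(paths["underway"], index=False)
        paths["truth"].write_text(self.truth.to_json())
        return paths


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Generate a full internally consistent synthetic survey."""
    env, fractions = simulate_environment(config)
    com = simulate_community(env, config)
    counts, taxonomy, factors, labels = com.counts, com.taxonomy, com.factors, com.labels
    ncp, underway = simulate_ncp(env, factors, config, fractions)

    true_qmp = com.true_qmp
    volume_l, spike_frac = com.volume_l, com.spike_fractions

    crypto = [a for a in true_qmp.columns if "Cryptophyta" in taxonomy[a]]
    allox = true_qmp[crypto].sum(axis=1) / 1000.0 / 2.05e6  # copies/L -> ug/L

    metadata = env.copy()
    metadata["volume_l"] = volume_l
    metadata["spike_ng"] = config.spike.gdna_ng
    metadata["alloxanthin"] = allox
    metadata["observed_ncp_volumetric"] = ncp["observed_ncp_volumetric"]
    metadata[["f_sim", "f_met", "f_cdw"]] = fractions

    truth = GroundTruth(
        fractions=fractions,
        factors=factors,
        module_labels=labels,
        true_qmp=true_qmp,
        spike_fractions=spike_frac,
        true_ncp_volumetric=ncp["true_ncp_volumetric"],
        true_ncp_areal=ncp["true_ncp_areal"],
        ncp_formula=config.ncp_formula,
    )
    return SyntheticDataset(
        config=config,
        environment=env,
        metadata=metadata,
        counts=counts,
        taxonomy=taxonomy,
        underway=underway,
        ncp=ncp,
        truth=truth,
    )
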