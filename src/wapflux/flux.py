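"""Mixed-layer net community production (NCP) from underway O2/Ar.

Argon has nearly the same solubility behaviour as oxygen but no biological
source or sink, so the deviation of the measured O2/Ar ratio from its
air-equilibrium value isolates the biological oxygen signal:

    delta(O2/Ar) = [ (O2/Ar)_sample / (O2/Ar)_sat - 1 ] * 100 %

Under steady state and negligible vertical mixing, the biological oxygen flux
out of the mixed layer equals net community production:

    NCP = k * [O2]_sat * delta(O2/Ar)        (mmol O2 m-2 d-1)

with k the gas transfer (piston) velocity for O2 and [O2]_sat the equilibrium
oxygen concentration.  A volumetric rate is obtained by dividing by the mixed
layer depth.  Because the mixed layer integrates gas exchange over the days
to weeks before sampling, k is evaluated as a ventilation-weighted mean over
a wind-speed history rather than from the instantaneous wind.

No time-derivative or vertical-mixing correction is applied: the estimates
deliberately reflect mixed-layer fluxes only.  Negative values (net
heterotrophy) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "biological_o2_supersaturation",
    "o2_equilibrium_concentration",
    "schmidt_number_o2",
    "gas_transfer_velocity",
    "weighted_gas_transfer",
    "ncp_areal",
    "ncp_volumetric",
    "CtdProfile",
    "MldEstimate",
    "mld_from_profile",
    "par_subsurface",
    "par_mld",
    "ncp_table",
]

# Oxygen solubility, combined fit to the Benson & Krause data
# (Garcia & Gordon 1992), mL(STP) L-1 version.  Scaled temperature
# Ts = ln[(298.15 - t) / (273.15 + t)].
_SOL_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_SOL_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_SOL_C0 = -4.88682e-7
# mL(STP) of O2 per mmol (molar volume 22.3916 L mol-1): mmol m-3 per (mL L-1)
_ML_PER_L_TO_MMOL_PER_M3 = 1000.0 / 22.3916

# O2 Schmidt number polynomial for seawater (salinity 35), valid -2..40 degC
_SC_O2 = (1920.4, -135.6, 5.2122, -0.10939, 0.00093777)

#: quadratic gas-exchange coefficient, cm h-1 (m s-1)-2
DEFAULT_K_COEF = 0.251
_CM_PER_H_TO_M_PER_D = 0.24


def biological_o2_supersaturation(o2ar_sample, o2ar_sat=1.0):
    """Percent biological O2 supersaturation, delta(O2/Ar).

    ``o2ar_sat`` defaults to 1 for instruments that already report the
    sample/saturation ratio.  The sign is preserved: negative values mean
    net heterotrophy.
    """
    sample = np.asarray(o2ar_sample, dtype=float)
    sat = np.asarray(o2ar_sat, dtype=float)
    if np.any(sample <= 0) or np.any(sat <= 0):
        raise ValueError("O2/Ar ratios must be positive")
    return 100.0 * (sample / sat - 1.0)


def o2_equilibrium_concentration(sst, salinity):
    """Equilibrium O2 saturation concentration, mmol O2 m-3.

    Combined-fit solubility polynomial in scaled temperature and salinity,
    converted from mL L-1 with the O2 molar volume.  Valid for
    -2 <= sst <= 40 degC and 0 <= salinity <= 42.
    """
    t = np.asarray(sst, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < -2) or np.any(t > 40):
        raise ValueError("sst outside the solubility fit range [-2, 40] degC")
    if np.any(s < 0) or np.any(s > 42):
        raise ValueError("salinity outside the solubility fit range [0, 42]")
    ts = np.log((298.15 - t) / (273.15 + t))
    ln_c = np.polynomial.polynomial.polyval(ts, _SOL_A)
    ln_c = ln_c + s * np.polynomial.polynomial.polyval(ts, _SOL_B)
    ln_c = ln_c + _SOL_C0 * s * s
    return np.exp(ln_c) * _ML_PER_L_TO_MMOL_PER_M3


def schmidt_number_o2(sst):
    """O2 Schmidt number in seawater as a quartic in temperature (degC)."""
    t = np.asarray(sst, dtype=float)
    return np.polynomial.polynomial.polyval(t, _SC_O2)


def gas_transfer_velocity(wind_speed, sst, salinity=35.0, k_coef=DEFAULT_K_COEF):
    """Instantaneous O2 gas transfer velocity, m d-1.

    Quadratic wind-speed dependence, ``k_coef`` in cm h-1 (m s-1)-2 referenced
    to Sc = 660, rescaled by (Sc_O2/660)^(-1/2) and converted to m d-1.
    ``salinity`` is accepted for interface symmetry; the Schmidt polynomial is
    a seawater fit.
    """
    u = np.asarray(wind_speed, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    sc = schmidt_number_o2(sst)
    k_cm_h = k_coef * u**2 * np.sqrt(660.0 / sc)
    return k_cm_h * _CM_PER_H_TO_M_PER_D


def weighted_gas_transfer(
    wind_history: Sequence[tuple[float, float]] | np.ndarray,
    mld,
    sst,
    salinity=35.0,
    k_coef=DEFAULT_K_COEF,
    dt_days: float = 1.0,
):
    """Ventilation-history weighted gas transfer velocity, m d-1.

    ``wind_history`` is a sequence of (age in days, wind speed in m s-1),
    age 0 being the sampling day.  Each day's instantaneous k is weighted by
    the fraction of the mixed layer left unventilated by all more recent
    days: with f_j = min(k_j * dt / mld, 1),

        w_i  proportional to  prod_{j more recent than i} (1 - f_j)

    and the weights are normalised to sum to one.  The result therefore
    always lies between the minimum and maximum instantaneous k of the
    history, and collapses to the most recent day's k as mld -> 0.
    """
    hist = np.asarray(wind_history, dtype=float)
    if hist.size == 0:
        raise ValueError("wind history is empty")
    if hist.ndim != 2 or hist.shape[1] != 2:
        raise ValueError("wind history must be (age, wind) pairs")
    if np.any(hist[:, 0] < 0):
        raise ValueError("ages must be non-negative")
    mld = float(mld)
    if mld <= 0:
        raise ValueError("mld must be positive")

    order = np.argsort(hist[:, 0])  # most recent first
    winds = hist[order, 1]
    k = gas_transfer_velocity(winds, sst, salinity, k_coef)
    f = np.minimum(k * dt_days / mld, 1.0)
    # weight of entry i: product of (1 - f_j) over all more recent entries j
    survival = np.concatenate([[1.0], np.cumprod(1.0 - f[:-1])])
    total = survival.sum()
    if total <= 0:  # every day fully ventilates the layer
        return float(k[0])
    return float(np.sum(survival * k) / total)


def ncp_areal(k, o2sat, delta_pct):
    """Areal NCP, mmol O2 m-2 d-1: k * [O2]_sat * delta(O2/Ar)/100."""
    k = np.asarray(k, dtype=float)
    o2sat = np.asarray(o2sat, dtype=float)
    if np.any(k < 0):
        raise ValueError("gas transfer velocity must be non-negative")
    if np.any(o2sat <= 0):
        raise ValueError("O2 saturation concentration must be positive")
    return k * o2sat * np.asarray(delta_pct, dtype=float) / 100.0


def ncp_volumetric(areal, mld):
    """Volumetric NCP, mmol O2 m-3 d-1: areal NCP divided by mixed layer depth."""
    mld = np.asarray(mld, dtype=float)
    if np.any(mld <= 0):
        raise ValueError("mld must be positive")
    return np.asarray(areal, dtype=float) / mld


@dataclass(frozen=True)
class CtdProfile:
    """Potential-density profile: depths (m, strictly increasing) and sigma-theta."""

    depth: np.ndarray
    sigma_theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        object.__setattr__(self, "sigma_theta", np.asarray(self.sigma_theta, dtype=float))
        if self.depth.size < 2:
            raise ValueError("profile needs at least two levels")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.depth.size != self.sigma_theta.size:
            raise ValueError("depth and sigma_theta lengths differ")


class MldEstimate(NamedTuple):
    mld: float
    threshold_crossed: bool


def mld_from_profile(
    profile: CtdProfile, threshold: float = 0.03, reference_depth: float = 10.0
) -> MldEstimate:
    """Mixed layer depth by the density-threshold method.

    The shallowest depth below ``reference_depth`` where sigma-theta exceeds
    its value at the reference depth by ``threshold`` (kg m-3), linearly
    interpolated between levels.  If the threshold is never crossed the
    deepest level is returned with ``threshold_crossed=False``.
    """
    z, sig = profile.depth, profile.sigma_theta
    if z[0] > reference_depth or z[-1] < reference_depth:
        raise ValueError("profile does not span the reference depth")
    sigma_ref = float(np.interp(reference_depth, z, sig))
    target = sigma_ref + threshold

    below = z >= reference_depth
    zb, sb = z[below], sig[below]
    # ensure the reference depth itself is the first point considered
    if zb[0] > reference_depth:
        zb = np.concatenate([[reference_depth], zb])
        sb = np.concatenate([[sigma_ref], sb])
    exceed = np.nonzero(sb > target)[0]
    if exceed.size == 0:
        return MldEstimate(float(z[-1]), False)
    i = exceed[0]
    if i == 0:
        return MldEstimate(float(zb[0]), True)
    # linear interpolation between level i-1 and i
    frac = (target - sb[i - 1]) / (sb[i] - sb[i - 1])
    return MldEstimate(float(zb[i - 1] + frac * (zb[i] - zb[i - 1])), True)


def par_subsurface(mast_par):
    """PAR just beneath the surface: 0.92 times the mast (above-water) PAR."""
    par = np.asarray(mast_par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be non-negative")
    return 0.92 * par


def par_mld(par0, kd, mld):
    """Mean PAR over the mixed layer under exponential attenuation.

    PAR_mld = PAR(0-) * (1 - exp(-kd*mld)) / (kd*mld); tends to PAR(0-) as
    kd*mld -> 0 (optically thin layer).
    """
    par0 = np.asarray(par0, dtype=float)
    kd = np.asarray(kd, dtype=float)
    mld = np.asarray(mld, dtype=float)
    if np.any(par0 < 0) or np.any(mld < 0):
        raise ValueError("PAR and mld must be non-negative")
    if np.any(kd <= 0):
        raise ValueError("kd must be positive")
    tau = kd * mld
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tau > 0, par0 * -np.expm1(-tau) / np.where(tau > 0, tau, 1.0), par0)
    return out


def ncp_table(
    underway: pd.DataFrame,
    k_coef: float = DEFAULT_K_COEF,
    window_days: int = 30,
) -> pd.DataFrame:
    """Per-record delta(O2/Ar), weighted k, areal and volumetric NCP.

    Expects columns ``sst``, ``salinity``, ``mld``, wind-history columns
    ``wind_00 .. wind_NN`` (age in days from the column suffix), and either
    ``delta_o2ar_pct`` or the pair ``o2ar_sample``/``o2ar_sat``.
    """
    wind_cols = sorted(c for c in underway.columns if c.startswith("wind_"))
    if not wind_cols:
        raise ValueError("no wind history columns (wind_00, wind_01, ...)")
    ages = np.array([int(c.split("_")[1]) for c in wind_cols], dtype=float)
    keep = ages < window_days
    wind_cols = [c for c, k_ in zip(wind_cols, keep) if k_]
    ages = ages[keep]

    if "delta_o2ar_pct" in underway.columns:
        delta = underway["delta_o2ar_pct"].to_numpy(dtype=float)
    else:
        sat = underway["o2ar_sat"] if "o2ar_sat" in underway.columns else 1.0
        delta = biological_o2_supersaturation(
            underway["o2ar_sample"].to_numpy(dtype=float), np.asarray(sat, dtype=float)
        )

    o2sat = o2_equilibrium_concentration(
        underway["sst"].to_numpy(dtype=float), underway["salinity"].to_numpy(dtype=float)
    )
    winds = underway[wind_cols].to_numpy(dtype=float)
    k = np.array(
        [
            weighted_gas_transfer(
                np.column_stack([ages, winds[i]]),
                underway["mld"].iloc[i],
                underway["sst"].iloc[i],
                underway["salinity"].iloc[i],
                k_coef=k_coef,
            )
            for i in range(len(underway))
        ]
    )
    areal = ncp_areal(k, o2sat, delta)
    vol = ncp_volumetric(areal, underway["mld"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "delta_o2ar_pct": delta,
            "o2sat_mmol_m3": o2sat,
            "k_m_d": k,
            "ncp_areal": areal,
            "ncp_volumetric": vol,
        },
        index=underway.index,
    )
    if "sample_id" in underway.columns:
        out.insert(0, "sample_id", underway["sample_id"].to_numpy())
    return out
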