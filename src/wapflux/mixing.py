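"""Three-end-member water-mass decomposition from salinity and oxygen isotopes.

Surface water along the West Antarctic Peninsula is treated as a mixture of
three sources: sea-ice melt, meteoric water (precipitation and glacial melt)
and upwelled Circumpolar Deep Water (CDW).  Each source has a characteristic
salinity and delta-18O signature, so a sample's (salinity, d18o) pair plus the
mass-conservation constraint determines the three fractions through a 3x3
linear system:

    f_sim + f_met + f_cdw             = 1
    f_sim*S_sim + f_met*S_met + f_cdw*S_cdw = salinity
    f_sim*d_sim + f_met*d_met + f_cdw*d_cdw = d18o

delta-18O is carried in per-mil throughout; the balance is linear in per-mil
to first order.  Fractions outside [0, 1] (possible with measurement noise)
are returned unclipped together with a QC flag so callers can decide how to
handle them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EndMemberSet", "endmember_fractions", "forward_mix", "fractions_table"]


@dataclass(frozen=True)
class EndMemberSet:
    """Salinity (PSU) and delta-18O (per mil) of the three mixing sources.

    Defaults are the standard WAP end members: sea-ice melt (7, 2.1),
    meteoric water (0, -16), CDW (34.73, 0.1).
    """

    names: tuple[str, str, str] = ("sea_ice_melt", "meteoric", "cdw")
    salinity: tuple[float, float, float] = (7.0, 0.0, 34.73)
    d18o: tuple[float, float, float] = (2.1, -16.0, 0.1)

    def matrix(self) -> np.ndarray:
        """The 3x3 system matrix: rows are (mass, salinity, d18o) balances."""
        return np.array(
            [
                [1.0, 1.0, 1.0],
                list(self.salinity),
                list(self.d18o),
            ]
        )

    def __post_init__(self) -> None:
        m = self.matrix()
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError(
                "end members are affinely dependent in (salinity, d18o) space; "
                "the mixing system is singular"
            )


DEFAULT_END_MEMBERS = EndMemberSet()


def endmember_fractions(
    salinity,
    d18o,
    endmembers: EndMemberSet = DEFAULT_END_MEMBERS,
):
    """Invert the mass balance for one or many samples.

    Parameters
    ----------
    salinity, d18o : float or array-like
        Observed salinity (PSU) and delta-18O (per mil).
    endmembers : EndMemberSet
        Source-water properties.

    Returns
    -------
    fractions : ndarray, shape (..., 3)
        (f_sim, f_met, f_cdw) in end-member order.  Unclipped.
    in_simplex : ndarray of bool
        True where all three fractions lie in [0, 1].
    """
    salinity = np.asarray(salinity, dtype=float)
    d18o = np.asarray(d18o, dtype=float)
    if not (np.all(np.isfinite(salinity)) and np.all(np.isfinite(d18o))):
        raise ValueError("salinity and d18o must be finite")
    scalar = salinity.ndim == 0 and d18o.ndim == 0
    salinity, d18o = np.broadcast_arrays(np.atleast_1d(salinity), np.atleast_1d(d18o))

    rhs = np.vstack([np.ones_like(salinity), salinity, d18o])
    frac = np.linalg.solve(endmembers.matrix(), rhs).T
    in_simplex = np.all((frac >= -1e-12) & (frac <= 1 + 1e-12), axis=1)
    if scalar:
        return frac[0], bool(in_simplex[0])
    return frac, in_simplex


def forward_mix(fractions, endmembers: EndMemberSet = DEFAULT_END_MEMBERS):
    """Map mixing fractions to (salinity, d18o) — the forward direction.

    ``fractions`` must sum to 1 within 1e-9 per sample (affine combination).
    """
    frac = np.asarray(fractions, dtype=float)
    scalar = frac.ndim == 1
    frac = np.atleast_2d(frac)
    if frac.shape[1] != 3:
        raise ValueError("fractions must have three components")
    sums = frac.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        bad = np.argmax(np.abs(sums - 1.0))
        raise ValueError(f"fractions must sum to 1 (row {bad} sums to {sums[bad]!r})")
    salinity = frac @ np.asarray(endmembers.salinity)
    d18o = frac @ np.asarray(endmembers.d18o)
    if scalar:
        return float(salinity[0]), float(d18o[0])
    return salinity, d18o


def fractions_table(
    metadata: pd.DataFrame,
    salinity_col: str = "salinity",
    d18o_col: str = "d18o",
    endmembers: EndMemberSet = DEFAULT_END_MEMBERS,
) -> pd.DataFrame:
    """Per-sample fractions with QC flag, indexed like ``metadata``."""
    frac, ok = endmember_fractions(
        metadata[salinity_col].to_numpy(), metadata[d18o_col].to_numpy(), endmembers
    )
    out = pd.DataFrame(
        frac, index=metadata.index, columns=["f_sim", "f_met", "f_cdw"]
    )
    out["in_simplex"] = ok
    return out
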