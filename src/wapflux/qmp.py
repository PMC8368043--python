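"""Quantitative microbiome profiling (QMP): read counts -> 18S copies per liter.

Amplicon counts are compositional; to compare plankton abundance across
samples they are rescaled to absolute 18S gene copies per liter of filtered
seawater.  Two routes are supported, mirroring how underway surveys are
typically run in batches:

* **Spike-in route** — a fixed mass of *Schizosaccharomyces pombe* genomic
  DNA is added to each sample before extraction.  The ratio of an ASV's reads
  to the spike's reads, times the number of spike copies added, divided by
  the filtration volume, gives copies per liter.  A spike read fraction of
  0.1 % or less is treated as a failed internal standard; the usable range
  observed in practice is about 0.7-5.7 % of total reads.

* **Pigment-calibration route** — for batches without a usable spike, total
  cryptophyte 18S abundance is predicted from the HPLC Alloxanthin
  concentration via an empirical linear calibration (y = 2.05e6 * x, with y
  in copies per mL and x in ug/L, valid for 0.01-6.22 ug/L), and the whole
  sample is rescaled so that its cryptophyte reads match that total.

Both routes preserve within-sample relative abundances exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeSpec",
    "CalibrationSpec",
    "spike_qc",
    "qmp_from_spike",
    "cryptophyte_copies_per_ml",
    "qmp_from_pigment_calibration",
    "qmp_auto",
]

#: spike fraction at or below which the internal standard is unusable
SPIKE_FAIL_FRACTION = 0.001
#: observed usable range of spike read fractions
SPIKE_EXPECTED_RANGE = (0.007, 0.057)


@dataclass(frozen=True)
class SpikeSpec:
    """Internal-standard bookkeeping for the spike-in route.

    ``copies_per_ng`` (18S copies per ng of spike gDNA) is organism- and
    assay-specific and is a required configuration constant; only ratios of
    copies matter downstream, so its absolute value rescales all QMP values
    uniformly.
    """

    spike_asv: str = "S.pombe_spike"
    gdna_ng: float = 16.0
    copies_per_ng: float = 1.0e5
    volume_l: float = 4.0

    def __post_init__(self):
        if self.gdna_ng < 0:
            raise ValueError("spike mass must be non-negative")
        if self.volume_l <= 0:
            raise ValueError("filtration volume must be positive")

    @property
    def copies_added(self) -> float:
        return self.gdna_ng * self.copies_per_ng


@dataclass(frozen=True)
class CalibrationSpec:
    """Alloxanthin -> cryptophyte 18S calibration (copies mL-1 per ug L-1)."""

    slope: float = 2.05e6
    valid_range: tuple[float, float] = (0.01, 6.22)
    cryptophyte_match: str = "Cryptophyta"

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.valid_range[0] <= 0:
            raise ValueError("calibration range lower bound must be positive")


def _spike_reads(counts: pd.DataFrame, spike_asv: str) -> pd.Series:
    if spike_asv not in counts.columns:
        raise ValueError(f"spike ASV {spike_asv!r} not present in the count table")
    return counts[spike_asv]


def spike_qc(counts: pd.DataFrame, spike: SpikeSpec) -> pd.DataFrame:
    """Per-sample spike read fraction with pass/fail and in-range flags.

    ``counts`` is samples x ASVs.  Fraction = spike reads / total reads.
    Fails at fractions <= 0.1 %; flags fractions outside the expected
    0.7-5.7 % window as a warning, not a failure.
    """
    spike_reads = _spike_reads(counts, spike.spike_asv)
    total = counts.sum(axis=1)
    frac = spike_reads / total
    lo, hi = SPIKE_EXPECTED_RANGE
    return pd.DataFrame(
        {
            "spike_fraction": frac,
            "passed": frac > SPIKE_FAIL_FRACTION,
            "in_expected_range": (frac >= lo) & (frac <= hi),
        }
    )


def qmp_from_spike(
    counts: pd.DataFrame,
    spike: SpikeSpec,
    volume_l: pd.Series | float | None = None,
    enforce_qc: bool = True,
) -> pd.DataFrame:
    """Spike-normalised QMP table (copies L-1); the spike column is dropped.

    QMP_i = (reads_i / reads_spike) * copies_added / volume.  Per-sample
    filtration volumes may be passed as a Series aligned to the count index;
    otherwise the SpikeSpec default is used for all samples.
    """
    spike_reads = _spike_reads(counts, spike.spike_asv)
    if (spike_reads == 0).any():
        bad = counts.index[spike_reads == 0].tolist()
        raise ValueError(f"zero spike reads in sample(s) {bad}")
    if enforce_qc:
        qc = spike_qc(counts, spike)
        if not qc["passed"].all():
            bad = qc.index[~qc["passed"]].tolist()
            raise ValueError(
                f"spike fraction <= {SPIKE_FAIL_FRACTION:.1%} in sample(s) {bad}; "
                "internal standard unusable"
            )
        if not qc["in_expected_range"].all():
            bad = qc.index[~qc["in_expected_range"]].tolist()
            warnings.warn(
                f"spike fraction outside the expected {SPIKE_EXPECTED_RANGE} "
                f"range in sample(s) {bad}",
                stacklevel=2,
            )
    if volume_l is None:
        volume = pd.Series(spike.volume_l, index=counts.index)
    else:
        volume = pd.Series(volume_l, index=counts.index) if np.isscalar(volume_l) else volume_l
    scale = spike.copies_added / (spike_reads * volume)
    out = counts.drop(columns=[spike.spike_asv]).astype(float)
    return out.mul(scale, axis=0)


def cryptophyte_copies_per_ml(
    alloxanthin_ug_l, calibration: CalibrationSpec = CalibrationSpec()
):
    """Total cryptophyte 18S copies per mL from Alloxanthin (ug L-1).

    Linear calibration y = slope * x.  Concentrations outside the calibrated
    range raise a warning (extrapolation, higher uncertainty near zero).
    """
    x = np.asarray(alloxanthin_ug_l, dtype=float)
    lo, hi = calibration.valid_range
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn(
            f"Alloxanthin outside the calibrated range [{lo}, {hi}] ug/L; "
            "extrapolated values carry higher uncertainty",
            stacklevel=2,
        )
    if np.any(x <= 0):
        raise ValueError("Alloxanthin concentration must be positive")
    return calibration.slope * x


def qmp_from_pigment_calibration(
    counts: pd.DataFrame,
    alloxanthin_ug_l: pd.Series,
    taxonomy: pd.Series,
    calibration: CalibrationSpec = CalibrationSpec(),
    spike_asv: str | None = None,
) -> pd.DataFrame:
    """Pigment-calibrated QMP table (copies L-1).

    The per-sample scale factor is (predicted cryptophyte copies per liter) /
    (cryptophyte read sum); all ASV reads are scaled by it.  ``taxonomy``
    maps ASV id -> taxonomy string; ASVs whose taxonomy contains the
    calibration's cryptophyte match rule define the cryptophyte subset.
    A spike column, if named, is dropped first.
    """
    tab = counts
    if spike_asv is not None and spike_asv in tab.columns:
        tab = tab.drop(columns=[spike_asv])
    crypto_cols = [
        a for a in tab.columns if calibration.cryptophyte_match in str(taxonomy.get(a, ""))
    ]
    if not crypto_cols:
        raise ValueError(
            f"no ASV matches the cryptophyte rule {calibration.cryptophyte_match!r}"
        )
    crypto_reads = tab[crypto_cols].sum(axis=1)
    if (crypto_reads == 0).any():
        bad = tab.index[crypto_reads == 0].tolist()
        raise ValueError(f"zero cryptophyte reads in sample(s) {bad}")
    allox = pd.Series(alloxanthin_ug_l).reindex(tab.index)
    copies_per_l = (
        cryptophyte_copies_per_ml(allox.to_numpy(), calibration) * 1000.0
    )  # mL-1 -> L-1
    scale = copies_per_l / crypto_reads.to_numpy()
    return tab.astype(float).mul(scale, axis=0)


def qmp_auto(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    spike: SpikeSpec = SpikeSpec(),
    calibration: CalibrationSpec = CalibrationSpec(),
    taxonomy: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route each sample through the spike or pigment normalisation.

    Samples whose spike passes QC use the spike route; remaining samples with
    an in-range ``alloxanthin`` metadata value use the pigment route; samples
    failing both are dropped.  Returns (qmp, routing report).
    """
    qc = spike_qc(counts, spike) if spike.spike_asv in counts.columns else None
    volume = metadata["volume_l"] if "volume_l" in metadata.columns else None

    route = pd.Series("dropped", index=counts.index, name="route")
    if qc is not None:
        route[qc["passed"]] = "spike"
    if "alloxanthin" in metadata.columns and taxonomy is not None:
        lo, hi = calibration.valid_range
        ok = metadata["alloxanthin"].between(lo, hi)
        route[(route == "dropped") & ok.reindex(counts.index, fill_value=False)] = "pigment"

    frames = []
    if (route == "spike").any():
        sub = counts.loc[route == "spike"]
        vol = volume.loc[sub.index] if volume is not None else None
        frames.append(qmp_from_spike(sub, spike, volume_l=vol, enforce_qc=False))
    if (route == "pigment").any():
        sub = counts.loc[route == "pigment"]
        frames.append(
            qmp_from_pigment_calibration(
                sub,
                metadata.loc[sub.index, "alloxanthin"],
                taxonomy,
                calibration,
                spike_asv=spike.spike_asv,
            )
        )
    if not frames:
        raise ValueError("no sample could be normalised by either route")
    qmp = pd.concat(frames).reindex(index=counts.index).dropna(how="all")
    qmp = qmp.fillna(0.0)
    report = pd.DataFrame({"route": route})
    if qc is not None:
        report = report.join(qc)
    return qmp, report
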