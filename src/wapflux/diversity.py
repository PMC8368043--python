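"""Rarefaction, alpha diversity and diversity-vs-temperature trends.

Alpha diversity of amplicon libraries is depth-dependent, so counts are first
rarefied (subsampled without replacement) to an even depth.  On the rarefied
table three standard indices are computed per sample:

* observed richness S and the bias-corrected Chao1 estimator
  S + f1(f1-1) / (2(f2+1)), f1/f2 the singleton/doubleton counts;
* Shannon entropy H' = -sum p_i ln p_i (natural log);
* Pielou's evenness J = H'/ln S, in [0, 1].

A linear trend of any index against sea-surface temperature is summarised by
an ordinary least squares fit with slope, 95% confidence interval, two-sided
p value, and the percent change over a 4 degC warming relative to the fitted
value at the coldest observed temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rarefy", "alpha_diversity", "TrendFit", "diversity_sst_trend"]


def rarefy(
    counts: pd.DataFrame,
    depth: int | None = None,
    seed: int = 0,
    n_draws: int = 1,
) -> pd.DataFrame:
    """Subsample each row to exactly ``depth`` reads without replacement.

    ``depth=None`` uses the minimum row total ("auto").  Samples whose total
    is below the depth are dropped.  With ``n_draws > 1`` the returned table
    is the average over independent draws (fractional counts); the default is
    a single draw.
    """
    if depth is None:
        depth = int(counts.sum(axis=1).min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = counts.sum(axis=1)
    kept = counts.loc[totals >= depth]
    rng = np.random.default_rng(seed)
    mat = kept.to_numpy(dtype=np.int64)
    acc = np.zeros_like(mat, dtype=float)
    for _ in range(n_draws):
        for i in range(mat.shape[0]):
            if mat[i].sum() == depth:
                acc[i] += mat[i]
            else:
                acc[i] += rng.multivariate_hypergeometric(mat[i], depth)
    acc /= n_draws
    if n_draws == 1:
        acc = acc.astype(np.int64)
    return pd.DataFrame(acc, index=kept.index, columns=kept.columns)


def _chao1(x: np.ndarray) -> float:
    s = int(np.count_nonzero(x))
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _chao1_classic(x: np.ndarray) -> float:
    s = int(np.count_nonzero(x))
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f2 == 0:
        return s + f1 * (f1 - 1) / 2.0
    return s + f1 * f1 / (2.0 * f2)


def alpha_diversity(
    rarefied: pd.DataFrame, bias_corrected: bool = True
) -> pd.DataFrame:
    """Per-sample S, Chao1, Shannon (natural log) and Pielou evenness.

    Pielou is undefined (NaN) for samples with fewer than two observed ASVs.
    The bias-corrected Chao1 variant is the default; set
    ``bias_corrected=False`` for the classic f1^2/(2 f2) form.
    """
    chao = _chao1 if bias_corrected else _chao1_classic
    rows = []
    for sid, row in rarefied.iterrows():
        x = row.to_numpy(dtype=float)
        x = x[x > 0]
        s = x.size
        p = x / x.sum()
        h = float(-np.sum(p * np.log(p)))
        j = h / np.log(s) if s >= 2 else np.nan
        rows.append(
            {
                "sample": sid,
                "observed_richness": s,
                "chao1": chao(row.to_numpy()),
                "shannon": h,
                "pielou": j,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    r: float
    n: int
    percent_change_per_4c: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "r": self.r,
            "n": self.n,
            "percent_change_per_4c": self.percent_change_per_4c,
        }


def diversity_sst_trend(index_values, sst) -> TrendFit:
    """OLS fit of a diversity index on SST.

    Besides slope, 95% CI and the two-sided p value, reports the percent
    change of the fitted index over a 4 degC warming, relative to the fitted
    value at the coldest observed SST (negative = decline with warming).
    """
    y = np.asarray(index_values, dtype=float)
    x = np.asarray(sst, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("SST is constant; trend undefined")
    res = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    base = res.intercept + res.slope * x.min()
    pct = 100.0 * res.slope * 4.0 / base if base != 0 else np.nan
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        p_value=float(res.pvalue),
        r=float(res.rvalue),
        n=int(n),
        percent_change_per_4c=float(pct),
    )
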