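"""Co-abundance module detection on log-transformed QMP matrices.

Weighted correlation network analysis applied to plankton community profiles:
ASVs whose absolute abundances co-vary across samples form modules
("assemblages") that are summarised by their eigenvalue — the first principal
component of the module's standardized member profiles.  The pipeline is

1. prevalence filter (an ASV must exceed 3 reads in at least 20% of samples);
2. log transform of the QMP matrix;
3. soft-thresholded adjacency a_ij = |cor(x_i, x_j)|^power, the power chosen
   as the smallest integer for which the network's degree distribution
   reaches a scale-free topology fit of R^2 >= 0.9;
4. topological overlap (TOM) similarity, which counts shared neighbours in
   addition to direct adjacency, and average-linkage clustering of the TOM
   dissimilarity with an adaptive height cut and a minimum module size;
5. module eigenvalues, module-trait correlations, module membership (kME),
   intramodular connectivity (kIN) and hub identification.

Modules are named by the conventional descending-size colour sequence
(turquoise = largest); unassigned ASVs are "grey".

The model interface follows the usual estimator pattern:
``CoabundanceNetwork(qmp, config).fit()`` returns a :class:`ModuleResults`
carrying labels, eigenvalues, membership statistics and export helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkConfig",
    "prevalence_filter",
    "log_transform",
    "adjacency_matrix",
    "scale_free_fit",
    "pick_soft_power",
    "tom_similarity",
    "tom_dissimilarity",
    "detect_modules",
    "module_eigenvalues",
    "module_trait_correlations",
    "module_membership",
    "intramodular_connectivity",
    "hub_taxa",
    "membership_vs_ncp",
    "export_network",
    "CoabundanceNetwork",
    "ModuleResults",
    "MODULE_COLORS",
]

# conventional module colour order, largest module first
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
GREY = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    """Knobs for network construction and module detection.

    soft_power
        Positive integer, or "auto" to pick the smallest power whose
        scale-free topology fit reaches ``scale_free_r2_target``.
    cut_height
        Absolute dendrogram cut height, or "auto" = ``cut_height_factor``
        times the largest merge height.  Clusters formed below the cut and
        larger than ``min_module_size`` become modules; everything else is
        grey (optionally rescued by the kME reassignment step).
    """

    soft_power: int | str = "auto"
    scale_free_r2_target: float = 0.9
    max_power: int = 20
    min_mean_connectivity: float = 1.0
    min_module_size: int = 10
    mode: str = "unsigned"
    cut_height: float | str = "auto"
    cut_height_factor: float = 0.95
    reassign_kme: float | None = 0.3
    merge_eigen_cut: float | None = None
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.soft_power != "auto" and int(self.soft_power) < 1:
            raise ValueError("soft_power must be >= 1 or 'auto'")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.mode not in ("unsigned", "signed"):
            raise ValueError("mode must be 'unsigned' or 'signed'")


def prevalence_filter(
    table: pd.DataFrame, min_count: int = 3, min_prevalence: float = 0.20
) -> pd.DataFrame:
    """Keep ASVs observed *more than* ``min_count`` times in at least
    ``min_prevalence`` of the samples (strict > on the count)."""
    n = len(table)
    keep = (table > min_count).sum(axis=0) >= min_prevalence * n
    out = table.loc[:, keep]
    if out.shape[1] == 0:
        warnings.warn("prevalence filter removed every ASV", stacklevel=2)
    return out


def log_transform(qmp: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Natural-log transform with a pseudocount for zeros."""
    return np.log(qmp + pseudocount)


def adjacency_matrix(
    log_qmp: pd.DataFrame, power: int, mode: str = "unsigned"
) -> pd.DataFrame:
    """Soft-thresholded adjacency; diagonal set to zero.

    unsigned: |cor|^power; signed: ((1 + cor)/2)^power.
    Constant ASV columns are dropped with a warning.
    """
    x = log_qmp
    sd = x.std(axis=0)
    if (sd == 0).any():
        dropped = sd.index[sd == 0].tolist()
        warnings.warn(f"dropping constant ASV column(s): {dropped}", stacklevel=2)
        x = x.loc[:, sd > 0]
    cor = np.corrcoef(x.to_numpy(dtype=float), rowvar=False)
    if mode == "unsigned":
        a = np.abs(cor) ** power
    else:
        a = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=x.columns, columns=x.columns)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index for one adjacency matrix.

    Connectivities k_i are binned into ``n_bins`` equal-width bins; within
    each non-empty bin the mean k and the frequency p(k) are computed and
    log10 p(k) is regressed on log10 k.  Returns (signed R^2, slope) where
    the R^2 is negated if the slope is positive (a scale-free degree
    distribution has a negative log-log slope).
    """
    k = adjacency.to_numpy().sum(axis=1)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k.append(k[sel].mean())
        freq.append(sel.mean())
    if len(mean_k) < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k), np.log10(freq)
    res = stats.linregress(lx, ly)
    r2 = res.rvalue**2
    return float(-np.sign(res.slope) * r2), float(res.slope)


def pick_soft_power(
    log_qmp: pd.DataFrame, config: NetworkConfig = NetworkConfig()
) -> tuple[int, pd.DataFrame]:
    """Smallest power in 1..max_power whose signed fit R^2 meets the target.

    Returns the chosen power and the full fit table (power, r2, slope,
    mean/max connectivity).  If no power reaches the target (degree
    distributions of small or strongly blocked matrices often plateau below
    it), the smallest power at which the fit curve saturates — marginal R^2
    gain below 0.02 per step once R^2 >= 0.5 — is returned with a warning,
    falling back to the overall maximum if the curve never saturates.
    """
    if log_qmp.shape[1] < 20:
        raise ValueError("need at least 20 ASVs for the scale-free fit")
    rows = []
    for p in range(1, config.max_power + 1):
        adj = adjacency_matrix(log_qmp, p, config.mode)
        r2, slope = scale_free_fit(adj)
        k = adj.to_numpy().sum(axis=1)
        rows.append(
            {"power": p, "r2": r2, "slope": slope, "mean_k": k.mean(), "max_k": k.max()}
        )
    table = pd.DataFrame(rows)
    ok = table[
        (table["r2"] >= config.scale_free_r2_target)
        & (table["mean_k"] >= config.min_mean_connectivity)
    ]
    if len(ok):
        power = int(ok["power"].iloc[0])
    else:
        power = None
        r2 = table["r2"].to_numpy()
        for i in range(len(r2) - 1):
            if r2[i] >= 0.5 and r2[i + 1] - r2[i] < 0.02:
                power = int(table["power"].iloc[i])
                break
        if power is None:
            power = int(table.loc[table["r2"].idxmax(), "power"])
        warnings.warn(
            f"no power reached scale-free R^2 {config.scale_free_r2_target}; "
            f"using power {power} where the fit curve saturates "
            f"(max R^2 {table['r2'].max():.3f})",
            stacklevel=2,
        )
    return power, table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour weight plus direct adjacency,
    normalised by the smaller connectivity.

        TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with a_ii = 0 and TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] < 3:
        raise ValueError("TOM needs at least 3 nodes")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def tom_dissimilarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    return 1.0 - tom_similarity(adjacency)


def detect_modules(
    diss_tom: pd.DataFrame, config: NetworkConfig = NetworkConfig()
) -> pd.Series:
    """Average-linkage clustering of the TOM dissimilarity with a height cut.

    Clusters formed below the cut height (default: 0.95 of the largest merge
    height, adapting the cut to how much structure the matrix contains) and
    of size >= min_module_size become modules; all other ASVs are labelled
    grey.  Modules are coloured in descending size order, so the largest is
    always "turquoise".  On structure-free input nearly all merges happen in
    a narrow band near the maximum height and essentially everything ends up
    grey.
    """
    d = diss_tom.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    dd = (d + d.T) / 2.0
    np.fill_diagonal(dd, 0.0)
    link = average(squareform(dd, checks=False))
    heights = link[:, 2]
    if config.cut_height == "auto":
        cut = config.cut_height_factor * heights.max()
    else:
        cut = float(config.cut_height)
    raw = fcluster(link, t=cut, criterion="distance")
    labels = pd.Series(GREY, index=diss_tom.index, name="module", dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    kept.sort(key=lambda c: -sizes[c])
    for color_i, cluster_id in enumerate(kept):
        labels[raw == cluster_id] = _color(color_i)
    return labels


def _color(i: int) -> str:
    if i < len(MODULE_COLORS):
        return MODULE_COLORS[i]
    return f"module_{i + 1}"


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    mapping = {old: _color(i) for i, old in enumerate(sizes.index)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def module_eigenvalues(log_qmp: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    Member profiles are standardized (z-scored across samples) before the
    SVD; the eigenvalue is scaled to unit standard deviation and its sign is
    chosen so that its correlation with the mean standardized member profile
    is positive.
    """
    eigens = {}
    for module in labels[labels != GREY].unique():
        members = labels.index[labels == module]
        if len(members) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 members")
        x = log_qmp[members].to_numpy(dtype=float)
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = u[:, 0]
        pc = pc / pc.std(ddof=1)
        mean_profile = z.mean(axis=1)
        if np.corrcoef(pc, mean_profile)[0, 1] < 0:
            pc = -pc
        eigens[module] = pc
    order = sorted(eigens, key=lambda m: -int((labels == m).sum()))
    return pd.DataFrame({m: eigens[m] for m in order}, index=log_qmp.index)


def module_trait_correlations(
    eigenvalues: pd.DataFrame, traits: pd.DataFrame, min_n: int = 4
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (module, trait) pair.

    Missing trait values are pairwise-deleted; pairs with fewer than
    ``min_n`` complete cases are reported as missing.  Long-format output
    with columns module, trait, r, p, n.
    """
    rows = []
    for m in eigenvalues.columns:
        for t in traits.columns:
            x = eigenvalues[m]
            y = traits[t].reindex(eigenvalues.index)
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < min_n or y[ok].std() == 0 or x[ok].std() == 0:
                rows.append({"module": m, "trait": t, "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"module": m, "trait": t, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def module_membership(
    log_qmp: pd.DataFrame, labels: pd.Series, eigenvalues: pd.DataFrame
) -> pd.Series:
    """kME: correlation of each ASV's profile with its own module eigenvalue.

    Grey ASVs get NaN.
    """
    kme = pd.Series(np.nan, index=labels.index, name="kME")
    for module in eigenvalues.columns:
        members = labels.index[labels == module]
        e = eigenvalues[module].to_numpy()
        for asv in members:
            kme[asv] = np.corrcoef(log_qmp[asv].to_numpy(), e)[0, 1]
    return kme


def intramodular_connectivity(
    adjacency: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    """kIN: sum of adjacency to same-module members (0 for grey)."""
    kin = pd.Series(0.0, index=labels.index, name="kIN")
    for module in labels[labels != GREY].unique():
        members = labels.index[labels == module]
        sub = adjacency.loc[members, members]
        kin[members] = sub.sum(axis=1)
    return kin


def hub_taxa(
    kin: pd.Series, labels: pd.Series, top_n: int = 10
) -> dict[str, list[str]]:
    """Top-``top_n`` ASVs by intramodular connectivity per module."""
    hubs = {}
    for module in labels[labels != GREY].unique():
        members = labels.index[labels == module]
        if len(members) < top_n:
            warnings.warn(
                f"module {module!r} has only {len(members)} members; "
                "all are reported as hubs",
                stacklevel=2,
            )
        hubs[module] = list(kin[members].sort_values(ascending=False).index[:top_n])
    return hubs


def membership_vs_ncp(
    log_qmp: pd.DataFrame,
    labels: pd.Series,
    kme: pd.Series,
    ncp: pd.Series,
    module: str,
) -> tuple[float, float]:
    """Within one module, correlate per-ASV NCP correlation against kME.

    For each member ASV the Pearson correlation of its abundance profile with
    NCP is computed; the returned (r, p) is the Pearson correlation of those
    values with the members' kME.  A strong positive r means the module's
    most central taxa track NCP most closely.
    """
    members = labels.index[labels == module]
    ncp = ncp.reindex(log_qmp.index)
    ok = ncp.notna()
    cors = np.array(
        [np.corrcoef(log_qmp.loc[ok, a], ncp[ok])[0, 1] for a in members]
    )
    r, p = stats.pearsonr(kme[members].to_numpy(), cors)
    return float(r), float(p)


def export_network(
    adjacency: pd.DataFrame,
    labels: pd.Series,
    threshold: float,
    kin: pd.Series | None = None,
    taxonomy: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted undirected edge list (weight >= threshold) + node attributes."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    a = adjacency.to_numpy()
    names = adjacency.index
    iu, ju = np.triu_indices_from(a, k=1)
    sel = a[iu, ju] >= threshold
    edges = pd.DataFrame(
        {
            "source": names[iu[sel]],
            "target": names[ju[sel]],
            "weight": a[iu, ju][sel],
        }
    )
    nodes = pd.DataFrame({"module": labels})
    if kin is not None:
        nodes["kIN"] = kin
    if taxonomy is not None:
        nodes["taxonomy"] = taxonomy.reindex(labels.index)
    return edges, nodes


class CoabundanceNetwork:
    """Co-abundance network model over a QMP (or count) table.

    Parameters
    ----------
    qmp : DataFrame, samples x ASVs
        Absolute abundances (copies per liter) or counts.  Log-transformed
        internally with the configured pseudocount.
    config : NetworkConfig
    apply_prevalence_filter : bool
        Apply the >3-reads-in-20%-of-samples filter before transforming.
    """

    def __init__(
        self,
        qmp: pd.DataFrame,
        config: NetworkConfig = NetworkConfig(),
        apply_prevalence_filter: bool = True,
    ):
        self.config = config
        table = prevalence_filter(qmp) if apply_prevalence_filter else qmp
        self.log_qmp = log_transform(table, config.pseudocount)

    def fit(self) -> "ModuleResults":
        cfg = self.config
        if cfg.soft_power == "auto":
            power, fit_table = pick_soft_power(self.log_qmp, cfg)
        else:
            power, fit_table = int(cfg.soft_power), None
        adj = adjacency_matrix(self.log_qmp, power, cfg.mode)
        log_qmp = self.log_qmp[adj.index]  # constant columns may have dropped
        diss = 1.0 - tom_similarity(adj)
        labels = detect_modules(diss, cfg)
        if labels.eq(GREY).all():
            eigen = pd.DataFrame(index=log_qmp.index)
        else:
            eigen = module_eigenvalues(log_qmp, labels)
            if cfg.reassign_kme is not None:
                labels = self._reassign_grey(log_qmp, labels, eigen, cfg.reassign_kme)
                labels = _relabel_by_size(labels)
                eigen = module_eigenvalues(log_qmp, labels)
        kme = module_membership(log_qmp, labels, eigen)
        kin = intramodular_connectivity(adj, labels)
        hubs = hub_taxa(kin, labels) if not labels.eq(GREY).all() else {}
        return ModuleResults(
            log_qmp=log_qmp,
            adjacency=adj,
            tom_dissimilarity=diss,
            labels=labels,
            eigenvalues=eigen,
            kme=kme,
            kin=kin,
            hubs=hubs,
            soft_power=power,
            power_fit_table=fit_table,
            config=cfg,
        )

    @staticmethod
    def _reassign_grey(log_qmp, labels, eigenvalues, threshold):
        labels = labels.copy()
        grey = labels.index[labels == GREY]
        if len(grey) == 0 or eigenvalues.shape[1] == 0:
            return labels
        x = log_qmp[grey].to_numpy()
        for asv in grey:
            cors = {
                m: np.corrcoef(log_qmp[asv], eigenvalues[m])[0, 1]
                for m in eigenvalues.columns
            }
            best = max(cors, key=cors.get)
            if cors[best] > threshold:
                labels[asv] = best
        return labels


@dataclass
class ModuleResults:
    """Fitted module structure: labels, eigenvalues, membership, hubs."""

    log_qmp: pd.DataFrame
    adjacency: pd.DataFrame
    tom_dissimilarity: pd.DataFrame
    labels: pd.Series
    eigenvalues: pd.DataFrame
    kme: pd.Series
    kin: pd.Series
    hubs: dict[str, list[str]]
    soft_power: int
    power_fit_table: pd.DataFrame | None
    config: NetworkConfig

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def trait_correlations(self, traits: pd.DataFrame) -> pd.DataFrame:
        return module_trait_correlations(self.eigenvalues, traits)

    def membership_vs_ncp(self, ncp: pd.Series, module: str) -> tuple[float, float]:
        return membership_vs_ncp(self.log_qmp, self.labels, self.kme, ncp, module)

    def export_network(self, threshold: float = 0.1, taxonomy: pd.Series | None = None):
        return export_network(self.adjacency, self.labels, threshold, self.kin, taxonomy)

    def modules_table(self) -> pd.DataFrame:
        """Per-ASV table: module, kME, kIN, hub flag."""
        hub_set = {a for hubs in self.hubs.values() for a in hubs}
        return pd.DataFrame(
            {
                "module": self.labels,
                "kME": self.kme,
                "kIN": self.kin,
                "hub": [a in hub_set for a in self.labels.index],
            }
        )

    def summary(self) -> str:
        lines = [
            "Co-abundance network modules",
            f"  ASVs: {len(self.labels)}   samples: {len(self.log_qmp)}",
            f"  soft-thresholding power: {self.soft_power}",
            f"  modules: {self.eigenvalues.shape[1]} "
            f"(grey: {int((self.labels == GREY).sum())} ASVs)",
            "",
            f"  {'module':<14}{'size':>6}{'top hub':>24}",
        ]
        sizes = self.module_sizes
        for m in self.eigenvalues.columns:
            top = self.hubs.get(m, [""])[0]
            lines.append(f"  {m:<14}{sizes.get(m, 0):>6}{top:>24}")
        return "\n".join(lines)
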