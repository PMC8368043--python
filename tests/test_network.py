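"""Co-abundance network construction, TOM, module detection and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wapflux.network import (
    GREY,
    NetworkConfig,
    adjacency_matrix,
    detect_modules,
    export_network,
    hub_taxa,
    intramodular_connectivity,
    module_eigenvalues,
    module_membership,
    module_trait_correlations,
    pick_soft_power,
    prevalence_filter,
    tom_similarity,
)


def _planted_blocks(sizes=(60, 30, 20), n_noise=70, n=112, rho=0.7, seed=0):
    """Log-abundance matrix with independent latent factors per block."""
    rng = np.random.default_rng(seed)
    cols, data = [], []
    s = np.sqrt(1 / rho - 1)
    for b, size in enumerate(sizes):
        f = rng.normal(size=n)
        for j in range(size):
            cols.append(f"b{b}_{j}")
            data.append(f + s * rng.normal(size=n))
    for j in range(n_noise):
        cols.append(f"noise_{j}")
        data.append(rng.normal(size=n))
    return pd.DataFrame(np.array(data).T, columns=cols)


class TestPrevalenceFilter:
    def test_kept_when_above_count_in_enough_samples(self):
        col = np.zeros(100)
        col[:25] = 4  # >3 in 25% of samples
        table = pd.DataFrame({"keep": col, "pad": np.full(100, 10)})
        assert "keep" in prevalence_filter(table).columns

    def test_count_rule_is_strict(self):
        table = pd.DataFrame({"border": np.full(100, 3), "pad": np.full(100, 10)})
        assert "border" not in prevalence_filter(table).columns

    def test_low_prevalence_removed_despite_high_counts(self):
        col = np.zeros(100)
        col[:10] = 100
        table = pd.DataFrame({"rare": col, "pad": np.full(100, 10)})
        assert "rare" not in prevalence_filter(table).columns


class TestSoftPower:
    def test_fit_table_covers_all_powers(self):
        x = _planted_blocks(sizes=(20, 15), n_noise=10, n=60)
        with pytest.warns(UserWarning):
            _power, table = pick_soft_power(x, NetworkConfig())
        assert list(table["power"]) == list(range(1, 21))
        assert table["r2"].notna().all()

    def test_vacuous_target_selects_power_one(self):
        x = _planted_blocks(sizes=(20, 15), n_noise=10, n=60)
        power, _ = pick_soft_power(
            x, NetworkConfig(scale_free_r2_target=-2.0)
        )
        assert power == 1

    def test_agrees_with_independent_fit(self):
        """Selected power matches a test-local re-implementation within +/-2."""
        x = _planted_blocks(seed=3)
        cfg = NetworkConfig()
        with pytest.warns(UserWarning):
            power, table = pick_soft_power(x, cfg)

        def fit_r2(p):
            a = np.abs(np.corrcoef(x.to_numpy(), rowvar=False)) ** p
            np.fill_diagonal(a, 0)
            k = a.sum(1)
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max() + 1e-12, 11)
            which = np.clip(np.digitize(k, edges) - 1, 0, 9)
            mk = [k[which == b].mean() for b in range(10) if (which == b).any()]
            pk = [(which == b).mean() for b in range(10) if (which == b).any()]
            res = stats.linregress(np.log10(mk), np.log10(pk))
            return -np.sign(res.slope) * res.rvalue**2

        r2s = {p: fit_r2(p) for p in range(1, 21)}
        candidates = [p for p, r in r2s.items() if r >= cfg.scale_free_r2_target]
        if candidates:
            assert abs(power - min(candidates)) <= 2

    def test_too_few_asvs_rejected(self):
        with pytest.raises(ValueError):
            pick_soft_power(pd.DataFrame(np.random.default_rng(0).normal(size=(30, 5))))


class TestAdjacencyAndTom:
    def test_correlation_extremes(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        x = pd.DataFrame({"x1": a, "x2": 2 * a + 3, "x3": rng.normal(size=200)})
        adj = adjacency_matrix(x, power=1)
        assert adj.loc["x1", "x2"] == pytest.approx(1.0)
        assert abs(adj.loc["x1", "x3"]) < 0.2
        assert adj.loc["x1", "x1"] == 0.0

    def test_constant_column_dropped_with_warning(self):
        x = pd.DataFrame(
            {"x1": [1.0, 2, 3, 4], "x2": [2.0, 2, 2, 2], "x3": [0.0, 1, 0, 1]}
        )
        with pytest.warns(UserWarning, match="constant"):
            adj = adjacency_matrix(x, power=2)
        assert "x2" not in adj.columns

    def test_tom_matches_brute_force(self):
        """Vectorised TOM equals the O(n^3) triple loop on 20 ASVs."""
        x = _planted_blocks(sizes=(8, 6), n_noise=6, n=50, seed=2)
        adj = adjacency_matrix(x, power=4)
        tom = tom_similarity(adj).to_numpy()
        a = adj.to_numpy()
        n = a.shape[0]
        k = a.sum(axis=1)
        brute = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                brute[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        assert np.max(np.abs(tom - brute)) < 1e-12

    def test_dissimilarity_bounds_and_symmetry(self):
        x = _planted_blocks(sizes=(10, 10), n_noise=10, n=60, seed=4)
        tom = tom_similarity(adjacency_matrix(x, power=4))
        d = (1 - tom).to_numpy()
        assert d.min() >= -1e-12 and d.max() <= 1 + 1e-12
        assert np.allclose(d, d.T)

    def test_too_few_nodes_rejected(self):
        adj = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            tom_similarity(adj)


class TestModuleDetection:
    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        x = _planted_blocks(seed=5)
        diss = 1 - tom_similarity(adjacency_matrix(x, power=4))
        labels = detect_modules(diss)
        truth = [c.split("_")[0] for c in x.columns]
        planted = [i for i, t in enumerate(truth) if t != "noise"]
        ari = adjusted_rand_score(
            [truth[i] for i in planted], labels.iloc[planted].tolist()
        )
        assert ari >= 0.9
        sizes = labels[labels != GREY].value_counts()
        assert sizes.index[0] == "turquoise"  # largest module gets turquoise

    def test_pure_noise_is_grey(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.normal(size=(112, 100)))
        x.columns = [f"n{i}" for i in range(100)]
        diss = 1 - tom_similarity(adjacency_matrix(x, power=4))
        labels = detect_modules(diss)
        assert (labels == GREY).mean() > 0.9

    def test_non_symmetric_rejected(self):
        d = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 5)))
        with pytest.raises(ValueError):
            detect_modules(d)


class TestEigenvalues:
    def test_rank_one_module(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(size=80)
        x = pd.DataFrame({f"m{i}": 3 * profile + i for i in range(5)})
        labels = pd.Series("turquoise", index=x.columns)
        eig = module_eigenvalues(x, labels)["turquoise"]
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(np.abs(eig), np.abs(z), atol=1e-9)
        assert np.corrcoef(eig, profile)[0, 1] > 0.999999

    def test_sign_orientation_invariant_to_member_flip(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(60, 6)), columns=[f"m{i}" for i in range(6)])
        x = x.add(rng.normal(size=(60, 1)))  # shared component
        labels = pd.Series("blue", index=x.columns)
        e1 = module_eigenvalues(x, labels)["blue"]
        e2 = module_eigenvalues(-x, labels)["blue"]
        assert np.corrcoef(e1, -e2)[0, 1] > 0.999999

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.normal(size=(40, 8)), columns=[f"m{i}" for i in range(8)])
        labels = pd.Series("red", index=x.columns)
        eig = module_eigenvalues(x, labels)["red"].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        pc = u[:, 0] / np.std(u[:, 0], ddof=1)
        assert min(np.max(np.abs(eig - pc)), np.max(np.abs(eig + pc))) < 1e-9

    def test_unit_variance(self, network_results):
        assert np.allclose(network_results.eigenvalues.std(ddof=1), 1.0)

    def test_first_pc_optimality(self, network_results):
        """The eigenvalue explains more member variance than any single member."""
        res = network_results
        for module in res.eigenvalues.columns:
            members = res.labels.index[res.labels == module]
            z = (res.log_qmp[members] - res.log_qmp[members].mean()) / res.log_qmp[
                members
            ].std(ddof=1)
            eig_r2 = (z.corrwith(res.eigenvalues[module]) ** 2).mean()
            for m in members[:5]:
                member_r2 = (z.corrwith(z[m]) ** 2).mean()
                assert eig_r2 >= member_r2 - 1e-9

    def test_singleton_module_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)), columns=["a", "b"])
        labels = pd.Series({"a": "green", "b": GREY})
        with pytest.raises(ValueError):
            module_eigenvalues(x, labels)


class TestTraitCorrelations:
    def test_identical_trait_gives_r_one(self):
        rng = np.random.default_rng(10)
        eig = pd.DataFrame({"turquoise": rng.normal(size=50)})
        traits = pd.DataFrame({"sst": eig["turquoise"]})
        out = module_trait_correlations(eig, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-30

    def test_matches_manual_t_test(self):
        rng = np.random.default_rng(11)
        eig = pd.DataFrame({f"m{i}": rng.normal(size=40) for i in range(4)})
        traits = pd.DataFrame({f"t{i}": rng.normal(size=40) for i in range(5)})
        out = module_trait_correlations(eig, traits)
        for _, row in out.iterrows():
            x = eig[row["module"]].to_numpy()
            y = traits[row["trait"]].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            n = len(x)
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert row["r"] == pytest.approx(r, abs=1e-12)
            assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_pairwise_deletion_and_minimum_n(self):
        rng = np.random.default_rng(12)
        eig = pd.DataFrame({"m": rng.normal(size=30)})
        sparse = pd.Series(np.nan, index=eig.index)
        sparse.iloc[:3] = 1.0
        dense = pd.Series(rng.normal(size=30), index=eig.index)
        dense.iloc[:10] = np.nan
        out = module_trait_correlations(eig, pd.DataFrame({"sparse": sparse, "dense": dense}))
        sparse_row = out[out["trait"] == "sparse"].iloc[0]
        assert np.isnan(sparse_row["r"]) and sparse_row["n"] == 3
        dense_row = out[out["trait"] == "dense"].iloc[0]
        assert dense_row["n"] == 20 and np.isfinite(dense_row["r"])


class TestMembershipAndHubs:
    def test_kme_and_hubs_on_planted_data(self, dataset, network_results):
        res = network_results
        members = res.labels.index[res.labels == "turquoise"]
        assert (res.kme[members] > 0.4).all()
        hubs = res.hubs["turquoise"]
        assert len(hubs) == 10
        # hubs are the top-10 by intramodular connectivity
        assert set(hubs) == set(res.kin[members].nlargest(10).index)

    def test_kme_of_eigenvalue_with_itself(self, network_results):
        res = network_results
        kme = module_membership(
            res.eigenvalues.rename(columns={"turquoise": "self"}),
            pd.Series({"self": "turquoise"}),
            res.eigenvalues,
        )
        assert kme["self"] == pytest.approx(1.0)

    def test_small_module_hub_warning(self):
        kin = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
        labels = pd.Series({"a": "red", "b": "red", "c": "red"})
        with pytest.warns(UserWarning, match="hubs"):
            hubs = hub_taxa(kin, labels)
        assert hubs["red"] == ["a", "b", "c"]

    def test_membership_vs_ncp_planted_signal(self, dataset, network_results):
        r, p = network_results.membership_vs_ncp(
            dataset.metadata["observed_ncp_volumetric"], "turquoise"
        )
        assert r > 0.5
        assert p < 0.01

    def test_grey_has_zero_intramodular_connectivity(self, network_results):
        res = network_results
        grey = res.labels.index[res.labels == GREY]
        assert (res.kin[grey] == 0).all()


class TestExportNetwork:
    def test_threshold_extremes_and_monotonicity(self):
        x = _planted_blocks(sizes=(6, 5), n_noise=4, n=50, seed=13)
        adj = adjacency_matrix(x, power=2)
        labels = pd.Series(GREY, index=adj.index)
        n = adj.shape[0]
        edges_all, nodes = export_network(adj, labels, 0.0)
        assert len(edges_all) == n * (n - 1) // 2
        edges_perfect, _ = export_network(adj, labels, 1.0)
        assert len(edges_perfect) <= 1  # only numerically perfect correlations
        counts = [len(export_network(adj, labels, t)[0]) for t in (0.0, 0.2, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)
        assert list(nodes.columns) == ["module"]
        kin = pd.Series(1.0, index=adj.index)
        tax = pd.Series("Eukaryota", index=adj.index)
        _, nodes_full = export_network(adj, labels, 0.5, kin=kin, taxonomy=tax)
        assert list(nodes_full.columns) == ["module", "kIN", "taxonomy"]

    def test_invalid_threshold(self):
        adj = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            export_network(adj, pd.Series(GREY, index=adj.index), 1.5)


def test_pipeline_determinism(qmp_table):
    """Same input and config give the identical ModuleSet."""
    from wapflux.network import CoabundanceNetwork

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = CoabundanceNetwork(qmp_table, NetworkConfig(soft_power=4)).fit()
        b = CoabundanceNetwork(qmp_table, NetworkConfig(soft_power=4)).fit()
    pd.testing.assert_series_equal(a.labels, b.labels)
    pd.testing.assert_frame_equal(a.eigenvalues, b.eigenvalues)
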