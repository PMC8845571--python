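"""Gene-taxon Spearman-FDR networks, Mantel tests, exponential decay fit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gradientnet.associations import (fit_exponential_decay, mantel,
                                      partial_mantel, spearman_fdr_network)


def _gene_table(signals, samples):
    """signals: dict probe -> vector."""
    df = pd.DataFrame(signals, index=samples).T
    df.insert(0, "family", "fam")
    df.insert(1, "category", "antioxidant")
    df.insert(2, "source_genus", "Genus")
    df.index.name = "probe"
    return df


def _dist(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestSpearmanFdrNetwork:
    def test_perfect_monotone_association_is_an_edge(self, rng):
        samples = [f"S{i}" for i in range(20)]
        x = rng.random(20)
        table = pd.DataFrame({"OTU1": x, "OTU2": rng.random(20)},
                             index=samples)
        genes = _gene_table({"probe1": np.exp(3 * x)}, samples)
        edges, net = spearman_fdr_network(genes, table)
        hit = edges[(edges["gene"] == "probe1") & (edges["taxon"] == "OTU1")]
        assert len(hit) == 1
        assert hit["r"].iloc[0] == pytest.approx(1.0)
        assert net.has_edge("probe1", "OTU1")

    def test_thresholds_are_conjunctive(self, rng):
        samples = [f"S{i}" for i in range(30)]
        x = rng.random(30)
        table = pd.DataFrame({"OTU1": x}, index=samples)
        genes = _gene_table({"p": x + rng.normal(0, 0.6, 30)}, samples)
        edges, _ = spearman_fdr_network(genes, table)
        assert ((edges["r"] > 0.6) & (edges["q"] < 0.01)).all()

    def test_negative_correlations_need_absolute_flag(self, rng):
        samples = [f"S{i}" for i in range(25)]
        x = np.arange(25, dtype=float)
        table = pd.DataFrame({"OTU1": x}, index=samples)
        genes = _gene_table({"p": -x}, samples)
        pos, _ = spearman_fdr_network(genes, table)
        neg, _ = spearman_fdr_network(genes, table, absolute=True)
        assert len(pos) == 0
        assert len(neg) == 1

    def test_monotone_transform_invariance(self, rng):
        samples = [f"S{i}" for i in range(15)]
        table = pd.DataFrame(rng.random((15, 4)),
                             index=samples,
                             columns=[f"O{j}" for j in range(4)])
        sig = {f"p{k}": rng.random(15) for k in range(3)}
        base, _ = spearman_fdr_network(_gene_table(sig, samples), table,
                                       r_threshold=0.3, q_threshold=0.5)
        warped, _ = spearman_fdr_network(
            _gene_table({k: np.exp(v) for k, v in sig.items()}, samples),
            table.apply(lambda c: c ** 3), r_threshold=0.3, q_threshold=0.5)
        key = ["gene", "taxon"]
        assert set(map(tuple, base[key].values)) == set(
            map(tuple, warped[key].values))

    def test_constant_vectors_skipped_with_warning(self, rng):
        samples = [f"S{i}" for i in range(10)]
        table = pd.DataFrame({"O1": rng.random(10), "O2": np.ones(10)},
                             index=samples)
        genes = _gene_table({"p": rng.random(10)}, samples)
        with pytest.warns(UserWarning, match="constant"):
            edges, _ = spearman_fdr_network(genes, table, r_threshold=-1,
                                            q_threshold=1.1)
        assert set(edges["taxon"]) == {"O1"}

    def test_too_few_shared_samples(self, rng):
        table = pd.DataFrame({"O1": [1.0, 2.0]}, index=["S0", "S1"])
        genes = _gene_table({"p": [1.0, 2.0]}, ["S0", "S1"])
        with pytest.raises(ValueError, match="5 shared"):
            spearman_fdr_network(genes, table)


class TestMantel:
    def test_identity_gives_r_one(self, rng):
        d = _dist(rng, 8)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1 / 100)

    def test_r_equals_lower_triangle_pearson(self, rng):
        d1, d2 = _dist(rng, 9), _dist(rng, 9)
        res = mantel(d1, d2, n_perm=9, seed=0)
        u = d1[np.tril_indices(9, -1)]
        v = d2[np.tril_indices(9, -1)]
        assert res.r == pytest.approx(np.corrcoef(u, v)[0, 1])

    def test_exact_enumeration_matches_bruteforce(self, rng):
        d1, d2 = _dist(rng, 3), _dist(rng, 3)
        res = mantel(d1, d2, n_perm="exact")
        u = d1[np.tril_indices(3, -1)]
        r_obs = np.corrcoef(u, d2[np.tril_indices(3, -1)])[0, 1]
        count = 0
        for p in itertools.permutations(range(3)):
            dp = d2[np.ix_(p, p)]
            r_p = np.corrcoef(u, dp[np.tril_indices(3, -1)])[0, 1]
            count += r_p >= r_obs - 1e-12
        assert res.pvalue == pytest.approx(count / 6)
        assert res.n_perm == 6

    def test_agrees_with_skbio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1, d2 = _dist(rng, 12), _dist(rng, 12)
        ours = mantel(d1, d2, n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1),
            skbio_distance.DistanceMatrix(d2),
            method="pearson", permutations=999, alternative="greater")
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        assert ours.pvalue == pytest.approx(p_ref, abs=0.05)

    def test_shape_and_symmetry_validation(self, rng):
        d = _dist(rng, 4)
        with pytest.raises(ValueError):
            mantel(d, _dist(rng, 5))
        bad = d.copy()
        bad[0, 1] = 99.0
        with pytest.raises(ValueError, match="symmetric"):
            mantel(d, bad)

    def test_deterministic_under_seed(self, rng):
        d1, d2 = _dist(rng, 7), _dist(rng, 7)
        assert (mantel(d1, d2, 199, seed=5).pvalue
                == mantel(d1, d2, 199, seed=5).pvalue)


class TestPartialMantel:
    def test_controlling_for_itself_gives_zero(self, rng):
        d1, d2 = _dist(rng, 8), _dist(rng, 8)
        res = partial_mantel(d1, d2, d2, n_perm=49, seed=0)
        assert abs(res.r) < 1e-10

    def test_independent_control_preserves_r(self):
        deltas = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            base = r.random((10, 10))
            d1 = (base + base.T) / 2
            d2 = d1 + r.normal(0, 0.05, (10, 10))
            d2 = (d2 + d2.T) / 2
            d3 = r.random((10, 10))
            d3 = (d3 + d3.T) / 2
            for d in (d1, d2, d3):
                np.fill_diagonal(d, 0.0)
            simple = mantel(d1, d2, n_perm=9, seed=0).r
            partial = partial_mantel(d1, d2, d3, n_perm=9, seed=0).r
            deltas.append(abs(simple - partial))
        assert np.mean(deltas) < 0.05

    def test_p_is_valid(self, rng):
        res = partial_mantel(_dist(rng, 6), _dist(rng, 6), _dist(rng, 6),
                             n_perm=99, seed=2)
        assert 1 / 100 <= res.pvalue <= 1.0
        assert res.flavor == "partial"


class TestFitExponentialDecay:
    def test_exact_model_recovered(self):
        x = np.linspace(3.5, 8.5, 40)
        y = 2.0 * np.exp(-1.5 * x)
        a, b, r2 = fit_exponential_decay(x, y)
        assert a == pytest.approx(2.0, rel=1e-6)
        assert b == pytest.approx(1.5, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_constant_y_gives_flat_decay(self):
        x = np.linspace(0, 5, 20)
        a, b, r2 = fit_exponential_decay(x, np.full(20, 3.0))
        assert b == pytest.approx(0.0, abs=1e-8)

    def test_generator_parameters_recovered(self):
        from gradientnet.synthetic import SimulationConfig, sample_design

        cfg = SimulationConfig(al_decay=(4000.0, 1.5, 0.1))
        meta = sample_design(cfg)
        _, b, _ = fit_exponential_decay(meta["pH"].to_numpy(),
                                        meta["Al"].to_numpy())
        assert abs(b - 1.5) / 1.5 < 0.10

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_exponential_decay([1, 2, 3], [1, -1, 1])
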