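import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phytoscale.composition import bray_curtis, filter_and_rarefy, pcoa, permanova
from phytoscale.errors import DataError
from phytoscale.simulate import SimulationConfig, simulate_asv_table


def counts_frame(rows, index=None):
    arr = np.asarray(rows, dtype=int)
    index = index or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=index, columns=[f"t{j}" for j in range(arr.shape[1])])


class TestRarefaction:
    def test_read_count_boundary(self):
        table = counts_frame([[999, 0], [1000, 0], [600, 500]])
        out = filter_and_rarefy(table, min_reads=1000, seed=0)
        assert list(out.index) == ["s1", "s2"]

    def test_rarefied_sums_equal_depth(self):
        table = counts_frame([[800, 400, 300], [2000, 100, 0], [500, 500, 500]])
        out = filter_and_rarefy(table, min_reads=1000, seed=1)
        assert (out.sum(axis=1) == 1500).all()

    def test_rarefy_to_own_sum_is_identity(self):
        table = counts_frame([[700, 300], [600, 400]])
        out = filter_and_rarefy(table, min_reads=0, depth=1000, seed=2)
        pd.testing.assert_frame_equal(out, table)

    def test_all_filtered_errors(self):
        with pytest.raises(DataError):
            filter_and_rarefy(counts_frame([[1, 2], [3, 4]]), min_reads=1000)

    def test_depth_above_minimum_rejected(self):
        with pytest.raises(DataError):
            filter_and_rarefy(counts_frame([[600, 500], [3000, 0]]), depth=2000)

    def test_seeded_determinism(self):
        table = counts_frame([[800, 400, 300], [2000, 100, 0]])
        a = filter_and_rarefy(table, min_reads=1000, seed=9)
        b = filter_and_rarefy(table, min_reads=1000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_non_integer_rejected(self):
        table = counts_frame([[10, 10], [10, 10]]).astype(float) + 0.5
        with pytest.raises(DataError):
            filter_and_rarefy(table, min_reads=0)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = bray_curtis(counts_frame([[5, 5], [5, 5]]))
        assert dm.iloc[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        dm = bray_curtis(counts_frame([[5, 0], [0, 7]]))
        assert dm.iloc[0, 1] == 1.0

    def test_hand_example(self):
        dm = bray_curtis(counts_frame([[1, 2], [2, 1]]))
        assert dm.iloc[0, 1] == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_against_scipy_oracle(self, rng):
        counts = counts_frame(rng.integers(0, 50, size=(8, 12)) + 1)
        ours = bray_curtis(counts).to_numpy()
        scipy_dm = squareform(pdist(counts.to_numpy(), metric="braycurtis"))
        assert np.allclose(ours, scipy_dm, atol=1e-12)

    def test_column_order_invariance(self, rng):
        counts = counts_frame(rng.integers(0, 50, size=(5, 9)) + 1)
        shuffled = counts[list(rng.permutation(counts.columns))]
        assert np.allclose(bray_curtis(counts).to_numpy(), bray_curtis(shuffled).to_numpy())

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            bray_curtis(counts_frame([[0, 0], [1, 1]]))


class TestPCoA:
    def test_recovers_planar_configuration(self, rng):
        points = rng.normal(size=(7, 2))
        d = squareform(pdist(points))
        dm = pd.DataFrame(d, index=list("abcdefg"), columns=list("abcdefg"))
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()[:, :2]
        recovered = squareform(pdist(coords))
        assert np.allclose(recovered, d, atol=1e-9)

    def test_percent_variance_sums_to_one(self, rng):
        counts = counts_frame(rng.integers(1, 60, size=(6, 10)))
        res = pcoa(bray_curtis(counts))
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_equilateral_three_points(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(pd.DataFrame(d, index=list("abc"), columns=list("abc")))
        assert res.eigenvalues.size == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)

    def test_non_symmetric_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(DataError):
            pcoa(pd.DataFrame(d))

    def test_negative_eigenvalues_reported(self, rng):
        counts = counts_frame(rng.integers(1, 30, size=(8, 5)))
        res = pcoa(bray_curtis(counts))
        assert (res.negative_eigenvalues <= 0).all()


def oracle_one_way_f(d, labels):
    """Independent one-factor pseudo-F from raw pairwise distances."""
    n = len(labels)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = len(groups) - 1, n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPermanova:
    @staticmethod
    def toy_instance():
        rng = np.random.default_rng(7)
        base = rng.integers(5, 40, size=(6, 8))
        base[:3, :4] += 40  # group contrast on the first taxa
        counts = counts_frame(base)
        labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
        meta = pd.DataFrame({"grp": labels}, index=counts.index)
        return bray_curtis(counts), meta

    def test_pseudo_f_matches_independent_oracle(self):
        dm, meta = self.toy_instance()
        table = permanova(dm, meta, n_perm=9, seed=0)
        expected = oracle_one_way_f(dm.to_numpy(), meta["grp"].to_numpy())
        assert table.loc["grp", "pseudo_F"] == pytest.approx(expected, rel=1e-9)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        dm, meta = self.toy_instance()
        d = dm.to_numpy()
        labels = meta["grp"].to_numpy()
        f_obs = oracle_one_way_f(d, labels)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            f_perm = oracle_one_way_f(d, labels[list(perm)])
            hits += f_perm >= f_obs - 1e-12
            total += 1
        p_exact = hits / total
        n_perm = 9999
        table = permanova(dm, meta, n_perm=n_perm, seed=3)
        p_sampled = table.loc["grp", "p"]
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) <= 3 * se + 2.0 / n_perm

    def test_perfect_separation_minimal_p(self):
        counts = counts_frame(
            [[50, 0, 0], [60, 0, 0], [55, 0, 0], [0, 50, 0], [0, 60, 0], [0, 55, 0]]
        )
        meta = pd.DataFrame(
            {"grp": ["a", "a", "a", "b", "b", "b"]}, index=counts.index
        )
        table = permanova(bray_curtis(counts), meta, n_perm=199, seed=0)
        # all 6!/(3!3!) relabelings tie at the observed F in a two-group
        # perfect split only for the observed split; minimal attainable p
        assert table.loc["grp", "p"] <= (1 + 199 * (1 / 10)) / 200 + 1e-9

    def test_partial_r2_sums_to_one(self):
        config = SimulationConfig(seed=41, n_mesocosms_per_treatment=3)
        counts, meta = simulate_asv_table(config)
        table = permanova(bray_curtis(counts), meta, n_perm=99, seed=1)
        assert table["partial_R2"].sum() == pytest.approx(1.0)

    def test_detects_treatment_signal(self):
        config = SimulationConfig(seed=42, composition_effect=0.9)
        counts, meta = simulate_asv_table(config)
        table = permanova(bray_curtis(counts), meta, n_perm=999, seed=2)
        assert table.loc["mesocosm_treatment", "p"] <= 0.005
        assert table.loc["incubator_treatment", "p"] > 0.05

    def test_null_p_values_spread(self):
        ps = []
        for rep in range(12):
            config = SimulationConfig(
                seed=100 + rep, composition_effect=0.0, n_mesocosms_per_treatment=3
            )
            counts, meta = simulate_asv_table(config)
            table = permanova(bray_curtis(counts), meta, n_perm=199, seed=rep)
            ps.append(table.loc["mesocosm_treatment", "p"])
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform under the null

    def test_confounded_factors_rejected(self):
        dm, meta = self.toy_instance()
        meta = meta.assign(grp2=meta["grp"])
        with pytest.raises(DataError, match="confounded|aliased"):
            permanova(dm, meta, n_perm=9, seed=0)

    def test_term_order_configurable(self):
        config = SimulationConfig(seed=43, n_mesocosms_per_treatment=3)
        counts, meta = simulate_asv_table(config)
        dm = bray_curtis(counts)
        a = permanova(dm, meta, n_perm=49, seed=0)
        b = permanova(
            dm, meta, n_perm=49, seed=0,
            order=["incubator_treatment", "mesocosm_treatment"],
        )
        assert list(a.index[:2]) == ["mesocosm_treatment", "incubator_treatment"]
        assert list(b.index[:2]) == ["incubator_treatment", "mesocosm_treatment"]

    def test_misaligned_factors_rejected(self):
        dm, meta = self.toy_instance()
        bad = meta.iloc[:-1]
        with pytest.raises(DataError):
            permanova(dm, bad, n_perm=9)
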