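"""Binned profiles, the spline zonation ANOVA, modules and overlaps."""

import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from hepzone.zonation import (
    ZonationProfile,
    assign_dpd_bins,
    classify_zonation,
    cluster_modules,
    hypergeom_overlap,
    overlap_table,
    profile_bins,
    spline_anova,
    zonated_call,
)
from hepzone.zonation import test_zonation as run_zonation_tests


def _norm_adata(X, genotype=None):
    X = np.asarray(X, float)
    obs = pd.DataFrame(index=[f"n{i}" for i in range(X.shape[0])])
    obs["genotype"] = genotype if genotype is not None else "CON"
    return ad.AnnData(X=X, obs=obs,
                      var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]))


class TestProfileBins:
    def test_single_bin_collapses_to_overall_mean(self, rng):
        X = rng.normal(2, 1, size=(50, 4))
        adata = _norm_adata(X)
        dpd = pd.Series(rng.uniform(size=50), index=adata.obs_names)
        prof = profile_bins(adata, dpd, n_bins=1)
        np.testing.assert_allclose(prof.means.values[:, 0], X.mean(axis=0),
                                   rtol=1e-12)

    def test_boundary_value_goes_to_last_bin(self):
        assert assign_dpd_bins(np.array([1.0]), 10)[0] == 9
        assert assign_dpd_bins(np.array([0.0]), 10)[0] == 0
        assert assign_dpd_bins(np.array([0.999999]), 10)[0] == 9

    def test_linear_gene_bin_means_track_expectation(self, rng):
        """A gene whose expression is linear in DPD has bin means within
        3 SE of the line evaluated at the bin midpoints."""
        n = 4000
        dpd_vals = rng.uniform(size=n)
        sd = 0.5
        X = (1.0 + 2.0 * dpd_vals + rng.normal(0, sd, n)).reshape(-1, 1)
        adata = _norm_adata(X)
        prof = profile_bins(adata, pd.Series(dpd_vals, index=adata.obs_names),
                            n_bins=10)
        for b in range(10):
            se = sd / math.sqrt(prof.bin_counts[b])
            expected = 1.0 + 2.0 * prof.midpoints[b]
            assert abs(prof.means.values[0, b] - expected) < 3.5 * se + 0.1

    def test_invalid_bins_error(self, rng):
        adata = _norm_adata(rng.normal(size=(10, 2)))
        dpd = pd.Series(rng.uniform(size=10), index=adata.obs_names)
        with pytest.raises(ValueError, match="n_bins"):
            profile_bins(adata, dpd, n_bins=0)


class TestSplineAnova:
    def test_constant_profile_not_zonated(self):
        mid = (np.arange(80) + 0.5) / 80
        F, dfn, dfd, p = spline_anova(mid, np.full(80, 3.0), np.full(80, 25.0))
        assert F == 0.0 and p == 1.0

    def test_strict_threshold(self):
        """p = 0.049 is called zonated; p = 0.05 exactly is not."""
        calls = zonated_call([0.049, 0.05, 0.051])
        assert list(calls) == [True, False, False]

    def test_strong_gradient_detected(self, rng):
        mid = (np.arange(80) + 0.5) / 80
        y = 2.0 + mid + rng.normal(0, 0.05, 80)
        F, _, _, p = spline_anova(mid, y, np.full(80, 25.0))
        assert p < 1e-6

    def test_needs_enough_bins(self):
        mid = (np.arange(8) + 0.5) / 8
        with pytest.raises(ValueError, match="10 non-empty bins"):
            spline_anova(mid, np.ones(8), np.ones(8))

    def test_type_one_error_roughly_nominal(self, rng):
        """Independent Gaussian bin means under the null reject near 5%."""
        mid = (np.arange(80) + 0.5) / 80
        w = np.full(80, 25.0)
        rejections = sum(
            spline_anova(mid, rng.normal(0, 1, 80), w)[3] < 0.05
            for _ in range(400))
        assert 0.02 <= rejections / 400 <= 0.09


class TestTestZonation:
    def test_gradient_genes_zonated_flat_genes_mostly_not(self, clean_norm,
                                                          clean_lobule):
        _, truth = clean_lobule
        u = pd.Series(truth.u, index=clean_norm.obs_names)
        genes = [f"PCg{i:03d}" for i in range(20)] + \
                [f"FLATg{i:03d}" for i in range(60)]
        res = run_zonation_tests(clean_norm, u, genotype="CON", genes=genes)
        assert res.loc[[g for g in genes if g.startswith("PC")], "zonated"].all()
        flat_rate = res.loc[[g for g in genes if g.startswith("FLAT")],
                            "zonated"].mean()
        assert flat_rate < 0.2


class TestClassify:
    def test_category_definitions_and_conservation(self):
        idx = pd.Index(["a", "b", "c", "d"], name="gene")
        con = pd.DataFrame({"zonated": [True, True, False, False]}, index=idx)
        ko = pd.DataFrame({"zonated": [True, False, True, False]}, index=idx)
        cl = classify_zonation(con, ko)
        assert cl.category.tolist() == ["both", "con_only", "ko_only", "neither"]
        assert sum(cl.counts.values()) == 4

    def test_no_zonation_all_neither(self):
        idx = pd.Index(list("abcde"), name="gene")
        res = pd.DataFrame({"zonated": [False] * 5}, index=idx)
        cl = classify_zonation(res, res.copy())
        assert cl.counts == {"both": 0, "con_only": 0, "ko_only": 0,
                             "neither": 5}

    def test_mismatched_gene_lists_error(self):
        con = pd.DataFrame({"zonated": [True]}, index=pd.Index(["a"]))
        ko = pd.DataFrame({"zonated": [True]}, index=pd.Index(["b"]))
        with pytest.raises(ValueError, match="different genes"):
            classify_zonation(con, ko)


def _profile_from_matrix(M, genotype):
    n_bins = M.shape[1]
    return ZonationProfile(
        means=pd.DataFrame(M, index=[f"g{i}" for i in range(M.shape[0])],
                           columns=[f"bin{b}" for b in range(n_bins)]),
        bin_counts=np.full(n_bins, 100), midpoints=(np.arange(n_bins) + 0.5) / n_bins,
        n_bins=n_bins, genotype=genotype)


class TestModules:
    def _planted(self, rng, n_per=15, noise=0.05):
        """Four archetypes in (CON 8 bins || KO 8 bins) space."""
        x = (np.arange(8) + 0.5) / 8
        down, up, bump, flat = 1 - x, x, np.exp(-(x - 0.5) ** 2 / 0.02), np.full(8, 0.5)
        arch = {
            "A": np.concatenate([down, flat]),   # pericentral, lost in KO
            "B": np.concatenate([up, flat]),     # periportal, lost in KO
            "C": np.concatenate([bump, bump]),   # mid-lobular, retained
            "D": np.concatenate([down, down]),   # pericentral, retained
        }
        rows, labels = [], []
        for name, a in arch.items():
            for _ in range(n_per):
                rows.append(a + rng.normal(0, noise, 16))
                labels.append(name)
        M = np.vstack(rows)
        return M[:, :8], M[:, 8:], labels

    def test_planted_archetypes_recovered(self, rng):
        con, ko, labels = self._planted(rng)
        pc = _profile_from_matrix(con, "CON")
        pk = _profile_from_matrix(ko, "KO")
        ma = cluster_modules(pc, pk, list(pc.means.index), k=4)
        assert adjusted_rand_score(labels, ma.modules.values) >= 0.9

    def test_k_one_single_module(self, rng):
        con, ko, _ = self._planted(rng, n_per=3)
        ma = cluster_modules(_profile_from_matrix(con, "CON"),
                             _profile_from_matrix(ko, "KO"),
                             [f"g{i}" for i in range(12)], k=1)
        assert set(ma.modules) == {"A"}

    def test_duplicated_genes_same_module(self, rng):
        con, ko, _ = self._planted(rng, n_per=5)
        con[1], ko[1] = con[0], ko[0]
        ma = cluster_modules(_profile_from_matrix(con, "CON"),
                             _profile_from_matrix(ko, "KO"),
                             [f"g{i}" for i in range(20)], k=4)
        assert ma.modules.iloc[0] == ma.modules.iloc[1]

    def test_k_exceeding_genes_errors(self, rng):
        con, ko, _ = self._planted(rng, n_per=1)
        with pytest.raises(ValueError, match="k must be"):
            cluster_modules(_profile_from_matrix(con, "CON"),
                            _profile_from_matrix(ko, "KO"),
                            [f"g{i}" for i in range(4)], k=9)


def hypergeom_tail_by_enumeration(universe_size, set_size, module_size, overlap):
    """Exhaustive oracle: fraction of all C(N, n) draws with >= overlap hits."""
    hits = 0
    total = 0
    target = set(range(set_size))
    for draw in itertools.combinations(range(universe_size), module_size):
        total += 1
        if len(target.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


class TestOverlap:
    def test_matches_exhaustive_enumeration(self):
        """Upper-tail p equals brute-force enumeration over all draws."""
        universe = [f"u{i}" for i in range(20)]
        for set_size, module_size, overlap in [(4, 5, 3), (6, 4, 2), (3, 7, 1)]:
            module = universe[:overlap] + universe[set_size:set_size + module_size - overlap]
            target = universe[:set_size]
            res = hypergeom_overlap(module, target, universe)
            assert res.overlap == overlap
            oracle = hypergeom_tail_by_enumeration(20, set_size, module_size,
                                                   overlap)
            assert res.p == pytest.approx(oracle, abs=1e-10)

    def test_printed_example(self):
        """Universe 20, set 4, module 5, overlap 3 -> p = 496/15504."""
        universe = [f"u{i}" for i in range(20)]
        res = hypergeom_overlap(universe[:3] + universe[4:6], universe[:4],
                                universe)
        assert res.p == pytest.approx(496 / 15504, abs=1e-12)

    def test_disjoint_sets_p_one(self):
        universe = list("abcdefgh")
        res = hypergeom_overlap(["a", "b"], ["c", "d"], universe)
        assert res.overlap == 0 and res.p == 1.0

    def test_module_subset_of_set_minimal_tail(self):
        universe = [f"u{i}" for i in range(12)]
        res = hypergeom_overlap(universe[:3], universe[:6], universe)
        assert res.overlap == 3
        assert res.p == pytest.approx(
            float(stats.hypergeom.sf(2, 12, 6, 3)), abs=1e-12)

    def test_union_fraction_and_table_bh(self):
        universe = [f"u{i}" for i in range(30)]
        modules = {"A": universe[:5], "B": universe[5:12]}
        sets = {"s1": universe[:4], "s2": universe[20:]}
        df = overlap_table(modules, sets, universe)
        row = df[(df.module == "A") & (df.gene_set == "s1")].iloc[0]
        assert row.fraction == pytest.approx(4 / 5)  # |A ∩ s1| / |A ∪ s1|
        assert (df.p_adj >= df.p - 1e-15).all()
        assert df.p_adj.max() <= 1.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeom_overlap([], [], [])
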