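"""Diversity, dissimilarity, PERMANOVA, db-RDA and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobnet.community import (DistanceMatrix, bray_curtis, cap_ordination,
                              filter_low_count, forward_select, group_compare,
                              log10_copies, pcoa_coordinates, permanova,
                              rarefy, relative_abundance, richness, vif)
from mobnet.io_tables import AsvTable, SoilTable


def make_asv(counts: np.ndarray, sites=None) -> AsvTable:
    n = counts.shape[0]
    ids = [f"s{i}" for i in range(n)]
    sites = sites or ["X"] * (n // 2) + ["Y"] * (n - n // 2)
    meta = pd.DataFrame({"site": sites, "depth": ["D1"] * n,
                         "plot": ids}, index=ids)
    cols = [f"A{j}" for j in range(counts.shape[1])]
    return AsvTable(pd.DataFrame(counts, index=ids, columns=cols), meta)


class TestFilterRarefy:
    def test_low_count_threshold_is_strict(self):
        counts = np.array([[4, 5, 3], [5, 5, 3], [0, 0, 4]])
        # totals: 9, 10, 10 -> first ASV dropped, others kept
        out = filter_low_count(make_asv(counts), min_reads=10)
        assert out.asv_ids == ["A1", "A2"]
        assert out.shape[0] == 3  # samples unchanged

    def test_empty_table_passes_through(self):
        out = filter_low_count(make_asv(np.zeros((2, 3), dtype=int)))
        assert out.shape == (2, 0)

    def test_rarefied_rows_sum_to_depth(self):
        rng = np.random.default_rng(0)
        asv = make_asv(rng.integers(0, 50, size=(6, 20)))
        out = rarefy(asv, depth=100, seed=1)
        kept = asv.counts.sum(axis=1) >= 100
        assert out.shape[0] == int(kept.sum())
        assert (out.counts.sum(axis=1) == 100).all()

    def test_sample_at_exact_depth_unchanged(self):
        counts = np.array([[60, 40, 0]])
        asv = make_asv(counts, sites=["X"])
        out = rarefy(asv, depth=100, seed=3)
        assert (out.counts.to_numpy() == counts).all()

    def test_shallow_samples_dropped_with_warning(self):
        asv = make_asv(np.array([[200, 0], [10, 5]]))
        with pytest.warns(UserWarning, match="below rarefaction depth"):
            out = rarefy(asv, depth=100, seed=0)
        assert out.sample_ids == ["s0"]

    def test_expected_counts_are_hypergeometric(self):
        # E[rarefied count] = depth * count / total, checked by Monte Carlo
        row = np.array([[300, 150, 50, 500]])
        depth, n_rep = 200, 2000
        total = row.sum()
        draws = np.zeros((n_rep, 4))
        for seed in range(n_rep):
            out = rarefy(make_asv(row, sites=["X"]), depth=depth, seed=seed)
            draws[seed] = out.counts.to_numpy()[0]
        expect = depth * row[0] / total
        # hypergeometric variance per ASV
        var = (depth * (row[0] / total) * (1 - row[0] / total)
               * (total - depth) / (total - 1))
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 3 * se)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(make_asv(np.ones((2, 2), dtype=int)), depth=0)


class TestRichnessAbundance:
    def test_richness_counts_presence_only(self):
        counts = np.array([[0, 0, 0], [1, 1, 1], [5, 0, 2]])
        r = richness(make_asv(counts, sites=["X", "X", "Y"]))
        assert list(r) == [0, 3, 2]
        doubled = richness(make_asv(counts * 2, sites=["X", "X", "Y"]))
        assert list(doubled) == list(r)

    def test_rows_sum_to_one(self, toy_asv, toy_taxonomy):
        for level in ("asv", "genus", "mob_class"):
            ra = relative_abundance(toy_asv, toy_taxonomy, level)
            assert np.allclose(ra.sum(axis=1), 1.0, atol=1e-12)

    def test_single_class_table(self, toy_asv, toy_taxonomy):
        sub = AsvTable(toy_asv.counts[["A1"]], toy_asv.sample_meta)
        ra = relative_abundance(sub, toy_taxonomy, "mob_class")
        nonzero = sub.counts["A1"] > 0
        assert np.allclose(ra.loc[nonzero, "typeI"], 1.0)

    def test_type_ii_dominated_site(self, study):
        from mobnet.synthetic_data import class_share
        shares = class_share(study.asv, study.taxonomy, "typeII").groupby(
            study.asv.sample_meta["site"]).mean()
        assert shares["MQ"] > 0.5  # nutrient-rich site is type II dominated
        assert shares["SGH"] < 0.5


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(make_asv(np.array([[3, 2, 1], [3, 2, 1]])))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = bray_curtis(make_asv(np.array([[5, 0], [0, 7]])))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        d = bray_curtis(make_asv(np.array([[1, 1, 0], [1, 0, 1]])))
        assert d.values[0, 1] == pytest.approx(0.5)  # 1 - 2*1/4


class TestPermanova:
    def dist_for(self, counts, sites):
        return bray_curtis(make_asv(counts, sites=sites))

    def test_minimal_p_under_perfect_separation(self):
        counts = np.array([[50, 0]] * 8 + [[0, 50]] * 8)
        sites = ["X"] * 8 + ["Y"] * 8
        d = self.dist_for(counts, sites)
        f, p = permanova(d, sites, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_f_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(10, 8))
        sites = ["X"] * 5 + ["Y"] * 5
        d = self.dist_for(counts, sites)
        f1, _ = permanova(d, sites, n_perm=49, seed=1)
        perm = rng.permutation(10)
        ids = [d.sample_ids[i] for i in perm]
        d2 = d.subset(ids)
        f2, _ = permanova(d2, [sites[i] for i in perm], n_perm=49, seed=1)
        assert f1 == pytest.approx(f2)

    def test_pseudo_f_matches_skbio(self):
        import skbio
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 40, size=(12, 10))
        sites = ["X"] * 4 + ["Y"] * 4 + ["Z"] * 4
        d = self.dist_for(counts, sites)
        f, _ = permanova(d, sites, n_perm=9, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.sample_ids), sites,
            permutations=9)
        assert f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_single_group_rejected(self):
        d = self.dist_for(np.eye(4, dtype=int) * 10, ["X"] * 4)
        with pytest.raises(ValueError):
            permanova(d, ["X"] * 4)


class TestCap:
    def test_reduces_to_rda_under_euclidean_distance(self):
        # independent classical-RDA oracle on a 10 x 4 toy matrix
        rng = np.random.default_rng(8)
        y_raw = rng.normal(size=(10, 4))
        x_raw = rng.normal(size=(10, 3))
        ids = [f"s{i}" for i in range(10)]
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(ids, squareform(pdist(y_raw)))
        soil = SoilTable(pd.DataFrame(
            x_raw, index=ids, columns=["pH", "EC", "TOC"]).abs() + 1)
        res = cap_ordination(d, soil, ["pH", "EC", "TOC"], n_perm=9, seed=0)

        yc = y_raw - y_raw.mean(axis=0)
        x = soil.table.to_numpy(dtype=float)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        b, *_ = np.linalg.lstsq(x, yc, rcond=None)
        sv = np.linalg.svd(x @ b, compute_uv=False)
        want = sv ** 2 / 9
        want = want[want > 1e-10]
        assert np.allclose(res.eigenvalues, want[: len(res.eigenvalues)],
                           rtol=1e-8)

    def test_axis_count_bounded_by_predictors(self, study):
        from mobnet.community import bray_curtis as bc
        sub = study.asv.subset_samples(study.asv.sample_ids[:30])
        d = bc(sub)
        res = cap_ordination(d, study.soil, ["pH", "EC"], n_perm=9, seed=0)
        assert res.site_scores.shape[1] <= 2
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_null_predictor_not_significant(self):
        # a predictor unrelated to composition keeps p > 0.05 most of the time
        hits = 0
        n_sim = 40
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            counts = rng.integers(0, 40, size=(16, 12))
            asv = make_asv(counts, sites=["X"] * 8 + ["Y"] * 8)
            d = bray_curtis(asv)
            soil = SoilTable(pd.DataFrame(
                {"pH": rng.uniform(6, 8, 16), "EC": rng.uniform(100, 900, 16)},
                index=asv.sample_ids))
            res = cap_ordination(d, soil, ["pH"], n_perm=99, seed=seed)
            if res.permutation_p["pH"] > 0.05:
                hits += 1
        assert hits >= int(0.85 * n_sim)


class TestVifForwardSelect:
    def test_orthogonal_predictors_unit_vif(self):
        x = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0],
                          "c": [1, -1, -1, 1.0]})
        v = vif(x, ["a", "b", "c"])
        assert all(val == pytest.approx(1.0) for val in v.values())

    def test_duplicated_predictor_flagged_infinite(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        v = vif(x, ["a", "b"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_closed_form_at_r_08(self):
        # two predictors with exact correlation 0.8 -> VIF = 1/(1-0.64)
        rng = np.random.default_rng(1)
        a = rng.normal(size=400)
        noise = rng.normal(size=400)
        noise -= noise.mean() + 0.0
        # construct exact sample correlation via orthogonalisation
        a_std = (a - a.mean()) / a.std()
        resid = noise - np.dot(noise, a_std) / np.dot(a_std, a_std) * a_std
        resid /= resid.std()
        b = 0.8 * a_std + np.sqrt(1 - 0.64) * resid
        v = vif(pd.DataFrame({"a": a_std, "b": b}), ["a", "b"])
        assert v["a"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)
        assert v["a"] == pytest.approx(2.7778, abs=1e-3)

    def test_no_signal_selects_nothing(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 40, size=(16, 12))
        asv = make_asv(counts, sites=["X"] * 8 + ["Y"] * 8)
        d = bray_curtis(asv)
        soil = SoilTable(pd.DataFrame(
            {"pH": rng.uniform(6, 8, 16), "EC": rng.uniform(100, 900, 16),
             "TOC": rng.uniform(1, 9, 16)}, index=asv.sample_ids))
        res = forward_select(d, soil, ["pH", "EC", "TOC"], n_perm=99, seed=3)
        assert res["selected"] in ([], ["pH"], ["EC"], ["TOC"]) \
            and len(res["selected"]) <= 1  # at most a chance pick

    def test_true_driver_selected_first(self, study):
        d = bray_curtis(rarefy(filter_low_count(study.asv), seed=0))
        res = forward_select(d, study.soil,
                             ["EC", "pH", "TP", "NH4", "NO3"],
                             n_perm=99, seed=0)
        assert res["selected"][0] in ("EC", "pH")  # the ion axis drives composition
        assert res["p_values"][res["selected"][0]] <= 0.05


class TestGroupCompare:
    def test_identical_groups_share_letter(self):
        res = group_compare([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert len(set(res["letters"].values())) == 1

    def test_widely_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(20, 1, 10)])
        res = group_compare(vals, ["a"] * 10 + ["b"] * 10)
        la, lb = res["letters"]["a"], res["letters"]["b"]
        assert set(la).isdisjoint(set(lb))

    def test_letters_match_studentized_range_oracle(self):
        # independent all-pairs Tukey from the studentized-range distribution
        rng = np.random.default_rng(5)
        groups = (["g1"] * 8 + ["g2"] * 8 + ["g3"] * 8)
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(0.5, 1, 8),
                               rng.normal(4, 1, 8)])
        res = group_compare(vals, groups)

        df = pd.DataFrame({"v": vals, "g": groups})
        k, n = 3, 24
        mse = df.groupby("g")["v"].apply(
            lambda s: ((s - s.mean()) ** 2).sum()).sum() / (n - k)
        sig = {}
        names = ["g1", "g2", "g3"]
        for i in range(3):
            for j in range(i + 1, 3):
                a = df.loc[df["g"] == names[i], "v"]
                b = df.loc[df["g"] == names[j], "v"]
                se = np.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
                q = abs(a.mean() - b.mean()) / se
                p = stats.studentized_range.sf(q, k, n - k)
                sig[(names[i], names[j])] = p < 0.05
        for pair, is_sig in sig.items():
            shared = set(res["letters"][pair[0]]) & set(res["letters"][pair[1]])
            assert (len(shared) == 0) == is_sig


def test_log10_copies_rejects_zero():
    q = pd.DataFrame({"copies_per_g": [1e6, 0.0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="b"):
        log10_copies(q)
    ok = log10_copies(q.iloc[[0]])
    assert ok.iloc[0] == pytest.approx(6.0)


def test_pcoa_lingoes_correction_removes_negative_eigenvalues(study):
    sub = study.asv.subset_samples(study.asv.sample_ids[:20])
    d = bray_curtis(sub)
    coords, eigs = pcoa_coordinates(d)
    assert np.all(eigs > 0)
    assert coords.shape[0] == 20
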