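import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverpopgen.dataset import GenotypeDataset
from riverpopgen.simulate import SimConfig, make_f1s, simulate
from riverpopgen.structure import (AncestryThresholds, classify_ancestry,
                                   mantel_test, pairwise_fst, run_pca)
from tests.conftest import hwe_dataset


def _two_pop_dataset(seed, ne=80, n_loci=400, t=25, n=30):
    cfg = SimConfig(deme_sizes=[ne, ne], n_loci=n_loci, n_generations=t,
                    sampling=[(0, 0, n), (1, 0, n)], seed=seed)
    return simulate(cfg)


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        ds, _ = _two_pop_dataset(1)
        pca = run_pca(ds, 4)
        site = ds.sample_meta["site"].to_numpy()
        s1 = pca.scores[site == "S1", 0]
        s2 = pca.scores[site == "S2", 0]
        pooled_sd = np.sqrt((s1.var() + s2.var()) / 2)
        assert abs(s1.mean() - s2.mean()) > 4 * pooled_sd

    def test_panmictic_population_no_fake_clusters(self, rng):
        hits = 0
        reps = 20
        for i in range(reps):
            ds = hwe_dataset(rng.uniform(0.1, 0.9, 200), 40, rng)
            pca = run_pca(ds, 2)
            half = rng.permutation(40) < 20
            p = stats.ttest_ind(pca.scores[half, 0],
                                pca.scores[~half, 0]).pvalue
            hits += p > 0.01
        assert hits >= int(0.95 * reps)

    def test_duplicated_individual_identical_scores(self, rng):
        ds = hwe_dataset(rng.uniform(0.2, 0.8, 100), 20, rng)
        d = np.vstack([ds.dosages, ds.dosages[[0]]])
        dup = GenotypeDataset(
            dosages=d,
            sample_ids=np.array([f"s{i}" for i in range(20)] + ["dup"],
                                dtype=object),
            locus_meta=None)
        pca = run_pca(dup, 3)
        np.testing.assert_allclose(pca.scores[0], pca.scores[-1], atol=1e-8)

    def test_constant_matrix_rejected(self):
        ds = GenotypeDataset(
            dosages=np.ones((5, 10), dtype=np.int8),
            sample_ids=np.array([f"s{i}" for i in range(5)], dtype=object),
            locus_meta=None)
        with pytest.raises(ValueError, match="constant"):
            run_pca(ds)

    def test_explained_variance_fractions_bounded(self):
        ds, _ = _two_pop_dataset(2)
        pca = run_pca(ds, 5)
        assert pca.explained_variance_ratio.sum() <= 1.0 + 1e-9
        assert (np.diff(pca.explained_variance_ratio) <= 1e-12).all()


class TestAncestryClassification:
    def _build(self, seed, n_f1=6):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(deme_sizes=[80, 200], n_loci=500, n_generations=30,
                        sampling=[(0, 0, 30), (1, 0, 20)], seed=seed)
        ds, _ = simulate(cfg)
        local = ds.dosages[np.asarray(ds.sample_meta.site == "S1")]
        src = ds.dosages[np.asarray(ds.sample_meta.site == "S2")]
        f1 = make_f1s(local, src, n_f1, rng)
        d = np.vstack([local, src, f1])
        ids = ([f"loc{i}" for i in range(len(local))]
               + [f"src{i}" for i in range(len(src))]
               + [f"f1_{i}" for i in range(n_f1)])
        full = GenotypeDataset(
            dosages=d, sample_ids=np.array(ids, dtype=object),
            locus_meta=None)
        return full, ids

    def test_f1s_labelled_admixed(self):
        total_f1 = 0
        correct = 0
        for seed in range(20):
            full, ids = self._build(seed)
            pca = run_pca(full, 3)
            # pick the axis that separates the reference groups
            for axis in range(3):
                try:
                    labels = classify_ancestry(
                        pca, [i for i in ids if i.startswith("src")],
                        [i for i in ids if i.startswith("loc")],
                        AncestryThresholds(axis=axis))
                    break
                except ValueError:
                    continue
            f1_labels = labels[[i for i in ids if i.startswith("f1_")]]
            total_f1 += len(f1_labels)
            correct += (f1_labels == "admixed").sum()
        assert correct / total_f1 >= 0.90

    def test_pure_locals_no_admixed_calls(self):
        full, ids = self._build(99, n_f1=2)
        pca = run_pca(full, 2)
        labels = classify_ancestry(
            pca, [i for i in ids if i.startswith("src")],
            [i for i in ids if i.startswith("loc")],
            AncestryThresholds(axis=0))
        locals_ = labels[[i for i in ids if i.startswith("loc")]]
        assert (locals_ == "local").all()

    def test_orientation_invariance(self):
        full, ids = self._build(7)
        pca = run_pca(full, 2)
        src = [i for i in ids if i.startswith("src")]
        loc = [i for i in ids if i.startswith("loc")]
        labels = classify_ancestry(pca, src, loc, AncestryThresholds(axis=0))
        flipped = pca
        flipped.scores = -pca.scores
        labels2 = classify_ancestry(flipped, src, loc,
                                    AncestryThresholds(axis=0))
        assert (labels == labels2).all()

    def test_overlapping_references_rejected(self, rng):
        ds = hwe_dataset(rng.uniform(0.2, 0.8, 100), 30, rng)
        pca = run_pca(ds, 2)
        ids = list(ds.sample_ids)
        with pytest.raises(ValueError, match="overlap"):
            classify_ancestry(pca, ids[:15], ids[15:],
                              AncestryThresholds(axis=0))


class TestFst:
    def test_single_population_split_near_zero(self, rng):
        ds = hwe_dataset(rng.uniform(0.1, 0.9, 400), 200, rng)
        labels = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
        fst, raw = pairwise_fst(ds, labels)
        assert abs(raw.iloc[0, 1]) < 0.01

    def test_identical_matrices_zero_after_flooring(self, rng):
        d = (rng.random((20, 100)) < 0.4).astype(np.int8) + \
            (rng.random((20, 100)) < 0.4).astype(np.int8)
        ds = GenotypeDataset(
            dosages=np.vstack([d, d]),
            sample_ids=np.array([f"x{i}" for i in range(40)], dtype=object),
            locus_meta=None)
        labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        fst, _ = pairwise_fst(ds, labels)
        assert fst.iloc[0, 1] == 0.0

    def test_drift_closed_form(self):
        """Diverged demes: FST ~ 1 - (1 - 1/(2Ne))^t."""
        ne, t = 60, 20
        vals = []
        for seed in range(6):
            ds, _ = _two_pop_dataset(seed, ne=ne, n_loci=500, t=t, n=40)
            fst, _ = pairwise_fst(ds)
            vals.append(fst.iloc[0, 1])
        expected = 1 - (1 - 1 / (2 * ne)) ** t
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)

    def test_monotone_in_divergence_time(self):
        means = []
        for t in (5, 15, 30):
            vals = [pairwise_fst(_two_pop_dataset(s + 10 * t, ne=50,
                                                  n_loci=300, t=t,
                                                  n=30)[0])[0].iloc[0, 1]
                    for s in range(3)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_symmetry_and_zero_diagonal(self):
        ds, _ = _two_pop_dataset(5)
        fst, _ = pairwise_fst(ds)
        assert np.allclose(fst, fst.T)
        assert np.all(np.diag(fst) == 0)


class TestMantel:
    def test_identity_and_affine(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        res = mantel_test(m, m, n_perm=99, seed=0)
        assert res["r"] == pytest.approx(1.0)
        res2 = mantel_test(m, -m, n_perm=99, seed=0)
        assert res2["r"] == pytest.approx(-1.0)

    def test_agrees_with_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + rng.random((7, 7)) * 0.1
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        ours = mantel_test(a, b, n_perm=999, seed=1)
        theirs_r, theirs_p, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(a), skbio_stats.DistanceMatrix(b),
            method="pearson", permutations=999, alternative="two-sided")
        assert ours["r"] == pytest.approx(float(theirs_r), abs=1e-10)
        assert ours["p"] == pytest.approx(float(theirs_p), abs=0.05)

    def test_null_p_uniform(self, rng):
        pvals = []
        for _ in range(300):
            a = rng.random((7, 7))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.random((7, 7))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            pvals.append(mantel_test(a, b, n_perm=199,
                                     seed=int(rng.integers(2**31)))["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mantel_test(np.zeros((4, 4)), np.zeros((4, 4)))
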