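import numpy as np
import pandas as pd
import pytest

from riverpopgen.dataset import GenotypeDataset
from riverpopgen.kinship import (family_connectivity, family_table,
                                 find_duplicates, pairwise_relatedness,
                                 sib_clusters)


def _beta_freqs(rng, n_loci=1000):
    f = rng.beta(0.5, 0.5, size=n_loci * 3)
    f = f[(f >= 0.05) & (f <= 0.95)]
    return f[:n_loci]


def _hwe(rng, freqs, n):
    return (rng.random((n, len(freqs))) < freqs).astype(np.int8) + \
        (rng.random((n, len(freqs))) < freqs).astype(np.int8)


def _children(rng, pa, pb, n):
    """n full-sib offspring of the two parent genotype rows."""
    a = rng.random((n, len(pa))) < pa / 2.0
    b = rng.random((n, len(pb))) < pb / 2.0
    return a.astype(np.int8) + b.astype(np.int8)


def _pedigree_dataset(rng, n_unrelated=50, fam_sizes=(5,), n_loci=1000):
    freqs = _beta_freqs(rng, n_loci)
    blocks = [_hwe(rng, freqs, n_unrelated)]
    ids = [f"u{i}" for i in range(n_unrelated)]
    for fi, size in enumerate(fam_sizes):
        parents = _hwe(rng, freqs, 2)
        blocks.append(_children(rng, parents[0], parents[1], size))
        ids += [f"f{fi}_{j}" for j in range(size)]
    return GenotypeDataset(
        dosages=np.vstack(blocks),
        sample_ids=np.array(ids, dtype=object),
        locus_meta=None)


class TestPairwiseRelatedness:
    def test_identical_genotypes_zero_mismatch(self, rng):
        freqs = _beta_freqs(rng, 200)
        g = _hwe(rng, freqs, 1)
        ds = GenotypeDataset(
            dosages=np.vstack([g, g]),
            sample_ids=np.array(["a", "b"], dtype=object), locus_meta=None)
        pairs = pairwise_relatedness(ds)
        assert pairs["mismatch_rate"].iloc[0] == 0.0

    def test_full_sibs_near_half_unrelateds_near_zero(self):
        rs_sib, rs_unrel = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = _pedigree_dataset(rng, n_unrelated=40, fam_sizes=(4,))
            pairs = pairwise_relatedness(ds)
            sib = pairs["id_a"].str.startswith("f0") & \
                pairs["id_b"].str.startswith("f0")
            unrel = pairs["id_a"].str.startswith("u") & \
                pairs["id_b"].str.startswith("u")
            rs_sib.append(pairs.loc[sib, "r_hat"].mean())
            rs_unrel.append(pairs.loc[unrel, "r_hat"].mean())
        assert 0.4 <= np.mean(rs_sib) <= 0.6
        assert -0.1 <= np.mean(rs_unrel) <= 0.1

    def test_parent_offspring_near_half(self, rng):
        # family embedded among unrelateds so dataset allele frequencies
        # are not dominated by the relatives themselves
        freqs = _beta_freqs(rng, 1000)
        background = _hwe(rng, freqs, 50)
        parents = _hwe(rng, freqs, 2)
        kids = _children(rng, parents[0], parents[1], 6)
        ids = [f"u{i}" for i in range(50)] + ["p0", "p1"] + \
            [f"k{i}" for i in range(6)]
        ds = GenotypeDataset(
            dosages=np.vstack([background, parents, kids]),
            sample_ids=np.array(ids, dtype=object),
            locus_meta=None)
        pairs = pairwise_relatedness(ds)
        po = pairs[(pairs.id_a.isin(["p0", "p1"]))
                   & pairs.id_b.str.startswith("k")]
        assert 0.4 <= po["r_hat"].mean() <= 0.6

    def test_low_confidence_flag(self, rng):
        freqs = _beta_freqs(rng, 30)
        ds = GenotypeDataset(
            dosages=_hwe(rng, freqs, 3),
            sample_ids=np.array(["a", "b", "c"], dtype=object),
            locus_meta=None)
        pairs = pairwise_relatedness(ds)
        assert pairs["low_confidence"].all()


class TestDuplicates:
    def test_planted_duplicate_with_genotyping_noise_detected(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            freqs = _beta_freqs(rng, 1000)
            g = _hwe(rng, freqs, 20)
            twin = g[0].copy()
            flip = rng.random(1000) < 0.01  # 1% genotyping error
            twin[flip] = rng.integers(0, 3, size=flip.sum())
            ds = GenotypeDataset(
                dosages=np.vstack([g, twin[None, :]]),
                sample_ids=np.array([f"s{i}" for i in range(20)] + ["recap"],
                                    dtype=object),
                locus_meta=None)
            groups = find_duplicates(pairwise_relatedness(ds))
            assert ["recap", "s0"] in [sorted(gr) for gr in groups]
            assert len(groups) == 1

    def test_full_sibs_not_grouped_as_duplicates(self, rng):
        ds = _pedigree_dataset(rng, n_unrelated=10, fam_sizes=(6,))
        groups = find_duplicates(pairwise_relatedness(ds))
        assert groups == []

    def test_empty_pairs(self):
        assert find_duplicates(pd.DataFrame(
            columns=["id_a", "id_b", "mismatch_rate"])) == []


class TestSibClusters:
    def test_planted_family_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ds = _pedigree_dataset(rng, n_unrelated=50, fam_sizes=(5,))
            fams = sib_clusters(pairwise_relatedness(ds))
            planted = [f for f in fams
                       if sum(m.startswith("f0") for m in f.members) >= 4]
            # recovered allowing one missed member, no spurious merging
            if planted and len(planted[0].members) <= 6:
                hits += 1
        assert hits >= 18

    def test_all_unrelateds_no_families(self):
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            ds = _pedigree_dataset(rng, n_unrelated=40, fam_sizes=())
            fams = sib_clusters(pairwise_relatedness(ds))
            clean += len(fams) == 0
        assert clean >= 18

    def test_two_disjoint_families_never_merged(self):
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            ds = _pedigree_dataset(rng, n_unrelated=20, fam_sizes=(4, 4))
            pairs = pairwise_relatedness(ds)
            cross = pairs[pairs.id_a.str.startswith("f0")
                          & pairs.id_b.str.startswith("f1")]
            if (cross["r_hat"] < 0.2).all():
                fams = sib_clusters(pairs)
                for f in fams:
                    tags = {m.split("_")[0] for m in f.members
                            if m.startswith("f")}
                    assert len(tags) <= 1

    def test_order_invariance(self, rng):
        ds = _pedigree_dataset(rng, n_unrelated=20, fam_sizes=(4,))
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        shuffled = ds.subset(sample_selector=perm)
        fams_a = sib_clusters(pairwise_relatedness(ds))
        fams_b = sib_clusters(pairwise_relatedness(shuffled))
        sets_a = sorted(tuple(f.members) for f in fams_a)
        sets_b = sorted(tuple(f.members) for f in fams_b)
        assert sets_a == sets_b


class TestFamilyConnectivity:
    def _meta(self, ids, sites):
        return pd.DataFrame({"sample_id": ids, "site": sites,
                             "cohort": [2020] * len(ids)})

    def test_single_site_families_no_edges(self, rng):
        ds = _pedigree_dataset(rng, n_unrelated=10, fam_sizes=(4,))
        meta = self._meta(list(ds.sample_ids), ["A"] * ds.n_samples)
        fams = sib_clusters(pairwise_relatedness(ds), sample_meta=meta)
        conn = family_connectivity(fams, meta)
        assert len(conn) == 0

    def test_split_family_produces_edge(self, rng):
        ds = _pedigree_dataset(rng, n_unrelated=10, fam_sizes=(4,))
        sites = ["X"] * 10 + ["A", "A", "B", "B"]
        meta = self._meta(list(ds.sample_ids), sites)
        fams = sib_clusters(pairwise_relatedness(ds), sample_meta=meta)
        conn = family_connectivity(fams, meta)
        edge = conn[(conn.site_a == "A") & (conn.site_b == "B")]
        assert len(edge) == 1 and edge["n_families"].iloc[0] == 1

    def test_family_table_shape(self, rng):
        ds = _pedigree_dataset(rng, n_unrelated=10, fam_sizes=(3, 3))
        meta = self._meta(list(ds.sample_ids), ["A"] * ds.n_samples)
        fams = sib_clusters(pairwise_relatedness(ds), sample_meta=meta)
        tab = family_table(fams)
        assert {"family_id", "n", "sites", "cohorts", "members"} <= \
            set(tab.columns)
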