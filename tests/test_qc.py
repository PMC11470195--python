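import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverpopgen.dataset import GenotypeDataset
from riverpopgen.qc import (QcConfig, apply_qc, excess_het_test, ld_decay,
                            thin_by_distance)
from riverpopgen.simulate import simulate_linked_chromosome


@pytest.mark.parametrize("het,called,expect_p,expect_flag", [
    (50, 50, 0.5 ** 50, True),     # every genotype het: p = 0.5^50
    (25, 50, None, False),         # observed rate equals the null rate
    (0, 50, 1.0, False),
])
def test_excess_het_exact_binomial(het, called, expect_p, expect_flag):
    p, flagged = excess_het_test(het, called, alpha=0.05)
    if expect_p is not None:
        assert p == pytest.approx(expect_p, rel=1e-9)
    else:
        assert p > 0.5
    assert flagged is expect_flag


def test_excess_het_rejects_empty():
    with pytest.raises(ValueError):
        excess_het_test(0, 0)


def _toy_qc_dataset():
    """10 loci: 2 fail depth (3x), 1 fails reproducibility (0.90)."""
    rng = np.random.default_rng(5)
    dosages = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
    dosages[:, 0] = [0, 1, 0, 1, 0, 1, 0, 1]  # keep every locus polymorphic
    depth = [10.0] * 10
    depth[2] = depth[5] = 3.0
    repro = [1.0] * 10
    repro[7] = 0.90
    return GenotypeDataset(
        dosages=dosages,
        sample_ids=np.array([f"s{i}" for i in range(8)], dtype=object),
        locus_meta=pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(10)],
            "tag_id": [f"T{i}" for i in range(10)],
            "mean_depth": depth,
            "reproducibility": repro,
        }),
    )


def test_apply_qc_depth_and_reproducibility_hand_count():
    ds = _toy_qc_dataset()
    out, report = apply_qc(ds, QcConfig(), seed=1)
    frame = report.to_frame().set_index("name")
    assert frame.loc["depth", "n_loci_after"] == 8
    assert frame.loc["reproducibility", "n_loci_after"] == 7
    assert set(report.stages[0].dropped_loci) == {"L2", "L5"}
    assert report.stages[1].dropped_loci == ["L7"]


def test_apply_qc_clean_dataset_is_identity(rng):
    from tests.conftest import hwe_dataset
    ds = hwe_dataset(rng.uniform(0.2, 0.5, 40), 30, rng)
    ds.locus_meta["mean_depth"] = 20.0
    ds.locus_meta["reproducibility"] = 1.0
    out, report = apply_qc(ds, QcConfig(), seed=0)
    np.testing.assert_array_equal(out.dosages, ds.dosages)
    assert (report.to_frame()["n_loci_before"] ==
            report.to_frame()["n_loci_after"]).all()


def test_apply_qc_idempotent(rng):
    from tests.conftest import hwe_dataset
    ds = hwe_dataset(rng.uniform(0.1, 0.5, 60), 25, rng)
    ds.locus_meta["tag_id"] = [f"T{i // 2}" for i in range(60)]  # 2 per tag
    ds.locus_meta["mean_depth"] = 20.0
    once, _ = apply_qc(ds, QcConfig(), seed=7)
    twice, rep2 = apply_qc(once, QcConfig(), seed=7)
    np.testing.assert_array_equal(once.dosages, twice.dosages)
    assert list(once.locus_ids) == list(twice.locus_ids)


def test_one_per_tag_deterministic_under_seed(rng):
    from tests.conftest import hwe_dataset
    ds = hwe_dataset(rng.uniform(0.2, 0.5, 30), 20, rng)
    ds.locus_meta["tag_id"] = [f"T{i // 3}" for i in range(30)]
    out1, _ = apply_qc(ds, QcConfig(), seed=11)
    out2, _ = apply_qc(ds, QcConfig(), seed=11)
    assert list(out1.locus_ids) == list(out2.locus_ids)
    assert out1.n_loci == 10  # one SNP per tag
    tags = out1.locus_meta["tag_id"]
    assert tags.is_unique


def test_excess_het_filter_removes_paralog_like_locus(rng):
    from tests.conftest import hwe_dataset
    ds = hwe_dataset(rng.uniform(0.3, 0.5, 20), 60, rng)
    ds.dosages[:, 4] = 1  # every individual heterozygous: paralog signature
    out, report = apply_qc(ds, QcConfig(), seed=0)
    dropped = report.to_frame().set_index("name")
    assert dropped.loc["excess_het", "n_loci_before"] - \
        dropped.loc["excess_het", "n_loci_after"] == 1
    assert "L4" not in list(out.locus_ids)


def test_mac_filter_only_when_configured(rng):
    from tests.conftest import hwe_dataset
    ds = hwe_dataset(np.full(10, 0.3), 30, rng)
    ds.dosages[:, 0] = 0
    ds.dosages[0, 0] = 1            # singleton: MAC = 1
    out_off, _ = apply_qc(ds, QcConfig(mac_min=0), seed=0)
    out_on, _ = apply_qc(ds, QcConfig(mac_min=2), seed=0)
    assert "L0" in list(out_off.locus_ids)
    assert "L0" not in list(out_on.locus_ids)


# ------------------------------------------------------------------ thinning

def _placed_dataset(positions, chroms, rng):
    n = len(positions)
    d = (rng.random((12, n)) < 0.4).astype(np.int8) + \
        (rng.random((12, n)) < 0.4).astype(np.int8)
    return GenotypeDataset(
        dosages=d,
        sample_ids=np.array([f"s{i}" for i in range(12)], dtype=object),
        locus_meta=pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(n)],
            "chrom": chroms, "pos": positions,
        }),
    )


def test_thin_window_partition_hand_example(rng):
    ds = _placed_dataset([1_000, 10_000, 49_000, 60_000, 120_000],
                         ["1"] * 5, rng)
    out = thin_by_distance(ds, window_bp=50_000, seed=3)
    # windows [0,50k), [50k,100k), [100k,150k) -> exactly one each
    assert out.n_loci == 3
    wins = (out.locus_meta["pos"] // 50_000).tolist()
    assert wins == [0, 1, 2]


def test_thin_distinct_chromosomes_identity(rng):
    ds = _placed_dataset([5_000] * 6, [f"c{i}" for i in range(6)], rng)
    out = thin_by_distance(ds, window_bp=50_000, seed=0)
    assert out.n_loci == 6


def test_thin_removes_unplaced_and_is_deterministic(rng):
    ds = _placed_dataset([1_000, 2_000, 3_000, None, None],
                         ["1", "1", "1", None, None], rng)
    a = thin_by_distance(ds, window_bp=50_000, seed=9)
    b = thin_by_distance(ds, window_bp=50_000, seed=9)
    assert a.n_loci == 1
    assert list(a.locus_ids) == list(b.locus_ids)


# ------------------------------------------------------------------ LD decay

def test_ld_decay_monotone_on_recombining_chromosome(rng):
    positions = np.arange(60) * 2_000 + 1  # 60 loci over 120 kb
    dos = simulate_linked_chromosome(80, positions, n_generations=30,
                                     recomb_scale_bp=25_000, seed=4)
    # add an unlinked chromosome for the background estimate
    extra = (rng.random((80, 30)) < 0.4).astype(np.int8) + \
        (rng.random((80, 30)) < 0.4).astype(np.int8)
    d = np.hstack([dos, extra])
    ds = GenotypeDataset(
        dosages=d,
        sample_ids=np.array([f"s{i}" for i in range(80)], dtype=object),
        locus_meta=pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(d.shape[1])],
            "chrom": ["1"] * 60 + ["2"] * 30,
            "pos": list(positions) + list(
                range(1_000_000, 1_000_000 + 30 * 20_000, 20_000)),
        }),
    )
    tab = ld_decay(ds, max_dist_bp=120_000, bin_bp=20_000, seed=0)
    # rank test: mean r2 decreases across distance bins
    rho = stats.spearmanr(tab["bin"], tab["mean_r2"]).statistic
    assert rho < 0
    assert tab["mean_r2"].iloc[0] > tab["mean_r2"].iloc[-1]
    assert np.isfinite(tab.attrs["background_r2"])
    # closest bin carries physical LD well above the cross-chromosome level
    assert tab["mean_r2"].iloc[0] > 2 * tab.attrs["background_r2"]


def test_ld_decay_duplicate_locus_bin_zero(rng):
    base = (rng.random(40) < 0.5).astype(np.int8) + \
        (rng.random(40) < 0.5).astype(np.int8)
    other = (rng.random((40, 10)) < 0.4).astype(np.int8) + \
        (rng.random((40, 10)) < 0.4).astype(np.int8)
    d = np.column_stack([base, base, other])
    ds = GenotypeDataset(
        dosages=d,
        sample_ids=np.array([f"s{i}" for i in range(40)], dtype=object),
        locus_meta=pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(12)],
            "chrom": ["1", "1"] + ["2"] * 10,
            # distant spacing keeps the duplicate pair alone in bin 0
            "pos": [500, 600] + list(range(100_000, 1_100_000, 100_000)),
        }),
    )
    tab = ld_decay(ds, max_dist_bp=1_200_000, bin_bp=1_000, seed=0)
    # a locus perfectly correlated with itself: r2 near 1 (sampling deviation
    # from exact HWE proportions only)
    assert tab["mean_r2"].iloc[0] > 0.9
    assert tab["n_pairs"].iloc[0] == 1


def test_ld_decay_requires_placed_loci(rng):
    from tests.conftest import hwe_dataset
    ds = hwe_dataset(np.full(5, 0.4), 10, rng)
    with pytest.raises(ValueError):
        ld_decay(ds)
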