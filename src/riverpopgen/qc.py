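"""Locus/individual QC filtering chain and physical-linkage thinning.

The chain mirrors standard reduced-representation SNP curation: mean read
depth window, technical reproducibility, locus and individual missingness,
an exact-binomial excess-heterozygosity screen (paralog artefacts), one SNP
per sequencing tag, and an optional minor-allele-count floor. Stages run in
that fixed order and the whole chain is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MISSING, GenotypeDataset


@dataclass
class QcConfig:
    depth_min: float = 6.0
    depth_max: float = 50.0
    reproducibility_min: float = 0.95
    locus_missing_max: float = 0.10
    individual_missing_max: float = 0.20
    excess_het_alpha: float = 0.05
    excess_het_correction: str = "bonferroni"  # or "fdr"
    one_per_tag: bool = True
    thin_window_bp: int = 50_000
    mac_min: int = 0  # 2 for sibship subsets

    def __post_init__(self):
        if not (0 <= self.locus_missing_max <= 1 and
                0 <= self.individual_missing_max <= 1 and
                0 <= self.reproducibility_min <= 1):
            raise ValueError("rate thresholds must lie in [0, 1]")
        if self.depth_min >= self.depth_max:
            raise ValueError("depth_min must be < depth_max")
        if self.excess_het_correction not in ("bonferroni", "fdr"):
            raise ValueError("excess_het_correction must be bonferroni or fdr")


@dataclass
class FilterStage:
    name: str
    n_loci_before: int
    n_loci_after: int
    n_samples_before: int
    n_samples_after: int
    dropped_loci: list = field(default_factory=list)
    dropped_samples: list = field(default_factory=list)


@dataclass
class FilterReport:
    stages: list = field(default_factory=list)
    seed: int | None = None

    def add(self, stage: FilterStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            assert stage.n_loci_before == prev.n_loci_after
            assert stage.n_samples_before == prev.n_samples_after
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {k: v for k, v in asdict(s).items()
             if k not in ("dropped_loci", "dropped_samples")}
            for s in self.stages
        ])

    def to_dict(self) -> dict:
        return {"seed": self.seed, "stages": [asdict(s) for s in self.stages]}


class AllLociRemovedError(RuntimeError):
    def __init__(self, report: FilterReport):
        super().__init__("QC removed every locus; see attached report")
        self.report = report


def excess_het_test(het_count: int, called_count: int, alpha: float = 0.05):
    """One-sided exact binomial test of heterozygote excess over rate 0.5.

    Returns ``(p_value, flagged)`` where ``flagged`` uses the raw per-test
    threshold ``alpha`` (multiple-testing correction is applied by
    :func:`apply_qc` across the tested loci).
    """
    if called_count < 1:
        raise ValueError("called_count must be >= 1")
    if not 0 <= het_count <= called_count:
        raise ValueError("need 0 <= het_count <= called_count")
    p = stats.binomtest(het_count, called_count, 0.5,
                        alternative="greater").pvalue
    return float(p), bool(p < alpha)


def _excess_het_pvalues(ds: GenotypeDataset) -> np.ndarray:
    called = ds.called_mask()
    n = called.sum(axis=0)
    het = (ds.dosages == 1).sum(axis=0)
    # P(X >= het) for X ~ Binomial(n, 0.5): exact survival function
    p = stats.binom.sf(het - 1, np.maximum(n, 1), 0.5)
    p[n == 0] = 1.0
    return p


def apply_qc(ds: GenotypeDataset, cfg: QcConfig | None = None,
             seed: int = 0):
    """Run the fixed-order filter chain; returns ``(dataset, FilterReport)``.

    Order: depth -> reproducibility -> locus missingness -> individual
    missingness -> excess heterozygosity -> one SNP per tag -> MAC floor.
    Deterministic under a fixed seed (the only randomness is the choice of
    SNP within a tag).
    """
    cfg = cfg or QcConfig()
    rng = np.random.default_rng(seed)
    report = FilterReport(seed=seed)
    cur = ds

    def stage(name, keep_loci=None, keep_samples=None):
        nonlocal cur
        nl0, ns0 = cur.n_loci, cur.n_samples
        dropped_l, dropped_s = [], []
        if keep_loci is not None and not keep_loci.all():
            dropped_l = list(cur.locus_ids[~keep_loci])
            if not keep_loci.any():
                report.add(FilterStage(name, nl0, 0, ns0, ns0, dropped_l, []))
                raise AllLociRemovedError(report)
            cur = cur.subset(locus_selector=keep_loci)
        if keep_samples is not None and not keep_samples.all():
            dropped_s = list(cur.sample_ids[~keep_samples])
            cur = cur.subset(sample_selector=keep_samples)
        report.add(FilterStage(name, nl0, cur.n_loci, ns0, cur.n_samples,
                               dropped_l, dropped_s))

    depth = cur.locus_meta["mean_depth"].to_numpy(dtype=float)
    keep = np.where(np.isnan(depth), True,
                    (depth >= cfg.depth_min) & (depth <= cfg.depth_max))
    stage("depth", keep_loci=keep)

    repro = cur.locus_meta["reproducibility"].to_numpy(dtype=float)
    keep = np.where(np.isnan(repro), True, repro >= cfg.reproducibility_min)
    stage("reproducibility", keep_loci=keep)

    miss_loc = (cur.dosages == MISSING).mean(axis=0)
    stage("locus_missingness", keep_loci=miss_loc <= cfg.locus_missing_max)

    miss_ind = (cur.dosages == MISSING).mean(axis=1)
    stage("individual_missingness",
          keep_samples=miss_ind <= cfg.individual_missing_max)

    p = _excess_het_pvalues(cur)
    m = cur.n_loci
    if cfg.excess_het_correction == "bonferroni":
        flagged = p < cfg.excess_het_alpha / m
    else:
        from statsmodels.stats.multitest import multipletests
        flagged = multipletests(p, alpha=cfg.excess_het_alpha,
                                method="fdr_bh")[0]
    stage("excess_het", keep_loci=~flagged)

    if cfg.one_per_tag:
        tags = cur.locus_meta["tag_id"].to_numpy(dtype=object)
        keep = np.zeros(cur.n_loci, dtype=bool)
        # stable iteration over tags in order of first appearance
        order: dict = {}
        for i, t in enumerate(tags):
            order.setdefault(t, []).append(i)
        for t, idx in order.items():
            keep[idx[int(rng.integers(len(idx)))] if len(idx) > 1 else idx[0]] = True
        stage("one_per_tag", keep_loci=keep)
    else:
        stage("one_per_tag", keep_loci=np.ones(cur.n_loci, dtype=bool))

    if cfg.mac_min > 0:
        called = cur.called_mask()
        alt = np.where(called, cur.dosages, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        mac = np.minimum(alt, total - alt)
        stage("mac", keep_loci=mac >= cfg.mac_min)
    else:
        stage("mac", keep_loci=np.ones(cur.n_loci, dtype=bool))

    cur = cur.copy()
    cur.log(f"apply_qc: {ds.n_loci}->{cur.n_loci} loci, "
            f"{ds.n_samples}->{cur.n_samples} samples (seed={seed})")
    return cur, report


# ----------------------------------------------------------------- LD decay

def ld_decay(ds: GenotypeDataset, max_dist_bp: int = 500_000,
             bin_bp: int = 10_000, n_background_pairs: int = 1000,
             seed: int = 0) -> pd.DataFrame:
    """Mean composite-LD r2 by physical distance bin, plus a background level.

    For every same-chromosome locus pair within ``max_dist_bp``, r2 is the
    Burrows composite correlation (same statistic the Ne estimator uses),
    binned by pair distance. The background is the mean r2 of a random sample
    of cross-chromosome pairs. Returns a tidy frame with one row per bin and
    one ``background`` row.
    """
    from .ldne import pair_r2_matrix

    meta = ds.locus_meta
    placed = meta["pos"].notna() & meta["chrom"].notna()
    if placed.sum() < 2:
        raise ValueError("need at least 2 placed loci for LD decay")
    sub = ds.subset(locus_selector=placed.to_numpy())
    chrom = sub.locus_meta["chrom"].to_numpy(dtype=object)
    pos = sub.locus_meta["pos"].to_numpy(dtype=float)

    r2, s_pair = pair_r2_matrix(sub.dosages)
    iu, ju = np.triu_indices(sub.n_loci, k=1)
    same = chrom[iu] == chrom[ju]
    dist = np.abs(pos[iu] - pos[ju])
    ok = np.isfinite(r2[iu, ju])

    cis = same & (dist <= max_dist_bp) & ok
    bins = (dist[cis] // bin_bp).astype(int)
    frame = pd.DataFrame({"bin": bins, "r2": r2[iu, ju][cis]})
    out = frame.groupby("bin")["r2"].agg(["mean", "count"]).reset_index()
    out["dist_bp_low"] = out["bin"] * bin_bp
    out["dist_bp_high"] = (out["bin"] + 1) * bin_bp
    out = out.rename(columns={"mean": "mean_r2", "count": "n_pairs"})

    cross_idx = np.flatnonzero(~same & ok)
    rng = np.random.default_rng(seed)
    if len(cross_idx):
        take = rng.choice(cross_idx,
                          size=min(n_background_pairs, len(cross_idx)),
                          replace=False)
        background = float(np.mean(r2[iu, ju][take]))
        n_bg = len(take)
    else:
        background = np.nan
        n_bg = 0
    out.attrs["background_r2"] = background
    out.attrs["n_background_pairs"] = n_bg
    return out


def thin_by_distance(ds: GenotypeDataset, window_bp: int = 50_000,
                     seed: int = 0) -> GenotypeDataset:
    """Keep one random locus per non-overlapping window per chromosome.

    Windows are anchored at position 0; unplaced loci are removed first.
    Deterministic under a fixed seed.
    """
    meta = ds.locus_meta
    placed = (meta["pos"].notna() & meta["chrom"].notna()).to_numpy()
    if not placed.any():
        raise ValueError("no placed loci to thin")
    sub = ds.subset(locus_selector=placed)
    chrom = sub.locus_meta["chrom"].to_numpy(dtype=object)
    win = (sub.locus_meta["pos"].to_numpy(dtype=float) // window_bp).astype(int)
    rng = np.random.default_rng(seed)
    keep = np.zeros(sub.n_loci, dtype=bool)
    groups: dict = {}
    for i, key in enumerate(zip(chrom, win)):
        groups.setdefault(key, []).append(i)
    for key in sorted(groups, key=lambda k: (str(k[0]), k[1])):
        idx = groups[key]
        keep[idx[int(rng.integers(len(idx)))] if len(idx) > 1 else idx[0]] = True
    out = sub.subset(locus_selector=keep)
    out.log(f"thin_by_distance: window={window_bp}bp, "
            f"{ds.n_loci}->{out.n_loci} loci (seed={seed})")
    return out
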