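"""Population structure: PCA, ancestry classification, FST, isolation-by-distance.

PCA runs on mean-imputed, column-centred dosages (the standard shortcut for
principal-coordinate analysis of SNP genotypes); component signs are fixed
so results are deterministic. Ancestry calls (local / source / admixed) use
one PC axis anchored by reference individuals of each parental population.
Pairwise FST is the Weir–Cockerham (1984) two-level estimator with
ratio-of-sums averaging across loci. Isolation-by-distance uses a seeded
Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass
class PcaResult:
    scores: np.ndarray            # individuals x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray          # loci x components
    sample_ids: np.ndarray

    def plot(self, components=(0, 1), labels=None, ax=None):
        """Scatter of two components, optionally coloured by group labels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i, j = components
        if labels is None:
            ax.scatter(self.scores[:, i], self.scores[:, j], s=14)
        else:
            labels = np.asarray(labels, dtype=object)
            for lab in pd.unique(labels):
                sel = labels == lab
                ax.scatter(self.scores[sel, i], self.scores[sel, j],
                           s=14, label=str(lab))
            ax.legend(fontsize=8)
        evr = self.explained_variance_ratio
        ax.set_xlabel(f"PC{i + 1} ({100 * evr[i]:.1f}%)")
        ax.set_ylabel(f"PC{j + 1} ({100 * evr[j]:.1f}%)")
        return ax


@dataclass
class AncestryThresholds:
    axis: int = 1
    source_cutoff: float | None = None   # derived from references when None
    local_cutoff: float | None = None
    band_fraction: float = 0.5           # central band of the reference gap


def run_pca(ds: GenotypeDataset, n_components: int = 10) -> PcaResult:
    """PCA of mean-imputed centred dosages via SVD, deterministic up to sign.

    Signs are fixed by making each component's largest-magnitude loading
    positive.
    """
    if ds.n_samples < 2 or ds.n_loci < 2:
        raise ValueError("need >= 2 individuals and >= 2 loci")
    x = ds.dosages.astype(float)
    called = x != MISSING
    with np.errstate(invalid="ignore"):
        col_mean = np.where(called, x, np.nan)
        col_mean = np.nanmean(col_mean, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(called, x, col_mean[None, :]) - col_mean[None, :]
    if not np.any(x):
        raise ValueError("constant genotype matrix; PCA undefined")
    k = min(n_components, ds.n_samples - 1, ds.n_loci)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    total_var = np.sum(s**2)
    return PcaResult(scores=scores,
                     explained_variance_ratio=s[:k] ** 2 / total_var,
                     loadings=vt[:k].T,
                     sample_ids=ds.sample_ids.copy())


def classify_ancestry(pca: PcaResult, source_ids, local_ids,
                      thr: AncestryThresholds | None = None) -> pd.Series:
    """Label each sample local / source / admixed from one PC axis.

    The axis is oriented so the source reference mean is below the local
    reference mean; default cutoffs delimit the central ``band_fraction`` of
    the gap between reference means. Reference groups overlapping on the
    axis raise (choose another axis or explicit thresholds).
    """
    thr = thr or AncestryThresholds()
    idx = {s: i for i, s in enumerate(pca.sample_ids)}
    si = [idx[s] for s in source_ids]
    li = [idx[s] for s in local_ids]
    if not si or not li:
        raise ValueError("need reference individuals for both parental groups")
    axis_scores = pca.scores[:, thr.axis].astype(float).copy()
    m_s, m_l = axis_scores[si].mean(), axis_scores[li].mean()
    if m_s > m_l:  # orient: source below local
        axis_scores = -axis_scores
        m_s, m_l = -m_s, -m_l
    if np.max(axis_scores[si]) >= np.min(axis_scores[li]):
        raise ValueError(
            "reference groups overlap on this axis; pick a different axis "
            "or supply explicit thresholds")
    if thr.source_cutoff is None or thr.local_cutoff is None:
        mid = 0.5 * (m_s + m_l)
        half = 0.5 * thr.band_fraction * (m_l - m_s)
        source_cutoff, local_cutoff = mid - half, mid + half
    else:
        source_cutoff, local_cutoff = thr.source_cutoff, thr.local_cutoff
        if source_cutoff >= local_cutoff:
            raise ValueError("source_cutoff must be < local_cutoff")
    labels = np.where(axis_scores <= source_cutoff, "source",
                      np.where(axis_scores >= local_cutoff, "local",
                               "admixed"))
    return pd.Series(labels, index=pca.sample_ids, name="ancestry")


# ------------------------------------------------------------------- FST

def _wc_components(ds: GenotypeDataset, rows_a, rows_b):
    """Per-locus Weir–Cockerham variance components for two populations."""
    comps = []
    for rows in (rows_a, rows_b):
        d = ds.dosages[rows]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2 * n),
                         np.nan)
            h = np.where(n > 0, (d == 1).sum(axis=0) / n, np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    n1, p1, h1 = n1[ok], p1[ok], h1[ok]
    n2, p2, h2 = n2[ok], p2[ok], h2[ok]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                               - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[good], b[good], c[good]


def pairwise_fst(ds: GenotypeDataset, site_labels=None,
                 floor_at_zero: bool = True):
    """Weir–Cockerham pairwise FST matrix over sites (ratio of sums).

    ``site_labels``: per-sample labels (defaults to ``sample_meta['site']``).
    Returns ``(fst_df, raw_df)``: the reported matrix (negatives floored at
    0) and the raw estimates. Sites with < 2 samples are excluded.
    """
    if site_labels is None:
        site_labels = ds.sample_meta["site"]
    labels = pd.Series(np.asarray(site_labels, dtype=object))
    sites = [s for s in labels.dropna().unique()
             if (labels == s).sum() >= 2]
    if len(sites) < 2:
        raise ValueError("need >= 2 sites with >= 2 individuals")
    k = len(sites)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ra = np.flatnonzero(labels == sites[i])
            rb = np.flatnonzero(labels == sites[j])
            a, b, c = _wc_components(ds, ra, rb)
            denom = np.sum(a + b + c)
            raw[i, j] = raw[j, i] = np.sum(a) / denom if denom > 0 else 0.0
    rep = np.maximum(raw, 0.0) if floor_at_zero else raw
    fst_df = pd.DataFrame(rep, index=sites, columns=sites)
    raw_df = pd.DataFrame(raw, index=sites, columns=sites)
    return fst_df, raw_df


# ------------------------------------------------------------------ Mantel

def mantel_test(m1, m2, n_perm: int = 999, seed: int = 0) -> dict:
    """Mantel correlation between two symmetric distance matrices.

    r is the Pearson correlation of the upper triangles; p is the two-sided
    permutation p-value ``(#{|r*| >= |r|} + 1) / (n_perm + 1)`` with rows and
    columns of the second matrix permuted jointly (seeded).
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    iu = np.triu_indices(a.shape[0], k=1)
    va = a[iu]
    if np.ptp(va) == 0 or np.ptp(b[iu]) == 0:
        raise ValueError("constant distance matrix; correlation undefined")
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    n = a.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vb = b[np.ix_(perm, perm)][iu]
        if np.ptp(vb) == 0:
            continue
        if abs(np.corrcoef(va, vb)[0, 1]) >= abs(r_obs) - 1e-12:
            count += 1
    return {"r": r_obs, "p": (count + 1) / (n_perm + 1), "n_perm": n_perm}
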