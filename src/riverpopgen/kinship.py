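"""Pairwise relatedness, duplicate detection, and full-sib family clustering.

Relatedness is the symmetrised Queller–Goodnight moment estimator computed
from dataset allele frequencies (expected ~0.5 for full sibs and
parent-offspring, ~0 for unrelateds). Identity (recapture) detection and
full-sib clustering are threshold graphs over the pair list: components of
near-identical genotypes are recapture groups; single-linkage components of
high-relatedness edges are full-sib-like families, summarised with the sites
and cohorts they span as connectivity evidence.

This is a deliberately simple surrogate for full-likelihood sibship
reconstruction: it supports the same downstream connectivity summaries and
is validated by pedigree simulation, but does not model genotyping error
likelihoods, polygamy or half-sib structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

#: pairs with fewer jointly called loci than this are flagged low-confidence
MIN_CONFIDENT_LOCI = 50


@dataclass
class SibFamily:
    family_id: int
    members: list
    sites: list = field(default_factory=list)
    cohorts: list = field(default_factory=list)


def pairwise_relatedness(ds: GenotypeDataset) -> pd.DataFrame:
    """Queller–Goodnight relatedness and genotype mismatch for all pairs.

    Returns a frame with ``id_a, id_b, r_hat, mismatch_rate, n_joint,
    low_confidence``. Allele frequencies come from the full dataset
    (relatives included; the small resulting bias is acceptable at the
    validation tolerances). Monomorphic loci carry no information and are
    dropped.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 individuals")
    freq = ds.allele_freq()
    poly = np.isfinite(freq) & (freq > 0) & (freq < 1)
    d = ds.dosages[:, poly].astype(np.float64)
    p = freq[poly]
    called = d != MISSING
    g0 = np.where(called, d, 0.0)          # dosage, 0 where missing
    h0 = np.where(called, 2.0 - d, 0.0)    # ref-allele count, 0 where missing
    m = called.astype(np.float64)

    # similarity: 0.5 * (gx*gy + (2-gx)(2-gy)) summed over joint loci
    sim = 0.5 * (g0 @ g0.T + h0 @ h0.T)
    # per-individual per-locus allele-frequency sum and QG denominator term
    af_sum = g0 * p[None, :] + h0 * (1.0 - p[None, :])
    hom = np.where(called, (d != 1).astype(float), 0.0)
    den_term = m + hom - af_sum            # (1 + I_homozygous - sum p_alleles)
    # numerator/denominator of r_{x|y}: sums restricted to joint loci
    num_xy = sim - af_sum @ m.T            # [x, y]
    den_xy = den_term @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r_dir = num_xy / den_xy
    r_sym = 0.5 * (r_dir + r_dir.T)

    n_joint = (m @ m.T).astype(int)
    matches = np.zeros_like(sim)
    for val in (0, 1, 2):
        ind = np.where(called & (d == val), 1.0, 0.0)
        matches += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mismatch = np.where(n_joint > 0, 1.0 - matches / n_joint, np.nan)

    iu, ju = np.triu_indices(ds.n_samples, k=1)
    return pd.DataFrame({
        "id_a": ds.sample_ids[iu], "id_b": ds.sample_ids[ju],
        "r_hat": r_sym[iu, ju], "mismatch_rate": mismatch[iu, ju],
        "n_joint": n_joint[iu, ju],
        "low_confidence": n_joint[iu, ju] < MIN_CONFIDENT_LOCI,
    })


def find_duplicates(pairs: pd.DataFrame,
                    mismatch_max: float = 0.02) -> list:
    """Recapture groups: components of pairs with mismatch <= threshold."""
    g = nx.Graph()
    if len(pairs):
        hits = pairs[pairs["mismatch_rate"] <= mismatch_max]
        g.add_edges_from(zip(hits["id_a"], hits["id_b"]))
    return sorted((sorted(c) for c in nx.connected_components(g)
                   if len(c) >= 2), key=lambda c: c[0])


def sib_clusters(pairs: pd.DataFrame, r_min: float = 0.35,
                 sample_meta: pd.DataFrame | None = None) -> list:
    """Single-linkage full-sib-like families from high-relatedness edges.

    Assumes recaptures are already collapsed. Families are connected
    components of edges with ``r_hat >= r_min``; output order is
    deterministic (sorted by first member id) so results are invariant to
    sample order.
    """
    g = nx.Graph()
    if len(pairs):
        hits = pairs[pairs["r_hat"] >= r_min]
        g.add_edges_from(zip(hits["id_a"], hits["id_b"]))
    comps = sorted((sorted(c) for c in nx.connected_components(g)
                    if len(c) >= 2), key=lambda c: c[0])
    meta_idx = None
    if sample_meta is not None:
        meta_idx = sample_meta.set_index("sample_id")
    fams = []
    for i, members in enumerate(comps, start=1):
        sites, cohorts = [], []
        if meta_idx is not None:
            rows = meta_idx.loc[[m for m in members if m in meta_idx.index]]
            sites = sorted(set(rows["site"].dropna()), key=str)
            # cohorts mix birth years with the pooled "adult" sentinel
            cohorts = sorted(set(rows["cohort"].dropna()), key=str)
        fams.append(SibFamily(family_id=i, members=members, sites=sites,
                              cohorts=cohorts))
    return fams


def family_table(families: list) -> pd.DataFrame:
    """Families with member counts per site and per cohort (one row each)."""
    rows = []
    for f in families:
        rows.append({"family_id": f.family_id, "n": len(f.members),
                     "sites": ";".join(map(str, f.sites)),
                     "cohorts": ";".join(map(str, f.cohorts)),
                     "members": ";".join(f.members)})
    return pd.DataFrame(rows)


def family_connectivity(families: list,
                        sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Cross-site connectivity evidence: families spanning each site pair."""
    meta = sample_meta.set_index("sample_id")
    edge_counts: dict = {}
    for f in families:
        rows = meta.loc[[m for m in f.members if m in meta.index]]
        sites = sorted(set(rows["site"].dropna()), key=str)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                key = (sites[i], sites[j])
                edge_counts.setdefault(key, {"n_families": 0, "families": []})
                edge_counts[key]["n_families"] += 1
                edge_counts[key]["families"].append(f.family_id)
    rows = [{"site_a": a, "site_b": b, "n_families": v["n_families"],
             "families": ";".join(map(str, v["families"]))}
            for (a, b), v in sorted(edge_counts.items())]
    return pd.DataFrame(rows,
                        columns=["site_a", "site_b", "n_families", "families"])
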