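"""Heterozygosity, FIS, effective inbreeding, and the diversity regressions.

Individual diversity is PHt, the proportion of an individual's called loci
that are heterozygous. Population summaries report per-locus observed (Ho)
and expected (He = 2p(1-p)) heterozygosity averaged over an explicit locus
panel so that groups are comparable. Effective inbreeding of a focal group
relative to an outbred reference is Fe = 1 - He_focal / He_reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dataset import MISSING, GenotypeDataset


@dataclass
class DiversitySummary:
    group: str
    n: int
    ho: float
    sd_ho: float
    he: float
    sd_he: float
    fis: float
    sd_fis: float

    def to_row(self) -> dict:
        return {"group": self.group, "n": self.n, "Ho": self.ho,
                "SD_Ho": self.sd_ho, "He": self.he, "SD_He": self.sd_he,
                "FIS": self.fis, "SD_FIS": self.sd_fis}


def individual_pht(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-individual heterozygosity: count(dosage==1) / count(called).

    Returns a frame with ``sample_id, pht, n_called``; individuals with zero
    called loci get NaN pht (with a warning).
    """
    if ds.n_samples == 0 or ds.n_loci == 0:
        raise ValueError("dataset is empty")
    called = ds.called_mask()
    n_called = called.sum(axis=1)
    het = (ds.dosages == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pht = np.where(n_called > 0, het / n_called, np.nan)
    if (n_called == 0).any():
        warnings.warn(
            f"{int((n_called == 0).sum())} individual(s) with zero called "
            "loci; PHt set to NaN", stacklevel=2)
    return pd.DataFrame({"sample_id": ds.sample_ids, "pht": pht,
                         "n_called": n_called})


def per_locus_heterozygosity(ds: GenotypeDataset, rows=None):
    """Per-locus (ho, he, fis) among called genotypes in the selected rows.

    ``fis = 1 - ho/he`` where ``he > 0``, NaN otherwise.
    """
    d = ds.dosages if rows is None else ds.dosages[rows]
    called = d != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, (d == 1).sum(axis=0) / n, np.nan)
        p = np.where(n > 0,
                     np.where(called, d, 0).sum(axis=0) / (2.0 * n), np.nan)
        he = 2.0 * p * (1.0 - p)
        fis = np.where(he > 0, 1.0 - ho / he, np.nan)
    return ho, he, fis


def pop_heterozygosity(ds: GenotypeDataset, group=None, label: str = "all",
                       panel=None) -> DiversitySummary:
    """Mean/SD of per-locus Ho, He, FIS for a group on a fixed locus panel.

    ``panel`` is a locus selector (ids or mask); supplying the same panel to
    every group keeps summaries comparable. FIS is summarised as the mean of
    per-locus ``1 - ho/he`` over loci with ``he > 0``.
    """
    sub = ds if group is None else ds.subset(sample_selector=group)
    if panel is not None:
        sub = sub.subset(locus_selector=panel)
    if sub.n_samples < 2:
        raise ValueError(f"group {label!r}: need >= 2 individuals")
    ho, he, fis = per_locus_heterozygosity(sub)
    ok = ~np.isnan(ho)
    fis_ok = ~np.isnan(fis)
    return DiversitySummary(
        group=label, n=sub.n_samples,
        ho=float(np.mean(ho[ok])), sd_ho=float(np.std(ho[ok], ddof=1)),
        he=float(np.mean(he[ok])), sd_he=float(np.std(he[ok], ddof=1)),
        fis=float(np.mean(fis[fis_ok])) if fis_ok.any() else np.nan,
        sd_fis=float(np.std(fis[fis_ok], ddof=1)) if fis_ok.sum() > 1 else np.nan,
    )


def diversity_table(ds: GenotypeDataset, groupings: dict,
                    panel=None) -> pd.DataFrame:
    """Diversity summaries for several named groups on one shared panel."""
    return pd.DataFrame([
        pop_heterozygosity(ds, group=sel, label=label, panel=panel).to_row()
        for label, sel in groupings.items()
    ])


def effective_inbreeding(he_inbred: float, he_outbred: float) -> float:
    """Fe = 1 - He_inbred / He_outbred (relative to an outbred reference).

    May be negative when the focal group is more diverse than the reference;
    returned as-is with a warning.
    """
    if he_outbred <= 0:
        raise ValueError("He_outbred must be > 0")
    fe = 1.0 - he_inbred / he_outbred
    if fe < 0:
        warnings.warn("He_inbred exceeds He_outbred; Fe is negative",
                      stacklevel=2)
    return fe


def het_distance_model(pht: pd.DataFrame, river_km) -> dict:
    """OLS of individual PHt on river distance (km from the upstream site).

    ``river_km`` may be a per-sample series aligned with ``pht`` rows.
    Returns slope, intercept, p_value (t-test on slope), and r2.
    """
    y = np.asarray(pht["pht"] if isinstance(pht, pd.DataFrame) else pht,
                   dtype=float)
    x = np.asarray(river_km, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need >= 3 samples with both PHt and river_km")
    if np.ptp(x) == 0:
        raise ValueError("river_km is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {"slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "p_value": float(model.pvalues[1]),
            "r2": float(model.rsquared),
            "model": model}


def group_anova(values, factors: pd.DataFrame, interaction: bool = False,
                tukey: bool = True) -> dict:
    """Fixed-effects ANOVA of ``values`` on one or two categorical factors.

    Returns the ANOVA table, fitted models for the nested ladder (each factor
    alone, both, optionally with interaction) with pairwise nested F-tests,
    and Tukey HSD pairwise comparisons per factor.
    """
    factors = pd.DataFrame(factors).reset_index(drop=True)
    names = list(factors.columns)
    if not 1 <= len(names) <= 2:
        raise ValueError("one or two factors supported")
    data = factors.copy()
    data["y"] = np.asarray(values, dtype=float)
    data = data.dropna()
    for f in names:
        counts = data[f].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError(f"factor {f!r}: need >= 2 groups with >= 2 members")

    terms = [f"C({f})" for f in names]
    models = {}
    for f, t in zip(names, terms):
        models[f] = smf.ols(f"y ~ {t}", data=data).fit()
    fitted = models[names[0]]
    if len(names) == 2:
        models["+".join(names)] = smf.ols(
            f"y ~ {terms[0]} + {terms[1]}", data=data).fit()
        fitted = models["+".join(names)]
        cells = data.groupby(names, observed=True).size()
        full_cells = len(data[names[0]].unique()) * len(data[names[1]].unique())
        if interaction:
            if len(cells) < full_cells:
                models["interaction"] = None
                models["interaction_note"] = (
                    "interaction refused: empty factor cells")
            else:
                models["interaction"] = smf.ols(
                    f"y ~ {terms[0]} * {terms[1]}", data=data).fit()
                fitted = models["interaction"]

    anova_table = sm.stats.anova_lm(fitted, typ=2)

    comparisons = []

    def compare(rname, fname):
        small, big = models[rname], models[fname]
        cmp_tab = sm.stats.anova_lm(small, big)
        comparisons.append({
            "restricted": rname, "full": fname,
            "F": float(cmp_tab["F"].iloc[-1]),
            "p_value": float(cmp_tab["Pr(>F)"].iloc[-1]),
        })

    if len(names) == 2:
        joint = "+".join(names)
        for f in names:
            compare(f, joint)
        if models.get("interaction") is not None:
            compare(joint, "interaction")

    tukey_results = {}
    if tukey:
        for f in names:
            if data[f].nunique() >= 2:
                tukey_results[f] = pairwise_tukeyhsd(
                    data["y"], data[f].astype(str))

    return {"anova": anova_table, "models": models,
            "nested_comparisons": pd.DataFrame(comparisons),
            "tukey": tukey_results}
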