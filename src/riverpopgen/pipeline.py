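"""Config-driven orchestration of the full monitoring analysis.

Stages run in a fixed order — QC, diversity, structure, kinship, LD-Ne scan,
life-history adjustment, rescue calculators, growth models — each writing
its tables to the output directory, finishing with a single JSON report.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography, diversity, growth, kinship, ldne, qc, structure
from .dataset import GenotypeDataset, attach_metadata, read_genotypes

logger = logging.getLogger("riverpopgen")


@dataclass
class PipelineConfig:
    genotypes: str | None = None
    genotype_format: str = "dosage_csv"
    sample_metadata: str | None = None
    output_dir: str = "riverpopgen_out"
    seed: int = 0
    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    ldne: ldne.LdneConfig = field(default_factory=ldne.LdneConfig)
    life_history: demography.LifeHistory = field(
        default_factory=demography.LifeHistory)
    age_rules: growth.AgeRules = field(default_factory=growth.AgeRules)
    fe_target: float = 0.1
    min_group_size: int = 11
    reference_he_outbred: float | None = None   # fallback: source samples
    sib_r_min: float = 0.35
    duplicate_mismatch_max: float = 0.02
    compute_ci: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in [("qc", qc.QcConfig), ("ldne", ldne.LdneConfig),
                           ("life_history", demography.LifeHistory),
                           ("age_rules", growth.AgeRules)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


def default_groupings(meta: pd.DataFrame) -> dict:
    """The four grouping schemes: site x cohort, cohort, site, and all.

    Selectors are boolean masks over the metadata frame. Groups containing
    admixed individuals get paired with/without variants.
    """
    groupings: dict = {}
    site = meta["site"].astype(object)
    cohort = meta["cohort"].astype(object)
    admixed = meta["ancestry"].astype(object) == "admixed"
    nonlocal_mask = meta["ancestry"].astype(object).isin(["admixed", "source"])

    def add(label, mask):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return
        if (mask & np.asarray(admixed)).any():
            groupings[f"{label} no admixed"] = mask & ~np.asarray(nonlocal_mask)
            groupings[f"{label} with admixed"] = mask
        else:
            groupings[label] = mask & ~np.asarray(nonlocal_mask)

    for s in pd.unique(site.dropna()):
        for c in pd.unique(cohort.dropna()):
            add(f"{s}.{c}", (site == s) & (cohort == c))
    for c in pd.unique(cohort.dropna()):
        add(f"all.sites.{c}", cohort == c)
    for s in pd.unique(site.dropna()):
        add(str(s), site == s)
    add("all.inds", np.ones(len(meta), dtype=bool))
    return {k: v for k, v in groupings.items() if np.asarray(v).sum() >= 2}


def run_pipeline(cfg: PipelineConfig,
                 dataset: GenotypeDataset | None = None) -> dict:
    """Execute every stage; returns the report dict (also written as JSON)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}

    if dataset is None:
        if cfg.genotypes is None:
            raise ValueError("config needs a genotypes path or a dataset")
        dataset = read_genotypes(cfg.genotypes, format=cfg.genotype_format)
        if cfg.sample_metadata:
            dataset = attach_metadata(dataset, cfg.sample_metadata)

    def stage(name, fn):
        logger.info("stage: %s", name)
        try:
            return fn()
        except Exception:
            logger.exception("stage %s failed; partial outputs kept in %s",
                             name, out)
            raise

    # ------------------------------------------------------------------ QC
    def _qc():
        ds, rep = qc.apply_qc(dataset, cfg.qc, seed=cfg.seed)
        rep.to_frame().to_csv(out / "qc_report.csv", index=False)
        (out / "qc_report.json").write_text(
            json.dumps(rep.to_dict(), indent=2, default=str))
        return ds, rep

    ds, qc_report = stage("qc", _qc)
    report["qc"] = {"n_loci": ds.n_loci, "n_samples": ds.n_samples}

    meta = ds.sample_meta
    if meta["cohort"].isna().all() and meta["total_length_mm"].notna().any():
        meta = growth.assign_ages_and_cohorts(meta, cfg.age_rules)
        ds.sample_meta = meta

    # ----------------------------------------------------------- diversity
    def _diversity():
        pht = diversity.individual_pht(ds)
        pht = pht.merge(meta[["sample_id", "site", "river_km", "cohort",
                              "ancestry"]], on="sample_id")
        pht.to_csv(out / "individual_pht.csv", index=False)
        groupings = default_groupings(meta)
        div = diversity.diversity_table(ds, groupings)
        div.to_csv(out / "diversity_by_group.csv", index=False)
        res = {}
        if pht["river_km"].notna().sum() >= 3 and \
                pht["river_km"].nunique() > 1:
            fit = diversity.het_distance_model(pht, pht["river_km"])
            res["het_vs_distance"] = {k: fit[k] for k in
                                      ("slope", "intercept", "p_value", "r2")}
        return pht, div, res

    pht, div_table, div_extra = stage("diversity", _diversity)
    report["diversity"] = div_extra

    # ----------------------------------------------------------- structure
    def _structure():
        res: dict = {}
        pca = structure.run_pca(ds, n_components=10)
        scores = pd.DataFrame(
            pca.scores, columns=[f"PC{i+1}" for i in
                                 range(pca.scores.shape[1])])
        scores.insert(0, "sample_id", pca.sample_ids)
        scores.to_csv(out / "pca_scores.csv", index=False)
        res["explained_variance"] = pca.explained_variance_ratio[:5].tolist()

        anc = meta["ancestry"].astype(object)
        source_ids = list(meta.loc[anc == "source", "sample_id"])
        local_ids = list(meta.loc[anc == "local", "sample_id"])
        if source_ids and local_ids:
            for axis in range(min(3, pca.scores.shape[1])):
                try:
                    labels = structure.classify_ancestry(
                        pca, source_ids, local_ids,
                        structure.AncestryThresholds(axis=axis))
                    res["ancestry_axis"] = axis
                    res["ancestry_counts"] = (
                        labels.value_counts().to_dict())
                    labels.rename("ancestry_called").to_frame().reset_index(
                        names="sample_id").to_csv(
                        out / "ancestry_calls.csv", index=False)
                    break
                except ValueError:
                    continue

        sites = meta["site"]
        if sites.notna().any() and \
                (sites.value_counts() >= 2).sum() >= 2:
            fst, raw = structure.pairwise_fst(ds)
            fst.to_csv(out / "fst_matrix.csv")
            res["mean_fst"] = float(
                fst.to_numpy()[np.triu_indices(len(fst), 1)].mean())
            km = meta.groupby("site")["river_km"].first()
            km = km.loc[fst.index]
            if km.notna().all() and km.nunique() > 1:
                dist = np.abs(km.to_numpy()[:, None] - km.to_numpy()[None, :])
                mant = structure.mantel_test(fst.to_numpy(), dist,
                                             n_perm=999, seed=cfg.seed)
                res["mantel"] = mant
        return res

    report["structure"] = stage("structure", _structure)

    # ------------------------------------------------------------- kinship
    def _kinship():
        pairs = kinship.pairwise_relatedness(ds)
        dups = kinship.find_duplicates(pairs, cfg.duplicate_mismatch_max)
        fams = kinship.sib_clusters(pairs, r_min=cfg.sib_r_min,
                                    sample_meta=meta)
        kinship.family_table(fams).to_csv(out / "sib_families.csv",
                                          index=False)
        conn = kinship.family_connectivity(fams, meta)
        conn.to_csv(out / "family_connectivity.csv", index=False)
        return {"n_recapture_groups": len(dups), "n_families": len(fams),
                "n_cross_site_edges": int(len(conn))}

    report["kinship"] = stage("kinship", _kinship)

    # ------------------------------------------------------------ Ne scan
    def _ne():
        groupings = default_groupings(meta)
        table = ldne.ne_scan(ds, groupings, cfg.ldne,
                             min_group_size=cfg.min_group_size,
                             ci=cfg.compute_ci)
        ratio = cfg.life_history.nb_ne_ratio
        if "ne_hat" in table.columns:
            div_col = 1.26 - 0.323 * ratio
            table["nb_adj"] = table["ne_hat"] / div_col
            table["ne_adj"] = table["nb_adj"] / ratio
        table.to_csv(out / "ne_estimates.csv", index=False)
        return table

    ne_table = stage("ldne", _ne)
    est = ne_table.dropna(subset=["ne_hat"]) if "ne_hat" in ne_table else \
        pd.DataFrame()
    report["ne"] = {"n_groups_estimated": int(len(est)),
                    "nb_ne_ratio": cfg.life_history.nb_ne_ratio}

    # ------------------------------------------------------------- rescue
    def _rescue():
        he_out = cfg.reference_he_outbred
        anc = meta["ancestry"].astype(object)
        if he_out is None and (anc == "source").sum() >= 2:
            he_out = diversity.pop_heterozygosity(
                ds, group=np.asarray(anc == "source"), label="source").he
        if he_out is None or not np.isfinite(he_out) or he_out <= 0:
            return pd.DataFrame(), {"note": "no outbred reference available"}
        fe_by_site, nb_by_site = {}, {}
        for s in pd.unique(meta["site"].dropna()):
            mask = np.asarray((meta["site"] == s) & (anc == "local"))
            if mask.sum() < 2:
                continue
            he_site = diversity.pop_heterozygosity(ds, group=mask,
                                                   label=str(s)).he
            fe = diversity.effective_inbreeding(he_site, he_out)
            if fe <= 0:
                continue
            fe_by_site[str(s)] = fe
            if "nb_adj" in ne_table.columns:
                row = ne_table[ne_table["group"] == str(s)]
                if len(row) and np.isfinite(row["nb_adj"].iloc[0]):
                    nb_by_site[str(s)] = float(row["nb_adj"].iloc[0])
        plans = demography.rescue_table(fe_by_site, nb_by_site,
                                       fe_target=cfg.fe_target)
        plans.to_csv(out / "rescue_plans.csv", index=False)
        return plans, {"he_outbred": he_out, "n_sites": len(plans)}

    plans, rescue_info = stage("rescue", _rescue)
    report["rescue"] = rescue_info

    # ------------------------------------------------------------- growth
    def _growth():
        juv = meta[meta["age_class"].isin([growth.YOY, growth.ONE_TWO,
                                           growth.TWO_THREE])].copy()
        if len(juv) < 10:
            return {"note": "too few aged juveniles for growth models"}
        ages = juv["age_class"].map(growth.CLASS_MID_AGE)
        fit = growth.GompertzGrowth(juv["total_length_mm"], ages).fit()
        juv["resid"] = fit.residuals
        juv[["sample_id", "site", "cohort", "resid"]].to_csv(
            out / "growth_residuals.csv", index=False)
        res = {"gompertz": {"b1": fit.b1, "b2": fit.b2, "b3": fit.b3,
                            "converged": fit.converged}}
        merged = juv.merge(pht[["sample_id", "pht"]], on="sample_id")
        if merged["site"].nunique() >= 2 and merged["cohort"].nunique() >= 2:
            ladder = growth.growth_model_ladder(
                merged["resid"], merged["site"], merged["cohort"],
                merged["pht"])
            ladder["table"].to_csv(out / "growth_model_ladder.csv",
                                   index=False)
            res["ladder_verdict"] = ladder["verdict"]
        return res

    report["growth"] = stage("growth", _growth)

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
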