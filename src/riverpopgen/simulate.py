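"""Wright-Fisher metapopulation simulator with riverine structure.

Generates SNP genotype datasets with known truth for validating the
monitoring pipeline: linearly ordered demes joined by (possibly asymmetric,
possibly barrier-interrupted) stepping-stone migration, a divergent and more
diverse source population, translocation events that seed F1 admixed
offspring, multi-cohort sampling, and a Gompertz length model so the growth
machinery can run end-to-end.

The model is deliberately minimal: discrete non-overlapping generations,
unlinked biallelic loci (Mendelian transmission of independent allele
draws), no mutation or selection — drift, migration and admixture are the
signals the estimators consume, and each has a closed-form oracle
(heterozygosity decay ``He_t = He_0 (1 - 1/(2Ne))^t``, divergence
``FST = 1 - (1 - 1/(2Ne))^t``, martingale allele frequencies) used by the
test suite. A separate haplotype-based helper simulates one recombining
chromosome for LD-decay checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset
from .growth import gompertz


@dataclass
class LengthModel:
    """Gompertz length-at-age with per-cohort growth offsets and noise."""

    b1: float = 420.0
    b2: float = 2.0
    b3: float = 0.35
    noise_sd_mm: float = 6.0
    cohort_offsets_mm: dict = field(default_factory=dict)

    def lengths(self, ages, cohorts, rng):
        base = gompertz(np.asarray(ages, dtype=float), self.b1, self.b2,
                        self.b3)
        off = np.array([self.cohort_offsets_mm.get(c, 0.0) for c in cohorts])
        return base + off + rng.normal(0.0, self.noise_sd_mm, size=len(base))


@dataclass
class Translocation:
    generation: int
    dest_deme: int
    count: int
    source: str | int = "source"   # "source" population or a deme index


@dataclass
class SimConfig:
    deme_sizes: list
    n_loci: int = 3000
    n_generations: int = 40
    migration: np.ndarray | None = None     # backward, row-stochastic
    beta_a: float = 0.5
    beta_b: float = 0.5
    freq_bounds: tuple = (0.05, 0.95)
    source_size: int | None = None          # None: no source population
    translocations: list = field(default_factory=list)
    # sampling: list of (deme_index, cohort_offset, n); cohort_offset 0 is
    # the final generation, "adult" samples a mixed-age adult pool
    sampling: list = field(default_factory=list)
    n_cohort_snapshots: int = 4
    length_model: LengthModel = field(default_factory=LengthModel)
    river_km: list | None = None
    final_year: int = 2023
    seed: int = 0

    def __post_init__(self):
        self.deme_sizes = [int(s) for s in self.deme_sizes]
        if any(s < 2 for s in self.deme_sizes):
            raise ValueError("deme sizes must be >= 2")
        k = len(self.deme_sizes)
        if self.migration is None:
            self.migration = np.eye(k)
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (k, k):
            raise ValueError("migration matrix shape must match deme count")
        if not np.allclose(self.migration.sum(axis=1), 1.0):
            raise ValueError("migration rows must sum to 1")


@dataclass
class SimTruth:
    """Ground truth against which estimators are validated."""

    config: SimConfig
    initial_freqs: np.ndarray
    he_trajectory: np.ndarray           # (n_generations+1, n_demes)
    source_he_trajectory: np.ndarray | None
    final_deme_freqs: np.ndarray        # (n_demes, n_loci)
    sample_ancestry_fraction: np.ndarray
    sample_birth_generation: np.ndarray
    sample_deme: np.ndarray
    sample_parent_demes: np.ndarray     # (n_samples, 2)


class _Deme:
    __slots__ = ("geno", "anc", "parent_demes")

    def __init__(self, geno, anc, parent_demes):
        self.geno = geno                      # (N, L) int8 dosages
        self.anc = anc                        # (N,) source-ancestry fraction
        self.parent_demes = parent_demes      # (N, 2) int


def _truncated_beta(rng, a, b, lo, hi, size):
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.beta(a, b, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - n)
        out[n:n + take] = keep[:take]
        n += take
    return out


def _hwe_genotypes(rng, freqs, n):
    return (rng.random((n, len(freqs))) < freqs).astype(np.int8) + \
        (rng.random((n, len(freqs))) < freqs).astype(np.int8)


def _mendelian_children(rng, parent1_geno, parent2_geno):
    """One allele from each parent per locus (unlinked loci)."""
    a1 = rng.random(parent1_geno.shape) < parent1_geno / 2.0
    a2 = rng.random(parent2_geno.shape) < parent2_geno / 2.0
    return (a1.astype(np.int8) + a2.astype(np.int8))


def _deme_he(geno):
    p = geno.mean(axis=0) / 2.0
    return float(np.mean(2.0 * p * (1.0 - p)))


def _next_generation(demes, sizes, migration, rng):
    k = len(demes)
    new = []
    for d in range(k):
        n = sizes[d]
        pdemes = np.stack([
            rng.choice(k, size=n, p=migration[d]),
            rng.choice(k, size=n, p=migration[d]),
        ], axis=1)
        pg = [np.empty((n, demes[0].geno.shape[1]), dtype=np.int8)
              for _ in range(2)]
        anc_par = np.empty((n, 2))
        for which in range(2):
            for src in np.unique(pdemes[:, which]):
                rows = np.flatnonzero(pdemes[:, which] == src)
                pick = rng.integers(0, len(demes[src].geno), size=len(rows))
                pg[which][rows] = demes[src].geno[pick]
                anc_par[rows, which] = demes[src].anc[pick]
        geno = _mendelian_children(rng, pg[0], pg[1])
        new.append(_Deme(geno, anc_par.mean(axis=1), pdemes))
    return new


def simulate(cfg: SimConfig):
    """Run the metapopulation forward and emit (GenotypeDataset, SimTruth)."""
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.deme_sizes)
    lo, hi = cfg.freq_bounds
    p0 = _truncated_beta(rng, cfg.beta_a, cfg.beta_b, lo, hi, cfg.n_loci)

    demes = [_Deme(_hwe_genotypes(rng, p0, n), np.zeros(n),
                   np.full((n, 2), d))
             for d, n in enumerate(cfg.deme_sizes)]
    source = None
    src_he = [] if cfg.source_size else None
    if cfg.source_size:
        source = _Deme(_hwe_genotypes(rng, p0, cfg.source_size),
                       np.ones(cfg.source_size),
                       np.full((cfg.source_size, 2), -1))
        src_he.append(_deme_he(source.geno))

    he = np.empty((cfg.n_generations + 1, k))
    he[0] = [_deme_he(d.geno) for d in demes]
    snapshots = []  # (generation, demes) for the final cohort window
    trans_by_gen: dict = {}
    for tr in cfg.translocations:
        trans_by_gen.setdefault(tr.generation, []).append(tr)

    for g in range(1, cfg.n_generations + 1):
        demes = _next_generation(demes, cfg.deme_sizes, cfg.migration, rng)
        if source is not None:
            source = _next_generation(
                [source], [cfg.source_size], np.eye(1), rng)[0]
            source.anc[:] = 1.0
            source.parent_demes[:] = -1
            src_he.append(_deme_he(source.geno))
        for tr in trans_by_gen.get(g, []):
            pool = source if tr.source == "source" else demes[tr.source]
            if pool is None:
                raise ValueError("translocation from absent source population")
            pick = rng.choice(len(pool.geno), size=tr.count, replace=False)
            dest = demes[tr.dest_deme]
            dest.geno = np.vstack([dest.geno, pool.geno[pick]])
            dest.anc = np.concatenate([dest.anc, pool.anc[pick]])
            dest.parent_demes = np.vstack(
                [dest.parent_demes,
                 np.full((tr.count, 2), -1 if tr.source == "source"
                         else tr.source)])
        he[g] = [_deme_he(d.geno) for d in demes]
        if g > cfg.n_generations - cfg.n_cohort_snapshots:
            snapshots.append((g, demes))

    final_freqs = np.stack([d.geno.mean(axis=0) / 2.0 for d in demes])

    # ------------------------------------------------------------- sampling
    sampling = cfg.sampling or [(d, 0, min(30, cfg.deme_sizes[d]))
                                for d in range(k)]
    by_gen = {g: ds for g, ds in snapshots}
    rows, meta_rows = [], []
    anc_frac, birth_gen, deme_of, par_demes = [], [], [], []
    counter = 0
    for deme_idx, cohort_offset, n in sampling:
        if cohort_offset == "adult":
            g = cfg.n_generations - cfg.n_cohort_snapshots + 1
            age_years = float(cfg.n_cohort_snapshots) + 2.0
        else:
            g = cfg.n_generations - int(cohort_offset)
            age_years = float(cohort_offset) + 0.5
        if g not in by_gen:
            raise ValueError(
                f"cohort offset {cohort_offset} outside the snapshot window "
                f"(n_cohort_snapshots={cfg.n_cohort_snapshots})")
        pool = by_gen[g][deme_idx]
        if n > len(pool.geno):
            raise ValueError(
                f"cannot sample {n} individuals from deme {deme_idx} "
                f"generation {g} of size {len(pool.geno)}")
        pick = rng.choice(len(pool.geno), size=n, replace=False)
        cohort_year = cfg.final_year - (cfg.n_generations - g)
        is_adult = cohort_offset == "adult"
        ages = np.full(n, age_years)
        lengths = cfg.length_model.lengths(
            ages, [cohort_year] * n, rng)
        for j, idx in enumerate(pick):
            sid = f"S{deme_idx + 1}_{counter:04d}"
            counter += 1
            rows.append(pool.geno[idx])
            a = pool.anc[idx]
            meta_rows.append({
                "sample_id": sid,
                "site": f"S{deme_idx + 1}",
                "river_km": (cfg.river_km[deme_idx]
                             if cfg.river_km else 10.0 * deme_idx),
                "capture_year": cfg.final_year,
                "capture_date": f"{cfg.final_year}-12-01",
                "total_length_mm": float(lengths[j]),
                "ancestry": ("source" if a >= 1.0 else
                             "admixed" if a > 0.0 else "local"),
                "cohort": "adult" if is_adult else cohort_year,
                "age_class": None,
            })
            anc_frac.append(a)
            birth_gen.append(g)
            deme_of.append(deme_idx)
            par_demes.append(pool.parent_demes[idx])

    dosages = np.stack(rows)
    n_loci = cfg.n_loci
    locus_meta = pd.DataFrame({
        "locus_id": [f"L{i:05d}" for i in range(n_loci)],
        "tag_id": [f"T{i:05d}" for i in range(n_loci)],
        "chrom": [f"chr{1 + (i % 24)}" for i in range(n_loci)],
        "pos": 1 + 75_000 * (np.arange(n_loci) // 24),
        "mean_depth": np.round(rng.uniform(10, 40, size=n_loci), 2),
        "reproducibility": 1.0,
    })
    meta = pd.DataFrame(meta_rows)
    ds = GenotypeDataset(
        dosages=dosages,
        sample_ids=meta["sample_id"].to_numpy(dtype=object),
        locus_meta=locus_meta,
        sample_meta=meta,
    )
    ds.log(f"simulate: {k} demes, sizes {cfg.deme_sizes}, "
           f"{cfg.n_generations} generations, seed={cfg.seed}")
    truth = SimTruth(
        config=cfg, initial_freqs=p0, he_trajectory=he,
        source_he_trajectory=np.array(src_he) if src_he is not None else None,
        final_deme_freqs=final_freqs,
        sample_ancestry_fraction=np.array(anc_frac),
        sample_birth_generation=np.array(birth_gen),
        sample_deme=np.array(deme_of),
        sample_parent_demes=np.stack(par_demes),
    )
    return ds, truth


# ------------------------------------------------------------- convenience

def stepping_stone_migration(n_demes: int, down: float = 0.02,
                             up: float = 0.005,
                             barriers_down=(), barriers_up=()) -> np.ndarray:
    """Backward migration matrix for a linear river.

    ``down`` is the probability an offspring in deme d+1 has a parent from
    deme d (downstream dispersal); ``up`` the reverse. ``barriers_down``
    lists deme boundaries (i, i+1) closed in the downstream direction,
    ``barriers_up`` in the upstream direction (boundary i means between
    demes i and i+1, 0-based).
    """
    m = np.zeros((n_demes, n_demes))
    for d in range(n_demes):
        if d > 0 and (d - 1) not in barriers_down:
            m[d, d - 1] = down
        if d < n_demes - 1 and d not in barriers_up:
            m[d, d + 1] = up
        m[d, d] = 1.0 - m[d].sum()
    return m


def single_deme_dataset(ne: int, sample_size: int, n_loci: int,
                        n_generations: int, seed: int = 0):
    """Isolated Wright-Fisher deme; samples from the final generation."""
    cfg = SimConfig(deme_sizes=[ne], n_loci=n_loci,
                    n_generations=n_generations,
                    sampling=[(0, 0, sample_size)], seed=seed)
    return simulate(cfg)


def make_f1s(geno_a: np.ndarray, geno_b: np.ndarray, n: int, rng):
    """F1 offspring of random parents drawn from two genotype pools."""
    pa = geno_a[rng.integers(0, len(geno_a), size=n)]
    pb = geno_b[rng.integers(0, len(geno_b), size=n)]
    return _mendelian_children(rng, pa, pb)


def simulate_linked_chromosome(n_ind: int, positions, init_freqs=None,
                               n_generations: int = 30,
                               recomb_scale_bp: float = 25_000.0,
                               seed: int = 0):
    """Haplotype-based single deme with one recombining chromosome.

    Adjacent-locus recombination probability is
    ``0.5 * (1 - exp(-d / recomb_scale_bp))`` so nearby loci stay in LD while
    distant ones approach independence. Used by LD-decay tests only.
    Returns a dosage matrix (n_ind x n_loci).
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    n_loci = len(positions)
    if init_freqs is None:
        init_freqs = _truncated_beta(rng, 0.5, 0.5, 0.1, 0.9, n_loci)
    hap = (rng.random((2 * n_ind, n_loci)) < init_freqs).astype(np.int8)
    gaps = np.diff(positions)
    c = 0.5 * (1.0 - np.exp(-np.abs(gaps) / recomb_scale_bp))
    for _ in range(n_generations):
        parents = rng.integers(0, n_ind, size=(n_ind, 2))
        new = np.empty_like(hap)
        for j in range(n_ind):
            for which in range(2):
                p = parents[j, which]
                h = hap[2 * p:2 * p + 2]
                cross = rng.random(n_loci - 1) < c
                strand = np.empty(n_loci, dtype=np.int64)
                strand[0] = rng.integers(2)
                strand[1:] = np.bitwise_xor.accumulate(
                    cross.astype(np.int64)) ^ strand[0]
                strand[1:] %= 2
                new[2 * j + which] = h[strand, np.arange(n_loci)]
        hap = new
    return (hap[0::2] + hap[1::2]).astype(np.int8)


def make_study_like(seed: int = 0, n_loci: int = 3000):
    """Preset emulating the monitored river system.

    Nine linearly ordered demes with small upstream and large downstream
    effective sizes, downstream-biased stepping-stone migration interrupted
    by barriers, a large divergent source population (higher diversity),
    translocations into the two downstream demes in the last generations
    (seeding F1 admixed offspring), and multi-cohort sampling of ~330
    individuals with a Gompertz length model.
    """
    sizes = [8, 10, 12, 8, 25, 12, 40, 130, 80]
    k = len(sizes)
    migration = stepping_stone_migration(
        k, down=0.02, up=0.005,
        # boundaries 2-3 and 3-4 closed both ways (isolated deme 4 analogue);
        # upstream passage blocked at the first two boundaries
        barriers_down=(2, 3), barriers_up=(0, 1, 2, 3, 6))
    n_gen = 40
    translocations = [
        Translocation(generation=n_gen - 3, dest_deme=7, count=20),
        Translocation(generation=n_gen - 2, dest_deme=8, count=15),
    ]
    sampling = []
    quota = {0: 6, 1: 40, 2: 25, 3: 6, 4: 20, 5: 8, 6: 10, 7: 70, 8: 30}
    for d in range(k):
        per = quota[d]
        cap = sizes[d]
        for off in (0, 1, 2):
            n = min(per // 3 if d != 7 else per // 3, cap)
            if n >= 2:
                sampling.append((d, off, n))
        n_adult = min(max(2, per // 5), cap)
        sampling.append((d, "adult", n_adult))
    cfg = SimConfig(
        deme_sizes=sizes, n_loci=n_loci, n_generations=n_gen,
        migration=migration, source_size=400,
        translocations=translocations, sampling=sampling,
        n_cohort_snapshots=6,
        river_km=[0.0, 9.4, 18.0, 35.2, 58.9, 73.6, 94.1, 104.9, 114.9],
        seed=seed,
    )
    return simulate(cfg)
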