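"""Genotype data model and readers/writers.

The universal currency of the pipeline is :class:`GenotypeDataset`: a dense
biallelic dosage matrix (individuals x loci, values 0/1/2 with ``MISSING`` as
sentinel) together with per-locus and per-sample metadata tables.

Dosages are oriented to count the minor allele, computed on the full dataset
at load time; the orientation is recorded per locus in ``locus_meta['flipped']``
so that downstream statistics (Ho, He, r2), which are orientation-invariant,
can be audited.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Distinct from any valid dosage.
MISSING: int = -1

LOCUS_META_COLUMNS = [
    "locus_id", "tag_id", "chrom", "pos", "mean_depth", "reproducibility",
    "call_rate", "flipped",
]
SAMPLE_META_COLUMNS = [
    "sample_id", "site", "river_km", "capture_year", "capture_date",
    "total_length_mm", "ancestry", "cohort", "age_class",
]


class GenotypeParseError(ValueError):
    """Raised when an input genotype file does not parse in the named dialect."""


@dataclass
class GenotypeDataset:
    """Biallelic dosage matrix plus locus/sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_loci)`` integer array with values in ``{0, 1, 2}`` or
        :data:`MISSING`.
    sample_ids
        Unique sample identifiers, one per row.
    locus_meta
        DataFrame with one row per locus; must contain ``locus_id``. Other
        recognised columns: ``tag_id, chrom, pos, mean_depth, reproducibility,
        call_rate, flipped``.
    sample_meta
        DataFrame with one row per sample (``sample_id`` column); populated by
        :func:`attach_metadata`.
    provenance
        Free-text log of the operations applied so far.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    locus_meta: pd.DataFrame
    sample_meta: pd.DataFrame = None  # type: ignore[assignment]
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix (individuals x loci)")
        vals = np.unique(self.dosages)
        bad = [v for v in vals if v not in (MISSING, 0, 1, 2)]
        if bad:
            raise ValueError(f"invalid dosage values {bad}; expected 0/1/2/{MISSING}")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length != number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        self.locus_meta = _normalise_locus_meta(self.locus_meta, self.dosages.shape[1])
        if self.locus_meta["locus_id"].duplicated().any():
            raise ValueError("locus ids are not unique")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame({"sample_id": self.sample_ids})
        self.sample_meta = _normalise_sample_meta(self.sample_meta, self.sample_ids)

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.locus_meta["locus_id"].to_numpy()

    def called_mask(self) -> np.ndarray:
        """Boolean mask, True where a genotype was called."""
        return self.dosages != MISSING

    def missing_fraction(self) -> float:
        return float(np.mean(self.dosages == MISSING))

    def log(self, message: str) -> None:
        self.provenance.append(message)

    # --------------------------------------------------------------- subsetting
    def subset(self, sample_selector=None, locus_selector=None) -> "GenotypeDataset":
        """Return a consistent submatrix with sliced metadata.

        Selectors may be boolean masks, integer index arrays, lists of ids, or
        callables mapping the metadata frame to a boolean mask. ``None`` keeps
        everything. Empty selections raise ``ValueError``.
        """
        rows = _resolve_selector(sample_selector, self.sample_meta,
                                 self.sample_ids, "sample")
        cols = _resolve_selector(locus_selector, self.locus_meta,
                                 self.locus_ids, "locus")
        out = GenotypeDataset(
            dosages=self.dosages[np.ix_(rows, cols)],
            sample_ids=self.sample_ids[rows],
            locus_meta=self.locus_meta.iloc[cols].reset_index(drop=True),
            sample_meta=self.sample_meta.iloc[rows].reset_index(drop=True),
            provenance=list(self.provenance),
        )
        out.log(f"subset: {len(rows)}/{self.n_samples} samples, "
                f"{len(cols)}/{self.n_loci} loci")
        return out

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            dosages=self.dosages.copy(),
            sample_ids=self.sample_ids.copy(),
            locus_meta=self.locus_meta.copy(),
            sample_meta=self.sample_meta.copy(),
            provenance=list(self.provenance),
        )

    # ------------------------------------------------------------- frequencies
    def allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-locus frequency of the counted allele among called genotypes.

        NaN where a locus has no calls in the selected rows.
        """
        d = self.dosages if rows is None else self.dosages[rows]
        called = d != MISSING
        n = called.sum(axis=0)
        s = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / (2.0 * n), np.nan)


def _normalise_locus_meta(meta, n_loci: int) -> pd.DataFrame:
    if meta is None:
        meta = pd.DataFrame({"locus_id": [f"L{i}" for i in range(n_loci)]})
    meta = pd.DataFrame(meta).reset_index(drop=True)
    if "locus_id" not in meta.columns:
        raise ValueError("locus_meta must contain a locus_id column")
    if len(meta) != n_loci:
        raise ValueError("locus_meta length != number of loci")
    for col, default in [("tag_id", None), ("chrom", None), ("pos", np.nan),
                         ("mean_depth", np.nan), ("reproducibility", np.nan),
                         ("call_rate", np.nan), ("flipped", False)]:
        if col not in meta.columns:
            meta[col] = default
    if meta["tag_id"].isna().all():
        meta["tag_id"] = meta["locus_id"]
    repro = meta["reproducibility"].dropna()
    if len(repro) and ((repro < 0).any() or (repro > 1).any()):
        raise ValueError("reproducibility must be within [0, 1]")
    pos = meta["pos"].dropna()
    if len(pos) and (pos <= 0).any():
        raise ValueError("pos must be positive (1-based) when present")
    return meta[LOCUS_META_COLUMNS + [c for c in meta.columns
                                      if c not in LOCUS_META_COLUMNS]]


def _normalise_sample_meta(meta, sample_ids) -> pd.DataFrame:
    meta = pd.DataFrame(meta).reset_index(drop=True)
    if "sample_id" not in meta.columns:
        raise ValueError("sample_meta must contain a sample_id column")
    if len(meta) != len(sample_ids) or list(meta["sample_id"]) != list(sample_ids):
        raise ValueError("sample_meta rows must match sample_ids in order")
    for col in SAMPLE_META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    if "ancestry" in meta.columns and meta["ancestry"].isna().all():
        meta["ancestry"] = "unknown"
    return meta


def _resolve_selector(selector, meta: pd.DataFrame, ids: np.ndarray, what: str):
    n = len(ids)
    if selector is None:
        return np.arange(n)
    if callable(selector):
        selector = np.asarray(selector(meta))
    selector = np.asarray(selector)
    if selector.dtype == bool:
        if selector.shape[0] != n:
            raise ValueError(f"{what} boolean mask has wrong length")
        idx = np.flatnonzero(selector)
    elif np.issubdtype(selector.dtype, np.integer):
        idx = selector
    else:  # ids
        lookup = {v: i for i, v in enumerate(ids)}
        missing = [v for v in selector if v not in lookup]
        if missing:
            raise KeyError(f"unknown {what} ids: {missing[:5]}")
        idx = np.array([lookup[v] for v in selector], dtype=int)
    if len(idx) == 0:
        raise ValueError(f"empty {what} selection")
    return idx


# ---------------------------------------------------------------------- I/O

def read_genotypes(path, format: str = "dosage_csv",
                   orient_minor: bool = True) -> GenotypeDataset:
    """Read genotypes from ``vcf``, ``dart_csv`` or ``dosage_csv``.

    Dosages are returned as counts of the minor allele (computed on the whole
    file) unless ``orient_minor=False``, in which case the file's own allele
    orientation (ALT for VCF, the counted allele for CSVs) is kept.
    """
    path = str(path)
    if format == "vcf":
        ds = _read_vcf(path)
    elif format == "dart_csv":
        ds = _read_dart_csv(path)
    elif format == "dosage_csv":
        ds = _read_dosage_csv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if orient_minor:
        _orient_to_minor(ds)
    ds.log(f"read_genotypes: {path} ({format}), "
           f"{ds.n_samples} samples x {ds.n_loci} loci")
    return ds


def _orient_to_minor(ds: GenotypeDataset) -> None:
    freq = ds.allele_freq()
    flip = freq > 0.5
    if flip.any():
        cols = np.flatnonzero(flip)
        block = ds.dosages[:, cols]
        called = block != MISSING
        block = np.where(called, 2 - block, MISSING).astype(np.int8)
        ds.dosages[:, cols] = block
        ds.locus_meta.loc[cols, "flipped"] = True


def _read_vcf(path: str) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    dosage_rows, meta_rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] not in ("A", "C", "G", "T"):
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosage_rows.append(dos.astype(np.int8))
        meta_rows.append({
            "locus_id": var.ID if var.ID not in (None, ".")
            else f"{var.CHROM}:{var.POS}",
            "chrom": var.CHROM,
            "pos": var.POS,
        })
    if not dosage_rows:
        raise GenotypeParseError(f"{path}: no biallelic SNP records")
    ds = GenotypeDataset(
        dosages=np.stack(dosage_rows, axis=1),
        sample_ids=np.array(samples, dtype=object),
        locus_meta=pd.DataFrame(meta_rows),
    )
    if n_skipped:
        ds.log(f"read_vcf: skipped {n_skipped} non-biallelic record(s)")
    return ds


_DART_FIXED = ["locus_id", "tag_id", "chrom", "pos", "depth", "reproducibility"]


def _read_dart_csv(path: str) -> GenotypeDataset:
    """One row per locus: fixed metadata columns then per-sample dosages.

    This single-row dosage dialect is a pragmatic stand-in for vendor two-row
    reports; a two-row parser is a documented extension point.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in _DART_FIXED if c not in df.columns]
    if missing_cols:
        raise GenotypeParseError(
            f"{path}: dart_csv requires columns {_DART_FIXED}; missing {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _DART_FIXED]
    if not sample_cols:
        raise GenotypeParseError(f"{path}: no sample columns found")
    dosages = df[sample_cols].to_numpy(dtype=float).T
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    meta = df[_DART_FIXED].rename(columns={"depth": "mean_depth"}).copy()
    return GenotypeDataset(
        dosages=dosages,
        sample_ids=np.array(sample_cols, dtype=object),
        locus_meta=meta,
    )


def _read_dosage_csv(path: str) -> GenotypeDataset:
    """Rows = samples (first column ``sample_id``), columns = loci."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise GenotypeParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise GenotypeParseError(
            f"{path}: dosage_csv must start with a sample_id column")
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeDataset(
        dosages=dosages,
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        locus_meta=pd.DataFrame({"locus_id": list(df.columns[1:])}),
    )


def write_dosage_csv(ds: GenotypeDataset, path) -> None:
    d = ds.dosages.astype(float)
    d[d == MISSING] = np.nan
    out = pd.DataFrame(d, columns=ds.locus_ids)
    out.insert(0, "sample_id", ds.sample_ids)
    out.to_csv(path, index=False, float_format="%.0f")


def write_dart_csv(ds: GenotypeDataset, path) -> None:
    meta = ds.locus_meta[["locus_id", "tag_id", "chrom", "pos", "mean_depth",
                          "reproducibility"]].rename(
        columns={"mean_depth": "depth"}).copy()
    d = ds.dosages.astype(float)
    d[d == MISSING] = np.nan
    for i, sid in enumerate(ds.sample_ids):
        meta[sid] = d[i]
    meta.to_csv(path, index=False, float_format="%.6g")


def write_sample_meta_csv(ds: GenotypeDataset, path) -> None:
    ds.sample_meta.to_csv(path, index=False)


# ----------------------------------------------------------------- metadata

def attach_metadata(ds: GenotypeDataset, table) -> GenotypeDataset:
    """Attach a sample-metadata table (CSV path, records, or DataFrame).

    Every dataset sample must appear exactly once in the table; unmatched
    table rows are logged and dropped.
    """
    if isinstance(table, (str,)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table)
    table = pd.DataFrame(table)
    if "sample_id" not in table.columns:
        raise ValueError("metadata table must contain a sample_id column")
    dup = table["sample_id"][table["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample_id in metadata table: {sorted(set(dup))}")
    have = set(table["sample_id"])
    absent = [s for s in ds.sample_ids if s not in have]
    if absent:
        raise ValueError(f"metadata table is missing sample ids: {absent}")
    indexed = table.set_index("sample_id")
    aligned = indexed.loc[list(ds.sample_ids)].reset_index()
    if "capture_date" in aligned.columns:
        aligned["capture_date"] = pd.to_datetime(
            aligned["capture_date"], errors="coerce")
    out = replace(ds, sample_meta=_normalise_sample_meta(aligned, ds.sample_ids),
                  provenance=list(ds.provenance))
    unmatched = len(table) - ds.n_samples
    out.log(f"attach_metadata: {ds.n_samples} matched, {unmatched} unmatched "
            "table row(s) dropped")
    if "river_km" in aligned.columns:
        km = aligned["river_km"].dropna()
        if len(km) and (~np.isfinite(km.to_numpy(dtype=float))).any():
            raise ValueError("river_km must be finite")
    return out
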