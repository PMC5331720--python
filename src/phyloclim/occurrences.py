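"""Occurrence-record cleaning and species-level climate summaries.

The cleaning chain mirrors standard GBIF-download hygiene for
distribution-climate analyses: drop fossil/literature records, keep one
record per species per 2.5-arcmin grid cell, drop species left with fewer
than 10 georeferenced records; then annotate each record with four
bioclim summaries (MAT/TAR/MAP/PS = BIO1/BIO7/BIO12/BIO15) from gridded
monthly normals, take per-species medians, and prepare standardized
regression predictors with a normality-gated log transform and a
collinearity (VIF) check.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ClimateGrid

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "decimalLatitude", "decimalLongitude", "basisOfRecord")

#: basis-of-record values removed by default (matched case-insensitively)
DEFAULT_BASIS_EXCLUDE = frozenset(
    {"FOSSIL_SPECIMEN", "LITERATURE", "MATERIAL_CITATION"}
)

BIOCLIM_VARS = ("MAT", "TAR", "MAP", "PS")


@dataclass
class FilterReport:
    n_input: int
    n_removed_basis: int
    n_removed_duplicate: int
    n_removed_sparse_species: int
    n_kept: int
    species_kept: list[str] = field(default_factory=list)

    def check_conservation(self) -> bool:
        return self.n_input == (
            self.n_kept
            + self.n_removed_basis
            + self.n_removed_duplicate
            + self.n_removed_sparse_species
        )


def read_occurrences(path) -> pd.DataFrame:
    """Read a Darwin-Core-like occurrence CSV.

    Rows with missing or out-of-range coordinates are dropped and counted
    in ``df.attrs['n_invalid_coordinates']``.  A missing required column
    raises a ``ValueError`` naming it.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"occurrence file lacks required column {col!r}")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    ok = (
        lat.notna() & lon.notna()
        & lat.between(-90.0, 90.0) & lon.between(-180.0, 180.0)
        & df["species"].notna() & (df["species"].astype(str) != "")
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("dropped %d records with invalid coordinates", n_bad)
    out = df.loc[ok].copy()
    out["decimalLatitude"] = lat[ok]
    out["decimalLongitude"] = lon[ok]
    out = out.reset_index(drop=True)
    out.attrs["n_invalid_coordinates"] = n_bad
    return out


def _cell_indices(lat, lon, cell_arcmin: float):
    """Global dedup lattice anchored at (-90, -180), half-open cells."""
    cell = cell_arcmin / 60.0
    ci = np.floor((np.asarray(lat) + 90.0) / cell).astype(np.int64)
    cj = np.floor((np.asarray(lon) + 180.0) / cell).astype(np.int64)
    return ci, cj


def filter_occurrences(
    records: pd.DataFrame,
    min_records: int = 10,
    cell_arcmin: float = 2.5,
    basis_exclude=DEFAULT_BASIS_EXCLUDE,
) -> tuple[pd.DataFrame, FilterReport]:
    """Three-stage cleaning: basis-of-record, per-species cell dedup, sparsity.

    Stage order is fixed: (1) remove excluded basis-of-record values,
    (2) keep the first record per species per ``cell_arcmin`` grid cell
    (stable input order), (3) drop species with fewer than ``min_records``
    remaining records.  Idempotent: filtering the output changes nothing.
    """
    n_input = len(records)
    excl = {b.upper() for b in basis_exclude}
    basis_ok = ~records["basisOfRecord"].astype(str).str.upper().isin(excl)
    stage1 = records.loc[basis_ok]
    n_basis = n_input - len(stage1)

    if len(stage1):
        ci, cj = _cell_indices(
            stage1["decimalLatitude"], stage1["decimalLongitude"], cell_arcmin
        )
        key = pd.DataFrame(
            {"species": stage1["species"].to_numpy(), "ci": ci, "cj": cj},
            index=stage1.index,
        )
        stage2 = stage1.loc[~key.duplicated(keep="first")]
    else:
        stage2 = stage1
    n_dup = len(stage1) - len(stage2)

    counts = stage2["species"].value_counts()
    keep_sp = set(counts[counts >= min_records].index)
    stage3 = stage2.loc[stage2["species"].isin(keep_sp)].reset_index(drop=True)
    n_sparse = len(stage2) - len(stage3)

    report = FilterReport(
        n_input=n_input,
        n_removed_basis=n_basis,
        n_removed_duplicate=n_dup,
        n_removed_sparse_species=n_sparse,
        n_kept=len(stage3),
        species_kept=sorted(keep_sp),
    )
    return stage3, report


def extract_bioclim(records: pd.DataFrame, grid: ClimateGrid) -> pd.DataFrame:
    """Annotate records with MAT, TAR, MAP, PS from their containing cell.

    MAT = mean monthly temperature; TAR = warmest minus coldest monthly
    mean; MAP = annual precipitation sum; PS = 100 * population SD / mean
    of the monthly precipitation totals (CV%).  Records outside the grid
    get NaN annotations, counted in ``attrs['n_outside_grid']``.
    """
    out = records.copy()
    i, j, ok = grid.cell_of(
        out["decimalLatitude"].to_numpy(), out["decimalLongitude"].to_numpy()
    )
    t = grid.temp[:, i, j]  # (12, n); garbage where ~ok
    p = grid.prec[:, i, j]
    mat = t.mean(axis=0)
    tar = t.max(axis=0) - t.min(axis=0)
    pmap = p.sum(axis=0)
    pmean = p.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(pmean > 0, 100.0 * p.std(axis=0) / pmean, 0.0)
    for name, vals in (("MAT", mat), ("TAR", tar), ("MAP", pmap), ("PS", ps)):
        out[name] = np.where(ok, vals, np.nan)
    out["cell_i"] = i
    out["cell_j"] = j
    out.attrs["n_outside_grid"] = int((~ok).sum())
    return out


def species_climate_medians(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-species medians of MAT/TAR/MAP/PS over annotated records.

    Even-count medians are the mean of the two middle values.  Species
    whose records all lack annotations are excluded (logged).
    """
    ok = annotated.dropna(subset=list(BIOCLIM_VARS))
    dropped = set(annotated["species"]) - set(ok["species"])
    if dropped:
        log.info("excluded %d species with no annotated records", len(dropped))
    med = ok.groupby("species")[list(BIOCLIM_VARS)].median()
    return med


def standardize_predictors(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Normality-gated log transform followed by z-scoring.

    For each column: Shapiro-Wilk on the raw values; if normality is
    rejected at ``alpha`` and all values exceed -1, apply log(x+1); then
    z-score (mean 0, SD 1, ddof=1).  Returns the design matrix and a
    per-variable transform log.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 species to standardize")
    Z = pd.DataFrame(index=table.index)
    decisions = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_p = float(stats.shapiro(x).pvalue)
        logged = sw_p < alpha and np.all(x > -1.0)
        if logged:
            x = np.log1p(x)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"predictor {col!r} has zero variance after transform")
        Z[col] = (x - mu) / sd
        decisions[col] = {"shapiro_p": sw_p, "log_transformed": bool(logged),
                          "mean": mu, "sd": sd}
    return Z, decisions


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    Each predictor is regressed (with intercept) on all others.  Perfect
    collinearity is reported as ``inf`` rather than raising.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors for VIF")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    out = {}
    M = X.to_numpy(dtype=float)
    n = len(M)
    for j, col in enumerate(X.columns):
        y = M[:, j]
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
        out[col] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")
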