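"""Koppen-Geiger climate classification (tropical/arid/warm-temperate part).

The engine covers the 14 categories relevant to (sub)tropical plant
distributions — Af, Am, As, Aw, Bsh, Bsk, Bwh, Bwk, Cwa, Cwb, Csa, Csb,
Cfa, Cfb — and aggregates them into four major climate groups (humid
tropics, dry tropics, arid, mild temperate).  Snow and polar climates, and
warm-temperate cells with fewer than four months above 10 deg C, fall
outside this set and are returned as ``UNCLASSIFIED``.

Decision precedence follows the standard scheme: the arid (B) test is
applied first on the dryness threshold P_th, then equatorial (A) climates
by coldest-month temperature, then warm-temperate (C) climates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ClimateGrid

CATEGORIES = (
    "Af", "Am", "As", "Aw",
    "Bsh", "Bsk", "Bwh", "Bwk",
    "Cwa", "Cwb", "Csa", "Csb", "Cfa", "Cfb",
)
UNCLASSIFIED = "UNCLASSIFIED"

GROUP_OF = {
    "Af": "humid_tropics", "Am": "humid_tropics",
    "As": "dry_tropics", "Aw": "dry_tropics",
    "Bsh": "arid", "Bsk": "arid", "Bwh": "arid", "Bwk": "arid",
    "Cwa": "mild_temperate", "Cwb": "mild_temperate",
    "Csa": "mild_temperate", "Csb": "mild_temperate",
    "Cfa": "mild_temperate", "Cfb": "mild_temperate",
    UNCLASSIFIED: "NA",
}

# Summer half-year: April-September in the northern hemisphere,
# October-March in the southern (0-based month indices).
_SUMMER_N = np.array([3, 4, 5, 6, 7, 8])
_SUMMER_S = np.array([9, 10, 11, 0, 1, 2])


@dataclass(frozen=True)
class SeasonalSummary:
    """Decision quantities derived from 12 monthly normals."""

    p_ann: float
    p_min: float
    p_max: float
    p_smin: float
    p_smax: float
    p_wmin: float
    p_wmax: float
    t_ann: float
    t_min: float
    t_max: float
    n_warm_months: int  # months with T_mon >= +10 C
    winter_precip_fraction: float
    p_th: float  # dryness threshold, mm
    driest_in_summer: bool


def seasonal_summary(t_mon, p_mon, hemisphere: str) -> SeasonalSummary:
    """Summarise 12 monthly normals into the classification quantities.

    ``hemisphere`` is ``"N"`` or ``"S"`` and fixes which calendar months
    form the summer half-year.  The dryness threshold P_th follows the
    Kottek convention: 2*T_ann when at least two thirds of annual
    precipitation falls in winter, 2*T_ann + 28 when at least two thirds
    falls in summer, and 2*T_ann + 14 otherwise.
    """
    t = np.asarray(t_mon, dtype=float)
    p = np.asarray(p_mon, dtype=float)
    if t.shape != (12,) or p.shape != (12,):
        raise ValueError("expected 12 monthly values")
    if np.any(p < 0):
        raise ValueError("negative monthly precipitation")
    if hemisphere not in ("N", "S"):
        raise ValueError("hemisphere must be 'N' or 'S'")
    summer = _SUMMER_N if hemisphere == "N" else _SUMMER_S
    winter = np.setdiff1d(np.arange(12), summer)
    p_ann = float(p.sum())
    t_ann = float(t.mean())
    p_winter = float(p[winter].sum())
    wfrac = p_winter / p_ann if p_ann > 0 else 0.5
    if wfrac >= 2.0 / 3.0:
        p_th = 2.0 * t_ann
    elif (1.0 - wfrac) >= 2.0 / 3.0:
        p_th = 2.0 * t_ann + 28.0
    else:
        p_th = 2.0 * t_ann + 14.0
    return SeasonalSummary(
        p_ann=p_ann,
        p_min=float(p.min()),
        p_max=float(p.max()),
        p_smin=float(p[summer].min()),
        p_smax=float(p[summer].max()),
        p_wmin=float(p[winter].min()),
        p_wmax=float(p[winter].max()),
        t_ann=t_ann,
        t_min=float(t.min()),
        t_max=float(t.max()),
        n_warm_months=int((t >= 10.0).sum()),
        winter_precip_fraction=wfrac,
        p_th=p_th,
        driest_in_summer=bool(int(np.argmin(p)) in set(summer.tolist())),
    )


def classify_koppen(ss: SeasonalSummary) -> str:
    """Map a seasonal summary to one of the 14 categories (or UNCLASSIFIED)."""
    # B: arid climates take precedence over the temperature-based classes.
    if ss.p_ann < 10.0 * ss.p_th:
        letter = "Bw" if ss.p_ann <= 5.0 * ss.p_th else "Bs"
        return letter + ("h" if ss.t_ann >= 18.0 else "k")
    # A: equatorial climates, coldest month at or above 18 C.
    if ss.t_min >= 18.0:
        if ss.p_min >= 60.0:
            return "Af"
        if ss.p_ann >= 25.0 * (100.0 - ss.p_min):
            return "Am"
        return "As" if ss.driest_in_summer else "Aw"
    # C: warm temperate, coldest month between -3 and +18 C.
    if ss.t_min > -3.0:
        if ss.p_smin < ss.p_wmin and ss.p_wmax > 3.0 * ss.p_smin and ss.p_smin < 40.0:
            stem = "Cs"
        elif ss.p_wmin < ss.p_smin and ss.p_smax > 10.0 * ss.p_wmin:
            stem = "Cw"
        else:
            stem = "Cf"
        if ss.t_max >= 22.0:
            return stem + "a"
        if ss.n_warm_months >= 4:
            return stem + "b"
        return UNCLASSIFIED  # Cc-type climates are outside the 14 categories
    return UNCLASSIFIED  # snow/polar


def group_major(category: str) -> str:
    """Aggregate a category into one of the four major climate groups."""
    try:
        return GROUP_OF[category]
    except KeyError:
        raise ValueError(f"unknown category {category!r}") from None


def classify_cell(t_mon, p_mon, lat: float) -> str:
    hemi = "N" if lat >= 0 else "S"
    return classify_koppen(seasonal_summary(t_mon, p_mon, hemi))


def classify_grid(grid: ClimateGrid) -> np.ndarray:
    """Classify every grid cell; returns an (nrows, ncols) array of labels."""
    lats = grid.lat_centers()
    out = np.empty((grid.nrows, grid.ncols), dtype=object)
    for i in range(grid.nrows):
        hemi = "N" if lats[i] >= 0 else "S"
        for j in range(grid.ncols):
            out[i, j] = classify_koppen(
                seasonal_summary(grid.temp[:, i, j], grid.prec[:, i, j], hemi)
            )
    return out


def assign_species_climate(cell_categories, threshold: float = 0.70):
    """Assign a species to its main climate from per-cell categories.

    ``cell_categories`` maps a distinct occupied grid cell (any hashable
    id) to that cell's Koppen category; the species' range is the set of
    distinct cells.  If a single one of the 14 categories covers strictly
    more than ``threshold`` of the range it is assigned and mapped to its
    major group; otherwise ``(None, None)``.
    """
    if not cell_categories:
        raise ValueError("species has no classified cells")
    cats = list(dict(cell_categories).values())
    n = len(cats)
    best, best_n = None, 0
    for c in set(cats):
        k = cats.count(c)
        if c in CATEGORIES and k > best_n:
            best, best_n = c, k
    if best is not None and best_n > threshold * n:
        return best, GROUP_OF[best]
    return None, None
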