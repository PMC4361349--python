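"""Processing of trawl-survey haul records into annual biomass-at-length indices.

The pipeline is: haul-level counts per 1-cm length class -> number density
per haul (count / swept area) -> annual mean number density per class ->
biomass density per class via an allometric length-weight conversion
(weight = a * length^b, grams) -> a :class:`LengthComposition` carrying the
annual total index u'_t (kg km^-2) and the per-length proportions pi_{i,t}.

Haul tables follow a simplified two-table CSV dialect:

``hauls``   columns: haul_id, year, region, distance_km, wingspread_km,
            duration_min, depth_m, and optionally swept_area_km2.
``lengths`` columns: haul_id, species, length_cm, count.

Counts are assumed already raised to haul totals (the DATRAS convention for
subsampled hauls); a ``subsample_factor`` column can be applied if present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "LengthWeightParams",
    "LengthComposition",
    "swept_area",
    "fit_swept_area_model",
    "add_swept_areas",
    "aggregate_taxa",
    "density_at_length",
    "biomass_index",
    "build_length_composition",
]


@dataclass(frozen=True)
class LengthWeightParams:
    """Allometric length-weight conversion, weight(g) = a * length(cm)^b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("a must be positive")
        if not 1.0 < self.b < 5.0:
            raise ValueError("b must lie in (1, 5)")

    def weight_g(self, length_cm):
        return self.a * np.asarray(length_cm, dtype=float) ** self.b


@dataclass
class LengthComposition:
    """Annual biomass density at length for one species.

    Attributes
    ----------
    species : str
    years : ndarray of int
    lengths : ndarray of float
        Midpoints of contiguous 1-cm classes.
    density : ndarray, shape (n_years, n_lengths)
        Biomass density (kg km^-2 cm^-1); non-negative.
    missing : ndarray of bool
        Years flagged missing.  A year is missing iff its total density is
        zero (a zero index carries no composition information and is
        treated as unobserved).
    """

    species: str
    years: np.ndarray
    lengths: np.ndarray
    density: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.years.size, self.lengths.size):
            raise ValueError("density must be years x lengths")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        totals = self.density.sum(axis=1)
        inferred = totals <= 0
        if self.missing is None:
            self.missing = inferred
        else:
            self.missing = np.asarray(self.missing, dtype=bool) | inferred

    @property
    def total_index(self) -> np.ndarray:
        """Annual total biomass index u'_t (kg km^-2); NaN for missing years."""
        tot = self.density.sum(axis=1)
        return np.where(self.missing, np.nan, tot)

    @property
    def proportions(self) -> np.ndarray:
        """pi_{i,t}: per-year length proportions; NaN rows for missing years."""
        tot = self.density.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = self.density / tot
        pi[self.missing] = np.nan
        return pi

    @property
    def mean_proportions(self) -> np.ndarray:
        """Unweighted across-year mean composition over non-missing years."""
        pi = self.proportions
        if np.all(self.missing):
            raise ValueError("no non-missing years to average")
        return np.nanmean(pi[~self.missing], axis=0)

    def proportions_filled(self) -> np.ndarray:
        """Proportions with missing years replaced by the mean composition."""
        pi = self.proportions
        if np.any(self.missing):
            pi[self.missing] = self.mean_proportions
        return pi

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: species, year, length_cm, kg_km2_cm."""
        yy, ll = np.meshgrid(self.years, self.lengths, indexing="ij")
        return pd.DataFrame({
            "species": self.species,
            "year": yy.ravel(),
            "length_cm": ll.ravel(),
            "kg_km2_cm": self.density.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, species: str | None = None) -> "LengthComposition":
        if species is not None:
            frame = frame[frame["species"] == species]
        else:
            species = str(frame["species"].iloc[0])
        pivot = frame.pivot_table(index="year", columns="length_cm",
                                  values="kg_km2_cm", fill_value=0.0)
        return cls(species, pivot.index.to_numpy(), pivot.columns.to_numpy(),
                   pivot.to_numpy())

    @classmethod
    def from_csv(cls, path, species: str | None = None) -> "LengthComposition":
        return cls.from_frame(pd.read_csv(path), species=species)


def swept_area(record, imputation_model=None) -> float:
    """Swept area (km^2) of one haul: distance towed x wing spread.

    Where the trawl geometry is unrecorded, the area is imputed from a
    fitted log-linear regression on tow duration and seabed depth
    (see :func:`fit_swept_area_model`).  Raises if neither route applies.
    """
    dist = record.get("distance_km")
    wing = record.get("wingspread_km")
    if dist is not None and wing is not None and np.isfinite(dist) and np.isfinite(wing):
        if dist <= 0 or wing <= 0:
            raise ValueError(f"non-positive tow geometry in haul {record.get('haul_id')}")
        return float(dist * wing)
    if imputation_model is not None:
        dur, depth = record.get("duration_min"), record.get("depth_m")
        if dur is not None and depth is not None and np.isfinite(dur) and np.isfinite(depth):
            x = pd.DataFrame({"const": [1.0], "log_duration": [np.log(dur)],
                              "log_depth": [np.log(depth)]})
            return float(np.exp(imputation_model.predict(x)[0]))
    raise ValueError(f"haul {record.get('haul_id')}: no usable swept-area inputs")


def fit_swept_area_model(hauls: pd.DataFrame):
    """Log-linear regression of swept area on tow duration and seabed depth.

    Fitted on hauls with complete geometry; used to impute areas where the
    trawl geometry was unrecorded.
    """
    ok = hauls.dropna(subset=["distance_km", "wingspread_km", "duration_min", "depth_m"])
    ok = ok[(ok["distance_km"] > 0) & (ok["wingspread_km"] > 0)
            & (ok["duration_min"] > 0) & (ok["depth_m"] > 0)]
    if len(ok) < 3:
        raise ValueError("need at least 3 hauls with complete geometry to fit imputation")
    y = np.log(ok["distance_km"] * ok["wingspread_km"])
    x = pd.DataFrame({"const": 1.0, "log_duration": np.log(ok["duration_min"]),
                      "log_depth": np.log(ok["depth_m"])})
    return sm.OLS(y, x).fit()


def add_swept_areas(hauls: pd.DataFrame, imputation_model=None,
                    fit_if_needed: bool = True) -> pd.DataFrame:
    """Return hauls with a ``swept_area_km2`` column; drop unusable hauls.

    Hauls with no geometry and no imputable covariates are excluded with a
    logged warning rather than failing the whole table.
    """
    hauls = hauls.copy()
    if "swept_area_km2" not in hauls.columns:
        hauls["swept_area_km2"] = np.nan
    need = hauls["swept_area_km2"].isna()
    if need.any() and imputation_model is None and fit_if_needed:
        try:
            imputation_model = fit_swept_area_model(hauls)
        except ValueError:
            imputation_model = None
    keep = []
    for idx, row in hauls.iterrows():
        if np.isfinite(row["swept_area_km2"]) and row["swept_area_km2"] > 0:
            keep.append(idx)
            continue
        try:
            hauls.loc[idx, "swept_area_km2"] = swept_area(row.to_dict(), imputation_model)
            keep.append(idx)
        except ValueError as err:
            logger.warning("excluding haul: %s", err)
            warnings.warn(str(err), stacklevel=2)
    return hauls.loc[keep]


def aggregate_taxa(lengths: pd.DataFrame, mapping: dict,
                   default_group: str = "discard-only") -> pd.DataFrame:
    """Collapse taxa to analysis groups; counts sum within group.

    Taxa absent from ``mapping`` route to ``default_group`` (species with
    no corresponding landings category, assumed fully discarded).
    """
    out = lengths.copy()
    out["species"] = out["species"].map(lambda s: mapping.get(s, default_group))
    grouped = (out.groupby(["haul_id", "species", "length_cm"], as_index=False)["count"]
               .sum())
    return grouped


def density_at_length(hauls: pd.DataFrame, lengths: pd.DataFrame, species: str,
                      year: int, length_grid: np.ndarray,
                      region_filter: set | None = None) -> np.ndarray | None:
    """Mean number density (fish km^-2 cm^-1) per class over hauls of a year.

    Hauls with zero catch of the species contribute zeros to the mean.
    Returns None (year missing) if no haul passes the filter.
    """
    sel = hauls[hauls["year"] == year]
    if region_filter is not None:
        sel = sel[sel["region"].isin(region_filter)]
    if len(sel) == 0:
        logger.warning("no hauls for %s in %d; year flagged missing", species, year)
        return None
    grid = np.asarray(length_grid, dtype=float)
    dens = np.zeros(grid.size)
    rec = lengths[(lengths["species"] == species)
                  & lengths["haul_id"].isin(sel["haul_id"])]
    area = sel.set_index("haul_id")["swept_area_km2"]
    if "subsample_factor" in rec.columns:
        counts = rec["count"] * rec["subsample_factor"]
    else:
        counts = rec["count"]
    per_haul = (counts / rec["haul_id"].map(area)).groupby(
        [rec["haul_id"], rec["length_cm"]]).sum()
    # mean over *all* hauls, including zero-catch ones
    by_class = per_haul.groupby(level=1).sum() / len(sel)
    idx = np.searchsorted(grid, by_class.index.to_numpy())
    ok = (idx < grid.size) & np.isclose(grid[np.clip(idx, 0, grid.size - 1)],
                                        by_class.index.to_numpy())
    dens[idx[ok]] = by_class.to_numpy()[ok]
    return dens


def biomass_index(number_density: np.ndarray, years, length_grid,
                  lw: LengthWeightParams, species: str = "",
                  missing: np.ndarray | None = None) -> LengthComposition:
    """Convert annual number density at length to a biomass composition.

    Biomass density = number density x a*l^b with l the class midpoint,
    converted g -> kg.  Years whose total biomass is zero are flagged
    missing (a zero index is treated as unobserved, not as zero biomass).
    """
    number_density = np.asarray(number_density, dtype=float)
    grid = np.asarray(length_grid, dtype=float)
    weights_kg = lw.weight_g(grid) / 1000.0
    density = number_density * weights_kg[np.newaxis, :]
    return LengthComposition(species, np.asarray(years, dtype=int), grid,
                             density, missing=missing)


def build_length_composition(hauls: pd.DataFrame, lengths: pd.DataFrame,
                             species: str, years, length_grid,
                             lw: LengthWeightParams,
                             region_filter: set | None = None) -> LengthComposition:
    """Full chain: haul tables -> swept areas -> densities -> biomass index."""
    hauls = add_swept_areas(hauls)
    years = np.asarray(years, dtype=int)
    grid = np.asarray(length_grid, dtype=float)
    nd = np.zeros((years.size, grid.size))
    missing = np.zeros(years.size, dtype=bool)
    for j, yr in enumerate(years):
        dens = density_at_length(hauls, lengths, species, int(yr), grid, region_filter)
        if dens is None:
            missing[j] = True
        else:
            nd[j] = dens
    return biomass_index(nd, years, grid, lw, species=species, missing=missing)
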