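"""Observation containers shared by the simulator and the fitted models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survey import LengthComposition

__all__ = ["FisheryObservations"]


@dataclass
class FisheryObservations:
    """Annual observations for one species.

    Attributes
    ----------
    species : str
    years : ndarray of int
    index : ndarray
        Observed survey biomass index u'_t (kg km^-2); NaN where the year
        is missing (zero survey catch).
    landings : ndarray
        Observed landed weight L'_t (tonnes); NaN allowed.
    discards : ndarray or None
        Observed discarded weight D'_t (tonnes); None for landings-only
        species, NaN for missing years within an observed series.
    composition : LengthComposition
        Survey biomass-at-length; supplies the proportions pi_{i,t}.
    """

    species: str
    years: np.ndarray
    index: np.ndarray
    landings: np.ndarray
    discards: np.ndarray | None
    composition: LengthComposition

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        self.landings = np.asarray(self.landings, dtype=float)
        if self.discards is not None:
            self.discards = np.asarray(self.discards, dtype=float)
            if self.discards.shape != self.years.shape:
                raise ValueError("discards must align with years")
        for name in ("index", "landings"):
            if getattr(self, name).shape != self.years.shape:
                raise ValueError(f"{name} must align with years")
        if not np.array_equal(self.composition.years, self.years):
            raise ValueError("composition years must match observation years")

    @property
    def has_discards(self) -> bool:
        return self.discards is not None

    def without_discards(self) -> "FisheryObservations":
        """Copy with the discard series withheld (for cross-validation)."""
        return FisheryObservations(self.species, self.years.copy(),
                                   self.index.copy(), self.landings.copy(),
                                   None, self.composition)
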