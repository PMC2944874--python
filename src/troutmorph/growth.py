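"""Size and condition phenotypes: weight-length allometry, relative condition
factor K_n, and development rate in accumulated temperature units (ATU).

K_n = W / W' where W' = 10^(a + b log10 L) is the standard weight predicted
by an ordinary least-squares regression of log10 weight on log10 length fitted
to the whole sample (all strains and sampling periods pooled).  Fish heavier
than predicted for their length have K_n > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FishMeasurement",
    "WeightLengthRegression",
    "fit_weight_length",
    "relative_condition",
    "accumulated_temperature_units",
]


@dataclass
class FishMeasurement:
    id: str
    length: float   # mm
    weight: float   # g
    family: str = ""
    strain: str = ""
    period: int = 1
    mature: bool = False

    def __post_init__(self):
        if not self.length > 0:
            raise ValueError(f"fish {self.id!r}: length must be positive")
        if not self.weight > 0:
            raise ValueError(f"fish {self.id!r}: weight must be positive")


def _length_weight_arrays(measurements) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(measurements, pd.DataFrame):
        L = measurements["length_mm"].to_numpy(float)
        W = measurements["weight_g"].to_numpy(float)
    else:
        L = np.array([m.length for m in measurements], float)
        W = np.array([m.weight for m in measurements], float)
    if np.any(L <= 0) or np.any(W <= 0):
        bad = int(np.argmax((L <= 0) | (W <= 0)))
        raise ValueError(f"non-positive length/weight at record {bad}")
    return L, W


class WeightLengthRegression(RegressorMixin, BaseEstimator):
    """OLS of log10 weight on log10 length.

    Attributes
    ----------
    intercept_ : a in log10 W = a + b log10 L
    slope_ : b (the allometric exponent; ~3 for isometric growth)
    n_ : number of fish used in the fit
    """

    def fit(self, X, y=None):
        """Fit from (lengths, weights) arrays or a phenotype table.

        ``X`` may be a list of :class:`FishMeasurement`, a DataFrame with
        ``length_mm``/``weight_g`` columns, or a 1-D array of lengths with
        ``y`` the weights.
        """
        if y is not None:
            L = np.asarray(X, float).ravel()
            W = np.asarray(y, float).ravel()
            if np.any(L <= 0) or np.any(W <= 0):
                raise ValueError("lengths and weights must be positive")
        else:
            L, W = _length_weight_arrays(X)
        if np.unique(L).size < 3:
            raise ValueError("need at least 3 distinct lengths")
        b, a = np.polyfit(np.log10(L), np.log10(W), 1)
        self.intercept_ = float(a)
        self.slope_ = float(b)
        self.n_ = int(L.size)
        return self

    def predict(self, lengths) -> np.ndarray:
        """Standard weight W' (g) at the given lengths (mm)."""
        L = np.asarray(lengths, float)
        return 10.0 ** (self.intercept_ + self.slope_ * np.log10(L))

    def condition(self, X, y=None) -> np.ndarray:
        """Relative condition factor K_n = W / W'."""
        if y is not None:
            L = np.asarray(X, float).ravel()
            W = np.asarray(y, float).ravel()
        else:
            L, W = _length_weight_arrays(X)
        return W / self.predict(L)


def fit_weight_length(measurements) -> WeightLengthRegression:
    """Pooled weight-length regression over all sampled fish."""
    return WeightLengthRegression().fit(measurements)


def relative_condition(measurements, model: WeightLengthRegression) -> np.ndarray:
    return model.condition(measurements)


def accumulated_temperature_units(temperatures, hatch_day: int) -> float:
    """Sum of daily mean temperatures (deg C) from fertilization to hatch.

    ``temperatures`` is a day-indexed series; ``hatch_day`` counts the days
    summed (day 0 = fertilization, ATU 0).  Negative daily means are legal
    (supercooled water) but flagged with a warning.
    """
    t = np.asarray(temperatures, float)
    if hatch_day < 0 or hatch_day > t.size:
        raise ValueError(f"hatch_day {hatch_day} outside temperature series of {t.size} days")
    part = t[:hatch_day]
    if np.any(part < 0):
        import warnings

        warnings.warn("negative daily temperatures in ATU sum", stacklevel=2)
    return float(part.sum())
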