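"""Age-indexed incidence curves for mutation carriers.

An :class:`IncidenceCurve` holds the population-average, age-specific
hazard of disease onset for carriers of a high-penetrance mutation.  It is
the constraint target for the penetrance-constrained proportional-hazards
models: whatever per-genotype effects a model assumes, the genotype-averaged
hazard must reproduce this curve.

The hazard is piecewise constant on one-year age bins.  The default grid
covers ages 20-80 (onset below 20 is treated as negligible for BRCA2-type
penetrance), so the curve stores 60 bin hazards for bins [20,21), ...,
[79,80).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_MIN = 20.0
AGE_MAX = 80.0


@dataclass(frozen=True)
class IncidenceCurve:
    """Piecewise-constant age-specific hazard on one-year bins.

    Parameters
    ----------
    ages:
        Bin-start ages, strictly increasing with unit spacing
        (default 20, 21, ..., 79).
    hazard:
        Hazard per year in each bin, all >= 0.
    """

    ages: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        hazard = np.asarray(self.hazard, dtype=float)
        if ages.ndim != 1 or ages.size < 1:
            raise ValueError("age grid must be a non-empty 1-d array")
        if hazard.shape != ages.shape:
            raise ValueError("hazard and age grids differ in length")
        if ages.size > 1 and not np.allclose(np.diff(ages), 1.0):
            raise ValueError("age grid must have one-year bins")
        if np.any(hazard < 0):
            raise ValueError("hazard must be non-negative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "hazard", hazard)

    # -- grid helpers -----------------------------------------------------

    @property
    def age_start(self) -> float:
        return float(self.ages[0])

    @property
    def age_end(self) -> float:
        """Upper edge of the last bin (bins have unit width)."""
        return float(self.ages[-1] + 1.0)

    @property
    def cum_hazard_grid(self) -> np.ndarray:
        """Cumulative hazard at each bin START (Λ(ages[0]) = 0)."""
        return np.concatenate([[0.0], np.cumsum(self.hazard)])[:-1]

    def cum_hazard(self, t) -> np.ndarray:
        """Λ(t), linear within bins, clamped to the grid range."""
        t = np.clip(np.asarray(t, dtype=float), self.age_start, self.age_end)
        idx = np.clip(
            np.searchsorted(self.ages, t, side="right") - 1, 0, self.ages.size - 1
        )
        frac = np.clip(t - self.ages[idx], 0.0, 1.0)
        return self.cum_hazard_grid[idx] + frac * self.hazard[idx]

    def survival(self, t) -> np.ndarray:
        """S(t) = exp(-Λ(t))."""
        return np.exp(-self.cum_hazard(t))

    def cumulative_risk(self, t) -> np.ndarray:
        """F(t) = 1 - S(t)."""
        return 1.0 - self.survival(t)

    def hazard_at(self, t) -> np.ndarray:
        """λ(t) of the bin containing t (right-open bins)."""
        t = np.clip(np.asarray(t, dtype=float), self.age_start, self.age_end)
        idx = np.clip(
            np.searchsorted(self.ages, t, side="right") - 1, 0, self.ages.size - 1
        )
        return self.hazard[idx]

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages.astype(int), "hazard": self.hazard})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceCurve":
        if not {"age", "hazard"} <= set(df.columns):
            raise ValueError("incidence table needs 'age' and 'hazard' columns")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(float), df["hazard"].to_numpy(float))

    @classmethod
    def read_csv(cls, path) -> "IncidenceCurve":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _step_curve(decade_hazards: list[float]) -> IncidenceCurve:
    ages = np.arange(AGE_MIN, AGE_MAX)
    hazard = np.repeat(np.asarray(decade_hazards, dtype=float), 10)
    return IncidenceCurve(ages, hazard)


def default_breast_incidence() -> IncidenceCurve:
    """Illustrative BRCA2-carrier breast cancer incidence.

    Smooth step curve by decade of age, rising steeply through the 30s and
    40s and plateauing after 50, with cumulative risk ~19% by age 50 and
    ~52% by age 80 — the penetrance shape reported for BRCA2 carriers.
    Published carrier-penetrance tables are not redistributable, so this
    synthetic curve is used as the default constraint target.
    """
    return _step_curve([0.001, 0.006, 0.014, 0.018, 0.018, 0.016])


def default_ovarian_incidence() -> IncidenceCurve:
    """Illustrative BRCA2-carrier ovarian cancer incidence (~12% by 80)."""
    return _step_curve([0.0001, 0.0005, 0.0015, 0.003, 0.004, 0.004])
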