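"""Exposure model: travel times and background activity to marginal MET-hours.

Exposure throughout is *marginal* MET·h/week — activity intensity over and
above the 1-MET resting rate, times weekly duration.  Within each sex x
age-band stratum, active-travel time is treated as a lognormal population
distribution summarised at equi-probable quantile midpoints; walking and
cycling are comonotonic (a person's rank in one applies to the other).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Compendium intensities below this are not counted as physical activity.
MET_INCLUSION_FLOOR = 1.5


class IntensityBelowFloorError(ValueError):
    """Raised when a compendium MET value falls under the inclusion floor."""


@dataclass(frozen=True)
class METDistribution:
    """Stochastic marginal-MET intensity of one activity.

    The location is either an arithmetic mean (with arithmetic sd) or a
    median (with geometric sd); either way draws are lognormal.
    """

    activity: str
    location: str            # 'mean' or 'median'
    location_value: float    # marginal METs
    spread_kind: str         # 'arithmetic_sd' or 'geometric_sd'
    spread_value: float

    def __post_init__(self) -> None:
        if self.location not in ("mean", "median"):
            raise ValueError(f"unknown location kind {self.location!r}")
        if self.spread_kind not in ("arithmetic_sd", "geometric_sd"):
            raise ValueError(f"unknown spread kind {self.spread_kind!r}")
        if self.location_value < 0.5:
            raise ValueError(
                f"{self.activity}: marginal MET location {self.location_value} "
                "is below the 0.5 implied by the 1.5-MET inclusion floor"
            )
        if self.spread_value <= 0:
            raise ValueError(f"{self.activity}: spread must be positive")
        if self.spread_kind == "geometric_sd" and self.spread_value <= 1:
            raise ValueError(f"{self.activity}: geometric sd must exceed 1")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal."""
        if self.spread_kind == "geometric_sd":
            sigma = np.log(self.spread_value)
            if self.location == "median":
                mu = np.log(self.location_value)
            else:  # mean with geometric sd
                mu = np.log(self.location_value) - sigma**2 / 2
        else:  # arithmetic sd: moment-matched lognormal
            m, s = self.location_value, self.spread_value
            if self.location == "median":
                raise ValueError(
                    f"{self.activity}: arithmetic sd requires a mean location"
                )
            sigma2 = np.log(1 + s**2 / m**2)
            mu = np.log(m) - sigma2 / 2
            sigma = np.sqrt(sigma2)
        return float(mu), float(sigma)

    def median(self) -> float:
        mu, _ = self.lognormal_params()
        return float(np.exp(mu))

    def mean(self) -> float:
        mu, sigma = self.lognormal_params()
        return float(np.exp(mu + sigma**2 / 2))

    def cv(self) -> float:
        """Coefficient of variation of the lognormal intensity."""
        _, sigma = self.lognormal_params()
        return float(np.sqrt(np.exp(sigma**2) - 1))

    def quantile(self, p: float) -> float:
        mu, sigma = self.lognormal_params()
        return float(np.exp(mu + sigma * stats.norm.ppf(p)))


@dataclass
class ExposureDistribution:
    """Population exposure within one stratum at equi-probable quantile points."""

    stratum: tuple[str, tuple[int, int]]
    quantile_points: np.ndarray  # marginal MET·h/week, non-decreasing

    def __post_init__(self) -> None:
        q = np.asarray(self.quantile_points, dtype=float)
        if np.any(~np.isfinite(q)) or np.any(q < 0):
            raise ValueError("exposure quantile points must be finite and >= 0")
        if np.any(np.diff(q) < 0):
            raise ValueError("exposure quantile points must be non-decreasing")
        self.quantile_points = q

    def mean(self) -> float:
        return float(self.quantile_points.mean())


def marginal_met(compendium_met: float) -> float:
    """Convert a compendium MET value to marginal METs (subtract 1 MET rest).

    Activities under the 1.5-MET floor do not count as physical activity and
    raise :class:`IntensityBelowFloorError`.
    """
    if compendium_met <= 0:
        raise ValueError(f"compendium MET must be positive, got {compendium_met}")
    if compendium_met < MET_INCLUSION_FLOOR:
        raise IntensityBelowFloorError(
            f"compendium intensity {compendium_met} MET is below the "
            f"{MET_INCLUSION_FLOOR}-MET inclusion floor"
        )
    return compendium_met - 1.0


def sample_met_intensity(
    dist: METDistribution, rng: np.random.Generator, size=None
) -> float | np.ndarray:
    """Lognormal draw(s) of marginal MET intensity, reproducible under ``rng``."""
    mu, sigma = dist.lognormal_params()
    draws = rng.lognormal(mean=mu, sigma=sigma, size=size)
    return float(draws) if size is None else draws


def travel_met_hours(minutes_per_day: float, mmet: float) -> float:
    """Weekly marginal MET-hours from daily minutes at a given marginal intensity."""
    if minutes_per_day < 0 or mmet < 0:
        raise ValueError("minutes_per_day and mmet must be >= 0")
    return minutes_per_day * 7.0 / 60.0 * mmet


def lognormal_time_quantiles(
    mean_min_per_day: float, cv: float, n_quantiles: int
) -> np.ndarray:
    """Daily-minute quantile midpoints of a lognormal with given mean and CV.

    cv = 0 degenerates to the mean at every point; mean 0 gives all zeros.
    """
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be >= 1")
    if cv < 0:
        raise ValueError("time_cv must be >= 0")
    p = (np.arange(n_quantiles) + 0.5) / n_quantiles
    if mean_min_per_day == 0 or cv == 0:
        return np.full(n_quantiles, mean_min_per_day, dtype=float)
    sigma2 = np.log(1 + cv**2)
    mu = np.log(mean_min_per_day) - sigma2 / 2
    return np.exp(mu + np.sqrt(sigma2) * stats.norm.ppf(p))


def combined_time_met_cv(time_cv: float, met_dist: METDistribution) -> float:
    """CV of the product of independent lognormal time and MET intensity.

    When MET variation is person-level heterogeneity rather than parameter
    uncertainty, a person's mode exposure is (their time) x (their
    intensity); for independent lognormals the product is lognormal with
    1 + cv^2 multiplying across factors.
    """
    cv_met = met_dist.cv()
    return float(np.sqrt((1 + time_cv**2) * (1 + cv_met**2) - 1))


def build_exposure_distribution(
    walk_min: float,
    cycle_min: float,
    background: float,
    met_draws: dict[str, float],
    n_quantiles: int = 5,
    time_cv: float = 1.0,
    stratum: tuple = ("", (0, 0)),
) -> ExposureDistribution:
    """Exposure quantile points for one stratum.

    walk/cycle daily minutes each follow a lognormal with the stratum mean
    and coefficient of variation ``time_cv``, evaluated comonotonically at
    quantile midpoints; each mode's weekly hours are weighted by its (drawn)
    marginal MET intensity and added to the scenario-invariant background.
    """
    if background < 0:
        raise ValueError("background exposure must be >= 0")
    walk_q = lognormal_time_quantiles(walk_min, time_cv, n_quantiles)
    cycle_q = lognormal_time_quantiles(cycle_min, time_cv, n_quantiles)
    x = (
        walk_q * 7.0 / 60.0 * met_draws["walk"]
        + cycle_q * 7.0 / 60.0 * met_draws["cycle"]
        + background
    )
    return ExposureDistribution(stratum=stratum, quantile_points=x)


#: Activity intensity table: marginal-MET distributions for the activities
#: contributing to travel and background physical activity.
DEFAULT_MET_DISTRIBUTIONS: dict[str, METDistribution] = {
    "walk": METDistribution("walk", "mean", 2.5, "arithmetic_sd", 1.6),
    "cycle": METDistribution("cycle", "median", 5.8, "geometric_sd", 1.3),
    "household": METDistribution("household", "median", 3.5, "geometric_sd", 1.5),
    "sport": METDistribution("sport", "median", 5.0, "geometric_sd", 1.5),
}
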