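"""Disease-specific dose-response curves for physical activity.

A log-linear relationship between exposure and outcome is assumed on a
power-transformed exposure axis:

    RR(x) = exp( ln(RR_ref) * x^k / x_ref^k ),    0.25 <= k <= 1

so the curve is pinned to the published relative risk RR_ref at its
reference dose x_ref for every transform exponent k, equals 1 at zero
exposure, and k < 1 concentrates benefit at low doses.  Uncertainty enters
through a normal draw of RR_ref (truncated to (0, 1]) and a uniform draw of
k shared across diseases within a Monte Carlo iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

K_RANGE_DEFAULT = (0.25, 1.0)


@dataclass(frozen=True)
class DoseResponseSpec:
    """Published relative risk at a reference marginal-MET-hour dose.

    ``group`` identifies specs that share one RR draw per iteration (pooled
    meta-analytic rows); ``outcome_types`` restricts which burden outcomes
    the disease contributes (depression, e.g., carries no deaths).
    """

    disease: str
    rr_ref_mean: float
    rr_ref_sd: float
    x_ref: float  # marginal MET·h/week
    sex_applicability: str = "both"   # 'both' | 'male' | 'female'
    outcome_types: frozenset[str] = frozenset({"deaths", "yll", "yld"})
    group: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.rr_ref_mean <= 1:
            raise ValueError(f"{self.disease}: rr_ref_mean must be in (0, 1]")
        if self.rr_ref_sd < 0:
            raise ValueError(f"{self.disease}: rr_ref_sd must be >= 0")
        if self.rr_ref_mean - 3 * self.rr_ref_sd <= 0:
            raise ValueError(
                f"{self.disease}: rr_ref_mean - 3*sd must stay positive"
            )
        if self.x_ref <= 0:
            raise ValueError(f"{self.disease}: x_ref must be positive")
        if self.sex_applicability not in ("both", "male", "female"):
            raise ValueError(f"{self.disease}: bad sex_applicability")
        if not self.outcome_types <= {"deaths", "yll", "yld"}:
            raise ValueError(f"{self.disease}: bad outcome_types")
        if not self.group:
            object.__setattr__(self, "group", self.disease)


def relative_risk(
    x, spec: DoseResponseSpec, rr_ref: float, k: float, allow_any_k: bool = False
):
    """RR at exposure x (marginal MET·h/week); vectorised over x.

    Pinned so RR(0) = 1 and RR(x_ref) = rr_ref for every k.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("exposure must be >= 0")
    if not 0 < rr_ref <= 1:
        raise ValueError("rr_ref must be in (0, 1]")
    if not allow_any_k and not (K_RANGE_DEFAULT[0] <= k <= K_RANGE_DEFAULT[1]):
        raise ValueError(
            f"power transform k={k} outside {K_RANGE_DEFAULT}; "
            "pass allow_any_k=True to override"
        )
    out = np.exp(np.log(rr_ref) * x**k / spec.x_ref**k)
    return float(out) if out.ndim == 0 else out


def sample_dr_parameters(
    spec: DoseResponseSpec,
    rng: np.random.Generator,
    k_range: tuple[float, float] = K_RANGE_DEFAULT,
    size=None,
):
    """Draw (rr_ref, k): truncated-normal RR and uniform power transform.

    The RR draw is truncated to (0, 1]; the caller is responsible for sharing
    one k across diseases within an iteration if that behaviour is wanted.
    """
    rr = sample_rr_ref(spec, rng, size=size)
    k = rng.uniform(k_range[0], k_range[1], size=size)
    if size is None:
        return float(rr), float(k)
    return rr, k


def sample_rr_ref(spec: DoseResponseSpec, rng: np.random.Generator, size=None):
    """Normal(mean, sd) draw of the reference RR, truncated to (0, 1]."""
    if spec.rr_ref_sd == 0:
        return (
            spec.rr_ref_mean if size is None
            else np.full(size, spec.rr_ref_mean)
        )
    a = (0.0 - spec.rr_ref_mean) / spec.rr_ref_sd
    b = (1.0 - spec.rr_ref_mean) / spec.rr_ref_sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    draws = spec.rr_ref_mean + spec.rr_ref_sd * stats.norm.ppf(u)
    return float(draws) if size is None else draws


def all_cause_mortality_rr(x, alt_spec: DoseResponseSpec | None, k: float):
    """All-cause mortality curve with user-supplied parameters.

    The disease-specific model is the main analysis; alternative all-cause
    curves are a sensitivity route and require an explicit spec.
    """
    if alt_spec is None:
        raise ValueError(
            "all-cause mortality analysis requires an explicit DoseResponseSpec "
            "(alt_spec); no default parameters are bundled"
        )
    return relative_risk(x, alt_spec, alt_spec.rr_ref_mean, k)


_ALL = frozenset({"deaths", "yll", "yld"})

#: Disease dose-response table.  Stroke, IHD and other cardiovascular
#: diseases pool one meta-analytic RR (group 'cvd'); colon cancer is
#: sex-specific; breast cancer applies to women only; depression carries
#: morbidity (YLD) but no deaths.
DEFAULT_DOSE_RESPONSE_SPECS: tuple[DoseResponseSpec, ...] = (
    DoseResponseSpec("stroke", 0.84, 0.03, 5.4, "both", _ALL, group="cvd"),
    DoseResponseSpec("ihd", 0.84, 0.03, 5.4, "both", _ALL, group="cvd"),
    DoseResponseSpec("other_cvd", 0.84, 0.03, 5.4, "both", _ALL, group="cvd"),
    DoseResponseSpec("diabetes", 0.83, 0.04, 5.6, "both", _ALL),
    DoseResponseSpec("colon_cancer", 0.80, 0.08, 24.1, "male", _ALL,
                     group="colon_cancer_male"),
    DoseResponseSpec("colon_cancer", 0.86, 0.06, 23.3, "female", _ALL,
                     group="colon_cancer_female"),
    DoseResponseSpec("breast_cancer", 0.94, 0.01, 3.5, "female", _ALL),
    DoseResponseSpec("dementia", 0.72, 0.07, 24.5, "both", _ALL),
    DoseResponseSpec("depression", 0.96, 0.02, 0.8, "both", frozenset({"yld"})),
)
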