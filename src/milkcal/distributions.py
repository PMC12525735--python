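"""Parametric input distributions for the intake model.

Four families are supported, matching the roles the model assigns to its
input variables:

* ``triangular`` — min / most-likely / max; used for feeding frequency,
  where only a plausible range and a modal value are known.
* ``pert`` — the Beta-PERT distribution on [a, b] with mode m and shape
  weight ``lam`` (default 4); used for volume per feed and for caloric
  density in age groups where pooled estimates are heterogeneous.  Its
  mean is (a + lam*m + b)/(lam + 2), the familiar (a + 4m + b)/6 at the
  default weight.
* ``normal`` — mean/SD; used for caloric density where pooled estimates
  are homogeneous.
* ``uniform`` — equal probability on [a, b]; used for infant weight
  bounded by reference-median values for girls and boys.

Sampling is fully deterministic given a :class:`numpy.random.Generator`:
triangular draws use the inverse-CDF transform, PERT draws a Beta variate
rescaled to [a, b].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

logger = logging.getLogger("milkcal")

FAMILIES = ("triangular", "pert", "normal", "uniform")

#: parameters each family requires (beyond the optional PERT ``lam``)
_REQUIRED = {
    "triangular": {"a", "m", "b"},
    "pert": {"a", "m", "b"},
    "normal": {"mu", "sigma"},
    "uniform": {"a", "b"},
}
_OPTIONAL = {"pert": {"lam"}}


class SpecValidationError(ValueError):
    """Raised when a distribution specification violates its invariants."""


@dataclass(frozen=True)
class DistributionSpec:
    """A validated, tagged parametric distribution with units.

    Only the fields relevant to ``family`` are meaningful; the rest are
    ``None``.  Instances are immutable and safe to share across age groups.
    """

    family: str
    a: float | None = None
    m: float | None = None
    b: float | None = None
    mu: float | None = None
    sigma: float | None = None
    lam: float = 4.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecValidationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family in ("triangular", "pert"):
            if self.a is None or self.m is None or self.b is None:
                raise SpecValidationError(f"{self.family} requires a, m, b")
            if not self.a < self.b:
                raise SpecValidationError(
                    f"{self.family} requires a < b, got a={self.a}, b={self.b}"
                )
            if not (self.a <= self.m <= self.b):
                raise SpecValidationError(
                    f"{self.family} mode m={self.m} outside [a={self.a}, b={self.b}]"
                )
            if self.family == "pert" and not self.lam > 0:
                raise SpecValidationError(f"pert requires lam > 0, got {self.lam}")
        elif self.family == "uniform":
            if self.a is None or self.b is None:
                raise SpecValidationError("uniform requires a, b")
            if not self.a < self.b:
                raise SpecValidationError(
                    f"uniform requires a < b, got a={self.a}, b={self.b}"
                )
        elif self.family == "normal":
            if self.mu is None or self.sigma is None:
                raise SpecValidationError("normal requires mu, sigma")
            if not self.sigma > 0:
                raise SpecValidationError(f"normal requires sigma > 0, got {self.sigma}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        """Config-format mapping: family + params + units."""
        params: dict[str, float] = {}
        if self.family in ("triangular", "pert"):
            params = {"a": self.a, "m": self.m, "b": self.b}
            if self.family == "pert" and self.lam != 4.0:
                params["lam"] = self.lam
        elif self.family == "uniform":
            params = {"a": self.a, "b": self.b}
        else:
            params = {"mu": self.mu, "sigma": self.sigma}
        return {"family": self.family, "params": params, "units": self.units}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return make_spec(d["family"], d.get("params", {}), d.get("units", ""))


def make_spec(family: str, params: Mapping[str, float], units: str = "") -> DistributionSpec:
    """Build a validated :class:`DistributionSpec`.

    ``params`` must contain exactly the parameters the family requires
    (``lam`` is optional for PERT); missing or extra keys are rejected
    with a descriptive error.
    """
    if family not in _REQUIRED:
        raise SpecValidationError(
            f"unknown family {family!r}; expected one of {FAMILIES}"
        )
    required = _REQUIRED[family]
    allowed = required | _OPTIONAL.get(family, set())
    given = set(params)
    if given - allowed:
        raise SpecValidationError(
            f"{family}: unexpected parameter(s) {sorted(given - allowed)}"
        )
    if required - given:
        raise SpecValidationError(
            f"{family}: missing parameter(s) {sorted(required - given)}"
        )
    kwargs = {k: float(v) for k, v in params.items()}
    return DistributionSpec(family=family, units=units, **kwargs)


# -- closed-form moments --------------------------------------------------


def pert_shape_params(a: float, m: float, b: float, lam: float = 4.0) -> tuple[float, float]:
    """Beta shape parameters (alpha1, alpha2) of the PERT construction.

    alpha1 = 1 + lam*(m - a)/(b - a),  alpha2 = 1 + lam*(b - m)/(b - a).
    """
    if not a < b:
        raise SpecValidationError(f"pert requires a < b, got a={a}, b={b}")
    if not (a <= m <= b):
        raise SpecValidationError(f"pert mode m={m} outside [a={a}, b={b}]")
    alpha1 = 1.0 + lam * (m - a) / (b - a)
    alpha2 = 1.0 + lam * (b - m) / (b - a)
    return alpha1, alpha2


def mean_of(spec: DistributionSpec) -> float:
    """Analytic mean of the distribution."""
    if spec.family == "triangular":
        return (spec.a + spec.m + spec.b) / 3.0
    if spec.family == "pert":
        return (spec.a + spec.lam * spec.m + spec.b) / (spec.lam + 2.0)
    if spec.family == "uniform":
        return (spec.a + spec.b) / 2.0
    return spec.mu


def variance_of(spec: DistributionSpec) -> float:
    """Analytic variance of the distribution."""
    if spec.family == "triangular":
        a, m, b = spec.a, spec.m, spec.b
        return (a * a + m * m + b * b - a * b - a * m - m * b) / 18.0
    if spec.family == "pert":
        mu = mean_of(spec)
        return (mu - spec.a) * (spec.b - mu) / (spec.lam + 3.0)
    if spec.family == "uniform":
        return (spec.b - spec.a) ** 2 / 12.0
    return spec.sigma**2


# -- sampling -------------------------------------------------------------


def _triangular_icdf(u: np.ndarray, a: float, m: float, b: float) -> np.ndarray:
    # piecewise inverse CDF; split point is the CDF value at the mode
    fc = (m - a) / (b - a)
    left = a + np.sqrt(u * (b - a) * (m - a))
    right = b - np.sqrt((1.0 - u) * (b - a) * (b - m))
    return np.where(u < fc, left, right)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. variates from ``spec`` using ``rng``.

    Normal draws are resampled in the (practically impossible at the
    model's default parameters) event of a non-positive value, so that
    physically meaningless quantities never enter the intake equations;
    the event is logged at WARNING level.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if spec.family == "triangular":
        return _triangular_icdf(rng.random(n), spec.a, spec.m, spec.b)
    if spec.family == "pert":
        alpha1, alpha2 = pert_shape_params(spec.a, spec.m, spec.b, spec.lam)
        return spec.a + (spec.b - spec.a) * rng.beta(alpha1, alpha2, size=n)
    if spec.family == "uniform":
        return rng.uniform(spec.a, spec.b, size=n)
    x = rng.normal(spec.mu, spec.sigma, size=n)
    bad = x <= 0.0
    while bad.any():
        logger.warning(
            "resampling %d non-positive normal draw(s) from N(%g, %g)",
            int(bad.sum()), spec.mu, spec.sigma,
        )
        x[bad] = rng.normal(spec.mu, spec.sigma, size=int(bad.sum()))
        bad = x <= 0.0
    return x
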