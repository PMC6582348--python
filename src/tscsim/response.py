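"""Supercoiling response curves for promoters and topoisomerases.

The superhelical density sigma (dimensionless, negative = underwound DNA) modulates
two things in the model:

* promoter initiation, through the thermodynamics of open-complex formation:
  the opening probability follows a descending sigmoid
  ``U(sigma) = 1 / (1 + exp((sigma - sigma_t) / epsilon))`` and the initiation
  rate of a promoter is multiplied by ``f(sigma) = exp(m * U(sigma))``, so that
  negative supercoiling activates transcription up to a factor ``exp(m)``;
* topoisomerase activity: topoisomerase I relaxes negatively supercoiled DNA only
  (descending sigmoid in sigma, pushing sigma up toward 0) while DNA gyrase
  introduces negative supercoils with an ascending sigmoid activity
  (fully active around sigma ~ +0.1, moderately active on relaxed DNA).

Default parameter values are the calibrated ones used throughout the simulator:
promoter sigma_t = -0.042, epsilon = 0.005, m = 2.5 (calibrated on the
supercoiling-sensitive pelE promoter of Dickeya dadantii); topoisomerase
thresholds -0.04 (topo I) and 0.01 (gyrase), widths 0.012 and 0.025, and a basal
supercoil-density rate constant k = 0.001 1/s for each enzyme at its reference
(calibration-assay) concentration.  Activity scales linearly with concentration
relative to that reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PromoterResponse",
    "TopoisomeraseModel",
    "opening_probability",
    "promoter_rate_factor",
    "topo_activity_fraction",
    "topo_sigma_rate",
    "topo_i",
    "gyrase",
]

_VARIANTS = ("standard", "reversed", "positive_repressed")


def _sigmoid_down(x: float) -> float:
    """Numerically safe 1 / (1 + exp(x))."""
    if x >= 0:
        z = math.exp(-x)
        return z / (1.0 + z)
    return 1.0 / (1.0 + math.exp(x))


@dataclass(frozen=True)
class PromoterResponse:
    """Sigma-dependence of a promoter's initiation rate.

    Parameters
    ----------
    sigma_t : float
        Threshold superhelical density of promoter opening (sigmoid midpoint).
    epsilon : float
        Crossover width of the opening sigmoid (> 0).
    m : float
        Activation log-factor; the maximal supercoiling activation is exp(m).
    variant : {"standard", "reversed", "positive_repressed"}
        ``standard``: activated by negative supercoiling.
        ``reversed``: mirror curve, activated by relaxation/positive
        supercoiling (gyrA-type homeostatic promoters).
        ``positive_repressed``: an effective curve for constructs where
        strongly positive torsional stress hampers transcription (initiation
        and elongation combined): the same sigmoidal form as the standard
        curve but with its threshold moved to positive supercoiling,
        ``exp(m / (1 + exp((sigma - sigma_r)/epsilon_r)))`` -- saturated
        (flat) at negative sigma, repressed above ``sigma_r``.
    sigma_r, epsilon_r : float
        Threshold and width of the positive-supercoiling repression sigmoid
        (only used by the ``positive_repressed`` variant).
    """

    sigma_t: float = -0.042
    epsilon: float = 0.005
    m: float = 2.5
    variant: str = "standard"
    sigma_r: float = 0.23
    epsilon_r: float = 0.05

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {_VARIANTS}"
            )
        if self.variant == "positive_repressed" and not self.epsilon_r > 0:
            raise ValueError(f"epsilon_r must be > 0, got {self.epsilon_r}")

    def with_variant(self, variant: str) -> "PromoterResponse":
        return replace(self, variant=variant)


@dataclass(frozen=True)
class TopoisomeraseModel:
    """Deterministic, continuous topoisomerase action on a topological domain.

    The enzyme changes the superhelical density of every domain at rate
    ``sign * k_basal * (concentration / reference_concentration) * t(sigma)``
    where ``t(sigma)`` in [0, 1] is a sigmoid activity fraction.

    ``sign = +1`` for topoisomerase I (relaxes negative supercoils, raising
    sigma toward 0) and ``-1`` for DNA gyrase (introduces negative supercoils).
    ``reference_concentration`` is the concentration of the in vitro
    calibration assay at which ``k_basal`` applies (41 nM topo I, 0.1 uM
    gyrase).
    """

    name: str
    sign: int
    sigma_0: float
    width: float
    k_basal: float = 0.001  # 1/s at the reference concentration
    concentration: float = 0.0  # molar
    reference_concentration: float = 1.0  # molar

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if not self.reference_concentration > 0:
            raise ValueError("reference_concentration must be > 0")

    def with_concentration(self, concentration: float) -> "TopoisomeraseModel":
        return replace(self, concentration=concentration)

    def scaled(self, factor: float) -> "TopoisomeraseModel":
        """Return a copy with the basal activity constant scaled by ``factor``."""
        return replace(self, k_basal=self.k_basal * factor)


def topo_i(concentration: float = 0.025e-6) -> TopoisomeraseModel:
    """Topoisomerase I with calibrated defaults; in vivo concentration 25 nM."""
    return TopoisomeraseModel(
        name="topoI",
        sign=+1,
        sigma_0=-0.04,
        width=0.012,
        k_basal=0.001,
        concentration=concentration,
        reference_concentration=41e-9,
    )


def gyrase(concentration: float = 0.25e-6) -> TopoisomeraseModel:
    """DNA gyrase with calibrated defaults; in vivo concentration 0.25 uM."""
    return TopoisomeraseModel(
        name="gyrase",
        sign=-1,
        sigma_0=0.01,
        width=0.025,
        k_basal=0.001,
        concentration=concentration,
        reference_concentration=0.1e-6,
    )


def opening_probability(sigma: float, p: PromoterResponse) -> float:
    """Promoter opening probability U(sigma) = 1/(1+exp((sigma-sigma_t)/epsilon)).

    Strictly decreasing in sigma: underwound (negative) DNA opens more easily.
    """
    if not math.isfinite(sigma):
        raise ValueError(f"sigma must be finite, got {sigma}")
    return _sigmoid_down((sigma - p.sigma_t) / p.epsilon)


def promoter_rate_factor(sigma: float, p: PromoterResponse) -> float:
    """Multiplicative factor applied to the basal initiation rate at ``sigma``.

    standard: exp(m * U(sigma)); reversed: exp(m * (1 - U(sigma)));
    positive_repressed: exp(m * U_r(sigma)) with the opening sigmoid moved to
    the positive threshold sigma_r (flat at negative sigma).
    """
    if p.variant == "standard":
        return math.exp(p.m * opening_probability(sigma, p))
    if p.variant == "reversed":
        return math.exp(p.m * (1.0 - opening_probability(sigma, p)))
    if p.variant == "positive_repressed":
        if not math.isfinite(sigma):
            raise ValueError(f"sigma must be finite, got {sigma}")
        return math.exp(p.m * _sigmoid_down((sigma - p.sigma_r) / p.epsilon_r))
    raise ValueError(f"unknown variant {p.variant!r}")


def topo_activity_fraction(sigma: float, t: TopoisomeraseModel) -> float:
    """Activity fraction t(sigma) in [0, 1] of a topoisomerase at ``sigma``.

    Topoisomerase I (sign +1) is active on negatively supercoiled DNA only
    (descending sigmoid); gyrase (sign -1) activity rises with sigma.
    """
    if not math.isfinite(sigma):
        raise ValueError(f"sigma must be finite, got {sigma}")
    x = (sigma - t.sigma_0) / t.width
    return _sigmoid_down(x if t.sign > 0 else -x)


def topo_sigma_rate(sigma: float, t: TopoisomeraseModel) -> float:
    """d(sigma)/dt contributed by the enzyme, in 1/s.

    ``sign * k_basal * (c / c_ref) * t(sigma)``: topo I pushes sigma up toward
    0 from below, gyrase pushes it down.  Linear in concentration.
    """
    if t.concentration < 0:
        raise ValueError("concentration must be >= 0")
    if t.concentration == 0.0:
        return 0.0
    scale = t.concentration / t.reference_concentration
    return t.sign * t.k_basal * scale * topo_activity_fraction(sigma, t)
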