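"""Genomic vs phenotypic selection efficiency calculus.

Truncation-selection intensity for an infinite population, accuracy from
predictive ability, expected genetic gain per cycle and per year, and the
cost-constrained GS/PS efficiency ratio in which the breeding-value SD
cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "GainScenario",
    "selection_intensity",
    "accuracy_from_ability",
    "gain_per_cycle_gs",
    "gain_per_year_gs",
    "gain_per_year_ps",
    "efficiency_ratio",
    "intensity_ratio_from_costs",
]

DEFAULT_INTENSITY_RATIO = 1.46  # intermediate of 1.379 and 1.539 at 5x cost ratio


def selection_intensity(p: float) -> float:
    """Standardized selection differential i = phi(z)/p, z = Phi^-1(1-p).

    Infinite-population truncation selection of the top fraction ``p`` of a
    standard normal (no finite-sample correction).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected fraction must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def accuracy_from_ability(r_ab: float, H: float) -> float:
    """GS accuracy r_Ac = r_Ab / H, H the square root of broad-sense H2."""
    if not 0.0 < H <= 1.0:
        raise ValueError("H must lie in (0, 1]")
    r_ac = r_ab / H
    if abs(r_ac) > 1.0:
        import warnings

        warnings.warn(f"accuracy {r_ac:.3f} exceeds 1 in magnitude")
    return r_ac


@dataclass
class GainScenario:
    """Inputs of one GS-vs-PS comparison.

    ``r_Ac`` is recomputed from ``r_Ab`` and ``H`` (never stored
    independently). ``s_A`` is the SD of breeding values in trait units; the
    efficiency ratio does not consume it.
    """

    r_Ab: float
    H: float
    s_A: float = 1.0
    selected_fraction_ps: float = 0.10
    intensity_ratio: float = DEFAULT_INTENSITY_RATIO
    t_G: float = 0.5
    t_P: float = 1.0
    cost_gs: float = 40.0
    cost_ps: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 < self.H <= 1.0:
            raise ValueError("H must lie in (0, 1]")
        if self.t_G <= 0 or self.t_P <= 0:
            raise ValueError("cycle durations must be positive")
        if self.intensity_ratio <= 0:
            raise ValueError("intensity ratio must be positive")
        if self.s_A < 0:
            raise ValueError("s_A must be >= 0")

    @property
    def r_Ac(self) -> float:
        return accuracy_from_ability(self.r_Ab, self.H)

    @property
    def i_P(self) -> float:
        return selection_intensity(self.selected_fraction_ps)

    @property
    def i_G(self) -> float:
        return self.intensity_ratio * self.i_P


def gain_per_cycle_gs(scenario: GainScenario) -> float:
    """Expected genetic gain per GS cycle, i_G * r_Ac * s_A."""
    return scenario.i_G * scenario.r_Ac * scenario.s_A


def gain_per_year_gs(scenario: GainScenario) -> float:
    """Expected genetic gain per year from GS, (i_G * r_Ac * s_A) / t_G."""
    return gain_per_cycle_gs(scenario) / scenario.t_G


def gain_per_year_ps(scenario: GainScenario) -> float:
    """Expected genetic gain per year from PS, (i_P * H * s_A) / t_P."""
    return scenario.i_P * scenario.H * scenario.s_A / scenario.t_P


def efficiency_ratio(
    r_ac: float,
    H: float,
    t_G: float = 0.5,
    t_P: float = 1.0,
    intensity_ratio: float = DEFAULT_INTENSITY_RATIO,
) -> float:
    """GS/PS predicted gain-per-year ratio for equal budget.

    (intensity_ratio * r_Ac / t_G) / (H / t_P); the breeding-value SD cancels.
    """
    if min(H, t_G, t_P, intensity_ratio) <= 0:
        raise ValueError("all inputs must be positive")
    return (intensity_ratio * r_ac / t_G) / (H / t_P)


def intensity_ratio_from_costs(base_selected_fraction_ps: float, cost_ratio: float) -> float:
    """i_G/i_P when a fixed budget buys ``cost_ratio`` times more GS genotypes.

    The GS selected fraction shrinks to p_PS / cost_ratio; both intensities
    come from the infinite-population truncation formula.
    """
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be positive")
    p_gs = base_selected_fraction_ps / cost_ratio
    if not 0.0 < p_gs < 1.0:
        raise ValueError("scaled GS selected fraction outside (0, 1)")
    return selection_intensity(p_gs) / selection_intensity(base_selected_fraction_ps)
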