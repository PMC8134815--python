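"""Historical-pandemic analogy arithmetic.

Back-of-envelope extrapolation from a past pandemic to a present one:
infer how many people the historical pandemic infected from its death
toll and case-fatality ratio (CFR), treat the implied attack fraction
as transferable, apply it to the modern population, and convert back
to deaths with the modern CFR.

The canonical instance is the 1918-1920 H1N1 ("Spanish flu") pandemic
in the United States: ~675,000 deaths at a CFR of ~2.5 % imply ~27
million infections out of a 1918 population of ~103 million — an
attack fraction of ~26 %. Applied to a present-day US population of
~325 million that fraction yields ~85 million infections, and at a
CFR of 1.8 % roughly 1.5 million deaths.

This module is deliberately that calculation and nothing more: no age
structure, no waning immunity, no transmission dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AnalogyParams",
    "SPANISH_FLU_US",
    "infections_from_deaths",
    "attack_fraction",
    "project_analogy",
    "round_to",
]


def _check_cfr(cfr: float, name: str = "cfr") -> None:
    if not 0.0 < cfr <= 1.0:
        raise ValueError(f"{name} must be in (0, 1], got {cfr}")


def infections_from_deaths(deaths: float, cfr: float) -> float:
    """Infections implied by a death toll at a given case-fatality ratio."""
    if deaths < 0:
        raise ValueError(f"deaths must be non-negative, got {deaths}")
    _check_cfr(cfr)
    return deaths / cfr


def attack_fraction(infections: float, population: float) -> float:
    """Cumulative fraction of the population infected."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if not 0 <= infections <= population:
        raise ValueError(
            f"infections ({infections}) must lie between 0 and the population ({population})"
        )
    return infections / population


@dataclass(frozen=True)
class AnalogyParams:
    """Constants driving the analogy.

    ``historical_deaths``, ``historical_cfr`` and
    ``historical_population`` describe the past pandemic;
    ``target_population`` and ``target_cfr`` the present one. The
    implied historical attack fraction must not exceed 1.
    """

    historical_deaths: float
    historical_cfr: float
    historical_population: float
    target_population: float
    target_cfr: float

    def __post_init__(self) -> None:
        for name in ("historical_deaths", "historical_population", "target_population"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        _check_cfr(self.historical_cfr, "historical_cfr")
        _check_cfr(self.target_cfr, "target_cfr")
        implied = self.historical_deaths / self.historical_cfr
        if implied > self.historical_population:
            raise ValueError(
                "historical deaths / CFR imply more infections than the historical population"
            )


def project_analogy(params: AnalogyParams) -> tuple[float, float]:
    """Project (infections, deaths) onto the target population.

    The historical attack fraction — infections back-calculated from
    deaths and CFR, divided by the historical population — is applied
    to ``target_population``; deaths follow at ``target_cfr``.
    Projecting onto the historical population with the historical CFR
    recovers the historical figures (self-consistency).
    """
    historical_infections = infections_from_deaths(
        params.historical_deaths, params.historical_cfr
    )
    fraction = attack_fraction(historical_infections, params.historical_population)
    projected_infections = fraction * params.target_population
    projected_deaths = projected_infections * params.target_cfr
    return projected_infections, projected_deaths


def round_to(value: float, step: float) -> float:
    """Round to the nearest multiple of ``step`` (presentation helper,
    mirroring the '~85 million' / '~1.5 million' style of reporting)."""
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    return round(value / step) * step


#: The Spanish-flu reference values for the United States, minus the
#: modern population (pass your own; any value in 324-331 million
#: reproduces the ~85 million figure at 5-million rounding).
SPANISH_FLU_US: dict[str, float] = {
    "historical_deaths": 675_000.0,
    "historical_cfr": 0.025,
    "historical_population": 103e6,
}
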