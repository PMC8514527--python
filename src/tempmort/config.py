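"""Configuration objects and reference constants.

The reference coefficient sets below are the published estimates of the
country-level damage functions for temperature-related mortality, fit to
multi-country epidemiological projections of heat- and cold-related
mortality (23 countries x 4 RCPs x 2 periods).  They serve two roles:

* defaults for the synthetic-data generator, so simulated worlds have
  realistic effect magnitudes, and
* ready-made coefficient vectors for projecting damages without refitting
  (see :func:`tempmort.models.reference_heat_fit`).

Units: the response is a percent change in the mortality rate; warming dT
is degrees Celsius above the 2001-2020 mean; month temperatures are degrees
Celsius; income enters as the natural log of per-capita GDP (PPP dollars).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Preferred heat specification: dT, dT^2, dT x hottest-month, dT x hottest x log GDP.
REFERENCE_HEAT_BETA: tuple[float, ...] = (-0.532, -0.0629, 0.525, -0.0409)
REFERENCE_HEAT_SE: tuple[float, ...] = (1.224, 0.0935, 0.208, 0.0222)

#: Preferred cold specification: dT, dT^2, dT x coldest-month.
REFERENCE_COLD_BETA: tuple[float, ...] = (-1.441, 0.199, -0.0113)
REFERENCE_COLD_SE: tuple[float, ...] = (0.137, 0.0366, 0.00680)

#: Published in-sample residual scale (%), used to calibrate synthetic noise.
REFERENCE_HEAT_RMSE: float = 2.251
REFERENCE_COLD_RMSE: float = 0.450

SCENARIOS: tuple[str, ...] = ("RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5")
PERIODS: tuple[str, ...] = ("mid", "end")

#: Global-mean warming (degC vs 2001-2020) per scenario x period for synthetic
#: runs.  With the default 0.7 degC preindustrial offset, end-of-century
#: RCP4.5 / RCP8.5 sit at 2.2 / 4.3 degC above preindustrial.
DEFAULT_GLOBAL_DT: dict[tuple[str, str], float] = {
    ("RCP2.6", "mid"): 0.6,
    ("RCP4.5", "mid"): 0.9,
    ("RCP6.0", "mid"): 1.0,
    ("RCP8.5", "mid"): 1.6,
    ("RCP2.6", "end"): 0.7,
    ("RCP4.5", "end"): 1.5,
    ("RCP6.0", "end"): 2.1,
    ("RCP8.5", "end"): 3.6,
}

DEFAULT_PREINDUSTRIAL_OFFSET: float = 0.7

#: Calendar midpoint year of each projection period, for income interpolation.
DEFAULT_PERIOD_YEARS: dict[str, int] = {"mid": 2055, "end": 2090}

BASE_YEAR: int = 2015


def _as_pair(value) -> tuple[float, float]:
    """Broadcast a scalar to a (heat, cold) pair."""
    if isinstance(value, (tuple, list)):
        if len(value) != 2:
            raise ConfigError(f"expected scalar or (heat, cold) pair, got {value!r}")
        return float(value[0]), float(value[1])
    return float(value), float(value)


# Equal variance split of the published residual scale between the country
# random effect and the observation-level noise.
_SQRT_HALF = 0.5 ** 0.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic toy world.

    Defaults reproduce the study conditions of the reference analysis:
    23 countries, 4 scenarios x 2 periods, true coefficients equal to the
    published heat Model 4 / cold Model 3 estimates, and clustered noise
    whose total standard deviation matches the published in-sample RMSEs
    (~2.25% heat, ~0.45% cold), split equally in variance between a
    country-level random effect (``sigma_country``) and i.i.d. observation
    noise (``sigma_obs``).

    ``sigma_country`` and ``sigma_obs`` accept a scalar or a (heat, cold)
    pair; scalars apply to both outcomes.
    """

    n_countries: int = 23
    seed: int = 42
    beta_hot: tuple[float, ...] = REFERENCE_HEAT_BETA
    beta_cold: tuple[float, ...] = REFERENCE_COLD_BETA
    sigma_country: float | tuple[float, float] = (
        REFERENCE_HEAT_RMSE * _SQRT_HALF,
        REFERENCE_COLD_RMSE * _SQRT_HALF,
    )
    sigma_obs: float | tuple[float, float] = (
        REFERENCE_HEAT_RMSE * _SQRT_HALF,
        REFERENCE_COLD_RMSE * _SQRT_HALF,
    )
    hottest_range: tuple[float, float] = (15.0, 35.0)
    coldest_range: tuple[float, float] = (-25.0, 20.0)
    income_range: tuple[float, float] = (1_000.0, 60_000.0)
    population_range: tuple[float, float] = (1e6, 3e8)
    mortality_rate_range: tuple[float, float] = (0.005, 0.012)
    pattern_spread: float = 0.15
    global_dt: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_DT)
    )

    @property
    def sigma_country_pair(self) -> tuple[float, float]:
        return _as_pair(self.sigma_country)

    @property
    def sigma_obs_pair(self) -> tuple[float, float]:
        return _as_pair(self.sigma_obs)

    def validate(self) -> "SyntheticConfig":
        if self.n_countries < 2:
            raise ConfigError("n_countries must be >= 2")
        if len(self.beta_hot) != 4:
            raise ConfigError("beta_hot must have 4 components (T, T2, TxM, TxMxG)")
        if len(self.beta_cold) != 3:
            raise ConfigError("beta_cold must have 3 components (T, T2, TxM)")
        for name, pair in (
            ("sigma_country", self.sigma_country_pair),
            ("sigma_obs", self.sigma_obs_pair),
        ):
            if min(pair) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {pair}")
        for name, (lo, hi) in (
            ("hottest_range", self.hottest_range),
            ("coldest_range", self.coldest_range),
            ("income_range", self.income_range),
            ("population_range", self.population_range),
            ("mortality_rate_range", self.mortality_rate_range),
        ):
            if not lo < hi:
                raise ConfigError(f"{name} lower bound must be < upper bound, got {lo}..{hi}")
        if self.income_range[0] <= 0:
            raise ConfigError("income_range must be strictly positive")
        if not (0 <= self.mortality_rate_range[0] and self.mortality_rate_range[1] < 1):
            raise ConfigError("mortality_rate_range must lie in [0, 1)")
        if self.pattern_spread < 0:
            raise ConfigError("pattern_spread must be nonnegative")
        return self
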