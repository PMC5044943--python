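"""Seeded synthetic daily weather with the structure the analysis assumes.

The generator is a deliberately minimal WGEN-style stochastic weather
model producing exactly the two variables the phenology and water
accounting consume:

* **Temperature** — annual mean, plus a uniform warming offset (the dial
  for future time slots), plus a single cosine harmonic peaking near the
  end of July, plus an AR(1) residual.  This gives realistic degree-day
  accrual and a controllable mean shift; it is not a full weather model.
* **Precipitation** — a two-state (wet/dry) Markov occurrence chain with
  gamma-distributed wet-day amounts.  Occurrence probabilities and gamma
  scales are per hydrological half-year (winter = Nov–Apr, summer =
  May–Oct, the same partition the analysis measures), and the scales are
  calibrated analytically so that the expected annual total and the
  expected winter share hit their configured targets.

The default configuration emulates the western study region of the North
German Plain in the 1981–2010 reference climate: 9.6 °C annual mean,
~705 mm over the hydrological year with a 0.47 winter share.  Future
scenarios are expressed as a uniform warming of +1/+2/+3 °C and, where
wanted, a higher winter share.

Identical (config, seed) pairs regenerate bit-identical series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .weather import WeatherSeries, WeatherConfigError

__all__ = [
    "SyntheticWeatherConfig",
    "calibrate_seasonal_precip",
    "generate_weather",
    "PRESETS",
    "preset",
]

# long-run mean season lengths in days (winter includes Feb 29 one year in four)
WINTER_DAYS = 181.25
SUMMER_DAYS = 184.0


def _as_pair(value: float | tuple[float, float]) -> tuple[float, float]:
    """Normalise a scalar or (winter, summer) pair to a pair."""
    if isinstance(value, (tuple, list)):
        if len(value) != 2:
            raise WeatherConfigError("per-season value must be scalar or length-2")
        return float(value[0]), float(value[1])
    return float(value), float(value)


@dataclass(frozen=True)
class SyntheticWeatherConfig:
    """Parameters of the synthetic climate.

    Temperature (°C): ``t_annual_mean`` + ``warming_per_slot`` +
    ``t_amplitude``·cos-cycle peaking at ``t_peak_doy`` + AR(1) noise with
    lag-one autocorrelation ``ar1_phi`` and stationary standard deviation
    ``ar1_sigma``.  ``seasonal_warming`` adds optional extra (winter,
    summer) offsets on top of the uniform warming; it defaults to (0, 0).

    Precipitation: two-state Markov occurrence with per-season
    probabilities ``p_wet_after_dry`` / ``p_wet_after_wet`` (scalar or
    (winter, summer) pair) and Gamma(``gamma_shape``, scale) wet-day
    amounts; the seasonal scales are derived from ``annual_prec_target``
    (mm over the hydrological year) and ``winter_share_target``.

    One integer ``seed`` drives every stochastic draw.
    """

    site_id: str = "SYN"
    t_annual_mean: float = 9.6
    t_amplitude: float = 8.2
    t_peak_doy: float = 200.0
    warming_per_slot: float = 0.0
    seasonal_warming: tuple[float, float] = (0.0, 0.0)
    ar1_phi: float = 0.7
    ar1_sigma: float = 3.0
    annual_prec_target: float = 705.0
    winter_share_target: float = 0.47
    p_wet_after_dry: float | tuple[float, float] = 0.30
    p_wet_after_wet: float | tuple[float, float] = 0.60
    gamma_shape: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_phi < 1.0):
            raise WeatherConfigError("ar1_phi must be in [0, 1)")
        if self.ar1_sigma < 0:
            raise WeatherConfigError("ar1_sigma must be >= 0")
        for name in ("p_wet_after_dry", "p_wet_after_wet"):
            for v in _as_pair(getattr(self, name)):
                if not (0.0 <= v <= 1.0):
                    raise WeatherConfigError(f"{name} must be in [0, 1]")
        if self.gamma_shape <= 0:
            raise WeatherConfigError("gamma_shape must be > 0")
        if not (0.0 <= self.winter_share_target <= 1.0):
            raise WeatherConfigError("winter_share_target must be in [0, 1]")
        if self.annual_prec_target < 0:
            raise WeatherConfigError("annual_prec_target must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticWeatherConfig":
        d = dict(d)
        for key in ("seasonal_warming", "p_wet_after_dry", "p_wet_after_wet"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _stationary_wet_prob(p01: float, p11: float) -> float:
    """Long-run wet-day probability of the two-state occurrence chain."""
    denom = 1.0 + p01 - p11
    if denom == 0.0:  # p01 = 0, p11 = 1: degenerate absorbing chain
        return 0.0
    return p01 / denom


def calibrate_seasonal_precip(
    annual_prec_target: float,
    winter_share_target: float,
    p_wet_after_dry: float | tuple[float, float],
    p_wet_after_wet: float | tuple[float, float],
    gamma_shape: float,
) -> dict[str, float]:
    """Gamma scales per season hitting the annual-total and winter-share targets.

    With stationary wet probability π_s and mean season length n_s, the
    expected seasonal total is n_s·π_s·shape·scale_s, so::

        scale_winter = share·annual / (n_w·π_w·shape)
        scale_summer = (1−share)·annual / (n_s·π_s·shape)

    Raises when a season is asked to carry precipitation its occurrence
    chain can never produce, or when a share of exactly 0 or 1 conflicts
    with a wet-capable opposite season.
    """
    p01_w, p01_s = _as_pair(p_wet_after_dry)
    p11_w, p11_s = _as_pair(p_wet_after_wet)
    pi_w = _stationary_wet_prob(p01_w, p11_w)
    pi_s = _stationary_wet_prob(p01_s, p11_s)

    targets = {
        "winter": (winter_share_target * annual_prec_target, pi_w, WINTER_DAYS),
        "summer": ((1.0 - winter_share_target) * annual_prec_target, pi_s, SUMMER_DAYS),
    }
    if annual_prec_target > 0 and winter_share_target in (0.0, 1.0):
        dry_season = "winter" if winter_share_target == 0.0 else "summer"
        if targets[dry_season][1] > 0:
            raise WeatherConfigError(
                f"winter_share_target={winter_share_target} is infeasible: the "
                f"{dry_season} occurrence chain still produces wet days"
            )
    scales: dict[str, float] = {}
    for season, (total, pi, ndays) in targets.items():
        if total == 0.0:
            scales[season] = 0.0
            continue
        if pi == 0.0:
            raise WeatherConfigError(
                f"{season} precipitation target {total:.0f} mm infeasible: "
                "occurrence chain never produces a wet day"
            )
        scales[season] = total / (ndays * pi * gamma_shape)
    return scales


def generate_weather(
    config: SyntheticWeatherConfig, start_year: int, end_year: int
) -> WeatherSeries:
    """Generate one daily record per calendar day of [start_year, end_year].

    February 29 is included in leap years.  The occurrence chain starts in
    its stationary distribution for the first day's season.  Identical
    (config, seed) pairs yield bit-identical output.
    """
    if start_year > end_year:
        raise WeatherConfigError("start_year must be <= end_year")

    rng = np.random.default_rng(config.seed)
    index = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    n = len(index)
    is_winter = (index.month >= 11) | (index.month <= 4)
    is_winter = np.asarray(is_winter)

    # --- temperature -------------------------------------------------------
    doy = index.dayofyear.to_numpy().astype(float)
    cycle = config.t_amplitude * np.cos(
        2.0 * np.pi * (doy - config.t_peak_doy) / 365.25
    )
    warm_w, warm_s = config.seasonal_warming
    offset = np.where(is_winter, warm_w, warm_s) + config.warming_per_slot

    phi, sigma = config.ar1_phi, config.ar1_sigma
    resid = np.zeros(n)
    if sigma > 0:
        innov_sd = sigma * math.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, 1.0, size=n)
        resid[0] = sigma * eps[0]
        for i in range(1, n):
            resid[i] = phi * resid[i - 1] + innov_sd * eps[i]
    else:
        rng.normal(0.0, 1.0, size=n)  # keep the draw layout stable

    t_mean = config.t_annual_mean + offset + cycle + resid

    # --- precipitation ------------------------------------------------------
    p01_w, p01_s = _as_pair(config.p_wet_after_dry)
    p11_w, p11_s = _as_pair(config.p_wet_after_wet)
    scales = calibrate_seasonal_precip(
        config.annual_prec_target,
        config.winter_share_target,
        config.p_wet_after_dry,
        config.p_wet_after_wet,
        config.gamma_shape,
    )
    p01 = np.where(is_winter, p01_w, p01_s)
    p11 = np.where(is_winter, p11_w, p11_s)
    scale = np.where(is_winter, scales["winter"], scales["summer"])

    u = rng.uniform(size=n)
    wet = np.zeros(n, dtype=bool)
    pi0 = _stationary_wet_prob(p01[0], p11[0])
    wet[0] = u[0] < pi0
    for i in range(1, n):
        wet[i] = u[i] < (p11[i] if wet[i - 1] else p01[i])

    prec = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        amounts = rng.gamma(config.gamma_shape, 1.0, size=n_wet)
        prec[wet] = amounts * scale[wet]

    frame = pd.DataFrame({"t_mean": t_mean, "prec": prec}, index=index)
    return WeatherSeries(config.site_id, frame)


# Ready-made configurations for the two study regions of the North German
# Plain (DH = western/oceanic, OS = eastern/sub-continental) across the
# reference climate (SCEN, 1981-2010 statistics) and the three future
# warming scenarios (+1 / +2 / +3 degC, with the stronger winter rainfall
# share the projections show).
PRESETS: dict[str, SyntheticWeatherConfig] = {
    "DH-SCEN": SyntheticWeatherConfig(
        site_id="DH", annual_prec_target=705.0, winter_share_target=0.47
    ),
    "DH-TMIN": SyntheticWeatherConfig(
        site_id="DH", warming_per_slot=1.0, annual_prec_target=683.0,
        winter_share_target=0.50,
    ),
    "DH-TMED": SyntheticWeatherConfig(
        site_id="DH", warming_per_slot=2.0, annual_prec_target=711.0,
        winter_share_target=0.54,
    ),
    "DH-TMAX": SyntheticWeatherConfig(
        site_id="DH", warming_per_slot=3.0, annual_prec_target=700.0,
        winter_share_target=0.54,
    ),
    "OS-SCEN": SyntheticWeatherConfig(
        site_id="OS", t_amplitude=9.25, annual_prec_target=566.0,
        winter_share_target=0.44,
    ),
    "OS-TMIN": SyntheticWeatherConfig(
        site_id="OS", t_amplitude=9.25, warming_per_slot=1.0,
        annual_prec_target=512.0, winter_share_target=0.48,
    ),
    "OS-TMED": SyntheticWeatherConfig(
        site_id="OS", t_amplitude=9.25, warming_per_slot=2.0,
        annual_prec_target=556.0, winter_share_target=0.53,
    ),
    "OS-TMAX": SyntheticWeatherConfig(
        site_id="OS", t_amplitude=9.25, warming_per_slot=3.0,
        annual_prec_target=570.0, winter_share_target=0.53,
    ),
}


def preset(name: str, *, seed: int | None = None) -> SyntheticWeatherConfig:
    """Fetch a named preset, optionally re-seeded."""
    key = name.upper().replace("_", "-")
    if key not in PRESETS:
        raise WeatherConfigError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[key]
    return cfg if seed is None else replace(cfg, seed=seed)
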