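"""Synthetic forcing, observations and the toy blackbox.

The generators emulate the roles of the real river data so the whole
calibration pipeline is testable end to end: seasonal/diurnal radiation,
a seasonal temperature cycle that crosses the 20 degC loss-rate
threshold in summer, a mean-reverting lognormal discharge walk, a
spring-high / summer-low boundary-silica profile, and chlorophyll
observations produced by the process model plus i.i.d. Gaussian noise.

All generators are pure functions of (config, seed): there is no global
random state anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .process_model import (
    ForcingSeries,
    ModelConstants,
    ModelParams,
    ExclusionWindows,
    SeriesSimulator,
    noon_arrivals,
)

__all__ = [
    "SyntheticConfig",
    "ToyConfig",
    "DEFAULT_TRUE_PARAMS",
    "generate_forcing",
    "generate_observations",
    "toy_model",
    "generate_toy_data",
]

#: Plausible "true" parameter values for synthesis.  f_si is the ratio
#: multiplying chlorophyll in the silica equation (mg Si per ug chl);
#: 0.02 corresponds to a diatom Si:C ratio of ~0.8 g/g at a C:chl mass
#: ratio of 40 and yields seasonal chlorophyll peaks above 100 ug/L
#: with near-exhausted silica in summer.
DEFAULT_TRUE_PARAMS = ModelParams(
    mu0=1.2, lambda_s=0.012, k_light=42.0, f_si=0.02, sigma0=0.15, a=1.25
)


@dataclass
class SyntheticConfig:
    """Knobs of the forcing generator.

    Radiation: clipped half-sine diurnal cycle whose daily peak follows
    a seasonal sinusoid (peak near the summer solstice) modulated by a
    daily lognormal cloud factor.  Temperature: seasonal sinusoid of
    daily means (24 h means, held constant within each day) with AR(1)
    day-to-day noise; the defaults put ~3 summer months above 20 degC.
    Discharge: mean-reverting random walk of daily log-discharge around
    ``q_base``.  Boundary silica: seasonal sinusoid, high in spring and
    low in late summer.  Setting the three noise scales to zero yields
    the deterministic skeletons.
    """

    start: str = "2001-03-01"
    end: str = "2001-10-31"
    rad_mean: float = 600.0       # W/m^2, seasonal mean of the daily peak
    rad_seasonal_amp: float = 350.0
    cloud_sigma: float = 0.25     # lognormal sd of the daily cloud factor
    temp_mean: float = 14.0       # degC
    temp_amp: float = 9.0
    temp_peak_doy: int = 201      # ~July 20
    temp_noise: float = 0.5       # degC, AR(1) innovation sd (daily)
    q_base: float = 270.0         # m^3/s
    q_sigma: float = 0.04         # daily log-discharge innovation sd
    q_revert: float = 0.05        # mean reversion rate (1/day)
    si_mean: float = 3.0          # mg Si/L
    si_amp: float = 2.4
    si_min_doy: int = 231         # ~Aug 19, seasonal silica minimum
    si_noise: float = 0.1         # mg Si/L


def _doy(times: pd.DatetimeIndex) -> np.ndarray:
    return times.dayofyear.to_numpy(float) + times.hour.to_numpy(float) / 24.0


def generate_forcing(config: SyntheticConfig, seed: int = 0) -> ForcingSeries:
    """Hourly forcing series over the configured date span."""
    times = pd.date_range(config.start, config.end, freq="h")
    if len(times) < 2:
        raise ValueError("empty or degenerate date span")
    rng = np.random.default_rng(seed)
    doy = _doy(times)
    days = pd.date_range(
        pd.Timestamp(config.start).normalize(), pd.Timestamp(config.end).normalize(),
        freq="D",
    )
    n_days = len(days)
    day_index = (times.normalize().asi8 - days.asi8[0]) // 86_400_000_000_000

    # --- radiation: seasonal daily peak * diurnal half-sine * cloud factor
    seasonal_peak = config.rad_mean + config.rad_seasonal_amp * np.sin(
        2 * np.pi * (doy - 81.0) / 365.0
    )
    daylength = 12.0 + 4.0 * np.sin(2 * np.pi * (doy - 81.0) / 365.0)
    hour = times.hour.to_numpy(float)
    sunrise = 12.0 - daylength / 2.0
    phase = (hour - sunrise) / daylength
    diurnal = np.where((phase > 0) & (phase < 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    if config.cloud_sigma > 0:
        cloud_daily = np.exp(
            rng.normal(-0.5 * config.cloud_sigma**2, config.cloud_sigma, n_days)
        )
        cloud = np.minimum(cloud_daily, 1.25)[day_index]
    else:
        cloud = 1.0
    radiation = np.maximum(seasonal_peak, 0.0) * diurnal * cloud

    # --- temperature: daily means (held within the day) + AR(1) noise
    doy_days = days.dayofyear.to_numpy(float)
    t_skel = config.temp_mean + config.temp_amp * np.cos(
        2 * np.pi * (doy_days - config.temp_peak_doy) / 365.0
    )
    if config.temp_noise > 0:
        eps = rng.normal(0.0, config.temp_noise, n_days)
        noise = np.empty(n_days)
        acc = 0.0
        for k in range(n_days):
            acc = 0.8 * acc + eps[k]
            noise[k] = acc
    else:
        noise = np.zeros(n_days)
    temperature = (t_skel + noise)[day_index]

    # --- discharge: mean-reverting daily log walk, interpolated hourly
    if config.q_sigma > 0:
        logq = np.full(n_days, np.log(config.q_base))
        for k in range(1, n_days):
            logq[k] = (
                logq[k - 1]
                + config.q_revert * (np.log(config.q_base) - logq[k - 1])
                + rng.normal(0.0, config.q_sigma)
            )
        q_daily = np.clip(np.exp(logq), 40.0, 4000.0)
    else:
        q_daily = np.full(n_days, config.q_base)
    day_frac = day_index + hour / 24.0
    discharge = np.interp(day_frac, np.arange(n_days), q_daily)

    # --- boundary silica: spring high, late-summer low
    si_skel = config.si_mean - config.si_amp * np.cos(
        2 * np.pi * (doy_days - config.si_min_doy) / 365.0
    )
    if config.si_noise > 0:
        si_daily = si_skel + rng.normal(0.0, config.si_noise, n_days)
    else:
        si_daily = si_skel
    si_boundary = np.maximum(np.interp(day_frac, np.arange(n_days), si_daily), 0.05)

    return ForcingSeries(
        time=times,
        radiation=radiation,
        temperature=temperature,
        discharge=discharge,
        si_boundary=si_boundary,
    )


def generate_observations(
    params_true: ModelParams,
    constants: ModelConstants,
    forcing: ForcingSeries,
    sigma_chl: float,
    seed: int = 0,
    arrival_times=None,
    exclusion: ExclusionWindows | None = None,
    every_third: bool = False,
) -> pd.DataFrame:
    """Noisy chlorophyll observations d_i = f_i(theta_true) + N(0, sigma_chl^2).

    Returns a frame with columns ``time``, ``chl`` (observed) and
    ``chl_true`` (noise-free model output, kept for testing).
    """
    if sigma_chl < 0:
        raise ValueError("sigma_chl must be >= 0")
    if arrival_times is None:
        arrival_times = noon_arrivals(forcing, constants, every_third=every_third)
    sim = SeriesSimulator(constants, forcing, arrival_times, exclusion)
    chl_true, _ = sim.run(params_true)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_chl, len(chl_true)) if sigma_chl > 0 else 0.0
    return pd.DataFrame(
        {"time": pd.DatetimeIndex(arrival_times), "chl": chl_true + noise,
         "chl_true": chl_true}
    )


# --------------------------------------------------------------------------
# toy blackbox


@dataclass
class ToyConfig:
    """The two-parameter toy calibration problem.

    The blackbox is y(t, x) = x1 * sin((t - x2)^3), with reference
    values (1.15, 1.4) and additive Gaussian noise of amplitude 0.05.
    The t-grid (200 points on [0, 3]) covers both the flat region near
    t = x2 and the fast oscillations at larger t.
    """

    x_ref: tuple = (1.15, 1.4)
    sigma: float = 0.05
    n_points: int = 200
    t_min: float = 0.0
    t_max: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def t_grid(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.n_points)


def toy_model(t, x) -> np.ndarray:
    """y = x1 * sin((t - x2)^3)."""
    t = np.asarray(t, dtype=float)
    x1, x2 = float(x[0]), float(x[1])
    return x1 * np.sin((t - x2) ** 3)


def generate_toy_data(config: ToyConfig, seed: int = 0, sigma: float | None = None):
    """Reference toy curve plus Gaussian noise; returns (t_grid, y_obs)."""
    t = config.t_grid
    y_ref = toy_model(t, config.x_ref)
    s = config.sigma if sigma is None else sigma
    rng = np.random.default_rng(seed)
    y = y_ref + (rng.normal(0.0, s, len(t)) if s > 0 else 0.0)
    return t, y
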