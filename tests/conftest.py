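import datetime as dt

import pytest

from cottonfibre.fibre_quality import QualityParams
from cottonfibre.weather import SeasonWeather, WeatherDay


@pytest.fixture(scope="session")
def quality_params() -> QualityParams:
    return QualityParams()


def make_constant_weather(
    t_min: float,
    t_max: float,
    start: dt.date = dt.date(2000, 4, 1),
    n_days: int = 214,
    label: str = "constant",
) -> SeasonWeather:
    """A flat daily series: every day identical (t_min, t_max)."""
    days = [
        WeatherDay(start + dt.timedelta(days=i), t_min, t_max) for i in range(n_days)
    ]
    return SeasonWeather(label, days)


@pytest.fixture(scope="session")
def optimal_weather() -> SeasonWeather:
    """Every day at the developmental optimum: t_mean = 25 °C, E(T) = 1."""
    return make_constant_weather(20.0, 30.0)


@pytest.fixture(scope="session")
def saturating_weather() -> SeasonWeather:
    """A season of days on which every temperature reduction factor is 1.

    t_mean = 27 °C sits in the narrow window where the length quadratic and
    the strength-mean linear both reach 1, t_min = 25.2 °C saturates the
    micronaire factor, and TD = 3.6 °C keeps the diurnal-range factor at 1.
    """
    return make_constant_weather(25.2, 28.8)


@pytest.fixture(scope="session")
def cold_autumn_weather():
    """Synthetic site with a warm mid-summer but rapidly cooling autumn."""
    from cottonfibre.weather import SyntheticWeatherSpec, generate_weather

    spec = SyntheticWeatherSpec(
        annual_mean=12.5,
        amplitude=14.0,
        diurnal_range=10.0,
        noise_sd=1.0,
        seed=7,
        site_label="cold-autumn",
    )
    return generate_weather(spec)
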