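"""Seeded generative simulator for class-discovery/resistance timelines.

Emulates the statistical structure the analysis assumes: screening draws
arrive as a homogeneous Poisson process at rate ``n`` per year once the
lag phase ends, each draw hits one of ``k`` classes uniformly at random,
a discovered class acquires detectable resistance after an exponential
waiting time with median ``half_life``, and an optional exponential
discovery-to-clinical-use delay fills the clinical_use_year column.
Resistance detected after the observation year is recorded as missing
(right-censoring). Continuous event times are floored to integer calendar
years on output, matching the resolution of the real tables.

A single numpy Generator seeded from the mandatory config seed drives all
sampling, so every output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discovery import DiscoveryParams
from .timeline import TimelineRecord, TimelineTable

_LN2 = float(np.log(2.0))


@dataclass
class SimulationConfig:
    """Generative settings: discovery params, resistance half-life (years),
    mean discovery-to-use delay (years; 0 = immediate), horizon and
    observation years, and the mandatory seed."""

    dparams: DiscoveryParams
    half_life: float
    horizon_year: int
    seed: int
    use_delay_mean: float = 8.0
    observation_year: int | None = None

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.use_delay_mean < 0:
            raise ValueError("use_delay_mean must be >= 0")
        if self.horizon_year <= self.dparams.t0:
            raise ValueError("horizon_year must be after the origin year")
        if self.observation_year is None:
            self.observation_year = self.horizon_year
        if self.observation_year > self.horizon_year:
            raise ValueError("observation_year cannot exceed horizon_year")


@dataclass
class DiscoverySample:
    """Raw draw events plus first-discovery times of each discovered class.

    ``draw_times`` are continuous calendar times on (t0+t_lag, horizon];
    ``draw_classes`` the 0-based class index of each draw;
    ``first_draw_time`` maps class index -> continuous first-draw time;
    ``discovery_year`` maps class index -> floor(first draw time).
    """

    draw_times: np.ndarray
    draw_classes: np.ndarray
    first_draw_time: dict[int, float]
    discovery_year: dict[int, int]


def simulate_discovery_process(config: SimulationConfig,
                               rng: np.random.Generator | None = None) -> DiscoverySample:
    """Sample the Poisson draw process and per-class first discoveries."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.dparams
    onset = p.t0 + p.t_lag
    span = config.horizon_year - onset
    if span <= 0:
        return DiscoverySample(np.array([]), np.array([], int), {}, {})
    m = rng.poisson(p.n * span)
    times = np.sort(onset + span * rng.random(m))
    classes = rng.integers(0, p.k, size=m)
    # times are sorted, so the first index of each class is its discovery
    uniq, first_idx = np.unique(classes, return_index=True)
    first = {int(c): float(times[i]) for c, i in zip(uniq, first_idx)}
    years = {cls: int(np.floor(t)) for cls, t in first.items()}
    return DiscoverySample(times, classes, first, years)


def simulate_timelines(config: SimulationConfig) -> TimelineTable:
    """Generate a full synthetic :class:`TimelineTable`.

    Each discovered class gets a clinical-use year (discovery time plus an
    exponential delay, floored) and a resistance year (discovery time plus
    an exponential waiting time with median ``half_life``, floored),
    recorded only if it falls on or before the observation year.
    """
    rng = np.random.default_rng(config.seed)
    sample = simulate_discovery_process(config, rng)
    records: list[TimelineRecord] = []
    scale = config.half_life / _LN2  # exponential mean giving median = half_life
    for cls in sorted(sample.first_draw_time):
        t_disc = sample.first_draw_time[cls]
        disc_year = sample.discovery_year[cls]
        if config.use_delay_mean > 0:
            use_year = int(np.floor(t_disc + rng.exponential(config.use_delay_mean)))
        else:
            use_year = disc_year
        t_res = t_disc + rng.exponential(scale)
        res_year = int(np.floor(t_res))
        records.append(
            TimelineRecord(
                class_name=f"class_{cls:03d}",
                discovery_year=disc_year,
                clinical_use_year=use_year,
                resistance_year=res_year if res_year <= config.observation_year else None,
            )
        )
    return TimelineTable(records)


def make_fixture() -> TimelineTable:
    """A small hard-coded illustrative table for docs and smoke tests.

    Entirely synthetic: the class names echo familiar antibacterial
    families but the years are invented, not historical ground truth. Two
    classes are right-censored (no resistance year) and one shows
    same-year resistance.
    """
    rows = [
        ("synthetic_sulfonamide", 1935, 1936, 1942),
        ("synthetic_beta_lactam", 1940, 1943, 1947),
        ("synthetic_aminoglycoside", 1944, 1946, 1950),
        ("synthetic_glycopeptide", 1953, 1958, 1987),
        ("synthetic_quinolone", 1962, 1967, 1968),
        ("synthetic_oxazolidinone", 1978, 2000, None),
        ("synthetic_lipopeptide", 1986, 2003, None),
        ("synthetic_nitrofuran", 1950, 1953, 1950),
    ]
    return TimelineTable(
        [TimelineRecord(name, d, u, r) for name, d, u, r in rows]
    )
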