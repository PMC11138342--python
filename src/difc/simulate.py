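"""Synthetic four-channel scan generation with known ground truth.

Emulates the two experiment classes the pipeline must handle:

* **flow phantom**: a cell suspension pumped through tubing in a
  tissue-mimicking scattering block — a steady Poisson stream of single
  cells (~10^3 cells/mL) or cultured clusters (~10^4 cells/mL, roughly
  10^3 clusters/mL) at 25 uL/min, all moving in one direction;
* **in vivo scan**: two fluorescent cell populations shed into
  circulation at rates that drift over minutes, modeled as a log-Gaussian
  (Ornstein-Uhlenbeck) modulation of the Poisson intensity that can be
  shared between the populations or independent — the knob that makes the
  rate-correlation analysis testable.

Each ground-truth event renders as a Gaussian transit pulse on both probes
of every expressed color (amplitude = sum of member-cell amplitudes, plus
spectral bleed into the opposite channel), delayed on probe 2 by the
transit time over the probe separation.  Channel noise, a slowly drifting
background, PMT saturation clipping and all-channel motion artifacts are
added on top.  Identical (config, seed) pairs give identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CHANNELS, GREEN, ORANGE, Scan

__all__ = [
    "SimConfig",
    "GroundTruthEvent",
    "sample_events",
    "render_scan",
    "simulate_scan",
    "preset_config",
    "write_events",
    "read_events",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic scan.

    Concentrations are events (single cells or whole clusters) per mL per
    population; the arrival rate of a population is
    ``concentration x flow_rate x duration``.  Per-cell brightness is
    log-normal per color (fluorescent-protein expression is heterogeneous
    and multiplicative).  ``tr_true[color]`` is the true bleed ratio of
    that fluorophore into the opposite channel.
    """

    duration_s: float
    sampling_rate: float = 2000.0
    probe_separation_mm: float = 3.0
    flow_rate_ul_min: float = 25.0
    concentration_per_ml: dict = field(
        default_factory=lambda: {GREEN: 1000.0, ORANGE: 1000.0}
    )
    #: mean of the shifted-geometric cluster size distribution; 1 = singles
    cluster_size_mean: float = 1.0
    #: probability that a cluster of >= 2 cells mixes both fluorophores
    two_fp_mixing: float = 0.0
    speed_mean_mm_s: float = 30.0
    speed_gsd: float = 1.15  # geometric sd of the log-normal speed jitter
    sensing_length_mm: float = 1.0  # transit FWHM = sensing_length / speed
    cell_amp_median_mv: dict = field(
        default_factory=lambda: {GREEN: 80.0, ORANGE: 80.0}
    )
    cell_amp_gsd: float = 2.0
    tr_true: dict = field(default_factory=lambda: {GREEN: 0.04, ORANGE: 0.06})
    noise_sigma_mv: float = 2.0
    background_mv: float = 50.0
    drift_amp_mv: float = 10.0
    drift_period_s: float = 120.0
    direction_forward_frac: float = 1.0
    artifact_rate_per_min: float = 0.0
    artifact_amp_mv: float = 300.0
    artifact_width_s: float = 0.05
    saturation_limit_mv: float = 1500.0
    #: log-intensity sd of the shedding-rate modulation (0 = steady)
    modulation_sigma: float = 0.0
    modulation_tau_s: float = 120.0  # correlation time of the modulation
    #: fraction of modulation variance shared between the two populations
    modulation_shared: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s < 0 or self.sampling_rate <= 0:
            raise ValueError("invalid duration or sampling rate")
        for name in ("flow_rate_ul_min", "speed_mean_mm_s", "sensing_length_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if any(v < 0 for v in self.concentration_per_ml.values()):
            raise ValueError("concentrations must be >= 0")
        if not 0.0 <= self.modulation_shared <= 1.0:
            raise ValueError("modulation_shared must be in [0, 1]")

    @property
    def flow_rate_ml_min(self) -> float:
        return self.flow_rate_ul_min / 1000.0


@dataclass(frozen=True)
class GroundTruthEvent:
    """One true arrival (cell, cluster or artifact) with its parameters."""

    time_s: float  # arrival time at probe 1
    population: str
    n_green: int
    n_orange: int
    amps_green: tuple  # per-cell peak amplitudes, mV
    amps_orange: tuple
    direction: str  # forward / reverse
    speed_mm_s: float
    is_artifact: bool = False
    artifact_amp_mv: float = 0.0

    def __post_init__(self) -> None:
        if not self.is_artifact and self.n_green + self.n_orange < 1:
            raise ValueError("non-artifact event must carry at least one cell")


def _cluster_size(rng: np.random.Generator, mean: float) -> int:
    """Shifted geometric: P(s) = p(1-p)^(s-1) with mean 1/p."""
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def _modulated_counts(
    rng: np.random.Generator,
    base_per_s: dict,
    duration_s: float,
    sigma: float,
    tau_s: float,
    shared: float,
) -> dict:
    """Per-1s-bin Poisson counts under a log-OU intensity modulation."""
    n_bins = max(int(math.ceil(duration_s)), 1)
    a = math.exp(-1.0 / tau_s)
    b = math.sqrt(1.0 - a * a)

    def ou() -> np.ndarray:
        g = np.empty(n_bins)
        g[0] = rng.standard_normal()
        eps = rng.standard_normal(n_bins - 1) if n_bins > 1 else np.empty(0)
        for i in range(1, n_bins):
            g[i] = a * g[i - 1] + b * eps[i - 1]
        return g

    g_shared = ou()
    counts = {}
    for pop, base in base_per_s.items():
        g = math.sqrt(shared) * g_shared + math.sqrt(1.0 - shared) * ou()
        lam = base * np.exp(sigma * g - 0.5 * sigma**2)
        # last (possibly partial) bin
        widths = np.ones(n_bins)
        widths[-1] = duration_s - (n_bins - 1)
        counts[pop] = rng.poisson(lam * widths)
    return counts


def sample_events(
    config: SimConfig, seed: int | np.random.SeedSequence | None = None
) -> list[GroundTruthEvent]:
    """Draw the ground-truth event list for one scan.

    Arrivals per population are Poisson with mean
    ``concentration x flow(mL/min) x duration(min)`` (inhomogeneous when a
    shedding-rate modulation is configured); cluster compositions come from
    the size distribution and the mixing probability.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    minutes = config.duration_s / 60.0
    events: list[GroundTruthEvent] = []

    base_per_min = {
        pop: conc * config.flow_rate_ml_min
        for pop, conc in config.concentration_per_ml.items()
    }

    if config.modulation_sigma > 0:
        counts_by_bin = _modulated_counts(
            rng,
            {p: r / 60.0 for p, r in base_per_min.items()},
            config.duration_s,
            config.modulation_sigma,
            config.modulation_tau_s,
            config.modulation_shared,
        )
        pop_times = {}
        for pop, counts in counts_by_bin.items():
            ts = []
            for i, c in enumerate(counts):
                width = min(1.0, config.duration_s - i)
                ts.extend(i + rng.uniform(0.0, width, size=int(c)))
            pop_times[pop] = np.array(ts)
    else:
        pop_times = {}
        for pop, rate in base_per_min.items():
            n = rng.poisson(rate * minutes)
            pop_times[pop] = rng.uniform(0.0, config.duration_s, size=n)

    for pop, ts in pop_times.items():
        for t in np.sort(ts):
            size = _cluster_size(rng, config.cluster_size_mean)
            mixed = size >= 2 and rng.random() < config.two_fp_mixing
            if mixed:
                # composition: binomial split conditioned on both colors present
                n_g = int(rng.binomial(size - 2, 0.5)) + 1
                n_o = size - n_g
                if pop == ORANGE:
                    n_g, n_o = n_o, n_g
            else:
                n_g = size if pop == GREEN else 0
                n_o = size if pop == ORANGE else 0
            amps_g = tuple(
                float(a)
                for a in config.cell_amp_median_mv[GREEN]
                * np.exp(math.log(config.cell_amp_gsd) * rng.standard_normal(n_g))
            )
            amps_o = tuple(
                float(a)
                for a in config.cell_amp_median_mv[ORANGE]
                * np.exp(math.log(config.cell_amp_gsd) * rng.standard_normal(n_o))
            )
            speed = config.speed_mean_mm_s * math.exp(
                math.log(config.speed_gsd) * rng.standard_normal()
            )
            direction = (
                "forward"
                if rng.random() < config.direction_forward_frac
                else "reverse"
            )
            events.append(
                GroundTruthEvent(
                    time_s=float(t),
                    population=pop,
                    n_green=n_g,
                    n_orange=n_o,
                    amps_green=amps_g,
                    amps_orange=amps_o,
                    direction=direction,
                    speed_mm_s=float(speed),
                )
            )

    n_art = rng.poisson(config.artifact_rate_per_min * minutes)
    for t in rng.uniform(0.0, config.duration_s, size=n_art):
        events.append(
            GroundTruthEvent(
                time_s=float(t),
                population="artifact",
                n_green=0,
                n_orange=0,
                amps_green=(),
                amps_orange=(),
                direction="forward",
                speed_mm_s=config.speed_mean_mm_s,
                is_artifact=True,
                artifact_amp_mv=float(
                    config.artifact_amp_mv * rng.uniform(0.5, 1.5)
                ),
            )
        )
    events.sort(key=lambda e: e.time_s)
    return events


def _add_pulse(
    trace: np.ndarray, center_s: float, amp: float, fwhm_s: float, fs: float
) -> None:
    sig = fwhm_s / _FWHM_TO_SIGMA
    lo = max(int((center_s - 5 * sig) * fs), 0)
    hi = min(int((center_s + 5 * sig) * fs) + 1, trace.size)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    trace[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sig) ** 2)


def render_scan(
    events: Sequence[GroundTruthEvent],
    config: SimConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> Scan:
    """Render ground-truth events into a noisy four-channel scan."""
    fs = config.sampling_rate
    n = int(round(fs * config.duration_s))
    rng = np.random.default_rng(config.seed if seed is None else seed)

    pulses = {ch: np.zeros(n) for ch in CHANNELS}
    for ev in events:
        if ev.is_artifact:
            for ch in CHANNELS:
                _add_pulse(
                    pulses[ch], ev.time_s, ev.artifact_amp_mv,
                    config.artifact_width_s, fs,
                )
            continue
        fwhm = config.sensing_length_mm / ev.speed_mm_s
        if fwhm < 2.0 / fs:
            warnings.warn(
                f"event at {ev.time_s:.3f} s transits faster than 2 samples; skipped",
                stacklevel=2,
            )
            continue
        g_total = sum(ev.amps_green)
        o_total = sum(ev.amps_orange)
        amp = {
            GREEN: g_total + config.tr_true[ORANGE] * o_total,
            ORANGE: o_total + config.tr_true[GREEN] * g_total,
        }
        delay = config.probe_separation_mm / ev.speed_mm_s
        centers = {
            1: ev.time_s,
            2: ev.time_s + (delay if ev.direction == "forward" else -delay),
        }
        for ch in CHANNELS:
            if amp[ch.color] > 0:
                _add_pulse(pulses[ch], centers[ch.probe], amp[ch.color], fwhm, fs)

    t = np.arange(n) / fs
    background = config.background_mv + (
        config.drift_amp_mv * np.sin(2 * math.pi * t / config.drift_period_s)
        if config.drift_amp_mv
        else 0.0
    )
    signal = {}
    for ch in CHANNELS:
        noise = (
            config.noise_sigma_mv * rng.standard_normal(n)
            if config.noise_sigma_mv
            else 0.0
        )
        # the detector rail clips the noisy analog signal
        signal[ch] = np.minimum(
            pulses[ch] + background + noise, config.saturation_limit_mv
        )
    return Scan(
        sampling_rate=fs,
        signal=signal,
        probe_separation_mm=config.probe_separation_mm,
        metadata={"scenario": "synthetic"},
    )


def simulate_scan(
    config: SimConfig, seed: int | None = None
) -> tuple[Scan, list[GroundTruthEvent]]:
    """Sample events and render the scan with one reproducible seed."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_events, s_noise = root.spawn(2)
    events = sample_events(config, s_events)
    scan = render_scan(events, config, s_noise)
    return scan, events


def preset_config(scenario: str, duration_s: float | None = None, **overrides) -> SimConfig:
    """Documented generative presets for the standard study conditions.

    * ``phantom_single``: 10^3 single cells/mL of each color pumped at
      25 uL/min (expected arrival rate 25/min per color).
    * ``phantom_cluster``: cultured clusters at ~10^3 clusters/mL per color
      (mean size 10, i.e. ~10^4 cells/mL); single-fluorophore suspensions
      by default — set ``two_fp_mixing`` for a co-culture run.
    * ``invivo_mm``: two populations shed into ~100 uL/min of tail-artery
      flow at slowly fluctuating rates; ``modulation_shared`` selects
      perfusion-like (shared) versus shedding-like (independent)
      fluctuation.
    """
    if scenario == "phantom_single":
        cfg = SimConfig(
            duration_s=600.0 if duration_s is None else duration_s,
            flow_rate_ul_min=25.0,
            concentration_per_ml={GREEN: 1000.0, ORANGE: 1000.0},
            cluster_size_mean=1.0,
            two_fp_mixing=0.0,
        )
    elif scenario == "phantom_cluster":
        cfg = SimConfig(
            duration_s=600.0 if duration_s is None else duration_s,
            flow_rate_ul_min=25.0,
            concentration_per_ml={GREEN: 1000.0, ORANGE: 1000.0},
            cluster_size_mean=10.0,
            two_fp_mixing=0.0,
        )
    elif scenario == "invivo_mm":
        cfg = SimConfig(
            duration_s=3600.0 if duration_s is None else duration_s,
            flow_rate_ul_min=100.0,
            concentration_per_ml={GREEN: 40.0, ORANGE: 40.0},
            cluster_size_mean=1.5,
            two_fp_mixing=0.1,
            modulation_sigma=0.7,
            modulation_tau_s=120.0,
            modulation_shared=0.0,
            artifact_rate_per_min=0.2,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# ground-truth tables

_EVENT_COLUMNS = [
    "time_s",
    "population",
    "n_green",
    "n_orange",
    "amps_green",
    "amps_orange",
    "direction",
    "speed_mm_s",
    "is_artifact",
    "artifact_amp_mv",
]


def write_events(events: Sequence[GroundTruthEvent], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "time_s": e.time_s,
                "population": e.population,
                "n_green": e.n_green,
                "n_orange": e.n_orange,
                "amps_green": ";".join(f"{a!r}" for a in e.amps_green),
                "amps_orange": ";".join(f"{a!r}" for a in e.amps_orange),
                "direction": e.direction,
                "speed_mm_s": e.speed_mm_s,
                "is_artifact": e.is_artifact,
                "artifact_amp_mv": e.artifact_amp_mv,
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_events(path: str | Path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GroundTruthEvent(
                time_s=float(row.time_s),
                population=str(row.population),
                n_green=int(row.n_green),
                n_orange=int(row.n_orange),
                amps_green=tuple(
                    float(a) for a in str(row.amps_green).split(";") if a
                ),
                amps_orange=tuple(
                    float(a) for a in str(row.amps_orange).split(";") if a
                ),
                direction=str(row.direction),
                speed_mm_s=float(row.speed_mm_s),
                is_artifact=bool(row.is_artifact)
                if not isinstance(row.is_artifact, str)
                else row.is_artifact == "True",
                artifact_amp_mv=float(row.artifact_amp_mv),
            )
        )
    return out
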