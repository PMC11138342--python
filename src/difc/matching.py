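"""Cross-probe peak matching and motion-artifact rejection.

A genuine circulating cell passes both probe sensing regions, producing the
same-colored peak on probe 1 and probe 2 separated by the transit time over
the 3 mm probe separation.  Matching candidate peaks across probes — on
amplitude, width and inter-probe delay — separates real directional
detections (forward = arterial, reverse = venous) from instrument noise.
Unmatched peaks, and peaks that appear simultaneously on all four channels
(motion artifacts), are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .detect import PeakCandidate
from .io import CHANNELS, ChannelId

__all__ = [
    "MatchParams",
    "MatchedDetection",
    "match_across_probes",
    "flag_motion_artifacts",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class MatchParams:
    """Tolerances for cross-probe matching.

    The delay window derives from a physiological speed range: with 3 mm
    separation, speeds of 5-150 mm/s give inter-probe delays of
    0.02-0.6 s.  Amplitude and width must agree within a multiplicative
    factor (probe sensitivity differs with vessel depth).
    """

    speed_min_mm_s: float = 5.0
    speed_max_mm_s: float = 150.0
    amp_ratio_tol: float = 2.0
    width_ratio_tol: float = 2.0
    artifact_window_s: float = 0.010

    def delay_bounds(self, probe_separation_mm: float) -> tuple[float, float]:
        min_delay = probe_separation_mm / self.speed_max_mm_s
        max_delay = probe_separation_mm / self.speed_min_mm_s
        if not min_delay < max_delay:
            raise ValueError("speed range yields empty delay window")
        return min_delay, max_delay


@dataclass(frozen=True)
class MatchedDetection:
    """A candidate peak pair matched across the two probes."""

    color: str
    peak_p1: PeakCandidate
    peak_p2: PeakCandidate
    direction: str  # forward: probe1 -> probe2 (positive delay)
    delay_s: float  # signed, peak_p2.time - peak_p1.time
    speed_mm_s: float
    match_score: float

    @property
    def time_s(self) -> float:
        """Detection time, taken at the probe-1 peak."""
        return self.peak_p1.time_s

    @property
    def amplitude_mV(self) -> float:
        return 0.5 * (self.peak_p1.amplitude_mV + self.peak_p2.amplitude_mV)

    @property
    def amplitude_sigma(self) -> float:
        return 0.5 * (self.peak_p1.amplitude_sigma + self.peak_p2.amplitude_sigma)

    @property
    def width_s(self) -> float:
        return 0.5 * (self.peak_p1.width_s + self.peak_p2.width_s)


def flag_motion_artifacts(
    candidates_by_channel: Mapping[ChannelId, Sequence[PeakCandidate]],
    coincidence_window_s: float = 0.010,
) -> set[PeakCandidate]:
    """Candidates co-occurring on all four channels within the window.

    Motion of the animal or probe produces a simultaneous intensity change
    on every channel, whereas a real transit hits the two probes at
    different times; the window must therefore stay below the minimum
    inter-probe delay.  Returns the set of flagged candidates, which are
    removed before matching.
    """
    times = {
        ch: np.array(
            sorted(c.time_s for c in candidates_by_channel.get(ch, ())),
            dtype=float,
        )
        for ch in CHANNELS
    }
    flagged: set[PeakCandidate] = set()
    for ch in CHANNELS:
        others = [o for o in CHANNELS if o != ch]
        for cand in candidates_by_channel.get(ch, ()):
            hit = True
            for o in others:
                t = times[o]
                if t.size == 0:
                    hit = False
                    break
                i = np.searchsorted(t, cand.time_s)
                near = min(
                    abs(t[j] - cand.time_s)
                    for j in (i - 1, i)
                    if 0 <= j < t.size
                )
                if near > coincidence_window_s:
                    hit = False
                    break
            if hit:
                flagged.add(cand)
    return flagged


def match_across_probes(
    candidates_p1: Sequence[PeakCandidate],
    candidates_p2: Sequence[PeakCandidate],
    probe_separation_mm: float = 3.0,
    params: MatchParams = MatchParams(),
) -> tuple[list[MatchedDetection], list[PeakCandidate]]:
    """Pair same-color candidates across the probes.

    Matching is one color at a time (green with green, orange with orange).
    A feasible pair has an inter-probe delay of either sign within the
    physiological window and amplitude and width ratios within tolerance.
    Feasible pairs are scored by ``|log amplitude ratio| + |log width
    ratio| + |delay deviation from the median feasible delay|`` (each term
    normalized), and accepted greedily in ascending score so each candidate
    is used at most once; ties break on earlier probe-1 time.

    Returns ``(matched, unmatched)``; unmatched candidates are excluded
    from downstream counting.
    """
    for c in candidates_p1:
        if c.channel.probe != 1:
            raise ValueError("candidates_p1 contains a probe-2 candidate")
    for c in candidates_p2:
        if c.channel.probe != 2:
            raise ValueError("candidates_p2 contains a probe-1 candidate")
    colors = {c.channel.color for c in candidates_p1} | {
        c.channel.color for c in candidates_p2
    }
    if len(colors) > 1:
        raise ValueError("matching is per color; mixed colors supplied")

    min_delay, max_delay = params.delay_bounds(probe_separation_mm)

    delays: list[float] = []
    pairs: list[tuple[int, int, float, float, float]] = []
    for i, a in enumerate(candidates_p1):
        for j, b in enumerate(candidates_p2):
            delay = b.time_s - a.time_s
            if not (min_delay <= abs(delay) <= max_delay):
                continue
            amp_ratio = a.amplitude_mV / b.amplitude_mV
            if not (1.0 / params.amp_ratio_tol <= amp_ratio <= params.amp_ratio_tol):
                continue
            width_ratio = a.width_s / b.width_s
            if not (
                1.0 / params.width_ratio_tol <= width_ratio <= params.width_ratio_tol
            ):
                continue
            pairs.append((i, j, delay, abs(math.log(amp_ratio)), abs(math.log(width_ratio))))
            delays.append(abs(delay))

    if not pairs:
        return [], list(candidates_p1) + list(candidates_p2)

    med_delay = float(np.median(delays))
    span = max_delay - min_delay
    scored = []
    for i, j, delay, la, lw in pairs:
        score = (
            la / math.log(params.amp_ratio_tol)
            + lw / math.log(params.width_ratio_tol)
            + abs(abs(delay) - med_delay) / span
        )
        scored.append((score, candidates_p1[i].time_s, i, j, delay))
    scored.sort()

    used_p1: set[int] = set()
    used_p2: set[int] = set()
    matched: list[MatchedDetection] = []
    for score, _, i, j, delay in scored:
        if i in used_p1 or j in used_p2:
            continue
        used_p1.add(i)
        used_p2.add(j)
        a, b = candidates_p1[i], candidates_p2[j]
        matched.append(
            MatchedDetection(
                color=a.channel.color,
                peak_p1=a,
                peak_p2=b,
                direction=FORWARD if delay > 0 else REVERSE,
                delay_s=delay,
                speed_mm_s=probe_separation_mm / abs(delay),
                match_score=score,
            )
        )
    matched.sort(key=lambda m: m.time_s)
    unmatched = [c for i, c in enumerate(candidates_p1) if i not in used_p1]
    unmatched += [c for j, c in enumerate(candidates_p2) if j not in used_p2]
    return matched, unmatched


# ---------------------------------------------------------------------------
# matched-detection tables (CLI plumbing)

import pandas as pd



def matched_to_frame(matched: Sequence[MatchedDetection]) -> "pd.DataFrame":
    """Matched detections as a flat DataFrame (per-peak columns inlined)."""
    rows = []
    for m in matched:
        row = {
            "color": m.color,
            "direction": m.direction,
            "delay_s": m.delay_s,
            "speed_mm_s": m.speed_mm_s,
            "match_score": m.match_score,
        }
        for tag, pk in (("p1", m.peak_p1), ("p2", m.peak_p2)):
            row[f"{tag}_time_s"] = pk.time_s
            row[f"{tag}_index"] = pk.index
            row[f"{tag}_amplitude_mV"] = pk.amplitude_mV
            row[f"{tag}_amplitude_sigma"] = pk.amplitude_sigma
            row[f"{tag}_width_s"] = pk.width_s
            row[f"{tag}_snr_db"] = pk.snr_db
            row[f"{tag}_raw_mV"] = pk.raw_mV
        rows.append(row)
    cols = ["color", "direction", "delay_s", "speed_mm_s", "match_score"] + [
        f"{t}_{f}"
        for t in ("p1", "p2")
        for f in ("time_s", "index", "amplitude_mV", "amplitude_sigma",
                  "width_s", "snr_db", "raw_mV")
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_matched(df: "pd.DataFrame") -> list[MatchedDetection]:
    from .detect import PeakCandidate

    out = []
    for row in df.itertuples(index=False):
        peaks = {}
        for tag, probe in (("p1", 1), ("p2", 2)):
            peaks[tag] = PeakCandidate(
                channel=ChannelId(probe, str(row.color)),
                time_s=float(getattr(row, f"{tag}_time_s")),
                index=int(getattr(row, f"{tag}_index")),
                amplitude_mV=float(getattr(row, f"{tag}_amplitude_mV")),
                amplitude_sigma=float(getattr(row, f"{tag}_amplitude_sigma")),
                width_s=float(getattr(row, f"{tag}_width_s")),
                snr_db=float(getattr(row, f"{tag}_snr_db")),
                raw_mV=float(getattr(row, f"{tag}_raw_mV", float("nan"))),
            )
        out.append(
            MatchedDetection(
                color=str(row.color),
                peak_p1=peaks["p1"],
                peak_p2=peaks["p2"],
                direction=str(row.direction),
                delay_s=float(row.delay_s),
                speed_mm_s=float(row.speed_mm_s),
                match_score=float(row.match_score),
            )
        )
    return out
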