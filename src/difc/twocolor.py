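"""Two-fluorophore coincidence classification and cluster sizing.

A cluster containing both GFP+ and tdTomato+ cells produces coincident
peaks in the green and orange channels of one probe (a "2-lambda peak").
But a bright single-fluorophore cell also produces a coincident secondary
peak through spectral bleed between the emission filter bands.  The two
cases are separated by the bleed threshold: with amplitudes in local-noise
sigma units (so the detection limit is the constant 5), the largest
secondary amplitude attributable to bleed from a primary of amplitude
``I_pr`` is

    max(I_sec) = I_pr * (TR * I_pr + 5) / (I_pr - 5)

where ``TR`` is the fluorophore's bleed ratio.  ``TR`` is calibrated from
known single-fluorophore detections by the inverse relation

    TR_i = (I_sec* * (I_pr* - 5) - 5 * I_pr*) / I_pr***2

taking the maximum over calibration points (clamped at zero), which is the
smallest ``TR`` for which no calibration point classifies as
two-fluorophore.  A secondary amplitude above the threshold marks a true
two-fluorophore (2FP) cluster; at or below it the detection is attributed
to the primary fluorophore alone (1FP).

Cluster sizes follow from amplitude additivity: the number of cells of a
color is the detection amplitude divided by the per-cell reference
amplitude.  A 1FP detection sized at three or more nuclei is a 1FP
cluster (the >= 3 rule excludes a single cell in mitosis); every 2FP
detection is by construction a cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .io import GREEN, ORANGE
from .matching import MatchedDetection

__all__ = [
    "DETECTION_THRESHOLD_SIGMA",
    "SATURATION_LIMIT_MV",
    "TwoLambdaPeak",
    "BleedCalibration",
    "ClusterDetection",
    "find_two_lambda",
    "bleed_max_secondary",
    "estimate_bleed_ratio",
    "classify_two_lambda",
    "flag_saturation",
    "size_cluster",
    "CalibrationError",
]

#: The k-sigma detection threshold; appears as the constant 5 in the bleed
#: equations because amplitudes there are in local-noise-sigma units.
DETECTION_THRESHOLD_SIGMA = 5.0

#: PMT amplitudes above this are saturated and their relative intensities
#: unreliable; such detections are excluded from 1FP/2FP classification.
SATURATION_LIMIT_MV = 1500.0

ONE_FP = "oneFP"
TWO_FP = "twoFP"
INDETERMINATE = "indeterminate"


class CalibrationError(ValueError):
    """Bleed-ratio calibration is impossible with the given points."""


@dataclass(frozen=True)
class TwoLambdaPeak:
    """Coincident green and orange matched detections on one probe pair.

    ``I_pr``/``I_sec`` are the larger/smaller of the two channel amplitudes
    in local-noise-sigma units.
    """

    green_det: MatchedDetection
    orange_det: MatchedDetection
    probe: int = 1  # probe whose peak times anchored the coincidence
    classification: str = INDETERMINATE
    saturated: bool = False

    @property
    def primary_color(self) -> str:
        return (
            GREEN
            if self.green_det.amplitude_sigma >= self.orange_det.amplitude_sigma
            else ORANGE
        )

    @property
    def I_pr(self) -> float:
        return max(self.green_det.amplitude_sigma, self.orange_det.amplitude_sigma)

    @property
    def I_sec(self) -> float:
        return min(self.green_det.amplitude_sigma, self.orange_det.amplitude_sigma)

    @property
    def time_s(self) -> float:
        return self.green_det.time_s

    def det(self, color: str) -> MatchedDetection:
        return self.green_det if color == GREEN else self.orange_det


@dataclass(frozen=True)
class BleedCalibration:
    """Bleed ratio of one fluorophore into the other's filter band."""

    fluorophore: str  # color of the *primary* (bleeding) fluorophore
    TR: float
    points: tuple  # retained (I_pr*, I_sec*) calibration pairs, sigma units

    def __post_init__(self) -> None:
        if self.TR < 0:
            raise ValueError("TR must be >= 0")


@dataclass(frozen=True)
class ClusterDetection:
    """A sized detection: cell counts per color and cluster status."""

    source: object  # MatchedDetection or TwoLambdaPeak
    n_green: int
    n_orange: int
    kind: str  # single_1FP | cluster_1FP | cluster_2FP

    @property
    def is_cluster(self) -> bool:
        return self.kind in ("cluster_1FP", "cluster_2FP")


def find_two_lambda(
    matched_green: Sequence[MatchedDetection],
    matched_orange: Sequence[MatchedDetection],
    coincidence_window_s: float | None = None,
) -> tuple[list[TwoLambdaPeak], list[MatchedDetection]]:
    """Pair coincident green and orange detections into 2-lambda peaks.

    Detections pair when their probe-1 peak times differ by at most the
    coincidence window; each detection joins at most one pair (nearest in
    time wins).  The default window is half the mean matched peak width,
    floored at 5 ms: both channel peaks of one transit come from the same
    passage through the sensing region.

    Returns ``(two_lambda, singletons)`` where singletons are the
    single-color detections left over.
    """
    if coincidence_window_s is None:
        widths = [m.width_s for m in matched_green] + [
            m.width_s for m in matched_orange
        ]
        mean_w = sum(widths) / len(widths) if widths else 0.0
        coincidence_window_s = max(0.5 * mean_w, 0.005)

    pairs = []
    for i, g in enumerate(matched_green):
        for j, o in enumerate(matched_orange):
            dt = abs(g.peak_p1.time_s - o.peak_p1.time_s)
            if dt <= coincidence_window_s:
                pairs.append((dt, g.peak_p1.time_s, i, j))
    pairs.sort()
    used_g: set[int] = set()
    used_o: set[int] = set()
    out: list[TwoLambdaPeak] = []
    for dt, _, i, j in pairs:
        if i in used_g or j in used_o:
            continue
        used_g.add(i)
        used_o.add(j)
        out.append(TwoLambdaPeak(green_det=matched_green[i], orange_det=matched_orange[j]))
    out.sort(key=lambda p: p.time_s)
    singletons = [m for i, m in enumerate(matched_green) if i not in used_g]
    singletons += [m for j, m in enumerate(matched_orange) if j not in used_o]
    return out, singletons


def bleed_max_secondary(i_pr: float, tr: float) -> float:
    """Largest secondary amplitude attributable to spectral bleed.

    ``max(I_sec) = I_pr * (TR * I_pr + 5) / (I_pr - 5)``, amplitudes in
    local-noise-sigma units.  Diverges as ``I_pr`` approaches the 5-sigma
    detection threshold from above (classification is maximally
    conservative near threshold) and approaches ``TR * I_pr`` from above
    for bright primaries.
    """
    if not i_pr > DETECTION_THRESHOLD_SIGMA:
        raise ValueError(
            f"primary amplitude must exceed the {DETECTION_THRESHOLD_SIGMA}-sigma "
            f"detection threshold, got {i_pr}"
        )
    t = DETECTION_THRESHOLD_SIGMA
    return i_pr * (tr * i_pr + t) / (i_pr - t)


def estimate_bleed_ratio(
    points: Sequence[tuple[float, float]], fluorophore: str = GREEN
) -> BleedCalibration:
    """Calibrate the bleed ratio TR from single-fluorophore detections.

    Each point is a known 1FP ``(I_pr*, I_sec*)`` pair in sigma units.  The
    per-point ratio ``TR_i = (I_sec*(I_pr*-5) - 5 I_pr*) / I_pr***2`` is the
    TR that would place the threshold exactly on that point; taking the
    maximum (clamped at zero) yields the lowest TR at which zero
    calibration points classify as two-fluorophore — the conservative
    operating point that absorbs the worst-case coincidence of noise and
    bleed seen in calibration.
    """
    t = DETECTION_THRESHOLD_SIGMA
    kept = []
    for i_pr, i_sec in points:
        if not i_pr > t:
            warnings.warn(
                f"calibration point with primary amplitude {i_pr} <= "
                f"{t} sigma rejected",
                stacklevel=2,
            )
            continue
        kept.append((float(i_pr), float(i_sec)))
    if not kept:
        raise CalibrationError("no usable calibration points (all I_pr* <= 5)")
    tr = max((i_sec * (i_pr - t) - t * i_pr) / i_pr**2 for i_pr, i_sec in kept)
    return BleedCalibration(fluorophore=fluorophore, TR=max(0.0, tr), points=tuple(kept))


def classify_two_lambda(
    peak: TwoLambdaPeak,
    calib_green: BleedCalibration,
    calib_orange: BleedCalibration,
) -> str:
    """Classify a 2-lambda peak as one- or two-fluorophore.

    The TR of the *primary* color's fluorophore sets the threshold: a
    secondary amplitude above ``bleed_max_secondary(I_pr, TR)`` cannot be
    bleed alone, so the detection contains cells of both colors (2FP).
    Saturated peaks and peaks whose primary is at or below the detection
    threshold are indeterminate.
    """
    if peak.saturated:
        return INDETERMINATE
    if not peak.I_pr > DETECTION_THRESHOLD_SIGMA:
        return INDETERMINATE
    calib = calib_green if peak.primary_color == GREEN else calib_orange
    limit = bleed_max_secondary(peak.I_pr, calib.TR)
    # relative tolerance so the calibration point that set TR (for which
    # I_sec equals the threshold up to round-off) never flips to 2FP
    return TWO_FP if peak.I_sec > limit * (1.0 + 1e-9) else ONE_FP


def flag_saturation(
    detection: MatchedDetection | TwoLambdaPeak,
    limit_mv: float = SATURATION_LIMIT_MV,
) -> bool:
    """True iff any constituent peak saturated the detector.

    Two conditions, either sufficient: the background-subtracted peak
    amplitude exceeds the limit, or the raw signal at the peak reached the
    rail (``raw_mV >= limit``) — a rail-clipped peak reports an amplitude
    *below* the limit yet its relative channel intensities are unreliable.
    """
    if isinstance(detection, TwoLambdaPeak):
        peaks = [
            detection.green_det.peak_p1,
            detection.green_det.peak_p2,
            detection.orange_det.peak_p1,
            detection.orange_det.peak_p2,
        ]
    else:
        peaks = [detection.peak_p1, detection.peak_p2]
    for p in peaks:
        if p.amplitude_mV > limit_mv:
            return True
        if math.isfinite(p.raw_mV) and p.raw_mV >= limit_mv:
            return True
    return False


def _round_count(x: float) -> int:
    # round half away from zero; cell counts are at least 1 once detected
    return max(1, int(x + 0.5))


def size_cluster(
    detection: MatchedDetection | TwoLambdaPeak,
    ref_green_mv: float,
    ref_orange_mv: float,
    calib_green: BleedCalibration | None = None,
    calib_orange: BleedCalibration | None = None,
) -> ClusterDetection:
    """Estimate cell counts from amplitude and assign the cluster kind.

    Counts assume linear amplitude additivity: ``n = round(amplitude /
    per-cell reference amplitude)``, at least 1 for a detected color.  For a
    2FP detection the secondary amplitude is first bleed-corrected by
    subtracting ``TR * primary amplitude`` so bleed does not inflate the
    minority-color count.  A single-color (or 1FP-classified) detection is
    a cluster only at three or more nuclei; every 2FP detection is a
    cluster.
    """
    if not (ref_green_mv > 0 and ref_orange_mv > 0):
        raise ValueError("per-cell reference amplitudes must be positive")
    refs = {GREEN: ref_green_mv, ORANGE: ref_orange_mv}

    if isinstance(detection, MatchedDetection):
        color = detection.color
        n = _round_count(detection.amplitude_mV / refs[color])
        n_green = n if color == GREEN else 0
        n_orange = n if color == ORANGE else 0
        kind = "cluster_1FP" if n >= 3 else "single_1FP"
        return ClusterDetection(detection, n_green, n_orange, kind)

    peak = detection
    if peak.classification == TWO_FP:
        pri = peak.primary_color
        sec = ORANGE if pri == GREEN else GREEN
        calib = calib_green if pri == GREEN else calib_orange
        tr = calib.TR if calib is not None else 0.0
        amp_pri = peak.det(pri).amplitude_mV
        amp_sec = max(peak.det(sec).amplitude_mV - tr * amp_pri, 0.0)
        counts = {pri: _round_count(amp_pri / refs[pri]), sec: _round_count(amp_sec / refs[sec])}
        return ClusterDetection(peak, counts[GREEN], counts[ORANGE], "cluster_2FP")

    # 1FP (or indeterminate) 2-lambda peak: attribute to the primary color
    pri = peak.primary_color
    n = _round_count(peak.det(pri).amplitude_mV / refs[pri])
    n_green = n if pri == GREEN else 0
    n_orange = n if pri == ORANGE else 0
    kind = "cluster_1FP" if n >= 3 else "single_1FP"
    return ClusterDetection(peak, n_green, n_orange, kind)
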