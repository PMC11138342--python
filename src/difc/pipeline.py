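"""End-to-end processing of one scan: detect, reject artifacts, match,
pair coincident colors, classify, size, and emit detection records."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .detect import DetectionParams, PeakCandidate, detect_channel
from .io import CHANNELS, COLORS, GREEN, ORANGE, ChannelId, DetectionRecord, Scan
from .matching import (
    MatchedDetection,
    MatchParams,
    flag_motion_artifacts,
    match_across_probes,
)
from .twocolor import (
    SATURATION_LIMIT_MV,
    BleedCalibration,
    TwoLambdaPeak,
    classify_two_lambda,
    find_two_lambda,
    flag_saturation,
    size_cluster,
)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "calibration_points"]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable of the processing chain, with the standard defaults."""

    detection: DetectionParams = DetectionParams()
    match: MatchParams = MatchParams()
    coincidence_window_s: float | None = None  # None: half mean width, >= 5 ms
    saturation_limit_mv: float = SATURATION_LIMIT_MV
    #: per-cell reference amplitudes for sizing; None: median single-color
    #: detection amplitude of this scan
    ref_green_mv: float | None = None
    ref_orange_mv: float | None = None


@dataclass
class PipelineResult:
    candidates: dict  # ChannelId -> list[PeakCandidate]
    artifacts: set  # flagged all-channel-coincident candidates
    matched: dict  # color -> list[MatchedDetection]
    unmatched: dict  # color -> list[PeakCandidate]
    two_lambda: list  # list[TwoLambdaPeak], classification filled in
    singletons: list  # single-color MatchedDetections
    records: list  # list[DetectionRecord]
    refs_mv: dict  # per-cell reference amplitude actually used, per color
    calibrations: dict  # color -> BleedCalibration or None


def _default_refs(singletons: Sequence[MatchedDetection]) -> dict:
    """Per-cell reference amplitude: median single-color detection amplitude."""
    refs = {}
    for color in COLORS:
        amps = [m.amplitude_mV for m in singletons if m.color == color]
        refs[color] = float(np.median(amps)) if amps else float("nan")
    return refs


def calibration_points(
    two_lambda: Sequence[TwoLambdaPeak], primary_color: str
) -> list[tuple[float, float]]:
    """(I_pr*, I_sec*) pairs from a known single-fluorophore run.

    Use on the 2-lambda peaks of a run where every cell carries only the
    ``primary_color`` fluorophore, so every coincident secondary peak is
    pure spectral bleed.  Saturated peaks are excluded.
    """
    return [
        (p.I_pr, p.I_sec)
        for p in two_lambda
        if p.primary_color == primary_color and not p.saturated
    ]


def _build_records(
    two_lambda: Sequence[TwoLambdaPeak],
    singletons: Sequence[MatchedDetection],
    refs: dict,
    calib_green: BleedCalibration | None,
    calib_orange: BleedCalibration | None,
    saturation_limit_mv: float,
) -> list[DetectionRecord]:
    calibs = {GREEN: calib_green, ORANGE: calib_orange}

    def _sizeable(color: str) -> bool:
        r = refs.get(color)
        return r is not None and np.isfinite(r) and r > 0

    records: list[DetectionRecord] = []
    for m in singletons:
        saturated = flag_saturation(m, saturation_limit_mv)
        if _sizeable(m.color):
            sized = size_cluster(
                m,
                refs[GREEN] if _sizeable(GREEN) else m.amplitude_mV,
                refs[ORANGE] if _sizeable(ORANGE) else m.amplitude_mV,
            )
            kind, n_g, n_o = sized.kind, sized.n_green, sized.n_orange
        else:
            kind = "single_1FP"
            n_g = 1 if m.color == GREEN else 0
            n_o = 1 if m.color == ORANGE else 0
        records.append(
            DetectionRecord(
                time_s=m.time_s,
                color=m.color,
                direction=m.direction,
                amplitude_mV=m.amplitude_mV,
                amplitude_sigma=m.amplitude_sigma,
                width_s=m.width_s,
                classification=kind,
                n_green=n_g,
                n_orange=n_o,
                flags=frozenset({"saturated"}) if saturated else frozenset(),
            )
        )

    for p in two_lambda:
        pri = p.primary_color
        det = p.det(pri)
        flags = frozenset({"saturated"}) if p.saturated else frozenset()
        if p.classification == "indeterminate":
            records.append(
                DetectionRecord(
                    time_s=p.time_s,
                    color=pri,
                    direction=det.direction,
                    amplitude_mV=det.amplitude_mV,
                    amplitude_sigma=det.amplitude_sigma,
                    width_s=det.width_s,
                    classification="indeterminate",
                    flags=flags,
                )
            )
            continue
        if _sizeable(GREEN) and _sizeable(ORANGE):
            sized = size_cluster(
                p, refs[GREEN], refs[ORANGE], calibs[GREEN], calibs[ORANGE]
            )
            kind, n_g, n_o = sized.kind, sized.n_green, sized.n_orange
        else:
            kind = "cluster_2FP" if p.classification == "twoFP" else "single_1FP"
            n_g = 1 if (kind == "cluster_2FP" or pri == GREEN) else 0
            n_o = 1 if (kind == "cluster_2FP" or pri == ORANGE) else 0
        records.append(
            DetectionRecord(
                time_s=p.time_s,
                color=pri,
                direction=det.direction,
                amplitude_mV=det.amplitude_mV,
                amplitude_sigma=det.amplitude_sigma,
                width_s=det.width_s,
                classification=kind,
                n_green=n_g,
                n_orange=n_o,
                flags=flags,
            )
        )
    records.sort(key=lambda r: r.time_s)
    return records


def _classify_peaks(
    two_lambda: Sequence[TwoLambdaPeak],
    calib_green: BleedCalibration | None,
    calib_orange: BleedCalibration | None,
    saturation_limit_mv: float,
) -> list[TwoLambdaPeak]:
    out = []
    for p in two_lambda:
        p = replace(p, saturated=flag_saturation(p, saturation_limit_mv))
        if calib_green is not None and calib_orange is not None:
            p = replace(
                p, classification=classify_two_lambda(p, calib_green, calib_orange)
            )
        out.append(p)
    return out


def _records_from_matched(
    matched_green: Sequence[MatchedDetection],
    matched_orange: Sequence[MatchedDetection],
    calib_green: BleedCalibration | None,
    calib_orange: BleedCalibration | None,
    coincidence_window_s: float | None = None,
    saturation_limit_mv: float = SATURATION_LIMIT_MV,
    ref_green_mv: float | None = None,
    ref_orange_mv: float | None = None,
) -> list[DetectionRecord]:
    """Records from already-matched detections (the CLI classify path)."""
    two_lambda, singletons = find_two_lambda(
        matched_green, matched_orange, coincidence_window_s
    )
    classified = _classify_peaks(
        two_lambda, calib_green, calib_orange, saturation_limit_mv
    )
    refs = {GREEN: ref_green_mv, ORANGE: ref_orange_mv}
    defaults = _default_refs(singletons)
    for color in COLORS:
        if refs[color] is None:
            refs[color] = defaults[color]
    return _build_records(
        classified, singletons, refs, calib_green, calib_orange, saturation_limit_mv
    )


def run_pipeline(
    scan: Scan,
    params: PipelineParams = PipelineParams(),
    calib_green: BleedCalibration | None = None,
    calib_orange: BleedCalibration | None = None,
) -> PipelineResult:
    """Process one scan into detection records.

    Without bleed calibrations, 2-lambda peaks are left indeterminate
    (use :func:`calibration_points` plus
    :func:`difc.twocolor.estimate_bleed_ratio` on single-fluorophore runs
    to obtain them).
    """
    candidates: dict[ChannelId, list[PeakCandidate]] = {}
    for ch in CHANNELS:
        cands, _, _ = detect_channel(
            scan.signal[ch], scan.sampling_rate, ch, params.detection
        )
        candidates[ch] = cands

    artifacts = flag_motion_artifacts(candidates, params.match.artifact_window_s)
    clean = {
        ch: [c for c in cands if c not in artifacts]
        for ch, cands in candidates.items()
    }

    matched: dict[str, list[MatchedDetection]] = {}
    unmatched: dict[str, list[PeakCandidate]] = {}
    for color in COLORS:
        m, u = match_across_probes(
            clean[ChannelId(1, color)],
            clean[ChannelId(2, color)],
            scan.probe_separation_mm,
            params.match,
        )
        matched[color], unmatched[color] = m, u

    two_lambda, singletons = find_two_lambda(
        matched[GREEN], matched[ORANGE], params.coincidence_window_s
    )
    classified = _classify_peaks(
        two_lambda, calib_green, calib_orange, params.saturation_limit_mv
    )

    refs = {GREEN: params.ref_green_mv, ORANGE: params.ref_orange_mv}
    defaults = _default_refs(singletons)
    for color in COLORS:
        if refs[color] is None:
            refs[color] = defaults[color]

    records = _build_records(
        classified, singletons, refs, calib_green, calib_orange,
        params.saturation_limit_mv,
    )
    return PipelineResult(
        candidates=candidates,
        artifacts=artifacts,
        matched=matched,
        unmatched=unmatched,
        two_lambda=classified,
        singletons=singletons,
        records=records,
        refs_mv=refs,
        calibrations={GREEN: calib_green, ORANGE: calib_orange},
    )
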