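"""Match peaks across the two probes and read off flow speed/direction.

A cell passes probe 1 and then (in forward, arterial flow) probe 2,
3 mm downstream.  Matching same-color candidates on delay, amplitude and
width turns per-channel spikes into directional detections with a speed.
"""

import numpy as np

from difc import (
    DetectionParams,
    PipelineParams,
    preset_config,
    run_pipeline,
    simulate_scan,
)

cfg = preset_config("phantom_single", duration_s=120.0)
scan, events = simulate_scan(cfg, seed=2)

res = run_pipeline(scan, PipelineParams(detection=DetectionParams(mask_peaks_for_noise=True)))

for color in ("green", "orange"):
    matched = res.matched[color]
    n_true = sum(1 for e in events if getattr(e, f"n_{color}"))
    speeds = [m.speed_mm_s for m in matched]
    print(f"{color}: {len(matched)} matched detections "
          f"({n_true} true {color} arrivals)")
    if speeds:
        print(f"    speeds {min(speeds):.1f}-{max(speeds):.1f} mm/s, "
              f"median {np.median(speeds):.1f} mm/s "
              f"(generator median {cfg.speed_mean_mm_s} mm/s)")
    print(f"    directions: "
          f"{sum(m.direction == 'forward' for m in matched)} forward, "
          f"{sum(m.direction == 'reverse' for m in matched)} reverse")

print(f"unmatched candidates discarded: "
      f"{sum(len(v) for v in res.unmatched.values())}")
# The phantom pumps everything one way, so matches are (near-)all forward;
# speeds cluster around the pump speed.  Unmatched candidates - noise or
# events missed on one probe - never reach the counting stage.
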