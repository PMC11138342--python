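"""Detect transit peaks in a short synthetic phantom scan.

Builds a 60 s two-color phantom scan (10^3 cells/mL per color at
25 uL/min), runs background subtraction, noise estimation and 5-sigma
peak finding on each channel, and prints the candidates found.
"""

from difc import CHANNELS, DetectionParams, detect_channel, preset_config, simulate_scan

cfg = preset_config("phantom_single", duration_s=60.0)
scan, events = simulate_scan(cfg, seed=1)
print(f"simulated {len(events)} true arrivals in {scan.duration_s:.0f} s")

params = DetectionParams(mask_peaks_for_noise=True)
for ch in CHANNELS:
    cands, _, noise = detect_channel(scan.signal[ch], scan.sampling_rate, ch, params)
    print(f"{ch.label}: {len(cands)} candidates "
          f"(median noise {float(noise.sigma[len(noise.sigma)//2]):.2f} mV)")
    for c in cands[:3]:
        print(f"    t={c.time_s:7.3f} s  amp={c.amplitude_mV:7.1f} mV "
              f"({c.amplitude_sigma:5.1f} sigma, {c.snr_db:4.1f} dB)  "
              f"FWHM={1e3 * c.width_s:.1f} ms")

# Every candidate is a >= 5-sigma transient, i.e. SNR >= 13.9 dB; the
# per-channel counts approximate the per-color arrival rate (25/min),
# plus bleed-induced candidates from bright opposite-color cells.
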