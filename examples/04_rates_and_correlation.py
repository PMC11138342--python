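"""Moving detection rates and green/orange rate correlation.

In vivo, detection rates fluctuate over minutes.  If the fluctuation is
shared between two independently labeled populations it points to
perfusion (blood sampling) changes; if independent, to population-level
shedding dynamics.  The Pearson correlation of paired 2-minute moving
rates separates the two regimes.
"""

from difc import correlate_rates, moving_rate, preset_config, sample_events

DUR = 2400.0  # 40 min

for shared, label in ((0.0, "independent shedding"), (1.0, "shared perfusion")):
    cfg = preset_config("invivo_mm", duration_s=DUR, modulation_shared=shared,
                        artifact_rate_per_min=0.0)
    events = sample_events(cfg, seed=21)
    times = {
        "green": [e.time_s for e in events if e.n_green],
        "orange": [e.time_s for e in events if e.n_orange],
    }
    rates = moving_rate(times, DUR, window_min=2.0, step_s=5.0)
    pcc, p = correlate_rates(
        rates.rates["green"], rates.rates["orange"],
        n_effective=DUR / 120.0,  # overlapping windows are not independent
    )
    print(f"{label:22s}: {len(times['green']):3d} green / "
          f"{len(times['orange']):3d} orange detections, "
          f"PCC = {pcc:+.3f} (p = {p:.3f})")

# With a fully shared rate modulation the two rate series track each
# other (PCC well above 0); with independent modulations the PCC is
# statistically indistinguishable from 0.  The p-value uses
# duration/window effective degrees of freedom, not the raw number of
# overlapping windows.
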