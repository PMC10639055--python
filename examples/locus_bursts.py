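"""Track a single gene locus and detect R-loop fluctuation cycles.

Simulates a two-channel 3D time-lapse of a reporter-gene locus: a
static marker spot and a sensor whose amplitude follows on/off bursts
with a 45 s period, imaged for 10 minutes at 8 s intervals.  The
tracker follows the marker's center of intensity frame by frame and
reads the locally background-subtracted sensor intensity at the locus;
peak detection on the smoothed series yields the burst period.

A second run applies a DRB-style transcription block at t = 0 and
tests, across 35 cells, when the intensity drop becomes significant.
"""

import numpy as np

from rloopkit import (
    detect_fluctuation_cycles,
    simulate_locus_timelapse,
    track_locus,
    treatment_response_test,
)

stack, truth = simulate_locus_timelapse(
    burst_period_s=45.0, burst_duration_s=20.0, n_frames=75, dt_s=8.0, seed=5
)
track = track_locus(stack)
peaks, period = detect_fluctuation_cycles(track, smooth_window=3)
print(f"bursts generated : {len(truth.burst_times)}")
print(f"peaks detected   : {len(peaks)}")
print(f"median period    : {period:.0f} s (true period 45 s)")

# DRB response: per-cell locus intensities before treatment vs 10-min
# time points afterwards (exponential signal loss, tau = 6 min).
rng = np.random.default_rng(5)
pre = rng.normal(1000, 100, 35)
t = np.arange(1, 13) * 600.0
post = pre[:, None] * np.exp(-t / 360.0) + rng.normal(0, 100, (35, 12))
p = treatment_response_test(pre, post)
first = t[np.nonzero(p < 0.05)[0][0]] / 60
print(f"signal loss significant from {first:.0f} min after treatment")
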