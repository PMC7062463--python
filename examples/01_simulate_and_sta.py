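"""Simulate a model retinal ganglion cell and characterize its STA.

Builds the default two-layer cascade (64 cones on a jittered hexagonal
mosaic feeding 12 bipolar subunits), runs 10 minutes of binary white
noise through it, and recovers the receptive field from the
spike-triggered average: significant-pixel mask, crop window, and the
common temporal filter used to prefilter the stimulus for subunit
estimation.
"""

import numpy as np

import stclust as sc

cell = sc.rgc_cell(seed=1)
T = 10 * 60 * 120  # 10 minutes at 120 Hz
raw = sc.white_noise(T, cell.grid_shape, contrast=0.48, seed=2)
rates, spikes = sc.simulate_cell(cell, raw, seed=3)
print(f"mean firing rate: {rates.mean() / cell.bin_width:.1f} spikes/s "
      "(cascade calibrated to ~19)")
print(f"total spikes in {T} bins: {spikes.total}")

X, info = sc.preprocess_recording(raw, spikes, cell.grid_shape)
rows = slice(info['crop'][0].start, info['crop'][0].stop)
print(f"RF mask: {info['mask'].sum()} significant pixels (|value| > 2.5 sigma)")
print(f"crop window: {X.grid_shape} of the {cell.grid_shape} stimulus grid")
tc = info["time_course"]
peak_ms = np.argmax(np.abs(tc)) * 1000 / 120
print(f"time course: {tc.shape[0]} lags, peak at {peak_ms:.0f} ms; "
      f"prefiltered stimulus standardized: {X.is_standardized()}")
# The mask should sit inside the cascade's true footprint:
support = (cell.true_subunits.sum(0).reshape(cell.grid_shape)
           > 0.05 * cell.true_subunits.sum(0).max())
inside = (info["mask"] & support).sum() / info["mask"].sum()
print(f"fraction of masked pixels inside the true RF support: {inside:.2f}")
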