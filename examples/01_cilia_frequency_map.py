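"""Map per-pixel ciliary beat frequency in a synthetic culture video.

Builds a 512-frame, 30 fps recording in which a patch of pixels beats at
8.5 Hz over a noisy background, then recovers the frequency map and the
two figures of merit: percent area covered by active cilia and mean CBF.
"""

import numpy as np

from alismoke import (
    CiliaRegion,
    CiliaVideoSpec,
    SpectralConfig,
    compute_frequency_map,
    generate_cilia_video,
    summarize_cilia,
)

mask = np.zeros((100, 100), dtype=bool)
mask[20:52, 30:62] = True  # ~10% of the field of view

spec = CiliaVideoSpec(
    height=100, width=100, n_frames=512, fps=30.0,
    regions=(CiliaRegion(mask=mask, frequency=8.5, amplitude=10.0, phase_jitter_sd=0.3),),
    noise_sd=2.0, seed=42,
)
stack, truth = generate_cilia_video(spec)

config = SpectralConfig(band_low=2.0, band_high=14.0, snr_threshold=15.0)
fmap = compute_frequency_map(stack, config)
summary = summarize_cilia(fmap)

print(f"true beating area : {100 * mask.mean():.2f} % at 8.5 Hz")
print(f"active area       : {summary.active_area_pct:.2f} %")
print(f"mean CBF          : {summary.mean_cbf:.2f} Hz")
print(f"active pixels     : {summary.n_active} of {summary.n_analyzed}")
# The detected area should track the true 10.24% patch (a healthy culture
# shows 5-20%), and the mean CBF should sit within one spectral bin
# (30/512 ~ 0.06 Hz) of the true 8.5 Hz, inside the physiological 7-10 Hz.
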