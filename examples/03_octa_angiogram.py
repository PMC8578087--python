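"""Compute an OCT angiogram from repeated B-scans.

Static tissue cancels in consecutive-frame differences; decorrelating blood
flow survives, so the angiogram highlights perfused regions only.
"""

import numpy as np

from vasculink import octa_angiogram, simulate_bscan_series

frames = simulate_bscan_series(
    shape=(64, 64), n_frames=8, flow_radius=10.0, flow_amplitude=0.5,
    noise_sigma=0.01, seed=0,
)
angiogram = octa_angiogram(frames, gaussian_sigma=1.0, threshold=0.0)

yy, xx = np.mgrid[0:64, 0:64]
disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 100
inside, outside = angiogram[disk].mean(), angiogram[~disk].mean()
print(f"mean angiogram inside flow disk: {inside:.4f}")
print(f"mean angiogram outside:          {outside:.4f}")
print(f"contrast ratio:                  {inside / outside:.1f}x")
print("-> values are mean absolute consecutive-frame differences; a ratio")
print("   well above 1 means moving blood is cleanly separated from static tissue.")
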