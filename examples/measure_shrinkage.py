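"""Measure shrinkage from a synthetic image stack of a drying slice.

Rasterizes 12 frames of a shrinking bright disk (with specks and interior
holes, as real slice images have), runs the segmentation pipeline and
compares the measured shrinkage to the commanded area schedule.
"""

import numpy as np

from mrfit import GeneratorConfig, generate_image_stack
from mrfit.imaging import process_series

config = GeneratorConfig(kmax=12, seed=9, image_size=200, disk_radius=70)
frames, commanded = generate_image_stack(config)
table = process_series(frames)

expected = commanded / commanded[0]  # ratios relative to the first frame
print(table.assign(commanded=np.round(expected, 4)).to_string(index=False))
err = np.abs(table["shrinkage"].to_numpy() - expected).max()
print(f"\nmax |measured - commanded| = {err:.4f}  (pixelization keeps this < 0.02)")
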