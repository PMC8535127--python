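"""Single-scale irregularity of synthetic textures.

Builds three 64×64 textures — a period-4 checkerboard, a noisy sinusoidal
grating and white noise — and prints their bidimensional fuzzy and
dispersion entropies.  Higher values mean less predictable pixel
patterns: white noise should score near the top of each measure's range,
the checkerboard near the bottom.
"""

import numpy as np

from entropy2d import DispParams, FuzzyParams, TextureSpec, disp_en2d, fuzzy_en2d, make_texture

textures = {
    "checkerboard (period 4)": TextureSpec("checkerboard", 64, 4),
    "grating (period 8, noise 20)": TextureSpec("grating", 64, 8, 20.0, seed=1),
    "white noise": TextureSpec("white_noise", 64, seed=1),
}

fuzzy_p = FuzzyParams(m=1, n=2, r=0.36)
disp_p = DispParams(m=2, c=3)

print(f"{'texture':32s} {'FuzzyEn2D':>10s} {'DispEn2D':>10s}")
for name, spec in textures.items():
    img = make_texture(spec)
    fz = fuzzy_en2d(img, fuzzy_p).value
    dp = disp_en2d(img, disp_p).value
    print(f"{name:32s} {fz:10.4f} {dp:10.4f}")

print()
print(f"DispEn2D upper bound at m=2, c=3 is 4·ln 3 = {4 * np.log(3):.4f} nats;")
print("white noise approaches it, periodic structure stays far below.")
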