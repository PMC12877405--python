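"""Actin-fiber orientation on synthetic monolayers: isotropic vs. reoriented.

Generates two fluorescence scenes — one with uniformly oriented fibers (an
unstretched monolayer) and one with fibers concentrated near 75° (a monolayer
reoriented away from the strain direction) — and runs the gradient/grid
orientation pipeline on both.
"""

import numpy as np

from stretchquant import make_fiber_scene, max_project
from stretchquant.orientation import image_mean_orientation
from stretchquant.synthetic import DEFAULT_NOISE, apply_noise


def analyse(label, law, seed):
    stack, _ = make_fiber_scene(200, law, seed=seed)
    noisy = apply_noise(stack, **DEFAULT_NOISE, seed=seed + 500)
    mean, per_square = image_mean_orientation(max_project(noisy, "actin"))
    print(f"{label:12s} mean orientation {mean:5.1f} deg  "
          f"({len(per_square)} grid squares, spread "
          f"{np.std(per_square):.1f} deg)")
    return mean


print("Per-image mean fiber orientation, folded to [0, 90] deg from the "
      "stretch axis\n(0 deg = parallel to strain, 90 deg = perpendicular, "
      "isotropic baseline = 45 deg):\n")
unstretched = analyse("unstretched", "uniform", seed=1)
stretched = analyse("4 h stretch", ("vonmises", 75.0, 8.0), seed=2)
print(f"\nReorientation shift: +{stretched - unstretched:.1f} deg toward "
      "perpendicular — the signature of strain-avoidant fiber remodeling.")
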