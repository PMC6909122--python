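"""Closed-loop film dosimetry: synthesize, register, calibrate, compare.

Creates a planned dose plane, turns it into a synthetic scanned film
(response values, four pin marks, a deliberate 1.5 mm misregistration and
mild response noise), then runs the full measurement pipeline: rigid
registration from the marks, response-to-dose conversion, plateau
normalization and a 3 %/1 mm gamma comparison.
"""

import numpy as np

import gpqa
from gpqa.film import default_calibration, process_film, synth_film
from gpqa.gamma import DosePlane, RegionSpec
from gpqa.profiles import erf_tophat

# planned dose plane: a flat-topped 8 Gy field
n = 81
u = np.arange(n) - n // 2
U, V = np.meshgrid(u, u, indexing="ij")
plane = DosePlane(origin=(-(n // 2), -(n // 2)), spacing=(1.0, 1.0),
                  values=8.0 * erf_tophat(np.hypot(U, V), 30.0, 3.0))

curve = default_calibration()
shift = (1.5 / np.sqrt(2), 1.5 / np.sqrt(2))
film = synth_film(plane, curve, noise_sd=0.002,
                  misregistration=gpqa.RegistrationTransform(rotation=2.0, translation=shift),
                  seed=42)

region = RegionSpec(center=(0.0, 0.0), half_width=(3.0, 3.0))
result, transform, _ = process_film(film, curve, plane, region)

print(f"injected misregistration : rotation 2.00 deg, shift 1.50 mm")
print(f"recovered registration   : rotation {transform.rotation:.2f} deg, "
      f"shift {np.hypot(*transform.translation):.2f} mm "
      f"(rms residual {transform.rms_residual:.2e} mm)")
print(f"gamma 3 %/1 mm pass rate : {result.pass_rate:.1f} % "
      f"over {int(result.evaluated_mask.sum())} pixels")
print("-> the four pin marks recover the film pose; after registration and")
print("   plateau normalization the film matches the plan, so the pass rate")
print("   reflects only the injected response noise.")
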