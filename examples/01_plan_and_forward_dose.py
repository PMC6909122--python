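"""Generate a synthetic plan and forward-compute its 3-D dose.

Builds a cohort-realistic plan (hundreds of dwell positions painting the
target), the synthetic kernel library, and superposes all shots onto a
dose grid around the planning target volume (PTV).
"""

import gpqa
from gpqa.grid import GridSpec

plan = gpqa.generate_synthetic_plan(seed=7)
ptv = plan.target("PTV")
print(f"plan {plan.plan_id}: cup {plan.cup.cup_id}, "
      f"{plan.n_control_points} control points, PTV {ptv.volume:.1f} cc, "
      f"total beam-on {plan.total_beam_on_time():.0f} s")

lib = gpqa.make_synthetic_library()
spec = GridSpec.from_center(ptv.centroid, ptv.equivalent_radius + 20.0, 2.0)
grid = gpqa.compute_dose_grid(plan, lib, spec)

centroid_dose = grid.neighborhood_mean(ptv.centroid)
print(f"dose at the PTV centroid (5x5x5 mean): {centroid_dose:.2f} Gy")
print(f"grid maximum: {grid.values.max():.2f} Gy  (prescription {plan.prescription_dose:.0f} Gy)")
print("-> the optimizer-flattened shot pattern delivers close to the")
print("   prescription inside the target; the distorting engine adds a")
print("   systematic excess the independent check must correct for.")
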