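"""Score one simulated FOV reconstruction pair with the sharpness metric.

Builds a random digital leg phantom, reconstructs it at a two-leg 423 mm
FOV and a single-leg 220 mm FOV (512 matrix), segments the anatomy on the
small-FOV volume, aligns the large-FOV volume onto the small-FOV grid by
cubic b-spline interpolation, and scores both under identical masks.
"""

from fovsharp import build_masks, compare_pair, random_phantom_spec, simulate_pair
from fovsharp.resampling import align_pair

spec = random_phantom_spec(seed=7)
print(f"phantom: {len(spec.bones)} bones, {len(spec.vessels)} vessels, "
      f"{len(spec.calcifications)} calcified arcs")

truth, large, small = simulate_pair(spec, seed=7)
masks = build_masks(small)                      # body/bone/ROI from the sharp volume
large_on_small, small = align_pair(large, small)
cmp = compare_pair(small, large_on_small, masks, identifier="example-pair")

print("\nper-slice sharpness (sum of gradient magnitude over significant edges, HU/mm):")
for k, s, l, d in zip(cmp.small.slice_index, cmp.small.value,
                      cmp.large.value, cmp.per_slice_difference):
    print(f"  slice {k}: small {s:9.0f}  large {l:9.0f}  difference {d:8.0f}")
print(f"\nmean difference (small - large): {cmp.mean_difference:.0f}")
print(f"one-sided t-test p-value:        {cmp.p_value:.2e}")
print("\nA positive difference on every slice means the single-leg FOV "
      "reconstruction resolves vessel and tissue edges better; the t-test "
      "says the improvement is larger than the slice-to-slice variation.")
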