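"""Hemocytometer counting arithmetic and growth-curve evaluation.

Converts per-square chamber counts to suspension density (cells/mL),
builds a growth curve from replicate samples, and scores a detector-count
series against ground truth with the relative error rates ERT/TERT.
"""

from sbfdetect import CountRecord, cells_per_ml, growth_curve, total_error_rate

# one chamber square is 1 mm^2 x 0.1 mm deep, so 1 count = 1e4 cells/mL
print("200 cells/square, no dilution ->",
      f"{cells_per_ml(200):.2e} cells/mL")
print("50 cells/square, 2x dilution  ->",
      f"{cells_per_ml(50, dilution_factor=2):.2e} cells/mL")

records = [
    CountRecord("s1", 24.0, (48, 52, 50, 49, 51)),
    CountRecord("s2", 24.0, (55, 53, 52, 54, 56)),
    CountRecord("s1", 48.0, (110, 108, 112, 109, 111)),
    CountRecord("s2", 48.0, (120, 118, 122, 119, 121)),
]
curve = growth_curve(records)
print("\ngrowth curve (density averaged over same-time samples):")
print(curve.to_string(index=False))

# relative count error of a hypothetical detector vs ground truth
rows = [(5.0e5, 5.1e5), (1.15e6, 1.13e6)]
print(f"\nTERT over both timepoints: {total_error_rate(rows):.4f}")
# TERT is the mean of |detected - truth| / truth across sampled densities.
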