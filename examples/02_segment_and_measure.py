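"""Seeded level-set segmentation and morphometry, checked against ground truth.

Ten capsule fibers spanning the biological width range (24-72 px = 30-90 um)
are rendered with noise, segmented by the inward level-set evolution from
rectangular seed polygons, and measured.  An independent oracle measures the
same fibers on their analytic geometry using the manual validation protocol
(5 perpendicular widths along the medial axis); the table printed at the end
is the per-feature signed percentage deviation, whose medians are expected
inside the -4%..+2% validation band.
"""

from flymuscle import (
    feature_validation_phantom,
    manual_protocol_oracle,
    measure_phantom,
    validate_features,
)

spec = feature_validation_phantom(seed=7, n_fibers=10, noise_sd=3.0)
features, rois, gt = measure_phantom(spec)

print(features[["label", "avg_diameter_um", "length_um", "area_um2", "elongation"]]
      .round(2).to_string(index=False))

oracle = manual_protocol_oracle(gt, frame_idx=0).rename(columns={"roi_label": "roi_id"})
pipeline = features[["label", "avg_diameter_um", "length_um", "area_um2", "elongation"]].rename(
    columns={"label": "roi_id"}
)
deviations = validate_features(pipeline, oracle)
print("\nsigned % deviation vs manual-protocol oracle (last row = median):")
print(deviations.round(2).to_string(index=False))
# A median diameter deviation of ~-1% means the pipeline recovers fiber
# widths to within a fraction of a pixel of the true geometry.
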