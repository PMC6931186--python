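"""Generate a small phantom cohort and describe it.

Each case is a pair of brain-like 3D volumes (two modalities with opposite
lesion contrast, emulating T1 and FLAIR) plus the exact ground-truth lesion
mask.  Lesions are placed in the left hemisphere and drawn small or large
according to the requested mix.
"""

from multipath25d import classify_lesion_size, generate_dataset

cases = generate_dataset(n=6, size_mix=0.5, seed=42)

print(f"{'case':8s} {'voxels':>7s} {'size':>6s}  extent-check")
for case in cases:
    n_vox = case.mask.foreground_count()
    measured = classify_lesion_size(case.mask.data, case.spec.spacing)
    print(f"{case.case_id:8s} {n_vox:7d} {case.size_class.value:>6s}  "
          f"measured={measured.value}")

# "voxels" is the lesion volume in mm^3 at 1 mm spacing; small lesions fit a
# 20 x 20 x 25 mm bounding box, large ones exceed it on at least one axis.
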