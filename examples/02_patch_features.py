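"""Two-level patch featureization of one image.

A 600x600 image tiles into 3x3 parent patches of 200x200; each parent
yields 49 overlapping 50x50 subpatches (stride 25). Subpatch ULBP /
gray-statistics / Lab-histogram descriptors are pooled per parent with
(mean, std, p10, p90), giving the 472/36/680-dim blocks and the 508-
and 1188-dim F1/F2 feature sets.
"""

from lymphopatch import assemble_feature_set, extract_image_features, generate_image
from lymphopatch.config import LBPConfig, PatchConfig, SynthConfig

img = generate_image("FL", SynthConfig(), seed=7)
feats = extract_image_features(img, "FL_007", PatchConfig(), LBPConfig())

print(f"parent patches: {feats.m}")
print(f"subpatches per parent: {len(feats.grid.subpatch_offsets)}")
blocks = feats.blocks[0]
for name, vec in blocks.items():
    print(f"{name}: {len(vec)} dims")
print(f"F1 (texture + statistics): {len(assemble_feature_set(blocks, 'F1'))} dims")
print(f"F2 (F1 + Lab color):       {len(assemble_feature_set(blocks, 'F2'))} dims")
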