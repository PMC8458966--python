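"""Segmentation-agreement metrics on constructed masks.

Shows AVD, ASD, Dice, Tanimoto error and the fused score on a pair of
cubes with known overlap, and the calibration point of the fused score.
"""

import numpy as np

from longimpute.metrics import (
    BinaryMask,
    MetricRefs,
    asd,
    avd,
    dice,
    fused_score,
    tanimoto_error,
)

s1 = np.zeros((20, 20, 20), bool)
s2 = np.zeros((20, 20, 20), bool)
s1[4:12, 4:12, 4:12] = True          # 8^3 cube
s2[6:14, 4:12, 4:12] = True          # same cube shifted 2 voxels

m1, m2 = BinaryMask(s1), BinaryMask(s2)
a = avd(m1, m2)
s = asd(m1, m2)
d = dice(m1, m2)
t = tanimoto_error(m1, m2)
fs = fused_score(a, s, t)

print(f"AVD            {a:7.3f} %   (volumes equal here, so 0)")
print(f"ASD            {s:7.3f} mm  (mean nearest-border distance, both ways)")
print(f"Dice           {d:7.3f}     (2|A∩B| / (|A|+|B|))")
print(f"TanimotoError  {t:7.3f} %   (Jaccard complement)")
print(f"FusedScore     {fs:7.3f}     (metrics scaled by expert references, averaged)")

print()
refs = MetricRefs()
print(f"fused_score(5.6, 0.27, 15.8) = {fused_score(5.6, 0.27, 15.8)}")
# Exactly 1.0: the reference constants are the inter-expert variability,
# so 1.0 reads as "disagrees with the reference as much as human experts
# disagree with each other"; below 1 is better than inter-expert spread.
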