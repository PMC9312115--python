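"""Sub-pixel fat fractions and the viable/IMAT ground-truth labeling rule.

Fits a two-component (water + fat) model per muscle pixel of a noiseless
phantom and labels pixels with fat fraction > 50% as IMAT.
"""

import numpy as np

from imatseg import (Protocol, build_dictionary, fit_two_component,
                     label_tissue_gt, make_phantom, simulate_mese)
from imatseg import labels as L
from imatseg.metrics import dice

protocol = Protocol()
dictionary = build_dictionary(protocol)
truth = make_phantom(128, "calf", 0.3, seed=11)
series = simulate_mese(truth, protocol, dictionary, snr=None)

mus = truth.muscle_region_mask
ff, t2w = fit_two_component(series, dictionary, mus)
err = np.abs(ff - truth.fat_fraction)[mus]
print(f"fat-fraction error: median {np.median(err):.4f}, "
      f"{100 * (err <= 0.05).mean():.1f}% of muscle pixels within 0.05")

labels = label_tissue_gt(ff, mus, threshold=0.5)
for code, name in ((L.VIABLE, "viable muscle"), (L.IMAT, "IMAT")):
    d = dice(labels.labels == code, truth.tissue_mask == code)
    print(f"{name} Dice vs phantom truth: {d:.3f} "
          "(1.0 = the >50% rule reproduces the phantom partition exactly)")
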