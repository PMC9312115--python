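"""Simulate one synthetic leg slice and fit quantitative T2/PD maps.

Builds the EPG decay-curve dictionary, renders a multi-echo spin-echo
series for a phantom with 25% intramuscular fat, adds Rician noise at
SNR 50, and matches every pixel's decay back to the dictionary.
"""

import numpy as np

from imatseg import (Protocol, build_dictionary, fit_t2_pd, make_phantom,
                     simulate_mese)

protocol = Protocol()                      # TR/TE 1479/8.7 ms, 17 echoes
dictionary = build_dictionary(protocol)    # T2 10..300 ms x B1+ 0.7..1.3
print(f"dictionary: {dictionary.curves.shape[0]} T2 x "
      f"{dictionary.curves.shape[1]} B1+ entries")

truth = make_phantom(shape=128, anatomy="calf", target_imat_fraction=0.25,
                     seed=7)
print(f"phantom IMAT fraction: {truth.imat_fraction_true:.3f} "
      "(fraction of the muscle region occupied by fat-infiltrated pixels)")

series = simulate_mese(truth, protocol, dictionary, snr=50.0, seed=1)
maps = fit_t2_pd(series, dictionary, mask=truth.muscle_region_mask)

mus = truth.muscle_region_mask
viable = mus & (truth.fat_fraction <= 0.5)
print(f"median fitted T2 over viable muscle: "
      f"{np.median(maps.t2[viable]):.1f} ms (above the ~38 ms water T2 "
      "because even viable pixels carry up to 20% long-T2 fat signal)")
print(f"median fitted B1+ error: "
      f"{np.median(np.abs(maps.b1_plus[mus] - truth.b1_plus[mus])):.3f} "
      "(transmit-field scale, grid step 0.02)")
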