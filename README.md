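# imatseg

Quantification of intramuscular adipose tissue (IMAT) in lower-limb
quantitative MRI.

Fat infiltration into the calf and thigh muscles is a hallmark of muscular
dystrophies such as dysferlinopathy and Charcot–Marie–Tooth disease.
`imatseg` turns a multi-echo spin-echo (MESE) scan into a per-slice disease
biomarker in four steps:

1. **T2/PD mapping** — MESE decay curves are simulated with the extended
   phase graph (EPG) recursion over a (T2, B1+) grid and matched per pixel
   by minimal l2 distance, which keeps T2 accurate in the presence of
   stimulated echoes; proton density is back-projected from the first
   echo. A two-component (water + fat) fit yields a sub-pixel fat fraction
   ff, and pixels with ff > 50% are labeled IMAT.
2. **Stage 1 segmentation** — a five-level U-net segments the muscle
   compartment inside the fascia lata on the T2/PD maps, discarding
   subcutaneous fat, bone and marrow.
3. **Stage 2 clustering** — 16×16 patches around each interior muscle
   pixel are embedded by a convolutional auto-encoder trained with a
   combined reconstruction + triplet loss (DCAETL, weak labels from the
   ff > 50% rule); k-means with k = 2 in the embedding separates viable
   muscle from IMAT. Intensity k-means, DCAE + k-means and deep embedded
   clustering (DCAE_DC) are included as comparison methods.
4. **Biomarker** — IMAT fraction = Area_IMAT / Area_whole-muscle per
   slice, banded into mild (0–33%), moderate (34–66%) and severe
   (67–100%), with cohort-level regression of predicted against reference
   fractions.

Because equivalent patient data are not publicly available, the package
ships a synthetic MESE leg phantom (geometry, tissue parameters, transmit/
receive field inhomogeneity, Rician noise, known ground truth) so every
stage is trainable and testable end-to-end from nothing but a seed. The
neural networks run on a small NumPy engine included in the package; no
GPU or deep-learning framework is required.

## Worked example

```python
import numpy as np
from imatseg import (Protocol, build_dictionary, make_phantom,
                     simulate_mese, fit_t2_pd, fit_two_component,
                     label_tissue_gt)
from imatseg.biomarker import imat_fraction, severity_class

protocol = Protocol()                    # TR/TE 1479/8.7 ms, 17 echoes
dictionary = build_dictionary(protocol)  # 146 T2 x 31 B1+ EPG curves

truth = make_phantom(128, "calf", target_imat_fraction=0.25, seed=7)
series = simulate_mese(truth, protocol, dictionary, snr=50.0, seed=1)

mus = truth.muscle_region_mask
maps = fit_t2_pd(series, dictionary, mask=mus)
ff, _ = fit_two_component(series, dictionary, mus, maps=maps)
labels = label_tissue_gt(ff, mus)        # ff > 50% -> IMAT

frac = imat_fraction(labels)
print(f"true IMAT fraction {truth.imat_fraction_true:.3f}")
print(f"estimated IMAT fraction {frac:.3f} -> {severity_class(frac)}")
```

prints

```
true IMAT fraction 0.250
estimated IMAT fraction 0.246 -> mild
```

i.e. the dictionary fit plus the 50% fat-fraction rule recovers the
phantom's infiltration level to about the pixel-counting precision, and
the slice is classified into the mild band (0–33% of the muscle region).

The full two-stage pipeline (train U-net and clusterer on a synthetic
cohort, evaluate held-out subjects) is one call — see
`examples/03_full_pipeline.py`, or from a shell:

```bash
imatseg run --seed 1 --out run_dir        # writes summary.json
imatseg simulate --n-subjects 6 --out cohort_dir
```

`examples/` contains one short script per capability; `docs/methods.md`
documents the models, the phantom, numerical choices and limitations.

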