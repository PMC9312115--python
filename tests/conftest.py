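"""Shared fixtures.

Heavy artifacts (the EPG dictionary, the standard phantom, trained models)
are session-scoped so the end-to-end checks share one training run.  All
sizes here are the package's desk-scale study conditions: 128x128 slices,
SNR 50, IMAT texture scale 4 px.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from imatseg.acquisition import Protocol
from imatseg.phantom import make_phantom, simulate_mese
from imatseg.relaxometry import (build_dictionary, fit_t2_pd,
                                 fit_two_component, label_tissue_gt)
from imatseg import tissuecluster as tc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def dictionary(protocol, tmp_path_factory):
    return build_dictionary(
        protocol, cache_dir=tmp_path_factory.mktemp("dictcache"))


@pytest.fixture(scope="session")
def standard_phantom():
    """One moderate-infiltration calf slice, the work-horse fixture."""
    return make_phantom(128, "calf", 0.25, seed=7)


@pytest.fixture(scope="session")
def noiseless_series(standard_phantom, protocol, dictionary):
    return simulate_mese(standard_phantom, protocol, dictionary, snr=None)


@pytest.fixture(scope="session")
def noisy_series(standard_phantom, protocol, dictionary):
    return simulate_mese(standard_phantom, protocol, dictionary, snr=50.0,
                         seed=11)


@pytest.fixture(scope="session")
def separable_patchset():
    """Constructed two-class patch set: T2 ~40 vs ~150 ms, trivially
    separable; used for clustering sanity checks."""
    rng = np.random.default_rng(5)
    n = 300
    patches = np.empty((2 * n, 2, 16, 16), dtype=np.float32)
    labels = np.empty(2 * n, dtype=np.int8)
    for i in range(2 * n):
        viable = i < n
        t2 = 40.0 if viable else 150.0
        patches[i, 0] = t2 + rng.normal(0, 3.0, (16, 16))
        patches[i, 1] = 0.9 + rng.normal(0, 0.05, (16, 16))
        labels[i] = tc.LABEL_VIABLE if viable else tc.LABEL_IMAT
    centers = np.full((2 * n, 2), 8, dtype=int)
    return tc.PatchSet(patches=patches, centers=centers, weak_labels=labels)


# ---------------------------------------------------------------------------
# trained-model fixtures (built once per session; used by the end-to-end and
# acceptance checks)
# ---------------------------------------------------------------------------

STAGE1_TRAIN = 40
STAGE1_TEST = 10
STAGE1_TARGETS = np.tile([0.1, 0.25, 0.45, 0.6, 0.8], 10)


def _prepare_stage1_slice(i, protocol, dictionary):
    """Simulate -> bias-correct -> fit -> crop -> normalize one slice."""
    from imatseg.preprocess import (correct_receiver_bias, crop_and_resize,
                                    normalize_input)

    truth = make_phantom(128, "calf", float(STAGE1_TARGETS[i]), seed=1000 + i)
    series = simulate_mese(truth, protocol, dictionary, snr=50.0,
                           seed=2000 + i)
    series, _ = correct_receiver_bias(series)
    fg = series.data.sum(axis=2) > 0.05 * series.data.sum(axis=2).max()
    maps = fit_t2_pd(series, dictionary, mask=fg)
    stack = np.stack(
        [maps.t2, maps.pd, truth.muscle_region_mask.astype(float)], axis=-1)
    cropped, _ = crop_and_resize(stack, 128, nearest_channels=(2,))
    x = np.stack([normalize_input(cropped[..., 0])[0],
                  normalize_input(cropped[..., 1])[0]], axis=-1)
    return x, cropped[..., 2] > 0.5


@pytest.fixture(scope="session")
def stage1_dataset(protocol, dictionary):
    """(X, Y) for 40 training + 10 held-out slices (T2+PD inputs)."""
    pairs = [_prepare_stage1_slice(i, protocol, dictionary)
             for i in range(STAGE1_TRAIN + STAGE1_TEST)]
    X = np.stack([p[0] for p in pairs])
    Y = np.stack([p[1] for p in pairs])
    return (X[:STAGE1_TRAIN], Y[:STAGE1_TRAIN],
            X[STAGE1_TRAIN:], Y[STAGE1_TRAIN:])


@pytest.fixture(scope="session")
def trained_unet(stage1_dataset):
    """U-net trained on the 40 synthetic slices for 20 epochs."""
    from imatseg.muscleseg import UNetConfig, train_stage1

    Xtr, Ytr, _, _ = stage1_dataset
    cfg = UNetConfig(in_channels=2, base_filters=8, epochs=20,
                     augmentation_factor=1, seed=0)
    model, history = train_stage1(Xtr, Ytr, cfg)
    return model, history


STAGE2_TARGETS = (0.15, 0.35, 0.55, 0.75)


@pytest.fixture(scope="session")
def stage2_training_slices(protocol, dictionary):
    """Four slices with fitted maps and weak labels for patch training."""
    out = []
    for i, tgt in enumerate(STAGE2_TARGETS):
        truth = make_phantom(128, "calf", tgt, seed=300 + i)
        series = simulate_mese(truth, protocol, dictionary, snr=50.0,
                               seed=400 + i)
        mus = truth.muscle_region_mask
        maps = fit_t2_pd(series, dictionary, mus)
        ff, _ = fit_two_component(series, dictionary, mus, maps=maps)
        weak = label_tissue_gt(ff, mus)
        out.append({"truth": truth, "maps": maps, "mask": mus, "weak": weak})
    return out


@pytest.fixture(scope="session")
def stage2_patchset(stage2_training_slices):
    sets = [tc.extract_patches(s["maps"].t2, s["maps"].pd, s["mask"], s["weak"])
            for s in stage2_training_slices]
    pset = tc.PatchSet.concatenate(sets)
    # subsample for tractable desk-scale training (deterministic)
    rng = np.random.default_rng(0)
    sel = np.sort(rng.choice(len(pset), 6000, replace=False))
    return tc.PatchSet(patches=pset.patches[sel], centers=pset.centers[sel],
                       weak_labels=pset.weak_labels[sel],
                       source_slice=pset.source_slice[sel])


@pytest.fixture(scope="session")
def trained_dcaetl(stage2_patchset):
    cfg = tc.DCAEConfig(epochs=16, seed=0)
    model, history = tc.train_dcaetl(stage2_patchset, cfg)
    cm = tc.fit_clusters(model, stage2_patchset, seed=0)
    return model, cm, history


@pytest.fixture(scope="session")
def trained_dcae(stage2_patchset):
    cfg = tc.DCAEConfig(epochs=16, seed=0)
    model, cm, history = tc.train_dcae_kmeans(stage2_patchset, cfg)
    return model, cm, history


@pytest.fixture(scope="session")
def stage2_eval_slice(protocol, dictionary):
    """Held-out moderate slice for stage-2 pixel-level evaluation."""
    truth = make_phantom(128, "calf", 0.45, seed=999)
    series = simulate_mese(truth, protocol, dictionary, snr=50.0, seed=998)
    mus = truth.muscle_region_mask
    maps = fit_t2_pd(series, dictionary, mus)
    return {"truth": truth, "maps": maps, "mask": mus}
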