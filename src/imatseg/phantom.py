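"""Synthetic lower-limb MESE phantom with known ground truth.

Generates a 2-D leg cross-section -- outer skin ellipse, subcutaneous fat
(SAT) ring, fascia-lata ellipse bounding the muscle compartment, one (thigh)
or two (calf) cortical-bone discs with marrow cores -- and infiltrates the
muscle with IMAT by thresholding a smoothed Gaussian random field, so the
achieved IMAT fraction hits a requested target.  Per-pixel MR tissue
parameters (water/fat T2, proton density, fat fraction) and smooth transmit
(B1+) / receive (B1-) field maps complete the ground truth, from which a
multi-echo magnitude series is simulated with a two-compartment water/fat
signal model and optional Rician noise.

Everything is deterministic given the seed, so downstream training and
evaluation are reproducible without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import EchoSeries, Protocol
from . import labels as L

# Severity bands for the IMAT-fraction biomarker: mild 0-33%,
# moderate 34-66%, severe 67-100% of the muscle region.
SEVERITY_BANDS = {
    "mild": (0.0, 1.0 / 3.0),
    "moderate": (1.0 / 3.0, 2.0 / 3.0),
    "severe": (2.0 / 3.0, 0.95),  # generator cap: muscle keeps viable pixels
}


@dataclass
class PhantomTruth:
    """Ground-truth maps for one synthetic slice (all on one pixel grid)."""

    tissue_mask: np.ndarray      # int codes, see imatseg.labels
    fat_fraction: np.ndarray     # in [0, 1]
    t2_water: np.ndarray         # ms
    t2_fat: np.ndarray           # ms
    pd: np.ndarray               # arbitrary units
    b1_plus: np.ndarray          # relative transmit field, ~[0.75, 1.25]
    b1_minus: np.ndarray         # relative receive field
    seed: int

    @property
    def muscle_region_mask(self) -> np.ndarray:
        return (self.tissue_mask == L.VIABLE) | (self.tissue_mask == L.IMAT)

    @property
    def imat_fraction_true(self) -> float:
        m = self.muscle_region_mask
        return float((self.tissue_mask[m] == L.IMAT).sum() / m.sum())

    @property
    def label_map(self) -> L.TissueLabelMap:
        """Viable/IMAT/background codes only (non-muscle -> background)."""
        lab = np.where(self.muscle_region_mask, self.tissue_mask, L.BACKGROUND)
        return L.TissueLabelMap(lab)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path),
            tissue_mask=self.tissue_mask, fat_fraction=self.fat_fraction,
            t2_water=self.t2_water, t2_fat=self.t2_fat, pd=self.pd,
            b1_plus=self.b1_plus, b1_minus=self.b1_minus,
            seed=np.array(self.seed),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PhantomTruth":
        with np.load(Path(path)) as f:
            return cls(
                tissue_mask=f["tissue_mask"], fat_fraction=f["fat_fraction"],
                t2_water=f["t2_water"], t2_fat=f["t2_fat"], pd=f["pd"],
                b1_plus=f["b1_plus"], b1_minus=f["b1_minus"],
                seed=int(f["seed"]),
            )


def _ellipse(shape: int, center, semi_axes, rr, cc) -> np.ndarray:
    cy, cx = center
    ay, ax = semi_axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _smooth_field(rng, shape: int, amplitude: float) -> np.ndarray:
    """Low-order 2-D polynomial surface, 1 +/- amplitude, mean ~1."""
    y, x = np.mgrid[0:shape, 0:shape]
    u = 2.0 * x / (shape - 1) - 1.0
    v = 2.0 * y / (shape - 1) - 1.0
    terms = [u, v, u * v, u ** 2 - 1 / 3, v ** 2 - 1 / 3]
    coef = rng.uniform(-1.0, 1.0, size=len(terms))
    f = sum(c * t for c, t in zip(coef, terms))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak * amplitude
    return 1.0 + f


def make_phantom(
    shape: int = 128,
    anatomy: str = "calf",
    target_imat_fraction: float = 0.2,
    seed: int = 0,
    texture_scale: float = 4.0,
) -> PhantomTruth:
    """Generate one synthetic slice with the requested IMAT fraction.

    Parameters
    ----------
    shape : image side in pixels (64..256).
    anatomy : "calf" (two bones) or "thigh" (one bone).
    target_imat_fraction : requested |IMAT| / |muscle region|, in [0, 0.95].
        The achieved fraction is within +/-0.02 of the target (quantile
        thresholding of the infiltration field makes it essentially exact).
    seed : RNG seed; identical arguments give a bit-identical phantom.
    texture_scale : Gaussian smoothing radius (px) of the infiltration
        random field; controls IMAT speckle size.
    """
    if not 64 <= shape <= 256:
        raise ValueError("shape must be in [64, 256]")
    if not 0.0 <= target_imat_fraction <= 0.95:
        raise ValueError("target_imat_fraction must be in [0, 0.95]")
    if anatomy not in ("calf", "thigh"):
        raise ValueError("anatomy must be 'calf' or 'thigh'")

    rng = np.random.default_rng(seed)
    s = shape / 128.0
    rr, cc = np.mgrid[0:shape, 0:shape].astype(np.float64)
    center = (shape / 2.0 + rng.uniform(-2, 2) * s,
              shape / 2.0 + rng.uniform(-2, 2) * s)

    # muscle dominates the cross-section: a thin SAT ring (~6-9 px at
    # 1.5 mm/px) separates skin from the fascia lata
    jit = rng.uniform(0.96, 1.04, size=4)
    outer = _ellipse(shape, center, (57 * s * jit[0], 51 * s * jit[1]), rr, cc)
    fascia = _ellipse(shape, center, (52 * s * jit[2], 46 * s * jit[3]), rr, cc)

    tissue = np.zeros((shape, shape), dtype=np.int16)
    tissue[outer] = L.SAT
    tissue[fascia] = L.VIABLE

    # bone discs with marrow cores, strictly inside the fascia
    if anatomy == "calf":
        bones = [
            ((center[0] + 12 * s, center[1] - 10 * s), 9.0 * s, 5.5 * s),
            ((center[0] + 6 * s, center[1] + 18 * s), 5.0 * s, 2.5 * s),
        ]
    else:
        bones = [((center[0] + 6 * s, center[1]), 11.0 * s, 6.5 * s)]
    for bc, r_bone, r_marrow in bones:
        bone = _ellipse(shape, bc, (r_bone, r_bone), rr, cc)
        marrow = _ellipse(shape, bc, (r_marrow, r_marrow), rr, cc)
        tissue[bone & fascia] = L.BONE
        tissue[marrow & fascia] = L.MARROW

    muscle = tissue == L.VIABLE
    n_muscle = int(muscle.sum())
    if n_muscle < 200:
        raise ValueError("shape too small to fit the leg geometry")

    # IMAT infiltration: smoothed random field thresholded at the quantile
    # that yields the target pixel count
    field = ndimage.gaussian_filter(
        rng.standard_normal((shape, shape)), sigma=texture_scale
    )
    n_imat = int(round(target_imat_fraction * n_muscle))
    if n_imat > 0:
        vals = field[muscle]
        thr = np.partition(vals, n_muscle - n_imat)[n_muscle - n_imat]
        imat = muscle & (field >= thr)
        # quantile ties could overshoot; trim deterministically if needed
        excess = int(imat.sum()) - n_imat
        if excess > 0:
            idx = np.argwhere(imat & (field == thr))
            for k in range(min(excess, len(idx))):
                imat[tuple(idx[k])] = False
        tissue[imat] = L.IMAT

    muscle_region = (tissue == L.VIABLE) | (tissue == L.IMAT)

    # per-pixel MR tissue parameters
    ff = np.zeros((shape, shape))
    ff[tissue == L.VIABLE] = rng.uniform(0.0, 0.2, (tissue == L.VIABLE).sum())
    ff[tissue == L.IMAT] = rng.uniform(0.6, 1.0, (tissue == L.IMAT).sum())
    fatty = (tissue == L.SAT) | (tissue == L.MARROW)
    ff[fatty] = rng.uniform(0.9, 1.0, fatty.sum())

    t2w = np.clip(rng.normal(38.0, 3.0, (shape, shape)), 15.0, 80.0)
    t2f = np.clip(rng.normal(150.0, 10.0, (shape, shape)), 112.0, 188.0)
    pd = np.zeros((shape, shape))
    body = tissue > 0
    pd[body] = np.clip(rng.normal(0.9, 0.03, int(body.sum())), 0.7, 1.1)
    pd[fatty | (tissue == L.IMAT)] *= rng.uniform(1.05, 1.15)
    pd[tissue == L.BONE] *= 0.15  # cortical bone: little mobile proton signal

    b1p = np.clip(_smooth_field(rng, shape, rng.uniform(0.08, 0.18)), 0.75, 1.25)
    b1m = np.clip(_smooth_field(rng, shape, rng.uniform(0.08, 0.18)), 0.7, 1.3)

    return PhantomTruth(
        tissue_mask=tissue, fat_fraction=ff, t2_water=t2w, t2_fat=t2f,
        pd=pd, b1_plus=b1p, b1_minus=b1m, seed=seed,
    )


def simulate_mese(
    truth: PhantomTruth,
    protocol: Protocol,
    dictionary,
    snr: float | None = None,
    seed: int = 0,
) -> EchoSeries:
    """Simulate the MESE magnitude series for a phantom.

    Per pixel: ``signal(TE_k) = b1_minus * pd * [(1-ff) * curve(t2_water, b1+)
    + ff * curve(t2_fat, b1+)]`` with decay curves looked up from the nearest
    dictionary grid entry.  When ``snr`` is given, complex Gaussian noise of
    standard deviation ``mean(first-echo muscle signal) / snr`` is added and
    the magnitude taken (Rician noise, the standard model for magnitude MRI).
    """
    if dictionary.protocol != protocol:
        raise ValueError("dictionary was simulated under a different protocol")

    curves = dictionary.unnormalized_curves  # (nT2, nB1, nE)
    it2w = dictionary.nearest_t2_index(truth.t2_water)
    it2f = dictionary.nearest_t2_index(truth.t2_fat)
    ib1 = dictionary.nearest_b1_index(truth.b1_plus)

    cw = curves[it2w, ib1]              # (H, W, nE)
    cf = curves[it2f, ib1]
    ff = truth.fat_fraction[..., None]
    amp = (truth.b1_minus * truth.pd)[..., None]
    signal = amp * ((1.0 - ff) * cw + ff * cf)

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        muscle = truth.muscle_region_mask
        sigma = float(signal[..., 0][muscle].mean()) / snr
        rng = np.random.default_rng(seed)
        noise_re = rng.normal(0.0, sigma, signal.shape)
        noise_im = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + noise_re) ** 2 + noise_im ** 2)

    return EchoSeries(data=signal, protocol=protocol)


def make_cohort(
    n_subjects: int,
    severity_mix: dict,
    out_dir: str | Path,
    seed: int = 0,
    protocol: Protocol | None = None,
    dictionary=None,
    snr: float | None = 50.0,
    shape: int = 128,
    anatomy: str = "calf",
) -> pd.DataFrame:
    """Write a cohort of synthetic subjects and return the manifest table.

    Each subject gets a target IMAT fraction sampled uniformly inside its
    severity band (mild 0-33%, moderate 34-66%, severe 67-95%), one echo
    series (``<id>_echoes.npz``) and one truth bundle (``<id>_truth.npz``).
    The manifest (``manifest.csv``) records subject_id, severity,
    imat_fraction_true and the per-subject seed.
    """
    if sum(severity_mix.values()) != n_subjects:
        raise ValueError("severity_mix counts must sum to n_subjects")
    unknown = set(severity_mix) - set(SEVERITY_BANDS)
    if unknown:
        raise ValueError(f"unknown severity levels: {sorted(unknown)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protocol = protocol or Protocol()
    if dictionary is None:
        from .relaxometry import build_dictionary

        dictionary = build_dictionary(protocol)

    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for severity in ("mild", "moderate", "severe"):
        lo, hi = SEVERITY_BANDS[severity]
        for _ in range(severity_mix.get(severity, 0)):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            target = float(rng.uniform(lo, hi))
            truth = make_phantom(shape, anatomy, target, seed=sub_seed)
            series = simulate_mese(truth, protocol, dictionary, snr=snr,
                                   seed=sub_seed + 1)
            sid = f"sub{i:03d}"
            series.save(out_dir / f"{sid}_echoes.npz")
            truth.save(out_dir / f"{sid}_truth.npz")
            rows.append({
                "subject_id": sid, "severity": severity,
                "target_imat_fraction": target,
                "imat_fraction_true": truth.imat_fraction_true,
                "seed": sub_seed,
            })
            i += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
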