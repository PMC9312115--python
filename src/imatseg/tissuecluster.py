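"""Stage 2: weakly supervised clustering of muscle pixels into viable
muscle and IMAT.

Patches of 16x16 pixels are cropped from the (mask-multiplied) T2 and PD
maps around every pixel of the eroded muscle mask, carrying the pixel's
weak label (from the fat-fraction > 50% rule).  A convolutional
auto-encoder embeds each patch on the unit hypersphere; training combines a
reconstruction (MSE) loss with a triplet loss whose anchor/positive share
the weak label and whose negative has the other label (DCAETL).  k-means
with k = 2 in the embedded space defines the tissue clusters; clusters take
the majority weak label of their members, and test pixels go to the nearest
centroid.  Three comparison clusterers are provided: plain intensity
k-means on (T2, PD) pixel values, the same auto-encoder trained with MSE
only (DCAE + k-means), and deep embedded clustering (DCAE_DC), which
fine-tunes the auto-encoder with a KL-divergence clustering loss over
Student's-t soft assignments to trainable centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from . import nn
from . import labels as L
from .labels import TissueLabelMap

LABEL_IMAT = 0
LABEL_VIABLE = 1
PATCH = 16
HALF = PATCH // 2   # even-kernel convention: center at index 8, rows r-8..r+7


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """16x16x2 patches with centers, weak labels and slice provenance."""

    patches: np.ndarray                 # (M, 2, 16, 16) float32
    centers: np.ndarray                 # (M, 2) int
    weak_labels: np.ndarray | None      # (M,) in {0 IMAT, 1 viable} or None
    source_slice: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim != 4 or self.patches.shape[1:] != (2, PATCH, PATCH):
            raise ValueError("patches must be (M, 2, 16, 16)")
        if self.source_slice is None:
            self.source_slice = np.zeros(len(self.patches), dtype=np.int32)

    def __len__(self) -> int:
        return len(self.patches)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path), patches=self.patches, centers=self.centers,
            weak_labels=(np.array([]) if self.weak_labels is None
                         else self.weak_labels),
            source_slice=self.source_slice,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchSet":
        with np.load(Path(path)) as f:
            wl = f["weak_labels"]
            return cls(patches=f["patches"], centers=f["centers"],
                       weak_labels=None if wl.size == 0 else wl,
                       source_slice=f["source_slice"])

    @staticmethod
    def concatenate(sets: list) -> "PatchSet":
        wl = None
        if all(s.weak_labels is not None for s in sets):
            wl = np.concatenate([s.weak_labels for s in sets])
        return PatchSet(
            patches=np.concatenate([s.patches for s in sets]),
            centers=np.concatenate([s.centers for s in sets]),
            weak_labels=wl,
            source_slice=np.concatenate([
                np.full(len(s), i, dtype=np.int32) for i, s in enumerate(sets)
            ]),
        )


def erode_muscle_mask(muscle_mask: np.ndarray) -> np.ndarray:
    """16x16 morphological erosion (center at index 8 of the kernel)."""
    return ndimage.binary_erosion(
        muscle_mask.astype(bool), structure=np.ones((PATCH, PATCH))
    )


def extract_patches(
    t2: np.ndarray,
    pd: np.ndarray,
    muscle_mask: np.ndarray,
    weak_label_map: TissueLabelMap | None = None,
) -> PatchSet:
    """One 16x16x2 patch per pixel of the eroded muscle mask.

    The T2/PD maps are multiplied by the (uneroded) mask first, so patches
    near the region boundary see zeros outside the muscle but their centers
    are guaranteed 8 pixels away from it.  The patch window for center
    (r, c) covers rows r-8..r+7 and columns c-8..c+7.  Weak labels are read
    from ``weak_label_map`` at the center pixel (1 viable, 0 IMAT).
    """
    muscle_mask = muscle_mask.astype(bool)
    eroded = erode_muscle_mask(muscle_mask)
    if not eroded.any():
        raise ValueError(
            f"eroded mask is empty: the muscle region must contain a full "
            f"{PATCH}x{PATCH} window"
        )
    t2m = t2 * muscle_mask
    pdm = pd * muscle_mask
    centers = np.argwhere(eroded)
    m = len(centers)
    patches = np.empty((m, 2, PATCH, PATCH), dtype=np.float32)
    for i, (r, c) in enumerate(centers):
        patches[i, 0] = t2m[r - HALF:r + HALF, c - HALF:c + HALF]
        patches[i, 1] = pdm[r - HALF:r + HALF, c - HALF:c + HALF]
    weak = None
    if weak_label_map is not None:
        codes = weak_label_map.labels[centers[:, 0], centers[:, 1]]
        weak = np.where(codes == L.IMAT, LABEL_IMAT, LABEL_VIABLE).astype(np.int8)
    return PatchSet(patches=patches, centers=centers, weak_labels=weak)


# ---------------------------------------------------------------------------
# Losses and triplet sampling
# ---------------------------------------------------------------------------

def sample_triplet(patchset: PatchSet, seed: int = 0) -> tuple:
    """Indices (anchor, positive, negative) under the weak-label rule.

    The anchor is uniform over all patches; the positive is uniform over
    the anchor's class excluding the anchor itself; the negative is uniform
    over the other class.
    """
    idx = _sample_triplets(patchset, 1, np.random.default_rng(seed))
    return tuple(int(v) for v in idx[0])


def _sample_triplets(patchset: PatchSet, n: int, rng) -> np.ndarray:
    if patchset.weak_labels is None:
        raise ValueError("triplet sampling needs weak labels")
    wl = patchset.weak_labels
    by_class = {c: np.where(wl == c)[0] for c in (LABEL_IMAT, LABEL_VIABLE)}
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(
                f"class {c} has {len(members)} patches; both tissue classes "
                "must be present (>=2 each) for triplet training"
            )
    a = rng.integers(0, len(wl), size=n)
    p = np.empty(n, dtype=np.int64)
    ng = np.empty(n, dtype=np.int64)
    for i, ai in enumerate(a):
        same = by_class[int(wl[ai])]
        other = by_class[1 - int(wl[ai])]
        while True:
            cand = same[rng.integers(0, len(same))]
            if cand != ai:
                break
        p[i] = cand
        ng[i] = other[rng.integers(0, len(other))]
    return np.stack([a, p, ng], axis=1)


def triplet_loss(f_a, f_p, f_n, margin: float = 1.0):
    """Sum over the batch of max(0, |a-p|^2 - |a-n|^2 + margin).

    Accepts single vectors or (N, d) batches; returns (loss, grads) where
    grads = (d/da, d/dp, d/dn).
    """
    f_a, f_p, f_n = (np.atleast_2d(np.asarray(v, dtype=np.float64))
                     for v in (f_a, f_p, f_n))
    if not (f_a.shape == f_p.shape == f_n.shape):
        raise ValueError("triplet vectors must have equal shapes")
    dap = ((f_a - f_p) ** 2).sum(axis=1)
    dan = ((f_a - f_n) ** 2).sum(axis=1)
    active = (dap - dan + margin) > 0
    loss = float(np.sum(np.maximum(0.0, dap - dan + margin)))
    w = active[:, None].astype(np.float64)
    ga = w * 2.0 * (f_n - f_p)
    gp = w * 2.0 * (f_p - f_a)
    gn = w * 2.0 * (f_a - f_n)
    return loss, (ga, gp, gn)


def combined_loss(l_triplet: float, mse_a: float, mse_p: float, mse_n: float,
                  beta: float = 0.5, lam: float = 1.0 / 6.0) -> float:
    """beta * L_triplet + lambda * (MSE_a + MSE_p + MSE_n)."""
    if beta < 0 or lam < 0:
        raise ValueError("loss weights must be non-negative")
    return beta * l_triplet + lam * (mse_a + mse_p + mse_n)


# ---------------------------------------------------------------------------
# The convolutional auto-encoder
# ---------------------------------------------------------------------------

@dataclass
class DCAEConfig:
    encoder_filters: tuple = (32, 64)
    latent_dim: int = 16
    margin: float = 1.0
    beta: float = 0.5            # triplet-loss weight
    lam: float = 1.0 / 6.0       # reconstruction-loss weight
    batch_size: int = 256
    epochs: int = 100
    lr: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.beta < 0 or self.lam < 0:
            raise ValueError("loss weights must be non-negative")


class DCAE:
    """Encoder/decoder for 16x16x2 patches with unit-norm embeddings.

    Encoder: two conv blocks (3x3 conv, ReLU, 2x2 max pool, batch norm)
    with 32 and 64 feature maps, flatten to 1024, dense to the latent
    dimension, l2 normalization.  Decoder: dense to 1024, reshape 4x4x64,
    two 3x3 stride-2 transposed convolutions (64->32->2).
    """

    def __init__(self, config: DCAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f1, f2 = config.encoder_filters
        flat = f2 * (PATCH // 4) ** 2      # 1024 for the default filters
        self.encoder = nn.Sequential(
            nn.Conv2d(2, f1, 3, rng=rng), nn.ReLU(), nn.MaxPool2(),
            nn.BatchNorm(f1),
            nn.Conv2d(f1, f2, 3, rng=rng), nn.ReLU(), nn.MaxPool2(),
            nn.BatchNorm(f2),
            nn.Flatten(),
            nn.Dense(flat, config.latent_dim, rng=rng),
            nn.L2Normalize(),
        )
        self.decoder = nn.Sequential(
            nn.Dense(config.latent_dim, flat, rng=rng), nn.ReLU(),
            nn.Reshape((f2, PATCH // 4, PATCH // 4)),
            nn.ConvTranspose2d(f2, f1, 3, stride=2, pad=1, output_padding=1,
                               rng=rng),
            nn.ReLU(),
            nn.ConvTranspose2d(f1, 2, 3, stride=2, pad=1, output_padding=1,
                               rng=rng),
        )
        # patch standardization constants (set at training time)
        self.norm_mean = np.zeros(2, dtype=np.float32)
        self.norm_std = np.ones(2, dtype=np.float32)

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def standardize(self, patches: np.ndarray) -> np.ndarray:
        return ((patches - self.norm_mean[None, :, None, None])
                / self.norm_std[None, :, None, None]).astype(nn.F32)

    def fit_normalization(self, patches: np.ndarray) -> None:
        self.norm_mean = patches.mean(axis=(0, 2, 3)).astype(np.float32)
        self.norm_std = (patches.std(axis=(0, 2, 3)) + 1e-8).astype(np.float32)

    def embed(self, patches: np.ndarray, batch: int = 4096) -> np.ndarray:
        """Unit-norm embeddings in eval mode, (M, latent_dim)."""
        x = self.standardize(patches)
        out = [self.encoder.forward(x[i:i + batch], train=False)
               for i in range(0, len(x), batch)]
        return np.concatenate(out).astype(np.float64)

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params())}
        bns = [lay for lay in self.encoder.layers if isinstance(lay, nn.BatchNorm)]
        for j, bn in enumerate(bns):
            arrays[f"bn{j}_mean"] = bn.run_mean
            arrays[f"bn{j}_var"] = bn.run_var
        np.savez_compressed(
            Path(path),
            config=np.array(list(asdict(self.config).items()), dtype=object),
            norm_mean=self.norm_mean, norm_std=self.norm_std, **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DCAE":
        with np.load(Path(path), allow_pickle=True) as f:
            cfg = {k: v for k, v in f["config"]}
            config = DCAEConfig(
                encoder_filters=tuple(cfg["encoder_filters"]),
                latent_dim=int(cfg["latent_dim"]), margin=float(cfg["margin"]),
                beta=float(cfg["beta"]), lam=float(cfg["lam"]),
                batch_size=int(cfg["batch_size"]), epochs=int(cfg["epochs"]),
                lr=float(cfg["lr"]), seed=int(cfg["seed"]),
            )
            model = cls(config)
            for i, (p, _) in enumerate(model.params()):
                p[...] = f[f"p{i}"]
            bns = [lay for lay in model.encoder.layers
                   if isinstance(lay, nn.BatchNorm)]
            for j, bn in enumerate(bns):
                bn.run_mean = f[f"bn{j}_mean"]
                bn.run_var = f[f"bn{j}_var"]
            model.norm_mean = f["norm_mean"]
            model.norm_std = f["norm_std"]
        return model


def _mse_and_grad(x_hat: np.ndarray, x: np.ndarray):
    """Element-mean MSE and its gradient wrt x_hat."""
    diff = (x_hat - x).astype(np.float64)
    return float((diff ** 2).mean()), (2.0 * diff / diff.size).astype(nn.F32)


def train_dcaetl(patchset: PatchSet, config: DCAEConfig) -> tuple:
    """Train the auto-encoder with combined triplet + reconstruction loss.

    Per batch, ``batch_size`` triplets are sampled under the weak-label
    rule; anchors, positives and negatives stream through the shared
    encoder/decoder, and the loss is ``beta * mean-triplet + lam * (MSE_a +
    MSE_p + MSE_n)``.  Returns (model, loss_history).
    """
    if patchset.weak_labels is None:
        raise ValueError("DCAETL needs weak labels; use train_dcae otherwise")
    model = DCAE(config)
    model.fit_normalization(patchset.patches)
    X = model.standardize(patchset.patches)
    opt = nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n_batches = max(1, len(patchset) // config.batch_size)
    nb = config.batch_size
    history = []
    for _ in range(config.epochs):
        losses = []
        for _ in range(n_batches):
            trip = _sample_triplets(patchset, nb, rng)
            # anchors, positives, negatives as one 3N batch through the
            # shared encoder/decoder
            xb = X[trip.T.reshape(-1)]
            z = model.encoder.forward(xb, train=True)
            xh = model.decoder.forward(z, train=True)
            z64 = z.astype(np.float64)
            za, zp, zn = z64[:nb], z64[nb:2 * nb], z64[2 * nb:]

            diff = (xh - xb).astype(np.float64)
            per_stream = diff.size / 3.0
            mses = [(diff[s * nb:(s + 1) * nb] ** 2).sum() / per_stream
                    for s in range(3)]
            gx = (2.0 * diff / per_stream) * config.lam

            lt, (ga, gp, gn) = triplet_loss(za, zp, zn, config.margin)
            lt_mean = lt / nb
            total = combined_loss(lt_mean, *mses, beta=config.beta,
                                  lam=config.lam)
            gz_trip = np.concatenate([ga, gp, gn]) * (config.beta / nb)

            opt.zero_grad()
            gz = model.decoder.backward(gx.astype(nn.F32))
            model.encoder.backward((gz + gz_trip).astype(nn.F32))
            opt.step()
            losses.append(total)
        history.append(float(np.mean(losses)))
    return model, history


def train_dcae(patchset: PatchSet, config: DCAEConfig) -> tuple:
    """Auto-encoder trained with the MSE reconstruction loss only."""
    model = DCAE(config)
    model.fit_normalization(patchset.patches)
    X = model.standardize(patchset.patches)
    opt = nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X[idx]
            z = model.encoder.forward(xb, train=True)
            xh = model.decoder.forward(z, train=True)
            mse, gx = _mse_and_grad(xh, xb)
            opt.zero_grad()
            gz = model.decoder.backward(gx)
            model.encoder.backward(gz.astype(nn.F32))
            opt.step()
            losses.append(mse)
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# Clustering on embeddings
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Two k-means centroids in latent space plus the cluster->label map."""

    centroids: np.ndarray                  # (2, d)
    cluster_to_label: dict                 # {0/1 -> LABEL_VIABLE/LABEL_IMAT}
    encoder_ref: str = ""

    def assign(self, z: np.ndarray) -> np.ndarray:
        d = ((z[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def labels_for(self, z: np.ndarray) -> np.ndarray:
        clusters = self.assign(z)
        lut = np.array([self.cluster_to_label[0], self.cluster_to_label[1]])
        return lut[clusters]


def _majority_map(clusters: np.ndarray, weak_labels: np.ndarray) -> dict:
    mapping = {}
    for c in (0, 1):
        members = weak_labels[clusters == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty; degenerate separation")
        mapping[c] = int(np.round(members.mean()) >= 0.5)
    if mapping[0] == mapping[1]:
        raise ValueError(
            "both clusters map to the same majority label; the embedding "
            "does not separate the tissues"
        )
    return mapping


def fit_clusters(model: DCAE, patchset: PatchSet, seed: int = 0,
                 n_init: int = 10) -> ClusterModel:
    """k-means (k = 2) on the embeddings + majority-vote cluster labeling."""
    z = model.embed(patchset.patches)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    clusters = km.fit_predict(z)
    mapping = _majority_map(clusters, patchset.weak_labels)
    return ClusterModel(centroids=km.cluster_centers_, cluster_to_label=mapping)


def classify_pixels(
    cluster_model: ClusterModel,
    encoder: DCAE,
    t2: np.ndarray,
    pd: np.ndarray,
    muscle_mask: np.ndarray,
) -> TissueLabelMap:
    """Label every muscle-mask pixel viable or IMAT.

    Interior pixels (surviving the 16x16 erosion) are classified by
    nearest-centroid assignment of their patch embedding; boundary pixels
    (inside the mask but removed by the erosion) take the label of the
    nearest labeled interior pixel (Euclidean distance transform), so the
    dilated mask is fully labeled.
    """
    muscle_mask = muscle_mask.astype(bool)
    ps = extract_patches(t2, pd, muscle_mask)
    z = encoder.embed(ps.patches)
    lab01 = cluster_model.labels_for(z)        # {0 IMAT, 1 viable}

    interior = np.zeros_like(muscle_mask)
    interior[ps.centers[:, 0], ps.centers[:, 1]] = True
    code_img = np.full(muscle_mask.shape, L.BACKGROUND, dtype=np.int16)
    codes = np.where(lab01 == LABEL_IMAT, L.IMAT, L.VIABLE)
    code_img[ps.centers[:, 0], ps.centers[:, 1]] = codes

    # nearest-interior fill for the boundary band
    _, (ir, ic) = ndimage.distance_transform_edt(
        ~interior, return_indices=True)
    filled = code_img[ir, ic]
    out = np.full(muscle_mask.shape, L.BACKGROUND, dtype=np.int16)
    out[muscle_mask] = filled[muscle_mask]
    return TissueLabelMap(out)


def baseline_intensity_kmeans(
    t2: np.ndarray,
    pd: np.ndarray,
    muscle_mask: np.ndarray,
    seed: int = 0,
    weak_label_map: TissueLabelMap | None = None,
) -> TissueLabelMap:
    """k-means (k = 2) on per-pixel (T2, PD) intensities inside the mask.

    Clusters map to tissue labels by majority weak label when a label map
    is given, otherwise by mean T2 (higher-T2 cluster -> IMAT).
    """
    muscle_mask = muscle_mask.astype(bool)
    n = int(muscle_mask.sum())
    if n < 2:
        raise ValueError("mask must contain at least 2 pixels")
    feats = np.stack([t2[muscle_mask], pd[muscle_mask]], axis=1)
    std = feats.std(axis=0)
    if np.all(std == 0):
        raise ValueError("degenerate clustering: identical T2/PD everywhere")
    feats = (feats - feats.mean(axis=0)) / np.where(std == 0, 1.0, std)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    clusters = km.fit_predict(feats)
    if weak_label_map is not None:
        wl = np.where(weak_label_map.labels[muscle_mask] == L.IMAT,
                      LABEL_IMAT, LABEL_VIABLE)
        mapping = _majority_map(clusters, wl)
    else:
        t2_means = [t2[muscle_mask][clusters == c].mean() for c in (0, 1)]
        hi = int(np.argmax(t2_means))
        mapping = {hi: LABEL_IMAT, 1 - hi: LABEL_VIABLE}
    codes = np.where(np.array([mapping[c] for c in clusters]) == LABEL_IMAT,
                     L.IMAT, L.VIABLE)
    out = np.full(muscle_mask.shape, L.BACKGROUND, dtype=np.int16)
    out[muscle_mask] = codes
    return TissueLabelMap(out)


def train_dcae_kmeans(patchset: PatchSet, config: DCAEConfig,
                      seed: int | None = None) -> tuple:
    """DCAE baseline: MSE-only training followed by embedded k-means."""
    model, history = train_dcae(patchset, config)
    cm = fit_clusters(model, patchset,
                      seed=config.seed if seed is None else seed)
    return model, cm, history


# ---------------------------------------------------------------------------
# Deep embedded clustering (DCAE_DC)
# ---------------------------------------------------------------------------

def soft_assignment(z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Student's-t soft labels: q_j ~ (1 + |z - mu_j|^2)^-1, normalized."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    d2 = ((z[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    u = 1.0 / (1.0 + d2)
    q = u / u.sum(axis=1, keepdims=True)
    return q[0] if z.shape[0] == 1 and np.asarray(z).ndim == 1 else q


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened targets p_ij = (q_ij^2 / f_j) / sum_j(q_ij^2 / f_j)."""
    Q = np.asarray(Q, dtype=np.float64)
    if Q.size == 0:
        raise ValueError("empty soft-label matrix")
    f = Q.sum(axis=0)
    w = Q ** 2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) summed over points and clusters."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    m = P > 0
    return float((P[m] * np.log(P[m] / Q[m])).sum())


def train_dcae_dc(
    patchset: PatchSet,
    config: DCAEConfig,
    gamma: float = 0.1,
    update_interval: int = 200,
    stop_delta: float = 1e-4,
    pretrain_epochs: int = 1,
    max_epochs: int | None = None,
) -> tuple:
    """Deep embedded clustering: pretrain, then fine-tune with L_r + gamma*L_c.

    The DCAE is pretrained with MSE only; k-means on the pretrained
    embeddings initializes trainable centroids.  Fine-tuning minimizes
    reconstruction + gamma * KL(P || Q), with the target distribution P
    recomputed from all embedded points every ``update_interval``
    iterations; training stops when the fraction of changed hard
    assignments between consecutive P-updates falls below ``stop_delta``
    (or after ``max_epochs``).  Returns (model, ClusterModel, history).
    """
    pre_cfg = dc_replace(config, epochs=pretrain_epochs)
    model, _ = train_dcae(patchset, pre_cfg)
    X = model.standardize(patchset.patches)
    z = model.embed(patchset.patches)
    km = KMeans(n_clusters=2, n_init=10, random_state=config.seed)
    km.fit(z)
    centroids = km.cluster_centers_.astype(np.float64)
    d_cent = np.zeros_like(centroids)

    opt = nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    max_epochs = max_epochs if max_epochs is not None else config.epochs
    P_full = target_distribution(soft_assignment(z, centroids))
    last_assign = np.argmax(P_full, axis=1)
    history = []
    it = 0
    stop = False
    for _ in range(max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            if it > 0 and it % update_interval == 0:
                z = model.embed(patchset.patches)
                Q_full = soft_assignment(z, centroids)
                P_full = target_distribution(Q_full)
                assign = np.argmax(Q_full, axis=1)
                changed = float(np.mean(assign != last_assign))
                last_assign = assign
                if changed < stop_delta:
                    stop = True
                    break
            idx = order[start:start + config.batch_size]
            xb = X[idx]
            zb = model.encoder.forward(xb, train=True).astype(np.float64)
            xh = model.decoder.forward(zb.astype(nn.F32), train=True)
            mse, gx = _mse_and_grad(xh, xb)
            Qb = soft_assignment(zb, centroids)
            Pb = P_full[idx]
            lc = kl_divergence(Pb, Qb) / len(idx)
            loss = mse + gamma * lc
            if not np.isfinite(loss):
                raise FloatingPointError("divergent DCAE_DC loss")
            # DEC gradients of KL wrt embeddings and centroids
            u = 1.0 / (1.0 + ((zb[:, None, :] - centroids[None]) ** 2).sum(axis=2))
            coeff = (u * (Pb - Qb))[..., None] * (zb[:, None, :] - centroids[None])
            gz_kl = 2.0 * coeff.sum(axis=1) * gamma / len(idx)
            g_cent = -2.0 * coeff.sum(axis=0) * gamma / len(idx)
            opt.zero_grad()
            gz = model.decoder.backward(gx)
            model.encoder.backward((gz + gz_kl).astype(nn.F32))
            opt.step()
            # centroid update shares Adam's learning rate (plain SGD step)
            d_cent = 0.9 * d_cent + g_cent
            centroids -= config.lr * 10.0 * d_cent
            losses.append(loss)
            it += 1
        if losses:
            history.append(float(np.mean(losses)))
        if stop:
            break

    z = model.embed(patchset.patches)
    clusters = np.argmax(soft_assignment(z, centroids), axis=1)
    mapping = _majority_map(clusters, patchset.weak_labels)
    cm = ClusterModel(centroids=centroids, cluster_to_label=mapping)
    return model, cm, history
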