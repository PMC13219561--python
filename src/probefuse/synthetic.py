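"""Seeded synthetic episode generators and planted-layer fixtures.

Two families of class-structured image tasks are provided, emulating the
shallow-versus-deep discriminability contrast of real imaging data:

* ``texture`` — each class is a high-frequency sinusoidal grating with a
  class-specific orientation and period, so the signal lives in local
  high-frequency content;
* ``shape`` — each class is a layout of Gaussian blobs at class-specific
  positions and widths, so the signal lives in global geometry.

Images are ``margin * class_pattern + noise_sd * white_noise``, standardized
per channel; margin = 0 therefore yields labels that are independent of the
pixels. The *planted task* fixture instead labels generic images by the sign
pattern of a seeded random projection of a chosen backbone layer's pooled
features (directions drawn within the layer's innovation subspace, so the
signal is specific to that depth), with samples too close to any decision
hyperplane resampled, so the planted layer carries a clean linear label
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import autodiff as ad
from .backbone import Backbone
from .episodes import Episode


@dataclass(frozen=True)
class SyntheticSpec:
    n_way: int = 4
    k_shot: int = 5
    n_query: int = 20
    image_size: int = 32
    channels: int = 1
    pattern: str = "texture"      # or "shape"
    noise_sd: float = 1.0
    margin: float = 5.0           # signal amplitude relative to noise
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("texture", "shape"):
            raise ValueError(f"unknown pattern family {self.pattern!r}")
        if self.n_way < 2 or self.k_shot < 1:
            raise ValueError("need n_way >= 2 and k_shot >= 1")
        if self.noise_sd < 0 or self.margin < 0:
            raise ValueError("noise_sd and margin must be nonnegative")


def _standardize(images: np.ndarray) -> np.ndarray:
    """Zero mean, unit variance per image and channel (guarded)."""
    mean = images.mean(axis=(-2, -1), keepdims=True)
    std = images.std(axis=(-2, -1), keepdims=True)
    return (images - mean) / (std + 1e-8)


def _texture_pattern(rng: np.random.Generator, size: int,
                     channels: int) -> np.ndarray:
    """High-frequency grating: random orientation, period of 2-4 pixels."""
    theta = rng.uniform(0, np.pi)
    period = rng.uniform(2.0, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    wave = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta))
                  / period + phase)
    return np.broadcast_to(wave, (channels, size, size)).copy()


def _shape_pattern(rng: np.random.Generator, size: int,
                   channels: int) -> np.ndarray:
    """Global layout: two Gaussian blobs at class-specific locations."""
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for _ in range(2):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
        sigma = rng.uniform(0.08 * size, 0.2 * size)
        img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    img -= img.mean()
    return np.broadcast_to(img, (channels, size, size)).copy()


def generate_episode(spec: SyntheticSpec) -> Episode:
    """One class-balanced N-way K-shot episode with M query images."""
    rng = np.random.default_rng(spec.seed)
    maker = _texture_pattern if spec.pattern == "texture" else _shape_pattern
    prototypes = [maker(rng, spec.image_size, spec.channels)
                  for _ in range(spec.n_way)]
    if spec.n_query < spec.n_way:
        warnings.warn("n_query < n_way: some classes absent from the query",
                      stacklevel=2)

    def draw(labels):
        shape = (len(labels), spec.channels, spec.image_size, spec.image_size)
        noise = rng.normal(0.0, 1.0, size=shape)
        signal = np.stack([prototypes[c] for c in labels])
        return _standardize(spec.margin * signal + spec.noise_sd * noise)

    sup_labels = np.repeat(np.arange(spec.n_way), spec.k_shot)
    qry_labels = rng.integers(0, spec.n_way, size=spec.n_query)
    # guarantee every class appears when the query is large enough
    if spec.n_query >= spec.n_way:
        qry_labels[: spec.n_way] = np.arange(spec.n_way)
        rng.shuffle(qry_labels)
    return Episode(
        support_images=draw(sup_labels), support_labels=sup_labels,
        query_images=draw(qry_labels), query_labels=qry_labels,
    )


@dataclass
class PlantedTask:
    """An episode whose labels are a function of one layer's features."""

    layer: int                     # informative layer, 1-based
    projection: np.ndarray         # [d, n_bits] random hyperplane directions
    center: np.ndarray             # feature mean used for centering
    scale: np.ndarray              # per-direction std used for margin units
    episode: Episode
    margin: float                  # exclusion half-width, in std units

    def label_of(self, pooled_features: np.ndarray) -> np.ndarray:
        """Apply the stored labeling rule to layer-`layer` pooled features."""
        z = (pooled_features - self.center) @ self.projection / self.scale
        bits = (z > 0).astype(int)
        return bits @ (1 << np.arange(bits.shape[1]))


def _generic_images(rng: np.random.Generator, n: int, size: int,
                    channels: int) -> np.ndarray:
    """Unlabeled probe images: white noise plus a random low-frequency wave."""
    imgs = rng.normal(0.0, 1.0, size=(n, channels, size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        theta = rng.uniform(0, np.pi)
        period = rng.uniform(size / 4, size)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta))
                      / period + phase)
        imgs[i] += 2.0 * wave
    return _standardize(imgs)


class GenerationError(RuntimeError):
    """Raised when margin filtering exhausts its retry budget."""


def generate_planted_task(backbone: Backbone, layer: int,
                          spec: SyntheticSpec, margin: float = 0.5,
                          max_batches: int = 400) -> PlantedTask:
    """Plant a linearly separable label signal at one backbone layer.

    Draws generic images, pools layer-`layer` features on the frozen
    backbone, and labels each image by the sign pattern of a seeded random
    projection (ceil(log2 N) directions -> up to 2^bits sign classes, of
    which the first N are kept). Images within `margin` standard deviations
    of any hyperplane are resampled so the task is learnably separable at
    small K. Support (K per class) and query sets are filled by rejection.
    """
    cfg = backbone.config
    if not 1 <= layer <= cfg.n_layers:
        raise ValueError(f"layer {layer} outside 1..{cfg.n_layers}")
    n_bits = max(1, int(np.ceil(np.log2(spec.n_way))))
    rng = np.random.default_rng(spec.seed)

    # calibrate the labeling rule on a reference batch
    ref = _generic_images(rng, 128, cfg.image_size, cfg.n_channels)
    with ad.no_grad():
        pooled = backbone.forward_features(ref).pooled
    ref_feats = pooled[layer - 1].numpy()
    centered = ref_feats - ref_feats.mean(axis=0)
    if layer > 1:
        # Hyperplane directions live in the span of the layer's *innovation*
        # (the residual after regressing out the previous layer's pooled
        # features): in a residual-stream encoder a fully random direction is
        # linearly present at every depth, which would defeat the plant.
        prev = pooled[layer - 2].numpy()
        prev_c = prev - prev.mean(axis=0)
        beta, *_ = np.linalg.lstsq(prev_c, centered, rcond=None)
        innovation = centered - prev_c @ beta
    else:
        innovation = centered
    n_basis = max(n_bits, 4)
    basis = np.linalg.svd(innovation, full_matrices=False)[2][:n_basis].T
    mix = rng.normal(size=(n_basis, n_bits))
    projection = np.linalg.qr(basis @ mix)[0]  # [d, n_bits], orthonormal
    center = ref_feats.mean(axis=0)
    z = (ref_feats - center) @ projection
    scale = z.std(axis=0) + 1e-12

    task = PlantedTask(layer=layer, projection=projection, center=center,
                       scale=scale, episode=None, margin=margin)

    need_support = {c: spec.k_shot for c in range(spec.n_way)}
    per_class_query = int(np.ceil(spec.n_query / spec.n_way))
    need_query = {c: per_class_query for c in range(spec.n_way)}
    sup_imgs, sup_lab, qry_imgs, qry_lab = [], [], [], []
    for _ in range(max_batches):
        batch = _generic_images(rng, 32, cfg.image_size, cfg.n_channels)
        with ad.no_grad():
            feats = backbone.forward_features(batch).pooled[layer - 1].numpy()
        zb = (feats - center) @ projection / scale
        ok = (np.abs(zb) > margin).all(axis=1)
        labels = task.label_of(feats)
        for i in np.flatnonzero(ok):
            c = int(labels[i])
            if c >= spec.n_way:
                continue
            if need_support[c] > 0:
                need_support[c] -= 1
                sup_imgs.append(batch[i])
                sup_lab.append(c)
            elif need_query[c] > 0:
                need_query[c] -= 1
                qry_imgs.append(batch[i])
                qry_lab.append(c)
        if not any(need_support.values()) and not any(need_query.values()):
            break
    else:
        raise GenerationError(
            "margin filtering exhausted the retry budget; lower the margin "
            "or the class count"
        )
    task.episode = Episode(
        support_images=np.stack(sup_imgs), support_labels=np.array(sup_lab),
        query_images=np.stack(qry_imgs), query_labels=np.array(qry_lab),
    )
    return task


# ----------------------------------------------------------------- export/IO
def export_episode(episode: Episode, directory) -> Path:
    """Write an episode as PNG files plus a CSV manifest.

    Pixel values are affinely mapped to 16-bit grayscale (or 8-bit RGB for
    3-channel images); the manifest stores the per-image value range so the
    loader can undo the mapping. Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, (images, labels) in (("support", episode.support),
                                    ("query", episode.query)):
        for i, (img, lab) in enumerate(zip(images, labels)):
            vmin, vmax = float(img.min()), float(img.max())
            span = (vmax - vmin) or 1.0
            name = f"{split}_{i:04d}.png"
            if img.shape[0] == 1:
                arr = ((img[0] - vmin) / span * 65535).round().astype(np.uint16)
                Image.fromarray(arr).save(directory / name)
            elif img.shape[0] == 3:
                arr = ((img - vmin) / span * 255).round().astype(np.uint8)
                Image.fromarray(arr.transpose(1, 2, 0), mode="RGB").save(
                    directory / name)
            else:
                raise ValueError("PNG export supports 1 or 3 channels")
            rows.append({"path": name, "split": split, "label": int(lab),
                         "vmin": vmin, "vmax": vmax})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_episode(manifest_path) -> Episode:
    """Load an episode previously written by :func:`export_episode`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    frame = pd.read_csv(manifest_path)
    required = {"path", "split", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{manifest_path}: manifest must have columns {sorted(required)}"
        )
    data = {"support": ([], []), "query": ([], [])}
    for row_no, row in frame.iterrows():
        if row["split"] not in data:
            raise ValueError(
                f"{manifest_path}:{row_no + 2}: unknown split {row['split']!r}"
            )
        path = directory / row["path"]
        if not path.exists():
            raise FileNotFoundError(f"{manifest_path}:{row_no + 2}: "
                                    f"missing image {path}")
        arr = np.asarray(Image.open(path), dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None] / 65535.0
        else:
            arr = arr.transpose(2, 0, 1) / 255.0
        vmin = float(row.get("vmin", 0.0))
        vmax = float(row.get("vmax", 1.0))
        arr = arr * ((vmax - vmin) or 1.0) + vmin
        data[row["split"]][0].append(arr)
        data[row["split"]][1].append(int(row["label"]))
    return Episode(
        support_images=np.stack(data["support"][0]),
        support_labels=np.array(data["support"][1]),
        query_images=np.stack(data["query"][0]),
        query_labels=np.array(data["query"][1]),
    )


def export_episode_npz(episode: Episode, path) -> Path:
    """Lossless compressed-array export of an episode."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez_compressed(
        path, support_images=episode.support_images,
        support_labels=episode.support_labels,
        query_images=episode.query_images,
        query_labels=episode.query_labels,
    )
    return path


def load_episode_npz(path) -> Episode:
    with np.load(path) as archive:
        return Episode(
            support_images=archive["support_images"],
            support_labels=archive["support_labels"],
            query_images=archive["query_images"],
            query_labels=archive["query_labels"],
        )
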