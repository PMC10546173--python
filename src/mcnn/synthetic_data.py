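"""Seeded two-class RGB image generator with a purely geometric class signal.

Real tasks in this problem family separate classes by *shape*, not by
brightness: glaucomatous optic discs differ from healthy ones in the
cup-to-disc ratio, and malignant skin lesions differ from benign ones in
border irregularity.  The generator emulates both structures:

``disc_cup``
    A bright disc on a dark background with an inner, brighter cup.  The
    cup-to-disc radius ratio is drawn from class-conditional normal
    distributions whose means are ``effect_size`` pooled standard
    deviations apart.

``lesion_border``
    A dark blob on a light background whose polar radius is perturbed by
    random Fourier harmonics; the harmonic amplitude (border roughness)
    differs between classes by ``effect_size`` pooled SDs.

Every nuisance parameter — disc size, center position, per-channel tint,
cup/disc intensities — is drawn independently of the class, and each
grayscale pattern is shifted to a fixed mean brightness before tinting, so
the label is recoverable from geometry only: a mean-intensity classifier
stays at chance.  ``effect_size = 0`` makes the two class-conditional
distributions identical.  Generation is a pure function of the
configuration: the same config yields bitwise-identical images.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate", "write_dataset"]

MODES = ("disc_cup", "lesion_border")

#: class-conditional geometry: baseline mean and within-class SD of the
#: class-separating parameter (cup/disc radius ratio, border roughness)
_CUP_RATIO_MEAN, _CUP_RATIO_SD = 0.40, 0.06
_ROUGHNESS_MEAN, _ROUGHNESS_SD = 0.04, 0.015

#: every pattern is shifted to this mean brightness before tinting so that
#: average intensity carries no class information
_TARGET_MEAN = 0.45

#: fundus-like channel weighting (red-dominant), jittered per image
_BASE_TINT = np.array([1.0, 0.75, 0.55])
_TINT_JITTER_SD = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic dataset.

    Attributes
    ----------
    effect_size
        Separation of the class-conditional parameter distributions in
        pooled-SD units; 0 makes the classes indistinguishable.
    noise_sd
        SD of additive Gaussian pixel noise (intensities are clipped to
        [0, 1] afterwards).
    class_balance
        Fraction of positive-class images; total size is
        ``2 * n_per_class``.
    """

    mode: str = "disc_cup"
    n_per_class: int = 200
    image_size: tuple[int, int] = (256, 256)
    effect_size: float = 3.0
    noise_sd: float = 0.05
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


def generate(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a labeled RGB image set.

    Returns
    -------
    images : (N, H, W, 3) float array in [0, 1]
    labels : (N,) int array in {0, 1}
    manifest : DataFrame with one row per image recording the label and
        every generating parameter.
    """
    rng = np.random.default_rng(config.seed)
    total = 2 * config.n_per_class
    n_pos = int(round(total * config.class_balance))
    labels = np.array([0] * (total - n_pos) + [1] * n_pos)
    rng.shuffle(labels)

    h, w = config.image_size
    images = np.empty((total, h, w, 3))
    records = []
    for i, label in enumerate(labels):
        gray, params = _render_pattern(config, int(label), rng)
        # brightness equalization: geometry only, no mean-intensity leakage
        gray = gray + (_TARGET_MEAN - gray.mean())
        tint = _BASE_TINT * (1.0 + rng.normal(0.0, _TINT_JITTER_SD, size=3))
        rgb = gray[..., None] * tint[None, None, :]
        rgb += rng.normal(0.0, config.noise_sd, size=rgb.shape)
        np.clip(rgb, 0.0, 1.0, out=rgb)
        images[i] = rgb
        params.update({"index": i, "label": int(label), **{f"tint_{c}": t for c, t in zip("rgb", tint)}})
        records.append(params)
    manifest = pd.DataFrame.from_records(records).set_index("index")
    return images, labels, manifest


def _render_pattern(config: SyntheticConfig, label: int, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    h, w = config.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # class-independent placement and size
    cy = h / 2 + rng.normal(0.0, 0.03 * h)
    cx = w / 2 + rng.normal(0.0, 0.03 * w)
    radius = min(h, w) * np.clip(rng.normal(0.30, 0.02), 0.22, 0.38)
    dist = np.hypot(yy - cy, xx - cx)

    if config.mode == "disc_cup":
        shift = config.effect_size * _CUP_RATIO_SD * label
        ratio = float(np.clip(rng.normal(_CUP_RATIO_MEAN + shift, _CUP_RATIO_SD), 0.05, 0.95))
        background, disc, cup = 0.20, 0.65, 0.90
        gray = np.full((h, w), background)
        gray[dist <= radius] = disc
        gray[dist <= ratio * radius] = cup
        params = {"mode": config.mode, "radius": radius, "cup_ratio": ratio,
                  "center_y": cy, "center_x": cx}
    else:  # lesion_border
        shift = config.effect_size * _ROUGHNESS_SD * label
        roughness = float(np.clip(rng.normal(_ROUGHNESS_MEAN + shift, _ROUGHNESS_SD), 0.0, 0.35))
        harmonics = np.arange(3, 9)
        amps = rng.normal(0.0, 1.0, size=harmonics.size)
        amps *= roughness / max(np.linalg.norm(amps), 1e-12)
        phases = rng.uniform(0.0, 2 * np.pi, size=harmonics.size)
        theta = np.arctan2(yy - cy, xx - cx)
        boundary = radius * (
            1.0 + (amps[:, None, None] * np.cos(harmonics[:, None, None] * theta[None] + phases[:, None, None])).sum(axis=0)
        )
        background, lesion = 0.75, 0.30
        gray = np.where(dist <= boundary, lesion, background)
        params = {"mode": config.mode, "radius": radius, "roughness": roughness,
                  "center_y": cy, "center_x": cx}
    return gray, params


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Render the dataset to PNG files plus a CSV manifest.

    The manifest (``manifest.csv``) lists filename, label, and generating
    parameters per image, and is directly loadable by :mod:`mcnn.dataset_io`.
    Returns the manifest path.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, labels, manifest = generate(config)
    filenames = []
    for i, img in enumerate(images):
        name = f"img_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / name)
        filenames.append(name)
    manifest = manifest.copy()
    manifest.insert(0, "filename", filenames)
    for key, value in asdict(config).items():
        manifest[f"config_{key}"] = str(value)
    path = out_dir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
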