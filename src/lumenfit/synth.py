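"""Synthetic cross-section dataset generator.

Emulates 15x15-pixel sections of a bright, smoothly bounded lumen on a darker
background, blurred by the scanner PSF.  Per-example parameters are drawn as:

* background ``a ~ U[0, 0.2]``, lumen step ``b ~ U[0.2, 0.3]``;
* shape vector ``d``: i.i.d. ``U[0, 1]`` per element, treated as a circular
  sequence and smoothed with the 3-tap lowpass kernel ``[0.15, 0.7, 0.15]``
  (introduces the inter-element correlation real contours exhibit); then,
  with probability 0.25, one uniformly chosen element is replaced by a draw
  from ``U[-0.2, 0.1]`` to produce concave, near-center boundaries.

The noisy dataset variant adds a zero-mean random fractal-like texture patch
(power-law radial spectrum) to each rendered image, emulating the smooth
spatial intensity variations of real angiographic backgrounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import CrossSectionImage, ImageFormationParams, render
from .geometry import ContourSpline

__all__ = [
    "DatasetConfig",
    "NoiseConfig",
    "SyntheticExample",
    "SyntheticDataset",
    "draw_parameters",
    "fractal_texture",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Fractal-texture noise: power spectrum ``P(f) ~ f**(-beta)``, given std."""

    beta: float = 2.5
    std: float = 0.03


@dataclass(frozen=True)
class DatasetConfig:
    n_images: int = 10_000
    D: int = 10
    N: int = 7
    delta_s: float = 1.0
    R: float = 11.0
    w_over_delta_s: float = 0.65
    a_range: tuple[float, float] = (0.0, 0.2)
    b_range: tuple[float, float] = (0.2, 0.3)
    d_range: tuple[float, float] = (0.0, 1.0)
    smoothing_kernel: tuple[float, float, float] = (0.15, 0.7, 0.15)
    negative_range: tuple[float, float] = (-0.2, 0.1)
    negative_prob: float = 0.25
    test_fraction: float = 0.10
    val_fraction: float = 0.20
    noisy: bool = False
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    supersample: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.smoothing_kernel) - 1.0) > 1e-12:
            raise ValueError("smoothing kernel must sum to 1")
        for frac in (self.test_fraction, self.val_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")

    @property
    def w(self) -> float:
        return self.w_over_delta_s * self.delta_s


@dataclass
class SyntheticExample:
    image: CrossSectionImage
    target_d: np.ndarray
    a: float
    b: float
    noisy: bool
    seed: int


@dataclass
class SyntheticDataset:
    """In-memory dataset: images ``(n, side, side)``, targets and split labels."""

    images: np.ndarray
    a: np.ndarray
    b: np.ndarray
    d: np.ndarray  # (n, D)
    split: np.ndarray  # array of {"train","val","test"}
    config: DatasetConfig

    def __len__(self) -> int:
        return self.images.shape[0]

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.split == part)

    def subset(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices(part)
        return self.images[idx], self.d[idx]

    def example(self, i: int) -> SyntheticExample:
        return SyntheticExample(
            image=CrossSectionImage(self.images[i].astype(float), self.config.delta_s),
            target_d=self.d[i].copy(),
            a=float(self.a[i]),
            b=float(self.b[i]),
            noisy=self.config.noisy,
            seed=self.config.seed,
        )


def draw_parameters(rng: np.random.Generator, config: DatasetConfig) -> tuple[float, float, np.ndarray]:
    """Draw one (a, b, d) parameter set from the generator's distributions."""
    a = rng.uniform(*config.a_range)
    b = rng.uniform(*config.b_range)
    d = rng.uniform(*config.d_range, size=config.D)
    k = np.asarray(config.smoothing_kernel, dtype=float)
    d = k[1] * d + k[0] * np.roll(d, 1) + k[2] * np.roll(d, -1)
    if rng.uniform() < config.negative_prob:
        idx = rng.integers(config.D)
        d[idx] = rng.uniform(*config.negative_range)
    return float(a), float(b), d


def fractal_texture(shape: tuple[int, int], rng: np.random.Generator,
                    noise: NoiseConfig = NoiseConfig()) -> np.ndarray:
    """Zero-mean random texture with isotropic power-law spectrum ``f**(-beta)``.

    Synthesized spectrally: unit-variance white noise is shaped in the
    frequency domain by ``f**(-beta/2)`` amplitude and transformed back; the
    patch is then centered and rescaled to the configured standard deviation.
    """
    ny, nx = shape
    white = rng.standard_normal(shape)
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill the DC term -> zero mean by construction
    spectrum *= f ** (-noise.beta / 2.0)
    patch = np.real(np.fft.ifft2(spectrum))
    patch -= patch.mean()
    sd = patch.std()
    if sd > 0:
        patch *= noise.std / sd
    return patch


def _assign_split(n: int, test_fraction: float, val_fraction: float) -> np.ndarray:
    """Carve the test split off the end, then validation off the remainder's end."""
    n_test = int(round(n * test_fraction))
    n_val = int(round((n - n_test) * val_fraction))
    split = np.full(n, "train", dtype="<U5")
    split[n - n_test:] = "test"
    split[n - n_test - n_val: n - n_test] = "val"
    return split


def generate_dataset(config: DatasetConfig) -> SyntheticDataset:
    """Render ``config.n_images`` synthetic examples, deterministic per seed.

    Noise (when enabled) is added after rendering, so the noisy and noiseless
    variants built from the same seed share identical target parameters.
    """
    rng = np.random.default_rng(config.seed)
    side = 2 * config.N + 1
    images = np.empty((config.n_images, side, side), dtype=np.float32)
    a_all = np.empty(config.n_images)
    b_all = np.empty(config.n_images)
    d_all = np.empty((config.n_images, config.D))
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for i in range(config.n_images):
        a, b, d = draw_parameters(rng, config)
        spline = ContourSpline(d=d, R=config.R, delta_s=config.delta_s)
        params = ImageFormationParams(
            spline=spline, a=a, b=b, w=config.w, delta_s=config.delta_s, N=config.N
        )
        img = render(params, config.supersample).intensities
        if config.noisy:
            img = img + fractal_texture((side, side), noise_rng, config.noise)
        images[i] = img
        a_all[i], b_all[i], d_all[i] = a, b, d
    split = _assign_split(config.n_images, config.test_fraction, config.val_fraction)
    return SyntheticDataset(images, a_all, b_all, d_all, split, config)


# --- archive I/O ----------------------------------------------------------

def _config_to_json(config: DatasetConfig) -> dict:
    obj = asdict(config)
    obj["noise"] = asdict(config.noise)
    return obj


def _config_from_json(obj: dict) -> DatasetConfig:
    obj = dict(obj)
    noise = NoiseConfig(**obj.pop("noise"))
    for key in ("a_range", "b_range", "d_range", "negative_range", "smoothing_kernel"):
        obj[key] = tuple(obj[key])
    return DatasetConfig(noise=noise, **obj)


def save_dataset(directory, dataset: SyntheticDataset) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "images.npz", images=dataset.images,
             delta_s=dataset.config.delta_s, N=dataset.config.N)
    cols = {"a": dataset.a, "b": dataset.b}
    cols.update({f"d{j}": dataset.d[:, j] for j in range(dataset.d.shape[1])})
    pd.DataFrame(cols).to_csv(directory / "targets.csv", index_label="id")
    pd.DataFrame({"split": dataset.split}).to_csv(directory / "split.csv", index_label="id")
    with open(directory / "config.json", "w") as fh:
        json.dump(_config_to_json(dataset.config), fh, indent=1)
    return directory


def load_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    with open(directory / "config.json") as fh:
        config = _config_from_json(json.load(fh))
    with np.load(directory / "images.npz") as data:
        images = data["images"]
    targets = pd.read_csv(directory / "targets.csv", index_col="id")
    split = pd.read_csv(directory / "split.csv", index_col="id")["split"].to_numpy()
    d_cols = [c for c in targets.columns if c.startswith("d")]
    return SyntheticDataset(
        images=images,
        a=targets["a"].to_numpy(),
        b=targets["b"].to_numpy(),
        d=targets[d_cols].to_numpy(),
        split=split,
        config=config,
    )
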