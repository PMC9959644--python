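"""Synthetic drying-experiment generator.

Real drying data for this problem come from a camera above a microwave oven
and are not redistributable, so every stage of the package is exercised on
generated fixtures instead.  The generator emulates the statistical
structure the model assumes:

* a monotone shrinkage trajectory ``S(k) = 1 - (1 - s_min) * (k/kmax)**beta``
  running from just below 1 down to ``s_min``;
* moisture ratios ``MR(k) = mu(S(k)) + w(k)`` where ``mu`` is a ground-truth
  polynomial and ``w`` is unclipped white Gaussian noise of standard
  deviation ``sigma``;
* matching image stacks: a bright disk of radius ``r0 * sqrt(S(k))`` on a
  dark background (so the true area ratio equals ``S(k)``), decorated with
  small bright specks and interior holes to exercise the mask-cleaning
  steps.

The default ground truth is a cubic with coefficients
``(-4.0180, 12.5609, -11.1670, 3.5632)``, a realistic fit for cantaloupe
slices; it is only physically sensible (MR in roughly [0, 1]) for shrinkage
above ~0.55, hence the default ``s_min = 0.55``.  The default noise level
``sigma = 0.02`` matches the residual scale of good experimental fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DryingDataset, write_dataset
from .model import PolynomialModel, predict

__all__ = [
    "DEFAULT_TRUE_GAMMA",
    "GeneratorConfig",
    "generate_shrinkage_trajectory",
    "generate_dataset",
    "generate_image_stack",
    "write_fixture_bundle",
]

DEFAULT_TRUE_GAMMA = (-4.0180, 12.5609, -11.1670, 3.5632)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic drying experiment.

    ``beta`` shapes the shrinkage trajectory (1 = linear in k, >1 = slow
    early shrinkage).  Image options control the raster fixtures:
    ``disk_radius`` is the initial slice radius in pixels, ``speck_count``
    bright noise blobs and ``hole_count`` interior holes are added per frame.
    """

    true_gamma: tuple = DEFAULT_TRUE_GAMMA
    kmax: int = 100
    s_min: float = 0.55
    beta: float = 1.0
    sigma: float = 0.02
    seed: int = 0
    image_size: int = 256
    disk_radius: float = 100.0
    speck_count: int = 6
    hole_count: int = 2
    image_noise_sigma: float = 5.0
    frame_count: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.s_min < 1.0:
            raise ValueError("s_min must lie in (0, 1)")
        if self.kmax < len(self.true_gamma) + 1:
            raise ValueError("kmax must exceed the number of coefficients")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def order(self) -> int:
        return len(self.true_gamma) - 1

    @property
    def true_model(self) -> PolynomialModel:
        return PolynomialModel(order=self.order, gamma=np.asarray(self.true_gamma))


def generate_shrinkage_trajectory(config: GeneratorConfig) -> np.ndarray:
    """Strictly decreasing shrinkage series ending exactly at ``s_min``."""
    k = np.arange(1, config.kmax + 1)
    return 1.0 - (1.0 - config.s_min) * (k / config.kmax) ** config.beta


def generate_dataset(config: GeneratorConfig) -> tuple[DryingDataset, dict]:
    """Draw one noisy dataset plus a truth sidecar.

    The sidecar records the ground-truth coefficients and the realized noise
    vector so recovery tests can separate estimation error from noise; it is
    returned (and written) separately from the dataset so estimation code
    cannot accidentally consume it.
    """
    rng = np.random.default_rng(config.seed)
    s = generate_shrinkage_trajectory(config)
    clean = predict(config.true_model, s)
    noise = config.sigma * rng.standard_normal(config.kmax)
    dataset = DryingDataset(
        shrinkage=s,
        moisture_ratio=clean + noise,
        time_min=0.5 * np.arange(config.kmax, dtype=float),
    )
    truth = {
        "true_gamma": list(config.true_gamma),
        "order": config.order,
        "sigma": config.sigma,
        "seed": config.seed,
        "noise": noise.tolist(),
    }
    return dataset, truth


def _rasterize_frame(size, center, radius, rng, speck_count, hole_count, noise_sigma):
    from skimage.draw import disk

    frame = np.full((size, size), 30.0)
    rr, cc = disk(center, radius, shape=frame.shape)
    frame[rr, cc] = 220.0
    # interior holes: dark blobs well inside the slice
    for _ in range(hole_count):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.5 * radius)
        hr, hc = disk(
            (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang)),
            rng.uniform(2.0, 4.0),
            shape=frame.shape,
        )
        frame[hr, hc] = 30.0
    # specks: small bright blobs scattered outside the slice
    placed = 0
    while placed < speck_count:
        y, x = rng.uniform(0, size, 2)
        if np.hypot(y - center[0], x - center[1]) < radius + 8:
            continue
        sr, sc = disk((y, x), rng.uniform(1.5, 3.0), shape=frame.shape)
        frame[sr, sc] = 220.0
        placed += 1
    if noise_sigma > 0:
        frame += rng.normal(0.0, noise_sigma, frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def generate_image_stack(config: GeneratorConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Rasterize a shrinking-disk frame series with a known area schedule.

    Frame ``k`` shows a disk of radius ``r0 * sqrt(S(k))`` so the commanded
    area ratio equals ``S(k)``; returns the frames and the commanded series.
    When ``frame_count`` is set, the trajectory is subsampled evenly so image
    stacks stay small while the tabular data keep full resolution.
    """
    s_full = generate_shrinkage_trajectory(config)
    if config.frame_count is not None and config.frame_count < config.kmax:
        idx = np.unique(np.linspace(0, config.kmax - 1, config.frame_count).round().astype(int))
    else:
        idx = np.arange(config.kmax)
    s = s_full[idx]
    radii = config.disk_radius * np.sqrt(s)
    if radii.min() < 10:
        raise ValueError(
            f"final disk radius {radii.min():.1f} px < 10 px; enlarge disk_radius"
        )
    if 2 * config.disk_radius + 10 > config.image_size:
        raise ValueError("raster too small for the initial disk")
    rng = np.random.default_rng(config.seed)
    center = (config.image_size / 2.0, config.image_size / 2.0)
    frames = [
        _rasterize_frame(
            config.image_size,
            center,
            r,
            rng,
            config.speck_count,
            config.hole_count,
            config.image_noise_sigma,
        )
        for r in radii
    ]
    return frames, s


def write_fixture_bundle(config: GeneratorConfig, directory, images: bool = True) -> dict:
    """Write a complete fixture bundle and return its manifest.

    Layout: ``data.csv`` (tabular dataset), ``truth.json`` (ground truth and
    realized noise, kept apart from the data), ``frames/frame_NNN.png`` plus
    ``manifest.csv`` (``k,filename``) when ``images`` is on, and
    ``bundle.json`` echoing the full configuration (including the seed, so
    the bundle can be regenerated identically).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(config)
    write_dataset(dataset, directory / "data.csv")
    (directory / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    manifest = {"config": asdict(config), "kmax": config.kmax, "files": ["data.csv", "truth.json"]}
    if images:
        import imageio.v3 as iio

        frames, commanded = generate_image_stack(config)
        frame_dir = directory / "frames"
        frame_dir.mkdir(exist_ok=True)
        rows = []
        for i, frame in enumerate(frames, start=1):
            name = f"frame_{i:03d}.png"
            iio.imwrite(frame_dir / name, frame)
            rows.append({"k": i, "filename": f"frames/{name}", "commanded_shrinkage": commanded[i - 1]})
        pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False, float_format="%.9g")
        manifest["files"] += ["manifest.csv", "frames/"]
        manifest["frame_count"] = len(frames)
    (directory / "bundle.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
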