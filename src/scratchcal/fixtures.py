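"""Synthetic experiments, toy images, and config / image I/O.

The generators here stand in for the two kinds of data the calibration
machinery consumes: an *in silico* experiment (one simulated realization,
rendered to images and read back through the edge pipeline, with the
generating parameters recorded for recovery tests) and an *in-vitro-like*
displacement series mimicking the shape of a real 3T3 scratch assay —
six imaging times (0, 3, 6, 9, 12, 24 h), four replicate positions, and
per-time sample standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .edges import EdgeConfig, ImageGray, front_series, occupancy_to_image
from .lattice import ModelParams, Occupancy, simulate
from .series import FrontSeries, average_series

__all__ = [
    "ExperimentFixture",
    "make_in_silico_experiment",
    "make_in_vitro_like_series",
    "make_toy_edge_image",
    "load_image",
    "save_image",
    "load_model_config",
    "save_model_config",
    "IN_VITRO_TIMES_H",
]

log = logging.getLogger(__name__)

# imaging schedule of the 3T3 scratch assay this package targets
IN_VITRO_TIMES_H = (0.0, 3.0, 6.0, 9.0, 12.0, 24.0)
IN_VITRO_REPLICATES = 4
# generating parameters of the in-vitro-like fixture: the typical 3T3
# estimates (D ~ 300 um^2/h, lam ~ 0.03 /h at delta=25 um, tau=0.09191 h)
IN_VITRO_LIKE_PM = 0.17
IN_VITRO_LIKE_PP = 2.7e-3
# field of view of one replicate position is ~2 mm wide
IN_VITRO_FOV_UM = 2000.0


def in_silico_sample_times(
    p: ModelParams,
    early_every: int = 5,
    late_every: int = 20,
    t_switch_h: float = 4.5,
) -> np.ndarray:
    """Observation schedule for an in silico experiment (hours).

    Dense sampling (every ``early_every``-th step, ~0.46 h) through the
    motility-dominated early window, sparser sampling (every
    ``late_every``-th step, ~1.8 h) afterwards; always includes t = 0.
    """
    steps = sorted(
        {0}
        | {s for s in range(early_every, p.n_steps + 1, early_every) if s * p.tau <= t_switch_h}
        | {s for s in range(late_every, p.n_steps + 1, late_every) if s * p.tau > t_switch_h}
    )
    return np.array(steps, dtype=float) * p.tau


@dataclass
class ExperimentFixture:
    """One synthetic experiment with its generating truth recorded."""

    truth: ModelParams
    series: FrontSeries
    images: list[tuple[float, ImageGray]]
    seed: int


def make_in_silico_experiment(
    truth: ModelParams,
    sample_times: np.ndarray,
    seed: int,
    cfg: EdgeConfig | None = None,
) -> ExperimentFixture:
    """One realization at ``truth``, observed through the edge pipeline.

    The displacement series is extracted from rendered snapshot images, not
    from the occupancy matrix, so the fixture carries the same edge-pipeline
    quantization a real image stack would.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    p = replace(truth, seed=seed)
    snaps = simulate(p, sample_times)
    images = [(t, occupancy_to_image(s)) for t, s in zip(sample_times, snaps)]
    series = front_series(images, cfg)
    return ExperimentFixture(truth=p, series=series, images=images, seed=seed)


def make_in_vitro_like_series(
    seed: int,
    cfg: EdgeConfig | None = None,
    template: ModelParams | None = None,
) -> FrontSeries:
    """Synthetic stand-in for a real 3T3 scratch-assay leading-edge dataset.

    One full-width realization at (Pm, Pp) = (0.17, 2.7e-3) is imaged at
    t = 0, 3, 6, 9, 12 and 24 h through four 2 mm fields of view evenly
    spaced along the scratch (away from the lateral walls), mirroring the
    protocol of photographing one well at four positions; each field is
    reduced through the edge pipeline independently, and the returned
    series carries the across-field mean displacement and sample s.d.
    """
    if template is None:
        template = ModelParams(pm=IN_VITRO_LIKE_PM, pp=IN_VITRO_LIKE_PP)
    p = replace(template, seed=int(np.random.SeedSequence([seed, 77]).generate_state(1)[0] % 2**31))
    times = np.array(IN_VITRO_TIMES_H)
    snaps = simulate(p, times)
    win = int(round(IN_VITRO_FOV_UM / p.delta))
    margin = max(1, int(round(0.1 * p.n_cols)))
    starts = np.linspace(margin, p.n_cols - margin - win, IN_VITRO_REPLICATES)
    fields = []
    for s0 in np.round(starts).astype(int):
        stack = [
            (t, occupancy_to_image(Occupancy(grid=s.grid[:, s0:s0 + win], delta=p.delta)))
            for t, s in zip(times, snaps)
        ]
        fields.append(front_series(stack, cfg))
    avg = average_series(fields)
    sd = np.std([f.y for f in fields], axis=0, ddof=1)
    return FrontSeries(times=avg.times, y=avg.ybar, sd=sd, label="in-vitro-like")


def make_toy_edge_image(
    front_profile: np.ndarray,
    width: int,
    pixel_size: float,
    noise: tuple[int, int] | None = None,
    height: int | None = None,
) -> tuple[ImageGray, float]:
    """Binary test image with a known column-wise front profile.

    ``front_profile[i]`` is the occupied height (px) of column ``i``;
    ``noise=(n, seed)`` sprinkles ``n`` isolated bright pixels ahead of the
    front.  Returns the image and the true enclosed area (µm²).
    """
    front_profile = np.asarray(front_profile, dtype=int)
    if len(front_profile) != width:
        raise ValueError("front profile length must equal the image width")
    h = height if height is not None else max(int(front_profile.max()) * 2, 20)
    px = np.zeros((h, width))
    for i, fh in enumerate(front_profile):
        px[:fh, i] = 1.0
    if noise is not None:
        n, nseed = noise
        rng = np.random.default_rng(nseed)
        for _ in range(n):
            i = int(rng.integers(width))
            j = int(rng.integers(front_profile[i] + 3, h - 2)) if front_profile[i] + 3 < h - 2 else h - 2
            px[j, i] = 1.0
    true_area = float(front_profile.sum()) * pixel_size**2
    return ImageGray(pixels=px, pixel_size=pixel_size, origin="low"), true_area


# --- image and config I/O -------------------------------------------------


def write_occupancy_csv(occ: Occupancy, path: str | Path) -> None:
    """Write a snapshot as a site list: ``x_um,y_um`` per occupied site."""
    import pandas as pd

    ys, xs = np.nonzero(occ.grid)
    pd.DataFrame({"x_um": xs * occ.delta, "y_um": ys * occ.delta}).to_csv(path, index=False)


def read_occupancy_csv(path: str | Path, delta: float, n_rows: int, n_cols: int) -> Occupancy:
    """Rebuild a snapshot from a site-list CSV on a lattice of known extent."""
    import pandas as pd

    df = pd.read_csv(path)
    grid = np.zeros((n_rows, n_cols), dtype=np.uint8)
    j = np.round(df["y_um"].to_numpy() / delta).astype(int)
    i = np.round(df["x_um"].to_numpy() / delta).astype(int)
    grid[j, i] = 1
    return Occupancy(grid=grid, delta=delta)


def load_image(path: str | Path, pixel_size: float, origin: str = "low") -> ImageGray:
    """Read PNG/TIFF/JPEG as grayscale in [0, 1] (RGB converted by luminance)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("F" if im.mode in ("F", "I") else "L"), dtype=float)
    if arr.max() > 1.0:
        arr = arr / 255.0 if arr.max() <= 255 else arr / arr.max()
    return ImageGray(pixels=np.clip(arr, 0.0, 1.0), pixel_size=pixel_size, origin=origin)


def save_image(img: ImageGray | Occupancy, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (occupancies are rendered first)."""
    if isinstance(img, Occupancy):
        img = occupancy_to_image(img)
    Image.fromarray((img.pixels * 255).astype(np.uint8)).save(path)


def load_model_config(path: str | Path) -> ModelParams:
    """Read a YAML/JSON config block (keys pm, pp, delta_um, tau_h, ...)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "model" in doc:
        doc = doc["model"]
    return ModelParams.from_dict(doc)


def save_model_config(p: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"model": p.to_dict()}, fh, sort_keys=False)
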