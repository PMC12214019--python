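"""Synthetic field-of-view image series for the spot-count exchange assay.

Each requested wall-clock time is rendered as a fresh field of view (the
assay images different surface areas to minimize photobleaching), with
the number of surviving labeled spots drawn from exponential survival
toward a residual non-exchanging fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FieldOfViewSeries", "synthesize_fov_series"]


@dataclass
class FieldOfViewSeries:
    """Time-stamped 2-D images plus the planted ground-truth positions."""

    times: np.ndarray
    images: list[np.ndarray]
    psf_sigma: float
    truth_positions: list[np.ndarray]  # (n, 2) arrays of (row, col)
    background: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("image dimensions must be constant across the series")

    def to_tiff(self, path) -> None:
        """Write the image series as a 16-bit TIFF stack."""
        import tifffile

        tifffile.imwrite(path, np.stack(self.images).astype(np.uint16))

    def truth_positions_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "time_s", "row", "col"])
            for i, (t, pos) in enumerate(zip(self.times, self.truth_positions)):
                for r, c in pos:
                    w.writerow([i, f"{t:.6g}", f"{r:.3f}", f"{c:.3f}"])


def _draw_positions(
    n: int, shape: tuple[int, int], min_separation: float, margin: float, rng
) -> np.ndarray:
    h, w = shape
    if (h - 2 * margin) * (w - 2 * margin) < 4.0 * n * min_separation**2:
        raise ValueError(
            f"image {shape} too small for {n} spots at min separation {min_separation}"
        )
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("could not place spots at requested min separation")
        p = rng.uniform([margin, margin], [h - margin, w - margin])
        if pts:
            d2 = ((np.array(pts) - p) ** 2).sum(axis=1)
            if (d2 < min_separation**2).any():
                continue
        pts.append(p)
    return np.array(pts).reshape(n, 2)


def _render(
    positions: np.ndarray,
    shape: tuple[int, int],
    psf_sigma: float,
    amplitude: float,
    background: float,
    read_noise_sd: float,
    shot_noise: bool,
    rng,
) -> np.ndarray:
    canvas = np.full(shape, float(background))
    r = max(int(np.ceil(4 * psf_sigma)), 2)
    ax = np.arange(-r, r + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    for row, col in positions:
        ir, ic = int(round(row)), int(round(col))
        dy, dx = row - ir, col - ic
        patch = amplitude * np.exp(
            -((yy - dy) ** 2 + (xx - dx) ** 2) / (2 * psf_sigma**2)
        )
        r0, r1 = max(ir - r, 0), min(ir + r + 1, shape[0])
        c0, c1 = max(ic - r, 0), min(ic + r + 1, shape[1])
        canvas[r0:r1, c0:c1] += patch[
            r0 - (ir - r) : patch.shape[0] - ((ir + r + 1) - r1),
            c0 - (ic - r) : patch.shape[1] - ((ic + r + 1) - c1),
        ]
    img = rng.poisson(canvas).astype(float) if shot_noise else canvas.copy()
    if read_noise_sd > 0:
        img += rng.normal(0.0, read_noise_sd, shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def synthesize_fov_series(
    n_initial_spots: int,
    k_exchange: float,
    residual_fraction: float,
    image_shape: tuple[int, int],
    times,
    seed,
    *,
    psf_sigma: float = 1.3,
    amplitude: float = 2500.0,
    background: float = 100.0,
    read_noise_sd: float = 5.0,
    shot_noise: bool = True,
    min_separation: float = 8.0,
) -> FieldOfViewSeries:
    """Render spot-count decay images: survival = res + (1-res)exp(-k t).

    Each time point is an independent field of view whose surviving-spot
    count is Binomial(n_initial, survival(t)); surviving spots are
    rendered as 2-D Gaussian PSFs at uniformly random positions with a
    minimum separation, over shot and read noise.
    """
    if n_initial_spots < 0:
        raise ValueError("n_initial_spots must be >= 0")
    if not 0.0 <= residual_fraction <= 1.0:
        raise ValueError("residual_fraction must be in [0,1]")
    if k_exchange < 0:
        raise ValueError("k_exchange must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = np.asarray(times, dtype=float)
    margin = 4 * psf_sigma + 2
    images, truth = [], []
    for t in times:
        surv = residual_fraction + (1.0 - residual_fraction) * np.exp(-k_exchange * t)
        n_t = int(rng.binomial(n_initial_spots, surv)) if n_initial_spots else 0
        pos = _draw_positions(n_t, image_shape, min_separation, margin, rng)
        images.append(
            _render(pos, image_shape, psf_sigma, amplitude, background, read_noise_sd, shot_noise, rng)
        )
        truth.append(pos)
    return FieldOfViewSeries(
        times, images, psf_sigma, truth, background=background,
        meta={"n_initial": n_initial_spots, "k": k_exchange, "residual": residual_fraction},
    )
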