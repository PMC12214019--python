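"""Camera, excitation, and dye-photophysics models for trace synthesis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticsModel", "ExcitationPattern", "GREEN", "RED", "DARK"]

GREEN = "G"
RED = "R"
DARK = "dark"


@dataclass(frozen=True)
class OpticsModel:
    """Optical parameters of one donor-acceptor pair on the camera.

    total_intensity is the summed donor+acceptor expected signal per frame
    for a single live donor under green excitation; leakage is the
    fraction of the recorded donor channel that bleeds into the acceptor
    channel.  Photobleaching is exponential per dye.  The flow background
    step models the diffusive labeled-competitor background that appears
    after the flow starts.  The paper reports none of these camera-level
    numbers; the defaults are documented assumptions chosen to give
    realistically broad histogram peaks.
    """

    total_intensity: float = 1000.0
    leakage: float = 0.08
    read_noise_sd: float = 15.0
    shot_noise: bool = True
    bleach_rate_donor: float = 0.0
    bleach_rate_acceptor: float = 0.0
    background_green: float = 0.0
    background_red: float = 0.0
    flow_background_step: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.leakage < 0.5:
            raise ValueError("leakage must be in [0, 0.5)")
        if self.total_intensity < 0 or self.background_green < 0 or self.background_red < 0:
            raise ValueError("intensities must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bleach_rate_donor < 0 or self.bleach_rate_acceptor < 0:
            raise ValueError("bleach rates must be >= 0")


@dataclass(frozen=True)
class ExcitationPattern:
    """Frame timing and laser alternation.

    ``alex`` mode interleaves blocks of green frames, one dark frame, and
    red frames (default 10/1/10); red excitation reports direct acceptor
    signal used to exclude donor-only molecules.  ``continuous_green`` is
    used for real-time event traces.
    """

    mode: str = "alex"
    frame_time: float = 0.050
    alex_green: int = 10
    alex_dark: int = 1
    alex_red: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("continuous_green", "alex"):
            raise ValueError("mode must be 'continuous_green' or 'alex'")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.mode == "alex" and min(self.alex_green, self.alex_red) < 1:
            raise ValueError("alex blocks need >= 1 green and red frame")

    @property
    def block_length(self) -> int:
        return self.alex_green + self.alex_dark + self.alex_red

    def labels(self, n_frames: int) -> np.ndarray:
        """Per-frame excitation labels for ``n_frames`` frames."""
        if self.mode == "continuous_green":
            return np.full(n_frames, GREEN, dtype=object)
        block = np.array(
            [GREEN] * self.alex_green + [DARK] * self.alex_dark + [RED] * self.alex_red,
            dtype=object,
        )
        reps = int(np.ceil(n_frames / block.size))
        return np.tile(block, reps)[:n_frames]
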