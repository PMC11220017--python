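"""Seeded synthetic photon-emission stacks with known ground truth.

The study's raw recordings are not public, so every metric and pipeline
stage is exercised on generated stacks whose statistics are known exactly.
The photon model is minimal and matches a single-photon-sensitive cooled
sensor: each pixel of each frame is an independent Poisson draw whose rate
is a dark (sensor) rate plus the local contribution of localized emission
sources; an optional multiscale texture field adds spatially structured
rate variation.  Temporal profiles emulate the biological scenarios:
sustained emission ("live"), emission collapsing to the noise floor after a
changepoint ("degenerate"), or none ("background").

Defaults are desk-scale study conditions: 60 frames of 60 s integration,
64x64 pixels in a 16-bit container, dark mean 3 counts/frame/pixel, one
Gaussian-profile source of peak 30 counts/frame/pixel and radius 8 centred
in the embryo window.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import FrameStack, RegionOfInterest

TEMPORAL_PROFILES = ("constant", "live", "degenerate")
TEXTURES = ("none", "multiscale")

#: Fraction of clipped pixels above which generation warns.
CLIP_WARN_FRACTION = 0.01


@dataclasses.dataclass
class ScenarioConfig:
    """Full description of one synthetic acquisition.

    ``sources`` is a sequence of ``(row, col, radius)`` emission centres;
    each contributes a Gaussian intensity profile of peak ``source_rate``
    (mean photons/frame/pixel) and scale ``radius / 2``.  ``dark_mean`` is
    the sensor's dark rate in counts/frame/pixel.  ``temporal_profile``
    selects sustained emission (``constant``/``live``) or collapse to the
    noise floor after frame ``t_star`` with an exponential decay of
    ``decay_frames`` frames (``degenerate``).  The seed fixes the stack
    bit-exactly; per-frame child seeds are derived by counter so frames are
    reproducible independent of generation order.
    """

    shape: tuple[int, int, int] = (60, 64, 64)
    container_bits: int = 16
    seed: int = 0
    dark_mean: float = 3.0
    sources: Sequence[tuple[float, float, float]] = ((34.0, 34.0, 8.0),)
    source_rate: float = 30.0
    temporal_profile: str = "constant"
    t_star: int = 30
    decay_frames: float = 3.0
    texture: str = "none"
    texture_amplitude: float = 0.3
    frame_interval: float = 60.0

    def __post_init__(self) -> None:
        T, H, W = self.shape
        if min(T, H, W) < 1:
            raise ValidationError(f"shape dimensions must be >= 1, got {self.shape}")
        if self.dark_mean < 0 or self.source_rate < 0:
            raise ValidationError("rates must be non-negative")
        if self.temporal_profile not in TEMPORAL_PROFILES:
            raise ValidationError(
                f"temporal_profile must be one of {TEMPORAL_PROFILES}, "
                f"got {self.temporal_profile!r}"
            )
        if self.texture not in TEXTURES:
            raise ValidationError(f"texture must be one of {TEXTURES}")
        if self.temporal_profile == "degenerate" and not 0 <= self.t_star < T:
            raise ValidationError(f"t_star must lie in [0, T={T}), got {self.t_star}")


def scenario_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Preset configurations for the three study scenarios.

    ``background`` has no sources (sensor dark counts only), ``live`` has a
    sustained source, ``degenerate`` the same source collapsing at the
    default changepoint.
    """
    presets = {
        "background": dict(sources=(), temporal_profile="constant"),
        "live": dict(temporal_profile="live"),
        "degenerate": dict(temporal_profile="degenerate"),
    }
    if name not in presets:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {sorted(presets)}"
        )
    return ScenarioConfig(seed=seed, **{**presets[name], **overrides})


def default_rois() -> list[RegionOfInterest]:
    """Background and embryo sampling windows matching the default scenario.

    Two disjoint 21x21 windows: background in the dark corner, embryo
    centred on the default source position.
    """
    return [
        RegionOfInterest(0, 0, role="background", name="background"),
        RegionOfInterest(24, 24, role="embryo", name="embryo"),
    ]


# ---------------------------------------------------------------------------
# rate fields
# ---------------------------------------------------------------------------

def source_rate_map(config: ScenarioConfig) -> np.ndarray:
    """Per-pixel mean source contribution (H, W), before temporal scaling."""
    _, H, W = config.shape
    rate = np.zeros((H, W), dtype=np.float64)
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    for r0, c0, radius in config.sources:
        if radius <= 0:
            raise ValidationError("source radius must be positive")
        sigma = radius / 2.0
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        rate += config.source_rate * np.exp(-d2 / (2.0 * sigma**2))
    return rate


def _texture_field(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Octave-mixed multiplicative field in [1-a, 1+a], drawn once per stack."""
    _, H, W = config.shape
    field = np.zeros((H, W))
    octaves, weight = 0, 1.0
    size = max(H, W)
    while (1 << octaves) < size:
        step = 1 << octaves
        coarse = rng.uniform(-1.0, 1.0, ((H + step - 1) // step, (W + step - 1) // step))
        field += weight * np.repeat(np.repeat(coarse, step, 0), step, 1)[:H, :W]
        weight *= 0.5
        octaves += 1
    peak = np.abs(field).max()
    if peak > 0:
        field /= peak
    return 1.0 + config.texture_amplitude * field


def temporal_factor(config: ScenarioConfig, t: int) -> float:
    """Source intensity multiplier at frame ``t`` for the configured profile."""
    if config.temporal_profile in ("constant", "live"):
        return 1.0
    if t < config.t_star:
        return 1.0
    return float(np.exp(-(t - config.t_star) / config.decay_frames))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_stack(config: ScenarioConfig) -> FrameStack:
    """Draw a full stack: ``pixel[t, p] ~ Poisson(dark + source(t, p))``.

    Values are clipped to the container range; if more than 1% of pixels
    clip, a warning is raised and recorded in the stack's ``meta``.
    Deterministic: the same config (seed included) yields a bit-identical
    stack.
    """
    T, H, W = config.shape
    root = np.random.SeedSequence(config.seed)
    frame_seeds = root.spawn(T + 1)
    base = source_rate_map(config)
    if config.texture == "multiscale":
        base = base * _texture_field(config, np.random.default_rng(frame_seeds[T]))
    vmax = (1 << config.container_bits) - 1
    frames = np.empty((T, H, W), dtype=np.int64)
    clipped = 0
    for t in range(T):
        lam = config.dark_mean + temporal_factor(config, t) * base
        raw = np.random.default_rng(frame_seeds[t]).poisson(lam)
        clipped += int((raw > vmax).sum())
        frames[t] = np.minimum(raw, vmax)
    frac = clipped / frames.size
    meta = {"scenario": config.temporal_profile, "clipped_fraction": frac}
    if frac > CLIP_WARN_FRACTION:
        warnings.warn(
            f"{frac:.1%} of pixels clipped at the {config.container_bits}-bit "
            "container ceiling; rates are too high for this depth",
            stacklevel=2,
        )
    return FrameStack(
        frames,
        container_bits=config.container_bits,
        frame_interval=config.frame_interval,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# frames with analytically known box counts
# ---------------------------------------------------------------------------

def generate_structured_frame(
    S: int,
    occupancy: float,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Single-band frame whose level-``j`` occupied-box count is
    ``ceil(occupancy * 2**j)`` for every ``j = 1 .. S-1`` by construction.

    Built top-down through the prefix tree of box addresses: the set of
    level-``j`` prefixes is grown so each coarser box keeps at least one
    child, which pins every box count exactly and makes the
    different-spectral-resolution SFD equal to the closed form
    ``sum_j log(ceil(q * 2**j)) / log(2**j) / (S - 1)``.
    """
    if not 0.0 < occupancy <= 1.0:
        raise ValidationError(f"occupancy must lie in (0, 1], got {occupancy}")
    if S < 2:
        raise ValidationError(f"depth S must be >= 2, got {S}")
    targets = [int(np.ceil(occupancy * (1 << j))) for j in range(1, S)]
    prefixes = [0]
    for j, m in zip(range(1, S), targets):
        # each prefix keeps its left child; the first m - len extras add a right child
        extra = m - len(prefixes)
        if not 0 <= extra <= len(prefixes):
            raise ValidationError(
                f"occupancy {occupancy} is not realisable at level {j}"
            )
        prefixes = sorted(
            [p << 1 for p in prefixes] + [(p << 1) | 1 for p in prefixes[:extra]]
        )
    values = np.array([p << 1 for p in prefixes], dtype=np.int64)  # S-bit values
    if shape is None:
        side = 1 << ((S - 1 + 1) // 2)
        shape = (side, side)
    npix = shape[0] * shape[1]
    if npix < values.size:
        raise ValidationError(
            f"{shape} frame has {npix} pixels but {values.size} distinct "
            "values are needed for this occupancy"
        )
    flat = np.full(npix, values[0], dtype=np.int64)
    flat[: values.size] = values
    return flat.reshape(shape)


def structured_frame_sfd_dsr(S: int, occupancy: float) -> float:
    """Closed-form DSR SFD of ``generate_structured_frame(S, occupancy)``."""
    terms = [
        np.log(np.ceil(occupancy * (1 << j))) / np.log(float(1 << j))
        for j in range(1, S)
    ]
    return float(np.sum(terms) / (S - 1))
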