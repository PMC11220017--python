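"""Shannon entropy, spectral fractal dimensions and their entropy weighting.

The metrics here act on *spectral* space: each pixel of an ``n``-band frame
is a point in the n-dimensional cube of possible band values, and that cube
is partitioned into "spectral boxes".  At spectral resolution level ``j``
(``1 <= j <= S-1`` for an analysis depth of ``S`` bits) the cube is cut into
``(2**j)**n`` boxes; a pixel falls in the box addressed by the top ``j`` bits
of each of its band values.  Counting occupied boxes across levels gives a
box-counting dimension over spectral space:

* ``SFD_ESR`` (equal spectral resolution) normalises every level by the
  constant ``log((2**S)**n)``;
* ``SFD_DSR`` (different spectral resolution) normalises level ``j`` by the
  level's own grid size ``log((2**j)**n)``;
* ``EW-SFD`` multiplies each level's occupied-box count ``SBM_j`` by an
  entropy weight ``f_j = H_j / (j * n) in [0, 1]``, where ``H_j`` is the
  Shannon entropy of the level-``j`` quantised value histogram, so that a
  level whose occupancy carries little information contributes little.

All metrics depend only on the histogram of pixel values, never on pixel
positions.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Union

import numpy as np

from .errors import ValidationError

BoxMode = Literal["esr", "dsr"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SpectralHistogram:
    """Occurrence counts of occupied level-``j`` spectral boxes.

    ``counts`` holds one positive count per occupied box (unoccupied boxes
    are not materialised); ``sum(counts) == total_pixels``.
    """

    level_bits: int
    counts: np.ndarray
    total_pixels: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.size and counts.min() <= 0:
            raise ValidationError("histogram counts must be positive")
        if int(counts.sum()) != self.total_pixels:
            raise ValidationError("histogram counts must sum to total_pixels")


@dataclasses.dataclass(frozen=True)
class BoxCountProfile:
    """Per-level spectral box census for one frame.

    Arrays are indexed by level ``j = 1 .. S-1`` (element 0 is level 1):
    ``sbm[j-1]`` occupied boxes, ``sbt_esr``/``sbt_dsr[j-1]`` possible boxes
    in the two normalisation modes, ``f[j-1]`` the entropy weight.
    """

    S: int
    n: int
    sbm: np.ndarray
    sbt_dsr: np.ndarray
    f: np.ndarray

    @property
    def sbt_esr(self) -> int:
        return (1 << self.S) ** self.n

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.S)


@dataclasses.dataclass(frozen=True)
class MetricResult:
    """Entropy and the three structure metrics for one frame/ROI."""

    entropy_bits: float
    sfd_esr: float
    sfd_dsr: float
    ew_sfd: float
    S: int
    n: int
    floored_levels: int = 0


# ---------------------------------------------------------------------------
# pixel plumbing
# ---------------------------------------------------------------------------

def _as_pixels(frame) -> np.ndarray:
    """Flatten an (H, W) or (H, W, n) frame to an (N, n) int64 array."""
    a = np.asarray(frame)
    if a.ndim == 2:
        a = a[..., None]
    if a.ndim != 3:
        raise ValidationError(
            f"frame must be (H, W) or (H, W, n), got shape {a.shape}"
        )
    if not np.issubdtype(a.dtype, np.integer):
        raise ValidationError(f"frame must hold integers, got dtype {a.dtype}")
    px = a.reshape(-1, a.shape[-1]).astype(np.int64)
    if px.size == 0:
        raise ValidationError("frame has no pixels")
    if px.min() < 0:
        raise ValidationError("pixel values must be non-negative")
    return px


def _check_depth(px: np.ndarray, S: int) -> None:
    if S < 1:
        raise ValidationError(f"analysis depth S must be >= 1, got {S}")
    if px.max() >= 1 << S:
        raise ValidationError(
            f"pixel value {int(px.max())} does not fit the {S}-bit analysis depth"
        )


def _box_codes(px: np.ndarray, S: int, j: int) -> np.ndarray:
    """Spectral box address of each pixel at level j (bands packed into one int)."""
    q = px >> (S - j)
    codes = q[:, 0].copy()
    for b in range(1, q.shape[1]):
        codes = (codes << j) | q[:, b]
    return codes


def quantize_to_level(frame, S: int, j: int) -> np.ndarray:
    """Keep the top ``j`` of ``S`` bits of every band value.

    Each value ``v`` maps to ``v // 2**(S - j)``, halving the spectral box
    edge per unit decrease in ``j``.
    """
    a = np.asarray(frame)
    px = _as_pixels(a if a.ndim >= 2 else a.reshape(1, -1))
    _check_depth(px, S)
    if not 1 <= j <= S:
        raise ValidationError(f"level j must satisfy 1 <= j <= S={S}, got {j}")
    return a >> (S - j)


# ---------------------------------------------------------------------------
# histograms and entropy
# ---------------------------------------------------------------------------

def spectral_histogram(frame, S: int, j: int) -> SpectralHistogram:
    """Histogram of occupied level-``j`` spectral boxes of a frame."""
    px = _as_pixels(frame)
    _check_depth(px, S)
    if not 1 <= j <= S:
        raise ValidationError(f"level j must satisfy 1 <= j <= S={S}, got {j}")
    _, counts = np.unique(_box_codes(px, S, j), return_counts=True)
    return SpectralHistogram(level_bits=j, counts=counts, total_pixels=px.shape[0])


def shannon_entropy(hist: Union[SpectralHistogram, np.ndarray]) -> float:
    """Information-theoretic entropy ``H = sum_i p_i * log2(1 / p_i)`` in bits.

    ``p_i`` is the relative frequency of symbol ``i``; zero-count symbols
    contribute nothing (``p * log2(1/p) -> 0`` as ``p -> 0``).  ``H`` is 0
    when a single symbol occurs and ``log2(m)`` when all ``m`` symbols are
    equally frequent.
    """
    counts = hist.counts if isinstance(hist, SpectralHistogram) else np.asarray(hist)
    counts = counts[counts > 0].astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("entropy of an empty histogram is undefined")
    p = counts / total
    return float(-(p * np.log2(p)).sum()) + 0.0  # normalise -0.0 to 0.0


# ---------------------------------------------------------------------------
# box counting
# ---------------------------------------------------------------------------

def count_spectral_boxes(frame, S: int, j: int) -> int:
    """Number of level-``j`` spectral boxes holding at least one pixel."""
    px = _as_pixels(frame)
    _check_depth(px, S)
    if not 1 <= j <= S - 1:
        raise ValidationError(f"level j must satisfy 1 <= j <= S-1={S - 1}, got {j}")
    return int(np.unique(_box_codes(px, S, j)).size)


def possible_boxes(S: int, n: int, j: int, mode: BoxMode = "dsr") -> int:
    """Total spectral boxes at level ``j``.

    ``esr`` uses the constant full-depth grid ``(2**S)**n`` at every level;
    ``dsr`` uses the level's own grid ``(2**j)**n``.
    """
    if S < 1 or n < 1 or not 1 <= j <= S:
        raise ValidationError(f"invalid box parameters S={S}, n={n}, j={j}")
    if mode == "esr":
        return (1 << S) ** n
    if mode == "dsr":
        return (1 << j) ** n
    raise ValidationError(f"mode must be 'esr' or 'dsr', got {mode!r}")


def entropy_weight(frame, S: int, j: int) -> float:
    """Entropy weight ``f_j = H_j / (j * n)``, clipped to [0, 1].

    ``H_j`` is the Shannon entropy of the level-``j`` quantised histogram
    over all pixels of the frame; ``j * n`` is the maximum entropy of an
    ``n``-tuple of ``j``-bit symbols, so ``f_j`` is 0 for a constant frame
    and 1 when every level-``j`` box is equally frequent.
    """
    hist = spectral_histogram(frame, S, j)
    n = _as_pixels(frame).shape[1]
    return float(np.clip(shannon_entropy(hist) / (j * n), 0.0, 1.0))


def box_count_profile(frame, S: int) -> BoxCountProfile:
    """Census of occupied boxes and entropy weights for levels 1..S-1."""
    px = _as_pixels(frame)
    _check_depth(px, S)
    if S < 2:
        raise ValidationError(f"analysis depth S must be >= 2, got {S}")
    n = px.shape[1]
    total = px.shape[0]
    sbm = np.empty(S - 1, dtype=np.int64)
    f = np.empty(S - 1, dtype=np.float64)
    for j in range(1, S):
        _, counts = np.unique(_box_codes(px, S, j), return_counts=True)
        sbm[j - 1] = counts.size
        p = counts / total
        h = float(-(p * np.log2(p)).sum())
        f[j - 1] = min(1.0, max(0.0, h / (j * n)))
    sbt_dsr = (1 << np.arange(1, S, dtype=np.int64)) ** n
    return BoxCountProfile(S=S, n=n, sbm=sbm, sbt_dsr=sbt_dsr.astype(np.int64), f=f)


# ---------------------------------------------------------------------------
# the fractal-dimension metrics
# ---------------------------------------------------------------------------

def _sfd_from_profile(profile: BoxCountProfile, mode: BoxMode) -> float:
    log_sbm = np.log(profile.sbm)
    if mode == "esr":
        denom = np.full(profile.S - 1, np.log(float(profile.sbt_esr)))
    else:
        denom = np.log(profile.sbt_dsr.astype(np.float64))
    return float(profile.n * np.sum(log_sbm / denom) / (profile.S - 1))


def sfd_esr(frame, S: int) -> float:
    """Equal-spectral-resolution SFD: constant denominator at every level."""
    return _sfd_from_profile(box_count_profile(frame, S), "esr")


def sfd_dsr(frame, S: int) -> float:
    """Different-spectral-resolution SFD: level-``j`` denominator ``(2**j)**n``.

    Ranges over ``[0, n]``: 0 for a constant frame, exactly ``n`` when every
    box at every level is occupied.
    """
    return _sfd_from_profile(box_count_profile(frame, S), "dsr")


def _ew_terms(profile: BoxCountProfile) -> tuple[float, int]:
    """Entropy-weighted sum and the number of levels floored to zero.

    A level whose weighted count ``f_j * SBM_j`` falls below one box is a
    structureless level; its logarithm would be negative, so the term is
    defined as zero (the floor rule).
    """
    weighted = profile.f * profile.sbm
    denom = np.log(profile.sbt_dsr.astype(np.float64))
    keep = weighted >= 1.0
    terms = np.where(keep, np.log(np.where(keep, weighted, 1.0)) / denom, 0.0)
    total = float(profile.n * terms.sum() / (profile.S - 1))
    return total, int((~keep).sum())


def ew_sfd(frame, S: int) -> float:
    """Entropy-weighted SFD; equals ``sfd_dsr`` when every level histogram is
    uniform (all ``f_j = 1``) and never exceeds it."""
    value, _ = _ew_terms(box_count_profile(frame, S))
    return value


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------

def compute_metrics(
    frame,
    S: int | None = None,
    *,
    exclude_zeros: bool = False,
) -> MetricResult:
    """Entropy, SFD_ESR, SFD_DSR and EW-SFD of one frame at depth ``S``.

    ``S=None`` uses the frame's own effective depth (smallest depth holding
    its maximum value, floored at 2 so the level range 1..S-1 is non-empty).
    ``exclude_zeros`` drops pixels whose bands are all zero before analysis;
    by default every pixel inside the frame counts, zeros included.  The
    frame entropy is taken over exact full-depth values (joint over bands),
    so ``0 <= entropy_bits <= S * n``.
    """
    px = _as_pixels(frame)
    n = px.shape[1]
    if exclude_zeros:
        px = px[px.any(axis=1)]
        if px.size == 0:
            s_eff = 2 if S is None else S
            return MetricResult(0.0, 0.0, 0.0, 0.0, s_eff, n, s_eff - 1)
    if S is None:
        S = max(2, int(px.max()).bit_length())
    elif S < 2:
        raise ValidationError(f"analysis depth S must be >= 2, got {S}")
    frame2d = px.reshape(1, px.shape[0], n)
    profile = box_count_profile(frame2d, S)
    ew, floored = _ew_terms(profile)
    _, counts = np.unique(_box_codes(px, S, S), return_counts=True)
    return MetricResult(
        entropy_bits=shannon_entropy(counts),
        sfd_esr=_sfd_from_profile(profile, "esr"),
        sfd_dsr=_sfd_from_profile(profile, "dsr"),
        ew_sfd=ew,
        S=S,
        n=n,
        floored_levels=floored,
    )
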