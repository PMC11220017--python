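"""Lossless image-stack I/O, validation and region-of-interest extraction.

Time-lapse photon-emission recordings arrive as multi-page lossless grayscale
stacks (TIFF or BigTIFF; the ".btf" batch container is a multi-page TIFF
dialect), one page per integration interval, unsigned integer samples of up
to 16 bits.  This module reads and writes such stacks bit-exactly, validates
their shape and depth, and slices rectangular regions of interest out of
them.  Coordinates are 0-based and half-open: a region covers rows
``[row0, row0 + height)`` and columns ``[col0, col0 + width)``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import tifffile
import yaml

from .errors import StackIOError, UnsupportedFormatError, ValidationError

#: Valid roles for a region of interest.
ROI_ROLES = ("background", "embryo", "reference")

#: Default square ROI edge, in pixels.
DEFAULT_ROI_SIZE = 21

#: Default seconds of photon integration per frame.
DEFAULT_FRAME_INTERVAL = 60.0

_MAX_CONTAINER_BITS = 16


@dataclasses.dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular pixel window tagged with its analysis role.

    ``role`` is one of ``background`` (reference area away from any object),
    ``embryo`` (object under study) or ``reference`` (any other control
    area).  Extents are half-open; the default window is the 21x21 pixel
    sampling area used throughout the analysis.
    """

    row0: int
    col0: int
    height: int = DEFAULT_ROI_SIZE
    width: int = DEFAULT_ROI_SIZE
    role: str = "embryo"
    name: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValidationError(
                f"ROI role must be one of {ROI_ROLES}, got {self.role!r}"
            )
        if self.height < 1 or self.width < 1:
            raise ValidationError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError("ROI offsets must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def slices(self) -> tuple[slice, slice]:
        """Row and column slices selecting this window from a frame."""
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def overlaps(self, other: "RegionOfInterest") -> bool:
        return (
            self.row0 < other.row0 + other.height
            and other.row0 < self.row0 + self.height
            and self.col0 < other.col0 + other.width
            and other.col0 < self.col0 + self.width
        )


@dataclasses.dataclass
class FrameStack:
    """Ordered stack of same-shape non-negative integer frames.

    ``frames`` has shape ``(T, H, W)`` for single-band data or
    ``(T, H, W, n)`` for ``n`` spectral bands.  ``container_bits`` is the
    storage depth S_c: every pixel value must be ``< 2**container_bits``.
    ``frame_interval`` is the integration time per frame in seconds and is
    carried as metadata only.
    """

    frames: np.ndarray
    container_bits: int = _MAX_CONTAINER_BITS
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        a = self.frames
        if a.ndim not in (3, 4):
            raise ValidationError(
                f"frames must be (T, H, W) or (T, H, W, n), got shape {a.shape}"
            )
        if not np.issubdtype(a.dtype, np.integer):
            raise ValidationError(f"frames must be integers, got dtype {a.dtype}")
        if min(a.shape[:3]) < 1 or (a.ndim == 4 and a.shape[3] < 1):
            raise ValidationError(f"every stack dimension must be >= 1, got {a.shape}")
        if not 1 <= self.container_bits <= 32:
            raise ValidationError(
                f"container_bits must be in [1, 32], got {self.container_bits}"
            )
        if a.size and int(a.min()) < 0:
            raise ValidationError("pixel values must be non-negative")
        if a.size and int(a.max()) >= 1 << self.container_bits:
            raise ValidationError(
                f"pixel value {int(a.max())} exceeds the "
                f"{self.container_bits}-bit container"
            )
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")

    # -- accessors ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def band_count(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[3]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def times(self) -> np.ndarray:
        """Start time of each frame in seconds from acquisition start."""
        return np.arange(self.n_frames) * self.frame_interval

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]


# ---------------------------------------------------------------------------
# stack read / write
# ---------------------------------------------------------------------------

def read_stack(path) -> FrameStack:
    """Read a multi-page TIFF/BigTIFF stack; page order is time order.

    The container depth is taken from the file's sample depth (8 or 16 bit
    storage classes), unless the file carries this package's JSON
    description, in which case the declared depth and frame interval are
    restored exactly.
    """
    try:
        tif = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackIOError(f"cannot read stack {path!s}: {exc}") from exc
    with tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValidationError(
                f"pages of {path!s} have inconsistent shapes: {sorted(shapes)}"
            )
        page = tif.pages[0]
        fmt = page.sampleformat
        if fmt not in (1, tifffile.SAMPLEFORMAT.UINT):
            raise UnsupportedFormatError(
                f"{path!s}: only unsigned integer samples are supported"
            )
        bits = page.bitspersample
        if isinstance(bits, (tuple, list)):
            bits = max(bits)
        if bits > _MAX_CONTAINER_BITS:
            raise UnsupportedFormatError(
                f"{path!s}: {bits}-bit samples exceed the 16-bit limit"
            )
        arr = tif.asarray()
        meta = _parse_description(page)
    if arr.ndim == 2:
        arr = arr[None, ...]
    container_bits = int(meta.get("container_bits", bits))
    interval = float(meta.get("frame_interval", DEFAULT_FRAME_INTERVAL))
    return FrameStack(arr, container_bits=container_bits, frame_interval=interval)


def _parse_description(page) -> dict:
    desc = page.description or ""
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    return meta if isinstance(meta, dict) else {}


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as a lossless multi-page TIFF; inverse of read_stack."""
    dtype = np.uint8 if stack.container_bits <= 8 else np.uint16
    arr = stack.frames.astype(dtype)
    desc = json.dumps(
        {
            "container_bits": stack.container_bits,
            "frame_interval": stack.frame_interval,
        }
    )
    try:
        tifffile.imwrite(
            path,
            arr,
            photometric="minisblack",
            description=desc,
            metadata=None,
            compression="zlib",
        )
    except OSError as exc:
        raise StackIOError(f"cannot write stack {path!s}: {exc}") from exc


# ---------------------------------------------------------------------------
# region-of-interest handling
# ---------------------------------------------------------------------------

def extract_roi(stack: FrameStack, roi: RegionOfInterest) -> FrameStack:
    """Slice a T x height x width sub-stack; no silent clipping at borders."""
    h, w = stack.frame_shape
    if roi.row0 + roi.height > h or roi.col0 + roi.width > w:
        raise ValidationError(
            f"ROI {roi.name or roi.shape} at ({roi.row0}, {roi.col0}) "
            f"exceeds the {h}x{w} frame bounds"
        )
    rows, cols = roi.slices()
    return FrameStack(
        stack.frames[:, rows, cols],
        container_bits=stack.container_bits,
        frame_interval=stack.frame_interval,
    )


def load_rois(path) -> list[RegionOfInterest]:
    """Load ROI definitions from a YAML or JSON file.

    The file holds a list of mappings with keys ``name``, ``role``,
    ``row0``, ``col0`` and optional ``height``/``width`` (default 21).
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise StackIOError(f"cannot read ROI file {path!s}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed ROI file {path!s}: {exc}") from exc
    if not isinstance(data, list) or not data:
        raise ValidationError(f"ROI file {path!s} must hold a non-empty list")
    rois = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict):
            raise ValidationError(f"ROI entry {i} in {path!s} is not a mapping")
        try:
            rois.append(
                RegionOfInterest(
                    row0=int(entry["row0"]),
                    col0=int(entry["col0"]),
                    height=int(entry.get("height", DEFAULT_ROI_SIZE)),
                    width=int(entry.get("width", DEFAULT_ROI_SIZE)),
                    role=str(entry.get("role", "embryo")),
                    name=str(entry.get("name", f"roi{i}")),
                )
            )
        except KeyError as exc:
            raise ValidationError(
                f"ROI entry {i} in {path!s} is missing key {exc}"
            ) from exc
    return rois
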