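"""Frame-stack container and on-disk formats.

A dynamic acquisition is a multi-page TIFF (one page per frame) plus a
human-readable YAML sidecar carrying the frame times (seconds from the
first frame), the pixel size (mm/pixel) and free-form acquisition
metadata.  Coordinates are row-major with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["FrameStack", "SubjectLimbRecord", "read_stack", "write_stack"]

GROUPS = ("C", "D", "M")
LIMBS = ("hand", "foot")
SIDES = ("left", "right")
CONDITIONS = ("rest", "post")


@dataclass(frozen=True)
class SubjectLimbRecord:
    """Key identifying one acquisition: who, which limb, which condition.

    Groups are C (control), D (diabetes without complications) and
    M (diabetes with microvascular complications).
    """

    subject: str
    group: str
    limb: str
    side: str
    condition: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.limb not in LIMBS:
            raise ValueError(f"limb must be one of {LIMBS}, got {self.limb!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """(subject, limb, side) — the pairing key across conditions."""
        return (self.subject, self.limb, self.side)

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "group": self.group,
            "limb": self.limb,
            "side": self.side,
            "condition": self.condition,
        }


@dataclass
class FrameStack:
    """Ordered fluorescence frames with their timing and scale.

    Attributes
    ----------
    frames
        ``(n_frames, H, W)`` float array, arbitrary fluorescence units.
    times
        Frame times in seconds from the first frame, strictly increasing.
    pixel_size_mm
        Physical pixel size in mm/pixel (> 0); required to convert drift
        to centimeters for motion QC.
    meta
        Free-form acquisition metadata (subject, group, limb, ...).
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        times = np.asarray(self.times, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        if times.ndim != 1 or times.size != frames.shape[0]:
            raise ValueError(
                f"{times.size} frame times for {frames.shape[0]} frames"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not (self.pixel_size_mm and self.pixel_size_mm > 0):
            raise ValueError("pixel size must be > 0 mm/pixel")
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def pixel_curve(self, row: int, col: int):
        from .kinetics import IntensityCurve

        return IntensityCurve(self.times, self.frames[:, row, col])


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def write_stack(stack: FrameStack, tiff_path, sidecar_path=None) -> None:
    """Write a stack as multi-page TIFF plus YAML sidecar."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(tiff_path)
    tifffile.imwrite(
        tiff_path, stack.frames.astype(np.float32), photometric="minisblack"
    )
    doc = {
        "frame_times_s": [float(t) for t in stack.times],
        "pixel_size_mm": float(stack.pixel_size_mm),
        "meta": stack.meta,
    }
    sidecar_path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_stack(tiff_path, sidecar_path=None) -> FrameStack:
    """Load a stack, validating the sidecar against the TIFF.

    Raises
    ------
    ValueError
        If the sidecar frame-time count does not match the page count,
        times are non-monotone, or the pixel size is missing/invalid.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    frames = frames.astype(np.float64)
    doc = yaml.safe_load(Path(sidecar_path).read_text())
    times = np.asarray(doc.get("frame_times_s", []), dtype=float)
    if times.size != frames.shape[0]:
        raise ValueError(
            f"sidecar lists {times.size} frame times for "
            f"{frames.shape[0]} TIFF pages"
        )
    pixel_size = doc.get("pixel_size_mm")
    if pixel_size is None:
        raise ValueError("sidecar is missing pixel_size_mm")
    return FrameStack(
        frames=frames,
        times=times,
        pixel_size_mm=float(pixel_size),
        meta=doc.get("meta") or {},
    )
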