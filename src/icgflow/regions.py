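"""Digit/dorsum compartments of a limb image and region-level kinetics.

The analyzed limb is divided into two compartments: the digits (toes or
fingers), taken as a surrogate for peripheral arterial input, and the
dorsum, a surrogate for microvascular (capillary) circulation.  Masks are
exchanged as 8-bit label images with codes 0 = background, 1 = digits,
2 = dorsum; no automatic segmentation is attempted — masks are an input
(the synthetic generator always emits ground-truth labels).

The canonical region value is mean-curve-then-parameters: the per-frame
spatial mean over the region forms one time–intensity vector per region
per limb, and the tracer parameters are extracted from that vector.  A
per-pixel dispersion summary (mean and SD of valid per-pixel parameters)
can be computed alongside, since parameter maps are also of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .kinetics import (
    DEFAULT_CONFIG,
    IntensityCurve,
    KineticParams,
    KineticsConfig,
    PARAM_NAMES,
    extract_params,
    map_stack,
)

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_DIGITS",
    "LABEL_DORSUM",
    "REGION_NAMES",
    "RegionSet",
    "RegionResult",
    "load_region_set",
    "write_region_set",
    "region_curve",
    "region_params",
]

LABEL_BACKGROUND = 0
LABEL_DIGITS = 1
LABEL_DORSUM = 2
REGION_NAMES = {LABEL_DIGITS: "digits", LABEL_DORSUM: "dorsum"}


@dataclass
class RegionSet:
    """Disjoint digit and dorsum masks for one limb image."""

    digit_mask: np.ndarray
    dorsum_mask: np.ndarray
    limb: str = "foot"
    side: str = "left"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dig = np.asarray(self.digit_mask, dtype=bool)
        dor = np.asarray(self.dorsum_mask, dtype=bool)
        if dig.shape != dor.shape:
            raise ValueError("digit and dorsum masks must share dimensions")
        if np.any(dig & dor):
            raise ValueError("digit and dorsum masks overlap")
        self.digit_mask = dig
        self.dorsum_mask = dor
        for name, m in (("digits", dig), ("dorsum", dor)):
            if not m.any() and f"empty-{name}" not in self.flags:
                self.flags.append(f"empty-{name}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.digit_mask.shape

    def mask(self, region: str) -> np.ndarray:
        if region == "digits":
            return self.digit_mask
        if region == "dorsum":
            return self.dorsum_mask
        raise KeyError(f"unknown region {region!r}")

    def regions(self):
        yield "digits", self.digit_mask
        yield "dorsum", self.dorsum_mask

    def to_label_image(self) -> np.ndarray:
        labels = np.zeros(self.shape, dtype=np.uint8)
        labels[self.digit_mask] = LABEL_DIGITS
        labels[self.dorsum_mask] = LABEL_DORSUM
        return labels


def load_region_set(label_image, limb: str = "foot", side: str = "left") -> RegionSet:
    """Build a :class:`RegionSet` from a label image (array or TIFF/PNG path).

    Codes: 0 background, 1 digits, 2 dorsum.  Unknown codes raise; an
    empty region is allowed but flagged (and warned about).
    """
    if isinstance(label_image, (str, Path)):
        path = Path(label_image)
        if path.suffix.lower() in (".tif", ".tiff"):
            labels = tifffile.imread(path)
        else:
            from imageio.v3 import imread

            labels = imread(path)
    else:
        labels = np.asarray(label_image)
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label image must be 2-D")
    known = {LABEL_BACKGROUND, LABEL_DIGITS, LABEL_DORSUM}
    present = set(np.unique(labels).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown label codes {sorted(unknown)}")
    if present == {LABEL_BACKGROUND}:
        raise ValueError("no regions: label image is all background")
    rs = RegionSet(
        digit_mask=labels == LABEL_DIGITS,
        dorsum_mask=labels == LABEL_DORSUM,
        limb=limb,
        side=side,
    )
    for flag in rs.flags:
        warnings.warn(f"region set: {flag}", stacklevel=2)
    return rs


def write_region_set(region_set: RegionSet, path) -> None:
    """Write the label image as 8-bit TIFF."""
    tifffile.imwrite(Path(path), region_set.to_label_image())


def region_curve(stack, mask: np.ndarray) -> IntensityCurve:
    """Per-frame spatial mean over the region — one vector per region."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    return IntensityCurve(stack.times, stack.frames[:, mask].mean(axis=1))


@dataclass
class RegionResult:
    """Region-level parameters plus the per-pixel dispersion summary."""

    params: KineticParams
    n_pixels: int
    n_valid_pixels: int | None = None
    dispersion: dict[str, tuple[float, float]] | None = None
    flags: list[str] = field(default_factory=list)


def region_params(
    stack,
    mask: np.ndarray,
    config: KineticsConfig = DEFAULT_CONFIG,
    compute_dispersion: bool = True,
    min_valid_pixels: int = 10,
) -> RegionResult:
    """Extract the canonical region parameters from the mean curve.

    With ``compute_dispersion`` the per-pixel maps are also computed and
    summarized as (mean, SD) of each parameter over valid pixels; the
    result is flagged low-confidence when fewer than ``min_valid_pixels``
    pixels are valid.
    """
    curve = region_curve(stack, mask)
    params = extract_params(curve, config)
    result = RegionResult(params=params, n_pixels=int(np.asarray(mask, bool).sum()))
    if compute_dispersion:
        pmap = map_stack(stack, mask, config)
        n_valid = int(pmap.valid.sum())
        result.n_valid_pixels = n_valid
        disp: dict[str, tuple[float, float]] = {}
        for name in PARAM_NAMES:
            vals = pmap[name][pmap.valid]
            if vals.size:
                disp[name] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
            else:
                disp[name] = (float("nan"), float("nan"))
        result.dispersion = disp
        if n_valid < min_valid_pixels:
            result.flags.append("low-confidence")
    return result
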