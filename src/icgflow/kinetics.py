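"""Time–intensity curve parameterization for bolus-transit fluorescence imaging.

After an intravenous indocyanine-green (ICG) bolus, the fluorescence
intensity of a limb pixel rises from a pre-bolus baseline to a maximum and
then washes out slowly.  This module extracts the standard vascular tracer
parameters from such a curve:

``i_max``
    maximum baseline-subtracted intensity (A.U.), a blood-volume surrogate;
``t_rising``
    time from curve onset to the intensity maximum (s);
``bfi``
    blood flow index, the ratio ``i_max / t_rising`` (A.U./s) — the slope
    of the rising limb;
``mtt``
    mean transit time (s), the first temporal moment of the
    baseline-subtracted curve (indicator-dilution reading);
``auc``
    trapezoidal area under the baseline-subtracted curve (A.U.·s).

Landmark detection (onset and peak location) runs on a lightly smoothed
copy of the curve so that single noisy samples do not dislodge the
landmarks; all parameter *values* (``i_max``, ``auc``, ``mtt``) are
computed on the raw baseline-subtracted curve so the printed definitions
are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np

__all__ = [
    "IntensityCurve",
    "KineticsConfig",
    "KineticParams",
    "ParameterMap",
    "BaselineEstimate",
    "estimate_baseline",
    "extract_params",
    "map_stack",
    "PARAM_NAMES",
    "REASON_OK",
    "REASON_CONSTANT",
    "REASON_LOW_SIGNAL",
    "REASON_DEGENERATE_RISE",
    "REASON_ZERO_MASS",
]

PARAM_NAMES = ("i_max", "t_rising", "bfi", "mtt", "auc")

REASON_OK = "ok"
REASON_CONSTANT = "constant-curve"
REASON_LOW_SIGNAL = "low-signal"
REASON_DEGENERATE_RISE = "degenerate-rise"
REASON_ZERO_MASS = "zero-mass"

#: stable integer codes used in map grids (0 reserved for valid)
REASON_CODES: Mapping[str, int] = {
    REASON_OK: 0,
    REASON_CONSTANT: 1,
    REASON_LOW_SIGNAL: 2,
    REASON_DEGENERATE_RISE: 3,
    REASON_ZERO_MASS: 4,
}


@dataclass(frozen=True)
class IntensityCurve:
    """One pixel's (or one region's) fluorescence time course.

    Parameters
    ----------
    times
        Sample times in seconds from acquisition start, strictly
        increasing, length >= 4.  Spacing is nominally uniform (5 s in the
        acquisition protocol this package targets) but need not be.
    intensities
        Fluorescence intensities in arbitrary units, same length.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1:
            raise ValueError("times and intensities must be 1-D")
        if t.size != y.size:
            raise ValueError(
                f"length mismatch: {t.size} times vs {y.size} intensities"
            )
        if t.size < 4:
            raise ValueError("curve needs at least 4 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("times and intensities must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class KineticsConfig:
    """Tunable knobs of the extraction.

    Attributes
    ----------
    baseline_fraction
        Fraction of the raw intensity range used for the *provisional*
        onset that delimits the baseline window (default 0.10).
    onset_fraction
        Onset threshold as a fraction of the smoothed net peak
        (default 0.10).
    smooth_window
        Moving-average window (frames) used only for landmark detection
        (default 3; 1 disables smoothing).
    noise_floor_sd
        Validity floor: a curve whose ``i_max`` is below
        ``noise_floor_sd`` times the SD of the pre-onset raw samples is
        flagged ``low-signal``.  0 disables the check (default 5).
    mtt_reference
        ``"acquisition"`` measures MTT from the first frame (default);
        ``"onset"`` measures it from the detected onset.
    """

    baseline_fraction: float = 0.10
    onset_fraction: float = 0.10
    smooth_window: int = 3
    noise_floor_sd: float = 5.0
    mtt_reference: str = "acquisition"

    def __post_init__(self) -> None:
        if not 0 < self.baseline_fraction < 1:
            raise ValueError("baseline_fraction must be in (0, 1)")
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset_fraction must be in (0, 1)")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.noise_floor_sd < 0:
            raise ValueError("noise_floor_sd must be >= 0")
        if self.mtt_reference not in ("acquisition", "onset"):
            raise ValueError("mtt_reference must be 'acquisition' or 'onset'")


DEFAULT_CONFIG = KineticsConfig()


@dataclass(frozen=True)
class KineticParams:
    """Extracted tracer parameters for one curve.

    Invalid curves carry ``valid=False`` with a ``reason`` code; numeric
    fields that could not be computed are NaN, never 0, so aggregation
    over maps is not biased.
    """

    baseline: float
    onset_time: float
    peak_time: float
    i_max: float
    t_rising: float
    bfi: float
    mtt: float
    auc: float
    valid: bool
    reason: str = REASON_OK

    def as_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "onset_time": self.onset_time,
            "peak_time": self.peak_time,
            "i_max": self.i_max,
            "t_rising": self.t_rising,
            "bfi": self.bfi,
            "mtt": self.mtt,
            "auc": self.auc,
            "valid": self.valid,
            "reason": self.reason,
        }


class BaselineEstimate(NamedTuple):
    baseline: float
    provisional_onset_index: int | None
    constant: bool


def estimate_baseline(
    curve: IntensityCurve, config: KineticsConfig = DEFAULT_CONFIG
) -> BaselineEstimate:
    """Estimate the pre-bolus basal intensity of a curve.

    A provisional onset — the first sample whose raw intensity exceeds
    ``raw_min + baseline_fraction * (raw_max - raw_min)`` — delimits the
    baseline window; the baseline is the median of all samples strictly
    before it (the median, unlike the mean, is insensitive to the early
    ramp samples below the threshold that fall inside the window, which
    matters at dense sampling).  If the very first sample already exceeds
    the threshold the raw minimum is used instead.  This breaks the
    baseline/onset circularity in a single deterministic pass.

    A constant curve has no onset: its value is returned as the baseline
    with ``constant=True`` and ``provisional_onset_index=None``.
    """
    y = curve.intensities
    rmin = float(y.min())
    rmax = float(y.max())
    if rmax == rmin:
        return BaselineEstimate(rmin, None, True)
    thresh = rmin + config.baseline_fraction * (rmax - rmin)
    idx = int(np.argmax(y > thresh))  # first True; y.max() > thresh always
    if idx == 0:
        return BaselineEstimate(rmin, 0, False)
    return BaselineEstimate(float(np.median(y[:idx])), idx, False)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the array ends."""
    if window <= 1:
        return y.astype(float, copy=True)
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return sums / counts


def _invalid(baseline: float, reason: str, **known) -> KineticParams:
    fields = dict(
        baseline=baseline,
        onset_time=np.nan,
        peak_time=np.nan,
        i_max=np.nan,
        t_rising=np.nan,
        bfi=np.nan,
        mtt=np.nan,
        auc=np.nan,
    )
    fields.update(known)
    return KineticParams(valid=False, reason=reason, **fields)


def extract_params(
    curve: IntensityCurve, config: KineticsConfig = DEFAULT_CONFIG
) -> KineticParams:
    """Extract the full tracer parameter set from one curve.

    Procedure
    ---------
    1. baseline via :func:`estimate_baseline`;
    2. net curve = intensities - baseline, clipped at 0 (noise below
       baseline must not contribute negative area or mass);
    3. a moving-average smoothed copy locates ``peak_time`` (earliest
       sample attaining the smoothed maximum) and ``onset_time`` (earliest
       sample with smoothed net >= ``onset_fraction`` x smoothed peak);
    4. ``i_max`` = maximum of the *unsmoothed* net curve (ties: earliest);
    5. ``t_rising`` = ``peak_time - onset_time``; ``bfi = i_max/t_rising``;
    6. ``auc`` = trapezoidal integral of the net curve over the window;
    7. ``mtt`` = trapezoid-weighted first temporal moment of the net
       curve, measured from acquisition start (or onset, per config).

    The acquisition window truncates the washout tail, so ``auc`` and
    ``mtt`` are window-limited quantities; no tail extrapolation is done.
    """
    est = estimate_baseline(curve, config)
    if est.constant:
        return _invalid(est.baseline, REASON_CONSTANT)

    t = curve.times
    net = np.clip(curve.intensities - est.baseline, 0.0, None)
    smoothed = _moving_average(net, config.smooth_window)

    peak_idx = int(np.argmax(smoothed))  # earliest maximizer
    speak = smoothed[peak_idx]
    if speak <= 0.0:
        return _invalid(est.baseline, REASON_ZERO_MASS)
    onset_idx = int(np.argmax(smoothed >= config.onset_fraction * speak))
    onset_time = float(t[onset_idx])
    peak_time = float(t[peak_idx])

    imax_idx = int(np.argmax(net))
    i_max = float(net[imax_idx])

    # Noise floor: background pixels never see the bolus; their "peak" is
    # noise and would otherwise produce absurd BFI values in maps.  On
    # curves with no usable pre-onset window (onset at the very start —
    # typical for background noise, whose "onset" is immediate) the noise
    # SD falls back to the robust successive-difference estimator.
    if config.noise_floor_sd > 0:
        if onset_idx >= 2:
            pre_sd = float(np.std(curve.intensities[:onset_idx], ddof=1))
        else:
            diffs = np.diff(curve.intensities)
            pre_sd = float(np.median(np.abs(diffs))) / (math.sqrt(2.0) * 0.6744897501960817)
        if i_max < config.noise_floor_sd * pre_sd:
            return _invalid(
                est.baseline,
                REASON_LOW_SIGNAL,
                onset_time=onset_time,
                peak_time=peak_time,
                i_max=i_max,
            )

    t_rising = peak_time - onset_time
    if t_rising <= 0.0:
        return _invalid(
            est.baseline,
            REASON_DEGENERATE_RISE,
            onset_time=onset_time,
            peak_time=peak_time,
            i_max=i_max,
        )
    bfi = i_max / t_rising

    mass = float(np.trapezoid(net, t))
    if mass <= 0.0:
        return _invalid(
            est.baseline,
            REASON_ZERO_MASS,
            onset_time=onset_time,
            peak_time=peak_time,
            i_max=i_max,
            t_rising=t_rising,
            bfi=bfi,
        )
    auc = mass
    t_ref = t if config.mtt_reference == "acquisition" else t - onset_time
    mtt = float(np.trapezoid(t_ref * net, t)) / mass

    return KineticParams(
        baseline=est.baseline,
        onset_time=onset_time,
        peak_time=peak_time,
        i_max=i_max,
        t_rising=t_rising,
        bfi=bfi,
        mtt=mtt,
        auc=auc,
        valid=True,
        reason=REASON_OK,
    )


@dataclass
class ParameterMap:
    """Per-pixel tracer parameter grids for one frame stack.

    Each grid shares the source frame dimensions.  Pixels outside the
    mask, and masked pixels whose curve failed validity checks, carry NaN
    (never 0) so that map statistics are not biased; ``reason_codes``
    distinguishes why (see :data:`REASON_CODES`; -1 marks out-of-mask).
    """

    grids: dict[str, np.ndarray]
    valid: np.ndarray
    reason_codes: np.ndarray
    mask: np.ndarray
    times: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.grids[name]

    def summary(self) -> dict[str, int]:
        """Counts of valid pixels and of each failure reason."""
        out = {"n_mask": int(self.mask.sum()), "n_valid": int(self.valid.sum())}
        codes = self.reason_codes[self.mask]
        for reason, code in REASON_CODES.items():
            if code == 0:
                continue
            n = int((codes == code).sum())
            if n:
                out[reason] = n
        return out

    def write_tiff(self, path) -> None:
        """Write the grids as one 32-bit float multi-page TIFF.

        Page order is ``PARAM_NAMES``; invalid pixels are NaN.
        """
        import tifffile

        pages = np.stack(
            [self.grids[name].astype(np.float32) for name in PARAM_NAMES]
        )
        tifffile.imwrite(
            path, pages, photometric="minisblack",
            metadata={"axes": "CYX", "params": list(PARAM_NAMES)},
        )


def _iter_masked(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    rows, cols = np.nonzero(mask)
    return zip(rows.tolist(), cols.tolist())


def map_stack(stack, mask: np.ndarray, config: KineticsConfig = DEFAULT_CONFIG) -> ParameterMap:
    """Apply :func:`extract_params` to every masked pixel of a stack.

    Parameters
    ----------
    stack
        A :class:`~icgflow.io.FrameStack` (frames shaped ``(n_t, H, W)``).
    mask
        Boolean grid of pixels to analyze, same ``(H, W)`` as the frames.
    """
    frames = stack.frames
    times = stack.times
    if frames.shape[0] < 4:
        raise ValueError("need at least 4 frames")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {frames.shape[1:]}"
        )
    if not mask.any():
        raise ValueError("empty mask")

    shape = mask.shape
    grids = {
        name: np.full(shape, np.nan, dtype=float)
        for name in PARAM_NAMES + ("baseline", "onset_time", "peak_time")
    }
    valid = np.zeros(shape, dtype=bool)
    reasons = np.full(shape, -1, dtype=np.int8)

    for r, c in _iter_masked(mask):
        curve = IntensityCurve(times, frames[:, r, c])
        p = extract_params(curve, config)
        reasons[r, c] = REASON_CODES[p.reason]
        if p.valid:
            valid[r, c] = True
            for name in PARAM_NAMES:
                grids[name][r, c] = getattr(p, name)
            grids["baseline"][r, c] = p.baseline
            grids["onset_time"][r, c] = p.onset_time
            grids["peak_time"][r, c] = p.peak_time

    return ParameterMap(
        grids=grids, valid=valid, reason_codes=reasons, mask=mask, times=times
    )
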