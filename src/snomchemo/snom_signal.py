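"""SNOM transmission-image arm: spectrum-like signal extraction and biomarker areas.

A near-field IR transmission scan of one cell at one fixed biomarker wavelength
is a small real matrix (rows = slow-scan lines, columns = fast-scan positions).
The analysis collapses each matrix to a 1-D "spectrum-like" profile by averaging
over the slow-scan rows, normalizes the profile by mean-centring followed by the
absolute value, and integrates the normalized profile over a spatial interval
covering the cell to obtain a per-biomarker area.  Areas are compared across
cytological classes as percentage changes relative to the normal class (ΔA%).

A separate, presentation-only image enhancement (row-median alignment plus 2-D
Fourier low-pass) is provided for display; it never feeds the analysis path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TransmissionImage",
    "SpectrumLikeSignal",
    "BiomarkerAreaRecord",
    "image_to_signal",
    "normalize_signal",
    "average_replicates",
    "signal_area",
    "delta_area_percent",
    "auto_interval",
    "build_area_table",
    "enhance_image",
]

BIOMARKERS = ("lipids", "amide_I", "amide_II", "dna")


class AlreadyNormalizedError(ValueError):
    """Raised when a signal that is already normalized is normalized again."""


@dataclass
class TransmissionImage:
    """One transmission scan of one cell at one biomarker wavelength.

    ``pixels[i, j]`` is the transmitted IR intensity at slow-scan line *i* and
    fast-scan position *j*.  The physical pixel pitch along the fast axis is
    ``scan_size_um / pixels.shape[1]``.
    """

    pixels: np.ndarray
    wavelength_um: float
    biomarker: str
    cell_id: str
    class_label: str
    scan_size_um: float = 400.0
    presentation_only: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError(
                f"image must be a 2-D matrix with both dimensions >= 2, "
                f"got shape {self.pixels.shape}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite pixels")
        if self.scan_size_um <= 0:
            raise ValueError("scan_size_um must be positive")

    @property
    def pixel_pitch_um(self) -> float:
        return self.scan_size_um / self.pixels.shape[1]


@dataclass
class SpectrumLikeSignal:
    """The 1-D row-averaged profile of a transmission image."""

    values: np.ndarray
    spatial_axis_um: np.ndarray
    biomarker: str
    source_cell_id: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spatial_axis_um = np.asarray(self.spatial_axis_um, dtype=float)
        if self.values.shape != self.spatial_axis_um.shape or self.values.ndim != 1:
            raise ValueError("values and spatial axis must be 1-D and equal length")
        if not (np.diff(self.spatial_axis_um) > 0).all():
            raise ValueError("spatial axis must be strictly increasing")
        if self.normalized and (self.values < 0).any():
            raise ValueError("a normalized signal must be non-negative")


@dataclass
class BiomarkerAreaRecord:
    """Integrated area of one class's biomarker profile and its change vs normal."""

    class_label: str
    biomarker: str
    interval_um: tuple[float, float]
    area: float
    delta_area_pct: float | None = None


def image_to_signal(image: TransmissionImage) -> SpectrumLikeSignal:
    """Collapse an image to its spectrum-like signal.

    Each output element is the arithmetic mean of one image column over all
    slow-scan rows: ``s_j = (1/m) * sum_i x_ij``.  The spatial axis spans
    ``[0, scan_size_um)`` at the fast-axis pixel pitch.
    """
    m, c = image.pixels.shape
    values = image.pixels.mean(axis=0)
    axis = np.arange(c) * (image.scan_size_um / c)
    return SpectrumLikeSignal(
        values=values,
        spatial_axis_um=axis,
        biomarker=image.biomarker,
        source_cell_id=image.cell_id,
        normalized=False,
    )


def normalize_signal(signal: SpectrumLikeSignal) -> SpectrumLikeSignal:
    """Mean-centre the signal, then take the absolute value elementwise.

    The centred (pre-absolute) vector has mean zero by construction; the
    output is non-negative, which makes downstream areas non-negative.
    Normalizing twice is a contract violation, not an idempotent no-op.
    """
    if signal.normalized:
        raise AlreadyNormalizedError("signal is already normalized")
    centred = signal.values - signal.values.mean()
    return replace(signal, values=np.abs(centred), normalized=True)


def average_replicates(signals: Sequence[SpectrumLikeSignal]) -> SpectrumLikeSignal:
    """Pointwise mean of replicate signals of one biomarker.

    All replicates must share length, biomarker and normalization state;
    metadata is inherited from the first replicate.
    """
    if len(signals) == 0:
        raise ValueError("need at least one signal to average")
    first = signals[0]
    for s in signals[1:]:
        if s.values.shape != first.values.shape:
            raise ValueError("replicate signals have mismatched lengths")
        if s.biomarker != first.biomarker:
            raise ValueError(
                f"mixed biomarkers in replicate set: {s.biomarker!r} vs {first.biomarker!r}"
            )
        if s.normalized != first.normalized:
            raise ValueError("replicates mix normalized and raw signals")
    stacked = np.stack([s.values for s in signals])
    return replace(first, values=stacked.mean(axis=0))


def signal_area(
    signal: SpectrumLikeSignal, interval_um: tuple[float, float]
) -> float:
    """Trapezoidal area of a normalized signal over a spatial interval.

    Interval endpoints are snapped to the nearest axis points; a snap that
    moves an endpoint is logged.
    """
    if not signal.normalized:
        raise ValueError("signal_area requires a normalized signal")
    lo, hi = interval_um
    if lo >= hi:
        raise ValueError(f"degenerate interval: lo={lo} >= hi={hi}")
    axis = signal.spatial_axis_um
    if lo < axis[0] - 1e-9 or hi > axis[-1] + 1e-9:
        raise ValueError(
            f"interval ({lo}, {hi}) outside axis range [{axis[0]}, {axis[-1]}]"
        )
    i_lo = int(np.argmin(np.abs(axis - lo)))
    i_hi = int(np.argmin(np.abs(axis - hi)))
    if i_lo >= i_hi:
        raise ValueError(f"interval ({lo}, {hi}) degenerate after snapping to axis")
    if axis[i_lo] != lo or axis[i_hi] != hi:
        logger.info(
            "interval (%g, %g) um snapped to axis points (%g, %g) um",
            lo, hi, axis[i_lo], axis[i_hi],
        )
    return float(np.trapezoid(signal.values[i_lo : i_hi + 1], axis[i_lo : i_hi + 1]))


def delta_area_percent(area: float, area_normal: float) -> float:
    """Percentage change of a biomarker area relative to the normal class."""
    if area_normal <= 0:
        raise ValueError("normal-class reference area must be positive")
    return 100.0 * (area - area_normal) / area_normal


def auto_interval(
    signal: SpectrumLikeSignal, threshold: float = 0.5, pad_fraction: float = 0.1
) -> tuple[float, float]:
    """Automatic integration interval around the cell content.

    Returns the smallest interval containing all points where the normalized
    signal exceeds ``threshold`` of its maximum, padded on each side by
    ``pad_fraction`` of the axis span and clipped to the axis range.  Falls
    back to the full axis for a flat (all-zero) signal.
    """
    axis = signal.spatial_axis_um
    vmax = signal.values.max()
    if vmax <= 0:
        return float(axis[0]), float(axis[-1])
    above = np.flatnonzero(signal.values > threshold * vmax)
    pad = pad_fraction * (axis[-1] - axis[0])
    lo = max(float(axis[above[0]]) - pad, float(axis[0]))
    hi = min(float(axis[above[-1]]) + pad, float(axis[-1]))
    if lo >= hi:  # single spike at an axis end
        return float(axis[0]), float(axis[-1])
    return lo, hi


def build_area_table(
    signals: Mapping[tuple[str, str], Sequence[SpectrumLikeSignal]],
    intervals: Mapping[str, tuple[float, float]] | None = None,
    *,
    normal_label: str = "normal",
    class_order: Sequence[str] | None = None,
    biomarker_order: Sequence[str] | None = None,
    average_first: bool = False,
) -> list[BiomarkerAreaRecord]:
    """Build the per-(class, biomarker) area and ΔA% table.

    Parameters
    ----------
    signals
        Raw (un-normalized) replicate signals keyed by ``(class_label,
        biomarker)``.
    intervals
        Optional per-class integration intervals in μm.  Classes without an
        entry get an automatic interval from their averaged normalized signal.
    average_first
        If True, replicates are averaged before normalization; the default
        normalizes each replicate and then averages.
    """
    keys = list(signals.keys())
    if class_order is None:
        class_order = list(dict.fromkeys(k[0] for k in keys))
    if biomarker_order is None:
        biomarker_order = list(dict.fromkeys(k[1] for k in keys))
    if normal_label not in class_order:
        raise ValueError(f"no class labelled {normal_label!r} in the dataset")
    for cls in class_order:
        for bm in biomarker_order:
            if (cls, bm) not in signals or len(signals[(cls, bm)]) == 0:
                raise ValueError(f"class {cls!r} is missing biomarker {bm!r}")

    def reduced(cls: str, bm: str) -> SpectrumLikeSignal:
        reps = signals[(cls, bm)]
        if average_first:
            return normalize_signal(average_replicates(reps))
        return average_replicates([normalize_signal(s) for s in reps])

    areas: dict[tuple[str, str], tuple[float, tuple[float, float]]] = {}
    for cls in class_order:
        for bm in biomarker_order:
            sig = reduced(cls, bm)
            if intervals is not None and cls in intervals:
                interval = intervals[cls]
            else:
                interval = auto_interval(sig)
                logger.info(
                    "class %s / %s: automatic interval (%.2f, %.2f) um",
                    cls, bm, interval[0], interval[1],
                )
            areas[(cls, bm)] = (signal_area(sig, interval), interval)

    records: list[BiomarkerAreaRecord] = []
    for cls in class_order:
        for bm in biomarker_order:
            area, interval = areas[(cls, bm)]
            if cls == normal_label:
                delta = None
            else:
                delta = delta_area_percent(area, areas[(normal_label, bm)][0])
            records.append(
                BiomarkerAreaRecord(
                    class_label=cls,
                    biomarker=bm,
                    interval_um=interval,
                    area=area,
                    delta_area_pct=delta,
                )
            )
    return records


def enhance_image(image: TransmissionImage, cutoff_fraction: float) -> TransmissionImage:
    """Presentation-only image enhancement; never fed back into the analysis.

    Step 1 aligns slow-scan rows by subtracting each row's median and adding
    back the median of the row medians (preserving the overall level, so a
    constant image is a fixed point).  Step 2 removes high-frequency noise by
    zeroing all 2-D spatial-frequency components whose radial frequency exceeds
    ``cutoff_fraction`` of the maximal (corner) radial frequency and inverse
    transforming; ``cutoff_fraction=1`` passes every component through.
    """
    if not (0 < cutoff_fraction <= 1):
        raise ValueError("cutoff_fraction must lie in (0, 1]")
    px = image.pixels
    row_med = np.median(px, axis=1)
    aligned = px - row_med[:, None] + np.median(row_med)

    r, c = aligned.shape
    fy = np.fft.fftfreq(r)[:, None]
    fx = np.fft.fftfreq(c)[None, :]
    # radius normalized so the extreme corner (Nyquist, Nyquist) sits at 1
    rho = np.sqrt((fy / 0.5) ** 2 + (fx / 0.5) ** 2) / np.sqrt(2.0)
    mask = rho <= cutoff_fraction + 1e-12
    smoothed = np.fft.ifft2(np.fft.fft2(aligned) * mask).real
    return replace(image, pixels=smoothed, presentation_only=True)
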