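"""Synthetic measurement generator for both analysis arms.

Emulates the study conditions the pipeline was designed around, with known
ground truth so every downstream stage can be exercised end-to-end:

* SNOM-like transmission images — 150×150 matrices over a 400 μm scan at the
  four biomarker wavelengths (lipids 5.71 μm, Amide I 6.06 μm, Amide II
  6.46 μm, DNA 8.16 μm), three replicates per (class, biomarker).  The cell is
  a cosine-tapered ellipse whose absorption amplitude scales with a per-class
  effect multiplier; the default effect table encodes the relative biomarker
  changes of each cytological class against normal (ΔA% = 100·(effect − 1)).
  The lipid channel carries extra noise, reflecting its lower source
  signal-to-noise near the edge of the laser's tuning range.
* ATR-FTIR-like spectra — Gaussian bands at ten diagnostic wavenumbers on a
  900–3100 cm⁻¹ axis at 8 cm⁻¹ spacing, ten spectra per class with
  class-dependent band amplitudes.

Every generator is a pure, deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemometrics import SpectralDataset
from .snom_signal import BIOMARKERS, TransmissionImage

__all__ = [
    "CLASSES",
    "ClassEffectTable",
    "SnomSimConfig",
    "AtrSimConfig",
    "generate_snom_image",
    "generate_snom_dataset",
    "generate_atr_dataset",
]

CLASSES = (
    "normal",
    "low_grade_dyskaryosis",
    "high_grade_dyskaryosis",
    "CIN2_HGCGIN",
    "adenocarcinoma_1B1",
)

# Relative biomarker amplitude of each class vs normal (normal ≡ 1).  With a
# noise-free generator the pipeline's ΔA% equals 100·(multiplier − 1), so this
# table is simultaneously the generator's dial and the recovery target.
_DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "normal":                 {"lipids": 1.00, "amide_I": 1.00, "amide_II": 1.00, "dna": 1.00},
    "low_grade_dyskaryosis":  {"lipids": 0.69, "amide_I": 0.27, "amide_II": 2.43, "dna": 2.11},
    "high_grade_dyskaryosis": {"lipids": 0.22, "amide_I": 0.06, "amide_II": 1.40, "dna": 2.32},
    "CIN2_HGCGIN":            {"lipids": 1.93, "amide_I": 1.38, "amide_II": 6.09, "dna": 13.72},
    "adenocarcinoma_1B1":     {"lipids": 0.53, "amide_I": 0.34, "amide_II": 0.54, "dna": 6.85},
}


@dataclass
class ClassEffectTable:
    """Per-(class, biomarker) absorption multipliers relative to normal."""

    classes: tuple[str, ...] = CLASSES
    biomarkers: tuple[str, ...] = BIOMARKERS
    effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(b) for c, b in _DEFAULT_EFFECTS.items()}
    )
    normal_label: str = "normal"

    def __post_init__(self) -> None:
        if self.normal_label not in self.classes:
            raise ValueError(f"normal class {self.normal_label!r} not in classes")
        for cls in self.classes:
            for bm in self.biomarkers:
                v = self.lookup(cls, bm)
                if v <= 0:
                    raise ValueError(f"effect({cls}, {bm}) = {v} must be positive")
        for bm in self.biomarkers:
            if self.lookup(self.normal_label, bm) != 1.0:
                raise ValueError("normal-class multipliers must all equal 1.0")

    def lookup(self, class_label: str, biomarker: str) -> float:
        try:
            return float(self.effect[class_label][biomarker])
        except KeyError as exc:
            raise KeyError(
                f"no effect entry for class {class_label!r}, biomarker {biomarker!r}"
            ) from exc


@dataclass
class SnomSimConfig:
    """Geometry, amplitude and noise settings for simulated transmission scans."""

    image_rows: int = 150
    image_cols: int = 150
    scan_size_um: float = 400.0
    wavelengths_um: Mapping[str, float] = field(
        default_factory=lambda: {
            "lipids": 5.71, "amide_I": 6.06, "amide_II": 6.46, "dna": 8.16
        }
    )
    cell_center_px: tuple[float, float] = (75.0, 75.0)   # (row, col)
    cell_radii_px: tuple[float, float] = (45.0, 55.0)    # (row, col)
    edge_taper_fraction: float = 0.2
    baseline_level: float = 0.0
    base_amplitude: float = 1.0
    polarity: str = "absorption_positive"  # or "transmission" (cell darker)
    noise_sd: float = 0.01
    lipid_noise_multiplier: float = 3.0
    line_offset_sd: float = 0.005
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.image_rows < 2 or self.image_cols < 2:
            raise ValueError("image must be at least 2x2")
        if self.noise_sd < 0 or self.line_offset_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.lipid_noise_multiplier < 1:
            raise ValueError("lipid_noise_multiplier must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.polarity not in ("absorption_positive", "transmission"):
            raise ValueError("polarity must be 'absorption_positive' or 'transmission'")
        cy, cx = self.cell_center_px
        ry, rx = self.cell_radii_px
        if ry <= 0 or rx <= 0:
            raise ValueError("cell radii must be positive")
        if (cy - ry < 0 or cy + ry > self.image_rows - 1
                or cx - rx < 0 or cx + rx > self.image_cols - 1):
            raise ValueError("cell ellipse does not fit inside the image bounds")


def _ellipse_mask(config: SnomSimConfig) -> np.ndarray:
    """Filled ellipse with a cosine-tapered edge, values in [0, 1]."""
    rows = np.arange(config.image_rows)[:, None]
    cols = np.arange(config.image_cols)[None, :]
    cy, cx = config.cell_center_px
    ry, rx = config.cell_radii_px
    rho = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    t = config.edge_taper_fraction
    inner = 1.0 - t
    mask = np.zeros_like(rho)
    mask[rho <= inner] = 1.0
    if t > 0:
        ramp = (rho > inner) & (rho < 1.0)
        mask[ramp] = 0.5 * (1.0 + np.cos(np.pi * (rho[ramp] - inner) / t))
    return mask


def generate_snom_image(
    class_label: str,
    biomarker: str,
    config: SnomSimConfig,
    effects: ClassEffectTable,
    seed: int,
    *,
    cell_id: str | None = None,
) -> TransmissionImage:
    """Simulate one transmission scan.

    The image is ``baseline + amplitude·effect(class, biomarker)·ellipse``
    (sign flipped for transmission polarity) plus per-row line offsets and
    pixel noise; the lipid channel's pixel noise is scaled by
    ``lipid_noise_multiplier``.  Deterministic for a fixed seed.
    """
    if class_label not in effects.classes:
        raise KeyError(f"unknown class {class_label!r}; known: {list(effects.classes)}")
    if biomarker not in effects.biomarkers:
        raise KeyError(
            f"unknown biomarker {biomarker!r}; known: {list(effects.biomarkers)}"
        )
    eff = effects.lookup(class_label, biomarker)
    rng = np.random.default_rng(seed)
    signal = config.base_amplitude * eff * _ellipse_mask(config)
    if config.polarity == "transmission":
        signal = -signal
    img = config.baseline_level + signal
    img += rng.normal(0.0, config.line_offset_sd, config.image_rows)[:, None]
    sd = config.noise_sd * (
        config.lipid_noise_multiplier if biomarker == "lipids" else 1.0
    )
    img += rng.normal(0.0, sd, img.shape)
    return TransmissionImage(
        pixels=img,
        wavelength_um=float(config.wavelengths_um[biomarker]),
        biomarker=biomarker,
        cell_id=cell_id if cell_id is not None else f"{class_label}_cell",
        class_label=class_label,
        scan_size_um=config.scan_size_um,
    )


def generate_snom_dataset(
    config: SnomSimConfig, effects: ClassEffectTable, seed: int
) -> tuple[list[TransmissionImage], "pd.DataFrame"]:
    """One image per (class, biomarker, replicate) plus a manifest table.

    The manifest (class, biomarker, wavelength, replicate, cell id) is the
    same for every seed; only the pixel data vary.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = len(effects.classes) * len(effects.biomarkers) * config.replicates
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    images: list[TransmissionImage] = []
    rows = []
    k = 0
    for cls in effects.classes:
        for bm in effects.biomarkers:
            for rep in range(1, config.replicates + 1):
                img = generate_snom_image(
                    cls, bm, config, effects, int(child_seeds[k]),
                    cell_id=f"{cls}_cell",
                )
                images.append(img)
                rows.append(
                    {
                        "cell_id": img.cell_id,
                        "class_label": cls,
                        "biomarker": bm,
                        "wavelength_um": img.wavelength_um,
                        "replicate_id": rep,
                    }
                )
                k += 1
    return images, pd.DataFrame(rows)


# Ten diagnostic band centres; eight sit in the 900–1800 cm⁻¹ fingerprint
# region (glycogen, C–O of proteins/carbohydrates, Amide III/deoxyribose,
# Amide III/phosphate, nucleic-acid stretches, polysaccharides/collagen,
# Amide II, Amide I), plus asymmetric CO2 at 2345 and CH stretch at 2939.
_DEFAULT_BAND_CENTERS = (
    1022.0, 1157.0, 1184.0, 1234.0, 1331.0, 1512.0, 1566.0, 1662.0, 2345.0, 2939.0
)

# Per-class band amplitudes (absorbance units).  Chosen once so that every
# pair of classes differs at three or more band positions by well over the
# noise floor — the strongly separated regime the discriminant models target.
_DEFAULT_ATR_AMPLITUDES: dict[str, tuple[float, ...]] = {
    "normal":                 (0.30, 0.20, 0.15, 0.25, 0.15, 0.10, 0.35, 0.60, 0.05, 0.20),
    "low_grade_dyskaryosis":  (0.20, 0.25, 0.18, 0.35, 0.20, 0.12, 0.50, 0.45, 0.06, 0.18),
    "high_grade_dyskaryosis": (0.15, 0.30, 0.22, 0.45, 0.25, 0.15, 0.42, 0.35, 0.08, 0.15),
    "CIN2_HGCGIN":            (0.45, 0.35, 0.28, 0.55, 0.35, 0.22, 0.65, 0.75, 0.10, 0.30),
    "adenocarcinoma_1B1":     (0.25, 0.28, 0.20, 0.50, 0.30, 0.18, 0.28, 0.40, 0.12, 0.25),
}


@dataclass
class AtrSimConfig:
    """Axis, band and noise settings for simulated ATR-FTIR absorbance spectra."""

    wavenumber_start: float = 900.0
    wavenumber_end: float = 3100.0
    spacing_cm1: float = 8.0
    band_centers_cm1: tuple[float, ...] = _DEFAULT_BAND_CENTERS
    band_width_cm1: float = 16.0
    class_amplitudes: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {c: tuple(a) for c, a in _DEFAULT_ATR_AMPLITUDES.items()}
    )
    class_separation: float = 1.0
    baseline_level: float = 0.05
    noise_sd: float = 0.005
    n_per_class: int = 10
    reference_class: str = "normal"

    def __post_init__(self) -> None:
        if self.spacing_cm1 <= 0:
            raise ValueError("spacing_cm1 must be positive")
        if self.wavenumber_end <= self.wavenumber_start:
            raise ValueError("wavenumber axis must be increasing")
        if self.band_width_cm1 <= 0:
            raise ValueError("band_width_cm1 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        axis = self.axis()
        for c in self.band_centers_cm1:
            if not (axis[0] <= c <= axis[-1]):
                raise ValueError(f"band centre {c} cm^-1 outside the axis range")
        nb = len(self.band_centers_cm1)
        for cls, amps in self.class_amplitudes.items():
            if len(amps) != nb:
                raise ValueError(
                    f"class {cls!r} has {len(amps)} amplitudes for {nb} bands"
                )
        if self.reference_class not in self.class_amplitudes:
            raise ValueError(f"reference class {self.reference_class!r} undefined")

    def axis(self) -> np.ndarray:
        n = int(np.floor((self.wavenumber_end - self.wavenumber_start)
                         / self.spacing_cm1)) + 1
        return self.wavenumber_start + self.spacing_cm1 * np.arange(n)


def generate_atr_dataset(config: AtrSimConfig, seed: int) -> SpectralDataset:
    """Simulate ``n_per_class`` absorbance spectra per class.

    Each spectrum is ``baseline + Σ_b amp_b·exp(−(ν − c_b)²/(2w²)) + noise``.
    ``class_separation`` scales each class's amplitude offset from the
    reference class (1 = configured amplitudes, 0 = all classes identical),
    giving a separability dial with the class geometry otherwise fixed.
    """
    axis = config.axis()
    rng = np.random.default_rng(seed)
    centers = np.asarray(config.band_centers_cm1)
    w = config.band_width_cm1
    profiles = np.exp(-((axis[None, :] - centers[:, None]) ** 2) / (2.0 * w**2))
    ref = np.asarray(config.class_amplitudes[config.reference_class], dtype=float)

    spectra, labels, ids = [], [], []
    for cls, amps in config.class_amplitudes.items():
        amps = np.asarray(amps, dtype=float)
        eff_amps = ref + config.class_separation * (amps - ref)
        clean = config.baseline_level + eff_amps @ profiles
        for i in range(config.n_per_class):
            noisy = clean + rng.normal(0.0, config.noise_sd, axis.size)
            spectra.append(noisy)
            labels.append(cls)
            ids.append(f"{cls}_{i + 1:02d}")
    return SpectralDataset(
        variables_axis=axis,
        intensities=np.vstack(spectra),
        class_labels=labels,
        sample_ids=ids,
    )
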