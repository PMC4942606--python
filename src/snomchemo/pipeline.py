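"""End-to-end orchestration of the two analysis arms.

``run_snom_pipeline`` takes a manifest of transmission images through signal
extraction, normalization, replicate averaging, the area/ΔA% table and a
per-biomarker PCA with T²/Q diagnostics.  ``run_atr_pipeline`` takes a spectra
table through the Kennard–Stone split, PCA-LDA and SPA-LDA, and prediction-set
confusion matrices.  Both write plain-CSV reports plus a JSON run summary that
embeds the fully resolved configuration, so identical inputs yield identical
numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import io_formats, snom_signal
from .snom_signal import SpectrumLikeSignal, TransmissionImage

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_snom_pipeline",
    "run_atr_pipeline",
    "run_simulation",
    "snom_report_from_images",
]


@dataclass
class PipelineConfig:
    """Single structured configuration for simulate / snom / atr runs."""

    mode: str
    manifest_path: str | None = None
    spectra_path: str | None = None
    out_dir: str = "snomchemo_out"
    seed: int = 0
    intervals_um: Mapping[str, tuple[float, float]] | None = None
    normal_label: str = "normal"
    average_first: bool = False
    max_components: int = 10
    max_vars: int = 15
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    pca_components_snom: int = 2
    simulate_kind: str = "both"  # snom | atr | both
    snom_config: dict = field(default_factory=dict)
    atr_config: dict = field(default_factory=dict)
    effects: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("snom", "atr", "simulate"):
            raise ValueError("mode must be one of snom, atr, simulate")
        if self.mode == "snom" and not self.manifest_path:
            raise ValueError("snom mode requires manifest_path")
        if self.mode == "atr" and not self.spectra_path:
            raise ValueError("atr mode requires spectra_path")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        if raw.get("intervals_um"):
            raw["intervals_um"] = {
                k: tuple(v) for k, v in raw["intervals_um"].items()
            }
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("intervals_um"):
            d["intervals_um"] = {k: list(v) for k, v in d["intervals_um"].items()}
        d["fractions"] = list(self.fractions)
        return d


def _write_summary(out: Path, config: PipelineConfig, payload: dict) -> None:
    summary = {"config": config.resolved(), "seed": config.seed, **payload}
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# SNOM arm


def _group_signals(
    images: list[TransmissionImage],
) -> dict[tuple[str, str], list[SpectrumLikeSignal]]:
    grouped: dict[tuple[str, str], list[SpectrumLikeSignal]] = {}
    for img in images:
        key = (img.class_label, img.biomarker)
        grouped.setdefault(key, []).append(snom_signal.image_to_signal(img))
    return grouped


def snom_report_from_images(
    images: list[TransmissionImage], config: PipelineConfig
) -> dict:
    """Core SNOM analysis on in-memory images; returns tables keyed by name."""
    grouped = _group_signals(images)
    records = snom_signal.build_area_table(
        grouped,
        intervals=config.intervals_um,
        normal_label=config.normal_label,
        average_first=config.average_first,
    )
    area_table = pd.DataFrame(
        {
            "class": r.class_label,
            "biomarker": r.biomarker,
            "interval_lo_um": r.interval_um[0],
            "interval_hi_um": r.interval_um[1],
            "area": r.area,
            "delta_area_pct": r.delta_area_pct,
        }
        for r in records
    )

    # Per-biomarker PCA on the class-averaged normalized signals (one row per
    # class), mirroring score plots of class separation per biomarker.
    biomarkers = list(dict.fromkeys(k[1] for k in grouped))
    classes = list(dict.fromkeys(k[0] for k in grouped))
    pca_tables: dict[str, pd.DataFrame] = {}
    diag_tables: dict[str, pd.DataFrame] = {}
    explained: dict[str, list[float]] = {}
    for bm in biomarkers:
        rows = []
        for cls in classes:
            reps = grouped[(cls, bm)]
            if config.average_first:
                sig = snom_signal.normalize_signal(
                    snom_signal.average_replicates(reps)
                )
            else:
                sig = snom_signal.average_replicates(
                    [snom_signal.normalize_signal(s) for s in reps]
                )
            rows.append(sig.values)
        X = np.vstack(rows)
        a = min(config.pca_components_snom, len(classes) - 1, X.shape[1])
        pca = chem.fit_pca(X, a)
        diag = chem.diagnostics(pca, X)
        pca_tables[bm] = pd.DataFrame(
            {
                "class": classes,
                **{f"PC{i+1}": pca.scores[:, i] for i in range(a)},
            }
        )
        diag_tables[bm] = pd.DataFrame(
            {
                "class": classes,
                "hotelling_t2": diag.t2_values,
                "q_residual": diag.q_values,
                "t2_limit_95": diag.t2_limit_95,
                "q_limit_95": diag.q_limit_95,
                "outlier": diag.outliers(),
            }
        )
        explained[bm] = [float(v) for v in pca.explained_variance_pct]
    return {
        "area_table": area_table,
        "pca_scores": pca_tables,
        "diagnostics": diag_tables,
        "explained_variance_pct": explained,
    }


def run_snom_pipeline(config: PipelineConfig) -> dict:
    """Manifest → signals → areas/ΔA% → per-biomarker PCA; writes reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        manifest = io_formats.read_manifest(config.manifest_path)
    except Exception as exc:
        raise RuntimeError(f"[stage: read_manifest] {exc}") from exc

    images: list[TransmissionImage] = []
    for _, row in manifest.table.iterrows():
        try:
            pixels = io_formats.read_matrix_text(manifest.resolve(row["file_path"]))
        except Exception as exc:
            raise RuntimeError(f"[stage: read_images] {exc}") from exc
        images.append(
            TransmissionImage(
                pixels=pixels,
                wavelength_um=float(row["wavelength_um"]),
                biomarker=row["biomarker"],
                cell_id=str(row["cell_id"]),
                class_label=str(row["class_label"]),
            )
        )
    try:
        report = snom_report_from_images(images, config)
    except Exception as exc:
        raise RuntimeError(f"[stage: snom_analysis] {exc}") from exc

    report["area_table"].to_csv(out / "area_table.csv", index=False)
    for bm, tbl in report["pca_scores"].items():
        tbl.to_csv(out / f"pca_scores_{bm}.csv", index=False)
    for bm, tbl in report["diagnostics"].items():
        tbl.to_csv(out / f"diagnostics_{bm}.csv", index=False)
    _write_summary(
        out,
        config,
        {
            "n_images": len(images),
            "n_area_records": int(len(report["area_table"])),
            "explained_variance_pct": report["explained_variance_pct"],
        },
    )
    return report


# ---------------------------------------------------------------------------
# ATR arm


def atr_report_from_dataset(dataset: chem.SpectralDataset, config: PipelineConfig) -> dict:
    """Core ATR analysis: KS split, PCA-LDA, SPA-LDA, confusion matrices."""
    split = chem.kennard_stone_split(dataset.intensities, config.fractions)
    ytrue = {
        part: [dataset.class_labels[i] for i in idx]
        for part, idx in (
            ("validation", split.validation_idx),
            ("prediction", split.prediction_idx),
        )
    }
    max_a = min(config.max_components, len(split.train_idx) - 1, dataset.n_variables)
    pcalda = chem.pca_lda_train(dataset, split, max_a)
    Xpred = dataset.intensities[split.prediction_idx]
    pred_pca = chem.predict(pcalda.lda, pcalda.pca.transform(Xpred))
    acc_pca = float(np.mean([p == t for p, t in zip(pred_pca, ytrue["prediction"])]))

    spa = chem.spa_lda_select(dataset, split, config.max_vars)
    pred_spa = chem.predict(spa.model, Xpred[:, list(spa.selected_variables)])
    acc_spa = float(np.mean([p == t for p, t in zip(pred_spa, ytrue["prediction"])]))

    classes = dataset.classes
    return {
        "split": split,
        "pcalda": pcalda,
        "spa": spa,
        "pca_lda_accuracy": acc_pca,
        "spa_lda_accuracy": acc_spa,
        "selected_wavenumbers": [
            float(dataset.variables_axis[j]) for j in spa.selected_variables
        ],
        "confusion_pca_lda": chem.confusion_matrix(
            ytrue["prediction"], pred_pca, classes
        ),
        "confusion_spa_lda": chem.confusion_matrix(
            ytrue["prediction"], pred_spa, classes
        ),
        "classes": classes,
    }


def run_atr_pipeline(config: PipelineConfig) -> dict:
    """Spectra table → KS split → PCA-LDA + SPA-LDA; writes reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        dataset = io_formats.read_spectra_table(config.spectra_path)
    except Exception as exc:
        raise RuntimeError(f"[stage: read_spectra] {exc}") from exc
    if len(dataset.classes) < 2:
        raise RuntimeError("[stage: read_spectra] need at least two classes")
    try:
        report = atr_report_from_dataset(dataset, config)
    except Exception as exc:
        raise RuntimeError(f"[stage: atr_analysis] {exc}") from exc

    split = report["split"]
    split_rows = []
    for part, idx in (
        ("train", split.train_idx),
        ("validation", split.validation_idx),
        ("prediction", split.prediction_idx),
    ):
        for i in idx:
            split_rows.append(
                {
                    "sample_id": dataset.sample_ids[i],
                    "class": dataset.class_labels[i],
                    "set": part,
                }
            )
    pd.DataFrame(split_rows).to_csv(out / "split_assignment.csv", index=False)

    pcalda = report["pcalda"]
    scores_all = pcalda.pca.transform(dataset.intensities)
    df_pca = chem.discriminant_scores(pcalda.lda, scores_all)
    pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "class": dataset.class_labels,
            **{f"DF_{c}": df_pca[:, k] for k, c in enumerate(report["classes"])},
        }
    ).to_csv(out / "pca_lda_scores.csv", index=False)

    spa = report["spa"]
    df_spa = chem.discriminant_scores(
        spa.model, dataset.intensities[:, list(spa.selected_variables)]
    )
    pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "class": dataset.class_labels,
            **{f"DF_{c}": df_spa[:, k] for k, c in enumerate(report["classes"])},
        }
    ).to_csv(out / "spa_lda_scores.csv", index=False)

    pd.DataFrame(
        {
            "variable_index": list(spa.selected_variables),
            "wavenumber_cm1": report["selected_wavenumbers"],
        }
    ).to_csv(out / "selected_wavenumbers.csv", index=False)
    for name in ("confusion_pca_lda", "confusion_spa_lda"):
        pd.DataFrame(
            report[name], index=report["classes"], columns=report["classes"]
        ).to_csv(out / f"{name}.csv")

    _write_summary(
        out,
        config,
        {
            "n_samples": dataset.n_samples,
            "chosen_pcs": report["pcalda"].chosen_a,
            "selected_wavenumbers": report["selected_wavenumbers"],
            "pca_lda_prediction_accuracy": report["pca_lda_accuracy"],
            "spa_lda_prediction_accuracy": report["spa_lda_accuracy"],
        },
    )
    return report


# ---------------------------------------------------------------------------
# Simulation mode


def run_simulation(config: PipelineConfig) -> dict:
    """Generate synthetic datasets and write them in the pipeline's dialects."""
    from . import synthetic

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    if config.simulate_kind in ("snom", "both"):
        sim_cfg = synthetic.SnomSimConfig(**config.snom_config)
        effects = (
            synthetic.ClassEffectTable(effect=config.effects)
            if config.effects
            else synthetic.ClassEffectTable()
        )
        images, manifest = synthetic.generate_snom_dataset(
            sim_cfg, effects, config.seed
        )
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        paths = []
        for img, (_, row) in zip(images, manifest.iterrows()):
            fname = f"{row['class_label']}_{row['biomarker']}_r{row['replicate_id']}.txt"
            io_formats.write_matrix_text(img.pixels, img_dir / fname)
            paths.append(f"images/{fname}")
        manifest = manifest.assign(file_path=paths)
        io_formats.write_manifest(manifest, out / "manifest.csv")
        written["manifest"] = str(out / "manifest.csv")
        written["n_images"] = len(images)
    if config.simulate_kind in ("atr", "both"):
        atr_cfg = synthetic.AtrSimConfig(**config.atr_config)
        dataset = synthetic.generate_atr_dataset(atr_cfg, config.seed)
        io_formats.write_spectra_table(dataset, out / "spectra.csv")
        written["spectra"] = str(out / "spectra.csv")
        written["n_spectra"] = dataset.n_samples
    _write_summary(out, config, {"written": written})
    return written
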