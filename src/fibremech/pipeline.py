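"""Configuration-driven orchestration: simulate a cohort, analyze a dataset
directory across all four modalities, and emit the dose-response report.

Dataset layout: ``<root>/<dye_count>/<fiber_id>.<modality>.txt`` with a
``manifest.csv`` at the root (written by the simulator; analysis falls back
to scanning the layout when no manifest exists).  Per-fiber analysis failures
are logged and skipped; the failure count is reported so callers can flag
partial success.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import force, ftir, io as fio, stats, synthetic, tensile, topography
from .datatypes import TensileCurve
from .errors import AnalysisError, DataFormatError, FibreMechError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "simulate",
    "analyze",
    "report",
    "AnalyzeResult",
    "RECOVERY_MAP",
]

# metric column -> manifest truth column, for the truth-vs-estimate table.
# Restricted to estimators that are unbiased under the default noise model.
RECOVERY_MAP = {
    "step_height_nm": "topo_step_height_mean",
    "stiffness_nN_per_nm": "fd_expected_slope",
    "attraction_nN": "fd_attraction_depth",
    "adhesion_nN": "fd_adhesion_depth",
    "elastic_modulus_MPa": "tensile_elastic_modulus",
    "fracture_strain": "tensile_fracture_strain",
    "amide_I_depth": "ftir_amide_I_depth",
    "water_depth": "ftir_water_depth",
}


class AfmParams(BaseModel):
    flatten_order: int = Field(1, ge=0, le=2)
    min_step_height_nm: float = Field(50.0, gt=0)
    min_terrace_um: float = Field(1.0, gt=0)
    fine_crop_um: float = Field(3.0, gt=0)
    crop_stride_um: float = Field(1.0, gt=0)


class FdParams(BaseModel):
    fit_fraction: float = Field(0.7, gt=0, le=1)
    use_retract_for_stiffness: bool = False


class TensileParams(BaseModel):
    subtract_gauge: bool = False


class FtirParams(BaseModel):
    band_table: str = "default8"
    smooth_width: int = Field(1, ge=1)


class SimulateParams(BaseModel):
    n_fibers: int = Field(25, ge=2)


class RunConfig(BaseModel):
    """Validated run configuration (YAML or JSON on disk)."""

    dataset_root: str
    output_dir: str = "fibremech_out"
    seed: int = 0
    modalities: list[str] = Field(default_factory=lambda: list(synthetic.MODALITIES))
    log_level: str = "INFO"
    simulate: SimulateParams = SimulateParams()
    afm: AfmParams = AfmParams()
    fd: FdParams = FdParams()
    tensile: TensileParams = TensileParams()
    ftir: FtirParams = FtirParams()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; schema violations are reported
    with their field paths."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise DataFormatError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise DataFormatError(f"{path}: invalid config ({locs})") from exc


# ------------------------------------------------------------------ simulate

def simulate(config: RunConfig) -> pd.DataFrame:
    """Generate the default dose-response cohort under ``dataset_root`` and
    write a config snapshot next to the manifest."""
    cohort = synthetic.paper_trend_cohort(
        n_fibers=config.simulate.n_fibers, seed=config.seed
    )
    manifest = synthetic.gen_cohort(cohort, config.dataset_root)
    snapshot = Path(config.dataset_root) / "config_snapshot.yaml"
    snapshot.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    logger.info("simulated %d fibers under %s", len(manifest), config.dataset_root)
    return manifest


# ------------------------------------------------------------------- analyze

@dataclass
class AnalyzeResult:
    features: pd.DataFrame
    failures: int
    failed_fibers: list[str] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.failures == 0


def _scan_layout(root: Path) -> pd.DataFrame:
    rows = []
    for gdir in sorted(root.iterdir()):
        if not gdir.is_dir() or not gdir.name.isdigit():
            continue
        dye = int(gdir.name)
        fiber_ids = sorted({p.name.split(".")[0] for p in gdir.glob("*.txt")})
        for fid in fiber_ids:
            row: dict[str, object] = {"fiber_id": fid, "dye_count": dye}
            for m in synthetic.MODALITIES:
                p = gdir / f"{fid}.{m}.txt"
                if p.exists():
                    row[f"{m}_path"] = str(p.relative_to(root))
            rows.append(row)
    return pd.DataFrame(rows)


def _analyze_topo(path: Path, params: AfmParams) -> dict[str, float]:
    image = fio.read_topography_txt(path)
    profile = topography.extract_profile(image, (0, image.shape[0]))
    events = topography.detect_steps(
        profile, params.min_step_height_nm, params.min_terrace_um
    )
    out: dict[str, float] = {
        "step_height_nm": float(np.mean([e.height for e in events])) if events else np.nan,
        "n_steps": float(len(events)),
    }
    coarse = topography.roughness(image, params.flatten_order)
    out["sa_coarse_nm"] = coarse.Sa
    out["sz_coarse_nm"] = coarse.Sz
    fine = topography.best_terrace_crop(
        image, params.fine_crop_um, params.crop_stride_um, params.flatten_order
    )
    fine_r = topography.roughness(fine, params.flatten_order)
    out["sa_fine_nm"] = fine_r.Sa
    out["sz_fine_nm"] = fine_r.Sz
    return out


def _analyze_fd(path: Path, params: FdParams) -> dict[str, float]:
    curve = fio.read_fd_txt(path)
    feats = force.extract_features(
        curve, params.fit_fraction, params.use_retract_for_stiffness
    )
    return {
        "stiffness_nN_per_nm": feats.stiffness,
        "sample_stiffness_nN_per_nm": feats.sample_stiffness,
        "attraction_nN": feats.attraction,
        "adhesion_nN": feats.adhesion,
        "fd_fit_r2": feats.fit_quality,
    }


def _analyze_tensile(path: Path, params: TensileParams) -> dict[str, float]:
    strain, force_mN, diameter, gauge = fio.read_tensile_txt(path)
    stress = tensile.compute_stress(
        force_mN, diameter, gauge_force_mN=gauge, subtract_gauge=params.subtract_gauge
    )
    curve = TensileCurve(strain, stress, diameter, gauge_force=gauge, source_id=path.stem)
    feats = tensile.extract_features(curve)
    return {
        "elastic_modulus_MPa": feats.elastic_modulus,
        "yield_stress_MPa": feats.yield_stress,
        "yield_strain": feats.yield_bounds[0],
        "fracture_stress_MPa": feats.fracture_stress,
        "fracture_strain": feats.fracture_strain,
    }


def _analyze_ftir(path: Path, params: FtirParams) -> dict[str, float]:
    if params.band_table != "default8":
        raise InvalidParameterError(f"unknown band table {params.band_table!r}")
    spectrum = fio.read_spectrum_txt(path)
    quants = ftir.quantify_all(spectrum, ftir.DEFAULT_BANDS, smooth_width=params.smooth_width)
    out: dict[str, float] = {}
    for q in quants:
        out[f"{q.name}_depth"] = q.depth
        out[f"{q.name}_center"] = q.center
        out[f"{q.name}_present"] = float(q.present)
    return out


_ANALYZERS = {
    "topo": lambda path, cfg: _analyze_topo(path, cfg.afm),
    "fd": lambda path, cfg: _analyze_fd(path, cfg.fd),
    "tensile": lambda path, cfg: _analyze_tensile(path, cfg.tensile),
    "ftir": lambda path, cfg: _analyze_ftir(path, cfg.ftir),
}


def analyze(config: RunConfig, modalities: list[str] | None = None) -> AnalyzeResult:
    """Run the enabled analyzers over every fiber of the dataset.

    Per-fiber failures are logged with the offending file and skipped; the
    returned failure count is nonzero on partial success.
    """
    root = Path(config.dataset_root)
    if not root.exists():
        raise FibreMechError(f"dataset root {root} does not exist")
    manifest_path = root / "manifest.csv"
    index = fio.read_manifest(manifest_path) if manifest_path.exists() else _scan_layout(root)
    if index.empty:
        raise FibreMechError(f"no fibers found under {root}")
    modalities = modalities or config.modalities

    rows = []
    failures: list[str] = []
    for _, entry in index.iterrows():
        row: dict[str, object] = {
            "fiber_id": entry["fiber_id"],
            "dye_count": int(entry["dye_count"]),
        }
        for m in modalities:
            col = f"{m}_path"
            if col not in entry or pd.isna(entry[col]):
                continue
            path = root / str(entry[col])
            try:
                row.update(_ANALYZERS[m](path, config))
            except (FibreMechError, OSError, ValueError) as exc:
                failures.append(f"{entry['fiber_id']}:{m}")
                logger.warning("fiber %s %s failed: %s", entry["fiber_id"], m, exc)
        rows.append(row)
    features = pd.DataFrame(rows)
    result = AnalyzeResult(features=features, failures=len(failures), failed_fibers=failures)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    features.to_csv(outdir / "features.csv", index=False)
    logger.info(
        "analyzed %d fibers (%d failures) -> %s", len(features), len(failures), outdir
    )
    return result


# -------------------------------------------------------------------- report

def report(
    config: RunConfig, features: pd.DataFrame | None = None
) -> dict[str, object]:
    """Dose-response report over the analyzed features.

    Emits one CSV per metric plus a human-readable summary; when the dataset
    has a generator manifest, a truth-vs-estimate recovery table is included.
    """
    outdir = Path(config.output_dir)
    if features is None:
        feat_path = outdir / "features.csv"
        if not feat_path.exists():
            raise FibreMechError(f"no feature table at {feat_path}; run analyze first")
        features = pd.read_csv(feat_path)

    manifest_path = Path(config.dataset_root) / "manifest.csv"
    manifest = fio.read_manifest(manifest_path) if manifest_path.exists() else None

    result = stats.dose_response_report(
        features,
        manifest=manifest,
        recovery_map=RECOVERY_MAP if manifest is not None else None,
    )
    report_dir = outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    lines = ["dose-response report", "===================="]
    for metric, table in result["tables"].items():
        table.to_csv(report_dir / f"{metric}.csv", index=False)
        lines.append(f"\n{metric}:")
        lines.append(table.to_string(index=False))
    recovery = result["recovery"]
    if recovery is not None and not recovery.empty:
        recovery.to_csv(report_dir / "recovery.csv", index=False)
        lines.append("\ntruth recovery (|rel_error| should be small):")
        lines.append(recovery.to_string(index=False))
    (report_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", report_dir)
    return result
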