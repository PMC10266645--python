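"""End-to-end workflow: preprocess -> feature routes -> split -> fit -> evaluate.

Feature routes mirror the comparative design of the study this package
re-implements:

* ``SI``   — optimal spectral-index tables (13 columns for k=1, 37 for k=3);
* ``full`` — every band of one spectral representation;
* ``CARS`` — the characteristic bands CARS selects per representation.

Each enabled route x representation x model family yields one report row
(R²/RMSE for calibration and validation, RPD, LCCC).  A single global seed
fans out to per-stage seeds through fixed offsets, so any stage can be
re-run reproducibly on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cars import CARSConfig, CARSResult, run_cars
from .exceptions import ParameterError
from .indices import assemble_si_features, index_defs_to_frame
from .io import read_spectra_table
from .metrics import evaluate_predictions
from .modeling import ModelSpec, SplitResult, fit_predict_model, kennard_stone_split
from .spectra import SoilSampleTable, SpectrumSet, all_transforms
from .synthetic import SyntheticConfig, generate_soil_spectra

log = logging.getLogger("somspec")

TRANSFORMS = ("R", "LR", "CR", "FDR")
ROUTES = ("SI", "full", "CARS")

# fixed per-stage seed offsets (global_seed + offset, kept below 2^31)
_SEED_SYNTH = 0
_SEED_CARS = 100  # + transform index
_SEED_MODEL = 200  # + model index


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    transforms: tuple = TRANSFORMS
    index_k: tuple = (1, 3)
    cars: CARSConfig = field(default_factory=CARSConfig)
    split_fraction: float = 133.0 / 178.0
    models: tuple = ("RF", "SVR", "DNN", "PLSR")
    model_grids: dict = field(default_factory=dict)  # method -> grid override
    routes: tuple = ROUTES
    band_step: int = 1
    selection_mode: str = "all-samples"  # or "calibration-only" (strict)
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.input_path is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed % 2**31)
        if not self.routes or not self.models:
            raise ParameterError("need at least one route and one model")
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError("split_fraction must lie in (0, 1)")
        if self.selection_mode not in ("all-samples", "calibration-only"):
            raise ParameterError("selection_mode must be 'all-samples' or 'calibration-only'")
        for r in self.routes:
            if r not in ROUTES:
                raise ParameterError(f"unknown route {r!r}")
        for t in self.transforms:
            if t not in TRANSFORMS:
                raise ParameterError(f"unknown transform {t!r}")


@dataclass
class ReportBundle:
    rows: list  # one dict per route x transform x model
    index_defs: dict  # k -> list of SpectralIndexDef
    cars_results: dict  # transform -> CARSResult
    split: SplitResult = None
    provenance: dict = field(default_factory=dict)

    @property
    def report(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _config_dict(cfg: RunConfig) -> dict:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (tuple, list)):
            return [enc(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o

    return enc(cfg)


def _provenance(cfg: RunConfig) -> dict:
    import sklearn

    cfg_json = json.dumps(_config_dict(cfg), sort_keys=True, default=str)
    return {
        "config": _config_dict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "selection_mode": cfg.selection_mode,
        "selection_uses_all_samples": cfg.selection_mode == "all-samples",
        "versions": {
            "somspec": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def run_full_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute every enabled stage; returns (and optionally writes) the bundle."""
    t0 = _stage("load")
    if cfg.input_path is not None:
        raw, som = read_spectra_table(cfg.input_path)
    else:
        raw, som = generate_soil_spectra(
            dataclasses.replace(cfg.synthetic, seed=(cfg.seed + _SEED_SYNTH) % 2**31)
        )
    log.info("loaded %d samples x %d bands (%.2fs)", raw.n_samples, raw.n_bands,
             time.perf_counter() - t0)

    t0 = _stage("preprocess")
    spectra = all_transforms(raw)
    log.info("transforms done: %d bands (%.2fs)", spectra["R"].n_bands,
             time.perf_counter() - t0)

    t0 = _stage("split")
    n_cal = int(round(cfg.split_fraction * raw.n_samples))
    split = kennard_stone_split(spectra["R"].values, n_cal, spectra["R"].sample_ids)
    cal_idx = [spectra["R"].sample_ids.index(i) for i in split.calibration_ids]
    val_idx = [spectra["R"].sample_ids.index(i) for i in split.validation_ids]
    y = som.som_g_per_kg
    y_cal, y_val = y[cal_idx], y[val_idx]
    log.info("Kennard-Stone split %d/%d (%.2fs)", len(cal_idx), len(val_idx),
             time.perf_counter() - t0)

    # --- feature routes -----------------------------------------------------
    feature_sets: list[tuple[str, np.ndarray]] = []  # (tag, samples x features)
    index_defs: dict = {}
    cars_results: dict = {}

    if "SI" in cfg.routes:
        t0 = _stage("indices")
        if cfg.selection_mode == "calibration-only":
            sel_spectra = {
                t: SpectrumSet([s.sample_ids[i] for i in cal_idx], s.wavelengths_nm,
                               s.values[cal_idx], s.transform_tag)
                for t, s in spectra.items()
            }
            sel_som = SoilSampleTable([som.sample_ids[i] for i in cal_idx], y_cal)
        else:
            sel_spectra, sel_som = spectra, som
        for k in cfg.index_k:
            frame, defs = assemble_si_features(sel_spectra, sel_som, k=k,
                                               band_step=cfg.band_step)
            index_defs[k] = defs
            # recompute columns on ALL samples from the stored definitions
            from .indices import compute_index_column

            cols = np.column_stack([compute_index_column(d, spectra) for d in defs])
            tag = "SI" if k == 1 else f"SI{k}"
            feature_sets.append((tag, cols))
        log.info("index routes done (%.2fs)", time.perf_counter() - t0)

    if "full" in cfg.routes:
        for t in cfg.transforms:
            s = spectra[t].select_bands(cfg.band_step) if cfg.band_step != 1 else spectra[t]
            feature_sets.append((t, s.values))

    if "CARS" in cfg.routes:
        for ti, t in enumerate(cfg.transforms):
            t0 = _stage(f"cars-{t}")
            s = spectra[t].select_bands(cfg.band_step) if cfg.band_step != 1 else spectra[t]
            ccfg = dataclasses.replace(
                cfg.cars, seed=(cfg.seed + _SEED_CARS + ti) % 2**31
            )
            res = run_cars(s.values[cal_idx], y_cal, ccfg, s.wavelengths_nm)
            cars_results[t] = res
            sel = np.isin(s.wavelengths_nm, res.best_bands_nm)
            feature_sets.append((f"CARS-{t}", s.values[:, sel]))
            log.info("CARS %s: %d bands, RMSECV %.3f (%.2fs)", t,
                     res.best_bands_nm.size, res.rmsecv_trace[res.best_run],
                     time.perf_counter() - t0)

    # --- fit and evaluate ----------------------------------------------------
    rows = []
    for fi, (ftag, feats) in enumerate(feature_sets):
        for mi, method in enumerate(cfg.models):
            t0 = _stage(f"fit {ftag}-{method}")
            spec = ModelSpec(
                method,
                grid=cfg.model_grids.get(method),
                seed=(cfg.seed + _SEED_MODEL + 10 * fi + mi) % 2**31,
            )
            fit = fit_predict_model(spec, feats[cal_idx], y_cal, feats[val_idx])
            rep = evaluate_predictions(y_val, fit.pred_val, y_cal, fit.pred_cal)
            row = {"model": f"{ftag}-{method}", "n_features": feats.shape[1]}
            row.update(rep.as_dict())
            row["best_params"] = json.dumps(fit.best_params, sort_keys=True, default=str)
            rows.append(row)
            log.info("%s: R2_val %.3f RPD %.2f (%.2fs)", row["model"],
                     rep.r2_val, rep.rpd, time.perf_counter() - t0)

    bundle = ReportBundle(rows, index_defs, cars_results, split, _provenance(cfg))
    if cfg.out_dir:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write the report bundle as CSV/JSON files (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.report.to_csv(out / "report.csv", index=False, float_format="%.6g")
    for k, defs in bundle.index_defs.items():
        index_defs_to_frame(defs).to_csv(
            out / f"selected_indexes_k{k}.csv", index=False, float_format="%.6g"
        )
    for t, res in bundle.cars_results.items():
        pd.DataFrame({"wavelength_nm": res.best_bands_nm}).to_csv(
            out / f"cars_bands_{t}.csv", index=False
        )
        trace = {
            "retained_ratio": list(res.retained_ratio_trace),
            "rmsecv": list(res.rmsecv_trace),
            "subset_size": [len(s) for s in res.subset_trace],
            "best_run": res.best_run,
        }
        (out / f"cars_trace_{t}.json").write_text(json.dumps(trace, indent=1))
    if bundle.split is not None:
        pd.DataFrame(
            {
                "sample_id": bundle.split.calibration_ids + bundle.split.validation_ids,
                "set": ["calibration"] * len(bundle.split.calibration_ids)
                + ["validation"] * len(bundle.split.validation_ids),
            }
        ).to_csv(out / "split.csv", index=False)
    (out / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=1, sort_keys=True, default=str)
    )
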