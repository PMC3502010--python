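"""End-to-end pipeline: denoise -> segment -> features -> select/classify.

``run_pipeline`` consumes a configuration mapping (typically loaded from
YAML), executes the requested stages, writes every intermediate artifact
into the output directory together with a provenance record (package
version, configuration hash, seeds), and returns the in-memory results.
All randomness derives from the single global seed through named
per-stage substreams, so a re-run with the same configuration is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .classify import SvmConfig, loocv
from .diffusion import DiffusionParams, edge_enhanced_diffusion
from .errors import NodemorphError, ParameterError
from .gvf_snake import SnakeParams, initialize_contour, segment
from .io_utils import (config_hash, read_contour_csv, read_image, save_json,
                       write_contour_csv, write_features_csv, write_image,
                       write_mask)
from .morphometry import extract_features
from .selection import SelectionConfig, select_features
from .synthetic import PhantomSpec, add_gaussian_noise, make_node_phantom

logger = logging.getLogger("nodemorph")

__all__ = ["run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream seed derived from the global seed (stable, < 2^31)."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2 ** 31)
    return (global_seed * 1_000_003 + h) % (2 ** 31)


def _validate(config: dict) -> None:
    if "output_dir" not in config:
        raise ParameterError("config requires 'output_dir'")
    stages = config.get("stages", [])
    if "segment" in stages:
        seg = config.get("segment", {})
        if "init_contour" not in seg and "seed_circle" not in seg:
            raise ParameterError(
                "segment stage requires 'init_contour' or 'seed_circle'")
        for key in ("init_contour",):
            if key in seg and not Path(seg[key]).exists():
                raise ParameterError(f"missing file: {seg[key]}")
    if "input_image" in config and not Path(config["input_image"]).exists():
        raise ParameterError(f"missing file: {config['input_image']}")


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; see the package README for the schema.

    Recognized stages (in execution order): ``denoise``, ``segment``,
    ``features``, ``select``, ``classify``.  The input image comes from
    ``input_image`` (a file) or ``simulate`` (a phantom specification).
    Returns a dict of in-memory results; artifacts and ``provenance.json``
    are written under ``output_dir``.  A stage failure aborts the run but
    leaves completed artifacts and an error manifest behind.
    """
    _validate(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["denoise", "segment", "features"])
    results: dict = {"config_hash": config_hash(config), "seed": seed}
    provenance = {
        "version": __version__,
        "config": config,
        "config_hash": results["config_hash"],
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in stages},
    }

    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    logger.setLevel(config.get("log_level", "INFO"))
    try:
        image, spacing = _load_input(config, seed)
        results["spacing"] = spacing

        if "denoise" in stages:
            logger.info("stage denoise")
            params = DiffusionParams(**config.get("denoise", {}))
            image = edge_enhanced_diffusion(image, params)
            write_image(outdir / "denoised.tif", image)
        mask = None
        if "segment" in stages:
            logger.info("stage segment")
            seg_cfg = dict(config.get("segment", {}))
            if "init_contour" in seg_cfg:
                init = read_contour_csv(seg_cfg.pop("init_contour"))
            else:
                x, y, r = seg_cfg.pop("seed_circle")
                init = initialize_contour((float(x), float(y)), float(r))
            repulsive = seg_cfg.pop("repulsive", True)
            sigma0 = seg_cfg.pop("sigma0", 1.0)
            params = SnakeParams(**seg_cfg)
            contour, mask = segment(image, init, params, sigma0=sigma0,
                                    repulsive=repulsive)
            write_contour_csv(outdir / "contour.csv", contour)
            write_mask(outdir / "mask.png", mask)
            results["contour"] = contour
            results["mask"] = mask
        if "features" in stages:
            logger.info("stage features")
            if mask is None:
                raise ParameterError("features stage requires a segmentation")
            feats = extract_features(image, mask, spacing=spacing)
            write_features_csv(outdir / "features.csv", [feats])
            results["features"] = feats
        if "select" in stages or "classify" in stages:
            table_cfg = config.get("table")
            if table_cfg is None:
                raise ParameterError(
                    "select/classify stages require a 'table' block")
            X, y = _load_table(table_cfg)
            svm = SvmConfig(**config.get("svm", {}))
            if "select" in stages:
                logger.info("stage select")
                sel_cfg = SelectionConfig(
                    seed=stage_seed(seed, "select"), svm=svm,
                    **config.get("select", {}))
                state = select_features(X, y, sel_cfg)
                results["selection"] = state
                save_json(outdir / "selection.json", {
                    "active_features": state.active_features,
                    "removed_features": state.removed_features,
                    "importances": state.importances,
                    "loss_history": state.loss_history,
                    "seed": state.rng_seed,
                })
            if "classify" in stages:
                logger.info("stage classify")
                active = (results["selection"].active_features
                          if "selection" in results else list(X.columns))
                metrics = loocv(X, y, active, svm)
                results["metrics"] = metrics
                save_json(outdir / "report.json", {
                    "metrics": metrics.as_dict(),
                    "active_features": active,
                    "seed": seed,
                })
        save_json(outdir / "provenance.json", provenance)
    except NodemorphError as exc:
        save_json(outdir / "error_manifest.json", {
            "error": str(exc),
            "type": type(exc).__name__,
            "completed": sorted(p.name for p in outdir.iterdir()),
        })
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results


def _load_input(config: dict, seed: int):
    if "input_image" in config:
        img = read_image(config["input_image"])
        return img.pixels, img.spacing
    sim = config.get("simulate")
    if sim is None:
        return None, 1.0
    spec = PhantomSpec(**sim.get("phantom", {}))
    image, _ = make_node_phantom(spec, seed=stage_seed(seed, "simulate"))
    if sim.get("snr_db") is not None:
        image = add_gaussian_noise(image, float(sim["snr_db"]),
                                   seed=stage_seed(seed, "noise"))
    return image, 1.0


def _load_table(table_cfg: dict):
    import pandas as pd

    df = pd.read_csv(table_cfg["path"])
    label_col = table_cfg.get("label_col", "label")
    y = df[label_col].to_numpy(dtype=int)
    X = df.drop(columns=[label_col] + table_cfg.get("drop", []))
    return X, y
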