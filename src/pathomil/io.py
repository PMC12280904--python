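"""Cohort/feature/model persistence and the end-to-end pipeline runner.

All artifacts are plain text (CSV/JSON) except CNN checkpoints (npz).
Feature matrices serialize floats with 17 significant digits, and model
JSON uses Python's shortest-round-trip float repr, so read(write(x))
reproduces values bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CohortSchemaError, SlideLikelihoods
from .mil import FUSED_NAMES, BoWVocabulary, encode_cohort
from .patch_model import (EXCLUDED, LRScheduleConfig, TrainConfig, assign_weak_labels,
                          infer_slide_likelihoods, load_checkpoint, save_checkpoint,
                          train_patch_classifier)
from .signature import (SignatureModel, fit_lasso_cox, published_signature,
                        score_slides, select_cutoff, stratify)

logger = logging.getLogger("pathomil")

__all__ = [
    "read_cohort",
    "write_features",
    "read_features",
    "save_model",
    "load_model",
    "PipelineConfig",
    "run_pipeline",
]

_SCHEMA_VERSION = 1
_REQUIRED_COHORT_COLUMNS = ("slide_id", "time", "event")


def read_cohort(path: str | Path, time_col: str = "time",
                event_col: str = "event") -> pd.DataFrame:
    """Read and validate a cohort CSV (slide_id, time, event, covariates...).

    Raises :class:`CohortSchemaError` naming the offending column/row for
    missing columns, non-positive times, non-binary events, or duplicate
    slide ids.
    """
    df = pd.read_csv(path)
    for col in ("slide_id", time_col, event_col):
        if col not in df.columns:
            raise CohortSchemaError(f"missing required column: {col!r}")
    dupes = df["slide_id"][df["slide_id"].duplicated()].tolist()
    if dupes:
        raise CohortSchemaError(f"duplicate slide_id: {dupes[0]!r}")
    bad_time = df.index[df[time_col] <= 0].tolist()
    if bad_time:
        raise CohortSchemaError(f"non-positive time in column {time_col!r}, row {bad_time[0]}")
    bad_event = df.index[~df[event_col].isin((0, 1))].tolist()
    if bad_event:
        raise CohortSchemaError(f"non-binary event in column {event_col!r}, row {bad_event[0]}")
    df["slide_id"] = df["slide_id"].astype(str)
    return df


def write_features(path: str | Path, X: pd.DataFrame) -> None:
    """Write a 206-column feature matrix (first column slide_id)."""
    if list(X.columns) != FUSED_NAMES:
        raise ValueError("feature matrix must carry the 206 canonical columns in order")
    X.to_csv(path, index=True, index_label="slide_id", float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix, restoring canonical column order by name."""
    X = pd.read_csv(path, index_col="slide_id", float_precision="round_trip")
    missing = set(FUSED_NAMES) - set(X.columns)
    extra = set(X.columns) - set(FUSED_NAMES)
    if missing or extra:
        raise ValueError(f"feature matrix has {len(X.columns)} columns; "
                         f"missing={sorted(missing)[:3]} extra={sorted(extra)[:3]}")
    X.index = X.index.astype(str)
    return X[FUSED_NAMES]


def save_model(path: str | Path, model: SignatureModel) -> None:
    """Persist a signature model (and its BoW vocabulary) as JSON."""
    vocab = model.vocabulary
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "features": list(model.features),
        "coefficients": [float(c) for c in model.coefficients],
        "lambda": model.lambda_,
        "cutoff": model.cutoff,
        "provenance": model.provenance,
        "vocabulary": None if vocab is None else {
            "document_frequency": [float(v) for v in vocab.document_frequency],
            "n_slides": int(vocab.n_slides),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> SignatureModel:
    """Load a signature model saved by :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version: {version!r}")
    vocab = payload.get("vocabulary")
    return SignatureModel(
        features=tuple(payload["features"]),
        coefficients=np.array(payload["coefficients"], dtype=float),
        lambda_=payload["lambda"],
        cutoff=payload["cutoff"],
        provenance=payload["provenance"],
        vocabulary=None if vocab is None else BoWVocabulary(
            document_frequency=np.array(vocab["document_frequency"]),
            n_slides=vocab["n_slides"],
        ),
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    slides_dir: str
    cohort_csv: str
    out_dir: str
    tile_size: int = 64
    min_tissue_fraction: float = 0.5
    stain_normalize: bool = False
    downsample: int = 1
    epochs: int = 8
    batch_size: int = 32
    channels: tuple[int, ...] = (8, 16, 32)
    horizon_months: float = 60.0
    cutoff: str = "auto"           # auto | published | <float as str>
    eval_horizons: tuple[float, ...] = (36.0, 60.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "channels" in data:
            data["channels"] = tuple(data["channels"])
        if "eval_horizons" in data:
            data["eval_horizons"] = tuple(data["eval_horizons"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str, started: float, outputs: list[Path]) -> None:
    manifest["stages"].append({
        "stage": name,
        "elapsed_s": round(_time.monotonic() - started, 3),
        "outputs": {str(p): _sha256(p) for p in outputs if p.is_file()},
    })
    logger.info("stage %s done (%d outputs)", name, len(outputs))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run tile -> train -> infer -> encode -> fit -> score -> stratify ->
    evaluate -> explain, persisting every artifact under ``config.out_dir``.

    Returns the run manifest (also written to ``run_manifest.json``).
    """
    from PIL import Image

    from . import interpret, preprocess, surv_eval

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slides_dir = Path(config.slides_dir)
    cohort_path = Path(config.cohort_csv)
    if not slides_dir.is_dir():
        raise FileNotFoundError(f"slides directory not found: {slides_dir}")
    if not cohort_path.is_file():
        raise FileNotFoundError(f"cohort file not found: {cohort_path}")
    cohort = read_cohort(cohort_path)
    manifest: dict = {"config": asdict(config), "stages": []}

    # -- tile ---------------------------------------------------------------
    t0 = _time.monotonic()
    tiles_by_slide: dict[str, list] = {}
    manifest_rows = []
    ref = None
    for img_path in sorted(slides_dir.glob("*.png")) + sorted(slides_dir.glob("*.tif*")):
        sid = img_path.stem
        image = np.asarray(Image.open(img_path).convert("RGB"))
        mask = preprocess.compute_tissue_mask(image, downsample=config.downsample)
        patches = preprocess.tile_slide(image, mask, slide_id=sid,
                                        tile_size=config.tile_size,
                                        min_tissue_fraction=config.min_tissue_fraction)
        if config.stain_normalize:
            normed = []
            for p in patches:
                try:
                    if ref is None:
                        ref = preprocess.estimate_stain_reference(p)
                    normed.append(preprocess.macenko_normalize(p, ref))
                except preprocess.StainEstimationError:
                    normed.append(p)
            patches = normed
        tiles_by_slide[sid] = patches
        for p in patches:
            frac = mask.tissue_fraction_per_tile.get((p.grid_row, p.grid_col), np.nan)
            manifest_rows.append({"slide_id": sid, "row": p.grid_row, "col": p.grid_col,
                                  "x": p.origin_xy[0], "y": p.origin_xy[1],
                                  "tissue_fraction": frac})
    tiles_manifest = pd.DataFrame(manifest_rows)
    tiles_manifest.to_csv(out / "tiles_manifest.csv", index=False)
    _stage(manifest, "tile", t0, [out / "tiles_manifest.csv"])

    # -- train --------------------------------------------------------------
    t0 = _time.monotonic()
    labels = assign_weak_labels(cohort, horizon_months=config.horizon_months)
    train_patches, train_labels = [], []
    for sid, patches in tiles_by_slide.items():
        lbl = labels.get(sid)
        if lbl is EXCLUDED or lbl is None:
            continue
        train_patches.extend(patches)
        train_labels.extend([lbl] * len(patches))
    lr_cfg = LRScheduleConfig(t_i=config.epochs)
    train_cfg = TrainConfig(batch_size=config.batch_size, seed=config.seed,
                            channels=config.channels)
    clf = train_patch_classifier(train_patches, np.array(train_labels), train_cfg, lr_cfg)
    save_checkpoint(out / "patch_model.npz", clf)
    _stage(manifest, "train", t0, [out / "patch_model.npz"])

    # -- infer --------------------------------------------------------------
    t0 = _time.monotonic()
    lik_dir = out / "likelihoods"
    lik_dir.mkdir(exist_ok=True)
    bags = []
    for sid in cohort["slide_id"]:
        patches = tiles_by_slide.get(sid, [])
        if not patches:
            continue
        bag = infer_slide_likelihoods(clf, patches)
        bags.append(bag)
        pd.DataFrame({
            "row": [p.grid_row for p in patches], "col": [p.grid_col for p in patches],
            "prob_pos": bag.probabilities, "pred_label": bag.predicted_labels,
        }).to_csv(lik_dir / f"{sid}.csv", index=False)
    _stage(manifest, "infer", t0, sorted(lik_dir.glob("*.csv")))

    # -- encode -------------------------------------------------------------
    t0 = _time.monotonic()
    X, vocab = encode_cohort(bags)
    write_features(out / "features.csv", X)
    _stage(manifest, "encode", t0, [out / "features.csv"])

    # -- fit ----------------------------------------------------------------
    t0 = _time.monotonic()
    sub = cohort.set_index("slide_id").loc[X.index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_lasso_cox(X, sub["time"].to_numpy(), sub["event"].to_numpy(),
                              seed=config.seed, ensure_nonzero=True)
    model = SignatureModel(features=model.features, coefficients=model.coefficients,
                           lambda_=model.lambda_, cutoff=model.cutoff,
                           provenance=model.provenance, vocabulary=vocab)
    # -- score --------------------------------------------------------------
    scores = score_slides(model, X)
    scores.to_frame().to_csv(out / "scores.csv")

    # -- stratify -----------------------------------------------------------
    if config.cutoff == "auto":
        cut = select_cutoff(scores, sub["time"].to_numpy(), sub["event"].to_numpy())
    elif config.cutoff == "published":
        cut = published_signature().cutoff
    else:
        cut = float(config.cutoff)
    model = model.with_cutoff(cut)
    save_model(out / "model.json", model)
    groups = stratify(scores, cut)
    groups.to_frame().to_csv(out / "groups.csv")
    _stage(manifest, "fit+score+stratify", t0,
           [out / "model.json", out / "scores.csv", out / "groups.csv"])

    # -- evaluate -----------------------------------------------------------
    t0 = _time.monotonic()
    tt, ee = sub["time"].to_numpy(), sub["event"].to_numpy()
    high = (groups == "high").to_numpy()
    report: dict = {"seed": config.seed, "n_slides": int(len(X)), "cutoff": cut,
                    "lambda": model.lambda_, "n_nonzero": model.n_nonzero}
    if high.any() and (~high).any() and ee.sum() >= 1:
        stat, p = surv_eval.logrank_test(tt, ee, groups.to_numpy())
        report["logrank"] = {"statistic": stat, "p": p}
        tau = min(config.horizon_months, float(tt[high].max()), float(tt[~high].max()))
        report["rmst"] = surv_eval.rmst_difference(tt[high], ee[high], tt[~high], ee[~high], tau)
    report["c_index"] = surv_eval.harrell_c(scores.to_numpy(), tt, ee)
    if "treatment" in sub.columns and sub["treatment"].nunique() == 2:
        work = pd.DataFrame({"time": tt, "event": ee, "high": high.astype(int),
                             "treatment": sub["treatment"].to_numpy()})
        try:
            report["interaction"] = surv_eval.interaction_test(work, "high", "treatment")
        except Exception as exc:  # noqa: BLE001 - degenerate cells must not kill the run
            report["interaction"] = {"error": str(exc)}
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    _stage(manifest, "evaluate", t0, [out / "report.json"])

    # -- explain ------------------------------------------------------------
    t0 = _time.monotonic()
    ranking = interpret.shap_global_ranking(model, X)
    ranking.to_csv(out / "shap_ranking.csv")
    if bags:
        overlay = interpret.render_slide_heatmap(
            bags[0], tiles_manifest[tiles_manifest["slide_id"] == bags[0].slide_id],
            tile_size=config.tile_size)
        Image.fromarray(overlay).save(out / "heatmap_example.png")
    _stage(manifest, "explain", t0, [out / "shap_ranking.csv"])

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
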