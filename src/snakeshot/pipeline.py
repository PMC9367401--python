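"""End-to-end orchestration: detector boxes → snake contours, and the n-shot study."""

from __future__ import annotations

import numpy as np

from . import detector as det
from . import evaluation, geometry, snake
from .config import RunConfig
from .detector import ClassSplit, DetectorModel
from .evaluation import Detection, EvalResult

__all__ = ["segment_image", "run_full_pipeline", "run_nshot_study", "predictions_for_split"]


def segment_image(image: np.ndarray, detections: list[Detection], snake_params: dict,
                  snake_cfg) -> list[dict]:
    """Deform every detection's box into a contour; one output per detection."""
    out = []
    if not detections:
        return out
    grid = snake.extract_features(snake_params, image, snake_cfg)
    for d in detections:
        contour = snake.segment_instance(d.box, grid, snake_params, snake_cfg)
        out.append({"contour": contour, "category_id": d.category_id,
                    "score": d.score, "box": d.box})
    return out


def run_full_pipeline(image: np.ndarray, detector_model, snake_params: dict,
                      cfg: RunConfig, oracle_detections: list[Detection] | None = None,
                      image_id: int = -1) -> list[dict]:
    """Detect (or take oracle boxes) then contour-approximate each instance."""
    if oracle_detections is not None:
        dets = oracle_detections
    else:
        if detector_model is None:
            raise ValueError("no detector model and no oracle detections supplied")
        dets = det.detect(detector_model, image, image_id=image_id)
    return segment_image(image, dets, snake_params, cfg.snake)


def predictions_for_split(model: DetectorModel, dataset, split: str = "val",
                          score_threshold: float = 0.05) -> list[Detection]:
    preds: list[Detection] = []
    for image_id in dataset.image_ids(split):
        im = dataset.image_by_id(image_id)
        preds.extend(det.detect(model, im["pixels"], score_threshold=score_threshold,
                                image_id=image_id))
    return preds


def _class_restricted(dataset, class_ids, predictions):
    """Evaluate only on the given classes' images and predictions."""
    keep_imgs = [im["id"] for im in dataset.images
                 if im["split"] == "val" and im.get("class_id") in class_ids]
    sub = det._subset(dataset, keep_imgs)
    preds = [p for p in predictions
             if p.category_id in class_ids and p.image_id in set(keep_imgs)]
    return evaluation.evaluate_run(preds, sub, mode="box")


def run_nshot_study(dataset, cfg: RunConfig, seeds=(0, 1, 2), shot_grid=None,
                    progress=None) -> dict:
    """The n-shot fine-tuning experiment.

    Per seed: split classes 3:1, base-train once on base-class images, then
    for each shot level build a balanced n-shot subset, fine-tune the box
    predictor and evaluate box AP/AP50/AP75 separately on novel-class and
    base-class evaluation images.  Returns a nested dict
    ``results[shot]["novel"|"base"]`` of per-seed metric lists plus seed
    means, and per-shot fine-tuning loss curves for the first seed.
    """
    shot_grid = list(shot_grid if shot_grid is not None else cfg.shot_grid)
    results: dict = {n: {"novel": [], "base": []} for n in shot_grid}
    curves: dict = {}
    for seed in seeds:
        tc = _with_seed(cfg.train, seed)
        split = det.split_base_novel([c["id"] for c in dataset.categories],
                                     ratio=cfg.base_novel_ratio, seed=seed)
        base_ds = det.filter_to_classes(dataset, split.base_classes, split="train")
        model = det.init_detector(len(split.base_classes), seed=seed)
        model = det.base_train(model, base_ds, tc, progress=progress)
        base_state = det.save_state(model)
        for n in shot_grid:
            m = det.load_state(base_state)
            subset = det.build_nshot_subset(dataset, split, n, seed=seed)
            m = det.fine_tune(m, subset, split, tc)
            preds = predictions_for_split(m, dataset)
            novel = _class_restricted(dataset, set(split.novel_classes), preds)
            base = _class_restricted(dataset, set(split.base_classes), preds)
            results[n]["novel"].append(novel)
            results[n]["base"].append(base)
            if seed == seeds[0]:
                curves[n] = list(m.finetune_history)
            if progress is not None:
                progress(f"seed {seed} {n}-shot", novel.ap50)
    summary = {}
    for n in shot_grid:
        summary[n] = {
            grp: {
                "AP": float(np.mean([r.ap for r in results[n][grp]])),
                "AP50": float(np.mean([r.ap50 for r in results[n][grp]])),
                "AP75": float(np.mean([r.ap75 for r in results[n][grp]])),
            }
            for grp in ("novel", "base")
        }
    return {"per_seed": results, "mean": summary, "curves": curves,
            "shot_grid": shot_grid, "seeds": list(seeds)}


def _with_seed(train_cfg, seed):
    import dataclasses

    return dataclasses.replace(train_cfg, seed=seed)
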