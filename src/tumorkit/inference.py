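"""Inference, evaluation metrics, and post-processing scores.

Detection thresholds the sigmoid output strictly at 0.5.  Segmentation
quality is the Dice overlap ``2|P n Q| / (|P| + |Q|)`` between the
thresholded prediction P and the reference mask Q (both-empty defined as a
perfect 1.0).  Post-processing derives the clinically reported scores from
a probability map: tumor area (positive pixels), tumor ratio (tumor area
over brain area, brain pixels being those above 5% of the image maximum),
and confidence (mean predicted probability over predicted-tumor pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, SizeError

__all__ = [
    "DetectionResult",
    "SegmentationResult",
    "detect",
    "accuracy",
    "dice_score",
    "postprocess_segmentation",
    "evaluate_detection",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class DetectionResult:
    label: int
    probability: float


@dataclass
class SegmentationResult:
    prob_map: np.ndarray
    mask: np.ndarray
    tumor_area: int
    tumor_ratio: float
    confidence: float


def _as_array(x):
    return np.asarray(getattr(x, "pixels", x))


def detect(model, x) -> DetectionResult:
    """Run a trained detection network on one preprocessed input.

    Accepts a :class:`~tumorkit.preprocess.DetectionInput`, a
    :class:`~tumorkit.features.FeatureVector`, or a raw array matching the
    model's input shape.
    """
    from .preprocess import DetectionInput

    arr = getattr(x, "pixels", None)
    if arr is None:
        values = getattr(x, "values", None)
        arr = np.asarray(values)[:, None] if values is not None else np.asarray(x)
    arr = np.asarray(arr, dtype=np.float32)
    if isinstance(x, DetectionInput):
        arr = arr / 255.0 - 0.5  # the network consumes zero-centered images
    expected = tuple(model.graph.layers[0].shape)
    if arr.shape != expected:
        raise ShapeError(f"input {arr.shape} does not match model input {expected}")
    prob = float(model.forward(arr[None], training=False).ravel()[0])
    return DetectionResult(label=int(prob > 0.5), probability=prob)


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of correctly predicted labels."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0 or t.shape != p.shape:
        raise SizeError(f"label sequences must be equal-length and non-empty "
                        f"({t.shape} vs {p.shape})")
    return float(np.mean(t == p))


def dice_score(P, Q) -> float:
    """Dice overlap ``2|P n Q| / (|P| + |Q|)`` of two aligned binary masks;
    1.0 when both are empty."""
    p = _as_array(P).astype(bool)
    q = _as_array(Q).astype(bool)
    if p.shape != q.shape:
        raise ShapeError(f"mask shapes differ: {p.shape} vs {q.shape}")
    denom = int(p.sum()) + int(q.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & q).sum()) / denom


def postprocess_segmentation(prob_map, brain_image) -> SegmentationResult:
    """Derive mask, tumor area, tumor ratio and confidence from a
    probability map over a brain image."""
    prob = np.squeeze(np.asarray(prob_map, dtype=np.float64))
    brain = np.squeeze(_as_array(brain_image)).astype(np.float64)
    if prob.shape != brain.shape:
        raise ShapeError(f"probability map {prob.shape} vs image {brain.shape}")
    mask = prob > 0.5
    tumor_area = int(mask.sum())
    brain_area = int((brain > 0.05 * brain.max()).sum()) if brain.max() > 0 else 0
    tumor_ratio = tumor_area / brain_area if brain_area > 0 else 0.0
    confidence = float(prob[mask].mean()) if tumor_area > 0 else 0.0
    return SegmentationResult(prob_map=prob, mask=mask.astype(np.uint8),
                              tumor_area=tumor_area, tumor_ratio=tumor_ratio,
                              confidence=confidence)


def evaluate_detection(model, test_records, input_mode: str = "image") -> dict:
    """Accuracy plus a per-record (name, truth, prediction, probability)
    table over labelled test records."""
    from .preprocess import prep_detection

    records = list(test_records)
    if not records:
        raise SizeError("empty test set")
    rows = []
    for rec in records:
        if input_mode == "image":
            x = prep_detection(rec.image)
            name, truth = rec.name, rec.label
        else:
            x, name, truth = rec, rec.name, rec.label
        res = detect(model, x)
        rows.append({"name": name, "truth": int(truth),
                     "prediction": res.label, "probability": res.probability})
    acc = accuracy([r["truth"] for r in rows], [r["prediction"] for r in rows])
    return {"accuracy": acc, "records": rows}


def evaluate_segmentation(model, test_samples) -> dict:
    """Mean and per-sample Dice over thresholded predictions, plus the mean
    absolute tumor-ratio error against the ground truth."""
    samples = list(test_samples)
    if not samples:
        raise SizeError("empty test set")
    dices = []
    ratio_errors = []
    rows = []
    for i, (x, truth) in enumerate(samples):
        xa = np.asarray(getattr(x, "pixels", x), dtype=np.float32)
        ta = _as_array(truth)
        prob = model.forward(xa[None], training=False)[0]
        pred = (np.squeeze(prob) > 0.5).astype(np.uint8)
        d = dice_score(pred, np.squeeze(ta))
        brain = xa[..., 0]
        res_pred = postprocess_segmentation(np.squeeze(prob), brain)
        res_true = postprocess_segmentation(np.squeeze(ta).astype(np.float64), brain)
        dices.append(d)
        ratio_errors.append(abs(res_pred.tumor_ratio - res_true.tumor_ratio))
        rows.append({"index": i, "dice": d, "tumor_area": res_pred.tumor_area,
                     "tumor_ratio": res_pred.tumor_ratio,
                     "confidence": res_pred.confidence})
    return {"mean_dice": float(np.mean(dices)),
            "mean_tumor_ratio_error": float(np.mean(ratio_errors)),
            "samples": rows}
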