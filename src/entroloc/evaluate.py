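"""Score predicted optic disc centres against ground truth.

A prediction is counted correct when its Euclidean distance to the true
centre is at most a distance criterion — by default the image's own true
disc radius (the conventional "one disc radius" rule in the optic disc
localization literature), optionally a fixed pixel threshold.  The boundary
is inclusive: distance equal to the criterion counts as correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "score"]


@dataclass
class EvaluationReport:
    n_images: int
    n_correct: int
    accuracy: float  # percent
    criterion: str
    per_image: pd.DataFrame  # name, pred/true centres, distance_px, correct

    def summary(self) -> str:
        return (
            f"{self.n_correct}/{self.n_images} correct "
            f"({self.accuracy:.1f}%), criterion: {self.criterion}"
        )


def _load(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    return table.copy()


def _name_key(series: pd.Series) -> pd.Series:
    # match on basenames so batch output (full paths) joins with truth (filenames)
    return series.astype(str).map(lambda s: Path(s).name)


def score(
    predictions: pd.DataFrame | str | Path,
    truth: pd.DataFrame | str | Path,
    radius_px: float | None = None,
) -> EvaluationReport:
    """Compare predicted centres with ground truth.

    ``predictions`` needs columns ``image`` (or ``filename``), ``center_row``,
    ``center_col``; ``truth`` needs ``filename``, ``center_row``,
    ``center_col`` and, unless ``radius_px`` is given, ``radius``.  Rows are
    matched by file basename; a prediction with no matching truth row is a
    validation error.  Row order of either table does not affect the result.
    """
    pred = _load(predictions)
    true = _load(truth)
    pred_name_col = "image" if "image" in pred.columns else "filename"
    if pred_name_col not in pred.columns:
        raise ValueError("predictions must have an 'image' or 'filename' column")
    pred["_key"] = _name_key(pred[pred_name_col])
    true["_key"] = _name_key(true["filename"])
    if pred["_key"].duplicated().any() or true["_key"].duplicated().any():
        raise ValueError("duplicate image names")

    missing = sorted(set(pred["_key"]) - set(true["_key"]))
    if missing:
        raise ValueError(f"predictions without ground truth: {missing}")

    merged = pred.merge(true, on="_key", suffixes=("_pred", "_true")).sort_values("_key")
    dist = np.hypot(
        merged["center_row_pred"] - merged["center_row_true"],
        merged["center_col_pred"] - merged["center_col_true"],
    )
    if radius_px is not None:
        if radius_px < 0:
            raise ValueError("radius_px must be non-negative")
        limit = pd.Series(float(radius_px), index=merged.index)
        criterion = f"distance <= {radius_px} px"
    else:
        if "radius" not in true.columns:
            raise ValueError("truth table has no 'radius' column; pass radius_px")
        limit = merged["radius"].astype(float)
        criterion = "distance <= true disc radius"
    correct = dist <= limit

    per_image = pd.DataFrame(
        {
            "name": merged["_key"].to_numpy(),
            "pred_row": merged["center_row_pred"].to_numpy(),
            "pred_col": merged["center_col_pred"].to_numpy(),
            "true_row": merged["center_row_true"].to_numpy(),
            "true_col": merged["center_col_true"].to_numpy(),
            "distance_px": dist.to_numpy(),
            "correct": correct.to_numpy(),
        }
    ).reset_index(drop=True)
    n = len(per_image)
    n_correct = int(correct.sum())
    return EvaluationReport(
        n_images=n,
        n_correct=n_correct,
        accuracy=100.0 * n_correct / n,
        criterion=criterion,
        per_image=per_image,
    )
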