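"""Evaluation of detections against generator ground truth.

Used by the test-suite and the reproduction script to score segmentation
quality (precision/recall by centroid matching) and intensity fidelity
(relative error of background-corrected means against true means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["SegmentationScore", "match_objects", "score_detection"]


@dataclass(frozen=True)
class SegmentationScore:
    n_truth: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    intensity_errors: np.ndarray  # relative, signed, one per match

    @property
    def max_abs_intensity_error(self) -> float:
        return float(np.max(np.abs(self.intensity_errors))) \
            if self.intensity_errors.size else float("nan")


def match_objects(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    max_dist: float = 15.0,
) -> list[tuple[int, int]]:
    """Optimal one-to-one centroid matching (Hungarian) within ``max_dist`` px.

    Returns (truth_index, detected_index) positional pairs.
    """
    if truth.empty or detected.empty:
        return []
    tx = truth[["x", "y"]].to_numpy(dtype=float)
    dx = detected[["x", "y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(tx[:, None, :] - dx[None, :, :], axis=2)
    cost = np.where(dist <= max_dist, dist, 1e9)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if dist[r, c] <= max_dist]


def score_detection(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    background: float,
    max_dist: float = 15.0,
) -> SegmentationScore:
    """Precision/recall and corrected-mean fidelity for one scene.

    The truth table's ``true_mean`` is an absolute intensity; the expected
    corrected mean is ``true_mean - background``.
    """
    pairs = match_objects(truth, detected, max_dist)
    errs = []
    for ti, di in pairs:
        expected = truth.iloc[ti]["true_mean"] - background
        got = detected.iloc[di]["corrected_mean"]
        if expected != 0:
            errs.append((got - expected) / expected)
    return SegmentationScore(
        n_truth=len(truth), n_detected=len(detected), n_matched=len(pairs),
        precision=len(pairs) / len(detected) if len(detected) else 0.0,
        recall=len(pairs) / len(truth) if len(truth) else 0.0,
        intensity_errors=np.asarray(errs),
    )
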