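"""Cross-modality plaque registration: landmark affine fit and
mutual-nearest-neighbour plaque matching between serial sections."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)


@dataclass
class AffineTransform:
    matrix: np.ndarray  # 2x2
    offset: np.ndarray  # 2
    rms_residual: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + self.offset


@dataclass
class PlaqueRegistry:
    matches: pd.DataFrame  # src_id, dst_id, distance
    unmatched_src: list = field(default_factory=list)
    unmatched_dst: list = field(default_factory=list)


def register_landmarks(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares 2-D affine from >= 3 non-collinear landmark pairs."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmarks must be matching (n, 2) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 landmark pairs")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("landmarks are collinear")
    design = np.hstack([src, np.ones((len(src), 1))])
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = params[:2].T
    offset = params[2]
    resid = dst - (src @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(matrix, offset, rms)


def match_plaques(
    src_centroids: pd.DataFrame,
    dst_centroids: pd.DataFrame,
    transform: AffineTransform | None = None,
    max_distance: float = 20.0,
) -> PlaqueRegistry:
    """Mutual-nearest-neighbour matching under a distance cap.

    Both inputs need columns ``id, y, x``; ``transform`` (if given) maps the
    source coordinate frame onto the destination frame first.
    """
    spts = src_centroids[["y", "x"]].to_numpy(float)
    dpts = dst_centroids[["y", "x"]].to_numpy(float)
    if transform is not None:
        spts = transform.apply(spts)
    if len(spts) == 0 or len(dpts) == 0:
        return PlaqueRegistry(
            pd.DataFrame(columns=["src_id", "dst_id", "distance"]),
            list(src_centroids["id"]), list(dst_centroids["id"]),
        )
    d = cdist(spts, dpts)
    nn_s = d.argmin(axis=1)
    nn_d = d.argmin(axis=0)
    rows = []
    matched_s, matched_d = set(), set()
    for i, j in enumerate(nn_s):
        if nn_d[j] == i and d[i, j] <= max_distance:
            rows.append({"src_id": src_centroids["id"].iloc[i],
                         "dst_id": dst_centroids["id"].iloc[j],
                         "distance": float(d[i, j])})
            matched_s.add(i)
            matched_d.add(j)
    unmatched_src = [src_centroids["id"].iloc[i] for i in range(len(spts))
                     if i not in matched_s]
    unmatched_dst = [dst_centroids["id"].iloc[j] for j in range(len(dpts))
                     if j not in matched_d]
    for u in unmatched_src:
        log.info("source plaque %s unmatched", u)
    return PlaqueRegistry(pd.DataFrame(rows, columns=["src_id", "dst_id", "distance"]),
                          unmatched_src, unmatched_dst)
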