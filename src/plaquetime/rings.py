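"""Concentric-ring quantification of marker intensity around plaques.

Markers (HOMER1 postsynaptic loss, LAMP1 dystrophic neurites, Abeta) are
averaged in 10-um annuli extending from each plaque's boundary to 30 um.
Distances are Euclidean from the mask edge (not the centroid), plaque
interiors are excluded, and any pixel within the outermost ring distance of
two or more plaques is contested and removed from every profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

DEFAULT_INCREMENTS = (10.0, 20.0, 30.0)  # um ring outer edges


def std_projection(zstack: np.ndarray) -> np.ndarray:
    """Project a z-stack to one plane by per-pixel standard deviation
    (population convention, ddof=0)."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3:
        raise ValueError("expected a (Z, H, W) stack")
    if zstack.shape[0] < 2:
        log.warning("single-plane input: std projection returns zeros-free identity")
        return zstack[0].copy()
    return zstack.std(axis=0, ddof=0)


def make_rings(
    plaque_labels: np.ndarray,
    pixel_size_um: float,
    increments: tuple[float, ...] = DEFAULT_INCREMENTS,
) -> dict[int, dict[int, np.ndarray]]:
    """Ring pixel masks per plaque.

    ``plaque_labels`` is an integer image, 0 = background, k > 0 = plaque k.
    Ring i (1-based) of a plaque holds pixels whose distance from that
    plaque's boundary lies in (increments[i-2], increments[i-1]] um (first
    ring starts at the edge). Pixels inside any plaque, or within
    ``increments[-1]`` of two or more plaques, belong to no ring.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive (um)")
    labels = np.asarray(plaque_labels)
    ids = [int(i) for i in np.unique(labels) if i != 0]
    if not ids:
        return {}
    edges = (0.0,) + tuple(increments)
    any_plaque = labels > 0
    dist_maps = {}
    for pid in ids:
        dist_maps[pid] = ndimage.distance_transform_edt(
            labels != pid, sampling=pixel_size_um
        )
    coverage = np.zeros(labels.shape, dtype=int)
    for pid in ids:
        coverage += (dist_maps[pid] <= increments[-1]).astype(int)
    contested = coverage >= 2
    rings: dict[int, dict[int, np.ndarray]] = {}
    for pid in ids:
        d = dist_maps[pid]
        rings[pid] = {}
        for i in range(len(increments)):
            ring = (d > edges[i]) & (d <= edges[i + 1]) & ~any_plaque & ~contested
            rings[pid][i + 1] = ring
    return rings


def ring_means(
    marker: np.ndarray,
    rings: dict[int, dict[int, np.ndarray]],
    plaque_meta: pd.DataFrame | None = None,
    marker_name: str = "marker",
) -> pd.DataFrame:
    """Mean marker intensity per plaque per ring.

    ``plaque_meta`` optionally supplies ``plaque_id, type, image, animal``
    columns for downstream aggregation. Empty rings are skipped with a log
    entry. Returns a tidy table (plaque_id, ring, marker, mean, n_pixels,
    plus any metadata columns).
    """
    meta = None
    if plaque_meta is not None:
        meta = plaque_meta.set_index("plaque_id")
    rows = []
    for pid in sorted(rings):
        for ring_idx in sorted(rings[pid]):
            mask = rings[pid][ring_idx]
            n = int(mask.sum())
            if n == 0:
                log.info("plaque %s ring %d empty; skipped", pid, ring_idx)
                continue
            row = {"plaque_id": pid, "ring": ring_idx, "marker": marker_name,
                   "mean": float(marker[mask].mean()), "n_pixels": n}
            if meta is not None and pid in meta.index:
                row.update(meta.loc[pid].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Hierarchical aggregation plaque -> type-within-image -> image-within-animal.

    Needs ``type``, ``image`` and ``animal`` columns (from ``ring_means``
    metadata). Returns the animal-level two-factor (ring x type) summary
    table, invariant to plaque enumeration order.
    """
    for col in ("type", "image", "animal"):
        if col not in profiles.columns:
            raise ValueError(f"aggregation needs a {col!r} column")
    per_image = (
        profiles.groupby(["animal", "image", "type", "ring", "marker"])["mean"]
        .mean()
        .reset_index()
    )
    per_animal = (
        per_image.groupby(["animal", "type", "ring", "marker"])["mean"]
        .mean()
        .reset_index()
    )
    return per_animal
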