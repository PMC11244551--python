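"""Spatial pairing of pre/post acquisitions and differential features.

For each post point the Euclidean-nearest pre point is identified; pairs
whose distance strictly exceeds the threshold (default 5 mm) are excluded.
The default mode allows several post points to share a pre point (literal
"for each post point" semantics); ``unique`` mode enforces a one-to-one
matching by repeated global minimum-distance selection with deterministic
tie rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import EAMStudy, FeatureMap
from .mesh_maps import interpolate_feature

log = logging.getLogger(__name__)

PAIR_DTYPE = np.dtype([("post", np.int64), ("pre", np.int64), ("distance", np.float64)])


def pair_points(
    pre_positions: np.ndarray,
    post_positions: np.ndarray,
    threshold_mm: float = 5.0,
    unique: bool = False,
) -> np.ndarray:
    """Pair each post point with its nearest pre point.

    Returns a structured array with fields ``post``, ``pre``,
    ``distance`` sorted by post index.  Ties go to the lowest pre index;
    distances exactly equal to the threshold are retained.  In unique
    mode, pairs are selected greedily by global minimum distance
    (ties: lowest post, then lowest pre index) and each pre point is used
    at most once.
    """
    pre = np.asarray(pre_positions, dtype=np.float64).reshape(-1, 3)
    post = np.asarray(post_positions, dtype=np.float64).reshape(-1, 3)
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both point sets must be non-empty")
    d = cdist(post, pre)

    if not unique:
        nearest = np.argmin(d, axis=1)  # first occurrence = lowest pre index
        dist = d[np.arange(len(post)), nearest]
        keep = dist <= threshold_mm
        out = np.empty(int(keep.sum()), dtype=PAIR_DTYPE)
        out["post"] = np.nonzero(keep)[0]
        out["pre"] = nearest[keep]
        out["distance"] = dist[keep]
        return out

    post_i, pre_i = np.nonzero(d <= threshold_mm)
    dist = d[post_i, pre_i]
    order = np.lexsort((pre_i, post_i, dist))
    used_pre = np.zeros(len(pre), dtype=bool)
    used_post = np.zeros(len(post), dtype=bool)
    chosen = []
    for k in order:
        i, j = post_i[k], pre_i[k]
        if not used_post[i] and not used_pre[j]:
            used_post[i] = used_pre[j] = True
            chosen.append((i, j, dist[k]))
    chosen.sort()
    result = np.empty(len(chosen), dtype=PAIR_DTYPE)
    for n, (i, j, dd) in enumerate(chosen):
        result[n] = (i, j, dd)
    return result


@dataclass
class PairedStudy:
    """Pre/post studies joined by a pairing index."""

    pre: EAMStudy
    post: EAMStudy
    pairs: np.ndarray  # structured PAIR_DTYPE
    threshold_mm: float
    deltas: dict = field(default_factory=dict)  # name -> per-pair post - pre


def pair_studies(
    pre: EAMStudy,
    post: EAMStudy,
    threshold_mm: float = 5.0,
    unique: bool = False,
    use_surface_positions: bool = True,
) -> PairedStudy:
    """Pair two acquisition phases; surface projections are used by default
    (they live on the map geometry), raw positions by flag."""
    if use_surface_positions:
        a, b = pre.surface_positions, post.surface_positions
    else:
        a, b = pre.positions, post.positions
    pairs = pair_points(a, b, threshold_mm=threshold_mm, unique=unique)
    return PairedStudy(pre=pre, post=post, pairs=pairs, threshold_mm=threshold_mm)


def delta_features(
    paired: PairedStudy,
    pre_values: np.ndarray,
    post_values: np.ndarray,
    name: str = "delta",
    method: str = "nearest",
    max_distance: float | None = None,
) -> tuple[np.ndarray, FeatureMap]:
    """Per-pair differences (post - pre) and the differential map.

    ``pre_values``/``post_values`` are per-point feature arrays on each
    study (NaN marks quality-rejected points; such pairs are dropped with a
    logged count).  The delta map is interpolated at the post surface
    positions onto the post-phase mesh.  The per-pair delta array is also
    recorded in ``paired.deltas[name]`` (NaN where dropped).
    """
    pre_values = np.asarray(pre_values, dtype=np.float64).ravel()
    post_values = np.asarray(post_values, dtype=np.float64).ravel()
    if len(pre_values) != paired.pre.n_points or len(post_values) != paired.post.n_points:
        raise ValueError("feature arrays must match study point counts")
    pairs = paired.pairs
    delta = post_values[pairs["post"]] - pre_values[pairs["pre"]]
    n_dropped = int(np.sum(~np.isfinite(delta)))
    if n_dropped:
        log.info("delta_features(%s): dropped %d pair(s) with rejected features", name, n_dropped)
    paired.deltas[name] = delta
    ok = np.isfinite(delta)
    if not np.any(ok):
        raise ValueError("no pairs with valid features on both sides")
    fmap = interpolate_feature(
        paired.post.surface_positions[pairs["post"][ok]],
        delta[ok],
        paired.post.mesh,
        method=method,
        max_distance=max_distance,
        name=name,
    )
    return delta, fmap
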