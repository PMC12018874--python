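"""Bidirectional local distance (BLD) displacement fields and COM shifts.

For every surface point b of the baseline structure, against one test
structure, the BLD algorithm:

1. finds the nearest test point to b (forward match);
2. finds every test point whose nearest baseline point is b (reverse
   matches);
3. takes, among these candidates, the one at the largest distance as the
   mapped point, and that distance as BLD(b).

The resulting 3D displacement vectors (mapped - baseline) are decomposed
into right-left (x), anterior-posterior (y) and cranial-caudal (z)
components and signed: the in-plane components get a common +/- factor
according to whether the mapped point lies outside (+) or inside (-) the
baseline structure, while the z component is signed outward (+) / inward
(-) relative to the axial plane through the baseline COM.

All nearest-neighbor and argmax ties are broken by the smallest point
index, which makes results machine-exact and directly comparable with the
exhaustive O(N*M) oracle ``bld_brute_force``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Com, SurfacePointCloud, points_inside
from .structures import StructureSet

__all__ = [
    "DisplacementField",
    "ComDisplacement",
    "bld_map",
    "bld_brute_force",
    "sign_components",
    "com_displacement",
    "nearest_with_ties",
    "field_to_frame",
]

_BRUTE_FORCE_LIMIT = 10**7
_TIE_RTOL = 1e-9


@dataclass(eq=False)
class DisplacementField:
    """Per-baseline-point BLD vectors to one test scan.

    ``vector_mm = mapped_point - baseline_point``; ``bld_mm`` is its norm.
    ``signed_mm`` holds the signed (RL, AP, CC) components and is ``None``
    until :func:`sign_components` fills it.
    """

    baseline_points: np.ndarray  # (N, 3)
    mapped_points: np.ndarray  # (N, 3)
    mapped_index: np.ndarray  # (N,) index into the test cloud
    bld_mm: np.ndarray  # (N,)
    vector_mm: np.ndarray  # (N, 3)
    baseline_scan_id: str = ""
    test_scan_id: str = ""
    signed_mm: np.ndarray | None = field(default=None)  # (N, 3) rl/ap/cc

    def __len__(self) -> int:
        return len(self.baseline_points)

    @property
    def signed_rl_mm(self) -> np.ndarray:
        return self.signed_mm[:, 0]

    @property
    def signed_ap_mm(self) -> np.ndarray:
        return self.signed_mm[:, 1]

    @property
    def signed_cc_mm(self) -> np.ndarray:
        return self.signed_mm[:, 2]


@dataclass(frozen=True)
class ComDisplacement:
    """Signed COM shift (test - baseline): +left, +posterior, +cranial."""

    test_scan_id: str
    shift_mm: tuple[float, float, float]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.shift_mm, dtype=float)


def _as_points(cloud) -> np.ndarray:
    pts = cloud.points if isinstance(cloud, SurfacePointCloud) else np.asarray(cloud, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("expected a non-empty (N, 3) point cloud")
    return pts


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distances between paired rows, same arithmetic as the oracle."""
    return np.sqrt(((a - b) ** 2).sum(axis=-1))


def nearest_with_ties(tree_points: np.ndarray, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest ``tree_points`` index per query; exact ties -> smallest index.

    A k-d tree answers the bulk; near-ties (second neighbor within relative
    1e-9) are re-resolved by exact numpy distances so the result matches the
    brute-force oracle bit for bit.
    """
    tree = cKDTree(tree_points)
    m = len(tree_points)
    if m == 1:
        idx = np.zeros(len(queries), dtype=np.intp)
        return idx, _dist(queries, tree_points[0])
    d, i = tree.query(queries, k=2)
    idx = i[:, 0].astype(np.intp)
    ambiguous = d[:, 1] <= d[:, 0] * (1.0 + _TIE_RTOL) + 1e-12
    for q in np.nonzero(ambiguous)[0]:
        radius = d[q, 0] * (1.0 + _TIE_RTOL) + 1e-12
        cand = np.sort(np.asarray(tree.query_ball_point(queries[q], radius), dtype=np.intp))
        dc = _dist(tree_points[cand], queries[q])
        idx[q] = cand[np.argmin(dc)]  # first occurrence = smallest index
    return idx, _dist(queries, tree_points[idx])


def bld_map(
    baseline: SurfacePointCloud | np.ndarray,
    test: SurfacePointCloud | np.ndarray,
) -> DisplacementField:
    """Accelerated BLD field from the baseline cloud to one test cloud."""
    b = _as_points(baseline)
    t = _as_points(test)
    fwd_idx, fwd_d = nearest_with_ties(t, b)
    rev_idx, rev_d = nearest_with_ties(b, t)

    best_idx = fwd_idx.copy()
    best_d = fwd_d.copy()
    # group test points by their assigned baseline point
    order = np.argsort(rev_idx, kind="stable")
    bounds = np.searchsorted(rev_idx[order], np.arange(len(b) + 1))
    for bi in np.unique(rev_idx):
        members = order[bounds[bi] : bounds[bi + 1]]  # ascending test indices
        cand = np.unique(np.concatenate([[fwd_idx[bi]], members]))
        dc = _dist(t[cand], b[bi])
        j = np.argmax(dc)  # first occurrence = smallest index among ties
        best_idx[bi] = cand[j]
        best_d[bi] = dc[j]

    mapped = t[best_idx]
    return DisplacementField(
        baseline_points=b,
        mapped_points=mapped,
        mapped_index=best_idx,
        bld_mm=best_d,
        vector_mm=mapped - b,
        baseline_scan_id=getattr(baseline, "source_scan_id", ""),
        test_scan_id=getattr(test, "source_scan_id", ""),
    )


def bld_brute_force(
    baseline: SurfacePointCloud | np.ndarray,
    test: SurfacePointCloud | np.ndarray,
) -> DisplacementField:
    """Exhaustive-distance-matrix BLD oracle (testing reference).

    Same contract and tie rule as :func:`bld_map`; refuses N*M > 10^7.
    """
    b = _as_points(baseline)
    t = _as_points(test)
    if len(b) * len(t) > _BRUTE_FORCE_LIMIT:
        raise MemoryError(f"brute-force BLD refused for N*M = {len(b) * len(t)}")
    d = np.sqrt(((b[:, None, :] - t[None, :, :]) ** 2).sum(axis=-1))  # (N, M)
    fwd_idx = np.argmin(d, axis=1)  # smallest index on ties
    rev_idx = np.argmin(d, axis=0)
    best_idx = np.empty(len(b), dtype=np.intp)
    best_d = np.empty(len(b))
    for bi in range(len(b)):
        cand = np.unique(np.concatenate([[fwd_idx[bi]], np.nonzero(rev_idx == bi)[0]]))
        j = np.argmax(d[bi, cand])
        best_idx[bi] = cand[j]
        best_d[bi] = d[bi, cand[j]]
    mapped = t[best_idx]
    return DisplacementField(
        baseline_points=b,
        mapped_points=mapped,
        mapped_index=best_idx,
        bld_mm=best_d,
        vector_mm=mapped - b,
        baseline_scan_id=getattr(baseline, "source_scan_id", ""),
        test_scan_id=getattr(test, "source_scan_id", ""),
    )


def sign_components(
    field: DisplacementField,
    baseline_structure: StructureSet,
    baseline_com: Com,
) -> DisplacementField:
    """Fill the signed (RL, AP, CC) components of a displacement field.

    In-plane: one common sign per point, + if the mapped point lies outside
    the baseline structure (displacement moved out of it), - if inside;
    applied to |dx| and |dy|.  CC: + if the z displacement points away from
    the axial plane through the baseline COM (outward), - if toward it.
    """
    outside = ~points_inside(baseline_structure, field.mapped_points)
    s_inplane = np.where(outside, 1.0, -1.0)
    dx, dy, dz = field.vector_mm[:, 0], field.vector_mm[:, 1], field.vector_mm[:, 2]
    above = field.baseline_points[:, 2] >= baseline_com.point[2]
    outward_z = np.where(above, dz >= 0, dz < 0)
    field.signed_mm = np.column_stack(
        [
            s_inplane * np.abs(dx),
            s_inplane * np.abs(dy),
            np.where(outward_z, 1.0, -1.0) * np.abs(dz),
        ]
    )
    return field


def com_displacement(
    baseline_com: Com, test_com: Com, test_scan_id: str = ""
) -> ComDisplacement:
    """COM shift test - baseline in the +left/+posterior/+cranial convention."""
    shift = test_com.array - baseline_com.array
    return ComDisplacement(test_scan_id=test_scan_id, shift_mm=tuple(float(v) for v in shift))


def field_to_frame(field: DisplacementField):
    """Per-point CSV-ready table of one displacement field."""
    import pandas as pd

    data = {
        "baseline_point_id": np.arange(len(field)),
        "x": field.baseline_points[:, 0],
        "y": field.baseline_points[:, 1],
        "z": field.baseline_points[:, 2],
        "test_scan_id": field.test_scan_id,
        "bld_mm": field.bld_mm,
        "dx": field.vector_mm[:, 0],
        "dy": field.vector_mm[:, 1],
        "dz": field.vector_mm[:, 2],
    }
    if field.signed_mm is not None:
        data["signed_rl"] = field.signed_mm[:, 0]
        data["signed_ap"] = field.signed_mm[:, 1]
        data["signed_cc"] = field.signed_mm[:, 2]
    return pd.DataFrame(data)
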