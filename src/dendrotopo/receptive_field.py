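"""Anatomical receptive-field estimation from dendritic point clouds.

The dendrites of a retinotopically organized neuron population lie on a
curved neuropil shell.  A quadratic surface fitted through the pooled
point cloud (in its PCA frame) captures that curvature; projecting each
neuron's points into the surface's (u, v) frame yields a 2-D footprint
polygon and a centroid — the anatomical estimate of the neuron's
receptive-field position.  Two landmark points calibrate a similarity
transform into eye coordinates, and an exact binomial test quantifies
hemisphere bias of the population's centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint

__all__ = [
    "QuadraticSurface",
    "ReceptiveFieldSet",
    "fit_quadratic_surface",
    "project_neuron",
    "estimate_receptive_fields",
    "landmark_transform",
    "hemisphere_bias_test",
]


@dataclass
class QuadraticSurface:
    """w = a0 + a1 u + a2 v + a3 u^2 + a4 u v + a5 v^2 in a PCA frame."""

    coeffs: np.ndarray       # (6,)
    origin: np.ndarray       # (3,) cloud mean
    axes: np.ndarray         # (3, 3) rows = u, v, w unit vectors
    residual_rms: float

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World (N,3) -> surface frame (N,3) = (u, v, w)."""
        return (np.atleast_2d(points) - self.origin) @ self.axes.T


@dataclass
class ReceptiveFieldSet:
    """Per-neuron polygons and centroids in 2-D field coordinates."""

    polygons: dict[int, np.ndarray]   # neuron_id -> (M,2) hull vertices
    centroids: dict[int, np.ndarray]  # neuron_id -> (2,)
    surface: QuadraticSurface | None = None
    transform: dict | None = None     # landmark-calibration parameters

    def centroid_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"neuron_id": nid, "u": c[0], "v": c[1]}
                             for nid, c in sorted(self.centroids.items())])


def _pca_frame(points: np.ndarray):
    origin = points.mean(axis=0)
    centered = points - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt  # rows ordered by decreasing variance; row 2 ~ surface normal
    # deterministic sign convention: largest-magnitude entry positive
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if axes.shape[0] < 3:  # degenerate; complete the frame
        axes = np.vstack([axes, np.cross(axes[0], axes[1])[None, :]])
    return origin, axes


def fit_quadratic_surface(points: np.ndarray) -> QuadraticSurface:
    """Least-squares quadratic surface through a pooled 3-D point cloud.

    The frame is the cloud's PCA frame (u, v span the sheet; w is the
    thin direction).  Requires at least 6 points; rank-deficient designs
    (e.g. points on a line) fall back to the minimum-norm solution.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(points) < 6:
        raise ValueError(f"need >= 6 points to fit a quadratic surface, "
                         f"got {len(points)}")
    origin, axes = _pca_frame(points)
    uvw = (points - origin) @ axes.T
    u, v, w = uvw[:, 0], uvw[:, 1], uvw[:, 2]
    design = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
    coeffs, *_ = np.linalg.lstsq(design, w, rcond=None)
    resid = w - design @ coeffs
    return QuadraticSurface(coeffs, origin, axes,
                            float(np.sqrt(np.mean(resid ** 2))))


def project_neuron(points: np.ndarray, surface: QuadraticSurface,
                   centroid_mode: str = "points",
                   dedupe: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Project one neuron's points onto the surface frame.

    Returns ``(polygon_vertices, centroid)``: the convex hull of the
    projected (u, v) points (counter-clockwise vertex array) and the mean
    of the projected points (or the polygon-area centroid with
    ``centroid_mode="polygon"``).  ``dedupe`` collapses duplicate points
    before computing the centroid.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 3:
        raise ValueError(f"need >= 3 points per neuron, got {len(points)}")
    uv = surface.to_frame(points)[:, :2]
    if dedupe:
        uv = np.unique(uv, axis=0)
    hull = MultiPoint([tuple(p) for p in uv]).convex_hull
    if hull.geom_type == "Polygon":
        verts = np.asarray(hull.exterior.coords)[:-1]
    else:  # collinear cloud: degenerate hull
        verts = np.asarray(hull.coords)
    if centroid_mode == "polygon" and hull.geom_type == "Polygon":
        centroid = np.asarray(hull.centroid.coords[0])
    else:
        centroid = uv.mean(axis=0)
    return verts, centroid


def estimate_receptive_fields(point_clouds: dict[int, np.ndarray],
                              surface: QuadraticSurface | None = None,
                              centroid_mode: str = "points"
                              ) -> ReceptiveFieldSet:
    """Fit a population surface (unless one is supplied, e.g. borrowing a
    sibling population's surface) and project every neuron."""
    if surface is None:
        pooled = np.vstack(list(point_clouds.values()))
        surface = fit_quadratic_surface(pooled)
    polys, cents = {}, {}
    for nid, pts in point_clouds.items():
        polys[nid], cents[nid] = project_neuron(pts, surface,
                                                centroid_mode=centroid_mode)
    return ReceptiveFieldSet(polys, cents, surface=surface)


def landmark_transform(fields: ReceptiveFieldSet,
                       landmark_pairs: list[tuple],
                       allow_reflection: bool = False) -> ReceptiveFieldSet:
    """Similarity transform (rotation + uniform scale + translation) fixed
    by exactly two landmark correspondences ``[(src_uv, dst_uv), ...]``.

    The two source points are typically reference-neuron centroids with
    known eye-coordinate positions (eye center; dorsal point on the
    central meridian).  With ``allow_reflection`` the source plane is
    mirrored first (hemisphere flip).
    """
    if len(landmark_pairs) != 2:
        raise ValueError("exactly 2 landmark pairs are required")
    (s1, t1), (s2, t2) = [(np.asarray(s, float), np.asarray(t, float))
                          for s, t in landmark_pairs]
    if np.allclose(s1, s2) or np.allclose(t1, t2):
        raise ValueError("coincident landmarks cannot fix a similarity")

    def c(p):
        return complex(p[0], p[1])

    def conj_if(z):
        return z.conjugate() if allow_reflection else z

    a = (c(t2) - c(t1)) / (conj_if(c(s2)) - conj_if(c(s1)))
    b = c(t1) - a * conj_if(c(s1))

    def apply(uv: np.ndarray) -> np.ndarray:
        z = uv[..., 0] + 1j * uv[..., 1]
        if allow_reflection:
            z = np.conj(z)
        w = a * z + b
        return np.stack([w.real, w.imag], axis=-1)

    polys = {nid: apply(p) for nid, p in fields.polygons.items()}
    cents = {nid: apply(c_[None, :])[0] for nid, c_ in fields.centroids.items()}
    transform = {"scale": abs(a), "rotation_deg": float(np.degrees(np.angle(a))),
                 "translation": (b.real, b.imag),
                 "reflection": allow_reflection}
    return ReceptiveFieldSet(polys, cents, surface=fields.surface,
                             transform=transform)


def hemisphere_bias_test(centroids, axis: str = "u",
                         divide_at: float = 0.5) -> dict:
    """Two-sided exact binomial test for hemisphere over-representation.

    ``centroids`` is a DataFrame with columns (neuron_id, u, v) or a dict
    ``{neuron_id: (u, v)}``.  Centroids exactly on the dividing line are
    excluded from the count (reported separately).
    """
    if isinstance(centroids, dict):
        vals = {"u": np.array([c[0] for c in centroids.values()]),
                "v": np.array([c[1] for c in centroids.values()])}[axis]
    else:
        vals = centroids[axis].to_numpy(dtype=float)
    above = int(np.sum(vals > divide_at))
    below = int(np.sum(vals < divide_at))
    on_line = int(len(vals) - above - below)
    n = above + below
    if n == 0:
        raise ValueError("all centroids lie exactly on the dividing line")
    test = stats.binomtest(above, n, p=0.5, alternative="two-sided")
    return {"axis": axis, "divide_at": divide_at, "n": n,
            "count_high": above, "count_low": below, "excluded_on_line": on_line,
            "p_value": float(test.pvalue)}
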