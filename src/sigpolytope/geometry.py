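"""Polytope construction and geometric descriptors.

Each 18-dimensional latent vector is expanded into a deterministic
36-vertex cross-polytope by perturbing every coordinate symmetrically:
along axis ``i`` the vertex pair ``x +/- delta_i * e_i`` is emitted with
``delta_i = max(alpha * |x_i|, epsilon)``.  Projecting the 36 vertices
into the shared PC1--PC3 space and taking their convex hull yields one
polytope per side; the pair of hulls carries the circuitry's geometric
descriptors:

* ``dbary``   — Euclidean distance between the two barycenters,
* ``vol_*``   — hull volumes (latent-complexity proxies),
* ``asym``    — sig:int volume ratio (and its symmetrized form),
* ``aniso_*`` — largest/smallest principal semi-axis ratio per side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .config import PipelineConfig
from .embedding import EmbeddingModel
from .encoding import build_latent_vector
from .errors import DegenerateGeometryError, DomainError, ShapeError
from .records import CircuitryRecord

#: Volume sentinel recorded for hulls that are rank-deficient after
#: projection (e.g. an all-zero latent vector whose cross-polytope
#: collapses); flagged and excluded from quantile fitting.
DEGENERATE_VOLUME = 0.0


def generate_vertices(latent: np.ndarray, alpha: float, epsilon: float) -> np.ndarray:
    """Expand a latent vector into its 2d axis-aligned cross-polytope vertices.

    For each axis ``i`` emits ``x + delta_i e_i`` and ``x - delta_i e_i``
    with ``delta_i = max(alpha |x_i|, epsilon)``; the vertex mean equals
    ``x`` exactly by symmetry.
    """
    if alpha <= 0 or epsilon <= 0:
        raise DomainError("alpha and epsilon must both be positive")
    x = np.asarray(latent, dtype=float)
    if x.ndim != 1:
        raise ShapeError("latent must be a 1-D vector")
    d = x.shape[0]
    deltas = np.maximum(alpha * np.abs(x), epsilon)
    vertices = np.repeat(x[None, :], 2 * d, axis=0)
    idx = np.arange(d)
    vertices[2 * idx, idx] += deltas
    vertices[2 * idx + 1, idx] -= deltas
    return vertices


def perturbation_deltas(latent: np.ndarray, alpha: float, epsilon: float) -> np.ndarray:
    """Per-axis perturbation magnitudes ``max(alpha |x_i|, epsilon)``."""
    if alpha <= 0 or epsilon <= 0:
        raise DomainError("alpha and epsilon must both be positive")
    return np.maximum(alpha * np.abs(np.asarray(latent, dtype=float)), epsilon)


def crosspolytope_volume_closed_form(deltas) -> float:
    """Volume of the axis-aligned cross-polytope with semi-axes ``deltas``.

    For dimension ``d`` the convex hull of ``{+/- delta_i e_i}`` has
    volume ``2^d / d! * prod(delta_i)``.
    """
    dl = np.asarray(deltas, dtype=float)
    if dl.ndim != 1 or dl.size == 0:
        raise DomainError("deltas must be a non-empty 1-D array")
    if np.any(dl <= 0):
        raise DomainError("all deltas must be positive")
    d = dl.size
    log_vol = d * math.log(2.0) - math.lgamma(d + 1) + float(np.sum(np.log(dl)))
    return math.exp(log_vol)


@dataclass
class HullSummary:
    """Convex-hull summary of a 3-D point cloud."""

    volume: float
    area: float
    n_hull_vertices: int
    vertices: np.ndarray  # (m x 3) hull vertex coordinates
    facets: np.ndarray  # (f x 3) integer simplices indexing `vertices`


def compute_hull(points: np.ndarray) -> HullSummary:
    """Convex hull (volume, area, facets) of a k x 3 point cloud.

    Raises :class:`DegenerateGeometryError` carrying the point rank when
    the cloud is coplanar or otherwise rank-deficient.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ShapeError(f"expected a k x 3 matrix, got shape {P.shape}")
    if P.shape[0] < 4:
        raise DegenerateGeometryError(
            f"need at least 4 points for a 3-D hull, got {P.shape[0]}"
        )
    rank = np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-10)
    if rank < 3:
        raise DegenerateGeometryError(
            f"point cloud has rank {rank} < 3 (coplanar or collapsed)", rank=int(rank)
        )
    try:
        hull = ConvexHull(P)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateGeometryError(f"qhull failure: {exc}") from exc
    # Re-index facet simplices onto the compacted hull-vertex array.
    vert_idx = hull.vertices
    remap = {int(v): i for i, v in enumerate(vert_idx)}
    facets = np.array(
        [[remap[int(v)] for v in simplex] for simplex in hull.simplices], dtype=int
    )
    return HullSummary(
        volume=float(hull.volume),
        area=float(hull.area),
        n_hull_vertices=int(len(vert_idx)),
        vertices=P[vert_idx].copy(),
        facets=facets,
    )


def barycenter(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the rows of a k x m point matrix."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.size == 0:
        raise DomainError("barycenter of an empty point set is undefined")
    return P.mean(axis=0)


def barycenter_distance(sig: np.ndarray, int_: np.ndarray) -> float:
    """Euclidean distance between two barycenters (same dimension)."""
    a = np.asarray(sig, dtype=float)
    b = np.asarray(int_, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def volume_asymmetry(vol_sig: float, vol_int: float) -> tuple[float, float]:
    """Volume ratio sig/int and its symmetrized form max(r, 1/r) >= 1."""
    if vol_sig <= 0 or vol_int <= 0:
        raise DegenerateGeometryError(
            f"volume asymmetry undefined for nonpositive volumes ({vol_sig}, {vol_int})"
        )
    r = vol_sig / vol_int
    return r, max(r, 1.0 / r)


def anisotropy(points: np.ndarray) -> float:
    """Largest-to-smallest principal semi-axis ratio of a point cloud.

    Computed as the square root of the extreme-eigenvalue ratio of the
    cloud covariance; 1 means isotropic extension.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 4:
        raise DegenerateGeometryError("anisotropy needs at least 4 points")
    cov = np.cov(P, rowvar=False)
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 1e-14 * max(eig[-1], 1.0):
        raise DegenerateGeometryError(
            "smallest covariance eigenvalue is zero (degenerate cloud)",
            rank=int(np.sum(eig > 1e-14 * max(eig[-1], 1.0))),
        )
    return float(math.sqrt(eig[-1] / eig[0]))


@dataclass
class DualPolytope:
    """Per-circuitry geometry: the sig and int polytopes plus descriptors."""

    id: str
    vertices_sig: np.ndarray  # (36 x 18)
    vertices_int: np.ndarray
    proj_sig: np.ndarray  # (36 x 3)
    proj_int: np.ndarray
    barycenter_sig: np.ndarray  # (3,)
    barycenter_int: np.ndarray
    dbary: float
    vol_sig: float
    vol_int: float
    asym_ratio: float
    asym_symmetrized: float
    anisotropy_sig: float
    anisotropy_int: float
    degenerate_sig: bool = False
    degenerate_int: bool = False
    hull_sig: HullSummary | None = field(default=None, repr=False)
    hull_int: HullSummary | None = field(default=None, repr=False)

    @property
    def degenerate(self) -> bool:
        return self.degenerate_sig or self.degenerate_int


def _side_geometry(
    latent: np.ndarray, model: EmbeddingModel, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, bool, HullSummary | None]:
    """Vertices, projection, barycenter, volume, anisotropy for one side."""
    vertices = generate_vertices(latent, cfg.alpha, cfg.epsilon)
    proj = model.project(vertices, n_components=cfg.n_components)
    bary = barycenter(proj)
    hull: HullSummary | None = None
    degenerate = False
    if cfg.volume_space == "latent18":
        volume = crosspolytope_volume_closed_form(
            perturbation_deltas(latent, cfg.alpha, cfg.epsilon)
        )
        try:
            hull = compute_hull(proj)
        except DegenerateGeometryError:
            degenerate = True
    else:
        try:
            hull = compute_hull(proj)
            volume = hull.volume
        except DegenerateGeometryError:
            volume = DEGENERATE_VOLUME
            degenerate = True
    try:
        aniso = anisotropy(proj)
    except DegenerateGeometryError:
        aniso = float("nan")
    return vertices, proj, bary, volume, aniso, degenerate, hull


def build_dual_polytope(
    record: CircuitryRecord, model: EmbeddingModel, config: PipelineConfig | None = None
) -> DualPolytope:
    """Full geometric construction for one circuitry (both sides)."""
    cfg = config or PipelineConfig()
    lat_sig = build_latent_vector(record.sig, cfg)
    lat_int = build_latent_vector(record.int_, cfg)
    v_s, p_s, b_s, vol_s, an_s, deg_s, hull_s = _side_geometry(lat_sig, model, cfg)
    v_i, p_i, b_i, vol_i, an_i, deg_i, hull_i = _side_geometry(lat_int, model, cfg)
    dbary = barycenter_distance(b_s, b_i)
    if vol_s > 0 and vol_i > 0:
        ratio, sym = volume_asymmetry(vol_s, vol_i)
    else:
        ratio, sym = float("nan"), float("nan")
    return DualPolytope(
        id=record.id,
        vertices_sig=v_s,
        vertices_int=v_i,
        proj_sig=p_s,
        proj_int=p_i,
        barycenter_sig=b_s,
        barycenter_int=b_i,
        dbary=dbary,
        vol_sig=vol_s,
        vol_int=vol_i,
        asym_ratio=ratio,
        asym_symmetrized=sym,
        anisotropy_sig=an_s,
        anisotropy_int=an_i,
        degenerate_sig=deg_s,
        degenerate_int=deg_i,
        hull_sig=hull_s,
        hull_int=hull_i,
    )
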