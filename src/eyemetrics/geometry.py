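"""Per-ommatidium optical geometry from crystalline-cone centers.

The chain of measurements mirrors how compound-eye optics are read off a
cloud of cone centers:

* a local eye radius ``R`` from a least-squares sphere through each center's
  60-point neighborhood (a hexagonal array four ommatidia out);
* the ommatidial diameter ``D`` as the mean distance to the 6 nearest
  neighbors;
* the interommatidial angle ``Δφ`` as the mean angle between radial vectors
  (from the local sphere center) of a cone and its 6 nearest neighbors;
* the diffraction-limited resolving power ``θ = 1.22 λ / D`` (λ = 0.5 μm by
  default, the broad peak of sunlight and insect photoreceptor sensitivity);
* the Barlow ratio ``Δφ / θ`` (dimensionless; ≈1 at the classical optimum)
  and Snyder's eye parameter ``p = D·Δφ`` in μm·rad, which equals
  ``0.61·(Δφ/θ)`` exactly at λ = 0.5 μm.

Angles are reported in degrees throughout; all internal trigonometry is in
radians.  Records with ``Δφ > 90°`` are biologically implausible edge
artifacts and are excluded with an explicit reason rather than deleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SphereFit",
    "OpticalConstants",
    "DEFAULT_CONSTANTS",
    "DegenerateSphereFitError",
    "fit_sphere",
    "local_sphere_fits",
    "nearest_neighbors",
    "ommatidial_diameters",
    "interommatidial_angles",
    "resolving_power",
    "barlow_ratio",
    "snyder_eye_parameter",
    "diameter_bias_bound",
    "radial_axes",
    "compute_ommatidium_metrics",
    "apply_metric_filters",
]

_COND_LIMIT = 1e8  # condition number above which a cluster is treated as coplanar


class DegenerateSphereFitError(ValueError):
    """Raised when a point cluster is too flat/collinear to define a sphere."""


@dataclass
class SphereFit:
    """A fitted sphere: local eye radius and the origin for radial vectors."""

    center_um: np.ndarray
    radius_um: float
    rms_residual_um: float
    n_points: int


@dataclass(frozen=True)
class OpticalConstants:
    wavelength_um: float = 0.5
    airy_coefficient: float = 1.22
    optimal_barlow_low: float = 0.4
    optimal_barlow_high: float = 1.0
    snyder_coefficient: float = 0.61

    def __post_init__(self) -> None:
        if not self.wavelength_um > 0:
            raise ValueError("wavelength_um must be positive")


DEFAULT_CONSTANTS = OpticalConstants()


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere through ≥4 non-coplanar points.

    Algebraic (linearized) fit — minimize the residuals of
    ``‖x‖² − 2 c·x + ‖c‖² − R²`` over center ``c`` and radius ``R`` — followed
    by one Gauss–Newton refinement of the geometric distance residuals.
    Deterministic and exact on noiseless spheres.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")

    centroid = pts.mean(axis=0)
    q = pts - centroid
    scale = math.sqrt(np.mean(np.sum(q * q, axis=1)))
    if scale <= 0:
        raise DegenerateSphereFitError("all points coincide")
    q = q / scale

    A = np.column_stack([2.0 * q, np.ones(len(q))])
    if np.linalg.cond(A) > _COND_LIMIT:
        raise DegenerateSphereFitError(
            f"cluster of {len(pts)} points is coplanar/collinear "
            "(ill-conditioned sphere fit)"
        )
    b = np.sum(q * q, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateSphereFitError("algebraic fit produced a nonpositive radius")
    R = math.sqrt(r2)

    # one Gauss-Newton pass on the geometric residuals |p - c| - R
    d = q - c
    dist = np.linalg.norm(d, axis=1)
    J = np.column_stack([-d / dist[:, None], -np.ones(len(q))])
    resid = dist - R
    delta, *_ = np.linalg.lstsq(J, -resid, rcond=None)
    c = c + delta[:3]
    R = R + delta[3]
    if R <= 0 or not np.isfinite(R):
        raise DegenerateSphereFitError("refinement produced a nonpositive radius")

    center = centroid + c * scale
    radius = R * scale
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return SphereFit(center, float(radius), rms, len(pts))


def _neighbor_order(centers: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-focal ordering of all other points by (distance, label).

    Returns an (n, n-1) index array; ties in distance (exact on lattice data)
    break deterministically by ascending label.
    """
    n = len(centers)
    order = np.empty((n, n - 1), dtype=np.intp)
    for i in range(n):
        d = np.linalg.norm(centers - centers[i], axis=1)
        idx = np.lexsort((labels, d))
        order[i] = idx[idx != i][: n - 1]
    return order


def nearest_neighbors(
    centers: np.ndarray, k: int, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of each center's ``k`` nearest neighbors."""
    centers = np.asarray(centers, dtype=np.float64)
    n = len(centers)
    if k > n - 1:
        raise ValueError(f"k_neighbors={k} exceeds available centers - 1 = {n - 1}")
    labels = np.arange(n) if labels is None else np.asarray(labels)
    order = _neighbor_order(centers, labels)[:, :k]
    dists = np.linalg.norm(centers[order] - centers[:, None, :], axis=-1)
    return order, dists


def local_sphere_fits(
    centers: np.ndarray,
    cluster_size: int = 60,
    labels: np.ndarray | None = None,
    *,
    on_degenerate: str = "raise",
) -> tuple[list[SphereFit | None], bool]:
    """Fit a sphere to each center's ``cluster_size``-point neighborhood.

    The cluster is the focal center plus its ``cluster_size − 1`` nearest
    centers (the default 60 covers a hexagonal array ~4 ommatidia out).  If
    fewer than ``cluster_size`` centers exist, a single global fit serves
    every record and the returned warning flag is set.  With
    ``on_degenerate="flag"`` a coplanar cluster yields ``None`` instead of
    raising.
    """
    centers = np.asarray(centers, dtype=np.float64)
    n = len(centers)
    labels = np.arange(n) if labels is None else np.asarray(labels)
    if on_degenerate not in ("raise", "flag"):
        raise ValueError("on_degenerate must be 'raise' or 'flag'")

    if n < cluster_size:
        fit = fit_sphere(centers)
        return [fit] * n, True

    order = _neighbor_order(centers, labels)
    fits: list[SphereFit | None] = []
    for i in range(n):
        cluster = np.vstack([centers[i : i + 1], centers[order[i, : cluster_size - 1]]])
        try:
            fits.append(fit_sphere(cluster))
        except DegenerateSphereFitError:
            if on_degenerate == "raise":
                raise DegenerateSphereFitError(
                    f"degenerate sphere fit for cluster around center {labels[i]}"
                )
            fits.append(None)
    return fits, False


def ommatidial_diameters(
    centers: np.ndarray,
    k_neighbors: int = 6,
    labels: np.ndarray | None = None,
    *,
    neighbor_dists: np.ndarray | None = None,
) -> np.ndarray:
    """Ommatidial diameter D: mean distance to the 6 nearest centers (μm)."""
    if neighbor_dists is None:
        _, neighbor_dists = nearest_neighbors(centers, k_neighbors, labels)
    return neighbor_dists.mean(axis=1)


def interommatidial_angles(
    centers: np.ndarray,
    fits: list[SphereFit | None],
    k_neighbors: int = 6,
    labels: np.ndarray | None = None,
    *,
    neighbor_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Interommatidial angle Δφ (degrees): mean angle to 6 nearest radial vectors.

    Radial vectors for the focal cone *and* its neighbors all originate at the
    focal cone's local sphere center (one consistent origin per record), and
    angles use the numerically stable ``atan2(‖v×w‖, v·w)``.  Records whose
    fit is ``None`` (degenerate cluster) get NaN.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if len(fits) != len(centers):
        raise ValueError("need one sphere fit per center")
    if neighbor_idx is None:
        neighbor_idx, _ = nearest_neighbors(centers, k_neighbors, labels)
    dphi = np.full(len(centers), np.nan)
    for i, fit in enumerate(fits):
        if fit is None:
            continue
        v = centers[i] - fit.center_um
        w = centers[neighbor_idx[i]] - fit.center_um
        cross = np.linalg.norm(np.cross(np.broadcast_to(v, w.shape), w), axis=1)
        dot = w @ v
        dphi[i] = np.degrees(np.mean(np.arctan2(cross, dot)))
    return dphi


def resolving_power(D_um, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Diffraction-limited resolving power θ = 1.22 λ / D, in degrees."""
    D = np.asarray(D_um, dtype=np.float64)
    if np.any(D[np.isfinite(D)] <= 0):
        raise ValueError("diameter must be positive")
    theta = np.degrees(constants.airy_coefficient * constants.wavelength_um / D)
    return float(theta) if np.isscalar(D_um) else theta


def barlow_ratio(delta_phi_deg, theta_deg):
    """Barlow ratio Δφ/θ (dimensionless; both angles in the same unit)."""
    theta = np.asarray(theta_deg, dtype=np.float64)
    if np.any(theta[np.isfinite(theta)] <= 0):
        raise ValueError("resolving power must be positive")
    out = np.asarray(delta_phi_deg, dtype=np.float64) / theta
    return float(out) if np.isscalar(theta_deg) else out


def snyder_eye_parameter(
    D_um, delta_phi_deg, constants: OpticalConstants = DEFAULT_CONSTANTS
):
    """Snyder eye parameter p = D·Δφ in μm·rad.

    At λ = 0.5 μm this equals ``0.61·(Δφ/θ)`` identically (0.61 = 1.22·λ/2
    with λ in μm... concretely 1.22 × 0.5), so p = 0.61 when the Barlow ratio
    is exactly 1.
    """
    p = np.asarray(D_um, dtype=np.float64) * np.radians(delta_phi_deg)
    return float(p) if np.isscalar(D_um) else p


def diameter_bias_bound(delta_phi_deg, cone_length_um):
    """Bound on the systematic underestimate of D (μm).

    Cone centers of mass lie below the facet surface, so center-to-center
    distances underestimate the facet diameter by at most a fraction of the
    cone length times Δφ in radians — of order 2 μm for typical values.
    """
    out = np.asarray(cone_length_um, dtype=np.float64) * np.radians(delta_phi_deg)
    return float(out) if np.isscalar(delta_phi_deg) else out


def radial_axes(centers: np.ndarray, fits: list[SphereFit | None]) -> np.ndarray:
    """Outward unit radial axis per cone: (center − local sphere center), normalized."""
    centers = np.asarray(centers, dtype=np.float64)
    axes = np.full_like(centers, np.nan)
    for i, fit in enumerate(fits):
        if fit is None:
            continue
        v = centers[i] - fit.center_um
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError(f"center {i} coincides with its fitted sphere center")
        axes[i] = v / nrm
    return axes


def compute_ommatidium_metrics(
    centers: np.ndarray,
    labels: np.ndarray | None = None,
    *,
    cluster_size: int = 60,
    k_neighbors: int = 6,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    edge_factor: float = 1.8,
) -> pd.DataFrame:
    """Full per-ommatidium metrics table for one eye.

    Runs local sphere fits, D, Δφ, θ, Barlow ratio and the Snyder eye
    parameter, then applies the exclusion rules (Δφ > 90°, degenerate fits)
    and the edge heuristic.  Columns: ``label, x_um, y_um, z_um, D_um,
    delta_phi_deg, theta_deg, barlow_ratio, eye_parameter_um_rad, R_local_um,
    rms_residual_um, n_fit_points, global_fit_warning, neighbor_labels,
    max_neighbor_dist_um, is_edge, excluded, reason``.
    """
    centers = np.asarray(centers, dtype=np.float64)
    n = len(centers)
    labels = np.arange(1, n + 1) if labels is None else np.asarray(labels)

    neighbor_idx, neighbor_dists = nearest_neighbors(centers, k_neighbors, labels)
    fits, global_warning = local_sphere_fits(
        centers, cluster_size, labels, on_degenerate="flag"
    )
    D = ommatidial_diameters(centers, k_neighbors, neighbor_dists=neighbor_dists)
    dphi = interommatidial_angles(centers, fits, k_neighbors, neighbor_idx=neighbor_idx)
    theta = resolving_power(D, constants)

    df = pd.DataFrame(
        {
            "label": labels,
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
            "z_um": centers[:, 2],
            "D_um": D,
            "delta_phi_deg": dphi,
            "theta_deg": theta,
            "barlow_ratio": barlow_ratio(dphi, theta),
            "eye_parameter_um_rad": snyder_eye_parameter(D, dphi, constants),
            "R_local_um": [f.radius_um if f else np.nan for f in fits],
            "rms_residual_um": [f.rms_residual_um if f else np.nan for f in fits],
            "n_fit_points": [f.n_points if f else 0 for f in fits],
            "global_fit_warning": global_warning,
            "neighbor_labels": [
                ";".join(str(labels[j]) for j in row) for row in neighbor_idx
            ],
            "max_neighbor_dist_um": neighbor_dists.max(axis=1),
        }
    )
    return apply_metric_filters(df, edge_factor=edge_factor, neighbor_dists=neighbor_dists)


def apply_metric_filters(
    metrics: pd.DataFrame,
    *,
    edge_factor: float = 1.8,
    neighbor_dists: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply exclusion rules and the edge-cone flag to a metrics table.

    Exclusions (recorded with a reason, never silently dropped):

    * ``angle>90`` — interommatidial angles above 90° are biologically
      implausible edge/defect artifacts;
    * ``degenerate_fit`` — the local sphere fit was coplanar (NaN radius).

    A cone is flagged ``is_edge`` (without being excluded) when any of its
    nearest-neighbor distances exceeds ``edge_factor`` times the eye-wide
    median neighbor distance — at a lattice border the neighbor set reaches
    into the second ring.
    """
    df = metrics.copy()
    excluded = np.zeros(len(df), dtype=bool)
    reason = np.array([""] * len(df), dtype=object)

    degenerate = df["R_local_um"].isna().to_numpy()
    excluded |= degenerate
    reason[degenerate] = "degenerate_fit"

    big_angle = (df["delta_phi_deg"] > 90).fillna(False).to_numpy()
    apply = big_angle & ~excluded
    excluded |= apply
    reason[apply] = "angle>90"

    if neighbor_dists is not None:
        med = np.median(neighbor_dists)  # eye-wide median over all neighbor pairs
        df["is_edge"] = neighbor_dists.max(axis=1) > edge_factor * med
    elif "max_neighbor_dist_um" in df:
        med = np.median(df["max_neighbor_dist_um"])
        df["is_edge"] = df["max_neighbor_dist_um"].to_numpy() > edge_factor * med
    else:
        df["is_edge"] = False
    df["excluded"] = excluded
    df["reason"] = reason
    return df
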