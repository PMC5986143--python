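"""Spatial morphometrics: membrane-layer occupancy, proximal-vesicle
statistics, radial density traces with lumen classification, distances to
microtubules, and polyline curvature.

Distance conventions: all distance fields are Euclidean distance transforms
over voxel centers. Surface-to-surface distances between labeled objects are
estimated as the minimum center-to-center distance minus one voxel (label
voxels sit about half a voxel inside the true surface on either side), floored
at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import DensityVolume, LabelVolume

__all__ = [
    "RadialTrace",
    "CurvatureMeasure",
    "layer_occupancy",
    "proximal_stats",
    "radial_trace",
    "classify_lumen",
    "select_dcv",
    "distance_to_microtubule",
    "polyline_curvature",
    "curvature_to_angular",
]


# ---------------------------------------------------------------------------
# layers parallel to the plasma membrane

def layer_occupancy(labels: LabelVolume, membrane_id: int,
                    vesicle_ids: Sequence[int],
                    max_distance_nm: float) -> pd.DataFrame:
    """Vesicle volume fraction in 1-voxel-thick layers parallel to the
    plasma membrane.

    Layer k (1-based) holds voxels whose center lies at distance
    ((k-1)*voxel, k*voxel] from the nearest membrane voxel. Occupancy is the
    fraction of the layer's vesicle + cytoplasm voxels that carry a vesicle
    label; other boundary voxels (microtubules etc.) are excluded from both
    numerator and denominator.
    """
    lab = labels.labels
    voxel = labels.voxel_size_nm
    membrane = lab == membrane_id
    if not membrane.any():
        raise ValueError(f"membrane boundary {membrane_id} is empty")
    dist = ndimage.distance_transform_edt(~membrane, sampling=voxel)
    vesicle_mask = np.isin(lab, np.asarray(list(vesicle_ids), dtype=lab.dtype)) \
        if len(vesicle_ids) else np.zeros(lab.shape, bool)
    countable = (lab == 0) | vesicle_mask

    n_layers = int(math.floor(max_distance_nm / voxel))
    rows = []
    for k in range(1, n_layers + 1):
        in_layer = (dist > (k - 1) * voxel) & (dist <= k * voxel) & countable
        total = int(in_layer.sum())
        nves = int((in_layer & vesicle_mask).sum())
        rows.append({"layer_index": k, "distance_nm": k * voxel,
                     "occupancy": nves / total if total else 0.0,
                     "layer_voxel_count": total})
    return pd.DataFrame(rows, columns=["layer_index", "distance_nm",
                                       "occupancy", "layer_voxel_count"])


def proximal_stats(labels: LabelVolume, membrane_id: int,
                   vesicle_ids: Sequence[int], proximal_nm: float = 45.0,
                   area_window_nm: float = 250.0) -> dict:
    """Count vesicles within ``proximal_nm`` of the plasma membrane and the
    vesicle density per um^2 of nearby membrane area.

    A vesicle is proximal iff its minimum surface-to-membrane distance is
    <= proximal_nm. Only membrane within ``area_window_nm`` of any vesicle is
    included in the area; area is the summed cytosol-facing voxel faces.
    """
    lab = labels.labels
    voxel = labels.voxel_size_nm
    membrane = lab == membrane_id
    if not membrane.any():
        raise ValueError(f"membrane boundary {membrane_id} is empty")
    dist = ndimage.distance_transform_edt(~membrane, sampling=voxel)

    distances = {}
    for vid in vesicle_ids:
        m = lab == vid
        if not m.any():
            raise ValueError(f"vesicle {vid} has no voxels")
        distances[int(vid)] = max(float(dist[m].min()) - voxel, 0.0)
    n_proximal = sum(1 for d in distances.values() if d <= proximal_nm)

    # membrane voxels near any vesicle
    vesicle_mask = np.isin(lab, np.asarray(list(vesicle_ids), dtype=lab.dtype)) \
        if len(vesicle_ids) else np.zeros(lab.shape, bool)
    if vesicle_mask.any():
        dv = ndimage.distance_transform_edt(~vesicle_mask, sampling=voxel)
        included = membrane & (dv <= area_window_nm)
    else:
        included = np.zeros(lab.shape, bool)

    # cytosol-facing faces: membrane voxel face adjacent to an unlabeled voxel
    free = lab == 0
    faces = 0
    for axis in range(3):
        for d in (1, -1):
            shifted = np.roll(free, d, axis=axis)
            # voxels rolled across the volume edge do not face anything
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if d == 1 else slice(-1, None)
            shifted[tuple(edge)] = False
            faces += int((included & shifted).sum())
    area_um2 = faces * (voxel ** 2) / 1e6

    if n_proximal and area_um2 == 0:
        raise ValueError("proximal vesicles present but zero included membrane area")
    return {
        "n_proximal": n_proximal,
        "membrane_area_um2": area_um2,
        "density_per_um2": n_proximal / area_um2 if area_um2 > 0 else 0.0,
        "surface_distances_nm": distances,
    }


# ---------------------------------------------------------------------------
# radial density traces

@dataclass
class RadialTrace:
    """Mean density per concentric 1-voxel-thick shell around a vesicle.

    shell_index < 0 is the lumen side, > 0 the cytoplasm side, 0 the surface
    shell. Shells are one *original* voxel thick; means are computed on a 4x
    cubic-spline-interpolated grid.
    """

    shell_index: np.ndarray
    mean_density: np.ndarray
    voxel_size_nm: float

    @property
    def membrane_min_shell(self) -> int:
        return int(self.shell_index[int(np.argmin(self.mean_density))])

    def shell_value(self, k: int) -> float:
        (i,) = np.where(self.shell_index == k)
        if i.size == 0:
            raise KeyError(f"no shell {k}")
        return float(self.mean_density[i[0]])


def radial_trace(volume: DensityVolume, center_nm, radius_nm: float,
                 n_shells_each_side: int = 5, magnification: int = 4) -> RadialTrace:
    """Radial density trace of a spherical vesicle.

    The density is resampled on a ``magnification``-times finer grid with
    cubic-spline interpolation; concentric shells of one original-voxel
    thickness are built inward (negative indices) and outward (positive) from
    the sphere surface at ``radius_nm``.
    """
    center = np.asarray(center_nm, dtype=float)
    voxel = volume.voxel_size_nm
    n = int(n_shells_each_side)
    if n < 1:
        raise ValueError("need at least 1 shell on each side")
    reach = radius_nm + (n + 0.5) * voxel
    extent = np.array(volume.shape) * voxel
    if np.any(center - reach < 0) or np.any(center + reach > extent):
        raise ValueError("shells exceed the volume bounds")

    step = voxel / magnification
    offs = np.arange(-reach, reach + step / 2, step)
    zz = center[0] + offs
    yy = center[1] + offs
    xx = center[2] + offs
    # physical position -> index coordinate of voxel centers
    iz = zz / voxel - 0.5
    iy = yy / voxel - 0.5
    ix = xx / voxel - 0.5
    grid = np.meshgrid(iz, iy, ix, indexing="ij")
    fine = ndimage.map_coordinates(volume.data.astype(float), np.array(grid),
                                   order=3, mode="nearest")

    dz = offs[:, None, None]
    dy = offs[None, :, None]
    dx = offs[None, None, :]
    r = np.sqrt(dz ** 2 + dy ** 2 + dx ** 2)
    shell = np.round((r - radius_nm) / voxel).astype(int)
    keep = (shell >= -n) & (shell <= n)
    idx = shell[keep] + n
    sums = np.bincount(idx, weights=fine[keep], minlength=2 * n + 1)
    cnts = np.bincount(idx, minlength=2 * n + 1)
    if np.any(cnts == 0):
        raise ValueError("empty shell encountered; increase magnification")
    return RadialTrace(shell_index=np.arange(-n, n + 1),
                       mean_density=sums / cnts, voxel_size_nm=voxel)


def classify_lumen(trace: RadialTrace, cytoplasm_mean: float,
                   cytoplasm_sd: float) -> str:
    """Classify a vesicle lumen from its radial trace.

    dense iff the interior lumen shells average below cytoplasm_mean - 1 sd;
    within dense, a halo is present iff some shell strictly between the
    membrane minimum and the core rises to >= cytoplasm_mean - 0.5 sd.
    Degenerate flat traces are classified 'light'.
    """
    if np.allclose(trace.mean_density, trace.mean_density[0]):
        return "light"  # flat trace: no membrane minimum, tie resolved light
    m0 = trace.membrane_min_shell
    interior = trace.shell_index <= m0 - 2
    if interior.sum() < 3:
        raise ValueError("need at least 3 interior lumen shells to classify")
    lumen_vals = trace.mean_density[interior]
    lumen_idx = trace.shell_index[interior]
    if lumen_vals.mean() >= cytoplasm_mean - cytoplasm_sd:
        return "light"
    core_shell = int(lumen_idx[int(np.argmin(lumen_vals))])
    between = (trace.shell_index > core_shell) & (trace.shell_index < m0)
    if between.any() and np.any(trace.mean_density[between]
                                >= cytoplasm_mean - 0.5 * cytoplasm_sd):
        return "dense_halo"
    return "dense_nohalo"


def select_dcv(vesicle_table: pd.DataFrame, min_diameter_nm: float = 70.0,
               max_diameter_nm: float = 90.0) -> pd.DataFrame:
    """Dense-core vesicle selection: dark lumen and diameter 70-90 nm."""
    dense = vesicle_table["lumen_class"].isin(["dense_halo", "dense_nohalo"])
    in_range = vesicle_table["diameter_nm"].between(min_diameter_nm, max_diameter_nm)
    return vesicle_table[dense & in_range].reset_index(drop=True)


def distance_to_microtubule(labels: LabelVolume, vesicle_id: int,
                            microtubule_ids: Optional[Sequence[int]] = None
                            ) -> Optional[float]:
    """Minimum surface-to-surface distance (nm) from a vesicle to any
    microtubule; None if there are no microtubules."""
    if microtubule_ids is None:
        microtubule_ids = labels.ids_of_kind("microtubule")
    if not len(microtubule_ids):
        return None
    lab = labels.labels
    voxel = labels.voxel_size_nm
    mt = np.isin(lab, np.asarray(list(microtubule_ids), dtype=lab.dtype))
    if not mt.any():
        return None
    ves = lab == vesicle_id
    if not ves.any():
        raise ValueError(f"vesicle {vesicle_id} has no voxels")
    dist = ndimage.distance_transform_edt(~mt, sampling=voxel)
    return max(float(dist[ves].min()) - voxel, 0.0)


# ---------------------------------------------------------------------------
# curvature

@dataclass
class CurvatureMeasure:
    """Curvature of a polyline: inverse circumradius (1/um) maximised over
    interior points, plus the chord-sampled angular rate (rad/um)."""

    kappa_per_um: float
    point_spacing_um: float
    angular_per_um: float


def _resample_polyline(points_um: np.ndarray, d: float) -> np.ndarray:
    """Resample to equal (chordal) arc spacing d; original vertices that fall
    exactly on a multiple of d are preserved."""
    seg = np.linalg.norm(np.diff(points_um, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 2 * d:
        raise ValueError("polyline shorter than two point spacings")
    targets = np.arange(0.0, total + 1e-12, d)
    out = np.empty((targets.size, 3))
    for dim in range(3):
        out[:, dim] = np.interp(targets, s, points_um[:, dim])
    # snap to original vertices where the arclength matches exactly
    for i, t in enumerate(targets):
        j = np.argmin(np.abs(s - t))
        if abs(s[j] - t) < 1e-9:
            out[i] = points_um[j]
    return out


def _circum_curvature(a, b, c) -> float:
    """Inverse circumradius of the circle through three points (0 if collinear)."""
    ab = b - a
    ac = c - a
    bc = c - b
    cross = np.cross(ab, ac)
    area2 = np.linalg.norm(cross)  # 2 * triangle area
    if area2 < 1e-14:
        return 0.0
    la, lb, lc = np.linalg.norm(bc), np.linalg.norm(ac), np.linalg.norm(ab)
    return float(2 * area2 / (la * lb * lc))


def polyline_curvature(points_nm, spacing_um: float = 0.5) -> CurvatureMeasure:
    """Maximum three-point (circumscribed-circle) curvature along a polyline.

    The polyline is resampled to equal spacing ``spacing_um``; for each
    interior point, kappa = 1/R of the circle through it and its two
    neighbors; the maximum over the polyline is reported together with its
    chord-angle conversion.
    """
    pts = np.asarray(points_nm, dtype=float) / 1000.0  # nm -> um
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need an (n >= 3, 3) array of points")
    res = _resample_polyline(pts, spacing_um)
    if res.shape[0] < 3:
        raise ValueError("resampled polyline has fewer than 3 points")
    kappas = [_circum_curvature(res[i - 1], res[i], res[i + 1])
              for i in range(1, res.shape[0] - 1)]
    kmax = float(max(kappas))
    return CurvatureMeasure(kappa_per_um=kmax, point_spacing_um=spacing_um,
                            angular_per_um=curvature_to_angular(kmax, spacing_um))


def curvature_to_angular(kappa_per_um: float, d_um: float) -> float:
    """Convert inverse-radius curvature to the turning angle per unit length
    of successive chords of length d on a circle of curvature kappa:
    2 arcsin(kappa d / 2) / d."""
    if kappa_per_um < 0 or d_um <= 0:
        raise ValueError("need kappa >= 0 and d > 0")
    x = kappa_per_um * d_um / 2.0
    if x > 1:
        raise ValueError("curvature radius smaller than half the chord spacing")
    return 2.0 * math.asin(x) / d_um
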