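"""Synthetic tomogram phantoms with known ground truth.

Generates density/label volume pairs that emulate neuronal boutons as seen in
denoised cryo-electron tomograms: spherical vesicles (synaptic ~40 nm, medium
50-120 nm with dense-core / halo / light-lumen variants), a plasma-membrane
slab, microtubules as curved hollow tubes, thin linker bridges (connectors
between vesicles, tethers from vesicles to the plasma membrane), free-standing
membrane protrusions, and additive Gaussian noise on the density only.

The density convention is *lower value = denser*. Defaults are chosen to
mirror the real imaging conditions the analysis targets: 3.2 nm voxels,
synaptic vesicle diameter 40 nm, dense-core vesicles 70-90 nm, connector
lengths with mean 15.5 nm and sd 7.7 nm, tether lengths 19.8 +/- 11.7 nm.

Linker gap lengths are drawn from a normal truncated below at 2 voxels (a
linker shorter than that has no cytoplasmic voxel support), with the parent
parameters solved so that the *realised* truncated distribution has exactly
the requested mean and sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy import stats as sps

from .volumes import Boundary, DensityVolume, LabelVolume

__all__ = [
    "VesicleSpec",
    "MembraneSpec",
    "MicrotubuleSpec",
    "LinkerSpec",
    "ProtrusionSpec",
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "render_sphere_shell",
    "render_cylinder",
    "smooth_stand_in",
]

VESICLE_KINDS = ("sv", "dcv_halo", "dcv_nohalo", "light_medium")


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed within the retry cap."""


@dataclass
class VesicleSpec:
    """One population of spherical vesicles.

    lumen_density applies to the core (dcv kinds) or whole lumen; for 'sv'
    and 'light_medium' the lumen defaults to cytoplasm density.
    """

    kind: str = "sv"
    diameter_nm: float = 40.0
    count: int = 0
    lumen_density: Optional[float] = None
    halo_width_nm: float = 8.0
    centers_nm: Optional[Sequence[Sequence[float]]] = None

    def __post_init__(self):
        if self.kind not in VESICLE_KINDS:
            raise ValueError(f"unknown vesicle kind {self.kind!r}")
        if self.diameter_nm <= 0:
            raise ValueError("diameter_nm must be positive")


@dataclass
class MembraneSpec:
    """Plasma membrane as a flat slab at the low-z face of the volume."""

    thickness_nm: float = 6.4


@dataclass
class MicrotubuleSpec:
    """Hollow tube swept along a polyline (points in nm, (z, y, x))."""

    points_nm: Sequence[Sequence[float]] = ()
    outer_radius_nm: float = 12.5
    inner_radius_nm: float = 7.5


@dataclass
class LinkerSpec:
    """Connector (vesicle-vesicle) or tether (vesicle-plasma membrane) spec.

    fraction_of_vesicles_connected controls how many vesicles take part;
    topology is 'pairs' (random nearest pairs), 'chain' or 'star'.
    """

    fraction_of_vesicles_connected: float = 0.0
    length_mean_nm: float = 15.5
    length_sd_nm: float = 7.7
    radius_nm: float = 2.4
    density: Optional[float] = None  # default: membrane density (protein >= lipid)
    topology: str = "pairs"

    def __post_init__(self):
        if not 0.0 <= self.fraction_of_vesicles_connected <= 1.0:
            raise ValueError("fraction_of_vesicles_connected must be in [0, 1]")
        if self.length_mean_nm <= 0:
            raise ValueError("linker length mean must be positive")
        if self.topology not in ("pairs", "chain", "star"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class ProtrusionSpec:
    """Free-standing rods attached to vesicle membranes."""

    per_vesicle_count: int = 0
    length_nm: float = 9.6
    radius_nm: float = 2.0
    density: Optional[float] = None  # default: membrane density


@dataclass
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_nm: float = 3.2
    rng_seed: int = 0
    cytoplasm_density_mean: float = 0.0
    cytoplasm_density_sd: float = 0.0
    membrane_density_mean: float = -2.0
    membrane_thickness_nm: float = 4.8
    vesicles: list[VesicleSpec] = field(default_factory=list)
    plasma_membrane: Optional[MembraneSpec] = None
    microtubules: list[MicrotubuleSpec] = field(default_factory=list)
    connectors: Optional[LinkerSpec] = None
    tethers: Optional[LinkerSpec] = None
    protrusions: Optional[ProtrusionSpec] = None
    noise_sd: float = 0.0
    # minimum surface separation between objects not joined by a linker;
    # None -> 6 voxels, enough that smoothed membrane halos stay disjoint
    min_separation_nm: Optional[float] = None


@dataclass
class GroundTruth:
    """Per-object truth tables for a generated phantom."""

    vesicles: pd.DataFrame      # boundary_id, kind, center z/y/x nm, diameter_nm
    linkers: pd.DataFrame       # linker_id, boundary_id_1, boundary_id_2, gap_nm, class
    protrusions: pd.DataFrame   # protrusion_id, boundary_id, length_nm
    microtubules: list[np.ndarray]
    linker_voxels: dict[int, np.ndarray] = field(default_factory=dict)
    protrusion_voxels: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level rasterisation

def _voxel_centers_grid(shape, voxel, bbox):
    """Open grids of voxel-center coordinates (nm) over an index bbox."""
    (z0, z1), (y0, y1), (x0, x1) = bbox
    z = (np.arange(z0, z1) + 0.5) * voxel
    y = (np.arange(y0, y1) + 0.5) * voxel
    x = (np.arange(x0, x1) + 0.5) * voxel
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _clip_bbox(shape, lo_nm, hi_nm, voxel):
    bbox = []
    for ax in range(3):
        a = int(np.floor(lo_nm[ax] / voxel)) - 1
        b = int(np.ceil(hi_nm[ax] / voxel)) + 2
        bbox.append((max(a, 0), min(b, shape[ax])))
    return bbox


def render_sphere_shell(center_nm, inner_radius_nm, outer_radius_nm, value,
                        data: np.ndarray, voxel_size_nm: float) -> np.ndarray:
    """Set voxels whose center lies in [inner, outer) of ``center_nm``.

    Modifies ``data`` in place and returns the boolean mask of voxels set.
    Raises if the shell extends outside the volume.
    """
    center = np.asarray(center_nm, dtype=float)
    if inner_radius_nm < 0 or outer_radius_nm < 0 or inner_radius_nm > outer_radius_nm:
        raise ValueError("need 0 <= inner_radius <= outer_radius")
    extent = np.array(data.shape) * voxel_size_nm
    if np.any(center - outer_radius_nm < 0) or np.any(center + outer_radius_nm > extent):
        raise ValueError("sphere shell extends outside the volume")
    mask = np.zeros(data.shape, dtype=bool)
    if inner_radius_nm == outer_radius_nm:
        return mask
    bbox = _clip_bbox(data.shape, center - outer_radius_nm, center + outer_radius_nm,
                      voxel_size_nm)
    z, y, x = _voxel_centers_grid(data.shape, voxel_size_nm, bbox)
    d2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    sub = (d2 >= inner_radius_nm ** 2) & (d2 < outer_radius_nm ** 2)
    (z0, z1), (y0, y1), (x0, x1) = bbox
    view = data[z0:z1, y0:y1, x0:x1]
    view[sub] = value
    mask[z0:z1, y0:y1, x0:x1] = sub
    return mask


def render_cylinder(p0_nm, p1_nm, radius_nm, value, data: np.ndarray,
                    voxel_size_nm: float, where: Optional[np.ndarray] = None) -> np.ndarray:
    """Set voxels within ``radius_nm`` of the segment p0-p1 to ``value``.

    ``where`` optionally restricts rendering (e.g. unlabeled voxels only).
    Returns the boolean mask of voxels set.
    """
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    lo = np.minimum(p0, p1) - radius_nm
    hi = np.maximum(p0, p1) + radius_nm
    bbox = _clip_bbox(data.shape, lo, hi, voxel_size_nm)
    z, y, x = _voxel_centers_grid(data.shape, voxel_size_nm, bbox)
    axis = p1 - p0
    L2 = float(axis @ axis)
    dz, dy, dx = z - p0[0], y - p0[1], x - p0[2]
    if L2 == 0:
        d2 = dz ** 2 + dy ** 2 + dx ** 2
        sub = d2 <= radius_nm ** 2
    else:
        t = (dz * axis[0] + dy * axis[1] + dx * axis[2]) / L2
        t = np.clip(t, 0.0, 1.0)
        qz = dz - t * axis[0]
        qy = dy - t * axis[1]
        qx = dx - t * axis[2]
        sub = qz ** 2 + qy ** 2 + qx ** 2 <= radius_nm ** 2
    (z0, z1), (y0, y1), (x0, x1) = bbox
    if where is not None:
        sub &= where[z0:z1, y0:y1, x0:x1]
    view = data[z0:z1, y0:y1, x0:x1]
    view[sub] = value
    mask = np.zeros(data.shape, dtype=bool)
    mask[z0:z1, y0:y1, x0:x1] = sub
    return mask


def _traverse_voxels(p0_nm, p1_nm, voxel: float, shape) -> np.ndarray:
    """Voxels pierced by the segment p0-p1, in order (Amanatides-Woo traversal).

    Crossing one voxel face at a time guarantees the visited voxels form a
    6-connected chain, which thin-cylinder rasterisation alone does not.
    """
    p0 = np.asarray(p0_nm, float) / voxel
    p1 = np.asarray(p1_nm, float) / voxel
    d = p1 - p0
    ijk = np.floor(p0).astype(int)
    end = np.floor(p1).astype(int)
    step = np.where(d > 0, 1, -1)
    tmax = np.empty(3)
    tdelta = np.empty(3)
    for ax in range(3):
        if d[ax] != 0:
            nxt = ijk[ax] + (1 if d[ax] > 0 else 0)
            tmax[ax] = (nxt - p0[ax]) / d[ax]
            tdelta[ax] = abs(1.0 / d[ax])
        else:
            tmax[ax] = np.inf
            tdelta[ax] = np.inf
    out = [ijk.copy()]
    guard = int(np.abs(end - ijk).sum()) + 8
    for _ in range(guard):
        if np.array_equal(ijk, end):
            break
        ax = int(np.argmin(tmax))
        ijk[ax] += step[ax]
        tmax[ax] += tdelta[ax]
        out.append(ijk.copy())
    vox = np.array(out)
    keep = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    return vox[keep]


def _render_linker(p0_nm, p1_nm, radius_nm, value, data, voxel, where,
                   overshoot_nm) -> np.ndarray:
    """Rasterise a linker: radius cylinder plus a 6-connected core line.

    The core line overshoots both endpoints (into the boundaries) so the
    rendered chain is face-adjacent to both boundary label sets; rendering is
    restricted to ``where`` (unlabeled voxels), so boundaries are untouched.
    """
    p0 = np.asarray(p0_nm, float)
    p1 = np.asarray(p1_nm, float)
    over = overshoot_nm if isinstance(overshoot_nm, tuple) \
        else (overshoot_nm, overshoot_nm)
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    mask = render_cylinder(p0, p1, radius_nm, value, data, voxel, where=where)
    line = _traverse_voxels(p0 - u * over[0], p1 + u * over[1],
                            voxel, data.shape)
    sel = where[tuple(line.T)]
    line = line[sel]
    data[tuple(line.T)] = value
    mask[tuple(line.T)] = True
    return mask


def smooth_stand_in(volume: DensityVolume, sigma_nm: float) -> DensityVolume:
    """Gaussian low-pass with a physical sigma; a simple denoising stand-in.

    sigma_nm = 0 returns the volume unchanged.
    """
    if sigma_nm < 0:
        raise ValueError("sigma_nm must be >= 0")
    if sigma_nm == 0:
        return DensityVolume(volume.data.copy(), volume.voxel_size_nm,
                             volume.origin_nm.copy())
    smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma_nm / volume.voxel_size_nm)
    return DensityVolume(smoothed, volume.voxel_size_nm, volume.origin_nm.copy())


# ---------------------------------------------------------------------------
# gap-length sampling

def truncated_normal_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (mu, sigma) such that N(mu, sigma) truncated at ``lower`` has
    the requested mean and sd."""
    if mean <= lower:
        raise ValueError(f"requested mean {mean} not above truncation bound {lower}")
    if sd <= 0:
        return mean, 0.0
    if (mean - lower) / sd > 6:  # truncation negligible
        return mean, sd

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        m, v = sps.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"could not calibrate truncated normal: {sol.message}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _sample_gap(rng, mean, sd, lower):
    if sd == 0:
        return max(mean, lower)
    mu, sigma = truncated_normal_params(mean, sd, lower)
    a = (lower - mu) / sigma
    return float(sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng))


# ---------------------------------------------------------------------------
# phantom generation

_RETRY_CAP = 1000


def _segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between 3D segments p0-p1 and q0-q1."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:  # parallel
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # one refinement pass keeps the clamped solution consistent
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
        if c > 1e-12:
            t = np.clip((b * s + e) / c, 0.0, 1.0)
    return float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))


_MIN_LINKER_ANGLE_DEG = 80.0  # separation of linkers sharing a vesicle


class _Placer:
    """Tracks placed objects for overlap rejection."""

    def __init__(self, shape, voxel, membrane_top_nm):
        self.extent = np.array(shape) * voxel
        self.voxel = voxel
        self.membrane_top = membrane_top_nm  # z of membrane upper surface, or None
        self.spheres: list[tuple[object, np.ndarray, float]] = []  # (key, center, radius)
        self.tubes: list[tuple[np.ndarray, float]] = []    # (polyline, outer radius)
        self.linkers: list[tuple[np.ndarray, np.ndarray, float, tuple]] = []
        self.attach_dirs: dict[object, list[np.ndarray]] = {}

    def fits(self, center, radius, clearance, touch_membrane_gap=None, ignore_key=None):
        margin = radius + self.voxel
        if np.any(center - margin < 0) or np.any(center + margin > self.extent):
            return False
        if self.membrane_top is not None:
            gap = center[0] - radius - self.membrane_top
            if touch_membrane_gap is not None:
                if abs(gap - touch_membrane_gap) > 1e-9:
                    return False
            elif gap < clearance:
                return False
        for key, c, r in self.spheres:
            if key == ignore_key:
                continue
            if np.linalg.norm(center - c) < radius + r + clearance:
                return False
        for pts, r in self.tubes:
            d = _point_polyline_distance(center, pts)
            if d < radius + r + clearance:
                return False
        for q0, q1, r, _keys in self.linkers:
            if _point_polyline_distance(center, np.array([q0, q1])) \
                    < radius + r + clearance:
                return False
        return True

    def linker_clear(self, p0, p1, radius, exclude_keys, clearance) -> bool:
        """True if the segment p0-p1 keeps clear of every object except the
        spheres it attaches to and linkers sharing one of those vesicles."""
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        for key, c, r in self.spheres:
            if key in exclude_keys:
                continue
            if _point_polyline_distance(c, np.array([p0, p1])) < r + radius + clearance:
                return False
        for pts, r in self.tubes:
            for a, b in zip(pts[:-1], pts[1:]):
                if _segment_segment_distance(p0, p1, a, b) < r + radius + clearance:
                    return False
        for q0, q1, r, keys in self.linkers:
            if exclude_keys & set(keys):
                continue  # shares a vesicle: the angle constraint separates them
            if _segment_segment_distance(p0, p1, q0, q1) < radius + r + clearance:
                return False
        return True

    def angle_ok(self, key, direction) -> bool:
        """Minimum angular separation between linkers attached to one vesicle,
        so distinct ground-truth linkers keep disjoint voxel support."""
        cos_cap = math.cos(math.radians(_MIN_LINKER_ANGLE_DEG))
        for d in self.attach_dirs.get(key, []):
            if float(direction @ d) > cos_cap:
                return False
        return True

    def add_sphere(self, center, radius, key=None):
        self.spheres.append((key, np.asarray(center, float), float(radius)))

    def add_tube(self, pts, radius):
        self.tubes.append((np.asarray(pts, float), float(radius)))

    def add_linker(self, p0, p1, radius, keys):
        self.linkers.append((np.asarray(p0, float), np.asarray(p1, float),
                             float(radius), tuple(keys)))

    def add_attach(self, key, direction):
        self.attach_dirs.setdefault(key, []).append(np.asarray(direction, float))


def _point_polyline_distance(p, pts):
    p = np.asarray(p, float)
    best = np.inf
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        t = 0.0 if L2 == 0 else float(np.clip((p - a) @ ab / L2, 0, 1))
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


def _random_unit(rng):
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def generate_phantom(spec: PhantomSpec) -> tuple[DensityVolume, LabelVolume, GroundTruth]:
    """Generate a phantom tomogram. Deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    voxel = spec.voxel_size_nm
    shape = tuple(int(s) for s in spec.volume_shape)
    extent = np.array(shape) * voxel

    if spec.cytoplasm_density_sd > 0:
        data = rng.normal(spec.cytoplasm_density_mean, spec.cytoplasm_density_sd,
                          size=shape).astype(np.float32)
    else:
        data = np.full(shape, spec.cytoplasm_density_mean, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    catalog: dict[int, Boundary] = {}
    next_id = 1

    # --- plasma membrane: slab at the low-z face ---
    membrane_top = None
    pm_id = None
    if spec.plasma_membrane is not None:
        th = spec.plasma_membrane.thickness_nm
        n_slab = max(1, int(round(th / voxel)))
        membrane_top = n_slab * voxel
        data[:n_slab] = spec.membrane_density_mean
        labels[:n_slab] = next_id
        pm_id = next_id
        catalog[next_id] = Boundary(next_id, "plasma_membrane")
        next_id += 1

    placer = _Placer(shape, voxel, membrane_top)

    # --- microtubules ---
    mt_polylines = []
    for mt in spec.microtubules:
        pts = np.asarray(mt.points_nm, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("microtubule polyline needs >= 2 points")
        mt_mask = np.zeros(shape, dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            mt_mask |= render_cylinder(a, b, mt.outer_radius_nm,
                                       spec.membrane_density_mean, data, voxel)
        inner = np.zeros(shape, dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):  # hollow lumen back at cytoplasm density
            inner |= render_cylinder(a, b, mt.inner_radius_nm,
                                     spec.cytoplasm_density_mean, data, voxel)
        wall = mt_mask & ~inner
        if labels[wall].any():
            raise PlacementError("microtubule overlaps an existing boundary")
        labels[wall] = next_id
        catalog[next_id] = Boundary(next_id, "microtubule")
        mt_polylines.append(pts)
        placer.add_tube(pts, mt.outer_radius_nm)
        next_id += 1

    # --- vesicle placement plan ---
    # expand specs into individual vesicles
    plan = []  # dicts: kind, radius, lumen_density, halo, center (or None)
    for vspec in spec.vesicles:
        if vspec.centers_nm is not None:
            centers = [np.asarray(c, float) for c in vspec.centers_nm]
        else:
            centers = [None] * vspec.count
        for c in centers:
            plan.append({"kind": vspec.kind, "radius": vspec.diameter_nm / 2.0,
                         "lumen_density": vspec.lumen_density,
                         "halo": vspec.halo_width_nm, "center": c})
    n_ves = len(plan)

    min_gap = 2.0 * voxel  # shortest linker with guaranteed voxel support
    clearance = spec.min_separation_nm if spec.min_separation_nm is not None \
        else 6.0 * voxel

    # decide connector groups (indices into plan) and tethered vesicles
    conn_edges: list[tuple[int, int, float]] = []   # (i, j, gap_nm)
    tether_idx: dict[int, float] = {}               # vesicle index -> gap_nm
    if spec.connectors is not None and spec.connectors.fraction_of_vesicles_connected > 0:
        cs = spec.connectors
        n_conn = int(round(cs.fraction_of_vesicles_connected * n_ves))
        chosen = list(rng.permutation(n_ves)[:n_conn])
        gap = lambda: _sample_gap(rng, cs.length_mean_nm, cs.length_sd_nm, min_gap)
        if cs.topology == "pairs":
            for k in range(0, len(chosen) - 1, 2):
                conn_edges.append((chosen[k], chosen[k + 1], gap()))
        elif cs.topology == "chain":
            for a, b in zip(chosen[:-1], chosen[1:]):
                conn_edges.append((a, b, gap()))
        else:  # star
            hub = chosen[0]
            for b in chosen[1:]:
                conn_edges.append((hub, b, gap()))
    if spec.tethers is not None and spec.tethers.fraction_of_vesicles_connected > 0:
        if membrane_top is None:
            raise ValueError("tether spec requires a plasma membrane")
        ts = spec.tethers
        n_teth = int(round(ts.fraction_of_vesicles_connected * n_ves))
        # prefer vesicles outside connector groups: a tether fixes the height,
        # which can be jointly infeasible with a prescribed connector gap
        in_conn = {a for a, b, _ in conn_edges} | {b for a, b, _ in conn_edges}
        order = list(rng.permutation(n_ves))
        candidates = [i for i in order if i not in in_conn] + \
                     [i for i in order if i in in_conn]
        for i in candidates[:n_teth]:
            tether_idx[int(i)] = _sample_gap(rng, ts.length_mean_nm, ts.length_sd_nm, min_gap)

    # adjacency for placement: connected vesicles must be placed relative to partner
    neighbors: dict[int, list[tuple[int, float]]] = {}
    for a, b, g in conn_edges:
        neighbors.setdefault(a, []).append((b, g))
        neighbors.setdefault(b, []).append((a, g))

    centers: dict[int, np.ndarray] = {}
    conn_radius = spec.connectors.radius_nm if spec.connectors is not None else 0.0
    teth_radius = spec.tethers.radius_nm if spec.tethers is not None else 0.0
    down = np.array([-1.0, 0.0, 0.0])  # tether direction (toward membrane)

    def tether_foot(c):
        return np.array([membrane_top, c[1], c[2]])

    def tether_clear(idx, c):
        if idx not in tether_idx:
            return True
        return placer.linker_clear(c, tether_foot(c), teth_radius, {idx}, clearance)

    def place_free(i):
        v = plan[i]
        if v["center"] is not None:
            c = v["center"]
            want_gap = tether_idx.get(i)
            if not (placer.fits(c, v["radius"], clearance, want_gap)
                    and tether_clear(i, c)):
                raise PlacementError(f"explicit center for vesicle {i} infeasible")
            return c
        lo = np.zeros(3) + v["radius"] + voxel
        hi = extent - v["radius"] - voxel
        if np.any(hi <= lo):
            raise PlacementError("vesicle does not fit in volume")
        for _ in range(_RETRY_CAP):
            c = rng.uniform(lo, hi)
            if i in tether_idx:
                c[0] = membrane_top + tether_idx[i] + v["radius"]
                if c[0] + v["radius"] + voxel > extent[0]:
                    continue
                if placer.fits(c, v["radius"], clearance, tether_idx[i]) \
                        and tether_clear(i, c):
                    return c
            elif placer.fits(c, v["radius"], clearance):
                return c
        raise PlacementError(f"could not place vesicle {i} after {_RETRY_CAP} attempts")

    def place_next_to(i, j, gap_nm):
        """Place vesicle j at surface gap gap_nm from already placed i, with
        the connecting linker clear of every unrelated object."""
        ri, rj = plan[i]["radius"], plan[j]["radius"]
        dist = ri + rj + gap_nm
        want_gap = tether_idx.get(j)
        for _ in range(_RETRY_CAP):
            u = _random_unit(rng)
            c = centers[i] + u * dist
            if want_gap is not None:
                c[0] = membrane_top + want_gap + rj
                # keep the prescribed pair distance by re-solving the offset
                dz = c[0] - centers[i][0]
                if abs(dz) >= dist:
                    continue
                rho = math.sqrt(dist ** 2 - dz ** 2)
                ang = rng.uniform(0, 2 * math.pi)
                c[1] = centers[i][1] + rho * math.cos(ang)
                c[2] = centers[i][2] + rho * math.sin(ang)
                u = (c - centers[i]) / dist
            if np.any(c - rj - voxel < 0) or np.any(c + rj + voxel > extent):
                continue
            if not placer.angle_ok(i, u):
                continue
            if want_gap is not None and \
                    float((-u) @ down) > math.cos(math.radians(_MIN_LINKER_ANGLE_DEG)):
                continue  # connector would collide with j's own tether
            # the partner sits at exactly the prescribed distance; exclude it
            # from the clearance test
            if not placer.fits(c, rj, clearance, want_gap, ignore_key=i):
                continue
            if not placer.linker_clear(centers[i], c, conn_radius, {i, j}, clearance):
                continue
            if not tether_clear(j, c):
                continue
            return c, u
        raise PlacementError(f"could not place vesicle {j} next to {i}")

    # breadth-first over connector groups so partners are placed relative;
    # root each group at a tethered vesicle (its height is constrained) so
    # tether and connector constraints stay jointly feasible
    def group_root(start):
        seen = {start}
        stack = [start]
        while stack:
            k = stack.pop()
            if k in tether_idx:
                return k
            for nb, _g in neighbors.get(k, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return start

    placed_order = []
    visited = set()
    for i0 in range(n_ves):
        if i0 in visited:
            continue
        i = group_root(i0)
        queue = [(i, None, None)]
        visited.add(i)
        while queue:
            k, parent, g = queue.pop(0)
            if parent is None:
                centers[k] = place_free(k)
            else:
                centers[k], u = place_next_to(parent, k, g)
                placer.add_linker(centers[parent], centers[k], conn_radius,
                                  (parent, k))
                placer.add_attach(parent, u)
                placer.add_attach(k, -u)
            placer.add_sphere(centers[k], plan[k]["radius"], key=k)
            if k in tether_idx:
                placer.add_linker(centers[k], tether_foot(centers[k]),
                                  teth_radius, (k,))
                placer.add_attach(k, down)
            placed_order.append(k)
            for nb, gg in neighbors.get(k, []):
                if nb not in visited:
                    visited.add(nb)
                    queue.append((nb, k, gg))

    # --- render vesicles ---
    ves_rows = []
    idx_to_id = {}
    mem_th = spec.membrane_thickness_nm
    for i in range(n_ves):
        v, c = plan[i], centers[i]
        r = v["radius"]
        ball = render_sphere_shell(c, 0.0, r, spec.membrane_density_mean, data, voxel)
        # lumen fill per kind
        r_in = max(r - mem_th, 0.0)
        if v["kind"] == "dcv_nohalo":
            core = v["lumen_density"] if v["lumen_density"] is not None else -1.2
            render_sphere_shell(c, 0.0, r_in, core, data, voxel)
        elif v["kind"] == "dcv_halo":
            core = v["lumen_density"] if v["lumen_density"] is not None else -1.2
            halo_w = min(v["halo"], r_in)
            render_sphere_shell(c, 0.0, r_in, spec.cytoplasm_density_mean, data, voxel)
            render_sphere_shell(c, 0.0, max(r_in - halo_w, 0.0), core, data, voxel)
        else:  # sv / light_medium: lumen near cytoplasm density
            lum = v["lumen_density"] if v["lumen_density"] is not None else \
                spec.cytoplasm_density_mean
            render_sphere_shell(c, 0.0, r_in, lum, data, voxel)
        if labels[ball].any():
            raise PlacementError(f"vesicle {i} overlaps an existing boundary")
        labels[ball] = next_id
        catalog[next_id] = Boundary(next_id, "vesicle", c.copy(), r, v["kind"])
        idx_to_id[i] = next_id
        ves_rows.append({"boundary_id": next_id, "kind": v["kind"],
                         "center_z_nm": c[0], "center_y_nm": c[1],
                         "center_x_nm": c[2], "diameter_nm": 2 * r})
        next_id += 1

    unlabeled = labels == 0

    # --- linkers ---
    link_rows = []
    linker_voxels = {}
    linker_id = 0
    if spec.connectors is not None:
        conn_density = spec.connectors.density \
            if spec.connectors.density is not None else spec.membrane_density_mean
        for a, b, g in conn_edges:
            ca, cb = centers[a], centers[b]
            ra, rb = plan[a]["radius"], plan[b]["radius"]
            u = (cb - ca) / np.linalg.norm(cb - ca)
            p0 = ca + u * ra
            p1 = cb - u * rb
            true_gap = float(np.linalg.norm(cb - ca) - ra - rb)
            mask = _render_linker(p0, p1, spec.connectors.radius_nm,
                                  conn_density, data, voxel, unlabeled,
                                  overshoot_nm=1.5 * voxel)
            vox = np.argwhere(mask)
            if vox.shape[0] == 0:
                raise PlacementError("connector rendered with no voxel support")
            linker_id += 1
            linker_voxels[linker_id] = vox
            link_rows.append({"linker_id": linker_id,
                              "boundary_id_1": idx_to_id[a],
                              "boundary_id_2": idx_to_id[b],
                              "gap_nm": true_gap, "class": "connector"})
    if spec.tethers is not None:
        teth_density = spec.tethers.density \
            if spec.tethers.density is not None else spec.membrane_density_mean
        for i, g in tether_idx.items():
            c = centers[i]
            r = plan[i]["radius"]
            p0 = c - np.array([r, 0, 0])
            p1 = np.array([membrane_top, c[1], c[2]])
            true_gap = float(c[0] - r - membrane_top)
            mask = _render_linker(p0, p1, spec.tethers.radius_nm,
                                  teth_density, data, voxel, unlabeled,
                                  overshoot_nm=1.5 * voxel)
            vox = np.argwhere(mask)
            if vox.shape[0] == 0:
                raise PlacementError("tether rendered with no voxel support")
            linker_id += 1
            linker_voxels[linker_id] = vox
            link_rows.append({"linker_id": linker_id,
                              "boundary_id_1": idx_to_id[i],
                              "boundary_id_2": pm_id,
                              "gap_nm": true_gap, "class": "tether"})

    # --- protrusions ---
    prot_rows = []
    prot_voxels = {}
    prot_id = 0
    if spec.protrusions is not None and spec.protrusions.per_vesicle_count > 0:
        ps = spec.protrusions
        dens = ps.density if ps.density is not None else spec.membrane_density_mean
        for i in range(n_ves):
            c, r = centers[i], plan[i]["radius"]
            for _ in range(ps.per_vesicle_count):
                ok = False
                for _attempt in range(_RETRY_CAP):
                    u = _random_unit(rng)
                    p0 = c + u * r
                    p1 = c + u * (r + ps.length_nm)
                    if np.any(p1 - ps.radius_nm - voxel < 0) or \
                       np.any(p1 + ps.radius_nm + voxel > extent):
                        continue
                    # keep rods clear of other boundaries and linkers
                    if not _rod_clear(p0, p1, ps.radius_nm, placer, i,
                                      centers, plan, clearance, voxel):
                        continue
                    mask = _render_linker(p0, p1, ps.radius_nm, dens, data, voxel,
                                          unlabeled,
                                          overshoot_nm=(1.5 * voxel, 0.0))
                    vox = np.argwhere(mask)
                    if vox.shape[0] == 0:
                        continue
                    prot_id += 1
                    prot_voxels[prot_id] = vox
                    prot_rows.append({"protrusion_id": prot_id,
                                      "boundary_id": idx_to_id[i],
                                      "length_nm": ps.length_nm})
                    ok = True
                    break
                if not ok:
                    raise PlacementError(
                        f"could not place protrusion on vesicle {i} after {_RETRY_CAP} attempts")

    # --- noise (density only; labels stay noise-free) ---
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    density = DensityVolume(data, voxel)
    labelvol = LabelVolume(labels, catalog, voxel)

    cols_v = ["boundary_id", "kind", "center_z_nm", "center_y_nm", "center_x_nm",
              "diameter_nm"]
    cols_l = ["linker_id", "boundary_id_1", "boundary_id_2", "gap_nm", "class"]
    cols_p = ["protrusion_id", "boundary_id", "length_nm"]
    truth = GroundTruth(
        vesicles=pd.DataFrame(ves_rows, columns=cols_v),
        linkers=pd.DataFrame(link_rows, columns=cols_l),
        protrusions=pd.DataFrame(prot_rows, columns=cols_p),
        microtubules=mt_polylines,
        linker_voxels=linker_voxels,
        protrusion_voxels=prot_voxels,
    )
    return density, labelvol, truth


def _rod_clear(p0, p1, radius, placer, own_idx, centers, plan, clearance, voxel):
    """True if a protrusion rod p0-p1 stays clear of every boundary and linker.

    Unrelated objects require the full ``clearance``; linkers attached to the
    rod's own vesicle only need local disjointness (one voxel), since they
    emanate from the same sphere."""
    for k, c in centers.items():
        if k == own_idx:
            continue
        if _point_polyline_distance(c, np.array([p0, p1])) \
                < plan[k]["radius"] + radius + clearance:
            return False
    for pts, r in placer.tubes:
        for a, b in zip(pts[:-1], pts[1:]):
            if _segment_segment_distance(p0, p1, a, b) < r + radius + clearance:
                return False
    for q0, q1, r, keys in placer.linkers:
        needed = radius + r + (voxel if own_idx in keys else clearance)
        if _segment_segment_distance(p0, p1, q0, q1) < needed:
            return False
    if placer.membrane_top is not None and \
            min(p0[0], p1[0]) - radius < placer.membrane_top + 2 * voxel:
        return False
    return True
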