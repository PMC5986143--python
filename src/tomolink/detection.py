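"""Detection of tethers, connectors and protrusions between boundaries.

The central operation is hierarchical connectivity segmentation: connected
components of sub-threshold (dense) cytoplasmic voxels are formed at a series
of density thresholds, from the densest level to the laxest. A candidate is
accepted at the *densest* level at which it contacts exactly two distinct
boundaries; once accepted, any laxer-level component containing its voxels is
skipped, so each linker is reported once, in its strongest-density form.

Classes:

* ``connector`` -- 2-bound segment between two vesicles (or a vesicle and a
  microtubule/SER/MVB; the pair's kinds are recorded).
* ``tether``    -- 2-bound segment with exactly one plasma-membrane contact.
* ``protrusion``-- 1-bound segment, detected at a single threshold (the mean
  density of the vesicle membranes) so counts are comparable across vesicles.
* ``multi``     -- contacts three or more boundaries at every level.

Size filters (minimum 3 voxels, maximum 320 nm^3) reclassify rather than
delete, keeping an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .volumes import DensityVolume, LabelVolume

__all__ = [
    "ThresholdSchedule",
    "LinkerSegment",
    "DegenerateScheduleError",
    "make_schedule",
    "hierarchical_segment",
    "filter_segments",
    "detect_protrusions",
    "segment_length",
    "measure_segments",
    "summarize_linkers",
    "segments_to_frame",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

MIN_VOXELS = 3
MAX_VOLUME_NM3 = 320.0


class DegenerateScheduleError(ValueError):
    """Raised when the cytoplasm density has no spread to threshold over."""


@dataclass
class ThresholdSchedule:
    """Strictly increasing density threshold levels (densest first when
    iterated ascending, because lower value = denser)."""

    levels: np.ndarray

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 2:
            raise ValueError("schedule needs at least 2 levels")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("schedule levels must be finite")
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("schedule levels must be strictly increasing")


@dataclass
class LinkerSegment:
    """One detected density segment and its classification."""

    segment_id: int
    voxels: np.ndarray                 # (N, 3) voxel indices (z, y, x)
    contacted: frozenset               # boundary ids touched (6-neighborhood)
    threshold_found: float
    volume_nm3: float
    class_: str                        # tether|connector|protrusion|multi|rejected_*
    base_class: str                    # class before size filtering
    contacted_kinds: tuple = ()
    length_b2c_nm: Optional[float] = None
    length_c2c_nm: Optional[float] = None
    length_bmax_nm: Optional[float] = None

    @property
    def n_contacted(self) -> int:
        return len(self.contacted)

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]


def make_schedule(volume: DensityVolume, labels: LabelVolume,
                  n_levels: int = 25) -> ThresholdSchedule:
    """Evenly spaced levels from (mu_cyto - 3 sigma_cyto) up to mu_cyto.

    mu/sigma are taken over unlabeled voxels at least 2 voxels away from any
    boundary, so membranes and linker-adjacent voxels barely contribute.
    """
    labels.check_paired(volume)
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    free = labels.labels == 0
    if not free.any():
        raise ValueError("no unlabeled voxels to estimate cytoplasm density from")
    if free.all():
        far = free
    else:
        dist = ndimage.distance_transform_edt(free)
        far = free & (dist >= 2)
        if not far.any():
            raise ValueError("no unlabeled voxels >= 2 voxels from a boundary")
    mu = float(volume.data[far].mean())
    sigma = float(volume.data[far].std())
    if sigma <= 0:
        raise DegenerateScheduleError(
            "cytoplasm density has zero spread; supply an explicit schedule")
    return ThresholdSchedule(np.linspace(mu - 3 * sigma, mu, n_levels))


def _contact_pairs(comp: np.ndarray, lab: np.ndarray) -> np.ndarray:
    """Unique (component_id, boundary_id) adjacency pairs (6-neighborhood)."""
    pairs = []
    for axis in range(3):
        for (sa, sb) in (((slice(None),) * axis + (slice(1, None),),
                          (slice(None),) * axis + (slice(None, -1),)),
                         ((slice(None),) * axis + (slice(None, -1),),
                          (slice(None),) * axis + (slice(1, None),))):
            a = comp[sa]
            b = lab[sb]
            sel = (a > 0) & (b > 0)
            if sel.any():
                pairs.append(np.stack([a[sel], b[sel]], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.concatenate(pairs, axis=0), axis=0)


def _contacts_by_component(comp: np.ndarray, lab: np.ndarray) -> dict[int, set]:
    out: dict[int, set] = {}
    for cid, bid in _contact_pairs(comp, lab):
        out.setdefault(int(cid), set()).add(int(bid))
    return out


def _classify_pair(contacted: Sequence[int], labels: LabelVolume) -> tuple[str, tuple]:
    kinds = tuple(sorted(labels.catalog[b].kind for b in contacted))
    n_pm = sum(1 for k in kinds if k == "plasma_membrane")
    cls = "tether" if n_pm == 1 else "connector"
    return cls, kinds


def _extract_voxels(comp: np.ndarray, cid: int, sl) -> np.ndarray:
    local = np.argwhere(comp[sl] == cid)
    offset = np.array([s.start for s in sl])
    return local + offset


def hierarchical_segment(volume: DensityVolume, labels: LabelVolume,
                         schedule: ThresholdSchedule) -> list[LinkerSegment]:
    """Multi-threshold connectivity segmentation of 2-bound segments.

    Returns accepted tether/connector segments (densest qualifying level
    each) plus ``multi`` segments that contact >= 3 boundaries at every
    level. Components never reaching 2 contacts are not emitted.
    """
    labels.check_paired(volume)
    data = volume.data
    lab = labels.labels
    free = lab == 0
    claimed = np.zeros(data.shape, dtype=bool)
    segments: list[LinkerSegment] = []
    seg_id = 0
    voxvol = volume.voxel_volume_nm3

    n_levels = schedule.levels.size
    for li, t in enumerate(schedule.levels):
        mask = (data <= t) & free
        if not mask.any():
            continue
        comp, ncomp = ndimage.label(mask, structure=_STRUCT6)
        if ncomp == 0:
            continue
        contacts = _contacts_by_component(comp, lab)
        claimed_ids = set(np.unique(comp[claimed])) - {0} if claimed.any() else set()
        objects = ndimage.find_objects(comp)
        last_level = li == n_levels - 1
        for cid in sorted(contacts):
            if cid in claimed_ids:
                continue  # superset of an already accepted segment
            nb = len(contacts[cid])
            if nb == 2:
                vox = _extract_voxels(comp, cid, objects[cid - 1])
                cls, kinds = _classify_pair(sorted(contacts[cid]), labels)
                seg_id += 1
                segments.append(LinkerSegment(
                    segment_id=seg_id, voxels=vox,
                    contacted=frozenset(contacts[cid]),
                    threshold_found=float(t),
                    volume_nm3=vox.shape[0] * voxvol,
                    class_=cls, base_class=cls, contacted_kinds=kinds))
                claimed[tuple(vox.T)] = True
                claimed_ids.add(cid)
            elif nb >= 3 and last_level:
                vox = _extract_voxels(comp, cid, objects[cid - 1])
                kinds = tuple(sorted(labels.catalog[b].kind
                                     for b in sorted(contacts[cid])))
                seg_id += 1
                segments.append(LinkerSegment(
                    segment_id=seg_id, voxels=vox,
                    contacted=frozenset(contacts[cid]),
                    threshold_found=float(t),
                    volume_nm3=vox.shape[0] * voxvol,
                    class_="multi", base_class="multi", contacted_kinds=kinds))
    return segments


def filter_segments(segments: Sequence[LinkerSegment],
                    voxel_size_nm: float,
                    min_voxels: int = MIN_VOXELS,
                    max_volume_nm3: float = MAX_VOLUME_NM3) -> list[LinkerSegment]:
    """Size filter: fewer than 3 voxels or more than 320 nm^3 are rejected.

    Segments are reclassified (``rejected_small`` / ``rejected_large``), never
    deleted, so the audit trail is complete.
    """
    voxvol = voxel_size_nm ** 3
    out = []
    for s in segments:
        vol = s.n_voxels * voxvol
        if s.n_voxels < min_voxels:
            cls = "rejected_small"
        elif vol > max_volume_nm3:
            cls = "rejected_large"
        else:
            cls = s.base_class
        out.append(LinkerSegment(
            segment_id=s.segment_id, voxels=s.voxels, contacted=s.contacted,
            threshold_found=s.threshold_found, volume_nm3=vol, class_=cls,
            base_class=s.base_class, contacted_kinds=s.contacted_kinds,
            length_b2c_nm=s.length_b2c_nm, length_c2c_nm=s.length_c2c_nm,
            length_bmax_nm=s.length_bmax_nm))
    return out


def detect_protrusions(volume: DensityVolume, labels: LabelVolume,
                       vesicle_ids: Sequence[int]) -> list[LinkerSegment]:
    """1-bound segments at a single threshold: the mean density of the listed
    vesicles' membrane voxels (outermost labeled shell of each vesicle)."""
    labels.check_paired(volume)
    if not len(vesicle_ids):
        raise ValueError("vesicle_ids must be nonempty")
    lab = labels.labels
    membrane = np.zeros(lab.shape, dtype=bool)
    for vid in vesicle_ids:
        m = lab == vid
        if not m.any():
            raise ValueError(f"vesicle {vid} has no voxels")
        shell = m & ~ndimage.binary_erosion(m, structure=_STRUCT6)
        if not shell.any():
            raise ValueError(f"vesicle {vid} has no membrane voxels")
        membrane |= shell
    threshold = float(volume.data[membrane].mean())

    mask = (volume.data <= threshold) & (lab == 0)
    segments: list[LinkerSegment] = []
    if not mask.any():
        return segments
    comp, _ = ndimage.label(mask, structure=_STRUCT6)
    contacts = _contacts_by_component(comp, lab)
    objects = ndimage.find_objects(comp)
    voxvol = volume.voxel_volume_nm3
    want = set(int(v) for v in vesicle_ids)
    seg_id = 0
    for cid in sorted(contacts):
        bids = contacts[cid]
        if len(bids) != 1:
            continue  # 2-bound or multi-bound: not a protrusion
        (bid,) = bids
        if bid not in want:
            continue
        vox = _extract_voxels(comp, cid, objects[cid - 1])
        seg_id += 1
        segments.append(LinkerSegment(
            segment_id=seg_id, voxels=vox, contacted=frozenset({bid}),
            threshold_found=threshold, volume_nm3=vox.shape[0] * voxvol,
            class_="protrusion", base_class="protrusion",
            contacted_kinds=(labels.catalog[bid].kind,)))
    return filter_segments(segments, volume.voxel_size_nm)


def _contact_regions(segment: LinkerSegment, labels: LabelVolume) -> dict[int, np.ndarray]:
    """Boundary voxels 6-adjacent to the segment, grouped by boundary id."""
    lab = labels.labels
    shape = lab.shape
    vox = segment.voxels
    neigh = []
    for axis in range(3):
        for d in (-1, 1):
            n = vox.copy()
            n[:, axis] += d
            ok = (n[:, axis] >= 0) & (n[:, axis] < shape[axis])
            neigh.append(n[ok])
    neigh = np.unique(np.concatenate(neigh, axis=0), axis=0)
    vals = lab[tuple(neigh.T)]
    regions = {}
    for bid in segment.contacted:
        regions[bid] = neigh[vals == bid]
    return regions


def segment_length(segment: LinkerSegment, labels: LabelVolume, mode: str,
                   voxel_size_nm: float) -> float:
    """Length of a segment in nm, by mode.

    * ``B2C``  -- membrane edge to membrane edge: minimum distance between a
      contact voxel of one boundary and a contact voxel of the other, measured
      between voxel *faces* (center-to-center minus one voxel, floored at 0).
    * ``C2C``  -- distance between the centroids of the two contact regions.
    * ``Bmax`` -- maximal extent: largest distance from a segment voxel to its
      nearest contact voxel (protrusions: 1-bound segments only).
    """
    if mode in ("B2C", "C2C") and segment.n_contacted != 2:
        raise ValueError(f"mode {mode} requires exactly 2 contacted boundaries")
    if mode == "Bmax" and segment.n_contacted != 1:
        raise ValueError("mode Bmax requires exactly 1 contacted boundary")
    regions = _contact_regions(segment, labels)
    for bid, r in regions.items():
        if r.shape[0] == 0:
            raise ValueError(f"segment {segment.segment_id} has no contact voxels "
                             f"on boundary {bid}")
    v = voxel_size_nm
    if mode == "B2C":
        r1, r2 = (regions[b] for b in sorted(regions))
        d = cdist(r1.astype(float), r2.astype(float)).min() * v
        return max(d - v, 0.0)
    if mode == "C2C":
        r1, r2 = (regions[b] for b in sorted(regions))
        return float(np.linalg.norm(r1.mean(axis=0) - r2.mean(axis=0))) * v
    if mode == "Bmax":
        (r1,) = regions.values()
        d = cdist(segment.voxels.astype(float), r1.astype(float)).min(axis=1)
        return float(d.max()) * v
    raise ValueError(f"unknown length mode {mode!r}")


def measure_segments(segments: Sequence[LinkerSegment], labels: LabelVolume,
                     voxel_size_nm: float) -> list[LinkerSegment]:
    """Fill in the length fields appropriate for each segment's contacts:
    B2C and C2C for 2-bound segments, B-max for 1-bound segments."""
    out = []
    for s in segments:
        b2c = c2c = bmax = None
        if s.n_contacted == 2:
            b2c = segment_length(s, labels, "B2C", voxel_size_nm)
            c2c = segment_length(s, labels, "C2C", voxel_size_nm)
        elif s.n_contacted == 1:
            bmax = segment_length(s, labels, "Bmax", voxel_size_nm)
        out.append(LinkerSegment(
            segment_id=s.segment_id, voxels=s.voxels, contacted=s.contacted,
            threshold_found=s.threshold_found, volume_nm3=s.volume_nm3,
            class_=s.class_, base_class=s.base_class,
            contacted_kinds=s.contacted_kinds,
            length_b2c_nm=b2c, length_c2c_nm=c2c, length_bmax_nm=bmax))
    return out


def segments_to_label_volume(segments: Sequence[LinkerSegment],
                             labels: LabelVolume) -> np.ndarray:
    """Integer volume with each segment's voxels set to its segment_id,
    for visualisation alongside the boundary labels."""
    out = np.zeros(labels.shape, dtype=np.int32)
    for s in segments:
        out[tuple(s.voxels.T)] = s.segment_id
    return out


def segments_to_frame(segments: Sequence[LinkerSegment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        rows.append({
            "segment_id": s.segment_id,
            "class": s.class_,
            "base_class": s.base_class,
            "boundaries": ";".join(str(b) for b in sorted(s.contacted)),
            "kinds": ";".join(s.contacted_kinds),
            "n_voxels": s.n_voxels,
            "volume_nm3": s.volume_nm3,
            "threshold_found": s.threshold_found,
            "length_b2c_nm": s.length_b2c_nm,
            "length_c2c_nm": s.length_c2c_nm,
            "length_bmax_nm": s.length_bmax_nm,
        })
    return pd.DataFrame(rows, columns=[
        "segment_id", "class", "base_class", "boundaries", "kinds", "n_voxels",
        "volume_nm3", "threshold_found", "length_b2c_nm", "length_c2c_nm",
        "length_bmax_nm"])


def summarize_linkers(segments: Sequence[LinkerSegment], labels: LabelVolume,
                      histogram_bin_nm: float = 5.0) -> tuple[pd.DataFrame, dict]:
    """Per-vesicle linker counts and aggregate statistics.

    Returns a per-vesicle table (connector/tether/protrusion counts, protrusion
    density per 1000 nm^2 of membrane area from the catalog diameter) and an
    aggregate dict: fraction of vesicles with >= 1 connector, mean counts, and
    per-class length histograms.
    """
    vesicles = labels.ids_of_kind("vesicle")
    counts = {vid: {"connectors": 0, "tethers": 0, "protrusions": 0}
              for vid in vesicles}
    lengths: dict[str, list[float]] = {"connector": [], "tether": [], "protrusion": []}
    for s in segments:
        if s.class_ not in ("connector", "tether", "protrusion"):
            continue
        for bid in s.contacted:
            if bid not in counts:
                if labels.catalog.get(bid) is None:
                    raise ValueError(f"segment {s.segment_id} touches boundary "
                                     f"{bid} missing from catalog")
                continue
            counts[bid][s.class_ + "s"] += 1
        if s.class_ == "protrusion" and s.length_bmax_nm is not None:
            lengths["protrusion"].append(s.length_bmax_nm)
        elif s.class_ in ("connector", "tether") and s.length_b2c_nm is not None:
            lengths[s.class_].append(s.length_b2c_nm)

    rows = []
    for vid in vesicles:
        b = labels.catalog[vid]
        area_nm2 = 4 * np.pi * (b.radius_nm ** 2) if b.radius_nm else np.nan
        n_prot = counts[vid]["protrusions"]
        rows.append({
            "boundary_id": vid,
            "kind": b.subkind or b.kind,
            "diameter_nm": 2 * b.radius_nm if b.radius_nm else np.nan,
            "n_connectors": counts[vid]["connectors"],
            "n_tethers": counts[vid]["tethers"],
            "n_protrusions": n_prot,
            "protrusions_per_1000nm2": 1000.0 * n_prot / area_nm2
            if np.isfinite(area_nm2) and area_nm2 > 0 else np.nan,
        })
    per_vesicle = pd.DataFrame(rows, columns=[
        "boundary_id", "kind", "diameter_nm", "n_connectors", "n_tethers",
        "n_protrusions", "protrusions_per_1000nm2"])

    n_ves = len(vesicles)
    connected = int((per_vesicle["n_connectors"] > 0).sum()) if n_ves else 0
    hists = {}
    for cls, vals in lengths.items():
        if vals:
            hi = max(vals)
            edges = np.arange(0, hi + histogram_bin_nm, histogram_bin_nm)
            h, e = np.histogram(vals, bins=edges)
            hists[cls] = {"edges_nm": e.tolist(), "counts": h.tolist()}
        else:
            hists[cls] = {"edges_nm": [], "counts": []}
    summary = {
        "n_vesicles": n_ves,
        "connected_fraction": connected / n_ves if n_ves else 0.0,
        "mean_connectors_per_vesicle": float(per_vesicle["n_connectors"].mean())
        if n_ves else 0.0,
        "mean_tethers_per_vesicle": float(per_vesicle["n_tethers"].mean())
        if n_ves else 0.0,
        "mean_protrusions_per_vesicle": float(per_vesicle["n_protrusions"].mean())
        if n_ves else 0.0,
        "length_histograms": hists,
    }
    return per_vesicle, summary
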