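"""Data model and I/O for tomographic density and label volumes.

Conventions used throughout the package:

* Density sign: **lower value = higher mass density**, as in energy-filtered
  cryo-electron tomograms. All thresholding selects voxels ``value <= t``.
* Axis order is ``(z, y, x)``; voxel indices are 0-based; the physical
  position of a voxel is its center, ``(index + 0.5) * voxel_size_nm``.
* All lengths are reported in nanometres; MRC headers store Angstrom and are
  converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._mrcio import MRCFormatError, read_mrc, write_mrc

__all__ = [
    "DensityVolume",
    "Boundary",
    "LabelVolume",
    "MRCFormatError",
    "read_density",
    "write_density",
    "read_labels",
    "write_labels",
]

# boundary kinds recognised by the analysis
BOUNDARY_KINDS = ("vesicle", "plasma_membrane", "microtubule", "ser", "mvb")


@dataclass
class DensityVolume:
    """A 3D scalar density grid with physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar densities; lower values are denser.
    voxel_size_nm : float
        Isotropic voxel edge length in nm.
    origin_nm : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0) in (z, y, x) nm.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"density volume must be 3D, got shape {self.data.shape}")
        if not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density volume contains non-finite values")
        self.origin_nm = np.asarray(self.origin_nm, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        return self.voxel_size_nm ** 3


@dataclass
class Boundary:
    """Catalog entry for one segmented boundary instance.

    ``subkind`` refines vesicles (sv, dcv_halo, dcv_nohalo, light_medium) so
    that e.g. DCV-SV connectors can be reported separately from SV-SV ones.
    """

    boundary_id: int
    kind: str
    center_nm: Optional[np.ndarray] = None  # (z, y, x)
    radius_nm: Optional[float] = None
    subkind: Optional[str] = None

    def __post_init__(self):
        if self.kind not in BOUNDARY_KINDS:
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.center_nm is not None:
            self.center_nm = np.asarray(self.center_nm, dtype=float).reshape(3)


@dataclass
class LabelVolume:
    """Integer boundary-instance labels paired with a boundary catalog.

    Label 0 is unassigned cytoplasm/background. Every nonzero label in
    ``labels`` must have a catalog entry; instance identity (one ID per
    boundary object, not per class) is what contact counting relies on.
    """

    labels: np.ndarray
    catalog: dict[int, Boundary]
    voxel_size_nm: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.catalog)
        if missing:
            raise ValueError(f"labels present in volume but absent from catalog: {sorted(missing)}")

    @property
    def shape(self):
        return self.labels.shape

    def ids_of_kind(self, kind: str) -> list[int]:
        return [i for i, b in self.catalog.items() if b.kind == kind]

    def check_paired(self, volume: DensityVolume) -> None:
        if self.labels.shape != volume.data.shape:
            raise ValueError(
                f"label shape {self.labels.shape} does not match density shape {volume.data.shape}")
        if not np.isclose(self.voxel_size_nm, volume.voxel_size_nm, rtol=1e-6):
            raise ValueError("label and density voxel sizes differ")


def read_density(path) -> DensityVolume:
    """Read a density volume from an MRC file (header Angstrom -> nm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, voxel_a, origin_a = read_mrc(path)
    if min(data.shape) < 2:
        raise MRCFormatError(f"{path}: not a 3D volume (shape {data.shape})")
    data = data.astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise MRCFormatError(f"{path}: volume contains non-finite values")
    return DensityVolume(data, voxel_a / 10.0, origin_a / 10.0)


def write_density(volume: DensityVolume, path) -> None:
    """Write a density volume as MRC mode 2 (float32); nm -> Angstrom."""
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("refusing to write non-finite densities")
    write_mrc(path, volume.data.astype(np.float32), volume.voxel_size_nm * 10.0,
              volume.origin_nm * 10.0)


def _catalog_to_frame(catalog: dict[int, Boundary]) -> pd.DataFrame:
    rows = []
    for bid, b in sorted(catalog.items()):
        c = b.center_nm if b.center_nm is not None else (np.nan,) * 3
        rows.append({
            "boundary_id": bid, "kind": b.kind,
            "center_z_nm": c[0], "center_y_nm": c[1], "center_x_nm": c[2],
            "radius_nm": b.radius_nm if b.radius_nm is not None else np.nan,
            "subkind": b.subkind if b.subkind is not None else "",
        })
    return pd.DataFrame(rows, columns=["boundary_id", "kind", "center_z_nm",
                                       "center_y_nm", "center_x_nm", "radius_nm",
                                       "subkind"])


def _frame_to_catalog(df: pd.DataFrame) -> dict[int, Boundary]:
    catalog = {}
    for _, row in df.iterrows():
        center = None
        if {"center_z_nm", "center_y_nm", "center_x_nm"} <= set(df.columns):
            c = np.array([row["center_z_nm"], row["center_y_nm"], row["center_x_nm"]], dtype=float)
            if np.all(np.isfinite(c)):
                center = c
        radius = row.get("radius_nm")
        radius = float(radius) if radius is not None and np.isfinite(radius) else None
        subkind = row.get("subkind")
        subkind = str(subkind) if isinstance(subkind, str) and subkind else None
        bid = int(row["boundary_id"])
        catalog[bid] = Boundary(bid, str(row["kind"]), center, radius, subkind)
    return catalog


def read_labels(path, catalog_path) -> LabelVolume:
    """Read an integer label volume (MRC mode 0/1/6) plus its catalog CSV."""
    data, voxel_a, _ = read_mrc(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise MRCFormatError(f"{path}: label volume must be integer (MRC mode 0/1/6)")
    df = pd.read_csv(catalog_path)
    return LabelVolume(data.astype(np.int32), _frame_to_catalog(df), voxel_a / 10.0)


def write_labels(labelvol: LabelVolume, path, catalog_path) -> None:
    """Write labels as integer MRC and the catalog as CSV."""
    maxlab = int(labelvol.labels.max(initial=0))
    dtype = np.int16 if maxlab < 2 ** 15 else np.uint16
    if maxlab >= 2 ** 16:
        raise ValueError("more than 65535 boundary labels not supported by MRC integer modes")
    write_mrc(path, labelvol.labels.astype(dtype), labelvol.voxel_size_nm * 10.0)
    _catalog_to_frame(labelvol.catalog).to_csv(catalog_path, index=False)
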