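"""Region-of-interest masks in MNI space and feature extraction.

ROIs are either spheres around an MNI millimetre coordinate or labelled
regions of an integer atlas volume.  A voxel belongs to a sphere when
the Euclidean distance from its centre (mapped through the affine) to
the ROI centre is at most the radius; boundary ties are included.  Mean
delta-zfALFF per ROI per subject forms the feature table that the
classification stage consumes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .falff import FALFFMap

__all__ = [
    "ROIDefinition",
    "ROISet",
    "sphere_mask",
    "label_mask",
    "intersect_mask",
    "extract_features",
    "bundled_catalog",
]


class EmptyROIError(ValueError):
    """Raised when a ROI mask contains no voxels on the given grid."""


@dataclass(frozen=True)
class ROIDefinition:
    """A named ROI: an MNI sphere or an atlas label."""

    name: str
    kind: str = "sphere"
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    label_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"sphere", "label"}:
            raise ValueError(f"ROI kind must be 'sphere' or 'label', got {self.kind!r}")
        if self.kind == "sphere":
            if self.center is None or self.radius is None:
                raise ValueError(f"sphere ROI {self.name!r} needs center and radius")
            if self.radius <= 0:
                raise ValueError(f"ROI {self.name!r}: radius must be positive")
        elif self.label_id is None:
            raise ValueError(f"label ROI {self.name!r} needs a label_id")

    def mask(self, shape: tuple[int, int, int], affine: np.ndarray,
             label_volume: np.ndarray | None = None) -> np.ndarray:
        if self.kind == "sphere":
            m = sphere_mask(self.center, self.radius, shape, affine)
        else:
            if label_volume is None:
                raise ValueError(f"label ROI {self.name!r} needs a label volume")
            m = label_mask(label_volume, self.label_id)
        if not m.any():
            raise EmptyROIError(f"ROI {self.name!r} contains no voxels on this grid")
        return m


@dataclass
class ROISet:
    """An ordered catalog of uniquely-named ROIs."""

    rois: list[ROIDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate ROI names: {dupes}")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[ROIDefinition]:
        return iter(self.rois)

    def __getitem__(self, name: str) -> ROIDefinition:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ROISet":
        """Read a catalog TSV: name, kind, x, y, z, radius_mm, label_id."""
        df = pd.read_csv(path, sep="\t", comment="#")
        rois = []
        for _, row in df.iterrows():
            kind = str(row.get("kind", "sphere"))
            if kind == "sphere":
                rois.append(ROIDefinition(
                    name=str(row["name"]), kind="sphere",
                    center=(float(row["x"]), float(row["y"]), float(row["z"])),
                    radius=float(row["radius_mm"])))
            else:
                rois.append(ROIDefinition(name=str(row["name"]), kind="label",
                                          label_id=int(row["label_id"])))
        return cls(rois)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for r in self.rois:
            x, y, z = r.center if r.center is not None else (np.nan,) * 3
            rows.append({"name": r.name, "kind": r.kind, "x": x, "y": y, "z": z,
                         "radius_mm": r.radius if r.radius is not None else np.nan,
                         "label_id": r.label_id if r.label_id is not None else ""})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bundled_catalog(which: str) -> ROISet:
    """Load a catalog shipped with the package.

    ``'rsn'``: resting-state network sphere ROIs (salience, reward,
    dorsal attention, control executive, visual), radius 6 mm.
    ``'brainstem'``: the 13-region brainstem set; atlas-derived nuclei
    are approximated as synthetic sphere stand-ins since atlases are not
    redistributable (supply real label volumes for exact masks).
    """
    fname = {"rsn": "rsn_rois.tsv",
             "brainstem": "brainstem_rois_synthetic.tsv"}.get(which)
    if fname is None:
        raise ValueError(f"unknown bundled catalog {which!r}")
    ref = importlib.resources.files("falffmvpa.data").joinpath(fname)
    with importlib.resources.as_file(ref) as p:
        return ROISet.from_tsv(p)


def sphere_mask(center: Sequence[float], radius: float,
                shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """Boolean grid of voxels whose centres lie within ``radius`` mm of
    ``center`` (MNI mm).  Boundary ties (distance == radius) included."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be invertible")
    center = np.asarray(center, dtype=float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((mm - center) ** 2, axis=1)
    return (d2 <= radius ** 2 + 1e-9).reshape(shape)


def label_mask(label_volume: np.ndarray, label_id: int) -> np.ndarray:
    return np.asarray(label_volume) == label_id


def intersect_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Logical AND of two masks on the same grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a & b


def extract_features(
    maps: Mapping[str, FALFFMap],
    rois: ROISet,
    groups: Mapping[str, str | int] | None = None,
    analysis_mask: np.ndarray | None = None,
    label_volume: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean delta-zfALFF per ROI per subject.

    Parameters
    ----------
    maps : mapping subject_id -> FALFFMap
        One (typically delta-zfALFF) map per subject; all on one grid.
    rois : ROISet
        Catalog defining the feature columns, in catalog order.
    groups : mapping subject_id -> label, optional
        Adds a ``group`` column when given.
    analysis_mask : bool array, optional
        Intersected with each ROI mask (e.g. a grey-matter mask).

    Returns
    -------
    DataFrame with one row per subject, one column per ROI (catalog
    order), plus ``group`` when provided.
    """
    if not maps:
        raise ValueError("no subject maps given")
    subjects = list(maps)
    ref = maps[subjects[0]]
    shape = ref.values.shape
    for sid, m in maps.items():
        if m.values.shape != shape:
            raise ValueError(f"subject {sid}: grid {m.values.shape} != {shape}")

    roi_masks = {}
    for r in rois:
        m = r.mask(shape, ref.affine, label_volume=label_volume)
        if analysis_mask is not None:
            m = intersect_mask(m, analysis_mask)
        # validity mask of the maps also applies
        m = intersect_mask(m, ref.mask)
        if not m.any():
            raise EmptyROIError(
                f"ROI {r.name!r} is empty after masking on this grid")
        roi_masks[r.name] = m

    rows = {}
    for sid in subjects:
        vals = {}
        for name, m in roi_masks.items():
            v = maps[sid].values[m]
            if np.isnan(v).any():
                raise ValueError(f"NaN inside ROI {name!r} for subject {sid!r}")
            vals[name] = float(v.mean())
        rows[sid] = vals
    table = pd.DataFrame.from_dict(rows, orient="index")[rois.names]
    table.index.name = "subject_id"
    if groups is not None:
        table["group"] = [groups[s] for s in subjects]
    return table
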