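"""ROI time-series containers and I/O.

The analysis operates on region-of-interest (ROI) mean time series: a
``samples x nodes`` matrix in which each column is the voxel-mean BOLD signal
of one spherical ROI and rows from several subjects are stacked, with segment
bounds recording which rows belong to which subject.  ROIs are defined in
world (MNI, millimetre) coordinates; spheres are resolved to voxels through
the image affine.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoiDefinition",
    "RoiTimeSeriesMatrix",
    "ImageVolume4D",
    "read_roi_table",
    "write_roi_table",
    "load_nifti",
    "extract_sphere_roi",
    "concatenate_subjects",
    "default_dmn_rois",
]


@dataclass(frozen=True)
class RoiDefinition:
    """A spherical ROI: label, centre in MNI millimetres, radius in mm."""

    label: str
    center_mni: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI {self.label!r}: radius must be > 0")
        if len(self.center_mni) != 3:
            raise ValueError(f"ROI {self.label!r}: center must be a 3-vector")


@dataclass
class RoiTimeSeriesMatrix:
    """Samples x nodes matrix with node labels and per-subject segments.

    ``segment_bounds`` is a list of ``(subject_id, start, stop)`` half-open
    row ranges that partition the rows without gap or overlap.
    ``sampling_interval`` is the repetition time (TR) in seconds.
    """

    values: np.ndarray
    node_labels: list[str]
    segment_bounds: list[tuple[str, int, int]] = field(default_factory=list)
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.node_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.node_labels)} labels for {self.values.shape[1]} columns"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("duplicate node labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in time series")
        if not self.segment_bounds:
            self.segment_bounds = [("subject0", 0, self.values.shape[0])]
        self._check_segments()

    def _check_segments(self) -> None:
        pos = 0
        for sid, start, stop in self.segment_bounds:
            if start != pos or stop <= start:
                raise ValueError(
                    f"segment {sid!r} ({start}:{stop}) does not tile the rows"
                )
            pos = stop
        if pos != self.values.shape[0]:
            raise ValueError("segments do not cover all rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def segments(self):
        """Yield ``(subject_id, row-block view)`` per segment."""
        for sid, start, stop in self.segment_bounds:
            yield sid, self.values[start:stop]

    def map_segments(self, func) -> "RoiTimeSeriesMatrix":
        """Apply ``func(subject_id, block) -> block`` per segment, same shape."""
        out = self.values.copy()
        for sid, start, stop in self.segment_bounds:
            block = np.asarray(func(sid, self.values[start:stop]), dtype=float)
            if block.shape != (stop - start, self.n_nodes):
                raise ValueError("segment function changed the block shape")
            out[start:stop] = block
        return replace(self, values=out, segment_bounds=list(self.segment_bounds))


@dataclass
class ImageVolume4D:
    """A 4-D image (x, y, z, t) with a voxel-to-world affine in millimetres."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValueError("data must be x*y*z*t with t >= 1")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")


def read_roi_table(path, sampling_interval: float = 2.0) -> RoiTimeSeriesMatrix:
    """Read a TSV time-series table (header of node labels, numeric body).

    A sidecar manifest ``<path>.yaml``, if present, supplies the segment
    bounds and sampling interval written by :func:`write_roi_table`.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate node labels in header")
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty time series (header only)")
    labels = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy())[0]) if bad.isna().any() else -1
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            ) from exc

    segment_bounds = None
    manifest = _manifest_path(path)
    if manifest.exists():
        with open(manifest) as fh:
            meta = yaml.safe_load(fh)
        sampling_interval = float(meta.get("sampling_interval", sampling_interval))
        segment_bounds = [
            (str(s["subject"]), int(s["start"]), int(s["stop"]))
            for s in meta.get("segments", [])
        ] or None
    return RoiTimeSeriesMatrix(
        values=values,
        node_labels=labels,
        segment_bounds=segment_bounds or [],
        sampling_interval=sampling_interval,
    )


def write_roi_table(ts: RoiTimeSeriesMatrix, path) -> None:
    """Write a TSV table at full precision plus a YAML sidecar manifest."""
    if ts.n_nodes == 0:
        raise ValueError("cannot write a table with no nodes")
    df = pd.DataFrame(ts.values, columns=ts.node_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "sampling_interval": float(ts.sampling_interval),
        "segments": [
            {"subject": sid, "start": int(a), "stop": int(b)}
            for sid, a, b in ts.segment_bounds
        ],
    }
    with open(_manifest_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _manifest_path(path):
    from pathlib import Path

    p = Path(path)
    return p.with_name(p.name + ".yaml")


def load_nifti(path) -> ImageVolume4D:
    """Load a 4-D NIfTI image."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    return ImageVolume4D(data=data, affine=np.asarray(img.affine, dtype=float))


def extract_sphere_roi(
    img: ImageVolume4D,
    rois: list[RoiDefinition],
    sampling_interval: float = 2.0,
    mask: np.ndarray | None = None,
) -> RoiTimeSeriesMatrix:
    """Mean time series over voxels whose world-space centre lies within each sphere.

    A voxel belongs to a sphere iff the Euclidean distance (mm) from its
    centre's world coordinate to the ROI centre is <= radius (closed ball).
    ``mask`` optionally restricts the sphere to a binary voxel mask of the
    image's spatial shape.
    """
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate ROI labels")
    shape = img.data.shape[:3]
    inv = np.linalg.inv(img.affine)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match image grid")

    nt = img.data.shape[3]
    out = np.empty((nt, len(rois)))
    for j, roi in enumerate(rois):
        center = np.asarray(roi.center_mni, dtype=float)
        vox_center = (inv @ np.append(center, 1.0))[:3]
        if np.any(vox_center < -0.5) or np.any(vox_center > np.array(shape) - 0.5):
            raise ValueError(f"ROI {roi.label!r}: center outside image grid")
        sel = _sphere_voxels(img.affine, shape, center, roi.radius)
        if mask is not None:
            sel = sel & mask
        n_vox = int(sel.sum())
        if n_vox == 0:
            raise ValueError(f"ROI {roi.label!r}: sphere contains zero voxels")
        out[:, j] = img.data[sel].mean(axis=0)
    return RoiTimeSeriesMatrix(
        values=out, node_labels=labels, sampling_interval=sampling_interval
    )


def _sphere_voxels(affine, shape, center_mm, radius_mm):
    """Boolean voxel mask of the closed ball around ``center_mm``."""
    # Bounding box in voxel space keeps the scan linear in the sphere volume.
    inv = np.linalg.inv(affine)
    vox_c = (inv @ np.append(center_mm, 1.0))[:3]
    # conservative per-axis voxel extent of the radius
    scale = np.linalg.norm(inv[:3, :3], axis=1) * radius_mm + 1.0
    lo = np.maximum(np.floor(vox_c - scale).astype(int), 0)
    hi = np.minimum(np.ceil(vox_c + scale).astype(int) + 1, np.array(shape))
    sel = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return sel
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(world - center_mm, axis=1)
    inside = vox[dist <= radius_mm]
    sel[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return sel


def concatenate_subjects(matrices: list[RoiTimeSeriesMatrix]) -> RoiTimeSeriesMatrix:
    """Stack subjects row-wise ("linked individual-by-individual")."""
    if not matrices:
        raise ValueError("no subjects to concatenate")
    ref = matrices[0].node_labels
    bad = [
        i for i, m in enumerate(matrices) if m.node_labels != ref
    ]
    if bad:
        raise ValueError(
            f"node labels differ from subject 0 in subjects {bad}; no silent reordering"
        )
    values = np.vstack([m.values for m in matrices])
    bounds: list[tuple[str, int, int]] = []
    pos = 0
    seen: set[str] = set()
    for i, m in enumerate(matrices):
        for sid, start, stop in m.segment_bounds:
            out_sid = sid if sid not in seen else f"{sid}.{i}"
            seen.add(out_sid)
            bounds.append((out_sid, pos, pos + (stop - start)))
            pos += stop - start
    return RoiTimeSeriesMatrix(
        values=values,
        node_labels=list(ref),
        segment_bounds=bounds,
        sampling_interval=matrices[0].sampling_interval,
    )


def default_dmn_rois(condition: str = "rest") -> list[RoiDefinition]:
    """The packaged default-mode-network ROI set (8 regions, 6-mm spheres).

    ``condition`` is ``"rest"`` or ``"task"``.  The bilateral hippocampus
    centres of the task set equal the resting-state centres: those regions do
    not reach threshold in task data, so the resting-state spheres are reused
    to keep the node set consistent across conditions.
    """
    if condition not in ("rest", "task"):
        raise ValueError("condition must be 'rest' or 'task'")
    ref = importlib.resources.files("bnec").joinpath("data/dmn_rois.tsv")
    df = pd.read_csv(ref, sep="\t")
    rows = df[df["condition"] == condition]
    return [
        RoiDefinition(
            label=str(r.label),
            center_mni=(float(r.x), float(r.y), float(r.z)),
            radius=float(r.radius),
        )
        for r in rows.itertuples()
    ]
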