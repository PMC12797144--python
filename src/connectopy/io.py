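"""File I/O: NIfTI timeseries/mask handling, TSV matrices, run provenance.

Volumetric NIfTI is the primary interchange format; tabular TSV (with a
voxel-id header row) covers pre-extracted timeseries and every matrix
output.  Voxel ordering is always ascending linear index in the mask's
native array order, and that convention is recorded in output provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import TimeseriesMatrix, SimilarityMatrix
from .manifold import GradientSet
from .spatial_stats import VoxelGeometry

__all__ = [
    "RegionMask",
    "RunConfig",
    "load_mask",
    "extract_timeseries",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_gradients_tsv",
    "read_gradients_tsv",
    "gradient_to_nifti",
    "read_map",
]


@dataclass
class RegionMask:
    """Integer label volume with its affine and the labels of interest."""

    volume: np.ndarray
    affine: np.ndarray
    selected_labels: tuple

    def __post_init__(self):
        self.volume = np.asarray(self.volume)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        present = set(np.unique(self.volume).tolist())
        missing = [l for l in self.selected_labels if l not in present]
        if missing:
            raise ValueError(f"labels {missing} not present in the mask volume")

    @property
    def binary(self) -> np.ndarray:
        return np.isin(self.volume, self.selected_labels)


@dataclass
class RunConfig:
    """Pipeline configuration, serialized into every output's provenance."""

    variant: str = "original"
    measure: str | None = None
    method: str = "DE"
    sparsity: float = 0.9
    g: int = 3
    align: bool = True
    master_seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        from .core import VARIANTS, MEASURES
        from .manifold import METHODS

        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.measure is not None and self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must lie in [0, 1)")
        if self.g < 1:
            raise ValueError("g must be >= 1")

    def provenance(self) -> dict:
        from . import __version__

        d = asdict(self)
        d["package_version"] = __version__
        d["voxel_order"] = "ascending-linear-index"
        return d

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; explicit overrides win."""
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        kwargs = {}
        for key in ("variant", "measure", "method"):
            if key in kv:
                kwargs[key] = kv[key]
        if "sparsity" in kv:
            kwargs["sparsity"] = float(kv["sparsity"])
        for key in ("g", "master_seed"):
            if key in kv:
                kwargs[key] = int(kv[key])
        if "align" in kv:
            kwargs["align"] = kv["align"].lower() in ("1", "true", "yes")
        kwargs.update(overrides)
        return cls(**kwargs)


def load_mask(path, labels=None) -> RegionMask:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(int)
    present = [int(l) for l in np.unique(vol) if l != 0]
    if labels is None:
        labels = present
    return RegionMask(
        volume=vol, affine=img.affine, selected_labels=tuple(int(l) for l in labels)
    )


def extract_timeseries(
    image_4d, mask: RegionMask, region_tag: str = "seed"
) -> tuple[TimeseriesMatrix, VoxelGeometry]:
    """Extract a time-by-voxel matrix and voxel coordinates from a 4D image.

    Columns are ordered by ascending linear voxel index; constant-signal
    voxels are excluded and recorded on ``TimeseriesMatrix.excluded_voxel_ids``.
    Coordinates follow the center-of-voxel convention through the affine.
    """
    img = nib.load(str(image_4d)) if not isinstance(image_4d, nib.Nifti1Image) else image_4d
    if img.shape[:3] != mask.volume.shape:
        raise ValueError(
            f"grid mismatch: image {img.shape[:3]} vs mask {mask.volume.shape}"
        )
    if not np.allclose(img.affine, mask.affine, atol=1e-4):
        raise ValueError(
            "affine mismatch between image and mask:\n"
            f"image affine:\n{img.affine}\nmask affine:\n{mask.affine}"
        )
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4D timeseries image")
    binary = mask.binary
    flat_ids = np.flatnonzero(binary.ravel())
    ijk = np.argwhere(binary)  # same ordering as flat_ids (C order)
    ts = data[binary].T.astype(float)  # t x v
    sd = ts.std(axis=0)
    good = sd > 0
    excluded = flat_ids[~good].tolist()
    if not good.any():
        raise ValueError("mask selects no voxels with non-constant signal")
    homog = np.hstack([ijk[good], np.ones((int(good.sum()), 1))])
    coords = (mask.affine @ homog.T).T[:, :3]
    tsm = TimeseriesMatrix(
        data=ts[:, good],
        voxel_ids=flat_ids[good],
        region_tag=region_tag,
        excluded_voxel_ids=excluded,
    )
    geom = VoxelGeometry(coordinates=coords, voxel_ids=flat_ids[good])
    return tsm, geom


# ---------------------------------------------------------------------------
# tabular round-trips


def write_timeseries_tsv(ts: TimeseriesMatrix, path) -> None:
    df = pd.DataFrame(ts.data, columns=[str(v) for v in ts.voxel_ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, region_tag: str = "seed") -> TimeseriesMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeseriesMatrix(
        data=df.to_numpy(dtype=float),
        voxel_ids=np.array([int(c) for c in df.columns]),
        region_tag=region_tag,
    )


def write_matrix_tsv(mat, path, voxel_ids=None) -> None:
    data = mat.data if hasattr(mat, "data") else np.asarray(mat)
    ids = voxel_ids if voxel_ids is not None else np.arange(data.shape[1])
    df = pd.DataFrame(data, columns=[str(v) for v in ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_matrix_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), np.array([int(c) for c in df.columns])


def write_gradients_tsv(gset: GradientSet, path) -> None:
    ids = (
        gset.voxel_ids
        if gset.voxel_ids is not None
        else np.arange(gset.n_voxels)
    )
    cols = {"voxel_id": ids}
    for j in range(gset.n_gradients):
        cols[f"gradient_{j + 1}"] = gset.gradients[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gradients_tsv(path, method: str = "DE", variant=None) -> GradientSet:
    df = pd.read_csv(path, sep="\t")
    gcols = [c for c in df.columns if c.startswith("gradient_")]
    return GradientSet(
        gradients=df[gcols].to_numpy(dtype=float),
        eigenvalues=np.zeros(len(gcols)),
        method=method,
        variant=variant,
        voxel_ids=df["voxel_id"].to_numpy(dtype=int),
    )


def gradient_to_nifti(
    values: np.ndarray, voxel_ids: np.ndarray, shape: tuple, affine: np.ndarray
) -> nib.Nifti1Image:
    """Place per-voxel values back into a volume (NaN background)."""
    vol = np.full(int(np.prod(shape)), np.nan)
    vol[np.asarray(voxel_ids, dtype=int)] = np.asarray(values, dtype=float)
    return nib.Nifti1Image(vol.reshape(shape).astype(np.float32), affine)


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a reference voxel map from NIfTI or TSV (voxel_id, value)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj).astype(float).ravel()
        ids = np.flatnonzero(np.isfinite(vol) & (vol != 0))
        return vol[ids], ids
    df = pd.read_csv(path, sep="\t")
    return (
        df["value"].to_numpy(dtype=float),
        df["voxel_id"].to_numpy(dtype=int),
    )


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
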