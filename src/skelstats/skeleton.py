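"""Data model and I/O for skeletonized scalar maps.

The TBSS-style analyses in this package never operate on full 3D volumes
directly: each subject's diffusion scalar map (FA, MD, RD or AD) is reduced
to its values on a common white-matter skeleton, and all statistics are
computed on a dense ``subjects x skeleton-voxels`` matrix.  The classes here
hold that representation and the bijection back to voxel space, which TFCE
needs to recover spatial adjacency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "SkeletonSpace",
    "MetricStack",
    "StatMap",
    "dti_scalars",
    "skeleton_mask_from_mean",
    "mean_skeleton_metric",
]

METRIC_NAMES = ("FA", "MD", "RD", "AD")
STAT_KINDS = ("t", "z", "tfce", "p", "mean")


@dataclass
class SkeletonSpace:
    """A voxel grid with a boolean skeleton mask and a voxel<->column map.

    Columns are the skeleton voxels enumerated in C (row-major) order of
    their voxel indices; all per-voxel statistics in this package are stored
    as flat arrays of length ``n_columns`` in this order.

    Parameters
    ----------
    mask:
        3D boolean array; True marks skeleton voxels.
    affine:
        4x4 voxel-to-world (mm) affine.  Synthetic spaces may use identity.
    tract_labels:
        Optional integer label per skeleton column (JHU-style atlas
        restricted to the skeleton); 0 means unlabeled.
    tract_names:
        Mapping from label integer to tract name.
    """

    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tract_labels: np.ndarray | None = None
    tract_names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        # column -> voxel map, fixed C order
        self._mask_ijk = np.argwhere(self.mask)
        flat = np.ravel_multi_index(self._mask_ijk.T, self.mask.shape)
        self._col_of_flat = {int(f): i for i, f in enumerate(flat)}
        if self.tract_labels is not None:
            self.tract_labels = np.asarray(self.tract_labels, dtype=int)
            if self.tract_labels.shape != (self.n_columns,):
                raise ValueError(
                    "tract_labels must have one entry per skeleton column"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_columns(self) -> int:
        return int(self._mask_ijk.shape[0])

    def column_to_voxel(self, col: int | np.ndarray) -> np.ndarray:
        """(i, j, k) voxel index of a skeleton column."""
        return self._mask_ijk[col]

    def voxel_to_column(self, ijk: Sequence[int]) -> int:
        """Column index of a skeleton voxel; raises if outside the mask."""
        flat = int(np.ravel_multi_index(tuple(ijk), self.mask.shape))
        try:
            return self._col_of_flat[flat]
        except KeyError:
            raise KeyError(f"voxel {tuple(ijk)} is not on the skeleton") from None

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-column values into a full 3D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_columns,):
            raise ValueError("values must have one entry per skeleton column")
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol

    def from_volume(self, vol: np.ndarray) -> np.ndarray:
        """Extract skeleton-column values from a full 3D volume."""
        vol = np.asarray(vol)
        if vol.shape != self.shape:
            raise ValueError("volume shape does not match the space")
        return vol[self.mask].astype(float)

    def voxel_to_world(self, ijk: Sequence[int]) -> np.ndarray:
        return (self.affine @ np.append(np.asarray(ijk, float), 1.0))[:3]

    # ---- I/O ------------------------------------------------------------

    def save_mask(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))

    def save_labels(self, nifti_path: str | Path, names_path: str | Path) -> None:
        if self.tract_labels is None:
            raise ValueError("space has no tract labels")
        vol = np.zeros(self.shape, dtype=np.int16)
        vol[self.mask] = self.tract_labels
        nib.save(nib.Nifti1Image(vol, self.affine), str(nifti_path))
        names = {str(k): v for k, v in (self.tract_names or {}).items()}
        Path(names_path).write_text(json.dumps(names, indent=2))

    @classmethod
    def load(
        cls,
        mask_path: str | Path,
        labels_path: str | Path | None = None,
        names_path: str | Path | None = None,
    ) -> "SkeletonSpace":
        img = nib.load(str(mask_path))
        mask = np.asarray(img.dataobj) > 0
        labels = None
        names = None
        if labels_path is not None:
            lab_vol = np.asarray(nib.load(str(labels_path)).dataobj).astype(int)
            labels = lab_vol[mask]
        if names_path is not None:
            names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
        return cls(mask=mask, affine=img.affine, tract_labels=labels, tract_names=names)


@dataclass
class MetricStack:
    """``subjects x skeleton-columns`` matrix of one DTI scalar."""

    metric: str
    data: np.ndarray
    subject_ids: np.ndarray
    space: SkeletonSpace

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"metric must be one of {METRIC_NAMES}")
        self.data = np.asarray(self.data, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (subjects x columns)")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        if self.data.shape[1] != self.space.n_columns:
            raise ValueError("column count must match the skeleton")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("metric values inside the mask must be finite")
        if self.metric == "FA" and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("FA values must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def subset(self, row_index: np.ndarray) -> "MetricStack":
        return MetricStack(
            metric=self.metric,
            data=self.data[row_index],
            subject_ids=self.subject_ids[row_index],
            space=self.space,
        )

    def save(self, path: str | Path) -> None:
        """Write as 4D NIfTI, subjects along the 4th axis; off-skeleton = 0."""
        vol = np.zeros(self.space.shape + (self.n_subjects,), dtype=np.float32)
        vol[self.space.mask, :] = self.data.T
        nib.save(nib.Nifti1Image(vol, self.space.affine), str(path))

    @classmethod
    def load(
        cls,
        path: str | Path,
        metric: str,
        space: SkeletonSpace,
        subject_ids: Sequence | None = None,
    ) -> "MetricStack":
        vol = np.asarray(nib.load(str(path)).dataobj)
        if vol.ndim != 4:
            raise ValueError("expected a 4D NIfTI stack")
        data = vol[space.mask, :].T
        if subject_ids is None:
            subject_ids = np.arange(data.shape[0])
        return cls(metric=metric, data=data, subject_ids=np.asarray(subject_ids), space=space)


@dataclass
class StatMap:
    """Per-skeleton-column statistic values tied to a SkeletonSpace."""

    values: np.ndarray
    kind: str
    space: SkeletonSpace
    direction: str | None = None  # "greater" | "less" for directional contrasts

    def __post_init__(self) -> None:
        if self.kind not in STAT_KINDS:
            raise ValueError(f"kind must be one of {STAT_KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.n_columns,):
            raise ValueError("values must have one entry per skeleton column")
        if self.kind == "p":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() <= 0 or finite.max() > 1):
                raise ValueError("p-values must lie in (0, 1]")

    def save(self, path: str | Path, fill: float = 0.0) -> None:
        vol = self.space.to_volume(np.nan_to_num(self.values, nan=fill), fill=fill)
        nib.save(nib.Nifti1Image(vol.astype(np.float32), self.space.affine), str(path))



def dti_scalars(eigenvalues: np.ndarray) -> dict[str, np.ndarray]:
    """Diffusion-tensor scalar maps from the three sorted eigenvalues.

    Parameters
    ----------
    eigenvalues:
        Array with last axis of length 3 holding ``(l1, l2, l3)`` with
        ``l1 >= l2 >= l3`` per voxel.

    Returns
    -------
    dict with keys ``FA``, ``MD``, ``RD``, ``AD``:
        MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2 and
        FA = sqrt(3/2) * ||l - MD|| / ||l||, which lies in [0, 1].
        An all-zero tensor gets FA = 0 by convention, with a warning.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("last axis must hold the 3 eigenvalues")
    if not np.all(np.isfinite(ev)):
        raise ValueError("eigenvalues must be finite")
    if np.any(np.diff(ev, axis=-1) > 1e-12):
        raise ValueError("eigenvalues must be sorted l1 >= l2 >= l3")

    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    num = np.sqrt(((ev - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    zero = den == 0
    if np.any(zero):
        warnings.warn(
            f"{int(np.count_nonzero(zero))} all-zero tensor(s); FA set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(zero, 0.0, fa)
    fa = np.clip(fa, 0.0, 1.0)
    return {"FA": fa, "MD": md, "RD": rd, "AD": ad}


def skeleton_mask_from_mean(
    mean_fa: np.ndarray,
    threshold: float = 0.2,
    affine: np.ndarray | None = None,
) -> SkeletonSpace:
    """Binary skeleton from a mean-FA map: voxels with FA strictly > threshold."""
    mean_fa = np.asarray(mean_fa, dtype=float)
    if mean_fa.ndim != 3:
        raise ValueError("mean FA map must be 3D")
    mask = mean_fa > threshold
    if not mask.any():
        raise ValueError(f"no voxels exceed the FA threshold {threshold}")
    return SkeletonSpace(mask=mask, affine=np.eye(4) if affine is None else affine)


def mean_skeleton_metric(stack: MetricStack) -> np.ndarray:
    """Per-subject mean of the metric over all skeleton voxels."""
    if stack.data.shape[1] == 0:
        raise ValueError("empty stack")
    return stack.data.mean(axis=1)
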