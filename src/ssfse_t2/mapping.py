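"""Voxelwise T2 mapping of co-registered multi-contrast volumes.

The modelling surface follows the familiar model/results split: a
:class:`T2DictionaryModel` is constructed from data (a
:class:`MultiContrastVolume` and a :class:`SignalDictionary`), its
``fit()`` performs the voxelwise dictionary matching and returns a
:class:`T2MapResult` carrying the T2 map, the fit-quality map
E = 1 - best normalized scalar product, the flagged-voxel mask,
provenance hashes and summary/ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dictionary import SignalDictionary, dictionary_match

__all__ = [
    "MultiContrastVolume",
    "T2DictionaryModel",
    "T2MapResult",
    "fit_volume",
    "roi_statistics",
]


@dataclass
class MultiContrastVolume:
    """Co-registered intensity volumes, one per TE, on a shared grid.

    Registration across TEs is assumed done upstream; construction
    validates shape and affine agreement and refuses misaligned inputs.
    """

    volumes: list[np.ndarray]
    tes: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.tes = np.asarray(self.tes, dtype=float)
        if len(self.volumes) != self.tes.size:
            raise ValueError("one volume per TE required")
        if np.any(np.diff(self.tes) <= 0):
            raise ValueError("tes must be strictly increasing")
        shape = self.volumes[0].shape
        for v in self.volumes[1:]:
            if v.shape != shape:
                raise ValueError("all volumes must share one shape")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError("mask shape must match the volumes")
        self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple:
        return self.volumes[0].shape

    @classmethod
    def from_nifti(
        cls,
        paths: list[str | Path],
        tes,
        mask_path: str | Path | None = None,
        atol: float = 1e-4,
    ) -> "MultiContrastVolume":
        """Load per-TE NIfTI volumes, checking grid/affine agreement."""
        import nibabel as nib

        imgs = [nib.load(str(p)) for p in paths]
        affine = imgs[0].affine
        for p, img in zip(paths, imgs):
            if img.shape != imgs[0].shape or not np.allclose(img.affine, affine, atol=atol):
                raise ValueError(f"volume {p} is not on the same grid/affine")
        mask = None
        if mask_path is not None:
            mimg = nib.load(str(mask_path))
            if mimg.shape != imgs[0].shape or not np.allclose(mimg.affine, affine, atol=atol):
                raise ValueError("mask is not on the same grid/affine")
            mask = np.asarray(mimg.dataobj) > 0
        spacing = tuple(float(s) for s in imgs[0].header.get_zooms()[:3])
        return cls(
            volumes=[np.asarray(i.dataobj, dtype=float) for i in imgs],
            tes=tes,
            mask=mask,
            affine=affine,
            spacing=spacing,
        )


class T2DictionaryModel:
    """Dictionary-matching T2 estimator for a multi-contrast volume.

    Parameters
    ----------
    data : MultiContrastVolume
        Co-registered per-TE volumes with an optional fitting mask.
    dictionary : SignalDictionary
        Slice-profile-corrected signal dictionary whose TE labels must
        match the data's TE order (no silent reordering).
    """

    def __init__(self, data: MultiContrastVolume, dictionary: SignalDictionary):
        if len(dictionary.sequences) != data.tes.size or not np.allclose(
            dictionary.tes, data.tes
        ):
            raise ValueError(
                f"dictionary TEs {dictionary.tes} do not match data TEs {data.tes}"
            )
        self.data = data
        self.dictionary = dictionary

    def fit(self) -> "T2MapResult":
        """Match every masked voxel against the dictionary.

        Voxels with non-finite intensities or no positive element are
        flagged (NaN in the maps) rather than imputed.  The fit is
        independent per voxel and deterministic.
        """
        shape = self.data.shape
        stack = np.stack([v for v in self.data.volumes], axis=-1)
        mask = self.data.mask
        t2_map = np.full(shape, np.nan)
        e_map = np.full(shape, np.nan)
        signals = stack[mask]
        t2_hat, e_fit = dictionary_match(signals, self.dictionary)
        t2_map[mask] = t2_hat
        e_map[mask] = e_fit
        flagged = mask & ~np.isfinite(t2_map)
        return T2MapResult(
            t2_map=t2_map,
            fit_quality_map=e_map,
            mask=mask,
            flagged_mask=flagged,
            dictionary_hash=self.dictionary.config_hash(),
            affine=self.data.affine,
            model=self,
        )


@dataclass
class T2MapResult:
    """Fitted T2 map plus fit-quality map and bookkeeping."""

    t2_map: np.ndarray
    fit_quality_map: np.ndarray
    mask: np.ndarray
    flagged_mask: np.ndarray
    dictionary_hash: str
    affine: np.ndarray
    model: T2DictionaryModel | None = None

    @property
    def n_fitted(self) -> int:
        return int(np.sum(self.mask & ~self.flagged_mask))

    def roi_statistics(self, labels: np.ndarray, erode: int = 1) -> pd.DataFrame:
        return roi_statistics(self, labels, erode=erode)

    def summary(self) -> str:
        """Human-readable fit summary."""
        valid = self.mask & ~self.flagged_mask
        t2 = self.t2_map[valid]
        e = self.fit_quality_map[valid]
        lines = [
            "T2 dictionary fit",
            "=" * 44,
            f"voxels fitted        {self.n_fitted}",
            f"voxels flagged       {int(self.flagged_mask.sum())}",
            f"T2 median [IQR] ms   {np.median(t2):.1f} "
            f"[{np.percentile(t2, 25):.1f}, {np.percentile(t2, 75):.1f}]"
            if t2.size
            else "T2 median [IQR] ms   n/a",
            f"fit quality E median {np.median(e):.2e}" if e.size else "fit quality E median n/a",
            f"dictionary hash      {self.dictionary_hash}",
        ]
        return "\n".join(lines)

    def to_nifti(self, out_dir: str | Path) -> None:
        import nibabel as nib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in [
            ("t2_map", self.t2_map),
            ("fit_quality", self.fit_quality_map),
            ("flagged", self.flagged_mask.astype(np.uint8)),
        ]:
            data = arr if arr.ndim == 3 else arr[..., None]
            nib.save(
                nib.Nifti1Image(np.asarray(data, dtype=np.float32), self.affine),
                out_dir / f"{name}.nii.gz",
            )


def fit_volume(mcv: MultiContrastVolume, dictionary: SignalDictionary) -> T2MapResult:
    """Functional wrapper: ``T2DictionaryModel(mcv, dictionary).fit()``."""
    return T2DictionaryModel(mcv, dictionary).fit()


def roi_statistics(result: T2MapResult, labels: np.ndarray, erode: int = 1) -> pd.DataFrame:
    """Per-label n / mean / SD of fitted T2 after label erosion.

    Each label is eroded by ``erode`` voxels (morphological, to avoid
    partial-volume contamination at region boundaries); flagged voxels
    are excluded.  Empty ROIs report n = 0 with NaN statistics.
    """
    if labels.shape != result.t2_map.shape:
        raise ValueError("labels must be on the same grid as the maps")
    rows = []
    valid = result.mask & ~result.flagged_mask & np.isfinite(result.t2_map)
    # erode in-plane only along non-singleton axes (a single-slice volume
    # would otherwise vanish under a 3D structuring element)
    shape = [3 if s > 1 else 1 for s in labels.shape]
    structure = np.zeros(shape, dtype=bool)
    centre = tuple(s // 2 for s in shape)
    structure[centre] = True
    for ax, s in enumerate(shape):
        if s == 3:
            for d in (0, 2):
                idx = list(centre)
                idx[ax] = d
                structure[tuple(idx)] = True
    for label in np.unique(labels):
        if label == 0:
            continue
        roi = labels == label
        if erode > 0:
            roi = ndimage.binary_erosion(roi, structure=structure, iterations=erode)
        roi = roi & valid
        vals = result.t2_map[roi]
        rows.append(
            {
                "label": int(label),
                "n": int(vals.size),
                "mean_t2": float(vals.mean()) if vals.size else np.nan,
                "sd_t2": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
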