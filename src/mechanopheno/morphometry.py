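"""Automated cell and focal-adhesion morphometry.

Reimplements a classic three-channel profiling workflow as code: channel
preprocessing (percentile contrast stretch, white top-hat on the FA
channel), primary segmentation of nuclei (Otsu two-class), secondary
segmentation of cell bodies (seeded watershed from the nuclei), FA
segmentation inside the cell footprint, and per-object size/shape
measurements.

Shape is summarized by the moments-equivalent ellipse: ``eccentricity =
sqrt(1 - (minor/major)^2)``, 0 for a circle and approaching 1 for an
elongated adhesion.  Areas are reported in um^2 via the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed

__all__ = [
    "ChannelImage", "LabelMap", "ObjectMeasurements",
    "preprocess", "segment_primary", "segment_secondary", "segment_fa",
    "measure_objects", "area_occupied",
]


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel with its physical scale and preprocessing
    record (immutable; preprocessing returns a new instance)."""

    data: np.ndarray
    channel: str                  # "nuclei" | "cell" | "fa"
    pixel_size: float             # um / px
    preprocessing: MappingProxyType = field(
        default_factory=lambda: MappingProxyType({}))

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("channel image must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.channel not in ("nuclei", "cell", "fa"):
            raise ValueError(f"unknown channel tag {self.channel!r}")
        if not isinstance(self.preprocessing, MappingProxyType):
            object.__setattr__(self, "preprocessing",
                               MappingProxyType(dict(self.preprocessing)))


@dataclass(frozen=True)
class LabelMap:
    """Segmented objects: 0 = background, k > 0 = object k (contiguous)."""

    labels: np.ndarray
    object_class: str             # "nucleus" | "cell" | "fa"
    pixel_size: float
    provenance: MappingProxyType = field(
        default_factory=lambda: MappingProxyType({}))

    def __post_init__(self):
        object.__setattr__(self, "labels",
                           np.asarray(self.labels, dtype=np.int32))
        if not isinstance(self.provenance, MappingProxyType):
            object.__setattr__(self, "provenance",
                               MappingProxyType(dict(self.provenance)))
        labs = np.unique(self.labels)
        labs = labs[labs > 0]
        if len(labs) and not np.array_equal(labs, np.arange(1, len(labs) + 1)):
            raise ValueError("labels must be contiguous from 1")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ObjectMeasurements:
    """Per-object morphometrics plus the per-image occupied-area fraction."""

    table: pd.DataFrame           # label, area_um2, eccentricity, ...
    area_occupied_fraction: float
    object_class: str


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Re-pack labels to 1..n preserving order of first appearance."""
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(image: ChannelImage, saturation: float = 0.35,
               tophat_radius: int = 5,
               apply_tophat: bool = False) -> ChannelImage:
    """Contrast stretch plus optional white top-hat background removal.

    ``saturation`` is the percentage of pixels clipped, split equally
    between the two histogram tails, after which intensities are rescaled
    to [0, 1].  ``apply_tophat`` runs a white top-hat with a disk of
    ``tophat_radius`` px — suppresses structures larger than the disk,
    keeping small bright puncta (the FA channel treatment).
    A constant image is returned unchanged with a warning record.
    """
    if not 0 <= saturation < 50:
        raise ValueError("saturation must be a percentage in [0, 50)")
    if apply_tophat and tophat_radius < 1:
        raise ValueError("tophat_radius must be >= 1 when applied")
    data = image.data
    record = dict(image.preprocessing)
    if data.max() == data.min():
        record["warning"] = "constant image: preprocessing skipped"
        return ChannelImage(data, image.channel, image.pixel_size,
                            MappingProxyType(record))
    lo, hi = np.percentile(data, [saturation / 2.0, 100.0 - saturation / 2.0])
    if hi <= lo:   # pathological histogram; fall back to full range
        lo, hi = data.min(), data.max()
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    record["saturation_percent"] = saturation
    if apply_tophat:
        out = white_tophat(out, footprint=disk(tophat_radius))
        record["tophat_radius_px"] = tophat_radius
    return ChannelImage(out, image.channel, image.pixel_size,
                        MappingProxyType(record))


# ---------------------------------------------------------------------------
# segmentation


def _otsu_mask(data: np.ndarray) -> np.ndarray | None:
    if data.max() == data.min():
        return None
    thr = threshold_otsu(data, nbins=256)
    return data > thr


def segment_primary(nuclei: ChannelImage, min_area: float = 30.0,
                    manual_removals: list[int] | None = None) -> LabelMap:
    """Nucleus segmentation: Otsu two-class threshold, hole filling,
    8-connected labeling, ``min_area`` (um^2) filter, then an explicit
    removal list standing in for interactive manual refinement."""
    mask = _otsu_mask(nuclei.data)
    prov = {"min_area_um2": min_area}
    if mask is None:
        return LabelMap(np.zeros(nuclei.data.shape, np.int32), "nucleus",
                        nuclei.pixel_size, MappingProxyType(prov))
    mask = ndi.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)
    min_px = min_area / nuclei.pixel_size**2
    sizes = np.bincount(labels.ravel())
    kill = np.flatnonzero(sizes < min_px)
    labels[np.isin(labels, kill)] = 0
    labels = _relabel(labels)
    if manual_removals:
        labels[np.isin(labels, manual_removals)] = 0
        labels = _relabel(labels)
        prov["manual_removals"] = list(manual_removals)
    return LabelMap(labels, "nucleus", nuclei.pixel_size,
                    MappingProxyType(prov))


def segment_secondary(cell: ChannelImage, seeds: LabelMap) -> LabelMap:
    """Cell-body segmentation by seeded watershed from nucleus seeds.

    The cell channel is Otsu-thresholded; the watershed of the inverted
    intensity, seeded by the nuclei and restricted to the foreground, then
    splits touching cells.  Each cell inherits its seed's label; a seed
    falling outside the foreground keeps (at least) its own region.
    """
    if seeds.n_objects == 0:
        raise ValueError("need at least one nucleus seed")
    mask = _otsu_mask(cell.data)
    fg = (seeds.labels > 0) if mask is None else (mask | (seeds.labels > 0))
    labels = watershed(-cell.data, markers=seeds.labels, mask=fg)
    labels = _relabel(labels)
    return LabelMap(labels, "cell", cell.pixel_size,
                    MappingProxyType({"seeds": "nuclei"}))


def segment_fa(fa: ChannelImage, cells: LabelMap, min_area: float = 0.1,
               max_area: float = 30.0) -> LabelMap:
    """Focal-adhesion segmentation inside the cell footprint.

    Pixels outside the cells are zeroed, Otsu runs on the in-cell
    intensities only, objects are labelled (8-connectivity) and kept when
    ``min_area <= area <= max_area`` (um^2).  Each FA records its parent
    cell by majority overlap (in provenance["parents"]).
    """
    region = cells.labels > 0
    if not region.any():
        raise ValueError("cell label map has no foreground")
    data = np.where(region, fa.data, 0.0)
    vals = fa.data[region]
    prov: dict = {"min_area_um2": min_area, "max_area_um2": max_area}
    if vals.max() == vals.min():
        return LabelMap(np.zeros(fa.data.shape, np.int32), "fa",
                        fa.pixel_size, MappingProxyType(prov))
    thr = threshold_otsu(vals, nbins=256)
    prov["threshold"] = float(thr)
    labels = sk_label((data > thr) & region, connectivity=2)
    px2 = fa.pixel_size**2
    sizes = np.bincount(labels.ravel()) * px2
    kill = np.flatnonzero((sizes < min_area) | (sizes > max_area))
    labels[np.isin(labels, kill)] = 0
    labels = _relabel(labels)
    parents = {}
    for p in regionprops(labels):
        under = cells.labels[labels == p.label]
        under = under[under > 0]
        parents[int(p.label)] = (int(np.bincount(under).argmax())
                                 if len(under) else 0)
    prov["parents"] = parents
    return LabelMap(labels, "fa", fa.pixel_size, MappingProxyType(prov))


# ---------------------------------------------------------------------------
# measurement


def measure_objects(labels: LabelMap,
                    pixel_size: float | None = None) -> ObjectMeasurements:
    """Size and shape of every labelled object.

    Area from the pixel count, centroid from first moments, axes and
    eccentricity from the second-central-moments-equivalent ellipse;
    single-pixel (degenerate) objects get eccentricity 0.
    """
    px = labels.pixel_size if pixel_size is None else pixel_size
    if labels.n_objects == 0:
        raise ValueError("empty label map")
    parents = dict(labels.provenance.get("parents", {}))
    rows = []
    for p in regionprops(labels.labels):
        major = p.axis_major_length * px
        minor = p.axis_minor_length * px
        ecc = (float(np.sqrt(1.0 - (minor / major)**2)) if major > 0 else 0.0)
        cy, cx = p.centroid
        rows.append({
            "label": int(p.label),
            "area_um2": p.area * px**2,
            "centroid_x_um": cx * px,
            "centroid_y_um": cy * px,
            "major_axis_um": major,
            "minor_axis_um": minor,
            "eccentricity": ecc,
            "orientation_rad": float(p.orientation),
            "parent_cell": parents.get(int(p.label), 0),
        })
    table = pd.DataFrame(rows)
    return ObjectMeasurements(table=table,
                              area_occupied_fraction=area_occupied(labels),
                              object_class=labels.object_class)


def area_occupied(labels: LabelMap) -> float:
    """Foreground fraction of the image: labelled pixels / total pixels."""
    return float(np.count_nonzero(labels.labels)) / labels.labels.size
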