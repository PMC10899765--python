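"""Synthetic fluorescence fields and their quantification.

Renders small three-channel fields (DNA, FBL, 5-EU) from an explicit cell
plan with exact ground-truth masks, then quantifies them the way a
high-content nucleolar screen does: segment nuclei on the DNA channel,
segment nucleoli within each nucleus on the FBL channel, count nucleoli per
nucleus, and measure per-nucleolus median 5-EU intensity.

Segmentation contract: global Otsu threshold on the smoothed DNA channel
with hole filling and distance-transform watershed splitting for nuclei
(border-touching and out-of-range areas removed); per-nucleus Otsu threshold
on the FBL channel restricted to the nucleus footprint for nucleoli. All
thresholds are relative, so the output is invariant to uniform intensity
scaling of the input. Image coordinates are row-major, origin top-left,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed


@dataclass(frozen=True)
class NucleolusPlan:
    center: tuple[float, float]  # (row, col), absolute image coordinates
    radius: float = 3.0
    eu_brightness: float = 1.0


@dataclass(frozen=True)
class NucleusPlan:
    center: tuple[float, float]
    radius: float = 18.0
    nucleoli: tuple[NucleolusPlan, ...] = ()


@dataclass
class FieldImage:
    dna: np.ndarray
    fbl: np.ndarray
    eu: np.ndarray

    def __post_init__(self):
        if not (self.dna.shape == self.fbl.shape == self.eu.shape):
            raise ValueError("channels must share one shape")
        for name in ("dna", "fbl", "eu"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{name} channel must be finite, nonnegative")


@dataclass
class LabelMask:
    labels: np.ndarray
    parents: dict[int, int] = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def _draw_blob(img, center, radius, amplitude):
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    img += amplitude * np.exp(-d2 / (2 * (radius / 1.6) ** 2))


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_field(
    plan: list[NucleusPlan],
    shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[FieldImage, LabelMask, LabelMask]:
    """Render a field and its exact ground-truth masks.

    Nuclei are smooth Gaussian blobs in the DNA channel; nucleoli are smaller
    blobs in FBL and (scaled by their brightness) in EU. ``noise_sd``
    controls additive Gaussian noise plus Poisson-like shot noise. A
    nucleolus planned outside its parent nucleus is rejected.

    Returns ``(image, nucleus_mask, nucleolus_mask)``; the nucleolus mask
    carries the parent map nucleolus label -> nucleus label.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dna = np.zeros(shape)
    fbl = np.zeros(shape)
    eu = np.zeros(shape)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    no_labels = np.zeros(shape, dtype=np.int32)
    parents: dict[int, int] = {}
    next_no = 1
    for i, nuc in enumerate(plan, start=1):
        for sub in nuc.nucleoli:
            d = np.hypot(
                sub.center[0] - nuc.center[0], sub.center[1] - nuc.center[1]
            )
            if d + sub.radius > nuc.radius:
                raise ValueError(
                    f"nucleolus at {sub.center} outside nucleus {i}"
                )
        _draw_blob(dna, nuc.center, nuc.radius, 1000.0)
        mask = _disk_mask(shape, nuc.center, nuc.radius)
        nuc_labels[mask & (nuc_labels == 0)] = i
        for sub in nuc.nucleoli:
            _draw_blob(fbl, sub.center, sub.radius, 1000.0)
            _draw_blob(eu, sub.center, sub.radius, 1000.0 * sub.eu_brightness)
            m = _disk_mask(shape, sub.center, sub.radius)
            no_labels[m & (no_labels == 0)] = next_no
            parents[next_no] = i
            next_no += 1
    if noise_sd > 0:
        for img in (dna, fbl, eu):
            img += rng.normal(0, noise_sd, shape)
            img += rng.normal(0, 1, shape) * np.sqrt(np.clip(img, 0, None)) * (
                noise_sd / 50.0
            )
            np.clip(img, 0, None, out=img)
    return (
        FieldImage(dna=dna, fbl=fbl, eu=eu),
        LabelMask(nuc_labels),
        LabelMask(no_labels, parents),
    )


def segment_nuclei(
    image: FieldImage,
    sigma: float = 2.0,
    min_area: int = 100,
    max_area: int = 10_000,
    min_distance: int = 10,
) -> LabelMask:
    """Segment nuclei from the DNA channel.

    Global Otsu threshold on the Gaussian-smoothed channel, hole filling,
    distance-transform watershed to split touching objects, then removal of
    border-touching objects and objects outside the area window. A blank
    image yields an empty mask.
    """
    smoothed = gaussian(image.dna, sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return LabelMask(np.zeros(image.dna.shape, dtype=np.int32))
    binary = smoothed > threshold_otsu(smoothed)
    if not binary.any() or binary.all():
        return LabelMask(np.zeros(image.dna.shape, dtype=np.int32))
    binary = ndi.binary_fill_holes(binary)
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=binary)
    labels = clear_border(labels)
    out = np.zeros_like(labels)
    nxt = 1
    for prop in regionprops(labels):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = nxt
            nxt += 1
    return LabelMask(out)


def segment_nucleoli(
    image: FieldImage,
    nuclei: LabelMask,
    min_area: int = 4,
) -> LabelMask:
    """Segment nucleoli within each nucleus footprint.

    Per-nucleus Otsu threshold on the FBL channel restricted to the nucleus;
    objects below ``min_area`` are removed; each kept object's parent is its
    enclosing nucleus. FBL signal outside any nucleus is ignored.
    """
    out = np.zeros(image.fbl.shape, dtype=np.int32)
    parents: dict[int, int] = {}
    nxt = 1
    for nuc_label in range(1, nuclei.n_objects + 1):
        footprint = nuclei.labels == nuc_label
        vals = image.fbl[footprint]
        if vals.size == 0 or np.ptp(vals) == 0:
            continue
        thr = threshold_otsu(vals)
        fg, bg = vals[vals > thr], vals[vals <= thr]
        # an Otsu split of pure noise has no real contrast; skip such nuclei
        if fg.size == 0 or fg.mean() < bg.mean() + 4 * (bg.std() + 1e-12):
            continue
        binary = footprint & (image.fbl > thr)
        labeled, n = ndi.label(binary)
        for j in range(1, n + 1):
            obj = labeled == j
            if obj.sum() < min_area:
                continue
            out[obj] = nxt
            parents[nxt] = nuc_label
            nxt += 1
    return LabelMask(out, parents)


def nucleus_records(
    nuclei: LabelMask, nucleoli: LabelMask, eu: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-nucleus nucleolus counts and median nucleolar EU intensity."""
    rows = []
    for nuc in range(1, nuclei.n_objects + 1):
        children = [c for c, p in nucleoli.parents.items() if p == nuc]
        med = np.nan
        if eu is not None and children:
            per_child = [
                float(np.median(eu[nucleoli.labels == c])) for c in children
            ]
            med = float(np.median(per_child))
        rows.append((nuc, len(children), med))
    return pd.DataFrame(
        rows, columns=["nucleus", "nucleolus_count", "median_nucleolar_EU"]
    )


def summarize_well(
    records: pd.DataFrame,
    cell_count_reference: float,
    nucleoli: LabelMask | None = None,
    eu: np.ndarray | None = None,
) -> dict:
    """Well-level phenotype measures from per-nucleus records.

    Returns n_cells, pct_one (% of nuclei with exactly one nucleolus),
    pct_fiveplus (% with five or more), the well EU value (median over all
    nucleoli in the well of per-nucleolus median EU, when masks are given),
    and percent viability relative to ``cell_count_reference``. A well with
    zero nuclei is flagged for downstream exclusion.
    """
    n = len(records)
    if n == 0:
        return {"n_cells": 0, "flagged": True}
    counts = records["nucleolus_count"]
    well_eu = np.nan
    if nucleoli is not None and eu is not None and nucleoli.n_objects:
        per_nucleolus = [
            float(np.median(eu[nucleoli.labels == c]))
            for c in range(1, nucleoli.n_objects + 1)
        ]
        well_eu = float(np.median(per_nucleolus))
    return {
        "n_cells": n,
        "pct_one": 100.0 * float((counts == 1).sum()) / n,
        "pct_fiveplus": 100.0 * float((counts >= 5).sum()) / n,
        "median_nucleolar_EU": well_eu,
        "percent_viability": 100.0 * n / cell_count_reference,
        "flagged": False,
    }
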