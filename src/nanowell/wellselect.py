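"""Image-based selection of single-cell nanowells.

Detects cells in two-channel well images with a Laplacian-of-Gaussian
(LoG) blob detector, classifies the resulting objects by size and shape,
and selects wells containing exactly one object in the live-stain
channel and none in the dead-stain channel. Wells with additional
debris-like objects are excluded. The output is a dispense file listing
the selected wells plus Poisson occupancy summary statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .chipsim import ChipLayout, WellImageSet

__all__ = [
    "SegmentationConfig",
    "DetectedObject",
    "log_response",
    "segment_objects",
    "call_wells",
    "select_wells",
    "write_dispense_file",
]


@dataclass
class SegmentationConfig:
    """Parameters of the LoG segmentation and object classification.

    ``threshold`` may be a number (absolute LoG response cutoff) or
    ``"auto"``, in which case the cutoff is ``median + auto_k * MAD`` of
    the response — a robust statistic, so selection is invariant to affine
    intensity rescaling of the input image.
    """

    log_scale: float = 1.3
    threshold: float | str = "auto"
    auto_k: float = 5.0
    min_area: int = 4
    max_area: int = 400
    max_eccentricity: float = 0.95

    def __post_init__(self) -> None:
        if self.log_scale <= 0:
            raise ValueError("log_scale must be positive")
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be below max_area")
        if not 0.0 <= self.max_eccentricity < 1.0:
            raise ValueError("max_eccentricity must be in [0, 1)")


@dataclass
class DetectedObject:
    """One segmented object: centroid in field pixels, size and shape."""

    field: int
    y: float
    x: float
    area: int
    eccentricity: float
    peak_response: float
    accepted: bool = True


def log_response(image: np.ndarray, scale: float) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response of an image.

    The sign is fixed so that bright blobs produce positive peaks; a
    constant image gives an identically zero response. The response of a
    Gaussian blob of width sigma is maximal at its centre when
    ``scale == sigma``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image is empty")
    raw = ndimage.gaussian_laplace(img, sigma=scale)
    # The truncated kernel does not sum exactly to zero, leaving a small
    # intensity-proportional bias; remove it so constants map to zero.
    k = float(ndimage.gaussian_laplace(np.ones((1, 1)), sigma=scale)[0, 0])
    raw -= k * ndimage.gaussian_filter(img, sigma=scale)
    return -(scale ** 2) * raw


def _resolve_threshold(response: np.ndarray, config: SegmentationConfig) -> float:
    if config.threshold == "auto":
        med = float(np.median(response))
        mad = float(np.median(np.abs(response - med)))
        peak = float(response.max())
        # Noise floor from robust statistics; on an essentially noise-free
        # field (MAD ~ 0) fall back to a fixed fraction of the peak so blob
        # tails do not merge into one giant component. Both branches scale
        # with the data, keeping auto-thresholding affine-invariant.
        floor = med + 0.05 * (peak - med) if peak > med else med
        return max(med + config.auto_k * mad, floor)
    return float(config.threshold)


def segment_objects(
    response: np.ndarray,
    config: SegmentationConfig,
    field: int = 0,
) -> list[DetectedObject]:
    """Segment a LoG response into objects and classify them.

    Connected components above the threshold become candidate objects;
    those failing the size or shape bounds are retained with
    ``accepted=False`` so that the well caller can apply its debris rule.
    Components smaller than ``min_area`` are treated as noise specks and
    dropped outright.
    """
    thr = _resolve_threshold(response, config)
    mask = response > thr
    labels = measure.label(mask, connectivity=2)
    out: list[DetectedObject] = []
    for prop in measure.regionprops(labels, intensity_image=response):
        if prop.area < config.min_area:
            continue
        ok = prop.area <= config.max_area and prop.eccentricity <= config.max_eccentricity
        cy, cx = prop.centroid
        out.append(DetectedObject(
            field=field, y=float(cy), x=float(cx), area=int(prop.area),
            eccentricity=float(prop.eccentricity),
            peak_response=float(prop.intensity_max), accepted=ok,
        ))
    return out


def call_wells(
    objects_ch1: list[DetectedObject],
    objects_ch2: list[DetectedObject],
    images: WellImageSet,
) -> pd.DataFrame:
    """Assign objects to wells and call single-cell wells.

    Objects are assigned to the well containing their centroid. A well is
    selected iff it has exactly one accepted object in channel 1 and no
    object in channel 2 (a dead-stain signal rejects the well). Wells
    holding any rejected (debris-like) object are excluded. Objects whose
    centroid falls outside all well bounds are counted and ignored.

    Returns a per-well DataFrame with columns ``row, col, n_ch1, n_ch2,
    n_debris, selected, reason``.
    """
    layout = images.layout
    n1 = np.zeros((layout.n_rows, layout.n_cols), dtype=int)
    n2 = np.zeros_like(n1)
    ndeb = np.zeros_like(n1)
    stray = 0
    for ch, objs in ((1, objects_ch1), (2, objects_ch2)):
        for o in objs:
            well = images.well_of_pixel(o.field, o.y, o.x)
            if well is None:
                stray += 1
                continue
            r, c = well
            if not o.accepted:
                ndeb[r, c] += 1
            elif ch == 1:
                n1[r, c] += 1
            else:
                n2[r, c] += 1

    rows = []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            if ndeb[r, c] > 0:
                sel, reason = False, "debris"
            elif n2[r, c] > 0:
                sel, reason = False, "PI-positive"
            elif n1[r, c] == 1:
                sel, reason = True, ""
            elif n1[r, c] == 0:
                sel, reason = False, "empty"
            else:
                sel, reason = False, "multiple-cells"
            rows.append((r, c, n1[r, c], n2[r, c], ndeb[r, c], sel, reason))
    calls = pd.DataFrame(
        rows, columns=["row", "col", "n_ch1", "n_ch2", "n_debris", "selected", "reason"]
    )
    calls.attrs["stray_objects"] = stray
    return calls


def select_wells(images: WellImageSet, config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Run LoG detection on every field of both channels and call wells."""
    config = config or SegmentationConfig()
    ch1: list[DetectedObject] = []
    ch2: list[DetectedObject] = []
    for f in range(images.n_fields):
        for ch, sink in ((0, ch1), (1, ch2)):
            resp = log_response(images.fields[f, ch], config.log_scale)
            sink.extend(segment_objects(resp, config, field=f))
    return call_wells(ch1, ch2, images)


def write_dispense_file(
    calls: pd.DataFrame,
    layout: ChipLayout,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the dispense TSV and a Poisson occupancy summary JSON.

    The dispense file lists each selected well's coordinate and barcode.
    The summary holds the observed occupancy histogram (0..4+ cells per
    well by channel-1 object count) and the maximum-likelihood Poisson
    rate, which for i.i.d. Poisson counts is the sample mean.
    """
    out_prefix = Path(out_prefix)
    dispense_path = out_prefix.with_suffix(".dispense.tsv")
    summary_path = out_prefix.with_suffix(".summary.json")

    sel = calls[calls["selected"]]
    rows = [
        (int(r), int(c), layout.barcode_map.get((int(r), int(c)), ""))
        for r, c in zip(sel["row"], sel["col"])
    ]
    pd.DataFrame(rows, columns=["row", "col", "barcode"]).to_csv(
        dispense_path, sep="\t", index=False
    )

    counts = calls["n_ch1"].to_numpy()
    hist = {str(k): int((counts == k).sum()) for k in range(4)}
    hist["4+"] = int((counts >= 4).sum())
    summary = {
        "n_wells": int(len(calls)),
        "n_selected": int(sel.shape[0]),
        "occupancy_histogram": hist,
        "fitted_lambda": float(counts.mean()),
    }
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return dispense_path, summary_path
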