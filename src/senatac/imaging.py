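"""Nucleus segmentation and SAHF scoring from DAPI-like grayscale images.

The segmentation recipe follows the classic particle-analysis workflow:
Otsu threshold on the (desaturated) image, hole filling, connected-
component labelling, and size/border filtering; measurements (area, mean,
SD and max DAPI intensity) are taken on the *original* intensities inside
each mask.  SAHF positivity — in the laboratory a manual call — is scored
here by an explicit automated proxy: bright foci are connected components
of pixels above mean + k*SD inside the nucleus with at least
``foci_min_area`` pixels, and a nucleus is SAHF-positive when it carries
at least ``sahf_min_foci`` of them.  All constants are configurable and
reported in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class SegmentationParams:
    min_area: int = 200
    max_area: int = 8000
    exclude_border: bool = True
    connectivity: int = 8  # 4 or 8
    foci_sigma_k: float = 2.0
    foci_min_area: int = 5
    sahf_min_foci: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("require 0 < min_area < max_area")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Desaturate RGB input to single-channel luminance; pass grayscale
    through unchanged."""
    if image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(float)
        return rgb @ np.array([0.2125, 0.7154, 0.0721])
    if image.ndim != 2:
        raise ValueError(f"expected 2-D or RGB image, got shape {image.shape}")
    return image


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance over an ``nbins``-bin
    histogram of the min-max-scaled image, returned on the original
    intensity scale.  Pixels strictly above the threshold are foreground."""
    x = np.asarray(to_grayscale(image), dtype=float).ravel()
    mn, mx = x.min(), x.max()
    if mn == mx:
        raise ValueError("constant image has no threshold")
    hist, edges = np.histogram(x, bins=nbins, range=(mn, mx))
    w = hist.astype(float)
    p = w / w.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)
    k = int(np.argmax(sigma_b))  # leftmost maximizer
    return float(edges[k + 1])  # upper edge of the last background bin


def segment_nuclei(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Binarize at the Otsu threshold, fill holes, label components and
    filter by area / border contact.  Returns a labelled image (0 =
    background, 1..n sequential labels)."""
    params = params or SegmentationParams()
    gray = to_grayscale(np.asarray(image))
    t = otsu_threshold(gray)
    binary = gray > t
    filled = ndimage.binary_fill_holes(binary, structure=None)
    labels, n = ndimage.label(filled, structure=params.structure)
    if n == 0:
        warnings.warn("no nuclei found")
        return labels
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = (areas >= params.min_area) & (areas <= params.max_area)
    if params.exclude_border:
        border_labels = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep &= ~np.isin(np.arange(1, n + 1), border_labels)
    if not keep.any():
        warnings.warn("no nuclei survive area/border filtering")
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    return relabel[labels]


def measure_and_score(
    image: np.ndarray,
    labels: np.ndarray,
    params: SegmentationParams | None = None,
    scale_um_per_px: float | None = None,
) -> pd.DataFrame:
    """Per-nucleus area, intensity statistics, foci count and SAHF call.

    Statistics use the original (pre-threshold) intensities inside each
    mask; foci are connected components of pixels above
    mean + ``foci_sigma_k`` * SD with area >= ``foci_min_area``.
    """
    params = params or SegmentationParams()
    gray = to_grayscale(np.asarray(image)).astype(float)
    if gray.shape != labels.shape:
        raise ValueError("image and label mask shapes differ")
    rows = []
    for lab in range(1, int(labels.max()) + 1):
        mask = labels == lab
        vals = gray[mask]
        mean, sd, mx = float(vals.mean()), float(vals.std(ddof=0)), float(vals.max())
        bright = (gray > mean + params.foci_sigma_k * sd) & mask
        fl, nf = ndimage.label(bright, structure=params.structure)
        if nf:
            fareas = ndimage.sum_labels(np.ones_like(fl), fl,
                                        index=np.arange(1, nf + 1))
            foci = int((fareas >= params.foci_min_area).sum())
        else:
            foci = 0
        cy, cx = ndimage.center_of_mass(mask)
        row = dict(
            nucleus_id=lab, area=int(mask.sum()), cx=cx, cy=cy,
            mean_intensity=mean, sd_intensity=sd, max_intensity=mx,
            foci_count=foci, sahf_positive=foci >= params.sahf_min_foci,
        )
        if scale_um_per_px is not None:
            row["area_um2"] = row["area"] * scale_um_per_px ** 2
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_population(
    measurements: pd.DataFrame,
    min_cells: int = 200,
    min_nuclei_intensity: int = 30,
) -> pd.DataFrame:
    """Per-condition (and per-replicate, when a ``replicate`` column is
    present) SAHF-positive fraction, mean area and mean intensity SD, with
    low-n warning flags mirroring the usual scoring thresholds (>=200
    cells for SAHF fractions, >=30 nuclei for intensity metrics)."""
    if len(measurements) == 0:
        raise ValueError("no measurements supplied")
    df = measurements.copy()
    if "condition" not in df.columns:
        df["condition"] = "all"
    group_cols = ["condition"] + (["replicate"] if "replicate" in df.columns else [])

    def _summary(g: pd.DataFrame, label) -> dict:
        n = len(g)
        return dict(
            **label, n=n,
            sahf_fraction=float(g["sahf_positive"].mean()),
            mean_area=float(g["area"].mean()),
            mean_sd_intensity=float(g["sd_intensity"].mean()),
            low_n_sahf=n < min_cells,
            low_n_intensity=n < min_nuclei_intensity,
        )

    rows = []
    for keys, g in df.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(_summary(g, dict(zip(group_cols, keys))))
    if "replicate" in df.columns:  # pooled per condition as well
        for cond, g in df.groupby("condition"):
            rows.append(_summary(g, {"condition": cond, "replicate": "pooled"}))
    return pd.DataFrame(rows)
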