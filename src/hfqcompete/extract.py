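"""Spot detection, AOI filtering, channel mapping and intensity integration.

A reference image (the average of the first both-excited frames) yields
candidate Cy3 spots; areas of interest (AOIs) closer together than a minimum
separation are all discarded so that every retained AOI holds a single Hfq.
Cy3 AOI centres are mapped into the Cy5 half-field through a known affine
transform, and per-frame box-integrated intensities give the two-channel
traces analysed downstream.

Coordinates are 0-based subpixel ``(x, y) = (column, row)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .errors import ConfigurationError, DataError
from .simulate import AcquisitionParams, _apply_affine
from .traces import IntensityTrace

__all__ = ["AOI", "detect_spots", "filter_aois", "map_channels", "integrate_aoi", "extract_traces"]

logger = logging.getLogger(__name__)


@dataclass
class AOI:
    """One single-molecule area of interest and its two channel centres."""

    id: str
    center_cy3: tuple  # (x, y), full-frame coordinates
    center_cy5: tuple
    box_halfwidth: int = 2

    @property
    def box_side(self) -> int:
        return 2 * self.box_halfwidth + 1


def _background_stats(image: np.ndarray):
    med = float(np.median(image))
    sd = float(1.4826 * np.median(np.abs(image - med)))
    return med, sd


def detect_spots(
    reference_image: np.ndarray,
    detection_threshold: float = 5.0,
    box_halfwidth: int = 2,
    min_distance: int = 3,
) -> list[tuple]:
    """Subpixel spot centres above ``background + threshold x SD``.

    The reference image should be an average of the first both-excited
    frames.  Local maxima above the robust background level are refined to
    the background-subtracted intensity centroid over the AOI box.
    """
    img = np.asarray(reference_image, dtype=float)
    if img.ndim != 2:
        raise DataError("reference image must be 2D")
    if np.issubdtype(np.asarray(reference_image).dtype, np.integer):
        sat = np.iinfo(np.asarray(reference_image).dtype).max
        frac = np.mean(np.asarray(reference_image) >= sat)
        if frac >= 0.01:
            warnings.warn(f"reference image saturated on {100 * frac:.1f}% of pixels", stacklevel=2)
    med, sd = _background_stats(img)
    peaks = peak_local_max(
        img,
        min_distance=min_distance,
        threshold_abs=med + detection_threshold * sd,
        exclude_border=box_halfwidth,
    )
    centers = []
    h, w = img.shape
    for r, c in peaks:
        win = img[r - box_halfwidth : r + box_halfwidth + 1, c - box_halfwidth : c + box_halfwidth + 1] - med
        win = np.clip(win, 0.0, None)
        tot = win.sum()
        if tot <= 0:
            centers.append((float(c), float(r)))
            continue
        ys, xs = np.mgrid[-box_halfwidth : box_halfwidth + 1, -box_halfwidth : box_halfwidth + 1]
        centers.append((float(c + (win * xs).sum() / tot), float(r + (win * ys).sum() / tot)))
    return centers


def filter_aois(centers, min_separation: float = 5.0) -> list[tuple]:
    """Discard every member of any pair of centres within ``min_separation``.

    Both spots of a close pair are removed (a multi-Hfq AOI cannot be
    rescued by keeping one centre).  The result is independent of input
    order.
    """
    pts = np.asarray([tuple(c) for c in centers], dtype=float)
    if pts.size == 0:
        return []
    tree = cKDTree(pts)
    bad = set()
    for i, j in tree.query_pairs(r=min_separation):
        bad.update((i, j))
    return [tuple(map(float, pts[i])) for i in range(len(pts)) if i not in bad]


def map_channels(
    centers,
    transform: np.ndarray,
    frame_shape: tuple,
    box_halfwidth: int = 2,
) -> list[AOI]:
    """Map Cy3 centres through the channel transform into paired AOIs.

    ``transform`` is a 3x3 affine matrix on (x, y); AOIs whose Cy3 or mapped
    Cy5 box leaves the frame are dropped (the count is logged).
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (3, 3) or abs(np.linalg.det(transform)) < 1e-12:
        raise ConfigurationError("channel transform must be an invertible 3x3 affine matrix")
    h, w = frame_shape
    aois = []
    dropped = 0

    def inside(x, y):
        return (
            box_halfwidth <= round(x) < w - box_halfwidth and box_halfwidth <= round(y) < h - box_halfwidth
        )

    pts = np.asarray([tuple(c) for c in centers], dtype=float)
    mapped = _apply_affine(transform, pts) if pts.size else pts
    for i, (c3, c5) in enumerate(zip(pts, mapped)):
        if inside(*c3) and inside(*c5):
            aois.append(AOI(id=f"aoi{i:04d}", center_cy3=tuple(c3), center_cy5=tuple(c5), box_halfwidth=box_halfwidth))
        else:
            dropped += 1
    if dropped:
        logger.info("map_channels: dropped %d AOI(s) whose box leaves the field", dropped)
    return aois


def integrate_aoi(
    stack: np.ndarray,
    aoi: AOI,
    channel: str,
    excited: np.ndarray | None = None,
    frame_interval: float = 0.1,
) -> IntensityTrace:
    """Per-frame sum over the AOI box at the channel's centre.

    ``excited`` attaches the per-frame excitation mask from the acquisition
    metadata (all frames when omitted).
    """
    if channel not in ("cy3", "cy5"):
        raise ConfigurationError("channel must be 'cy3' or 'cy5'")
    x, y = aoi.center_cy3 if channel == "cy3" else aoi.center_cy5
    cx, cy = int(round(x)), int(round(y))
    hwidth = aoi.box_halfwidth
    n_frames, h, w = stack.shape
    if not (hwidth <= cx < w - hwidth and hwidth <= cy < h - hwidth):
        raise DataError(f"AOI {aoi.id}: {channel} box out of bounds at ({x:.1f}, {y:.1f})")
    box = stack[:, cy - hwidth : cy + hwidth + 1, cx - hwidth : cx + hwidth + 1]
    trace = box.sum(axis=(1, 2)).astype(float)
    if excited is None:
        excited = np.ones(n_frames, dtype=bool)
    return IntensityTrace(aoi.id, channel, trace, excited, frame_interval)


def extract_traces(stack: np.ndarray, aois, acq: AcquisitionParams):
    """Integrate every AOI in both channels; returns {aoi_id: {channel: trace}}."""
    masks = acq.excitation_masks()
    out = {}
    for aoi in aois:
        out[aoi.id] = {
            ch: integrate_aoi(stack, aoi, ch, excited=masks[ch], frame_interval=acq.frame_interval)
            for ch in ("cy3", "cy5")
        }
    return out
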