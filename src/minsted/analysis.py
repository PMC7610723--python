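"""Post-processing of localization traces and tables.

Covers the analysis pipeline applied to photon-by-photon centre traces and
localization tables, simulated or recorded: segment-based precision
estimates, grouping of repeated localizations of the same fluorophore by
distance clustering, quality filters (dimness and excessive spread),
repeated-localization statistics across the activation sequence, and
Gaussian-splat rendering of the final image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import erf

__all__ = [
    "SegmentSpec",
    "RenderConfig",
    "segment_precision",
    "cluster_localizations",
    "filter_localizations",
    "repeated_localization_stats",
    "render_image",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentSpec:
    """Segmenting of a floor-phase centre trace.

    M : segment length in detections.
    min_tail : minimum number of floor-phase detections required of the
        trace (traces shorter than this are rejected to avoid boundary
        artefacts near the floor-reaching detection).
    """

    M: int = 50
    min_tail: int = 25

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("segment length M must be >= 2")
        if self.min_tail < 0:
            raise ValueError("min_tail must be non-negative")


def _floor_positions(trace: pd.DataFrame) -> np.ndarray:
    """Centre positions of the floor phase (d at its minimum) of a trace."""
    d = trace["d"].to_numpy(dtype=float)
    floor = d.min() * (1.0 + 1e-12)
    at = d <= floor
    return trace.loc[at, ["Cx", "Cy"]].to_numpy(dtype=float)


def segment_precision(trace: pd.DataFrame, spec: SegmentSpec) -> float:
    """Segment-based precision sigma_M of one centre trace.

    The floor-phase centre sequence is split into consecutive
    non-overlapping segments of M detections (the trailing partial segment
    is discarded); sigma_M is the pooled per-axis standard deviation of the
    segment means.  This is how precision is measured from a single long
    trace after the FWHM floor is reached.
    """
    pos = _floor_positions(trace)
    n = len(pos)
    need = max(2 * spec.M, spec.min_tail)
    if n < need:
        raise ValueError(
            f"trace has {n} floor-phase detections; need at least {need} "
            f"(2*M={2 * spec.M}, min_tail={spec.min_tail})")
    n_seg = n // spec.M
    means = pos[: n_seg * spec.M].reshape(n_seg, spec.M, 2).mean(axis=1)
    return float(np.sqrt(means.var(axis=0, ddof=1).mean()))


def cluster_localizations(table: pd.DataFrame, link_radius: float = 25.0,
                          min_size: int = 6,
                          method: str = "single") -> pd.DataFrame:
    """Group localizations that belong to the same fluorophore.

    Agglomerative clustering (default single linkage, i.e. transitive
    chaining: any pair closer than ``link_radius`` links their clusters;
    ``method='complete'`` available) on the (Cx, Cy) positions.  Returns
    the table with added columns ``cluster`` (label) and ``retained``
    (cluster size >= min_size; the default 6 keeps sets with more than
    five localizations).
    """
    out = table.copy()
    if len(table) == 0:
        out["cluster"] = pd.Series(dtype=int)
        out["retained"] = pd.Series(dtype=bool)
        return out
    pos = table[["Cx", "Cy"]].to_numpy(dtype=float)
    if len(pos) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pos, method=method)
        labels = fcluster(Z, t=link_radius, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    out["cluster"] = labels
    out["retained"] = out["cluster"].map(sizes) >= min_size
    return out


def filter_localizations(table: pd.DataFrame, min_tail_detections: int = 250,
                         max_sigma: float | None = None):
    """Quality filter: drop dim localizations, then poorly converged ones.

    A localization is dim when fewer than ``min_tail_detections`` photons
    were collected after the FWHM floor (N - N_c < threshold); among the
    remaining rows, those with ``sigma_hat`` above ``max_sigma`` (default:
    three times the table median, the 'excessive sigma' rule) are dropped.
    A row failing both rules is attributed to the dimness rule, which is
    applied first.  Returns ``(filtered table, report dict)``.
    """
    for col in ("N", "Nc", "sigma_hat"):
        if col not in table.columns:
            raise KeyError(f"localization table lacks required column {col!r}")
    n0 = len(table)
    if max_sigma is None:
        med = float(table["sigma_hat"].median()) if n0 else 0.0
        max_sigma = 3.0 * med
    tail = table["N"] - table["Nc"]
    bright = table[tail >= min_tail_detections]
    kept = bright[bright["sigma_hat"] <= max_sigma]
    n_dim = n0 - len(bright)
    n_sigma = len(bright) - len(kept)
    report = {
        "n_input": n0,
        "n_dropped_dim": n_dim,
        "frac_dropped_dim": n_dim / n0 if n0 else 0.0,
        "n_dropped_sigma": n_sigma,
        "frac_dropped_sigma": n_sigma / n0 if n0 else 0.0,
        "n_kept": len(kept),
        "frac_kept": len(kept) / n0 if n0 else 0.0,
        "min_tail_detections": int(min_tail_detections),
        "max_sigma": float(max_sigma),
    }
    return kept.copy(), report


def repeated_localization_stats(table: pd.DataFrame, window: int = 2,
                                radii=(20.0, 2.0)) -> dict:
    """How often consecutive localizations revisit the same fluorophore.

    For every localization after the first, it counts as a 'recent' event
    when its scan index is within ``window`` scans of the previous
    localization in activation order; among recent events the fraction
    closer than each radius (nm) to that previous localization is reported.
    ``radii`` must be positive and sorted descending.
    """
    if "scan" not in table.columns:
        raise KeyError("localization table lacks required column 'scan'")
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii) or radii != sorted(radii, reverse=True):
        raise ValueError("radii must be positive and sorted descending")
    n = len(table)
    if n < 2:
        return {"n_pairs": 0, "frac_within_window": 0.0,
                "frac_within_radius": {r: 0.0 for r in radii}}
    scan = table["scan"].to_numpy()
    pos = table[["Cx", "Cy"]].to_numpy(dtype=float)
    gap = scan[1:] - scan[:-1]
    dist = np.hypot(*(pos[1:] - pos[:-1]).T)
    recent = gap <= window
    n_recent = int(recent.sum())
    frac_recent = n_recent / (n - 1)
    frac_r = {}
    for r in radii:
        frac_r[r] = float((dist[recent] < r).mean()) if n_recent else 0.0
    return {"n_pairs": n - 1, "frac_within_window": float(frac_recent),
            "frac_within_radius": frac_r}


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry: pixel size (nm), the precision floor (nm) applied
    to every localization's splat width, and the field bounding box
    (xmin, xmax, ymin, ymax) in nm."""

    pixel_size: float = 2.0
    sigma_floor: float = 3.0
    field: tuple = (0.0, 200.0, 0.0, 200.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be non-negative")
        xmin, xmax, ymin, ymax = self.field
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("field box must have positive extent")


def render_image(table: pd.DataFrame, cfg: RenderConfig) -> np.ndarray:
    """Render localizations as unit-integral Gaussian splats.

    Each localization contributes a 2D Gaussian of standard deviation
    ``max(sigma_hat, sigma_floor)`` integrated exactly over each pixel (via
    the error function), so the image sums to the number of rendered
    localizations up to boundary truncation, which is logged when
    noticeable.  Returns a float32 array of shape (ny, nx), row 0 at ymin.
    """
    xmin, xmax, ymin, ymax = cfg.field
    nx = int(round((xmax - xmin) / cfg.pixel_size))
    ny = int(round((ymax - ymin) / cfg.pixel_size))
    if nx < 1 or ny < 1:
        raise ValueError("field box smaller than one pixel")
    img = np.zeros((ny, nx), dtype=np.float64)
    if len(table) == 0:
        return img.astype(np.float32)
    xs = xmin + cfg.pixel_size * np.arange(nx + 1)
    ys = ymin + cfg.pixel_size * np.arange(ny + 1)
    sig = table["sigma_hat"].to_numpy(dtype=float) if "sigma_hat" in table.columns \
        else np.zeros(len(table))
    sig = np.maximum(sig, cfg.sigma_floor)
    cx = table["Cx"].to_numpy(dtype=float)
    cy = table["Cy"].to_numpy(dtype=float)
    for x0, y0, s in zip(cx, cy, sig):
        if s == 0:
            ix = int(np.floor((x0 - xmin) / cfg.pixel_size))
            iy = int(np.floor((y0 - ymin) / cfg.pixel_size))
            if 0 <= ix < nx and 0 <= iy < ny:
                img[iy, ix] += 1.0
            continue
        q = 1.0 / (s * math.sqrt(2.0))
        fx = 0.5 * (erf((xs - x0) * q))
        fy = 0.5 * (erf((ys - y0) * q))
        img += np.outer(np.diff(fy), np.diff(fx))
    total = float(img.sum())
    loss = abs(total - len(table))
    if loss > 1e-6 * max(len(table), 1):
        logger.info("rendered mass %.6f of %d localizations "
                    "(boundary truncation %.3g)", total, len(table), loss)
    return img.astype(np.float32)
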