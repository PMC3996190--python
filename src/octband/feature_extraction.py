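"""Per-layer diagnostic features (TH, TR, FD) from a synthetic B-scan.

Implements the macular region partition (foveola / fovea / parafovea /
perifovea, diameters 0.35 / 1.85 / 2.85 / 5.85 mm), mean layer thickness,
normalized total reflectance, and the Higuchi fractal dimension of the lateral
thickness profile — the "roughness" of a layer.

Coordinate conventions: lateral position in mm from the foveal center, signed
along the scan line; radial distance is its absolute value; depth in um from
the image top, increasing outward; a layer occupies [inner boundary, outer
boundary) in depth.  Region intervals are half-open at the inner edge and
closed at the outer edge.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .enums import (
    FEATURE_COLUMNS,
    LAYER_ORDER,
    REGION_OUTER_RADIUS_MM,
    LayerName,
    RegionName,
)
from .errors import OctbandError, ValidationError
from .synthetic_cohort import SyntheticScan

MIN_FD_SAMPLES = 64


class ConstantProfileWarning(UserWarning):
    """Raised (as a warning) when FD is requested for a flat profile."""


@dataclasses.dataclass
class LayerProfile:
    """Lateral thickness profile of one layer on one scan."""

    positions_mm: np.ndarray  # strictly increasing
    thickness_um: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if self.positions_mm.size < 2:
            raise ValidationError("LayerProfile: need >= 2 samples")
        if self.positions_mm.size != self.thickness_um.size:
            raise ValidationError("LayerProfile: positions/thickness length mismatch")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValidationError("LayerProfile: positions not strictly increasing")
        if np.any(self.thickness_um <= 0):
            raise ValidationError("LayerProfile: thickness must be > 0")


def assign_region(radial_distance_mm: float) -> RegionName | None:
    """Macular region of a point at the given radial distance from the center.

    Foveola for r <= 0.175 mm, then annuli with outer radii 0.925, 1.425 and
    2.925 mm; ``None`` beyond the perifovea.
    """
    r = float(radial_distance_mm)
    if r < 0:
        raise ValidationError(f"radial_distance_mm: {r} < 0")
    for region in RegionName:
        if r <= REGION_OUTER_RADIUS_MM[region]:
            return region
    return None


def _region_mask(scan: SyntheticScan, region: RegionName) -> np.ndarray:
    radii = np.abs(scan.x_mm)
    lo = 0.0
    names = list(RegionName)
    idx = names.index(region)
    if idx > 0:
        lo = REGION_OUTER_RADIUS_MM[names[idx - 1]]
    hi = REGION_OUTER_RADIUS_MM[region]
    return (radii > lo) & (radii <= hi) if idx > 0 else radii <= hi


def _layer_index(layer: LayerName) -> int:
    return list(LAYER_ORDER).index(layer)


def layer_thickness(
    scan: SyntheticScan, layer: LayerName, region: RegionName
) -> float:
    """Mean thickness (um) of ``layer`` over the lateral extent of ``region``."""
    mask = _region_mask(scan, region)
    if not mask.any():
        raise OctbandError(f"region {region} has no lateral samples on this scan")
    j = _layer_index(layer)
    widths = scan.boundaries[j + 1, mask] - scan.boundaries[j, mask]
    return float(widths.mean())


def total_reflectance(
    scan: SyntheticScan, layer: LayerName, region: RegionName
) -> float:
    """Within-layer intensity sum over ``region``, normalized by the
    whole-retina (ILM to OS/RPE outer bound) sum in the same region.

    Dimensionless, in [0, 1]; the seven layer values in a region sum to 1 up
    to pixel-row quantization at the boundaries.
    """
    if scan.image.min() < 0 or scan.image.max() > 1:
        raise ValidationError("image intensities must lie in [0, 1]")
    mask = _region_mask(scan, region)
    if not mask.any():
        raise OctbandError(f"region {region} has no lateral samples on this scan")
    depth = (np.arange(scan.image.shape[0]) + 0.5) * scan.axial_pitch_um
    cols = np.flatnonzero(mask)
    j = _layer_index(layer)
    layer_sum = 0.0
    retina_sum = 0.0
    for c in cols:
        in_layer = (depth >= scan.boundaries[j, c]) & (depth < scan.boundaries[j + 1, c])
        in_retina = (depth >= scan.boundaries[0, c]) & (depth < scan.boundaries[-1, c])
        layer_sum += scan.image[in_layer, c].sum()
        retina_sum += scan.image[in_retina, c].sum()
    if retina_sum <= 0:
        raise OctbandError("whole-retina intensity sum is zero in this region")
    return float(layer_sum / retina_sum)


def fractal_dimension(profile: LayerProfile, k_max: int = 8) -> float:
    """Higuchi fractal dimension of the thickness-vs-position series.

    The Higuchi construction measures the mean curve length L(k) of the series
    subsampled at lags 1..k_max; for a profile with fractal (roughness)
    dimension D, L(k) ~ k^(-D), and D is read off a log-log least-squares fit.
    The estimate is clipped to the geometrically admissible range [1, 2] for a
    planar curve.  A constant profile returns 1.0 with a warning.

    Requires >= 64 uniformly spaced samples for a stable slope.
    """
    series = np.asarray(profile.thickness_um, dtype=float)
    if series.size < MIN_FD_SAMPLES:
        raise ValidationError(
            f"fractal_dimension: need >= {MIN_FD_SAMPLES} samples, got {series.size}"
        )
    return higuchi_fd(series, k_max=k_max)


def higuchi_fd(series: np.ndarray, k_max: int = 8) -> float:
    """Higuchi estimator on a raw 1-D series (see :func:`fractal_dimension`)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if k_max < 2:
        raise ValidationError(f"k_max: {k_max} < 2")
    if np.ptp(x) == 0.0:
        warnings.warn(
            "constant profile: fractal dimension fixed at 1.0", ConstantProfileWarning
        )
        return 1.0
    ks = np.arange(1, k_max + 1)
    lengths = np.empty(ks.size)
    for i, k in enumerate(ks):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lk.append(dist * norm / k)
        lengths[i] = np.mean(lk)
    valid = lengths > 0
    slope = np.polyfit(np.log(ks[valid]), np.log(lengths[valid]), 1)[0]
    return float(np.clip(-slope, 1.0, 2.0))


def extract_features(
    scan: SyntheticScan,
    *,
    k_max: int = 8,
    group: str | None = None,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """All (layer, region) feature rows of one scan: 7 layers x 4 regions.

    FD is computed on the region-restricted thickness profile when it has at
    least 64 lateral samples; narrower regions (typically the foveola) fall
    back to the full-scan profile, recorded in the ``fd_full_profile`` column.
    """
    x = scan.x_mm
    records = []
    group = group if group is not None else (scan.group or "")
    subject = subject_id if subject_id is not None else (scan.subject_id or "")
    for layer in LAYER_ORDER:
        j = _layer_index(layer)
        widths_full = scan.boundaries[j + 1] - scan.boundaries[j]
        for region in RegionName:
            mask = _region_mask(scan, region)
            if not mask.any():
                raise OctbandError(f"region {region} has no lateral samples")
            th = float(widths_full[mask].mean())
            tr = total_reflectance(scan, layer, region)
            fd_full = False
            if mask.sum() >= MIN_FD_SAMPLES:
                series = widths_full[mask]
            else:
                series = widths_full
                fd_full = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConstantProfileWarning)
                fd = higuchi_fd(series, k_max=k_max)
            records.append(
                (
                    scan.eye_id, subject, group, scan.scan_index,
                    layer.value, region.value, th, tr, fd, fd_full,
                )
            )
    return pd.DataFrame.from_records(
        records, columns=list(FEATURE_COLUMNS) + ["fd_full_profile"]
    )
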