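"""Synthetic cohorts of eyes with per-scan, per-layer OCT features.

The generator emulates a Stratus-OCT macular study population: three groups
(healthy controls, type 1 diabetics without retinopathy, and eyes with mild
diabetic retinopathy), six 6-mm radial scans per eye, and seven intraretinal
layers, each characterized by thickness (TH, um), normalized total reflectance
(TR) and profile fractal dimension (FD).

A two-level latent model is used: each eye draws one latent (TH, TR, FD)
vector per layer from a group- and layer-specific trivariate normal (TH-FD and
TR-FD correlated via ``rho``), and each of the six radial scans observes the
latent vector plus independent Gaussian measurement noise.  Eye-level
parameters are therefore the biological signal; scan noise models acquisition
variability.

The default parameters encode the cohort structure the classifier assumes:

* group sizes 74 / 38 / 43 eyes and per-group layer thicknesses that sum to
  total macular thicknesses of 324.36, 316.72 and 297.40 um respectively;
* mild-retinopathy alterations concentrated in the GCL+IPL complex and OPL
  (thinning plus increased profile roughness relative to healthy eyes);
* diabetic-without-retinopathy alterations concentrated in the RNFL, OS and
  RPE, so that those layers separate DM from MDR eyes while remaining
  uninformative for healthy-vs-MDR discrimination.

The per-layer distributions are synthetic stand-ins (no public per-layer
reference data exist); see docs/methods.md for how they were chosen.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enums import (
    FEATURE_COLUMNS,
    INNER_LAYERS,
    LAYER_ORDER,
    GroupLabel,
    LayerName,
    RegionName,
)
from .errors import ValidationError

FEATURES = ("TH", "TR", "FD")

# --------------------------------------------------------------------------
# Default per-group, per-layer distribution parameters
# --------------------------------------------------------------------------

# Layer thickness means (um).  Per group they sum to the total macular
# thickness of that group: 324.36 (healthy), 316.72 (DM), 297.40 (MDR).
_TH_MEANS = {
    GroupLabel.HEALTHY: {
        LayerName.RNFL: 40.00, LayerName.GCL_IPL: 80.00, LayerName.INL: 35.00,
        LayerName.OPL: 35.00, LayerName.ONL_IS: 95.00, LayerName.OS: 20.00,
        LayerName.RPE: 19.36,
    },
    GroupLabel.DM: {
        LayerName.RNFL: 45.00, LayerName.GCL_IPL: 73.00, LayerName.INL: 34.50,
        LayerName.OPL: 29.50, LayerName.ONL_IS: 94.00, LayerName.OS: 24.00,
        LayerName.RPE: 16.72,
    },
    GroupLabel.MDR: {
        LayerName.RNFL: 39.00, LayerName.GCL_IPL: 68.00, LayerName.INL: 33.00,
        LayerName.OPL: 25.50, LayerName.ONL_IS: 93.00, LayerName.OS: 19.50,
        LayerName.RPE: 19.40,
    },
}

# Total macular thickness spread per group (um); per-layer sds are allocated
# proportionally to the layer mean so that, for independent layers, the seven
# layer thicknesses sum with approximately the reported total sd.
_TH_TOTAL_SD = {GroupLabel.HEALTHY: 10.27, GroupLabel.DM: 21.56, GroupLabel.MDR: 21.79}

# Normalized total reflectance means (fraction of whole-retina reflectance).
_TR_MEANS = {
    GroupLabel.HEALTHY: {
        LayerName.RNFL: 0.170, LayerName.GCL_IPL: 0.130, LayerName.INL: 0.080,
        LayerName.OPL: 0.090, LayerName.ONL_IS: 0.150, LayerName.OS: 0.110,
        LayerName.RPE: 0.270,
    },
    GroupLabel.DM: {
        LayerName.RNFL: 0.180, LayerName.GCL_IPL: 0.122, LayerName.INL: 0.079,
        LayerName.OPL: 0.083, LayerName.ONL_IS: 0.148, LayerName.OS: 0.118,
        LayerName.RPE: 0.262,
    },
    GroupLabel.MDR: {
        LayerName.RNFL: 0.168, LayerName.GCL_IPL: 0.112, LayerName.INL: 0.077,
        LayerName.OPL: 0.077, LayerName.ONL_IS: 0.146, LayerName.OS: 0.109,
        LayerName.RPE: 0.269,
    },
}
_TR_SD = {GroupLabel.HEALTHY: 0.012, GroupLabel.DM: 0.015, GroupLabel.MDR: 0.015}

# Fractal dimension of the lateral thickness profile (dimensionless, [1, 2]).
_FD_MEANS = {
    GroupLabel.HEALTHY: {
        LayerName.RNFL: 1.260, LayerName.GCL_IPL: 1.180, LayerName.INL: 1.140,
        LayerName.OPL: 1.160, LayerName.ONL_IS: 1.100, LayerName.OS: 1.080,
        LayerName.RPE: 1.120,
    },
    GroupLabel.DM: {
        LayerName.RNFL: 1.175, LayerName.GCL_IPL: 1.265, LayerName.INL: 1.145,
        LayerName.OPL: 1.250, LayerName.ONL_IS: 1.103, LayerName.OS: 1.175,
        LayerName.RPE: 1.214,
    },
    GroupLabel.MDR: {
        LayerName.RNFL: 1.265, LayerName.GCL_IPL: 1.280, LayerName.INL: 1.150,
        LayerName.OPL: 1.260, LayerName.ONL_IS: 1.108, LayerName.OS: 1.085,
        LayerName.RPE: 1.124,
    },
}
_FD_SD = {GroupLabel.HEALTHY: 0.030, GroupLabel.DM: 0.035, GroupLabel.MDR: 0.040}

DEFAULT_GROUP_SIZES = {GroupLabel.HEALTHY: 74, GroupLabel.DM: 38, GroupLabel.MDR: 43}
DEFAULT_SCAN_NOISE_SD = {"TH": 2.0, "TR": 0.008, "FD": 0.015}
DEFAULT_RHO = 0.5


def default_feature_params() -> dict:
    """Default ``{group: {layer: {feature: (mean, sd)}}}`` parameter table."""
    params: dict = {}
    for group in GroupLabel:
        th_means = _TH_MEANS[group]
        scale = _TH_TOTAL_SD[group] / np.sqrt(
            sum(m * m for m in th_means.values())
        )
        params[group] = {}
        for layer in LAYER_ORDER:
            params[group][layer] = {
                "TH": (th_means[layer], scale * th_means[layer]),
                "TR": (_TR_MEANS[group][layer], _TR_SD[group]),
                "FD": (_FD_MEANS[group][layer], _FD_SD[group]),
            }
    return params


@dataclasses.dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    Parameters
    ----------
    n_eyes_per_group
        Number of eyes per diagnostic group.
    scans_per_eye
        Radial scans acquired per eye (the macular protocol uses 6).
    feature_params
        ``{group: {layer: {"TH"|"TR"|"FD": (mean, sd)}}}`` eye-level latent
        distribution parameters.  TH in um, TR as a fraction, FD in [1, 2].
    scan_noise_sd
        Scan-level measurement noise sd per feature (same units).
    rho
        Correlation between TH and FD (and TR and FD) at the eye level.
    regions
        Macular regions to emit rows for (features are defined at the
        analysis region; default parafovea only).
    rng_seed
        Seed of the single named generator driving all draws.
    """

    n_eyes_per_group: Mapping[GroupLabel, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    scans_per_eye: int = 6
    feature_params: Mapping = dataclasses.field(default_factory=default_feature_params)
    scan_noise_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SCAN_NOISE_SD)
    )
    rho: float = DEFAULT_RHO
    regions: Sequence[RegionName] = (RegionName.PARAFOVEA,)
    rng_seed: int = 0

    def validate(self) -> None:
        for group, n in self.n_eyes_per_group.items():
            if not isinstance(group, GroupLabel):
                raise ValidationError(f"n_eyes_per_group: unknown group {group!r}")
            if n < 0:
                raise ValidationError(f"n_eyes_per_group[{group}]: count {n} < 0")
        if self.scans_per_eye < 1:
            raise ValidationError(f"scans_per_eye: {self.scans_per_eye} < 1")
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho: {self.rho} outside [-1, 1]")
        if 2.0 * self.rho * self.rho > 1.0 + 1e-12:
            raise ValidationError(
                f"rho: |{self.rho}| > 1/sqrt(2); TH-FD/TR-FD correlation matrix "
                "would not be positive semi-definite"
            )
        for feat, sd in self.scan_noise_sd.items():
            if feat not in FEATURES:
                raise ValidationError(f"scan_noise_sd: unknown feature {feat!r}")
            if sd < 0:
                raise ValidationError(f"scan_noise_sd[{feat}]: {sd} < 0")
        for group in self.n_eyes_per_group:
            layers = self.feature_params.get(group)
            if layers is None:
                raise ValidationError(f"feature_params: missing group {group}")
            for layer in LAYER_ORDER:
                if layer not in layers:
                    raise ValidationError(
                        f"feature_params[{group}]: missing layer {layer}"
                    )
                entry = layers[layer]
                for feat in FEATURES:
                    mean, sd = entry[feat]
                    if sd < 0:
                        raise ValidationError(
                            f"feature_params[{group}][{layer}][{feat}]: sd {sd} < 0"
                        )
                th_mean = entry["TH"][0]
                if th_mean <= 0:
                    raise ValidationError(
                        f"feature_params[{group}][{layer}][TH]: mean {th_mean} <= 0"
                    )
                fd_mean = entry["FD"][0]
                if not 1.0 <= fd_mean <= 2.0:
                    raise ValidationError(
                        f"feature_params[{group}][{layer}][FD]: mean {fd_mean} "
                        "outside [1, 2]"
                    )


def _latent_covariance(sds: np.ndarray, rho: float) -> np.ndarray:
    """Covariance of (TH, TR, FD) with FD correlated rho to both TH and TR."""
    corr = np.array([[1.0, 0.0, rho], [0.0, 1.0, rho], [rho, rho, 1.0]])
    return corr * np.outer(sds, sds)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a feature table with one row per (eye, scan, layer, region).

    Returns a DataFrame with the canonical schema
    ``eye_id, subject_id, group, scan_index, layer, region, TH_um, TR, FD``.
    Deterministic for a fixed ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    records: list[tuple] = []
    for group in GroupLabel:  # fixed iteration order for determinism
        n_eyes = int(spec.n_eyes_per_group.get(group, 0))
        if n_eyes == 0:
            continue
        layer_params = spec.feature_params[group]
        # eye-level latents: (n_eyes, n_layers, 3)
        latents = np.empty((n_eyes, len(LAYER_ORDER), 3))
        for j, layer in enumerate(LAYER_ORDER):
            entry = layer_params[layer]
            means = np.array([entry[f][0] for f in FEATURES])
            sds = np.array([entry[f][1] for f in FEATURES])
            cov = _latent_covariance(sds, spec.rho)
            latents[:, j, :] = rng.multivariate_normal(
                means, cov, size=n_eyes, method="cholesky"
            )
        noise_sd = np.array([spec.scan_noise_sd.get(f, 0.0) for f in FEATURES])
        for i in range(n_eyes):
            eye_id = f"{group.value}_{i:03d}"
            subject_id = f"S_{group.value}_{i // 2:03d}"  # up to two eyes/subject
            for s in range(spec.scans_per_eye):
                obs = latents[i] + noise_sd * rng.standard_normal(
                    (len(LAYER_ORDER), 3)
                )
                obs[:, 0] = np.clip(obs[:, 0], 0.5, None)  # TH > 0
                obs[:, 1] = np.clip(obs[:, 1], 0.0, None)  # TR >= 0
                obs[:, 2] = np.clip(obs[:, 2], 1.0, 2.0)  # FD in [1, 2]
                for j, layer in enumerate(LAYER_ORDER):
                    for region in spec.regions:
                        records.append(
                            (
                                eye_id, subject_id, group.value, s,
                                layer.value, region.value,
                                obs[j, 0], obs[j, 1], obs[j, 2],
                            )
                        )
    table = pd.DataFrame.from_records(records, columns=FEATURE_COLUMNS)
    table["scan_index"] = table["scan_index"].astype(np.int64)
    return table


# --------------------------------------------------------------------------
# Image-level generator
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticScan:
    """A rendered radial B-scan with ground-truth layer boundaries.

    ``image`` holds reflectance in [0, 1], ``boundaries`` the 8 layer
    interfaces (ILM first, OS/RPE outer bound last) as depth in um from the
    image top, one value per lateral pixel, strictly ordered in depth.
    """

    image: np.ndarray
    boundaries: np.ndarray  # (8, width) um
    lateral_pitch_um: float
    axial_pitch_um: float
    eye_id: str
    scan_index: int
    group: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.boundaries.shape[0] != len(LAYER_ORDER) + 1:
            raise ValidationError(
                f"boundaries: expected {len(LAYER_ORDER) + 1} curves, "
                f"got {self.boundaries.shape[0]}"
            )
        if self.boundaries.shape[1] != self.image.shape[1]:
            raise ValidationError("boundaries: curve length != image width")
        if np.any(np.diff(self.boundaries, axis=0) <= 0):
            raise ValidationError("boundaries: not strictly ordered in depth")

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def x_mm(self) -> np.ndarray:
        """Signed lateral position of each column, mm from the foveal center."""
        w = self.width
        return (np.arange(w) - (w - 1) / 2.0) * self.lateral_pitch_um / 1000.0


def _smooth_noise(rng: np.random.Generator, n: int, corr_px: int) -> np.ndarray:
    """Unit-variance correlated noise (moving-average smoothed white noise)."""
    raw = rng.standard_normal(n + corr_px)
    kernel = np.ones(corr_px) / np.sqrt(corr_px)
    out = np.convolve(raw, kernel, mode="valid")[:n]
    return out


def generate_bscan(
    eye_latent_features: Mapping[LayerName, Sequence[float]],
    scan_index: int,
    rng_seed: int,
    *,
    eye_id: str = "EYE_000",
    group: str | None = None,
    subject_id: str | None = None,
    width_px: int = 512,
    lateral_extent_mm: float = 6.0,
    axial_pitch_um: float = 12.0,
    pit_depth: float = 0.85,
    pit_sigma_mm: float = 0.35,
    roughness_um: float = 3.0,
    noise_sd: float = 0.01,
    region: RegionName = RegionName.PARAFOVEA,
) -> SyntheticScan:
    """Render a synthetic B-scan from per-layer latent (TH, TR, FD) features.

    Seven stacked bands are drawn over a 6-mm scan line.  The inner layers
    (RNFL..OPL) are depressed near the center by an inverted-Gaussian foveal
    pit of fractional depth ``pit_depth`` and lateral scale ``pit_sigma_mm``;
    each band's thickness profile is rescaled so that its mean over ``region``
    equals the latent TH.  Band reflectance is laid down so that the summed
    intensity of a band is proportional to its latent TR, and boundary
    roughness increases with latent FD (scaled by ``roughness_um``; the
    rendered roughness is qualitative, not calibrated to the Higuchi value).
    Additive speckle-like Gaussian noise of sd ``noise_sd`` is applied last.

    Deterministic for fixed inputs; the same seed yields a bit-identical scan.
    """
    th = np.array([float(eye_latent_features[l][0]) for l in LAYER_ORDER])
    tr = np.array([float(eye_latent_features[l][1]) for l in LAYER_ORDER])
    fd = np.array([float(eye_latent_features[l][2]) for l in LAYER_ORDER])
    if np.any(th <= 0):
        bad = LAYER_ORDER[int(np.argmax(th <= 0))]
        raise ValidationError(f"latent TH for layer {bad} must be > 0")
    if np.any(tr < 0):
        raise ValidationError("latent TR must be >= 0")

    rng = np.random.default_rng(rng_seed)
    lateral_pitch_um = lateral_extent_mm * 1000.0 / width_px
    x_mm = (np.arange(width_px) - (width_px - 1) / 2.0) * lateral_pitch_um / 1000.0

    in_region = np.zeros(width_px, dtype=bool)
    from .feature_extraction import assign_region  # local import, no cycle at load

    for i, x in enumerate(np.abs(x_mm)):
        in_region[i] = assign_region(x) is region
    if not in_region.any():
        raise ValidationError(f"region {region} has no lateral samples on this scan")

    pit = 1.0 - pit_depth * np.exp(-(x_mm**2) / (2.0 * pit_sigma_mm**2))
    thickness = np.empty((len(LAYER_ORDER), width_px))
    for j, layer in enumerate(LAYER_ORDER):
        shape = pit if layer in INNER_LAYERS else np.ones(width_px)
        profile = th[j] * shape / shape[in_region].mean()
        if roughness_um > 0:
            amp = roughness_um * max(fd[j] - 1.0, 0.0)
            bump = amp * _smooth_noise(rng, width_px, corr_px=5)
            profile = profile + bump - bump[in_region].mean()
        thickness[j] = np.clip(profile, 1.0, None)

    top_margin_um = 3.0 * axial_pitch_um
    boundaries = np.vstack(
        [np.full(width_px, top_margin_um), top_margin_um + np.cumsum(thickness, 0)]
    )

    height = int(np.ceil(boundaries[-1].max() / axial_pitch_um)) + 3
    depth_centers = (np.arange(height) + 0.5) * axial_pitch_um  # (H,)

    # per-um reflectance density: band intensity sum proportional to TR
    density = tr[:, None] / thickness  # (7, W)
    gain = 0.85 / (density.max() * axial_pitch_um) if density.max() > 0 else 1.0

    image = np.full((height, width_px), 0.02)
    for j in range(len(LAYER_ORDER)):
        mask = (depth_centers[:, None] >= boundaries[j][None, :]) & (
            depth_centers[:, None] < boundaries[j + 1][None, :]
        )
        image += mask * (gain * axial_pitch_um) * density[j][None, :]
    if noise_sd > 0:
        image = image + noise_sd * rng.standard_normal(image.shape)
    image = np.clip(image, 0.0, 1.0)

    return SyntheticScan(
        image=image,
        boundaries=boundaries,
        lateral_pitch_um=lateral_pitch_um,
        axial_pitch_um=axial_pitch_um,
        eye_id=eye_id,
        scan_index=scan_index,
        group=group,
        subject_id=subject_id,
    )
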