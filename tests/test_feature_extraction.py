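"""Region partition, thickness/reflectance measures, Higuchi FD."""

import numpy as np
import pytest

from octband.enums import LayerName, RegionName
from octband.errors import OctbandError, ValidationError
from octband.feature_extraction import (
    ConstantProfileWarning,
    LayerProfile,
    assign_region,
    extract_features,
    fractal_dimension,
    higuchi_fd,
    layer_thickness,
    total_reflectance,
)
from octband.synthetic_cohort import SyntheticScan, generate_bscan

from oracles import box_counting_fd, fbm_profile

LAYERS = list(LayerName)


# ------------------------------- regions ----------------------------------


@pytest.mark.parametrize(
    "r, expected",
    [
        (0.0, RegionName.FOVEOLA),
        (0.175, RegionName.FOVEOLA),
        (0.176, RegionName.FOVEA),
        (0.925, RegionName.FOVEA),
        (1.0, RegionName.PARAFOVEA),
        (1.425, RegionName.PARAFOVEA),
        (2.0, RegionName.PERIFOVEA),
        (2.925, RegionName.PERIFOVEA),
        (3.0, None),
    ],
)
def test_assign_region_boundaries(r, expected):
    assert assign_region(r) is expected


def test_assign_region_rejects_negative_distance():
    with pytest.raises(ValidationError):
        assign_region(-0.1)


def test_region_partition_is_disjoint_and_exhaustive():
    for r in np.linspace(0.0, 2.925, 1171):
        hits = [
            reg
            for reg in RegionName
            if assign_region(float(r)) is reg
        ]
        assert len(hits) == 1


# ------------------------------- thickness --------------------------------


def _scan_from_thickness(thickness_rows, width=512, axial_pitch=12.0):
    """Build a scan with given per-layer thickness profiles (7 x width)."""
    thickness = np.asarray(thickness_rows, dtype=float)
    top = np.full(width, 36.0)
    boundaries = np.vstack([top, top + np.cumsum(thickness, axis=0)])
    height = int(np.ceil(boundaries[-1].max() / axial_pitch)) + 2
    image = np.zeros((height, width))
    return SyntheticScan(
        image=image,
        boundaries=boundaries,
        lateral_pitch_um=6000.0 / width,
        axial_pitch_um=axial_pitch,
        eye_id="E",
        scan_index=0,
    )


def test_constant_band_thickness():
    scan = _scan_from_thickness([[50.0] * 512] + [[30.0] * 512] * 6)
    assert layer_thickness(scan, LayerName.RNFL, RegionName.PARAFOVEA) == 50.0


def test_linear_wedge_averages_to_midpoint():
    ramp = np.linspace(40.0, 60.0, 512)
    scan = _scan_from_thickness([ramp] + [[30.0] * 512] * 6)
    # full-scan symmetric wedge: parafovea samples both sides symmetrically
    assert layer_thickness(
        scan, LayerName.RNFL, RegionName.PARAFOVEA
    ) == pytest.approx(50.0, abs=0.1)


def test_pit_profile_matches_quadrature_oracle():
    x = (np.arange(512) - 255.5) * (6000.0 / 512) / 1000.0
    pit = 60.0 * (1.0 - 0.8 * np.exp(-(x**2) / (2 * 0.35**2)))
    scan = _scan_from_thickness([pit] + [[30.0] * 512] * 6)
    sides = []
    for m in [(x > 0.925) & (x <= 1.425), (x < -0.925) & (x >= -1.425)]:
        sides.append(np.trapezoid(pit[m], x[m]) / (x[m][-1] - x[m][0]))
    oracle = np.mean(sides)
    got = layer_thickness(scan, LayerName.RNFL, RegionName.PARAFOVEA)
    assert got == pytest.approx(oracle, abs=0.1)


def test_thickness_additivity_over_layers(flat_scan):
    total = flat_scan.boundaries[-1] - flat_scan.boundaries[0]
    sum_layers = sum(
        layer_thickness(flat_scan, l, RegionName.PARAFOVEA) for l in LAYERS
    )
    mask = np.abs(flat_scan.x_mm) <= 1.425
    mask &= np.abs(flat_scan.x_mm) > 0.925
    assert sum_layers == pytest.approx(
        float(total[mask].mean()), abs=7 * flat_scan.axial_pitch_um
    )


# ------------------------------- reflectance ------------------------------


def _two_layer_scan(i1, i2, th=48.0, width=256, axial_pitch=4.0):
    """Seven bands; the first two carry intensities i1/i2, the rest are thin."""
    thickness = [[th] * width, [th] * width] + [[4.0] * width] * 5
    scan = _scan_from_thickness(thickness, width=width, axial_pitch=axial_pitch)
    depth = (np.arange(scan.image.shape[0]) + 0.5) * axial_pitch
    for j, val in [(0, i1), (1, i2)]:
        mask = (depth[:, None] >= scan.boundaries[j][None, :]) & (
            depth[:, None] < scan.boundaries[j + 1][None, :]
        )
        scan.image[mask] = val
    return scan


def test_zero_intensity_layer_has_zero_tr():
    scan = _two_layer_scan(0.0, 0.6)
    assert total_reflectance(scan, LayerName.RNFL, RegionName.PARAFOVEA) == 0.0


def test_two_layer_closed_form_ratio():
    scan = _two_layer_scan(0.2, 0.6)
    tr1 = total_reflectance(scan, LayerName.RNFL, RegionName.PARAFOVEA)
    tr2 = total_reflectance(scan, LayerName.GCL_IPL, RegionName.PARAFOVEA)
    # equal areas, intensities 0.2 / 0.6 -> shares 0.25 / 0.75
    assert tr1 == pytest.approx(0.25, abs=0.02)
    assert tr2 == pytest.approx(0.75, abs=0.02)


def test_uniform_image_tr_equals_pixel_fraction(flat_scan):
    scan = SyntheticScan(
        image=np.full_like(flat_scan.image, 0.5),
        boundaries=flat_scan.boundaries,
        lateral_pitch_um=flat_scan.lateral_pitch_um,
        axial_pitch_um=flat_scan.axial_pitch_um,
        eye_id="E",
        scan_index=0,
    )
    th = {l: layer_thickness(scan, l, RegionName.PARAFOVEA) for l in LAYERS}
    total = sum(th.values())
    rows = total / scan.axial_pitch_um
    for layer in LAYERS:
        tr = total_reflectance(scan, layer, RegionName.PARAFOVEA)
        assert tr == pytest.approx(th[layer] / total, abs=2.0 / rows)


def test_tr_normalization_sums_to_one(latent_features):
    scan = generate_bscan(latent_features, 0, rng_seed=5, axial_pitch_um=4.0)
    for region in (RegionName.PARAFOVEA, RegionName.PERIFOVEA):
        s = sum(total_reflectance(scan, l, region) for l in LAYERS)
        rows = (scan.boundaries[-1] - scan.boundaries[0]).mean() / scan.axial_pitch_um
        assert s == pytest.approx(1.0, abs=2.0 / rows)


# ------------------------------- fractal dimension ------------------------


def test_straight_line_profile_has_dimension_one():
    prof = LayerProfile(np.linspace(-3, 3, 512), np.linspace(40, 60, 512))
    assert fractal_dimension(prof) == pytest.approx(1.0, abs=0.02)


def test_constant_profile_returns_one_with_warning():
    with pytest.warns(ConstantProfileWarning):
        fd = higuchi_fd(np.full(128, 50.0))
    assert fd == 1.0


def test_too_few_samples_rejected():
    with pytest.raises(ValidationError, match="64"):
        fractal_dimension(LayerProfile(np.linspace(0, 1, 32), np.full(32, 5.0)))


def test_white_noise_dimension_near_two_and_matches_box_counting(rng):
    series = rng.standard_normal(4096)
    fd = higuchi_fd(series)
    assert fd == pytest.approx(2.0, abs=0.05)
    # independent box-counting oracle agrees white noise is rough (FD >> 1)
    assert box_counting_fd(series[:1024]) > 1.55


def test_brownian_profile_matches_fd_equals_two_minus_hurst():
    # H = 0.5: ordinary Brownian motion, FD = 1.5
    fd = higuchi_fd(fbm_profile(0.5, 4096, seed=8))
    assert fd == pytest.approx(1.5, abs=0.1)
    # H = 0.8: smoother persistent path, FD = 1.2
    fd = higuchi_fd(fbm_profile(0.8, 4096, seed=8))
    assert fd == pytest.approx(1.2, abs=0.1)


def test_fd_nondecreasing_with_noise_amplitude(rng):
    base = 50.0 + 5.0 * np.sin(np.linspace(0, 2 * np.pi, 1024))
    noise = rng.standard_normal(1024)
    fds = [higuchi_fd(base + a * noise) for a in [0.0, 0.2, 0.5, 1.0, 2.0]]
    assert all(b >= a - 1e-9 for a, b in zip(fds, fds[1:]))


# ------------------------------- extract_features -------------------------


def test_extract_features_cardinality_and_determinism(latent_features):
    scan = generate_bscan(latent_features, 0, rng_seed=31)
    rows = extract_features(scan)
    assert len(rows) == 7 * 4
    assert set(rows["region"]) == {r.value for r in RegionName}
    again = extract_features(scan)
    assert rows.equals(again)


def test_extract_features_roundtrip_recovers_latent_th(latent_features):
    scan = generate_bscan(
        latent_features, 0, rng_seed=2, pit_depth=0.0, roughness_um=0.0, noise_sd=0.0
    )
    rows = extract_features(scan).query("region == 'PARAFOVEA'").set_index("layer")
    for layer in LAYERS:
        assert rows.loc[layer.value, "TH_um"] == pytest.approx(
            latent_features[layer][0], abs=scan.axial_pitch_um
        )


def test_narrow_region_falls_back_to_full_profile(latent_features):
    scan = generate_bscan(latent_features, 0, rng_seed=2)
    rows = extract_features(scan)
    # foveola spans ~0.35 mm: fewer than 64 of 512 columns
    assert rows.query("region == 'FOVEOLA'")["fd_full_profile"].all()
    assert not rows.query("region == 'PERIFOVEA'")["fd_full_profile"].any()


def test_tr_requires_nonzero_retina_signal():
    scan = _scan_from_thickness([[30.0] * 512] * 7)
    with pytest.raises(OctbandError, match="zero"):
        total_reflectance(scan, LayerName.INL, RegionName.FOVEA)
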