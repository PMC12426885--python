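"""Forward simulator: contact images, TIE propagation, blur, full scans."""

import numpy as np
import pytest

from dtvtomo.geometry import SystemGeometry
from dtvtomo.phantom import build_phantom, optics_maps
from dtvtomo.projector import ParallelProjector, Sinogram, fbp_reconstruct
from dtvtomo.simulate import (ScanProtocol, apply_system_blur, contact_image,
                              simulate_scan, tie_intensity)


@pytest.fixture(scope="module")
def geom():
    return SystemGeometry(R1=320, R2=140, sigma_s=70, sigma_d=30,
                          pixel_pitch=15, lambda_eff=6.53e-11, delta_beta=1000)


def test_contact_image_empty_object(geom):
    z = np.zeros((32, 32))
    att, phi = contact_image(z, z, 0.0, geom, 10.5)
    np.testing.assert_allclose(att, 1.0)
    np.testing.assert_allclose(phi, 0.0)


def test_contact_image_uniform_slab(geom):
    """A slab spanning the field gives exp(-mu T) at interior pixels."""
    n, vox = 64, 10.5
    beta = np.zeros((n, n))
    beta[20:40, :] = 4e-10  # slab crossed along y: 20 voxels thick at angle 0
    att, _ = contact_image(np.zeros_like(beta), beta, 0.0, geom, vox)
    mu = 4 * np.pi * 4e-10 / geom.wavelength_um
    expected = np.exp(-mu * 20 * vox)
    np.testing.assert_allclose(att[0, 10:54], expected, rtol=1e-6)


def test_contact_image_disc_chord(geom):
    n, vox = 256, 5.0
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    r = 80
    disc = (((xx - c) ** 2 + (yy - c) ** 2) <= r ** 2)
    beta = disc * 4e-10
    att, _ = contact_image(np.zeros_like(beta), beta, 0.0, geom, vox)
    mu = 4 * np.pi * 4e-10 / geom.wavelength_um
    s = np.arange(n) - c
    chord = 2 * np.sqrt(np.clip(r ** 2 - s ** 2, 0, None)) * vox
    rel = np.abs(-np.log(att[0]) - mu * chord) / max(mu * chord.max(), 1e-30)
    assert rel.max() < 0.01


def test_contact_image_rejects_negative_beta(geom):
    with pytest.raises(ValueError):
        contact_image(np.zeros((8, 8)), -np.ones((8, 8)), 0.0, geom, 10.5)


def test_tie_reduces_to_contact(geom):
    rng = np.random.default_rng(0)
    att = np.exp(-rng.uniform(0, 1, (16, 16)))
    M = geom.magnification
    # flat phase: no Laplacian term for any R2
    out = tie_intensity(att, np.full_like(att, 3.7), geom)
    np.testing.assert_allclose(out, att / M ** 2, rtol=1e-12)
    # R2 = 0: exactly contact / M^2 (M = 1 then)
    geom0 = SystemGeometry(R1=460, R2=0, sigma_s=70, sigma_d=30,
                           pixel_pitch=15, lambda_eff=6.53e-11, delta_beta=1000)
    phi = rng.standard_normal((16, 16))
    np.testing.assert_allclose(tie_intensity(att, phi, geom0, spacing=15.0), att,
                               rtol=1e-12)


def test_tie_quadratic_phase(geom):
    """phi = a(x^2+y^2) has exact discrete Laplacian 4a in the interior."""
    n, h = 64, geom.effective_pixel_um
    yy, xx = np.mgrid[0:n, 0:n] * h
    a = 1e-6
    phi = a * (xx ** 2 + yy ** 2)
    out = tie_intensity(np.ones((n, n)), phi, geom)
    M = geom.magnification
    coeff = geom.r2_um * geom.wavelength_um / (2 * np.pi * M)
    expected = (1 - coeff * 4 * a) / M ** 2
    np.testing.assert_allclose(out[2:-2, 2:-2], expected, rtol=1e-9)


def test_blur_conserves_flux_and_width(geom):
    rng = np.random.default_rng(3)
    img = rng.uniform(0, 2, (64, 64))
    out = apply_system_blur(img, geom)
    assert out.sum() == pytest.approx(img.sum(), rel=1e-6)
    # a point spreads into a sampled Gaussian of the system width
    pt = np.zeros((129, 129))
    pt[64, 64] = 1.0
    blurred = apply_system_blur(pt, geom)
    s = geom.system_sigma_um / geom.effective_pixel_um
    yy, xx = np.mgrid[0:129, 0:129]
    ref = np.exp(-((xx - 64) ** 2 + (yy - 64) ** 2) / (2 * s ** 2))
    ref /= ref.sum()
    assert np.abs(blurred - ref).max() < 1e-4
    # sigma = 0 is the identity
    geom0 = SystemGeometry(R1=460, R2=0, sigma_s=0, sigma_d=0,
                           pixel_pitch=15, lambda_eff=6.53e-11, delta_beta=1000)
    np.testing.assert_array_equal(apply_system_blur(img, geom0), img)


def test_scan_protocol_bookkeeping():
    """180 x 50 ms frames at 20 deg/s span exactly 9 s and 180 degrees."""
    p = ScanProtocol(mode="continuous", n_projections=180, exposure=0.05,
                     angular_velocity=20.0)
    assert p.duration == pytest.approx(9.0)
    angles = p.nominal_angles()
    assert angles[0] == 0.0
    assert angles[-1] + 20.0 * 0.05 == pytest.approx(180.0)
    with pytest.raises(ValueError):
        ScanProtocol(mode="continuous", n_projections=10, angular_velocity=0.0)
    with pytest.raises(ValueError):
        ScanProtocol(mode="warp")


@pytest.fixture(scope="module")
def small_phantom():
    return build_phantom(3, (48, 48), 10.5, seed=2, radius_range_um=(25, 40))


def test_scan_determinism(small_phantom, geom):
    proto = ScanProtocol(mode="static", n_projections=12, angular_range=180.0,
                         exposure=1.0, photons_per_pixel=5000, seed=9)
    a = simulate_scan(small_phantom, proto, geom)
    b = simulate_scan(small_phantom, proto, geom)
    np.testing.assert_array_equal(a.intensity, b.intensity)
    np.testing.assert_array_equal(a.flat, b.flat)


def test_scan_noise_scaling(small_phantom, geom):
    """Relative deviation from the noiseless scan shrinks as photons grow."""
    proto0 = ScanProtocol(mode="static", n_projections=6, angular_range=180.0,
                          exposure=1.0, photons_per_pixel=None)
    clean = simulate_scan(small_phantom, proto0, geom).intensity

    def rel_rms(photons):
        proto = ScanProtocol(mode="static", n_projections=6, angular_range=180.0,
                             exposure=1.0, photons_per_pixel=photons, seed=4)
        noisy = simulate_scan(small_phantom, proto, geom).corrected()
        cleanc = clean * geom.magnification ** 2
        return np.sqrt(np.mean((noisy - cleanc) ** 2)) / np.sqrt(np.mean(cleanc ** 2))

    assert rel_rms(1e8) < 1e-3
    assert rel_rms(1e4) > rel_rms(1e8)


def test_attenuation_only_reduction(geom):
    """With delta = 0 the simulator is a plain attenuation CT system."""
    n, vox = 96, 10.5
    ph = build_phantom(2, (n, n), vox, seed=5, radius_range_um=(40, 60),
                       optics={"air": (0.0, 1e-13), "wood": (0.0, 4e-10),
                               "water": (0.0, 5.2e-10)})
    proto = ScanProtocol(mode="static", n_projections=240, angular_range=180.0,
                         exposure=1.0, photons_per_pixel=None)
    # no blur either: pure Radon data
    geom_sharp = SystemGeometry(R1=320, R2=140, sigma_s=0, sigma_d=0,
                                pixel_pitch=15, lambda_eff=6.53e-11, delta_beta=1000)
    scan = simulate_scan(ph, proto, geom_sharp)
    sino = Sinogram(-np.log(np.clip(scan.corrected()[:, 0, :], 1e-9, None)),
                    scan.angles_deg, vox)
    rec = fbp_reconstruct(sino, "ram-lak")
    _, beta = optics_maps(ph)
    mu_true = beta[0] * 4 * np.pi / geom_sharp.wavelength_um
    inside = mu_true > 0
    err = np.sqrt(np.mean((rec.values[inside] - mu_true[inside]) ** 2))
    assert err / mu_true.max() < 0.05


def test_fringe_contrast_vs_propagation_distance():
    """Edge fringes grow with R2 up to the blur-imposed optimum.

    At fixed system length the fringe amplitude at a sharp edge rises
    with propagation distance while source blur increasingly damps it;
    the grid maximum sits at an interior R2 near the closed-form optimum.
    """
    from scipy import ndimage

    n, pitch, length = 128, 15.0, 460.0
    base_b = np.zeros((n, n))
    base_b[:, : n // 2] = 4e-10
    base_d = np.zeros((n, n))
    base_d[:, : n // 2] = 4e-8  # weak edge: stays in the near-field regime
    amplitudes = []
    r2s = np.linspace(5.0, 350.0, 24)
    for r2 in r2s:
        g = SystemGeometry(R1=length - r2, R2=r2, sigma_s=70, sigma_d=30,
                           pixel_pitch=pitch, lambda_eff=6.53e-11, delta_beta=100)
        vox = g.effective_pixel_um
        s_e = 30.0 / vox  # edge pre-smoothed to 30 um in object space
        beta = ndimage.gaussian_filter(base_b, (0, s_e))
        delta = ndimage.gaussian_filter(base_d, (0, s_e))
        att, phi = contact_image(delta, beta, 0.0, g, vox)
        with_phase = apply_system_blur(tie_intensity(att, phi, g, vox), g, vox)
        no_phase = apply_system_blur(
            tie_intensity(att, np.zeros_like(phi), g, vox), g, vox)
        amplitudes.append(
            float(np.abs(with_phase - no_phase).max()) * g.magnification ** 2)
    amplitudes = np.array(amplitudes)
    k_best = int(np.argmax(amplitudes))
    assert 0 < k_best < len(r2s) - 1  # interior optimum
    assert np.all(np.diff(amplitudes[: k_best + 1]) > 0)
    # the optimum sits near the closed-form optimal magnification
    m_opt = 1 + 30 / 70
    r2_opt = length * (1 - 1 / m_opt)
    assert abs(r2s[k_best] - r2_opt) < 60.0


def test_frame_skip_and_offset_metadata(small_phantom, geom):
    proto = ScanProtocol(mode="continuous", n_projections=20, exposure=0.05,
                         angular_velocity=20.0, angle_offset_deg=3.0,
                         skip_at=10, skip_frames=4)
    scan = simulate_scan(small_phantom, proto, geom)
    true = scan.meta["true_angles_deg"]
    nominal = scan.angles_deg
    step = 20.0 * 0.05
    np.testing.assert_allclose(true[:10], 3.0 + step * np.arange(10))
    np.testing.assert_allclose(true[10:] - nominal[10:], 3.0 + step * 4)
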