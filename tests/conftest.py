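"""Shared fixtures: a desk-scale phantom, its simulated circular-scan
datasets and the reconstructions the heavier tests share.

The fixture phantom keeps the full-size design's rod cross-section
(0.5 × 1.8 µm), gap statistics and layer pitch but shrinks the cube to
12 µm and the cell target proportionally, so the microstructure stays
resolvable at the 0.25 µm test pitch.  The cube is embedded centred in
a 16 µm field of view of immersion medium, mirroring a phantom
surrounded by oil.
"""

import dataclasses

import numpy as np
import pytest

from tpmphantom import (
    CellTargetSpec,
    OpticalConfig,
    PhantomSpec,
    add_phase_noise,
    direct_inversion,
    generate_phantom,
    gpsc_reconstruct,
    make_support,
    simulate_projection_set,
    tv_initial_reconstruction,
)
from tpmphantom.geometry import pad_volume
from tpmphantom.msbp import MsbpSettings, msbp_reconstruct

PITCH = 0.25
FOV_SHAPE = (64, 64, 64)
N_PROJECTIONS = 45
AZIMUTH_STEP = 8.0
NOISE_SIGMA_STRONG = 0.10  # matches the 633 nm dataset noise floor
NOISE_SIGMA_WEAK = 0.08  # matches the 835 nm dataset noise floor


def small_phantom_spec(delta_ri_max: float = 0.03) -> tuple[PhantomSpec, CellTargetSpec]:
    spec = dataclasses.replace(
        PhantomSpec(), cube_size=(12.0, 12.0, 12.0), delta_ri_max=delta_ri_max
    )
    sc = delta_ri_max / 0.03
    cspec = CellTargetSpec(
        ellipsoid_size=(6.0, 5.0, 2.4),
        truncation=0.1,
        line_group_frequencies=(833.0, 1190.0, 1667.0),
        bars_per_group=3,
        bar_length=1.0,
        bar_thickness=0.8,
        line_row_y=-1.2,
        group_margin=0.4,
        nucleus_center=(0.0, 1.4, 0.0),
        nucleus_semiaxes=(1.2, 1.0, 0.8),
        nucleoli_centers=((-0.5, 1.4, -0.2), (0.5, 1.4, 0.3)),
        nucleoli_radii=(0.35, 0.35),
        gradient_center=(-1.8, 0.1, 0.0),
        gradient_size=(1.2, 1.0, 1.0),
        cytoplasm_offset=0.010 * sc,
        nucleus_offset=0.015 * sc,
        nucleolus_offset=0.030 * sc,
        line_offset=0.025 * sc,
        gradient_max_offset=0.020 * sc,
    )
    return spec, cspec


def build_small_phantom(delta_ri_max: float = 0.03, seed: int = 11):
    spec, cspec = small_phantom_spec(delta_ri_max)
    vol = generate_phantom(spec, cspec, voxel_pitch=PITCH, seed=seed)
    return spec, pad_volume(vol, FOV_SHAPE, spec.n_background)


@pytest.fixture(scope="session")
def sim_config():
    return OpticalConfig(
        wavelength_nm=633.0,
        zenith_deg=47.0,
        n_projections=N_PROJECTIONS,
        azimuth_step_deg=AZIMUTH_STEP,
    )


@pytest.fixture(scope="session")
def strong_phantom():
    """Full-contrast (ΔRI = 0.03) phantom and its spec."""
    return build_small_phantom(0.03)


@pytest.fixture(scope="session")
def weak_phantom():
    """Reduced-contrast phantom emulating the weak-scattering regime."""
    return build_small_phantom(0.005)


@pytest.fixture(scope="session")
def pset_clean(strong_phantom, sim_config):
    _, truth = strong_phantom
    return simulate_projection_set(truth, sim_config)


@pytest.fixture(scope="session")
def pset_noisy(pset_clean):
    return add_phase_noise(pset_clean, NOISE_SIGMA_STRONG, seed=5)


@pytest.fixture(scope="session")
def pset_weak(weak_phantom, sim_config):
    _, truth = weak_phantom
    return add_phase_noise(
        simulate_projection_set(truth, sim_config), NOISE_SIGMA_WEAK, seed=5
    )


@pytest.fixture(scope="session")
def object_mask(strong_phantom):
    spec, truth = strong_phantom
    return truth.values > spec.n_background + 1e-12


@pytest.fixture(scope="session")
def di_noisy(pset_noisy):
    return direct_inversion(pset_noisy)


@pytest.fixture(scope="session")
def support_noisy(pset_noisy, di_noisy):
    di, cov = di_noisy
    smooth = tv_initial_reconstruction(
        pset_noisy, tv_weight=1e-2, coverage=cov, di_volume=di
    )
    # closing bridges the rod lattice pores so the support outlines the
    # phantom envelope (6 voxels = 1.5 µm, half the maximal rod gap)
    return make_support(smooth, dilation=2, closing=6)


@pytest.fixture(scope="session")
def gpsc_noisy(pset_noisy, di_noisy, support_noisy):
    di, cov = di_noisy
    return gpsc_reconstruct(
        pset_noisy, support_noisy, eps=0.02, init=di, coverage=cov
    )


@pytest.fixture(scope="session")
def msbp_e_clean(pset_clean):
    """MSBP-E on noise-free data, with its Direct Inversion init."""
    init, _ = direct_inversion(pset_clean)
    vol, hist = msbp_reconstruct(
        pset_clean, MsbpSettings(mode="field", max_iter=25), init_volume=init
    )
    return init, vol, hist


@pytest.fixture(scope="session")
def msbp_e_noisy(pset_noisy):
    return msbp_reconstruct(pset_noisy, MsbpSettings(mode="field", max_iter=25))


@pytest.fixture(scope="session")
def msbp_i_noisy(pset_noisy):
    return msbp_reconstruct(pset_noisy, MsbpSettings(mode="intensity", max_iter=25))


# ---------------------------------------------------------------------------
# Born-oracle fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def born_blob_pair():
    """Weak Gaussian blob: brute-force Born field vs MSBP field."""
    from tpmphantom.forward import msbp_forward
    from oracles import born_scattered_field

    n, pitch, dn, sigma = 48, 0.25, 5e-4, 1.0
    c = (np.arange(n) - n // 2 + 0.0) * pitch
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    from tpmphantom import RIVolume

    vol = RIVolume(
        1.5123 + dn * np.exp(-(X**2 + Y**2 + Z**2) / (2 * sigma**2)),
        [pitch] * 3,
        0.0,
    )
    cfg = OpticalConfig(
        zenith_deg=47.0, n_projections=1, azimuth_step_deg=2.0, pupil=False
    )
    d_born, _ = born_scattered_field(
        vol, [0, 0, 1], cfg, source_threshold=1e-3, detector="exit"
    )
    d_msbp = msbp_forward(vol, [0, 0, 1], cfg).values
    return vol, d_born, d_msbp


@pytest.fixture(scope="session")
def born_sphere_recovery():
    """Weak sphere reconstructed by Direct Inversion from Born-oracle
    fields under dense multi-zenith angular coverage."""
    from tpmphantom.forward import ProjectionSet
    from tpmphantom import RIVolume
    from oracles import born_scattered_field

    n, pitch, dn_true, radius = 60, 0.2, 1e-3, 1.5
    c = (np.arange(n) - n // 2 + 0.0) * pitch
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    v = np.full((n, n, n), 1.5123)
    v[X**2 + Y**2 + Z**2 <= radius**2] += dn_true
    vol = RIVolume(v, [pitch] * 3, 0.0)
    cfg = OpticalConfig(
        zenith_deg=47.0, n_projections=1, azimuth_step_deg=2.0, pupil=False
    )
    dirs = []
    for zen, naz in [(0, 1), (20, 8), (35, 12), (50, 16)]:
        th = np.radians(zen)
        for k in range(naz):
            ph = 2 * np.pi * k / naz
            dirs.append(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
    fields, eff = [], []
    for d in dirs:
        f, s = born_scattered_field(vol, d, cfg, detector="near")
        fields.append(f)
        eff.append(s)
    pset = ProjectionSet(np.array(fields), np.array(eff), [pitch] * 2, cfg)
    rec, cov = direct_inversion(pset)
    return vol, dn_true, rec, cov
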