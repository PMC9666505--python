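"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's FFT-based forward machinery:
the first-Born oracle evaluates the scattering integral with the
free-space Green's function by direct summation over source voxels.
"""

import numpy as np

from tpmphantom import OpticalConfig, RIVolume
from tpmphantom.forward import _propagation_kernel, snap_direction


def born_scattered_field(volume: RIVolume, direction, config: OpticalConfig,
                         source_threshold: float = 1e-2,
                         detector: str = "exit") -> np.ndarray:
    """First-Born total/incident field at the volume mid-plane.

    Direct summation of G(r-r') f(r') u0(r') over all source voxels with
    |Δn| above ``source_threshold`` of the peak, evaluated on a detector
    plane and backpropagated (free space) to the mid-plane — the same
    referencing convention as the MSBP simulator.

    ``detector="exit"`` samples just past the volume exit face (clean of
    evanescent near-field, appropriate for modest illumination tilts);
    ``detector="near"`` samples just above the topmost source, before
    obliquely scattered light walks off the finite lateral window
    (needed when combining steep-zenith projections).
    """
    nx, ny, nz = volume.shape
    p = volume.voxel_pitch
    k_m = config.k_medium
    k0 = 2 * np.pi / config.wavelength_um
    s = snap_direction(direction, (nx, ny), p[:2], k_m)
    x = (np.arange(nx) - nx // 2) * p[0]
    y = (np.arange(ny) - ny // 2) * p[1]
    z = (np.arange(nz) - nz // 2) * p[2]
    dn = volume.values - config.n_immersion
    idx = np.argwhere(np.abs(dn) > source_threshold * np.abs(dn).max())
    rp = np.stack([x[idx[:, 0]], y[idx[:, 1]], z[idx[:, 2]]], axis=1)
    f = k0**2 * (volume.values[idx[:, 0], idx[:, 1], idx[:, 2]] ** 2
                 - config.n_immersion**2)
    src = f * np.exp(1j * k_m * (rp @ s)) * np.prod(p)

    if detector == "near":
        zd = rp[:, 2].max() + 2 * p[2]
    elif detector == "exit":
        zd = z[-1] + p[2]
    else:
        raise ValueError(f"unknown detector placement {detector!r}")
    Xd, Yd = np.meshgrid(x, y, indexing="ij")
    pts = np.stack([Xd.ravel(), Yd.ravel(), np.full(nx * ny, zd)], axis=1)
    uB = np.zeros(nx * ny, dtype=complex)
    step = max(1, int(2**25 / max(len(rp), 1)))
    for c in range(0, len(pts), step):
        d = pts[c:c + step, None, :] - rp[None, :, :]
        R = np.sqrt((d**2).sum(axis=2))
        uB[c:c + step] = (np.exp(1j * k_m * R) / (4 * np.pi * R)) @ src
    uB = uB.reshape(nx, ny)
    kern = _propagation_kernel((nx, ny), p[:2], -zd, k_m)
    uB = np.fft.ifft2(np.fft.fft2(uB) * kern)
    u0_mid = np.exp(1j * k_m * (s[0] * Xd + s[1] * Yd))
    return 1.0 + uB / u0_mid, s
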