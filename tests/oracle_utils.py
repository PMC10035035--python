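"""Independent brute-force oracles used by the test suite.

These deliberately avoid the closed forms in the package: amplitudes are
recomputed by direct numerical Fourier/orientation integration (adaptive
radial quadrature, real-space 2D grids, Monte-Carlo orientation sampling,
explicit layer-pair sums) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import j0


def radial_shell_amplitude(q, boundaries, slds, solvent_sld):
    """4 pi int (rho(r) - rho_s) r^2 sinc(qr) dr by adaptive quadrature."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    total = np.zeros_like(q)
    r0 = 0.0
    for r1, sld in zip(boundaries, slds):
        contrast = sld - solvent_sld
        if contrast != 0.0:
            for i, qi in enumerate(q):
                val, _ = quad(
                    lambda r: r**2 * np.sinc(qi * r / np.pi), r0, r1, limit=400
                )
                total[i] += 4.0 * np.pi * contrast * val
        r0 = r1
    return total


def mc_ellipsoid_intensity(q, layers, solvent_sld, n_orient=2**17, seed=0):
    """Orientation average of nested ellipsoids by quasi-Monte-Carlo
    direction sampling (scrambled Sobol over the orientation octant)."""
    from scipy.stats import qmc

    from solusaxs.formfactors import _ellipsoid_layer_amplitude

    sampler = qmc.Sobol(d=2, scramble=True, seed=seed)
    pts = sampler.random(n_orient)
    cos_t = pts[:, 0]                      # uniform in cos(theta)
    phi = pts[:, 1] * np.pi / 2.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    u = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    amp = _ellipsoid_layer_amplitude(q, u, layers, solvent_sld)
    return np.mean(amp**2, axis=1)


def ellipsoid_revolution_intensity_quad(q, a, c, sld, solvent_sld):
    """Single-angle adaptive integral for an ellipsoid of revolution."""
    from solusaxs.formfactors import sphere_volume_kernel

    V = 4.0 / 3.0 * np.pi * a * a * c
    out = []
    for qi in np.atleast_1d(q):
        def f(al):
            r = np.sqrt(a**2 * np.sin(al) ** 2 + c**2 * np.cos(al) ** 2)
            A = (sld - solvent_sld) * V * sphere_volume_kernel(qi * r)
            return A**2 * np.sin(al)
        val, _ = quad(f, 0.0, np.pi / 2.0, limit=200)
        out.append(val)  # int_0^{pi/2} sin = 1, already normalized
    return np.array(out)


def disc_amplitude_grid(q, alpha, core_radius, rim_thickness, half_height,
                        face_thickness, sld_core, sld_face, sld_rim,
                        solvent_sld, nr=1800, nz=1000):
    """Real-space 2D midpoint integration of the bicelle density map."""
    rmax = core_radius + rim_thickness
    zmax = half_height + face_thickness
    r = (np.arange(nr) + 0.5) * rmax / nr
    z = (np.arange(nz) + 0.5) * zmax / nz
    Rg, Zg = np.meshgrid(r, z, indexing="ij")
    rho = np.where(
        (Rg <= core_radius) & (Zg <= half_height), sld_core - solvent_sld,
        np.where((Rg <= core_radius), sld_face - solvent_sld,
                 sld_rim - solvent_sld),
    )
    out = []
    for qi in np.atleast_1d(q):
        qpar, qz = qi * np.sin(alpha), qi * np.cos(alpha)
        integ = rho * j0(qpar * Rg) * np.cos(qz * Zg) * Rg
        out.append(2.0 * 2.0 * np.pi * np.sum(integ) * (rmax / nr) * (zmax / nz))
    return np.array(out)


def paracrystal_pair_sum(q, n_layers, d_spacing, sigma):
    """Stacking factor as an explicit double sum over layer pairs."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    S = np.zeros_like(q)
    for j in range(n_layers):
        for k in range(n_layers):
            m = abs(j - k)
            S += np.cos(m * q * d_spacing) * np.exp(-m * q**2 * sigma**2 / 2.0)
    return S / n_layers


def rod_longitudinal_quad(q, length, n_grid=20001):
    """Thin-rod orientational average by dense midpoint integration of the
    defining tilt integral <sinc^2(qL cos(t)/2)> over uniform cos(t)."""
    cos_t = (np.arange(n_grid) + 0.5) / n_grid
    out = np.empty(np.atleast_1d(q).size)
    for i, qi in enumerate(np.atleast_1d(q)):
        x = qi * length * cos_t / 2.0
        amp = np.where(np.abs(x) < 1e-12, 1.0,
                       np.sin(x) / np.where(np.abs(x) < 1e-12, 1.0, x))
        out[i] = np.mean(amp**2)
    return out
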