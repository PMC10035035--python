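"""Scattering amplitudes and orientational averages for geometric bodies.

All assembly models are composed from these primitives: spheres and
concentric shells, ellipsoids (of revolution and triaxial), core-shell
discs with a distinct rim, and semiflexible (worm-like) rods.  Internal
units are Angstrom-based throughout: q in 1/A, lengths in A, SLD in 1/A^2,
so amplitudes carry units of A (contrast x volume) and squared amplitudes
A^2; conversion to absolute intensity in 1/cm happens once at the model
layer.

All bodies here are centrosymmetric, so amplitudes are real.  q = 0 is
evaluated by series expansion, never special-cased to NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import j1, sici

#: Default Gauss-Legendre order for single-angle orientational averages.
DEFAULT_ORIENT_ORDER = 76
#: Default product-grid order per angle for triaxial averages.
DEFAULT_TRIAXIAL_ORDER = 76


@lru_cache(maxsize=32)
def _gauss_legendre(n: int, a: float, b: float):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def sphere_volume_kernel(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude 3[sin x - x cos x]/x^3, = 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _j1c(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x, = 1 at x = 0 (disc radial kernel)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    out[small] = 1.0 - x[small] ** 2 / 8.0
    out[~small] = 2.0 * j1(x[~small]) / x[~small]
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x, = 1 at x = 0 (slab axial kernel)."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def sphere_amplitude(q, R: float, contrast: float) -> np.ndarray:
    """Amplitude of a homogeneous sphere: contrast * V * kernel(qR)  [A]."""
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    q = np.asarray(q, dtype=float)
    V = 4.0 / 3.0 * np.pi * R**3
    return contrast * V * sphere_volume_kernel(q * R)


@dataclass(frozen=True)
class ShellProfile:
    """Radial step profile of concentric spherical layers.

    `boundaries[i]` is the outer radius of layer i (strictly increasing);
    layer 0 spans (0, boundaries[0]).  A solvent-filled core (a vesicle
    lumen) is expressed as an innermost layer with sld = solvent_sld.
    """

    boundaries: tuple
    slds: tuple
    solvent_sld: float = 0.0

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        s = tuple(float(x) for x in self.slds)
        if len(b) != len(s):
            raise ValueError("layer count must equal sld count")
        if len(b) == 0:
            raise ValueError("profile needs at least one layer")
        if b[0] <= 0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be positive and strictly increasing")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "slds", s)

    @property
    def outer_radius(self) -> float:
        return self.boundaries[-1]

    def total_excess_scattering(self) -> float:
        """Sum of contrast x volume over layers = amplitude at q -> 0."""
        total = 0.0
        r_prev = 0.0
        for r, sld in zip(self.boundaries, self.slds):
            v = 4.0 / 3.0 * np.pi * (r**3 - r_prev**3)
            total += (sld - self.solvent_sld) * v
            r_prev = r
        return total


def shell_amplitude(q, profile: ShellProfile) -> np.ndarray:
    """Amplitude of nested spherical shells as sphere differences [A]."""
    q = np.asarray(q, dtype=float)
    amp = np.zeros_like(q)
    r_prev = 0.0
    for r, sld in zip(profile.boundaries, profile.slds):
        contrast = sld - profile.solvent_sld
        if contrast != 0.0:
            amp += contrast * (
                4.0 / 3.0 * np.pi * r**3 * sphere_volume_kernel(q * r)
                - 4.0 / 3.0 * np.pi * r_prev**3 * sphere_volume_kernel(q * r_prev)
            )
        r_prev = r
    return amp


# ---------------------------------------------------------------------------
# Ellipsoids


def _ellipsoid_layer_amplitude(q, u, layers, solvent_sld):
    """Amplitude at orientation(s) u for nested coaxial ellipsoids.

    `layers` is a list of ((a, b, c), sld), strictly nested; `u` is an
    array of unit direction vectors of shape (m, 3).  Returns array of
    shape (len(q), m).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    u = np.atleast_2d(u)
    amp = np.zeros((q.size, u.shape[0]))
    prev = None
    for (a, b, c), sld in layers:
        contrast = sld - solvent_sld
        r_eff = np.sqrt((a * u[:, 0]) ** 2 + (b * u[:, 1]) ** 2 + (c * u[:, 2]) ** 2)
        V = 4.0 / 3.0 * np.pi * a * b * c
        term = V * sphere_volume_kernel(q[:, None] * r_eff[None, :])
        if prev is not None:
            (pa, pb, pc) = prev
            r_prev = np.sqrt(
                (pa * u[:, 0]) ** 2 + (pb * u[:, 1]) ** 2 + (pc * u[:, 2]) ** 2
            )
            Vp = 4.0 / 3.0 * np.pi * pa * pb * pc
            term = term - Vp * sphere_volume_kernel(q[:, None] * r_prev[None, :])
        amp += contrast * term
        prev = (a, b, c)
    return amp


def ellipsoid_orientavg_intensity(
    q,
    layers,
    solvent_sld: float = 0.0,
    n_alpha: int = DEFAULT_ORIENT_ORDER,
    n_beta: int = DEFAULT_TRIAXIAL_ORDER,
    return_mean_amplitude: bool = False,
):
    """Orientation-averaged <|A|^2> for nested coaxial ellipsoids [A^2].

    `layers`: list of ((a, b, c) semi-axes, sld), innermost first, each
    layer's axes strictly containing the previous.  Uses Gauss-Legendre
    quadrature over the orientation octant; collapses to a single angle
    when all layers are ellipsoids of revolution (a == b).

    With `return_mean_amplitude`, also returns <A> for the decoupling
    approximation.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    for (a, b, c), _ in layers:
        if a <= 0 or b <= 0 or c <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
    revolution = all(abs(a - b) < 1e-12 for (a, b, _), _ in layers)
    if revolution:
        alpha, w_a = _gauss_legendre(n_alpha, 0.0, np.pi / 2.0)
        u = np.stack(
            [np.sin(alpha), np.zeros_like(alpha), np.cos(alpha)], axis=1
        )
        w = w_a * np.sin(alpha)
    else:
        alpha, w_a = _gauss_legendre(n_alpha, 0.0, np.pi / 2.0)
        beta, w_b = _gauss_legendre(n_beta, 0.0, np.pi / 2.0)
        A, B = np.meshgrid(alpha, beta, indexing="ij")
        u = np.stack(
            [
                (np.sin(A) * np.cos(B)).ravel(),
                (np.sin(A) * np.sin(B)).ravel(),
                np.cos(A).ravel(),
            ],
            axis=1,
        )
        w = (w_a[:, None] * w_b[None, :] * np.sin(A) * (2.0 / np.pi)).ravel()
    w = w / w.sum()
    amp = _ellipsoid_layer_amplitude(q, u, layers, solvent_sld)
    mean_sq = amp**2 @ w
    if return_mean_amplitude:
        return mean_sq, amp @ w
    return mean_sq


# ---------------------------------------------------------------------------
# Discs / bicelles


def cylinder_amplitude(q, alpha, radius: float, half_height: float,
                       contrast: float) -> np.ndarray:
    """Amplitude of a homogeneous cylinder at tilt angle alpha [A].

    alpha is the angle between the cylinder axis and q.  Broadcasts q
    against alpha: returns shape (len(q), len(alpha)).
    """
    if radius <= 0 or half_height <= 0:
        raise ValueError("cylinder dimensions must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    V = 2.0 * np.pi * radius**2 * half_height
    qr = q[:, None] * radius * np.sin(alpha)[None, :]
    qh = q[:, None] * half_height * np.cos(alpha)[None, :]
    return contrast * V * _j1c(qr) * _sinc(qh)


def coreshell_disc_amplitude(
    q,
    alpha,
    core_radius: float,
    rim_thickness: float,
    half_height: float,
    face_thickness: float,
    sld_core: float,
    sld_face: float,
    sld_rim: float,
    solvent_sld: float = 0.0,
) -> np.ndarray:
    """Amplitude of a core-shell disc (bicelle) at tilt angle alpha [A].

    Geometry: a lipid-tail core cylinder (core_radius, 2*half_height),
    polar faces of `face_thickness` on both flat sides, and a rim annulus
    of `rim_thickness` spanning the full face-to-face height — the
    standard disc model with detergent accumulated in the high-curvature
    rim.  rim and face thickness may be zero (plain cylinder reductions).
    Shape (len(q), len(alpha)).
    """
    if core_radius <= 0 or half_height <= 0:
        raise ValueError("core radius and half height must be positive")
    if rim_thickness < 0 or face_thickness < 0:
        raise ValueError("rim/face thickness cannot be negative")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    h_tot = half_height + face_thickness
    # contrast-step decomposition over three nested cylinders:
    # core (R, h) inside face-capped cylinder (R, h_tot) inside rim (R+t, h_tot)
    amp = np.zeros((q.size, alpha.size))
    if face_thickness > 0:
        amp += cylinder_amplitude(q, alpha, core_radius, half_height, sld_core - sld_face)
        inner_full = sld_face
    else:
        inner_full = sld_core
    if rim_thickness > 0:
        amp += cylinder_amplitude(q, alpha, core_radius, h_tot, inner_full - sld_rim)
        amp += cylinder_amplitude(
            q, alpha, core_radius + rim_thickness, h_tot, sld_rim - solvent_sld
        )
    else:
        amp += cylinder_amplitude(q, alpha, core_radius, h_tot, inner_full - solvent_sld)
    return amp


def disc_orientavg_intensity(
    q,
    core_radius: float,
    rim_thickness: float,
    half_height: float,
    face_thickness: float,
    sld_core: float,
    sld_face: float,
    sld_rim: float,
    solvent_sld: float = 0.0,
    n_alpha: int = DEFAULT_ORIENT_ORDER,
    return_mean_amplitude: bool = False,
):
    """Orientation-averaged <|A|^2> of the core-shell disc [A^2]."""
    alpha, w = _gauss_legendre(n_alpha, 0.0, np.pi / 2.0)
    w = w * np.sin(alpha)
    w = w / w.sum()
    amp = coreshell_disc_amplitude(
        q, alpha, core_radius, rim_thickness, half_height, face_thickness,
        sld_core, sld_face, sld_rim, solvent_sld,
    )
    mean_sq = amp**2 @ w
    if return_mean_amplitude:
        return mean_sq, amp @ w
    return mean_sq


# ---------------------------------------------------------------------------
# Rods and worm-like micelles


def rod_longitudinal_factor(q, length: float) -> np.ndarray:
    """Normalized orientational average of an infinitely thin rigid rod.

    2 Si(x)/x - 4 sin^2(x/2)/x^2 with x = qL (Neugebauer); -> 1 at q -> 0.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = q * length
    out = np.ones_like(x)
    big = x > 1e-4
    xb = x[big]
    si, _ = sici(xb)
    out[big] = 2.0 * si / xb - 4.0 * np.sin(xb / 2.0) ** 2 / xb**2
    return out


def wormlike_chain_factor(q, contour_length: float, kuhn_length: float,
                          n_quad: int = 128) -> np.ndarray:
    """Normalized scattering factor of a semiflexible (Kholodenko) chain.

    S(q) = (2/x) [I1(x) - I2(x)/x], x = 3 L / l_k, with
    In(x) = int_0^x f(z) z^(n-1) dz and

        f(z) = sinh(E z) / (E sinh z),  E = sqrt(1 - (q l_k / 3)^2),  q l_k <= 3
        f(z) = sin(F z) / (F sinh z),   F = sqrt((q l_k / 3)^2 - 1),  q l_k > 3

    Interpolates between the flexible-coil and rigid-rod limits; -> 1 at
    q -> 0.  `kuhn_length` l_k is the Kuhn (= 2x persistence) length.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    L, lk = float(contour_length), float(kuhn_length)
    x = 3.0 * L / lk
    z, w = _gauss_legendre(n_quad, 0.0, x)
    big = z > 30.0  # sinh overflow guard: sinh(z) -> e^z / 2
    out = np.empty_like(q)
    for i, qi in enumerate(q):
        u = qi * lk / 3.0
        if u <= 1e-12:
            out[i] = 1.0
            continue
        if u <= 1.0:
            E = np.sqrt(max(1.0 - u**2, 0.0))
            if E < 1e-8:
                f = np.where(z < 1e-12, 1.0, z / np.sinh(np.minimum(z, 700.0)))
                f[big] = 2.0 * z[big] * np.exp(-z[big])
            else:
                f = np.empty_like(z)
                f[~big] = np.sinh(E * z[~big]) / (E * np.sinh(z[~big]))
                # sinh(a)/sinh(b) ~ exp(a - b) for large arguments
                f[big] = np.exp((E - 1.0) * z[big]) / E
        else:
            F = np.sqrt(u**2 - 1.0)
            f = np.empty_like(z)
            f[~big] = np.sin(F * z[~big]) / (F * np.sinh(z[~big]))
            f[big] = 2.0 * np.sin(F * z[big]) * np.exp(-z[big]) / F
        I1 = np.sum(w * f)
        I2 = np.sum(w * f * z)
        out[i] = (2.0 / x) * (I1 - I2 / x)
    return np.clip(out, 0.0, None)


def circular_cs_amplitude(q, radii, slds, solvent_sld: float = 0.0) -> np.ndarray:
    """Cross-section amplitude per unit length of nested circular shells.

    radii increasing, slds per annulus (innermost disc first).  Units
    contrast x area = 1/A^2 * A^2 (dimensionless); multiply by length for
    the full amplitude.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    amp = np.zeros_like(q)
    r_prev = 0.0
    for r, sld in zip(radii, slds):
        contrast = sld - solvent_sld
        if contrast != 0.0:
            amp += contrast * (
                np.pi * r**2 * _j1c(q * r)
                - np.pi * r_prev**2 * _j1c(q * r_prev)
            )
        r_prev = r
    return amp


def flexible_rod_intensity(
    q,
    contour_length: float,
    kuhn_length: float,
    cs_radii,
    cs_slds,
    solvent_sld: float = 0.0,
) -> np.ndarray:
    """<|A|^2> of a semiflexible rod with core-shell circular cross-section
    [A^2].

    Longitudinal factor: worm-like chain; for kuhn_length >= contour_length
    the exact rigid-rod orientational average is used so the straight
    finite-cylinder limit is recovered.  Valid in the standard decoupled
    regime contour >> cross-section radius.
    """
    if not (kuhn_length > 0 and contour_length > 0):
        raise ValueError("contour and Kuhn lengths must be positive")
    if kuhn_length >= contour_length:
        # rigid limit: exact straight-rod orientational average
        s_long = rod_longitudinal_factor(q, contour_length)
    else:
        s_long = wormlike_chain_factor(q, contour_length, kuhn_length)
    a_cs = circular_cs_amplitude(q, cs_radii, cs_slds, solvent_sld)
    return s_long * (a_cs * contour_length) ** 2
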