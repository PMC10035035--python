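"""Parametric I(Q) models for every morphology seen in detergent-mediated
vesicle solubilization.

Morphologies: uni- and multilamellar three-shell vesicles, asymmetric
four-shell vesicles (unequal detergent in the two leaflets), ellipsoidal
and triaxial core-shell micelles with Percus-Yevick hard-sphere repulsion,
fuzzy-sphere micelles, core-shell bicelles (detergent-rich rim), and
rigid/semiflexible rod micelles.

Each model exposes the orientation/size-averaged squared excess amplitude
per particle, <|A|^2> in A^2, and an :meth:`intensity` that scales it to
absolute units: I [1/cm] = n [1/cm^3] * <|A|^2> [A^2] * 1e-16 [cm^2/A^2]
(+ flat background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import formfactors as ff
from .composition import CompositionLedger, mixed_sld
from .curves import QGrid, ScatteringCurve

#: (1 A)^2 in cm^2: converts n * <A^2> to 1/cm.
A2_TO_CM2 = 1e-16
#: Percus-Yevick closure is unphysical above random close packing.
MAX_HS_VOLUME_FRACTION = 0.74
#: Gaussian polydispersity beyond this truncates unsoundly at +-3 sigma.
MAX_RADIUS_POLYDISPERSITY = 0.5


def _as_q(qgrid) -> np.ndarray:
    if isinstance(qgrid, QGrid):
        return qgrid.values
    return np.atleast_1d(np.asarray(qgrid, dtype=float))


# ---------------------------------------------------------------------------
# Structure factors


def py_hard_sphere_sq(q, hs_radius: float, volume_fraction: float) -> np.ndarray:
    """Percus-Yevick hard-sphere structure factor.

    Closed analytical form for qd >~ 0.5 (d = 2R); below that the defining
    integral of the PY direct correlation function is evaluated by
    Gauss-Legendre quadrature, which is numerically stable at q -> 0 and
    reproduces S(0) = (1-phi)^4 / (1+2phi)^2.
    """
    phi = float(volume_fraction)
    if not 0.0 <= phi < MAX_HS_VOLUME_FRACTION:
        raise ValueError(f"hard-sphere volume fraction outside [0, 0.74): {phi}")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if phi == 0.0 or hs_radius == 0.0:
        return np.ones_like(q)
    alpha = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    beta = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    gamma = phi * alpha / 2.0
    A = 2.0 * hs_radius * q
    out = np.empty_like(A)

    big = A >= 0.5
    Ab = A[big]
    if Ab.size:
        sinA, cosA = np.sin(Ab), np.cos(Ab)
        G = (
            alpha / Ab**2 * (sinA - Ab * cosA)
            + beta / Ab**3 * (2.0 * Ab * sinA + (2.0 - Ab**2) * cosA - 2.0)
            + gamma
            / Ab**5
            * (
                -(Ab**4) * cosA
                + 4.0 * ((3.0 * Ab**2 - 6.0) * cosA + (Ab**3 - 6.0 * Ab) * sinA + 6.0)
            )
        )
        out[big] = 1.0 / (1.0 + 24.0 * phi * G / Ab)
    if (~big).any():
        x, w = ff._gauss_legendre(64, 0.0, 1.0)
        As = A[~big]
        integrand = (alpha + beta * x + gamma * x**3) * x**2
        sinc = np.sinc(As[:, None] * x[None, :] / np.pi)
        nc = -24.0 * phi * (sinc * integrand[None, :]) @ w
        out[~big] = 1.0 / (1.0 - nc)
    return out


def multilamellar_structure_factor(q, n_layers: int, d_spacing: float,
                                   displacement_sigma: float) -> np.ndarray:
    """Paracrystalline stacking factor of N correlated bilayers.

    One-dimensional paracrystal with Gaussian cumulative displacement
    disorder: S_N(q) = 1 + (2/N) Re sum_{k=1}^{N-1} (N-k) r^k with
    r = exp(i q d - q^2 sigma^2 / 2).  n_layers = 1 gives 1 at all q;
    Bragg maxima sit near q = 2 pi k / d_spacing.
    """
    n = int(n_layers)
    if n < 1:
        raise ValueError("n_layers must be >= 1")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if n == 1:
        return np.ones_like(q)
    r = np.exp(1j * q * d_spacing - q**2 * displacement_sigma**2 / 2.0)
    one_minus = 1.0 - r
    # geometric sums sum r^k and sum k r^k for k = 1..N-1
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = (r - r**n) / one_minus
        sk = r * (1.0 - n * r ** (n - 1) + (n - 1) * r**n) / one_minus**2
        total = n * s1 - sk
    S = 1.0 + (2.0 / n) * total.real
    # r -> 1 (q sigma -> 0 and qd -> 2 pi k): sum is N(N-1)/2 exactly
    degenerate = np.abs(one_minus) < 1e-8
    S[degenerate] = float(n)
    return S


def effective_structure_factor(s_q: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Decoupling approximation: S_eff = 1 + beta(q) (S(q) - 1)."""
    return 1.0 + beta * (s_q - 1.0)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class VesicleParams:
    """Symmetric three-shell vesicle (head / tail / head), optionally with a
    multilamellar sub-population.

    `mean_radius` is the radius of the bilayer midplane.  The multilamellar
    fraction `f_multilamellar` of vesicles carries `n_layers` correlated
    bilayers at spacing `d_spacing` with Gaussian displacement disorder.
    """

    mean_radius: float = 250.0
    radius_polydispersity: float = 0.25
    head_thickness_in: float = 6.0
    head_thickness_out: float = 6.0
    tail_thickness: float = 30.0
    sld_head: float = 1.44e-5
    sld_tail: float = 8.2e-6
    f_multilamellar: float = 0.0
    n_layers: int = 1
    d_spacing: float = 65.0
    displacement_sigma: float = 6.0
    number_density: float = 1e13  # 1/cm^3
    background: float = 0.0

    def validate(self):
        if min(self.head_thickness_in, self.head_thickness_out, self.tail_thickness) <= 0:
            raise ValueError("layer thicknesses must be positive")
        if not 0.0 <= self.f_multilamellar <= 1.0:
            raise ValueError("f_multilamellar must be in [0, 1]")
        if self.radius_polydispersity < 0 or self.radius_polydispersity >= MAX_RADIUS_POLYDISPERSITY:
            raise ValueError(
                "radius polydispersity must be in [0, 0.5): distribution "
                "truncation is unsound beyond"
            )
        bilayer = self.head_thickness_in + self.tail_thickness + self.head_thickness_out
        if self.n_layers > 1 and self.d_spacing <= bilayer:
            raise ValueError("d_spacing must exceed the bilayer thickness")
        if self.mean_radius - self.tail_thickness / 2 - self.head_thickness_in <= 0:
            raise ValueError("vesicle lumen radius must be positive")


@dataclass
class AsymmetricBilayerParams(VesicleParams):
    """Four-shell vesicle with leaflet-resolved detergent mole fractions.

    x_in / x_out are the detergent mole fractions of the inner and outer
    leaflet; each leaflet's head and tail SLDs follow by volume-fraction
    mixing of lipid and detergent head/tail regions.
    """

    x_in: float = 0.0
    x_out: float = 0.0
    sld_head_lipid: float = 1.44e-5
    sld_tail_lipid: float = 8.2e-6
    sld_head_detergent: float = 1.44e-5
    sld_tail_detergent: float = 7.8e-6
    v_head_lipid: float = 319.0
    v_tail_lipid: float = 825.0
    v_head_detergent: float = 350.0
    v_tail_detergent: float = 350.0

    def validate(self):
        super().validate()
        if not (0.0 <= self.x_in <= 1.0 and 0.0 <= self.x_out <= 1.0):
            raise ValueError("leaflet detergent fractions must be in [0, 1]")

    def leaflet_slds(self, x: float) -> tuple[float, float]:
        """(head, tail) SLD of one leaflet at detergent mole fraction x."""
        head = mixed_sld(self.sld_head_lipid, self.v_head_lipid, x,
                         self.sld_head_detergent, self.v_head_detergent)
        tail = mixed_sld(self.sld_tail_lipid, self.v_tail_lipid, x,
                         self.sld_tail_detergent, self.v_tail_detergent)
        return head, tail


@dataclass
class MicelleParams:
    """Core-shell detergent micelle in one of three shapes.

    shape 'ellipsoid_revolution': core semi-axes (a, a, c); 'triaxial':
    (a, b, c); 'fuzzy_sphere': spherical core with the outer interface
    smeared by a Gaussian of width fuzziness_sigma, and optionally a
    fraction of tail volume mixed into the shell.  Inter-micellar
    repulsion enters via a Percus-Yevick hard-sphere structure factor in
    the decoupling approximation.
    """

    shape: str = "ellipsoid_revolution"
    core_a: float = 16.0
    core_b: float = 16.0
    core_c: float = 24.0
    shell_thickness: float = 6.0
    fuzziness_sigma: float = 0.0
    tail_in_shell_fraction: float = 0.0
    sld_core: float = 7.8e-6
    sld_shell: float = 1.5e-5
    aggregation_number: float | None = None
    hs_volume_fraction: float = 0.0
    hs_radius: float = 25.0
    number_density: float = 1e17
    background: float = 0.0

    def validate(self):
        if self.shape not in ("ellipsoid_revolution", "triaxial", "fuzzy_sphere"):
            raise ValueError(f"unknown micelle shape {self.shape!r}")
        if min(self.core_a, self.core_b, self.core_c) <= 0 or self.shell_thickness <= 0:
            raise ValueError("micelle dimensions must be positive")
        if not 0.0 <= self.hs_volume_fraction < MAX_HS_VOLUME_FRACTION:
            raise ValueError("hs_volume_fraction must be in [0, 0.74)")
        if not 0.0 <= self.tail_in_shell_fraction <= 1.0:
            raise ValueError("tail_in_shell_fraction must be in [0, 1]")


@dataclass
class BicelleParams:
    """Disc-shaped mixed micelle with a detergent-rich rim.

    The lipid-tail core is a cylinder (core_radius, 2*half_height) capped
    by polar faces of `face_thickness`; the rim annulus of `rim_thickness`
    carries detergent at mole fraction `rim_detergent_fraction`.
    """

    core_radius: float = 40.0
    half_height: float = 13.0
    face_thickness: float = 6.0
    rim_thickness: float = 12.0
    rim_detergent_fraction: float = 1.0
    sld_core: float = 8.2e-6
    sld_face: float = 1.44e-5
    sld_rim: float = 1.1e-5
    number_density: float = 1e15
    background: float = 0.0

    def validate(self):
        if min(self.core_radius, self.half_height, self.face_thickness) <= 0:
            raise ValueError("bicelle core dimensions must be positive")
        if self.rim_thickness < 0:
            raise ValueError("rim thickness cannot be negative")
        if not 0.0 <= self.rim_detergent_fraction <= 1.0:
            raise ValueError("rim detergent fraction must be in [0, 1]")


@dataclass
class WormParams:
    """Semiflexible rod micelle with circular core-shell cross-section."""

    contour_length: float = 800.0
    kuhn_length: float = 200.0
    core_radius: float = 15.0
    shell_thickness: float = 8.0
    sld_core: float = 7.8e-6
    sld_shell: float = 1.4e-5
    number_density: float = 1e13
    background: float = 0.0

    def validate(self):
        if self.contour_length <= 0 or self.kuhn_length <= 0:
            raise ValueError("contour and Kuhn lengths must be positive")
        if self.core_radius <= 0 or self.shell_thickness < 0:
            raise ValueError("cross-section dimensions invalid")


# ---------------------------------------------------------------------------
# Assembly models


class AssemblyModel:
    """A parametric particle population: per-particle <|A|^2> plus the
    composition needed to convert concentrations into number densities."""

    name: str = "assembly"
    #: amphiphiles per particle (None until set by a from_ledger builder)
    lipids_per_particle: float | None = None
    detergents_per_particle: float | None = None

    def mean_sq_amplitude(self, q) -> np.ndarray:  # A^2
        raise NotImplementedError

    def intensity(self, qgrid, number_density: float | None = None,
                  background: float | None = None) -> ScatteringCurve:
        q = _as_q(qgrid)
        n = self._number_density if number_density is None else number_density
        b = self._background if background is None else background
        i_q = n * self.mean_sq_amplitude(q) * A2_TO_CM2 + b
        return ScatteringCurve(q, i_q, metadata={"model": self.name})

    _number_density = 0.0
    _background = 0.0


def _gaussian_radius_nodes(mean: float, rel_sigma: float, n: int = 25):
    """Nodes/weights of a +-3 sigma truncated Gaussian number distribution."""
    if rel_sigma == 0.0:
        return np.array([mean]), np.array([1.0])
    sigma = rel_sigma * mean
    x, w = ff._gauss_legendre(n, -3.0, 3.0)
    weights = w * np.exp(-x**2 / 2.0)
    weights /= weights.sum()
    return mean + sigma * x, weights


class VesicleModel(AssemblyModel):
    name = "vesicle3"

    def __init__(self, params: VesicleParams, solvent_sld: float = 9.41e-6):
        params.validate()
        self.params = params
        self.solvent_sld = solvent_sld
        self._number_density = params.number_density
        self._background = params.background

    def _profile(self, radius: float) -> ff.ShellProfile:
        p = self.params
        r_in = radius - p.tail_thickness / 2.0 - p.head_thickness_in
        b = (
            r_in,
            r_in + p.head_thickness_in,
            r_in + p.head_thickness_in + p.tail_thickness,
            r_in + p.head_thickness_in + p.tail_thickness + p.head_thickness_out,
        )
        slds = (self.solvent_sld, p.sld_head, p.sld_tail, p.sld_head)
        return ff.ShellProfile(b, slds, self.solvent_sld)

    def _unilamellar_sq(self, q) -> np.ndarray:
        p = self.params
        radii, w = _gaussian_radius_nodes(p.mean_radius, p.radius_polydispersity)
        total = np.zeros_like(np.atleast_1d(np.asarray(q, dtype=float)))
        for r, wi in zip(radii, w):
            if r - p.tail_thickness / 2.0 - p.head_thickness_in <= 0:
                continue
            total += wi * ff.shell_amplitude(q, self._profile(r)) ** 2
        return total

    def mean_sq_amplitude(self, q) -> np.ndarray:
        p = self.params
        uni = self._unilamellar_sq(q)
        if p.f_multilamellar == 0.0:
            return uni
        s_ml = multilamellar_structure_factor(q, p.n_layers, p.d_spacing,
                                              p.displacement_sigma)
        return (1.0 - p.f_multilamellar) * uni + p.f_multilamellar * uni * s_ml

    def total_excess_scattering(self) -> float:
        return self._profile(self.params.mean_radius).total_excess_scattering()

    def bilayer_volume(self) -> float:
        """Volume of one bilayer (heads + tails) at the mean radius, A^3."""
        prof = self._profile(self.params.mean_radius)
        return 4.0 / 3.0 * np.pi * (prof.boundaries[-1] ** 3 - prof.boundaries[0] ** 3)

    @classmethod
    def from_ledger(cls, ledger: CompositionLedger, lipid: str,
                    params: VesicleParams | None = None,
                    detergent: str | None = None,
                    detergent_mole_fraction: float = 0.0) -> "VesicleModel":
        """Build with SLDs and per-particle composition from the ledger."""
        p = params or VesicleParams()
        sp = ledger.species[lipid]
        p.sld_head = sp.sld_head
        p.sld_tail = sp.sld_tail
        model = cls(p, ledger.solvent_sld)
        v_per_amphiphile = sp.volume
        x = detergent_mole_fraction
        if detergent is not None and x > 0:
            v_det = ledger.species[detergent].volume
            v_per_amphiphile = (1 - x) * sp.volume + x * v_det
            model.detergents_per_particle = (
                model.bilayer_volume() / v_per_amphiphile * x
            )
        model.lipids_per_particle = model.bilayer_volume() / v_per_amphiphile * (1 - x)
        return model


class AsymmetricVesicleModel(VesicleModel):
    """Four-shell vesicle; leaflet SLDs recomputed from x_in / x_out."""

    name = "vesicle4_asym"

    def __init__(self, params: AsymmetricBilayerParams, solvent_sld: float = 9.41e-6):
        params.validate()
        self.params = params
        self.solvent_sld = solvent_sld
        self._number_density = params.number_density
        self._background = params.background

    def _profile(self, radius: float) -> ff.ShellProfile:
        p = self.params
        head_in, tail_in = p.leaflet_slds(p.x_in)
        head_out, tail_out = p.leaflet_slds(p.x_out)
        r_in = radius - p.tail_thickness / 2.0 - p.head_thickness_in
        b = (
            r_in,
            r_in + p.head_thickness_in,
            radius,
            radius + p.tail_thickness / 2.0,
            radius + p.tail_thickness / 2.0 + p.head_thickness_out,
        )
        slds = (self.solvent_sld, head_in, tail_in, tail_out, head_out)
        return ff.ShellProfile(b, slds, self.solvent_sld)

    @classmethod
    def from_ledger(cls, ledger: CompositionLedger, lipid: str, detergent: str,
                    params: AsymmetricBilayerParams | None = None
                    ) -> "AsymmetricVesicleModel":
        p = params or AsymmetricBilayerParams()
        lip, det = ledger.species[lipid], ledger.species[detergent]
        p.sld_head_lipid, p.sld_tail_lipid = lip.sld_head, lip.sld_tail
        p.sld_head_detergent, p.sld_tail_detergent = det.sld_head, det.sld_tail
        p.v_head_lipid, p.v_tail_lipid = lip.volume_head, lip.volume_tail
        p.v_head_detergent, p.v_tail_detergent = det.volume_head, det.volume_tail
        model = cls(p, ledger.solvent_sld)
        x_mean = (p.x_in + p.x_out) / 2.0
        v_mean = (1 - x_mean) * lip.volume + x_mean * det.volume
        n_amphiphiles = model.bilayer_volume() / v_mean
        model.lipids_per_particle = n_amphiphiles * (1 - x_mean)
        model.detergents_per_particle = n_amphiphiles * x_mean
        return model


class MicelleModel(AssemblyModel):
    def __init__(self, params: MicelleParams, solvent_sld: float = 9.41e-6):
        params.validate()
        self.params = params
        self.solvent_sld = solvent_sld
        self.name = {
            "ellipsoid_revolution": "micelle_sds",
            "triaxial": "micelle_ddm",
            "fuzzy_sphere": "micelle_tx100",
        }[params.shape]
        self._number_density = params.number_density
        self._background = params.background

    def _form_moments(self, q):
        """(<A^2>, <A>) of the bare micelle form factor."""
        p = self.params
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if p.shape == "fuzzy_sphere":
            rc = p.core_a
            ro = rc + p.shell_thickness
            vc = 4.0 / 3.0 * np.pi * rc**3
            vo = 4.0 / 3.0 * np.pi * ro**3
            smear = np.exp(-(q**2) * p.fuzziness_sigma**2 / 2.0)
            amp = (p.sld_core - p.sld_shell) * vc * ff.sphere_volume_kernel(q * rc) + (
                p.sld_shell - self.solvent_sld
            ) * vo * ff.sphere_volume_kernel(q * ro) * smear
            return amp**2, amp
        t = p.shell_thickness
        layers = [
            ((p.core_a, p.core_b, p.core_c), p.sld_core),
            ((p.core_a + t, p.core_b + t, p.core_c + t), p.sld_shell),
        ]
        return ff.ellipsoid_orientavg_intensity(
            q, layers, self.solvent_sld, return_mean_amplitude=True
        )

    def mean_sq_amplitude(self, q) -> np.ndarray:
        p = self.params
        mean_sq, mean_amp = self._form_moments(q)
        if p.hs_volume_fraction == 0.0:
            return mean_sq
        s_py = py_hard_sphere_sq(q, p.hs_radius, p.hs_volume_fraction)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(mean_sq > 0, mean_amp**2 / mean_sq, 1.0)
        return mean_sq * effective_structure_factor(s_py, beta)

    def total_excess_scattering(self) -> float:
        p = self.params
        t = p.shell_thickness
        vc = 4.0 / 3.0 * np.pi * p.core_a * p.core_b * p.core_c
        vo = 4.0 / 3.0 * np.pi * (p.core_a + t) * (p.core_b + t) * (p.core_c + t)
        return (p.sld_core - self.solvent_sld) * vc + (
            p.sld_shell - self.solvent_sld
        ) * (vo - vc)

    @classmethod
    def from_ledger(cls, ledger: CompositionLedger, detergent: str,
                    params: MicelleParams | None = None) -> "MicelleModel":
        """Core = tails, shell = hydrated heads; aggregation number from the
        core volume over the tail volume.  tail_in_shell_fraction moves that
        share of tail material (volume and electrons) into the shell."""
        p = params or MicelleParams()
        det = ledger.species[detergent]
        f = p.tail_in_shell_fraction
        vc = 4.0 / 3.0 * np.pi * p.core_a * p.core_b * p.core_c
        n_agg = vc / ((1.0 - f) * det.volume_tail) if f < 1.0 else 0.0
        p.aggregation_number = n_agg
        p.sld_core = det.sld_tail
        t = p.shell_thickness
        v_shell = (
            4.0 / 3.0 * np.pi * (p.core_a + t) * (p.core_b + t) * (p.core_c + t) - vc
        )
        # shell = heads + tail share + hydration water
        e_shell = n_agg * (det.n_electrons_head + f * det.n_electrons_tail)
        v_dry = n_agg * (det.volume_head + f * det.volume_tail)
        v_water = max(v_shell - v_dry, 0.0)
        e_water = v_water * ledger.solvent_electron_density
        from .composition import xray_sld

        p.sld_shell = xray_sld(e_shell + e_water, v_shell)
        model = cls(p, ledger.solvent_sld)
        model.detergents_per_particle = n_agg
        model.lipids_per_particle = 0.0
        return model


class BicelleModel(AssemblyModel):
    name = "bicelle"

    def __init__(self, params: BicelleParams, solvent_sld: float = 9.41e-6):
        params.validate()
        self.params = params
        self.solvent_sld = solvent_sld
        self._number_density = params.number_density
        self._background = params.background

    def mean_sq_amplitude(self, q) -> np.ndarray:
        p = self.params
        return ff.disc_orientavg_intensity(
            q, p.core_radius, p.rim_thickness, p.half_height, p.face_thickness,
            p.sld_core, p.sld_face, p.sld_rim, self.solvent_sld,
        )

    def total_excess_scattering(self) -> float:
        p = self.params
        h = p.half_height + p.face_thickness
        v_core = 2.0 * np.pi * p.core_radius**2 * p.half_height
        v_face = 2.0 * np.pi * p.core_radius**2 * h - v_core
        v_rim = 2.0 * np.pi * ((p.core_radius + p.rim_thickness) ** 2 - p.core_radius**2) * h
        s = self.solvent_sld
        return (
            (p.sld_core - s) * v_core + (p.sld_face - s) * v_face + (p.sld_rim - s) * v_rim
        )

    @classmethod
    def from_ledger(cls, ledger: CompositionLedger, lipid: str, detergent: str,
                    params: BicelleParams | None = None) -> "BicelleModel":
        """Lipid fills core (tails) and faces (heads); the rim mixes
        detergent at `rim_detergent_fraction` with lipid."""
        p = params or BicelleParams()
        lip, det = ledger.species[lipid], ledger.species[detergent]
        p.sld_core = lip.sld_tail
        p.sld_face = lip.sld_head
        p.sld_rim = mixed_sld(lip.sld_mean, lip.volume, p.rim_detergent_fraction,
                              det.sld_mean, det.volume)
        model = cls(p, ledger.solvent_sld)
        v_core = 2.0 * np.pi * p.core_radius**2 * p.half_height
        n_lip = v_core / lip.volume_tail
        h = p.half_height + p.face_thickness
        v_rim = 2.0 * np.pi * ((p.core_radius + p.rim_thickness) ** 2 - p.core_radius**2) * h
        x = p.rim_detergent_fraction
        v_mix = (1 - x) * lip.volume + x * det.volume
        n_rim = v_rim / v_mix if v_mix > 0 else 0.0
        model.lipids_per_particle = n_lip + n_rim * (1 - x)
        model.detergents_per_particle = n_rim * x
        return model


class WormModel(AssemblyModel):
    name = "worm"

    def __init__(self, params: WormParams, solvent_sld: float = 9.41e-6):
        params.validate()
        self.params = params
        self.solvent_sld = solvent_sld
        if params.kuhn_length >= params.contour_length:
            self.name = "rod"
        self._number_density = params.number_density
        self._background = params.background

    def mean_sq_amplitude(self, q) -> np.ndarray:
        p = self.params
        radii = [p.core_radius]
        slds = [p.sld_core]
        if p.shell_thickness > 0:
            radii.append(p.core_radius + p.shell_thickness)
            slds.append(p.sld_shell)
        return ff.flexible_rod_intensity(
            q, p.contour_length, p.kuhn_length, radii, slds, self.solvent_sld
        )

    def total_excess_scattering(self) -> float:
        p = self.params
        s = self.solvent_sld
        a_core = np.pi * p.core_radius**2
        a_out = np.pi * (p.core_radius + p.shell_thickness) ** 2
        return ((p.sld_core - s) * a_core + (p.sld_shell - s) * (a_out - a_core)) * p.contour_length

    @classmethod
    def from_ledger(cls, ledger: CompositionLedger, lipid: str, detergent: str,
                    params: WormParams | None = None,
                    detergent_mole_fraction: float = 0.5) -> "WormModel":
        p = params or WormParams()
        lip, det = ledger.species[lipid], ledger.species[detergent]
        x = detergent_mole_fraction
        p.sld_core = mixed_sld(lip.sld_tail, lip.volume_tail, x, det.sld_tail,
                               det.volume_tail)
        p.sld_shell = mixed_sld(lip.sld_head, lip.volume_head, x, det.sld_head,
                                det.volume_head)
        model = cls(p, ledger.solvent_sld)
        v_core = np.pi * p.core_radius**2 * p.contour_length
        v_tail_mix = (1 - x) * lip.volume_tail + x * det.volume_tail
        n_amph = v_core / v_tail_mix
        model.lipids_per_particle = n_amph * (1 - x)
        model.detergents_per_particle = n_amph * x
        return model


# ---------------------------------------------------------------------------
# Spec-style operation wrappers


def vesicle_intensity(params: VesicleParams, ledger: CompositionLedger,
                      qgrid) -> ScatteringCurve:
    """Three-shell (multi)lamellar vesicle I(Q) in absolute units."""
    return VesicleModel(params, ledger.solvent_sld).intensity(qgrid)


def asymmetric_vesicle_intensity(params: AsymmetricBilayerParams,
                                 ledger: CompositionLedger, qgrid) -> ScatteringCurve:
    """Four-shell vesicle with leaflet-resolved detergent content."""
    return AsymmetricVesicleModel(params, ledger.solvent_sld).intensity(qgrid)


def micelle_intensity(params: MicelleParams, ledger: CompositionLedger,
                      qgrid) -> ScatteringCurve:
    """Core-shell micelle with PY hard-sphere repulsion (decoupling)."""
    return MicelleModel(params, ledger.solvent_sld).intensity(qgrid)


def bicelle_intensity(params: BicelleParams, ledger: CompositionLedger,
                      qgrid) -> ScatteringCurve:
    """Core-shell disc with a detergent-rich rim."""
    return BicelleModel(params, ledger.solvent_sld).intensity(qgrid)


# ---------------------------------------------------------------------------
# Flat-parameter registry for fitting and the CLI


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: a flat-parameter evaluator plus fit defaults.

    `defaults` maps parameter name -> (value, min, max, vary).
    """

    name: str
    evaluate: object  # callable(q, **params) -> intensity array [1/cm]
    defaults: dict
    n_varied: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_varied", sum(1 for v in self.defaults.values() if v[3]))


def _vesicle3_eval(q, mean_radius, radius_polydispersity, tail_thickness,
                   head_thickness, sld_head, sld_tail, sld_solvent, f_ml,
                   n_layers, d_spacing, displacement_sigma, log10_nd, background):
    p = VesicleParams(
        mean_radius=mean_radius, radius_polydispersity=radius_polydispersity,
        head_thickness_in=head_thickness, head_thickness_out=head_thickness,
        tail_thickness=tail_thickness, sld_head=sld_head, sld_tail=sld_tail,
        f_multilamellar=f_ml, n_layers=int(round(n_layers)), d_spacing=d_spacing,
        displacement_sigma=displacement_sigma, number_density=10.0**log10_nd,
        background=background,
    )
    return VesicleModel(p, sld_solvent).intensity(q).intensity


def _micelle_eval(shape):
    def evaluate(q, core_a, core_b, core_c, shell_thickness, fuzziness_sigma,
                 sld_core, sld_shell, sld_solvent, hs_volume_fraction, hs_radius,
                 log10_nd, background):
        p = MicelleParams(
            shape=shape, core_a=core_a, core_b=core_b, core_c=core_c,
            shell_thickness=shell_thickness, fuzziness_sigma=fuzziness_sigma,
            sld_core=sld_core, sld_shell=sld_shell,
            hs_volume_fraction=hs_volume_fraction, hs_radius=hs_radius,
            number_density=10.0**log10_nd, background=background,
        )
        return MicelleModel(p, sld_solvent).intensity(q).intensity

    return evaluate


def _bicelle_eval(q, core_radius, half_height, face_thickness, rim_thickness,
                  sld_core, sld_face, sld_rim, sld_solvent, log10_nd, background):
    p = BicelleParams(
        core_radius=core_radius, half_height=half_height,
        face_thickness=face_thickness, rim_thickness=rim_thickness,
        sld_core=sld_core, sld_face=sld_face, sld_rim=sld_rim,
        number_density=10.0**log10_nd, background=background,
    )
    return BicelleModel(p, sld_solvent).intensity(q).intensity


def _worm_eval(q, contour_length, kuhn_length, core_radius, shell_thickness,
               sld_core, sld_shell, sld_solvent, log10_nd, background):
    p = WormParams(
        contour_length=contour_length, kuhn_length=kuhn_length,
        core_radius=core_radius, shell_thickness=shell_thickness,
        sld_core=sld_core, sld_shell=sld_shell, number_density=10.0**log10_nd,
        background=background,
    )
    return WormModel(p, sld_solvent).intensity(q).intensity


def _asym_vesicle_eval(q, mean_radius, radius_polydispersity, tail_thickness,
                       head_thickness, x_in, x_out, sld_head_lipid,
                       sld_tail_lipid, sld_head_det, sld_tail_det, v_head_lipid,
                       v_tail_lipid, v_head_det, v_tail_det, sld_solvent,
                       log10_nd, background):
    p = AsymmetricBilayerParams(
        mean_radius=mean_radius, radius_polydispersity=radius_polydispersity,
        head_thickness_in=head_thickness, head_thickness_out=head_thickness,
        tail_thickness=tail_thickness, x_in=x_in, x_out=x_out,
        sld_head_lipid=sld_head_lipid, sld_tail_lipid=sld_tail_lipid,
        sld_head_detergent=sld_head_det, sld_tail_detergent=sld_tail_det,
        v_head_lipid=v_head_lipid, v_tail_lipid=v_tail_lipid,
        v_head_detergent=v_head_det, v_tail_detergent=v_tail_det,
        number_density=10.0**log10_nd, background=background,
    )
    return AsymmetricVesicleModel(p, sld_solvent).intensity(q).intensity


_W = 9.41e-6  # water SLD, fixed default for registry entries

MODEL_REGISTRY: dict[str, ModelSpec] = {}


def _register(name, evaluate, defaults):
    MODEL_REGISTRY[name] = ModelSpec(name, evaluate, defaults)


_vesicle_defaults = {
    "mean_radius": (250.0, 120.0, 600.0, True),
    "radius_polydispersity": (0.25, 0.05, 0.45, False),
    "tail_thickness": (30.0, 15.0, 45.0, True),
    "head_thickness": (6.0, 3.0, 12.0, False),
    "sld_head": (1.44e-5, 1.0e-5, 1.8e-5, False),
    "sld_tail": (8.2e-6, 6.5e-6, 9.3e-6, False),
    "sld_solvent": (_W, _W, _W, False),
    "f_ml": (0.0, 0.0, 1.0, False),
    "n_layers": (1.0, 1.0, 12.0, False),
    "d_spacing": (65.0, 45.0, 120.0, False),
    "displacement_sigma": (6.0, 1.0, 20.0, False),
    "log10_nd": (13.0, 9.0, 16.0, True),
    "background": (0.0, -0.01, 0.1, False),
}

_register("vesicle3", _vesicle3_eval, _vesicle_defaults)
_register(
    "mlv",
    _vesicle3_eval,
    {**_vesicle_defaults, "f_ml": (0.25, 0.0, 1.0, True),
     "n_layers": (4.0, 1.0, 12.0, False), "d_spacing": (65.0, 45.0, 120.0, True)},
)
_register(
    "micelle_sds",
    _micelle_eval("ellipsoid_revolution"),
    {
        "core_a": (16.0, 8.0, 30.0, True),
        "core_b": (16.0, 8.0, 30.0, False),
        "core_c": (24.0, 8.0, 60.0, True),
        "shell_thickness": (6.0, 3.0, 12.0, False),
        "fuzziness_sigma": (0.0, 0.0, 0.0, False),
        "sld_core": (7.8e-6, 7.0e-6, 8.5e-6, False),
        "sld_shell": (1.5e-5, 1.0e-5, 2.2e-5, False),
        "sld_solvent": (_W, _W, _W, False),
        "hs_volume_fraction": (0.02, 0.0, 0.4, True),
        "hs_radius": (25.0, 10.0, 60.0, False),
        "log10_nd": (17.0, 14.0, 19.0, True),
        "background": (0.0, -0.01, 0.1, False),
    },
)
_register(
    "micelle_ddm",
    _micelle_eval("triaxial"),
    {
        "core_a": (14.0, 8.0, 30.0, True),
        "core_b": (20.0, 8.0, 40.0, True),
        "core_c": (28.0, 10.0, 60.0, True),
        "shell_thickness": (7.0, 3.0, 14.0, False),
        "fuzziness_sigma": (0.0, 0.0, 0.0, False),
        "sld_core": (7.8e-6, 7.0e-6, 8.5e-6, False),
        "sld_shell": (1.3e-5, 1.0e-5, 2.2e-5, False),
        "sld_solvent": (_W, _W, _W, False),
        "hs_volume_fraction": (0.0, 0.0, 0.4, False),
        "hs_radius": (30.0, 10.0, 60.0, False),
        "log10_nd": (16.5, 14.0, 19.0, True),
        "background": (0.0, -0.01, 0.1, False),
    },
)
_register(
    "micelle_tx100",
    _micelle_eval("fuzzy_sphere"),
    {
        "core_a": (25.0, 12.0, 45.0, True),
        "core_b": (25.0, 12.0, 45.0, False),
        "core_c": (25.0, 12.0, 45.0, False),
        "shell_thickness": (12.0, 5.0, 25.0, True),
        "fuzziness_sigma": (5.0, 0.0, 15.0, True),
        "sld_core": (8.4e-6, 7.5e-6, 9.2e-6, False),
        "sld_shell": (1.15e-5, 1.0e-5, 1.6e-5, False),
        "sld_solvent": (_W, _W, _W, False),
        "hs_volume_fraction": (0.0, 0.0, 0.4, False),
        "hs_radius": (35.0, 15.0, 70.0, False),
        "log10_nd": (16.0, 13.0, 19.0, True),
        "background": (0.0, -0.01, 0.1, False),
    },
)
_register(
    "bicelle",
    _bicelle_eval,
    {
        "core_radius": (40.0, 10.0, 150.0, True),
        "half_height": (13.0, 6.0, 22.0, True),
        "face_thickness": (6.0, 3.0, 12.0, False),
        "rim_thickness": (12.0, 0.0, 30.0, True),
        "sld_core": (8.2e-6, 6.5e-6, 9.3e-6, False),
        "sld_face": (1.44e-5, 1.0e-5, 1.8e-5, False),
        "sld_rim": (1.1e-5, 9.5e-6, 1.6e-5, False),
        "sld_solvent": (_W, _W, _W, False),
        "log10_nd": (15.0, 12.0, 18.0, True),
        "background": (0.0, -0.01, 0.1, False),
    },
)
_worm_defaults = {
    "contour_length": (800.0, 100.0, 3000.0, True),
    "kuhn_length": (200.0, 50.0, 3000.0, True),
    "core_radius": (15.0, 8.0, 30.0, True),
    "shell_thickness": (8.0, 3.0, 15.0, False),
    "sld_core": (7.8e-6, 7.0e-6, 8.7e-6, False),
    "sld_shell": (1.4e-5, 1.0e-5, 2.0e-5, False),
    "sld_solvent": (_W, _W, _W, False),
    "log10_nd": (13.0, 10.0, 16.0, True),
    "background": (0.0, -0.01, 0.1, False),
}
_register("worm", _worm_eval, _worm_defaults)
_register(
    "rod",
    _worm_eval,
    {**_worm_defaults, "contour_length": (400.0, 50.0, 2000.0, True),
     "kuhn_length": (5000.0, 5000.0, 5000.0, False)},
)
_register(
    "vesicle4_asym",
    _asym_vesicle_eval,
    {
        "mean_radius": (250.0, 120.0, 600.0, True),
        "radius_polydispersity": (0.25, 0.05, 0.45, False),
        "tail_thickness": (30.0, 15.0, 45.0, True),
        "head_thickness": (6.0, 3.0, 12.0, False),
        "x_in": (0.05, 0.0, 1.0, True),
        "x_out": (0.30, 0.0, 1.0, True),
        "sld_head_lipid": (1.44e-5, 1.0e-5, 1.8e-5, False),
        "sld_tail_lipid": (8.2e-6, 6.5e-6, 9.3e-6, False),
        "sld_head_det": (1.46e-5, 1.0e-5, 1.8e-5, False),
        "sld_tail_det": (7.8e-6, 6.5e-6, 9.3e-6, False),
        "v_head_lipid": (319.0, 319.0, 319.0, False),
        "v_tail_lipid": (825.0, 825.0, 825.0, False),
        "v_head_det": (350.0, 350.0, 350.0, False),
        "v_tail_det": (350.0, 350.0, 350.0, False),
        "sld_solvent": (_W, _W, _W, False),
        "log10_nd": (13.0, 9.0, 16.0, True),
        "background": (0.0, -0.01, 0.1, False),
    },
)
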