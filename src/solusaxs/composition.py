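"""Composition bookkeeping: concentrations, molecular volumes, contrasts.

Every scattering model in the package draws its X-ray contrast from a
:class:`CompositionLedger` that records which amphiphiles are present, at
what mass concentration, and with what per-molecule head/tail volumes and
electron counts.  Electron densities are converted to scattering length
densities (SLD) with the Thomson scattering length of the electron.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import yaml

#: Thomson scattering length of the electron, in Angstrom.
R_E = 2.818e-5
#: Avogadro's number, 1/mol.
N_A = 6.02214076e23
#: Electron density of water at ambient conditions, e/A^3.
WATER_ELECTRON_DENSITY = 0.334


def mass_to_molar(c_mass: float, mw: float) -> float:
    """Convert a mass concentration [mg/mL] to a molar one [mM].

    Parameters
    ----------
    c_mass : mass concentration in mg/mL (g/L).
    mw : molecular weight in g/mol.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if c_mass < 0:
        raise ValueError(f"mass concentration must be non-negative, got {c_mass}")
    return c_mass / mw * 1000.0


def molar_to_mass(c_molar: float, mw: float) -> float:
    """Convert a molar concentration [mM] to mass [mg/mL]; inverse of
    :func:`mass_to_molar`."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return c_molar * mw / 1000.0


def detergent_per_lipid(mass_ratio: float, mw_lipid: float, mw_detergent: float) -> float:
    """Detergent molecules per lipid molecule at a given w/w detergent:lipid
    mass ratio."""
    if mass_ratio <= 0 or mw_lipid <= 0 or mw_detergent <= 0:
        raise ValueError("mass_ratio and molecular weights must be positive")
    return mass_ratio * mw_lipid / mw_detergent


def apparent_molecular_volume(
    density_solution: float,
    density_solvent: float,
    c_mass: float,
    mw: float,
) -> float:
    """Apparent per-molecule volume [A^3] from densitometry.

    The apparent specific volume of the solute is

        v_bar = (1 - (rho_sol - rho_solv)/c) / rho_solv      [mL/g]

    with the mass concentration ``c`` in g/mL, then scaled per molecule via
    mw/N_A and converted from cm^3 to A^3.
    """
    if density_solution <= 0 or density_solvent <= 0:
        raise ValueError("densities must be positive")
    if c_mass <= 0:
        raise ValueError("apparent volume undefined at zero concentration")
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    c = c_mass / 1000.0  # mg/mL -> g/mL
    v_bar = (1.0 - (density_solution - density_solvent) / c) / density_solvent
    return v_bar * mw / N_A * 1e24


def xray_sld(n_electrons: float, volume: float) -> float:
    """X-ray scattering length density [1/A^2] of `n_electrons` electrons in
    `volume` A^3."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return R_E * n_electrons / volume


def electron_density_to_sld(rho_e: float) -> float:
    """e/A^3 -> 1/A^2."""
    return R_E * rho_e


@dataclass(frozen=True)
class Species:
    """One amphiphile: identity, molecular weight and head/tail partition.

    Volumes default to ambient (20 C) values; temperature dependence enters
    by overriding them per sample (see :meth:`with_volumes`).
    """

    name: str
    molecular_weight: float  # g/mol
    n_electrons_head: int
    n_electrons_tail: int
    volume_head: float  # A^3
    volume_tail: float  # A^3
    cmc: float | None = None  # mg/mL; None for lipids

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.volume_head <= 0 or self.volume_tail <= 0:
            raise ValueError("volumes must be positive")
        if (
            self.n_electrons_head <= 0
            or self.n_electrons_tail <= 0
            or self.n_electrons_head != int(self.n_electrons_head)
            or self.n_electrons_tail != int(self.n_electrons_tail)
        ):
            raise ValueError("electron counts must be positive integers")

    @property
    def n_electrons(self) -> int:
        return self.n_electrons_head + self.n_electrons_tail

    @property
    def volume(self) -> float:
        return self.volume_head + self.volume_tail

    @property
    def sld_head(self) -> float:
        return xray_sld(self.n_electrons_head, self.volume_head)

    @property
    def sld_tail(self) -> float:
        return xray_sld(self.n_electrons_tail, self.volume_tail)

    @property
    def sld_mean(self) -> float:
        return xray_sld(self.n_electrons, self.volume)

    def with_volumes(self, volume_head: float | None = None,
                     volume_tail: float | None = None) -> "Species":
        """Copy with overridden (e.g. per-temperature) molecular volumes."""
        return replace(
            self,
            volume_head=self.volume_head if volume_head is None else volume_head,
            volume_tail=self.volume_tail if volume_tail is None else volume_tail,
        )


# Built-in amphiphiles.  Molecular weights are the values that reproduce the
# standard mass<->molar arithmetic for these compounds (TX-100 is
# polydisperse in ethoxylation and is carried as a monodisperse average).
# Head/tail electron partition for PC lipids: phosphocholine + glycerol +
# carbonyls = head, acyl chains = tail.  Volumes are ambient defaults.
SPECIES: dict[str, Species] = {
    "DPPC": Species("DPPC", 734.05, 164, 242, 319.0, 825.0),
    "DMPC": Species("DMPC", 677.93, 164, 210, 319.0, 722.0),
    "SDS": Species("SDS", 288.38, 59, 97, 62.0, 350.0, cmc=0.7),
    "DDM": Species("DDM", 510.62, 181, 97, 350.0, 350.0, cmc=0.08),
    "TX100": Species("TX100", 625.0, 237, 105, 670.0, 300.0, cmc=0.3),
}


@dataclass
class CompositionLedger:
    """Per-sample record of species and mass concentrations.

    All model contrasts are derived from this object: molar concentrations,
    aggregate-forming concentrations (above the CMC), volume fractions and
    scattering-length densities.
    """

    species: dict[str, Species]
    mass_concentration: dict[str, float]  # mg/mL per species name
    temperature: float = 20.0  # Celsius
    solvent_electron_density: float = WATER_ELECTRON_DENSITY  # e/A^3

    def __post_init__(self):
        for name, c in self.mass_concentration.items():
            if name not in self.species:
                raise KeyError(f"concentration given for unknown species {name!r}")
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")

    @classmethod
    def from_names(cls, concentrations: dict[str, float], temperature: float = 20.0,
                   **kw) -> "CompositionLedger":
        """Build from built-in species names and mg/mL concentrations."""
        sp = {n: SPECIES[n] for n in concentrations}
        return cls(sp, dict(concentrations), temperature, **kw)

    @property
    def solvent_sld(self) -> float:
        return electron_density_to_sld(self.solvent_electron_density)

    def molar(self, name: str) -> float:
        """Molar concentration of one species, mM."""
        return mass_to_molar(self.mass_concentration[name], self.species[name].molecular_weight)

    def number_concentration(self, name: str) -> float:
        """Molecules per cm^3 of one species."""
        return self.molar(name) * 1e-3 * N_A / 1000.0

    def aggregate_mass_concentration(self, name: str) -> float:
        """Mass concentration available for aggregates, mg/mL.

        Free monomer below the CMC is scattering-silent; the
        aggregate-forming concentration is max(0, c - cmc).
        """
        sp = self.species[name]
        c = self.mass_concentration[name]
        if sp.cmc is None:
            return c
        return max(0.0, c - sp.cmc)

    def aggregate_number_concentration(self, name: str) -> float:
        """Aggregate-forming molecules per cm^3 (above-CMC fraction)."""
        c = self.aggregate_mass_concentration(name)
        return mass_to_molar(c, self.species[name].molecular_weight) * 1e-3 * N_A / 1000.0

    def sld(self, name: str, part: str = "mean") -> float:
        """SLD of a species region: part in {'head', 'tail', 'mean'}."""
        sp = self.species[name]
        return {"head": sp.sld_head, "tail": sp.sld_tail, "mean": sp.sld_mean}[part]

    def contrast(self, name: str, part: str = "mean") -> float:
        return self.sld(name, part) - self.solvent_sld

    def molar_ratio(self, detergent: str, lipid: str) -> float:
        """Detergent:lipid molar ratio (the x-axis of phase maps)."""
        m_lip = self.molar(lipid)
        if m_lip == 0:
            raise ZeroDivisionError("no lipid in ledger")
        return self.molar(detergent) / m_lip


def mixed_sld(sld_a: float, volume_a: float, x_b: float, sld_b: float,
              volume_b: float) -> float:
    """Volume-fraction-weighted SLD of a two-component region.

    `x_b` is the mole fraction of component b; the volume fraction follows
    from the per-molecule region volumes.
    """
    if not 0.0 <= x_b <= 1.0:
        raise ValueError(f"mole fraction outside [0, 1]: {x_b}")
    vb = x_b * volume_b
    va = (1.0 - x_b) * volume_a
    if va + vb == 0:
        return sld_a
    phi_b = vb / (va + vb)
    return (1.0 - phi_b) * sld_a + phi_b * sld_b


def ledger_from_config(path) -> CompositionLedger:
    """Read a YAML composition config.

    Layout::

        species:            # optional; overrides/extends the built-ins
          SDS: {mw: 288.38, e_head: 59, e_tail: 97, v_head: 62, v_tail: 350, cmc: 0.7}
        sample:
          temperature: 20
          concentrations: {DPPC: 2.5, SDS: 5.0}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    species = dict(SPECIES)
    for name, blk in (cfg.get("species") or {}).items():
        species[name] = Species(
            name, blk["mw"], blk["e_head"], blk["e_tail"],
            blk["v_head"], blk["v_tail"], blk.get("cmc"),
        )
    sample = cfg["sample"]
    conc = {k: float(v) for k, v in sample["concentrations"].items()}
    return CompositionLedger(
        {n: species[n] for n in conc},
        conc,
        temperature=float(sample.get("temperature", 20.0)),
        solvent_electron_density=float(
            sample.get("solvent_electron_density", WATER_ELECTRON_DENSITY)
        ),
    )
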