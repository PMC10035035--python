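"""Population coexistence and solubilization-kinetics models.

During solubilization several particle populations coexist (e.g. saturated
vesicles with bicelles, or vesicles with pure detergent micelles).  Their
curves add incoherently — uncorrelated particles in dilute solution carry
no cross terms — with each population's number density fixed by the share
of the total lipid/detergent pool assigned to it and its per-particle
composition.  Time series are fitted frame by frame with shared geometry
and a per-frame solubilized fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .composition import CompositionLedger
from .curves import ScatteringCurve
from .models import A2_TO_CM2, AssemblyModel, _as_q


class ConstraintViolation(ValueError):
    """Raised when assigned population fractions break mass conservation."""


@dataclass
class PopulationMixture:
    """Weighted set of assembly models sharing one amphiphile pool.

    populations: list of (model, lipid_fraction, detergent_fraction).
    In 'mass-conserving' mode lipid fractions must sum to 1 and detergent
    fractions to <= 1 (the remainder is free monomer); in 'free' mode the
    fractions are taken at face value.
    """

    populations: list
    mode: str = "mass-conserving"

    def __post_init__(self):
        if self.mode not in ("free", "mass-conserving"):
            raise ValueError(f"unknown constraint mode {self.mode!r}")
        for _, fl, fd in self.populations:
            if not (0.0 <= fl <= 1.0 and 0.0 <= fd <= 1.0):
                raise ConstraintViolation("population fractions must be in [0, 1]")
        if self.mode == "mass-conserving":
            sum_l = sum(fl for _, fl, _ in self.populations)
            sum_d = sum(fd for _, _, fd in self.populations)
            if abs(sum_l - 1.0) > 1e-9:
                raise ConstraintViolation(
                    f"lipid fractions must sum to 1 in mass-conserving mode, got {sum_l}"
                )
            if sum_d > 1.0 + 1e-9:
                raise ConstraintViolation(
                    f"detergent fractions sum to {sum_d} > 1"
                )

    def number_densities(self, ledger: CompositionLedger, lipid: str,
                         detergent: str | None = None) -> list[float]:
        """Per-population particle number densities [1/cm^3]."""
        n_lipid_total = ledger.number_concentration(lipid)
        n_det_total = (
            ledger.aggregate_number_concentration(detergent) if detergent else 0.0
        )
        densities = []
        for model, fl, fd in self.populations:
            if model.lipids_per_particle and model.lipids_per_particle > 0:
                densities.append(fl * n_lipid_total / model.lipids_per_particle)
            elif model.detergents_per_particle and model.detergents_per_particle > 0:
                densities.append(fd * n_det_total / model.detergents_per_particle)
            else:
                raise ConstraintViolation(
                    f"population {model.name!r} has no per-particle composition"
                )
        return densities


def mixture_intensity(mixture: PopulationMixture, ledger: CompositionLedger,
                      qgrid, lipid: str, detergent: str | None = None,
                      background: float = 0.0) -> ScatteringCurve:
    """Incoherent sum of population curves in absolute units."""
    q = _as_q(qgrid)
    densities = mixture.number_densities(ledger, lipid, detergent)
    i_q = np.full_like(q, float(background))
    for (model, _, _), n in zip(mixture.populations, densities):
        i_q = i_q + n * model.mean_sq_amplitude(q) * A2_TO_CM2
    return ScatteringCurve(q, i_q, metadata={
        "model": "+".join(m.name for m, _, _ in mixture.populations)})


# ---------------------------------------------------------------------------
# Trajectories


def solubilized_fraction_trajectory(t, model: str, params: dict) -> np.ndarray:
    """Solubilized lipid fraction f(t) for a named trajectory model.

    models:
      'single_exp'    f = f_end + (f_start - f_end) exp(-k t)
      'stretched_exp' f = f_end + (f_start - f_end) exp(-(k t)^beta)
      'two_stage'     insertion lag of length t_lag (f stays at f_start,
                      the structural ramp), then exponential growth — the
                      slow-insertion-then-solubilization pattern.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    f0, f1 = params["f_start"], params["f_end"]
    if not (0.0 <= f0 <= 1.0 and 0.0 <= f1 <= 1.0):
        raise ValueError("f_start and f_end must be in [0, 1]")
    k = params.get("k", 1.0)
    if k <= 0:
        raise ValueError("rate must be positive")
    if model == "single_exp":
        f = f1 + (f0 - f1) * np.exp(-k * t)
    elif model == "stretched_exp":
        beta = params.get("beta", 0.5)
        if beta <= 0:
            raise ValueError("stretching exponent must be positive")
        f = f1 + (f0 - f1) * np.exp(-((k * t) ** beta))
    elif model == "two_stage":
        t_lag = params.get("t_lag", 0.0)
        if t_lag < 0:
            raise ValueError("lag time cannot be negative")
        f = np.where(t <= t_lag, f0, f1 + (f0 - f1) * np.exp(-k * (t - t_lag)))
    else:
        raise ValueError(f"unknown trajectory model {model!r}")
    return f


@dataclass
class KineticSeries:
    """Time-stamped scattering curves with a trajectory annotation."""

    frames: list  # of (time_s, ScatteringCurve)
    trajectory_model: str = "single_exp"
    trajectory_params: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [t for t, _ in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames])

    def sorted(self) -> "KineticSeries":
        return KineticSeries(sorted(self.frames, key=lambda f: f[0]),
                             self.trajectory_model, dict(self.trajectory_params))


def _frame_chi2(frame: ScatteringCurve, model_curve: np.ndarray) -> float:
    sigma = frame.sigma if frame.sigma is not None else np.maximum(
        0.01 * np.abs(frame.intensity), 1e-12)
    return float(np.sum(((frame.intensity - model_curve) / sigma) ** 2))


def fit_population_fraction(
    curve: ScatteringCurve,
    source_model: AssemblyModel,
    product_model: AssemblyModel,
    ledger: CompositionLedger,
    lipid: str,
    background: float = 0.0,
) -> tuple[float, float]:
    """Best-fit lipid fraction in the product population for one curve.

    Mass-conserving two-population model with fixed geometry; returns
    (fraction, 1-sigma uncertainty from the chi2 curvature).
    """
    q = curve.q
    kern_src = source_model.mean_sq_amplitude(q) * A2_TO_CM2
    kern_prod = product_model.mean_sq_amplitude(q) * A2_TO_CM2
    n_lip = ledger.number_concentration(lipid)
    lp_src = source_model.lipids_per_particle
    lp_prod = product_model.lipids_per_particle
    if not lp_src or not lp_prod:
        raise ValueError("both models need lipids_per_particle set")

    def model_curve(f):
        return ((1.0 - f) * n_lip / lp_src * kern_src
                + f * n_lip / lp_prod * kern_prod + background)

    res = minimize_scalar(lambda f: _frame_chi2(curve, model_curve(f)),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    f_hat = float(res.x)
    h = 1e-3
    lo, hi = max(f_hat - h, 0.0), min(f_hat + h, 1.0)
    c0 = _frame_chi2(curve, model_curve(f_hat))
    c_lo = _frame_chi2(curve, model_curve(lo))
    c_hi = _frame_chi2(curve, model_curve(hi))
    curv = (c_lo + c_hi - 2 * c0) / ((hi - lo) / 2) ** 2
    err = float(np.sqrt(2.0 / curv)) if curv > 0 else np.nan
    return f_hat, err


def fit_kinetic_series(
    series: KineticSeries,
    source_model: AssemblyModel,
    product_model: AssemblyModel,
    ledger: CompositionLedger,
    lipid: str,
    detergent: str | None = None,
    background: float = 0.0,
) -> pd.DataFrame:
    """Fit a per-frame solubilized fraction with shared particle geometry.

    Every frame is modeled as a mass-conserving two-population mixture of
    `source_model` (bilayer) and `product_model` (solubilized) whose
    geometry is held fixed; only the lipid fraction in the product is free
    per frame.  Returns a tidy table (time, fraction, uncertainty, chi2)
    analogous to fraction-vs-time plots from time-resolved runs.

    Frames must share a common Q grid (the kinetic frames of one run).
    """
    if len(series.frames) < 3:
        raise ValueError("need at least 3 frames")
    series = series.sorted()
    q0 = series.frames[0][1].q
    for _, c in series.frames:
        if len(c.q) != len(q0) or not np.allclose(c.q, q0):
            raise ValueError("frames must share one Q grid")

    rows = []
    for t, frame in series.frames:
        f_hat, err = fit_population_fraction(frame, source_model, product_model,
                                             ledger, lipid, background)
        rows.append({"time": t, "fraction": f_hat, "uncertainty": err,
                     "n_points": len(frame)})
    return pd.DataFrame(rows)


def fit_trajectory(times, fractions, model: str = "single_exp",
                   sigma=None) -> dict:
    """Least-squares fit of a named trajectory to a fraction-vs-time table."""
    from scipy.optimize import curve_fit

    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)

    if model == "single_exp":
        def f(t, f0, f1, k):
            return solubilized_fraction_trajectory(
                t, "single_exp", {"f_start": f0, "f_end": f1, "k": k})
        p0 = [fractions[0], fractions[-1], 1.0 / max(times[-1] / 3.0, 1e-9)]
        bounds = ([0, 0, 1e-12], [1, 1, np.inf])
        names = ["f_start", "f_end", "k"]
    elif model == "two_stage":
        def f(t, f0, f1, k, t_lag):
            return solubilized_fraction_trajectory(
                t, "two_stage", {"f_start": f0, "f_end": f1, "k": k, "t_lag": t_lag})
        p0 = [fractions[0], fractions[-1], 1.0 / max(times[-1] / 3.0, 1e-9),
              times[len(times) // 4]]
        bounds = ([0, 0, 1e-12, 0], [1, 1, np.inf, times[-1]])
        names = ["f_start", "f_end", "k", "t_lag"]
    else:
        raise ValueError(f"unknown trajectory model {model!r}")

    popt, _ = curve_fit(f, times, fractions, p0=p0, bounds=bounds,
                        sigma=sigma, maxfev=20000)
    return dict(zip(names, popt))
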