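"""Weighted least-squares fitting and model selection.

Fits are bounded local trust-region least squares (via lmfit's
`least_squares` backend) on sigma-weighted residuals, optionally with a
seeded multi-start to escape shallow local minima.  Model comparison
ranks candidates by chi^2 + 2k (an AIC-like parsimony penalty on the
parameter count) with residual diagnostics per Q region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .curves import ScatteringCurve
from .models import MODEL_REGISTRY, ModelSpec


class ModelEvaluationError(RuntimeError):
    """Non-finite model values encountered during a fit."""


@dataclass
class FitProblem:
    """A curve, a registered model, and the free/fixed parameter layout.

    `overrides` maps parameter name -> (value, min, max, vary) or a bare
    value (keeping the registry's bounds and vary flag).
    """

    curve: ScatteringCurve
    model: str | ModelSpec
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.model, str):
            self.model = MODEL_REGISTRY[self.model]
        if self.curve.sigma is not None and np.any(self.curve.sigma <= 0):
            raise ValueError("sigma must be positive everywhere")

    def make_parameters(self) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for name, (value, lo, hi, vary) in self.model.defaults.items():
            ov = self.overrides.get(name)
            if ov is not None:
                if np.isscalar(ov):
                    value = float(ov)
                else:
                    value, lo, hi, vary = ov
            if vary:
                if not lo <= value <= hi:
                    raise ValueError(f"start value of {name} outside bounds")
                params.add(name, value=value, min=lo, max=hi, vary=True)
            else:
                # fixed parameters carry no active bounds
                params.add(name, value=value, vary=False)
        return params

    @property
    def sigma(self) -> np.ndarray:
        if self.curve.sigma is not None:
            return self.curve.sigma
        return np.maximum(0.01 * np.abs(self.curve.intensity), 1e-12)


@dataclass
class FitResult:
    parameters: dict
    errors: dict
    chi2: float
    reduced_chi2: float
    n_free: int
    n_points: int
    success: bool
    at_bounds: list
    covariance: np.ndarray | None
    score: float  # chi2 + 2k penalty, for model comparison
    model_name: str

    def __repr__(self):
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.parameters.items())
        return (f"FitResult({self.model_name}: redchi={self.reduced_chi2:.3g}, "
                f"{pars})")


def _residual(params, problem: FitProblem):
    values = {k: float(v) for k, v in params.valuesdict().items()}
    model_i = problem.model.evaluate(problem.curve.q, **values)
    if not np.all(np.isfinite(model_i)):
        raise ModelEvaluationError(
            f"model {problem.model.name} returned non-finite intensity at "
            f"parameters {values}"
        )
    return (model_i - problem.curve.intensity) / problem.sigma


def _chi2_profiled_scale(params, problem: FitProblem, profile: bool):
    """chi2 at `params`, optionally with the particle-number scale profiled
    out analytically (the model is linear in 10**log10_nd)."""
    values = {k: float(v) for k, v in params.valuesdict().items()}
    model_i = problem.model.evaluate(problem.curve.q, **values)
    if not np.all(np.isfinite(model_i)):
        return np.inf, 1.0
    sigma = problem.sigma
    data = problem.curve.intensity
    if not profile:
        return float(np.sum(((model_i - data) / sigma) ** 2)), 1.0
    b = values.get("background", 0.0)
    m = (model_i - b) / sigma
    d = (data - b) / sigma
    denom = float(m @ m)
    s = float(m @ d) / denom if denom > 0 else 1.0
    s = max(s, 1e-12)
    return float(np.sum((s * m - d) ** 2)), s


def fit(problem: FitProblem, seed: int = 0, n_starts: int = 1,
        scan: dict | None = None, max_nfev: int | None = None) -> FitResult:
    """Bounded least-squares fit; deterministic given `seed`.

    With n_starts > 1 the start vector is additionally perturbed uniformly
    within +-15% of each free parameter's value (clipped to bounds) and the
    best converged solution is kept.

    `scan` maps parameter names to a grid size: before the local fits each
    named free parameter is scanned over that many equispaced values within
    its bounds (others held at start) and the lowest-chi2 value becomes the
    start — the standard guard against the oscillatory local minima of
    sphere/shell form factors.
    """
    rng = np.random.default_rng(seed)
    base = problem.make_parameters()
    free = [n for n in base if base[n].vary]
    if not free:
        raise ValueError("fit needs at least one free parameter")

    for name, n_grid in (scan or {}).items():
        if name not in free:
            continue
        p = base[name]
        grid = np.linspace(p.min, p.max, int(n_grid))
        chis, scales = [], []
        profile_scale = "log10_nd" in free and name != "log10_nd"
        for val in grid:
            base[name].value = float(val)
            chi2, s = _chi2_profiled_scale(base, problem, profile_scale)
            chis.append(chi2)
            scales.append(s)
        i_best = int(np.argmin(chis))
        base[name].value = float(grid[i_best])
        if profile_scale and scales[i_best] > 0:
            pn = base["log10_nd"]
            pn.value = float(np.clip(pn.value + np.log10(scales[i_best]),
                                     pn.min, pn.max))

    best = None
    for start in range(max(1, n_starts)):
        params = base.copy()
        if start > 0:
            for name in free:
                p = params[name]
                scale = abs(p.value) if p.value != 0 else (p.max - p.min) * 0.1
                p.value = float(np.clip(
                    p.value + rng.uniform(-0.15, 0.15) * scale, p.min, p.max))
        try:
            out = lmfit.minimize(
                _residual, params, args=(problem,), method="least_squares",
                nan_policy="raise", x_scale="jac", diff_step=1e-4,
                max_nfev=max_nfev,
            )
        except ModelEvaluationError:
            raise
        chi2 = float(np.sum(np.asarray(out.residual) ** 2))
        if best is None or chi2 < best[0]:
            best = (chi2, out)
    chi2, out = best

    values = {n: float(out.params[n].value) for n in out.params}
    errors = {
        n: (float(out.params[n].stderr) if out.params[n].stderr else np.nan)
        for n in free
    }
    at_bounds = [
        n for n in free
        if (out.params[n].value - out.params[n].min) < 1e-10 * max(1, abs(out.params[n].min))
        or (out.params[n].max - out.params[n].value) < 1e-10 * max(1, abs(out.params[n].max))
    ]
    n_pts = len(problem.curve)
    dof = max(n_pts - len(free), 1)
    return FitResult(
        parameters=values,
        errors=errors,
        chi2=chi2,
        reduced_chi2=chi2 / dof,
        n_free=len(free),
        n_points=n_pts,
        success=bool(out.success),
        at_bounds=at_bounds,
        covariance=getattr(out, "covar", None),
        score=chi2 + 2.0 * len(free),
        model_name=problem.model.name,
    )


def residual_diagnostics(problem: FitProblem, result: FitResult) -> dict:
    """Mean squared sigma-weighted residual in low/mid/high Q thirds."""
    res = _residual_from_values(problem, result.parameters)
    q = problem.curve.q
    edges = np.quantile(q, [0.0, 1 / 3, 2 / 3, 1.0])
    out = {}
    for lo, hi, label in zip(edges[:-1], edges[1:], ("low_q", "mid_q", "high_q")):
        sel = (q >= lo) & (q <= hi)
        out[label] = float(np.mean(res[sel] ** 2))
    return out


def _residual_from_values(problem: FitProblem, values: dict) -> np.ndarray:
    model_i = problem.model.evaluate(problem.curve.q, **values)
    return (model_i - problem.curve.intensity) / problem.sigma


def compare_models(curve: ScatteringCurve, candidates, seed: int = 0,
                   n_starts: int = 1, max_nfev: int | None = None) -> list:
    """Fit each candidate and rank by penalized score (chi2 + 2k).

    `candidates` is a list of model names, ModelSpecs, or (model, overrides)
    pairs.  Returns a ranked list of dicts; candidates that fail to
    converge are ranked last and flagged.  Exact ties keep submission
    order and are reported via the 'tied_with_next' flag.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    entries = []
    for i, cand in enumerate(candidates):
        if isinstance(cand, tuple):
            model, overrides = cand
        else:
            model, overrides = cand, {}
        problem = FitProblem(curve, model, overrides)
        try:
            result = fit(problem, seed=seed + i, n_starts=n_starts,
                         max_nfev=max_nfev)
            diag = residual_diagnostics(problem, result)
            entries.append({
                "model": problem.model.name, "result": result,
                "score": result.score, "converged": result.success,
                "diagnostics": diag,
            })
        except ModelEvaluationError as err:
            entries.append({
                "model": problem.model.name, "result": None,
                "score": np.inf, "converged": False,
                "diagnostics": {"error": str(err)},
            })
    ranked = sorted(
        range(len(entries)),
        key=lambda i: (not entries[i]["converged"], entries[i]["score"], i),
    )
    out = [entries[i] for i in ranked]
    for a, b in zip(out[:-1], out[1:]):
        a["tied_with_next"] = bool(
            np.isfinite(a["score"]) and abs(a["score"] - b["score"]) < 1e-9
        )
    if out:
        out[-1]["tied_with_next"] = False
    for rank, entry in enumerate(out):
        entry["rank"] = rank
    return out
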