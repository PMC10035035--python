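"""Shared parameter-recovery harness for fixtures with known ground truth.

Used by both the test suite and scripts/acceptance.py: generate a seeded
noisy fixture, refit its own model from a perturbed start, and report the
error of each key dimension against the manifest.
"""

from __future__ import annotations

from solusaxs.fitting import FitProblem, fit
from solusaxs.synthetic import InstrumentEmulation, perturbed_start, scenario_fixtures

# checks: (parameter, 'rel' | 'abs', tolerance)
RECOVERY_CASES = {
    "dppc_vesicles_20C": dict(
        model="mlv", scan={"mean_radius": 33}, n_starts=3,
        checks=[("tail_thickness", "rel", 0.02), ("f_ml", "abs", 0.05),
                ("d_spacing", "rel", 0.05)]),
    "sds_micelles_20C": dict(
        model="micelle_sds", max_nfev=400,
        checks=[("core_a", "rel", 0.05), ("core_c", "rel", 0.05)]),
    "ddm_micelles_20C": dict(
        model="micelle_ddm", max_nfev=400,
        checks=[("core_a", "rel", 0.05), ("core_b", "rel", 0.05),
                ("core_c", "rel", 0.05)]),
    "tx100_micelles_20C": dict(
        model="micelle_tx100",
        checks=[("core_a", "rel", 0.05), ("shell_thickness", "rel", 0.05)]),
    "dmpc_sds_bicelles_20C": dict(
        model="bicelle",
        checks=[("core_radius", "rel", 0.05), ("half_height", "rel", 0.05)]),
    "dmpc_ddm_worms_20C": dict(
        model="worm",
        checks=[("core_radius", "rel", 0.05), ("shell_thickness", "rel", 0.05)]),
    "dppc_ddm_asym_vesicles_20C": dict(
        model="vesicle4_asym", scan={"mean_radius": 33}, n_starts=3,
        checks=[("x_in", "abs", 0.05), ("x_out", "abs", 0.05),
                ("tail_thickness", "rel", 0.02)]),
}


def run_recovery(scenario: str, seed: int, n_points: int = 300) -> dict:
    """Refit one scenario fixture; returns {param: (error, mode, tol)}."""
    case = RECOVERY_CASES[scenario]
    inst = InstrumentEmulation(n_points=n_points)
    fx = scenario_fixtures(scenario, seed, inst)
    truth = fx["manifest"]["truth"]
    start = perturbed_start(case["model"], truth, seed=seed + 17)
    result = fit(
        FitProblem(fx["curve"], case["model"], start),
        seed=seed,
        n_starts=case.get("n_starts", 1),
        scan=case.get("scan"),
        max_nfev=case.get("max_nfev"),
    )
    out = {}
    for name, mode, tol in case["checks"]:
        err = abs(result.parameters[name] - truth[name])
        if mode == "rel":
            err /= abs(truth[name])
        out[name] = (err, mode, tol)
    return out
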