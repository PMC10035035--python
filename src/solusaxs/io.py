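"""Reading/writing 1D SAXS curves and phase-map reporting.

The on-disk dialect is the de facto beamline ``.dat`` format: 2-3
whitespace- or comma-separated numeric columns (Q, I, optional sigma)
with ``#``-prefixed header lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import ScatteringCurve

logger = logging.getLogger(__name__)

#: model-registry labels that count as solubilized micellar units
SOLUBILIZED_LABELS = frozenset({
    "micelle", "micelle_sds", "micelle_ddm", "micelle_tx100",
    "bicelle", "rod", "worm",
})
#: labels with intact bilayer structure.  Large lamellar sheets are
#: bilayer-class: they are not considered solubilized.
BILAYER_LABELS = frozenset({
    "vesicle", "vesicle3", "vesicle4_asym", "mlv", "sheet", "ripple",
})


class CurveFormatError(ValueError):
    """Unparseable curve file; message names the offending line."""


def read_curve(path, units: str = "invA") -> ScatteringCurve:
    """Read a 2/3-column ASCII curve; returns Q in 1/A.

    units='invnm' divides Q by 10 on load.  Rows with NaN, non-positive
    sigma, or non-numeric fields after the header are dropped with a
    logged count.
    """
    if units not in ("invA", "invnm"):
        raise ValueError("units must be 'invA' or 'invnm'")
    rows, header, dropped = [], [], 0
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                header.append(s.lstrip("# "))
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                dropped += 1
                logger.warning("dropping malformed row at %s:%d", path, lineno)
                continue
            if len(vals) < 2:
                raise CurveFormatError(
                    f"{path}:{lineno}: need at least 2 numeric columns"
                )
            if n_cols is None:
                n_cols = min(len(vals), 3)
            rows.append(vals[:3])
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    width = min(len(r) for r in rows)
    data = np.array([r[:width] for r in rows], dtype=float)
    keep = np.isfinite(data).all(axis=1)
    if width >= 3:
        keep &= data[:, 2] > 0
    if (~keep).sum():
        dropped += int((~keep).sum())
        logger.warning("dropped %d invalid rows from %s", int((~keep).sum()), path)
    data = data[keep]
    order = np.argsort(data[:, 0])
    data = data[order]
    q = data[:, 0] / (10.0 if units == "invnm" else 1.0)
    sigma = data[:, 2] if width >= 3 else None
    return ScatteringCurve(q, data[:, 1], sigma,
                           metadata={"header": header, "dropped_rows": dropped})


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write the 3-column (or 2-column) ASCII dialect with # headers."""
    with open(path, "w") as fh:
        fh.write("# Q(1/A)  I(1/cm)" + ("  sigma(1/cm)" if curve.sigma is not None else "") + "\n")
        for key, val in curve.metadata.items():
            if key != "header":
                fh.write(f"# {key}: {val}\n")
        cols = [curve.q, curve.intensity]
        if curve.sigma is not None:
            cols.append(curve.sigma)
        # full round-trip precision: read_curve(write_curve(c)) is bit-equal
        np.savetxt(fh, np.column_stack(cols), fmt="%.17e")


# ---------------------------------------------------------------------------
# Phase maps


@dataclass
class PhaseMapEntry:
    """One fitted sample: composition point plus assigned morphologies.

    `labels` holds the population labels present in the best-fitting model
    (registry vocabulary); a population counts as present only if its
    fitted lipid fraction exceeds 0.05 with its uncertainty excluding 0 —
    callers apply that threshold before constructing the entry.
    """

    lipid: str
    detergent: str
    molar_ratio: float  # detergent:lipid
    temperature: float  # Celsius
    labels: tuple

    def __post_init__(self):
        self.labels = tuple(self.labels)
        known = SOLUBILIZED_LABELS | BILAYER_LABELS
        for lab in self.labels:
            if lab not in known:
                raise ValueError(f"label {lab!r} not in the model registry vocabulary")

    @property
    def has_solubilized(self) -> bool:
        return any(l in SOLUBILIZED_LABELS for l in self.labels)

    @property
    def has_bilayer(self) -> bool:
        return any(l in BILAYER_LABELS for l in self.labels)


def build_phase_map(entries) -> pd.DataFrame:
    """Saturation and solubilization limits per (lipid, detergent, T).

    saturation limit: lowest detergent:lipid molar ratio at which any
    solubilized population coexists with the rest; solubilization limit:
    lowest ratio with no bilayer population left.  When a limit falls
    outside the sampled ratio grid the bound marker records the direction
    ('>' at the top edge, '<=' at the bottom edge); interior limits get '='.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("empty entry set")
    rows = []
    key = lambda e: (e.lipid, e.detergent, e.temperature)
    groups: dict = {}
    for e in entries:
        groups.setdefault(key(e), []).append(e)
    for (lipid, det, temp), group in sorted(groups.items()):
        group = sorted(group, key=lambda e: e.molar_ratio)
        ratios = [e.molar_ratio for e in group]
        sat = next((e.molar_ratio for e in group if e.has_solubilized), None)
        sol = next((e.molar_ratio for e in group if not e.has_bilayer), None)
        if sat is None:
            sat, sat_bound = ratios[-1], ">"
        else:
            sat_bound = "<=" if sat == ratios[0] else "="
        if sol is None:
            sol, sol_bound = ratios[-1], ">"
        else:
            sol_bound = "<=" if sol == ratios[0] else "="
        rows.append({
            "lipid": lipid, "detergent": det, "temperature": temp,
            "saturation_limit": sat, "saturation_bound": sat_bound,
            "solubilization_limit": sol, "solubilization_bound": sol_bound,
        })
    df = pd.DataFrame(rows)
    # by construction saturation <= solubilization on a consistent grid
    return df
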