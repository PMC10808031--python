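"""Nuclear stiffness from microneedle force-deformation measurements.

A nucleus is pressed between a stiff microneedle and a flexible,
stiffness-calibrated one (k_tip in nN/um). Per press cycle, once the
nuclear deformation reaches an equilibrium plateau, the deformation is
the reduction of the nuclear span (um) and the force is the flexible
tip's deflection times k_tip (nN). Stiffness is the slope of the
ordinary least-squares line through the force-deformation points; the
purely nuclear stiffness subtracts the slope measured at a nucleus-free
location (condition "cell only").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ManipulationTrace",
    "ForceDeformationPoints",
    "StiffnessEstimate",
    "extract_points",
    "fit_stiffness",
    "net_stiffness",
]

CONDITIONS = ("nucleus+cell", "cell only")


@dataclass
class ManipulationTrace:
    """A time-lapse micromanipulation record (nominal 0.5 s frames)."""

    time_s: np.ndarray
    tip_disp_um: np.ndarray  # flexible-tip displacement from equilibrium
    span_um: np.ndarray  # nuclear span between opposite sides
    k_tip: float  # calibrated tip stiffness, nN/um
    condition: str = "nucleus+cell"
    cycles: list[tuple[int, int]] = field(default_factory=list)  # press [start, end) frames

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.tip_disp_um = np.asarray(self.tip_disp_um, dtype=float)
        self.span_um = np.asarray(self.span_um, dtype=float)
        if self.k_tip <= 0:
            raise ValueError("k_tip must be positive")
        if not (self.time_s.size == self.tip_disp_um.size == self.span_um.size):
            raise ValueError("trace columns differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @classmethod
    def from_csv(cls, path, cycles=None) -> "ManipulationTrace":
        """Read a trace CSV (columns time_s, tip_disp_um, span_um) whose
        header comments carry ``# k_tip_nN_per_um=..`` and ``# condition=..``;
        cycle frame pairs come from ``cycles`` or ``# cycles=s0-e0;s1-e1``."""
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "=" in line:
                    k, v = line.lstrip("# ").strip().split("=", 1)
                    meta[k] = v
        df = pd.read_csv(path, comment="#")
        if cycles is None and "cycles" in meta:
            cycles = [tuple(map(int, c.split("-"))) for c in meta["cycles"].split(";") if c]
        return cls(
            df["time_s"].to_numpy(), df["tip_disp_um"].to_numpy(),
            df["span_um"].to_numpy(),
            k_tip=float(meta.get("k_tip_nN_per_um", 12.0)),
            condition=meta.get("condition", "nucleus+cell"),
            cycles=list(cycles or []),
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k_tip_nN_per_um={self.k_tip}\n")
            fh.write(f"# condition={self.condition}\n")
            fh.write("# cycles=" + ";".join(f"{s}-{e}" for s, e in self.cycles) + "\n")
            pd.DataFrame({
                "time_s": self.time_s,
                "tip_disp_um": self.tip_disp_um,
                "span_um": self.span_um,
            }).to_csv(fh, index=False)


@dataclass
class ForceDeformationPoints:
    """Equilibrium (deformation um, force nN) pairs, one per press cycle."""

    deformation_um: np.ndarray
    force_nN: np.ndarray
    condition: str = "nucleus+cell"

    def __post_init__(self):
        self.deformation_um = np.asarray(self.deformation_um, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)

    def __len__(self) -> int:
        return self.deformation_um.size


@dataclass
class StiffnessEstimate:
    slope: float  # nN/um
    intercept: float  # nN
    r_squared: float
    n: int
    condition: str = "nucleus+cell"


def extract_points(
    trace: ManipulationTrace,
    plateau_eps: float = 0.1,
    plateau_window: int = 4,
) -> ForceDeformationPoints:
    """Sample one force-deformation point per press cycle at equilibrium.

    Within each annotated cycle the equilibrium frame is the first frame
    after which |Delta span| stays below ``plateau_eps`` um for
    ``plateau_window`` consecutive frame steps. The baseline span is
    re-taken at the cycle's first frame; the equilibrium span and tip
    displacement are averaged over the detected plateau window (this is
    what waiting for equilibrium buys: tracking jitter averages out);
    deformation = baseline span - equilibrium span, force = equilibrium
    tip displacement x k_tip. Cycles without a plateau are skipped with
    a warning.
    """
    if not trace.cycles:
        raise ValueError("trace has no annotated press cycles")
    defs, forces = [], []
    skipped = 0
    for start, end in trace.cycles:
        span = trace.span_um[start:end]
        baseline = span[0]
        dspan = np.abs(np.diff(span))
        eq = None
        for i in range(dspan.size - plateau_window + 1):
            if np.all(dspan[i: i + plateau_window] < plateau_eps):
                eq = start + i
                break
        if eq is None:
            skipped += 1
            warnings.warn(f"cycle [{start},{end}): no equilibrium plateau found; skipped")
            continue
        hi = min(eq + plateau_window + 1, end)
        defs.append(baseline - float(np.mean(trace.span_um[eq:hi])))
        forces.append(float(np.mean(trace.tip_disp_um[eq:hi])) * trace.k_tip)
    if not defs:
        raise ValueError("no cycle reached an equilibrium plateau")
    if skipped:
        warnings.warn(f"{skipped} of {len(trace.cycles)} cycles skipped")
    return ForceDeformationPoints(np.array(defs), np.array(forces), trace.condition)


def fit_stiffness(
    points: ForceDeformationPoints, through_origin: bool = False
) -> StiffnessEstimate:
    """Ordinary least squares of force on deformation.

    The slope (nN/um) is the stiffness. Warns when R^2 < 0.96, the
    fit-quality level expected of clean elastic press-release data.
    """
    d, f = points.deformation_um, points.force_nN
    if len(points) < 2 or np.unique(d).size < 2:
        raise ValueError("need >= 2 distinct deformation values")
    if through_origin:
        slope = float(np.sum(d * f) / np.sum(d * d))
        intercept = 0.0
        ss_res = float(np.sum((f - slope * d) ** 2))
        ss_tot = float(np.sum((f - f.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(d, f)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    r2 = max(0.0, min(1.0, r2))
    if r2 < 0.96:
        warnings.warn(f"force-deformation fit R^2 = {r2:.3f} < 0.96")
    return StiffnessEstimate(slope=slope, intercept=intercept, r_squared=r2,
                             n=len(points), condition=points.condition)


def net_stiffness(
    total: StiffnessEstimate, cell_only: StiffnessEstimate
) -> tuple[float, bool]:
    """Nuclear stiffness after subtracting the non-nuclear contribution.

    Returns ``(total.slope - cell_only.slope, physical)`` where
    ``physical`` is False when the result is non-positive (flagged, not
    clamped).
    """
    if total.condition != "nucleus+cell" or cell_only.condition != "cell only":
        raise ValueError(
            "expected conditions 'nucleus+cell' and 'cell only', got "
            f"{total.condition!r} and {cell_only.condition!r}"
        )
    k = total.slope - cell_only.slope
    if k <= 0:
        warnings.warn(f"non-physical net stiffness {k:.3f} nN/um")
    return k, k > 0
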