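"""Forward-mapping calibration and the partition-RMSE statistic.

``fit_widths`` adjusts the element-specific Gaussian widths of the MM density
(and optionally the self-energy constants k_SE) so that model interaction
energies reproduce reference energies, by bounded nonlinear least squares.
References can come from a higher-level internal run (an all-QM
multi-subsystem calculation) or from a user-supplied plain-text table.

``partition_rmse`` analyses a cluster partition study: for an n-molecule
cluster there are binomial(n, k) ways to place k molecules at the QM level;
a perfect embedding would give every member of a partition the same
interaction energy.  The spread sigma(k) is regressed through the origin
against sqrt(binomial(n, k)); the slope, scaled by sqrt(pi/2) (the
half-normal mean/RMS relation), estimates the average error contributed per
QM/MM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from math import comb, pi, sqrt

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InconsistencyError, ParseError

__all__ = [
    "FitProblem",
    "FitResult",
    "fit_widths",
    "PartitionStudy",
    "partition_rmse",
    "read_reference_table",
]


@dataclass
class FitProblem:
    """A width-calibration problem.

    ``evaluator(theta) -> array`` returns the model interaction energies
    (kcal/mol) of all configurations at parameter vector ``theta``; how the
    configurations are represented is the evaluator's business (typically a
    closure over QMMMSystem variants).  ``param_names`` orders theta, e.g.
    ("sigma_q_O", "sigma_q_H", "sigma_mu_O", "sigma_mu_H").
    """

    evaluator: callable
    reference_energies: np.ndarray
    param_names: tuple
    x0: np.ndarray
    bounds: tuple  # (lower array, upper array)

    def __post_init__(self):
        self.reference_energies = np.asarray(self.reference_energies, float)
        self.x0 = np.asarray(self.x0, float)
        lo, hi = (np.asarray(b, float) for b in self.bounds)
        if not np.isfinite(self.reference_energies).all():
            raise InconsistencyError("reference energies must be finite")
        if len(self.reference_energies) < len(self.param_names):
            raise InconsistencyError(
                "need at least as many configurations as parameters"
            )
        if np.any(lo <= 0) and any("sigma" in p for p in self.param_names):
            if np.any(lo[[i for i, p in enumerate(self.param_names) if "sigma" in p]] <= 0):
                raise InconsistencyError("width bounds must be strictly positive")
        self.bounds = (lo, hi)


@dataclass
class FitResult:
    theta: np.ndarray
    param_names: tuple
    residuals: np.ndarray
    rmse: float
    n_evaluations: int
    stalled: bool = False

    def report(self) -> str:
        lines = ["parameter fit report", "-" * 40]
        for name, val in zip(self.param_names, self.theta):
            lines.append(f"{name:<16s} = {val:.6f}")
        lines.append(f"{'rmse':<16s} = {self.rmse:.6f} kcal/mol")
        lines.append(f"{'stalled':<16s} = {self.stalled}")
        lines.append("residuals (kcal/mol):")
        for i, r in enumerate(self.residuals):
            lines.append(f"  config {i:3d}: {r:+.6f}")
        return "\n".join(lines)


def fit_widths(
    problem: FitProblem,
    xtol: float = 1e-10,
    ftol: float = 1e-12,
    max_nfev: int = 400,
) -> FitResult:
    """Least-squares fit of the MM density parameters.

    Minimizes sum_c (E_model(theta) - E_ref)^2 with bounded trust-region
    least squares and finite-difference gradients.  Guaranteed not to return
    a point worse than the start; an optimizer stall is flagged rather than
    raised, with the best-so-far parameters.
    """
    n_eval = [0]

    def resid(theta):
        n_eval[0] += 1
        return np.asarray(problem.evaluator(theta), float) - problem.reference_energies

    r0 = resid(problem.x0)
    try:
        sol = least_squares(
            resid, problem.x0, bounds=problem.bounds,
            xtol=xtol, ftol=ftol, gtol=None, max_nfev=max_nfev,
            diff_step=1e-4,
        )
        theta, res, stalled = sol.x, sol.fun, not sol.success
    except Exception:  # optimizer blow-up: fall back to the start point
        theta, res, stalled = problem.x0, r0, True
    if float(res @ res) > float(r0 @ r0):
        theta, res, stalled = problem.x0, r0, True
    return FitResult(
        theta=np.asarray(theta, float),
        param_names=tuple(problem.param_names),
        residuals=np.asarray(res, float),
        rmse=float(np.sqrt(np.mean(np.asarray(res) ** 2))),
        n_evaluations=n_eval[0],
        stalled=stalled,
    )


# ---------------------------------------------------------------------------
# partition statistics
# ---------------------------------------------------------------------------

@dataclass
class PartitionStudy:
    """Member interaction energies of every k-partition of an n-cluster.

    ``member_energies[k]`` lists the interaction energies (kcal/mol) of the
    binomial(n, k) ways of putting k molecules at the QM level.
    """

    n: int
    member_energies: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        for k, vals in self.member_energies.items():
            expected = comb(self.n, int(k))
            if len(vals) != expected:
                raise InconsistencyError(
                    f"partition k={k}: got {len(vals)} members, expected "
                    f"binomial({self.n},{k}) = {expected}"
                )


def partition_rmse(study: PartitionStudy, fit_intercept: bool = False):
    """Per-partition RMSE, the sqrt(binomial) slope, and the boundary error.

    For each k with at least two members, computes the RMSE of the member
    energies about their mean; fits sigma(k) = slope * sqrt(binomial(n, k))
    (through the origin unless ``fit_intercept``); returns
    ``(rmse_per_k, slope, error_per_boundary)`` with error_per_boundary =
    slope * sqrt(pi/2).
    """
    ks, sig, w = [], [], []
    rmse_per_k = {}
    for k in sorted(study.member_energies):
        vals = np.asarray(study.member_energies[k], float)
        if len(vals) < 2:
            continue
        rmse = float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
        rmse_per_k[int(k)] = rmse
        ks.append(int(k))
        sig.append(rmse)
        w.append(sqrt(comb(study.n, int(k))))
    sig = np.asarray(sig)
    w = np.asarray(w)
    if len(sig) == 0:
        raise InconsistencyError("no partition has >= 2 members")
    if fit_intercept:
        A = np.column_stack([w, np.ones_like(w)])
        slope = float(np.linalg.lstsq(A, sig, rcond=None)[0][0])
    else:
        slope = float((w @ sig) / (w @ w))
    error_per_boundary = slope * sqrt(pi / 2.0)
    return rmse_per_k, slope, error_per_boundary


def read_reference_table(path) -> dict:
    """Read a plain columnar reference-energy table: config-id  E(kcal/mol)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError("expected two columns: id energy", line=lineno)
            try:
                out[parts[0]] = float(parts[1])
            except ValueError:
                raise ParseError(f"malformed energy {parts[1]!r}", line=lineno) from None
    return out
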