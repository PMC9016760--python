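"""Thin wrappers around scipy's HiGHS-based LP/MILP interface.

All optimisation in this package goes through :func:`solve_lp` and
:func:`solve_milp` so that solver options, statuses and error handling are
uniform.  Problems are stated as

    min/max  c.x   s.t.  A_eq.x = b_eq,  A_ub.x <= b_ub,  lo <= x <= up

with sparse matrices throughout.
"""

from __future__ import annotations

import contextlib
import os
import sys
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp


@contextlib.contextmanager
def _quiet_stdout():
    """Drop stray solver prints emitted from the C++ core at the fd level."""
    for stream in (sys.stdout, sys.stderr):
        try:
            stream.flush()
        except (OSError, ValueError, AttributeError):
            pass
    fds = [1, 2]  # raw process streams: the C++ core writes past sys.stdout
    try:
        saved = [os.dup(fd) for fd in fds]
    except OSError:
        yield
        return
    try:
        with open(os.devnull, "w") as devnull:
            for fd in fds:
                os.dup2(devnull.fileno(), fd)
            yield
    finally:
        try:  # flush any C-level buffers while still pointed at devnull
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:
            pass
        for fd, sv in zip(fds, saved):
            os.dup2(sv, fd)
            os.close(sv)

#: primal/dual feasibility tolerance used for every solve
LP_TOL = 1e-9
#: reported fluxes are rounded to this grid to stabilise comparisons
FLUX_DECIMALS = 6


class OptimizationError(Exception):
    """Base class for solver failures."""


class InfeasibleProblemError(OptimizationError):
    """The constraint system admits no solution."""


class UnboundedProblemError(OptimizationError):
    """The objective is unbounded in the requested direction."""


@dataclass
class LPResult:
    objective: float
    x: np.ndarray


def round_flux(x: np.ndarray | float) -> np.ndarray | float:
    """Round fluxes to the package-wide reporting precision."""
    return np.round(x, FLUX_DECIMALS)


def _as_bounds(lo: np.ndarray, up: np.ndarray):
    return np.column_stack([lo, up])


def solve_lp(
    c: np.ndarray,
    A_eq: sp.spmatrix | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: sp.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    lo: np.ndarray | None = None,
    up: np.ndarray | None = None,
    sense: str = "min",
    context: str = "",
) -> LPResult:
    """Solve a linear program; raise on infeasibility/unboundedness.

    ``sense`` is ``"min"`` or ``"max"``; the returned objective is always on
    the caller's scale (maximisation results are not negated).
    """
    c = np.asarray(c, dtype=float)
    sign = 1.0 if sense == "min" else -1.0
    n = c.size
    if lo is None:
        lo = np.full(n, -np.inf)
    if up is None:
        up = np.full(n, np.inf)
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=_as_bounds(lo, up),
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOL,
            "dual_feasibility_tolerance": LP_TOL,
        },
    )
    if res.status == 2:
        raise InfeasibleProblemError(
            f"linear program infeasible{': ' + context if context else ''}"
        )
    if res.status == 3:
        raise UnboundedProblemError(
            f"objective unbounded{': ' + context if context else ''}"
        )
    if not res.success:  # pragma: no cover - numerical trouble
        raise OptimizationError(f"LP solve failed (status {res.status}): {res.message}")
    return LPResult(objective=sign * res.fun, x=res.x)


def solve_milp(
    c: np.ndarray,
    constraints: list[LinearConstraint],
    integrality: np.ndarray,
    lo: np.ndarray,
    up: np.ndarray,
    sense: str = "min",
    mip_gap: float = 0.0,
    time_limit: float | None = None,
    context: str = "",
) -> LPResult:
    """Solve a mixed-integer linear program via HiGHS branch-and-bound."""
    c = np.asarray(c, dtype=float)
    sign = 1.0 if sense == "min" else -1.0
    options: dict = {
        "mip_rel_gap": mip_gap,
        # tighter than the HiGHS defaults: big-M rows carry coefficients on
        # the order of the production-floor slack (1e-6), which the default
        # integrality tolerance can absorb into spurious infeasibility
        "mip_feasibility_tolerance": 1e-8,
        "primal_feasibility_tolerance": LP_TOL,
        "dual_feasibility_tolerance": LP_TOL,
    }
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    import warnings as _warnings

    from scipy.optimize import Bounds

    with _quiet_stdout(), _warnings.catch_warnings():
        # scipy forwards the HiGHS-specific tolerance options verbatim but
        # warns about them; the forwarding is exactly what we want
        _warnings.filterwarnings("ignore", message="Unrecognized options")
        res = milp(
            sign * c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(np.asarray(lo, dtype=float), np.asarray(up, dtype=float)),
            options=options,
        )
    if res.status == 2:
        raise InfeasibleProblemError(
            f"MILP infeasible{': ' + context if context else ''}"
        )
    if res.status == 3:
        raise UnboundedProblemError(
            f"MILP unbounded{': ' + context if context else ''}"
        )
    if res.x is None:  # pragma: no cover
        raise OptimizationError(f"MILP solve failed (status {res.status}): {res.message}")
    return LPResult(objective=sign * res.fun, x=res.x)
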