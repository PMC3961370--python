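"""Cluster/site model for dominant-negative fusion titrations.

Cell-cell fusion by FAST proteins is driven by plasma-membrane clusters
("fusion platforms") of ``n`` protein copies, with ``s`` independent fusion
sites per cell.  When a fraction ``f`` of the expressed protein is functional
and incorporation of a single non-functional copy poisons a whole cluster,
the residual fusion activity is

    F(f) = 1 - (1 - f**n)**s

i.e. the probability that at least one of the ``s`` sites is built entirely
from functional subunits.  Fitting F to a titration of functional vs.
dominant-negative protein yields the cluster stoichiometry ``n`` and the
number of fusion sites ``s``; the single-site special case ``s = 1`` reduces
to the binomial probability ``f**n`` that one cluster is all-functional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "StoichModel",
    "StoichFit",
    "TitrationPoint",
    "TitrationCurve",
    "ClusterSizeEstimate",
    "HalfMaxResult",
    "predict_fusion",
    "fit_stoichiometry",
    "single_site_probability",
    "infer_cluster_size",
    "half_max_fraction",
]

DEFAULT_INIT = (5.0, 3.0)
DEFAULT_BOUNDS = ((1.0, 30.0), (1.0, 100.0))


@dataclass(frozen=True)
class StoichModel:
    """Point parameters of the cluster/site fusion model.

    Parameters
    ----------
    n : float
        Protein copies per cluster (>= 1, real-valued).
    s : float
        Fusion sites per cell (>= 1, real-valued).
    """

    n: float
    s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.n) and math.isfinite(self.s)):
            raise ValueError("model parameters must be finite")
        if self.n < 1 or self.s < 1:
            raise ValueError(f"require n >= 1 and s >= 1, got n={self.n}, s={self.s}")


@dataclass(frozen=True)
class TitrationPoint:
    """One measured activity at functional fraction ``f``."""

    f: float
    activity: float
    experiment_id: str = "exp1"
    field_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"functional fraction must lie in [0, 1], got {self.f}")
        if not math.isfinite(self.activity) or self.activity < 0:
            raise ValueError(f"activity must be finite and >= 0, got {self.activity}")


@dataclass
class TitrationCurve:
    """Fusion activity across functional fractions, with replicate structure.

    Activities are expected to be normalized so the all-functional (f = 1)
    condition averages 1; :meth:`normalized` rescales raw activities that way.
    """

    points: list[TitrationPoint]
    normalization_reference: str = "mean activity at f = 1 scaled to 1"

    @property
    def f(self) -> np.ndarray:
        return np.array([p.f for p in self.points], dtype=float)

    @property
    def activity(self) -> np.ndarray:
        return np.array([p.activity for p in self.points], dtype=float)

    @property
    def experiment_ids(self) -> list[str]:
        return [p.experiment_id for p in self.points]

    def n_distinct_fractions(self) -> int:
        return len(set(p.f for p in self.points))

    def normalized(self) -> "TitrationCurve":
        """Rescale activities so the f = 1 condition averages exactly 1."""
        at_one = [p.activity for p in self.points if p.f == 1.0]
        if not at_one:
            raise ValueError("cannot normalize: no points at f = 1")
        ref = float(np.mean(at_one))
        if ref <= 0:
            raise ValueError("cannot normalize: mean activity at f = 1 is <= 0")
        pts = [
            TitrationPoint(p.f, p.activity / ref, p.experiment_id, p.field_id)
            for p in self.points
        ]
        return TitrationCurve(pts, f"raw activities divided by {ref!r} (mean at f = 1)")


@dataclass
class StoichFit:
    """Least-squares estimate of (n, s) with Jacobian-based uncertainties."""

    model: StoichModel
    se_n: float
    se_s: float
    covariance: np.ndarray
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    sse: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "n": self.model.n,
            "s": self.model.s,
            "se_n": self.se_n,
            "se_s": self.se_s,
            "covariance": np.asarray(self.covariance).tolist(),
            "r_squared": self.r_squared,
            "residuals": np.asarray(self.residuals).tolist(),
            "converged": self.converged,
            "n_points": self.n_points,
            "sse": self.sse,
        }


def _as_fraction_array(f) -> np.ndarray:
    arr = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("functional fraction f must lie in [0, 1]")
    return arr


def predict_fusion(model: StoichModel, f):
    """Residual fusion activity F(f) = 1 - (1 - f**n)**s.

    Accepts a scalar or array of functional fractions in [0, 1]; returns the
    same shape.  F(0) = 0, F(1) = 1, and F is continuous and nondecreasing.
    """
    arr = _as_fraction_array(f)
    if model.s == 1.0:
        # exact single-site reduction: 1 - (1 - f^n) would lose ulps
        out = arr**model.n
    else:
        out = 1.0 - (1.0 - arr**model.n) ** model.s
    if np.isscalar(f) or np.ndim(f) == 0:
        return float(out)
    return out


def single_site_probability(f: float, n: int, as_percent: bool = False) -> float:
    """Probability f**n that a single cluster of ``n`` copies is all-functional.

    ``n`` must be an integer cluster size (use :func:`predict_fusion` with
    s = 1 for real-valued n).  With ``as_percent`` the value is multiplied
    by 100.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f}")
    if isinstance(n, bool) or (not isinstance(n, (int, np.integer)) and n != int(n)):
        raise ValueError(f"cluster size n must be an integer, got {n!r}")
    n = int(n)
    if n < 1:
        raise ValueError(f"cluster size n must be >= 1, got {n}")
    # same power computation as predict_fusion so the s = 1 reduction is exact
    p = float(np.asarray(f, dtype=float) ** float(n))
    return 100.0 * p if as_percent else p


@dataclass
class ClusterSizeEstimate:
    """Continuous and ranked-integer cluster sizes explaining a residual."""

    n_continuous: float
    candidates: list[tuple[int, float]]  # (n, |f**n - residual|), best first

    @property
    def best(self) -> int:
        return self.candidates[0][0]

    @property
    def ranking(self) -> list[int]:
        return [n for n, _ in self.candidates]


def infer_cluster_size(residual: float, f: float, n_max: int = 20) -> ClusterSizeEstimate:
    """Invert the single-site binomial: which cluster size explains ``residual``?

    The continuous estimate solves f**n = residual, i.e.
    n = ln(residual)/ln(f).  Integer candidates 1..n_max are ranked by
    |f**n - residual| ascending; on an exact tie the smaller n ranks first,
    so both adjacent candidates are reported with the larger last.
    """
    if not 0.0 < residual < 1.0:
        raise ValueError(f"residual must lie strictly in (0, 1), got {residual}")
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must lie strictly in (0, 1), got {f}")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n_cont = math.log(residual) / math.log(f)
    cands = sorted(
        ((n, abs(f**n - residual)) for n in range(1, n_max + 1)),
        key=lambda t: (t[1], t[0]),
    )
    return ClusterSizeEstimate(n_continuous=n_cont, candidates=cands)


@dataclass
class HalfMaxResult:
    """Functional fraction at half-maximal fusion and the implied ratio."""

    f_star: float
    ratio: float  # functional : non-functional, i.e. f*/(1-f*)
    ratio_rounded: int


def half_max_fraction(model: StoichModel, xtol: float = 1e-9) -> HalfMaxResult:
    """Solve F(f*) = 0.5·F(1) = 0.5 by bracketed root-finding on [0, 1].

    F is strictly increasing on (0, 1) for valid models, so the root is
    unique.  Returns f*, the functional:non-functional ratio f*/(1-f*), and
    that ratio rounded to the nearest integer.
    """
    target = 0.5 * predict_fusion(model, 1.0)
    f_star = optimize.brentq(
        lambda f: predict_fusion(model, f) - target, 0.0, 1.0, xtol=xtol
    )
    ratio = f_star / (1.0 - f_star)
    return HalfMaxResult(f_star=float(f_star), ratio=float(ratio), ratio_rounded=round(ratio))


def _multistart_inits(
    init: StoichModel, bounds, n_starts: int, seed: int
) -> list[tuple[float, float]]:
    inits = [(init.n, init.s)]
    rng = np.random.default_rng(seed)
    (n_lo, n_hi), (s_lo, s_hi) = bounds
    for _ in range(max(0, n_starts - 1)):
        # log-uniform draws cover the box evenly across scales
        n0 = math.exp(rng.uniform(math.log(n_lo), math.log(n_hi)))
        s0 = math.exp(rng.uniform(math.log(s_lo), math.log(s_hi)))
        inits.append((n0, s0))
    return inits


def fit_stoichiometry(
    curve: TitrationCurve,
    init: Optional[StoichModel] = None,
    bounds: Sequence[Sequence[float]] = DEFAULT_BOUNDS,
    weights: Optional[np.ndarray] = None,
    n_starts: int = 5,
    seed: int = 0,
) -> StoichFit:
    """Fit (n, s) to a normalized titration curve by trust-region least squares.

    Runs ``n_starts`` seeded initializations (the supplied ``init`` plus
    log-uniform draws from the parameter box) and keeps the lowest-SSE
    solution, guarding against local minima.  Standard errors come from the
    Gauss-Newton covariance ``inv(J'J) * SSE/(m - 2)`` at the optimum.

    Parameters
    ----------
    curve : TitrationCurve
        Needs >= 3 distinct f values and non-constant activity.
    weights : array, optional
        Per-point weights (e.g. 1/SEM**2); residuals are scaled by sqrt(w).
    """
    if init is None:
        init = StoichModel(*DEFAULT_INIT)
    if curve.n_distinct_fractions() < 3:
        raise ValueError(
            f"fitting needs >= 3 distinct f values, got {curve.n_distinct_fractions()}"
        )
    f = curve.f
    y = curve.activity
    m = len(y)
    if np.ptp(y) == 0:
        raise ValueError("degenerate curve: activity is constant, model unidentifiable")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("weights must be nonnegative and match the data length")
    else:
        w = np.ones_like(y)

    lo = [bounds[0][0], bounds[1][0]]
    hi = [bounds[0][1], bounds[1][1]]

    def resid(p):
        n, s = p
        return w * ((1.0 - (1.0 - f**n) ** s) - y)

    best = None
    for n0, s0 in _multistart_inits(init, bounds, n_starts, seed):
        p0 = np.clip([n0, s0], lo, hi)
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    res = best.fun
    sse = float(res @ res)
    dof = max(m - 2, 1)
    s2 = sse / dof
    J = best.jac
    JTJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    cov = 0.5 * (cov + cov.T)  # symmetrize against roundoff
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    ybar = float(np.mean(y))
    sst = float(np.sum((w * (y - ybar)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return StoichFit(
        model=StoichModel(float(best.x[0]), float(best.x[1])),
        se_n=float(se[0]),
        se_s=float(se[1]),
        covariance=cov,
        r_squared=r2,
        residuals=res / np.where(w == 0, 1.0, w),
        converged=bool(best.success),
        n_points=m,
        sse=sse,
    )
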