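"""Dual-effector modified Michaelis-Menten model of SARM1 NADase activity.

SARM1 is an allosteric NAD glycohydrolase whose ARM domain carries both an
activation site and an inhibition site for small pyridine-mononucleotide
effectors (NMN, VMN).  A single readily reversible effector I therefore acts
on the enzyme through two independent regulatory factors multiplying a
hyperbolic substrate term:

    V = Vmax * A([I]) * B([I]) * [S] / (Km + [S])

    A([I]) = X + (1 - X) / (1 + ([I]/Ka)^n_act)     (activation limb)
    B([I]) = Y + (1 - Y) / (1 + ([I]/Ki)^n_inh)     (inhibition limb)

``X`` is the fold-activation factor at saturating effector, ``Y`` the residual
activity fraction at saturating effector, ``Ka``/``Ki`` the affinity constants
of the two sites and the Hill exponents capture binding cooperativity.  Both
factors are exactly 1 at [I] = 0, so ``A*B`` is directly the fold change of
activity relative to the substrate-only control.  With X > 1, Y < 1 and
Ka < Ki the fold-activation curve is biphasic (bell-shaped), the signature of
an activator that becomes self-inhibitory at high dose.

Units package-wide: concentrations in µM, specific activity in milliU/mg
(nmol·min⁻¹·mg⁻¹), time in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "DualEffectorParams",
    "DoseResponseTable",
    "FitResult",
    "activation_factor",
    "inhibition_factor",
    "rate",
    "fold_activation",
    "peak_effector_response",
    "fit_dual_effector",
    "fit_michaelis_menten",
]

# Fitting bounds, log-uniform multi-start space.  Ka/Ki span sub-nM to molar
# affinities; X allows up to 1000-fold induction; n is kept in a physically
# plausible cooperativity range so the optimiser cannot escape to step
# functions.
BOUNDS = {
    "vmax": (1e-9, 1e9),
    "km": (1e-3, 1e6),
    "x_act": (0.0, 1e3),
    "y_res": (1e-6, 1.0),
    "ka": (1e-3, 1e6),
    "ki": (1e-3, 1e6),
    "n_act": (0.25, 8.0),
    "n_inh": (0.25, 8.0),
}

N_STARTS = 32
_PIN_TOL = 0.01  # fraction of a bound's magnitude counting as "pinned"


@dataclass(frozen=True)
class DualEffectorParams:
    """Parameters of the dual-site activator/inhibitor rate law.

    vmax : basal specific activity, milliU/mg (rate at [I]=0, saturating [S])
    km : substrate half-saturation, µM NAD
    x_act : fold-activation factor X at saturating effector (dimensionless)
    y_res : residual activity fraction Y at saturating effector, in (0, 1]
    ka, ki : effector affinity constants of the activation / inhibition
        sites, µM
    n_act, n_inh : Hill coefficients of the two limbs (n_inh defaults to
        n_act when not given)
    """

    vmax: float
    km: float
    x_act: float
    y_res: float
    ka: float
    ki: float
    n_act: float = 1.0
    n_inh: float | None = None

    def __post_init__(self):
        if self.n_inh is None:
            object.__setattr__(self, "n_inh", self.n_act)
        for name in ("vmax", "km", "ka", "ki", "n_act", "n_inh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.y_res <= 1:
            raise ValueError(f"y_res must be in (0, 1], got {self.y_res}")
        if self.x_act < 0:
            raise ValueError(f"x_act must be >= 0, got {self.x_act}")


@dataclass
class DoseResponseTable:
    """Effector dose-response data: concentration vs rate or fold-activation.

    ``response_kind`` is "rate" (absolute, milliU/mg) or "fold"
    (dimensionless ratio to the zero-effector control).
    """

    effector: str
    concentrations: np.ndarray
    responses: np.ndarray
    response_kind: str
    replicates: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.response_kind not in ("rate", "fold"):
            raise ValueError("response_kind must be 'rate' or 'fold'")
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if self.replicates is None:
            self.replicates = np.zeros(len(self.concentrations), dtype=int)
        else:
            self.replicates = np.asarray(self.replicates, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effector": self.effector,
                "conc_uM": self.concentrations,
                "response": self.responses,
                "response_kind": self.response_kind,
                "replicate": self.replicates,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseTable":
        kinds = df["response_kind"].unique()
        if len(kinds) != 1:
            raise ValueError("mixed response kinds in one table")
        effectors = df["effector"].unique()
        if len(effectors) != 1:
            raise ValueError("one effector per table")
        return cls(
            effector=str(effectors[0]),
            concentrations=df["conc_uM"].to_numpy(float),
            responses=df["response"].to_numpy(float),
            response_kind=str(kinds[0]),
            replicates=df["replicate"].to_numpy(int) if "replicate" in df else None,
        )


def _check_nonneg(value, name):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def activation_factor(i_conc, params: DualEffectorParams):
    """Activation limb A([I]) = X + (1-X)/(1 + ([I]/Ka)^n_act).

    Equals 1 at [I]=0 and tends to X at saturating effector.
    """
    i = _check_nonneg(i_conc, "i_conc")
    x = params.x_act
    out = x + (1.0 - x) / (1.0 + (i / params.ka) ** params.n_act)
    return float(out) if np.isscalar(i_conc) else out


def inhibition_factor(i_conc, params: DualEffectorParams):
    """Inhibition limb B([I]) = Y + (1-Y)/(1 + ([I]/Ki)^n_inh).

    Equals 1 at [I]=0 and tends to Y at saturating effector; non-increasing
    for Y < 1.
    """
    i = _check_nonneg(i_conc, "i_conc")
    y = params.y_res
    out = y + (1.0 - y) / (1.0 + (i / params.ki) ** params.n_inh)
    return float(out) if np.isscalar(i_conc) else out


def rate(s_conc, i_conc, params: DualEffectorParams):
    """NADase rate V([S],[I]) in milliU/mg under the dual-effector law."""
    s = _check_nonneg(s_conc, "s_conc")
    a = activation_factor(i_conc, params)
    b = inhibition_factor(i_conc, params)
    out = params.vmax * a * b * s / (params.km + s)
    return float(out) if np.isscalar(s_conc) and np.isscalar(i_conc) else out


def fold_activation(i_conc, params: DualEffectorParams):
    """Fold change of activity vs the zero-effector control: A([I])·B([I]).

    The hyperbolic substrate factor cancels in the ratio, so fold activation
    is independent of [S]; it is exactly 1 at [I]=0.
    """
    a = activation_factor(i_conc, params)
    b = inhibition_factor(i_conc, params)
    return a * b


def peak_effector_response(
    params: DualEffectorParams,
    i_grid_bounds: tuple[float, float],
    n_grid: int = 2000,
) -> tuple[float, float]:
    """Locate the maximum of fold_activation on an effector range.

    Dense log-spaced grid (plus the lower endpoint) followed by golden-section
    refinement of the best bracket.  Biphasic parameter sets give an interior
    maximum; monotone curves return the appropriate boundary.

    Returns (i_star µM, fold_star).
    """
    lo, hi = float(i_grid_bounds[0]), float(i_grid_bounds[1])
    if not (hi > lo >= 0) or not math.isfinite(hi):
        raise ValueError("need a positive, bounded, non-degenerate range")
    grid_lo = max(lo, hi * 1e-12)
    grid = np.concatenate([[lo], np.geomspace(grid_lo, hi, n_grid)])
    vals = fold_activation(grid, params)
    k = int(np.argmax(vals))
    # golden-section refinement inside the bracketing neighbours
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if a == b:
        return float(grid[k]), float(vals[k])
    invphi = (math.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = fold_activation(c, params), fold_activation(d, params)
    for _ in range(200):
        if b - a < 1e-12 * max(1.0, b):
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fold_activation(c, params)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fold_activation(d, params)
    i_star = (a + b) / 2
    f_star = fold_activation(i_star, params)
    # the refined point can only improve on the grid point
    if vals[k] > f_star:
        i_star, f_star = grid[k], vals[k]
    return float(i_star), float(f_star)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a least-squares fit: estimates plus diagnostics."""

    params: DualEffectorParams
    rss: float
    residuals: np.ndarray
    n_points: int
    pinned: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    seed: int | None = None
    free_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "vmax": p.vmax, "km": p.km, "x_act": p.x_act, "y_res": p.y_res,
                "ka": p.ka, "ki": p.ki, "n_act": p.n_act, "n_inh": p.n_inh,
            },
            "rss": self.rss,
            "n_points": self.n_points,
            "pinned": self.pinned,
            "flags": self.flags,
            "seed": self.seed,
            "free": self.free_names,
        }


_FOLD_FREE = ["x_act", "y_res", "ka", "ki", "n_act", "n_inh"]
_LOG_PARAMS = {"vmax", "km", "ka", "ki", "n_act", "n_inh"}


def _pack(values: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    out = []
    for n in names:
        v = values[n]
        out.append(math.log(v) if n in _LOG_PARAMS else v)
    return np.array(out)


def _unpack(theta: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    return {
        n: (math.exp(t) if n in _LOG_PARAMS else float(t))
        for n, t in zip(names, theta)
    }


def _bounds_arrays(names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for n in names:
        a, b = BOUNDS[n]
        if n in _LOG_PARAMS:
            a, b = math.log(a), math.log(b)
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


def _lhs_starts(names: Sequence[str], n_starts: int, seed: int) -> np.ndarray:
    lo, hi = _bounds_arrays(names)
    # keep starts away from the extreme corners of very wide boxes
    span = hi - lo
    lo_s, hi_s = lo + 0.05 * span, hi - 0.05 * span
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    return lo_s + sampler.random(n_starts) * (hi_s - lo_s)


def fit_dual_effector(
    table: DoseResponseTable,
    s_conc: float = 250.0,
    fixed: Mapping[str, float] | None = None,
    options: Mapping | None = None,
) -> FitResult:
    """Fit the dual-effector model to a dose-response table.

    Fold-kind data fix the baseline at 1 so ``vmax`` and ``km`` are not
    estimable and are held at nominal values; rate-kind data additionally fit
    ``vmax`` (with ``km`` fixed or supplied via ``fixed``).  Weighted least
    squares with multi-start from a deterministic Latin-hypercube in
    log-parameter space; the best run by residual sum of squares wins, ties
    broken by the lower ``ka``.  Parameters ending within 1% of a bound are
    reported in ``pinned`` rather than trusted silently.

    options: ``seed`` (default 0), ``n_starts`` (default 32), ``weighting``
    ("unit" or "relative" = 1/response²), ``tie_rtol`` for the RSS tie band.
    """
    opts = dict(options or {})
    seed = int(opts.get("seed", 0))
    n_starts = int(opts.get("n_starts", N_STARTS))
    weighting = opts.get("weighting", "unit")
    tie_rtol = float(opts.get("tie_rtol", 1e-6))
    fixed = dict(fixed or {})

    conc = table.concentrations
    resp = table.responses
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")

    if table.response_kind == "fold":
        fixed.setdefault("vmax", 1.0)
        fixed.setdefault("km", 1.0)
    else:
        fixed.setdefault("km", 70.0)

    all_names = ["vmax", "km", "x_act", "y_res", "ka", "ki", "n_act", "n_inh"]
    free = [n for n in all_names if n not in fixed]
    if not free:
        raise ValueError("no free parameters")

    if weighting == "relative":
        w = 1.0 / np.maximum(np.abs(resp), 1e-12)
    else:
        w = np.ones_like(resp)

    def model(values: Mapping[str, float]) -> np.ndarray:
        full = {**fixed, **values}
        pr = DualEffectorParams(
            vmax=full["vmax"], km=full["km"], x_act=full["x_act"],
            y_res=full["y_res"], ka=full["ka"], ki=full["ki"],
            n_act=full["n_act"], n_inh=full["n_inh"],
        )
        if table.response_kind == "fold":
            return fold_activation(conc, pr)
        return rate(s_conc, conc, pr)

    def resid(theta: np.ndarray) -> np.ndarray:
        return w * (model(_unpack(theta, free)) - resp)

    lo, hi = _bounds_arrays(free)
    starts = list(_lhs_starts(free, n_starts, seed))
    # one data-informed start: neutral-ish parameters at the observed scale
    guess = {
        "vmax": max(np.max(np.abs(resp)), 1e-6),
        "km": 70.0,
        "x_act": float(np.clip(np.max(resp) / max(resp[np.argmin(conc)], 1e-9), 0.5, 999)),
        "y_res": float(np.clip(resp[np.argmax(conc)] / max(np.max(resp), 1e-9), 1e-5, 1.0)),
        "ka": float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0,
        "ki": float(np.max(conc)) if np.any(conc > 0) else 100.0,
        "n_act": 1.0,
        "n_inh": 1.0,
    }
    starts.append(np.clip(_pack(guess, free), lo, hi))

    best = None
    for th0 in starts:
        try:
            sol = least_squares(resid, th0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        ka_val = _unpack(sol.x, free).get("ka", fixed.get("ka", math.inf))
        if best is None:
            best = (rss, ka_val, sol)
        else:
            b_rss, b_ka, _ = best
            if rss < b_rss * (1 - tie_rtol):
                best = (rss, ka_val, sol)
            elif abs(rss - b_rss) <= tie_rtol * max(b_rss, 1e-300) and ka_val < b_ka:
                best = (rss, ka_val, sol)
    if best is None:
        raise RuntimeError("dual-effector fit failed to converge from any start")

    rss, _, sol = best
    est = _unpack(sol.x, free)
    full = {**fixed, **est}
    params = DualEffectorParams(
        vmax=full["vmax"], km=full["km"], x_act=full["x_act"], y_res=full["y_res"],
        ka=full["ka"], ki=full["ki"], n_act=full["n_act"], n_inh=full["n_inh"],
    )

    pinned = []
    for n in free:
        a, b = BOUNDS[n]
        v = est[n]
        if n in _LOG_PARAMS:
            la, lb, lv = math.log(a), math.log(b), math.log(v)
            span = lb - la
            near = min(lv - la, lb - lv) < _PIN_TOL * span
        else:
            # closeness relative to the bound's own magnitude, so mid-range
            # estimates inside wide boxes are never mistaken for pinned
            near = (v - a) < _PIN_TOL * max(abs(a), 1e-2) or (
                b - v
            ) < _PIN_TOL * abs(b)
        if near:
            pinned.append(n)

    flags = []
    if pinned:
        flags.append("boundary-pinned: " + ",".join(pinned))
    # flat data cannot constrain the regulatory parameters: the optimum is a
    # degenerate manifold (e.g. cancelling limbs with ka = ki, x·y = 1)
    scale = max(float(np.mean(np.abs(resp))), 1e-300)
    if float(np.ptp(resp)) < 1e-6 * scale:
        flags.append("unidentifiable: response shows no dose dependence")
    if table.response_kind == "fold" and "vmax" in fixed:
        flags.append("vmax not estimable from fold data (baseline fixed at 1)")

    residuals = model(est) - resp
    return FitResult(
        params=params, rss=rss, residuals=residuals, n_points=len(resp),
        pinned=pinned, flags=flags, seed=seed, free_names=free,
    )


def fit_michaelis_menten(
    s_grid: Iterable[float], rates: Iterable[float]
) -> tuple[float, float, list[str]]:
    """Least-squares hyperbola fit V = Vmax·[S]/(Km+[S]).

    Returns (vmax, km, flags).  Noiseless model data are recovered exactly;
    designs with no information below ~Km get a ``km unidentifiable`` flag.
    """
    s = np.asarray(list(s_grid), dtype=float)
    v = np.asarray(list(rates), dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    if np.any(s < 0):
        raise ValueError("substrate concentrations must be non-negative")
    flags: list[str] = []
    if np.allclose(v, 0):
        return 0.0, float("nan"), ["km undefined: all rates zero"]

    vmax0 = float(np.max(v)) * 1.2
    # half-saturation guess from the first point crossing vmax0/2
    km0 = float(np.interp(vmax0 / 2, np.sort(v), s[np.argsort(v)])) or float(np.median(s))
    km0 = max(km0, 1e-6)

    def resid(theta):
        vmax, km = np.exp(theta)
        return vmax * s / (km + s) - v

    best = None
    for km_try in (km0, np.median(s), np.min(s[s > 0]) if np.any(s > 0) else 1.0):
        sol = least_squares(
            resid, np.log([vmax0, max(km_try, 1e-6)]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    vmax, km = np.exp(best[1].x)
    if km < np.min(s[s > 0]) / 20:
        flags.append("km unidentifiable: all substrate concentrations >> km")
    return float(vmax), float(km), flags
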