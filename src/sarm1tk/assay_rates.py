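"""Rate extraction from discontinuous NADase assay time courses.

The assay samples a reaction mixture (2-20 µg/ml enzyme, 250 µM NAD) at
discrete times, quenches, and quantifies products by HPLC.  Each mole of
ADPR or cADPR formed corresponds to one mole of NAD cleaved, so their sum
tracks substrate consumption (nicotinamide is co-produced and is excluded to
avoid double counting).  Rates are taken from the linear early phase where
substrate consumption stays at or below 20%, by ordinary least squares on
summed product concentration vs time.  Specific activity follows the unit
definition 1 U = 1 µmol product/min, i.e. milliU/mg = nmol·min⁻¹·mg⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeCourse",
    "RateResult",
    "CONSUMPTION_PRODUCTS",
    "consumption_window",
    "product_rate",
    "specific_activity",
    "fold_change",
    "relative_percent",
]

VALID_ANALYTES = ("ADPR", "cADPR", "NAM", "NaMN")
#: products whose 1:1 stoichiometry with cleaved NAD defines consumption
CONSUMPTION_PRODUCTS = ("ADPR", "cADPR")


@dataclass
class TimeCourse:
    """Product-concentration series from a discontinuous assay.

    times in minutes (strictly increasing), product series in µM, initial
    substrate ``s0`` in µM (e.g. 250 for NAD) and ``enzyme_conc`` in µg/ml.
    """

    times: np.ndarray
    products: dict[str, np.ndarray]
    s0: float
    enzyme_conc: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")
        clean = {}
        for name, series in self.products.items():
            if name not in VALID_ANALYTES:
                raise ValueError(f"unknown analyte {name!r}")
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"series {name!r} does not match times")
            if np.any(arr < 0):
                raise ValueError(f"negative concentrations in {name!r}")
            clean[name] = arr
        self.products = clean


@dataclass
class RateResult:
    slope: float  # µM/min
    window: list[int]
    specific_activity: float  # milliU/mg
    r_squared: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "slope_uM_per_min": self.slope,
            "window": self.window,
            "specific_activity_milliU_per_mg": self.specific_activity,
            "r_squared": self.r_squared,
            "flags": self.flags,
        }


def consumption_window(tc: TimeCourse, max_fraction: float = 0.2) -> list[int]:
    """Maximal prefix of time points with substrate consumption <= threshold.

    Consumption is estimated as ADPR + cADPR (µM); the boundary is inclusive
    (a point at exactly ``max_fraction * s0`` is retained).  Only a prefix is
    returned: once a point crosses the threshold, later points are not
    re-admitted even if a noisy dip brings them back under it.
    """
    if not 0 < max_fraction < 1:
        raise ValueError("max_fraction must be in (0, 1)")
    consumed = np.zeros_like(tc.times)
    for name in CONSUMPTION_PRODUCTS:
        if name in tc.products:
            consumed = consumed + tc.products[name]
    limit = max_fraction * tc.s0
    keep: list[int] = []
    for k, c in enumerate(consumed):
        if c <= limit:
            keep.append(k)
        else:
            break
    if not keep:
        raise ValueError(
            "no linear window: first time point already exceeds "
            f"{max_fraction:.0%} substrate consumption"
        )
    return keep


def product_rate(
    tc: TimeCourse,
    analytes: tuple[str, ...] | None = None,
    max_fraction: float = 0.2,
) -> RateResult:
    """Initial rate from linearly accumulating products.

    Sums the requested analytes (default: whichever of ADPR/cADPR the time
    course carries), restricts to the consumption window, and fits an
    ordinary least-squares line with free intercept (tolerant of a small
    t=0 background).  Slope is µM/min; specific activity uses the time
    course's enzyme concentration.
    """
    if analytes is None:
        analytes = tuple(a for a in CONSUMPTION_PRODUCTS if a in tc.products)
        if not analytes:
            raise ValueError("time course has none of the rate products")
    window = consumption_window(tc, max_fraction)
    if len(window) < 2:
        raise ValueError("need at least 2 points inside the linear window")
    missing = [a for a in analytes if a not in tc.products]
    if missing:
        raise ValueError(f"analytes not in time course: {missing}")
    t = tc.times[window]
    y = np.sum([tc.products[a][window] for a in analytes], axis=0)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flags = []
    # tolerance keeps round-off on perfectly flat series from flagging
    if slope < -1e-12 * max(1.0, float(np.max(np.abs(y)))):
        flags.append("negative slope")
    return RateResult(
        slope=float(slope),
        window=window,
        specific_activity=specific_activity(slope, tc.enzyme_conc),
        r_squared=r2,
        flags=flags,
    )


def specific_activity(slope: float, enzyme_conc: float) -> float:
    """Convert a product-formation slope to specific activity.

    slope µM/min = nmol·ml⁻¹·min⁻¹; dividing by enzyme concentration in
    mg/ml gives nmol·min⁻¹·mg⁻¹ = milliU/mg (1 U = 1 µmol/min).
    ``enzyme_conc`` is in µg/ml.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    return float(slope) / (enzyme_conc / 1000.0)


def fold_change(test: float, control: float) -> float:
    """Activity ratio relative to a substrate-only control."""
    if control <= 0:
        raise ValueError("control activity must be positive")
    return test / control


def relative_percent(rates, control: float):
    """Rates as percentages of a control rate (e.g. NMN-only deamidase runs)."""
    if control <= 0:
        raise ValueError("control rate must be positive")
    arr = np.asarray(rates, dtype=float)
    return list(100.0 * arr / control)
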