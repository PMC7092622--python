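"""Synthetic bioreactor time courses for gas fermentation.

The generator emulates fed-batch fermentations of *C. ljungdahlii* on
CO or H2/CO2 at controlled pH: logistic growth to a stated peak OD and
logistic product accumulation to stated end titers, sampled every 12 h,
with additive Gaussian replicate noise at the stated spreads.  It makes
no kinetic claims — its contract is endpoint fidelity and monotone
accumulation, which is all the downstream end-product ratio analysis
consumes.

Default conditions (mM, h):

==========  ======  =========================================  ============
condition   OD max  product caps                               peak reached
==========  ======  =========================================  ============
CO          8.4     ethanol 713, butanediol 188, acetate 185   120 h
H2_CO2      1.6     acetate 512, ethanol 42                    168 h
==========  ======  =========================================  ============
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "TimeCourse",
    "TimeCourseFormatError",
    "default_params",
    "simulate_fermentation",
    "end_product_ratios",
    "growth_summary",
    "read_timecourse",
    "write_timecourse",
    "DEFAULT_HORIZONS",
]

#: default fermentation horizons (h) per condition
DEFAULT_HORIZONS = {"CO": 120.0, "H2_CO2": 168.0}

#: hours between withdrawn samples
DEFAULT_STEP_H = 12.0


class TimeCourseFormatError(ValueError):
    """A time-course file violates the CSV schema or an invariant."""


@dataclass
class GrowthParams:
    """Logistic growth/accumulation parameters for one condition.

    ``lag_midpoint`` is the inflection time of the OD curve (h); product
    curves share the growth rate and are shifted ``product_lag_h`` later,
    so accumulation trails growth with the same sigmoid ordering.
    """

    condition: str
    od_max: float
    growth_rate: float  # 1/h
    lag_midpoint: float  # h
    product_caps: dict[str, float]  # mM
    noise_sd: dict[str, float]  # mM, replicate spread per product
    od_noise_sd: float = 0.0
    product_lag_h: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.od_max <= 0:
            raise ValueError(f"od_max must be positive, got {self.od_max}")
        if self.growth_rate <= 0:
            raise ValueError(f"growth_rate must be positive, got {self.growth_rate}")
        for prod, cap in self.product_caps.items():
            if cap < 0:
                raise ValueError(f"product cap for {prod} must be non-negative")
        for prod, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {prod} must be non-negative")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be non-negative")


def default_params(condition: str, seed: int = 0) -> GrowthParams:
    """Bundled study conditions for the CO and H2/CO2 fermentations."""
    if condition == "CO":
        return GrowthParams(
            condition="CO",
            od_max=8.4,
            growth_rate=0.12,
            lag_midpoint=45.0,
            product_caps={"ethanol": 713.0, "butanediol": 188.0, "acetate": 185.0},
            noise_sd={"ethanol": 21.0, "butanediol": 4.0, "acetate": 7.0},
            od_noise_sd=0.4,
            seed=seed,
        )
    if condition == "H2_CO2":
        return GrowthParams(
            condition="H2_CO2",
            od_max=1.6,
            growth_rate=0.09,
            lag_midpoint=78.0,
            product_caps={"acetate": 512.0, "ethanol": 42.0},
            noise_sd={"acetate": 6.0, "ethanol": 1.0},
            od_noise_sd=0.3,
            seed=seed,
        )
    raise ValueError(f"unknown condition {condition!r}; use 'CO' or 'H2_CO2'")


@dataclass
class TimeCourse:
    """Sampled OD and product concentrations over fermentation time."""

    condition: str
    times: np.ndarray  # h, strictly increasing
    od600: np.ndarray
    products: dict[str, np.ndarray]  # mM per time point
    replicate_sd: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.times) == 0:
            raise TimeCourseFormatError("empty time series")
        if not np.all(np.diff(self.times) > 0):
            raise TimeCourseFormatError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise TimeCourseFormatError("OD values must be non-negative")
        for prod, conc in self.products.items():
            if len(conc) != len(self.times):
                raise TimeCourseFormatError(f"length mismatch for product {prod!r}")
            if np.any(conc < 0):
                raise TimeCourseFormatError(f"negative concentration for {prod!r}")


def _logistic(t: np.ndarray, cap: float, rate: float, midpoint: float) -> np.ndarray:
    return cap / (1.0 + np.exp(-rate * (t - midpoint)))


def simulate_fermentation(
    params: GrowthParams,
    horizon_h: float | None = None,
    step_h: float = DEFAULT_STEP_H,
) -> TimeCourse:
    """Generate one noisy fermentation time course; deterministic under seed."""
    params.validate()
    if horizon_h is None:
        horizon_h = DEFAULT_HORIZONS.get(params.condition, 120.0)
    if horizon_h <= 0 or step_h <= 0:
        raise ValueError("horizon and step must be positive")
    rng = np.random.default_rng(params.seed)
    n = int(math.floor(horizon_h / step_h + 1e-9)) + 1
    times = np.arange(n) * step_h
    od = _logistic(times, params.od_max, params.growth_rate, params.lag_midpoint)
    od = np.maximum(od + rng.normal(0.0, params.od_noise_sd, size=n)
                    if params.od_noise_sd > 0 else od, 0.0)
    products: dict[str, np.ndarray] = {}
    mid = params.lag_midpoint + params.product_lag_h
    for prod in sorted(params.product_caps):
        conc = _logistic(times, params.product_caps[prod], params.growth_rate, mid)
        sd = params.noise_sd.get(prod, 0.0)
        if sd > 0:
            conc = conc + rng.normal(0.0, sd, size=n)
        products[prod] = np.maximum(conc, 0.0)
    tc = TimeCourse(
        condition=params.condition,
        times=times,
        od600=od,
        products=products,
        replicate_sd=dict(params.noise_sd),
    )
    tc.validate()
    return tc


def end_product_ratios(
    tc: TimeCourse, reference_product: str, at_max: bool = False
) -> dict[str, dict[str, float]]:
    """Mole ratios of end products relative to a reference.

    Concentrations are in mM, so concentration ratios are mole ratios
    directly.  The endpoint is the final sampled time by default
    (``at_max=True`` uses each product's maximum instead, for
    non-monotone inputs).  Returns, per product, the ratio and its
    nearest-integer rounding.
    """
    if reference_product not in tc.products:
        raise KeyError(f"reference product {reference_product!r} not in time course")

    def endpoint(conc: np.ndarray) -> float:
        return float(conc.max() if at_max else conc[-1])

    ref = endpoint(tc.products[reference_product])
    if ref == 0:
        raise ZeroDivisionError(
            f"reference product {reference_product!r} has zero final concentration"
        )
    out = {}
    for prod, conc in tc.products.items():
        ratio = endpoint(conc) / ref
        out[prod] = {"ratio": ratio, "rounded": float(round(ratio))}
    return out


def growth_summary(tc: TimeCourse) -> dict[str, float]:
    """Peak OD and the first time it is attained."""
    tc.validate()
    idx = int(np.argmax(tc.od600))  # argmax returns the first maximum
    return {"peak_od": float(tc.od600[idx]), "time_of_peak": float(tc.times[idx])}


# ---------------------------------------------------------------------------
# CSV round trip: header time_h,od600,<product>_mM,...


def write_timecourse(tc: TimeCourse, path: Union[str, Path]) -> None:
    tc.validate()
    frame = pd.DataFrame({"time_h": tc.times, "od600": tc.od600})
    for prod, conc in tc.products.items():
        frame[f"{prod}_mM"] = conc
    with open(path, "w") as fh:
        fh.write(f"# condition: {tc.condition}\n")
        sd = ",".join(f"{p}={v:g}" for p, v in sorted(tc.replicate_sd.items()))
        fh.write(f"# replicate_sd: {sd}\n")
        frame.to_csv(fh, index=False)


def read_timecourse(path: Union[str, Path]) -> TimeCourse:
    condition = ""
    replicate_sd: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].partition(":")
        key = key.strip()
        if key == "condition":
            condition = value.strip()
        elif key == "replicate_sd" and value.strip():
            for item in value.strip().split(","):
                prod, _, sd = item.partition("=")
                replicate_sd[prod.strip()] = float(sd)
    from io import StringIO

    try:
        frame = pd.read_csv(StringIO("".join(lines[body_start:])))
    except Exception as exc:
        raise TimeCourseFormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    for col in ("time_h", "od600"):
        if col not in frame.columns:
            raise TimeCourseFormatError(f"{path}: missing column {col!r}")
    product_cols = [c for c in frame.columns if c.endswith("_mM")]
    if not product_cols:
        raise TimeCourseFormatError(f"{path}: no product columns (*_mM) found")
    if frame[["time_h", "od600"] + product_cols].isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax()) + body_start + 2
        raise TimeCourseFormatError(f"{path}: malformed row near line {bad}")
    tc = TimeCourse(
        condition=condition,
        times=frame["time_h"].to_numpy(dtype=float),
        od600=frame["od600"].to_numpy(dtype=float),
        products={c[:-3]: frame[c].to_numpy(dtype=float) for c in product_cols},
        replicate_sd=replicate_sd,
    )
    tc.validate()
    return tc
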