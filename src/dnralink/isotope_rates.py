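"""Potential DNRA rates from 15N tracer slurry incubations.

A sediment slurry is spiked with 15N-labelled nitrate and the label is chased
into the extractable ammonium pool.  The rate of dissimilatory nitrate
reduction to ammonium (DNRA) follows from how much label accumulates:

    rate = MF_15NH4 * [NH4]  /  (MF_15NO3 * t)

where ``MF_15NH4`` is the mole fraction excess of 15N in the extractable
ammonium pool (corrected for the unlabelled carrier ammonium added before
diffusion trapping), ``[NH4]`` the extractable ammonium pool (nmol N per g
sediment), ``MF_15NO3`` the enrichment of the added tracer, and ``t`` the
incubation time in hours.  Rates are in nmol N g^-1 h^-1 throughout.

Two estimators are provided: the single-time-point (endpoint) form above and
an ordinary least-squares regression of excess 15NH4 mass against time, which
reduces to the endpoint form for exactly linear, zero-intercept series and is
the default for time-series data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TracerSample",
    "TracerSeries",
    "RateResult",
    "carrier_correct",
    "dnra_rate_endpoint",
    "dnra_rate_regression",
    "rates_from_table",
]

#: nmol of unlabelled carrier NH4 added before diffusion trapping (3 umol)
DEFAULT_CARRIER_NMOL = 3000.0
#: enrichment of the nitrate tracer (99 atom-%)
DEFAULT_MF_NO3 = 0.99


@dataclass(frozen=True)
class TracerSample:
    t: float  # hours
    mf_nh4_measured: float  # mole fraction excess of the diffused NH4 pool
    nh4_extractable: float  # nmol N g^-1


@dataclass
class TracerSeries:
    """Time series of 15NH4 label accumulation for one incubation."""

    site_id: str
    samples: list[TracerSample] = field(default_factory=list)
    mf_no3: float = DEFAULT_MF_NO3
    carrier_nh4: float = DEFAULT_CARRIER_NMOL

    def __post_init__(self) -> None:
        if not 0.0 < self.mf_no3 <= 1.0:
            raise ValueError("mf_no3 must be in (0, 1]")
        if self.carrier_nh4 < 0:
            raise ValueError("carrier_nh4 must be >= 0")
        for s in self.samples:
            if s.t < 0:
                raise ValueError("times must be >= 0")
            if not 0.0 <= s.mf_nh4_measured <= 1.0:
                raise ValueError("mole fractions must be in [0, 1]")
            if s.nh4_extractable <= 0:
                raise ValueError("nh4_extractable must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    def excess_mass(self) -> np.ndarray:
        """Carrier-corrected excess 15NH4 mass (nmol 15N g^-1) per sample."""
        return np.array(
            [
                carrier_correct(s.mf_nh4_measured, s.nh4_extractable, self.carrier_nh4)
                * s.nh4_extractable
                for s in self.samples
            ]
        )


@dataclass(frozen=True)
class RateResult:
    rate: float  # nmol N g^-1 h^-1
    se: float
    method: str  # "endpoint" | "regression"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")


def carrier_correct(mf_measured: float, pool: float, carrier: float) -> float:
    """Undo the isotope dilution caused by the unlabelled carrier ammonium.

    The measured pool is (pool + carrier) nmol, of which only ``pool`` came
    from the slurry; the excess label all sits in the slurry-derived fraction,
    so the true mole fraction excess is ``mf_measured * (pool + carrier) / pool``.
    """
    if pool <= 0:
        raise ValueError("pool must be > 0")
    if carrier < 0:
        raise ValueError("carrier must be >= 0")
    corrected = mf_measured * (pool + carrier) / pool
    if corrected > 1.0:
        warnings.warn(
            f"carrier-corrected mole fraction {corrected:.3g} exceeds 1; "
            "inputs are inconsistent",
            stacklevel=2,
        )
    return corrected


def dnra_rate_endpoint(series: TracerSeries, index: int = -1) -> RateResult:
    """Single-time-point rate: corrected MF x pool / (tracer MF x t)."""
    sample = series.samples[index]
    if sample.t <= 0:
        raise ValueError("endpoint estimate needs t > 0")
    mf = carrier_correct(sample.mf_nh4_measured, sample.nh4_extractable, series.carrier_nh4)
    rate = mf * sample.nh4_extractable / (series.mf_no3 * sample.t)
    return RateResult(rate=rate, se=0.0, method="endpoint")


def dnra_rate_regression(series: TracerSeries) -> RateResult:
    """OLS slope of excess 15NH4 mass vs time, divided by the tracer MF."""
    if len(series.samples) < 3:
        raise ValueError("regression estimate needs >= 3 time points")
    t = series.times
    y = series.excess_mass()
    fit = stats.linregress(t, y)
    rate = fit.slope / series.mf_no3
    se = fit.stderr / series.mf_no3
    if rate < 0:
        warnings.warn(
            f"fitted DNRA rate is negative ({rate:.3g} nmol N g^-1 h^-1); "
            "reported as-is",
            stacklevel=2,
        )
    return RateResult(rate=rate, se=se, method="regression")


def rates_from_table(
    table: pd.DataFrame,
    mf_no3: float = DEFAULT_MF_NO3,
    carrier_nmol: float = DEFAULT_CARRIER_NMOL,
) -> pd.DataFrame:
    """Per-site regression rates from a tidy incubation table.

    Expected columns: ``site_id``, ``t_hours``, ``mf_nh4``,
    ``nh4_extractable_umol_g`` (converted to nmol g^-1 internally).
    Returns a frame with columns site_id, rate, se (Table-2-style schema).
    """
    required = {"site_id", "t_hours", "mf_nh4", "nh4_extractable_umol_g"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for site, grp in table.groupby("site_id", sort=False):
        series = TracerSeries(
            site_id=str(site),
            samples=[
                TracerSample(
                    t=row.t_hours,
                    mf_nh4_measured=row.mf_nh4,
                    nh4_extractable=row.nh4_extractable_umol_g * 1000.0,
                )
                for row in grp.itertuples()
            ],
            mf_no3=mf_no3,
            carrier_nh4=carrier_nmol,
        )
        result = dnra_rate_regression(series)
        rows.append({"site_id": site, "rate": result.rate, "se": result.se})
    return pd.DataFrame(rows)
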