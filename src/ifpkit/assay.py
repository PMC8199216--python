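"""Fluorescence-polarization assay mathematics.

Polarization in millipolarization units (mP) is computed from the parallel
(S) and perpendicular (P) channel intensities after blank correction as

    mP = 1000 * (I_S - G * I_P) / (I_S + G * I_P)

with G the device-specific grating factor. Percent inhibition normalises an
inhibitor well against positive (bound tracer) and negative (free tracer)
controls:

    I% = 100 * (1 - (P_I - P_neg) / (P_pos - P_neg))

Dose-response curves are fitted with the four-parameter logistic (4PL,
variable-slope sigmoid)

    y(x) = bottom + (top - bottom) / (1 + 10**(hill * (log10 IC50 - log10 x)))

by bounded least squares. IC50 is reported in the unit of the input
concentrations; no unit inference is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ifpkit.errors import DegenerateDataError

__all__ = [
    "FPMeasurement",
    "InhibitionPoint",
    "DoseResponseFit",
    "polarization_mP",
    "blank_correct",
    "percent_inhibition",
    "four_param_logistic",
    "FourParamLogistic",
    "fit_4pl",
]


@dataclass(frozen=True)
class FPMeasurement:
    """One blank-corrected polarization read: S/P intensities and G factor."""

    I_S: float
    I_P: float
    G: float = 1.0

    def __post_init__(self):
        if self.I_S < 0 or self.I_P < 0:
            raise ValueError("intensities must be >= 0")
        if self.G <= 0:
            raise ValueError("G factor must be > 0")


@dataclass(frozen=True)
class InhibitionPoint:
    """mP values of an inhibitor well and its two controls."""

    P_I: float
    P_neg: float
    P_pos: float
    concentration: Optional[float] = None


def polarization_mP(m: FPMeasurement) -> float:
    """Polarization in mP units; result lies in [-1000, 1000]."""
    denom = m.I_S + m.G * m.I_P
    if denom == 0:
        raise ZeroDivisionError("I_S + G*I_P is zero; polarization undefined")
    return 1000.0 * (m.I_S - m.G * m.I_P) / denom


def blank_correct(raw, blank):
    """Channel-wise blank subtraction; negatives clamp to 0 with a warning."""
    raw_arr = np.asarray(raw, dtype=float)
    blank_arr = np.asarray(blank, dtype=float)
    if raw_arr.shape != blank_arr.shape:
        raise ValueError(f"shape mismatch: raw {raw_arr.shape} vs blank {blank_arr.shape}")
    out = raw_arr - blank_arr
    if np.any(out < 0):
        warnings.warn("blank exceeds raw intensity; clamping to 0", stacklevel=2)
        out = np.clip(out, 0.0, None)
    return out


def percent_inhibition(p: InhibitionPoint) -> float:
    """Percent inhibition; may fall outside [0, 100] and is reported as-is."""
    if p.P_pos == p.P_neg:
        raise ZeroDivisionError("positive and negative controls are equal")
    return 100.0 * (1.0 - (p.P_I - p.P_neg) / (p.P_pos - p.P_neg))


def four_param_logistic(x, bottom, top, log_ic50, hill):
    """Variable-slope sigmoid evaluated at concentration(s) ``x`` (> 0)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - np.log10(x))))


@dataclass
class DoseResponseFit:
    """Results of a 4PL dose-response fit.

    Parameter standard errors are asymptotic (from the covariance of the
    least-squares estimate). ``converged`` is False when the optimizer
    failed or the covariance is singular; the point estimates are still
    reported in that case.
    """

    ic50: float
    hill: float
    top: float
    bottom: float
    ic50_se: float
    hill_se: float
    top_se: float
    bottom_se: float
    residual_rms: float
    n_points: int
    converged: bool
    compound: str = "compound"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "compound": self.compound, "ic50": self.ic50, "hill": self.hill,
            "top": self.top, "bottom": self.bottom, "ic50_se": self.ic50_se,
            "hill_se": self.hill_se, "top_se": self.top_se,
            "bottom_se": self.bottom_se, "residual_rms": self.residual_rms,
            "n_points": self.n_points, "converged": self.converged,
        }])

    def to_dict(self) -> dict:
        d = self.to_frame().iloc[0].to_dict()
        d["n_points"] = int(d["n_points"])
        d["converged"] = bool(d["converged"])
        d["metadata"] = self.metadata
        return d

    def predict(self, x):
        return four_param_logistic(x, self.bottom, self.top,
                                   np.log10(self.ic50), self.hill)

    def summary(self) -> str:
        rows = [
            ("IC50", self.ic50, self.ic50_se),
            ("Hill slope", self.hill, self.hill_se),
            ("Top plateau", self.top, self.top_se),
            ("Bottom plateau", self.bottom, self.bottom_se),
        ]
        lines = [f"4PL dose-response fit: {self.compound}",
                 f"  n points: {self.n_points}   converged: {self.converged}"
                 f"   residual RMS: {self.residual_rms:.4g}",
                 f"  {'parameter':<16}{'estimate':>14}{'std err':>14}"]
        for name, est, se in rows:
            lines.append(f"  {name:<16}{est:>14.6g}{se:>14.3g}")
        return "\n".join(lines)


class FourParamLogistic:
    """Four-parameter logistic dose-response model.

    Parameters
    ----------
    concentration : array-like of positive concentrations (any single unit)
    response : array-like of responses (percent inhibition by default)

    Replicate wells are passed as repeated concentration values and fitted
    as individual points unless ``fit(average_replicates=True)``.

    Examples
    --------
    >>> fit = FourParamLogistic(conc, inhib).fit()
    >>> fit.ic50, fit.hill
    """

    #: response span below which the data are considered flat
    MIN_RESPONSE_RANGE = 1e-6

    def __init__(self, concentration, response, compound: str = "compound"):
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("concentration and response must be equal-length 1-D")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        if len(np.unique(conc)) < 4:
            raise ValueError("4PL fit needs >= 4 distinct concentrations")
        self.concentration = conc
        self.response = resp
        self.compound = compound

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, compound: str = "compound",
                       G: float = 1.0):
        """Build from a long table with ``concentration`` and either a
        ``response`` column or raw ``I_S``/``I_P`` intensity columns."""
        if "response" in df.columns:
            resp = df["response"].to_numpy(dtype=float)
        elif {"I_S", "I_P"} <= set(df.columns):
            resp = np.array([
                polarization_mP(FPMeasurement(r.I_S, r.I_P, G))
                for r in df.itertuples()
            ])
        else:
            raise ValueError("need a 'response' column or 'I_S'/'I_P' columns")
        return cls(df["concentration"].to_numpy(dtype=float), resp, compound=compound)

    def _initial_params(self, conc, resp):
        bottom0 = float(resp.min())
        top0 = float(resp.max())
        mid = 0.5 * (top0 + bottom0)
        log_ic50_0 = float(np.log10(conc[np.argmin(np.abs(resp - mid))]))
        return [bottom0, top0, log_ic50_0, 1.0]

    def fit(self, average_replicates: bool = False) -> DoseResponseFit:
        """Bounded least-squares fit; returns a :class:`DoseResponseFit`.

        Raises
        ------
        DegenerateDataError
            When the response range is below ``MIN_RESPONSE_RANGE`` (flat
            data carry no dose-response signal).
        """
        conc = self.concentration
        resp = self.response
        if average_replicates:
            df = pd.DataFrame({"c": conc, "r": resp}).groupby("c", sort=True).mean()
            conc = df.index.to_numpy()
            resp = df["r"].to_numpy()
        span = float(resp.max() - resp.min())
        if span < self.MIN_RESPONSE_RANGE:
            raise DegenerateDataError(
                f"response range {span:.3g} below {self.MIN_RESPONSE_RANGE}; "
                "flat data cannot constrain a sigmoid")
        p0 = self._initial_params(conc, resp)
        lg = np.log10(conc)
        # IC50 kept within 3 decades of the tested range; hill sign free
        bounds = ([-np.inf, -np.inf, lg.min() - 3.0, -10.0],
                  [np.inf, np.inf, lg.max() + 3.0, 10.0])
        converged = True
        try:
            popt, pcov = curve_fit(four_param_logistic, conc, resp, p0=p0,
                                   bounds=bounds, maxfev=20000)
        except RuntimeError:
            converged = False
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((4, 4), np.nan)
        bottom, top, log_ic50, hill = popt
        resid = resp - four_param_logistic(conc, *popt)
        perr = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(perr)):
            converged = converged and False
        ic50 = float(10.0 ** log_ic50)
        # delta method: se(IC50) = ln(10) * IC50 * se(log10 IC50)
        ic50_se = float(np.log(10.0) * ic50 * perr[2]) if np.isfinite(perr[2]) else np.nan
        return DoseResponseFit(
            ic50=ic50, hill=float(hill), top=float(top), bottom=float(bottom),
            ic50_se=ic50_se, hill_se=float(perr[3]), top_se=float(perr[1]),
            bottom_se=float(perr[0]),
            residual_rms=float(np.sqrt(np.mean(resid ** 2))),
            n_points=len(conc), converged=bool(converged),
            compound=self.compound,
            metadata={
                "model": "4PL variable slope",
                "initialization": "top/bottom from response extrema, IC50 from "
                                  "concentration nearest half-response, hill=1",
                "average_replicates": bool(average_replicates),
            },
        )


def fit_4pl(concentrations, inhibitions, average_replicates: bool = False,
            compound: str = "compound") -> DoseResponseFit:
    """Convenience wrapper: 4PL fit of inhibition percent vs concentration."""
    return FourParamLogistic(concentrations, inhibitions,
                             compound=compound).fit(average_replicates=average_replicates)
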