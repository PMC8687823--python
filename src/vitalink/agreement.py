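"""Device-agreement statistics for paired measured/reference readings.

Given K pairs (measured_i, reference_i) from a device under test and a
commercial reference, computes the standard method-comparison suite:

* RMSE  = sqrt( sum_i (ref_i - mes_i)^2 / K )
* MAE   = sum_i |ref_i - mes_i| / K
* MRE   = (1/K) sum_i |ref_i - mes_i| / ref_i   (fraction; x100 as percent)
* per-reading percent error 100 |mes - ref| / ref
* ordinary least squares of reference on measured, with R^2 the squared
  Pearson correlation (a perfect device matches the identity line y = x)
* Bland-Altman analysis: differences d_i = measured_i - reference_i against
  pair averages, with 95% limits of agreement mean(d) +/- 1.96 SD(d)

Sign conventions: the error statistics use ref - mes (absolute values make
the choice moot); Bland-Altman differences are measured - reference.  The
SD in the limits of agreement uses the sample convention (divisor K-1) by
default; this is configurable and recorded in the result.  All statistics
are computed at full precision — rounding is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)

LOA_Z = 1.96  # normal 95% quantile used for the limits of agreement


@dataclass
class PairedReadings:
    """K paired (measured, reference) values for one vital parameter."""

    parameter: str
    measured: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.measured.shape != self.reference.shape or self.measured.ndim != 1:
            raise InvalidParameterError("measured and reference must be equal-length 1-D")
        if self.K < 2:
            raise InsufficientDataError("need at least 2 pairs")
        if not (
            np.all(np.isfinite(self.measured)) and np.all(np.isfinite(self.reference))
        ):
            raise InvalidParameterError("readings must be finite")
        if np.any(self.reference <= 0):
            raise InvalidParameterError(
                "reference values must be positive (relative-error denominator)"
            )

    @property
    def K(self) -> int:
        return int(self.measured.size)

    @classmethod
    def from_pairs(cls, parameter: str, pairs) -> "PairedReadings":
        arr = np.asarray(pairs, dtype=float)
        return cls(parameter, arr[:, 0], arr[:, 1])


def rmse(p: PairedReadings) -> float:
    """Root mean squared error between reference and measured readings."""
    d = p.reference - p.measured
    return float(np.sqrt(np.mean(d * d)))


def mae(p: PairedReadings) -> float:
    """Mean absolute error."""
    return float(np.mean(np.abs(p.reference - p.measured)))


def mre(p: PairedReadings) -> float:
    """Mean relative error as a dimensionless fraction (x100 for percent)."""
    return float(np.mean(np.abs(p.reference - p.measured) / p.reference))


def per_reading_error(measured, reference):
    """Percent error of a single reading, rounded to 2 d.p. for display."""
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise InvalidParameterError("reference must be positive")
    err = 100.0 * np.abs(np.asarray(measured, float) - reference) / reference
    out = np.round(err, 2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def linear_fit(p: PairedReadings) -> LinearFit:
    """OLS of reference (y) on measured (x); R^2 = squared Pearson r.

    The squared-correlation definition (not 1 - SSres/SStot about the
    identity line) is the one under which a device can have tiny errors yet
    near-zero R^2 when the underlying quantity barely varies — exactly the
    situation for SpO2 readings clustered in 97-100%.
    """
    if p.K < 3:
        raise InsufficientDataError("need at least 3 pairs for a linear fit")
    if np.ptp(p.measured) == 0:
        raise DegenerateFitError("measured values have zero variance")
    res = sps.linregress(p.measured, p.reference)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclass
class BlandAltman:
    """Difference-vs-average analysis with 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n_outside_loa: int
    averages: np.ndarray
    differences: np.ndarray
    sd_ddof: int


def bland_altman(p: PairedReadings, sd_ddof: int = 1) -> BlandAltman:
    """Bland-Altman limits mean(d) +/- 1.96 SD(d), d = measured - reference.

    ``sd_ddof=1`` (sample SD, divisor K-1) is the default; pass 0 for the
    population convention.  ``n_outside_loa`` counts differences strictly
    beyond either limit.
    """
    if p.K < 3:
        raise InsufficientDataError("need at least 3 pairs for Bland-Altman limits")
    d = p.measured - p.reference
    avg = 0.5 * (p.measured + p.reference)
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=sd_ddof))
    upper = mean_d + LOA_Z * sd_d
    lower = mean_d - LOA_Z * sd_d
    outside = int(np.sum((d > upper) | (d < lower)))
    return BlandAltman(mean_d, sd_d, lower, upper, outside, avg, d, sd_ddof)


@dataclass
class AgreementReport:
    """All agreement statistics for one paired table."""

    parameter: str
    n_pairs: int
    rmse: float
    mae: float
    mre: float            # fraction
    mre_percent: float    # fraction x 100
    slope: float
    intercept: float
    r_squared: float
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n_outside_loa: int
    sd_ddof: int

    def summary_row(self) -> tuple[float, float, float, float]:
        """(RMSE, MAE, MRE, R^2) rounded for display: 2, 2, 3, 3 d.p."""
        return (
            round(self.rmse, 2),
            round(self.mae, 2),
            round(self.mre, 3),
            round(self.r_squared, 3),
        )

    def to_text(self) -> str:
        lines = [
            f"Agreement report: {self.parameter} (K = {self.n_pairs})",
            f"  RMSE            {self.rmse:8.2f}",
            f"  MAE             {self.mae:8.2f}",
            f"  MRE             {self.mre:8.3f}  ({self.mre_percent:.2f} %)",
            f"  fit slope       {self.slope:8.3f}",
            f"  fit intercept   {self.intercept:8.3f}",
            f"  R^2             {self.r_squared:8.3f}",
            f"  mean difference {self.mean_diff:8.4f}",
            f"  SD difference   {self.sd_diff:8.4f}  (ddof={self.sd_ddof})",
            f"  95% LoA         [{self.loa_lower:.4f}, {self.loa_upper:.4f}]",
            f"  points outside  {self.n_outside_loa:4d}",
        ]
        return "\n".join(lines)


def agreement_report(p: PairedReadings, sd_ddof: int = 1) -> AgreementReport:
    """Compose every statistic above into one report."""
    fit = linear_fit(p)
    ba = bland_altman(p, sd_ddof=sd_ddof)
    the_mre = mre(p)
    return AgreementReport(
        parameter=p.parameter,
        n_pairs=p.K,
        rmse=rmse(p),
        mae=mae(p),
        mre=the_mre,
        mre_percent=100.0 * the_mre,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        n_outside_loa=ba.n_outside_loa,
        sd_ddof=ba.sd_ddof,
    )
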