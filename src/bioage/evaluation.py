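"""Model-assessment statistics: regression of corrected age on chronological
age, standard error of the estimate, Bland-Altman agreement, and a paired t
test of the mean age difference (CA - BAc; positive = biologically younger).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import DomainError

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement


@dataclass
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    see: float


@dataclass
class AgreementReport:
    """Everything needed to judge agreement between BAc and CA."""

    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    see: float
    bias: float
    loa_low: float
    loa_high: float
    paired_t: float
    paired_t_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def regress_bac_on_ca(bac, ca) -> RegressionResult:
    """OLS of corrected age on chronological age, with the SEE.

    SEE = sqrt(sum residuals^2 / (n - 2)) in years.
    """
    bac, ca = _pair(bac, ca)
    n = len(bac)
    if n < 3:
        raise DomainError("need >= 3 records")
    if np.ptp(ca) == 0:
        raise DomainError("zero CA variance")
    fit = stats.linregress(ca, bac)
    resid = bac - (fit.intercept + fit.slope * ca)
    see = float(np.sqrt((resid**2).sum() / (n - 2)))
    return RegressionResult(n=n, slope=float(fit.slope),
                            intercept=float(fit.intercept), r=float(fit.rvalue),
                            r_squared=float(fit.rvalue**2), see=see)


def bland_altman(ca, bac, loa_multiplier: float = LOA_MULTIPLIER):
    """Bias and limits of agreement of the differences d = CA - BAc.

    Returns ``(bias, (loa_low, loa_high))`` with LoA = bias +/- 1.96*SD(d).
    """
    ca, bac = _pair(ca, bac)
    if len(ca) < 2:
        raise DomainError("need >= 2 records")
    d = ca - bac
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - loa_multiplier * sd, bias + loa_multiplier * sd)


def paired_t(ca, bac) -> tuple[float, float, bool]:
    """Paired t test of mean(CA - BAc) = 0; returns (t, two-sided p, degenerate).

    With zero-variance differences the statistic is undefined; the degenerate
    flag is set and p is reported as the limit (1 when the bias is 0, else 0).
    """
    ca, bac = _pair(ca, bac)
    if len(ca) < 2:
        raise DomainError("need >= 2 records")
    d = ca - bac
    if d.std(ddof=1) == 0:
        return (0.0 if d.mean() == 0 else np.inf * np.sign(d.mean()),
                1.0 if d.mean() == 0 else 0.0, True)
    t, p = stats.ttest_rel(ca, bac)
    return float(t), float(p), False


def agreement_report(ca, bac) -> AgreementReport:
    """Full evaluation of predictions against chronological age."""
    reg = regress_bac_on_ca(bac, ca)
    bias, (lo, hi) = bland_altman(ca, bac)
    t, p, degenerate = paired_t(ca, bac)
    return AgreementReport(n=reg.n, slope=reg.slope, intercept=reg.intercept,
                           r=reg.r, r_squared=reg.r_squared, see=reg.see,
                           bias=bias, loa_low=lo, loa_high=hi,
                           paired_t=t, paired_t_p=p, degenerate=degenerate)
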