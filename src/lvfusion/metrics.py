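"""Global cardiac function parameters and study evaluation statistics.

Given paired end-diastolic/end-systolic endocardial volumes (and an
epicardial end-diastolic volume for mass), this module derives the clinical
summary numbers — stroke volume SV = EDV - ESV, ejection fraction
EF = 100 * SV / EDV, and LV myocardial mass LVM = density * (epi EDV - EDV)
with the standard myocardial density of 1.05 g/ml — plus the agreement
statistics used to evaluate volume estimators: percent-error mean/SD,
Bland-Altman bias and limits of agreement, and a paired significance test.

All standard deviations use the sample (n - 1) denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class FunctionReport:
    """Global-function summary for one subject/phantom and method."""

    edv: float
    esv: float
    sv: float
    ef: float
    lvm: float
    method: str = ""
    n_slices: int | None = None


def global_function(
    edv: float,
    esv: float,
    epi_edv: float,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
    method: str = "",
    n_slices: int | None = None,
) -> FunctionReport:
    """Ejection fraction, stroke volume and LV mass from volume estimates.

    Volumes in ml, mass in g.  A pathological ESV > EDV passes through with a
    warning (EF reported negative); myocardial mass uses the end-diastolic
    epicardial-minus-endocardial volume.
    """
    if edv <= 0:
        raise ConfigurationError("EDV must be positive")
    if esv < 0:
        raise ConfigurationError("ESV must be non-negative")
    if epi_edv < edv:
        raise ConfigurationError("epicardial EDV must be >= endocardial EDV")
    if esv > edv:
        warnings.warn("ESV exceeds EDV; EF will be negative", RuntimeWarning,
                      stacklevel=2)
    sv = edv - esv
    ef = 100.0 * sv / edv
    lvm = density * (epi_edv - edv)
    return FunctionReport(edv=edv, esv=esv, sv=sv, ef=ef, lvm=lvm,
                          method=method, n_slices=n_slices)


def percent_error_stats(estimates, truths) -> tuple[float, float]:
    """Mean and sample SD of per-case percent errors 100 * (est - truth) / truth."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ConfigurationError("estimates and truths must be equal-length, non-empty")
    if np.any(tru <= 0):
        raise ConfigurationError("truth volumes must be positive")
    err = 100.0 * (est - tru) / tru
    sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return float(np.mean(err)), sd


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement of paired differences (a - b)."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(method_a, method_b) -> BlandAltman:
    """Bland-Altman agreement between two paired volume series (ml).

    Differences are a - b; limits of agreement are bias +/- 1.96 SD.  The
    per-pair (mean, difference) points are returned for plotting.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ConfigurationError("need paired lists with n >= 2")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=0.5 * (a + b),
        differences=diff,
    )


def paired_significance(
    errors_a, errors_b, alpha: float = 0.05, method: str = "t"
) -> tuple[float, float, bool]:
    """Two-sided paired comparison of two error series.

    Default is the paired t-test; ``method="wilcoxon"`` switches to the
    Wilcoxon signed-rank test.  Returns (statistic, p-value, significant
    flag at ``alpha``).  All-zero differences degenerate to p = 1 with a
    warning.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ConfigurationError("need paired lists with n >= 3")
    diff = a - b
    if np.allclose(diff, 0.0):
        warnings.warn("all paired differences are zero; test degenerate",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 1.0, False
    if method == "t":
        res = stats.ttest_rel(a, b)
    elif method == "wilcoxon":
        res = stats.wilcoxon(a, b)
    else:
        raise ConfigurationError(f"unknown test method {method!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    return stat, p, bool(p < alpha)
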