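"""Limiting-dilution analysis under the single-hit Poisson model.

Graded doses of cells are seeded across many wells and each well is scored
positive or negative for an outgrowth readout.  Under the single-hit Poisson
model a well seeded with n cells is negative with probability exp(-f * n),
where f is the frequency of competent progenitors.  The reciprocal 1/f is
therefore exactly the dose at which the expected failure (negative-well)
rate is e^-1 ~ 0.37 — the conventional way such frequencies are reported.
The maximum-likelihood estimate of f is found on the log scale, with Wald or
profile-likelihood confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "LDADataset",
    "FrequencyEstimate",
    "estimate_frequency",
    "predicted_failure_rate",
]

_LOGF_LO, _LOGF_HI = -30.0, 0.0  # search bounds on log f; f in (1e-13, 1]


@dataclass
class LDADataset:
    """Per-dose well counts: cells/well, wells tested, wells negative."""

    dose: np.ndarray
    tested: np.ndarray
    negative: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.tested = np.asarray(self.tested, dtype=int)
        self.negative = np.asarray(self.negative, dtype=int)
        if not (len(self.dose) == len(self.tested) == len(self.negative)):
            raise ValueError("dose/tested/negative lengths differ")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if len(np.unique(self.dose)) != len(self.dose):
            raise ValueError("doses must be distinct")
        if np.any(self.tested <= 0):
            raise ValueError("tested well counts must be positive")
        if np.any((self.negative < 0) | (self.negative > self.tested)):
            raise ValueError("need 0 <= negative <= tested at every dose")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "LDADataset":
        required = {"dose", "tested", "negative"}
        if not required.issubset(df.columns):
            raise ValueError(f"LDA table needs columns {sorted(required)}")
        return cls(
            dose=df["dose"].to_numpy(),
            tested=df["tested"].to_numpy(),
            negative=df["negative"].to_numpy(),
            meta=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose": self.dose.astype(int), "tested": self.tested, "negative": self.negative}
        )


@dataclass
class FrequencyEstimate:
    f: float  # per-cell progenitor frequency
    reciprocal: float  # cells per progenitor, 1/f
    ci95: tuple[float, float]  # on the reciprocal scale, low <= 1/f <= high
    loglik: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def predicted_failure_rate(f: float, n: float) -> float:
    """Expected negative-well fraction exp(-f*n) at dose n cells/well."""
    if f <= 0 or n <= 0:
        raise ValueError("f and n must be positive")
    return math.exp(-f * n)


def loglik(f: float, data: LDADataset) -> float:
    """Binomial log-likelihood of the negative-well counts at frequency f.

    l(f) = sum_i [ neg_i * (-f * n_i) + (tested_i - neg_i) * log(1 - exp(-f * n_i)) ]
    """
    fn = f * data.dose
    pos = data.tested - data.negative
    with np.errstate(divide="ignore"):
        log_p_pos = np.log(-np.expm1(-fn))
    ll = -(data.negative * fn).sum()
    if np.any(pos > 0):
        ll += float((pos * log_p_pos)[pos > 0].sum())
    return float(ll)


def _observed_information_logf(logf: float, data: LDADataset) -> float:
    """-d^2 l / d(log f)^2 at logf, by central finite differences."""
    h = 1e-4
    f0, fp, fm = (math.exp(logf + d) for d in (0.0, h, -h))
    l0, lp, lm = (loglik(f, data) for f in (f0, fp, fm))
    return -(lp - 2 * l0 + lm) / h**2


def _profile_ci(fhat: float, data: LDADataset) -> tuple[float, float]:
    """95% profile-likelihood interval for f (then inverted to reciprocal)."""
    lmax = loglik(fhat, data)
    cut = lmax - chi2.ppf(0.95, df=1) / 2

    def g(logf: float) -> float:
        return loglik(math.exp(logf), data) - cut

    lo_log = math.log(fhat)
    while g(lo_log) > 0 and lo_log > _LOGF_LO:
        lo_log -= 1.0
    f_lo = math.exp(brentq(g, lo_log, math.log(fhat))) if g(lo_log) <= 0 else math.exp(_LOGF_LO)
    hi_log = math.log(fhat)
    while g(hi_log) > 0 and hi_log < _LOGF_HI:
        hi_log += 1.0
    f_hi = math.exp(brentq(g, math.log(fhat), hi_log)) if g(hi_log) <= 0 else math.exp(_LOGF_HI)
    return f_lo, f_hi


def estimate_frequency(data: LDADataset, ci: str = "wald") -> FrequencyEstimate:
    """Maximum-likelihood single-hit Poisson frequency estimate.

    The likelihood is maximized over log f (unconstrained 1-D bracketed
    search).  Degenerate datasets — all wells negative, or all wells
    positive at every dose — pin the estimate at a search boundary and are
    returned with ``converged=False`` and an explanatory flag rather than an
    infinite estimate.  ``ci`` selects "wald" (on log f, back-transformed)
    or "profile" (likelihood-ratio inversion).
    """
    flags: list[str] = []
    all_negative = bool(np.all(data.negative == data.tested))
    all_positive = bool(np.all(data.negative == 0))

    if all_negative:
        f = math.exp(_LOGF_LO)
        return FrequencyEstimate(
            f=f,
            reciprocal=1.0 / f,
            ci95=(1.0, math.inf),
            loglik=loglik(f, data),
            converged=False,
            flags=["no positive wells: frequency at lower boundary"],
        )
    if all_positive:
        f = math.exp(_LOGF_HI)
        return FrequencyEstimate(
            f=f,
            reciprocal=1.0 / f,
            ci95=(0.0, 1.0 / f),
            loglik=loglik(f, data),
            converged=False,
            flags=["no negative wells: frequency at upper boundary"],
        )

    res = minimize_scalar(
        lambda logf: -loglik(math.exp(logf), data),
        bounds=(_LOGF_LO, _LOGF_HI),
        method="bounded",
        options={"xatol": 1e-12},
    )
    logf_hat = float(res.x)
    fhat = math.exp(logf_hat)
    lmax = loglik(fhat, data)

    if ci == "profile":
        f_lo, f_hi = _profile_ci(fhat, data)
    else:
        info = _observed_information_logf(logf_hat, data)
        if info > 0:
            se = 1.0 / math.sqrt(info)
            f_lo = math.exp(logf_hat - 1.959963984540054 * se)
            f_hi = math.exp(logf_hat + 1.959963984540054 * se)
        else:
            f_lo, f_hi = 0.0, math.inf
            flags.append("non-positive observed information: CI unavailable")
    # invert to the reciprocal (cells-per-progenitor) scale
    ci_rec = (1.0 / f_hi, 1.0 / f_lo if f_lo > 0 else math.inf)
    return FrequencyEstimate(
        f=fhat,
        reciprocal=1.0 / fhat,
        ci95=ci_rec,
        loglik=lmax,
        converged=bool(res.success),
        flags=flags,
    )
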