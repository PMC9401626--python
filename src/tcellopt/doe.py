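"""Orthogonal central composite designs with logarithmic concentration scaling.

A central composite design (CCD) augments a two-level (fractional) factorial
in coded units (-1, +1) with axial points at +/- alpha and replicated center
points, yielding a five-level design that supports a full second-order
response-surface model.  Cytokine concentrations map to coded units on a
log10 scale, so the coded center is the geometric mean of the tested range
and equal coded steps correspond to equal fold-changes in concentration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "CCDesign",
    "make_ccd",
    "coded_to_conc",
    "conc_to_coded",
]

DEFAULT_ALPHA = 2.366


@dataclass(frozen=True)
class FactorSpec:
    """One cytokine factor: name and the concentration range mapped to coded -1/+1.

    Concentrations must be strictly positive because the coded scale is
    logarithmic; a zero dose has no finite coded value.
    """

    name: str
    conc_low: float
    conc_high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.conc_low < self.conc_high):
            raise ValueError(
                f"factor {self.name!r}: require 0 < conc_low < conc_high, "
                f"got ({self.conc_low}, {self.conc_high})"
            )


@dataclass
class CCDesign:
    """A central composite design in coded units plus the factor mappings."""

    factors: list[FactorSpec]
    coded_matrix: np.ndarray  # runs x factors
    point_type: list[str]  # per-run: "factorial" | "axial" | "center"
    alpha: float = DEFAULT_ALPHA
    n_center: int = 8
    run_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coded_matrix = np.asarray(self.coded_matrix, dtype=float)
        if self.coded_matrix.shape != (len(self.point_type), len(self.factors)):
            raise ValueError("coded_matrix shape inconsistent with factors/point_type")
        if not self.run_ids:
            self.run_ids = [f"run{i + 1:03d}" for i in range(self.n_runs)]

    @property
    def n_runs(self) -> int:
        return self.coded_matrix.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def concentrations(self) -> np.ndarray:
        """Concentration matrix (runs x factors) implied by the coded matrix."""
        out = np.empty_like(self.coded_matrix)
        for j, fac in enumerate(self.factors):
            out[:, j] = coded_to_conc(fac, self.coded_matrix[:, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run_id, point_type, coded and concentration columns."""
        df = pd.DataFrame(
            self.coded_matrix,
            columns=[f"coded_{n}" for n in self.factor_names],
        )
        conc = self.concentrations()
        for j, n in enumerate(self.factor_names):
            df[f"conc_{n}"] = conc[:, j]
        df.insert(0, "point_type", self.point_type)
        df.insert(0, "run_id", self.run_ids)
        return df


def _fractional_factorial(k: int) -> np.ndarray:
    """Two-level factorial portion in standard (Yates) order.

    Up to 4 factors the full 2^k factorial is used.  For 5-8 factors a
    half fraction is generated from the full factorial in the first k-1
    factors with the last column defined as the product of the others
    (defining relation I = ABC...K), the highest-resolution half fraction.
    For six factors this is the 32-run resolution-VI fraction in which all
    main effects, quadratics and two-factor interactions are estimable.
    """
    if k <= 4:
        base = k
        frac = False
    else:
        base = k - 1
        frac = True
    # Yates standard order: first factor alternates fastest.
    rows = np.array(
        [levels[::-1] for levels in itertools.product([-1.0, 1.0], repeat=base)]
    )
    if frac:
        gen = rows.prod(axis=1, keepdims=True)
        rows = np.hstack([rows, gen])
    return rows


def make_ccd(
    factors: list[FactorSpec],
    alpha: float = DEFAULT_ALPHA,
    n_center: int = 8,
    shuffle_seed: int | None = None,
) -> CCDesign:
    """Construct a central composite design for the given factors.

    Runs are ordered deterministically: factorial block in standard order,
    then axial pairs (-alpha, +alpha) factor by factor, then center runs.
    Pass ``shuffle_seed`` to randomize run order reproducibly.
    """
    k = len(factors)
    if not 2 <= k <= 8:
        raise ValueError(f"supported factor count is 2..8, got {k}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")

    fact = _fractional_factorial(k)
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, k))

    coded = np.vstack([fact, axial, center])
    ptype = (
        ["factorial"] * fact.shape[0]
        + ["axial"] * (2 * k)
        + ["center"] * n_center
    )
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(coded.shape[0])
        coded = coded[order]
        ptype = [ptype[i] for i in order]
    return CCDesign(
        factors=list(factors),
        coded_matrix=coded,
        point_type=ptype,
        alpha=alpha,
        n_center=n_center,
    )


def coded_to_conc(factor: FactorSpec, x):
    """Map coded level(s) to concentration on the log10 scale.

    conc(x) = 10 ** (log10(sqrt(low*high)) + x * log10(high/low) / 2),
    so conc(-1) = low, conc(0) = geometric mean, conc(+1) = high.
    """
    center = 0.5 * (np.log10(factor.conc_low) + np.log10(factor.conc_high))
    halfwidth = 0.5 * (np.log10(factor.conc_high) - np.log10(factor.conc_low))
    out = 10.0 ** (center + np.asarray(x, dtype=float) * halfwidth)
    return float(out) if out.ndim == 0 else out


def conc_to_coded(factor: FactorSpec, c):
    """Inverse of :func:`coded_to_conc`; concentrations must be positive."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0")
    center = 0.5 * (np.log10(factor.conc_low) + np.log10(factor.conc_high))
    halfwidth = 0.5 * (np.log10(factor.conc_high) - np.log10(factor.conc_low))
    out = (np.log10(c) - center) / halfwidth
    return float(out) if out.ndim == 0 else out
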