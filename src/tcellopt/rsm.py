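"""Polynomial dose-response surfaces over coded cytokine concentrations.

Counts of each phenotype (proT, CD4ISP, DP, CD8SP, ...) are modelled as a
second-order polynomial in the coded design variables — intercept, linear,
pure-quadratic, and two-factor-interaction terms — optionally extended with
selected third-order terms when they improve the adjusted R^2.  Responses may
be fitted on the raw count scale or after a log(x+1) transform (natural log);
least-squares coefficients are obtained by ordinary least squares.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .doe import CCDesign

__all__ = [
    "TermSpec",
    "ResponseModel",
    "build_terms",
    "term_name",
    "parse_term",
    "design_matrix",
    "fit_response",
    "select_third_order",
    "predict",
    "write_coefficients",
    "read_coefficients",
]

TRANSFORMS = ("identity", "log1p")

# A term is a tuple of per-factor exponents, e.g. (1, 0, 2) = A * C^2.
TermSpec = tuple[int, ...]


def term_degree(term: TermSpec) -> int:
    return sum(term)


def term_name(term: TermSpec, factor_names: list[str]) -> str:
    """Human-readable term token, e.g. ``IL7``, ``IL7^2``, ``IL7*TNFa``."""
    if term_degree(term) == 0:
        return "Intercept"
    parts = []
    for e, name in zip(term, factor_names):
        if e == 1:
            parts.append(name)
        elif e > 1:
            parts.append(f"{name}^{e}")
    return "*".join(parts)


def parse_term(token: str, factor_names: list[str]) -> TermSpec:
    """Inverse of :func:`term_name`; raises on unknown factors or degree > 3."""
    token = token.strip()
    exps = [0] * len(factor_names)
    if token in ("Intercept", "1", ""):
        return tuple(exps)
    for part in token.split("*"):
        m = re.fullmatch(r"\s*([^\^\s]+)\s*(?:\^\s*(\d+))?\s*", part)
        if m is None:
            raise ValueError(f"cannot parse term token {token!r}")
        name, power = m.group(1), int(m.group(2) or 1)
        if name not in factor_names:
            raise ValueError(f"unknown factor {name!r} in term token {token!r}")
        exps[factor_names.index(name)] += power
    term = tuple(exps)
    if term_degree(term) > 3:
        raise ValueError(f"term {token!r} has degree {term_degree(term)} > 3")
    return term


def canonical_sort(terms: list[TermSpec]) -> list[TermSpec]:
    """Order by total degree, then lexicographically by exponent vector."""
    return sorted(set(terms), key=lambda t: (term_degree(t), t))


def build_terms(
    n_factors: int, third_order: list[TermSpec] | None = None
) -> list[TermSpec]:
    """Full second-order model terms plus any requested third-order terms.

    Returns intercept, n linear, n quadratic and C(n,2) interaction terms
    (28 terms for six factors), deduplicated and canonically ordered.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    terms: list[TermSpec] = [tuple([0] * n_factors)]
    for i in range(n_factors):
        e = [0] * n_factors
        e[i] = 1
        terms.append(tuple(e))
    for i in range(n_factors):
        e = [0] * n_factors
        e[i] = 2
        terms.append(tuple(e))
    for i, j in itertools.combinations(range(n_factors), 2):
        e = [0] * n_factors
        e[i] = e[j] = 1
        terms.append(tuple(e))
    for t in third_order or []:
        if len(t) != n_factors:
            raise ValueError(f"term {t} has wrong arity for {n_factors} factors")
        if term_degree(t) > 3:
            raise ValueError(f"supplied term {t} exceeds degree 3")
        terms.append(tuple(t))
    return canonical_sort(terms)


def design_matrix(coded: np.ndarray, terms: list[TermSpec]) -> np.ndarray:
    """Evaluate each polynomial term at each coded design point."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = [np.prod(coded ** np.asarray(t), axis=1) for t in terms]
    return np.column_stack(cols)


@dataclass
class ResponseModel:
    """A fitted polynomial surface for one phenotype response."""

    response_name: str
    transform: str  # "identity" | "log1p"
    factor_names: list[str]
    terms: list[TermSpec]
    coefficients: np.ndarray
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.terms):
            raise ValueError("coefficients and terms misaligned")

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def term_names(self) -> list[str]:
        return [term_name(t, self.factor_names) for t in self.terms]


def _apply_transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(y, dtype=float)
    if transform == "log1p":
        return np.log1p(np.asarray(y, dtype=float))
    raise ValueError(f"unknown transform {transform!r}")


def _aliased_terms(X: np.ndarray, terms: list[TermSpec], names: list[str]) -> list[str]:
    """Name the columns responsible for rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    bad = sorted(piv[rank:])
    return [term_name(terms[i], names) for i in bad]


def fit_response(
    design: CCDesign,
    table: pd.DataFrame,
    response: str,
    transform: str = "log1p",
    terms: list[TermSpec] | None = None,
) -> ResponseModel:
    """Ordinary least squares fit of one response over the design.

    ``table`` must hold columns run_id, response_name (or response), count.
    Every design run needs a count for the requested response; the model
    matrix must be full rank (aliased terms are named in the error).
    """
    names = design.factor_names
    if terms is None:
        terms = build_terms(len(names))

    resp_col = "response_name" if "response_name" in table.columns else "response"
    sub = table[table[resp_col] == response]
    counts = sub.set_index("run_id")["count"]
    missing = [rid for rid in design.run_ids if rid not in counts.index]
    if missing:
        raise ValueError(
            f"response {response!r} missing counts for runs: {missing}"
        )
    y = counts.loc[design.run_ids].to_numpy(dtype=float)

    X = design_matrix(design.coded_matrix, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_terms(X, terms, names)
        raise ValueError(
            f"model matrix rank-deficient (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased}"
        )

    yt = _apply_transform(y, transform)
    res = sm.OLS(yt, X).fit()
    n, p = X.shape
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    fit_stats = {
        "r_squared": float(res.rsquared) if ss_tot > 0 else float("nan"),
        "adj_r_squared": float(res.rsquared_adj) if ss_tot > 0 else float("nan"),
        "resid_se": float(np.sqrt(res.mse_resid)) if n > p else float("nan"),
        "n": n,
        "p": p,
        "degenerate_response": ss_tot == 0,
    }
    return ResponseModel(
        response_name=response,
        transform=transform,
        factor_names=list(names),
        terms=list(terms),
        coefficients=res.params,
        fit_stats=fit_stats,
    )


def select_third_order(
    design: CCDesign,
    table: pd.DataFrame,
    response: str,
    transform: str,
    base_terms: list[TermSpec],
    candidates: list[TermSpec],
    min_improvement: float = 0.0,
) -> list[TermSpec]:
    """Greedy forward selection of third-order terms by adjusted R^2.

    At each step the candidate giving the largest adjusted-R^2 improvement
    is added; ties break toward the lowest canonical order.  Stops when no
    candidate improves the criterion by more than ``min_improvement``.
    """
    for c in candidates:
        if term_degree(c) != 3:
            raise ValueError(f"candidate {c} is not a third-order term")
    current = list(base_terms)
    remaining = canonical_sort(list(candidates))
    remaining = [c for c in remaining if c not in current]

    def adj_r2(terms: list[TermSpec]) -> float:
        m = fit_response(design, table, response, transform, canonical_sort(terms))
        v = m.fit_stats["adj_r_squared"]
        return v if math.isfinite(v) else -math.inf

    best = adj_r2(current)
    while remaining:
        scores = []
        for c in remaining:
            try:
                scores.append(adj_r2(current + [c]))
            except ValueError:  # candidate aliased with current terms
                scores.append(-math.inf)
        i_best = int(np.argmax(scores))  # argmax takes first max: canonical tie-break
        if scores[i_best] <= best + min_improvement:
            break
        best = scores[i_best]
        current.append(remaining.pop(i_best))
    return canonical_sort(current)


def predict(model: ResponseModel, coded_point) -> tuple[float, float]:
    """Evaluate the surface at a coded point.

    Returns (transformed_value, count_scale).  For log1p models the count
    scale is exp(value) - 1 clipped at zero; identity predictions are also
    clipped at zero on the count scale since counts are nonnegative.
    """
    x = np.asarray(coded_point, dtype=float)
    if x.shape != (model.n_factors,):
        raise ValueError(
            f"coded point has shape {x.shape}, expected ({model.n_factors},)"
        )
    tv = (design_matrix(x[None, :], model.terms) @ model.coefficients).item()
    if model.transform == "log1p":
        count = max(math.expm1(tv), 0.0)
    else:
        count = max(tv, 0.0)
    return tv, count


def write_coefficients(models: list[ResponseModel], path) -> None:
    """Write a coefficient table (response, term, coefficient, transform).

    Mirrors the shape of a published regression-coefficient table so that
    fitted models can be exchanged without the raw response data.
    """
    rows = []
    for m in models:
        for t, c in zip(m.terms, m.coefficients):
            rows.append(
                {
                    "response": m.response_name,
                    "term": term_name(t, m.factor_names),
                    "coefficient": repr(float(c)),
                    "transform": m.transform,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coefficients(path, factor_names: list[str]) -> list[ResponseModel]:
    """Read a coefficient CSV back into :class:`ResponseModel` objects."""
    df = pd.read_csv(path)
    required = {"response", "term", "coefficient"}
    if not required.issubset(df.columns):
        raise ValueError(f"coefficient CSV needs columns {sorted(required)}")
    models = []
    for resp, grp in df.groupby("response", sort=False):
        terms = [parse_term(t, factor_names) for t in grp["term"]]
        transform = (
            str(grp["transform"].iloc[0]) if "transform" in grp.columns else "log1p"
        )
        models.append(
            ResponseModel(
                response_name=str(resp),
                transform=transform,
                factor_names=list(factor_names),
                terms=terms,
                coefficients=grp["coefficient"].astype(float).to_numpy(),
            )
        )
    return models
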