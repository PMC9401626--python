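"""Synthetic data generators with known ground truth for every pipeline stage.

Three generators mirror the three experimental readouts:

* polynomial dose-response surfaces evaluated on a coded design, with
  Gaussian noise added on the fitting (transformed) scale so least squares
  is the exact maximum-likelihood estimator of the truth coefficients;
* limiting-dilution plates in which each seeded cell is independently a
  progenitor with probability p, so a well of n cells is negative with
  probability (1-p)^n — the exact Bernoulli model, deliberately finer than
  the estimator's Poisson approximation exp(-f*n) so that approximation is
  exercised, not assumed;
* negative-binomial cell x gene count matrices in which a signature gene
  set is elevated by a condition-dependent multiplicative effect over
  bin-matched background genes, with optional injected QC-violating cells.

The count noise models are stand-ins: the real assays publish no noise
model, so these choices define the test conditions, not the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import CCDesign
from .lda import LDADataset
from .rsm import design_matrix, parse_term
from .scqc import CountMatrix

__all__ = [
    "ResponseSurfaceTruth",
    "LDATruth",
    "ExpressionTruth",
    "gen_dose_response",
    "gen_lda_wells",
    "gen_expression",
]


@dataclass(frozen=True)
class ResponseSurfaceTruth:
    """True polynomial surface for one response, on the transformed scale.

    ``true_coefficients`` maps term tokens (e.g. ``"Intercept"``, ``"IL7"``,
    ``"IL7^2"``, ``"IL7*TNFa"``) to coefficients; ``noise_sd`` is the SD of
    additive Gaussian noise applied on the transformed scale.
    """

    response_name: str
    true_coefficients: dict[str, float]
    transform: str = "log1p"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.transform not in ("identity", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class LDATruth:
    """Per-cell probability that a seeded cell yields a positive readout."""

    hit_probability: float

    def __post_init__(self) -> None:
        if not 0 <= self.hit_probability <= 1:
            raise ValueError("hit_probability must lie in [0, 1]")


@dataclass(frozen=True)
class ExpressionTruth:
    """Generative parameters for a two-or-more condition count matrix."""

    n_cells_per_condition: dict[str, int]
    n_genes: int
    baseline_means: np.ndarray  # per-gene mean counts per cell
    signature_genes: list[str]
    signature_effect: dict[str, float]  # condition -> multiplicative elevation
    mito_fraction: float = 0.05
    qc_violator_counts: dict[str, int] = field(
        default_factory=lambda: {"high_count": 0, "high_gene": 0, "high_mito": 0}
    )
    dispersion: float = 0.1  # NB dispersion alpha: var = mu + alpha * mu^2
    mito_prefix: str = "MT-"
    n_mito_genes: int = 13

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "baseline_means", np.asarray(self.baseline_means, dtype=float)
        )
        if len(self.baseline_means) != self.n_genes:
            raise ValueError("baseline_means length must equal n_genes")
        if np.any(self.baseline_means < 0):
            raise ValueError("baseline means must be nonnegative")
        if not 0 <= self.mito_fraction < 1:
            raise ValueError("mito_fraction must lie in [0, 1)")
        if any(e < 0 for e in self.signature_effect.values()):
            raise ValueError("signature effects must be >= 0")
        if self.n_genes < len(self.signature_genes):
            raise ValueError("n_genes smaller than the signature")

    def gene_names(self) -> list[str]:
        n_bg = self.n_genes - len(self.signature_genes) - self.n_mito_genes
        if n_bg < 0:
            raise ValueError("n_genes too small for signature plus mito genes")
        names = list(self.signature_genes)
        names += [f"{self.mito_prefix}G{i + 1}" for i in range(self.n_mito_genes)]
        names += [f"GENE{i + 1:05d}" for i in range(n_bg)]
        return names


def gen_dose_response(
    truths: list[ResponseSurfaceTruth], design: CCDesign, seed: int
) -> pd.DataFrame:
    """Simulate phenotype cell counts at every design run.

    For each response the true polynomial is evaluated at the coded point,
    Gaussian noise (``noise_sd``) is added on the transformed scale, the
    value is back-transformed, clipped at zero and rounded to an integer
    count.  Output columns: run_id, response_name, count.
    """
    if not truths:
        raise ValueError("at least one truth surface required")
    if design.n_runs == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    names = design.factor_names
    rows = []
    for truth in truths:
        terms, coefs = [], []
        for token, c in truth.true_coefficients.items():
            terms.append(parse_term(token, names))  # raises on unknown factor
            coefs.append(float(c))
        X = design_matrix(design.coded_matrix, terms)
        yt = X @ np.asarray(coefs)
        if truth.noise_sd > 0:
            yt = yt + rng.normal(0.0, truth.noise_sd, size=yt.shape)
        if truth.transform == "log1p":
            y = np.expm1(yt)
        else:
            y = yt
        counts = np.rint(np.clip(y, 0.0, None)).astype(int)
        for rid, cnt in zip(design.run_ids, counts):
            rows.append(
                {"run_id": rid, "response_name": truth.response_name, "count": cnt}
            )
    return pd.DataFrame(rows)


def gen_lda_wells(
    truth: LDATruth,
    doses: list[int],
    wells_per_dose: int,
    seed: int,
) -> LDADataset:
    """Simulate a limiting-dilution plate series.

    Each seeded cell is independently a progenitor with probability p, so a
    well of n cells is negative with probability (1-p)^n; the number of
    negative wells per dose is Binomial(wells, (1-p)^n).
    """
    doses_arr = np.asarray(doses, dtype=int)
    if np.any(doses_arr <= 0):
        raise ValueError("doses must be positive")
    if wells_per_dose <= 0:
        raise ValueError("wells_per_dose must be positive")
    rng = np.random.default_rng(seed)
    p_neg = (1.0 - truth.hit_probability) ** doses_arr
    negative = rng.binomial(wells_per_dose, p_neg)
    return LDADataset(
        dose=doses_arr,
        tested=np.full(len(doses_arr), wells_per_dose),
        negative=negative,
        meta={"hit_probability": truth.hit_probability, "seed": seed},
    )


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """Negative-binomial draws via gamma-Poisson; alpha -> 0 is Poisson."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=np.maximum(mu, 1e-300) * alpha)
    lam[mu == 0] = 0.0
    return rng.poisson(lam)


def gen_expression(truth: ExpressionTruth, seed: int) -> CountMatrix:
    """Simulate a cell x gene count matrix with per-cell condition labels.

    Per-gene means are the baseline means with (a) signature genes scaled by
    the condition's multiplicative effect and (b) mitochondrial genes scaled
    so they carry ``mito_fraction`` of the expected per-cell total; counts
    are negative binomial.  QC violators are injected afterwards: extra
    cells whose totals exceed 36,000, whose detected genes exceed 6,000, or
    whose mitochondrial fraction exceeds 18%, flagged by cell id suffix.
    """
    viol = {"high_count": 0, "high_gene": 0, "high_mito": 0}
    viol.update(truth.qc_violator_counts)
    if viol["high_gene"] > 0 and truth.n_genes <= 6000:
        raise ValueError(
            "cannot inject high-gene violators: need n_genes > 6000 detected genes"
        )

    rng = np.random.default_rng(seed)
    gene_names = truth.gene_names()
    is_sig = np.array([g in set(truth.signature_genes) for g in gene_names])
    is_mito = np.array([g.startswith(truth.mito_prefix) for g in gene_names])

    base = truth.baseline_means.copy()
    # rescale mito genes to carry the requested share of the per-cell total
    non_mito_total = base[~is_mito].sum()
    if truth.mito_fraction > 0 and is_mito.any():
        target_mito = non_mito_total * truth.mito_fraction / (1 - truth.mito_fraction)
        cur = base[is_mito].sum()
        base[is_mito] *= target_mito / cur if cur > 0 else 0.0

    blocks, cell_ids, conditions = [], [], []
    for cond in sorted(truth.n_cells_per_condition):
        n_cells = truth.n_cells_per_condition[cond]
        mu = base.copy()
        mu[is_sig] *= truth.signature_effect.get(cond, 1.0)
        counts = _nb_counts(
            rng, np.broadcast_to(mu, (n_cells, truth.n_genes)).copy(), truth.dispersion
        )
        blocks.append(counts)
        cell_ids += [f"{cond}_cell{i + 1:05d}" for i in range(n_cells)]
        conditions += [cond] * n_cells

    # injected QC violators, assigned round-robin to conditions
    conds = sorted(truth.n_cells_per_condition)
    extra_rows, k = [], 0
    for kind, n_extra in (
        ("high_count", viol["high_count"]),
        ("high_gene", viol["high_gene"]),
        ("high_mito", viol["high_mito"]),
    ):
        for i in range(n_extra):
            cond = conds[k % len(conds)]
            k += 1
            mu = base.copy()
            mu[is_sig] *= truth.signature_effect.get(cond, 1.0)
            if kind == "high_count":
                mu = mu * (45_000 / max(mu.sum(), 1e-12))
            elif kind == "high_gene":
                # uniform low mean over all genes: E[detected] > 6000 needs
                # most of >6000 genes hit at least once, while the total
                # stays below the 36,000-count cutoff
                mu = np.full(truth.n_genes, 30_000 / truth.n_genes)
            else:  # high_mito
                mito_target = 0.30
                mu = mu.copy()
                nm = mu[~is_mito].sum()
                mu[is_mito] *= (
                    nm * mito_target / (1 - mito_target) / max(mu[is_mito].sum(), 1e-12)
                )
            row = _nb_counts(rng, mu[None, :].copy(), truth.dispersion)
            extra_rows.append(row[0])
            cell_ids.append(f"{cond}_viol_{kind}_{i + 1}")
            conditions.append(cond)
    X = np.vstack(blocks + [np.array(extra_rows)]) if extra_rows else np.vstack(blocks)
    return CountMatrix(
        counts=X.astype(int),
        gene_names=gene_names,
        cell_ids=cell_ids,
        cell_condition=conditions,
    )
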