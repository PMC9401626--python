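"""Single-cell count-matrix QC, normalization and notch activity scoring.

Cells failing droplet-level QC (doublet-scale total counts, doublet-scale
gene complexity, or dying cells with a high mitochondrial read fraction) are
removed, genes detected in too few remaining cells are dropped, counts are
depth-normalized to 1e4 per cell and log1p-transformed, and a per-cell gene
signature score is computed as the mean signature expression minus the mean
of randomly drawn reference genes taken from the same expression bins.  The
default signature is the panel of canonical notch target genes (HES1, CD3D,
HES4, DTX1, BCL11B, HEY2), so the score reads out per-cell notch pathway
activity; conditions are compared by mean fold change and a Mann-Whitney
U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "SignatureScoreResult",
    "NOTCH_SIGNATURE",
    "apply_qc",
    "normalize_log",
    "score_signature",
    "compare_conditions",
]

NOTCH_SIGNATURE = ["HES1", "CD3D", "HES4", "DTX1", "BCL11B", "HEY2"]


@dataclass
class CountMatrix:
    """Cells x genes matrix with per-cell condition labels.

    ``counts`` holds raw nonnegative integers or, after
    :func:`normalize_log`, real normalized values (``normalized=True``).
    """

    counts: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    cell_condition: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_names) != n_genes:
            raise ValueError("gene_names length mismatch")
        if len(self.cell_ids) != n_cells or len(self.cell_condition) != n_cells:
            raise ValueError("cell metadata length mismatch")
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC cutoffs (strict inequalities for removal)."""

    max_counts: float = 36_000
    max_genes: int = 6_000
    max_mito_frac: float = 0.18
    min_cells_per_gene: int = 3
    mito_prefix: str = "MT-"


@dataclass
class QCReport:
    removed_high_counts: list[str] = field(default_factory=list)
    removed_high_genes: list[str] = field(default_factory=list)
    removed_high_mito: list[str] = field(default_factory=list)
    removed_genes: list[str] = field(default_factory=list)

    @property
    def n_cells_removed(self) -> int:
        return len(
            set(self.removed_high_counts)
            | set(self.removed_high_genes)
            | set(self.removed_high_mito)
        )


def apply_qc(
    matrix: CountMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[CountMatrix, QCReport]:
    """Remove QC-failing cells, then sparsely detected genes.

    A cell is removed when its total count exceeds ``max_counts``, its
    detected-gene count exceeds ``max_genes``, or its mitochondrial read
    fraction exceeds ``max_mito_frac`` (all strict).  Genes detected in
    fewer than ``min_cells_per_gene`` of the remaining cells are then
    dropped.  The report itemizes removals per rule; a cell failing several
    rules appears under each.
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty count matrix")
    X = matrix.counts
    totals = X.sum(axis=1)
    n_detected = (X > 0).sum(axis=1)
    mito_mask = np.array(
        [g.startswith(thresholds.mito_prefix) for g in matrix.gene_names]
    )
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(
            totals > 0, X[:, mito_mask].sum(axis=1) / np.maximum(totals, 1), 0.0
        )

    bad_counts = totals > thresholds.max_counts
    bad_genes = n_detected > thresholds.max_genes
    bad_mito = mito_frac > thresholds.max_mito_frac
    keep_cells = ~(bad_counts | bad_genes | bad_mito)
    if not keep_cells.any():
        raise ValueError("all cells filtered")

    report = QCReport(
        removed_high_counts=[c for c, b in zip(matrix.cell_ids, bad_counts) if b],
        removed_high_genes=[c for c, b in zip(matrix.cell_ids, bad_genes) if b],
        removed_high_mito=[c for c, b in zip(matrix.cell_ids, bad_mito) if b],
    )

    Xk = X[keep_cells]
    cells_per_gene = (Xk > 0).sum(axis=0)
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    report.removed_genes = [
        g for g, k in zip(matrix.gene_names, keep_genes) if not k
    ]

    filtered = CountMatrix(
        counts=Xk[:, keep_genes],
        gene_names=[g for g, k in zip(matrix.gene_names, keep_genes) if k],
        cell_ids=[c for c, k in zip(matrix.cell_ids, keep_cells) if k],
        cell_condition=[c for c, k in zip(matrix.cell_condition, keep_cells) if k],
        normalized=matrix.normalized,
    )
    return filtered, report


def normalize_log(matrix: CountMatrix, target_sum: float = 1e4) -> CountMatrix:
    """Depth-normalize each cell to ``target_sum`` counts, then log1p (natural log)."""
    totals = matrix.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"{[matrix.cell_ids[i] for i in zero[:10]]}"
        )
    scaled = matrix.counts * (target_sum / totals)[:, None]
    return replace(matrix, counts=np.log1p(scaled), normalized=True)


@dataclass
class SignatureScoreResult:
    per_cell_score: np.ndarray
    cell_ids: list[str]
    cell_condition: list[str]
    signature_genes: list[str]
    control_genes: list[str]
    n_ctrl_per_gene: int
    n_bins: int
    seed: int
    sampled_with_replacement: bool = False
    dropped_signature_genes: list[str] = field(default_factory=list)
    per_condition_mean: dict[str, float] = field(default_factory=dict)
    fold_change: float | None = None
    fold_change_defined: bool = True
    mw_p: float | None = None

    def scores_for(self, condition: str) -> np.ndarray:
        mask = np.array([c == condition for c in self.cell_condition])
        if not mask.any():
            raise KeyError(f"no cells with condition {condition!r}")
        return self.per_cell_score[mask]


def score_signature(
    norm_matrix: CountMatrix,
    signature_genes: list[str] = NOTCH_SIGNATURE,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    mode: str = "subtract",
) -> SignatureScoreResult:
    """Per-cell signature score against bin-matched random reference genes.

    Genes are ranked by mean normalized expression and cut into ``n_bins``
    equal-size bins.  For each signature gene, ``n_ctrl`` reference genes
    are drawn (without replacement when the bin allows, excluding all
    signature genes) from the same bin; the per-cell score is the mean over
    signature genes minus the mean over the pooled reference genes
    (``mode="ratio"`` divides instead, for the alternative reading of
    "normalized to the average").
    """
    if mode not in ("subtract", "ratio"):
        raise ValueError("mode must be 'subtract' or 'ratio'")
    gene_index = {g: j for j, g in enumerate(norm_matrix.gene_names)}
    present = [g for g in signature_genes if g in gene_index]
    dropped = [g for g in signature_genes if g not in gene_index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if dropped:
        import warnings

        warnings.warn(f"signature genes absent from matrix, dropped: {dropped}")

    X = norm_matrix.counts
    mean_expr = X.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(norm_matrix.n_genes, dtype=int)
    for b, idx in enumerate(np.array_split(order, n_bins)):
        bin_of[idx] = b

    sig_idx = np.array([gene_index[g] for g in present])
    sig_set = set(sig_idx.tolist())
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    with_replacement = False
    for gi in sig_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        pool = np.array([j for j in pool if j not in sig_set])
        if pool.size == 0:
            raise ValueError(
                f"no eligible control genes in the bin of {norm_matrix.gene_names[gi]!r}"
            )
        if pool.size >= n_ctrl:
            ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=False).tolist())
        else:
            with_replacement = True
            ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=True).tolist())

    sig_mean = X[:, sig_idx].mean(axis=1)
    ctrl_mean = X[:, np.array(ctrl_idx)].mean(axis=1)
    if mode == "subtract":
        score = sig_mean - ctrl_mean
    else:
        score = np.divide(
            sig_mean, ctrl_mean, out=np.full_like(sig_mean, np.nan), where=ctrl_mean != 0
        )

    conditions = sorted(set(norm_matrix.cell_condition))
    cond_arr = np.asarray(norm_matrix.cell_condition)
    per_cond = {c: float(score[cond_arr == c].mean()) for c in conditions}
    return SignatureScoreResult(
        per_cell_score=score,
        cell_ids=list(norm_matrix.cell_ids),
        cell_condition=list(norm_matrix.cell_condition),
        signature_genes=present,
        control_genes=sorted({norm_matrix.gene_names[j] for j in ctrl_idx}),
        n_ctrl_per_gene=n_ctrl,
        n_bins=n_bins,
        seed=seed,
        sampled_with_replacement=with_replacement,
        dropped_signature_genes=dropped,
        per_condition_mean=per_cond,
    )


def compare_conditions(
    result: SignatureScoreResult, groups: tuple[str, str]
) -> tuple[float | None, float]:
    """Mean-score fold change g2/g1 and two-sided Mann-Whitney U p-value.

    The fold change is undefined (None, flagged on the result) when either
    group's mean score is nonpositive; the rank-sum p-value is reported
    regardless.  The exact null distribution is used when SciPy can afford
    it (small groups, no ties), the normal approximation otherwise.
    """
    g1, g2 = groups
    s1, s2 = result.scores_for(g1), result.scores_for(g2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 cells")
    m1, m2 = float(s1.mean()), float(s2.mean())
    if m1 > 0 and m2 > 0:
        fold = m2 / m1
        result.fold_change = fold
        result.fold_change_defined = True
    else:
        fold = None
        result.fold_change = None
        result.fold_change_defined = False
    p = float(mannwhitneyu(s2, s1, alternative="two-sided").pvalue)
    result.mw_p = p
    return fold, p
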