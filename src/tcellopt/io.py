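"""File I/O, configuration and the end-to-end pipeline runner.

All tabular artifacts are plain CSV (comma-separated, UTF-8, mandatory
headers, "." decimal); count matrices use Matrix Market ``.mtx`` with
``genes.tsv``/``barcodes.tsv`` sidecars; configuration is YAML (JSON is a
YAML subset and is accepted).  Numeric fields round-trip at full double
precision (written via ``repr``), and every pipeline output directory
carries the config hash and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.io import mmread, mmwrite

from . import desopt, rsm, synth
from .doe import CCDesign, FactorSpec, make_ccd
from .lda import LDADataset, estimate_frequency
from .scqc import CountMatrix

__all__ = [
    "read_factors",
    "write_design",
    "read_design",
    "write_response_table",
    "read_response_table",
    "write_lda",
    "read_lda",
    "write_count_matrix",
    "read_count_matrix",
    "write_scores",
    "PipelineConfig",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"  # >= 15 significant digits: lossless double round-trip


# ---------------------------------------------------------------- factors


def read_factors(path) -> list[FactorSpec]:
    """Read factor specs from YAML/JSON: list of {name, low, high, units}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items = raw["factors"] if isinstance(raw, dict) else raw
    return [
        FactorSpec(
            name=str(d["name"]),
            conc_low=float(d["low"]),
            conc_high=float(d["high"]),
            units=str(d.get("units", "")),
        )
        for d in items
    ]


# ----------------------------------------------------------------- design


def write_design(design: CCDesign, path) -> None:
    df = design.to_frame()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_design(path, factors: list[FactorSpec], alpha: float | None = None) -> CCDesign:
    """Rebuild a CCDesign from its CSV and the factor specs."""
    df = pd.read_csv(path)
    for col in ("run_id", "point_type"):
        if col not in df.columns:
            raise ValueError(f"design CSV missing column {col!r} in {path}")
    coded_cols = [f"coded_{f.name}" for f in factors]
    missing = [c for c in coded_cols if c not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing coded columns {missing} in {path}")
    coded = df[coded_cols].to_numpy(dtype=float)
    if alpha is None:
        axial = coded[np.asarray(df["point_type"]) == "axial"]
        alpha = float(np.abs(axial).max()) if axial.size else 1.0
    return CCDesign(
        factors=list(factors),
        coded_matrix=coded,
        point_type=list(df["point_type"]),
        alpha=alpha,
        n_center=int((df["point_type"] == "center").sum()),
        run_ids=list(df["run_id"].astype(str)),
    )


# --------------------------------------------------------- response table


def write_response_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_response_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"run_id", "response_name", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"response table needs columns {sorted(required)}: {path}")
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0, "run_id"].tolist()
        raise ValueError(f"negative counts for runs {bad} in {path}")
    return df


# -------------------------------------------------------------------- lda


def write_lda(data: LDADataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_lda(path) -> LDADataset:
    df = pd.read_csv(path)
    try:
        return LDADataset.from_frame(df, source=str(path))
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


# ----------------------------------------------------------- count matrix


def write_count_matrix(matrix: CountMatrix, outdir) -> None:
    """Write Matrix Market (genes x cells, the 10x convention) plus sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(matrix.counts).T)
    mmwrite(str(outdir / "matrix.mtx"), mat)
    pd.Series(matrix.gene_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame(
        {"barcode": matrix.cell_ids, "condition": matrix.cell_condition}
    ).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_count_matrix(outdir) -> CountMatrix:
    outdir = Path(outdir)
    mat = mmread(str(outdir / "matrix.mtx"))
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0].tolist()
    bc = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)
    counts = np.asarray(mat.todense()).T if sparse.issparse(mat) else np.asarray(mat).T
    return CountMatrix(
        counts=counts.astype(int),
        gene_names=[str(g) for g in genes],
        cell_ids=[str(b) for b in bc[0]],
        cell_condition=[str(c) for c in (bc[1] if 1 in bc.columns else [""] * len(bc))],
    )


def write_scores(result, path) -> None:
    pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "condition": result.cell_condition,
            "score": result.per_cell_score,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ----------------------------------------------------------------- config


@dataclass
class PipelineConfig:
    """Validated configuration for the design->fit->optimize pipeline."""

    factors: list[FactorSpec]
    alpha: float = 2.366
    n_center: int = 8
    responses: list[str] = field(default_factory=list)
    transforms: dict[str, str] = field(default_factory=dict)  # response -> transform
    truths: list[synth.ResponseSurfaceTruth] = field(default_factory=list)
    desirability: dict[str, dict] = field(default_factory=dict)  # response -> {lower,upper,weight}
    opt: desopt.OptimizationConfig = field(default_factory=desopt.OptimizationConfig)
    seed: int = 0
    outdir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        factors = [
            FactorSpec(
                str(d["name"]), float(d["low"]), float(d["high"]), str(d.get("units", ""))
            )
            for d in raw["factors"]
        ]
        truths = [
            synth.ResponseSurfaceTruth(
                response_name=str(t["response"]),
                true_coefficients={str(k): float(v) for k, v in t["coefficients"].items()},
                transform=str(t.get("transform", "log1p")),
                noise_sd=float(t.get("noise_sd", 0.0)),
            )
            for t in raw.get("truths", [])
        ]
        responses = [str(r) for r in raw.get("responses", [])] or [
            t.response_name for t in truths
        ]
        opt_raw = raw.get("optimization", {})
        opt = desopt.OptimizationConfig(
            radius=float(opt_raw.get("radius", raw.get("alpha", 2.366))),
            n_restarts=int(opt_raw.get("n_restarts", 25)),
            top_k=int(opt_raw.get("top_k", 5)),
            seed=int(raw.get("seed", 0)),
            n_hops=int(opt_raw.get("n_hops", 10)),
            step_size=float(opt_raw.get("step_size", 0.5)),
        )
        cfg = cls(
            factors=factors,
            alpha=float(raw.get("alpha", 2.366)),
            n_center=int(raw.get("n_center", 8)),
            responses=responses,
            transforms={str(k): str(v) for k, v in raw.get("transforms", {}).items()},
            truths=truths,
            desirability={
                str(k): dict(v) for k, v in raw.get("desirability", {}).items()
            },
            opt=opt,
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "pipeline_out")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.factors:
            raise ValueError("config defines no factors")
        if not self.responses:
            raise ValueError("config defines no responses")
        names = {t.response_name for t in self.truths}
        for r in self.responses:
            if self.truths and r not in names:
                raise ValueError(f"response {r!r} has no synthetic truth surface")
        for r, spec in self.desirability.items():
            if r not in self.responses:
                raise ValueError(f"desirability spec for unknown response {r!r}")
            if "lower" in spec and "upper" in spec and not spec["lower"] < spec["upper"]:
                raise ValueError(f"desirability for {r!r}: lower must be < upper")
        for r, t in self.transforms.items():
            if t not in ("identity", "log1p"):
                raise ValueError(f"unknown transform {t!r} for response {r!r}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "factors": [(f.name, f.conc_low, f.conc_high, f.units) for f in self.factors],
                "alpha": self.alpha,
                "n_center": self.n_center,
                "responses": self.responses,
                "transforms": self.transforms,
                "truths": [
                    (t.response_name, sorted(t.true_coefficients.items()), t.transform, t.noise_sd)
                    for t in self.truths
                ],
                "desirability": self.desirability,
                "opt": (self.opt.radius, self.opt.n_restarts, self.opt.top_k, self.opt.n_hops, self.opt.step_size),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Design -> (synthetic) measurement -> fit -> optimize, fully seeded.

    Writes the coded design, the response table, the fitted coefficient
    table and the optimization result (coded and concentration units) under
    ``config.outdir`` together with a run log carrying the config hash and
    seed; returns the summary dict.  Any stage failure raises with the
    stage name prefixed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    design = stage("design", lambda: make_ccd(config.factors, config.alpha, config.n_center))
    write_design(design, outdir / "design.csv")

    if config.truths:
        table = stage(
            "simulate", lambda: synth.gen_dose_response(config.truths, design, config.seed)
        )
    else:
        table = stage("load_responses", lambda: read_response_table(outdir / "responses.csv"))
    write_response_table(table, outdir / "responses.csv")

    models = []
    for resp in config.responses:
        transform = config.transforms.get(resp, "log1p")
        models.append(
            stage(f"fit:{resp}", lambda r=resp, t=transform: rsm.fit_response(design, table, r, t))
        )
    rsm.write_coefficients(models, outdir / "coefficients.csv")

    specs = []
    for m in models:
        d = config.desirability.get(m.response_name, {})
        if "lower" in d and "upper" in d:
            specs.append(
                desopt.DesirabilitySpec(
                    m.response_name,
                    lower=float(d["lower"]),
                    upper=float(d["upper"]),
                    weight=float(d.get("weight", 1.0)),
                )
            )
        else:
            base = desopt.default_anchors(m, design, weight=float(d.get("weight", 1.0)))
            specs.append(base)

    result = stage("optimize", lambda: desopt.optimize(models, specs, config.opt, config.factors))

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_runs": design.n_runs,
        "overall_desirability": result.overall_desirability,
        "optimum_coded": [float(v) for v in result.averaged_optimum_coded],
        "optimum_conc": {k: float(v) for k, v in result.averaged_optimum_conc.items()},
        "predicted_counts": {k: float(v) for k, v in result.predicted_counts.items()},
        "degenerate": result.degenerate,
        "fit_stats": {m.response_name: m.fit_stats for m in models},
    }
    with open(outdir / "optimum.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(
            f"config_hash={config.config_hash()}\nseed={config.seed}\n"
            f"stages=design,simulate,fit,optimize\n"
        )
    return summary


def estimate_lda_file(path, ci: str = "wald") -> dict:
    """Fit the single-hit Poisson model to an LDA CSV; JSON-ready output."""
    est = estimate_frequency(read_lda(path), ci=ci)
    return {
        "f": est.f,
        "reciprocal": est.reciprocal,
        "ci95_reciprocal": list(est.ci95),
        "loglik": est.loglik,
        "converged": est.converged,
        "flags": est.flags,
    }
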