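"""End-to-end orchestration and the consolidated machine-readable report.

The pipeline follows the method's flow chart: (simulate or load raw trials)
-> preprocess -> assemble and whiten -> PCA scoring -> iterative SVM
decomposition -> ICA in the SVM space -> effect sizes -> reconstruction
exports.  The report is versioned JSON with full provenance (seeds,
threshold mode, SVM C, library versions, input hash); all marker/axis/time
indices are reported 1-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ica import ICASubspaceDiscriminant, select_ica_discriminant
from .layout import AssembledMatrix, assemble_matrix
from .pca import ClassifyingPCA
from .reconstruction import condition_average, export_frames, reconstruct
from .stats import ClassifiabilityRule
from .svm import SVMSubspaceDecomposition
from .synthetic import SyntheticConfig, generate, truth_alignment
from .whitening import whiten

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gaitspace")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of a full run (simulation-driven or matrix-driven)."""

    sim: SyntheticConfig | None = None
    matrix: AssembledMatrix | None = None  # preassembled, unwhitened
    mode: str = "paper"
    alpha: float = 0.05
    svm_C: float = 1.0
    max_iter: int = 100
    pca_components: int | None = 30
    ica_algorithm: str = "infomax"
    ica_seed: int = 0
    plane: str = "sagittal"
    magnification: float = 5.0
    export_dir: str | None = None


def _loso_summary(rates) -> list[dict]:
    return [
        {
            "rate": r.rate,
            "significant": r.significant,
            "per_subject": {s: list(v) for s, v in r.per_subject.items()},
        }
        for r in rates
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full decomposition pipeline and return the report dict."""
    t0 = time.time()
    if (config.sim is None) == (config.matrix is None):
        raise ValueError("provide exactly one of sim= or matrix=")
    truth = None
    if config.sim is not None:
        log.info("simulate: %s", config.sim)
        trials, truth = generate(config.sim)
        matrix = assemble_matrix(trials)
    else:
        matrix = config.matrix
    log.info("assemble: %d trials x %d variables", matrix.n_trials, matrix.n_variables)
    input_hash = hashlib.sha256(np.ascontiguousarray(matrix.values).tobytes()).hexdigest()
    white = whiten(matrix)
    rule = ClassifiabilityRule(mode=config.mode, alpha=config.alpha)
    X, y, groups = white.values, white.labels, white.groups

    log.info("pca: scoring up to %s components", config.pca_components)
    pca = ClassifyingPCA(
        n_components=config.pca_components, mode=rule.mode, alpha=rule.alpha
    ).fit(X, y, groups=groups)

    log.info("svm: iterative decomposition (C=%g, mode=%s)", config.svm_C, rule.mode)
    svm = SVMSubspaceDecomposition(
        C=config.svm_C, mode=rule.mode, alpha=rule.alpha, max_iter=config.max_iter
    ).fit(X, y, groups=groups)
    res = svm.result_

    ica_block = {"n_vectors": 0, "discriminant_index": None}
    if res.n_svm_vectors >= 1:
        log.info("ica: %d-dimensional SVM space", res.n_svm_vectors)
        ica = ICASubspaceDiscriminant(
            algorithm=config.ica_algorithm,
            random_state=config.ica_seed,
            mode=rule.mode,
            alpha=rule.alpha,
        ).fit(X, y, groups=groups, basis=svm.svm_basis_)
        idx, rate, eff = select_ica_discriminant(ica.result_())
        ica_block = {
            "n_vectors": len(ica.ica_vectors_),
            "discriminant_index": idx,
            "discriminant_rate": rate,
            "discriminant_effect_size": eff,
            "rates": _loso_summary(ica.rates_),
            "effect_sizes": ica.effect_sizes_.tolist(),
            "variance_fraction": ica.variance_fraction_.tolist(),
            "condition_number": ica.condition_number_,
            "seed": config.ica_seed,
            "algorithm": config.ica_algorithm,
        }

    export_block = None
    if config.export_dir is not None and res.n_svm_vectors >= 1:
        out = Path(config.export_dir)
        out.mkdir(parents=True, exist_ok=True)
        recon = reconstruct(white, svm.svm_basis_)
        averages = condition_average(recon, y)
        frames = export_frames(averages, plane=config.plane, magnification=config.magnification)
        frames_path = out / f"frames_{config.plane}.csv"
        frames.to_csv(frames_path, index=False)
        export_block = {"frames": str(frames_path), "plane": config.plane,
                        "magnification": config.magnification}

    sig = pca.significant_
    best_pca = None
    if sig.any():
        rates = np.array([r.rate for r in pca.rates_])
        rates = np.where(sig, rates, -1.0)
        j = int(np.argmax(rates))
        best_pca = {
            "component": j + 1,
            "rate": pca.rates_[j].rate,
            "effect_size": float(pca.effect_sizes_[j]),
            "variance_fraction": float(pca.explained_variance_ratio_[j]),
        }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "gaitspace_version": __version__,
            "numpy": np.__version__,
            "input_sha256": input_hash,
            "mode": rule.mode,
            "alpha": rule.alpha,
            "svm_C": config.svm_C,
            "ica_seed": config.ica_seed,
            "sim_seed": None if config.sim is None else config.sim.seed,
            "no_multiple_testing_correction": True,
        },
        "data": {
            "n_trials": matrix.n_trials,
            "n_variables": matrix.n_variables,
            "n_subjects": len(matrix.subjects),
            "conditions": matrix.conditions,
        },
        "pca": {
            "n_scored": pca.n_scored_,
            "rates": _loso_summary(pca.rates_),
            "significant": sig.tolist(),
            "variance_fraction": pca.explained_variance_ratio_[: pca.n_scored_].tolist(),
            "effect_sizes": pca.effect_sizes_.tolist(),
            "best_classifying": best_pca,
        },
        "svm": {
            "n_vectors": res.n_svm_vectors,
            "rates": _loso_summary([r for r in res.svm_basis.rates or []]),
            "variance_fraction": svm.variance_fraction_svm_.tolist(),
            "variance_fraction_total": float(svm.variance_fraction_svm_.sum()),
            "effect_size_first": res.effect_size_first,
            "normality_first": res.normality_first,
            "iteration_log": [
                {k: v for k, v in e.items()} for e in res.iteration_log
            ],
            "termination": res.termination,
        },
        "ica": ica_block,
        "export": export_block,
        "elapsed_s": round(time.time() - t0, 3),
    }
    if truth is not None:
        al = truth_alignment(svm.svm_basis_, truth) if res.n_svm_vectors else {
            "cosines": np.zeros(len(truth.amplitudes)), "principal_angles": np.array([])}
        report["truth"] = {
            "amplitudes": truth.amplitudes.tolist(),
            "svm_space_cosines": np.asarray(al["cosines"]).tolist(),
        }
    return report


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_strip_times(report), indent=2, default=float))


def _strip_times(report: dict) -> dict:
    """Drop wall-clock fields so identical runs produce identical files."""
    out = dict(report)
    out.pop("elapsed_s", None)
    return out
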