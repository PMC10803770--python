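"""End-to-end orchestration: features → fit → cutoff → filters → RNA filter.

`run_screen` is the pure in-memory pipeline on DataFrames; `run_pipeline`
wraps it with file I/O, logging and a JSON run manifest. Both are fully
deterministic given their inputs: the only randomness in the package lives
in the synthetic-data generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from . import confidence, filters, interactome, io
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable knobs of the screen, with their defaults."""

    known_positives: tuple[str, ...] = confidence.DEFAULT_KNOWN_POSITIVES
    learning_rate: float = 0.05
    max_iter: int = 5000
    tol: float = 1e-8
    cutoff_mode: str = "exact_single"
    default_cutoff: float = 0.5
    #: "per_experiment" tests each experiment's own score against the
    #: cutoff; "mean" tests the protein's mean score everywhere.
    score_mode: str = "per_experiment"
    rna_filter: bool = True
    rna_alpha: float = 0.05
    rna_min_log2fc: float = 1.0
    interactors_pooled: bool = True


@dataclass
class ScreenResult:
    """Everything one screen computes, as DataFrames plus the model."""

    interactors: pd.DataFrame
    features: pd.DataFrame
    labels: pd.DataFrame
    model: confidence.ConfidenceModel
    scores: pd.DataFrame
    cutoff: float
    cutoff_anchors: list[str]
    cutoff_fallback: bool
    ref_ratios: dict[str, float]
    verdicts: pd.DataFrame
    calls: pd.DataFrame

    @property
    def candidates(self) -> pd.DataFrame:
        """Final substrate candidates, highest mean score first."""
        cand = self.calls[self.calls["final_candidate"]]
        return cand.sort_values(
            ["mean_score", "protein_id"], ascending=[False, True],
            ignore_index=True,
        )


def run_screen(
    psm: pd.DataFrame,
    annotations: pd.DataFrame,
    de: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> ScreenResult:
    """Run the full substrate screen on in-memory tables."""
    params = params or PipelineParams()
    if params.rna_filter and de is None:
        raise ConfigError("RNA filter enabled but no differential-expression table")

    inter = interactome.select_interactors(
        psm, annotations, pooled=params.interactors_pooled
    )

    feats = confidence.compute_features(psm)
    per_protein = confidence.aggregate_features(feats, psm)
    labels = confidence.derive_labels(
        annotations, params.known_positives,
        observed_proteins=psm["protein_id"].unique(),
    )
    model = confidence.fit_from_tables(
        per_protein, labels,
        learning_rate=params.learning_rate,
        max_iter=params.max_iter,
        tol=params.tol,
    )

    if params.score_mode not in ("per_experiment", "mean"):
        raise ConfigError(f"unknown score_mode {params.score_mode!r}")
    scores = feats[["protein_id", "experiment_id"]].copy()
    scores["score"] = confidence.score(model, feats["x1"], feats["x2"])
    protein_scores = pd.Series(
        confidence.score(model, per_protein["x1"], per_protein["x2"]),
        index=pd.Index(per_protein["protein_id"], name="protein_id"),
    )
    cutoff, anchors, fallback = confidence.select_cutoff(
        protein_scores, psm, mode=params.cutoff_mode,
        default=params.default_cutoff,
    )
    if params.score_mode == "mean":
        scores = scores.assign(
            score=scores["protein_id"].map(protein_scores).to_numpy()
        )

    ref_ratios = {
        exp: filters.reference_ratio(psm, exp, annotations)
        for exp in sorted(psm["experiment_id"].unique())
    }
    verdicts = filters.apply_filter_cascade(psm, annotations, scores, cutoff, ref_ratios)
    calls = filters.call_candidates(verdicts, psm, scores)
    if params.rna_filter:
        calls = filters.rna_exclusion(
            calls, de, annotations,
            filters.RnaFilterParams(
                alpha=params.rna_alpha, min_log2fc=params.rna_min_log2fc
            ),
        )
    return ScreenResult(
        interactors=inter,
        features=feats,
        labels=labels,
        model=model,
        scores=scores,
        cutoff=cutoff,
        cutoff_anchors=anchors,
        cutoff_fallback=fallback,
        ref_ratios=ref_ratios,
        verdicts=verdicts,
        calls=calls,
    )


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    psm_path,
    annot_path,
    out_dir,
    de_path=None,
    params: PipelineParams | None = None,
) -> ScreenResult:
    """File-based pipeline run: read inputs, screen, write a run directory.

    Writes interactors.tsv, scores.tsv, model.json, verdicts.tsv,
    calls.tsv, candidates.tsv, manifest.json and run.log. Deterministic:
    identical inputs and parameters yield byte-identical outputs.
    """
    params = params or PipelineParams()
    io.ensure_dir(out_dir)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("erad_screen")
    root.addHandler(handler)
    try:
        psm = io.read_psm_table(psm_path)
        annotations = io.read_annotation_table(annot_path)
        de = io.read_de_table(de_path) if de_path else None
        result = run_screen(psm, annotations, de, params)

        io.write_table(result.interactors, os.path.join(out_dir, "interactors.tsv"))
        io.write_table(result.scores, os.path.join(out_dir, "scores.tsv"))
        io.write_table(result.verdicts, os.path.join(out_dir, "verdicts.tsv"))
        io.write_table(result.calls, os.path.join(out_dir, "calls.tsv"))
        io.write_table(result.candidates, os.path.join(out_dir, "candidates.tsv"))
        model_info = {
            **result.model.to_dict(),
            "cutoff": result.cutoff,
            "cutoff_anchors": result.cutoff_anchors,
            "cutoff_fallback": result.cutoff_fallback,
            "reference_ratios": result.ref_ratios,
        }
        with open(os.path.join(out_dir, "model.json"), "w") as fh:
            json.dump(model_info, fh, indent=2, sort_keys=True)

        manifest = {
            "package_version": __version__,
            "params": asdict(params),
            "inputs": {
                "psm": {"path": str(psm_path), "sha256": _file_sha256(psm_path)},
                "annotations": {
                    "path": str(annot_path), "sha256": _file_sha256(annot_path)
                },
            },
            "n_proteins": int(psm["protein_id"].nunique()),
            "n_experiments": int(psm["experiment_id"].nunique()),
            "n_candidates": int(result.calls["final_candidate"].sum()),
        }
        if de_path:
            manifest["inputs"]["de"] = {
                "path": str(de_path), "sha256": _file_sha256(de_path)
            }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
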