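"""Hard-filter cascade, consensus candidate calling and the RNA filter.

Per (protein, experiment), after keratin removal and the score cutoff, a
hit must satisfy:

- its HRD1-KO/WT PSM ratio exceeds (strictly) the smaller of the SEL1L and
  OS9 HRD1-KO/WT ratios in the same experiment;
- the SEL1L-KO PSM is smaller than WT, unless the SEL1L-KO PSM is <= 1;
- the HRD1-KO PSM is strictly greater than the SEL1L-KO PSM;
- the IgG PSM is zero or no greater than one tenth of the HRD1-KO PSM
  (inclusive).

Nucleus-only proteins are excluded unless they carry a signal peptide,
N-glycosylation, disulfide bond or transmembrane domain. Proteins passing
in at least two independent experiments are substrate candidates, split
into Group A (detected in WT in any experiment) and Group B (never
detected in WT); candidates whose mRNA is significantly upregulated in
HRD1-KO are removed as transcriptional artifacts.

Boundary readings are documented one-liners: "no greater than one-tenth"
is inclusive (<=); "smaller than WT" is strict (<); "no >1" is <= 1;
"must be greater" is strict (>). All failing reasons are recorded; the
rules do not short-circuit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StageError

logger = logging.getLogger(__name__)

REASON_CODES = (
    "KERATIN",
    "SCORE_BELOW_CUTOFF",
    "RATIO_VS_REFERENCE",
    "SKO_NOT_BELOW_WT",
    "HKO_NOT_ABOVE_SKO",
    "IGG_TOO_HIGH",
    "NUCLEUS_ONLY",
)

REFERENCE_SYMBOLS = ("SEL1L", "OS9")


def reference_ratio(
    psm: pd.DataFrame,
    experiment_id: str,
    annotations: pd.DataFrame | None = None,
) -> float:
    """Smaller HRD1-KO/WT PSM ratio of SEL1L and OS9 in one experiment.

    Denominators are floored at 1, consistent with the feature policy. If
    one reference protein is missing its partner is used alone (warning);
    both missing is a stage error naming the experiment.
    """
    sub = psm[psm["experiment_id"] == experiment_id]
    if annotations is not None:
        symbols = annotations.set_index("protein_id")["gene_symbol"].astype(str)
        gene = sub["protein_id"].map(symbols).fillna(sub["protein_id"]).str.upper()
    else:
        gene = sub["protein_id"].astype(str).str.upper()
    ratios = []
    for ref in REFERENCE_SYMBOLS:
        rows = sub[gene == ref]
        if rows.empty:
            logger.warning(
                "reference protein %s absent from experiment %s", ref, experiment_id
            )
            continue
        hko = float(rows["psm_hko"].sum())
        wt = float(rows["psm_wt"].sum())
        ratios.append(hko / max(wt, 1.0))
    if not ratios:
        raise StageError(
            f"reference_ratio: neither SEL1L nor OS9 found in experiment "
            f"{experiment_id!r}"
        )
    return min(ratios)


def cascade_reasons(
    hko: int,
    wt: int,
    sko: int,
    igg: int,
    *,
    is_keratin: bool,
    score: float,
    cutoff: float,
    ref_ratio: float,
    localizations: frozenset[str],
    has_signal_peptide: bool,
    n_glycosylation_sites: int,
    has_disulfide: bool,
    n_tm_domains: int,
) -> list[str]:
    """All failure reasons for one (protein, experiment) hit, in rule order."""
    reasons: list[str] = []
    if is_keratin:
        reasons.append("KERATIN")
    if score < cutoff:
        reasons.append("SCORE_BELOW_CUTOFF")
    if not hko / max(wt, 1.0) > ref_ratio:  # strict: "greater than"
        reasons.append("RATIO_VS_REFERENCE")
    if not (sko < wt or sko <= 1):  # "smaller than WT unless ... no >1"
        reasons.append("SKO_NOT_BELOW_WT")
    if not hko > sko:  # strict: "must be greater"
        reasons.append("HKO_NOT_ABOVE_SKO")
    if not (igg == 0 or igg <= hko / 10.0):  # inclusive: "no greater than"
        reasons.append("IGG_TOO_HIGH")
    nucleus_only = localizations == frozenset({"nucleus"})
    client_feature = (
        has_signal_peptide
        or n_glycosylation_sites > 0
        or has_disulfide
        or n_tm_domains > 0
    )
    if nucleus_only and not client_feature:
        reasons.append("NUCLEUS_ONLY")
    return reasons


def _loc_set(value) -> frozenset[str]:
    return frozenset(p.strip() for p in str(value).split(";") if p.strip())


def apply_filter_cascade(
    psm: pd.DataFrame,
    annotations: pd.DataFrame,
    scores: pd.DataFrame,
    cutoff: float,
    ref_ratios: dict[str, float],
) -> pd.DataFrame:
    """Per-(protein, experiment) verdicts for the whole PSM table.

    ``scores`` holds per-experiment confidence scores (protein_id,
    experiment_id, score); ``ref_ratios`` maps experiment id to that
    experiment's reference ratio.
    """
    ann = annotations.set_index("protein_id")
    score_map = scores.set_index(["protein_id", "experiment_id"])["score"]

    records = []
    for row in psm.itertuples(index=False):
        pid, exp = row.protein_id, row.experiment_id
        try:
            a = ann.loc[pid]
        except KeyError as exc:
            raise StageError(f"filter: no annotation for protein {pid!r}") from exc
        reasons = cascade_reasons(
            row.psm_hko, row.psm_wt, row.psm_sko, row.psm_igg,
            is_keratin=bool(a["is_keratin_family"]),
            score=float(score_map.get((pid, exp), 0.0)),
            cutoff=cutoff,
            ref_ratio=ref_ratios[exp],
            localizations=_loc_set(a["localizations"]),
            has_signal_peptide=bool(a["has_signal_peptide"]),
            n_glycosylation_sites=int(a["n_glycosylation_sites"]),
            has_disulfide=bool(a["has_disulfide"]),
            n_tm_domains=int(a["n_tm_domains"]),
        )
        records.append(
            {
                "protein_id": pid,
                "experiment_id": exp,
                "passed": not reasons,
                "failure_reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame.from_records(records)


def call_candidates(
    verdicts: pd.DataFrame,
    psm: pd.DataFrame,
    scores: pd.DataFrame,
) -> pd.DataFrame:
    """Consensus candidate calls with Group A/B assignment.

    A protein is a candidate when it passes the cascade in at least two
    independent experiments. Group A: detected in WT (psm_wt > 0) in any
    experiment; Group B: never detected in WT. mean_score averages the
    per-experiment scores over experiments with hko > 0.
    """
    n_passed = verdicts.groupby("protein_id")["passed"].sum().astype(int)
    wt_any = psm.groupby("protein_id")["psm_wt"].max() > 0

    sc = scores.merge(
        psm[["protein_id", "experiment_id", "psm_hko"]],
        on=["protein_id", "experiment_id"],
    )
    mean_score = (
        sc[sc["psm_hko"] > 0].groupby("protein_id")["score"].mean()
    )

    ids = sorted(n_passed.index)
    out = pd.DataFrame({"protein_id": ids})
    out["n_experiments_passed"] = n_passed.reindex(ids).to_numpy()
    candidate = out["n_experiments_passed"] >= 2
    out["group"] = np.where(
        candidate, np.where(wt_any.reindex(ids).to_numpy(), "A", "B"), "none"
    )
    out["mean_score"] = mean_score.reindex(ids).fillna(0.0).to_numpy()
    out["rna_excluded"] = False
    out["final_candidate"] = candidate.to_numpy()
    return out


@dataclass
class RnaFilterParams:
    """Thresholds defining "significant transcriptional upregulation"."""

    alpha: float = 0.05
    min_log2fc: float = 1.0
    contrast: str = "HRD1KO_vs_WT"


def rna_exclusion(
    calls: pd.DataFrame,
    de: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    params: RnaFilterParams | None = None,
) -> pd.DataFrame:
    """Remove candidates whose enrichment is explained by mRNA upregulation.

    A candidate is excluded when a DE row for the configured contrast has
    padj < alpha and log2fc > min_log2fc. Candidates absent from the DE
    table are retained (logged). Excluded candidates lose candidate status
    and their group.
    """
    params = params or RnaFilterParams()
    if annotations is not None:
        sym = annotations.set_index("protein_id")["gene_symbol"].astype(str)
        genes = calls["protein_id"].map(sym).fillna(calls["protein_id"])
    else:
        genes = calls["protein_id"].astype(str)
    genes = genes.str.upper()

    sub = de[de["contrast"] == params.contrast]
    up = sub[(sub["padj"] < params.alpha) & (sub["log2fc"] > params.min_log2fc)]
    upregulated = set(up["gene_symbol"].astype(str).str.upper())
    in_de = set(sub["gene_symbol"].astype(str).str.upper())

    out = calls.copy()
    cand = out["final_candidate"].astype(bool)
    missing = cand & ~genes.isin(in_de)
    if missing.any():
        logger.warning(
            "%d candidates have no DE row and are retained (e.g. %s)",
            int(missing.sum()),
            out.loc[missing, "protein_id"].head(3).tolist(),
        )
    excluded = cand & genes.isin(upregulated)
    out.loc[excluded, "rna_excluded"] = True
    out.loc[excluded, "final_candidate"] = False
    out.loc[excluded, "group"] = "none"
    return out
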