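"""Logistic confidence score for ERAD substrate candidacy.

The score of a protein hit in one experiment is

    y = 1 / (1 + exp(-(w0 + w1*x1 + w2*x2)))

with enrichment features computed from the four genotype PSM counts:

    x1 = hko / max(wt, IgG)      (enrichment over the WT pulldown)
    x2 = hko / max(sko, IgG)     (enrichment over the SEL1L-KO control)

Denominators are floored at 1: PSMs are integers, so absence in both
control columns is maximal enrichment and must stay finite.

The three weights are optimized by gradient ascent to maximize the Matthews
correlation coefficient (MCC) over literature-labeled positive (known ERAD
substrates) and negative (non-client) proteins. The hard MCC is
piecewise-constant in the weights, so the ascent runs on a smooth surrogate
built from soft confusion counts (sums of predicted probabilities); the
model reports the hard MCC at probability threshold 0.5, taken over the
best iterate visited.

The score cutoff is anchored on the weakest credible hits: the lowest score
among proteins detected exclusively in the HRD1-KO pulldown with 2 PSMs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TrainingError

logger = logging.getLogger(__name__)

#: Subcellular compartments compatible with being a SEL1L-HRD1 client.
CLIENT_COMPARTMENTS = frozenset({"ER", "Golgi", "lysosome", "membrane"})

#: Default literature positives used when none are supplied.
DEFAULT_KNOWN_POSITIVES = ("SIGMAR1", "HLA-C", "HLA-E", "HLA-F", "OS9", "ATF6")


def compute_features(psm: pd.DataFrame) -> pd.DataFrame:
    """Per-(protein, experiment) enrichment features x1, x2.

    x1 = hko / max(wt, igg, 1) and x2 = hko / max(sko, igg, 1); both are
    finite and non-negative, and invariant to scaling all four counts by a
    positive integer while the denominators stay above the floor.
    """
    hko = psm["psm_hko"].to_numpy(dtype=float)
    igg = psm["psm_igg"].to_numpy(dtype=float)
    d1 = np.maximum.reduce([psm["psm_wt"].to_numpy(dtype=float), igg,
                            np.ones_like(hko)])
    d2 = np.maximum.reduce([psm["psm_sko"].to_numpy(dtype=float), igg,
                            np.ones_like(hko)])
    return pd.DataFrame(
        {
            "protein_id": psm["protein_id"].to_numpy(),
            "experiment_id": psm["experiment_id"].to_numpy(),
            "x1": hko / d1,
            "x2": hko / d2,
        }
    )


def aggregate_features(features: pd.DataFrame, psm: pd.DataFrame) -> pd.DataFrame:
    """Per-protein training features: mean over experiments with hko > 0.

    A protein never detected in the HRD1-KO pulldown gets (0, 0) — both
    features are zero in every experiment anyway.
    """
    feats = features.merge(
        psm[["protein_id", "experiment_id", "psm_hko"]],
        on=["protein_id", "experiment_id"],
    )
    detected = feats[feats["psm_hko"] > 0]
    agg = detected.groupby("protein_id")[["x1", "x2"]].mean()
    all_ids = pd.Index(features["protein_id"].unique(), name="protein_id")
    agg = agg.reindex(all_ids, fill_value=0.0).reset_index()
    return agg.sort_values("protein_id", ignore_index=True)


def derive_labels(
    annotations: pd.DataFrame,
    known_positives,
    observed_proteins=None,
) -> pd.DataFrame:
    """Training labels from annotation features and a known-substrate list.

    positive : gene symbol is a literature-known ERAD substrate (and, when
        ``observed_proteins`` is given, present in the PSM data).
    negative : the protein has none of signal peptide / transmembrane
        domain / N-glycosylation / disulfide bond, OR is localized entirely
        outside ER, Golgi, lysosome and membrane.
    unlabeled : everything else.
    """
    if not len(list(known_positives)):
        raise TrainingError("known_positives must be non-empty")
    known = {str(s).upper() for s in known_positives}

    df = annotations.copy()
    if observed_proteins is not None:
        df = df[df["protein_id"].isin(set(observed_proteins))]

    featureless = (
        ~df["has_signal_peptide"].astype(bool)
        & (df["n_tm_domains"] == 0)
        & (df["n_glycosylation_sites"] == 0)
        & ~df["has_disulfide"].astype(bool)
    )
    loc_sets = df["localizations"].map(
        lambda v: frozenset(p.strip() for p in str(v).split(";") if p.strip())
    )
    outside = loc_sets.map(lambda s: not (s & CLIENT_COMPARTMENTS))
    is_pos = df["gene_symbol"].astype(str).str.upper().isin(known)
    is_neg = (featureless | outside) & ~is_pos

    label = np.where(is_pos, "positive", np.where(is_neg, "negative", "unlabeled"))
    source = np.where(
        is_pos, "known_substrate",
        np.where(is_neg, "non_client_annotation", ""),
    )
    out = pd.DataFrame(
        {"protein_id": df["protein_id"].to_numpy(), "label": label, "source": source}
    )
    n_pos = int((out["label"] == "positive").sum())
    n_neg = int((out["label"] == "negative").sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError(
            f"labeling produced {n_pos} positives and {n_neg} negatives; "
            "both classes are required"
        )
    return out.sort_values("protein_id", ignore_index=True)


def mcc(tp: float, tn: float, fp: float, fn: float) -> float:
    """Matthews correlation coefficient with the 0/0 -> 0 convention."""
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den <= 0:
        return 0.0
    return float(num / np.sqrt(den))


@dataclass
class ConfidenceModel:
    """Fitted logistic score: weights plus fit diagnostics."""

    w0: float
    w1: float
    w2: float
    achieved_mcc: float
    n_pos: int
    n_neg: int
    n_iter: int = 0
    final_step: float = float("nan")
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w0, self.w1, self.w2])

    def to_dict(self) -> dict:
        return {
            "w0": self.w0, "w1": self.w1, "w2": self.w2,
            "achieved_mcc": self.achieved_mcc,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "n_iter": self.n_iter, "final_step": self.final_step,
            "converged": self.converged,
        }


def score(model, x1, x2):
    """Confidence score(s) for feature values; overflow-safe, in (0, 1)."""
    w = model.weights if isinstance(model, ConfidenceModel) else np.asarray(model, float)
    logit = w[0] + w[1] * np.asarray(x1, float) + w[2] * np.asarray(x2, float)
    return 1.0 / (1.0 + np.exp(-np.clip(logit, -500.0, 500.0)))


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _soft_mcc_and_grad(w, Xd, y):
    """Smooth MCC surrogate and its gradient in the weights.

    Soft confusion counts: TP = sum of predicted probabilities over
    positives, FP = sum over negatives, FN/TN complementary.
    """
    p = 1.0 / (1.0 + np.exp(-np.clip(Xd @ w, -500.0, 500.0)))
    pos = y.astype(bool)
    tp = p[pos].sum()
    fn = (1.0 - p[pos]).sum()
    fp = p[~pos].sum()
    tn = (1.0 - p[~pos]).sum()

    a, b, c, e = tp + fp, tp + fn, tn + fp, tn + fn
    d2 = a * b * c * e
    if d2 <= 1e-12:
        # degenerate surface: push probabilities toward the labels
        grad_n = Xd.T @ ((y - p) * p * (1 - p))
        return 0.0, grad_n
    d = np.sqrt(d2)
    num = tp * tn - fp * fn
    val = num / d

    # dD^2/dp_i = B*C*E - A*B*C for every sample (A grows, E shrinks)
    dd = (b * c * e - a * b * c) / (2.0 * d)
    dnum = np.where(pos, tn + fp, -(tp + fn))
    dmcc_dp = (dnum * d - num * dd) / d2
    grad = Xd.T @ (dmcc_dp * p * (1.0 - p))
    return float(val), grad


def hard_mcc(w, Xd, y) -> float:
    """Hard MCC of the 0.5-threshold classifier at weights w."""
    p = 1.0 / (1.0 + np.exp(-np.clip(Xd @ w, -500.0, 500.0)))
    pred = p >= 0.5
    pos = y.astype(bool)
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    return mcc(tp, tn, fp, fn)


def best_intercept(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact intercept maximizing hard MCC of the rule ``z + w0 >= 0``.

    The classifier's hard MCC depends on (w1, w2) only through the ranking
    of the linear scores z, so for a fixed direction the best intercept is
    found by scanning the n + 1 realizable splits of the sorted scores.
    Splits falling inside a run of tied scores are not realizable by any
    threshold and are skipped. Returns (w0, mcc at that w0).
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=bool)
    order = np.argsort(z, kind="stable")
    zs, ys = z[order], y[order]
    n = len(zs)
    n_pos, n_neg = int(ys.sum()), int((~ys).sum())
    cum_pos = np.concatenate([[0], np.cumsum(ys)])
    # predict positive for the suffix starting at split k (k = 0 .. n)
    tp = n_pos - cum_pos
    fp = n_neg - (np.arange(n + 1) - cum_pos)
    fn = n_pos - tp
    tn = n_neg - fp
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    m = np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1)), 0.0)
    realizable = np.ones(n + 1, dtype=bool)
    realizable[1:n] = zs[1:] > zs[:-1]
    m = np.where(realizable, m, -2.0)
    k = int(np.argmax(m))
    if k == 0:
        t = zs[0] - 1.0
    elif k == n:
        t = zs[-1] + 1.0
    else:
        t = 0.5 * (zs[k - 1] + zs[k])
    return -t, float(m[k])


#: Deterministic initial directions for the ascent; the surrogate is
#: non-convex, so the fit restarts from each and keeps the best iterate.
ASCENT_STARTS = (
    (0.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (0.0, -1.0, 0.0),
    (0.0, 0.0, -1.0),
    (0.0, 1.0, 1.0),
    (0.0, -1.0, -1.0),
    (0.0, 1.0, -1.0),
    (0.0, -1.0, 1.0),
)


def fit_model(
    X,
    labels,
    learning_rate: float = 0.05,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> ConfidenceModel:
    """Fit (w0, w1, w2) by gradient ascent on the smooth MCC surrogate.

    Deterministic: a fixed set of initial directions (w = 0 first), no
    randomness. Steps follow the surrogate gradient, clipped to unit norm
    for stability on the strongly skewed feature scale. Because the hard
    MCC is piecewise-constant in the weights, the fit tracks every iterate
    and refines its intercept by an exact line search over the score
    ranking; the returned weights are the best such iterate and
    ``achieved_mcc`` is their hard MCC at probability threshold 0.5.

    Parameters
    ----------
    X : array-like, shape (n, 2)
        Per-protein features (x1, x2).
    labels : array-like of bool or {0,1}
        True/1 for known substrates, False/0 for non-clients.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = (y == "positive")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise TrainingError("training labels contain a single class")
    X = np.asarray(X, dtype=float)
    Xd = _design(X)
    # intercept refinement is O(n log n); thin it out on large label sets
    refine_every = 1 if len(y) <= 500 else 10

    best_w = np.zeros(3)
    best_hard = -2.0
    total_iter = 0
    n_starts = 0
    n_converged = 0
    step = float("nan")
    for start in ASCENT_STARTS:
        n_starts += 1
        w = np.array(start, dtype=float)
        soft, grad = _soft_mcc_and_grad(w, Xd, y)
        for it in range(1, max_iter + 1):
            if it % refine_every == 0 or it == 1:
                w0, h = best_intercept(X @ w[1:], y)
                if h > best_hard:
                    best_w = np.array([w0, w[1], w[2]])
                    best_hard = h
                if best_hard >= 1.0:
                    n_converged += 1
                    break
            gnorm = np.linalg.norm(grad)
            if gnorm > 1.0:
                grad = grad / gnorm
            w = w + learning_rate * grad
            new_soft, grad = _soft_mcc_and_grad(w, Xd, y)
            step = abs(new_soft - soft)
            soft = new_soft
            if step < tol:
                n_converged += 1
                break
        total_iter += it
        w0, h = best_intercept(X @ w[1:], y)
        if h > best_hard:
            best_w = np.array([w0, w[1], w[2]])
            best_hard = h
        if best_hard >= 1.0:  # perfect separation; nothing left to gain
            break
    converged = n_converged == n_starts
    if not converged:
        warnings.warn(
            f"MCC ascent did not reach tolerance within {max_iter} iterations "
            f"per start (last surrogate change {step:.3g}); best iterate kept",
            RuntimeWarning,
            stacklevel=2,
        )
    return ConfidenceModel(
        w0=float(best_w[0]), w1=float(best_w[1]), w2=float(best_w[2]),
        achieved_mcc=best_hard,
        n_pos=int(y.sum()), n_neg=int((~y).sum()),
        n_iter=total_iter, final_step=step, converged=converged,
    )


def fit_from_tables(
    features_per_protein: pd.DataFrame,
    labels: pd.DataFrame,
    **hyper,
) -> ConfidenceModel:
    """Fit the model from per-protein features and a TrainingLabel table."""
    lab = labels[labels["label"].isin(["positive", "negative"])]
    merged = lab.merge(features_per_protein, on="protein_id", how="inner")
    return fit_model(
        merged[["x1", "x2"]].to_numpy(),
        (merged["label"] == "positive").to_numpy(),
        **hyper,
    )


def select_cutoff(
    protein_scores: pd.Series,
    psm: pd.DataFrame,
    mode: str = "exact_single",
    default: float = 0.5,
) -> tuple[float, list[str], bool]:
    """Anchor the score cutoff on marginal HRD1-KO-exclusive hits.

    Anchor proteins are detected only in the HRD1-KO pulldown (WT, SEL1L-KO
    and IgG all zero in every experiment) with 2 PSMs; the cutoff is the
    lowest score among them. Interpretations of "2 PSMs" (``mode``):

    - ``exact_single`` (default): exactly 2 PSMs in at least one experiment
    - ``exact_sum``: exactly 2 PSMs summed over experiments
    - ``at_least``: >= 2 PSMs in at least one experiment

    Returns (cutoff, anchor protein ids, used_fallback). With no anchor the
    configured default is returned and a warning logged.
    """
    g = psm.groupby("protein_id")
    exclusive = (
        g[["psm_wt", "psm_sko", "psm_igg"]].sum().sum(axis=1) == 0
    )
    if mode == "exact_single":
        hits = g["psm_hko"].agg(lambda s: bool((s == 2).any()))
    elif mode == "exact_sum":
        hits = g["psm_hko"].sum() == 2
    elif mode == "at_least":
        hits = g["psm_hko"].agg(lambda s: bool((s >= 2).any()))
    else:
        raise ValueError(f"unknown cutoff mode {mode!r}")
    anchors = sorted(exclusive.index[exclusive & hits].tolist())
    anchors = [a for a in anchors if a in protein_scores.index]
    if not anchors:
        logger.warning(
            "no HRD1-KO-exclusive 2-PSM anchor protein found; "
            "falling back to default cutoff %.3g", default,
        )
        return float(default), [], True
    return float(protein_scores.loc[anchors].min()), anchors, False
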