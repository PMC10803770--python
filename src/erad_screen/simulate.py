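"""Seeded synthetic IP-MS datasets for the SEL1L substrate screen.

The generator emulates the structure of a bait-trapping affinity-purification
experiment: per protein and replicate experiment, non-negative integer
peptide-spectrum-match (PSM) counts for four pulldown genotypes (IgG mock
control, SEL1L-KO, WT, HRD1-KO), plus the protein annotations, a
differential-expression table, and a ground-truth role table used by
recovery tests.

Planted roles
-------------
substrate
    Retained on the SEL1L bait when HRD1 is lost: high HRD1-KO means, near
    absence in WT, SEL1L-KO and IgG pulldowns.
machinery
    ERAD complex members that co-purify with the bait regardless of HRD1
    status; the baits SEL1L, HRD1 and OS9 are always emitted with fixed,
    genotype-consistent counts (SEL1L absent in the SEL1L-KO column, HRD1
    absent in the HRD1-KO column) so the reference-ratio filter is always
    computable.
contaminant
    Keratin-family proteins binding resin and antibody non-specifically:
    similar means in every column including IgG.
transcriptional_decoy
    Substrate-like PSM profile caused by mRNA upregulation in HRD1-KO; each
    decoy carries a differential-expression row with a large positive
    log2 fold change and a tiny adjusted p value, so the RNA filter can
    remove it.
background
    Low, genotype-independent counts; never ER-client-like.

Counts are negative-binomially distributed (mean per role and genotype,
common overdispersion); PSM counts from replicate injections are
well known to be overdispersed relative to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

GENOTYPES = ("igg", "sko", "wt", "hko")
ROLES = ("substrate", "machinery", "contaminant", "transcriptional_decoy", "background")

#: Default role mix: mostly background, a non-trivial substrate class.
DEFAULT_ROLE_FRACTIONS = {
    "background": 0.80,
    "substrate": 0.08,
    "contaminant": 0.05,
    "transcriptional_decoy": 0.04,
    "machinery": 0.03,
}

#: Default per-(role, genotype) negative-binomial means. Background and
#: contaminants bind independently of genotype (contaminants also in IgG);
#: machinery follows the bait, which is present in all pulldowns except the
#: mock; substrates and decoys accumulate only when HRD1 is lost.
DEFAULT_MEAN_PSM = {
    ("substrate", "igg"): 0.05,
    ("substrate", "sko"): 0.3,
    ("substrate", "wt"): 0.8,
    ("substrate", "hko"): 20.0,
    ("machinery", "igg"): 0.3,
    ("machinery", "sko"): 0.5,
    ("machinery", "wt"): 25.0,
    ("machinery", "hko"): 25.0,
    ("contaminant", "igg"): 8.0,
    ("contaminant", "sko"): 8.0,
    ("contaminant", "wt"): 8.0,
    ("contaminant", "hko"): 8.0,
    ("transcriptional_decoy", "igg"): 0.05,
    ("transcriptional_decoy", "sko"): 0.3,
    ("transcriptional_decoy", "wt"): 0.8,
    ("transcriptional_decoy", "hko"): 18.0,
    ("background", "igg"): 1.0,
    ("background", "sko"): 1.0,
    ("background", "wt"): 1.0,
    ("background", "hko"): 1.0,
}

#: Fixed per-experiment counts for the bait and reference proteins. SEL1L is
#: the IP bait (absent when knocked out); HRD1 vanishes in its own KO; OS9
#: is the lectin co-factor used, with SEL1L, by the reference-ratio filter.
#: SEL1L HRD1-KO/WT ratio = 400/300 ≈ 1.33; OS9 ratio = 120/60 = 2.0.
BAIT_COUNTS = {
    "SEL1L": {"igg": 0, "sko": 0, "wt": 300, "hko": 400},
    "HRD1": {"igg": 0, "sko": 0, "wt": 80, "hko": 0},
    "OS9": {"igg": 0, "sko": 0, "wt": 60, "hko": 120},
}


@dataclass
class SimConfig:
    """Configuration of one synthetic screen.

    Parameters
    ----------
    n_proteins
        Total number of proteins emitted, including the three fixed baits.
    n_experiments
        Replicate IP-MS experiments (>= 2; the consensus rule needs two).
    role_fractions
        Fraction of non-bait proteins per role; must sum to 1.
    mean_psm
        Negative-binomial mean per (role, genotype).
    dispersion
        Negative-binomial size parameter r (variance = mu + mu^2 / r);
        smaller r means more overdispersion.
    de_effect_log2fc
        Minimum mRNA log2 fold change planted for transcriptional decoys.
    known_positive_fraction
        Fraction of substrates flagged as literature-known positives for
        training-label construction (OS9 is always flagged).
    seed
        Seed for all randomness; identical config + seed reproduces the
        dataset byte for byte.
    """

    n_proteins: int = 2000
    n_experiments: int = 3
    role_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_FRACTIONS)
    )
    mean_psm: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_PSM)
    )
    dispersion: float = 10.0
    de_effect_log2fc: float = 2.5
    known_positive_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < len(BAIT_COUNTS) + 1:
            raise ConfigError(f"n_proteins must exceed the {len(BAIT_COUNTS)} baits")
        if self.n_experiments < 2:
            raise ConfigError("n_experiments must be >= 2 (consensus rule)")
        if set(self.role_fractions) - set(ROLES):
            raise ConfigError(f"unknown roles: {set(self.role_fractions) - set(ROLES)}")
        total = sum(self.role_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"role_fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.role_fractions.values()):
            raise ConfigError("role_fractions must be non-negative")
        if any(m < 0 for m in self.mean_psm.values()):
            raise ConfigError("mean_psm values must be non-negative")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if not 0.0 <= self.known_positive_fraction <= 1.0:
            raise ConfigError("known_positive_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """The four tables a synthetic run produces."""

    psm: pd.DataFrame
    annotations: pd.DataFrame
    de: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def known_positives(self) -> list[str]:
        """Gene symbols of literature-known substrates for label training."""
        mask = self.truth["known_positive"].astype(bool)
        return sorted(self.truth.loc[mask, "protein_id"].tolist())

    def write(self, out_dir) -> None:
        from . import io as _io  # local import: io depends on nothing here

        _io.ensure_dir(out_dir)
        _io.write_table(self.psm, f"{out_dir}/psm.tsv")
        _io.write_table(self.annotations, f"{out_dir}/annotations.tsv")
        _io.write_table(self.de, f"{out_dir}/de.tsv")
        _io.write_table(self.truth, f"{out_dir}/truth.tsv")


def _role_counts(config: SimConfig) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of non-bait proteins."""
    n = config.n_proteins - len(BAIT_COUNTS)
    fracs = {r: config.role_fractions.get(r, 0.0) for r in ROLES}
    raw = {r: n * f for r, f in fracs.items()}
    counts = {r: int(np.floor(v)) for r, v in raw.items()}
    short = n - sum(counts.values())
    # hand leftovers to the largest fractional remainders, ties by role order
    order = sorted(ROLES, key=lambda r: (-(raw[r] - counts[r]), ROLES.index(r)))
    for r in order[:short]:
        counts[r] += 1
    return counts


def _sample_nb(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _substrate_annotations(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """ER-client feature draws for substrates and decoys.

    Matches the prevalence observed among validated ERAD clients: roughly
    60% transmembrane, 70% N-glycosylated, 30% disulfide-bonded. Luminal
    (non-TM) clients enter the ER via a signal peptide, so every protein has
    at least one client feature.
    """
    has_tm = rng.random(n) < 0.6
    n_tm = np.where(has_tm, rng.integers(1, 9, n), 0)
    has_sp = np.where(has_tm, rng.random(n) < 0.5, True)
    has_glyc = rng.random(n) < 0.7
    n_glyc = np.where(has_glyc, rng.poisson(2.0, n) + 1, 0)
    has_ds = rng.random(n) < 0.3
    loc = np.where(has_tm, "ER;membrane", "ER")
    return {
        "localizations": loc,
        "has_signal_peptide": has_sp.astype(bool),
        "n_glycosylation_sites": n_glyc.astype(np.int64),
        "has_disulfide": has_ds,
        "n_tm_domains": n_tm.astype(np.int64),
    }


def _background_annotations(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Background proteins: mostly featureless cytosolic/nuclear, with a
    small secreted-like minority carrying a signal peptide and glycans."""
    u = rng.random(n)
    loc = np.select(
        [u < 0.40, u < 0.70, u < 0.82, u < 0.90],
        ["cytosol", "nucleus", "mitochondrion", "cytosol;nucleus"],
        default="secreted",
    )
    secreted = loc == "secreted"
    n_glyc = np.where(secreted, rng.poisson(1.5, n) + 1, 0)
    return {
        "localizations": loc,
        "has_signal_peptide": secreted,
        "n_glycosylation_sites": n_glyc.astype(np.int64),
        "has_disulfide": secreted & (rng.random(n) < 0.5),
        "n_tm_domains": np.zeros(n, dtype=np.int64),
    }


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one synthetic screen: PSM counts, annotations, DE, truth.

    Deterministic given the config (including its seed). The truth table
    carries exactly one row per emitted protein with its planted role and
    the generative means used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _role_counts(config)
    n_exp = config.n_experiments

    ids: list[str] = []
    roles: list[str] = []
    for role, prefix in [
        ("substrate", "SUB"),
        ("transcriptional_decoy", "DEC"),
        ("machinery", "MACH"),
        ("background", "BG"),
    ]:
        for i in range(counts[role]):
            ids.append(f"{prefix}{i + 1:04d}")
            roles.append(role)
    # contaminants get keratin-family symbols (KRT / KRTAP prefixes)
    for i in range(counts["contaminant"]):
        ids.append(f"KRT{i + 1}" if i % 3 else f"KRTAP{i + 1}")
        roles.append("contaminant")
    bait_ids = list(BAIT_COUNTS)
    ids += bait_ids
    roles += ["machinery"] * len(bait_ids)

    role_arr = np.asarray(roles)
    id_arr = np.asarray(ids)
    n_random = len(ids) - len(bait_ids)

    # ---- PSM counts ------------------------------------------------------
    exp_ids = [f"expt{k + 1}" for k in range(n_exp)]
    frames = []
    for exp in exp_ids:
        cols: dict[str, np.ndarray] = {}
        for g in GENOTYPES:
            col = np.zeros(len(ids), dtype=np.int64)
            for role in ROLES:
                mask = (role_arr == role) & ~np.isin(id_arr, bait_ids)
                m = config.mean_psm.get((role, g), 0.0)
                col[mask] = _sample_nb(rng, m, config.dispersion, int(mask.sum()))
            for b in bait_ids:
                col[id_arr == b] = BAIT_COUNTS[b][g]
            cols[f"psm_{g}"] = col
        frames.append(
            pd.DataFrame({"protein_id": ids, "experiment_id": exp, **cols})
        )
    psm = pd.concat(frames, ignore_index=True)

    # ---- annotations -----------------------------------------------------
    annot = pd.DataFrame({"protein_id": ids, "gene_symbol": ids})
    annot["species"] = "human"
    fields = {
        "localizations": np.empty(len(ids), dtype=object),
        "has_signal_peptide": np.zeros(len(ids), dtype=bool),
        "n_glycosylation_sites": np.zeros(len(ids), dtype=np.int64),
        "has_disulfide": np.zeros(len(ids), dtype=bool),
        "n_tm_domains": np.zeros(len(ids), dtype=np.int64),
    }
    client_mask = np.isin(role_arr, ["substrate", "transcriptional_decoy"]) & ~np.isin(
        id_arr, bait_ids
    )
    for k, v in _substrate_annotations(rng, int(client_mask.sum())).items():
        fields[k][client_mask] = v
    bg_mask = role_arr == "background"
    for k, v in _background_annotations(rng, int(bg_mask.sum())).items():
        fields[k][bg_mask] = v
    cont_mask = role_arr == "contaminant"
    fields["localizations"][cont_mask] = "cytosol"
    mach_mask = (role_arr == "machinery")
    fields["localizations"][mach_mask] = "ER;membrane"
    fields["has_signal_peptide"][mach_mask] = True
    fields["n_glycosylation_sites"][mach_mask] = 1
    fields["n_tm_domains"][mach_mask] = 1
    for k, v in fields.items():
        annot[k] = v
    annot["is_keratin_family"] = annot["gene_symbol"].str.upper().str.match(
        r"KRT(AP)?\d"
    )

    # ---- differential expression (HRD1-KO vs WT) -------------------------
    decoy_mask = role_arr == "transcriptional_decoy"
    log2fc = rng.normal(0.0, 0.15, len(ids))
    padj = rng.uniform(0.2, 1.0, len(ids))
    nd = int(decoy_mask.sum())
    log2fc[decoy_mask] = config.de_effect_log2fc * (1.0 + 0.3 * rng.random(nd))
    padj[decoy_mask] = 10.0 ** -rng.uniform(4.0, 8.0, nd)
    de = pd.DataFrame(
        {
            "gene_symbol": ids,
            "contrast": "HRD1KO_vs_WT",
            "log2fc": np.round(log2fc, 6),
            "padj": padj,
        }
    )

    # ---- truth -----------------------------------------------------------
    sub_mask = role_arr == "substrate"
    known = np.zeros(len(ids), dtype=bool)
    known[sub_mask] = rng.random(int(sub_mask.sum())) < config.known_positive_fraction
    known[id_arr == "OS9"] = True  # OS9 is a literature-known ERAD substrate
    truth = pd.DataFrame({"protein_id": ids, "role": roles, "known_positive": known})
    for g in GENOTYPES:
        means = np.array(
            [
                BAIT_COUNTS[i][g]
                if i in BAIT_COUNTS
                else config.mean_psm.get((r, g), 0.0)
                for i, r in zip(ids, roles)
            ]
        )
        truth[f"mean_{g}"] = means

    return SyntheticDataset(psm=psm, annotations=annot, de=de, truth=truth, config=config)


@dataclass
class ConfusionCounts:
    """Binary confusion counts against planted substrate truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def truth_confusion(called_ids, truth: pd.DataFrame) -> ConfusionCounts:
    """Score a candidate list against the planted roles.

    A call is a true positive when the protein's planted role is
    ``substrate``; any other called role is a false positive. Unknown
    protein ids are an error.
    """
    called = set(called_ids)
    known_ids = set(truth["protein_id"])
    unknown = called - known_ids
    if unknown:
        raise KeyError(f"called proteins absent from truth: {sorted(unknown)[:5]}")
    is_sub = truth.set_index("protein_id")["role"].eq("substrate")
    tp = sum(1 for p in called if is_sub[p])
    fp = len(called) - tp
    fn = int(is_sub.sum()) - tp
    tn = len(known_ids) - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable view of a config (tuple keys flattened)."""
    d = asdict(config)
    d["role_fractions"] = dict(config.role_fractions)
    d["mean_psm"] = {f"{r}:{g}": m for (r, g), m in config.mean_psm.items()}
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "mean_psm" in d:
        d["mean_psm"] = {
            tuple(k.split(":")): v for k, v in d["mean_psm"].items()
        }
    return SimConfig(**d)
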