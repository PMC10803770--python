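"""Cross-cell-type cataloging of substrate candidates.

Mouse gene symbols are mapped to human ortholog symbols (user-supplied
Alliance-of-Genome-Resources-style TSV), class-I MHC heavy-chain genes
(human HLA-*, mouse H2-*) are collapsed into the single comparative unit
``MHC-I`` because one-to-one orthology cannot be established for them, and
the harmonized candidate sets are split into shared and cell-type-specific
groups with integer-rounded percentages. Pathway overrepresentation uses
group-size-normalized counts: a pathway is overrepresented in a group when
that group's normalized count exceeds 50% of the sum over the three
groups, otherwise it is shared.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

MHC_TOKEN = "MHC-I"
_MHC_PATTERN = re.compile(r"^(HLA-|H2-)", re.IGNORECASE)


def is_mhc_class_i(symbol: str) -> bool:
    """Match class-I MHC heavy-chain symbols by HLA-/H2- prefix."""
    return bool(_MHC_PATTERN.match(str(symbol).strip()))


def harmonize_symbols(
    symbols,
    ortholog_map: dict[str, str] | None = None,
    species: str = "human",
) -> tuple[set[str], list[str]]:
    """Map a candidate symbol list onto human symbols with MHC-I grouping.

    Mouse symbols are converted through the ortholog map (case-normalized);
    unmapped mouse symbols are dropped and returned for logging. Any HLA-*
    or H2-* symbol collapses to the token ``MHC-I`` (counted once per
    cell type). Human input needing no mapping passes through unchanged.
    """
    unmapped: list[str] = []
    out: set[str] = set()
    if species == "mouse" and not ortholog_map:
        raise ConfigError("mouse candidate symbols require an ortholog map")
    for s in symbols:
        s = str(s).strip()
        if is_mhc_class_i(s):
            out.add(MHC_TOKEN)
            continue
        key = s.upper()
        if species == "mouse":
            mapped = ortholog_map.get(key)
            if mapped is None:
                unmapped.append(s)
                continue
            out.add(mapped)
        else:
            out.add(key)
    if unmapped:
        logger.warning(
            "%d symbols had no human ortholog and were dropped (e.g. %s)",
            len(unmapped), unmapped[:5],
        )
    return out, unmapped


@dataclass
class ComparativeCatalog:
    """Shared vs cell-type-specific partition of two candidate sets."""

    shared: set[str]
    specific: dict[str, set[str]]
    celltypes: tuple[str, str]
    counts: dict[str, int] = field(init=False)
    percentages: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        c1, c2 = self.celltypes
        n_shared = len(self.shared)
        n1, n2 = len(self.specific[c1]), len(self.specific[c2])
        total = n_shared + n1 + n2
        self.counts = {
            "shared": n_shared,
            f"{c1}_specific": n1,
            f"{c2}_specific": n2,
            "total": total,
        }
        # percentage of each cell type's catalog that is shared, and the
        # overall specific share of the union; nearest-integer rounding
        self.percentages = {
            f"shared_pct_{c1}": _pct(n_shared, n_shared + n1),
            f"shared_pct_{c2}": _pct(n_shared, n_shared + n2),
            f"specific_pct_{c1}": _pct(n1, n_shared + n1),
            f"specific_pct_{c2}": _pct(n2, n_shared + n2),
            "specific_pct_overall": _pct(n1 + n2, total),
        }

    def group_of(self, symbol: str) -> str:
        if symbol in self.shared:
            return "shared"
        for ct, s in self.specific.items():
            if symbol in s:
                return ct
        raise KeyError(symbol)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, "shared") for s in sorted(self.shared)]
        for ct in self.celltypes:
            rows += [(s, ct) for s in sorted(self.specific[ct])]
        return pd.DataFrame(rows, columns=["symbol", "group"])


def _pct(num: int, den: int) -> int:
    return int(round(100.0 * num / den)) if den else 0


def classify_shared(
    set1: set[str],
    set2: set[str],
    celltypes: tuple[str, str] = ("celltype1", "celltype2"),
) -> ComparativeCatalog:
    """Partition two harmonized candidate sets into shared and specific."""
    shared = set(set1) & set(set2)
    return ComparativeCatalog(
        shared=shared,
        specific={celltypes[0]: set(set1) - shared, celltypes[1]: set(set2) - shared},
        celltypes=tuple(celltypes),
    )


def pathway_overrepresentation(
    assignments: pd.DataFrame,
    catalog: ComparativeCatalog,
    mhc_shared_count: int | None = None,
) -> pd.DataFrame:
    """Classify each pathway as overrepresented in one group or shared.

    ``assignments`` has columns (gene_symbol, pathway); multi-assignment is
    allowed. Counts per group are normalized to the group's total catalog
    size; a group whose normalized count exceeds 50% of the three-group sum
    claims the pathway (at most one group can), otherwise the pathway is
    shared across groups. A group with zero total contributes 0 and cannot
    claim a pathway.

    ``mhc_shared_count`` substitutes the raw count contributed by the
    ``MHC-I`` token in the shared group (the larger of the actual HLA- or
    H2- hit counts), applied before normalization.
    """
    c1, c2 = catalog.celltypes
    groups = {"shared": catalog.shared, c1: catalog.specific[c1], c2: catalog.specific[c2]}
    totals = {g: len(s) for g, s in groups.items()}

    asg = assignments.copy()
    asg["symbol"] = asg["gene_symbol"].astype(str).str.strip()
    asg.loc[asg["symbol"].map(is_mhc_class_i), "symbol"] = MHC_TOKEN
    asg["symbol"] = asg["symbol"].where(asg["symbol"] == MHC_TOKEN,
                                        asg["symbol"].str.upper())
    asg = asg[["symbol", "pathway"]].drop_duplicates()

    records = []
    for pathway, sub in asg.groupby("pathway", sort=True):
        members = set(sub["symbol"])
        counts = {g: len(members & s) for g, s in groups.items()}
        if mhc_shared_count is not None and MHC_TOKEN in members & groups["shared"]:
            counts["shared"] += mhc_shared_count - 1
        norm = {
            g: (counts[g] / totals[g]) if totals[g] else 0.0 for g in groups
        }
        total_norm = sum(norm.values())
        verdict = "shared_across_groups"
        if total_norm > 0:
            for g in groups:
                if totals[g] and norm[g] > 0.5 * total_norm:
                    verdict = {
                        "shared": "enriched_in_shared",
                        c1: f"enriched_in_{c1}",
                        c2: f"enriched_in_{c2}",
                    }[g]
                    break
        records.append(
            {
                "pathway": pathway,
                "count_shared": counts["shared"],
                f"count_{c1}": counts[c1],
                f"count_{c2}": counts[c2],
                "norm_shared": norm["shared"],
                f"norm_{c1}": norm[c1],
                f"norm_{c2}": norm[c2],
                "verdict": verdict,
            }
        )
    return pd.DataFrame.from_records(records)


def ternary_coordinates(pathway_calls: pd.DataFrame) -> pd.DataFrame:
    """Normalized triples summing to 1 per pathway, for ternary plotting."""
    norm_cols = [c for c in pathway_calls.columns if c.startswith("norm_")]
    out = pathway_calls[["pathway"] + norm_cols].copy()
    total = out[norm_cols].sum(axis=1)
    for c in norm_cols:
        out[c.replace("norm_", "tern_")] = (out[c] / total).where(total > 0, 0.0)
    return out[["pathway"] + [c.replace("norm_", "tern_") for c in norm_cols]]
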