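"""Selection of SEL1L-interacting proteins from WT vs SEL1L-KO pulldowns.

A protein is called an interactor when it is ER-resident or a membrane
protein and its PSM signal in the SEL1L-KO negative control is smaller than
one tenth of its signal in the WT pulldown (strict inequality). By default
the rule is applied to PSMs pooled across replicate experiments; the IgG
column plays no part here.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

ELIGIBLE_LOCALIZATIONS = frozenset({"ER", "membrane"})


def _parse_loc(value: str) -> frozenset[str]:
    return frozenset(p.strip() for p in str(value).split(";") if p.strip())


def select_interactors(
    psm: pd.DataFrame,
    annotations: pd.DataFrame,
    pooled: bool = True,
) -> pd.DataFrame:
    """Call SEL1L interactors from the WT / SEL1L-KO columns.

    Parameters
    ----------
    psm
        Long-format PSM table.
    annotations
        Protein annotations; proteins without an annotation row are
        ineligible (logged).
    pooled
        Sum PSMs across experiments before applying the one-tenth rule
        (default). When False the rule must hold in every experiment in
        which the protein was observed.

    Returns
    -------
    DataFrame with columns protein_id, wt_psm, sko_psm,
    eligible_localization, selected.
    """
    loc = annotations.set_index("protein_id")["localizations"].map(_parse_loc)
    sums = psm.groupby("protein_id")[["psm_wt", "psm_sko"]].sum()

    missing = sums.index.difference(loc.index)
    if len(missing):
        logger.warning(
            "%d proteins lack annotations and are ineligible (e.g. %s)",
            len(missing), list(missing[:3]),
        )

    eligible = sums.index.to_series().map(
        lambda p: bool(loc.get(p, frozenset()) & ELIGIBLE_LOCALIZATIONS)
    )

    if pooled:
        rule = sums["psm_sko"] < sums["psm_wt"] / 10.0
    else:
        per = psm.set_index("protein_id")
        rule = (per["psm_sko"] < per["psm_wt"] / 10.0).groupby(level=0).all()
        rule = rule.reindex(sums.index, fill_value=False)

    out = pd.DataFrame(
        {
            "protein_id": sums.index,
            "wt_psm": sums["psm_wt"].to_numpy(),
            "sko_psm": sums["psm_sko"].to_numpy(),
            "eligible_localization": eligible.to_numpy(),
            "selected": (eligible & rule).to_numpy(),
        }
    ).reset_index(drop=True)
    return out.sort_values("protein_id", ignore_index=True)
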