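import numpy as np
import pandas as pd
import pytest

from erad_screen.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic screen (seed 1), shared across tests."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture()
def small_psm():
    """A hand-written three-protein, two-experiment PSM table."""
    rows = []
    for exp in ("expt1", "expt2"):
        rows += [
            {"protein_id": "P1", "experiment_id": exp,
             "psm_igg": 0, "psm_sko": 0, "psm_wt": 2, "psm_hko": 15},
            {"protein_id": "P2", "experiment_id": exp,
             "psm_igg": 3, "psm_sko": 4, "psm_wt": 5, "psm_hko": 4},
            {"protein_id": "P3", "experiment_id": exp,
             "psm_igg": 0, "psm_sko": 0, "psm_wt": 0, "psm_hko": 0},
        ]
    return pd.DataFrame(rows)


def make_annotation(
    protein_id,
    gene_symbol=None,
    localizations="ER",
    has_signal_peptide=True,
    n_glycosylation_sites=1,
    has_disulfide=False,
    n_tm_domains=0,
):
    return {
        "protein_id": protein_id,
        "gene_symbol": gene_symbol or protein_id,
        "species": "human",
        "localizations": localizations,
        "has_signal_peptide": has_signal_peptide,
        "n_glycosylation_sites": n_glycosylation_sites,
        "has_disulfide": has_disulfide,
        "n_tm_domains": n_tm_domains,
    }


@pytest.fixture()
def small_annotations():
    df = pd.DataFrame(
        [
            make_annotation("P1"),
            make_annotation("P2", localizations="cytosol",
                            has_signal_peptide=False, n_glycosylation_sites=0),
            make_annotation("P3", localizations="membrane", n_tm_domains=2),
        ]
    )
    df["is_keratin_family"] = False
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
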