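import numpy as np
import pandas as pd
import pytest

from msoxome.ingest import (
    StudyDesign,
    META_COLUMNS,
    parse_peptidoform,
    render_peptidoform,
)


def make_table(rows, samples, scores=None):
    """Build an internal peptidoform table from (peptide, protein, aucs) rows.

    ``aucs`` may contain None/NaN for missing values.
    """
    out = []
    for i, (pep, protein, aucs) in enumerate(rows):
        bare, mods = parse_peptidoform(pep)
        rec = {
            "peptidoform": render_peptidoform(bare, mods),
            "bare_sequence": bare,
            "mods": mods,
            "protein": protein,
            "gene": None,
            "score": np.nan if scores is None else scores[i],
        }
        for s, v in zip(samples, aucs):
            rec[s] = np.nan if v is None else float(v)
        out.append(rec)
    return pd.DataFrame(out, columns=list(META_COLUMNS) + list(samples))


@pytest.fixture
def toy_design():
    """One batch of 8 samples (4 WT / 4 5XFAD, balanced sex) plus a second batch."""
    rows = []
    for tp in ("3m", "9m"):
        for geno in ("WT", "FAD5X"):
            for i, sex in enumerate(["F", "F", "M", "M"], start=1):
                rows.append(
                    {
                        "sample_id": f"{tp}_{geno}_{i}",
                        "genotype": geno,
                        "sex": sex,
                        "timepoint": tp,
                        "batch": f"B{tp}",
                    }
                )
    return StudyDesign(pd.DataFrame(rows))


@pytest.fixture
def small_study():
    """A compact simulated study shared by read-only tests."""
    from msoxome.synthetic import SimConfig, simulate_study

    return simulate_study(SimConfig(n_proteins=40, seed=11))
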