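import numpy as np
import pandas as pd
import pytest

import admixomics as ax


@pytest.fixture(scope="session")
def aim_panel_654():
    """Synthetic 654-marker AIM panel at K=5, F=0.15 (study-scale panel)."""
    return ax.make_reference_panel(654, 5, (0.15,) * 5, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 50+50 patient cohort with mutations and counts, shared read-only."""
    clinical = ax.make_clinical(50, 50, seed=7)
    cfg = ax.SimConfig(seed=7, n_AA=50, n_EA=50, G=300)
    counts, samples, truth = ax.make_counts(clinical, cfg)
    mutations = ax.make_mutations(clinical, seed=7)
    return {
        "clinical": clinical,
        "counts": counts,
        "samples": samples,
        "truth": truth,
        "mutations": mutations,
    }


@pytest.fixture()
def toy_panel_file(tmp_path):
    """Three-marker, two-population panel TSV on disk."""
    path = tmp_path / "panel.tsv"
    pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 300],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "f_AFR": [0.9, 0.1, 0.5],
            "f_EUR": [0.1, 0.9, 0.0],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
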