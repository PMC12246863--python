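import pandas as pd
import pytest

from astrokin import kinome, synthetic


@pytest.fixture
def small_de_table():
    """Five genes with hand-checkable statistics."""
    return pd.DataFrame({
        "gene": ["gA", "gB", "gC", "gD", "gE"],
        "log2FC": [2.0, -1.0, 0.5, -2.5, 1.2],
        "pvalue": [0.01, 0.1, 0.5, 0.001, 0.04],
        "padj": [0.02, 0.2, 0.7, 0.004, 0.08],
    })


@pytest.fixture(scope="session")
def kinome_fixture():
    """One generated kinome run with two planted active kinases, processed to
    per-peptide statistics (session-scoped: the slope fits dominate runtime)."""
    kmap = synthetic.gen_kinase_map(seed=0)
    run, truth = synthetic.gen_kinome_run(kmap, ["K000", "K001"], shift=1.0,
                                          noise_sd=0.1, seed=0)
    values = kinome.peptide_signal(run)
    stats = kinome.peptide_lfc(values)
    return {"map": kmap, "run": run, "truth": truth, "values": values,
            "stats": stats}
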