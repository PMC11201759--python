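import pandas as pd
import pytest

from netprio.pipeline import write_study
from netprio.synth import simulate_study


P3_EDGES = [("A", "B"), ("B", "C")]
K3_EDGES = [("A", "B"), ("B", "C"), ("A", "C")]


@pytest.fixture
def p3_edges():
    """Path graph A - B - C."""
    return list(P3_EDGES)


@pytest.fixture
def k3_edges():
    """Triangle on A, B, C."""
    return list(K3_EDGES)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by aggregation/pipeline tests."""
    return simulate_study(
        7,
        n_genes=600,
        frac_deg=0.15,
        effect_sd=0.6,
        n_term_pairs=4,
        size_range=(40, 80),
        mean_degree=6.0,
        n_hubs=2,
        hub_degree_factor=8.0,
    )


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_study):
    """The same study written to disk, plus its run config path."""
    d = tmp_path_factory.mktemp("study")
    cfg = write_study(small_study, d)
    return d, cfg


def canonical_degs(table: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """On-disk dialect -> canonical (gene, log2fc, qvalue), q-filtered."""
    out = table.rename(columns={"log2FoldChange": "log2fc", "padj": "qvalue"})
    return out[out["qvalue"] < q_threshold].reset_index(drop=True)
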