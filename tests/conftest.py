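import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from graftnet.io import AbundanceTable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(values, proteins=None, conditions=None, timepoints=None, replicates=None):
    """Small AbundanceTable helper: values is (n_proteins, n_samples)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    proteins = proteins or [f"PROT{i}" for i in range(n)]
    samples = [f"S{j}" for j in range(m)]
    ann = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": conditions or ["A"] * m,
            "timepoint": timepoints or ["T1"] * m,
            "replicate": replicates or list(range(1, m + 1)),
        }
    )
    data = pd.DataFrame(values, index=proteins, columns=samples)
    return AbundanceTable(data, ann)


@pytest.fixture
def path5():
    """Path graph 1-2-3-4-5 with string node ids."""
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in g.nodes})


@pytest.fixture(scope="session")
def bundle_run(tmp_path_factory):
    """One full pipeline run on the default synthetic bundle (seed 0)."""
    import warnings

    from graftnet.cli import write_bundle
    from graftnet.pipeline import load_config, run_pipeline

    out = tmp_path_factory.mktemp("bundle")
    info = write_bundle(out, seed=0)
    cfg = load_config(out / "config.yaml")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(cfg)
    return {"dir": out, "info": info, "config": cfg, "result": result}
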