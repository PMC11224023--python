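import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

from nimx.kb_ingest import load_and_build_role_sets
from nimx.synthetic import FixtureKBSpec, generate_fixture_kb


@pytest.fixture(scope="session")
def fixture_kb(tmp_path_factory):
    """Seed-0 fixture knowledge base: (directory, manifest)."""
    kb_dir = tmp_path_factory.mktemp("kb0")
    manifest = generate_fixture_kb(FixtureKBSpec(seed=0), kb_dir)
    return kb_dir, manifest


@pytest.fixture(scope="session")
def fixture_roles(fixture_kb):
    """(roles, filtered interaction rows) for the seed-0 fixture."""
    kb_dir, _ = fixture_kb
    return load_and_build_role_sets(
        kb_dir / "omnipath.tsv",
        kb_dir / "cpdb_proteins.csv",
        kb_dir / "enzymes.tsv",
        kb_dir / "ion_channels.txt",
    )


def make_adata(counts, cell_types=None, sample_ids=None, **obs_extra):
    """Small AnnData from a dense count array (cells x genes)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else ["s1"] * n,
            "condition": obs_extra.pop("condition", ["zymosan"] * n),
            "timepoint_h": obs_extra.pop("timepoint_h", [4] * n),
            "cell_type": cell_types if cell_types is not None else ["T"] * n,
            "doublet_flag": obs_extra.pop("doublet_flag", [False] * n),
            "mito_fraction": obs_extra.pop("mito_fraction", [0.01] * n),
        },
        index=pd.Index([f"c{i:04d}" for i in range(n)], name="barcode"),
    )
    for key, value in obs_extra.items():
        obs[key] = value
    var = pd.DataFrame(index=pd.Index([f"g{j:03d}" for j in range(g)], name="gene"))
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
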