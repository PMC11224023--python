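"""Communication probability, permutation null, filters, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_adata
from nimx import communication as comm
from nimx import sc_pipeline as scp
from nimx.synthetic import generate_null_communication, toy_interactome


# ---------------------------------------------------------------------------
# Summarization
# ---------------------------------------------------------------------------

def test_summarize_constant_and_absent_gene():
    counts = np.zeros((8, 2), dtype=int)
    counts[:, 0] = 5  # every cell expresses g000 identically
    adata = make_adata(counts)
    scp.normalize(adata)
    profile = comm.summarize_expression(adata)
    # constant CP10K value: 5 / 5 * 1e4
    assert profile.expr.loc["T", "g000"] == pytest.approx(1e4, rel=1e-5)
    assert profile.expr.loc["T", "g001"] == 0.0
    assert profile.frac.loc["T", "g001"] == 0.0
    assert profile.n_cells["T"] == 8


def test_summarize_matches_hand_computed_trimmed_mean():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(20, 3))
    counts[:, 0] += 1  # nonzero libraries regardless
    adata = make_adata(counts)
    scp.normalize(adata)
    profile = comm.summarize_expression(adata, trim=0.25)
    cp10k = counts / counts.sum(axis=1, keepdims=True) * 1e4
    for j, gene in enumerate(["g000", "g001", "g002"]):
        values = np.sort(cp10k[:, j])
        hand = values[5:15].mean()  # drop 25% from each tail of 20 cells
        assert profile.expr.loc["T", gene] == pytest.approx(hand, rel=1e-6)


# ---------------------------------------------------------------------------
# Probability
# ---------------------------------------------------------------------------

def test_probability_closed_forms():
    assert comm.communication_probability(0.0, 5.0) == 0.0
    assert comm.communication_probability(1.0, 1.0, kh=0.5) == pytest.approx(2.0 / 3.0)
    assert comm.communication_probability(1e9, 1e9, kh=0.5) == pytest.approx(1.0)


def test_probability_rejects_nonpositive_kh():
    with pytest.raises(ValueError):
        comm.communication_probability(1.0, 1.0, kh=0.0)


@settings(max_examples=200, deadline=None)
@given(
    L1=st.floats(0, 1e3),
    dL=st.floats(0, 1e3),
    R=st.floats(0, 1e3),
    kh=st.floats(1e-3, 10),
)
def test_probability_is_monotone_and_bounded(L1, dL, R, kh):
    p1 = comm.communication_probability(L1, R, kh)
    p2 = comm.communication_probability(L1 + dL, R, kh)
    assert 0.0 <= p1 < 1.0
    assert p2 >= p1 - 1e-12


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _null_scores(seed=0, n_pairs=40, n_perm=50):
    adata, recv, itx = generate_null_communication(seed=seed, n_pairs=n_pairs)
    scp.normalize(adata)
    return comm.score_communication(
        adata, itx, receiver_profile=recv, n_perm=n_perm, seed=seed
    )


def test_permutation_pvalues_live_on_the_plus_one_grid():
    scores = _null_scores(n_perm=50)
    grid = {(1 + k) / 51 for k in range(51)}
    assert set(np.round(scores["p_perm"], 12)) <= {round(g, 12) for g in grid}


def test_permutation_is_seed_reproducible():
    s1 = _null_scores(seed=3)
    s2 = _null_scores(seed=3)
    pd.testing.assert_frame_equal(s1, s2)


def test_zero_probability_gives_p_one_and_no_adjustment():
    counts = np.zeros((30, 1), dtype=int)
    counts[:, 0] = 1
    adata = make_adata(counts, cell_types=["A"] * 15 + ["B"] * 15)
    adata.var_names = ["LigX"]
    scp.normalize(adata)
    recv = comm.CellTypeProfile(
        expr=pd.DataFrame(
            0.0, index=pd.Index(["N"], name="cell_type"),
            columns=pd.Index(["RecX"], name="gene"),
        ),
        frac=pd.DataFrame(0.0, index=pd.Index(["N"]), columns=pd.Index(["RecX"])),
        n_cells=pd.Series([50], index=pd.Index(["N"]), name="n_cells"),
    )
    itx = toy_interactome([("LigX", "RecX")])
    scores = comm.score_communication(adata, itx, receiver_profile=recv, n_perm=20, seed=0)
    assert (scores["probability"] == 0).all()
    assert (scores["p_perm"] == 1.0).all()
    assert (scores["p_adj"] == 1.0).all()
    assert not scores["significant"].any()


def test_min_cells_filter_and_boundary():
    scores = pd.DataFrame(
        {
            "sender_gene": ["a", "b", "c"],
            "receiver_gene": ["r", "r", "r"],
            "modality": ["ligand_receptor"] * 3,
            "sender_type": ["S1", "S2", "S3"],
            "receiver_type": ["N"] * 3,
            "probability": [0.5, 0.5, 0.5],
            "p_adj": [0.049, 0.049, 0.051],
            "n_sender_cells": [10, 9, 50],
            "n_receiver_cells": [50, 50, 50],
        }
    )
    kept = comm.filter_significant(scores, min_cells=10, alpha=0.05)
    assert list(kept["sender_gene"]) == ["a"]  # 9 cells excluded; p 0.051 excluded


def test_aggregate_strength_additivity_and_zero():
    empty = pd.DataFrame(
        columns=[
            "sender_gene", "receiver_gene", "modality", "sender_type",
            "receiver_type", "probability", "significant",
        ]
    )
    mat = comm.aggregate_strength(empty, sender_types=["S"], receiver_types=["N"])
    assert mat.loc["S", "N"] == 0.0

    scores = pd.DataFrame(
        {
            "sender_gene": ["a", "b"],
            "receiver_gene": ["r1", "r2"],
            "modality": ["ligand_receptor"] * 2,
            "sender_type": ["S", "S"],
            "receiver_type": ["N", "N"],
            "probability": [0.3, 0.2],
            "significant": [True, True],
        }
    )
    mat = comm.aggregate_strength(scores)
    assert mat.loc["S", "N"] == pytest.approx(0.5)


def test_compare_conditions_partition_and_regions():
    def scoreset(keys):
        return pd.DataFrame(
            {
                "sender_gene": [k[0] for k in keys],
                "receiver_gene": [k[1] for k in keys],
                "modality": ["ligand_receptor"] * len(keys),
                "significant": [True] * len(keys),
            }
        )

    sets = {
        "zymosan": scoreset([("Ptgs2", "Ptgir"), ("Hbegf", "Cd44")]),
        "incision": scoreset([("Ptgs2", "Ptgir")]),
        "uv_burn": scoreset([("Ptgs2", "Ptgir"), ("Aldh3a2", "Mrgprd")]),
    }
    result = comm.compare_conditions(sets)
    assert result["sizes"]["incision & uv_burn & zymosan"] == 1
    assert result["sizes"]["zymosan"] == 1
    assert result["sizes"]["uv_burn"] == 1
    n_keys = len({k for df in sets.values() for k in zip(df.sender_gene, df.receiver_gene)})
    assert sum(result["sizes"].values()) == n_keys


def test_compare_conditions_needs_two():
    with pytest.raises(ValueError):
        comm.compare_conditions({"zymosan": pd.DataFrame()})


def test_read_write_neuron_profiles_round_trip(tmp_path):
    from nimx.synthetic import generate_neuron_profiles

    profile = generate_neuron_profiles(seed=4)
    comm.write_neuron_profiles(profile, tmp_path / "n.csv", tmp_path / "n_cells.csv")
    back = comm.read_neuron_profiles(tmp_path / "n.csv", tmp_path / "n_cells.csv")
    pd.testing.assert_frame_equal(back.expr, profile.expr)
    pd.testing.assert_series_equal(back.n_cells, profile.n_cells)
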