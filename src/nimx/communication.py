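"""Cell-type-to-cell-type communication scoring over the interactome.

For each interactome record and each (sender cell type, receiver cell
type) pair, the communication probability is the Hill-saturated
mass-action score

    P = L * R / (kh + L * R)

where L and R are 25%-trimmed means of the per-cell counts-per-10k
(non-log) values of the sender and receiver genes in their respective
cell types. For enzyme-mediated records L is the enzyme transcript
(the metabolite itself is unmeasured in scRNA-seq); for ion-channel
records R is the channel transcript.

Significance comes from a label permutation null: cell-type labels are
shuffled globally across cells ``n_perm`` times and

    p_perm = (1 + #{permuted P >= observed P}) / (1 + n_perm).

Receiver-side sensory-neuron profiles are fixed summarized matrices
(steady-state, constant across injury conditions) and do not permute.
Benjamini-Hochberg adjustment runs over the triples with nonzero
observed probability within one dataset; zero-probability triples are
untestable and keep p_adj = 1. A triple is significant when
p_adj <= alpha and both cell types contain at least ``min_cells`` cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactome import Interactome

logger = logging.getLogger(__name__)

DEFAULT_KH = 0.5
DEFAULT_TRIM = 0.25
DEFAULT_N_PERM = 100
DEFAULT_MIN_CELLS = 10
DEFAULT_ALPHA = 0.05


@dataclass
class CellTypeProfile:
    """Summarized expression per (cell type, gene) plus cell counts."""

    expr: pd.DataFrame  # cell types x genes, trimmed-mean CP10K
    frac: pd.DataFrame  # cell types x genes, expressing fraction
    n_cells: pd.Series  # per cell type

    def __post_init__(self):
        if (self.expr.values < 0).any():
            raise ValueError("negative summarized expression")


def _cp10k(adata: ad.AnnData) -> np.ndarray:
    """Non-log CP10K values from a normalized AnnData (dense)."""
    if not adata.uns.get("normalized"):
        raise ValueError("adata must be normalized (CP10K + log1p) first")
    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    return np.expm1(X)


def summarize_expression(
    adata: ad.AnnData,
    genes: Optional[Iterable[str]] = None,
    cell_type_key: str = "cell_type",
    trim: float = DEFAULT_TRIM,
) -> CellTypeProfile:
    """Trimmed-mean CP10K and expressing fraction per cell type.

    ``trim`` is the fraction removed from each tail before averaging.
    Cell types with zero cells are omitted.
    """
    if genes is None:
        genes = list(adata.var_names)
    else:
        genes = [g for g in genes if g in adata.var_names]
    sub = adata[:, genes]
    values = _cp10k(sub)
    labels = sub.obs[cell_type_key].astype(str).to_numpy()
    types = sorted(set(labels))
    expr = np.zeros((len(types), len(genes)))
    frac = np.zeros((len(types), len(genes)))
    n_cells = np.zeros(len(types), dtype=int)
    for i, t in enumerate(types):
        block = values[labels == t]
        n_cells[i] = block.shape[0]
        expr[i] = stats.trim_mean(block, trim, axis=0)
        frac[i] = (block > 0).mean(axis=0)
    idx = pd.Index(types, name="cell_type")
    cols = pd.Index(genes, name="gene")
    return CellTypeProfile(
        expr=pd.DataFrame(expr, index=idx, columns=cols),
        frac=pd.DataFrame(frac, index=idx, columns=cols),
        n_cells=pd.Series(n_cells, index=idx, name="n_cells"),
    )


def communication_probability(L, R, kh: float = DEFAULT_KH):
    """Hill-saturated mass-action probability (elementwise)."""
    if kh <= 0:
        raise ValueError("kh must be positive")
    LR = np.asarray(L, dtype=float) * np.asarray(R, dtype=float)
    return LR / (kh + LR)


def read_neuron_profiles(path, n_cells_path=None, default_n_cells: int = 100) -> CellTypeProfile:
    """Read a gene x subtype summarized-expression CSV as a receiver profile.

    An optional sidecar CSV (columns subtype, n_cells) supplies nucleus
    counts per subtype for the minimum-cell filter.
    """
    mat = pd.read_csv(path, index_col=0)
    expr = mat.T  # -> subtypes x genes
    expr.index.name = "cell_type"
    expr.columns.name = "gene"
    if n_cells_path is not None and Path(n_cells_path).exists():
        nc = pd.read_csv(n_cells_path, index_col="subtype")["n_cells"]
        n_cells = nc.reindex(expr.index).fillna(default_n_cells).astype(int)
    else:
        n_cells = pd.Series(default_n_cells, index=expr.index, dtype=int)
    n_cells.name = "n_cells"
    return CellTypeProfile(
        expr=expr.astype(float),
        frac=(expr > 0).astype(float),
        n_cells=n_cells,
    )


def write_neuron_profiles(profile: CellTypeProfile, path, n_cells_path=None) -> None:
    profile.expr.T.to_csv(path)  # genes x subtypes on disk
    if n_cells_path is not None:
        df = profile.n_cells.rename_axis("subtype").reset_index()
        df.to_csv(n_cells_path, index=False)


def _grouped_trim_mean(
    values: np.ndarray, labels: np.ndarray, types: list, trim: float
) -> np.ndarray:
    out = np.zeros((len(types), values.shape[1]))
    for i, t in enumerate(types):
        block = values[labels == t]
        if block.shape[0]:
            out[i] = stats.trim_mean(block, trim, axis=0)
    return out


def score_communication(
    adata: ad.AnnData,
    itx: Interactome,
    receiver_profile: Optional[CellTypeProfile] = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    kh: float = DEFAULT_KH,
    trim: float = DEFAULT_TRIM,
    min_cells: int = DEFAULT_MIN_CELLS,
    alpha: float = DEFAULT_ALPHA,
    cell_type_key: str = "cell_type",
) -> pd.DataFrame:
    """Score every (record, sender type, receiver type) triple.

    Senders are the cell types present in ``adata``. Receivers come from
    ``receiver_profile`` (fixed summarized profiles, e.g. DRG neuron
    subtypes) when given, otherwise from ``adata`` itself (and then
    permute together with the senders). Records whose sender gene is
    absent from ``adata`` or whose receiver gene is absent from the
    receiver side are skipped.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    rng = np.random.default_rng(seed)

    records = itx.sorted_records()
    sender_genes = sorted({r.sender_gene for r in records} & set(adata.var_names))
    receivers_from_adata = receiver_profile is None
    if receivers_from_adata:
        receiver_gene_pool = set(adata.var_names)
    else:
        receiver_gene_pool = set(receiver_profile.expr.columns)
    receiver_genes = sorted({r.receiver_gene for r in records} & receiver_gene_pool)

    usable = [
        r
        for r in records
        if r.sender_gene in set(sender_genes) and r.receiver_gene in set(receiver_genes)
    ]
    if not usable:
        logger.warning("no interactome record is measurable in this dataset")
        return _empty_scores()

    need = sorted(set(sender_genes) | (set(receiver_genes) if receivers_from_adata else set()))
    sub = adata[:, need]
    values = _cp10k(sub)
    labels = sub.obs[cell_type_key].astype(str).to_numpy()
    sender_types = sorted(set(labels))
    col_of = {g: j for j, g in enumerate(need)}

    obs_profile = _grouped_trim_mean(values, labels, sender_types, trim)
    sender_counts = pd.Series(
        {t: int((labels == t).sum()) for t in sender_types}, name="n_cells"
    )

    if receivers_from_adata:
        receiver_types = sender_types
        recv_obs = obs_profile
        recv_counts = sender_counts
        recv_col_of = col_of
    else:
        receiver_types = list(receiver_profile.expr.index)
        recv_obs = receiver_profile.expr.values
        recv_counts = receiver_profile.n_cells
        recv_col_of = {g: j for j, g in enumerate(receiver_profile.expr.columns)}

    s_idx = np.array([col_of[r.sender_gene] for r in usable])
    r_idx = np.array([recv_col_of[r.receiver_gene] for r in usable])

    # observed probabilities: (records, senders, receivers)
    L_obs = obs_profile[:, s_idx].T  # (records, senders)
    R_obs = recv_obs[:, r_idx].T  # (records, receivers)
    prob_obs = communication_probability(
        L_obs[:, :, None], R_obs[:, None, :], kh
    )

    exceed = np.zeros_like(prob_obs)
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        perm_profile = _grouped_trim_mean(values, perm_labels, sender_types, trim)
        Lp = perm_profile[:, s_idx].T
        if receivers_from_adata:
            Rp = perm_profile[:, r_idx].T
        else:
            Rp = R_obs
        prob_p = communication_probability(Lp[:, :, None], Rp[:, None, :], kh)
        exceed += prob_p >= prob_obs
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, rec in enumerate(usable):
        for si, st in enumerate(sender_types):
            for ri, rt in enumerate(receiver_types):
                rows.append(
                    (
                        rec.sender_gene,
                        rec.receiver_gene,
                        rec.modality,
                        rec.intermediate_product or "",
                        st,
                        rt,
                        prob_obs[i, si, ri],
                        p_perm[i, si, ri],
                        int(sender_counts[st]),
                        int(recv_counts[rt]),
                    )
                )
    scores = pd.DataFrame(
        rows,
        columns=[
            "sender_gene",
            "receiver_gene",
            "modality",
            "intermediate_product",
            "sender_type",
            "receiver_type",
            "probability",
            "p_perm",
            "n_sender_cells",
            "n_receiver_cells",
        ],
    )

    tested = scores["probability"] > 0
    scores["p_adj"] = 1.0
    if tested.any():
        _, p_adj, _, _ = multipletests(scores.loc[tested, "p_perm"], method="fdr_bh")
        scores.loc[tested, "p_adj"] = np.maximum(p_adj, scores.loc[tested, "p_perm"])
    scores["significant"] = (
        (scores["p_adj"] <= alpha)
        & (scores["n_sender_cells"] >= min_cells)
        & (scores["n_receiver_cells"] >= min_cells)
    )
    return scores


def _empty_scores() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "sender_gene",
            "receiver_gene",
            "modality",
            "intermediate_product",
            "sender_type",
            "receiver_type",
            "probability",
            "p_perm",
            "n_sender_cells",
            "n_receiver_cells",
            "p_adj",
            "significant",
        ]
    )


def filter_significant(
    scores: pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Apply the minimum-cell and adjusted-p exclusion rules."""
    keep = (
        (scores["p_adj"] <= alpha)
        & (scores["n_sender_cells"] >= min_cells)
        & (scores["n_receiver_cells"] >= min_cells)
    )
    return scores[keep].reset_index(drop=True)


def aggregate_strength(
    scores: pd.DataFrame,
    sender_types: Optional[Iterable[str]] = None,
    receiver_types: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Sender x receiver matrix of summed probabilities over significant triples."""
    if "significant" in scores:
        sig = scores[scores["significant"].astype(bool)]
    else:
        sig = scores
    senders = sorted(sender_types) if sender_types is not None else sorted(
        scores["sender_type"].unique()
    )
    receivers = sorted(receiver_types) if receiver_types is not None else sorted(
        scores["receiver_type"].unique()
    )
    mat = pd.DataFrame(0.0, index=pd.Index(senders, name="sender_type"),
                       columns=pd.Index(receivers, name="receiver_type"))
    if sig.empty:
        return mat
    grouped = sig.groupby(["sender_type", "receiver_type"], observed=True)["probability"].sum()
    for (s, r), v in grouped.items():
        if s in mat.index and r in mat.columns:
            mat.loc[s, r] = v
    return mat


def compare_conditions(score_sets: Mapping[str, pd.DataFrame]) -> dict:
    """Partition significant interaction keys by the condition sets they occur in.

    ``score_sets`` maps condition label -> scored (or filtered) triples at
    that condition's peak-hypersensitivity timepoint. An interaction key
    (sender_gene, receiver_gene, modality) counts for a condition when it
    is significant for at least one cell-type pair there.
    """
    if len(score_sets) < 2:
        raise ValueError("need at least two conditions")
    key_conditions: dict = {}
    for cond in sorted(score_sets):
        df = score_sets[cond]
        sig = df[df["significant"]] if "significant" in df else df
        keys = set(
            zip(sig["sender_gene"], sig["receiver_gene"], sig["modality"])
        )
        for key in keys:
            key_conditions.setdefault(key, set()).add(cond)
    regions: dict = {}
    for key, conds in key_conditions.items():
        label = " & ".join(sorted(conds))
        regions.setdefault(label, []).append("|".join(key))
    regions = {label: sorted(keys) for label, keys in sorted(regions.items())}
    sizes = {label: len(keys) for label, keys in regions.items()}
    assert sum(sizes.values()) == len(key_conditions)
    return {"regions": regions, "sizes": sizes}
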