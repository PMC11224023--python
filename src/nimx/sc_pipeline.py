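"""Single-cell QC, normalization, Wilcoxon DE, DiVenn set algebra, proportions.

The expression container is an :class:`anndata.AnnData` (cells x genes)
with raw counts in ``layers["counts"]`` after normalization and per-cell
annotations in ``obs``: ``sample_id``, ``condition`` (zymosan, incision,
uv_burn or contralateral), ``timepoint_h`` (4, 24, 48), ``cell_type``,
``doublet_flag`` and ``mito_fraction``. ``library_size``/``n_features``
are recomputed from the counts on load.

Differential expression follows the FindMarkers convention: genes are
tested only when the larger of the two expressing fractions reaches
``min_pct`` and the Seurat-style fold change reaches ``log2fc_min``; the
two-sided Wilcoxon rank-sum p-value is exact (full enumeration of group
assignments) when n1+n2 <= 14 and a tie-corrected normal approximation
otherwise; Benjamini-Hochberg adjustment runs over the tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as spio
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_MAX_N = 14  # largest pooled size for the exact permutation p-value

CONDITIONS = ("zymosan", "incision", "uv_burn", "contralateral")
TIMEPOINTS = (4, 24, 48)

OBS_COLUMNS = [
    "sample_id",
    "condition",
    "timepoint_h",
    "cell_type",
    "doublet_flag",
    "mito_fraction",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotated_expression(directory) -> ad.AnnData:
    """Read MTX counts (genes x cells on disk) plus gene/cell annotations.

    Expects ``matrix.mtx``, ``genes.tsv`` (one symbol per line),
    ``barcodes.tsv`` (one barcode per line) and ``cell_meta.csv`` keyed by
    barcode with the annotation columns.
    """
    directory = Path(directory)
    mat = spio.mmread(directory / "matrix.mtx").tocsr().T.tocsr()  # -> cells x genes
    genes = (directory / "genes.tsv").read_text().split()
    barcodes = (directory / "barcodes.tsv").read_text().split()
    meta = pd.read_csv(directory / "cell_meta.csv", index_col="barcode")
    if mat.shape != (len(barcodes), len(genes)):
        raise ValueError("matrix dimensions do not match gene/barcode files")
    meta = meta.loc[barcodes]
    missing = [c for c in OBS_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell_meta.csv missing columns {missing}")
    adata = ad.AnnData(
        X=mat.astype(np.int64), obs=meta.copy(), var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    adata.obs_names = barcodes
    adata.obs["doublet_flag"] = adata.obs["doublet_flag"].astype(bool)
    _refresh_cell_stats(adata)
    return adata


def write_annotated_expression(adata: ad.AnnData, directory) -> None:
    """Write the MTX + TSV + CSV dialect read by :func:`read_annotated_expression`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.layers.get("counts", adata.X)
    spio.mmwrite(str(directory / "matrix.mtx"), sp.csr_matrix(X).T.tocoo())
    (directory / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    meta = adata.obs[OBS_COLUMNS].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(directory / "cell_meta.csv", index=False)


def _refresh_cell_stats(adata: ad.AnnData) -> None:
    X = sp.csr_matrix(adata.X)
    adata.obs["library_size"] = np.asarray(X.sum(axis=1)).ravel().astype(np.int64)
    adata.obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel().astype(np.int64)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    per_sample: pd.DataFrame  # index sample_id, columns n_before/n_after
    reasons: dict = field(default_factory=dict)

    def total_removed(self) -> int:
        return int((self.per_sample["n_before"] - self.per_sample["n_after"]).sum())


def qc_filter(
    adata: ad.AnnData,
    mito_max: float = 0.05,
    z: float = 1.96,
) -> tuple:
    """Remove doublets, per-sample size/feature outliers and high-mito cells.

    The 95% interval is mean +/- ``z``*sd of log10 library size and log10
    feature count, computed per sample over singlets. Samples with fewer
    than three singlet cells skip the interval (undefined) with a warning.
    """
    _refresh_cell_stats(adata)
    obs = adata.obs
    doublet = obs["doublet_flag"].to_numpy(dtype=bool)
    mito = obs["mito_fraction"].to_numpy(dtype=float) > mito_max

    log_lib = np.log10(np.maximum(obs["library_size"].to_numpy(dtype=float), 1.0))
    log_feat = np.log10(np.maximum(obs["n_features"].to_numpy(dtype=float), 1.0))

    size_low = np.zeros(adata.n_obs, dtype=bool)
    size_high = np.zeros(adata.n_obs, dtype=bool)
    feat_low = np.zeros(adata.n_obs, dtype=bool)
    feat_high = np.zeros(adata.n_obs, dtype=bool)

    samples = obs["sample_id"].astype(str)
    for sample in sorted(samples.unique()):
        in_sample = (samples == sample).to_numpy()
        singlet = in_sample & ~doublet
        if singlet.sum() < 3:
            logger.warning(
                "sample %s has <3 singlet cells; size/feature interval skipped", sample
            )
            continue
        for values, low, high in (
            (log_lib, size_low, size_high),
            (log_feat, feat_low, feat_high),
        ):
            mu = values[singlet].mean()
            sd = values[singlet].std(ddof=1)
            low[in_sample & (values < mu - z * sd)] = True
            high[in_sample & (values > mu + z * sd)] = True

    # interval outliers only count against singlets (doublets go first)
    size_low &= ~doublet
    size_high &= ~doublet
    feat_low &= ~doublet
    feat_high &= ~doublet
    mito_sing = mito & ~doublet

    remove = doublet | size_low | size_high | feat_low | feat_high | mito_sing
    keep = ~remove

    per_sample = pd.DataFrame(
        {
            "n_before": samples.value_counts().sort_index(),
            "n_after": samples[keep].value_counts().reindex(
                sorted(samples.unique()), fill_value=0
            ),
        }
    )
    per_sample.index.name = "sample_id"
    reasons = {
        "doublet": int(doublet.sum()),
        "size_low": int(size_low.sum()),
        "size_high": int(size_high.sum()),
        "features_low": int(feat_low.sum()),
        "features_high": int(feat_high.sum()),
        "mito": int(mito_sing.sum()),
    }
    report = QCReport(per_sample=per_sample, reasons=reasons)
    assert (per_sample["n_after"] <= per_sample["n_before"]).all()
    return adata[keep].copy(), report


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """CP10K + log1p normalization; raw counts kept in ``layers['counts']``."""
    import scanpy as sc

    _refresh_cell_stats(adata)
    if (adata.obs["library_size"] == 0).any():
        raise ValueError("zero-library cell encountered; run qc_filter first")
    adata.layers["counts"] = sp.csr_matrix(adata.X).copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    adata.uns["normalized"] = True
    return adata


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _tie_term(col: np.ndarray) -> float:
    _, counts = np.unique(col, return_counts=True)
    t = counts.astype(float)
    return float((t**3 - t).sum())


def rank_sum_pvalues(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per column.

    ``x1`` is (n1, G), ``x2`` is (n2, G). The p-value is
    P(|W - mu| >= |w_obs - mu|) under random assignment of the pooled
    values to the two groups: computed by exhaustive enumeration for
    n1+n2 <= 14 and by the tie-corrected normal approximation otherwise.
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    n = n1 + n2
    pooled = np.vstack([np.atleast_2d(x1), np.atleast_2d(x2)]).astype(float)
    ranks = stats.rankdata(pooled, axis=0)
    w_obs = ranks[:n1].sum(axis=0)
    mu = n1 * (n + 1) / 2.0

    if n <= EXACT_MAX_N:
        idx = np.array(list(combinations(range(n), n1)))  # (ncomb, n1)
        sums = ranks[idx].sum(axis=1)  # (ncomb, G)
        dev_obs = np.abs(w_obs - mu)
        dev = np.abs(sums - mu)
        # rank sums land on a 0.5 grid, so a tiny slack makes >= exact
        p = (dev >= dev_obs[None, :] - 1e-9).mean(axis=0)
        return p

    G = pooled.shape[1]
    tie = np.array([_tie_term(pooled[:, g]) for g in range(G)])
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    p = np.ones(G)
    pos = var > 0
    zscore = np.zeros(G)
    zscore[pos] = (w_obs[pos] - mu) / np.sqrt(var[pos])
    p[pos] = 2.0 * stats.norm.sf(np.abs(zscore[pos]))
    return np.minimum(p, 1.0)


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def find_markers_wilcoxon(
    adata: ad.AnnData,
    group1: np.ndarray,
    group2: np.ndarray,
    log2fc_min: float = 0.25,
    min_pct: float = 0.1,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """FindMarkers-style DE between two cell selections on normalized data.

    ``group1``/``group2`` are boolean masks over ``adata.obs``; they must
    not overlap. Returns one row per *tested* gene with ``log2_fc``,
    ``pct_group1``, ``pct_group2``, ``p_value``, ``p_adj``, ``direction``
    and ``significant`` (p_adj < ``alpha``).
    """
    if not adata.uns.get("normalized"):
        raise ValueError("run normalize() before find_markers_wilcoxon")
    group1 = np.asarray(group1, dtype=bool)
    group2 = np.asarray(group2, dtype=bool)
    if (group1 & group2).any():
        raise ValueError("groups overlap")
    if group1.sum() == 0 or group2.sum() == 0:
        raise ValueError("both groups must be nonempty")

    X1 = _dense(adata.X[group1])
    X2 = _dense(adata.X[group2])

    pct1 = (X1 > 0).mean(axis=0)
    pct2 = (X2 > 0).mean(axis=0)
    mean1 = np.expm1(X1).mean(axis=0)
    mean2 = np.expm1(X2).mean(axis=0)
    log2_fc = np.log2((mean1 + pseudocount) / (mean2 + pseudocount))

    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(log2_fc) >= log2fc_min)
    genes = adata.var_names[tested]
    result = pd.DataFrame(
        {
            "log2_fc": log2_fc[tested],
            "pct_group1": pct1[tested],
            "pct_group2": pct2[tested],
        },
        index=pd.Index(genes, name="gene"),
    )
    if len(result) == 0:
        result["p_value"] = np.array([], dtype=float)
        result["p_adj"] = np.array([], dtype=float)
        result["direction"] = pd.Series(dtype=str)
        result["significant"] = pd.Series(dtype=bool)
        return result

    p = rank_sum_pvalues(X1[:, tested], X2[:, tested])
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    result["p_value"] = p
    result["p_adj"] = np.maximum(p_adj, p)  # BH never below raw p
    result["direction"] = np.where(result["log2_fc"] > 0, "up", "down")
    result["significant"] = result["p_adj"] < alpha
    return result.sort_values(["p_adj", "p_value", "log2_fc"], kind="stable")


def de_contrast(
    adata: ad.AnnData,
    cell_type: str,
    condition: str,
    timepoint_h: int,
    control_condition: str = "contralateral",
    **kwargs,
) -> Optional[pd.DataFrame]:
    """DE for one (cell_type, condition, timepoint) against contralateral cells.

    Contralateral cells of the same cell type at the same timepoint are
    the control group. Returns None when either group is empty.
    """
    obs = adata.obs
    ct = obs["cell_type"].astype(str) == cell_type
    tp = obs["timepoint_h"].astype(int) == int(timepoint_h)
    g1 = (ct & tp & (obs["condition"].astype(str) == condition)).to_numpy()
    g2 = (ct & tp & (obs["condition"].astype(str) == control_condition)).to_numpy()
    if g1.sum() == 0 or g2.sum() == 0:
        return None
    return find_markers_wilcoxon(adata, g1, g2, **kwargs)


def de_all_contrasts(
    adata: ad.AnnData,
    conditions: Iterable[str] = ("zymosan", "incision", "uv_burn"),
    timepoints: Iterable[int] = TIMEPOINTS,
    min_cells: int = 3,
    **kwargs,
) -> dict:
    """Run every (cell_type, condition, timepoint)-vs-contralateral contrast."""
    results: dict = {}
    obs = adata.obs
    for cell_type in sorted(obs["cell_type"].astype(str).unique()):
        for condition in conditions:
            for tp in timepoints:
                ct = obs["cell_type"].astype(str) == cell_type
                sel = obs["timepoint_h"].astype(int) == int(tp)
                n1 = int((ct & sel & (obs["condition"] == condition)).sum())
                n2 = int((ct & sel & (obs["condition"] == "contralateral")).sum())
                if n1 < min_cells or n2 < min_cells:
                    continue
                res = de_contrast(adata, cell_type, condition, int(tp), **kwargs)
                if res is not None:
                    results[(cell_type, condition, int(tp))] = res
    return results


# ---------------------------------------------------------------------------
# DiVenn-style DE set comparison
# ---------------------------------------------------------------------------

def compare_de_sets(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assign each significant gene to its Venn region across contrasts.

    A gene's region is the set of contrasts in which it is significant;
    its color is ``up`` if upregulated in all of them, ``down`` if
    downregulated in all, ``divergent`` otherwise. Every significant gene
    lands in exactly one region with exactly one color.
    """
    if len(results) < 2:
        raise ValueError("need at least two contrasts")
    membership: dict = {}
    directions: dict = {}
    for contrast in sorted(results):
        df = results[contrast]
        sig = df[df["significant"]]
        for gene, row in sig.iterrows():
            membership.setdefault(gene, []).append(contrast)
            directions.setdefault(gene, []).append(row["direction"])
    rows = []
    for gene in sorted(membership):
        dirs = set(directions[gene])
        color = dirs.pop() if len(dirs) == 1 else "divergent"
        rows.append(
            {
                "gene": gene,
                "region": " & ".join(str(c) for c in membership[gene]),
                "n_contrasts": len(membership[gene]),
                "color": color,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "region", "n_contrasts", "color"]).set_index(
        "gene"
    )


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def compute_proportions(adata: ad.AnnData) -> tuple:
    """Per-sample cell-type fractions and unweighted per-group means.

    Returns ``(per_sample, group_means)``: the first has one row per
    (sample, cell_type) with count and fraction (fractions per sample sum
    to one); the second averages fractions unweighted across replicate
    samples per (condition, timepoint, cell_type), with absent types
    counted as zero.
    """
    obs = adata.obs
    cell_types = sorted(obs["cell_type"].astype(str).unique())
    counts = (
        obs.groupby(["sample_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cell_types, fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)

    sample_info = (
        obs[["sample_id", "condition", "timepoint_h"]]
        .drop_duplicates()
        .set_index("sample_id")
    )
    per_sample = fractions.stack().rename("fraction").reset_index()
    per_sample.columns = ["sample_id", "cell_type", "fraction"]
    per_sample["count"] = counts.stack().values
    per_sample = per_sample.merge(sample_info, on="sample_id")
    per_sample = per_sample.sort_values(["sample_id", "cell_type"]).reset_index(drop=True)

    frac_annot = fractions.join(sample_info)
    group_means = (
        frac_annot.groupby(["condition", "timepoint_h"], observed=True)[cell_types]
        .mean()
        .stack()
        .rename("mean_fraction")
        .reset_index()
    )
    group_means.columns = ["condition", "timepoint_h", "cell_type", "mean_fraction"]
    group_means = group_means.sort_values(
        ["condition", "timepoint_h", "cell_type"]
    ).reset_index(drop=True)
    return per_sample, group_means
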