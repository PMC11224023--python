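"""End-to-end orchestration: roles -> assembly -> ortholog mapping -> QC ->
DE -> DiVenn -> proportions -> communication -> injury comparison.

Each stage writes a plain-text artifact into the run directory; the run
finishes with a ``manifest.json`` listing every output with a SHA-256
checksum plus the effective configuration, so a rerun with the same
configuration and seed is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

from . import communication as comm
from . import interactome as itx_mod
from . import kb_ingest
from . import sc_pipeline as scp
from . import synthetic
from .config import RunConfig

logger = logging.getLogger(__name__)

STAGES = [
    "roles",
    "assemble",
    "map_orthologs",
    "qc",
    "de",
    "divenn",
    "proportions",
    "commun",
    "compare",
]


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", str(text)).strip("-")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Missing knowledge-base or expression inputs are produced by the
    synthetic generators under the run's seed, making the default
    invocation a fully self-contained simulated study.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    completed = []

    try:
        # ------------------------------------------------ knowledge base
        if config.kb_paths_given():
            kb = {
                "omnipath": config.omnipath,
                "cpdb": config.cpdb,
                "enzymes": config.enzymes,
                "channels": config.channels,
                "sif": config.sif,
                "statements": config.statements,
                "orthologs": config.orthologs,
            }
        else:
            kb_dir = out / "kb"
            synthetic.generate_fixture_kb(synthetic.FixtureKBSpec(seed=config.seed), kb_dir)
            kb = {
                "omnipath": kb_dir / "omnipath.tsv",
                "cpdb": kb_dir / "cpdb_proteins.csv",
                "enzymes": kb_dir / "enzymes.tsv",
                "channels": kb_dir / "ion_channels.txt",
                "sif": kb_dir / "pc_sif.tsv",
                "statements": kb_dir / "statements.jsonl",
                "orthologs": kb_dir / "orthologs.tsv",
            }
        for name, path in kb.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input for stage roles: {name} = {path}")

        roles, rows = kb_ingest.load_and_build_role_sets(
            kb["omnipath"], kb["cpdb"], kb["enzymes"], kb["channels"]
        )
        roles.to_json(out / "roles.json")
        completed.append("roles")

        itx = itx_mod.assemble_interactome(rows, roles, kb["sif"], kb["statements"])
        itx_mod.export_cellchat_db(itx, roles, out / "itx_human.tsv")
        completed.append("assemble")

        omap = itx_mod.load_ortholog_map(kb["orthologs"])
        itx_mouse, dropped = itx_mod.map_orthologs(itx, omap)
        itx_mod.export_cellchat_db(itx_mouse, roles, out / "itx_mouse.tsv")
        (out / "ortholog_dropped.json").write_text(
            json.dumps(sorted(list(k) for k in dropped), indent=1) + "\n"
        )
        completed.append("map_orthologs")

        # ------------------------------------------------ expression
        if config.expr_dir is not None:
            adata = scp.read_annotated_expression(config.expr_dir)
            neurons = comm.read_neuron_profiles(config.neurons, config.neurons_n_cells)
        else:
            adata, truth = synthetic.generate_expression(
                synthetic.SyntheticSCSpec(seed=config.seed)
            )
            expr_dir = out / "expr"
            scp.write_annotated_expression(adata, expr_dir)
            (expr_dir / "truth.json").write_text(
                json.dumps(truth, indent=1, sort_keys=True) + "\n"
            )
            neurons = synthetic.generate_neuron_profiles(seed=config.seed)
            comm.write_neuron_profiles(
                neurons, out / "neurons.csv", out / "neurons_n_cells.csv"
            )

        adata, qc_report = scp.qc_filter(adata, mito_max=config.mito_max)
        qc_report.per_sample.to_csv(out / "qc_report.csv")
        (out / "qc_reasons.json").write_text(
            json.dumps(qc_report.reasons, indent=1, sort_keys=True) + "\n"
        )
        completed.append("qc")

        scp.normalize(adata)

        de_results = scp.de_all_contrasts(
            adata,
            min_cells=config.de_min_cells,
            log2fc_min=config.immune_log2fc_min,
            min_pct=config.immune_min_pct,
            alpha=config.alpha,
        )
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for (cell_type, condition, tp), df in sorted(de_results.items()):
            df.to_csv(de_dir / f"{_slug(cell_type)}_{condition}_{tp}h.tsv", sep="\t")
        completed.append("de")

        # DiVenn across injuries at T_max for the configured cell type
        tmax_results = {
            f"{cond}@{tp}h": de_results[(config.divenn_cell_type, cond, tp)]
            for cond, tp in sorted(config.t_max.items())
            if (config.divenn_cell_type, cond, tp) in de_results
        }
        if len(tmax_results) >= 2:
            divenn = scp.compare_de_sets(tmax_results)
        else:
            logger.warning("fewer than two T_max contrasts available for DiVenn")
            import pandas as pd

            divenn = pd.DataFrame(columns=["region", "n_contrasts", "color"])
            divenn.index.name = "gene"
        divenn.to_csv(out / "divenn.tsv", sep="\t")
        completed.append("divenn")

        per_sample, group_means = scp.compute_proportions(adata)
        per_sample.to_csv(out / "proportions_per_sample.csv", index=False)
        group_means.to_csv(out / "proportions_group_means.csv", index=False)
        completed.append("proportions")

        # ------------------------------------------------ communication
        comm_dir = out / "commun"
        net_dir = out / "networks"
        comm_dir.mkdir(exist_ok=True)
        net_dir.mkdir(exist_ok=True)
        score_sets = {}
        for cond, tp in sorted(config.t_max.items()):
            mask = (
                (adata.obs["condition"].astype(str) == cond)
                & (adata.obs["timepoint_h"].astype(int) == tp)
            ).to_numpy()
            if mask.sum() == 0:
                logger.warning("no cells for %s at %dh; skipping scoring", cond, tp)
                continue
            subset = adata[mask].copy()
            scores = comm.score_communication(
                subset,
                itx_mouse,
                receiver_profile=neurons,
                n_perm=config.n_perm,
                seed=config.seed,
                kh=config.kh,
                trim=config.trim,
                min_cells=config.min_cells,
                alpha=config.alpha,
            )
            scores.to_csv(comm_dir / f"{cond}_{tp}h.tsv", sep="\t", index=False)
            sig = comm.filter_significant(scores, config.min_cells, config.alpha)
            network = comm.aggregate_strength(
                sig,
                sender_types=sorted(subset.obs["cell_type"].astype(str).unique()),
                receiver_types=list(neurons.expr.index),
            )
            network.to_csv(net_dir / f"{cond}_{tp}h.csv")
            score_sets[cond] = scores
        completed.append("commun")

        if len(score_sets) >= 2:
            comparison = comm.compare_conditions(score_sets)
        else:
            comparison = {"regions": {}, "sizes": {}}
        (out / "comparison.json").write_text(
            json.dumps(comparison, indent=1, sort_keys=True) + "\n"
        )
        completed.append("compare")

    except Exception:
        (out / "FAILED").write_text("failed after stages: " + ", ".join(completed) + "\n")
        raise

    # ------------------------------------------------ manifest
    outputs = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "stages": completed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
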