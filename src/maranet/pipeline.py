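"""End-to-end orchestration: from a fixture/input bundle to all artifacts.

The stages mirror the analysis: per-dataset activity fits, cross-dataset
standardization into z-scores, target scoring combined into probability
products, network construction, and gene-level summaries. Every writer uses
a fixed float format and sorted ordering so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import combine, io as mio, mara, network as net, targets

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def read_bundle(input_dir):
    """Load manifest, per-dataset expression, site counts and both maps."""
    d = Path(input_dir)
    manifest = mio.read_manifest(d / "manifest.tsv")
    sitecounts = mio.read_sitecounts(
        d / "sitecounts.tsv" if (d / "sitecounts.tsv").exists() else d / "sitecounts.triplets.tsv"
    )
    expression = {
        ds: mio.read_expression(d / f"expression_{ds}.tsv")
        for ds in manifest["dataset_id"].unique()
    }
    reg_map = mio.read_motif_regulators(d / "motif_regulators.tsv")
    p2g = mio.read_promoter_gene(d / "promoter_gene.tsv")
    return manifest, expression, sitecounts, reg_map, p2g


def fit_all(expression: dict, sitecounts: pd.DataFrame, ridge_lambda: float = 1.0) -> dict:
    """Fit one activity model per dataset."""
    return {
        ds: mara.fit_mara(expr, sitecounts[expr.index], ridge_lambda=ridge_lambda)
        for ds, expr in expression.items()
    }


def combined_posteriors(models: dict, expression: dict, sitecounts: pd.DataFrame):
    """Per-dataset target posteriors multiplied into p_comb."""
    per_ds = {}
    for ds, model in models.items():
        r = targets.score_all_targets(model, expression[ds], sitecounts[expression[ds].index])
        per_ds[ds] = pd.DataFrame(
            targets.posterior(r.to_numpy()), index=r.index, columns=r.columns
        )
    return targets.combine_across_datasets(per_ds)


def run_all(
    input_dir,
    out_dir,
    ridge_lambda: float = 1.0,
    z_threshold: float = 2.0,
    edge_threshold: float = 0.35,
    species: str | None = None,
    top_n: int = 100,
    seed: int = 0,
    negative_color: str = "green",
) -> dict:
    """Run every stage and write all artifacts; returns artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, expression, sitecounts, reg_map, p2g = read_bundle(input_dir)

    models = fit_all(expression, sitecounts, ridge_lambda=ridge_lambda)
    artifacts = {}
    for ds, model in sorted(models.items()):
        acts = out / f"activities_{ds}.tsv"
        model.activities.to_csv(acts, sep="\t", index_label="motif", float_format=FLOAT_FMT)
        model.activity_errors.to_csv(
            out / f"activity_errors_{ds}.tsv", sep="\t", index_label="motif", float_format=FLOAT_FMT
        )
        artifacts[f"activities_{ds}"] = str(acts)
        with open(out / f"fit_meta_{ds}.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "dataset_id": ds,
                    "ridge_lambda": model.ridge_lambda,
                    "residual_variance": model.residual_variance,
                    "inestimable_motifs": model.inestimable,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    zscores = combine.zscores_from_models(models, manifest)
    z_path = out / "zscores.tsv"
    zscores.sort_index().to_csv(z_path, sep="\t", float_format=FLOAT_FMT)
    artifacts["zscores"] = str(z_path)

    p_comb, n_ds = combined_posteriors(models, expression, sitecounts)
    tp = p_comb.stack().rename("p_comb").rename_axis(["motif", "promoter"]).reset_index()
    tp["gene"] = p2g.reindex(tp["promoter"]).to_numpy()
    tp["n_datasets"] = n_ds.stack().reindex(
        pd.MultiIndex.from_frame(tp[["motif", "promoter"]])
    ).to_numpy()
    tp = tp[["motif", "promoter", "gene", "p_comb", "n_datasets"]].sort_values(
        ["motif", "promoter"], kind="mergesort"
    )
    tp_path = out / "target_posteriors.tsv"
    tp.to_csv(tp_path, sep="\t", index=False, float_format=FLOAT_FMT)
    artifacts["target_posteriors"] = str(tp_path)

    motif_net = net.build_network(
        zscores,
        p_comb,
        reg_map,
        p2g,
        z_threshold=z_threshold,
        edge_threshold=edge_threshold,
        species=species,
    )
    artifacts["network_edges"] = mio.write_network(motif_net, out / "network_edges.tsv", fmt="tsv")
    artifacts["network_dot"] = mio.write_network(
        motif_net, out / "network.dot", fmt="dot", negative_color=negative_color
    )

    for motif in motif_net.graph.nodes:
        ranked = targets.top_n_targets(p_comb.loc[motif].dropna(), p2g, n=top_n)
        ranked.to_csv(
            out / f"top_targets_{motif}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )

    with open(out / "run_meta.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": seed,
                "ridge_lambda": ridge_lambda,
                "z_threshold": z_threshold,
                "edge_threshold": edge_threshold,
                "species": species,
                "top_n": top_n,
                "n_datasets": len(models),
                "n_network_nodes": motif_net.graph.number_of_nodes(),
                "n_network_edges": motif_net.graph.number_of_edges(),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    artifacts["run_meta"] = str(out / "run_meta.json")
    return artifacts
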