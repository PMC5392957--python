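"""Synthetic multi-dataset fixtures with planted regulatory ground truth.

The generator emulates a collection of epithelial-vs-mesenchymal expression
studies: several independent datasets, each with replicated samples in two
conditions (``a`` epithelial-like, ``b`` mesenchymal-like), promoter-level
log2 expression produced by the linear motif-activity model

    E[p, s] = c_s + c_p + sum_m N[m, p] * A[m, s] + noise,

a sparse non-negative site-count matrix ``N``, and a planted motif -> motif
regulatory network. A subset of motifs is "active": their activity differs
between the two conditions by a fixed effect size with a per-motif sign that
is consistent across datasets. Planted network edges A -> B place binding
sites for motif A on the promoter(s) of a regulator gene known to bind
motif B. Regulator-gene promoters carry *only* planted sites, so the planted
edge set is the unique ground truth for edge-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

# deterministic sub-stream tags, combined with the user seed
_STREAM_TRUTH = 11
_STREAM_SITES = 23
_STREAM_DATASET = 47

PLANTED_SITE_COUNT = 3  # binding sites placed on a planted-edge promoter


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic fixture collection."""

    n_datasets: int = 3
    n_motifs: int = 50
    n_promoters: int = 2000
    n_regulator_promoters: int = 50
    replicates_per_condition: int = 2
    noise_sd: float = 0.2
    activity_effect_size: float = 1.0
    fraction_active_motifs: float = 0.2
    site_count_density: float = 0.1
    edges_per_active_motif: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_datasets",
            "n_motifs",
            "n_promoters",
            "n_regulator_promoters",
            "replicates_per_condition",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.fraction_active_motifs <= 1.0:
            raise ValueError("fraction_active_motifs must lie in [0, 1]")
        if not 0.0 <= self.site_count_density <= 1.0:
            raise ValueError("site_count_density must lie in [0, 1]")
        if self.n_regulator_promoters > self.n_promoters:
            raise ValueError("n_regulator_promoters cannot exceed n_promoters")

    @property
    def motif_ids(self) -> list[str]:
        return [f"M{i:03d}" for i in range(self.n_motifs)]

    @property
    def promoter_ids(self) -> list[str]:
        return [f"P{i:05d}" for i in range(self.n_promoters)]

    @property
    def dataset_ids(self) -> list[str]:
        return [f"D{i}" for i in range(self.n_datasets)]


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic fixture bundle."""

    active_motifs: list[str]
    motif_signs: dict[str, int]  # +1: activity rises upon EMT, -1: falls
    true_network: set  # {(motif_a, regulator_gene_of_b)}
    true_promoter_targets: set = field(default_factory=set)  # {(motif, promoter)}
    true_activities: dict = field(default_factory=dict)  # dataset_id -> DataFrame


def regulator_map(config: SyntheticConfig) -> pd.DataFrame:
    """Map each motif to the regulator gene that binds it (one gene per motif)."""
    return pd.DataFrame(
        {
            "motif": config.motif_ids,
            "regulator_gene": [f"REG{i:03d}" for i in range(config.n_motifs)],
        }
    )


def promoter_gene_map(config: SyntheticConfig) -> pd.Series:
    """Assign promoters to genes.

    The first ``n_regulator_promoters`` promoters belong to regulator genes
    (round-robin over motifs, so genes may own several promoters); the rest
    belong to ordinary genes with two promoters each, exercising the
    best-promoter-per-gene rule downstream.
    """
    genes = []
    for i in range(config.n_promoters):
        if i < config.n_regulator_promoters:
            genes.append(f"REG{i % config.n_motifs:03d}")
        else:
            genes.append(f"G{(i - config.n_regulator_promoters) // 2:05d}")
    return pd.Series(genes, index=pd.Index(config.promoter_ids), name="gene")


def make_manifest(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for ds in config.dataset_ids:
        for cond in ("a", "b"):
            for r in range(1, config.replicates_per_condition + 1):
                rows.append((ds, f"{ds}_{cond}{r}", cond, str(r)))
    return pd.DataFrame(rows, columns=mio.MANIFEST_COLUMNS)


def plant_truth(config: SyntheticConfig) -> PlantedTruth:
    """Choose active motifs, their EMT direction, and the planted network."""
    rng = np.random.default_rng([_STREAM_TRUTH, config.seed])
    motifs = config.motif_ids
    n_active = int(round(config.fraction_active_motifs * config.n_motifs))
    active = sorted(str(m) for m in rng.choice(motifs, size=n_active, replace=False))
    signs = {m: int(s) for m, s in zip(active, rng.choice([-1, 1], size=n_active))}

    reg = regulator_map(config)
    p2g = promoter_gene_map(config)
    genes_with_promoters = set(p2g.values)
    reg_of = dict(zip(reg["motif"], reg["regulator_gene"]))
    # only edges whose target regulator gene owns a promoter are observable
    targetable = [m for m in active if reg_of[m] in genes_with_promoters]

    network = set()
    for a in active:
        if not targetable:
            break
        k = min(config.edges_per_active_motif, len(targetable))
        for b in rng.choice(targetable, size=k, replace=False):
            network.add((str(a), str(reg_of[b])))

    truth = PlantedTruth(active_motifs=list(active), motif_signs=signs, true_network=network)
    truth.true_activities = {
        ds: _planted_activities(config, truth, ds) for ds in config.dataset_ids
    }
    return truth


def _planted_activities(config: SyntheticConfig, truth: PlantedTruth, dataset_id: str) -> pd.DataFrame:
    manifest = make_manifest(config)
    sub = manifest[manifest["dataset_id"] == dataset_id]
    half = config.activity_effect_size / 2.0
    a = pd.DataFrame(
        0.0, index=pd.Index(config.motif_ids), columns=pd.Index(sub["sample_id"].to_numpy())
    )
    for m in truth.active_motifs:
        sign = truth.motif_signs[m]
        cond = sub.set_index("sample_id")["condition"]
        a.loc[m] = np.where(cond.values == "b", sign * half, -sign * half)
    return a


def generate_sitecounts(config: SyntheticConfig, truth: PlantedTruth | None = None) -> pd.DataFrame:
    """Draw the motifs x promoters site-count matrix.

    Background sites: Bernoulli(density) mask, count 1 + Poisson(1) where the
    mask fires, so the realized nonzero fraction matches the density.
    Regulator-gene promoters are kept free of background sites and receive
    only the planted sites of their upstream motifs.
    """
    if truth is None:
        truth = plant_truth(config)
    rng = np.random.default_rng([_STREAM_SITES, config.seed])
    shape = (config.n_motifs, config.n_promoters)
    mask = rng.random(shape) < config.site_count_density
    counts = np.where(mask, 1 + rng.poisson(1.0, size=shape), 0).astype(float)
    counts[:, : config.n_regulator_promoters] = 0.0

    df = pd.DataFrame(counts, index=pd.Index(config.motif_ids), columns=pd.Index(config.promoter_ids))
    p2g = promoter_gene_map(config)
    promoters_of = p2g.groupby(p2g.values).groups
    targets = set()
    for motif_a, gene in truth.true_network:
        for promoter in promoters_of.get(gene, []):
            df.loc[motif_a, promoter] = float(PLANTED_SITE_COUNT)
            targets.add((motif_a, promoter))
    # every nonzero site of an active motif drives condition-dependent expression
    for m in truth.active_motifs:
        for p in df.columns[df.loc[m].to_numpy() > 0]:
            targets.add((m, p))
    truth.true_promoter_targets = targets
    return df


def generate_dataset(
    config: SyntheticConfig,
    sitecounts: pd.DataFrame,
    truth: PlantedTruth,
    dataset_index: int,
) -> pd.DataFrame:
    """Generate one dataset's promoters x samples log2 expression table."""
    ds = config.dataset_ids[dataset_index]
    activities = truth.true_activities[ds]
    rng = np.random.default_rng([_STREAM_DATASET, dataset_index, config.seed])
    n_samples = activities.shape[1]
    c_s = rng.normal(0.0, 0.5, size=n_samples)  # sample offsets, var 0.25
    c_p = rng.normal(5.0, 2.0, size=config.n_promoters)  # promoter baselines, var 4
    signal = sitecounts.to_numpy().T @ activities.to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_promoters, n_samples))
    values = c_s[None, :] + c_p[:, None] + signal + noise
    return pd.DataFrame(values, index=sitecounts.columns.copy(), columns=activities.columns.copy())


@dataclass
class FixtureBundle:
    config: SyntheticConfig
    truth: PlantedTruth
    sitecounts: pd.DataFrame
    manifest: pd.DataFrame
    expression: dict  # dataset_id -> DataFrame
    motif_regulators: pd.DataFrame
    promoter_gene: pd.Series


def generate_bundle(config: SyntheticConfig) -> FixtureBundle:
    """Generate the full in-memory fixture collection for one seed."""
    truth = plant_truth(config)
    sitecounts = generate_sitecounts(config, truth)
    expression = {
        ds: generate_dataset(config, sitecounts, truth, i)
        for i, ds in enumerate(config.dataset_ids)
    }
    return FixtureBundle(
        config=config,
        truth=truth,
        sitecounts=sitecounts,
        manifest=make_manifest(config),
        expression=expression,
        motif_regulators=regulator_map(config),
        promoter_gene=promoter_gene_map(config),
    )


def write_fixture_bundle(config: SyntheticConfig, out_dir) -> Path:
    """Write a complete fixture bundle to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    for ds, expr in bundle.expression.items():
        mio.write_expression(expr, out / f"expression_{ds}.tsv")
    mio.write_sitecounts(bundle.sitecounts, out / "sitecounts.tsv")
    manifest_path = out / "manifest.tsv"
    mio.write_manifest(bundle.manifest, manifest_path)
    bundle.motif_regulators.to_csv(out / "motif_regulators.tsv", sep="\t", index=False)
    mio.write_map(bundle.promoter_gene, out / "promoter_gene.tsv")
    truth = {
        "config": asdict(config),
        "active_motifs": bundle.truth.active_motifs,
        "motif_signs": bundle.truth.motif_signs,
        "true_network": sorted(map(list, bundle.truth.true_network)),
        "true_promoter_targets": sorted(map(list, bundle.truth.true_promoter_targets)),
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return manifest_path


def read_truth(path) -> PlantedTruth:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return PlantedTruth(
        active_motifs=raw["active_motifs"],
        motif_signs={k: int(v) for k, v in raw["motif_signs"].items()},
        true_network={tuple(e) for e in raw["true_network"]},
        true_promoter_targets={tuple(e) for e in raw["true_promoter_targets"]},
    )
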