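"""Readers and writers for the tabular interchange formats.

Every matrix travels as TSV with a header row and row names in the first
column (UTF-8, ``.`` decimal). Expression tables are promoters x samples on
log2 scale; site-count matrices are motifs x promoters and may also be given
in sparse triplet form with columns ``motif``, ``promoter``, ``count``.
Networks are exported as edge-list TSV or DOT.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["dataset_id", "sample_id", "condition", "replicate"]
CONDITIONS = ("a", "b")


class FormatError(ValueError):
    """A file violated the expected tabular contract."""


def _check_unique(values, what: str, path) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate {what}: {', '.join(map(str, dup[:5]))}")


def read_expression(path) -> pd.DataFrame:
    """Read a promoters x samples log2 expression table.

    Raises :class:`FormatError` on duplicate promoter or sample IDs and on
    non-finite values, naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    _check_unique(df.index, "promoter IDs", path)
    _check_unique(df.columns, "sample IDs", path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric expression values")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"{path}: non-finite expression at promoter "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="promoter", float_format="%.10g")


def read_sitecounts(path) -> pd.DataFrame:
    """Read a motifs x promoters site-count matrix (dense TSV or triplets).

    The triplet dialect is detected by its header ``motif/promoter/count``;
    absent (motif, promoter) pairs are zero. Counts must be non-negative.
    """
    head = pd.read_csv(path, sep="\t", nrows=0)
    if list(head.columns[:3]) == ["motif", "promoter", "count"] or (
        list(head.columns) and head.columns[0] == "motif" and "count" in head.columns
    ):
        trip = pd.read_csv(path, sep="\t", dtype={"motif": str, "promoter": str})
        dense = trip.pivot_table(
            index="motif", columns="promoter", values="count", fill_value=0.0, aggfunc="sum"
        )
        dense.index.name = None
        dense.columns.name = None
        df = dense
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(df.index, "motif IDs", path)
        _check_unique(df.columns, "promoter IDs", path)
    values = df.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any():
        bad = np.argwhere(~(np.isfinite(values) & (values >= 0)))[0]
        raise FormatError(
            f"{path}: negative or non-finite site count at motif "
            f"{df.index[bad[0]]!r}, promoter {df.columns[bad[1]]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df.astype(float)


def write_sitecounts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="motif", float_format="%.10g")


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest (dataset_id, sample_id, condition, replicate).

    Conditions are ``a`` (epithelial-like) and ``b`` (mesenchymal-like);
    each dataset must carry at least one sample of each.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    df = df[MANIFEST_COLUMNS]
    bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
    if bad_cond:
        raise FormatError(f"{path}: unknown condition labels {bad_cond}; expected a/b")
    for ds, grp in df.groupby("dataset_id"):
        _check_unique(grp["sample_id"], f"sample IDs in dataset {ds}", path)
        for cond in CONDITIONS:
            if not (grp["condition"] == cond).any():
                raise FormatError(f"{path}: dataset {ds} has no condition-{cond} sample")
    return df.reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_motif_regulators(path) -> pd.DataFrame:
    """Read the many-to-many (motif, regulator_gene) binding map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["motif", "regulator_gene"]:
        raise FormatError(f"{path}: expected columns motif, regulator_gene")
    if df.empty:
        raise FormatError(f"{path}: regulator map is empty")
    return df[["motif", "regulator_gene"]].drop_duplicates().reset_index(drop=True)


def read_promoter_gene(path) -> pd.Series:
    """Read the promoter -> gene map; each promoter maps to exactly one gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["promoter", "gene"]:
        raise FormatError(f"{path}: expected columns promoter, gene")
    _check_unique(df["promoter"], "promoter IDs", path)
    return pd.Series(df["gene"].values, index=df["promoter"].values, name="gene")


def write_map(pairs: pd.DataFrame | pd.Series, path, columns=None) -> None:
    if isinstance(pairs, pd.Series):
        pairs = pairs.rename_axis("promoter").reset_index().rename(columns={pairs.name or 0: "gene"})
    if columns is not None:
        pairs = pairs[list(columns)]
    pairs.to_csv(path, sep="\t", index=False)


def write_network(network, path, fmt: str = "tsv", negative_color: str = "green") -> str:
    """Write a motif network as edge-list TSV or DOT.

    The edge list has columns (motif_a, motif_b, regulator_gene,
    probability_product). DOT nodes carry the z score and a color encoding
    its sign: positive activity change red, negative ``negative_color``.
    """
    path = str(path)
    edges = network.edge_table()
    if fmt == "tsv":
        edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "dot":
        lines = ["digraph motifs {"]
        g = network.graph
        for node in sorted(g.nodes):
            z = g.nodes[node].get("z", 0.0)
            color = "red" if z > 0 else negative_color
            lines.append(f'  "{node}" [z="{z:.6g}", color="{color}"];')
        for _, row in edges.iterrows():
            lines.append(
                f'  "{row.motif_a}" -> "{row.motif_b}" '
                f'[regulator_gene="{row.regulator_gene}", weight="{row.probability_product:.6g}"];'
            )
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'tsv' or 'dot'")
    return path
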