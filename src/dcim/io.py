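"""File formats: TSV matrices, Newick trees, YAML configs, JSON manifests.

Everything is plain text so results are diffable: expression and PPP
matrices as tab-separated tables (genes in rows, identifiers in the first
column, samples in the header), dendrograms as Newick with merge heights as
node heights, and a JSON manifest recording the configuration, seed,
package versions and SHA-256 checksums of every written file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from skbio.tree import TreeNode

from .dcs import DCSResult
from .model import ExpressionMatrix
from .summaries import MergeTree, PPPMatrix

__all__ = [
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_ppp_tsv",
    "tree_to_newick",
    "write_newick",
    "write_contexts_tsv",
    "write_dcs_tsv",
    "write_outputs",
]


@dataclass
class RunConfig:
    """Flat, YAML-serialisable configuration for a pipeline run."""

    n_burnin: int = 500
    n_keep: int = 2000
    thin: int = 1
    seed: int = 0
    resample_concentrations: bool = False
    alpha: float = 1.0
    beta: float = 1.0
    phi: float = 1.0
    lam: float = 1.0
    a: float = 2.0
    tau: Optional[float] = None  # None: overall data variance
    k_contexts: int = 2
    copa_percentile: float = 95.0
    top_k_genes: Optional[int] = None
    center_mode: str = "per_gene"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV: first column gene ids, header sample ids.

    Rejects duplicate identifiers, missing values and non-numeric cells,
    naming the offending gene/sample in the error message.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    values = np.empty(df.shape)
    for jx, col in enumerate(df.columns):
        try:
            # numpy's parser round-trips float64 exactly
            parsed = df[col].to_numpy(dtype="U32").astype(np.float64)
        except ValueError:
            parsed = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = ~np.isfinite(parsed)
        if bad.any():
            gene = df.index[bad][0]
            cell = df.loc[gene, col]
            raise ValueError(
                f"{path}: non-numeric or missing value {cell!r} at gene {gene!r}, "
                f"sample {col!r}; impute or drop during preprocessing"
            )
        values[:, jx] = parsed
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def write_expression_tsv(X: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_ppp_tsv(ppp: PPPMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ppp.values, index=ppp.item_ids, columns=ppp.item_ids)
    df.to_csv(path, sep="\t", index_label="id")


def tree_to_newick(tree: MergeTree) -> str:
    """Newick string with merge heights encoded as branch lengths."""
    node = TreeNode.from_linkage_matrix(tree.linkage_matrix, tree.leaf_ids)
    return str(node).strip()


def write_newick(tree: MergeTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def write_contexts_tsv(sample_ids: list[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "context": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_contexts_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["sample_id"].astype(str).tolist(), df["context"].to_numpy()


def write_dcs_tsv(result: DCSResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(
    outdir: str | Path,
    files: dict[str, object],
    config: RunConfig,
    extra: dict | None = None,
) -> dict:
    """Write a set of artifacts plus a manifest with checksums.

    ``files`` maps file names to artifacts (ExpressionMatrix, PPPMatrix,
    MergeTree, DCSResult, DataFrames, or (sample_ids, labels) context
    tuples); the writer is chosen by type.  Returns the manifest dict,
    also written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in files.items():
        path = outdir / name
        if isinstance(obj, ExpressionMatrix):
            write_expression_tsv(obj, path)
        elif isinstance(obj, PPPMatrix):
            write_ppp_tsv(obj, path)
        elif isinstance(obj, MergeTree):
            write_newick(obj, path)
        elif isinstance(obj, DCSResult):
            write_dcs_tsv(obj, path)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False, float_format="%.6g")
        elif isinstance(obj, tuple) and len(obj) == 2:
            write_contexts_tsv(obj[0], obj[1], path)
        else:
            raise TypeError(f"no writer for artifact {name!r} of type {type(obj)}")
        written.append(path)
    import scipy

    from . import __version__

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "dcim": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "files": {p.name: _sha256(p) for p in written},
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
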