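"""Core data containers and plain-text I/O.

Three formats are supported, all tab-separated UTF-8 text:

* expression matrices — first row sample IDs, first column gene IDs,
  numeric body (log-ratio scale assumed but not enforced);
* gene sets — standard GMT (``pathway_id TAB description TAB gene ...``);
* gene-pair association scores — three columns ``geneA geneB score``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PathwayAnnotation",
    "AssociationScoreTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_scores",
    "write_scores",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with row/column identifiers.

    ``values[n, m]`` is the expression of gene ``gene_ids[n]`` in sample
    ``sample_ids[m]``. Identifiers are unique; the body holds no missing
    values (rows containing any are dropped at load time).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.n_genes < 1:
            raise ValueError("matrix must contain at least one gene")
        if self.n_samples < 2:
            raise ValueError("matrix must contain at least two samples")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, genes) -> np.ndarray:
        """Rows for ``genes`` (those present), preserving sample order.

        Genes are returned in matrix row order so the extraction is
        deterministic regardless of the order of ``genes``.
        """
        rows = sorted(self._gene_index[g] for g in genes if g in self._gene_index)
        return self.values[rows, :]

    def genes_present(self, genes) -> list[str]:
        """Subset of ``genes`` measured in the matrix, in matrix row order."""
        rows = sorted(self._gene_index[g] for g in genes if g in self._gene_index)
        return [self.gene_ids[i] for i in rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PathwayAnnotation:
    """Mapping pathway id -> set of gene ids (gene sets may overlap)."""

    pathways: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has no genes")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pid: str) -> set[str]:
        return self.pathways[pid]


class AssociationScoreTable:
    """Symmetric lookup of nonnegative gene-pair association scores.

    Absent pairs score 0. The table is flavour-agnostic: it may hold
    Bayesian-integrated or single-evidence scores; which one was loaded
    is the caller's concern.
    """

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), s in entries.items():
                self.add(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, score: float, keep_max: bool = True) -> None:
        if score < 0:
            raise ValueError(f"negative association score for ({a}, {b}): {score}")
        if a == b:
            raise ValueError(f"self-pair ({a}, {a}) is not allowed")
        k = self._key(a, b)
        if k in self._entries and keep_max:
            self._entries[k] = max(self._entries[k], score)
        else:
            self._entries[k] = score

    def lookup(self, a: str, b: str) -> float:
        return self._entries.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._entries:
            out.add(a)
            out.add(b)
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first row samples, first column genes).

    Rows with any missing value are dropped with a warning; duplicate gene
    rows keep the first occurrence.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression matrix needs at least 2 samples")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("%s: %d duplicate gene rows, keeping first: %s",
                       path, len(dups), dups[:5])
        df = df[~df.index.duplicated(keep="first")]
    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.warning("%s: dropping %d gene rows with missing values", path, n_na)
        df = df.dropna(axis=0)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no complete gene rows")
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            df.to_numpy())


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> PathwayAnnotation:
    """Read a GMT gene-set file. Duplicate genes within a line are dropped."""
    pathways: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            pid, desc, *genes = fields
            pathways[pid] = {g for g in genes if g}
            names[pid] = desc
    if not pathways:
        raise ValueError(f"{path}: empty GMT file")
    return PathwayAnnotation(pathways, names)


def write_gmt(annotation: PathwayAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, genes in annotation.pathways.items():
            desc = annotation.names.get(pid, pid)
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def read_scores(path) -> AssociationScoreTable:
    """Read a 3-column gene-pair score table (geneA, geneB, score >= 0).

    If a pair appears more than once the maximum score is kept (logged).
    """
    table = AssociationScoreTable()
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            a, b, raw = fields
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed score {raw!r}") from exc
            if score < 0:
                raise ValueError(f"{path}:{ln}: negative score {score}")
            key = AssociationScoreTable._key(a, b)
            if key in seen:
                n_dup += 1
            seen.add(key)
            table.add(a, b, score)
    if n_dup:
        logger.warning("%s: %d duplicate gene pairs, kept maximum score", path, n_dup)
    return table


def write_scores(table: AssociationScoreTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), s in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{s:.12g}\n")
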