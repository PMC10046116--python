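"""Core domain containers and readers/writers for DREAM5-dialect files.

The on-disk dialect follows the DREAM5 network-inference benchmark
distribution: the expression matrix is a UTF-8 tab-separated file with one
header row of gene identifiers and one numeric row per experimental
condition; the regulator list is one identifier per line; the gold standard
is a three-column TSV ``tf<TAB>target<TAB>{0,1}``.  All in-memory matrices
are oriented conditions (rows) x genes (columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Real-valued expression of N genes across D conditions.

    ``values`` has shape (D, N); rows are conditions, columns are genes.
    All values must be finite and both identifier lists unique.
    """

    values: np.ndarray
    condition_ids: list[str]
    gene_ids: list[str]
    orientation_detected: str = "conditions_by_genes"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition_ids = [str(c) for c in self.condition_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.condition_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.condition_ids)} conditions x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition identifiers")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self._gene_index[gene_id]]

    def columns(self, gene_ids: Iterable[str]) -> np.ndarray:
        idx = [self._gene_index[g] for g in gene_ids]
        return self.values[:, idx]

    def subset_conditions(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            self.values[rows],
            [self.condition_ids[i] for i in rows],
            list(self.gene_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.condition_ids, columns=self.gene_ids)


@dataclass
class RegulatorSet:
    """Ordered set of gene identifiers allowed to act as predictive features."""

    regulator_ids: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for r in self.regulator_ids:
            seen.setdefault(str(r), None)
        self.regulator_ids = list(seen)
        if not self.regulator_ids:
            raise ValueError("regulator set must be non-empty")

    def __len__(self) -> int:
        return len(self.regulator_ids)

    def __iter__(self):
        return iter(self.regulator_ids)

    def __contains__(self, item: str) -> bool:
        return item in set(self.regulator_ids)

    def intersect(self, expression: ExpressionMatrix) -> "RegulatorSet":
        """Drop regulators absent from the expression matrix (with a warning)."""
        present = [r for r in self.regulator_ids if r in expression._gene_index]
        missing = [r for r in self.regulator_ids if r not in expression._gene_index]
        if missing:
            warnings.warn(
                f"{len(missing)} regulator(s) absent from the expression matrix "
                f"were dropped: {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        return RegulatorSet(present)


@dataclass
class GoldStandard:
    """Experimentally tested regulator->target links.

    ``true_links`` are confirmed directed interactions; ``tested_tfs`` /
    ``tested_genes`` delimit the experimentally tested universe.  When
    ``dense`` is true (the DREAM5 convention) every non-self pair in
    tested_tfs x tested_genes not listed as true is a tested negative;
    otherwise only explicitly listed 0-rows are negatives.
    """

    true_links: set[tuple[str, str]]
    tested_tfs: set[str]
    tested_genes: set[str]
    dense: bool = True
    negative_links: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.tested_tfs <= self.tested_genes:
            self.tested_genes = self.tested_genes | self.tested_tfs
        for tf, tg in self.true_links:
            if tf == tg:
                raise ValueError("gold standard contains a self-loop")
            if tf not in self.tested_tfs or tg not in self.tested_genes:
                raise ValueError(f"true link ({tf},{tg}) outside the tested universe")

    @property
    def universe_size(self) -> int:
        """|Egoldfull|: tested pairs excluding self-loops (dense convention)."""
        n_self = len(self.tested_tfs & self.tested_genes)
        return len(self.tested_tfs) * len(self.tested_genes) - n_self

    def universe(self) -> Iterable[tuple[str, str]]:
        for tf in sorted(self.tested_tfs):
            for tg in sorted(self.tested_genes):
                if tf != tg:
                    yield (tf, tg)


@dataclass
class SampleClasses:
    """Mapping condition id -> class label (tissue, cell type, or condition)."""

    mapping: dict[str, str]

    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def conditions_of(self, label: str) -> list[str]:
        return [c for c, l in self.mapping.items() if l == label]

    def validate_against(self, expression: ExpressionMatrix) -> None:
        unknown = set(self.mapping) - set(expression.condition_ids)
        if unknown:
            raise ValueError(f"class labels refer to unknown conditions: {sorted(unknown)[:5]}")
        if len(self.labels()) < 2:
            raise ValueError("at least two classes are required for enrichment")


@dataclass
class AnnotationTable:
    """Gene -> ontology-term annotations plus a term parent graph (a DAG)."""

    gene_to_terms: dict[str, set[str]]
    term_parents: dict[str, set[str]]

    def __post_init__(self) -> None:
        # reject cycles in the parent graph
        import networkx as nx

        g = nx.DiGraph()
        for term, parents in self.term_parents.items():
            for p in parents:
                g.add_edge(term, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term parent graph contains a cycle")

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        out |= set(self.term_parents)
        for ps in self.term_parents.values():
            out |= ps
        return out

    def descendants(self, root: str) -> set[str]:
        """Transitive closure of child terms under ``root`` (root included)."""
        children: dict[str, set[str]] = {}
        for term, parents in self.term_parents.items():
            for p in parents:
                children.setdefault(p, set()).add(term)
        out = {root}
        stack = [root]
        while stack:
            t = stack.pop()
            for c in children.get(t, ()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def genes_for(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_numeric_body(rows: list[list[str]], col_labels: list[str]) -> np.ndarray:
    values = np.empty((len(rows), len(col_labels)), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell at (row {i + 2}, column {col_labels[j]})"
                ) from None
    return values


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_expression(
    path: str | Path,
    orientation_hint: str = "auto",
    regulators: "RegulatorSet | Iterable[str] | None" = None,
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    ``orientation_hint`` is one of ``conditions_by_genes`` (DREAM5 layout:
    gene ids in the header, one row per condition), ``genes_by_conditions``
    (transposed exports), or ``auto``.  Auto mode transposes when the file
    has more rows than columns — genes outnumber conditions in virtually
    every real dataset — refined, when a regulator list (or any known gene
    vocabulary) is supplied, by checking which axis labels overlap it.  The
    detected choice is recorded in ``orientation_detected``; detection never
    alters numeric values, only which axis is labelled as genes.
    """
    if orientation_hint not in {"conditions_by_genes", "genes_by_conditions", "auto"}:
        raise ValueError(f"unknown orientation hint: {orientation_hint}")
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError("expression file needs a header row and at least one data row")
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ParseError("ragged rows in expression file")
    # Detect a leading row-label column: either the header is one field
    # short of the body, or the first body column is non-numeric (the
    # header then carries a corner label that is dropped).
    if width == len(header) + 1:
        row_labels = [r[0] for r in rows]
        body_rows = [r[1:] for r in rows]
        col_labels = list(header)
    elif width == len(header) and rows and not _is_number(rows[0][0]):
        row_labels = [r[0] for r in rows]
        body_rows = [r[1:] for r in rows]
        col_labels = list(header[1:])
    elif width == len(header):
        row_labels = [f"R{i + 1}" for i in range(len(rows))]
        body_rows = rows
        col_labels = list(header)
    else:
        raise ParseError(
            f"header has {len(header)} fields but data rows have {width}"
        )
    values = _parse_numeric_body(body_rows, col_labels)

    orientation = orientation_hint
    if orientation == "auto":
        transpose = values.shape[0] > values.shape[1]
        if regulators is not None:
            vocab = (
                set(regulators.regulator_ids)
                if isinstance(regulators, RegulatorSet)
                else set(map(str, regulators))
            )
            in_cols = len(vocab & set(col_labels))
            in_rows = len(vocab & set(row_labels))
            if in_cols != in_rows:
                transpose = in_rows > in_cols
        orientation = "genes_by_conditions" if transpose else "conditions_by_genes"

    if orientation == "genes_by_conditions":
        return ExpressionMatrix(
            values.T,
            condition_ids=col_labels,
            gene_ids=row_labels,
            orientation_detected="genes_by_conditions",
        )
    return ExpressionMatrix(
        values,
        condition_ids=row_labels,
        gene_ids=col_labels,
        orientation_detected="conditions_by_genes",
    )


def read_regulators(path: str | Path) -> RegulatorSet:
    """Read a regulator list, one gene identifier per line."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return RegulatorSet(ids)


def read_gold_standard(path: str | Path, dense: bool = True) -> GoldStandard:
    """Read a 3-column TSV gold standard (tf, target, label in {0,1}).

    Rows with label 1 are true links; every row contributes its TF and
    target to the tested universe.  Self-loop rows are dropped with a
    warning.  ``dense`` declares whether unlisted pairs inside the tested
    universe count as tested negatives (the DREAM5 convention).
    """
    true_links: set[tuple[str, str]] = set()
    negative_links: set[tuple[str, str]] = set()
    tfs: set[str] = set()
    genes: set[str] = set()
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ParseError(f"gold standard line {ln}: expected 3 columns, got {len(parts)}")
        tf, tg, label = parts[0].strip(), parts[1].strip(), parts[2].strip()
        if label not in {"0", "1"}:
            raise ParseError(f"gold standard line {ln}: label {label!r} outside {{0,1}}")
        if tf == tg:
            warnings.warn(f"gold standard line {ln}: self-loop ({tf},{tg}) dropped")
            continue
        tfs.add(tf)
        genes.add(tg)
        if label == "1":
            true_links.add((tf, tg))
        else:
            negative_links.add((tf, tg))
    genes |= tfs
    return GoldStandard(
        true_links=true_links,
        tested_tfs=tfs,
        tested_genes=genes,
        dense=dense,
        negative_links=negative_links,
    )


def read_sample_classes(path: str | Path) -> SampleClasses:
    """Read a 2-column TSV (condition id, class label)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ParseError("sample class file must have exactly 2 columns")
    return SampleClasses(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_annotations(
    annotation_path: str | Path, parent_path: str | Path | None = None
) -> AnnotationTable:
    """Read annotations as a 2-column TSV (gene, term) plus an optional
    2-column parent table (term, parent)."""
    ann = pd.read_csv(annotation_path, sep="\t", header=None, dtype=str)
    if ann.shape[1] != 2:
        raise ParseError("annotation file must have exactly 2 columns (gene, term)")
    gene_to_terms: dict[str, set[str]] = {}
    for g, t in zip(ann.iloc[:, 0], ann.iloc[:, 1]):
        gene_to_terms.setdefault(str(g), set()).add(str(t))
    parents: dict[str, set[str]] = {}
    if parent_path is not None:
        par = pd.read_csv(parent_path, sep="\t", header=None, dtype=str)
        if par.shape[1] != 2:
            raise ParseError("parent table must have exactly 2 columns (term, parent)")
        for t, p in zip(par.iloc[:, 0], par.iloc[:, 1]):
            parents.setdefault(str(t), set()).add(str(p))
    return AnnotationTable(gene_to_terms, parents)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

EDGE_TABLE_COLUMNS = ("regulator", "target", "coefficient", "target_mean_validation_R2")


def write_edge_table(model, path: str | Path) -> None:
    """Write a fitted model's nonzero coefficients as a TSV edge table.

    Columns: regulator, target, coefficient, target mean validation R2;
    sorted by |coefficient| descending.  Round-trips losslessly through
    :func:`read_edge_table`.
    """
    rows = []
    for reg, tg, coef in model.edges():
        r2 = model.per_gene[tg].mean_r2
        rows.append((reg, tg, coef, r2))
    rows.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_TABLE_COLUMNS) + "\n")
        for reg, tg, coef, r2 in rows:
            fh.write(f"{reg}\t{tg}\t{coef!r}\t{r2!r}\n")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    if list(df.columns) != list(EDGE_TABLE_COLUMNS):
        raise ParseError(f"unexpected edge table header: {list(df.columns)}")
    return df


def write_expression(
    expression: ExpressionMatrix, path: str | Path, condition_labels: bool = True
) -> None:
    """Write the DREAM5 layout: gene ids as header, one row per condition.

    With ``condition_labels`` (default) a leading row-label column keeps the
    condition ids, which downstream sample-class files refer to; pass False
    for the strict label-free benchmark layout.
    """
    expression.to_frame().to_csv(path, sep="\t", index=condition_labels)


def write_regulators(regulators: RegulatorSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(regulators.regulator_ids) + "\n")


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    """Write true links as 1-rows and explicitly listed negatives as 0-rows."""
    lines = [f"{tf}\t{tg}\t1" for tf, tg in sorted(gold.true_links)]
    lines += [f"{tf}\t{tg}\t0" for tf, tg in sorted(gold.negative_links)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_sample_classes(classes: SampleClasses, path: str | Path) -> None:
    lines = [f"{c}\t{l}" for c, l in classes.mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotations(
    table: AnnotationTable, annotation_path: str | Path, parent_path: str | Path
) -> None:
    lines = [
        f"{g}\t{t}" for g in sorted(table.gene_to_terms) for t in sorted(table.gene_to_terms[g])
    ]
    Path(annotation_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    plines = [
        f"{t}\t{p}" for t in sorted(table.term_parents) for p in sorted(table.term_parents[t])
    ]
    Path(parent_path).write_text("\n".join(plines) + ("\n" if plines else ""))


def write_communities(partition: Mapping[str, int], path: str | Path) -> None:
    df = pd.DataFrame(sorted(partition.items()), columns=["gene", "community_id"])
    df.to_csv(path, sep="\t", index=False)


def read_communities(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"gene": str, "community_id": int})
    return dict(zip(df["gene"], df["community_id"]))
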