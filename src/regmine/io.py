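"""Readers and writers for the plain-text formats the pipeline consumes.

Everything is tab-separated text: expression matrices (genes x measurements,
signed log-ratio values), two-column TF/TG pair lists, gene->GO-term
annotation tables with a child/parent term hierarchy, and the prediction
table written at the end of a run.
"""
from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: cell contents treated as missing in expression matrices
MISSING_TOKENS = frozenset({"", "NA"})

MISSING_POLICIES = ("drop_gene", "impute_row_mean")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A genes x measurements matrix of signed expression values.

    When ``is_timeseries`` is true the measurement columns are consecutive,
    evenly indexed time points t = 0..T-1 and profiles may be treated as a
    sampled function of time.
    """

    gene_ids: list[str]
    measurement_labels: list[str]
    values: np.ndarray
    is_timeseries: bool = True
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.measurement_labels),
        ):
            raise DataError(
                "value matrix shape does not match gene/measurement labels"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_measurements(self) -> int:
        return len(self.measurement_labels)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def profile(self, gene_id: str) -> np.ndarray:
        """Expression profile of one gene as a 1-D array."""
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.measurement_labels
        )


@dataclass(frozen=True)
class GenePair:
    """A directed candidate regulatory pair (TF -> target gene)."""

    tf_id: str
    tg_id: str
    label: Optional[str] = None  # "positive", "negative" or None

    def __post_init__(self) -> None:
        if self.tf_id == self.tg_id:
            raise DataError(f"self-pair not allowed: {self.tf_id!r}")
        if self.label not in (None, "positive", "negative"):
            raise DataError(f"unknown pair label {self.label!r}")


@dataclass
class GOAnnotationSet:
    """Gene -> GO-term annotations plus the term DAG and term depths.

    ``term_grade`` maps every term to its grade: 1 + the length of the
    longest parent path to a root (roots have grade 1), the conventional
    "most specific depth" of a term.
    """

    term_parents: dict[str, frozenset[str]]
    term_grade: dict[str, int]
    gene_terms: dict[str, frozenset[str]]
    _ancestor_cache: dict[str, frozenset[str]] = field(
        init=False, repr=False, default_factory=dict
    )

    @classmethod
    def build(
        cls,
        term_parents: Mapping[str, Iterable[str]],
        gene_terms: Mapping[str, Iterable[str]],
    ) -> "GOAnnotationSet":
        """Validate the DAG and compute grades by longest path to a root."""
        graph = nx.DiGraph()  # parent -> child
        for child, parents in term_parents.items():
            graph.add_node(child)
            for parent in parents:
                graph.add_edge(parent, child)
        for terms in gene_terms.values():
            graph.add_nodes_from(terms)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise DataError(f"GO hierarchy contains a cycle involving {cycle[0][0]!r}")
        grade: dict[str, int] = {}
        for term in nx.topological_sort(graph):
            parents = list(graph.predecessors(term))
            grade[term] = 1 + max((grade[p] for p in parents), default=0)
        parents_clean = {
            t: frozenset(graph.predecessors(t)) for t in graph.nodes
        }
        return cls(
            term_parents=parents_clean,
            term_grade=grade,
            gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        )

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (transitive parents)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = list(self.term_parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.term_parents.get(t, ()))
        result = frozenset(seen)
        self._ancestor_cache[term] = result
        return result

    def annotation_closure(self, gene_id: str) -> frozenset[str]:
        """Terms annotated to a gene, directly or through an ancestor."""
        direct = self.gene_terms.get(gene_id, frozenset())
        closure: set[str] = set(direct)
        for term in direct:
            closure |= self.ancestors(term)
        return frozenset(closure)


def read_expression_matrix(
    path: str | os.PathLike,
    missing_policy: str = "drop_gene",
    is_timeseries: bool = True,
) -> ExpressionMatrix:
    """Read a genes x measurements TSV (first row labels, first column ids).

    Cells equal to "NA" or empty are missing. Genes with more than 50% of
    cells missing are dropped under either policy; remaining gaps are then
    handled by ``missing_policy``: ``drop_gene`` removes the gene,
    ``impute_row_mean`` fills the cell with the mean of the row's other
    values.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw = raw.apply(lambda col: col.str.strip())
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise DataError(f"duplicate gene id {dup!r}")
    missing = raw.isin(MISSING_TOKENS)
    numeric = raw.mask(missing).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise DataError(
            f"non-numeric cell at gene {gene!r}, measurement {col!r}"
        )
    keep = missing.mean(axis=1) <= 0.5
    numeric, missing = numeric[keep], missing[keep]
    if missing_policy == "drop_gene":
        numeric = numeric[~missing.any(axis=1)]
    else:
        row_means = numeric.mean(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    if numeric.empty:
        raise DataError("no genes left after applying missing-value policy")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        measurement_labels=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        is_timeseries=is_timeseries,
    )


def write_expression_matrix(path: str | os.PathLike, matrix: ExpressionMatrix) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def read_pair_list(
    path: str | os.PathLike, label: Optional[str] = None
) -> list[GenePair]:
    """Read a two-column (TF, TG) TSV, deduplicating on first occurrence."""
    pairs: list[GenePair] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise DataError(
                    f"{path}: line {line_no}: expected two tab-separated columns"
                )
            tf, tg = parts[0].strip(), parts[1].strip()
            if tf == tg:
                raise DataError(f"{path}: line {line_no}: self-pair {tf!r}")
            if (tf, tg) in seen:
                continue
            seen.add((tf, tg))
            pairs.append(GenePair(tf, tg, label))
    return pairs


def write_pair_list(path: str | os.PathLike, pairs: Sequence[GenePair]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pair in pairs:
            fh.write(f"{pair.tf_id}\t{pair.tg_id}\n")


def read_go_tables(
    annotation_path: str | os.PathLike, hierarchy_path: str | os.PathLike
) -> GOAnnotationSet:
    """Read (gene, term) annotation rows and (child, parent) hierarchy rows.

    Grades are computed as 1 + longest path to a root and are invariant to
    the row order of the hierarchy file. A cycle in the hierarchy is a hard
    error naming one member of the cycle.
    """
    gene_terms: dict[str, set[str]] = defaultdict(set)
    with open(annotation_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise DataError(
                    f"{annotation_path}: line {line_no}: expected (gene, term)"
                )
            gene_terms[parts[0].strip()].add(parts[1].strip())
    term_parents: dict[str, set[str]] = defaultdict(set)
    with open(hierarchy_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise DataError(
                    f"{hierarchy_path}: line {line_no}: expected (child, parent)"
                )
            term_parents[parts[0].strip()].add(parts[1].strip())
    return GOAnnotationSet.build(term_parents, gene_terms)


PREDICTION_COLUMNS = [
    "tf",
    "tg",
    "pcc",
    "eld",
    "dmean",
    "dsd",
    "modulus",
    "angle",
    "go_score",
    "lr_pcc_eld",
    "lr_dmean_dsd",
    "lr_modulus_angle",
    "lr_go",
    "total_lr",
    "posterior_odds",
    "classification",
    "direction",
    "delay",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One scored pair: features, per-group LRs, odds, call, direction."""

    tf: str
    tg: str
    pcc: float
    eld: float
    dmean: float
    dsd: float
    modulus: float
    angle: float
    go_score: float
    lr_pcc_eld: float
    lr_dmean_dsd: float
    lr_modulus_angle: float
    lr_go: float
    total_lr: float
    posterior_odds: float
    classification: str  # "positive" / "negative"
    direction: str  # "forward" / "reverse" / "undetermined"
    delay: Optional[int]  # None when undetermined


def write_predictions(
    path: str | os.PathLike, records: Sequence[PredictionRecord]
) -> None:
    """Write the prediction table; floats carry 6 decimals for round-trips."""
    if not records:
        raise DataError("no prediction records to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            row = [
                r.tf,
                r.tg,
                f"{r.pcc:.6f}",
                f"{r.eld:.6f}",
                f"{r.dmean:.6f}",
                f"{r.dsd:.6f}",
                f"{r.modulus:.6f}",
                f"{r.angle:.6f}",
                f"{r.go_score:.6f}",
                f"{r.lr_pcc_eld:.6f}",
                f"{r.lr_dmean_dsd:.6f}",
                f"{r.lr_modulus_angle:.6f}",
                f"{r.lr_go:.6f}",
                f"{r.total_lr:.6f}",
                f"{r.posterior_odds:.6f}",
                r.classification,
                r.direction,
                "" if r.delay is None else str(r.delay),
            ]
            fh.write("\t".join(row) + "\n")


def read_predictions(path: str | os.PathLike) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PREDICTION_COLUMNS:
            raise DataError(f"{path}: unexpected prediction header")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(PREDICTION_COLUMNS):
                raise DataError(f"{path}: malformed prediction row")
            records.append(
                PredictionRecord(
                    tf=parts[0],
                    tg=parts[1],
                    pcc=float(parts[2]),
                    eld=float(parts[3]),
                    dmean=float(parts[4]),
                    dsd=float(parts[5]),
                    modulus=float(parts[6]),
                    angle=float(parts[7]),
                    go_score=float(parts[8]),
                    lr_pcc_eld=float(parts[9]),
                    lr_dmean_dsd=float(parts[10]),
                    lr_modulus_angle=float(parts[11]),
                    lr_go=float(parts[12]),
                    total_lr=float(parts[13]),
                    posterior_odds=float(parts[14]),
                    classification=parts[15],
                    direction=parts[16],
                    delay=None if parts[17] == "" else int(parts[17]),
                )
            )
    if not records:
        raise DataError(f"{path}: no prediction rows")
    return records
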