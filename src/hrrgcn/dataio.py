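"""Reading, writing and slicing expression compendia, metadata and GO annotations.

The toolkit consumes a normalized (log-scale) expression matrix of probesets
by arrays, an array-metadata table describing each hybridization
(sub-species, organ, experiment type), and a probeset-to-GO annotation table,
optionally backed by an OBO ontology for true-path propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

NAMESPACES = ("BP", "MF", "CC")

#: aliases found in annotation exports for the three GO branches
_NAMESPACE_ALIASES = {
    "BP": "BP", "P": "BP", "BIOLOGICAL_PROCESS": "BP",
    "MF": "MF", "F": "MF", "MOLECULAR_FUNCTION": "MF",
    "CC": "CC", "C": "CC", "CELLULAR_COMPONENT": "CC",
}


class DataError(ValueError):
    """Malformed or degenerate input data."""


@dataclass
class ExpressionMatrix:
    """A probesets x arrays matrix of normalized expression values.

    Rows are probesets (the network's node identity), columns are arrays.
    At least 3 arrays are required: Pearson correlation is degenerate below
    that, and every downstream stage is correlation-based.
    """

    probeset_ids: list[str]
    array_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.probeset_ids) or m != len(self.array_ids):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.array_ids)} arrays"
            )
        for label, ids in (("probeset", self.probeset_ids), ("array", self.array_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataError(f"duplicate {label} identifier: {dup!r}")
        if m < 3:
            raise DataError(f"need at least 3 arrays, got {m}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at probeset {self.probeset_ids[bad[0]]!r}, "
                f"array {self.array_ids[bad[1]]!r}"
            )

    @property
    def n_probesets(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probeset_ids, columns=self.array_ids)


def _first_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def load_expression(
    path: str | Path,
    missing_policy: str = "drop_probeset",
    normalize_ids: bool = False,
    exclude: set[str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first row array ids, first column probeset ids).

    Parameters
    ----------
    missing_policy
        ``"drop_probeset"`` removes every probeset with a missing/non-numeric
        cell (rank comparability requires all genes to be correlated over the
        identical array set); ``"error"`` raises with the cell coordinates.
    normalize_ids
        Upper-case probeset identifiers (annotation sources mix spellings of
        the same platform ids).
    exclude
        Optional set of probeset ids (e.g. platform control probesets) to drop
        before network construction.
    """
    if missing_policy not in ("drop_probeset", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    df.index = df.index.astype(str)
    if normalize_ids:
        df.index = df.index.str.upper()
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise DataError(f"duplicate probeset identifier: {dup!r}")
    dup = _first_duplicate(list(df.columns))
    if dup is not None:
        raise DataError(f"duplicate array identifier: {dup!r}")
    if exclude:
        excl = {e.upper() for e in exclude} if normalize_ids else set(exclude)
        df = df.loc[[p for p in df.index if p not in excl]]
    num = df.apply(pd.to_numeric, errors="coerce")
    missing = num.isna()
    if missing.values.any():
        if missing_policy == "error":
            r, c = np.argwhere(missing.values)[0]
            raise DataError(
                f"missing or non-numeric value at probeset {df.index[r]!r}, "
                f"array {df.columns[c]!r}"
            )
        num = num.loc[~missing.any(axis=1)]
    return ExpressionMatrix(list(num.index), list(num.columns), num.values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that :func:`load_expression` reads back identically."""
    # %.17g round-trips IEEE doubles exactly
    matrix.to_frame().to_csv(
        path, sep="\t", index_label="probeset_id", float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# array metadata

METADATA_FIELDS = ("subspecies", "organ", "experiment_type", "description")


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the array metadata table; returns a frame indexed by array_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "array_id" not in df.columns:
        raise DataError("metadata table must have an 'array_id' column")
    dup = _first_duplicate(list(df["array_id"]))
    if dup is not None:
        raise DataError(f"duplicate array_id in metadata: {dup!r}")
    return df.set_index("array_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="array_id")


def subset_by_condition(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    selector: dict[str, str] | None,
) -> ExpressionMatrix:
    """Restrict the compendium to arrays matching a metadata selector.

    ``selector`` is a conjunction of field=value terms over the metadata
    columns (e.g. ``{"organ": "fruit"}``); ``None`` or ``{}`` keeps all
    arrays.  The probeset set is unchanged.  Fewer than 3 matching arrays is
    an error — the downstream correlations would be degenerate.
    """
    missing = [a for a in matrix.array_ids if a not in metadata.index]
    if missing:
        raise DataError(f"arrays without metadata: {missing[:5]}")
    if selector:
        for fld in selector:
            if fld not in metadata.columns:
                raise DataError(f"unknown metadata field {fld!r}")
        keep = [
            a for a in matrix.array_ids
            if all(metadata.at[a, f] == v for f, v in selector.items())
        ]
    else:
        keep = list(matrix.array_ids)
    if len(keep) < 3:
        raise DataError(
            f"selector {selector!r} matches {len(keep)} arrays; at least 3 required"
        )
    cols = [matrix.array_ids.index(a) for a in keep]
    return ExpressionMatrix(list(matrix.probeset_ids), keep, matrix.values[:, cols])


def parse_selector(terms: tuple[str, ...] | list[str]) -> dict[str, str]:
    """Parse CLI-style ``field=value`` terms into a selector dict."""
    sel: dict[str, str] = {}
    for t in terms:
        if "=" not in t:
            raise ValueError(f"selector term {t!r} is not of the form field=value")
        f, v = t.split("=", 1)
        sel[f] = v
    return sel


# ---------------------------------------------------------------------------
# GO annotations


@dataclass
class AnnotationSet:
    """Probeset -> GO term associations over the three GO namespaces.

    ``associations`` maps probeset id to a set of ``(term_id, namespace)``
    pairs; ``dag`` (if present) is a directed graph with edges child -> parent
    used for true-path propagation.
    """

    associations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)
    dag: nx.DiGraph | None = None

    def __post_init__(self) -> None:
        for ps, terms in self.associations.items():
            for _, ns in terms:
                if ns not in NAMESPACES:
                    raise DataError(f"unknown namespace {ns!r} for probeset {ps!r}")
        if self.dag is not None and not nx.is_directed_acyclic_graph(self.dag):
            raise DataError("ontology graph is cyclic")

    def annotated_probesets(self, namespace: str | None = None) -> set[str]:
        if namespace is None:
            return {p for p, t in self.associations.items() if t}
        return {
            p for p, terms in self.associations.items()
            if any(ns == namespace for _, ns in terms)
        }

    def term_to_genes(self, namespace: str | None = None) -> dict[str, set[str]]:
        """Invert the associations: term id -> probesets annotated to it."""
        out: dict[str, set[str]] = {}
        for ps, terms in self.associations.items():
            for term, ns in terms:
                if namespace is None or ns == namespace:
                    out.setdefault(term, set()).add(ps)
        return out

    def n_associations(self) -> int:
        return sum(len(t) for t in self.associations.values())


def load_annotations(
    path: str | Path,
    obo_path: str | Path | None = None,
    propagate: bool = False,
    normalize_ids: bool = False,
) -> AnnotationSet:
    """Read a (probeset_id, term_id, namespace[, description]) TSV.

    With ``propagate`` and an OBO file, each association is extended to all
    ancestor terms in the same namespace (true-path rule).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(3))
    if len(df) == 0:
        dag = load_obo(obo_path) if obo_path is not None else None
        return AnnotationSet({}, {}, dag)
    if df.shape[1] < 3:
        raise DataError("annotation table needs >= 3 columns (probeset, term, namespace)")
    associations: dict[str, set[tuple[str, str]]] = {}
    term_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ps = str(row[0]).upper() if normalize_ids else str(row[0])
        term = str(row[1])
        ns = _NAMESPACE_ALIASES.get(str(row[2]).strip().upper())
        if ns is None:
            raise DataError(f"unknown namespace {row[2]!r} for term {term!r}")
        associations.setdefault(ps, set()).add((term, ns))
        if df.shape[1] >= 4 and not pd.isna(row[3]):
            term_names[term] = str(row[3])
    dag = load_obo(obo_path) if obo_path is not None else None
    annset = AnnotationSet(associations, term_names, dag)
    if propagate:
        if dag is None:
            raise ValueError("propagate=True requires an OBO file")
        annset = propagate_annotations(annset)
    return annset


def load_obo(path: str | Path) -> nx.DiGraph:
    """Parse an OBO 1.2 ontology into a child -> parent DAG."""
    import obonet

    graph = obonet.read_obo(path)
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes(data=True))
    # obonet edges already point child -> parent for is_a relations
    dag.add_edges_from((u, v) for u, v, k in graph.edges(keys=True) if k == "is_a")
    if not nx.is_directed_acyclic_graph(dag):
        raise DataError("ontology graph is cyclic")
    return dag


def propagate_annotations(annset: AnnotationSet) -> AnnotationSet:
    """Apply the true-path rule: annotate each probeset to all ancestors.

    Ancestors are followed within the child's namespace; terms absent from
    the DAG are kept unpropagated with a warning.  Propagation is idempotent.
    """
    if annset.dag is None:
        raise ValueError("AnnotationSet has no ontology graph to propagate over")
    dag = annset.dag
    ancestor_cache: dict[str, set[str]] = {}
    warned: set[str] = set()
    new_assoc: dict[str, set[tuple[str, str]]] = {}
    for ps, terms in annset.associations.items():
        out = set(terms)
        for term, ns in terms:
            if term not in dag:
                if term not in warned:
                    warnings.warn(
                        f"term {term} not in ontology; kept unpropagated", stacklevel=2
                    )
                    warned.add(term)
                continue
            if term not in ancestor_cache:
                # edges run child -> parent, so graph descendants are ontology ancestors
                ancestor_cache[term] = nx.descendants(dag, term)
            out.update((anc, ns) for anc in ancestor_cache[term])
        new_assoc[ps] = out
    return AnnotationSet(new_assoc, dict(annset.term_names), dag)


def write_annotations(annset: AnnotationSet, path: str | Path) -> None:
    rows = [
        (ps, term, ns, annset.term_names.get(term, ""))
        for ps, terms in sorted(annset.associations.items())
        for term, ns in sorted(terms)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
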