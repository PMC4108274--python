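"""Hypergeometric GO over-representation and enrichment-based clustering scores.

For a cluster of size n drawn from a background universe of size N in which
K genes carry a term, the enrichment p-value is the upper-tail
hypergeometric probability of observing at least k annotated genes in the
cluster.  P-values are Benjamini-Hochberg adjusted within each cluster and
namespace family, and a term is called significant when FDR < 0.05 and at
least 2 cluster genes carry it.

Clustering performance for parameter selection:
  specificity = fraction of clusters with >= 1 significant term,
  sensitivity = fraction of background annotations significant in >= 1 cluster,
  F = harmonic mean of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dataio import NAMESPACES, AnnotationSet
from .hrrnet import GuideCluster
from .mclcluster import Clustering

RESULT_COLUMNS = [
    "cluster_id",
    "term_id",
    "namespace",
    "n_in_cluster",
    "n_in_background",
    "cluster_size",
    "background_size",
    "p",
    "fdr",
    "significant",
    "description",
]


@dataclass
class PerformanceReport:
    specificity: float
    sensitivity: float
    f_measure: float
    n_clusters: int
    n_annotations: int


def _namespace_universe(
    annotations: AnnotationSet, background: set[str], namespace: str, universe: str
) -> set[str]:
    if universe == "all":
        return set(background)
    if universe == "annotated":
        return background & annotations.annotated_probesets(namespace)
    raise ValueError(f"universe must be 'annotated' or 'all', got {universe!r}")


def hypergeom_enrich(
    cluster: set[str],
    annotations: AnnotationSet,
    background: set[str],
    cluster_id=None,
    universe: str = "annotated",
    fdr_threshold: float = 0.05,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Test every GO term represented in the cluster for over-representation.

    ``universe="annotated"`` restricts the background, per namespace, to
    probesets carrying at least one annotation in that namespace (genes that
    can never contribute to any term would otherwise deflate p-values);
    ``"all"`` uses the full background.  BH adjustment is applied separately
    per namespace within the cluster.
    """
    cluster = set(cluster)
    background = set(background)
    if not cluster <= background:
        extra = sorted(cluster - background)[:5]
        raise ValueError(f"cluster members outside the background universe: {extra}")
    frames = []
    for ns in NAMESPACES:
        uni = _namespace_universe(annotations, background, ns, universe)
        if not uni:
            continue
        term_genes = {
            t: genes & uni
            for t, genes in annotations.term_to_genes(ns).items()
        }
        cluster_ns = cluster & uni
        n_draw = len(cluster_ns)
        if n_draw == 0:
            continue
        rows = []
        for term, genes in sorted(term_genes.items()):
            k = len(genes & cluster_ns)
            if k == 0:
                continue
            K = len(genes)
            p = float(hypergeom.sf(k - 1, len(uni), K, n_draw))
            rows.append((term, ns, k, K, n_draw, len(uni), p))
        if not rows:
            continue
        df = pd.DataFrame(
            rows,
            columns=[
                "term_id",
                "namespace",
                "n_in_cluster",
                "n_in_background",
                "cluster_size",
                "background_size",
                "p",
            ],
        )
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["n_in_cluster"] >= min_genes)
    out["description"] = out["term_id"].map(lambda t: annotations.term_names.get(t, ""))
    out.insert(0, "cluster_id", cluster_id)
    return out.sort_values(["namespace", "p"], ignore_index=True)[RESULT_COLUMNS]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(pvalues) == 0:
        return np.asarray([], dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def enrich_clustering(
    clustering: Clustering,
    annotations: AnnotationSet,
    background: set[str],
    **kwargs,
) -> pd.DataFrame:
    """Per-cluster enrichment for every retained cluster of a partition."""
    frames = [
        hypergeom_enrich(set(members), annotations, background, cluster_id=cid, **kwargs)
        for cid, members in clustering.clusters.items()
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def guide_enrichment(
    guide_clusters: list[GuideCluster],
    annotations: AnnotationSet,
    background: set[str],
    **kwargs,
) -> pd.DataFrame:
    """Enrichment of each guide-gene cluster (guide included as a member)."""
    frames = [
        hypergeom_enrich(
            set(gc.member_ids) | {gc.guide},
            annotations,
            background,
            cluster_id=gc.guide,
            **kwargs,
        )
        for gc in guide_clusters
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def clustering_performance(
    clustering: Clustering,
    annotations: AnnotationSet,
    background: set[str] | None = None,
    universe: str = "annotated",
    fdr_threshold: float = 0.05,
    min_genes: int = 2,
) -> PerformanceReport:
    """Enrichment-based clustering quality (specificity, sensitivity, F).

    The annotation denominator for sensitivity is the set of distinct
    (term, namespace) pairs carried by at least one background gene.
    """
    if clustering.n_clusters < 1:
        raise ValueError("clustering has no retained clusters")
    if background is None:
        background = set().union(*clustering.clusters.values()) | set(
            clustering.unassigned
        )
    all_terms = {
        (term, ns)
        for ps in background
        for term, ns in annotations.associations.get(ps, ())
    }
    if not all_terms:
        raise ValueError("no annotated genes in the background universe")
    results = enrich_clustering(
        clustering,
        annotations,
        background,
        universe=universe,
        fdr_threshold=fdr_threshold,
        min_genes=min_genes,
    )
    if results.empty:
        enriched_clusters, enriched_terms = 0, 0
    else:
        sig = results[results["significant"].astype(bool)]
        enriched_clusters = sig["cluster_id"].nunique()
        enriched_terms = len(set(zip(sig["term_id"], sig["namespace"])) & all_terms)
    specificity = enriched_clusters / clustering.n_clusters
    sensitivity = enriched_terms / len(all_terms)
    if specificity + sensitivity == 0:
        f = 0.0
    else:
        f = 2 * specificity * sensitivity / (specificity + sensitivity)
    return PerformanceReport(
        specificity=specificity,
        sensitivity=sensitivity,
        f_measure=f,
        n_clusters=clustering.n_clusters,
        n_annotations=len(all_terms),
    )


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
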