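"""Expression specificity index (ESI) and cluster cumulative ESI (cESI).

The ESI standardizes expression twice: first within each array across genes
(removing per-array scale and location), then within each gene across arrays
(removing per-gene baseline and dynamic range).  The result is in standard
deviation units: a probeset is called well expressed in an array when its
ESI exceeds 1 and specifically expressed when it exceeds 5.

The cluster cumulative ESI in an array is the fraction of cluster members
with ESI > 1 there; condition-group profiles average the per-array fractions
within the group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix

WELL_EXPRESSED = 1.0
SPECIFICALLY_EXPRESSED = 5.0


@dataclass
class ESIMatrix:
    probeset_ids: list[str]
    array_ids: list[str]
    esi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.esi, index=self.probeset_ids, columns=self.array_ids)


@dataclass
class CESIProfile:
    cluster_id: object
    per_array: pd.Series  # array_id -> fraction of members with ESI > threshold
    per_group: pd.Series | None = None  # group label -> mean per-array fraction


def standardize_columns(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score each column across rows (population SD by default)."""
    mu = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, ddof=ddof, keepdims=True)
    if (sd == 0).any():
        bad = np.flatnonzero(sd.ravel() == 0)
        raise ValueError(f"zero-variance array columns at indices {bad.tolist()[:5]}")
    return (values - mu) / sd


def standardize_rows(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score each row across columns; zero-variance rows become all zeros."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    ok = (sd != 0).ravel()
    out[ok] = (values[ok] - mu[ok]) / sd[ok]
    return out


def esi(matrix: ExpressionMatrix, ddof: int = 0, between_on: str = "staged") -> ESIMatrix:
    """Two-stage standardization: within arrays, then between arrays.

    Stage 1 z-scores each array column across probesets; stage 2 z-scores
    each probeset row of the stage-1 matrix across arrays.  Probesets with
    no variance left after stage 1 get ESI 0 everywhere.  ``between_on=
    "raw"`` applies stage 2 to the raw values instead of the stage-1 output.
    """
    if matrix.n_arrays < 3:
        raise ValueError("ESI needs at least 3 arrays")
    if matrix.n_probesets < 2:
        raise ValueError("ESI needs at least 2 probesets")
    stage1 = standardize_columns(matrix.values, ddof=ddof)
    base = stage1 if between_on == "staged" else matrix.values
    if between_on not in ("staged", "raw"):
        raise ValueError(f"between_on must be 'staged' or 'raw', got {between_on!r}")
    stage2 = standardize_rows(base, ddof=ddof)
    return ESIMatrix(list(matrix.probeset_ids), list(matrix.array_ids), stage2)


def cesi(
    members,
    esi_matrix: ESIMatrix,
    metadata: pd.DataFrame | None = None,
    grouping: str | None = None,
    threshold: float = WELL_EXPRESSED,
    cluster_id=None,
) -> CESIProfile:
    """Fraction of cluster members with ESI above threshold, per array.

    With ``metadata`` and a ``grouping`` field (e.g. ``"organ"``), a
    per-group profile is added: the mean of the per-array fractions within
    each group — the size-weighted mean over groups then equals the
    all-array mean fraction.
    """
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    index = {p: i for i, p in enumerate(esi_matrix.probeset_ids)}
    missing = [m for m in members if m not in index]
    if missing:
        raise ValueError(f"cluster members missing from the ESI matrix: {missing[:5]}")
    rows = [index[m] for m in members]
    above = esi_matrix.esi[rows] > threshold
    per_array = pd.Series(
        above.mean(axis=0), index=esi_matrix.array_ids, name="cesi"
    )
    per_group = None
    if grouping is not None:
        if metadata is None:
            raise ValueError("grouping requires array metadata")
        groups = metadata.loc[per_array.index, grouping]
        per_group = per_array.groupby(groups).mean()
        per_group.name = "cesi"
    return CESIProfile(cluster_id, per_array, per_group)


def cesi_profiles(
    clustering,
    esi_matrix: ESIMatrix,
    metadata: pd.DataFrame | None = None,
    grouping: str | None = None,
    threshold: float = WELL_EXPRESSED,
) -> pd.DataFrame:
    """Long-format cESI table for every retained cluster of a partition."""
    rows = []
    for cid, members in clustering.clusters.items():
        profile = cesi(
            members, esi_matrix, metadata, grouping, threshold, cluster_id=cid
        )
        series = profile.per_group if grouping is not None else profile.per_array
        label = grouping if grouping is not None else "array_id"
        for key, value in series.items():
            rows.append({"cluster_id": cid, label: key, "cesi": value})
    return pd.DataFrame(rows)


def write_esi(esi_matrix: ESIMatrix, path) -> None:
    esi_matrix.to_frame().to_csv(path, sep="\t", index_label="probeset_id")
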