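"""Permutation-based significance of HRR values.

Each permutation independently shuffles every probeset's values across
arrays, destroying all inter-gene correlation while preserving each gene's
marginal distribution, then recomputes the full HRR matrix.  Pooling the
HRR values of all pairs over all permutations gives an empirical null from
which a network-wide cutoff at a requested significance level is read off.
Small HRR means strong co-expression, so significance is a left-tail test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionMatrix
from .hrrnet import hrr_network


@dataclass
class NullHRRDistribution:
    """Pooled empirical distribution of null HRR values.

    ``counts[h]`` is the number of null pairs with HRR exactly h
    (index 0 unused); the total mass is n_permutations * n(n-1)/2.
    """

    n_genes: int
    n_permutations: int
    counts: np.ndarray  # length n_genes, counts[h] for h in 1..n-1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cutoff_at(self, alpha: float) -> int:
        """Largest integer h with empirical P(HRR_null <= h) < alpha.

        Returns 0 when no HRR value reaches significance at alpha.  For
        alpha >= 1 every value is trivially significant and n-1 is returned.
        """
        if not 0 < alpha:
            raise ValueError(f"alpha must be positive, got {alpha}")
        if alpha >= 1.0:
            return self.n_genes - 1
        cdf = np.cumsum(self.counts) / self.total
        below = np.flatnonzero(cdf < alpha)
        return int(below[-1]) if below.size else 0


def permute_rows(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle each row independently across columns (marginals preserved)."""
    return rng.permuted(values, axis=1)


def permutation_null(
    matrix: ExpressionMatrix,
    n_permutations: int = 100,
    seed: int | None = None,
    block_size: int | None = None,
    subsample: int | None = None,
) -> NullHRRDistribution:
    """Estimate the null HRR distribution by row-wise permutation.

    ``subsample`` optionally restricts to a random gene subset *before*
    network construction; HRR values scale with network size, so cutoffs
    derived from a subsample apply only to networks of that size (a warning
    is emitted).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    values = matrix.values
    ids = list(matrix.probeset_ids)
    if subsample is not None and subsample < matrix.n_probesets:
        keep = np.sort(rng.choice(matrix.n_probesets, size=subsample, replace=False))
        values = values[keep]
        ids = [ids[i] for i in keep]
        warnings.warn(
            f"null estimated on a {subsample}-gene subsample; the cutoffs apply "
            "to networks of that size only",
            stacklevel=2,
        )
    n = values.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    for _ in range(n_permutations):
        permuted = permute_rows(values, rng)
        em = ExpressionMatrix(ids, list(matrix.array_ids), permuted)
        net = hrr_network(em, block_size=block_size, keep_ranks=False)
        counts += np.bincount(net.hrr[iu], minlength=n)
    return NullHRRDistribution(n_genes=n, n_permutations=n_permutations, counts=counts)


def hrr_pvalue(dist: NullHRRDistribution, h: int) -> float:
    """Empirical left-tail p-value of an observed HRR value.

    Uses the add-one correction p = (#null <= h + 1) / (total + 1) so that no
    observed value gets p = 0; monotone non-decreasing in h.
    """
    if not 1 <= h <= dist.n_genes - 1:
        raise ValueError(f"h must be in [1, {dist.n_genes - 1}], got {h}")
    below = int(dist.counts[1 : h + 1].sum())
    return (below + 1) / (dist.total + 1)


def significance_report(
    dist: NullHRRDistribution, alphas: tuple[float, ...] = (0.01, 0.05)
) -> dict:
    return {
        "n_genes": dist.n_genes,
        "n_permutations": dist.n_permutations,
        "cutoffs": {a: dist.cutoff_at(a) for a in alphas},
    }
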