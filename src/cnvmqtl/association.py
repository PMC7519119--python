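"""Rank-correlation association with permutation multiple-test correction.

The numerical kernel shared by the mQTL, eQTL and eQTM scans:

* Spearman rank correlation between a genotype (or methylation) vector and a
  phenotype vector, with the usual large-sample t approximation for the
  nominal p-value;
* a per-phenotype permutation correction in the Stranger et al. style — the
  phenotype is shuffled across samples and, for each permutation, the maximum
  |rho| over the phenotype's tested variant family is recorded; each pair's
  permutation p is the add-one empirical tail of its observed |rho| in that
  max-null;
* the closed-form permutation FDR estimate
  ``n_phenotypes_tested × cutoff / n_significant_phenotypes``.

Permutation p-values are therefore family-wise corrected within a phenotype:
a pair is significant only if its correlation beats what the best variant in
the family achieves on shuffled phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AssociationRecord:
    """One tested variant-phenotype pair."""

    variant_id: str
    phenotype_id: str
    rho: float
    nominal_p: float
    perm_p: float
    mode: str  # "proximal" | "distal"
    distance: int  # signed bp, variant midpoint - phenotype midpoint

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho out of range: {self.rho}")
        if not 0.0 < self.perm_p <= 1.0:
            raise ValueError(f"perm_p out of range: {self.perm_p}")
        if self.mode not in ("proximal", "distal"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PermutationScheme:
    """Permutation correction settings.

    ``n_perm`` shuffles of the phenotype vector; the family is the
    phenotype's tested variant set; tail probabilities use the add-one
    estimator ``(1 + k) / (n_perm + 1)`` so no p is ever zero.
    """

    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")


class ConstantInputError(ValueError):
    """A vector without variation: correlation is undefined."""


def _complete_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided nominal p for a pair of vectors.

    Missing entries (NaN) are dropped pairwise-complete first.  Raises
    :class:`ConstantInputError` when either vector is constant after
    filtering, and ``ValueError`` when fewer than 3 complete pairs remain.
    """
    x, y = _complete_pair(x, y)
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("constant vector: correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _standardized_ranks(values: np.ndarray) -> np.ndarray:
    """Row-wise average-tie ranks, centred and scaled to unit norm.

    With both vectors in this form, Spearman rho is a plain dot product.
    """
    values = np.atleast_2d(values)
    ranks = stats.rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ConstantInputError("constant row: correlation undefined")
    return ranks / norms


def permutation_correct(
    phenotype: np.ndarray,
    genotype_rows: np.ndarray,
    scheme: PermutationScheme,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Family-wise permutation p-value for each genotype row vs one phenotype.

    For each of ``scheme.n_perm`` shuffles of the phenotype across samples,
    the maximum |rho| over all rows is recorded;
    ``perm_p[i] = (1 + #{max-null >= |rho_obs[i]|}) / (n_perm + 1)``.

    Rows with missing genotypes are scored against the phenotype re-ranked on
    their complete-sample subset (slower path).  The phenotype itself must be
    complete and non-constant.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    genotype_rows = np.atleast_2d(np.asarray(genotype_rows, dtype=float))
    if genotype_rows.shape[0] == 0:
        raise ValueError("empty genotype family")
    if np.isnan(phenotype).any():
        raise ValueError("phenotype must be complete")
    if np.all(phenotype == phenotype[0]):
        raise ConstantInputError("constant phenotype")
    n = phenotype.size
    if genotype_rows.shape[1] != n:
        raise ValueError("genotype rows and phenotype differ in sample count")
    if rng is None:
        rng = np.random.default_rng(scheme.seed)

    perms = np.array([rng.permutation(n) for _ in range(scheme.n_perm)])
    missing = np.isnan(genotype_rows)
    obs = np.empty(genotype_rows.shape[0])
    if not missing.any():
        g = _standardized_ranks(genotype_rows)  # k × n
        p = _standardized_ranks(phenotype[None, :])[0]
        obs = g @ p
        # shuffling raw values then ranking == shuffling the ranks
        null_rho = g @ p[perms].T  # k × n_perm
        max_null = np.max(np.abs(null_rho), axis=0)
    else:
        max_null = np.zeros(scheme.n_perm)
        all_null = np.empty((genotype_rows.shape[0], scheme.n_perm))
        for i, row in enumerate(genotype_rows):
            keep = ~missing[i]
            if keep.sum() < 3:
                raise ValueError(f"row {i}: fewer than 3 complete pairs")
            sub = row[keep]
            if np.all(sub == sub[0]):
                raise ConstantInputError(f"row {i} constant on complete subset")
            g = _standardized_ranks(sub[None, :])[0]
            obs[i] = float(g @ _standardized_ranks(phenotype[keep][None, :])[0])
            shuffled = phenotype[perms][:, keep]  # n_perm × n_keep
            pr = _standardized_ranks(shuffled)
            all_null[i] = pr @ g
        max_null = np.max(np.abs(all_null), axis=0)

    exceed = (max_null[None, :] >= np.abs(obs)[:, None]).sum(axis=1)
    return (1.0 + exceed) / (scheme.n_perm + 1.0)


def estimate_fdr(n_phenotypes_tested: int, cutoff: float, n_significant_phenotypes: int) -> float:
    """Permutation FDR: expected false positives over observed positives.

    ``min(1, n_phenotypes_tested × cutoff / n_significant_phenotypes)`` —
    at a permutation cutoff *c*, each tested phenotype has chance *c* of a
    significant call under the null, so ``n_tested × c`` estimates the false
    discovery count.
    """
    if n_phenotypes_tested <= 0 or n_significant_phenotypes < 0:
        raise ValueError("counts must be positive")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    if n_significant_phenotypes == 0:
        raise ValueError("FDR undefined with zero significant phenotypes")
    return min(1.0, n_phenotypes_tested * cutoff / n_significant_phenotypes)


def call_significant(records, threshold: float = 0.01):
    """Records with permutation p strictly below ``threshold``."""
    return [r for r in records if r.perm_p < threshold]
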