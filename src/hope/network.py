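"""Co-occurrence network inference from OTU abundance tables.

Abundances from amplicon sequencing are compositional: each sample carries
information only about relative proportions, so naive correlations between
raw counts are biased.  The default estimator here is the SparCC
linear-approximation estimator, which works on log-ratio variances

    t_ij = Var_s[ log(x_is / x_js) ]

and solves the approximate system ``t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)``
for basis variances ``w_i`` under the sparsity assumption that correlations
average out.  Pairs whose correlation exceeds a threshold become edges of an
undirected co-occurrence network over the OTUs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .containers import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric OTU x OTU correlation matrix with unit diagonal."""

    otu_ids: list
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.otu_ids)
        if self.rho.shape != (n, n):
            raise ValueError(f"rho shape {self.rho.shape} != ({n}, {n})")
        if not np.allclose(self.rho, self.rho.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.rho) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class CooccurrenceNetwork:
    """Undirected simple graph over OTU identifiers.

    ``adjacency`` is a dense binary symmetric matrix with zero diagonal;
    ``edges()`` yields the upper-triangle edge list as (otu_a, otu_b) pairs.
    """

    otu_ids: list
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        A = np.asarray(self.adjacency)
        n = len(self.otu_ids)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not (A == A.T).all():
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = A.astype(np.int8)
        self._index = {o: i for i, o in enumerate(self.otu_ids)}
        # neighbor index lists, precomputed once for the samplers
        self._neighbors = [np.flatnonzero(row) for row in self.adjacency]

    @property
    def n_nodes(self) -> int:
        return len(self.otu_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, otu_id) -> int:
        return self._index[otu_id]

    def neighbors_of(self, i: int) -> np.ndarray:
        return self._neighbors[i]

    def edges(self):
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(iu, ju):
            if self.adjacency[i, j]:
                yield self.otu_ids[i], self.otu_ids[j]


def _log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix of Var over samples of log(x_i / x_j), for all OTU pairs."""
    logf = np.log(fractions)
    # Var(a - b) = Var(a) + Var(b) - 2 Cov(a, b)
    var = logf.var(axis=1, ddof=1)
    cov = np.cov(logf, ddof=1)
    return var[:, None] + var[None, :] - 2.0 * cov


def sparcc_correlation(
    table: AbundanceTable,
    pseudocount: float = 1.0,
    n_exclusion_iters: int = 0,
) -> CorrelationMatrix:
    """SparCC basis correlations from a count table.

    Parameters
    ----------
    table : AbundanceTable
        Count table with at least 4 OTUs (the basis-variance linear system
        is underdetermined below that).
    pseudocount : float
        Added to every count before conversion to per-sample fractions, so
        zero counts do not break the log-ratio transform.
    n_exclusion_iters : int
        Number of refinement rounds.  Each round removes the most strongly
        correlated remaining pair from the variance system and re-solves,
        which reduces the bias those pairs introduce into the basis
        variances.  0 keeps the single-pass approximation.

    Returns
    -------
    CorrelationMatrix
        Estimated basis correlations, clipped to [-1, 1].
    """
    table.require_correlatable()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    D = table.n_otus
    if D < 4:
        raise ValueError(
            f"SparCC needs at least 4 OTUs (got {D}); "
            "fall back to spearman_correlation for small tables"
        )
    counts = table.counts + pseudocount
    fractions = counts / counts.sum(axis=0, keepdims=True)
    T = _log_ratio_variances(fractions)

    # include[i, j] marks pairs whose t_ij participates in the linear system
    include = ~np.eye(D, dtype=bool)
    omega, rho = _solve_basis(T, include)
    for _ in range(n_exclusion_iters):
        masked = np.where(include, np.abs(rho), -np.inf)
        np.fill_diagonal(masked, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= 0:
            break
        include[i, j] = include[j, i] = False
        if include.sum(axis=1).min() < 3:  # row too sparse to re-solve stably
            break
        omega, rho = _solve_basis(T, include)

    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(table.otu_ids, rho)


def _solve_basis(T: np.ndarray, include: np.ndarray):
    """Solve the SparCC approximation for basis variances and correlations.

    Summing t_ij over included partners J_i and dropping the cross term
    (the sparsity assumption) gives the linear system
    ``sum_{j in J_i} t_ij = |J_i| * w_i + sum_{j in J_i} w_j``.
    """
    D = T.shape[0]
    M = include.astype(float)
    M[np.arange(D), np.arange(D)] = include.sum(axis=1)
    t_row = (T * include).sum(axis=1)
    omega = np.linalg.solve(M, t_row)
    omega = np.maximum(omega, 1e-12)  # variances; numerical floor
    root = np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - T) / (2.0 * root)
    return omega, rho


def spearman_correlation(table: AbundanceTable) -> CorrelationMatrix:
    """Rank correlation across samples for every OTU pair.

    A fallback backend for tables too small for SparCC.  Constant rows have
    undefined rank correlation and are reported as 0 by convention.
    """
    table.require_correlatable()
    import warnings

    with warnings.catch_warnings():
        # constant rows are handled explicitly below
        warnings.simplefilter("ignore")
        rho, _ = scipy.stats.spearmanr(table.counts, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-OTU case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.asarray(rho, dtype=float)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    constant = np.ptp(table.counts, axis=1) == 0
    if constant.any():
        logger.warning(
            "%d constant OTU row(s); their correlations are set to 0",
            int(constant.sum()),
        )
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(table.otu_ids, rho)


def build_network(
    corr: CorrelationMatrix,
    threshold: float = 0.3,
    mode: str = "positive-only",
) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into an undirected network.

    An edge joins OTUs i and j iff ``rho_ij > threshold`` (mode
    ``positive-only``) or ``|rho_ij| > threshold`` (mode ``absolute``);
    the inequality is strict.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if mode == "positive-only":
        A = corr.rho > threshold
    elif mode == "absolute":
        A = np.abs(corr.rho) > threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(A, False)
    net = CooccurrenceNetwork(corr.otu_ids, A.astype(np.int8))
    if net.n_edges == 0:
        logger.warning("thresholding at %.3g produced an empty network", threshold)
    return net


def reachability_within(net: CooccurrenceNetwork, steps: int) -> np.ndarray:
    """Binary matrix marking node pairs connected by a path of length <= steps.

    Computed as the boolean OR of A, A^2, ..., A^steps; the diagonal is
    left 0 (a node does not count as reaching itself).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    A = net.adjacency.astype(bool)
    reach = A.copy()
    frontier = A.copy()
    for _ in range(steps - 1):
        frontier = frontier @ A
        reach |= frontier
    np.fill_diagonal(reach, False)
    return reach.astype(np.int8)
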