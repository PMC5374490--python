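"""Brain co-activation networks and their comparison.

Nodes are brain nuclei; the tie between two nuclei is the Pearson
correlation of their c-fos relative expression across fish of one
treatment (functional co-activation).  Networks from different treatments
are compared with the quadratic assignment procedure (QAP): the observed
correlation between the two off-diagonal patterns is referred to the null
distribution obtained by permuting one network's node labels (rows and
columns jointly), which preserves the within-matrix dependence structure
that invalidates naive tests.  Following the similarity-test reading of
QAP, two matrices are declared *different* when the QAP p-value exceeds
alpha — failure to detect pattern similarity.

Structure is summarized by valued-graph density (mean |r| over node pairs)
and eigenvector centrality (principal eigenvector of the |r| weight
matrix).  Absolute values keep the weight matrix nonnegative so the
Perron-Frobenius eigenvector is well defined; a significance-filtered
variant (edges with p < alpha only) is available for both measures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoactivationNetwork",
    "QAPResult",
    "coactivation_matrix",
    "qap_correlation",
    "network_density",
    "eigenvector_centrality",
    "compare_networks",
]

#: Node count at or below which QAP enumerates all permutations exactly.
EXACT_MAX_NODES = 8


@dataclass
class CoactivationNetwork:
    """Nucleus x nucleus Pearson matrix with per-edge significance.

    ``R`` is symmetric with unit diagonal; ``P`` holds two-sided p-values
    from the t transform; ``n_pairs`` the fish count behind each edge
    (pairwise-complete).  Undefined edges (too few fish, zero variance)
    are NaN in both ``R`` and ``P``.
    """

    treatment: str
    nodes: tuple[str, ...]
    R: np.ndarray
    P: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.nodes)
        for name in ("R", "P", "n_pairs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            setattr(self, name, arr)
        if not np.allclose(self.R, self.R.T, equal_nan=True):
            raise ValueError("R must be symmetric")
        finite = np.isfinite(self.R)
        if np.any(np.abs(self.R[finite]) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")

    @property
    def has_undefined_edges(self) -> bool:
        iu = np.triu_indices(len(self.nodes), k=1)
        return bool(np.isnan(self.R[iu]).any())

    def edge_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Edge list: node_a, node_b, r, p, n, significant."""
        rows = []
        for i, j in zip(*np.triu_indices(len(self.nodes), k=1)):
            rows.append(
                {
                    "treatment": self.treatment,
                    "node_a": self.nodes[i],
                    "node_b": self.nodes[j],
                    "r": self.R[i, j],
                    "p": self.P[i, j],
                    "n": self.n_pairs[i, j],
                    "significant": bool(self.P[i, j] < alpha),
                }
            )
        return pd.DataFrame(rows)


def coactivation_matrix(
    expr: pd.DataFrame,
    treatment: str = "",
    *,
    min_pairs: int = 3,
    log2: bool = False,
) -> CoactivationNetwork:
    """Pairwise-complete Pearson matrix across fish for one treatment.

    ``expr`` is a fish x nucleus grid of relative quantities (NaN = missing
    cell).  Each edge uses the fish with both nuclei present; edges with
    fewer than ``min_pairs`` fish or a zero-variance nucleus are NaN.

    ``log2`` correlates log2-transformed values instead (requires strictly
    positive entries).  qPCR relative quantities are log-normally
    distributed, so the pipeline correlates them on the log scale; Pearson
    on the raw scale would attenuate the co-activation structure.
    """
    nodes = tuple(str(c) for c in expr.columns)
    k = len(nodes)
    X = expr.to_numpy(dtype=float)
    if log2:
        if np.any(X[np.isfinite(X)] <= 0):
            raise ValueError("log2 co-activation requires positive quantities")
        X = np.log2(X)
    R = np.eye(k)
    P = np.zeros((k, k))
    n_pairs = np.full((k, k), float(len(expr)))
    for i in range(k):
        for j in range(i + 1, k):
            both = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n = int(both.sum())
            n_pairs[i, j] = n_pairs[j, i] = n
            if n < min_pairs or np.ptp(X[both, i]) == 0 or np.ptp(X[both, j]) == 0:
                R[i, j] = R[j, i] = np.nan
                P[i, j] = P[j, i] = np.nan
                continue
            r, p = stats.pearsonr(X[both, i], X[both, j])
            R[i, j] = R[j, i] = float(r)
            P[i, j] = P[j, i] = float(p)
    return CoactivationNetwork(
        treatment=treatment, nodes=nodes, R=R, P=P, n_pairs=n_pairs
    )


@dataclass(frozen=True)
class QAPResult:
    """Outcome of a QAP correlation test between two networks.

    ``r_obs`` is the Pearson correlation between the two matrices'
    upper-off-diagonal entries; ``p`` the proportion of node permutations
    whose permuted correlation reaches ``r_obs`` (one-sided toward
    similarity unless ``two_sided``); ``verdict`` is ``"different"`` when
    ``p > alpha`` — the matrices share no detectable pattern.
    """

    treatment_a: str
    treatment_b: str
    r_obs: float
    p: float
    n_perm: int
    mode: str  # "exact" | "monte_carlo"
    verdict: str  # "different" | "not_different"
    alpha: float


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("QAP undefined: constant off-diagonal vector")
    return float(a @ b) / denom


def qap_correlation(
    A: CoactivationNetwork,
    B: CoactivationNetwork,
    *,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    two_sided: bool = False,
    method: str = "auto",
) -> QAPResult:
    """QAP correlation test between two co-activation matrices.

    The null distribution relabels B's nodes: for a permutation ``pi``,
    ``r_perm = pearson(offdiag(A), offdiag(B[pi][:, pi]))``.  With at most
    :data:`EXACT_MAX_NODES` nodes all ``n!`` permutations are enumerated
    and ``p = #{r_perm >= r_obs} / n!`` (identity included); otherwise
    ``n_perm`` random permutations are drawn and the add-one estimator
    ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)`` is used so p stays in
    (0, 1].  ``two_sided`` compares ``|r_perm| >= |r_obs|`` instead.
    ``method`` forces ``"exact"`` or ``"monte_carlo"`` regardless of node
    count (exact is refused above :data:`EXACT_MAX_NODES`).
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if A.nodes != B.nodes:
        raise ValueError(f"node sets differ: {A.nodes} vs {B.nodes}")
    k = len(A.nodes)
    if k < 3:
        raise ValueError("QAP needs at least 3 nodes")
    for net in (A, B):
        if net.has_undefined_edges:
            raise ValueError(f"network {net.treatment!r} has undefined edges")
    a = _offdiag(A.R)
    r_obs = _pearson(a, _offdiag(B.R))

    def exceeds(r_perm: float) -> bool:
        if two_sided:
            return abs(r_perm) >= abs(r_obs) - 1e-12
        return r_perm >= r_obs - 1e-12

    use_exact = k <= EXACT_MAX_NODES if method == "auto" else method == "exact"
    if use_exact and k > EXACT_MAX_NODES:
        raise ValueError(f"exact enumeration limited to {EXACT_MAX_NODES} nodes")
    if use_exact:
        count = total = 0
        for perm in itertools.permutations(range(k)):
            idx = np.asarray(perm)
            r_perm = _pearson(a, _offdiag(B.R[np.ix_(idx, idx)]))
            count += exceeds(r_perm)
            total += 1
        p = count / total
        mode, n_used = "exact", total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(k)
            r_perm = _pearson(a, _offdiag(B.R[np.ix_(idx, idx)]))
            count += exceeds(r_perm)
        p = (1 + count) / (1 + n_perm)
        mode, n_used = "monte_carlo", n_perm
    verdict = "different" if p > alpha else "not_different"
    return QAPResult(
        treatment_a=A.treatment,
        treatment_b=B.treatment,
        r_obs=r_obs,
        p=p,
        n_perm=n_used,
        mode=mode,
        verdict=verdict,
        alpha=alpha,
    )


def _weight_matrix(
    net: CoactivationNetwork,
    *,
    signed: bool = False,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> np.ndarray:
    W = net.R.copy()
    np.fill_diagonal(W, 0.0)
    if significant_only:
        P = net.P.copy()
        np.fill_diagonal(P, 1.0)
        W = np.where(P < alpha, W, 0.0)
    if np.isnan(W).any():
        raise ValueError(
            f"network {net.treatment!r} has undefined edges; mask or drop them first"
        )
    return W if signed else np.abs(W)


def network_density(
    net: CoactivationNetwork,
    *,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> float:
    """Valued-graph density: mean |r| over the upper off-diagonal.

    With ``significant_only``, edges with p >= alpha contribute 0.  For
    correlation weights the result lies in [0, 1].
    """
    W = _weight_matrix(net, significant_only=significant_only, alpha=alpha)
    return float(_offdiag(W).mean())


def eigenvector_centrality(
    net: CoactivationNetwork,
    *,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> pd.Series:
    """Eigenvector centrality on the |r| weight matrix (diagonal zeroed).

    Returns the principal eigenvector, nonnegative and normalized to unit
    Euclidean norm, indexed by node.  The symmetric eigensolver is accurate
    to machine precision (well below 1e-10).
    """
    W = _weight_matrix(net, significant_only=significant_only, alpha=alpha)
    if not np.any(W > 0):
        raise ValueError("all-zero weight matrix: centrality undefined")
    vals, vecs = np.linalg.eigh(W)
    v = vecs[:, -1]
    # Perron vector of a nonnegative matrix: fix sign, clip rounding noise
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v = v / np.linalg.norm(v)
    return pd.Series(v, index=list(net.nodes), name="centrality")


def compare_networks(
    nets: dict[str, CoactivationNetwork],
    pairs: list[tuple[str, str]],
    *,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Run QAP for each declared treatment pair; tabulate verdicts.

    All networks must share node order.  Requesting a pair that names an
    unknown treatment is an error.
    """
    if not nets:
        raise ValueError("no networks given")
    node_orders = {net.nodes for net in nets.values()}
    if len(node_orders) != 1:
        raise ValueError("all networks must share the same node order")
    rows = []
    for a, b in pairs:
        for name in (a, b):
            if name not in nets:
                raise ValueError(f"undeclared treatment {name!r} in comparison pair")
        res = qap_correlation(
            nets[a], nets[b], n_perm=n_perm, seed=seed, alpha=alpha, two_sided=two_sided
        )
        rows.append(
            {
                "treatment_a": a,
                "treatment_b": b,
                "r_obs": res.r_obs,
                "p": res.p,
                "n_perm": res.n_perm,
                "mode": res.mode,
                "verdict": res.verdict,
            }
        )
    return pd.DataFrame(rows)
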