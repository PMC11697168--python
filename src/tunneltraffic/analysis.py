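"""Analysis machinery: k-means grouping, path-probability histograms,
H/M/L coding, a 2-D t-SNE embedding, and partial rank correlation (PRCC).

These routines are written out in full rather than delegated, because
their exact arithmetic is what the surrounding study rests on: k-means is
plain Lloyd iteration with random restarts; t-SNE follows the classic
formulation (Gaussian conditional affinities with per-point bandwidths
matched to a target perplexity by bisection, symmetrized and normalized,
Student-t low-dimensional affinities, gradient descent with momentum on
the Kullback-Leibler cost); PRCC is the Pearson correlation of the
residuals left after regressing each rank-transformed input and the
rank-transformed output on all remaining rank-transformed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import ConfigurationError

__all__ = [
    "ClusterAssignment",
    "Embedding2D",
    "PrccResult",
    "kmeans",
    "group_sorted_efficiencies",
    "probability_histograms",
    "categorize_hml",
    "tsne",
    "correlation_coefficient",
    "prcc",
    "prcc_by_delta",
]


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float  # total within-cluster sum of squared distances
    n_iter: int
    sse_history: np.ndarray  # objective after each Lloyd iteration (best run)

    @property
    def k(self) -> int:
        return len(self.centroids)


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int):
    labels = None
    history = []
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(len(X)), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(len(centroids)):
            members = X[labels == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                far = d2[np.arange(len(X)), labels].argmax()
                centroids[j] = X[far]
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return labels, centroids, inertia, len(history), np.asarray(history)


def kmeans(
    values,
    k: int = 3,
    seed: Optional[int] = None,
    max_iter: int = 300,
    restarts: int = 10,
) -> ClusterAssignment:
    """Lloyd's algorithm, best of ``restarts`` random initializations."""
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k > n:
        raise ConfigurationError(f"k={k} exceeds number of points n={n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        # distinct starting points where possible
        uniq = np.unique(X, axis=0)
        if len(uniq) >= k:
            centroids = uniq[rng.choice(len(uniq), size=k, replace=False)]
        else:
            centroids = X[rng.choice(n, size=k, replace=False)]
        out = _lloyd(X, centroids.astype(float).copy(), max_iter)
        if best is None or out[2] < best[2]:
            best = out
    labels, centroids, inertia, n_iter, hist = best
    return ClusterAssignment(labels, centroids, inertia, n_iter, hist)


def group_sorted_efficiencies(table, k: int = 3, seed: Optional[int] = None) -> pd.DataFrame:
    """Cluster per-combination efficiencies into k ordered groups.

    Accepts a SweepTable (its per-combination summary is used) or any
    DataFrame with a ``mean_E`` column.  Returns the rows sorted by
    descending E with a ``group`` column where group 1 has the highest
    centroid (high E) and group k the lowest.
    """
    df = table.summary if hasattr(table, "summary") else table
    if len(df) == 0:
        raise ConfigurationError("empty sweep table")
    df = df.sort_values("mean_E", ascending=False).reset_index(drop=True)
    E = df["mean_E"].to_numpy(dtype=float)
    k_eff = min(k, len(np.unique(E)))
    assign = kmeans(E, k=k_eff, seed=seed)
    order = np.argsort(-assign.centroids[:, 0])  # descending centroid
    relabel = np.empty(k_eff, dtype=int)
    relabel[order] = np.arange(1, k_eff + 1)
    df["group"] = relabel[assign.labels]
    return df


# ---------------------------------------------------------------------------
# histograms and H/M/L coding
# ---------------------------------------------------------------------------


def probability_histograms(
    combos: pd.DataFrame, bins: int = 10, columns: Sequence[str] = ("P1", "P2", "P3", "P4")
) -> pd.DataFrame:
    """Per-variable histograms over equal bins of [0, 1], each summing to 1."""
    if len(combos) == 0:
        raise ConfigurationError("empty group: nothing to histogram")
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {}
    for col in columns:
        counts, _ = np.histogram(combos[col].to_numpy(dtype=float), bins=edges)
        out[col] = counts / counts.sum()
    idx = pd.IntervalIndex.from_breaks(np.round(edges, 10), closed="left")
    return pd.DataFrame(out, index=idx)


def categorize_hml(p: float) -> str:
    """Code a probability as Low [0, 0.33), Medium [0.33, 0.66) or High [0.66, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"probability {p!r} outside [0, 1]")
    if p < 0.33:
        return "L"
    if p < 0.66:
        return "M"
    return "H"


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------


@dataclass
class Embedding2D:
    coords: np.ndarray  # (n, 2)
    kl: float  # final Kullback-Leibler cost C
    cost_history: np.ndarray


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    s = (X**2).sum(axis=1)
    D = s[:, None] + s[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _row_affinity(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Gaussian affinities for one point at precision beta = 1/(2 sigma^2).

    Returns the normalized row and its Shannon entropy (nats).
    """
    w = np.exp(-d2_row * beta)
    total = w.sum()
    if total <= 0:
        p = np.full_like(d2_row, 1.0 / len(d2_row))
        return p, np.log(len(d2_row))
    p = w / total
    nz = p > 0
    H = -np.sum(p[nz] * np.log(p[nz]))
    return p, H


def _conditional_p(D: np.ndarray, perplexity: float, tol: float = 1e-5) -> np.ndarray:
    """Per-point bandwidths by bisection to match the target perplexity."""
    n = len(D)
    target = np.log(perplexity)
    P = np.zeros((n, n))
    for i in range(n):
        d2 = np.delete(D[i], i)
        if np.allclose(d2, d2[0]):
            # all neighbors equidistant: entropy is flat in beta, use uniform
            row = np.full(n - 1, 1.0 / (n - 1))
        else:
            lo, hi = 0.0, None
            beta = 1.0
            for _ in range(100):
                row, H = _row_affinity(d2, beta)
                if abs(H - target) < tol:
                    break
                if H > target:  # too spread out -> narrow the kernel
                    lo = beta
                    beta = beta * 2 if hi is None else (beta + hi) / 2
                else:
                    hi = beta
                    beta = (lo + beta) / 2
        P[i, np.arange(n) != i] = row
    return P


def _joint_q(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    num = 1.0 / (1.0 + _pairwise_sq(Y))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return Q, num


def _kl_cost_and_grad(P: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """KL(P || Q) and its analytic gradient with respect to Y."""
    Q, num = _joint_q(Y)
    eps = 1e-12
    mask = P > 0
    C = float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], eps))))
    PQ = (P - Q) * num
    grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
    return C, grad


def tsne(
    points,
    perplexity: Optional[float] = None,
    iterations: int = 500,
    learning_rate: float = 100.0,
    seed: Optional[int] = None,
    early_exaggeration: float = 4.0,
    exaggeration_iters: int = 100,
) -> Embedding2D:
    """Embed high-dimensional points in 2-D by classic t-SNE.

    Gaussian conditional affinities with bandwidths matched to the target
    perplexity are symmetrized and normalized into a joint distribution P;
    the embedding minimizes KL(P || Q) for Student-t affinities Q by
    gradient descent with momentum from a small random start.
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    if n < 3:
        raise ConfigurationError("t-SNE needs at least 3 points")
    if perplexity is None:
        perplexity = 30.0 if n >= 120 else max(2.0, n / 4)
    if perplexity >= n:
        raise ConfigurationError(
            f"perplexity {perplexity} must be below the number of points {n}"
        )
    D = _pairwise_sq(X)
    Pc = _conditional_p(D, perplexity)
    P = (Pc + Pc.T) / (2.0 * n)
    P = np.maximum(P, 0.0)
    P /= P.sum()

    rng = np.random.default_rng(seed)
    Y = 1e-4 * rng.standard_normal((n, 2))
    velocity = np.zeros_like(Y)
    history = []
    for it in range(iterations):
        boost = early_exaggeration if it < exaggeration_iters else 1.0
        C, grad = _kl_cost_and_grad(P * boost, Y)
        momentum = 0.5 if it < 250 else 0.8
        velocity = momentum * velocity - learning_rate * grad
        Y = Y + velocity
        Y = Y - Y.mean(axis=0)
        history.append(C)
    C_final, _ = _kl_cost_and_grad(P, Y)
    history.append(C_final)
    return Embedding2D(coords=Y, kl=C_final, cost_history=np.asarray(history))


# ---------------------------------------------------------------------------
# correlation and PRCC
# ---------------------------------------------------------------------------


def correlation_coefficient(x, y) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("x and y must be equal-length 1-D, n >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx**2).sum() * (dy**2).sum())
    if den == 0:
        raise ConfigurationError("correlation undefined for a constant vector")
    return float(np.clip((dx * dy).sum() / den, -1.0, 1.0))


@dataclass
class PrccResult:
    coefficients: dict[str, float]
    n: int

    def __getitem__(self, name: str) -> float:
        return self.coefficients[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.coefficients),
                "prcc": list(self.coefficients.values()),
                "N": self.n,
            }
        )


def prcc(X, y, names: Optional[Sequence[str]] = None) -> PrccResult:
    """Partial rank correlation of each input column against the output.

    All columns are rank-transformed (average ranks on ties).  For input
    j, both rank(x_j) and rank(y) are regressed on the remaining rank
    inputs (with intercept) and the Pearson correlation of the two
    residual vectors is the PRCC.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ConfigurationError(f"need more than {p + 2} samples, got {n}")
    constant = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0]
    if np.ptp(y) == 0:
        constant.append("y")
    if constant:
        raise ConfigurationError(f"constant columns: {', '.join(constant)}")

    Rx = np.column_stack([rankdata(X[:, j]) for j in range(p)])
    Ry = rankdata(y)
    coeffs = {}
    for j in range(p):
        others = np.delete(Rx, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = [names[q] for q in range(p) if q != j]
            raise ConfigurationError(
                f"singular regression among rank inputs: {', '.join(bad)}"
            )
        bx, *_ = np.linalg.lstsq(design, Rx[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(design, Ry, rcond=None)
        res_x = Rx[:, j] - design @ bx
        res_y = Ry - design @ by
        coeffs[names[j]] = correlation_coefficient(res_x, res_y)
    return PrccResult(coefficients=coeffs, n=n)


def prcc_by_delta(
    runs: pd.DataFrame,
    prob_cols: Sequence[str] = ("P1", "P2", "P3", "P4"),
    value_col: str = "E",
) -> pd.DataFrame:
    """PRCC of each branch probability against E, stratified by loop position."""
    rows = []
    for delta, sub in runs.groupby("delta"):
        res = prcc(sub[list(prob_cols)], sub[value_col].to_numpy())
        for var, coef in res.coefficients.items():
            rows.append(
                {"delta": delta, "variable": var, "prcc": coef, "N": res.n}
            )
    return pd.DataFrame(rows)
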