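"""Nonlinear principal component analysis by optimal scaling.

Each variable is replaced by a monotone non-decreasing quadratic B-spline
transformation of itself (ordinal scaling level) chosen, together with a
low-rank component model, to minimize the Gifi least-squares loss

    L(Z, A, X) = || Z - X A^T ||_F^2,

where ``Z`` holds the transformed (quantified) variables, each centered
and scaled to norm sqrt(n), ``X`` the subject scores and ``A`` the
component loadings.  Alternating least squares iterates two exact
minimizations: (a) the model step updates the rank-r approximation of
``Z`` by singular value decomposition; (b) the optimal-scaling step
projects each variable's model reconstruction onto the convex cone of
centered monotone splines of the raw variable (a non-negative-increment
B-spline coefficient fit solved by NNLS) and rescales to norm sqrt(n),
which is the exact minimizer over the cone intersected with the sphere.
Both steps lower the same loss, so the recorded loss trace is
monotonically non-increasing; when all relations are linear, the solution
coincides with linear PCA on the standardized data.

Spline defaults follow the ordinal variant used in movement phenotyping:
degree 2 with 3 interior knots placed at the quartiles of each variable.
Ties in a variable map to identical transformed values by construction,
and transformations are initialized at the z-scored raw data so the fit is
deterministic.

Loadings are standardized (interpretable as the correlation between each
quantified variable and a component, so |loading| <= 1); the variance
accounted for by component k is its eigenvalue share lambda_k / p on the
quantified data.  Each component's sign is fixed so its largest-magnitude
loading is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .errors import InvalidArgumentError, InvalidDataError


@dataclass(frozen=True)
class NLPCAConfig:
    """Settings of the optimal-scaling PCA fit."""

    n_components: int = 3
    scaling: str = "ordinal-monotone"
    spline_degree: int = 2
    n_interior_knots: int = 3       # placed at quantiles (quartiles by default)
    max_iterations: int = 100
    convergence_tol: float = 1e-7   # absolute change of the normalized loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spline_degree < 1:
            raise InvalidArgumentError("spline_degree must be >= 1")
        if self.n_interior_knots < 0:
            raise InvalidArgumentError("n_interior_knots must be >= 0")
        if self.convergence_tol <= 0:
            raise InvalidArgumentError("convergence_tol must be > 0")
        if self.scaling != "ordinal-monotone":
            raise InvalidArgumentError(f"unsupported scaling level {self.scaling!r}")


@dataclass
class MonotoneSpline:
    """A fitted monotone transformation of one variable.

    ``z = scale * ((G(x_clamped) - centers) @ deltas)`` where ``G`` is the
    cumulative B-spline design (columns are reverse-cumulative sums of the
    basis, so non-negative ``deltas`` make the spline non-decreasing).
    """

    knots: np.ndarray         # full knot vector
    degree: int
    deltas: np.ndarray        # (n_basis - 1,) non-negative increments
    centers: np.ndarray       # column means of G on the fit data
    scale: float
    x_range: tuple[float, float]
    linear_fallback: tuple[float, float] | None = None   # (mean, sd) if degenerate

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.linear_fallback is not None:
            mu, sd = self.linear_fallback
            return (x - mu) / sd
        G = _cumulative_design(np.clip(x, *self.x_range), self.knots, self.degree)
        return self.scale * ((G - self.centers) @ self.deltas)


@dataclass
class NLPCASolution:
    """Loadings, scores, quantified data and fit diagnostics."""

    transformed_data: np.ndarray       # (n, p), columns centered, norm sqrt(n)
    loadings: np.ndarray               # (p, r), standardized
    scores: np.ndarray                 # (n, r), columns orthogonal
    vaf: np.ndarray                    # (r,), variance accounted for, in [0, 1]
    eigenvalues: np.ndarray            # all min(n, p) eigenvalues of Z'Z / n
    loss_trace: np.ndarray
    transformations: list[MonotoneSpline]
    converged: bool
    config: NLPCAConfig
    feature_names: list[str] = field(default_factory=list)
    _projection: np.ndarray | None = None   # (p, r): scores = Z @ projection

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _knot_vector(x: np.ndarray, degree: int, n_interior: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_interior > 0:
        qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = [q for q in np.unique(qs) if lo < q < hi]
    else:
        interior = []
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _cumulative_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    B = BSpline.design_matrix(x, knots, degree).toarray()
    # Column j of G sums basis functions j..end; with delta >= 0 the spline
    # coefficients are non-decreasing, hence the spline is non-decreasing.
    return np.cumsum(B[:, ::-1], axis=1)[:, ::-1][:, 1:]


def _extract_matrix(table) -> tuple[np.ndarray, list[str]]:
    if hasattr(table, "features"):          # FeatureTable
        df = table.features
        return df.to_numpy(dtype=float), list(df.columns)
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    arr = np.asarray(table, dtype=float)
    return arr, [f"v{j}" for j in range(arr.shape[1])]


def fit_nlpca(table, config: NLPCAConfig | None = None) -> NLPCASolution:
    """Fit the ordinal optimal-scaling PCA.

    ``table`` may be a :class:`~stsbiomech.features.FeatureTable`, a
    DataFrame, or a plain (subjects x variables) array.  Deterministic
    given the config; non-convergence is reported via
    ``solution.converged`` rather than raised.
    """
    config = config or NLPCAConfig()
    X, names = _extract_matrix(table)
    n, p = X.shape
    if n < 2:
        raise InvalidDataError("at least two subjects are required")
    if not np.all(np.isfinite(X)):
        raise InvalidDataError("input contains missing or non-finite values")
    sds = X.std(axis=0)
    constant = [names[j] for j in np.flatnonzero(sds == 0)]
    if constant:
        raise InvalidDataError(f"constant columns cannot be scaled: {constant[:5]}")
    r = config.n_components
    if not 1 <= r < min(n, p) + 1:
        raise InvalidArgumentError(
            f"n_components must be in [1, min(subjects, variables)], got {r}"
        )

    # Per-variable cumulative spline designs (centered columns).
    designs: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    knot_vectors: list[np.ndarray] = []
    for j in range(p):
        kv = _knot_vector(X[:, j], config.spline_degree, config.n_interior_knots)
        G = _cumulative_design(X[:, j], kv, config.spline_degree)
        mu = G.mean(axis=0)
        designs.append(G - mu)
        centers.append(mu)
        knot_vectors.append(kv)

    sqrt_n = np.sqrt(n)
    Z = (X - X.mean(axis=0)) / sds * 1.0
    Z = Z / np.linalg.norm(Z, axis=0) * sqrt_n

    deltas: list[np.ndarray | None] = [None] * p
    scales = np.ones(p)
    loss_trace: list[float] = []
    converged = False
    U = S = Vt = None
    for _ in range(config.max_iterations):
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        Zhat = (U[:, :r] * S[:r]) @ Vt[:r]
        for j in range(p):
            delta, _ = nnls(designs[j], Zhat[:, j])
            zj = designs[j] @ delta
            norm = np.linalg.norm(zj)
            if norm > 1e-10:
                Z[:, j] = zj * (sqrt_n / norm)
                deltas[j] = delta
                scales[j] = sqrt_n / norm
        loss = float(np.sum((Z - Zhat) ** 2) / (n * p))
        loss_trace.append(loss)
        if len(loss_trace) > 1 and abs(loss_trace[-2] - loss_trace[-1]) < config.convergence_tol:
            converged = True
            break

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:r].T * S[:r] / sqrt_n
    scores = U[:, :r] * sqrt_n
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(r)])
    signs[signs == 0] = 1.0
    loadings *= signs
    scores *= signs
    with np.errstate(divide="ignore"):
        projection = sqrt_n * (Vt[:r].T / S[:r]) * signs

    transformations = []
    for j in range(p):
        if deltas[j] is None:
            transformations.append(MonotoneSpline(
                knots=knot_vectors[j], degree=config.spline_degree,
                deltas=np.zeros(designs[j].shape[1]), centers=centers[j], scale=1.0,
                x_range=(float(X[:, j].min()), float(X[:, j].max())),
                linear_fallback=(float(X[:, j].mean()), float(sds[j])),
            ))
        else:
            transformations.append(MonotoneSpline(
                knots=knot_vectors[j], degree=config.spline_degree,
                deltas=deltas[j], centers=centers[j], scale=float(scales[j]),
                x_range=(float(X[:, j].min()), float(X[:, j].max())),
            ))

    return NLPCASolution(
        transformed_data=Z,
        loadings=loadings,
        scores=scores,
        vaf=S[:r] ** 2 / (n * p),
        eigenvalues=S**2 / n,
        loss_trace=np.asarray(loss_trace),
        transformations=transformations,
        converged=converged,
        config=config,
        feature_names=names,
        _projection=projection,
    )


def transform(solution: NLPCASolution, table) -> np.ndarray:
    """Apply the stored monotone transformations to new raw data."""
    X, names = _extract_matrix(table)
    if solution.feature_names and names != solution.feature_names:
        if sorted(names) == sorted(solution.feature_names):
            order = [names.index(c) for c in solution.feature_names]
            X = X[:, order]
        else:
            raise InvalidDataError("columns do not match the fitted variables")
    if X.shape[1] != len(solution.transformations):
        raise InvalidDataError(
            f"expected {len(solution.transformations)} variables, got {X.shape[1]}"
        )
    return np.column_stack([tr(X[:, j]) for j, tr in enumerate(solution.transformations)])


def project(solution: NLPCASolution, table) -> np.ndarray:
    """Component scores for new data under the fitted transformations."""
    Z = transform(solution, table)
    return Z @ solution._projection


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def solution_to_json(solution: NLPCASolution, path: str | Path) -> None:
    payload = {
        "vaf": solution.vaf.tolist(),
        "eigenvalues": solution.eigenvalues.tolist(),
        "loadings": solution.loadings.tolist(),
        "feature_names": solution.feature_names,
        "loss_trace": solution.loss_trace.tolist(),
        "converged": solution.converged,
        "transformations": [
            {"knots": tr.knots.tolist(), "degree": tr.degree,
             "deltas": tr.deltas.tolist(), "centers": tr.centers.tolist(),
             "scale": tr.scale, "x_range": list(tr.x_range),
             "linear_fallback": tr.linear_fallback}
            for tr in solution.transformations
        ],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def scores_to_csv(solution: NLPCASolution, path: str | Path,
                  index: pd.Index | None = None) -> None:
    cols = [f"PC{k + 1}" for k in range(solution.n_components)]
    pd.DataFrame(solution.scores, columns=cols, index=index).to_csv(
        path, index=index is not None)
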