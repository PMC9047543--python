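"""Component retention and stability diagnostics.

Retention (:func:`permutation_retention`) uses a permD-style permutation
test: each permutation independently shuffles the rows of every column,
which destroys inter-variable structure while preserving marginals, the
optimal-scaling PCA is refit, and a component is deemed significant when
its observed variance-accounted-for exceeds the 95th percentile of its
permutation null.  The report also carries the Kaiser rule (eigenvalue of
the quantified-data correlation structure > 1), an acceleration-based
scree elbow (advisory), and the count of salient loadings (|loading| >=
0.5) per component.

Stability (:func:`bootstrap_stability`) follows the linear-PCA-on-
quantified-data approximation: balanced bootstrap resamples (every subject
appears exactly ``n_boot`` times across all replicates) of the stored
transformed data are re-decomposed by linear PCA; replicate components are
matched to the reference solution by maximal absolute Tucker congruence
(an assignment, so no two replicate components map to the same reference
component), sign-aligned, and compared by the RMS loading difference,
Tucker's congruence coefficient, and the Pearson correlation of loading
patterns, each summarized by its mean and non-parametric 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InvalidArgumentError
from .nlpca import NLPCAConfig, NLPCASolution, _extract_matrix, fit_nlpca


@dataclass
class RetentionReport:
    """Per-component retention diagnostics."""

    observed_vaf: np.ndarray          # (r,)
    null_mean: np.ndarray             # (r,)
    null_upper: np.ndarray            # (r,), (1 - alpha) percentile of the null
    significant: np.ndarray           # (r,) bool
    kaiser_eigenvalues: np.ndarray    # all eigenvalues of the quantified data
    n_salient_loadings: np.ndarray    # (r,), count of |loading| >= threshold
    loading_threshold: float
    n_permutations: int
    alpha: float
    n_failed: int = 0
    scree_elbow: int = 0              # advisory-only elbow position

    @property
    def n_significant_leading(self) -> int:
        """Length of the leading run of significant components."""
        k = 0
        for flag in self.significant:
            if not flag:
                break
            k += 1
        return k


@dataclass
class ComponentStability:
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class StabilityReport:
    """Bootstrap pattern-matching statistics per component."""

    rms_difference: list[ComponentStability]
    congruence: list[ComponentStability]
    pearson: list[ComponentStability]
    n_boot: int
    n_skipped: int = 0


def permutation_retention(
    table,
    config: NLPCAConfig | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    solution: NLPCASolution | None = None,
    loading_threshold: float = 0.5,
) -> RetentionReport:
    """permD-style permutation test of per-component VAF.

    ``solution`` may carry a pre-computed fit of ``table`` to avoid
    refitting the observed data; permutation fits always use ``config``.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    config = config or NLPCAConfig()
    X, _ = _extract_matrix(table)
    n, p = X.shape
    if solution is None:
        solution = fit_nlpca(X, config)
    r = solution.n_components

    rng = np.random.default_rng(seed)
    null_vaf = np.full((n_perm, r), np.nan)
    n_failed = 0
    for b in range(n_perm):
        perm = np.empty_like(X)
        for j in range(p):
            perm[:, j] = X[rng.permutation(n), j]
        try:
            null_vaf[b] = fit_nlpca(perm, config).vaf
        except Exception:
            n_failed += 1
    if n_failed > 0.01 * n_perm:
        warnings.warn(f"{n_failed}/{n_perm} permutation fits failed", RuntimeWarning)
    valid = null_vaf[~np.isnan(null_vaf).any(axis=1)]

    upper = np.quantile(valid, 1.0 - alpha, axis=0)
    eig = solution.eigenvalues
    second_diff = np.diff(eig, 2) if len(eig) >= 3 else np.array([0.0])
    scree_elbow = int(np.argmax(second_diff)) + 1 if len(eig) >= 3 else 1

    return RetentionReport(
        observed_vaf=solution.vaf.copy(),
        null_mean=valid.mean(axis=0),
        null_upper=upper,
        significant=solution.vaf > upper,
        kaiser_eigenvalues=eig.copy(),
        n_salient_loadings=(np.abs(solution.loadings) >= loading_threshold).sum(axis=0),
        loading_threshold=loading_threshold,
        n_permutations=n_perm,
        alpha=alpha,
        n_failed=n_failed,
        scree_elbow=scree_elbow,
    )


def balanced_bootstrap_indices(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n) index array where every subject appears exactly n_boot times."""
    pool = np.tile(np.arange(n), n_boot)
    rng.shuffle(pool)
    return pool.reshape(n_boot, n)


def _pca_loadings(Z: np.ndarray, r: int) -> np.ndarray | None:
    Zc = Z - Z.mean(axis=0)
    norms = np.linalg.norm(Zc, axis=0)
    if np.any(norms < 1e-12):
        return None
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    if np.sum(S > 1e-12) < r:
        return None
    return Vt[:r].T * S[:r] / np.sqrt(Z.shape[0])


def _congruence_matrix(ref: np.ndarray, rep: np.ndarray) -> np.ndarray:
    num = ref.T @ rep
    den = np.outer(np.linalg.norm(ref, axis=0), np.linalg.norm(rep, axis=0))
    return num / den


def bootstrap_stability(
    table=None,
    config: NLPCAConfig | None = None,
    n_boot: int = 300,
    n_components: int = 3,
    seed: int = 0,
    solution: NLPCASolution | None = None,
    indices: np.ndarray | None = None,
) -> StabilityReport:
    """Balanced-bootstrap stability of the leading loading patterns.

    Replicates decompose resamples of the solution's quantified data with
    linear PCA (the standard approximation for the ordinal solution).
    ``indices`` may inject explicit resamples (rows of subject indices),
    e.g. identity resamples for degenerate-case checks.
    """
    if solution is None:
        if table is None:
            raise InvalidArgumentError("either a table or a fitted solution is required")
        solution = fit_nlpca(table, config or NLPCAConfig(n_components=n_components))
    Z = solution.transformed_data
    n = Z.shape[0]
    r = min(n_components, solution.n_components)
    ref = solution.loadings[:, :r]

    if indices is None:
        if n_boot < 50:
            raise InvalidArgumentError("n_boot must be >= 50")
        rng = np.random.default_rng(seed)
        indices = balanced_bootstrap_indices(n, n_boot, rng)
    else:
        indices = np.atleast_2d(np.asarray(indices))
        n_boot = indices.shape[0]

    rms = np.full((n_boot, r), np.nan)
    congr = np.full((n_boot, r), np.nan)
    pears = np.full((n_boot, r), np.nan)
    n_skipped = 0
    for b in range(n_boot):
        rep = _pca_loadings(Z[indices[b]], r)
        if rep is None:
            n_skipped += 1
            continue
        phi = _congruence_matrix(ref, rep)
        row, col = linear_sum_assignment(-np.abs(phi))
        for i, j in zip(row, col):
            vec = rep[:, j] * np.sign(phi[i, j] if phi[i, j] != 0 else 1.0)
            a = ref[:, i]
            congr[b, i] = float(np.clip(
                a @ vec / (np.linalg.norm(a) * np.linalg.norm(vec)), -1.0, 1.0))
            rms[b, i] = float(np.sqrt(np.mean((a - vec) ** 2)))
            ac, vc = a - a.mean(), vec - vec.mean()
            pears[b, i] = float(np.clip(
                ac @ vc / (np.linalg.norm(ac) * np.linalg.norm(vc)), -1.0, 1.0))

    def summarize(arr: np.ndarray) -> list[ComponentStability]:
        out = []
        for i in range(r):
            col = arr[:, i]
            col = col[~np.isnan(col)]
            out.append(ComponentStability(
                mean=float(col.mean()),
                ci_low=float(np.quantile(col, 0.025)),
                ci_high=float(np.quantile(col, 0.975)),
            ))
        return out

    return StabilityReport(
        rms_difference=summarize(rms),
        congruence=summarize(congr),
        pearson=summarize(pears),
        n_boot=n_boot,
        n_skipped=n_skipped,
    )


@dataclass(frozen=True)
class RetentionRules:
    """Which retention rules participate in the final component count."""

    use_permutation: bool = True
    use_kaiser: bool = True
    use_loading_count: bool = True
    min_salient_loadings: int = 1
    use_scree: bool = False      # advisory by default


def select_components(report: RetentionReport, rules: RetentionRules | None = None) -> int:
    """Conservative (smallest) component count satisfying the enabled rules.

    The permutation rule counts the leading run of significant components;
    Kaiser counts eigenvalues above 1; the loading-count rule counts the
    leading components with at least ``min_salient_loadings`` salient
    loadings.  The scree elbow participates only when enabled.
    """
    rules = rules or RetentionRules()
    counts: list[int] = []
    if rules.use_permutation:
        counts.append(report.n_significant_leading)
    if rules.use_kaiser:
        counts.append(int(np.sum(report.kaiser_eigenvalues > 1.0)))
    if rules.use_loading_count:
        k = 0
        for c in report.n_salient_loadings:
            if c < rules.min_salient_loadings:
                break
            k += 1
        counts.append(k)
    if rules.use_scree:
        counts.append(report.scree_elbow)
    if not counts:
        raise InvalidArgumentError("at least one retention rule must be enabled")
    return max(0, min(counts))
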