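"""Reference-free methylome deconvolution by constrained matrix factorization.

The window-level beta matrix D (windows x samples) is modelled as a convex
mixture of K latent methylation components (LMCs):

    minimize  ||D - T A||_F^2  +  lambda * sum_ij T_ij (1 - T_ij)
    subject to  T in [0, 1]^(W x K),  A >= 0,  columns of A on the simplex

The quadratic binarization penalty pushes component methylomes toward the
biologically expected near-binary beta values; lambda = 0 reduces to plain
constrained least squares. Optimization is alternating minimization: the
A-step solves, per sample, a simplex-constrained least-squares problem by
monotone projected gradient; the T-step minimizes each entry's quadratic
coordinate objective exactly (closed form, clipped to [0, 1]). Both steps
decrease the objective, so the trace is non-increasing by construction.

Multiple seeded random restarts guard against local minima; the best final
objective wins. Model selection couples sample-fold cross-validation with
a restart-stability score (mean matched-component correlation across the
random initializations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MethylomeDeconvolution",
    "DeconvolutionModel",
    "ModelSelectionGrid",
    "ComponentMatch",
    "factorize",
    "fit_proportions",
    "cross_validate",
    "match_components",
]


# ---------------------------------------------------------------------------
# numerical core (D is windows x samples, T windows x K, A K x samples)
# ---------------------------------------------------------------------------

def _project_simplex_columns(a: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    k, n = a.shape
    u = -np.sort(-a, axis=0)  # descending per column
    css = np.cumsum(u, axis=0) - 1.0
    ind = np.arange(1, k + 1)[:, None]
    cond = u - css / ind > 0
    rho = k - 1 - np.argmax(cond[::-1], axis=0)  # last True index per column
    theta = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(a - theta[None, :], 0.0)


def _objective(d: np.ndarray, t: np.ndarray, a: np.ndarray, lam: float) -> float:
    r = d - t @ a
    return float(np.sum(r * r) + lam * np.sum(t * (1.0 - t)))


def fit_proportions(
    t: np.ndarray,
    d: np.ndarray,
    a_init: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Simplex-constrained least-squares proportions for fixed components.

    Solves ``min_A ||D - T A||_F^2`` with simplex columns by projected
    gradient with the Lipschitz step 1/L, L = 2 * lambda_max(T'T); each
    step is a guaranteed descent on every column's convex subproblem.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    w, k = t.shape
    n = d.shape[1]
    gram = t.T @ t
    td = t.T @ d
    lip = 2.0 * max(np.linalg.eigvalsh(gram).max(), 1e-12)
    a = (
        np.full((k, n), 1.0 / k)
        if a_init is None
        else _project_simplex_columns(np.asarray(a_init, dtype=float).copy())
    )
    step = 1.0 / lip
    for _ in range(max_iter):
        grad = 2.0 * (gram @ a - td)
        a_new = _project_simplex_columns(a - step * grad)
        delta = np.abs(a_new - a).max()
        a = a_new
        if delta < tol:
            break
    return a


def _update_components(
    d: np.ndarray, t: np.ndarray, a: np.ndarray, lam: float, n_sweeps: int = 1
) -> np.ndarray:
    """Exact per-entry coordinate minimization of the T objective.

    For entry T_wk with everything else fixed the objective is the quadratic
    (c2 - lam) t^2 - (2 c1 - lam) t + const with c2 = sum_s A_ks^2 and c1 the
    residual correlation; it is minimized in closed form on [0, 1] (interior
    stationary point when convex, otherwise the better endpoint — ties go
    to 0).
    """
    t = t.copy()
    r = d - t @ a
    for _ in range(n_sweeps):
        for k in range(t.shape[1]):
            ak = a[k]
            c2 = float(ak @ ak)
            c1 = r @ ak + c2 * t[:, k]
            quad = c2 - lam
            lin = 2.0 * c1 - lam
            if quad > 0:
                t_new = np.clip(lin / (2.0 * quad), 0.0, 1.0)
            else:
                # concave/linear coordinate objective: best endpoint
                f1 = quad - lin  # f(1) - f(0)
                t_new = np.where(f1 < 0, 1.0, 0.0)
            r -= np.outer(t_new - t[:, k], ak)
            t[:, k] = t_new
    return t


def _single_fit(
    d: np.ndarray,
    k: int,
    lam: float,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
    inner_max_iter: int,
    callback=None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    w, n = d.shape
    t = rng.random((w, k))
    a = rng.dirichlet(np.ones(k), size=n).T
    trace = [_objective(d, t, a, lam)]
    # Monotone extrapolation: after each pair of block updates, try a
    # momentum step (clipped/projected back to the feasible set) and accept
    # it only if it lowers the objective; otherwise shrink the momentum.
    # Keeps the trace non-increasing while much accelerating the tail.
    beta = 0.5
    t_prev, a_prev = t, a
    for it in range(max_iter):
        a1 = fit_proportions(t, d, a_init=a, max_iter=inner_max_iter)
        t1 = _update_components(d, t, a1, lam)
        obj1 = _objective(d, t1, a1, lam)
        t_ex = np.clip(t1 + beta * (t1 - t_prev), 0.0, 1.0)
        a_ex = _project_simplex_columns(a1 + beta * (a1 - a_prev))
        obj_ex = _objective(d, t_ex, a_ex, lam)
        t_prev, a_prev = t1, a1
        if obj_ex < obj1:
            t, a, obj = t_ex, a_ex, obj_ex
            beta = min(1.0, beta * 1.2)
        else:
            t, a, obj = t1, a1, obj1
            beta = max(0.1, beta * 0.5)
        trace.append(obj)
        if callback is not None:
            callback(it, t, a, obj)
        prev = trace[-2]
        if prev - obj <= tol * max(prev, 1e-30):
            break
    return t, a, trace


class MethylomeDeconvolution(TransformerMixin, BaseEstimator):
    """Constrained NMF of methylomes into latent components with proportions.

    Follows the scikit-learn decomposition convention: ``X`` is
    (n_samples, n_windows); ``components_`` is (k, n_windows) with entries
    in [0, 1]; ``transform`` returns simplex mixture proportions
    (n_samples, k).

    Parameters
    ----------
    n_components : number of latent methylation components K.
    lam : weight of the T(1-T) binarization penalty (lambda >= 0).
    max_iter : maximum alternating iterations per restart.
    n_init : number of seeded random restarts; the best final objective wins.
    tol : relative objective-decrease stopping threshold.
    inner_max_iter : projected-gradient steps per A-step.
    random_state : int seed (spawns one substream per restart) or None.
    keep_inits : retain every restart's components (for stability scoring).

    Attributes
    ----------
    components_ : (k, n_windows) component methylomes in [0, 1].
    proportions_ : (n_samples, k) simplex rows for the training samples.
    objective_trace_ : per-iteration objective of the winning restart.
    best_init_index_, init_objectives_, init_components_ (if kept),
    reconstruction_err_ : squared Frobenius residual of the fit.
    """

    def __init__(
        self,
        n_components: int = 9,
        lam: float = 0.01,
        max_iter: int = 300,
        n_init: int = 10,
        tol: float = 1e-6,
        inner_max_iter: int = 100,
        random_state=None,
        keep_inits: bool = False,
    ):
        self.n_components = n_components
        self.lam = lam
        self.max_iter = max_iter
        self.n_init = n_init
        self.tol = tol
        self.inner_max_iter = inner_max_iter
        self.random_state = random_state
        self.keep_inits = keep_inits

    def _validate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x windows)")
        if not np.all(np.isfinite(x)):
            raise ValueError("X contains non-finite values; betas must be complete")
        if not (1 <= self.n_components <= min(x.shape)):
            raise ValueError(
                f"n_components={self.n_components} must lie in [1, min(n_samples, n_windows)={min(x.shape)}]"
            )
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        return x

    def fit(self, X, y=None, callback=None):
        x = self._validate(X)
        d = x.T  # windows x samples
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_init)
        best = None
        init_objs, init_components = [], []
        for i, ss in enumerate(seeds):
            t, a, trace = _single_fit(
                d,
                self.n_components,
                self.lam,
                self.max_iter,
                self.tol,
                np.random.default_rng(ss),
                self.inner_max_iter,
                callback=callback,
            )
            init_objs.append(trace[-1])
            if self.keep_inits:
                init_components.append(t.T)
            if best is None or trace[-1] < best[3][-1]:
                best = (i, t, a, trace)
        idx, t, a, trace = best
        # polish proportions at the winning restart
        a = fit_proportions(t, d, a_init=a)
        self.components_ = t.T
        self.proportions_ = a.T
        self.objective_trace_ = np.asarray(trace)
        self.best_init_index_ = idx
        self.init_objectives_ = np.asarray(init_objs)
        if self.keep_inits:
            self.init_components_ = init_components
        self.reconstruction_err_ = float(np.sum((d - t @ a) ** 2))
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Simplex least-squares proportions for (possibly new) samples."""
        x = np.asarray(X, dtype=float)
        if x.shape[1] != self.components_.shape[1]:
            raise ValueError("X has a different number of windows than the fit")
        return fit_proportions(self.components_.T, x.T).T

    def inverse_transform(self, A) -> np.ndarray:
        return np.asarray(A, dtype=float) @ self.components_

    def score(self, X, y=None) -> float:
        """Negative mean squared reconstruction error (higher is better)."""
        x = np.asarray(X, dtype=float)
        a = self.transform(x)
        return -float(np.mean((x - a @ self.components_) ** 2))


# ---------------------------------------------------------------------------
# result containers and functional wrappers (matrix convention: D = T A)
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionModel:
    """Fitted factorization in the windows-x-samples convention."""

    t: pd.DataFrame  # windows x K
    a: pd.DataFrame  # K x samples
    k: int
    lam: float
    objective_trace: np.ndarray
    n_init: int
    seed: object
    best_init_index: int

    @property
    def component_names(self) -> list[str]:
        return list(self.t.columns)


def _as_window_frame(d) -> pd.DataFrame:
    if hasattr(d, "beta"):  # WindowMatrix
        return d.beta
    if isinstance(d, pd.DataFrame):
        return d
    arr = np.asarray(d, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"w{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def factorize(
    d,
    k: int,
    lam: float = 0.01,
    max_iter: int = 300,
    n_init: int = 10,
    tol: float = 1e-6,
    seed=None,
) -> DeconvolutionModel:
    """Factorize a window matrix (windows x samples) into K components.

    Thin wrapper over :class:`MethylomeDeconvolution` keeping the
    windows-as-rows orientation used throughout the pipeline.
    """
    frame = _as_window_frame(d)
    est = MethylomeDeconvolution(
        n_components=k,
        lam=lam,
        max_iter=max_iter,
        n_init=n_init,
        tol=tol,
        random_state=seed,
    ).fit(frame.to_numpy(dtype=float).T)
    comp_names = [f"LMC{i + 1}" for i in range(k)]
    return DeconvolutionModel(
        t=pd.DataFrame(est.components_.T, index=frame.index, columns=comp_names),
        a=pd.DataFrame(est.proportions_.T, index=comp_names, columns=frame.columns),
        k=k,
        lam=lam,
        objective_trace=est.objective_trace_,
        n_init=n_init,
        seed=seed,
        best_init_index=est.best_init_index_,
    )


@dataclass
class ModelSelectionGrid:
    """Cross-validation error and restart stability over a (K, lambda) grid."""

    cv_error: pd.DataFrame  # index = k values, columns = lambda values
    stability: pd.DataFrame
    n_folds: int
    k_values: list = field(default_factory=list)
    lambda_values: list = field(default_factory=list)
    fold_assignment: list = field(default_factory=list)  # per-fold sample indices


def _stability_score(components: list[np.ndarray], best_idx: int) -> float:
    """Mean best-matched component correlation of each restart vs the winner."""
    ref = components[best_idx]
    scores = []
    for i, comp in enumerate(components):
        if i == best_idx:
            continue
        match = match_components(ref.T, comp.T)
        if match.pairs:
            scores.append(float(np.mean([s for _, _, s in match.pairs])))
    return float(np.mean(scores)) if scores else 1.0


def cross_validate(
    d,
    k_values,
    lambda_values,
    n_folds: int = 10,
    seed=None,
    n_init: int = 5,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ModelSelectionGrid:
    """Sample-fold CV error and restart stability over a (K, lambda) grid.

    Samples (columns of D) are partitioned into ``n_folds`` folds. Per
    fold, T is fit on the training samples; held-out proportions are then
    the simplex least-squares fit with T fixed, and the fold error is the
    mean squared reconstruction error on the held-out columns. Stability
    is the mean matched-component correlation of the restarts against the
    winning restart of a full-data fit.
    """
    frame = _as_window_frame(d)
    x = frame.to_numpy(dtype=float)
    n = x.shape[1]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    k_values = list(k_values)
    lambda_values = list(lambda_values)
    ss = np.random.SeedSequence(seed)
    fold_rng = np.random.default_rng(ss.spawn(1)[0])
    perm = fold_rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    cv = pd.DataFrame(index=k_values, columns=lambda_values, dtype=float)
    stab = pd.DataFrame(index=k_values, columns=lambda_values, dtype=float)
    cell_seeds = ss.spawn(len(k_values) * len(lambda_values))
    cell = 0
    for k in k_values:
        for lam in lambda_values:
            cseed = cell_seeds[cell]
            cell += 1
            fold_seeds = cseed.spawn(n_folds + 1)
            errors = []
            for f, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(perm, test_idx)
                est = MethylomeDeconvolution(
                    n_components=k,
                    lam=lam,
                    max_iter=max_iter,
                    n_init=n_init,
                    tol=tol,
                    random_state=fold_seeds[f].generate_state(1)[0] % (2**31),
                ).fit(x[:, train_idx].T)
                t = est.components_.T
                a_test = fit_proportions(t, x[:, test_idx])
                errors.append(float(np.mean((x[:, test_idx] - t @ a_test) ** 2)))
            cv.loc[k, lam] = float(np.mean(errors))
            full = MethylomeDeconvolution(
                n_components=k,
                lam=lam,
                max_iter=max_iter,
                n_init=n_init,
                tol=tol,
                random_state=fold_seeds[-1].generate_state(1)[0] % (2**31),
                keep_inits=True,
            ).fit(x.T)
            stab.loc[k, lam] = _stability_score(
                full.init_components_, full.best_init_index_
            )
    return ModelSelectionGrid(
        cv_error=cv,
        stability=stab,
        n_folds=n_folds,
        k_values=k_values,
        lambda_values=lambda_values,
        fold_assignment=[np.sort(f) for f in folds],
    )


@dataclass
class ComponentMatch:
    """One-to-one component pairing by correlation over shared windows."""

    pairs: list  # (component_i, component_j, pearson_r)
    distance_matrix: np.ndarray  # (K1 x K2) of 1 - r
    dendrogram_order: list  # complete-linkage leaf order over pooled components
    excluded: list  # zero-variance components, as ("a"|"b", index)


def match_components(t_a, t_b, shared_windows=None) -> ComponentMatch:
    """Match components of two models by minimum total (1 - Pearson r).

    ``t_a`` and ``t_b`` are windows x K matrices (DataFrames are aligned on
    ``shared_windows`` or their index intersection). Zero-variance
    components over the shared windows have undefined correlations; they
    are flagged and excluded from the pairing. Also emits a
    complete-linkage dendrogram leaf ordering over the pooled components
    using correlation distance.
    """
    if isinstance(t_a, pd.DataFrame) and isinstance(t_b, pd.DataFrame):
        shared = (
            pd.Index(shared_windows)
            if shared_windows is not None
            else t_a.index.intersection(t_b.index)
        )
        ta = t_a.loc[shared].to_numpy(dtype=float)
        tb = t_b.loc[shared].to_numpy(dtype=float)
    else:
        ta = np.asarray(t_a, dtype=float)
        tb = np.asarray(t_b, dtype=float)
        if shared_windows is not None:
            ta = ta[np.asarray(shared_windows)]
            tb = tb[np.asarray(shared_windows)]
    if ta.shape[0] < 3:
        raise ValueError("need at least 3 shared windows to correlate components")

    sd_a = ta.std(axis=0)
    sd_b = tb.std(axis=0)
    ok_a = np.flatnonzero(sd_a > 0)
    ok_b = np.flatnonzero(sd_b > 0)
    excluded = [("a", int(i)) for i in np.flatnonzero(sd_a == 0)] + [
        ("b", int(j)) for j in np.flatnonzero(sd_b == 0)
    ]
    za = (ta - ta.mean(axis=0)) / np.where(sd_a > 0, sd_a, 1.0)
    zb = (tb - tb.mean(axis=0)) / np.where(sd_b > 0, sd_b, 1.0)
    corr = (za.T @ zb) / ta.shape[0]
    dist = 1.0 - corr

    sub = dist[np.ix_(ok_a, ok_b)]
    pairs = []
    if sub.size:
        ri, ci = linear_sum_assignment(sub)
        pairs = [
            (int(ok_a[i]), int(ok_b[j]), float(corr[ok_a[i], ok_b[j]]))
            for i, j in zip(ri, ci)
        ]

    pooled = np.concatenate([ta, tb], axis=1)
    psd = pooled.std(axis=0)
    zp = (pooled - pooled.mean(axis=0)) / np.where(psd > 0, psd, 1.0)
    pooled_corr = np.clip((zp.T @ zp) / pooled.shape[0], -1.0, 1.0)
    pooled_dist = 1.0 - pooled_corr
    if pooled.shape[1] > 1:
        condensed = pooled_dist[np.triu_indices(pooled.shape[1], k=1)]
        order = [int(i) for i in leaves_list(linkage(condensed, method="complete"))]
    else:
        order = [0]
    return ComponentMatch(
        pairs=pairs,
        distance_matrix=dist,
        dendrogram_order=order,
        excluded=excluded,
    )
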