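"""Trimmed Gaussian fitting and automatic trimming-level selection.

The classifier fits a single multivariate Gaussian while discarding
(trimming) a fraction alpha of the least-plausible observations — trimmed
clustering with one cluster.  Estimation uses the concentration step
(C-step): score all points under the current (mu, sigma), retain the
n - floor(n * alpha) densest, re-estimate moments on the retained set, and
repeat until the retained set is stable.  Each C-step can only increase the
trimmed log-likelihood, so every start converges; the best of several starts
is kept (the first start is always the deterministic full-sample moment
estimate, so single-start runs need no seed).

The trimming level is chosen from the classification trimmed likelihood
(CTL) curve: the per-retained-point trimmed log-likelihood as a function of
alpha.  With contamination fraction f, the curve climbs steeply while
outliers are still being absorbed (alpha < f) and flattens once they are all
trimmed; the first point of sustained flatness is the selected alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: relative ridge added to the scatter estimate (coverage bins are strongly
#: correlated, so conditioning must be controlled even with one cluster).
SCATTER_RIDGE = 1e-6
#: absolute floor on scatter eigenvalues.
EIGENVALUE_FLOOR = 1e-12

DEFAULT_N_STARTS = 20
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-8
DEFAULT_FLATNESS_TOL = 0.02


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


@dataclass
class TrimmedFitResult:
    alpha: float
    mu: np.ndarray
    sigma: np.ndarray
    retained: np.ndarray  # sorted index array, size n - floor(n*alpha)
    trimmed: np.ndarray  # complementary sorted index array
    objective: float  # trimmed log-likelihood over retained points
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    @property
    def mean_objective(self) -> float:
        return self.objective / len(self.retained)


@dataclass
class CTLCurve:
    alphas: np.ndarray
    objectives: np.ndarray
    mean_objectives: np.ndarray
    n_trimmed: np.ndarray
    fits: list[TrimmedFitResult]
    selected_alpha: float | None = None
    selection_mode: str = "auto"
    low_confidence: bool = False


def _regularize(sigma: np.ndarray) -> np.ndarray:
    d = sigma.shape[0]
    tr = np.trace(sigma)
    sigma = sigma + (SCATTER_RIDGE * max(tr, 0.0) / d) * np.eye(d)
    # enforce the absolute eigenvalue floor
    w, v = np.linalg.eigh(sigma)
    if w[0] < EIGENVALUE_FLOOR:
        w = np.maximum(w, EIGENVALUE_FLOOR)
        sigma = (v * w) @ v.T
    return sigma


def _log_density(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Gaussian log-density of each row of X under (mu, sigma)."""
    d = X.shape[1]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "covariance is singular even after regularization; "
            "increase the ridge or reduce dimensionality"
        ) from exc
    diff = X - mu
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    diff = X - mu
    sigma = (diff.T @ diff) / X.shape[0]
    return mu, _regularize(sigma)


def fit_objective(X: np.ndarray, retained: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Trimmed log-likelihood of a given retained index set (moments refit on it)."""
    mu, sigma = _moments(X[retained])
    return float(_log_density(X[retained], mu, sigma).sum()), mu, sigma


def _one_start(
    X: np.ndarray,
    h: int,
    mu: np.ndarray,
    sigma: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = X.shape[0]
    retained_prev: np.ndarray | None = None
    objective_prev = -np.inf
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        logdens = _log_density(X, mu, sigma)
        # retain the h densest points (ties broken by index for determinism)
        order = np.argsort(-logdens, kind="stable")
        retained = np.sort(order[:h])
        mu, sigma = _moments(X[retained])
        objective = float(_log_density(X[retained], mu, sigma).sum())
        trace.append(objective)
        if objective < objective_prev - 1e-7 * max(1.0, abs(objective_prev)):
            logger.warning(
                "C-step objective decreased (%.12g -> %.12g); regularization artifact",
                objective_prev, objective,
            )
        if retained_prev is not None and np.array_equal(retained, retained_prev):
            converged = True
            break
        if abs(objective - objective_prev) <= tol * max(1.0, abs(objective)):
            converged = True
            retained_prev = retained
            break
        retained_prev = retained
        objective_prev = objective
    return retained, mu, sigma, trace[-1], iterations, converged, trace


def trimmed_fit(
    X: np.ndarray,
    alpha: float,
    n_starts: int = DEFAULT_N_STARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrimmedFitResult:
    """Fit one trimmed Gaussian at trimming level ``alpha``.

    Exactly floor(n * alpha) points are trimmed.  Start 1 is the
    deterministic full-sample moment estimate; the remaining starts draw
    d + 1 random observations each (elemental starts).  ``warm_start``
    optionally supplies an extra (mu, sigma) start, used by
    :func:`ctl_curve` to chain fits across the alpha grid.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, d = X.shape
    if not 0.0 <= alpha <= 0.5:
        raise ValueError(f"alpha must be in [0, 0.5], got {alpha}")
    n_trim = int(np.floor(n * alpha))
    h = n - n_trim
    if h < d + 1:
        raise ValueError(
            f"retained set of size {h} cannot estimate a {d}-D scatter "
            f"(need at least {d + 1} retained points)"
        )
    rng = np.random.default_rng(seed)

    starts: list[tuple[np.ndarray, np.ndarray]] = [_moments(X)]
    if h < n:
        # robust deterministic start: moments of the h points nearest the
        # coordinate-wise median (MAD-scaled), immune to far contamination
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        dist = np.linalg.norm((X - med) / np.maximum(mad, 1e-9), axis=1)
        core = np.argsort(dist, kind="stable")[:h]
        starts.append(_moments(X[core]))
    if warm_start is not None:
        starts.append((np.asarray(warm_start[0]), _regularize(np.asarray(warm_start[1]))))
    for _ in range(max(0, n_starts - 1)):
        pick = rng.choice(n, size=min(n, d + 1), replace=False)
        starts.append(_moments(X[pick]))

    best = None
    for mu0, sigma0 in starts:
        retained, mu, sigma, objective, iterations, converged, trace = _one_start(
            X, h, mu0, sigma0, max_iter, tol
        )
        if best is None or objective > best[3] + 1e-12:
            best = (retained, mu, sigma, objective, iterations, converged, trace)

    retained, mu, sigma, objective, iterations, converged, trace = best
    trimmed = np.setdiff1d(np.arange(n), retained, assume_unique=False)
    return TrimmedFitResult(
        alpha=float(alpha),
        mu=mu,
        sigma=sigma,
        retained=retained,
        trimmed=trimmed,
        objective=objective,
        iterations=iterations,
        converged=converged,
        objective_trace=trace,
    )


def default_alpha_grid() -> np.ndarray:
    """Default trimming-level grid: 0.01 to 0.45 in steps of 0.01."""
    return np.round(np.arange(1, 46) * 0.01, 2)


def ctl_curve(
    X: np.ndarray,
    alpha_grid: np.ndarray | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> CTLCurve:
    """Sweep the alpha grid, fitting one trimmed Gaussian per level.

    Every alpha uses the same seed policy, so the curve is reproducible.  In
    addition to the configured starts, each fit is warm-started from the
    previous (smaller-alpha) solution; trimming further from an already-good
    solution can only raise the per-point likelihood, which keeps
    ``mean_objectives`` non-decreasing along the grid.
    """
    X = np.asarray(X, dtype=float)
    grid = default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid, dtype=float)
    if grid.size < 5:
        raise ValueError(f"alpha grid needs at least 5 values, got {grid.size}")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("alpha grid must be strictly ascending")
    if grid[0] < 0 or grid[-1] > 0.5:
        raise ValueError("alpha grid must lie within [0, 0.5]")

    fits: list[TrimmedFitResult] = []
    warm: tuple[np.ndarray, np.ndarray] | None = None
    for alpha in grid:
        try:
            fit = trimmed_fit(
                X, float(alpha), n_starts=n_starts, max_iter=max_iter,
                tol=tol, seed=seed, warm_start=warm,
            )
        except Exception as exc:
            raise RuntimeError(f"trimmed fit failed at alpha={alpha}: {exc}") from exc
        fits.append(fit)
        warm = (fit.mu, fit.sigma)

    # propagate good solutions across the grid: alternate backward/forward
    # warm-start-only sweeps until no fit improves, so a solution found at one
    # alpha rescues neighboring alphas stuck in local optima
    for _ in range(5):
        improved = False
        for direction in ("backward", "forward"):
            idxs = range(grid.size - 2, -1, -1) if direction == "backward" else range(1, grid.size)
            for i in idxs:
                neighbor = fits[i + 1] if direction == "backward" else fits[i - 1]
                cand = trimmed_fit(
                    X, float(grid[i]), n_starts=1, max_iter=max_iter, tol=tol,
                    seed=seed, warm_start=(neighbor.mu, neighbor.sigma),
                )
                if cand.objective > fits[i].objective + 1e-9 * max(1.0, abs(fits[i].objective)):
                    fits[i] = cand
                    improved = True
        if not improved:
            break
    # closing forward sweep guarantees mean_objectives is non-decreasing even
    # if the refinement loop hit its round cap while still improving
    for i in range(1, grid.size):
        cand = trimmed_fit(
            X, float(grid[i]), n_starts=1, max_iter=max_iter, tol=tol,
            seed=seed, warm_start=(fits[i - 1].mu, fits[i - 1].sigma),
        )
        if cand.objective > fits[i].objective:
            fits[i] = cand

    objectives = np.array([f.objective for f in fits])
    mean_objectives = np.array([f.mean_objective for f in fits])
    n_trimmed = np.array([len(f.trimmed) for f in fits])
    return CTLCurve(
        alphas=grid,
        objectives=objectives,
        mean_objectives=mean_objectives,
        n_trimmed=n_trimmed,
        fits=fits,
    )


def select_alpha_auto(curve: CTLCurve, flatness_tol: float = DEFAULT_FLATNESS_TOL) -> float:
    """Pick the elbow of the CTL curve: first point of sustained flatness.

    The statistic per grid interval is the gain in ``mean_objectives``
    normalized by the curve's total range and by the interval width in grid
    steps — i.e. the fraction of the curve's range gained per grid step.
    Because trimming counts are integers (floor(n * alpha)), adjacent grid
    steps can trim unequal numbers of points; each interval's gain is
    rescaled to the average trimming increment so that this discreteness
    does not masquerade as slope.
    The selected alpha is the smallest grid point from which every subsequent
    normalized gain stays below ``flatness_tol``: while the trimming level is
    below the contamination fraction each extra step still expels genuine
    outliers and the curve climbs fast; once they are gone the curve settles
    onto the slow drift of trimming a clean Gaussian's own tail.  If no grid
    point qualifies, the grid minimum is returned and ``curve.low_confidence``
    is set.
    """
    m = np.asarray(curve.mean_objectives, dtype=float)
    a = np.asarray(curve.alphas, dtype=float)
    span = float(m.max() - m.min())
    if span == 0.0:
        curve.selected_alpha = float(a[0])
        curve.selection_mode = "auto"
        curve.low_confidence = False
        return curve.selected_alpha
    steps = np.diff(a)
    slopes = np.diff(m) / span * (steps.mean() / steps)
    dk = np.diff(np.asarray(curve.n_trimmed, dtype=float))
    if dk.sum() > 0:
        # rescale each interval's gain to the mean per-step trimming increment
        slopes = slopes * np.where(dk > 0, dk.mean() / np.maximum(dk, 1.0), 1.0)
    flat = slopes < flatness_tol
    # smallest index i such that all slopes from i onward are flat
    selected = None
    suffix_flat = np.logical_and.accumulate(flat[::-1])[::-1]
    idx = np.nonzero(suffix_flat)[0]
    if idx.size:
        selected = int(idx[0])
    if selected is None:
        curve.selected_alpha = float(a[0])
        curve.low_confidence = True
    else:
        curve.selected_alpha = float(a[selected])
        curve.low_confidence = False
    curve.selection_mode = "auto"
    return curve.selected_alpha


def save_ctl_curve(curve: CTLCurve, path) -> None:
    """Export the curve as TSV: alpha, objective, mean_objective, n_trimmed."""
    import pandas as pd

    pd.DataFrame(
        {
            "alpha": curve.alphas,
            "objective": curve.objectives,
            "mean_objective": curve.mean_objectives,
            "n_trimmed": curve.n_trimmed,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def plot_ctl_curve(curve: CTLCurve, path) -> None:
    """Plot mean trimmed log-likelihood vs alpha with the selected level marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.alphas, curve.mean_objectives, marker="o", ms=3)
    if curve.selected_alpha is not None:
        ax.axvline(curve.selected_alpha, color="red", ls="--",
                   label=f"selected alpha = {curve.selected_alpha:g}")
        ax.legend()
    ax.set_xlabel("trimming level alpha")
    ax.set_ylabel("mean trimmed log-likelihood")
    ax.set_title("CTL curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
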