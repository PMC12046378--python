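"""Sparse symbolic regression for dynamical-model discovery.

Given sampled state trajectories X and their time derivatives X', find
a sparse coefficient matrix Xi such that X' = Theta(X) Xi, where
Theta(X) is a library of candidate functions (here polynomials in the
state variables).  Two optimizers are provided:

* STLSQ — sequentially thresholded (ridge) least squares: solve,
  hard-threshold coefficients below ``threshold``, and iterate on the
  surviving terms until the active set is stable.
* Constrained SR3 — sparse relaxed regularized regression with linear
  equality constraints C vec(Xi) = d, used for second-order models to
  pin the auxiliary equation to y = 1.00 x' exactly while sparsifying
  the y' equation.

Feature matrices are column-scaled to unit Euclidean norm internally,
so a single threshold is commensurable across terms of very different
magnitude (e.g. 1 versus x^3); thresholds apply to the scaled
coefficients and coefficients are reported unscaled.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import differentiate

__all__ = [
    "FeatureLibrary",
    "SparseModel",
    "OptimizerConfig",
    "build_polynomial_library",
    "stlsq",
    "sr3_constrained",
    "second_order_constraints",
    "discover_first_order",
    "discover_second_order",
    "discover_token",
    "refine_linear_parameters",
    "threshold_grid_search",
    "extract_oscillator_params",
    "OscillatorEstimate",
]

#: coefficient-threshold grid searched when optimizing model fit
THRESHOLD_GRID = (0.001, 0.01, 0.1)


class FeatureLibrary:
    """Ordered monomial feature library over named state variables.

    Each term is an exponent tuple over the states; ``(0, 0)`` is the
    constant, ``(1, 0)`` is x, ``(0, 3)`` is v^3, and so on.  Term order
    is stable and serializable.
    """

    def __init__(self, state_names: Sequence[str],
                 exponents: Sequence[tuple[int, ...]]):
        if not state_names:
            raise ValueError("state list must not be empty")
        self.state_names = tuple(state_names)
        self.exponents = tuple(tuple(e) for e in exponents)
        for e in self.exponents:
            if len(e) != len(self.state_names):
                raise ValueError("exponent tuple arity mismatch")

    @property
    def n_terms(self) -> int:
        return len(self.exponents)

    @property
    def term_names(self) -> list[str]:
        names = []
        for exps in self.exponents:
            parts = []
            for name, p in zip(self.state_names, exps):
                if p == 1:
                    parts.append(name)
                elif p > 1:
                    parts.append(f"{name}^{p}")
            names.append(" ".join(parts) if parts else "1")
        return names

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the library: (n, n_states) -> (n, n_terms)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.state_names):
            raise ValueError(
                f"expected {len(self.state_names)} state columns, "
                f"got {X.shape[1]}"
            )
        cols = []
        for exps in self.exponents:
            col = np.ones(X.shape[0])
            for j, p in enumerate(exps):
                if p:
                    col = col * X[:, j] ** p
            cols.append(col)
        return np.column_stack(cols)

    def term_index(self, name: str) -> int:
        return self.term_names.index(name)

    def __eq__(self, other) -> bool:
        return (isinstance(other, FeatureLibrary)
                and self.state_names == other.state_names
                and self.exponents == other.exponents)

    def __repr__(self) -> str:
        return f"FeatureLibrary({list(self.term_names)})"

    def to_dict(self) -> dict:
        return {"state_names": list(self.state_names),
                "exponents": [list(e) for e in self.exponents]}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureLibrary":
        return cls(d["state_names"], [tuple(e) for e in d["exponents"]])


def build_polynomial_library(
    state_names: Sequence[str], degree: int, include_constant: bool = True,
) -> FeatureLibrary:
    """All monomials of the states up to ``degree``, graded lexicographic."""
    if not state_names:
        raise ValueError("state list must not be empty")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    nvars = len(state_names)
    exps = []
    lo = 0 if include_constant else 1
    for total in range(lo, degree + 1):
        # lexicographic within a fixed total degree
        combos = sorted(
            (e for e in itertools.product(range(total + 1), repeat=nvars)
             if sum(e) == total),
            reverse=True,
        )
        exps.extend(combos)
    return FeatureLibrary(state_names, exps)


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters of the sparse optimizers.

    ``alpha`` is the ridge weight of STLSQ; ``nu`` the SR3 relaxation
    (coupling) weight; ``threshold`` the coefficient threshold (lambda
    for STLSQ, eta for SR3) applied to the column-normalized
    coefficients; ``grid`` the thresholds tried during model selection.
    """

    algorithm: str = "stlsq"
    threshold: float = 0.1
    alpha: float = 0.05
    nu: float = 1.0
    max_iter: int = 20
    grid: tuple[float, ...] = THRESHOLD_GRID
    normalize_columns: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.nu <= 0 or self.threshold < 0:
            raise ValueError("weights must be non-negative (nu positive)")


@dataclass
class SparseModel:
    """A discovered sparse model X' = Theta(X) Xi.

    ``coef`` has one column per state equation (n_terms, n_eqs); the
    active-term mask is ``coef != 0``.  For second-order models the
    first column is the constrained auxiliary equation y = x' and the
    second column is the discovered law for y' = x''.
    """

    library: FeatureLibrary
    coef: np.ndarray
    order: str = "first"
    threshold: float = 0.0
    iterations: int = 0
    converged: bool = True
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.coef = np.atleast_2d(np.asarray(self.coef, dtype=float))
        if self.coef.shape[0] == 1 and self.library.n_terms > 1:
            self.coef = self.coef.T
        if self.coef.shape[0] != self.library.n_terms:
            raise ValueError("coefficient rows must match library terms")

    @property
    def mask(self) -> np.ndarray:
        return self.coef != 0.0

    @property
    def n_equations(self) -> int:
        return self.coef.shape[1]

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        """Model right-hand side for numerical integration."""
        theta = self.library.transform(np.asarray(state)[None, :])
        return (theta @ self.coef)[0]

    def equation_strings(self, precision: int = 3) -> list[str]:
        names = self.library.term_names
        eqs = []
        for j in range(self.n_equations):
            terms = [
                f"{self.coef[i, j]:+.{precision}f} {names[i]}"
                for i in range(self.library.n_terms)
                if self.coef[i, j] != 0.0
            ]
            eqs.append(" ".join(terms) if terms else "0")
        return eqs

    def to_json(self) -> str:
        return json.dumps({
            "library": self.library.to_dict(),
            "coef": self.coef.tolist(),
            "order": self.order,
            "threshold": self.threshold,
            "iterations": self.iterations,
            "converged": self.converged,
            "sample_rate": self.sample_rate,
        })

    @classmethod
    def from_json(cls, s: str) -> "SparseModel":
        d = json.loads(s)
        return cls(
            library=FeatureLibrary.from_dict(d["library"]),
            coef=np.array(d["coef"]),
            order=d["order"],
            threshold=d["threshold"],
            iterations=d["iterations"],
            converged=d["converged"],
            sample_rate=d.get("sample_rate"),
        )


def _column_norms(theta: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(theta, axis=0)
    norms[norms == 0.0] = 1.0
    return norms


def _ridge(A: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Least squares / ridge solve via the stacked augmented system."""
    if alpha > 0:
        p = A.shape[1]
        A = np.vstack([A, np.sqrt(alpha) * np.eye(p)])
        y = np.concatenate([y, np.zeros(p)])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return sol


def stlsq(
    theta: np.ndarray,
    xdot: np.ndarray,
    threshold: float = 0.1,
    alpha: float = 0.05,
    max_iter: int = 20,
    normalize_columns: bool = True,
) -> tuple[np.ndarray, int, bool]:
    """Sequentially thresholded (ridge) least squares.

    Iterates (1) ridge solve on surviving terms, (2) zero out
    coefficients whose column-normalized magnitude falls below
    ``threshold``, until the active set is stable or ``max_iter``.
    Returns (coefficients in original scale, iterations, converged).
    Set ``alpha=0`` for plain least squares; a rank-deficient surviving
    design will then raise.
    """
    theta = np.asarray(theta, dtype=float)
    xdot = np.asarray(xdot, dtype=float)
    single = xdot.ndim == 1
    Y = xdot[:, None] if single else xdot
    if theta.shape[0] != Y.shape[0]:
        raise ValueError("theta rows must match xdot length")
    if threshold < 0 or alpha < 0:
        raise ValueError("threshold and alpha must be non-negative")
    norms = _column_norms(theta) if normalize_columns else np.ones(theta.shape[1])
    A = theta / norms
    p, k = theta.shape[1], Y.shape[1]
    coef_s = np.zeros((p, k))
    active = np.ones((p, k), dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_active = active.copy()
        for j in range(k):
            idx = np.flatnonzero(active[:, j])
            coef_s[:, j] = 0.0
            if idx.size == 0:
                continue
            Aj = A[:, idx]
            if alpha == 0.0 and np.linalg.matrix_rank(Aj) < idx.size:
                raise np.linalg.LinAlgError(
                    "rank-deficient design with alpha=0: ill-conditioned fit"
                )
            w = _ridge(Aj, Y[:, j], alpha)
            keep = np.abs(w) >= threshold
            coef_s[idx, j] = np.where(keep, w, 0.0)
            new_active[:, j] = False
            new_active[idx[keep], j] = True
        if np.array_equal(new_active, active):
            converged = True
            break
        active = new_active
    # final debiased solve on the converged support
    for j in range(k):
        idx = np.flatnonzero(active[:, j])
        coef_s[:, j] = 0.0
        if idx.size:
            coef_s[idx, j] = _ridge(A[:, idx], Y[:, j], alpha)
    coef = coef_s / norms[:, None]
    return (coef[:, 0] if single else coef), it, converged


def second_order_constraints(
    library: FeatureLibrary, velocity_state: str = "v",
) -> tuple[np.ndarray, np.ndarray]:
    """Equality constraints pinning the auxiliary equation to y = 1.00 x'.

    Fixes every coefficient of the first equation: 1 on the velocity
    term, 0 elsewhere.  Returns (C, dvec) acting on vec(Xi) with
    columns stacked (first equation first).
    """
    p = library.n_terms
    j_v = library.term_index(velocity_state)
    C = np.zeros((p, 2 * p))
    C[np.arange(p), np.arange(p)] = 1.0
    dvec = np.zeros(p)
    dvec[j_v] = 1.0
    return C, dvec


def _split_pinned(C: np.ndarray, dvec: np.ndarray):
    """Separate single-entry constraint rows (which pin one coefficient to
    an exact value) from general rows.  Returns (pin_idx, pin_val, C_rest,
    d_rest); raises on contradictory pins."""
    pins: dict[int, float] = {}
    rest_rows = []
    for row, d in zip(C, dvec):
        nz = np.flatnonzero(row)
        if nz.size == 1:
            j = int(nz[0])
            val = d / row[nz[0]]
            if j in pins and not np.isclose(pins[j], val):
                raise ValueError("infeasible constraints: contradictory pins")
            pins[j] = val
        else:
            rest_rows.append((row, d))
    pin_idx = np.array(sorted(pins), dtype=int)
    pin_val = np.array([pins[j] for j in pin_idx])
    if rest_rows:
        C_rest = np.array([r for r, _ in rest_rows])
        d_rest = np.array([d for _, d in rest_rows])
    else:
        C_rest = np.zeros((0, C.shape[1]))
        d_rest = np.zeros(0)
    return pin_idx, pin_val, C_rest, d_rest


def _constrained_lstsq(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, dvec: np.ndarray,
    support: np.ndarray,
) -> np.ndarray:
    """Equality-constrained least squares restricted to a support set.

    Minimizes sum_j ||B_j - A Xi_j||^2 over entries in ``support``
    subject to C vec(Xi) = dvec, the remaining entries being exactly 0.
    Constraint rows touching a single coefficient pin it to its exact
    value (no round-off).
    """
    p, k = support.shape
    pin_idx, pin_val, C_rest, d_rest = _split_pinned(C, dvec)
    xi = np.zeros(p * k)
    xi[pin_idx] = pin_val
    pinned = np.zeros(p * k, dtype=bool)
    pinned[pin_idx] = True
    free = np.flatnonzero(support.ravel(order="F") & ~pinned)
    if free.size == 0:
        return xi.reshape((p, k), order="F")
    AtA = A.T @ A
    H_full = np.kron(np.eye(k), AtA)
    g_full = (A.T @ B).ravel(order="F")
    # move the pinned contribution to the right-hand side
    g = g_full[free] - H_full[np.ix_(free, pin_idx)] @ pin_val
    H = H_full[np.ix_(free, free)]
    Cf = C_rest[:, free] if C_rest.size else np.zeros((0, free.size))
    df = d_rest - (C_rest[:, pin_idx] @ pin_val if C_rest.size else 0.0)
    keep_rows = np.any(Cf != 0.0, axis=1) if Cf.size else \
        np.zeros(Cf.shape[0], dtype=bool)
    if np.any(~keep_rows & (np.abs(np.atleast_1d(df)) > 1e-12)):
        raise ValueError("infeasible constraints for the given support")
    Cf, df = Cf[keep_rows], np.atleast_1d(df)[keep_rows]
    m = Cf.shape[0]
    KKT = np.block([[H, Cf.T], [Cf, np.zeros((m, m))]])
    rhs_v = np.concatenate([g, df])
    sol, *_ = np.linalg.lstsq(KKT, rhs_v, rcond=None)
    xi[free] = sol[: free.size]
    return xi.reshape((p, k), order="F")


def sr3_constrained(
    theta: np.ndarray,
    xdot: np.ndarray,
    C: np.ndarray,
    dvec: np.ndarray,
    threshold: float = 0.1,
    nu: float = 1.0,
    max_iter: int = 30,
    normalize_columns: bool = True,
    term_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Constrained sparse relaxed regularized regression (SR3).

    Minimizes  1/2 ||X' - Theta Xi||^2 + lambda R(W) + 1/(2 nu) ||Xi - W||^2
    subject to C vec(Xi) = dvec, where R is a weighted l0 penalty whose
    prox is elementwise hard thresholding at ``threshold`` (optionally
    scaled per term by ``term_weights``).  Alternates a KKT-constrained
    least-squares step for Xi with the thresholding step for W;
    constraint-protected entries are never thresholded.  On support
    convergence a final constrained least-squares polish on the active
    set is returned, so C vec(Xi) = dvec holds to solver precision.

    Returns (coefficients (p, k), iterations, converged).
    """
    theta = np.asarray(theta, dtype=float)
    B = np.asarray(xdot, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    C = np.atleast_2d(np.asarray(C, dtype=float))
    dvec = np.asarray(dvec, dtype=float)
    n, p = theta.shape
    k = B.shape[1]
    if C.shape[1] != p * k:
        raise ValueError("constraint matrix width must equal n_terms * n_eqs")

    norms = _column_norms(theta) if normalize_columns else np.ones(p)
    A = theta / norms
    # xi_raw = xi_scaled / norm  =>  C_scaled = C * (1/norm per entry)
    scale_vec = np.tile(norms, k)
    Cs = C / scale_vec[None, :]

    protected = np.any(C != 0.0, axis=0)  # entries appearing in constraints
    weights = np.ones(p * k) if term_weights is None else np.tile(
        np.asarray(term_weights, dtype=float), k)

    AtA = np.kron(np.eye(k), A.T @ A)
    Atb = (A.T @ B).ravel(order="F")
    H = AtA + np.eye(p * k) / nu
    m = C.shape[0]
    KKT = np.block([[H, Cs.T], [Cs, np.zeros((m, m))]])

    w = np.zeros(p * k)
    support = np.ones(p * k, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rhs_v = np.concatenate([Atb + w / nu, dvec])
        sol, *_ = np.linalg.lstsq(KKT, rhs_v, rcond=None)
        xi = sol[: p * k]
        keep = protected | (np.abs(xi) >= threshold * weights)
        w = np.where(keep, xi, 0.0)
        if np.array_equal(keep, support):
            converged = True
            break
        support = keep
    support_mat = support.reshape((p, k), order="F")
    xi_s = _constrained_lstsq(A, B, Cs, dvec, support_mat)
    coef = xi_s / norms[:, None]
    return coef, it, converged


def _derivative_series(
    x: np.ndarray,
    v: np.ndarray | None,
    sample_rate: float,
    smooth_window: int = 0,
    polyorder: int = 3,
    upsample: int = 1,
):
    """Prepare (x, v, v') series for regression.

    Optionally smooths the position with a Savitzky-Golay filter
    (measurement-noise suppression) and resamples onto a finer grid by
    cubic-spline interpolation before finite differencing, which keeps
    the second-order difference bias negligible for gestural
    frequencies at pellet-style sample rates.
    """
    from scipy.interpolate import CubicSpline
    from scipy.signal import savgol_filter

    x = np.asarray(x, dtype=float)
    n = len(x)
    if smooth_window and smooth_window >= 3 and n >= smooth_window:
        win = smooth_window + 1 - smooth_window % 2  # force odd
        x = savgol_filter(x, win, min(polyorder, win - 1))
        v = None  # recompute from the smoothed positions
    if upsample > 1 and n >= 4:
        t = np.arange(n) / sample_rate
        cs = CubicSpline(t, x)
        tf = np.linspace(t[0], t[-1], (n - 1) * upsample + 1)
        x = cs(tf)
        sample_rate = sample_rate * upsample
        v = None
    if v is None:
        v = differentiate(x, sample_rate, order=1)
    else:
        v = np.asarray(v, dtype=float)
    vdot = differentiate(v, sample_rate, order=1)
    return x, v, vdot, sample_rate


@dataclass
class DiscoveryOptions:
    """Numerical options for token-level discovery.

    ``smooth_window``: Savitzky-Golay window (samples) applied to
    positions before differentiation; 0 disables.  ``upsample``:
    cubic-spline resampling factor applied before differencing;
    ``edge_trim``: samples dropped from each end of the regression —
    the one-sided finite-difference stencils contaminate the outermost
    two samples after two gradient applications, so those carry the
    largest derivative error and are excluded by default.

    The remaining fields configure the token-level pathway
    (:func:`discover_token`) for noisy sampled gestures: ``lowpass_hz``
    applies a zero-phase Butterworth filter to the token plus its raw
    context before spline differentiation; ``edge_weighting``
    downweights regression rows by sin(pi u) across the token
    (derivative estimates are least reliable near the segment
    boundaries); ``refine`` polishes the coefficients of a discovered
    second-order linear structure by an output-error trajectory fit.
    """

    smooth_window: int = 0
    polyorder: int = 3
    upsample: int = 1
    edge_trim: int = 2
    lowpass_hz: float | None = 15.0
    edge_weighting: bool = True
    refine: bool = True


def discover_first_order(
    x: np.ndarray,
    sample_rate: float,
    library: FeatureLibrary | None = None,
    config: OptimizerConfig | None = None,
    options: DiscoveryOptions | None = None,
) -> SparseModel:
    """Discover a first-order model x' = f(x) from one gesture token."""
    config = config or OptimizerConfig()
    options = options or DiscoveryOptions()
    library = library or build_polynomial_library(["x"], 3)
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("token too short for discovery")
    xs, v, _, _ = _derivative_series(
        x, None, sample_rate, options.smooth_window, options.polyorder,
        options.upsample,
    )
    tr = options.edge_trim
    sl = slice(tr, len(xs) - tr if tr else None)
    theta = library.transform(xs[sl, None])
    coef, it, conv = stlsq(
        theta, v[sl], threshold=config.threshold, alpha=config.alpha,
        max_iter=config.max_iter, normalize_columns=config.normalize_columns,
    )
    return SparseModel(library, coef, order="first",
                       threshold=config.threshold, iterations=it,
                       converged=conv, sample_rate=sample_rate)


def discover_second_order(
    x: np.ndarray,
    v: np.ndarray | None,
    sample_rate: float,
    library: FeatureLibrary | None = None,
    config: OptimizerConfig | None = None,
    options: DiscoveryOptions | None = None,
) -> SparseModel:
    """Discover a second-order model x'' = f(x, x') from one gesture token.

    The system is split into coupled first-order equations (y = x',
    y' = f(x, y)) and fitted with constrained SR3 so that the first
    equation is exactly y = 1.00 x'.  If ``v`` is None the velocity is
    computed by finite differences from the position.
    """
    config = config or OptimizerConfig(algorithm="sr3", max_iter=30)
    options = options or DiscoveryOptions()
    library = library or build_polynomial_library(["x", "v"], 1)
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("token too short for discovery")
    xs, vs, vdot, _ = _derivative_series(
        x, v, sample_rate, options.smooth_window, options.polyorder,
        options.upsample,
    )
    tr = options.edge_trim
    sl = slice(tr, len(xs) - tr if tr else None)
    X = np.column_stack([xs[sl], vs[sl]])
    theta = library.transform(X)
    targets = np.column_stack([vs[sl], vdot[sl]])
    C, dvec = second_order_constraints(library, velocity_state="v")
    coef, it, conv = sr3_constrained(
        theta, targets, C, dvec, threshold=config.threshold, nu=config.nu,
        max_iter=config.max_iter, normalize_columns=config.normalize_columns,
    )
    return SparseModel(library, coef, order="second",
                       threshold=config.threshold, iterations=it,
                       converged=conv, sample_rate=sample_rate)


def threshold_grid_search(
    x: np.ndarray | None,
    sample_rate: float | None = None,
    library: FeatureLibrary | None = None,
    grid: Sequence[float] = THRESHOLD_GRID,
    order: str = "second",
    config: OptimizerConfig | None = None,
    options: DiscoveryOptions | None = None,
    v: np.ndarray | None = None,
    segment=None,
) -> tuple[SparseModel, float, float]:
    """Fit at each threshold and keep the best-scoring model.

    Models are scored by forward-prediction variance-weighted R^2;
    non-convergent or unstable fits score -inf.  Ties keep the first
    threshold in grid order.  Accepts either a raw position series or a
    :class:`~gesturedyn.preprocess.GestureSegment` (``segment=...``,
    which routes through the context-aware token pathway).  Returns
    (model, threshold, score); raises if every candidate is unstable.
    """
    from . import evaluate  # deferred: evaluate imports SparseModel

    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if segment is not None:
        x = np.asarray(segment.x, dtype=float)
        sample_rate = segment.sample_rate
    if x is None or sample_rate is None:
        raise ValueError("need either a position series or a segment")
    base = config or OptimizerConfig()
    best = None
    for thr in grid:
        cfg = OptimizerConfig(
            algorithm=base.algorithm, threshold=thr, alpha=base.alpha,
            nu=base.nu, max_iter=base.max_iter, grid=tuple(grid),
            normalize_columns=base.normalize_columns,
        )
        try:
            if segment is not None:
                model = discover_token(segment, order, library, cfg, options)
            elif order == "second":
                model = discover_second_order(
                    x, v, sample_rate, library, cfg, options)
            else:
                model = discover_first_order(
                    x, sample_rate, library, cfg, options)
            score = evaluate.score_model(model, x, sample_rate, v=v)
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            continue
        if best is None or score > best[2]:
            best = (model, thr, score)
    if best is None or not np.isfinite(best[2]):
        raise RuntimeError("all threshold candidates were unstable")
    return best


def _token_series(
    segment, options: "DiscoveryOptions", sample_rate: float,
):
    """Filtered spline derivatives of one segment on an upsampled grid.

    Filters the raw context slice (real neighboring samples absorb the
    filter transient), fits a cubic spline, and evaluates position,
    velocity and acceleration on a fine grid spanning the token only.
    Returns (x, v, a, weights).
    """
    from scipy.interpolate import CubicSpline

    from .preprocess import lowpass

    ctx = segment.context if segment.context is not None else segment.x
    off = segment.context_offset if segment.context is not None else 0
    ctx = np.asarray(ctx, dtype=float)
    n_tok = segment.stop - segment.start
    if options.lowpass_hz:
        ctx = lowpass(ctx, sample_rate, options.lowpass_hz)
    tt = np.arange(len(ctx)) / sample_rate
    cs = CubicSpline(tt, ctx)
    t0 = off / sample_rate
    t1 = (off + n_tok) / sample_rate
    up = max(1, options.upsample)
    nf = n_tok * up + 1
    tf = np.linspace(t0, t1, nf)
    x = cs(tf)
    v = cs(tf, 1)
    a = cs(tf, 2)
    if options.edge_weighting:
        w = np.sin(np.pi * np.linspace(0.0, 1.0, nf))
    else:
        w = np.ones(nf)
    return x, v, a, w


def discover_token(
    segment,
    order: str = "second",
    library: FeatureLibrary | None = None,
    config: OptimizerConfig | None = None,
    options: DiscoveryOptions | None = None,
    structure: tuple[str, ...] | None = None,
) -> SparseModel:
    """Discover a dynamical model from one segmented gesture token.

    The token pathway for sampled (possibly noisy) pellet data: the raw
    token plus context is low-pass filtered, derivatives come from a
    cubic spline on an upsampled grid, and regression rows are
    edge-downweighted.  Second-order fits use constrained SR3 with the
    y = 1.00 x' constraint; when the discovered structure is a linear
    oscillator (terms within {1, x, x'}) and ``options.refine`` is on,
    the coefficients are re-estimated by an output-error fit of the
    closed-form trajectory with the initial velocity pinned to zero
    (segment bounds are velocity zero crossings), which is markedly
    more noise-efficient than derivative regression.

    ``structure``, when given (e.g. the ensemble majority structure),
    forces that set of active terms on the final-state equation instead
    of the token's own thresholding outcome.
    """
    config = config or OptimizerConfig(algorithm="sr3", max_iter=30)
    options = options or DiscoveryOptions(upsample=4)
    sr = segment.sample_rate
    if segment.stop - segment.start < 5:
        raise ValueError("token too short for discovery")
    x, v, a, w = _token_series(segment, options, sr)
    sw = np.sqrt(w)[:, None]
    if order == "first":
        library = library or build_polynomial_library(["x"], 3)
        theta = library.transform(x[:, None]) * sw
        coef, it, conv = stlsq(
            theta, v * sw[:, 0], threshold=config.threshold,
            alpha=config.alpha, max_iter=config.max_iter,
            normalize_columns=config.normalize_columns,
        )
        return SparseModel(library, coef, order="first",
                           threshold=config.threshold, iterations=it,
                           converged=conv, sample_rate=sr)
    library = library or build_polynomial_library(["x", "v"], 1)
    theta = library.transform(np.column_stack([x, v])) * sw
    targets = np.column_stack([v, a]) * sw
    C, dvec = second_order_constraints(library, velocity_state="v")
    coef, it, conv = sr3_constrained(
        theta, targets, C, dvec, threshold=config.threshold, nu=config.nu,
        max_iter=config.max_iter, normalize_columns=config.normalize_columns,
    )
    model = SparseModel(library, coef, order="second",
                        threshold=config.threshold, iterations=it,
                        converged=conv, sample_rate=sr)
    if structure is not None:
        # force the (e.g. ensemble-majority) structure on this token
        keep = set(structure)
        for i, name in enumerate(library.term_names):
            if name not in keep:
                model.coef[i, 1] = 0.0
    if options.refine:
        model = _maybe_refine_linear(model, segment, structure)
    return model


def _maybe_refine_linear(
    model: SparseModel, segment, structure: tuple[str, ...] | None = None,
) -> SparseModel:
    """Output-error polish of a discovered second-order linear structure."""
    names = model.library.term_names
    if structure is not None:
        active = set(structure)
    else:
        active = {n for n, on in zip(names, model.mask[:, 1]) if on}
    if not active or not active <= {"1", "x", "v"}:
        return model
    try:
        est = extract_oscillator_params(model)
    except ValueError:
        return model
    # fit the unfiltered samples when available (white measurement noise)
    pre = post = None
    if segment.context is not None:
        off = segment.context_offset
        n_tok = segment.stop - segment.start
        ctx = np.asarray(segment.context, dtype=float)
        x_obs = ctx[off:off + n_tok + 1]
        pre = ctx[:off]
        post = ctx[off + n_tok + 1:]
    else:
        x_obs = np.asarray(segment.x, dtype=float)
    fit_b = "v" in active
    try:
        k, b, Tv = refine_linear_parameters(
            x_obs, segment.sample_rate, est.k, est.Tv,
            b0=est.b, fit_damping=fit_b, pre=pre, post=post,
        )
    except (ValueError, RuntimeError):
        return model
    coef = model.coef.copy()
    if "1" in active:
        coef[names.index("1"), 1] = k * Tv
    coef[names.index("x"), 1] = -k
    if fit_b:
        coef[names.index("v"), 1] = -b
    model.coef = coef
    return model


def refine_linear_parameters(
    x: np.ndarray,
    sample_rate: float,
    k0: float,
    Tv0: float,
    b0: float = 0.0,
    fit_damping: bool = False,
    pre: np.ndarray | None = None,
    post: np.ndarray | None = None,
    max_wing: int = 12,
) -> tuple[float, float, float]:
    """Output-error fit of the linear oscillator to one observed token.

    Minimizes the position residual between the closed-form solution of
    x'' = -b x' - k (x - Tv) started from rest (the token is bounded by
    velocity zero crossings) and the observed samples, over
    (k, Tv, x0, tau) and optionally b in [0, critical); tau is a small
    free time offset (bounded by ±2.5 samples) absorbing the sub-sample
    and rounding error of the segmentation boundary.  Position-domain
    fitting avoids the noise amplification of differentiation and is
    near-efficient for half-cycle tokens.

    When raw neighboring samples are supplied (``pre``/``post``, up to
    ``max_wing`` each), they are fitted jointly as rest-start cosine
    wings sharing the token's boundary corners: adjacent movements also
    begin and end at velocity zeros, so the wing data pin down the
    boundary phase — by far the most informative quantity for the
    stiffness — far better than the token samples alone.

    Returns (k, b, Tv).
    """
    from scipy.optimize import least_squares

    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("token too short to refine")
    if k0 <= 0:
        raise ValueError("need a positive initial stiffness")
    pre = np.asarray(pre, dtype=float)[-max_wing:] if pre is not None \
        else np.empty(0)
    post = np.asarray(post, dtype=float)[:max_wing] if post is not None \
        else np.empty(0)
    y = np.concatenate([pre, x, post])
    t = (np.arange(len(y)) - len(pre)) / sample_rate
    tau_max = 2.5 / sample_rate
    wings = len(pre) > 0 or len(post) > 0

    def trajectory(k, b, Tv, x0p, tau, kpre, apre, kpost, apost):
        zeta2 = max(k - b * b / 4.0, 1e-12)
        om = np.sqrt(zeta2)
        ts = t - tau
        c1 = x0p - Tv
        xm = Tv + np.exp(-b / 2.0 * ts) * (
            c1 * np.cos(om * ts) + (b / 2.0 * c1 / om) * np.sin(om * ts)
        )
        t_end = tau + np.pi / om
        x_end = Tv - c1 * np.exp(-b / 2.0 * (np.pi / om))
        om_pre = np.sqrt(max(kpre, 1e-12))
        om_post = np.sqrt(max(kpost, 1e-12))
        xpre = x0p + apre * (1.0 - np.cos(om_pre * ts))
        xpost = x_end + apost * (1.0 - np.cos(om_post * (ts - np.pi / om)))
        return np.where(ts < 0, xpre, np.where(ts > np.pi / om, xpost, xm))

    lo_w = [1e-6, -np.inf, 1e-6, -np.inf]
    hi_w = [np.inf, np.inf, np.inf, np.inf]
    p0_w = [k0, 0.0, k0, 0.0]

    def residual0(p):
        return trajectory(p[0], 0.0, p[1], p[2], p[3], *p[4:]) - y

    sol0 = least_squares(
        residual0, [k0, Tv0, x[0], 0.0] + p0_w,
        bounds=([1e-6, -np.inf, -np.inf, -tau_max] + lo_w,
                [np.inf, np.inf, np.inf, tau_max] + hi_w),
    )
    k, Tv, b = sol0.x[0], sol0.x[1], 0.0
    sol = sol0
    if fit_damping:
        # damping is weakly identified over a half cycle; keep it only if
        # the damped fit is preferred by BIC over the undamped one
        b_hi = 1.98 * np.sqrt(k0)

        def residual1(p):
            return trajectory(p[0], p[1], p[2], p[3], p[4], *p[5:]) - y

        p0 = [k0, float(np.clip(b0, 0.0, 0.5 * b_hi)), Tv0, x[0], 0.0]
        sol1 = least_squares(
            residual1, p0 + p0_w,
            bounds=([1e-6, 0.0, -np.inf, -np.inf, -tau_max] + lo_w,
                    [np.inf, b_hi, np.inf, np.inf, tau_max] + hi_w),
        )
        m = len(y)
        sse0 = max(2.0 * sol0.cost, 1e-300)
        sse1 = max(2.0 * sol1.cost, 1e-300)
        n_par = 4 + (4 if wings else 0)
        bic0 = m * np.log(sse0 / m) + n_par * np.log(m)
        bic1 = m * np.log(sse1 / m) + (n_par + 1) * np.log(m)
        if bic1 < bic0:
            k, b, Tv = sol1.x[0], sol1.x[1], sol1.x[2]
            sol = sol1
    if not sol.success and sol.status <= 0:
        raise RuntimeError("trajectory refinement did not converge")
    return float(k), float(b), float(Tv)


@dataclass(frozen=True)
class OscillatorEstimate:
    """Mass-spring reading of a discovered second-order linear model.

    k and b are the stiffness and damping, Tv = constant/k the virtual
    target (the discovered equilibrium), and T = 2 Tv - x0 the empirical
    target implied by the half-cycle undamped reading.
    """

    k: float
    b: float
    Tv: float
    T: float | None = None
    d: float = 0.0


def extract_oscillator_params(
    model: SparseModel, x0: float | None = None,
) -> OscillatorEstimate:
    """Interpret a second-order model x'' = c0 + cx x + cv x' (+ c3 x^3).

    k = -cx, b = -cv, Tv = c0 / k; the empirical target T = 2 Tv - x0
    is reported when the token's initial position is supplied.  An
    extracted k <= 0 signals a non-oscillatory model and raises.
    """
    if model.order != "second" or model.n_equations < 2:
        raise ValueError("oscillator extraction needs a second-order model")
    lib = model.library
    col = model.coef[:, 1]
    names = lib.term_names

    def coef_of(name: str) -> float:
        return float(col[names.index(name)]) if name in names else 0.0

    c0 = coef_of("1")
    cx = coef_of("x")
    cv = coef_of("v")
    c3 = coef_of("x^3")
    k = -cx
    if k <= 0:
        raise ValueError(f"extracted stiffness k={k:.4g} is not positive: "
                         "non-oscillatory model")
    b = -cv
    Tv = c0 / k
    T = None if x0 is None else 2.0 * Tv - x0
    return OscillatorEstimate(k=k, b=b, Tv=Tv, T=T, d=c3)
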