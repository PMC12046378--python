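"""Model evaluation: forward prediction, fit scoring and portrait diagnostics.

A discovered model is judged by solving it forward in time from the
token's initial conditions and scoring the prediction against the data
with a variance-weighted coefficient of determination over position and
velocity.  Qualitative adequacy is judged with phase portraits
(position vs velocity) and Hooke portraits (position vs acceleration):
harmonic motion produces a linear Hooke portrait, so the R^2 of a
by-token regression of acceleration on position (RH^2) quantifies
anharmonicity; RH^2 <= 0.9 indicates substantial nonlinearity and
RH^2 > 0.95 quasi-linearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .oscillators import Trajectory
from .preprocess import GestureSegment, differentiate
from .sindy import (
    DiscoveryOptions,
    OptimizerConfig,
    SparseModel,
    build_polynomial_library,
)

__all__ = [
    "UnstablePredictionError",
    "FitReport",
    "HookeStats",
    "EnsembleSummary",
    "predict_trajectory",
    "variance_weighted_r2",
    "score_model",
    "train_test_split",
    "library_comparison",
    "ensemble_structure",
    "hooke_linearity",
    "classify_hooke",
    "portrait_data",
    "target_correlation",
]


class UnstablePredictionError(RuntimeError):
    """Forward integration of a discovered model diverged."""


@dataclass
class FitReport:
    """Per-token fit scores with per-variable summaries."""

    scores: dict[str, list[float]]
    threshold: float | None = None
    structure: tuple[str, ...] | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for var, vals in self.scores.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[np.isfinite(arr)]
            rows.append({
                "variable": var,
                "n": len(vals),
                "mean_r2": arr.mean() if arr.size else np.nan,
                "sd_r2": arr.std(ddof=1) if arr.size > 1 else np.nan,
                "min_r2": arr.min() if arr.size else np.nan,
                "max_r2": arr.max() if arr.size else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass
class HookeStats:
    """Distribution of Hooke-portrait linearity across tokens."""

    rh2: dict[str, list[float]]

    def fractions(self) -> pd.DataFrame:
        rows = []
        for var, vals in self.rh2.items():
            arr = np.asarray(vals, dtype=float)
            rows.append({
                "variable": var,
                "n": arr.size,
                "frac_quasilinear": float(np.mean(arr > 0.95)),
                "frac_borderline": float(np.mean((arr > 0.9) & (arr <= 0.95))),
                "frac_nonlinear": float(np.mean(arr <= 0.9)),
            })
        return pd.DataFrame(rows)


@dataclass
class EnsembleSummary:
    """Per-term inclusion fractions and the majority model structure."""

    term_names: tuple[str, ...]
    inclusion_fraction: np.ndarray
    majority_structure: tuple[str, ...]
    structure_histogram: dict[tuple[str, ...], int]
    n_models: int


def predict_trajectory(
    model: SparseModel,
    x0: float,
    v0: float = 0.0,
    duration: float = 0.25,
    dt: float = 0.001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Solve a discovered model forward in time from (x0, v0).

    First-order models integrate x' = f(x); second-order models
    integrate the coupled system (x' = y, y' = f(x, y)).  Divergent
    integrations raise :class:`UnstablePredictionError` (scored -inf
    downstream).
    """
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    y0 = [x0] if model.order == "first" else [x0, v0]

    budget = [100_000]  # rhs-evaluation cap: stiff fits must fail fast

    def rhs(ti, yi):
        budget[0] -= 1
        if budget[0] < 0:
            raise UnstablePredictionError("integration budget exhausted")
        return model.rhs(ti, yi)

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(rhs, (0.0, t[-1]), y0, method="RK45",
                            t_eval=t, rtol=rtol, atol=atol)
    except (UnstablePredictionError, ValueError, OverflowError) as exc:
        raise UnstablePredictionError(str(exc)) from exc
    if (not sol.success or sol.y.shape[1] != n
            or not np.all(np.isfinite(sol.y))):
        raise UnstablePredictionError("unstable forward prediction")
    if model.order == "first":
        x = sol.y[0]
        v = model.library.transform(x[:, None]) @ model.coef[:, 0]
        return Trajectory(t=t, x=x, v=v, sample_rate=1.0 / dt)
    x, v = sol.y[0], sol.y[1]
    acc = model.library.transform(np.column_stack([x, v])) @ model.coef[:, 1]
    return Trajectory(t=t, x=x, v=v, a=acc, sample_rate=1.0 / dt)


def variance_weighted_r2(data, pred) -> float:
    """Coefficient of determination averaged over signals, variance weighted.

    ``data`` and ``pred`` are sequences of aligned equal-length signals
    (e.g. position and velocity).  Per signal, R^2 = 1 - SSres/SStot
    with SStot about the data mean; signals are combined with weights
    proportional to their variance, so a zero-variance signal carries
    zero weight.  R^2 may be negative when the prediction is worse than
    a horizontal line through the data.
    """
    data = [np.asarray(d, dtype=float) for d in np.atleast_2d(data)]
    pred = [np.asarray(p, dtype=float) for p in np.atleast_2d(pred)]
    if len(data) != len(pred):
        raise ValueError("data and pred must have the same number of signals")
    num = 0.0
    den = 0.0
    for d, p in zip(data, pred):
        if d.shape != p.shape:
            raise ValueError("aligned signals must have equal lengths")
        sst = float(np.sum((d - d.mean()) ** 2))
        if sst == 0.0:
            continue
        ssr = float(np.sum((d - p) ** 2))
        var = sst / len(d)
        num += var * (1.0 - ssr / sst)
        den += var
    if den == 0.0:
        raise ValueError("all signals have zero variance: R^2 undefined")
    return num / den


def score_model(
    model: SparseModel,
    x: np.ndarray,
    sample_rate: float,
    v: np.ndarray | None = None,
) -> float:
    """Variance-weighted R^2 of a model's forward prediction of one token.

    The prediction starts from the token's first position/velocity
    sample and runs on the token's grid; unstable predictions score
    -inf.
    """
    x = np.asarray(x, dtype=float)
    if v is None:
        v = differentiate(x, sample_rate)
    duration = (len(x) - 1) / sample_rate
    try:
        pred = predict_trajectory(
            model, x0=x[0], v0=v[0], duration=duration, dt=1.0 / sample_rate)
    except UnstablePredictionError:
        return -np.inf
    return variance_weighted_r2([x, v], [pred.x, pred.v])


def train_test_split(
    tokens: Sequence, train_frac: float = 0.8, seed: int = 0,
) -> tuple[list, list]:
    """Random per-variable split of tokens into train and test sets.

    Tokens are grouped by their ``variable`` attribute and each group is
    partitioned independently, reproducibly under ``seed``.
    """
    if len(tokens) < 5:
        raise ValueError("need at least 5 tokens to split")
    rng = np.random.default_rng(seed)
    groups: dict[str, list] = {}
    for tok in tokens:
        groups.setdefault(getattr(tok, "variable", ""), []).append(tok)
    train: list = []
    test: list = []
    for var in sorted(groups):
        toks = groups[var]
        idx = rng.permutation(len(toks))
        n_train = int(round(train_frac * len(toks)))
        train.extend(toks[i] for i in idx[:n_train])
        test.extend(toks[i] for i in idx[n_train:])
    return train, test


def _fit_token(seg: GestureSegment, order, library, cfg, options):
    from .sindy import discover_token

    return discover_token(seg, order=order, library=library,
                          config=cfg, options=options)


def library_comparison(
    tokens: Sequence[GestureSegment],
    degrees: Sequence[int] = (1, 2, 3, 4),
    order: str = "second",
    grid: Sequence[float] = (0.001, 0.01, 0.1),
    config: OptimizerConfig | None = None,
    options: DiscoveryOptions | None = None,
) -> pd.DataFrame:
    """Compare polynomial feature libraries across articulatory variables.

    For each degree and variable the coefficient threshold is optimized
    over ``grid`` to maximize the mean forward-prediction R^2, and the
    mean/sd/min of per-token scores at that threshold are reported.
    Unstable fits score -inf and cells where no threshold converges are
    reported with NaN statistics rather than dropped.
    """
    base = config or OptimizerConfig()
    options = options or DiscoveryOptions()
    groups: dict[str, list[GestureSegment]] = {}
    for tok in tokens:
        groups.setdefault(tok.variable, []).append(tok)
    rows = []
    for degree in degrees:
        states = ["x", "v"] if order == "second" else ["x"]
        library = build_polynomial_library(states, degree)
        for var in sorted(groups):
            toks = groups[var]
            best_thr, best_scores, best_mean = None, None, -np.inf
            for thr in grid:
                cfg = OptimizerConfig(
                    algorithm=base.algorithm, threshold=thr, alpha=base.alpha,
                    nu=base.nu, max_iter=base.max_iter,
                    normalize_columns=base.normalize_columns)
                scores = []
                for seg in toks:
                    try:
                        model = _fit_token(seg, order, library, cfg, options)
                        scores.append(score_model(
                            model, seg.x, seg.sample_rate))
                    except (ValueError, np.linalg.LinAlgError, RuntimeError):
                        scores.append(-np.inf)
                finite = [s for s in scores if np.isfinite(s)]
                mean = np.mean(finite) if finite else -np.inf
                if mean > best_mean:
                    best_thr, best_scores, best_mean = thr, scores, mean
            finite = np.array(
                [s for s in (best_scores or []) if np.isfinite(s)])
            rows.append({
                "order": order,
                "degree": degree,
                "variable": var,
                "threshold": best_thr,
                "n_tokens": len(toks),
                "n_unstable": (len(best_scores) - finite.size
                               if best_scores else len(toks)),
                "mean_r2": finite.mean() if finite.size else np.nan,
                "sd_r2": finite.std(ddof=1) if finite.size > 1 else np.nan,
                "min_r2": finite.min() if finite.size else np.nan,
            })
    return pd.DataFrame(rows)


def ensemble_structure(models: Sequence[SparseModel]) -> EnsembleSummary:
    """Distribution of discovered model structures across tokens.

    Reports the inclusion fraction of each library term (for the final
    state equation), the majority structure (terms present in more than
    half the models), and a histogram of full structure signatures.
    """
    if not models:
        raise ValueError("need at least one model")
    lib = models[0].library
    for m in models[1:]:
        if m.library != lib:
            raise ValueError("models must share one feature library")
    names = tuple(lib.term_names)
    eq = models[0].n_equations - 1  # the discovered (last) state equation
    masks = np.array([m.mask[:, eq] for m in models])
    frac = masks.mean(axis=0)
    majority = tuple(n for n, f in zip(names, frac) if f > 0.5)
    hist: dict[tuple[str, ...], int] = {}
    for row in masks:
        sig = tuple(n for n, on in zip(names, row) if on)
        hist[sig] = hist.get(sig, 0) + 1
    return EnsembleSummary(
        term_names=names, inclusion_fraction=frac,
        majority_structure=majority, structure_histogram=hist,
        n_models=len(models),
    )


def hooke_linearity(segment: GestureSegment) -> float:
    """RH^2: linearity of the Hooke portrait for one token.

    Ordinary least squares of acceleration on position (with intercept);
    returns the coefficient of determination.  Near 1 for harmonic
    (linear-spring) motion; low values indicate anharmonicity.
    """
    x = np.asarray(segment.x, dtype=float)
    a = (np.asarray(segment.a, dtype=float) if segment.a is not None
         else differentiate(segment.x, segment.sample_rate, order=2))
    if np.ptp(x) == 0.0:
        raise ValueError("constant position: Hooke regression undefined")
    res = stats.linregress(x, a)
    return float(res.rvalue ** 2)


def classify_hooke(rh2: float) -> str:
    """Nonlinearity class of a Hooke portrait at the 0.9 / 0.95 thresholds."""
    if rh2 > 0.95:
        return "quasi-linear"
    if rh2 > 0.9:
        return "borderline"
    return "substantial nonlinearity"


def portrait_data(segment: GestureSegment) -> dict[str, np.ndarray]:
    """Aligned phase-portrait (x, v) and Hooke-portrait (x, a) coordinates."""
    x = np.asarray(segment.x, dtype=float)
    v = np.asarray(segment.v, dtype=float)
    a = (np.asarray(segment.a, dtype=float) if segment.a is not None
         else differentiate(segment.x, segment.sample_rate, order=2))
    return {"phase": np.column_stack([x, v]),
            "hooke": np.column_stack([x, a])}


def target_correlation(
    segments: Sequence[GestureSegment],
    estimates: Sequence,
) -> pd.DataFrame:
    """Correlate reconstructed |T| with the empirical end position.

    For each articulatory variable, Pearson r between the magnitude of
    the target reconstructed from the discovered virtual target
    (T = 2 Tv - x0) and the magnitude of the token's final position
    (the position at the closing velocity zero crossing).
    """
    if len(segments) != len(estimates):
        raise ValueError("one estimate per segment required")
    groups: dict[str, list[tuple[float, float]]] = {}
    for seg, est in zip(segments, estimates):
        x0 = float(seg.x[0])
        Tv = est.Tv if hasattr(est, "Tv") else float(est)
        T = 2.0 * Tv - x0
        groups.setdefault(seg.variable, []).append(
            (abs(T), abs(float(seg.x[-1]))))
    rows = []
    for var in sorted(groups):
        pairs = np.asarray(groups[var])
        if len(pairs) < 3 or pairs[:, 0].std() == 0 or pairs[:, 1].std() == 0:
            rows.append({"variable": var, "n": len(pairs), "r": np.nan})
            continue
        r, p = stats.pearsonr(pairs[:, 0], pairs[:, 1])
        rows.append({"variable": var, "n": len(pairs), "r": float(r),
                     "p": float(p)})
    return pd.DataFrame(rows)
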