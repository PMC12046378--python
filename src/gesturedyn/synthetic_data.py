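"""Synthetic pellet-style recordings with ground-truth ledgers.

Generates articulatory recordings that emulate the processed structure
of pellet-tracked corpora: four articulatory variables (LA, TT, TD,
TR) sampled at 160 Hz, organized as interpause intervals containing
chains of gesture tokens.  Each token is one movement of a damped
mass-spring oscillator with known parameters; lip aperture is emitted
as upper/lower lip vertical channels and tongue variables as 2-D
sensor coordinates obtained by embedding the latent 1-D signal along a
fixed orientation, so that the preprocessing stages (lip-aperture
differencing, principal-component projection, velocity-zero-crossing
segmentation) can be validated against the ledger.

Not emulated: X-ray measurement physics, pellet mistracking, head
correction, or forced alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .oscillators import GestureParams, Trajectory, simulate, critical_damping
from .preprocess import PelletRecording

__all__ = [
    "CorpusSpec",
    "TokenRecord",
    "TokenLedger",
    "generate_token",
    "generate_recording",
]

_SENSOR_OF = {"TT": "T1", "TD": "T3", "TR": "T4"}


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a synthetic gesture corpus.

    ``n_tokens`` is per articulatory variable.  Token time scales are
    controlled by ``duration_range``: stiffness is derived from the
    drawn duration via the undamped half-period relation k = (pi/t)^2
    (stiffness sets time-to-target), then clamped to ``k_range``.
    ``damping_mode`` is "undamped" (the regime the discovered linear
    models occupy), "critical" (the classical task-dynamic setting), or
    ("fraction", lo, hi) for damping drawn as that fraction of critical.
    ``d_fraction_range`` draws the cubic stiffness as a fraction of k,
    normalized by squared movement amplitude so the cubic/linear force
    ratio at the start of movement equals the fraction (the d = 0.95 k
    convention at unit amplitude).  ``noise_frac``, when set, overrides
    ``noise_sd`` with a per-token noise level of that fraction of the
    token's oscillation amplitude — half the movement excursion, i.e.
    the amplitude of the half-cycle about the virtual target.
    Positions are in signal units
    (mm-like); ``duration_range`` caps below the 200 ms token-inclusion
    rule so clean tokens are never excluded by duration.
    """

    n_tokens: int = 50
    variables: tuple[str, ...] = ("LA", "TT", "TD", "TR")
    duration_range: tuple[float, float] = (0.08, 0.19)
    k_range: tuple[float, float] = (250.0, 3000.0)
    damping_mode: str | tuple = "undamped"
    d_fraction_range: tuple[float, float] = (0.0, 0.0)
    start_range: tuple[float, float] = (6.0, 14.0)
    target_range: tuple[float, float] = (4.0, 16.0)
    min_amplitude: float = 1.5
    sample_rate: float = 160.0
    noise_sd: float = 0.05
    noise_frac: float | None = None
    tokens_per_interval: tuple[int, int] = (3, 8)
    pause_duration_range: tuple[float, float] = (0.15, 0.4)
    orth_jitter_sd: float = 0.02
    lip_baseline: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_range", "k_range", "start_range",
                     "target_range", "pause_duration_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0 or self.orth_jitter_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be positive")


@dataclass
class TokenRecord:
    """Ground truth for one emitted gesture token.

    ``start``/``stop`` are half-open recording sample indices of the
    velocity lobe (both ends sit at velocity zero crossings).
    """

    token_id: int
    variable: str
    start: int
    stop: int
    params: GestureParams
    family: str  # "linear" or "cubic"
    amplitude: float = 0.0  # movement amplitude |x_end - x0|


@dataclass
class TokenLedger:
    """Ground-truth ledger for one synthetic recording."""

    tokens: list[TokenRecord]
    pauses: list[tuple[int, int]]  # half-open sample spans
    holds: dict[str, list[tuple[int, int]]]  # constant-latent spans per var
    embeddings: dict[str, dict]
    sample_rate: float
    n_samples: int

    def tokens_for(self, variable: str) -> list[TokenRecord]:
        return [t for t in self.tokens if t.variable == variable]

    def to_json(self) -> str:
        def enc(tok: TokenRecord) -> dict:
            d = asdict(tok)
            d["params"].pop("m", None)
            return d
        return json.dumps({
            "tokens": [enc(t) for t in self.tokens],
            "pauses": self.pauses,
            "holds": self.holds,
            "embeddings": {
                v: {k: (list(val) if isinstance(val, np.ndarray) else val)
                    for k, val in emb.items()}
                for v, emb in self.embeddings.items()},
            "sample_rate": self.sample_rate,
            "n_samples": self.n_samples,
        })

    @classmethod
    def from_json(cls, s: str) -> "TokenLedger":
        d = json.loads(s)
        tokens = [
            TokenRecord(
                token_id=t["token_id"], variable=t["variable"],
                start=t["start"], stop=t["stop"],
                params=GestureParams(**t["params"]), family=t["family"],
                amplitude=t.get("amplitude", 0.0))
            for t in d["tokens"]
        ]
        return cls(
            tokens=tokens,
            pauses=[tuple(p) for p in d["pauses"]],
            holds={v: [tuple(h) for h in hs] for v, hs in d["holds"].items()},
            embeddings=d["embeddings"],
            sample_rate=d["sample_rate"],
            n_samples=d["n_samples"],
        )


def _draw_damping_fraction(spec: CorpusSpec, rng) -> float:
    mode = spec.damping_mode
    if mode == "undamped":
        return 0.0
    if mode == "critical":
        return 1.0
    if isinstance(mode, (tuple, list)) and mode[0] == "fraction":
        return float(rng.uniform(mode[1], mode[2]))
    raise ValueError(f"unknown damping_mode {mode!r}")


def _draw_target(spec: CorpusSpec, rng, x0: float, direction: int) -> float:
    lo, hi = spec.target_range
    if direction > 0 and x0 + spec.min_amplitude > hi:
        direction = -1
    elif direction < 0 and x0 - spec.min_amplitude < lo:
        direction = 1
    if direction > 0:
        return float(rng.uniform(x0 + spec.min_amplitude, max(hi, x0 + spec.min_amplitude)))
    return float(rng.uniform(min(lo, x0 - spec.min_amplitude), x0 - spec.min_amplitude))


def _first_velocity_zero(params: GestureParams, t_max: float) -> float:
    """First interior velocity zero crossing of a simulated token."""
    fine = simulate(params, duration=t_max, dt=1e-4)
    v = fine.v
    moving = np.flatnonzero(np.abs(v) > 1e-6 * np.max(np.abs(v)))
    if moving.size == 0:
        return t_max
    i0 = moving[0]
    sign0 = np.sign(v[moving[0] + 1] if moving.size > 1 else v[i0])
    for i in range(i0 + 1, len(v)):
        if np.sign(v[i]) != sign0 and np.sign(v[i]) != 0:
            return fine.t[i]
    return t_max


def generate_token(
    spec: CorpusSpec,
    rng: np.random.Generator,
    x0: float | None = None,
    direction: int | None = None,
    noise_sd: float | None = None,
) -> tuple[Trajectory, GestureParams]:
    """Draw one gesture token: parameters, simulation, resampling, noise.

    Parameters are drawn from the spec ranges, the oscillator is
    integrated at fine internal resolution and evaluated on the coarse
    sample grid, and i.i.d. Gaussian noise is added to the position.
    The token spans one movement from x0 toward T, starting and ending
    at (near-)zero velocity; its duration is snapped to a whole number
    of samples, with stiffness adjusted so the closing velocity zero
    falls exactly on the final sample for the linear underdamped
    families.
    """
    sr = spec.sample_rate
    if x0 is None:
        x0 = float(rng.uniform(*spec.start_range))
    if direction is None:
        direction = int(rng.choice([-1, 1]))
    # the empirical target: the position at the closing velocity zero
    T_emp = _draw_target(spec, rng, x0, direction)
    if abs(T_emp - x0) < 1e-12:
        raise ValueError("zero-amplitude token: x0 == T")

    duration = float(rng.uniform(*spec.duration_range))
    frac_b = _draw_damping_fraction(spec, rng)
    frac_d = float(rng.uniform(*spec.d_fraction_range))

    if frac_b >= 1.0:  # critically damped: asymptotic, duration as drawn
        n = max(2, int(round(duration * sr)))
        duration = n / sr
        k = float(np.clip((np.pi / duration) ** 2, *spec.k_range))
        b = critical_damping(k)
        r = 0.0  # target approached asymptotically, no mirror overshoot
    else:
        # snap the half-cycle between velocity zeros to the sample grid
        n = max(2, int(round(duration * sr)))
        duration = n / sr
        omega_d = np.pi / duration
        k = omega_d**2 / (1.0 - frac_b**2)
        if not (spec.k_range[0] <= k <= spec.k_range[1]):
            k = float(np.clip(k, *spec.k_range))
            omega_d = np.sqrt(k * (1.0 - frac_b**2))
            n = max(2, int(round(np.pi / omega_d * sr)))
            duration = n / sr
            k = (np.pi / duration) ** 2 / (1.0 - frac_b**2)
        b = frac_b * critical_damping(k)
        # underdamped half cycle ends at T + (T - x0) r with
        # r = exp(-zeta pi / sqrt(1 - zeta^2)); undamped: the mirror 2T - x0
        r = float(np.exp(-np.pi * frac_b / np.sqrt(1.0 - frac_b**2)))

    # oscillator equilibrium ("virtual target") placed so the movement
    # ends at the drawn empirical target: T = (T_emp + r x0) / (1 + r)
    T = (T_emp + r * x0) / (1.0 + r)
    disp = abs(T - x0)  # initial displacement from equilibrium
    d = frac_d * k / disp**2
    params = GestureParams(k=k, b=b, T=T, d=d, x0=x0, v0=0.0)
    if d != 0.0:
        # the cubic force retards the movement; locate the true half cycle
        t_zero = _first_velocity_zero(params, 3.0 * duration)
        n = max(2, int(round(t_zero * sr)))
        duration = n / sr

    traj = simulate(params, duration=duration, dt=1.0 / sr)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    if spec.noise_frac is not None and noise_sd is None:
        sd = spec.noise_frac * abs(T_emp - x0) / 2.0
    x = traj.x + sd * rng.standard_normal(len(traj.x))
    noisy = Trajectory(t=traj.t, x=x, v=traj.v, a=traj.a,
                       sample_rate=traj.sample_rate)
    return noisy, params


def _pause_samples(spec: CorpusSpec, rng) -> int:
    dur = float(rng.uniform(*spec.pause_duration_range))
    return max(2, int(round(dur * spec.sample_rate)))


def _noise_profile(spec: CorpusSpec, ledger_tokens, n: int) -> np.ndarray:
    """Per-sample noise sd; constant unless noise_frac scaling is on."""
    if spec.noise_frac is None:
        return np.full(n, spec.noise_sd)
    sd = np.full(n, np.nan)
    for tok in ledger_tokens:
        sd[tok.start:tok.stop] = spec.noise_frac * tok.amplitude / 2.0
    # pauses/holds inherit the nearest token's level
    if np.all(np.isnan(sd)):
        return np.full(n, spec.noise_sd)
    idx = np.arange(n)
    good = ~np.isnan(sd)
    sd = np.interp(idx, idx[good], sd[good])
    return sd


def generate_recording(
    spec: CorpusSpec, rng: np.random.Generator | None = None,
) -> tuple[PelletRecording, TokenLedger]:
    """Generate one multichannel recording and its ground-truth ledger.

    The recording alternates speech intervals and annotated pauses,
    shared across articulatory variables.  Within a speech interval
    each variable runs a chain of gesture tokens, each starting from
    the previous token's end position with alternating movement
    direction; variables whose chain ends early hold their position for
    the remainder of the interval.  Lip aperture is emitted as upper
    and lower lip vertical channels; tongue variables as 2-D sensor
    coordinates embedding the latent signal along a fixed random
    orientation plus small orthogonal jitter.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    variables = spec.variables

    latent: dict[str, list[float]] = {v: [] for v in variables}
    tokens: list[TokenRecord] = []
    holds: dict[str, list[tuple[int, int]]] = {v: [] for v in variables}
    pauses_idx: list[tuple[int, int]] = []
    remaining = {v: spec.n_tokens for v in variables}
    cur = {v: float(rng.uniform(*spec.start_range)) for v in variables}
    direction = {v: int(rng.choice([-1, 1])) for v in variables}
    token_id = 0

    def add_pause() -> None:
        m = _pause_samples(spec, rng)
        start = len(latent[variables[0]])
        for v in variables:
            latent[v].extend([cur[v]] * m)
        pauses_idx.append((start, start + m))

    add_pause()
    while any(remaining.values()):
        chains: dict[str, np.ndarray] = {}
        recs: dict[str, list] = {}
        lo, hi = spec.tokens_per_interval
        for v in variables:
            m_v = min(remaining[v], int(rng.integers(lo, hi + 1))) \
                if remaining[v] else 0
            pieces = [np.array([cur[v]])]
            local = [0]
            rlist = []
            for _ in range(m_v):
                traj, params = generate_token(
                    spec, rng, x0=cur[v], direction=direction[v],
                    noise_sd=0.0)
                n_i = len(traj) - 1
                rlist.append((local[-1], local[-1] + n_i, params))
                pieces.append(traj.x[1:])
                local.append(local[-1] + n_i)
                cur[v] = float(traj.x[-1])
                # alternate relative to the realized movement direction
                # (the drawn direction may flip near the range edge)
                direction[v] = -int(np.sign(params.T - params.x0))
            remaining[v] -= m_v
            chains[v] = np.concatenate(pieces)
            recs[v] = rlist
        L = max(len(c) - 1 for c in chains.values())
        g0 = len(latent[variables[0]])
        for v in variables:
            c = chains[v]
            for s_loc, e_loc, params in recs[v]:
                tokens.append(TokenRecord(
                    token_id=token_id, variable=v,
                    start=g0 + s_loc, stop=g0 + e_loc,
                    params=params,
                    family="cubic" if params.d != 0.0 else "linear",
                    amplitude=float(abs(c[e_loc] - c[s_loc]))))
                token_id += 1
            pad = L - (len(c) - 1)
            latent[v].extend(c.tolist())
            if pad > 0:
                latent[v].extend([cur[v]] * pad)
                holds[v].append((g0 + len(c), g0 + L + 1))
        add_pause()

    n = len(latent[variables[0]])
    t = np.arange(n) / sr
    channels: dict[str, np.ndarray] = {}
    embeddings: dict[str, dict] = {}
    for v in variables:
        sig = np.asarray(latent[v])
        sd = _noise_profile(spec, [tk for tk in tokens if tk.variable == v], n)
        if v == "LA":
            e1 = sd / np.sqrt(2) * rng.standard_normal(n)
            e2 = sd / np.sqrt(2) * rng.standard_normal(n)
            channels["UL_y"] = spec.lip_baseline + e1
            channels["LL_y"] = spec.lip_baseline - sig + e2
            embeddings[v] = {"kind": "lips", "baseline": spec.lip_baseline}
        else:
            sensor = _SENSOR_OF[v]
            theta = float(rng.uniform(0.3, np.pi / 2 - 0.3))
            flip = float(rng.choice([-1.0, 1.0]))
            u = flip * np.array([np.cos(theta), np.sin(theta)])
            w = np.array([-u[1], u[0]])
            center = np.array([float(rng.uniform(30.0, 60.0)),
                               float(rng.uniform(-20.0, 10.0))])
            noisy = sig + sd * rng.standard_normal(n)
            jitter = spec.orth_jitter_sd * rng.standard_normal(n)
            xy = center[None, :] + noisy[:, None] * u[None, :] \
                + jitter[:, None] * w[None, :]
            channels[f"{sensor}_x"] = xy[:, 0]
            channels[f"{sensor}_y"] = xy[:, 1]
            embeddings[v] = {"kind": "pc", "sensor": sensor,
                             "u": u.tolist(), "center": center.tolist()}

    annotations = [
        (s / sr, (e - 1) / sr, "pause") for s, e in pauses_idx
    ]
    rec = PelletRecording(t=t, channels=channels, sample_rate=sr,
                          pauses=annotations)
    ledger = TokenLedger(
        tokens=tokens, pauses=pauses_idx, holds=holds,
        embeddings=embeddings, sample_rate=sr, n_samples=n)
    return rec, ledger
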