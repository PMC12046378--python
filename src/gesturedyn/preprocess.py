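"""Articulatory-variable extraction and kinematic segmentation.

Converts multichannel pellet recordings into one-dimensional
articulatory variables (lip aperture as the vertical inter-lip
distance; tongue variables as the first principal component of 2-D
sensor coordinates), differentiates them by finite differences, splits
signals at annotated pauses, and segments movements at velocity zero
crossings.  A gesture token is a single velocity peak or trough bounded
by two velocity zero crossings; tokens with multiple velocity peaks,
tokens longer than 200 ms, and tokens touching the recording edge are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "PelletRecording",
    "GestureSegment",
    "lip_aperture",
    "pca_first_component",
    "differentiate",
    "split_interpause",
    "segment_gestures",
    "count_velocity_peaks",
    "apply_exclusions",
    "extract_variables",
    "preprocess_recording",
]

#: maximum token duration (s); longer movements are treated as passive
MAX_DURATION_S = 0.2

#: relative prominence floor for counting velocity peaks within a token
PROMINENCE_FRAC = 0.1


@dataclass
class PelletRecording:
    """Uniformly sampled multichannel pellet recording with pause annotations.

    ``channels`` maps names such as ``UL_y``, ``LL_y``, ``T1_x``, ``T1_y``
    to 1-D arrays; ``pauses`` is a list of (start_s, end_s, label).
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    sample_rate: float
    pauses: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        for name, sig in self.channels.items():
            sig = np.asarray(sig, dtype=float)
            if len(sig) != n:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = sig
        prev_end = -np.inf
        for start, end, _ in sorted(self.pauses):
            if start < prev_end:
                raise ValueError("pause annotations overlap")
            prev_end = end

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path, pause_path=None) -> None:
        pd.DataFrame({"t": self.t, **self.channels}).to_csv(path, index=False)
        if pause_path is not None:
            pd.DataFrame(
                self.pauses, columns=["start_s", "end_s", "label"]
            ).to_csv(pause_path, index=False)

    @classmethod
    def from_csv(cls, path, pause_path=None) -> "PelletRecording":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        channels = {c: df[c].to_numpy() for c in df.columns if c != "t"}
        pauses = []
        if pause_path is not None:
            pdf = pd.read_csv(pause_path)
            pauses = [
                (float(r.start_s), float(r.end_s), str(r.label))
                for r in pdf.itertuples()
            ]
        dt = np.diff(t)
        return cls(t=t, channels=channels, sample_rate=1.0 / dt[0],
                   pauses=pauses)


@dataclass
class GestureSegment:
    """One velocity-lobe interval of an articulatory variable.

    Sample spans are 0-based half-open ``[start, stop)`` indices into
    the recording-level signal.
    """

    variable: str
    start: int
    stop: int
    x: np.ndarray
    v: np.ndarray
    sample_rate: float
    a: np.ndarray | None = None
    n_velocity_peaks: int = 1
    status: str = "kept"
    touches_edge: bool = False
    token_id: int | None = None
    #: unfiltered signal slice with margin, for discovery-time derivative
    #: estimation; ``context_offset`` is the segment start index within it
    context: np.ndarray | None = None
    context_offset: int = 0

    @property
    def duration(self) -> float:
        return (self.stop - self.start) / self.sample_rate


def lip_aperture(UL_y: np.ndarray, LL_y: np.ndarray) -> np.ndarray:
    """Lip aperture: distance between upper- and lower-lip vertical coordinates.

    Elementwise |UL_y - LL_y| (the Euclidean distance in one dimension).
    """
    UL_y = np.asarray(UL_y, dtype=float)
    LL_y = np.asarray(LL_y, dtype=float)
    if UL_y.shape != LL_y.shape:
        raise ValueError("lip channels must have equal length")
    return np.abs(UL_y - LL_y)


def pca_first_component(xy: np.ndarray, return_variance: bool = False):
    """Project 2-D sensor coordinates onto their first principal component.

    The series is centered and projected onto the leading eigenvector of
    its covariance; the sign is fixed so the projection correlates
    positively with the vertical (y) channel.  Optionally also returns
    the fraction of variance explained by the first component.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (n, 2) coordinate series")
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("degenerate channel: zero variance")
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, -1]
    proj = centered @ u
    y = centered[:, 1]
    s = proj @ y
    if s < 0 or (s == 0 and u[1] < 0):
        proj = -proj
    if return_variance:
        return proj, float(evals[-1] / total)
    return proj


def differentiate(x: np.ndarray, sample_rate: float, order: int = 1) -> np.ndarray:
    """Finite-difference derivative of a uniformly sampled signal.

    Second-order central differences in the interior and second-order
    one-sided differences at the edges; ``order=2`` applies the operator
    twice.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    dt = 1.0 / sample_rate
    d = np.gradient(x, dt, edge_order=2)
    if order == 2:
        d = np.gradient(d, dt, edge_order=2)
    return d


def split_interpause(
    n_or_signal, annotations: Sequence[tuple[float, float, str]],
    sample_rate: float,
) -> list[tuple[int, int]]:
    """Maximal half-open sample intervals lying strictly between pauses."""
    n = n_or_signal if isinstance(n_or_signal, int) else len(n_or_signal)
    edges = [0]
    for start, end, _ in sorted(annotations):
        i0 = int(np.ceil(start * sample_rate))
        i1 = int(np.floor(end * sample_rate)) + 1
        edges.extend([max(0, i0), min(n, i1)])
    edges.append(n)
    out = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= 2:
            out.append((lo, hi))
    return out


def _sign_runs(v: np.ndarray, dead_band: float = 0.0):
    """Contiguous runs of same-sign velocity; dead-band values count as zero."""
    s = np.sign(v)
    s[np.abs(v) <= dead_band] = 0
    runs = []
    start = None
    cur = 0
    for i, si in enumerate(s):
        if si == 0:
            if start is not None:
                runs.append((start, i, cur))
                start = None
            continue
        if start is None:
            start, cur = i, si
        elif si != cur:
            runs.append((start, i, cur))
            start, cur = i, si
    if start is not None:
        runs.append((start, len(s), cur))
    return runs


def segment_gestures(
    v: np.ndarray,
    sample_rate: float,
    variable: str = "",
    offset: int = 0,
    n_total: int | None = None,
    x: np.ndarray | None = None,
    dead_band: float = 0.0,
) -> list[GestureSegment]:
    """Segment a velocity signal into single-lobe gesture tokens.

    Boundaries sit at sign changes of ``v`` (zero crossings rounded to
    the nearest sample); each returned segment spans one contiguous
    same-sign velocity lobe.  ``offset``/``n_total`` place the local
    signal within the full recording so segments touching the recording
    edge can be flagged.
    """
    v = np.asarray(v, dtype=float)
    if n_total is None:
        n_total = offset + len(v)
    segments: list[GestureSegment] = []
    for start, stop, _ in _sign_runs(v, dead_band):
        touches = (offset + start <= 0) or (offset + stop >= n_total)
        seg = GestureSegment(
            variable=variable,
            start=offset + start,
            stop=offset + stop,
            x=x[start:stop] if x is not None else np.array([]),
            v=v[start:stop],
            sample_rate=sample_rate,
            touches_edge=touches,
        )
        if len(seg.v) >= 3:
            seg.n_velocity_peaks = count_velocity_peaks(seg)
        segments.append(seg)
    return segments


def count_velocity_peaks(
    segment: GestureSegment, prominence_frac: float = PROMINENCE_FRAC
) -> int:
    """Number of prominent local maxima of |v| within one segment.

    A maximum counts if its prominence exceeds ``prominence_frac`` times
    the segment's peak speed; a monotone speed profile counts as one
    peak (the endpoint maximum).
    """
    speed = np.abs(np.asarray(segment.v, dtype=float))
    if len(speed) < 3:
        return 1
    vmax = speed.max()
    if vmax == 0:
        return 0
    # pad so endpoint maxima are visible to the interior peak finder
    padded = np.concatenate([[0.0], speed, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * vmax)
    return max(1, len(peaks))


def apply_exclusions(
    segments: list[GestureSegment],
    max_duration: float = MAX_DURATION_S,
    prominence_frac: float = PROMINENCE_FRAC,
) -> tuple[list[GestureSegment], list[GestureSegment], dict]:
    """Apply the token-inclusion filters and tally exclusion reasons.

    Kept tokens have exactly one velocity peak, duration at most
    ``max_duration`` (200 ms default), and do not touch the recording
    edge.  Returns (kept, excluded, summary), where the summary carries
    counts and percentages per reason.
    """
    kept: list[GestureSegment] = []
    excluded: list[GestureSegment] = []
    counts = {"kept": 0, "excluded_multipeak": 0,
              "excluded_duration": 0, "excluded_edge": 0}
    for seg in segments:
        n_peaks = count_velocity_peaks(seg, prominence_frac)
        seg.n_velocity_peaks = n_peaks
        if seg.touches_edge:
            seg.status = "excluded_edge"
        elif n_peaks >= 2:
            seg.status = "excluded_multipeak"
        elif seg.duration > max_duration:
            seg.status = "excluded_duration"
        else:
            seg.status = "kept"
        counts[seg.status] += 1
        (kept if seg.status == "kept" else excluded).append(seg)
    total = max(1, len(segments))
    summary = {
        "n_total": len(segments),
        "counts": counts,
        "percent": {k: 100.0 * c / total for k, c in counts.items()},
    }
    return kept, excluded, summary


def lowpass(x: np.ndarray, sample_rate: float, cutoff_hz: float,
            order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth low-pass with even boundary reflection.

    The signal is extended by even reflection about its endpoints before
    filtering, which is the physically consistent continuation when a
    recording begins and ends at rest.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 7:
        return x.copy()
    sos = butter(order, cutoff_hz / (0.5 * sample_rate), "low", output="sos")
    ext = np.concatenate([x[1:][::-1], x, x[-2::-1]])
    return sosfiltfilt(sos, ext)[n - 1:2 * n - 1]


def extract_variables(rec: PelletRecording) -> dict[str, np.ndarray]:
    """Derive 1-D articulatory variables from recording channels.

    LA from the lip channels; TT/TD/TR as the first principal component
    of the T1/T3/T4 sensor coordinates (computed per recording, standing
    in for per-speaker per-sensor computation on real corpora).
    """
    out: dict[str, np.ndarray] = {}
    ch = rec.channels
    if "UL_y" in ch and "LL_y" in ch:
        out["LA"] = lip_aperture(ch["UL_y"], ch["LL_y"])
    for var, sensor in (("TT", "T1"), ("TD", "T3"), ("TR", "T4")):
        cx, cy = f"{sensor}_x", f"{sensor}_y"
        if cx in ch and cy in ch:
            out[var] = pca_first_component(np.column_stack([ch[cx], ch[cy]]))
    return out


def preprocess_recording(
    rec: PelletRecording,
    max_duration: float = MAX_DURATION_S,
    prominence_frac: float = PROMINENCE_FRAC,
    dead_band: float = 0.0,
    lowpass_hz: float | None = None,
    context_margin: int = 12,
) -> dict[str, dict]:
    """Full preprocessing pipeline for one recording.

    Extracts articulatory variables, optionally low-pass filters them
    (``lowpass_hz``; measurement-noise suppression before
    differentiation), differentiates, splits at pauses, segments each
    interpause interval at velocity zero crossings, and applies the
    exclusion filters.  Each segment also carries an unfiltered context
    slice (``context_margin`` samples each side) so discovery can apply
    its own derivative estimation to the raw signal.  Returns, per
    variable, a dict with ``kept``, ``excluded``, ``summary``, and the
    derived ``x``/``v``/``a`` signals.
    """
    results: dict[str, dict] = {}
    for var, x_raw in extract_variables(rec).items():
        x = (lowpass(x_raw, rec.sample_rate, lowpass_hz)
             if lowpass_hz else x_raw)
        v = differentiate(x, rec.sample_rate, order=1)
        acc = differentiate(x, rec.sample_rate, order=2)
        segments: list[GestureSegment] = []
        intervals = split_interpause(len(x), rec.pauses, rec.sample_rate)
        for lo, hi in intervals:
            segs = segment_gestures(
                v[lo:hi], rec.sample_rate, variable=var, offset=lo,
                n_total=len(x), x=x[lo:hi], dead_band=dead_band,
            )
            segments.extend(segs)
        for seg in segments:
            seg.a = acc[seg.start:seg.stop]
            c_lo = max(0, seg.start - context_margin)
            c_hi = min(len(x_raw), seg.stop + 1 + context_margin)
            seg.context = x_raw[c_lo:c_hi]
            seg.context_offset = seg.start - c_lo
        kept, excl, summary = apply_exclusions(
            segments, max_duration=max_duration,
            prominence_frac=prominence_frac,
        )
        results[var] = {
            "kept": kept, "excluded": excl, "summary": summary,
            "x": x, "v": v, "a": acc, "intervals": intervals,
        }
    return results


def segments_to_frame(segments: list[GestureSegment]) -> pd.DataFrame:
    """Tabulate segments as variable,start_sample,end_sample,duration_s,n_peaks,status."""
    return pd.DataFrame(
        {
            "variable": [s.variable for s in segments],
            "start_sample": [s.start for s in segments],
            "end_sample": [s.stop for s in segments],
            "duration_s": [s.duration for s in segments],
            "n_peaks": [s.n_velocity_peaks for s in segments],
            "status": [s.status for s in segments],
        }
    )
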