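"""Combined 119-dimensional aEEG feature set.

Three blocks are extracted from each recording and concatenated in a fixed
order:

* **basic** (4) — minimum, maximum and mean amplitude of the whole trace, and
  the percentage of the recording-level second-order *lower envelope* that
  lies strictly below 5 µV (a persistently depressed lower margin is the
  classic marker of an abnormal background);
* **histogram** (55) — amplitude distribution with 1 µV bins below 50 µV
  (50 bins) and 10 µV bins above (5 bins, the last open-ended), expressed as
  proportions so recordings of different lengths are comparable;
* **segment** (60) — the trace is cut into overlapping 3-minute windows
  stepped by 1.5 minutes; each window yields (upper boundary, lower boundary,
  mean, approximate entropy), where the boundaries are means of the window's
  second-order envelopes; the windows with the 10 highest and 5 lowest ApEn
  values are kept, 15 × 4 = 60 values.

Approximate entropy follows the standard Pincus convention: embedding
dimension ``m``, Chebyshev distance, tolerance ``r`` (default 0.2 × SD of the
window), self-matches included, ``ApEn = Φ_m(r) − Φ_{m+1}(r)`` with
``Φ_m(r)`` the mean natural log of the template match frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import Recording

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Amplitude threshold (µV) below which the lower margin counts as depressed.
LOWER_MARGIN_THRESHOLD_UV = 5.0

#: Histogram bin edges: [0,1),...,[49,50),[50,60),...,[90,inf) — 55 bins.
HISTOGRAM_EDGES = np.concatenate([np.arange(0.0, 51.0), [60.0, 70.0, 80.0, 90.0, np.inf]])
N_HISTOGRAM_BINS = len(HISTOGRAM_EDGES) - 1  # 55


@dataclass
class ApEnParams:
    """Approximate-entropy parameters.

    ``r`` is the tolerance in signal units; when ``None`` it is resolved per
    series as ``r_frac × SD``. A constant series has SD 0, no meaningful
    tolerance, and is perfectly regular — its ApEn is defined as 0.
    """

    m: int = 2
    r: Optional[float] = None
    r_frac: float = 0.2

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r is not None and self.r <= 0:
            raise ValueError("r must be > 0")
        if self.r is None and self.r_frac <= 0:
            raise ValueError("r_frac must be > 0")


@dataclass
class ExtractionConfig:
    """Window/step, ApEn and segment-selection settings for extraction."""

    window_s: float = 180.0
    step_s: float = 90.0
    n_top: int = 10
    n_bottom: int = 5
    apen: ApEnParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.apen is None:
            self.apen = ApEnParams()

    def validate(self) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be > 0")
        if self.n_top < 0 or self.n_bottom < 0 or self.n_top + self.n_bottom < 1:
            raise ValueError("need at least one selected segment")
        self.apen.validate()


@dataclass
class Segment:
    """One windowed slice of a recording."""

    index: int
    start_s: float
    samples: np.ndarray


@dataclass
class SegmentFeatures:
    """Per-segment summary: envelope boundaries, mean and ApEn."""

    upper_boundary: float
    lower_boundary: float
    mean_value: float
    apen: float


@dataclass
class CombinedFeatureVector:
    """Named 119-dimensional combined feature vector (4 + 55 + 60)."""

    values: np.ndarray
    names: Tuple[str, ...]
    n_basic: int = 4
    n_histogram: int = N_HISTOGRAM_BINS

    @property
    def basic(self) -> np.ndarray:
        return self.values[: self.n_basic]

    @property
    def histogram(self) -> np.ndarray:
        return self.values[self.n_basic : self.n_basic + self.n_histogram]

    @property
    def segment(self) -> np.ndarray:
        return self.values[self.n_basic + self.n_histogram :]

    def __len__(self) -> int:
        return int(self.values.size)


def feature_names(cfg: Optional[ExtractionConfig] = None) -> Tuple[str, ...]:
    """Stable column names: basic block, histogram block, segment block."""
    cfg = cfg or ExtractionConfig()
    names = ["basic_min", "basic_max", "basic_mean", "basic_pct_lower_under_5uV"]
    names += [f"hist_{i:03d}" for i in range(N_HISTOGRAM_BINS)]
    for k in range(cfg.n_top + cfg.n_bottom):
        names += [f"seg_{k:02d}_upper", f"seg_{k:02d}_lower", f"seg_{k:02d}_mean", f"seg_{k:02d}_apen"]
    return tuple(names)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_recording(rec: Recording, window_s: float = 180.0, step_s: float = 90.0) -> List[Segment]:
    """Cut a recording into overlapping windows.

    Yields ``floor((L − window) / step) + 1`` segments for a recording of
    duration ``L`` seconds; a 3-hour trace at the default 3-min window and
    1.5-min step gives 119 segments.
    """
    if step_s <= 0:
        raise ValueError("step_s must be > 0")
    L = rec.duration_s
    if L < window_s:
        raise ValueError(
            f"recording {rec.id!r} ({L:.0f} s) is shorter than the window ({window_s:.0f} s)"
        )
    win_len = int(round(window_s / rec.sample_interval))
    n_seg = int(np.floor((L - window_s) / step_s)) + 1
    segments = []
    for i in range(n_seg):
        start_s = i * step_s
        i0 = int(round(start_s / rec.sample_interval))
        segments.append(Segment(index=i, start_s=start_s, samples=rec.samples[i0 : i0 + win_len]))
    return segments


# ---------------------------------------------------------------------------
# Second-order envelope
# ---------------------------------------------------------------------------

def _extrema_interp(x: np.ndarray, find_max: bool) -> np.ndarray:
    # One pass: linear interpolation through local extrema; endpoints count as
    # extrema so the result spans the full length. Plateau points qualify.
    n = x.size
    if n < 3:
        return x.copy()
    inner = np.arange(1, n - 1)
    if find_max:
        keep = (x[inner] >= x[inner - 1]) & (x[inner] >= x[inner + 1])
    else:
        keep = (x[inner] <= x[inner - 1]) & (x[inner] <= x[inner + 1])
    idx = np.concatenate([[0], inner[keep], [n - 1]])
    return np.interp(np.arange(n), idx, x[idx])


def second_order_envelope(samples: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Upper and lower second-order envelopes of a series.

    Each envelope is two iterated passes of local-extremum linear
    interpolation (endpoints treated as extrema), which tracks the outer edge
    of the aEEG band rather than individual oscillations.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("envelope needs at least 3 samples")
    upper = _extrema_interp(_extrema_interp(x, True), True)
    lower = _extrema_interp(_extrema_interp(x, False), False)
    return upper, lower


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

def _phi(x: np.ndarray, m: int, r: float) -> float:
    # Mean log match frequency Φ_m(r); self-matches included so every count
    # is >= 1 and the log is finite.
    n_vec = x.size - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    c = np.count_nonzero(dist <= r, axis=1) / n_vec
    return float(np.mean(np.log(c)))


def apen(samples: Sequence[float], params: Optional[ApEnParams] = None) -> float:
    """Approximate entropy ``Φ_m(r) − Φ_{m+1}(r)`` of a series.

    Requires ``N >= m + 2`` so both Φ terms are defined. With self-matches
    included the value is non-negative; a constant series returns exactly 0.
    """
    params = params or ApEnParams()
    params.validate()
    x = np.asarray(samples, dtype=float)
    m = params.m
    if x.size < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {x.size}")
    r = params.r
    if r is None:
        sd = float(np.std(x))
        if sd == 0.0:
            return 0.0  # constant series: perfectly regular
        r = params.r_frac * sd
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    return _phi(x, m, r) - _phi(x, m + 1, r)


# ---------------------------------------------------------------------------
# Feature blocks
# ---------------------------------------------------------------------------

def basic_features(rec: Recording) -> np.ndarray:
    """(min, max, mean, % of the lower envelope strictly below 5 µV)."""
    upper, lower = second_order_envelope(rec.samples)
    pct = 100.0 * float(np.mean(lower < LOWER_MARGIN_THRESHOLD_UV))
    return np.array(
        [float(rec.samples.min()), float(rec.samples.max()), float(rec.samples.mean()), pct]
    )


def histogram_features(rec: Recording) -> np.ndarray:
    """55 amplitude-histogram proportions (1 µV bins to 50 µV, 10 µV above)."""
    counts, _ = np.histogram(rec.samples, bins=HISTOGRAM_EDGES)
    return counts / rec.n_samples


def segment_feature_table(
    segments: Sequence[Segment], params: Optional[ApEnParams] = None
) -> List[SegmentFeatures]:
    """Per-segment (upper, lower, mean, ApEn) rows."""
    if not segments:
        raise ValueError("segment list is empty")
    params = params or ApEnParams()
    table = []
    for seg in segments:
        try:
            upper, lower = second_order_envelope(seg.samples)
            table.append(
                SegmentFeatures(
                    upper_boundary=float(upper.mean()),
                    lower_boundary=float(lower.mean()),
                    mean_value=float(seg.samples.mean()),
                    apen=apen(seg.samples, params),
                )
            )
        except ValueError as exc:
            raise ValueError(f"segment {seg.index}: {exc}") from exc
    return table


def select_segments_by_apen(
    table: Sequence[SegmentFeatures], n_top: int = 10, n_bottom: int = 5
) -> np.ndarray:
    """Keep the highest- and lowest-ApEn segments and flatten their features.

    Rows are emitted top block first (rank 1 = highest ApEn) then bottom block
    (rank 1 = lowest ApEn), each row contributing (upper, lower, mean, apen).
    Ties in ApEn are broken toward the lower segment index.
    """
    need = n_top + n_bottom
    if len(table) < need:
        raise ValueError(f"need at least {need} segments, got {len(table)}")
    order = sorted(range(len(table)), key=lambda i: (table[i].apen, i))  # ascending
    chosen = list(reversed(order[-n_top:])) + order[:n_bottom] if n_top else order[:n_bottom]
    out = []
    for i in chosen:
        row = table[i]
        out.extend([row.upper_boundary, row.lower_boundary, row.mean_value, row.apen])
    return np.asarray(out)


def extract_combined(rec: Recording, cfg: Optional[ExtractionConfig] = None) -> CombinedFeatureVector:
    """Full combined vector: basic(4) ‖ histogram(55) ‖ selected segments(60)."""
    cfg = cfg or ExtractionConfig()
    cfg.validate()
    segments = segment_recording(rec, cfg.window_s, cfg.step_s)
    table = segment_feature_table(segments, cfg.apen)
    seg_block = select_segments_by_apen(table, cfg.n_top, cfg.n_bottom)
    values = np.concatenate([basic_features(rec), histogram_features(rec), seg_block])
    return CombinedFeatureVector(values=values, names=feature_names(cfg))


def extract_matrix(
    recordings: Sequence[Recording], cfg: Optional[ExtractionConfig] = None
) -> Tuple[np.ndarray, Tuple[str, ...], List[Optional[str]]]:
    """Extract every recording into an ``(n, p)`` matrix plus names and labels."""
    cfg = cfg or ExtractionConfig()
    vecs = [extract_combined(r, cfg) for r in recordings]
    X = np.vstack([v.values for v in vecs]) if vecs else np.empty((0, len(feature_names(cfg))))
    return X, feature_names(cfg), [r.label for r in recordings]
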