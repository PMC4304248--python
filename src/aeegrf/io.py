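"""Reading, validation and writing of aEEG recordings and feature matrices.

The canonical on-disk format for a single recording is a two-column CSV
(``time_s,amplitude_uV``). aEEG traces are rectified amplitude trends, so
amplitudes must be finite and non-negative. EDF/EDF+ reading is optional and
requires :mod:`mne`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Recognised class labels for a recording.
LABELS = ("normal", "abnormal")

#: Nominal analysis duration in seconds (3 hours). Shorter recordings are
#: allowed (test fixtures are small) but trigger a warning.
DEFAULT_ANALYSIS_DURATION_S = 10_800.0

RECORDING_HEADER = ("time_s", "amplitude_uV")


class ValidationError(ValueError):
    """Raised when a recording or feature matrix violates an invariant."""


class ParseError(ValueError):
    """Raised when an input file is malformed; the message names the line."""


@dataclass
class Recording:
    """A rectified aEEG amplitude trace in microvolts.

    Parameters
    ----------
    id:
        Identifier used in manifests and file names.
    samples:
        Amplitude values in µV; finite, non-negative, at least two.
    sample_interval:
        Seconds per sample (> 0). aEEG trend traces are slow; 1 Hz default.
    label:
        Optional clinical class, ``"normal"`` or ``"abnormal"``.
    meta:
        Free-form provenance (synthesis seed, pattern name, source file).
    """

    id: str
    samples: np.ndarray
    sample_interval: float = 1.0
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError(f"samples must be 1-D, got shape {self.samples.shape}")
        if self.samples.size < 2:
            raise ValidationError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("amplitudes must be finite")
        if np.any(self.samples < 0):
            raise ValidationError("aEEG amplitudes are rectified and must be >= 0")
        if not (self.sample_interval > 0):
            raise ValidationError("sample_interval must be > 0")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        """Total duration covered by the samples, in seconds."""
        return self.samples.size * self.sample_interval

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


def check_duration(rec: Recording, expected_s: float = DEFAULT_ANALYSIS_DURATION_S) -> None:
    """Warn (do not fail) when a recording is shorter than the analysis window."""
    if rec.duration_s < expected_s:
        warnings.warn(
            f"recording {rec.id!r} covers {rec.duration_s:.0f} s, shorter than the "
            f"configured analysis duration of {expected_s:.0f} s",
            stacklevel=2,
        )


# ---------------------------------------------------------------------------
# Single-recording I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str = "csv") -> Recording:
    """Read one aEEG recording.

    CSV files must carry a ``time_s,amplitude_uV`` header. The sample interval
    is inferred as the median difference of the time column; time must be
    strictly increasing. The returned recording has no label.
    """
    path = Path(path)
    if format == "csv":
        return _read_recording_csv(path)
    if format == "edf":
        return _read_recording_edf(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'edf'")


def _read_recording_csv(path: Path) -> Recording:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns[:2]) != list(RECORDING_HEADER):
        raise ParseError(
            f"{path}: expected header {','.join(RECORDING_HEADER)!r}, got {list(df.columns)!r}"
        )
    for col in RECORDING_HEADER:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    amp = df["amplitude_uV"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"{path}: a recording needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValidationError(f"{path}: time column not strictly increasing at line {i + 3}")
    neg = np.nonzero(amp < 0)[0]
    if neg.size:
        raise ValidationError(f"{path}: negative amplitude at line {neg[0] + 2}")
    return Recording(id=path.stem, samples=amp, sample_interval=float(np.median(dt)))


def _read_recording_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # Volts -> µV
    return Recording(id=path.stem, samples=data, sample_interval=1.0 / raw.info["sfreq"])


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as the canonical two-column CSV (round-trip safe)."""
    path = Path(path)
    t = np.arange(rec.n_samples) * rec.sample_interval
    df = pd.DataFrame({RECORDING_HEADER[0]: t, RECORDING_HEADER[1]: rec.samples})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature-matrix I/O
# ---------------------------------------------------------------------------

def write_feature_matrix(
    vectors: Sequence,
    labels: Sequence[Optional[str]],
    path: str | Path,
    feature_names: Optional[Sequence[str]] = None,
) -> None:
    """Write extracted feature vectors plus a trailing ``label`` column.

    ``vectors`` are :class:`~aeegrf.features.CombinedFeatureVector` objects (or
    anything exposing ``values``/``names``). All vectors must share one length,
    equal to the length of the shared name list; column order is the stable
    extraction order (basic block, histogram block, segment block).
    """
    vectors = list(vectors)
    if len(vectors) != len(labels):
        raise ValidationError(
            f"{len(vectors)} vectors but {len(labels)} labels"
        )
    if not vectors and feature_names is None:
        raise ValidationError("cannot infer feature names from an empty vector list")
    if feature_names is None:
        feature_names = list(vectors[0].names)
    rows = []
    for i, v in enumerate(vectors):
        vals = np.asarray(getattr(v, "values", v), dtype=float)
        if vals.shape != (len(feature_names),):
            raise ValidationError(
                f"vector {i} has {vals.size} entries, expected {len(feature_names)}"
            )
        rows.append(vals)
    df = pd.DataFrame(np.asarray(rows).reshape(len(rows), len(feature_names)),
                      columns=list(feature_names))
    df["label"] = ["" if l is None else l for l in labels]
    df.to_csv(Path(path), index=False)


def read_feature_matrix(path: str | Path):
    """Read a feature matrix CSV back as ``(X, feature_names, labels)``.

    ``labels`` entries are ``None`` where the label cell was empty.
    """
    df = pd.read_csv(Path(path), keep_default_na=False, float_precision="round_trip")
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing 'label' column")
    names = [c for c in df.columns if c != "label"]
    X = df[names].to_numpy(dtype=float)
    labels = [l if l in LABELS else None for l in df["label"].astype(str)]
    return X, names, labels


def write_manifest(recs: Iterable[Recording], path: str | Path) -> None:
    """Write a dataset manifest CSV: id, label, seed, pattern."""
    rows = [
        {
            "id": r.id,
            "label": "" if r.label is None else r.label,
            "seed": r.meta.get("seed", ""),
            "pattern": r.meta.get("pattern", ""),
        }
        for r in recs
    ]
    pd.DataFrame(rows, columns=["id", "label", "seed", "pattern"]).to_csv(
        Path(path), index=False
    )
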