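"""Per-event predictor variables.

Eighteen predictors describe each transit: the natural logs of all 15
unordered pairwise ratios among the six optical cross sections (two of which
are, before the log, the body and wing depolarization ratios), the wingbeat
frequency, and the power of the first two harmonics relative to the
fundamental.  Log-ratios are invariant to the position coefficient and to
laser power, since every channel shares the beam.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from .signal import DecomposedEvent
from .simulate import SIGMA_COMPONENTS

__all__ = [
    "FEATURE_NAMES",
    "LOG_RATIO_PAIRS",
    "DELTA_BODY_FEATURE",
    "DELTA_WING_FEATURE",
    "WbfResult",
    "FeatureVector",
    "FeatureExtractionError",
    "LabeledDataset",
    "depolarization_ratio",
    "estimate_wbf",
    "build_feature_vector",
    "assemble_dataset",
]

# Pair order: all unordered pairs of the six components in SIGMA_COMPONENTS
# order.  SIGMA_COMPONENTS lists cross-polarized before co-polarized, so the
# depolarization pairs come out as ln(sigma_perp / sigma_par) = ln(delta).
LOG_RATIO_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(SIGMA_COMPONENTS, 2)
)
assert len(LOG_RATIO_PAIRS) == 15

DELTA_BODY_FEATURE = "lr_1320perp_b__1320par_b"
DELTA_WING_FEATURE = "lr_1320perp_w__1320par_w"

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"lr_{a}__{b}" for a, b in LOG_RATIO_PAIRS] + ["wbf_hz", "h1_power_ratio", "h2_power_ratio"]
)
assert len(FEATURE_NAMES) == 18
assert DELTA_BODY_FEATURE in FEATURE_NAMES and DELTA_WING_FEATURE in FEATURE_NAMES


class FeatureExtractionError(ValueError):
    """Event cannot yield a valid feature vector (reason in the message)."""


def depolarization_ratio(i_perp: float, i_par: float, g_factor: float = 1.0) -> float:
    """Linear depolarization ratio ``delta = G * I_perp / I_par``.

    Defined on intensities; with calibrated inputs (G folded in) it equals
    the cross-section ratio sigma_perp / sigma_par.
    """
    if i_par == 0:
        raise ValueError("depolarization ratio undefined: co-polarized intensity is zero")
    if i_par < 0 or i_perp < 0:
        raise ValueError("intensities must be non-negative")
    if g_factor <= 0:
        raise ValueError("g_factor must be > 0")
    return g_factor * i_perp / i_par


@dataclass
class WbfResult:
    """Wingbeat-frequency estimate for one event.

    ``detected`` is False when no spectral peak clears the noise floor by the
    configured factor; the event is then excluded from classification rather
    than given a fabricated frequency.
    """

    detected: bool
    wbf_hz: float = float("nan")
    h1_power_ratio: float = float("nan")
    h2_power_ratio: float = float("nan")
    peak_power: float = float("nan")
    noise_floor: float = float("nan")


@dataclass
class FeatureVector:
    """The 18 predictors for one event, ordered as FEATURE_NAMES."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (18,):
            raise ValueError("a feature vector has exactly 18 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector entries must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]


def comb_score(freqs: np.ndarray, psd: np.ndarray, candidates: np.ndarray, n_teeth: int = 3) -> np.ndarray:
    """Sum of spectral power at each candidate fundamental and its harmonics.

    Scoring f, 2f, 3f jointly rejects octave errors: a strong second harmonic
    alone cannot out-score the true fundamental's full comb.
    """
    score = np.zeros_like(candidates, dtype=float)
    for k in range(1, n_teeth + 1):
        score += np.interp(k * candidates, freqs, psd, left=0.0, right=0.0)
    return score


def _parabolic_refine(freqs: np.ndarray, psd: np.ndarray, i: int) -> float:
    """Sub-bin peak location via a parabola through log-power at i-1, i, i+1."""
    if i <= 0 or i >= len(psd) - 1:
        return float(freqs[i])
    a, b, c = psd[i - 1], psd[i], psd[i + 1]
    if min(a, b, c) <= 0:
        return float(freqs[i])
    la, lb, lc = np.log(a), np.log(b), np.log(c)
    denom = la - 2 * lb + lc
    if denom >= 0:
        return float(freqs[i])
    delta = 0.5 * (la - lc) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def estimate_wbf(
    wing_series: np.ndarray,
    sampling_rate_hz: float,
    f_range: tuple[float, float] = (150.0, 900.0),
    noise_floor_factor: float = 5.0,
    nperseg_max: int = 1024,
    zero_pad_factor: int = 4,
) -> WbfResult:
    """Estimate the wingbeat frequency from the wing component of a transit.

    Welch's method (Hann window, 50% overlap, segment length capped at
    ``nperseg_max``, zero-padded by ``zero_pad_factor``) yields the power
    spectrum; the fundamental is the candidate in ``f_range`` maximizing the
    comb score over (f, 2f, 3f), refined to sub-bin precision by parabolic
    interpolation of log power.  Harmonic power ratios are read off at the
    refined fundamental's multiples.
    """
    f_lo, f_hi = f_range
    if not (0 < f_lo < f_hi < sampling_rate_hz / 2):
        raise ValueError("f_range must satisfy 0 < min < max < Nyquist")
    x = np.asarray(wing_series, dtype=float)
    if len(x) / sampling_rate_hz < 3.0 / f_lo:
        raise ValueError(
            f"series too short for f_range min {f_lo} Hz: need >= {3.0 / f_lo:.4f} s"
        )
    nperseg = min(len(x), nperseg_max)
    freqs, psd = welch(
        x,
        fs=sampling_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=zero_pad_factor * nperseg,
        detrend="constant",
    )
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():
        raise ValueError("f_range contains no spectral bins")
    candidates = freqs[band]
    band_idx = np.flatnonzero(band)
    score = comb_score(freqs, psd, candidates)
    best = int(np.argmax(score))
    floor = float(np.median(psd[band]))
    threshold = noise_floor_factor * floor

    # The fundamental bin itself must clear the noise floor.  A near-pure
    # tone ties the comb score at its half-frequency subharmonic (whose own
    # bin is empty); promoting by octaves resolves that degeneracy.
    while psd[band_idx[best]] < threshold:
        f2 = 2.0 * candidates[best]
        if f2 > f_hi:
            break
        best = int(np.argmin(np.abs(candidates - f2)))
    f0_bin_index = int(band_idx[best])
    peak = float(psd[f0_bin_index])
    if floor > 0 and peak < threshold:
        return WbfResult(detected=False, peak_power=peak, noise_floor=floor)

    # walk to the local PSD maximum before refining (comb argmax can sit one
    # bin off the fundamental's own peak)
    i = f0_bin_index
    while 0 < i < len(psd) - 1 and psd[i + 1] > psd[i]:
        i += 1
    while 0 < i < len(psd) - 1 and psd[i - 1] > psd[i]:
        i -= 1
    f0 = _parabolic_refine(freqs, psd, i)

    p1 = float(np.interp(f0, freqs, psd))
    p2 = float(np.interp(2 * f0, freqs, psd, right=0.0))
    p3 = float(np.interp(3 * f0, freqs, psd, right=0.0))
    if p1 <= 0:
        return WbfResult(detected=False, peak_power=peak, noise_floor=floor)
    return WbfResult(
        detected=True,
        wbf_hz=f0,
        h1_power_ratio=p2 / p1,
        h2_power_ratio=p3 / p1,
        peak_power=peak,
        noise_floor=floor,
    )


def build_feature_vector(sigma: dict[str, float], wbf: WbfResult) -> FeatureVector:
    """Assemble the 18 predictors from the six cross sections and the WBF.

    Events with any non-positive cross section or an undetected wingbeat
    frequency cannot form a valid vector and raise
    :class:`FeatureExtractionError` (callers drop them with a logged reason).
    """
    missing = [c for c in SIGMA_COMPONENTS if c not in sigma]
    if missing:
        raise FeatureExtractionError(f"missing cross-section components: {missing}")
    bad = [c for c in SIGMA_COMPONENTS if sigma[c] <= 0]
    if bad:
        raise FeatureExtractionError(f"non-positive cross sections: {bad}")
    if not wbf.detected:
        raise FeatureExtractionError("no wingbeat frequency detected")
    values = [float(np.log(sigma[a] / sigma[b])) for a, b in LOG_RATIO_PAIRS]
    values += [wbf.wbf_hz, wbf.h1_power_ratio, wbf.h2_power_ratio]
    return FeatureVector(np.asarray(values))


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and a stable column order."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X rows must match y length")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X columns must match feature_names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.y.tolist()))

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[indices], self.y[indices], self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        if "label" not in df.columns:
            raise ValueError("feature table must contain a 'label' column")
        names = tuple(c for c in df.columns if c != "label")
        return cls(df[list(names)].to_numpy(dtype=float), df["label"].to_numpy(), names)

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        # round_trip parsing keeps write->read lossless for float64
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def assemble_dataset(
    events: Sequence[tuple[DecomposedEvent, str]],
    f_range: tuple[float, float] = (150.0, 900.0),
    noise_floor_factor: float = 5.0,
    wbf_channel: str = "i924",
) -> tuple[LabeledDataset, list[dict]]:
    """Extract features for many decomposed events into one labelled table.

    Events whose feature extraction fails (non-positive cross section,
    undetected wingbeat) are dropped; the returned drop log records each
    exclusion with its index, label and reason.  A class losing every event
    is an error, since the classifier downstream needs all classes populated.
    Cross sections must already be present on each event
    (:func:`entolidar.signal.extract_cross_sections`).
    """
    rows: list[np.ndarray] = []
    labels: list[str] = []
    drop_log: list[dict] = []
    seen: set[str] = set()
    for idx, (dec, label) in enumerate(events):
        seen.add(label)
        if dec.sigma is None:
            raise ValueError(f"event {idx}: cross sections not extracted yet")
        try:
            wbf = estimate_wbf(
                dec.wing(wbf_channel),
                dec.sampling_rate_hz,
                f_range=f_range,
                noise_floor_factor=noise_floor_factor,
            )
            fv = build_feature_vector(dec.sigma, wbf)
        except (FeatureExtractionError, ValueError) as exc:
            drop_log.append({"index": idx, "label": label, "reason": str(exc)})
            continue
        rows.append(fv.values)
        labels.append(label)
    surviving = set(labels)
    lost = sorted(seen - surviving)
    if lost:
        raise ValueError(f"classes lost all events to filters: {lost}")
    if not rows:
        raise ValueError("no events survived feature extraction")
    dataset = LabeledDataset(np.vstack(rows), np.asarray(labels))
    if drop_log:
        warnings.warn(f"dropped {len(drop_log)} of {len(events)} events during feature extraction")
    return dataset, drop_log
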