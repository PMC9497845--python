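"""Signal-feature battery for absorbance series and their amplitude sub-signals.

The full battery has 12 named features:

    MAV, WL, SSC, ZC, 4thAR, SampEN, Ceps, MFL, HFD, DFA, MF, SP

After amplitude-band decomposition the ZC, DFA and MF features are redundant
and are dropped, leaving the 9-feature reduced battery.

Conventions
-----------
* The "time" index of a series is its array index, not the wavenumber.
* Autoregressive coefficients are reported in the prediction-error-filter
  sign convention, i.e. ``A(z) = 1 + a1 z^-1 + ... + a4 z^-4``; the first
  cepstral coefficient of that model is ``c1 = -a1``.
* Sub-signal samples are treated as one contiguous series (gaps closed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import periodogram
from statsmodels.regression.linear_model import burg

from .errors import DegenerateInputError, ValidationError

FULL_BATTERY = (
    "MAV", "WL", "SSC", "ZC", "4thAR", "SampEN",
    "Ceps", "MFL", "HFD", "DFA", "MF", "SP",
)
REDUCED_DROPS = ("ZC", "DFA", "MF")
REDUCED_BATTERY = tuple(n for n in FULL_BATTERY if n not in REDUCED_DROPS)

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureMatrix",
    "FULL_BATTERY",
    "REDUCED_BATTERY",
    "mav",
    "waveform_length",
    "slope_sign_changes",
    "zero_crossings",
    "ar_coefficients",
    "ar4_coefficient",
    "sample_entropy",
    "cepstral_coefficient",
    "maximum_fractal_length",
    "higuchi_fd",
    "dfa_exponent",
    "median_frequency",
    "sum_of_peaks",
    "extract_features",
    "extract_matrix",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the battery.

    ``amp_threshold`` gates SSC and ZC; the default 1e-6 keeps the printed
    "1 micro-unit" magnitude in native absorbance units.
    """

    amp_threshold: float = 1e-6
    sampen_m: int = 2
    sampen_r: float = 0.2
    # short regular sub-signals can have zero template matches; with this set
    # the estimator's upper bound -ln(2/((N-m-1)(N-m))) stands in for +inf
    sampen_use_ceiling: bool = True
    ar_order: int = 4
    hfd_kmax: int = 8
    dfa_scales: tuple[int, ...] | None = None  # None -> log-spaced 4..N//4
    reduced_after_lsdl: bool = False

    def __post_init__(self):
        if self.ar_order != 4:
            raise ValidationError("ar_order is fixed at 4")
        if self.sampen_m < 1:
            raise ValidationError("sampen_m must be >= 1")
        if self.hfd_kmax < 2:
            raise ValidationError("hfd_kmax must be >= 2")
        if self.sampen_r <= 0:
            raise ValidationError("sampen_r must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return REDUCED_BATTERY if self.reduced_after_lsdl else FULL_BATTERY

    @property
    def config_id(self) -> str:
        kind = "reduced" if self.reduced_after_lsdl else "full"
        return (
            f"{kind}-battery/eps={self.amp_threshold:g}/m={self.sampen_m}"
            f"/r={self.sampen_r:g}/kmax={self.hfd_kmax}"
        )


@dataclass
class FeatureVector:
    """Named feature values for one (sub-)signal; NaN entries are flagged."""

    values: dict[str, float]
    missing: set[str] = field(default_factory=set)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.values], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """Per-sample feature rows plus labels — the classifier input table."""

    X: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray  # dtype=object/str
    sample_ids: np.ndarray | None = None
    is_synthetic: np.ndarray | None = None  # set by SMOTE balancing

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length mismatch")
        if self.X.shape[0] != len(self.labels):
            raise ValidationError("labels length mismatch")
        if self.is_synthetic is None:
            self.is_synthetic = np.zeros(len(self.labels), dtype=bool)
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"s{i:04d}" for i in range(len(self.labels))], dtype=object
            )

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> dict[str, int]:
        uniq, cnt = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = self.labels
        df["is_synthetic"] = self.is_synthetic.astype(int)
        return df

    @classmethod
    def from_dataframe(cls, df) -> "FeatureMatrix":
        cols = [c for c in df.columns if c not in ("sample_id", "label", "is_synthetic")]
        return cls(
            X=df[cols].to_numpy(dtype=float),
            feature_names=tuple(cols),
            labels=df["label"].to_numpy(dtype=object),
            sample_ids=df["sample_id"].to_numpy(dtype=object)
            if "sample_id" in df
            else None,
            is_synthetic=df["is_synthetic"].to_numpy(dtype=bool)
            if "is_synthetic" in df
            else None,
        )


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("empty series")
    return arr


def mav(x) -> float:
    """Mean absolute value."""
    return float(np.mean(np.abs(_as_series(x))))


def waveform_length(x) -> float:
    """Total variation: sum of absolute successive differences."""
    return float(np.sum(np.abs(np.diff(_as_series(x)))))


def slope_sign_changes(x, eps: float = 1e-6) -> int:
    """Count of interior samples where the slope flips sign.

    A flip at index i requires ``(x_i - x_{i-1}) * (x_i - x_{i+1}) >= eps``.
    """
    arr = _as_series(x)
    if arr.size < 3:
        return 0
    prod = (arr[1:-1] - arr[:-2]) * (arr[1:-1] - arr[2:])
    return int(np.count_nonzero(prod >= eps))


def zero_crossings(x, eps: float = 1e-6) -> int:
    """Sign changes between consecutive samples with step at least ``eps``."""
    arr = _as_series(x)
    if arr.size < 2:
        return 0
    sign_change = np.sign(arr[:-1]) != np.sign(arr[1:])
    big_enough = np.abs(np.diff(arr)) >= eps
    return int(np.count_nonzero(sign_change & big_enough))


def ar_coefficients(x, order: int = 4) -> np.ndarray:
    """Burg-method AR fit of the mean-removed series.

    Returns the prediction-error-filter coefficients (a1..a_order) of
    ``A(z) = 1 + a1 z^-1 + ...``, i.e. the negated autoregression weights.
    """
    arr = _as_series(x)
    if arr.size < 2 * order:
        raise ValidationError(f"AR({order}) fit needs at least {2 * order} samples")
    centered = arr - arr.mean()
    if np.allclose(centered, 0):
        raise DegenerateInputError("constant series has no AR representation")
    rho, _sigma2 = burg(centered, order=order, demean=False)
    return -np.asarray(rho, dtype=float)


def ar4_coefficient(x) -> float:
    """Fourth coefficient of the order-4 Burg AR fit."""
    return float(ar_coefficients(x, order=4)[3])


def sample_entropy(x, m: int = 2, r_multiplier: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) for template matches at Chebyshev tolerance r.

    B counts pairs of m-length templates (self-matches excluded) among the
    first N-m windows; A counts pairs of the corresponding (m+1)-length
    templates. Returns ``inf`` when no (m+1)-length pair matches.
    """
    arr = _as_series(x)
    n = arr.size
    if n < 2 * (m + 1):
        raise ValidationError(f"sample entropy needs at least {2 * (m + 1)} samples")
    sd = float(np.std(arr))
    if sd == 0:
        raise DegenerateInputError("constant series: tolerance r would be zero")
    r = r_multiplier * sd

    # Chebyshev template matches via diagonal-AND of the pairwise |dx| <= r
    # matrix: match(i,j; m) = AND_k |x[i+k]-x[j+k]| <= r. The first N-m
    # templates serve both orders so every m-template extends to m+1.
    n_templates = n - m
    close = np.abs(arr[:, None] - arr[None, :]) <= r
    match = close
    for k in range(1, m):
        match = match[:-1, :-1] & close[k:, k:]
    match_m1 = match[:-1, :-1] & close[m:, m:]  # (m+1)-length matches
    b = int(match[:n_templates, :n_templates].sum()) - n_templates
    a = int(match_m1[:n_templates, :n_templates].sum()) - n_templates
    if b <= 0 or a <= 0:
        return math.inf
    return float(-math.log(a / b))


def sampen_ceiling(n: int, m: int = 2) -> float:
    """Largest estimable sample entropy at length n: -ln(2 / ((N-m-1)(N-m)))."""
    if n - m - 1 <= 0:
        raise ValidationError("series too short for a sample-entropy bound")
    return float(math.log((n - m - 1) * (n - m) / 2.0))


def cepstral_coefficient(x) -> float:
    """First cepstral coefficient c1 = -a1 of the order-4 AR model."""
    return float(-ar_coefficients(x, order=4)[0])


def maximum_fractal_length(x) -> float:
    """log10 of the Euclidean length of the first-difference vector."""
    arr = _as_series(x)
    tv2 = float(np.sum(np.diff(arr) ** 2))
    if tv2 == 0:
        return -math.inf
    return float(np.log10(np.sqrt(tv2)))


def higuchi_fd(x, kmax: int = 8) -> float:
    """Higuchi fractal dimension from the slope of log L(k) vs log(1/k)."""
    arr = _as_series(x)
    n = arr.size
    if n < 2 * kmax:
        raise ValidationError(f"Higuchi FD with kmax={kmax} needs >= {2 * kmax} samples")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(arr[idx])))
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    if np.any(lk <= 0):
        raise DegenerateInputError("zero curve length at some scale")
    ks = np.arange(1, kmax + 1)
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


def _default_dfa_scales(n: int) -> np.ndarray:
    hi = n // 4
    if hi < 4:
        return np.array([], dtype=int)
    return np.unique(np.round(np.geomspace(4, hi, num=10)).astype(int))


def dfa_exponent(x, scales: Sequence[int] | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent (linear detrending)."""
    arr = _as_series(x)
    n = arr.size
    sc = np.asarray(scales, dtype=int) if scales is not None else _default_dfa_scales(n)
    sc = sc[(sc >= 4) & (sc <= n // 2)]
    if sc.size < 3:
        raise ValidationError("DFA needs at least 3 usable scales")
    profile = np.cumsum(arr - arr.mean())
    fn = np.empty(sc.size)
    for i, s in enumerate(sc):
        nwin = n // s
        segs = profile[: nwin * s].reshape(nwin, s)
        t = np.arange(s)
        # linear detrend per window via least squares
        tm = t - t.mean()
        denom = float(np.sum(tm * tm))
        slopes = segs @ tm / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tm
        fn[i] = np.sqrt(np.mean(resid**2))
    if np.any(fn <= 0):
        raise DegenerateInputError("zero fluctuation at some scale")
    alpha, _ = np.polyfit(np.log(sc), np.log(fn), 1)
    return float(alpha)


def median_frequency(x) -> float:
    """Frequency (cycles/sample) splitting the periodogram power in half."""
    arr = _as_series(x)
    f, pxx = periodogram(arr - arr.mean(), fs=1.0)
    total = float(np.sum(pxx))
    if total <= 0:
        raise DegenerateInputError("zero total power")
    cum = np.cumsum(pxx)
    half = total / 2.0
    j = int(np.searchsorted(cum, half))
    if j == 0:
        return float(f[0])
    # linear interpolation between periodogram bins
    frac = (half - cum[j - 1]) / (cum[j] - cum[j - 1])
    return float(f[j - 1] + frac * (f[j] - f[j - 1]))


def sum_of_peaks(x) -> int:
    """Count of local maxima: x_i >= x_{i-1} and x_i > x_{i+1}."""
    arr = _as_series(x)
    if arr.size < 3:
        return 0
    return int(np.count_nonzero((arr[1:-1] >= arr[:-2]) & (arr[1:-1] > arr[2:])))


# ---------------------------------------------------------------------------
# battery extraction
# ---------------------------------------------------------------------------

_MIN_LEN_REDUCED = 8


def min_signal_length(config: FeatureConfig) -> int:
    if config.reduced_after_lsdl:
        return _MIN_LEN_REDUCED
    return max(2 * config.hfd_kmax, 2 * config.ar_order, 24)


def extract_features(signal, config: FeatureConfig | None = None) -> FeatureVector:
    """Compute the battery on a Spectrum, SubSignal or plain array."""
    config = config or FeatureConfig()
    if hasattr(signal, "retained"):
        x = np.asarray(signal.retained, dtype=float)
    elif hasattr(signal, "intensities"):
        x = np.asarray(signal.intensities, dtype=float)
    else:
        x = np.asarray(signal, dtype=float).ravel()
    need = min_signal_length(config)
    if x.size < need:
        raise ValidationError(
            f"battery '{config.config_id}' needs >= {need} samples, got {x.size}"
        )

    values: dict[str, float] = {}
    missing: set[str] = set()

    def put(name: str, fn):
        try:
            v = fn()
        except DegenerateInputError:
            v = math.nan
        if not math.isfinite(v):
            missing.add(name)
            v = math.nan
        values[name] = float(v)

    eps = config.amp_threshold
    put("MAV", lambda: mav(x))
    put("WL", lambda: waveform_length(x))
    put("SSC", lambda: slope_sign_changes(x, eps))
    if not config.reduced_after_lsdl:
        put("ZC", lambda: zero_crossings(x, eps))
    put("4thAR", lambda: ar4_coefficient(x))

    def _sampen():
        v = sample_entropy(x, config.sampen_m, config.sampen_r)
        if math.isinf(v) and config.sampen_use_ceiling:
            return sampen_ceiling(x.size, config.sampen_m)
        return v

    put("SampEN", _sampen)
    put("Ceps", lambda: cepstral_coefficient(x))
    put("MFL", lambda: maximum_fractal_length(x))
    # short sub-signals: shrink kmax so the estimator stays defined
    kmax = min(config.hfd_kmax, x.size // 2)
    put("HFD", lambda: higuchi_fd(x, kmax))
    if not config.reduced_after_lsdl:
        put("DFA", lambda: dfa_exponent(x, config.dfa_scales))
        put("MF", lambda: median_frequency(x))
    put("SP", lambda: sum_of_peaks(x))

    ordered = {n: values[n] for n in config.names}
    return FeatureVector(values=ordered, missing=missing)


def extract_matrix(
    signals,
    config: FeatureConfig | None = None,
    labels: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Battery over a collection (SpectraDataset, list of SubSignals/arrays)."""
    config = config or FeatureConfig()
    sig_list = list(signals)
    if labels is None and hasattr(signals, "labels"):
        labels = signals.labels
    if labels is None:
        raise ValidationError("labels are required to build a FeatureMatrix")
    if sample_ids is None:
        ids = []
        for i, s in enumerate(sig_list):
            ids.append(
                getattr(s, "sample_id", None) or getattr(s, "parent_id", None) or f"s{i:04d}"
            )
        sample_ids = ids
    rows = [extract_features(s, config) for s in sig_list]
    X = np.vstack([r.as_array() for r in rows]) if rows else np.empty((0, len(config.names)))
    return FeatureMatrix(
        X=X,
        feature_names=config.names,
        labels=np.asarray(list(labels), dtype=object),
        sample_ids=np.asarray(list(sample_ids), dtype=object),
    )
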