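"""The 70-dimensional multi-domain feature vector and 4x70 sequence.

Families, in fixed manifest order:

* time domain (12): mean, variance, coefficient of variation, skewness,
  kurtosis, IQR, Hjorth activity/mobility/complexity, zero crossings,
  Hurst exponent (rescaled range), DFA scaling exponent;
* frequency domain (6): sub-band power ratio 60-140/0-60 Hz (computed
  on the wide-band, pre-low-pass signal), mean PSD, mean ASD, spectral
  centroid, spectral kurtosis, normalized spectral entropy;
* time-frequency (2): first and third quartiles of the fuzzy entropies
  of the first five EMD intrinsic mode functions;
* nonlinear (50): Kraskov (Kozachenko-Leonenko) entropy, Renyi (alpha=2),
  permutation (order 3), sample (m=2, r=0.2*sigma), Shannon entropy,
  energy, SVD entropy, Petrosian, Katz and Higuchi fractal dimensions
  - each on the five DWT sub-bands A4, D4, D3, D2, D1.

Degenerate inputs (constant or zero-energy signals) map to finite
sentinel values (0) so downstream models never see NaN or inf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial import cKDTree
from scipy.special import digamma

from .emd import emd, fuzzy_entropy
from .preprocess import (
    SUBBAND_ORDER,
    PreprocessConfig,
    SubbandSet,
    bandpass,
    decompose_subbands,
    resample_to,
    split_timesteps,
)
from .types import Segment

__all__ = [
    "FeatureConfig",
    "FeatureSequence",
    "FEATURE_NAMES",
    "time_domain_features",
    "frequency_domain_features",
    "emd_fuzzy_features",
    "subband_entropy_features",
    "extract_feature_vector",
    "extract_feature_sequence",
]


@dataclass
class FeatureConfig:
    """Entropy and estimator parameters (defaults follow the method's table)."""

    sampen_m: int = 2
    sampen_r: float = 0.2  # times the sub-band SD
    perment_order: int = 3
    renyi_alpha: float = 2.0
    kraskov_k: int = 4
    fuzzy_m: int = 2
    fuzzy_r: float = 0.2  # times the IMF SD
    n_imfs: int = 5
    higuchi_kmax: int = 10
    svd_embed_dim: int = 10
    welch_window_seconds: float = 1.0
    spr_num_band: tuple[float, float] = (60.0, 140.0)
    spr_den_band: tuple[float, float] = (0.0, 60.0)


TIME_NAMES = [
    "mean", "variance", "cv", "skewness", "kurtosis", "iqr",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "zero_crossings", "hurst", "dfa",
]
FREQ_NAMES = [
    "spr", "psd_mean", "asd_mean", "spectral_centroid",
    "spectral_kurtosis", "spectral_entropy",
]
TF_NAMES = ["emd_fuzzyent_q1", "emd_fuzzyent_q3"]
ENTROPY_KINDS = [
    "kraskov", "renyi", "permutation", "sample", "shannon",
    "energy", "svd_entropy", "pfd", "kfd", "hfd",
]
SUBBAND_NAMES = [f"{kind}_{band}" for kind in ENTROPY_KINDS for band in SUBBAND_ORDER]

#: fixed, release-stable order of all 70 features
FEATURE_NAMES: list[str] = TIME_NAMES + FREQ_NAMES + TF_NAMES + SUBBAND_NAMES
assert len(FEATURE_NAMES) == 70


@dataclass
class FeatureSequence:
    """Ordered per-timestep feature vectors, shape (n_timesteps, 70)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError("value/name length mismatch")


def _safe(x: float) -> float:
    return float(x) if np.isfinite(x) else 0.0


# ---------------------------------------------------------------------------
# time domain


def _quantile_n_plus_1(xs: np.ndarray, p: float) -> float:
    """(N+1)*p order-statistic quantile with linear interpolation."""
    n = xs.size
    h = (n + 1) * p  # 1-based fractional index
    if h <= 1:
        return float(xs[0])
    if h >= n:
        return float(xs[-1])
    lo = int(np.floor(h))
    frac = h - lo
    return float(xs[lo - 1] + frac * (xs[lo] - xs[lo - 1]))


def _hurst_rs(x: np.ndarray) -> float:
    """Rescaled-range Hurst exponent on the cumulative-deviation profile."""
    n = x.size
    sd = x.std()
    if sd == 0:
        return 0.0
    y = np.cumsum(x - x.mean())
    rs = (y.max() - y.min()) / sd
    if rs <= 0:
        return 0.0
    return float(np.log(rs) / np.log(n))


def _dfa(x: np.ndarray) -> float:
    """Detrended fluctuation scaling exponent, dyadic windows 4..N/4."""
    n = x.size
    if n < 16:
        return 0.0
    y = np.cumsum(x - x.mean())
    sizes = []
    s = 4
    while s <= n // 4:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0
    flucts = []
    for s in sizes:
        n_win = n // s
        segs = y[: n_win * s].reshape(n_win, s)
        t = np.arange(s)
        tc = t - t.mean()
        slope = segs @ tc / np.sum(tc**2)
        resid = segs - segs.mean(axis=1, keepdims=True) - slope[:, None] * tc
        flucts.append(np.sqrt(np.mean(resid**2)))
    flucts = np.asarray(flucts)
    if np.any(flucts <= 0):
        return 0.0
    alpha = np.polyfit(np.log(sizes), np.log(flucts), 1)[0]
    return float(alpha)


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """The 12 time-domain features, population-moment conventions."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    mu = x.mean()
    dev = x - mu
    var = float(np.mean(dev**2))
    sd = np.sqrt(var)
    cv = _safe(sd / mu) if mu != 0 else 0.0
    if var > 0:
        skew = float(np.mean(dev**3) / (np.sum(dev**2) / (n - 1)) ** 1.5)
        kurt = float(np.mean(dev**4) / var**2 - 3.0)
    else:
        skew = kurt = 0.0
    xs = np.sort(x)
    iqr = _quantile_n_plus_1(xs, 0.75) - _quantile_n_plus_1(xs, 0.25)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1 = float(np.mean((d1 - d1.mean()) ** 2))
    v2 = float(np.mean((d2 - d2.mean()) ** 2))
    mobility = np.sqrt(v1 / var) if var > 0 else 0.0
    mob_d = np.sqrt(v2 / v1) if v1 > 0 else 0.0
    complexity = mob_d / mobility if mobility > 0 else 0.0
    sgn = np.sign(x)
    zc = float(0.5 * np.sum(np.abs(sgn[1:] - sgn[:-1])))
    return {
        "mean": float(mu),
        "variance": var,
        "cv": cv,
        "skewness": skew,
        "kurtosis": kurt,
        "iqr": float(iqr),
        "hjorth_activity": var,
        "hjorth_mobility": float(mobility),
        "hjorth_complexity": float(complexity),
        "zero_crossings": zc,
        "hurst": _hurst_rs(x),
        "dfa": _dfa(x),
    }


# ---------------------------------------------------------------------------
# frequency domain


def frequency_domain_features(
    x: np.ndarray, fs: float, cfg: FeatureConfig | None = None
) -> dict[str, float]:
    """The 6 frequency-domain features from a Welch spectrum of ``x``.

    ``x`` should be the wide-band signal (before any 80 Hz low-pass) so
    the 60-140 Hz numerator of the sub-band power ratio is populated
    whenever the sampling rate allows.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, max(8, int(round(cfg.welch_window_seconds * fs))))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    total = psd.sum()
    if total <= 0:
        return {name: 0.0 for name in FREQ_NAMES}

    def bandpower(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[m], freqs[m])) if m.sum() > 1 else 0.0

    lo_n, hi_n = cfg.spr_num_band
    if fs / 2.0 <= lo_n:
        warnings.warn(
            f"Nyquist {fs / 2:.1f} Hz below the {lo_n}-{hi_n} Hz numerator band; SPR=0",
            stacklevel=2,
        )
        spr = 0.0
    else:
        den = bandpower(*cfg.spr_den_band)
        spr = _safe(bandpower(lo_n, min(hi_n, fs / 2.0)) / den) if den > 0 else 0.0
    p = psd / total
    centroid = float(np.sum(freqs * p))
    spread2 = float(np.sum((freqs - centroid) ** 2 * p))
    skurt = _safe(np.sum((freqs - centroid) ** 4 * p) / spread2**2) if spread2 > 0 else 0.0
    nz = p[p > 0]
    sent = float(-(nz * np.log(nz)).sum() / np.log(p.size)) if p.size > 1 else 0.0
    return {
        "spr": spr,
        "psd_mean": float(psd.mean()),
        "asd_mean": float(np.sqrt(psd).mean()),
        "spectral_centroid": centroid,
        "spectral_kurtosis": skurt,
        "spectral_entropy": sent,
    }


# ---------------------------------------------------------------------------
# time-frequency (EMD)


def emd_fuzzy_features(x: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Q1 and Q3 of the fuzzy entropies of the first ``n_imfs`` IMFs."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for EMD features")
    imfs = emd(x, max_imfs=cfg.n_imfs)
    if len(imfs) < 2:
        warnings.warn("fewer than 2 IMFs extracted; EMD features set to 0", stacklevel=2)
        return {"emd_fuzzyent_q1": 0.0, "emd_fuzzyent_q3": 0.0}
    fes = np.array([fuzzy_entropy(imf, m=cfg.fuzzy_m, r_factor=cfg.fuzzy_r) for imf in imfs])
    return {
        "emd_fuzzyent_q1": float(np.quantile(fes, 0.25)),
        "emd_fuzzyent_q3": float(np.quantile(fes, 0.75)),
    }


# ---------------------------------------------------------------------------
# sub-band entropies and fractal dimensions


def kraskov_entropy(x: np.ndarray, k: int = 4) -> float:
    """Kozachenko-Leonenko k-NN differential entropy (1-D, nats)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= k:
        return 0.0
    tree = cKDTree(x[:, None])
    dist, _ = tree.query(x[:, None], k=k + 1)
    delta = np.maximum(dist[:, k], 1e-12)
    # unit-ball "volume" for d=1 with the half-width convention: log V_1 = 0
    return float(-digamma(k) + digamma(n) + np.mean(np.log(2.0 * delta)))


def _energy_probs(x: np.ndarray) -> np.ndarray | None:
    e = x**2
    s = e.sum()
    return None if s <= 0 else e / s


def renyi_entropy(x: np.ndarray, alpha: float = 2.0) -> float:
    """Renyi entropy of the normalized coefficient-energy distribution."""
    p = _energy_probs(x)
    if p is None:
        return 0.0
    return float(np.log(np.sum(p**alpha)) / (1.0 - alpha))


def shannon_entropy(x: np.ndarray) -> float:
    p = _energy_probs(x)
    if p is None:
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def permutation_entropy(x: np.ndarray, order: int = 3) -> float:
    """Normalized permutation entropy (base-2 logs, delay 1)."""
    x = np.asarray(x, dtype=float)
    n = x.size - order + 1
    if n < 1:
        return 0.0
    emb = np.lib.stride_tricks.sliding_window_view(x, order)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n
    h = -(p * np.log2(p)).sum()
    return float(h / np.log2(float(math.factorial(order))))


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy, Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = r_factor * x.std()
    if n < m + 2 or r == 0:
        return 0.0

    def count(mm: int) -> int:
        n_tpl = n - m  # common template count for both lengths
        X = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_tpl]
        d = np.zeros((n_tpl, n_tpl))
        for k in range(mm):
            np.maximum(d, np.abs(X[:, k, None] - X[None, :, k]), out=d)
        matches = (d <= r).sum() - n_tpl  # drop self-matches on the diagonal
        return int(matches)

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def svd_entropy(x: np.ndarray, embed_dim: int = 10) -> float:
    """Entropy of normalized squared singular values of a delay embedding."""
    x = np.asarray(x, dtype=float)
    if x.size < embed_dim + 1:
        return 0.0
    X = np.lib.stride_tricks.sliding_window_view(x, embed_dim)
    s = np.linalg.svd(X, compute_uv=False)
    s2 = s**2
    tot = s2.sum()
    if tot <= 0:
        return 0.0
    p = s2 / tot
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def petrosian_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    d = np.diff(x)
    sgn = np.sign(d)
    n_delta = int(np.sum(sgn[1:] * sgn[:-1] < 0))
    logn = np.log(n)
    return float(logn / (logn + np.log(n / (n + 0.4 * n_delta))))


def katz_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    length = float(np.abs(np.diff(x)).sum())
    if length == 0:
        return 0.0
    d = float(np.abs(x - x[0]).max())
    if d == 0:
        return 0.0
    n = x.size - 1
    return float(np.log(n) / (np.log(d / length) + np.log(n)))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    kmax = min(kmax, max(2, n // 4))
    ks, lks = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            ll = np.abs(np.diff(x[idx])).sum() * (n - 1) / ((idx.size - 1) * k) / k
            lm.append(ll)
        if lm:
            mean_l = np.mean(lm)
            if mean_l > 0:
                ks.append(k)
                lks.append(mean_l)
    if len(ks) < 2:
        return 0.0
    slope = np.polyfit(np.log(1.0 / np.asarray(ks)), np.log(lks), 1)[0]
    return float(slope)


_SUBBAND_FUNCS = {
    "kraskov": lambda c, cfg: kraskov_entropy(c, k=cfg.kraskov_k),
    "renyi": lambda c, cfg: renyi_entropy(c, alpha=cfg.renyi_alpha),
    "permutation": lambda c, cfg: permutation_entropy(c, order=cfg.perment_order),
    "sample": lambda c, cfg: sample_entropy(c, m=cfg.sampen_m, r_factor=cfg.sampen_r),
    "shannon": lambda c, cfg: shannon_entropy(c),
    "energy": lambda c, cfg: float(np.sum(c**2)),
    "svd_entropy": lambda c, cfg: svd_entropy(c, embed_dim=cfg.svd_embed_dim),
    "pfd": lambda c, cfg: petrosian_fd(c),
    "kfd": lambda c, cfg: katz_fd(c),
    "hfd": lambda c, cfg: higuchi_fd(c, kmax=cfg.higuchi_kmax),
}


def subband_entropy_features(
    sb: SubbandSet, cfg: FeatureConfig | None = None
) -> dict[str, float]:
    """10 entropy/fractal measures on each of the 5 sub-bands (50 values)."""
    cfg = cfg or FeatureConfig()
    out: dict[str, float] = {}
    for kind in ENTROPY_KINDS:
        fn = _SUBBAND_FUNCS[kind]
        for band in SUBBAND_ORDER:
            out[f"{kind}_{band}"] = _safe(fn(sb.coeffs[band], cfg))
    return out


# ---------------------------------------------------------------------------
# assembly


def extract_feature_vector(
    segment: Segment,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
) -> dict[str, float]:
    """All 70 features of a segment, keyed by manifest name.

    Frequency-domain features use the raw wide-band signal at its native
    rate; time-domain, EMD and sub-band features use the band-passed
    signal resampled to the analysis rate.
    """
    pcfg = pcfg or PreprocessConfig()
    fcfg = fcfg or FeatureConfig()
    wide = segment.channel_mean()
    bp = bandpass(segment, *pcfg.bandpass, order=pcfg.filter_order)
    y = resample_to(bp.channel_mean(), segment.fs, pcfg.analysis_fs)
    feats = time_domain_features(y)
    feats.update(frequency_domain_features(wide, segment.fs, fcfg))
    feats.update(emd_fuzzy_features(y, fcfg))
    feats.update(subband_entropy_features(decompose_subbands(bp, pcfg), fcfg))
    return {name: feats[name] for name in FEATURE_NAMES}


def extract_feature_sequence(
    segment: Segment,
    n: int | None = None,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
) -> FeatureSequence:
    """Split into ``n`` timesteps and extract a 70-vector per timestep."""
    pcfg = pcfg or PreprocessConfig()
    n = n if n is not None else pcfg.n_timesteps
    vectors = [
        extract_feature_vector(ts, pcfg, fcfg) for ts in split_timesteps(segment, n)
    ]
    values = np.array([[v[name] for name in FEATURE_NAMES] for v in vectors])
    return FeatureSequence(values=values, names=list(FEATURE_NAMES))
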