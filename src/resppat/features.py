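"""Per-window feature extraction.

Four candidate descriptor families are computed per 45-s window:

* breathing rate — inverse of the median breath-cycle length (Hz);
* amplitude — median inspiratory depth (pressure units);
* ARIMA(1,1,1) coefficients — maximum-likelihood estimates of the drift,
  autoregressive and moving-average parameters (mu, phi, theta) of

      y_t = mu + y_{t-1} + phi (y_{t-1} - y_{t-2}) - theta e_{t-1} + e_t

  i.e. an ARMA(1,1) with constant on the first-differenced signal, with
  stationarity (|phi| < 1) and invertibility (|theta| < 1) enforced;
* Fourier magnitudes — |c_n| of the finite-window Fourier coefficients
  c_n = (1/T) \\int_0^T f(t) exp(-i n w t) dt with T = 45 s, restricted
  to bin frequencies n/T <= 2 Hz (breathing above 2 Hz is non-
  physiological, so higher bins carry only noise).

A 5-component PCA is provided to reduce the Fourier set; it must be
fitted on training rows only (the projection never sees held-out data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocess import BreathSegmentation, Window

__all__ = [
    "FeatureConfig",
    "PcaProjection",
    "breathing_rate",
    "amplitude",
    "fourier_features",
    "fourier_bin_count",
    "arima_features",
    "simulate_arima111_diff",
    "fit_pca",
    "project",
    "build_feature_table",
    "fourier_columns",
]

MAX_FREQ_HZ = 2.0
ARIMA_NAN = (np.nan, np.nan, np.nan)


@dataclass
class FeatureConfig:
    """Feature-extraction options.

    ``include_dc`` keeps the n = 0 Fourier bin (it encodes the baseline
    level rather than breathing, but the 2 Hz rule alone does not exclude
    it); ``max_freq_hz`` is the inclusive spectral cut.
    """

    include_dc: bool = True
    max_freq_hz: float = MAX_FREQ_HZ


def breathing_rate(seg: BreathSegmentation) -> float:
    """Inverse of the median breath-cycle length, in Hz.

    Returns NaN for windows with fewer cycles than the quality rule
    admits (they are filtered upstream).
    """
    if seg.n_cycles < 4:
        return np.nan
    med = float(np.median(seg.cycle_lengths))
    return 1.0 / med if med > 0 else np.nan


def amplitude(seg: BreathSegmentation) -> float:
    """Median inspiratory depth (baseline minus pressure minimum)."""
    if seg.n_cycles < 4:
        return np.nan
    return float(np.median(seg.inspiratory_depths))


def fourier_features(samples: np.ndarray, sampling_rate: float,
                     config: FeatureConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitudes of the windowed Fourier coefficients up to 2 Hz.

    The discrete approximation of c_n over the N samples of the window is
    FFT(x)[n] / N, whose magnitude at a bin-aligned sinusoid of amplitude
    A is A/2 (one-sided).  No tapering or detrending is applied.  Returns
    (bin_freqs_hz, magnitudes); with a 450-sample window at 10 Hz the
    resolution is 1/45 Hz and 91 bins (n = 0..90) fall at or below 2 Hz.
    """
    config = config or FeatureConfig()
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    n = len(x)
    coeffs = np.fft.rfft(x) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    keep = freqs <= config.max_freq_hz + 1e-12
    if not config.include_dc:
        keep = keep & (freqs > 0)
    return freqs[keep], np.abs(coeffs[keep])


def fourier_bin_count(n_samples: int = 450, sampling_rate: float = 10.0,
                      config: FeatureConfig | None = None) -> int:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    config = config or FeatureConfig()
    keep = freqs <= config.max_freq_hz + 1e-12
    if not config.include_dc:
        keep = keep & (freqs > 0)
    return int(keep.sum())


def fourier_columns(n_samples: int = 450, sampling_rate: float = 10.0,
                    config: FeatureConfig | None = None) -> list[str]:
    """Column names f_<mHz> for the retained Fourier bins (f_0000..f_2000)."""
    config = config or FeatureConfig()
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    keep = freqs <= config.max_freq_hz + 1e-12
    if not config.include_dc:
        keep = keep & (freqs > 0)
    return [f"f_{int(round(f * 1000)):04d}" for f in freqs[keep]]


def arima_features(samples: np.ndarray) -> tuple[float, float, float]:
    """Exact-MLE estimates (mu, phi, theta) of the ARIMA(1,1,1) model.

    Fitted as ARMA(1,1) with constant on the differenced series.  The
    moving-average sign follows the subtracted-theta convention of the
    prediction equation above, so theta here is the negative of the
    usual additive MA(1) coefficient.  The intercept mu is recovered from
    the fitted mean m of the differenced series as mu = m (1 - phi).
    Returns NaNs for constant series or failed fits.
    """
    from statsmodels.tsa.arima.model import ARIMA

    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        return ARIMA_NAN
    w = np.diff(x)
    if len(w) < 20 or np.std(w) < 1e-12:
        return ARIMA_NAN
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(w, order=(1, 0, 1), trend="c",
                        enforce_stationarity=True,
                        enforce_invertibility=True).fit()
        params = dict(zip(res.param_names, res.params))
        phi = float(params["ar.L1"])
        theta = -float(params["ma.L1"])
        mu = float(params["const"]) * (1.0 - phi)
    except Exception:
        return ARIMA_NAN
    if not all(np.isfinite(v) for v in (mu, phi, theta)):
        return ARIMA_NAN
    return mu, phi, theta


def simulate_arima111_diff(mu: float, phi: float, theta: float, n: int,
                           sigma: float = 1.0,
                           rng: np.random.Generator | None = None,
                           burn: int = 100) -> np.ndarray:
    """Simulate the differenced series of the ARIMA(1,1,1) prediction
    equation literally: w_t = mu + phi w_{t-1} - theta e_{t-1} + e_t.

    Used as the independent generator for parameter-recovery checks; the
    undifferenced signal is its cumulative sum.
    """
    rng = rng or np.random.default_rng()
    total = n + burn
    e = rng.normal(0.0, sigma, size=total)
    w = np.zeros(total)
    for t in range(1, total):
        w[t] = mu + phi * w[t - 1] - theta * e[t - 1] + e[t]
    return w[burn:]


@dataclass
class PcaProjection:
    """Training-data PCA used to reduce the Fourier magnitude vectors."""

    loadings: np.ndarray  # (n_components, n_bins), orthonormal rows
    center: np.ndarray  # per-bin training mean
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(training_rows: np.ndarray, n_components: int = 5) -> PcaProjection:
    """Fit the reduction on training rows only.

    Raises if there are not enough rows to estimate the components.
    """
    X = np.asarray(training_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} training rows, got {X.shape[0]}"
        )
    p = PCA(n_components=n_components, svd_solver="full")
    p.fit(X)
    return PcaProjection(
        loadings=p.components_.copy(),
        center=p.mean_.copy(),
        explained_variance=p.explained_variance_.copy(),
    )


def project(p: PcaProjection, rows: np.ndarray) -> np.ndarray:
    """Apply the training center and loadings to any rows."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    return (X - p.center) @ p.loadings.T


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

SCALAR_FEATURES = ["breathing_rate", "amplitude", "arima_mu", "arima_phi", "arima_theta"]


def build_feature_table(windows: list[Window],
                        segs: dict[int, "BreathSegmentation"],
                        config: FeatureConfig | None = None,
                        fit_arima: bool = True) -> pd.DataFrame:
    """One row per window with all features, label and quality.

    Rate/amplitude/ARIMA features are computed only for quality-ok
    windows; excluded or poor-quality windows keep their row (for
    bookkeeping) with NaN features.  Fourier magnitudes are computed for
    every quality-ok window from the raw samples.
    """
    config = config or FeatureConfig()
    f_cols = None
    rows = []
    for w in windows:
        row: dict = {
            "subject": w.subject_id,
            "window": w.index,
            "label": w.label,
            "quality": w.quality,
        }
        usable = w.quality == "ok" and w.label != "excluded"
        seg = segs.get(w.index)
        if usable and seg is not None:
            row["breathing_rate"] = breathing_rate(seg)
            row["amplitude"] = amplitude(seg)
            if fit_arima:
                mu, phi, theta = arima_features(w.samples)
            else:
                mu = phi = theta = np.nan
            row["arima_mu"], row["arima_phi"], row["arima_theta"] = mu, phi, theta
            freqs, mags = fourier_features(w.samples, w.sampling_rate, config)
            if f_cols is None:
                f_cols = [f"f_{int(round(f * 1000)):04d}" for f in freqs]
            row.update(dict(zip(f_cols, mags)))
        else:
            row.update({k: np.nan for k in SCALAR_FEATURES})
        rows.append(row)
    df = pd.DataFrame(rows)
    if f_cols:
        df[f_cols] = df[f_cols].astype(float)
    return df
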