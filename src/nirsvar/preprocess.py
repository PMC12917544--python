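"""Raw dual-wavelength fNIRS signals to cleaned ΔHbO/ΔHbR.

The chain mirrors a HOMER-style continuous-wave pipeline:

1. intensity -> optical density change (ΔOD);
2. wavelet motion-artifact correction (outlier detail coefficients zeroed);
3. zero-phase band-pass, pass band 0.005–0.05 Hz;
4. modified Beer–Lambert conversion to ΔHbO/ΔHbR (µmol/l);
5. GLM nuisance regression: best-correlated short-separation channel plus a
   third-order polynomial drift, with HRF-convolved block regressors kept in
   the design so task-locked variance is retained;
6. baseline correction over the 5 s before the first block onset;
7. extraction of the analysis window.

Every step is length-preserving except the final extraction, and every step
appends itself to the recording's provenance list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal as sps
from scipy.stats import norm

from .protocols import StimEvent, TaskProtocol

__all__ = [
    "Channel",
    "ChannelLayout",
    "HaemoSeries",
    "PreprocessConfig",
    "default_layout",
    "intensity_to_od",
    "motion_correct",
    "bandpass",
    "od_to_haemo",
    "hrf_double_gamma",
    "short_channel_glm",
    "baseline_correct",
    "extract_window",
    "preprocess_recording",
    "BandpassFilter",
    "WaveletMotionCorrector",
]

# Molar extinction coefficients at the two laser lines, 1/(M*cm).
# Compiled from the tabulation of W.B. Gratzer / S. Prahl as distributed with
# the HOMER GetExtinctions table; overridable through ChannelLayout.
EXTINCTION_1_M_CM: dict[int, tuple[float, float]] = {
    #      (eps_HbO, eps_HbR)
    760: (586.0, 1548.52),
    850: (1058.0, 691.32),
}


@dataclass(frozen=True)
class Channel:
    source: str
    detector: str
    role: str  # "long" | "short"
    distance_m: float

    @property
    def name(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass(frozen=True)
class ChannelLayout:
    """Optode montage: channel geometry plus optical constants."""

    channels: tuple[Channel, ...]
    wavelengths: tuple[int, int] = (760, 850)
    dpf: dict[int, float] = field(default_factory=lambda: {760: 6.0, 850: 6.0})
    extinction: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(EXTINCTION_1_M_CM)
    )

    def __post_init__(self) -> None:
        for wl in self.wavelengths:
            if wl not in self.extinction:
                raise ValueError(f"no extinction coefficients for {wl} nm")
            if wl not in self.dpf:
                raise ValueError(f"no DPF for {wl} nm")
        if any(c.distance_m <= 0 for c in self.channels):
            raise ValueError("source-detector distances must be > 0")
        if abs(np.linalg.det(self._ext_matrix())) < 1e-12:
            raise ValueError("extinction matrix is singular")

    def _ext_matrix(self) -> np.ndarray:
        return np.array([self.extinction[wl] for wl in self.wavelengths])

    @property
    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.role == "long"]

    @property
    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.role == "short"]


def default_layout(
    n_long: int = 17,
    n_short: int = 8,
    long_distance_m: float = 0.03,
    short_distance_m: float = 0.008,
) -> ChannelLayout:
    """Bi-hemispheric prefrontal montage: 17 long + 8 short channels.

    Channel names are synthetic S*-D* labels; the study montage's 10-10
    electrode naming is not reproduced.
    """
    chans = [
        Channel(f"S{i + 1}", f"D{i + 1}", "long", long_distance_m)
        for i in range(n_long)
    ] + [
        Channel(f"S{i + 1}", f"Dsh{i + 1}", "short", short_distance_m)
        for i in range(n_short)
    ]
    return ChannelLayout(channels=tuple(chans))


@dataclass
class HaemoSeries:
    """Per-channel haemoglobin concentration changes with event markers."""

    participant_id: str
    task: str
    fs: float
    channels: list[str]
    roles: list[str]  # "long" | "short" per channel
    hbo: np.ndarray  # (n_channels, n_samples), µmol/l
    hbr: np.ndarray | None = None
    events: list[StimEvent] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.hbr is not None and self.hbr.shape != self.hbo.shape:
            raise ValueError("hbo and hbr shapes differ")
        if len(self.channels) != self.hbo.shape[0]:
            raise ValueError("channel list does not match data")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def first_block_onset(self) -> float:
        starts = [e.onset_s for e in self.events if e.kind == "block_start"]
        if not starts:
            raise ValueError("no block_start events present")
        return min(starts)


@dataclass(frozen=True)
class PreprocessConfig:
    band: tuple[float, float] = (0.005, 0.05)
    filter_order: int = 3
    wavelet: str = "db5"
    wavelet_alpha: float = 0.02
    glm_poly_order: int = 3
    baseline_window_s: float = 5.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if self.glm_poly_order < 0:
            raise ValueError("glm_poly_order must be >= 0")


# ---------------------------------------------------------------------------
# elementary steps


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """ΔOD(t) = -log10(I(t) / geometric_mean(I)); zero-mean-log by construction.

    Accepts a 1-D series or an (n_channels, n_samples) array.  Non-positive
    intensities are rejected with the offending channel/sample index.
    """
    x = np.asarray(intensity, dtype=float)
    bad = np.argwhere(~(x > 0))
    if bad.size:
        idx = tuple(int(i) for i in bad[0])
        raise ValueError(f"non-positive intensity at index {idx}")
    logx = np.log10(x)
    ref = logx.mean(axis=-1, keepdims=True)
    return -(logx - ref)


def motion_correct(
    od: np.ndarray,
    wavelet: str = "db5",
    alpha: float = 0.02,
) -> np.ndarray:
    """Wavelet motion-artifact removal on ΔOD.

    Discrete wavelet decomposition; per detail level, coefficients are
    centred on the level median with a robust scale from the IQR
    (sigma = IQR/1.349) and any coefficient whose two-sided Gaussian tail
    probability falls below ``alpha`` is set to zero; the series is then
    reconstructed.  Motion spikes concentrate in few large detail
    coefficients, while smooth physiology stays below the threshold.
    """
    x = np.asarray(od, dtype=float)
    if x.ndim == 2:
        return np.vstack([motion_correct(row, wavelet, alpha) for row in x])
    w = pywt.Wavelet(wavelet)
    if x.size < 2 * w.dec_len:
        raise ValueError(
            f"series of {x.size} samples shorter than wavelet support"
        )
    coeffs = pywt.wavedec(x, w, mode="symmetric")
    z = norm.ppf(1 - alpha / 2)
    cleaned = [coeffs[0]]
    for detail in coeffs[1:]:
        med = np.median(detail)
        q1, q3 = np.percentile(detail, [25, 75])
        scale = (q3 - q1) / 1.349
        if scale == 0:
            cleaned.append(detail)
            continue
        keep = np.abs(detail - med) <= z * scale
        cleaned.append(np.where(keep, detail, 0.0))
    out = pywt.waverec(cleaned, w, mode="symmetric")
    return out[: x.size]


def bandpass(
    series: np.ndarray,
    band: tuple[float, float] = (0.005, 0.05),
    order: int = 3,
    fs: float = 10.2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, order per pass)."""
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} not inside (0, fs/2) for fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(series, dtype=float)
    return sps.sosfiltfilt(sos, x, axis=-1)


def od_to_haemo(
    od_by_wavelength: dict[int, np.ndarray],
    channel: Channel,
    layout: ChannelLayout,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Beer–Lambert inversion for one channel.

    Solves, per sample, ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)
    for the concentration changes; returns (ΔHbO, ΔHbR) in µmol/l.
    """
    wls = layout.wavelengths
    try:
        od = np.vstack([np.asarray(od_by_wavelength[wl], float) for wl in wls])
    except KeyError as e:
        raise ValueError(f"missing ΔOD for wavelength {e.args[0]} nm") from None
    if od[0].shape != od[1].shape:
        raise ValueError("ΔOD series lengths differ between wavelengths")
    d_cm = channel.distance_m * 100.0
    # rows: wavelength; cols: (HbO, HbR); units 1/M
    mat = np.array(
        [
            [e * d_cm * layout.dpf[wl] for e in layout.extinction[wl]]
            for wl in wls
        ]
    )
    if abs(np.linalg.det(mat)) < 1e-12:
        raise ValueError("extinction system is singular for this layout")
    conc_m = np.linalg.solve(mat, od)  # mol/l
    return conc_m[0] * 1e6, conc_m[1] * 1e6


def hrf_double_gamma(
    fs: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised."""
    from scipy.stats import gamma

    t = np.arange(0, duration_s, 1.0 / fs)
    h = gamma.pdf(t, peak_s) - undershoot_ratio * gamma.pdf(t, undershoot_s)
    return h / h.max()


def _poly_design(n: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns over [-1, 1] (well-conditioned)."""
    t = np.linspace(-1.0, 1.0, n)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(k)(t) for k in range(order + 1)])


def short_channel_glm(
    long_series: np.ndarray,
    short_series: np.ndarray,
    task_regressor: np.ndarray,
    poly_order: int = 3,
) -> tuple[np.ndarray, dict]:
    """Nuisance regression of one long channel on short-channel + drift.

    The design matrix holds the HRF-convolved task regressor, Legendre
    polynomials up to ``poly_order``, and the single short channel with the
    highest Pearson correlation to the long channel.  The returned series is
    the input minus the fitted short-channel and polynomial contributions
    only — the task-locked variance stays in, because the entropy analysis
    targets task-related blood-flow fluctuation.
    """
    y = np.asarray(long_series, dtype=float)
    shorts = np.atleast_2d(np.asarray(short_series, dtype=float))
    if shorts.shape[1] != y.size:
        raise ValueError("short channels and long channel lengths differ")
    if shorts.shape[0] < 1:
        raise ValueError("need at least one short channel")

    cors = np.zeros(shorts.shape[0])
    for i, s in enumerate(shorts):
        sd = s.std()
        cors[i] = 0.0 if sd == 0 else float(np.corrcoef(y, s)[0, 1])
    best = int(np.argmax(cors))

    polys = _poly_design(y.size, poly_order)
    X = np.column_stack([np.asarray(task_regressor, float), polys, shorts[best]])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"rank-deficient GLM design (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    nuisance = polys @ beta[1 : 1 + polys.shape[1]] + shorts[best] * beta[-1]
    diagnostics = {
        "selected_short": best,
        "short_correlations": cors,
        "beta_task": float(beta[0]),
        "beta_poly": beta[1:-1].copy(),
        "beta_short": float(beta[-1]),
        "condition_number": float(cond),
    }
    return y - nuisance, diagnostics


def baseline_correct(
    series: np.ndarray,
    first_onset_s: float,
    fs: float,
    baseline_window_s: float = 5.0,
) -> np.ndarray:
    """Subtract the mean over the window preceding the first block onset."""
    x = np.asarray(series, dtype=float)
    i1 = int(round(first_onset_s * fs))
    i0 = int(round((first_onset_s - baseline_window_s) * fs))
    if i0 < 0 or i1 <= i0:
        raise ValueError(
            f"insufficient pre-stimulus samples for a {baseline_window_s} s baseline"
        )
    return x - x[..., i0:i1].mean(axis=-1, keepdims=x.ndim > 1)


def extract_window(
    series: np.ndarray,
    first_onset_s: float,
    protocol: TaskProtocol,
    fs: float,
    window_s: float | None = None,
) -> np.ndarray:
    """Cut the analysis window from a longer recording.

    The window starts ``pre_pad`` seconds before the first block onset and
    spans ``window_s`` seconds (defaults to the protocol's reported analysis
    period, falling back to the computed one), so the reported per-task
    sample counts are reproduced at the recording's own sampling rate.
    """
    x = np.asarray(series, dtype=float)
    if window_s is None:
        window_s = protocol.reported_window_s or protocol.analysis_window_s
    i0 = int(round((first_onset_s - protocol.pre_pad) * fs))
    n = int(round(window_s * fs))
    if i0 < 0 or i0 + n > x.shape[-1]:
        raise ValueError(
            f"analysis window [{i0}, {i0 + n}) exceeds recording of "
            f"{x.shape[-1]} samples"
        )
    return x[..., i0 : i0 + n]


# ---------------------------------------------------------------------------
# full chain


def preprocess_recording(
    intensity: dict[int, np.ndarray],
    layout: ChannelLayout,
    events: list[StimEvent],
    protocol: TaskProtocol,
    fs: float,
    participant_id: str,
    task: str,
    config: PreprocessConfig | None = None,
) -> HaemoSeries:
    """Raw intensities to cleaned, windowed ΔHbO/ΔHbR.

    ``intensity`` maps wavelength (nm) to an (n_channels, n_samples) array in
    the order of ``layout.channels``.  Steps run in the order documented in
    the module docstring; provenance records each applied step.
    """
    cfg = config or PreprocessConfig()
    provenance: list[str] = []

    od = {wl: intensity_to_od(intensity[wl]) for wl in layout.wavelengths}
    provenance.append("intensity_to_od")
    od = {
        wl: motion_correct(od[wl], cfg.wavelet, cfg.wavelet_alpha)
        for wl in layout.wavelengths
    }
    provenance.append(f"motion_correct({cfg.wavelet}, alpha={cfg.wavelet_alpha})")
    od = {
        wl: bandpass(od[wl], cfg.band, cfg.filter_order, fs)
        for wl in layout.wavelengths
    }
    provenance.append(f"bandpass{cfg.band}")

    n_ch = len(layout.channels)
    hbo = np.zeros((n_ch, od[layout.wavelengths[0]].shape[-1]))
    hbr = np.zeros_like(hbo)
    for i, ch in enumerate(layout.channels):
        hbo[i], hbr[i] = od_to_haemo(
            {wl: od[wl][i] for wl in layout.wavelengths}, ch, layout
        )
    provenance.append("od_to_haemo")

    first_onset = min(e.onset_s for e in events if e.kind == "block_start")
    boxcar_full = np.zeros(hbo.shape[1])
    fs_idx = lambda t: int(round(t * fs))  # noqa: E731
    starts = sorted(e.onset_s for e in events if e.kind == "block_start")
    ends = sorted(e.onset_s for e in events if e.kind == "block_end")
    for s, e in zip(starts, ends):
        boxcar_full[fs_idx(s) : fs_idx(e)] = 1.0
    hrf = hrf_double_gamma(fs, peak_s=cfg.hrf_peak_s, undershoot_s=cfg.hrf_undershoot_s)
    task_reg = np.convolve(boxcar_full, hrf)[: hbo.shape[1]]

    short_idx = [i for i, c in enumerate(layout.channels) if c.role == "short"]
    glm_notes = []
    if short_idx:
        shorts = hbo[short_idx]
        for i, ch in enumerate(layout.channels):
            if ch.role != "long":
                continue
            hbo[i], diag = short_channel_glm(
                hbo[i], shorts, task_reg, cfg.glm_poly_order
            )
            glm_notes.append((ch.name, diag["selected_short"]))
        provenance.append(f"short_channel_glm(poly_order={cfg.glm_poly_order})")

    hbo = baseline_correct(hbo, first_onset, fs, cfg.baseline_window_s)
    hbr = baseline_correct(hbr, first_onset, fs, cfg.baseline_window_s)
    provenance.append(f"baseline_correct({cfg.baseline_window_s}s)")

    hbo = extract_window(hbo, first_onset, protocol, fs)
    hbr = extract_window(hbr, first_onset, protocol, fs)
    provenance.append(f"extract_window(n={hbo.shape[1]})")

    shift = first_onset - protocol.pre_pad
    shifted = [
        StimEvent(e.onset_s - shift, e.kind, e.stimulus_type) for e in events
    ]
    return HaemoSeries(
        participant_id=participant_id,
        task=task,
        fs=fs,
        channels=[c.name for c in layout.channels],
        roles=[c.role for c in layout.channels],
        hbo=hbo,
        hbr=hbr,
        events=shifted,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# sklearn-style transformer layer


class _ArrayTransformer:
    """Minimal estimator base: get/set_params over __init__ args."""

    def get_params(self, deep: bool = True) -> dict:
        import inspect

        keys = [
            k
            for k in inspect.signature(type(self).__init__).parameters
            if k != "self"
        ]
        return {k: getattr(self, k) for k in keys}

    def set_params(self, **params):
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[-1]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class BandpassFilter(_ArrayTransformer):
    """Zero-phase Butterworth band-pass over the rows of X."""

    def __init__(self, band=(0.005, 0.05), order: int = 3, fs: float = 10.2):
        self.band = band
        self.order = order
        self.fs = fs

    def transform(self, X):
        return bandpass(np.asarray(X, float), self.band, self.order, self.fs)


class WaveletMotionCorrector(_ArrayTransformer):
    """Wavelet motion-artifact correction over the rows of X."""

    def __init__(self, wavelet: str = "db5", alpha: float = 0.02):
        self.wavelet = wavelet
        self.alpha = alpha

    def transform(self, X):
        return motion_correct(np.asarray(X, float), self.wavelet, self.alpha)
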