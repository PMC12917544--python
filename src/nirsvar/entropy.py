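"""Sample entropy and the two blood-flow variability metrics.

Temporal variability of a channel's ΔHbO series is quantified by sample
entropy SampEn(m, r) = -ln(A/B), where B counts pairs of length-m templates
whose Chebyshev distance is <= r and A counts the corresponding length-(m+1)
pairs (Richman & Moorman counting: both template sets range over indices
1..N-m, self-matches excluded, inclusive tolerance).  The tolerance is
r = r_frac * SD of the analysed window of the individual channel, so the
statistic is invariant to affine rescaling of the signal.

Two participant-level metrics follow:

* temporal variability  — SampEn averaged over the 17 long channels;
* spatial variability   — the coefficient of variation CV(SampEn) = SD/mean
  of the per-channel entropies, measuring how unevenly the cortical patch
  responds.

A fast O(N^2) counting kernel (numba when available, lag-vectorised numpy
otherwise) is paired with a literal brute-force oracle used for verification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "EntropyParams",
    "MatchCounts",
    "SampEnResult",
    "ChannelEntropyMap",
    "VariabilitySummary",
    "sample_entropy",
    "sample_entropy_oracle",
    "channel_entropy_map",
    "variability_summary",
    "SampleEntropy",
]


@dataclass(frozen=True)
class EntropyParams:
    """Sample entropy parameters: embedding dimension and relative tolerance."""

    m: int = 2
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be > 0")


@dataclass(frozen=True)
class MatchCounts:
    """Template-pair match counts underlying one SampEn value."""

    A: int  # (m+1)-template pairs within tolerance
    B: int  # m-template pairs within tolerance
    n_templates: int

    def __post_init__(self) -> None:
        if self.A > self.B:
            raise ValueError("A cannot exceed B")


@dataclass(frozen=True)
class SampEnResult:
    value: float  # nan when undefined
    counts: MatchCounts

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


if _HAVE_NUMBA:

    @njit(cache=False)
    def _counts_kernel(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0]
        n_tpl = n - m
        A = 0
        B = 0
        for i in range(n_tpl - 1):
            for j in range(i + 1, n_tpl):
                ok = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    B += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        A += 1
        return A, B


def _counts_lagged(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Vectorised per-lag counting; exact same semantics as the kernel."""
    n = x.size
    n_tpl = n - m
    A = 0
    B = 0
    for d in range(1, n_tpl):
        within = np.abs(x[: n - d] - x[d:]) <= r
        c = np.cumsum(within)
        # window sums of length m and m+1 starting at i = 0..n-d-m
        wm = c[m - 1 :].copy()
        wm[1:] -= c[:-m]
        wm1 = c[m:].copy()
        wm1[1:] -= c[: -(m + 1)]
        # valid template starts: i <= n_tpl - 1 - d
        B += int(np.count_nonzero(wm[: n - d - m] == m))
        A += int(np.count_nonzero(wm1[: n - d - m] == m + 1))
    return A, B


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    if _HAVE_NUMBA:
        a, b = _counts_kernel(np.ascontiguousarray(x, dtype=np.float64), m, r)
        return int(a), int(b)
    return _counts_lagged(x, m, r)


def _finish(x: np.ndarray, m: int, r_frac: float, A: int, B: int) -> SampEnResult:
    counts = MatchCounts(A=A, B=B, n_templates=x.size - m)
    if A == 0 or B == 0:
        warnings.warn(
            "sample entropy undefined: no template matches (A=%d, B=%d)" % (A, B),
            stacklevel=3,
        )
        return SampEnResult(value=float("nan"), counts=counts)
    return SampEnResult(value=float(-np.log(A / B)), counts=counts)


def _validate(x: np.ndarray, params: EntropyParams) -> float | None:
    """Return the tolerance r, or None when the series is degenerate."""
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size <= params.m + 1:
        raise ValueError(f"series length {x.size} must exceed m+1 = {params.m + 1}")
    sd = float(np.std(x, ddof=1))
    # a constant series can carry rounding noise of order eps*|x|
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return None
    return params.r_frac * sd


def sample_entropy(
    series: np.ndarray, params: EntropyParams | None = None
) -> SampEnResult:
    """SampEn(m, r_frac*SD) of one series with exact match counts.

    Degenerate inputs (zero SD, or no template matches) yield a result with
    ``value`` = NaN and ``defined`` False; they are flagged with a warning
    and excluded from aggregates downstream rather than silently propagated.
    """
    params = params or EntropyParams()
    x = np.asarray(series, dtype=float)
    r = _validate(x, params)
    if r is None:
        warnings.warn("sample entropy undefined: series SD is zero", stacklevel=2)
        return SampEnResult(
            value=float("nan"), counts=MatchCounts(A=0, B=0, n_templates=x.size - params.m)
        )
    A, B = _match_counts(x, params.m, r)
    return _finish(x, params.m, params.r_frac, A, B)


def sample_entropy_oracle(
    series: np.ndarray, params: EntropyParams | None = None
) -> SampEnResult:
    """Literal double loop over all template pairs (verification oracle).

    Quadratic in N with Python-level loops; restricted to N <= 2000.
    Semantics are identical to :func:`sample_entropy` by construction.
    """
    params = params or EntropyParams()
    x = np.asarray(series, dtype=float)
    if x.size > 2000:
        raise ValueError("oracle restricted to N <= 2000 (quadratic cost)")
    r = _validate(x, params)
    if r is None:
        warnings.warn("sample entropy undefined: series SD is zero", stacklevel=2)
        return SampEnResult(
            value=float("nan"), counts=MatchCounts(A=0, B=0, n_templates=x.size - params.m)
        )
    m = params.m
    n_tpl = x.size - m
    A = 0
    B = 0
    for i in range(n_tpl - 1):
        for j in range(i + 1, n_tpl):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return _finish(x, m, params.r_frac, A, B)


@dataclass
class ChannelEntropyMap:
    """Per-long-channel SampEn for one participant x task."""

    participant_id: str
    task: str
    channels: list[str]
    values: np.ndarray  # nan where undefined
    undefined_channels: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class VariabilitySummary:
    """Participant-level temporal (mean) and spatial (CV) variability."""

    participant_id: str
    task: str
    mean_sampen: float
    cv_sampen: float
    n_channels_used: int


def channel_entropy_map(haemo, params: EntropyParams | None = None) -> ChannelEntropyMap:
    """SampEn per long channel of a cleaned recording.

    ``haemo`` is a :class:`~nirsvar.preprocess.HaemoSeries`; only channels
    with role ``"long"`` enter the map.  Undefined channels are recorded in
    ``undefined_channels``, never silently dropped.
    """
    params = params or EntropyParams()
    long_idx = [i for i, role in enumerate(haemo.roles) if role == "long"]
    if not long_idx:
        raise ValueError("recording has no long channels")
    names = [haemo.channels[i] for i in long_idx]
    values = np.full(len(long_idx), np.nan)
    undefined: list[str] = []
    for out_i, ch_i in enumerate(long_idx):
        res = sample_entropy(haemo.hbo[ch_i], params)
        values[out_i] = res.value
        if not res.defined:
            undefined.append(haemo.channels[ch_i])
    return ChannelEntropyMap(
        participant_id=haemo.participant_id,
        task=haemo.task,
        channels=names,
        values=values,
        undefined_channels=undefined,
    )


def variability_summary(emap: ChannelEntropyMap) -> VariabilitySummary:
    """Mean SampEn and CV(SampEn) over the defined channels.

    CV uses the sample standard deviation (n-1 denominator).  At least two
    defined channels and a non-zero mean are required.
    """
    vals = emap.values[np.isfinite(emap.values)]
    if vals.size < 2:
        raise ValueError("need >= 2 defined channels for a variability summary")
    mean = float(np.mean(vals))
    if mean == 0.0:
        raise ValueError("mean sample entropy is zero; CV undefined")
    cv = float(np.std(vals, ddof=1) / mean)
    return VariabilitySummary(
        participant_id=emap.participant_id,
        task=emap.task,
        mean_sampen=mean,
        cv_sampen=cv,
        n_channels_used=int(vals.size),
    )


class SampleEntropy:
    """sklearn-style transformer: rows of X are series, output their SampEn.

    Parameters mirror :class:`EntropyParams`.  ``fit`` is stateless (records
    ``n_features_in_`` only); ``transform`` maps an (n_series, n_samples)
    array to an (n_series, 1) column of entropy values (NaN when undefined).
    """

    def __init__(self, m: int = 2, r_frac: float = 0.2):
        self.m = m
        self.r_frac = r_frac

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"m": self.m, "r_frac": self.r_frac}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("m", "r_frac"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_series, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_series, n_samples)")
        p = EntropyParams(m=self.m, r_frac=self.r_frac)
        out = np.full((X.shape[0], 1), np.nan)
        for i in range(X.shape[0]):
            out[i, 0] = sample_entropy(X[i], p).value
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
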