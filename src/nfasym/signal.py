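"""Preprocessing chain for 2 Hz HbO time series.

Hemisphere averaging and L-R asymmetry, linear-phase FIR low-pass filtering
(order 20, 0.1 Hz cut-off by default), least-squares linear detrending,
linear epoch resampling, and sliding-window motion-artifact rejection
(SMAR). Rejected samples are carried as validity flags and are dropped, not
interpolated, so downstream sample counts stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "FilterSpec",
    "ArtifactConfig",
    "MaskedSeries",
    "AsymmetrySeries",
    "average_hemispheres",
    "compute_asymmetry",
    "design_fir",
    "lowpass",
    "smar",
    "epoch_scorable",
    "detrend",
    "resample_epoch",
]


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR low-pass: `order` taps + 1 coefficients, `cutoff` Hz."""

    order: int = 20
    cutoff: float = 0.1
    sampling_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"FIR order must be >= 1, got {self.order}")
        if not 0.0 < self.cutoff < self.sampling_rate / 2.0:
            raise ValueError(
                f"cutoff must lie in (0, Nyquist) = (0, {self.sampling_rate / 2}), got {self.cutoff}"
            )


@dataclass(frozen=True)
class ArtifactConfig:
    """Sliding-window motion-artifact rejection parameters.

    A window is rejected when its peak-to-peak excursion exceeds
    ``threshold_k`` times the series' robust scale (the median window-local
    SD, floored at the global SD so proportionate excursions never trip the
    detector). Epochs retaining fewer than ``min_valid_fraction`` of their
    samples are unscorable.
    """

    window_s: float = 5.0
    threshold_k: float = 5.0
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError(f"window_s must be > 0, got {self.window_s}")
        if self.threshold_k <= 0:
            raise ValueError(f"threshold_k must be > 0, got {self.threshold_k}")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError(f"min_valid_fraction must be in [0, 1], got {self.min_valid_fraction}")


@dataclass
class MaskedSeries:
    """A sampled series with per-sample validity flags (True = usable)."""

    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"series must be 1-D, got shape {self.values.shape}")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape != values shape")

    def __len__(self) -> int:
        return self.values.size

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0


#: Timestamped L-R asymmetry on the acquisition grid, with validity flags.
AsymmetrySeries = MaskedSeries


def _as_masked(series: MaskedSeries | np.ndarray) -> MaskedSeries:
    if isinstance(series, MaskedSeries):
        return series
    return MaskedSeries(np.asarray(series, dtype=float))


def average_hemispheres(
    hbo: np.ndarray, valid: np.ndarray | None = None
) -> tuple[MaskedSeries, MaskedSeries]:
    """Average the 4 leftmost and 4 rightmost channels of an 8 x T matrix.

    Channel rows are ordered left 1-4 then right 5-8. If a per-channel
    validity mask is given, a hemisphere sample is invalid when any of its
    four channels is invalid at that sample.
    """
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    if hbo.shape[0] != 8:
        raise ValueError(f"expected 8 channel rows (left 1-4, right 5-8), got {hbo.shape[0]}")
    if valid is None:
        vleft = vright = np.ones(hbo.shape[1], dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != hbo.shape:
            raise ValueError("channel validity mask shape != hbo shape")
        vleft = valid[:4].all(axis=0)
        vright = valid[4:].all(axis=0)
    left = MaskedSeries(hbo[:4].mean(axis=0), vleft)
    right = MaskedSeries(hbo[4:].mean(axis=0), vright)
    return left, right


def compute_asymmetry(
    left: MaskedSeries | np.ndarray, right: MaskedSeries | np.ndarray
) -> AsymmetrySeries:
    """Left minus right hemisphere HbO: the prefrontal asymmetry signal.

    A sample is invalid iff either input is invalid there.
    """
    l, r = _as_masked(left), _as_masked(right)
    if len(l) != len(r):
        raise ValueError(f"length mismatch: left {len(l)} vs right {len(r)}")
    return MaskedSeries(l.values - r.values, l.valid & r.valid)


def design_fir(spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Windowed-sinc (Hamming) low-pass kernel, normalized to unity DC gain."""
    kernel = scipy.signal.firwin(
        spec.order + 1, spec.cutoff, fs=spec.sampling_rate, window="hamming", pass_zero="lowpass"
    )
    return kernel / kernel.sum()


def lowpass(series: MaskedSeries | np.ndarray, spec: FilterSpec = FilterSpec()) -> MaskedSeries:
    """Zero-lag FIR low-pass: group delay of order/2 samples is compensated.

    The input is edge-padded by one kernel length before convolution so a
    constant series passes through unchanged. Validity flags are preserved.
    """
    s = _as_masked(series)
    kernel = design_fir(spec)
    n = len(s)
    if n <= spec.order:
        raise ValueError(f"series length {n} must exceed filter order {spec.order}")
    pad = kernel.size
    xp = np.pad(s.values, pad, mode="edge")
    y = np.convolve(xp, kernel, mode="same")[pad:-pad]
    return MaskedSeries(y, s.valid.copy())


def smar(series: MaskedSeries | np.ndarray, cfg: ArtifactConfig = ArtifactConfig(),
         sampling_rate: float = 2.0) -> MaskedSeries:
    """Sliding-window motion-artifact rejection.

    Slides a ``window_s`` window one sample at a time; every sample inside a
    window whose peak-to-peak excursion exceeds ``threshold_k`` x the robust
    scale is flagged invalid. The robust scale is the median of the
    window-local SDs, floored at the global SD of the series, so a series
    whose overall excursion stays below ``threshold_k`` x its own SD is
    never flagged.
    """
    s = _as_masked(series)
    n = len(s)
    w = max(2, int(round(cfg.window_s * sampling_rate)))
    if n < w:
        return MaskedSeries(s.values.copy(), s.valid.copy())
    x = s.values
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    ptp = windows.max(axis=1) - windows.min(axis=1)
    local_sd = windows.std(axis=1, ddof=0)
    scale = max(float(np.median(local_sd)), float(x.std(ddof=0)))
    threshold = cfg.threshold_k * scale
    valid = s.valid.copy()
    bad_windows = np.flatnonzero(ptp > threshold)
    for i in bad_windows:
        valid[i:i + w] = False
    return MaskedSeries(x.copy(), valid)


def epoch_scorable(series: MaskedSeries, cfg: ArtifactConfig = ArtifactConfig()) -> bool:
    """An epoch is scorable iff enough samples survived artifact rejection."""
    return series.valid_fraction >= cfg.min_valid_fraction


def detrend(series: MaskedSeries | np.ndarray) -> MaskedSeries:
    """Subtract the least-squares straight line fitted over valid samples.

    The line is fitted on valid samples only but subtracted everywhere, so
    invalid samples stay on the same (detrended) scale.
    """
    s = _as_masked(series)
    t = np.arange(len(s), dtype=float)
    if int(s.valid.sum()) < 2:
        raise ValueError("detrend needs >= 2 valid samples")
    slope, intercept = np.polyfit(t[s.valid], s.values[s.valid], 1)
    return MaskedSeries(s.values - (slope * t + intercept), s.valid.copy())


def resample_epoch(
    time: np.ndarray, values: np.ndarray, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto ``n_samples`` equally spaced points.

    The new grid spans [time[0], time[-1]]. ``values`` may be 1-D (time,) or
    2-D (channel, time); rows are interpolated independently.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.size < 2:
        raise ValueError("resampling needs >= 2 samples")
    if n_samples < 2:
        raise ValueError("target grid needs >= 2 samples")
    new_time = np.linspace(time[0], time[-1], n_samples)
    if values.ndim == 1:
        return new_time, np.interp(new_time, time, values)
    if values.ndim == 2:
        out = np.empty((values.shape[0], n_samples))
        for i, row in enumerate(values):
            out[i] = np.interp(new_time, time, row)
        return new_time, out
    raise ValueError(f"values must be 1-D or 2-D, got shape {values.shape}")
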