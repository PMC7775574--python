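"""Closed-loop mapping from prefrontal asymmetry to visual feedback.

Each block's asymmetry is mapped linearly onto a [0, 1] feedback signal at
the 2 Hz acquisition rate. The mapping range is either *dynamic* — Min is
the mean of the reference (View) epoch asymmetry plus 1.28 standard
deviations (so ~90% of spontaneous reference variation produces no
feedback), Max is Min plus the reference variation range — or *fixed*
(threshold 0, maximum 1.1) for the protocol without a reference epoch.

``run_block`` drives one full block: epoch segmentation by protocol plan,
optional per-channel filtering / artifact rejection / detrending, bound
computation, feedback generation, and success scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import signal as sig
from .datamodel import (
    BlockRecord,
    EpochData,
    MARKER_NF,
    MARKER_REST,
    MARKER_VIEW,
)
from .scoring import (
    BlockScore,
    SuccessCriterion,
    baseline_success_ttest,
    block_success_ttest,
    bootstrap_success,
    trim_delay_mask,
)
from .signal import ArtifactConfig, AsymmetrySeries, FilterSpec, MaskedSeries

__all__ = [
    "MappingParams",
    "EpochSpec",
    "ProtocolConfig",
    "ANG",
    "RAP",
    "HEU",
    "PROTOCOLS",
    "get_protocol",
    "mapping_bounds",
    "fixed_bounds",
    "map_feedback",
    "BlockRun",
    "run_block",
]

#: z such that Phi(z) ~ 0.90: the no-feedback quantile of the dynamic bound.
THRESHOLD_Z = 1.28

_EPOCH_MARKERS = {"Rest": MARKER_REST, "View": MARKER_VIEW, "NF": MARKER_NF}


@dataclass(frozen=True)
class MappingParams:
    """Feedback mapping range in asymmetry units (umol/L HbO difference)."""

    min_threshold: float
    max_threshold: float
    mode: str = "dynamic"  # "dynamic" | "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("dynamic", "fixed"):
            raise ValueError(f"mode must be 'dynamic' or 'fixed', got {self.mode!r}")
        if not self.max_threshold >= self.min_threshold:
            raise ValueError(
                f"max_threshold {self.max_threshold} < min_threshold {self.min_threshold}"
            )


@dataclass(frozen=True)
class EpochSpec:
    """One epoch of the block plan: label in {Rest, View, NF} and duration."""

    label: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in _EPOCH_MARKERS:
            raise ValueError(f"epoch label must be one of {sorted(_EPOCH_MARKERS)}, got {self.label!r}")
        if self.duration_s <= 0:
            raise ValueError(f"epoch duration must be > 0, got {self.duration_s}")


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol variant: block structure, processing chain, success test.

    The shipped presets reconcile the published protocol tables; every
    field stays configurable because the sources report epoch lengths both
    as scheduled and as effective durations.
    """

    name: str
    n_blocks: int
    n_practice: int
    epoch_plan: tuple[EpochSpec, ...]
    hemodynamic_delay_s: float = 7.0
    sampling_rate: float = 2.0
    mapping_mode: str = "dynamic"  # "dynamic" | "fixed"
    fixed_min: float = 0.0
    fixed_max: float = 1.1
    success_test: str = "parametric"  # "parametric" | "bootstrap"
    success_measure: str = "d"  # "d" | "r"
    use_filter: bool = False
    use_smar: bool = False
    use_detrend: bool = False
    #: reference each channel to its mean over the Rest epoch (the per-block
    #: HbO baseline is acquired during Rest)
    baseline_to_rest: bool = True
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    artifact_config: ArtifactConfig = field(default_factory=ArtifactConfig)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_practice < 0:
            raise ValueError("block counts must be positive")
        if self.mapping_mode not in ("dynamic", "fixed"):
            raise ValueError(f"bad mapping_mode {self.mapping_mode!r}")
        if self.success_test not in ("parametric", "bootstrap"):
            raise ValueError(f"bad success_test {self.success_test!r}")
        labels = [e.label for e in self.epoch_plan]
        if "NF" not in labels:
            raise ValueError("epoch plan must contain an NF epoch")
        if self.mapping_mode == "dynamic" and "View" not in labels:
            raise ValueError("dynamic mapping requires a View (reference) epoch in the plan")

    @property
    def has_reference_epoch(self) -> bool:
        return any(e.label == "View" for e in self.epoch_plan)

    def samples_per_epoch(self) -> tuple[int, ...]:
        return tuple(int(round(e.duration_s * self.sampling_rate)) for e in self.epoch_plan)

    def samples_per_block(self) -> int:
        return sum(self.samples_per_epoch())


# Rest is 30 s in all presets; View/NF durations follow the protocol tables
# (ANG's 22 s epochs leave 15 s = 30 samples after the 7 s trim).
ANG = ProtocolConfig(
    name="ANG",
    n_blocks=6,
    n_practice=2,
    epoch_plan=(EpochSpec("Rest", 30.0), EpochSpec("View", 22.0), EpochSpec("NF", 22.0)),
    mapping_mode="dynamic",
    success_test="parametric",
    success_measure="d",
)

RAP = ProtocolConfig(
    name="RAP",
    n_blocks=8,
    n_practice=1,
    epoch_plan=(EpochSpec("Rest", 30.0), EpochSpec("View", 40.0), EpochSpec("NF", 40.0)),
    mapping_mode="dynamic",
    success_test="bootstrap",
    success_measure="r",
    use_filter=True,
    use_smar=True,
    use_detrend=True,
)

HEU = ProtocolConfig(
    name="HEU",
    n_blocks=6,
    n_practice=3,
    epoch_plan=(EpochSpec("Rest", 30.0), EpochSpec("NF", 30.0)),
    mapping_mode="fixed",
    success_test="parametric",
    success_measure="r",
)

PROTOCOLS = {"ANG": ANG, "RAP": RAP, "HEU": HEU}


def get_protocol(name: str) -> ProtocolConfig:
    try:
        return PROTOCOLS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown protocol {name!r}; expected one of {sorted(PROTOCOLS)}") from None


# ---------------------------------------------------------------------------
# mapping


def mapping_bounds(view_asym: AsymmetrySeries | np.ndarray) -> MappingParams:
    """Per-block dynamic bounds from the reference (View) epoch asymmetry.

    Min = mean + 1.28 x sample SD (ddof = 1) of the valid View samples, so
    for normally distributed reference asymmetry ~90% of spontaneous
    variation falls below Min and yields no feedback. Max = Min + the
    variation range (max - min) of the View samples.
    """
    view = view_asym.valid_values if isinstance(view_asym, MaskedSeries) else np.asarray(view_asym, dtype=float)
    if view.size < 2:
        raise ValueError(f"need >= 2 valid reference samples, got {view.size}")
    sd = float(view.std(ddof=1))
    rng = float(view.max() - view.min())
    if rng == 0.0:  # all samples identical => SD is zero too (modulo fp noise)
        raise ValueError("degenerate reference epoch: zero variance and zero range")
    lo = float(view.mean()) + THRESHOLD_Z * sd
    return MappingParams(min_threshold=lo, max_threshold=lo + rng, mode="dynamic")


def fixed_bounds(protocol: ProtocolConfig) -> MappingParams:
    """Protocol-fixed bounds (threshold 0, maximum 1.1) for HEU-style blocks."""
    if protocol.mapping_mode != "fixed":
        raise ValueError(f"protocol {protocol.name} uses dynamic mapping; no fixed bounds")
    return MappingParams(min_threshold=protocol.fixed_min, max_threshold=protocol.fixed_max, mode="fixed")


def map_feedback(asym_value: float | np.ndarray, params: MappingParams) -> float | np.ndarray:
    """Linear map of asymmetry onto [0, 1], clamped outside [Min, Max].

    Emitted once per 2 Hz sample in the real-time loop; vectorized here so a
    whole NF epoch maps in one call.
    """
    span = params.max_threshold - params.min_threshold
    if span == 0.0:
        raise ValueError("degenerate mapping: max_threshold equals min_threshold")
    x = np.asarray(asym_value, dtype=float)
    fb = np.clip((x - params.min_threshold) / span, 0.0, 1.0)
    return float(fb) if np.isscalar(asym_value) or fb.ndim == 0 else fb


# ---------------------------------------------------------------------------
# block execution


@dataclass(frozen=True)
class BlockRun:
    """Outcome of one block: the storable record plus its detailed score."""

    record: BlockRecord
    score: BlockScore | None
    scorable: bool
    asymmetry: AsymmetrySeries  # processed series used for mapping/scoring


def _slice_epoch(
    hbo_f: np.ndarray, hbo_raw: np.ndarray, time: np.ndarray, marker: np.ndarray,
    left: np.ndarray, right: np.ndarray, asym: np.ndarray, lo: int, hi: int,
) -> EpochData:
    return EpochData(
        time=time[lo:hi],
        marker=marker[lo:hi],
        hbo=hbo_f[:, lo:hi],
        hbo_unfiltered=hbo_raw[:, lo:hi],
        average_left=left[lo:hi],
        average_right=right[lo:hi],
        asymmetry=asym[lo:hi],
    )


def run_block(
    hbo: np.ndarray,
    protocol: ProtocolConfig,
    block_number: int = 0,
    is_practice: bool = False,
    t0: float = 0.0,
    criterion: SuccessCriterion | None = None,
    seed: int | np.random.Generator = 0,
) -> BlockRun:
    """Execute one block of the closed loop on an 8 x T HbO matrix.

    Segments samples into the protocol's epoch plan (half-open slices on
    the sample grid), applies the protocol's processing chain (FIR low-pass,
    Rest-epoch baselining, SMAR, detrending as configured), computes the
    mapping bounds from the
    reference epoch (or the protocol's fixed bounds), produces the feedback
    series over the NF epoch, and scores block success. ``t0`` offsets the
    wall-clock time vector; ``seed`` feeds the bootstrap test only.

    Raises if the input is shorter than the epoch plan.
    """
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    fs = protocol.sampling_rate
    counts = protocol.samples_per_epoch()
    n_total = sum(counts)
    if hbo.shape[1] < n_total:
        raise ValueError(
            f"input has {hbo.shape[1]} samples; epoch plan needs {n_total} at {fs} Hz"
        )
    hbo = hbo[:, :n_total]
    time = t0 + np.arange(n_total) / fs

    # epoch boundaries, half-open [lo, hi) on the sample grid
    edges = np.concatenate([[0], np.cumsum(counts)])
    spans = {}
    marker = np.zeros(n_total, dtype=int)
    for spec, lo, hi in zip(protocol.epoch_plan, edges[:-1], edges[1:]):
        spans[spec.label] = (int(lo), int(hi))
        marker[lo:hi] = _EPOCH_MARKERS[spec.label]

    # processing chain (per channel), kept consistent with the stored epochs
    if protocol.use_filter:
        hbo_f = np.vstack([sig.lowpass(ch, protocol.filter_spec).values for ch in hbo])
    else:
        hbo_f = hbo.copy()
    if protocol.baseline_to_rest and "Rest" in spans:
        rlo, rhi = spans["Rest"]
        hbo_f = hbo_f - hbo_f[:, rlo:rhi].mean(axis=1, keepdims=True)
    if protocol.use_smar:
        # artifact detection on the raw series: smoothing attenuates the
        # short transients SMAR is meant to catch
        ch_valid = np.vstack(
            [sig.smar(ch, protocol.artifact_config, fs).valid for ch in hbo]
        )
    else:
        ch_valid = np.ones_like(hbo_f, dtype=bool)

    left, right = sig.average_hemispheres(hbo_f, ch_valid)
    asym = sig.compute_asymmetry(left, right)
    processed = sig.detrend(asym) if protocol.use_detrend else asym

    # mapping bounds from the reference epoch (or fixed)
    vlo, vhi = spans.get("View", (0, 0))
    nlo, nhi = spans["NF"]
    if protocol.mapping_mode == "fixed":
        params = fixed_bounds(protocol)
    else:
        view_series = MaskedSeries(processed.values[vlo:vhi], processed.valid[vlo:vhi])
        params = mapping_bounds(view_series)
    feedback = np.asarray(map_feedback(processed.values[nlo:nhi], params))

    # success scoring on the delay-trimmed processed asymmetry
    criterion = criterion or SuccessCriterion(delay_trim_s=protocol.hemodynamic_delay_s)
    nf_keep = trim_delay_mask(time[nlo:nhi], criterion.delay_trim_s)
    nf_series = MaskedSeries(
        processed.values[nlo:nhi][nf_keep], processed.valid[nlo:nhi][nf_keep]
    )
    scorable = sig.epoch_scorable(nf_series, protocol.artifact_config)
    score: BlockScore | None = None
    if protocol.has_reference_epoch:
        view_keep = trim_delay_mask(time[vlo:vhi], criterion.delay_trim_s)
        view_series = MaskedSeries(
            processed.values[vlo:vhi][view_keep], processed.valid[vlo:vhi][view_keep]
        )
        scorable = scorable and sig.epoch_scorable(view_series, protocol.artifact_config)
        if scorable:
            if protocol.success_test == "bootstrap":
                score = bootstrap_success(view_series, nf_series, seed=seed, criterion=criterion)
            else:
                score = block_success_ttest(view_series, nf_series, criterion)
    elif scorable:
        score = baseline_success_ttest(nf_series, criterion)

    record = BlockRecord(
        block_number=block_number,
        is_practice=is_practice,
        success=bool(score.success) if score is not None else False,
        whole_block=_slice_epoch(hbo_f, hbo, time, marker, left.values, right.values,
                                 asym.values, 0, n_total),
        nf_epoch=_slice_epoch(hbo_f, hbo, time, marker, left.values, right.values,
                              asym.values, nlo, nhi),
        view_epoch=(
            _slice_epoch(hbo_f, hbo, time, marker, left.values, right.values, asym.values, vlo, vhi)
            if protocol.has_reference_epoch
            else None
        ),
        mapping_min=params.min_threshold if params.mode == "dynamic" else None,
        mapping_max=params.max_threshold if params.mode == "dynamic" else None,
        mapping_feedback=feedback,
    )
    return BlockRun(record=record, score=score, scorable=scorable, asymmetry=processed)
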