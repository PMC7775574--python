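"""Synthetic 8-channel HbO generator with known ground truth.

Emulates the statistical structure the pipeline assumes: per-channel
baseline plus slow linear drift plus iid Gaussian noise at 2 Hz, a
task-evoked *left-lateralized* response during NF epochs that follows a
gamma-CDF ramp reaching plateau at the ~7 s hemodynamic delay, and optional
simultaneous motion spikes. The injected effect is expressed in units of
the asymmetry-level noise SD, so ``effect_size`` is directly comparable to
the Cohen's d the scoring module recovers. Subjects are responders with
probability ``responder_fraction``; ground truth (epoch boundaries,
responder flags, injected effects) is recorded so parameter-recovery tests
need no inference about the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from . import signal as sig
from .datamodel import (
    ExperimentDataset,
    GenericHeader,
    MarkerTable,
    SubjectRecord,
)
from .nfengine import ProtocolConfig, get_protocol, run_block

__all__ = [
    "SynthConfig",
    "BlockGroundTruth",
    "hemodynamic_response",
    "generate_block",
    "generate_dataset",
]

#: gamma shape of the HRF ramp; the scale is tuned per-config so that the
#: CDF reaches 0.95 exactly at the hemodynamic delay.
_HRF_SHAPE = 4.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    ``effect_size`` is the NF asymmetry shift in units of the asymmetry
    noise SD (noise_sd / sqrt(2) for 4-channel hemisphere means of iid
    channel noise); ``noise_sd`` is per-channel, in umol/L; ``drift_slope_sd``
    is the SD of the per-block shared drift slope in umol/L per second;
    ``artifact_rate`` is motion spikes per minute.
    """

    protocol: ProtocolConfig
    n_subjects: int = 11
    effect_size: float = 1.5
    responder_fraction: float = 0.7
    noise_sd: float = 0.3
    drift_slope_sd: float = 0.002
    baseline_sd: float = 0.2
    hrf_delay_s: float = 7.0
    artifact_rate: float = 0.0
    artifact_amplitude_k: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        for name in ("noise_sd", "drift_slope_sd", "baseline_sd", "hrf_delay_s",
                     "artifact_rate", "artifact_amplitude_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def asymmetry_noise_sd(self) -> float:
        """SD of the L-R asymmetry induced by iid per-channel noise."""
        return self.noise_sd / math.sqrt(2.0)


@dataclass(frozen=True)
class BlockGroundTruth:
    """What the generator actually injected into one block."""

    block_number: int
    is_practice: bool
    responder: bool
    injected_effect: float  # asymmetry shift in asymmetry-noise-SD units
    epoch_bounds: dict[str, tuple[int, int]]  # label -> half-open sample span
    n_artifacts: int
    artifact_samples: tuple[int, ...]


def hemodynamic_response(t_since_onset: float | np.ndarray, delay_s: float = 7.0) -> np.ndarray | float:
    """Gamma-CDF activation ramp: 0 at onset, >= 0.95 of plateau at ``delay_s``.

    Models the sluggish hemodynamic response that motivates discarding the
    first ~7 s of each scored epoch.
    """
    t = np.asarray(t_since_onset, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_onset must be >= 0")
    scale = delay_s / scipy.stats.gamma.ppf(0.95, _HRF_SHAPE)
    out = scipy.stats.gamma.cdf(t, _HRF_SHAPE, scale=scale)
    return float(out) if np.isscalar(t_since_onset) else out


def generate_block(
    cfg: SynthConfig,
    rng: np.random.Generator,
    responder: bool,
    block_number: int = 0,
    is_practice: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, BlockGroundTruth]:
    """One block of raw 8-channel HbO: (hbo, time, marker, ground_truth).

    Channels are baseline + shared linear drift + iid Gaussian noise.
    During the NF epoch responders receive +delta/2 on the four left
    channels and -delta/2 on the four right channels, ramped by the HRF,
    where delta = effect_size x asymmetry-noise SD; channel sums are thus
    unchanged and only the asymmetry pathway carries the effect. Motion
    artifacts (Poisson, ``artifact_rate``/min) hit all channels
    simultaneously as short decaying transients (~1.5 s).
    """
    proto = cfg.protocol
    fs = proto.sampling_rate
    counts = proto.samples_per_epoch()
    n = sum(counts)
    time = np.arange(n) / fs

    baseline = rng.normal(0.0, cfg.baseline_sd, size=(8, 1))
    drift_slope = rng.normal(0.0, cfg.drift_slope_sd)
    drift = drift_slope * time  # shared slow drift, cancels in asymmetry on average
    noise = rng.normal(0.0, cfg.noise_sd, size=(8, n))
    hbo = baseline + drift + noise

    edges = np.concatenate([[0], np.cumsum(counts)])
    bounds: dict[str, tuple[int, int]] = {}
    marker = np.zeros(n, dtype=int)
    from .nfengine import _EPOCH_MARKERS  # shared label -> id vocabulary

    for spec, lo, hi in zip(proto.epoch_plan, edges[:-1], edges[1:]):
        bounds[spec.label] = (int(lo), int(hi))
        marker[lo:hi] = _EPOCH_MARKERS[spec.label]

    effect = cfg.effect_size if responder else 0.0
    if effect:
        nlo, nhi = bounds["NF"]
        t_rel = time[nlo:nhi] - time[nlo]
        ramp = hemodynamic_response(t_rel, cfg.hrf_delay_s)
        delta = effect * cfg.asymmetry_noise_sd * ramp
        hbo[:4, nlo:nhi] += delta / 2.0
        hbo[4:, nlo:nhi] -= delta / 2.0

    artifact_samples: list[int] = []
    if cfg.artifact_rate > 0:
        expected = cfg.artifact_rate * (n / fs) / 60.0
        n_spikes = rng.poisson(expected)
        if n_spikes:
            pos = np.sort(rng.integers(0, n, size=n_spikes))
            amp = cfg.artifact_amplitude_k * cfg.noise_sd
            decay = np.array([1.0, 0.6, 0.3])  # ~1.5 s movement transient
            for p in pos:
                sign = rng.choice([-1.0, 1.0])
                stop = min(n, p + decay.size)
                hbo[:, p:stop] += sign * amp * decay[: stop - p]
            artifact_samples = [int(p) for p in pos]

    truth = BlockGroundTruth(
        block_number=block_number,
        is_practice=is_practice,
        responder=responder,
        injected_effect=effect,
        epoch_bounds=bounds,
        n_artifacts=len(artifact_samples),
        artifact_samples=tuple(artifact_samples),
    )
    return hbo, time, marker, truth


def _subject_ids(n: int, rng: np.random.Generator) -> list[str]:
    """Unique ids following the MDDN convention (month, day, order-on-day)."""
    ids: list[str] = []
    while len(ids) < n:
        month = int(rng.integers(1, 10))  # single digit keeps ids 4 chars
        day = int(rng.integers(1, 29))
        for order in range(1, 10):
            sid = f"{month}{day:02d}{order}"
            if sid not in ids:
                ids.append(sid)
                break
        if len(ids) > 10 * n:  # pragma: no cover - defensive
            break
    return ids[:n]


def generate_dataset(cfg: SynthConfig) -> tuple[ExperimentDataset, dict]:
    """A full experiment dataset plus its ground-truth sidecar.

    Runs every generated block through the real closed loop (``run_block``)
    so the stored epochs, mapping parameters, feedback series and success
    flags are exactly what the pipeline produces. Practice blocks come
    first and are flagged; the responder flag is drawn once per subject.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    proto = cfg.protocol
    n_per_block = proto.samples_per_block()
    n_blocks_total = proto.n_blocks + proto.n_practice

    header = GenericHeader(
        sampling_rate=proto.sampling_rate,
        number_of_channels=8,
        filter_kernel=(sig.design_fir(proto.filter_spec) if proto.use_filter else np.array([1.0])),
        experiment_id=proto.name,
    )
    subjects: list[SubjectRecord] = []
    truth_subjects = []
    sids = _subject_ids(cfg.n_subjects, rng)
    block_gap_s = 10.0  # wall-clock pause between blocks

    for sid in sids:
        responder = bool(rng.random() < cfg.responder_fraction)
        channel_data = np.empty((8, n_per_block, n_blocks_total))
        asym_data = np.empty((n_per_block, n_blocks_total))
        blocks = []
        truths = []
        norm_time = np.arange(n_per_block) / proto.sampling_rate
        norm_marker = None
        t0 = 0.0
        for b in range(n_blocks_total):
            is_practice = b < proto.n_practice
            hbo, _, marker, truth = generate_block(cfg, rng, responder, b, is_practice)
            run = run_block(hbo, proto, block_number=b, is_practice=is_practice,
                            t0=t0, seed=rng)
            channel_data[:, :, b] = run.record.whole_block.hbo
            asym_data[:, b] = run.asymmetry.values
            blocks.append(run.record)
            truths.append(truth)
            if norm_marker is None:
                norm_marker = marker
            t0 += n_per_block / proto.sampling_rate + block_gap_s
        subjects.append(
            SubjectRecord(
                id=sid,
                channel_data=channel_data,
                asymmetry_data=asym_data,
                time=norm_time,
                marker=norm_marker,
                blocks=blocks,
            )
        )
        truth_subjects.append(
            {
                "id": sid,
                "responder": responder,
                "blocks": [
                    {
                        "block_number": t.block_number,
                        "is_practice": t.is_practice,
                        "responder": t.responder,
                        "injected_effect": t.injected_effect,
                        "epoch_bounds": {k: list(v) for k, v in t.epoch_bounds.items()},
                        "n_artifacts": t.n_artifacts,
                        "artifact_samples": list(t.artifact_samples),
                    }
                    for t in truths
                ],
            }
        )
    dataset = ExperimentDataset(header=header, markers=MarkerTable(), subjects=subjects)
    ground_truth = {
        "protocol": proto.name,
        "effect_size": cfg.effect_size,
        "responder_fraction": cfg.responder_fraction,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "subjects": truth_subjects,
    }
    return dataset, ground_truth
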