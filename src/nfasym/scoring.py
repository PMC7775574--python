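"""Block-success statistics and effect sizes.

A block succeeds when the mean asymmetry during its NF epoch is
significantly larger than during its reference (View) epoch — or, for
protocols without a reference epoch, larger than zero. Following the
original real-time software, the first 7 s of each scored epoch are
discarded (hemodynamic delay) and the comparison uses a *fixed* critical
value of 2.05 (two-tailed Student t at alpha = 0.05 with 28 degrees of
freedom, the worst case for 15 s of 2 Hz data), applied one-sidedly
(NF > reference). Effect sizes: Cohen's d (mean difference over pooled SD)
and r = sqrt(t^2 / (t^2 + df)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import EpochData, ExperimentDataset
from .signal import MaskedSeries

__all__ = [
    "SuccessCriterion",
    "BlockScore",
    "ExperimentSummary",
    "trim_delay",
    "trim_delay_mask",
    "block_success_ttest",
    "baseline_success_ttest",
    "bootstrap_success",
    "summarize_experiment",
    "rescore_dataset",
]


@dataclass(frozen=True)
class SuccessCriterion:
    """Fixed success threshold used by the real-time software.

    ``critical_t`` is frozen at the df = 28 value regardless of the actual
    per-block sample counts, reproducing the stored success booleans; it
    must agree (to 2 decimals) with the two-tailed Student-t critical value
    at ``alpha`` for ``df``.
    """

    alpha: float = 0.05
    critical_t: float = 2.05
    df: int = 28
    delay_trim_s: float = 7.0

    def __post_init__(self) -> None:
        exact = scipy.stats.t.ppf(1.0 - self.alpha / 2.0, self.df)
        if round(float(exact), 2) != round(self.critical_t, 2):
            raise ValueError(
                f"critical_t {self.critical_t} does not round-match the two-tailed "
                f"t critical value {exact:.4f} at alpha={self.alpha}, df={self.df}"
            )


@dataclass(frozen=True)
class BlockScore:
    t_stat: float
    success: bool
    cohens_d: float
    effect_r: float
    n_view: int
    n_nf: int
    test: str = "parametric"
    ci_low: float | None = None  # bootstrap only: percentile CI of mean diff
    ci_high: float | None = None


def trim_delay_mask(time: np.ndarray, delay_s: float) -> np.ndarray:
    """Keep-mask removing samples within ``delay_s`` of the epoch start."""
    time = np.asarray(time, dtype=float)
    if time.size == 0:
        raise ValueError("empty epoch")
    keep = time >= time[0] + delay_s
    if not keep.any():
        raise ValueError(f"epoch shorter than delay ({delay_s} s): nothing left after trim")
    return keep


def trim_delay(epoch: EpochData, delay_s: float) -> EpochData:
    """Drop the first ``delay_s`` seconds of an epoch (hemodynamic lag).

    A 22 s epoch at 2 Hz (44 samples) trimmed by 7 s retains 30 samples.
    """
    keep = trim_delay_mask(epoch.time, delay_s)
    return EpochData(
        time=epoch.time[keep],
        marker=epoch.marker[keep],
        hbo=epoch.hbo[:, keep],
        hbo_unfiltered=epoch.hbo_unfiltered[:, keep],
        average_left=epoch.average_left[keep],
        average_right=epoch.average_right[keep],
        asymmetry=epoch.asymmetry[keep],
    )


def _valid_values(series: MaskedSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, MaskedSeries):
        return series.valid_values
    return np.asarray(series, dtype=float)


def _effect_r(t: float, df: int) -> float:
    return math.sqrt(t * t / (t * t + df))


def block_success_ttest(
    view_asym: MaskedSeries | np.ndarray,
    nf_asym: MaskedSeries | np.ndarray,
    criterion: SuccessCriterion = SuccessCriterion(),
) -> BlockScore:
    """Pooled-variance independent-samples t-test of NF vs View asymmetry.

    Inputs must already be delay-trimmed; SMAR-flagged samples are dropped.
    Success is the one-sided exceedance t > critical_t (NF above reference).
    """
    view = _valid_values(view_asym)
    nf = _valid_values(nf_asym)
    n1, n2 = view.size, nf.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 valid samples per epoch, got view={n1}, nf={n2}")
    m1, m2 = view.mean(), nf.mean()
    s1, s2 = view.var(ddof=1), nf.var(ddof=1)
    pooled_var = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if pooled_var <= 0.0:
        raise ValueError("zero pooled variance: epochs are constant")
    pooled_sd = math.sqrt(pooled_var)
    d = (m2 - m1) / pooled_sd
    t = (m2 - m1) / (pooled_sd * math.sqrt(1.0 / n1 + 1.0 / n2))
    return BlockScore(
        t_stat=float(t),
        success=bool(t > criterion.critical_t),
        cohens_d=float(d),
        effect_r=_effect_r(float(t), criterion.df),
        n_view=n1,
        n_nf=n2,
        test="parametric",
    )


def baseline_success_ttest(
    nf_asym: MaskedSeries | np.ndarray,
    criterion: SuccessCriterion = SuccessCriterion(),
    baseline: float = 0.0,
) -> BlockScore:
    """One-sample t-test of NF asymmetry against a fixed baseline (default 0).

    Used by protocols without a reference epoch, where any left-lateralized
    asymmetry above the resting zero counts toward success.
    """
    nf = _valid_values(nf_asym)
    if nf.size < 2:
        raise ValueError(f"need >= 2 valid samples, got {nf.size}")
    sd = nf.std(ddof=1)
    if sd <= 0.0:
        raise ValueError("zero variance: epoch is constant")
    t = (nf.mean() - baseline) / (sd / math.sqrt(nf.size))
    d = (nf.mean() - baseline) / sd
    return BlockScore(
        t_stat=float(t),
        success=bool(t > criterion.critical_t),
        cohens_d=float(d),
        effect_r=_effect_r(float(t), criterion.df),
        n_view=0,
        n_nf=int(nf.size),
        test="parametric",
    )


def bootstrap_success(
    view_asym: MaskedSeries | np.ndarray,
    nf_asym: MaskedSeries | np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    criterion: SuccessCriterion = SuccessCriterion(),
) -> BlockScore:
    """Percentile-bootstrap test of mean(NF) - mean(View) > 0.

    Each epoch is resampled with replacement ``n_boot`` times; the block
    succeeds when the central 95% percentile interval of the resampled mean
    difference excludes zero from below. Effect sizes are computed exactly
    as in the parametric path.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    view = _valid_values(view_asym)
    nf = _valid_values(nf_asym)
    if view.size < 2 or nf.size < 2:
        raise ValueError(f"need >= 2 valid samples per epoch, got view={view.size}, nf={nf.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vm = view[rng.integers(0, view.size, size=(n_boot, view.size))].mean(axis=1)
    nm = nf[rng.integers(0, nf.size, size=(n_boot, nf.size))].mean(axis=1)
    diffs = nm - vm
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    parametric = block_success_ttest(view, nf, criterion)
    return BlockScore(
        t_stat=parametric.t_stat,
        success=bool(lo > 0.0),
        cohens_d=parametric.cohens_d,
        effect_r=parametric.effect_r,
        n_view=view.size,
        n_nf=nf.size,
        test="bootstrap",
        ci_low=float(lo),
        ci_high=float(hi),
    )


# ---------------------------------------------------------------------------
# experiment-level summaries


@dataclass
class ExperimentSummary:
    """Per-block table plus the headline success rates.

    ``block_success_rate`` is successes / non-practice blocks;
    ``subject_success_rate`` is the fraction of subjects with at least half
    of their non-practice blocks successful.
    """

    blocks: pd.DataFrame
    n_subjects: int
    n_blocks: int
    n_successful_blocks: int
    block_success_rate: float
    n_successful_subjects: int
    subject_success_rate: float
    per_subject: dict[str, int] = field(default_factory=dict)

    @property
    def block_success_pct(self) -> int:
        return round(100.0 * self.block_success_rate)

    @property
    def subject_success_pct(self) -> int:
        return round(100.0 * self.subject_success_rate)


def _summary_from_records(records: list[dict]) -> ExperimentSummary:
    df = pd.DataFrame.from_records(
        records,
        columns=["subject", "block_number", "is_practice", "success",
                 "t_stat", "cohens_d", "effect_r", "n_view", "n_nf"],
    )
    scored = df[~df["is_practice"]]
    n_blocks = len(scored)
    n_succ = int(scored["success"].sum())
    per_subject: dict[str, int] = {}
    n_succ_subjects = 0
    subjects = scored["subject"].unique().tolist()
    for sid in subjects:
        sub = scored[scored["subject"] == sid]
        wins = int(sub["success"].sum())
        per_subject[sid] = wins
        if len(sub) and wins >= math.ceil(len(sub) / 2):
            n_succ_subjects += 1
    n_subjects = len(subjects)
    return ExperimentSummary(
        blocks=df,
        n_subjects=n_subjects,
        n_blocks=n_blocks,
        n_successful_blocks=n_succ,
        block_success_rate=(n_succ / n_blocks) if n_blocks else 0.0,
        n_successful_subjects=n_succ_subjects,
        subject_success_rate=(n_succ_subjects / n_subjects) if n_subjects else 0.0,
        per_subject=per_subject,
    )


def summarize_experiment(dataset: ExperimentDataset) -> ExperimentSummary:
    """Success summary using the success flags stored in the dataset.

    Practice blocks are excluded from all rates.
    """
    records = []
    for subj in dataset.subjects:
        for b in subj.blocks:
            records.append(
                {
                    "subject": subj.id,
                    "block_number": b.block_number,
                    "is_practice": b.is_practice,
                    "success": bool(b.success),
                    "t_stat": np.nan,
                    "cohens_d": np.nan,
                    "effect_r": np.nan,
                    "n_view": b.view_epoch.n_samples if b.view_epoch is not None else 0,
                    "n_nf": b.nf_epoch.n_samples,
                }
            )
    return _summary_from_records(records)


def rescore_dataset(
    dataset: ExperimentDataset,
    criterion: SuccessCriterion = SuccessCriterion(),
    test: str = "parametric",
    seed: int = 0,
) -> ExperimentSummary:
    """Recompute every block's success from its stored epoch asymmetry.

    Applies the 7 s delay trim to the View and NF epochs, then the
    independent t-test (or bootstrap) against the reference epoch — or the
    one-sample test against zero when the block has no reference epoch.
    The returned table carries the recomputed statistics, so a comparison
    with the stored ``success`` flags is a pure re-analysis.
    """
    if test not in ("parametric", "bootstrap"):
        raise ValueError(f"unknown test {test!r}")
    rng = np.random.default_rng(seed)
    records = []
    for subj in dataset.subjects:
        for b in subj.blocks:
            nf = trim_delay(b.nf_epoch, criterion.delay_trim_s).asymmetry
            if b.view_epoch is not None:
                view = trim_delay(b.view_epoch, criterion.delay_trim_s).asymmetry
                if test == "bootstrap":
                    score = bootstrap_success(view, nf, seed=rng, criterion=criterion)
                else:
                    score = block_success_ttest(view, nf, criterion)
            else:
                score = baseline_success_ttest(nf, criterion)
            records.append(
                {
                    "subject": subj.id,
                    "block_number": b.block_number,
                    "is_practice": b.is_practice,
                    "success": score.success,
                    "t_stat": score.t_stat,
                    "cohens_d": score.cohens_d,
                    "effect_r": score.effect_r,
                    "n_view": score.n_view,
                    "n_nf": score.n_nf,
                }
            )
    return _summary_from_records(records)
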