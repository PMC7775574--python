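"""Object model for prefrontal-asymmetry neurofeedback datasets.

The on-disk format is a single JSON document per experiment, mirroring the
hierarchy used in the published fNIRS neurofeedback datasets: a generic
header (sampling rate, channel count, FIR filter kernel, experiment id), a
marker table, and a list of subjects, each carrying the full channel tensor,
the asymmetry matrix, a shared time/marker grid, and per-block records with
whole-block / reference (View) / NF epoch slices, mapping parameters and the
block success flag.

Arrays are serialized as nested lists with explicit shape metadata so a
save/load cycle is bit-exact (Python's float repr round-trips IEEE doubles).
``validate_dataset`` reports every invariant violation instead of raising,
so files can be triaged; ``save_dataset`` refuses to write an invalid
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any, Iterator

import numpy as np

__all__ = [
    "GenericHeader",
    "MarkerDef",
    "MarkerTable",
    "EpochData",
    "BlockRecord",
    "SubjectRecord",
    "ExperimentDataset",
    "Violation",
    "DatasetValidationError",
    "load_dataset",
    "save_dataset",
    "validate_dataset",
    "dataset_to_dict",
    "dataset_from_dict",
]

PROTOCOL_NAMES = ("ANG", "RAP", "HEU")

#: Marker vocabulary used by the shipped writer. Only the NF-epoch id (54) is
#: fixed by convention in the source datasets; readers must always resolve ids
#: through the file's own marker table rather than these constants.
MARKER_REST = 50
MARKER_VIEW = 52
MARKER_NF = 54
MARKER_NONE = 0

DEFAULT_MARKER_TABLE = (
    (MARKER_NONE, "inter-epoch"),
    (MARKER_REST, "Rest epoch"),
    (MARKER_VIEW, "View epoch"),
    (MARKER_NF, "NF epoch"),
)

_ASYM_TOL = 1e-9


class DatasetValidationError(ValueError):
    """Raised on load/save when a dataset violates its structural contract."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "\n".join(f"  {v.path}: {v.message}" for v in violations)
        super().__init__(f"dataset validation failed with {len(violations)} violation(s):\n{lines}")


@dataclass(frozen=True)
class Violation:
    """One invariant violation, locating the offending JSON path."""

    path: str
    message: str


@dataclass
class GenericHeader:
    """Experiment-wide acquisition metadata.

    ``filter_kernel`` holds the FIR low-pass coefficients applied to the
    stored ``hbo`` series (unity DC sum after normalization); experiments
    that ship unfiltered data store the trivial kernel ``[1.0]``.
    """

    sampling_rate: float = 2.0
    number_of_channels: int = 8
    filter_kernel: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    experiment_id: str = "ANG"

    def __post_init__(self) -> None:
        self.filter_kernel = np.asarray(self.filter_kernel, dtype=float)


@dataclass(frozen=True)
class MarkerDef:
    num: int
    description: str


@dataclass
class MarkerTable:
    """Id -> description table; the per-file authority on marker semantics."""

    entries: list[MarkerDef] = field(
        default_factory=lambda: [MarkerDef(n, d) for n, d in DEFAULT_MARKER_TABLE]
    )

    def ids(self) -> set[int]:
        return {e.num for e in self.entries}

    def describe(self, num: int) -> str:
        for e in self.entries:
            if e.num == num:
                return e.description
        raise KeyError(f"marker id {num} not in table")

    def id_for(self, description: str) -> int:
        for e in self.entries:
            if e.description == description:
                return e.num
        raise KeyError(f"no marker with description {description!r}")


@dataclass
class EpochData:
    """One contiguous slice of a block (whole block, View, or NF epoch).

    ``time`` is un-normalized wall-clock seconds; ``hbo`` is the filtered
    channel x time matrix and ``hbo_unfiltered`` its raw counterpart;
    ``asymmetry`` must equal ``average_left - average_right`` sample-wise.
    """

    time: np.ndarray
    marker: np.ndarray
    hbo: np.ndarray
    hbo_unfiltered: np.ndarray
    average_left: np.ndarray
    average_right: np.ndarray
    asymmetry: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.marker = np.asarray(self.marker, dtype=int)
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbo_unfiltered = np.atleast_2d(np.asarray(self.hbo_unfiltered, dtype=float))
        self.average_left = np.asarray(self.average_left, dtype=float)
        self.average_right = np.asarray(self.average_right, dtype=float)
        self.asymmetry = np.asarray(self.asymmetry, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        if self.time.size < 2:
            return 0.0
        return float(self.time[-1] - self.time[0])


@dataclass
class BlockRecord:
    """One experimental block with its epoch slices and NF outcome.

    ``view_epoch`` is ``None`` for protocols without a reference epoch
    (HEU-style), in which case the mapping bounds are fixed by the protocol
    and ``mapping_min``/``mapping_max`` are absent from the file.
    """

    block_number: int
    success: bool
    whole_block: EpochData
    nf_epoch: EpochData
    view_epoch: EpochData | None = None
    mapping_min: float | None = None
    mapping_max: float | None = None
    mapping_feedback: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_practice: bool = False

    def __post_init__(self) -> None:
        self.mapping_feedback = np.asarray(self.mapping_feedback, dtype=float)


@dataclass
class SubjectRecord:
    """Per-subject data: channel tensor, asymmetry matrix, grid, blocks.

    ``id`` follows the "MDDN" convention (month, day, order-on-day).
    ``channel_data`` has shape (channel, time, block); ``asymmetry_data``
    has shape (time, block); ``time`` is the normalized (block-relative)
    time vector shared by every block; ``marker`` labels each sample.
    """

    id: str
    channel_data: np.ndarray
    asymmetry_data: np.ndarray
    time: np.ndarray
    marker: np.ndarray
    blocks: list[BlockRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channel_data = np.asarray(self.channel_data, dtype=float)
        self.asymmetry_data = np.asarray(self.asymmetry_data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.marker = np.asarray(self.marker, dtype=int)


@dataclass
class ExperimentDataset:
    header: GenericHeader
    markers: MarkerTable = field(default_factory=MarkerTable)
    subjects: list[SubjectRecord] = field(default_factory=list)

    def iter_blocks(self, include_practice: bool = False) -> Iterator[tuple[SubjectRecord, BlockRecord]]:
        for subj in self.subjects:
            for block in subj.blocks:
                if block.is_practice and not include_practice:
                    continue
                yield subj, block


# ---------------------------------------------------------------------------
# serialization


def _array_to_json(a: np.ndarray) -> dict[str, Any]:
    return {"shape": list(a.shape), "data": a.tolist()}


def _array_from_json(obj: Any, path: str) -> np.ndarray:
    if not isinstance(obj, dict) or "shape" not in obj or "data" not in obj:
        raise DatasetValidationError(
            [Violation(path, "expected an array object with 'shape' and 'data'")]
        )
    a = np.asarray(obj["data"], dtype=float)
    if list(a.shape) != list(obj["shape"]):
        raise DatasetValidationError(
            [Violation(path, f"declared shape {obj['shape']} != actual {list(a.shape)}")]
        )
    return a


def _epoch_to_json(e: EpochData) -> dict[str, Any]:
    return {
        "time": e.time.tolist(),
        "marker": e.marker.tolist(),
        "hbo": _array_to_json(e.hbo),
        "hbo_unfiltered": _array_to_json(e.hbo_unfiltered),
        "average_left": e.average_left.tolist(),
        "average_right": e.average_right.tolist(),
        "asymmetry": e.asymmetry.tolist(),
    }


def _epoch_from_json(obj: dict[str, Any], path: str) -> EpochData:
    _require_keys(obj, ("time", "marker", "hbo", "hbo_unfiltered",
                        "average_left", "average_right", "asymmetry"), path)
    return EpochData(
        time=np.asarray(obj["time"], dtype=float),
        marker=np.asarray(obj["marker"], dtype=int),
        hbo=_array_from_json(obj["hbo"], f"{path}.hbo"),
        hbo_unfiltered=_array_from_json(obj["hbo_unfiltered"], f"{path}.hbo_unfiltered"),
        average_left=np.asarray(obj["average_left"], dtype=float),
        average_right=np.asarray(obj["average_right"], dtype=float),
        asymmetry=np.asarray(obj["asymmetry"], dtype=float),
    )


def _require_keys(obj: Any, keys: tuple[str, ...], path: str) -> None:
    if not isinstance(obj, dict):
        raise DatasetValidationError([Violation(path, f"expected object, got {type(obj).__name__}")])
    missing = [k for k in keys if k not in obj]
    if missing:
        raise DatasetValidationError(
            [Violation(path, f"missing required field(s): {', '.join(missing)}")]
        )


def dataset_to_dict(ds: ExperimentDataset) -> dict[str, Any]:
    """Plain-JSON-types view of a dataset (canonical structure)."""
    out: dict[str, Any] = {
        "header": {
            "sampling_rate": float(ds.header.sampling_rate),
            "number_of_channels": int(ds.header.number_of_channels),
            "filter_kernel": ds.header.filter_kernel.tolist(),
            "experiment_id": ds.header.experiment_id,
        },
        "markers": [{"num": e.num, "description": e.description} for e in ds.markers.entries],
        "subjects": [],
    }
    for subj in ds.subjects:
        blocks = []
        for b in subj.blocks:
            bj: dict[str, Any] = {
                "block_number": int(b.block_number),
                "is_practice": bool(b.is_practice),
                "success": bool(b.success),
                "whole_block": _epoch_to_json(b.whole_block),
                "nf_epoch": _epoch_to_json(b.nf_epoch),
                "view_epoch": _epoch_to_json(b.view_epoch) if b.view_epoch is not None else None,
                "mapping_feedback": b.mapping_feedback.tolist(),
            }
            # Fixed-mapping protocols (no reference epoch) omit the bounds.
            if b.mapping_min is not None:
                bj["mapping_min"] = float(b.mapping_min)
            if b.mapping_max is not None:
                bj["mapping_max"] = float(b.mapping_max)
            blocks.append(bj)
        out["subjects"].append(
            {
                "id": subj.id,
                "channel_data": _array_to_json(subj.channel_data),
                "asymmetry_data": _array_to_json(subj.asymmetry_data),
                "time": subj.time.tolist(),
                "marker": subj.marker.tolist(),
                "blocks": blocks,
            }
        )
    return out


def dataset_from_dict(obj: dict[str, Any]) -> ExperimentDataset:
    """Inverse of :func:`dataset_to_dict`; structural errors raise."""
    _require_keys(obj, ("header", "markers", "subjects"), "$")
    h = obj["header"]
    _require_keys(h, ("sampling_rate", "number_of_channels", "filter_kernel", "experiment_id"), "$.header")
    header = GenericHeader(
        sampling_rate=float(h["sampling_rate"]),
        number_of_channels=int(h["number_of_channels"]),
        filter_kernel=np.asarray(h["filter_kernel"], dtype=float),
        experiment_id=str(h["experiment_id"]),
    )
    markers = MarkerTable(
        entries=[MarkerDef(int(m["num"]), str(m["description"])) for m in obj["markers"]]
    )
    subjects = []
    for i, s in enumerate(obj["subjects"]):
        spath = f"$.subjects[{i}]"
        _require_keys(s, ("id", "channel_data", "asymmetry_data", "time", "marker", "blocks"), spath)
        blocks = []
        for j, b in enumerate(s["blocks"]):
            bpath = f"{spath}.blocks[{j}]"
            _require_keys(b, ("block_number", "success", "whole_block", "nf_epoch"), bpath)
            view = b.get("view_epoch")
            blocks.append(
                BlockRecord(
                    block_number=int(b["block_number"]),
                    is_practice=bool(b.get("is_practice", False)),
                    success=bool(b["success"]),
                    whole_block=_epoch_from_json(b["whole_block"], f"{bpath}.whole_block"),
                    nf_epoch=_epoch_from_json(b["nf_epoch"], f"{bpath}.nf_epoch"),
                    view_epoch=_epoch_from_json(view, f"{bpath}.view_epoch") if view is not None else None,
                    mapping_min=float(b["mapping_min"]) if "mapping_min" in b else None,
                    mapping_max=float(b["mapping_max"]) if "mapping_max" in b else None,
                    mapping_feedback=np.asarray(b.get("mapping_feedback", []), dtype=float),
                )
            )
        subjects.append(
            SubjectRecord(
                id=str(s["id"]),
                channel_data=_array_from_json(s["channel_data"], f"{spath}.channel_data"),
                asymmetry_data=_array_from_json(s["asymmetry_data"], f"{spath}.asymmetry_data"),
                time=np.asarray(s["time"], dtype=float),
                marker=np.asarray(s["marker"], dtype=int),
                blocks=blocks,
            )
        )
    return ExperimentDataset(header=header, markers=markers, subjects=subjects)


def load_dataset(path: str | Path | IO[str]) -> ExperimentDataset:
    """Read and validate an experiment dataset from a JSON file.

    Raises :class:`DatasetValidationError` naming the offending JSON path if
    the file violates the structural schema or any cross-field invariant.
    """
    if hasattr(path, "read"):
        obj = json.load(path)  # type: ignore[arg-type]
    else:
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
    ds = dataset_from_dict(obj)
    report = validate_dataset(ds)
    if report:
        raise DatasetValidationError(report)
    return ds


def save_dataset(ds: ExperimentDataset, path: str | Path | IO[str]) -> None:
    """Write a dataset as canonical JSON (sorted keys, compact separators).

    Refuses to write a dataset that fails validation, so every file on disk
    is loadable. Canonical form makes save -> load -> save byte-identical.
    """
    report = validate_dataset(ds)
    if report:
        raise DatasetValidationError(report)
    text = json.dumps(dataset_to_dict(ds), sort_keys=True, separators=(",", ":"), allow_nan=False)
    if hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# validation


def _check_epoch(e: EpochData, n_channels: int, known_ids: set[int],
                 path: str, out: list[Violation]) -> None:
    n = e.time.size
    for name in ("marker", "average_left", "average_right", "asymmetry"):
        v = getattr(e, name)
        if v.shape != (n,):
            out.append(Violation(f"{path}.{name}", f"length {v.shape} != time length ({n},)"))
    for name in ("hbo", "hbo_unfiltered"):
        m = getattr(e, name)
        if m.shape != (n_channels, n):
            out.append(Violation(f"{path}.{name}", f"shape {m.shape} != (channels, time) = ({n_channels}, {n})"))
    if e.marker.shape == (n,):
        unknown = sorted(set(e.marker.tolist()) - known_ids)
        if unknown:
            out.append(Violation(f"{path}.marker", f"marker id(s) {unknown} not in marker table"))
    if n and e.time.size >= 2 and np.any(np.diff(e.time) <= 0):
        out.append(Violation(f"{path}.time", "time vector not strictly increasing"))
    # cross-field identities
    if e.asymmetry.shape == (n,) and e.average_left.shape == (n,) and e.average_right.shape == (n,):
        resid = np.abs(e.asymmetry - (e.average_left - e.average_right))
        if resid.size and float(np.max(resid)) > _ASYM_TOL:
            k = int(np.argmax(resid))
            out.append(Violation(
                f"{path}.asymmetry",
                f"asymmetry != average_left - average_right at sample {k} (|diff| = {resid[k]:.3g})",
            ))
    if e.hbo.shape == (n_channels, n) and n_channels % 2 == 0 and e.average_left.shape == (n,):
        half = n_channels // 2
        left = e.hbo[:half].mean(axis=0)
        right = e.hbo[half:].mean(axis=0)
        if n and float(np.max(np.abs(left - e.average_left))) > _ASYM_TOL:
            out.append(Violation(f"{path}.average_left",
                                 f"not the mean of the {half} leftmost hbo channels"))
        if e.average_right.shape == (n,) and n and float(np.max(np.abs(right - e.average_right))) > _ASYM_TOL:
            out.append(Violation(f"{path}.average_right",
                                 f"not the mean of the {half} rightmost hbo channels"))


def validate_dataset(ds: ExperimentDataset) -> list[Violation]:
    """Check every structural and cross-field invariant; report, never raise.

    Returns an empty list iff the dataset is consistent.
    """
    out: list[Violation] = []
    h = ds.header
    if not h.sampling_rate > 0:
        out.append(Violation("$.header.sampling_rate", f"must be > 0, got {h.sampling_rate}"))
    if h.number_of_channels < 1:
        out.append(Violation("$.header.number_of_channels", f"must be >= 1, got {h.number_of_channels}"))
    if h.experiment_id not in PROTOCOL_NAMES:
        out.append(Violation("$.header.experiment_id",
                             f"unknown experiment id {h.experiment_id!r} (expected one of {PROTOCOL_NAMES})"))
    k = h.filter_kernel
    if k.ndim != 1 or k.size < 1:
        out.append(Violation("$.header.filter_kernel", "must be a 1-D list of >= 1 coefficients"))
    elif abs(float(k.sum()) - 1.0) > 1e-6:
        out.append(Violation("$.header.filter_kernel", f"DC sum {float(k.sum()):.6g} != 1 (kernel must be normalized)"))

    ids = [e.num for e in ds.markers.entries]
    if len(ids) != len(set(ids)):
        out.append(Violation("$.markers", "duplicate marker ids"))
    if "NF epoch" not in {e.description for e in ds.markers.entries}:
        out.append(Violation("$.markers", 'missing required entry with description "NF epoch"'))
    known = set(ids)

    for i, subj in enumerate(ds.subjects):
        spath = f"$.subjects[{i}]"
        cd, ad = subj.channel_data, subj.asymmetry_data
        if cd.ndim != 3:
            out.append(Violation(f"{spath}.channel_data", f"expected (channel, time, block) tensor, got ndim {cd.ndim}"))
        if ad.ndim != 2:
            out.append(Violation(f"{spath}.asymmetry_data", f"expected (time, block) matrix, got ndim {ad.ndim}"))
        if cd.ndim == 3 and ad.ndim == 2:
            if cd.shape[0] != h.number_of_channels:
                out.append(Violation(f"{spath}.channel_data",
                                     f"{cd.shape[0]} channels != header number_of_channels {h.number_of_channels}"))
            if cd.shape[1] != ad.shape[0]:
                out.append(Violation(f"{spath}.asymmetry_data",
                                     f"time axis {ad.shape[0]} != channel_data time axis {cd.shape[1]}"))
            if cd.shape[2] != ad.shape[1]:
                out.append(Violation(f"{spath}.asymmetry_data",
                                     f"block axis {ad.shape[1]} != channel_data block axis {cd.shape[2]}"))
            if subj.time.size != cd.shape[1]:
                out.append(Violation(f"{spath}.time", f"length {subj.time.size} != time axis {cd.shape[1]}"))
        if subj.marker.size != subj.time.size:
            out.append(Violation(f"{spath}.marker", f"length {subj.marker.size} != time length {subj.time.size}"))
        unknown = sorted(set(subj.marker.tolist()) - known)
        if unknown:
            out.append(Violation(f"{spath}.marker", f"marker id(s) {unknown} not in marker table"))

        for j, b in enumerate(subj.blocks):
            bpath = f"{spath}.blocks[{j}]"
            _check_epoch(b.whole_block, h.number_of_channels, known, f"{bpath}.whole_block", out)
            _check_epoch(b.nf_epoch, h.number_of_channels, known, f"{bpath}.nf_epoch", out)
            if b.view_epoch is not None:
                _check_epoch(b.view_epoch, h.number_of_channels, known, f"{bpath}.view_epoch", out)
            if (b.mapping_min is None) != (b.mapping_max is None):
                out.append(Violation(bpath, "mapping_min and mapping_max must both be present or both absent"))
            if b.mapping_min is not None and b.mapping_max is not None and not b.mapping_max >= b.mapping_min:
                out.append(Violation(bpath, f"mapping_max {b.mapping_max} < mapping_min {b.mapping_min}"))
            fb = b.mapping_feedback
            if fb.size and (float(fb.min()) < 0.0 or float(fb.max()) > 1.0):
                out.append(Violation(f"{bpath}.mapping_feedback",
                                     f"values outside [0, 1] (range [{fb.min():.4g}, {fb.max():.4g}])"))
            # epoch slices must be sub-intervals of the whole block, View before NF, disjoint
            wt = b.whole_block.time
            for name, ep in (("view_epoch", b.view_epoch), ("nf_epoch", b.nf_epoch)):
                if ep is None or not ep.time.size or not wt.size:
                    continue
                if ep.time[0] < wt[0] - _ASYM_TOL or ep.time[-1] > wt[-1] + _ASYM_TOL:
                    out.append(Violation(f"{bpath}.{name}", "time range not inside whole_block"))
            if b.view_epoch is not None and b.view_epoch.time.size and b.nf_epoch.time.size:
                if b.view_epoch.time[-1] >= b.nf_epoch.time[0]:
                    out.append(Violation(
                        bpath,
                        "view_epoch overlaps nf_epoch: view ends at "
                        f"{b.view_epoch.time[-1]:.4g} s, nf starts at {b.nf_epoch.time[0]:.4g} s",
                    ))
    return out
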