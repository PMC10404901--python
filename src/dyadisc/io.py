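"""Reading, validating and assembling parcel time series.

On disk, one file per subject per run holds a tab-separated matrix written
timepoints x parcels with a single header row of parcel labels; in memory the
contract is parcels x timepoints (the reader transposes).  All runs of a
study must share identical parcel labels in identical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, MissingRunError, ParseError, ValidationError

__all__ = [
    "RunTimeSeries",
    "SubjectSeries",
    "read_parcel_timeseries",
    "write_parcel_timeseries",
    "concatenate_runs",
    "load_study_series",
]

DEFAULT_PATTERN = "sub-{subject:03d}_run-{run}.tsv"


@dataclass
class RunTimeSeries:
    """One subject's response in one run: (n_parcels, timepoints) matrix."""

    subject_id: object
    run_id: object
    matrix: np.ndarray
    parcel_labels: list[str]

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SubjectSeries:
    """All available runs of one subject, with exclusions recorded."""

    subject_id: object
    #: run_id -> (n_parcels, timepoints) matrix
    runs: dict
    parcel_labels: list[str]
    #: run_id -> reason code for runs excluded from analysis
    excluded: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.runs:
            raise ValidationError(
                f"subject {self.subject_id!r} has no available runs"
            )

    @property
    def available_runs(self) -> list:
        return sorted(self.runs)


def write_parcel_timeseries(path, matrix: np.ndarray,
                            parcel_labels=None) -> None:
    """Write a (n_parcels, timepoints) matrix in the on-disk layout."""
    matrix = np.asarray(matrix, dtype=float)
    labels = (
        [str(lbl) for lbl in parcel_labels]
        if parcel_labels is not None
        else [str(i) for i in range(1, matrix.shape[0] + 1)]
    )
    # %.17g round-trips float64 exactly, so writer -> reader is bit-exact
    pd.DataFrame(matrix.T, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_parcel_timeseries(path, expected_parcels: int | None = None,
                           subject_id=None, run_id=None) -> RunTimeSeries:
    """Read one run's matrix, validating shape and numeric content.

    Raises :class:`DimensionError` if the parcel count differs from
    ``expected_parcels`` and :class:`ParseError` (with row/column location)
    on any non-numeric or non-finite cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        t, p = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: non-numeric or non-finite value at timepoint row {t + 1},"
            f" parcel column {raw.columns[p]!r}"
        )
    matrix = numeric.to_numpy(dtype=float).T  # -> parcels x timepoints
    if expected_parcels is not None and matrix.shape[0] != expected_parcels:
        raise DimensionError(
            f"{path}: expected {expected_parcels} parcels, found {matrix.shape[0]}"
        )
    return RunTimeSeries(
        subject_id=subject_id,
        run_id=run_id,
        matrix=matrix,
        parcel_labels=[str(c) for c in raw.columns],
    )


def concatenate_runs(subject: SubjectSeries, runs=None,
                     trim: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Concatenate the requested runs, in the given order, along time.

    ``trim`` removes the first/last ``trim[0]``/``trim[1]`` timepoints of
    every run before concatenation (e.g. black-screen frames); default keeps
    everything.
    """
    if runs is None:
        runs = subject.available_runs
    missing = [r for r in runs if r not in subject.runs]
    if missing:
        raise MissingRunError(
            f"subject {subject.subject_id!r}: run(s) {missing} not available "
            f"(excluded: {subject.excluded})"
        )
    lo, hi = trim
    blocks = []
    for r in runs:
        m = subject.runs[r]
        stop = m.shape[1] - hi
        if stop - lo < 1:
            raise ValidationError(
                f"trim {trim} leaves no timepoints in run {r!r} of subject "
                f"{subject.subject_id!r}"
            )
        blocks.append(m[:, lo:stop])
    return np.hstack(blocks)


def load_study_series(series_dir, subjects, n_runs: int,
                      expected_parcels: int | None = None,
                      pattern: str = DEFAULT_PATTERN) -> list[SubjectSeries]:
    """Load every subject's runs from ``series_dir``.

    A missing file is recorded as an excluded run (reason ``"absent"``);
    parcel labels must agree across all loaded files.
    """
    series_dir = Path(series_dir)
    out = []
    labels = None
    for sid in subjects:
        runs, excluded = {}, {}
        for run in range(1, n_runs + 1):
            path = series_dir / pattern.format(subject=sid, run=run)
            if not path.exists():
                excluded[run] = "absent"
                continue
            rts = read_parcel_timeseries(path, expected_parcels, sid, run)
            if labels is None:
                labels = rts.parcel_labels
            elif rts.parcel_labels != labels:
                raise ValidationError(
                    f"{path}: parcel labels differ from the study's"
                )
            runs[run] = rts.matrix
        out.append(SubjectSeries(subject_id=sid, runs=runs,
                                 parcel_labels=labels or [],
                                 excluded=excluded))
    return out
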