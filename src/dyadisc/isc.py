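"""Parcelwise dyadic intersubject correlations (ISC).

For every unordered pair of subjects, the Pearson correlation between their
response time series is computed in each parcel over the concatenation of the
runs available to *both* members (dyads with too few overlapping runs are
dropped and recorded).  Correlations are variance-stabilized with the Fisher
z-transform (arctanh) and then z-scored across retained dyads within each
parcel, so each parcel's values enter the downstream model on a common scale.

Dyads are keyed by the sorted pair (subject_a < subject_b); this canonical
orientation is kept until the design is explicitly doubled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateParcelError,
    DegenerateSeriesError,
    ValidationError,
)

__all__ = [
    "ISCTable",
    "pearson_isc",
    "fisher_z",
    "dyad_run_overlap",
    "compute_isc_table",
    "zscore_by_region",
    "DyadicISC",
]

_CLIP_R = 1.0 - 1e-6


def pearson_isc(x, y) -> float:
    """Pearson product-moment correlation between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be one-dimensional and equal length")
    if x.size < 3:
        raise ValidationError("series must have length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSeriesError(None, None, "zero-variance input series")
    xc = x - x.mean()
    yc = y - y.mean()
    # symmetric form: bitwise identical under argument swap
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def fisher_z(r, clip: bool = False):
    """Fisher z-transform, ``z = arctanh(r)``.

    ``|r| >= 1`` raises unless ``clip`` is set, in which case r is clipped to
    +/-(1 - 1e-6); perfect correlation in real data signals a data error, so
    clipping is opt-in for degenerate synthetic cases.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -_CLIP_R, _CLIP_R)
    elif (np.abs(r) >= 1.0).any():
        raise ValidationError("|r| >= 1 has no finite Fisher z; pass clip=True "
                              "if this is intentional")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def zscore_by_region(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each parcel column across dyads (sample SD, ddof=1)."""
    if len(values) < 2:
        raise ValidationError("need >= 2 retained dyads to z-score")
    sd = values.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise DegenerateParcelError(flat)
    return (values - values.mean()) / sd


def dyad_run_overlap(available_runs: dict, min_overlap_runs: int = 1
                     ) -> pd.DataFrame:
    """Run-overlap bookkeeping for every unordered dyad.

    ``available_runs`` maps subject id -> iterable of run ids.  Returns one
    row per dyad (canonical order) with the shared run ids, their count, and
    whether the dyad is retained under the minimum-overlap rule.
    """
    subjects = sorted(available_runs)
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects")
    rows = []
    for a, b in combinations(subjects, 2):
        shared = sorted(set(available_runs[a]) & set(available_runs[b]))
        rows.append((a, b, tuple(shared), len(shared),
                     len(shared) >= min_overlap_runs))
    return pd.DataFrame(
        rows,
        columns=["subject_a", "subject_b", "shared_runs", "n_overlap_runs",
                 "retained"],
    )


@dataclass
class ISCTable:
    """Parcel x dyad ISC values in raw, Fisher-z and z-scored form.

    Each DataFrame is indexed by the canonical (subject_a, subject_b)
    MultiIndex with one column per parcel label.
    """

    r: pd.DataFrame
    z: pd.DataFrame
    z_scored: pd.DataFrame
    #: per-dyad overlap bookkeeping (including dropped dyads)
    overlap: pd.DataFrame
    #: per-dyad total concatenated timepoints
    n_timepoints: pd.Series
    #: parcels whose values were constant across dyads (z_scored is NaN there)
    degenerate_parcels: list = None

    @property
    def dyads(self) -> list[tuple]:
        return list(self.r.index)

    @property
    def parcels(self) -> list[str]:
        return list(self.r.columns)

    @property
    def dropped(self) -> pd.DataFrame:
        return self.overlap[~self.overlap["retained"]]

    def to_long(self) -> pd.DataFrame:
        """Long export: one row per dyad per parcel."""
        retained = self.overlap[self.overlap["retained"]].set_index(
            ["subject_a", "subject_b"]
        )
        frames = []
        for name, df in (("r", self.r), ("fisher_z", self.z),
                         ("z_scored", self.z_scored)):
            s = df.stack()
            s.name = name
            frames.append(s)
        long = pd.concat(frames, axis=1).reset_index()
        long.columns = ["subject_a", "subject_b", "parcel_id",
                        "r", "fisher_z", "z_scored"]
        long["n_overlap_runs"] = long.set_index(
            ["subject_a", "subject_b"]
        ).index.map(retained["n_overlap_runs"])
        long["n_timepoints"] = long.set_index(
            ["subject_a", "subject_b"]
        ).index.map(self.n_timepoints)
        return long

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


def _per_run_stats(subjects, runs, trim):
    """Sufficient statistics per run: sums, sums of squares and per-parcel
    Gram matrices across subjects, from which any dyad's correlation over
    any run subset follows in O(1) per parcel."""
    stats = {}
    for run in runs:
        have = [s for s in subjects if run in s.runs]
        if not have:
            continue
        lo, hi = trim
        mats = []
        for s in have:
            m = s.runs[run]
            stop = m.shape[1] - hi
            mats.append(m[:, lo:stop])
        cube = np.stack(mats)  # (k, p, t)
        k, p, t = cube.shape
        gram = np.empty((p, k, k))
        for j in range(p):
            x = np.ascontiguousarray(cube[:, j, :])
            gram[j] = x @ x.T
        stats[run] = {
            "index": {s.subject_id: i for i, s in enumerate(have)},
            "T": t,
            "sum": cube.sum(axis=2),       # (k, p)
            "ss": (cube ** 2).sum(axis=2),  # (k, p)
            "gram": gram,                   # (p, k, k)
        }
    return stats


def compute_isc_table(subjects, min_overlap_runs: int = 1,
                      clip: bool = False,
                      trim: tuple[int, int] = (0, 0)) -> ISCTable:
    """Compute the full dyadic ISC table for a list of SubjectSeries.

    Per dyad, the correlation is taken over the concatenation of the runs
    available to both members; dyads whose overlap falls below
    ``min_overlap_runs`` are dropped (and reported in ``overlap``).
    """
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects to form dyads")
    labels = subjects[0].parcel_labels
    for s in subjects[1:]:
        if s.parcel_labels != labels:
            raise ValidationError(
                f"subject {s.subject_id!r} has inconsistent parcel labels"
            )
    ids = sorted(s.subject_id for s in subjects)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject ids")
    by_id = {s.subject_id: s for s in subjects}
    all_runs = sorted({r for s in subjects for r in s.runs})
    overlap = dyad_run_overlap(
        {s.subject_id: s.available_runs for s in subjects}, min_overlap_runs
    )
    stats = _per_run_stats(subjects, all_runs, trim)

    p = len(labels)
    kept = overlap[overlap["retained"]]
    r_rows, index, n_time = [], [], []
    for a, b, shared in zip(kept["subject_a"], kept["subject_b"],
                            kept["shared_runs"]):
        t_tot = 0
        s_a = np.zeros(p)
        s_b = np.zeros(p)
        q_a = np.zeros(p)
        q_b = np.zeros(p)
        dot = np.zeros(p)
        for run in shared:
            st = stats[run]
            ia, ib = st["index"][a], st["index"][b]
            t_tot += st["T"]
            s_a += st["sum"][ia]
            s_b += st["sum"][ib]
            q_a += st["ss"][ia]
            q_b += st["ss"][ib]
            dot += st["gram"][:, ia, ib]
        var_a = q_a - s_a ** 2 / t_tot
        var_b = q_b - s_b ** 2 / t_tot
        for arr, q, sid in ((var_a, q_a, a), (var_b, q_b, b)):
            flat = np.flatnonzero(arr <= 1e-12 * np.maximum(q, 1.0))
            if flat.size:
                raise DegenerateSeriesError(by_id[sid].subject_id,
                                            labels[flat[0]])
        cov = dot - s_a * s_b / t_tot
        r_rows.append(cov / np.sqrt(var_a * var_b))
        index.append((a, b))
        n_time.append(t_tot)

    if not r_rows:
        raise ValidationError(
            f"no dyad has >= {min_overlap_runs} overlapping runs"
        )
    idx = pd.MultiIndex.from_tuples(index, names=["subject_a", "subject_b"])
    r = pd.DataFrame(np.vstack(r_rows), index=idx, columns=labels)
    # numerical safety: exact arithmetic can land a hair outside [-1, 1]
    r = r.clip(-1.0, 1.0)
    z = pd.DataFrame(fisher_z(r.to_numpy(), clip=clip), index=idx,
                     columns=labels)
    # z-score per parcel; parcels that cannot be z-scored (a single dyad, or
    # a constant column) become NaN and are reported rather than fatal, so
    # the pipeline can skip and log them
    if len(z) >= 2:
        sd = z.std(ddof=1)
        degenerate = sd.index[sd == 0].tolist()
        zs = (z - z.mean()) / sd.replace(0.0, np.nan)
    else:
        degenerate = list(z.columns)
        zs = z * np.nan
    return ISCTable(
        r=r, z=z, z_scored=zs, overlap=overlap,
        n_timepoints=pd.Series(n_time, index=idx, name="n_timepoints"),
        degenerate_parcels=degenerate,
    )


class DyadicISC(TransformerMixin, BaseEstimator):
    """Transformer from subject time series to the dyadic ISC table.

    The transform is stateless (``fit`` only validates); it exists so the
    ISC stage composes with sklearn-style pipelines and parameter search.

    Parameters
    ----------
    min_overlap_runs : int
        Minimum number of runs a dyad's members must share to be retained.
    clip : bool
        Clip |r| = 1 before the Fisher transform instead of raising.
    zscore : bool
        Return the regionwise z-scored values from :meth:`transform`
        (the full :class:`ISCTable` is kept on ``table_``).
    trim : tuple of int
        Timepoints dropped at the start/end of every run.
    """

    def __init__(self, min_overlap_runs: int = 1, clip: bool = False,
                 zscore: bool = True, trim: tuple[int, int] = (0, 0)):
        self.min_overlap_runs = min_overlap_runs
        self.clip = clip
        self.zscore = zscore
        self.trim = trim

    def fit(self, X, y=None):
        if len(X) < 2:
            raise ValidationError("need at least 2 subjects")
        return self

    def transform(self, X) -> pd.DataFrame:
        table = compute_isc_table(
            X, min_overlap_runs=self.min_overlap_runs, clip=self.clip,
            trim=self.trim,
        )
        self.table_ = table
        return table.z_scored if self.zscore else table.z
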