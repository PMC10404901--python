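"""End-to-end orchestration: ISC -> dyadic design -> per-parcel mixed model
-> FDR across parcels, plus score summaries and the loneliness-ordered ISC
matrix plot.

The FDR family is all analyzed parcels within one contrast, corrected
separately per contrast (Benjamini-Hochberg step-up); parcels skipped as
degenerate are excluded from the family size, so m counts performed tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import build_dyad_table, double_rows, median_split
from .errors import (
    DegenerateCovariateError,
    DegenerateParcelError,
    DegenerateSeriesError,
    NotConvergedError,
    SingularDesignError,
    ValidationError,
)
from .io import load_study_series
from .isc import compute_isc_table
from .lmm import CrossedLMM

__all__ = [
    "PipelineConfig",
    "bh_fdr",
    "analyze_study",
    "run_pipeline",
    "summarize_scores",
    "plot_isc_matrix",
    "COVARIATE_SETS",
]

CONTRAST_NAMES = ("LL_vs_NN", "LL_vs_NL", "NL_vs_NN")

#: named covariate sets for the adjusted models; member-level degree terms
#: are attached to the roles of the doubled design (out_degree_1 is
#: participant_1's out-degree), which keeps estimates invariant to member
#: labelling
COVARIATE_SETS = {
    "none": (),
    "full": ("friendship", "out_degree_1", "out_degree_2", "same_gender",
             "age_diff", "same_ethnicity", "same_country"),
    "indegree": ("friendship", "in_degree_1", "in_degree_2", "same_gender",
                 "age_diff", "same_ethnicity", "same_country"),
}


def bh_fdr(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size (defaults to ``len(p)``); adjusted values are
    ``q_(i) = min_{j >= i} min(1, m p_(j) / j)`` returned in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValidationError("family size m cannot be below len(p)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    series_dir: str | None = None
    subject_table: str | None = None
    edges: str | None = None
    n_parcels: int = 214
    n_runs: int = 4
    min_overlap_runs: int = 1
    trim: tuple[int, int] = (0, 0)
    mode: str = "binarized"          # or "continuous"
    covariates: str = "none"         # none | full | indegree
    split_threshold: float | None = None
    friendship_rule: str = "union"
    ethnicity_match: str = "exact"
    fdr_q: float = 0.05
    alternative: str = "two-sided"
    redundancy_correction: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("binarized", "continuous"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.covariates not in COVARIATE_SETS:
            raise ValidationError(f"unknown covariate set {self.covariates!r}")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValidationError("fdr_q must be in (0, 1)")


_SKIPPABLE = (DegenerateParcelError, DegenerateCovariateError,
              SingularDesignError, NotConvergedError, DegenerateSeriesError)


def analyze_study(subject_series, subject_table: pd.DataFrame,
                  edges: pd.DataFrame | None, cfg: PipelineConfig):
    """Run the per-parcel analysis on in-memory inputs.

    Returns ``(results, isc_table, log)`` where ``results`` has one row per
    parcel per contrast (or per parcel for the continuous slope) with
    BH-adjusted p-values per contrast family, and ``log`` records dropped
    dyads and skipped parcels.
    """
    isc = compute_isc_table(subject_series,
                            min_overlap_runs=cfg.min_overlap_runs,
                            trim=cfg.trim)
    dyads = [tuple(d) for d in isc.z_scored.index]
    dyad_df = build_dyad_table(
        subject_table, edges, dyads=dyads, threshold=cfg.split_threshold,
        friendship_rule=cfg.friendship_rule,
        ethnicity_match=cfg.ethnicity_match,
    )
    doubled = double_rows(dyad_df)
    key = list(zip(doubled["subject_a"], doubled["subject_b"]))
    covs = COVARIATE_SETS[cfg.covariates]

    rows, skipped = [], []
    degenerate = set(isc.degenerate_parcels or ())
    for parcel in isc.z_scored.columns:
        if parcel in degenerate:
            skipped.append({"parcel_id": parcel,
                            "reason": "constant ISC across dyads"})
            continue
        y = isc.z_scored[parcel]
        y_doubled = pd.Series(y.to_numpy(), index=y.index).reindex(key).to_numpy()
        try:
            if cfg.mode == "binarized":
                model = CrossedLMM(
                    covariates=covs, alternative=cfg.alternative,
                    redundancy_correction=cfg.redundancy_correction,
                ).fit(doubled, y_doubled)
                res = model.contrasts()
            else:
                model = CrossedLMM(
                    continuous_col="max_loneliness", covariates=covs,
                    alternative=cfg.alternative,
                    redundancy_correction=cfg.redundancy_correction,
                ).fit(doubled, y_doubled)
                res = model.slope_test()
        except _SKIPPABLE as err:
            skipped.append({"parcel_id": parcel, "reason": str(err)})
            continue
        res = res.copy()
        res.insert(0, "parcel_id", parcel)
        res["var_participant1"] = model.var_participant1_
        res["var_participant2"] = model.var_participant2_
        res["var_resid"] = model.var_resid_
        res["converged"] = model.converged_
        rows.append(res)

    if not rows:
        raise ValidationError("no parcel could be analyzed")
    results = pd.concat(rows, ignore_index=True)
    parts = []
    for name, grp in results.groupby("contrast", sort=False):
        grp = grp.copy()
        grp["p_fdr"] = bh_fdr(grp["p"].to_numpy())
        grp["significant"] = grp["p_fdr"] < cfg.fdr_q
        parts.append(grp)
    results = pd.concat(parts, ignore_index=True)
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_subjects": len(subject_table),
        "n_dyads_retained": len(dyads),
        "dropped_dyads": [
            {"subject_a": a, "subject_b": b, "n_overlap_runs": int(k)}
            for a, b, k in isc.dropped[
                ["subject_a", "subject_b", "n_overlap_runs"]
            ].itertuples(index=False, name=None)
        ],
        "skipped_parcels": skipped,
    }
    return results, isc, log


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """File-based entry point: load inputs, analyze, write result tables."""
    if not (cfg.series_dir and cfg.subject_table):
        raise ValidationError("series_dir and subject_table are required")
    subject_table = pd.read_csv(cfg.subject_table)
    edges = pd.read_csv(cfg.edges) if cfg.edges else None
    subjects = sorted(subject_table["subject_id"])
    series = load_study_series(cfg.series_dir, subjects, cfg.n_runs,
                               expected_parcels=cfg.n_parcels)
    results, isc, log = analyze_study(series, subject_table, edges, cfg)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        for name, grp in results.groupby("contrast", sort=False):
            grp.to_csv(out / f"results_{name}.csv", index=False)
        isc.write_csv(out / "isc_table.csv")
        (out / "run_log.json").write_text(json.dumps(log, indent=2,
                                                     default=str))
    return results


def summarize_scores(subject_table: pd.DataFrame,
                     threshold: float | None = None) -> dict:
    """Descriptive summary of the loneliness totals and the median split."""
    s = subject_table["uls8_total"]
    status = median_split(s.set_axis(subject_table["subject_id"]),
                          threshold=threshold)
    return {
        "n": int(len(s)),
        "min": float(s.min()),
        "max": float(s.max()),
        "mean": float(s.mean()),
        "median": float(s.median()),
        "mode": float(s.mode().iloc[0]),
        "sd": float(s.std(ddof=1)),
        "n_lonely": int((status == "lonely").sum()),
        "n_nonlonely": int((status == "nonlonely").sum()),
    }


def plot_isc_matrix(isc_table, scores: pd.Series, parcel, path=None):
    """Subject-by-subject ISC matrix ordered by increasing loneliness.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(scores.sort_values(kind="mergesort").index)
    n = len(order)
    pos = {sid: i for i, sid in enumerate(order)}
    mat = np.full((n, n), np.nan)
    col = isc_table.z[parcel]
    for (a, b), v in col.items():
        mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = v
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="RdYlBu_r")
    ax.set_xlabel("subjects (increasing loneliness)")
    ax.set_ylabel("subjects (increasing loneliness)")
    ax.set_title(f"Fisher-z ISC, parcel {parcel}")
    fig.colorbar(im, ax=ax, label="Fisher z")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
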