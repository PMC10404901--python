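"""Synthetic dyadic-ISC studies with known ground truth.

The generator emulates a naturalistic-viewing study: ``n_subjects`` people
watch the same stimulus over ``n_runs`` runs while a parcellated "neural"
response is recorded, and each person also reports a loneliness total on an
8-item scale (items 1-4, totals 8-32), demographics, and directed friendship
nominations.

The neural model is a shared-signal construction.  Each subject *i* carries a
per-parcel attunement weight ``w_ip`` in [0, 1] and the response in parcel *p*
on a run is::

    y_ip(t) = w_ip * s_p(t) + sqrt(1 - w_ip**2) * noise_sd * eta_ip(t)

with ``s_p`` a shared unit-variance Gaussian signal (independent across
parcels and runs) and ``eta_ip`` independent unit-variance Gaussian noise.
With ``noise_sd = 1`` the population Pearson correlation between two subjects
is exactly ``w_ip * w_jp``, which makes every downstream stage testable
against a closed form.

The Anna-Karenina structure is injected through the attunement map: in
*affected* parcels, attunement decreases linearly with standardized
loneliness (lonelier people drift away from the shared response), so the
expected ISC of a dyad is driven down by its lonelier member; in unaffected
parcels attunement is constant and loneliness is irrelevant.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "generate_loneliness_scores",
    "attunement_from_loneliness",
    "attunement_matrix",
    "generate_timeseries",
    "generate_network",
    "generate_demographics",
    "simulate_study",
    "make_parcel_labels",
]

#: default categorical frequency tables (roughly matching a US first-year
#: university cohort; exact values are arbitrary study conditions)
DEFAULT_GENDER_PROBS = {"female": 41 / 66, "male": 25 / 66}
DEFAULT_ETHNICITY_PROBS = {
    "asian": 0.35,
    "white": 0.30,
    "hispanic": 0.20,
    "black": 0.08,
    "other": 0.07,
}
DEFAULT_COUNTRY_PROBS = {
    "usa": 0.80,
    "china": 0.08,
    "india": 0.05,
    "korea": 0.04,
    "other": 0.03,
}


def make_parcel_labels(n_cortical: int = 200, n_subcortical: int = 14) -> list[str]:
    """Labels for a whole-brain parcellation: cortical + subcortical parcels.

    The default emulates a 200-parcel cortical scheme augmented with 14
    subcortical parcels (214 analysis units in total).
    """
    return [f"ctx-{i:03d}" for i in range(1, n_cortical + 1)] + [
        f"sctx-{i:02d}" for i in range(1, n_subcortical + 1)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic study.

    Parameters
    ----------
    n_subjects, n_parcels, n_runs, timepoints_per_run
        Study dimensions.  Defaults emulate 66 subjects, 214 parcels and
        four runs of 1,125 samples (~60 min at 0.8 s sampling).
    affected_parcels
        1-based parcel indices in which attunement depends on loneliness.
    attunement_max
        Attunement of a perfectly "typical" subject, in [0, 1].
    attunement_slope
        Decrease in attunement per standard deviation of loneliness,
        applied only in affected parcels (>= 0).
    noise_sd
        Scale of the idiosyncratic noise component (> 0).  At 1.0 the
        pairwise correlation closed form ``w_i * w_j`` is exact.
    loneliness_mean, loneliness_sd
        Target moments of the loneliness totals (truncated-normal draw);
        also used to standardize totals inside the attunement map so the
        ground truth is config-determined, not sample-determined.
    loneliness_item_count, item_min, item_max
        Item structure of the loneliness scale (defaults 8 items, 1-4).
    network_mean_degree
        Mean number of outgoing friendship nominations (Poisson).
    degree_loneliness_corr
        Log-linear coupling between standardized loneliness and expected
        out-degree; 0 decouples objective from subjective disconnection.
    """

    n_subjects: int = 66
    n_parcels: int = 214
    affected_parcels: tuple[int, ...] = ()
    n_runs: int = 4
    timepoints_per_run: int = 1125
    attunement_max: float = 0.75
    attunement_slope: float = 0.15
    noise_sd: float = 1.0
    loneliness_mean: float = 15.91
    loneliness_sd: float = 4.879
    loneliness_item_count: int = 8
    item_min: int = 1
    item_max: int = 4
    age_min: int = 18
    age_max: int = 21
    gender_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_PROBS)
    )
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS)
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS)
    )
    network_mean_degree: float = 5.0
    degree_loneliness_corr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        for name in ("n_parcels", "n_runs", "timepoints_per_run",
                     "loneliness_item_count"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        bad = [p for p in self.affected_parcels
               if not 1 <= p <= self.n_parcels]
        if bad:
            raise ValidationError(
                f"affected_parcels must lie in 1..{self.n_parcels}; got {bad}"
            )
        if not 0.0 <= self.attunement_max <= 1.0:
            raise ValidationError("attunement_max must be in [0, 1]")
        if self.attunement_slope < 0:
            raise ValidationError("attunement_slope must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.item_min >= self.item_max:
            raise ValidationError("item_min must be < item_max")
        if self.loneliness_sd <= 0:
            raise ValidationError("loneliness_sd must be > 0")
        if self.network_mean_degree < 0:
            raise ValidationError("network_mean_degree must be >= 0")

    @property
    def score_min(self) -> int:
        """Lowest possible loneliness total (all items at item_min)."""
        return self.loneliness_item_count * self.item_min

    @property
    def score_max(self) -> int:
        """Highest possible loneliness total (all items at item_max)."""
        return self.loneliness_item_count * self.item_max

    @property
    def subject_ids(self) -> list[int]:
        return list(range(1, self.n_subjects + 1))


@dataclass
class SimulatedStudy:
    """A complete synthetic study with its generating truth."""

    config: SimulationConfig
    #: subject_id, uls8_total, item_1..item_k, age, gender, ethnicity, home_country
    subject_table: pd.DataFrame
    #: subject_id -> run_id -> (n_parcels, timepoints) array
    series: dict[int, dict[int, np.ndarray]]
    #: directed nominations: columns nominator_id, nominee_id
    network: pd.DataFrame
    #: long truth table: subject_id, parcel_id, attunement
    truth: pd.DataFrame

    def to_subject_series(self, exclude: Mapping[int, set] | None = None):
        """Bridge to :class:`dyadisc.io.SubjectSeries` objects.

        ``exclude`` maps subject ids to run ids to drop (recorded with the
        reason code ``"excluded"``), emulating per-run quality exclusions.
        """
        from .io import SubjectSeries  # local import to avoid a cycle

        exclude = exclude or {}
        labels = [str(p) for p in range(1, self.config.n_parcels + 1)]
        out = []
        for sid, runs in self.series.items():
            dropped = set(exclude.get(sid, ()))
            kept = {r: m for r, m in runs.items() if r not in dropped}
            out.append(
                SubjectSeries(
                    subject_id=sid,
                    runs=kept,
                    parcel_labels=labels,
                    excluded={r: "excluded" for r in dropped},
                )
            )
        return out

    def write(self, directory) -> None:
        """Write the study in the pipeline's on-disk formats.

        Per-run matrices go to ``sub-<id:03d>_run-<k>.tsv`` (timepoints x
        parcels, tab-separated, one header row of parcel labels); the subject
        table, edge list and attunement truth go to CSV.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from .io import write_parcel_timeseries

        for sid, runs in self.series.items():
            for run_id, mat in runs.items():
                write_parcel_timeseries(
                    directory / f"sub-{sid:03d}_run-{run_id}.tsv", mat,
                    parcel_labels=[str(p) for p in range(1, mat.shape[0] + 1)],
                )
        self.subject_table.to_csv(directory / "subjects.csv", index=False)
        self.network.to_csv(directory / "edges.csv", index=False)
        self.truth.to_csv(directory / "truth.csv", index=False)


def _split_total_into_items(total: int, k: int, lo: int, hi: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Random item vector in [lo, hi]^k summing exactly to ``total``."""
    items = np.full(k, lo, dtype=int)
    for _ in range(int(total) - k * lo):
        eligible = np.flatnonzero(items < hi)
        items[rng.choice(eligible)] += 1
    return items


def generate_loneliness_scores(cfg: SimulationConfig,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
    """Draw per-subject item responses and totals on the loneliness scale.

    Totals come from a truncated normal on ``[score_min, score_max]`` with
    the configured target mean/SD, rounded to integers; each total is then
    split uniformly at random into item responses, so item-total consistency
    holds exactly and totals can never leave the scale bounds.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.score_min, cfg.score_max
    a = (lo - cfg.loneliness_mean) / cfg.loneliness_sd
    b = (hi - cfg.loneliness_mean) / cfg.loneliness_sd
    totals = stats.truncnorm.rvs(
        a, b, loc=cfg.loneliness_mean, scale=cfg.loneliness_sd,
        size=cfg.n_subjects, random_state=rng,
    )
    totals = np.clip(np.rint(totals).astype(int), lo, hi)
    k = cfg.loneliness_item_count
    items = np.vstack(
        [_split_total_into_items(t, k, cfg.item_min, cfg.item_max, rng)
         for t in totals]
    )
    table = pd.DataFrame({"subject_id": cfg.subject_ids, "uls8_total": totals})
    for j in range(k):
        table[f"item_{j + 1}"] = items[:, j]
    return table


def attunement_from_loneliness(total, parcel: int,
                               cfg: SimulationConfig) -> float:
    """Ground-truth attunement of a subject in one parcel.

    In affected parcels ``w = clip(attunement_max - slope * z(total), 0, 1)``
    with ``z`` standardizing by the config's target mean/SD; in unaffected
    parcels ``w = attunement_max`` regardless of loneliness.
    """
    if not cfg.score_min <= total <= cfg.score_max:
        raise ValidationError(
            f"loneliness total {total} outside scale bounds "
            f"[{cfg.score_min}, {cfg.score_max}]"
        )
    if not 1 <= parcel <= cfg.n_parcels:
        raise ValidationError(f"parcel {parcel} outside 1..{cfg.n_parcels}")
    if parcel not in cfg.affected_parcels:
        return float(cfg.attunement_max)
    z = (total - cfg.loneliness_mean) / cfg.loneliness_sd
    return float(np.clip(cfg.attunement_max - cfg.attunement_slope * z, 0.0, 1.0))


def attunement_matrix(totals: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Vectorized attunement: (n_subjects, n_parcels) array in [0, 1]."""
    totals = np.asarray(totals, dtype=float)
    if ((totals < cfg.score_min) | (totals > cfg.score_max)).any():
        raise ValidationError("loneliness totals outside scale bounds")
    z = (totals - cfg.loneliness_mean) / cfg.loneliness_sd
    w = np.full((totals.size, cfg.n_parcels), cfg.attunement_max, dtype=float)
    affected = np.array(sorted(cfg.affected_parcels), dtype=int) - 1
    if affected.size:
        w[:, affected] = np.clip(
            cfg.attunement_max - cfg.attunement_slope * z[:, None], 0.0, 1.0
        )
    return w


def generate_timeseries(w: np.ndarray, cfg: SimulationConfig,
                        rng: np.random.Generator
                        ) -> dict[int, dict[int, np.ndarray]]:
    """Shared-signal time series for all subjects and runs.

    ``w`` is the (n_subjects, n_parcels) attunement matrix.  The shared
    signal is drawn independently per parcel and per run but is common to
    all subjects within a run.
    """
    n, p, t = cfg.n_subjects, cfg.n_parcels, cfg.timepoints_per_run
    amp = np.sqrt(1.0 - w ** 2) * cfg.noise_sd  # idiosyncratic scale
    series: dict[int, dict[int, np.ndarray]] = {
        sid: {} for sid in cfg.subject_ids
    }
    for run in range(1, cfg.n_runs + 1):
        shared = rng.standard_normal((p, t))
        for i, sid in enumerate(cfg.subject_ids):
            eta = rng.standard_normal((p, t))
            series[sid][run] = w[i][:, None] * shared + amp[i][:, None] * eta
    return series


def generate_network(cfg: SimulationConfig, subject_table: pd.DataFrame,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Directed friendship nominations.

    Each subject nominates a Poisson number of distinct others (no
    self-nominations).  ``degree_loneliness_corr`` couples the expected
    out-degree log-linearly to standardized loneliness (mean-preserving),
    so objective and subjective disconnection can be correlated or
    decoupled by configuration.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids = subject_table["subject_id"].to_numpy()
    n = len(ids)
    if cfg.network_mean_degree == 0:
        return pd.DataFrame(columns=["nominator_id", "nominee_id"])
    z = (subject_table["uls8_total"].to_numpy() - cfg.loneliness_mean) / cfg.loneliness_sd
    b = cfg.degree_loneliness_corr
    lam = cfg.network_mean_degree * np.exp(b * z - b ** 2 / 2.0)
    rows = []
    for i, sid in enumerate(ids):
        k = min(int(rng.poisson(lam[i])), n - 1)
        if k == 0:
            continue
        others = ids[ids != sid]
        for nominee in rng.choice(others, size=k, replace=False):
            rows.append((sid, nominee))
    return pd.DataFrame(rows, columns=["nominator_id", "nominee_id"])


def _draw_categorical(probs: Mapping[str, float], size: int,
                      rng: np.random.Generator) -> np.ndarray:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=size, p=p)


def generate_demographics(cfg: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Ages (integer, uniform in [age_min, age_max]) and categorical columns."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    return pd.DataFrame(
        {
            "subject_id": cfg.subject_ids,
            "age": rng.integers(cfg.age_min, cfg.age_max + 1, size=n),
            "gender": _draw_categorical(cfg.gender_probs, n, rng),
            "ethnicity": _draw_categorical(cfg.ethnicity_probs, n, rng),
            "home_country": _draw_categorical(cfg.country_probs, n, rng),
        }
    )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a full study: scores, demographics, network, truth, series.

    Fully deterministic given the config (including its seed): identical
    configs yield bit-identical studies.
    """
    rng = np.random.default_rng(cfg.seed)
    scores = generate_loneliness_scores(cfg, rng)
    demo = generate_demographics(cfg, rng)
    subject_table = scores.merge(demo, on="subject_id", validate="1:1")
    network = generate_network(cfg, subject_table, rng)
    w = attunement_matrix(subject_table["uls8_total"].to_numpy(), cfg)
    series = generate_timeseries(w, cfg, rng)
    truth = pd.DataFrame(
        {
            "subject_id": np.repeat(cfg.subject_ids, cfg.n_parcels),
            "parcel_id": np.tile(np.arange(1, cfg.n_parcels + 1),
                                 cfg.n_subjects),
            "attunement": w.ravel(),
        }
    )
    return SimulatedStudy(
        config=dataclasses.replace(cfg),
        subject_table=subject_table,
        series=series,
        network=network,
        truth=truth,
    )
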