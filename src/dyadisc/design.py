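"""Dyad-level design construction.

Individual traits, the friendship network and demographics are turned into
one row per unordered dyad: the Anna-Karenina group label from a median
split (LL = both lonely, NN = both nonlonely, NL = mixed), the dyad's
maximum loneliness, a friendship indicator, member degrees, and demographic
similarity covariates.  Every derivation is symmetric in the two members.

``double_rows`` then produces the redundant two-rows-per-dyad layout needed
for crossed random intercepts: each dyad appears once as (i, j) and once as
(j, i), with role-attached columns (member degrees) swapped accordingly and
all dyad-level columns replicated.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DuplicateDyadError,
    MissingDataError,
    UnknownSubjectError,
    ValidationError,
)

__all__ = [
    "median_split",
    "dyad_group",
    "max_loneliness",
    "network_degrees",
    "friendship_indicator",
    "demographic_similarity",
    "build_dyad_table",
    "double_rows",
]

LONELY, NONLONELY = "lonely", "nonlonely"

#: role-attached column pairs: (_a/_b in the canonical table -> _1/_2 roles)
_ROLE_COLS = ("out_degree", "in_degree")


def median_split(scores, threshold=None) -> pd.Series:
    """Binarize scores: strictly above the median is "lonely".

    ``scores`` maps subject id -> loneliness total (dict or Series).  Ties
    at the median go to "nonlonely".  An explicit ``threshold`` replaces the
    sample median (useful to reproduce a published split).
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValidationError("median split needs >= 2 subjects")
    cut = float(np.median(s.to_numpy())) if threshold is None else float(threshold)
    return pd.Series(np.where(s > cut, LONELY, NONLONELY), index=s.index)


def dyad_group(status_i: str, status_j: str) -> str:
    """AK group label: LL both lonely, NN both nonlonely, NL mixed."""
    for st in (status_i, status_j):
        if st not in (LONELY, NONLONELY):
            raise ValidationError(f"unknown loneliness status {st!r}")
    n_lonely = (status_i == LONELY) + (status_j == LONELY)
    return {2: "LL", 1: "NL", 0: "NN"}[n_lonely]


def max_loneliness(score_i, score_j):
    """The dyad's loneliness value is the larger member score."""
    return max(score_i, score_j)


def network_degrees(edges: pd.DataFrame, subjects) -> pd.DataFrame:
    """Out- and in-degree per subject from a directed nomination list.

    Duplicate nominations count once (distinct-nominee semantics); isolated
    subjects get degree 0.  Edges naming unknown subjects raise.
    """
    subjects = list(subjects)
    known = set(subjects)
    g = nx.DiGraph()
    g.add_nodes_from(subjects)
    if len(edges):
        unknown = sorted(
            set(edges["nominator_id"]).union(edges["nominee_id"]) - known
        )
        if unknown:
            raise UnknownSubjectError(
                f"edge list references unknown subject(s): {unknown}"
            )
        g.add_edges_from(edges[["nominator_id", "nominee_id"]].itertuples(
            index=False, name=None))
    return pd.DataFrame(
        {
            "out_degree": [g.out_degree(v) for v in subjects],
            "in_degree": [g.in_degree(v) for v in subjects],
        },
        index=pd.Index(subjects, name="subject_id"),
    )


def friendship_indicator(edges: pd.DataFrame, dyad, rule: str = "union") -> int:
    """1 if the dyad members are friends, else 0.

    ``rule="union"`` (default) counts a nomination in either direction;
    ``rule="reciprocal"`` requires both directions.
    """
    a, b = dyad
    if len(edges) == 0:
        return 0
    pairs = set(edges[["nominator_id", "nominee_id"]].itertuples(
        index=False, name=None))
    ab, ba = (a, b) in pairs, (b, a) in pairs
    if rule == "union":
        return int(ab or ba)
    if rule == "reciprocal":
        return int(ab and ba)
    raise ValidationError(f"unknown friendship rule {rule!r}")


def _check_demographics(subject_table: pd.DataFrame, fields) -> pd.DataFrame:
    t = subject_table.set_index("subject_id")
    for f in fields:
        if f not in t.columns:
            raise MissingDataError(f"subject table lacks column {f!r}")
        null = t.index[t[f].isna()]
        if len(null):
            raise MissingDataError(
                f"subject {null[0]!r} is missing demographic field {f!r}"
            )
    return t


def demographic_similarity(subject_table: pd.DataFrame, dyad,
                           ethnicity_match: str = "exact") -> dict:
    """Similarity covariates for one dyad.

    Exact-match indicators for gender/ethnicity/home country and the
    absolute age difference.  ``ethnicity_match="overlap"`` treats
    multi-ethnicity codes as '+'-separated sets matched on non-empty
    intersection.
    """
    t = _check_demographics(
        subject_table, ["age", "gender", "ethnicity", "home_country"]
    )
    a, b = dyad
    for sid in dyad:
        if sid not in t.index:
            raise UnknownSubjectError(f"unknown subject {sid!r}")
    if ethnicity_match == "exact":
        same_eth = int(t.at[a, "ethnicity"] == t.at[b, "ethnicity"])
    elif ethnicity_match == "overlap":
        ea = set(str(t.at[a, "ethnicity"]).split("+"))
        eb = set(str(t.at[b, "ethnicity"]).split("+"))
        same_eth = int(bool(ea & eb))
    else:
        raise ValidationError(f"unknown ethnicity_match {ethnicity_match!r}")
    return {
        "same_gender": int(t.at[a, "gender"] == t.at[b, "gender"]),
        "age_diff": abs(float(t.at[a, "age"]) - float(t.at[b, "age"])),
        "same_ethnicity": same_eth,
        "same_country": int(t.at[a, "home_country"] == t.at[b, "home_country"]),
    }


def build_dyad_table(subject_table: pd.DataFrame,
                     edges: pd.DataFrame | None = None,
                     dyads=None, threshold=None,
                     friendship_rule: str = "union",
                     ethnicity_match: str = "exact") -> pd.DataFrame:
    """One row per unordered dyad with group label, trait and covariates.

    ``dyads`` restricts the table to the given canonical pairs (e.g. those
    retained by the ISC stage); by default all pairs are formed.  The
    binarization threshold defaults to the sample median (strict-above
    rule); pass ``threshold`` to reproduce a fixed published split.
    """
    ids = sorted(subject_table["subject_id"])
    scores = subject_table.set_index("subject_id")["uls8_total"]
    status = median_split(scores, threshold=threshold)
    if edges is None:
        edges = pd.DataFrame(columns=["nominator_id", "nominee_id"])
    degrees = network_degrees(edges, ids)
    pairs = (
        set(edges[["nominator_id", "nominee_id"]].itertuples(index=False,
                                                             name=None))
        if len(edges) else set()
    )
    demo = _check_demographics(
        subject_table, ["age", "gender", "ethnicity", "home_country"]
    )

    if dyads is None:
        dyads = list(combinations(ids, 2))
    rows = []
    for a, b in dyads:
        if not a < b:
            raise ValidationError(f"dyad {(a, b)} is not in canonical order")
        for sid in (a, b):
            if sid not in scores.index:
                raise UnknownSubjectError(f"unknown subject {sid!r} in dyads")
        ab, ba = (a, b) in pairs, (b, a) in pairs
        friend = int(ab or ba) if friendship_rule == "union" else int(ab and ba)
        if friendship_rule not in ("union", "reciprocal"):
            raise ValidationError(f"unknown friendship rule {friendship_rule!r}")
        if ethnicity_match == "exact":
            same_eth = int(demo.at[a, "ethnicity"] == demo.at[b, "ethnicity"])
        elif ethnicity_match == "overlap":
            same_eth = int(bool(
                set(str(demo.at[a, "ethnicity"]).split("+"))
                & set(str(demo.at[b, "ethnicity"]).split("+"))
            ))
        else:
            raise ValidationError(f"unknown ethnicity_match {ethnicity_match!r}")
        rows.append({
            "subject_a": a,
            "subject_b": b,
            "group": dyad_group(status[a], status[b]),
            "max_loneliness": max_loneliness(scores[a], scores[b]),
            "friendship": friend,
            "out_degree_a": degrees.at[a, "out_degree"],
            "out_degree_b": degrees.at[b, "out_degree"],
            "in_degree_a": degrees.at[a, "in_degree"],
            "in_degree_b": degrees.at[b, "in_degree"],
            "same_gender": int(demo.at[a, "gender"] == demo.at[b, "gender"]),
            "age_diff": abs(float(demo.at[a, "age"]) - float(demo.at[b, "age"])),
            "same_ethnicity": same_eth,
            "same_country": int(
                demo.at[a, "home_country"] == demo.at[b, "home_country"]
            ),
        })
    return pd.DataFrame(rows)


def double_rows(dyad_table: pd.DataFrame) -> pd.DataFrame:
    """Two role-ordered rows per canonical dyad.

    Row one assigns (participant_1, participant_2) = (a, b), row two the
    mirror image; member-level degree columns follow their subject into the
    role slots (out_degree_1 is always participant_1's out-degree) so the
    doubled design is invariant to member labelling.  Dyad-level columns are
    replicated exactly.
    """
    keyed = list(zip(dyad_table["subject_a"], dyad_table["subject_b"]))
    if len(set(keyed)) != len(keyed):
        raise DuplicateDyadError("canonical dyad table contains duplicates")
    if any(not a < b for a, b in keyed):
        raise ValidationError("dyad table rows must be canonical (a < b)")

    def orient(first: str, second: str) -> pd.DataFrame:
        out = dyad_table.copy()
        out["participant_1"] = dyad_table[f"subject_{first}"]
        out["participant_2"] = dyad_table[f"subject_{second}"]
        for col in _ROLE_COLS:
            if f"{col}_a" in dyad_table.columns:
                out[f"{col}_1"] = dyad_table[f"{col}_{first}"]
                out[f"{col}_2"] = dyad_table[f"{col}_{second}"]
        return out

    doubled = pd.concat([orient("a", "b"), orient("b", "a")],
                        ignore_index=True)
    drop = [c for c in doubled.columns
            if c.endswith("_a") or c.endswith("_b")]
    keep = ["participant_1", "participant_2", "subject_a", "subject_b"]
    doubled["subject_a"] = np.minimum(doubled["participant_1"],
                                      doubled["participant_2"])
    doubled["subject_b"] = np.maximum(doubled["participant_1"],
                                      doubled["participant_2"])
    cols = keep + [c for c in doubled.columns
                   if c not in keep and c not in ("subject_a", "subject_b")
                   and c not in drop]
    return doubled[cols]
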