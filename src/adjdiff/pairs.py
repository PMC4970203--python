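"""Pairwise between-neighbor difference dataset and descriptive summaries.

For each ordered pair of adjacent units (index county j, neighbor county i)
the dataset holds the outcome difference dY_ij = Y_j - Y_i and covariate
differences dX_ij = X_j - X_i.  Every unordered pair therefore appears twice,
once in each direction with exactly negated values; a 0/1 *modifier* flag
marks one direction of each pair so models can absorb the duplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import AdjacencyGraph

#: descriptive averaging conventions for between-neighbor differences
CONVENTIONS = ("two-stage", "all-ordered-pairs", "modifier-1-only")

PAIR_META_COLUMNS = ("index_id", "neighbor_id", "modifier")


@dataclass
class CountyTable:
    """Per-unit outcome and covariates.

    ``data`` has one row per unit, indexed by unit id, with the outcome in
    ``outcome_col`` (a rate per 100,000 population in the mortality
    application) and all remaining numeric columns treated as covariates
    unless ``covariate_cols`` restricts them.  ``metadata`` optionally maps
    covariate name -> {"source": ..., "units": ...} labels.
    """

    data: pd.DataFrame
    outcome_col: str = "outcome"
    covariate_cols: tuple[str, ...] | None = None
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome_col not in self.data.columns:
            raise ValueError(f"outcome column {self.outcome_col!r} missing")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate unit ids in table")
        if self.covariate_cols is None:
            self.covariate_cols = tuple(
                c for c in self.data.columns
                if c != self.outcome_col and pd.api.types.is_numeric_dtype(self.data[c])
            )
        missing = [c for c in self.covariate_cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"covariate columns missing from table: {missing}")
        cols = [self.outcome_col, *self.covariate_cols]
        if self.data[cols].isna().any().any():
            bad = self.data[cols].isna().any()
            raise ValueError(
                f"missing values not allowed; columns with NaN: "
                f"{list(bad.index[bad])}"
            )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.data.index)

    @classmethod
    def read_csv(cls, path, id_col: str = "id", outcome_col: str = "outcome",
                 **kwargs) -> "CountyTable":
        df = pd.read_csv(path, dtype={id_col: str}).set_index(id_col)
        return cls(df, outcome_col=outcome_col, **kwargs)

    def write_csv(self, path, id_col: str = "id") -> None:
        self.data.rename_axis(id_col).to_csv(path)


class NeighborDifferencer(TransformerMixin, BaseEstimator):
    """Transformer: county table -> ordered-pair difference dataset.

    The output has one row per ordered adjacent pair with columns
    ``index_id, neighbor_id, modifier, delta_outcome, delta_<covariate>...``.
    The modifier is 1 on the row of each unordered pair whose index id sorts
    lexicographically first, 0 on its reverse — any deterministic rule is
    statistically equivalent; this one is reproducible.
    """

    def __init__(self, graph: AdjacencyGraph):
        self.graph = graph

    def fit(self, X: CountyTable | pd.DataFrame, y=None) -> "NeighborDifferencer":
        return self

    def transform(self, X: CountyTable | pd.DataFrame) -> pd.DataFrame:
        table = X if isinstance(X, CountyTable) else CountyTable(X)
        ids = set(table.ids)
        missing = [s for s in self.graph.ids if s not in ids]
        if missing:
            raise ValueError(f"graph units missing from county table: {missing}")
        cols = [table.outcome_col, *table.covariate_cols]
        values = table.data.loc[list(self.graph.ids), cols].to_numpy(float)
        pos = {s: k for k, s in enumerate(self.graph.ids)}
        rows = self.graph.ordered_pairs()
        j_idx = np.array([pos[j] for j, _ in rows])
        i_idx = np.array([pos[i] for _, i in rows])
        deltas = values[j_idx] - values[i_idx]
        out = pd.DataFrame(
            {
                "index_id": [j for j, _ in rows],
                "neighbor_id": [i for _, i in rows],
                "modifier": [1 if j < i else 0 for j, i in rows],
            }
        )
        out["delta_outcome"] = deltas[:, 0]
        for k, c in enumerate(table.covariate_cols, start=1):
            out[f"delta_{c}"] = deltas[:, k]
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(PAIR_META_COLUMNS)


def build_pairs(table: CountyTable | pd.DataFrame,
                graph: AdjacencyGraph) -> pd.DataFrame:
    """One row per ordered adjacent pair; deltas are index minus neighbor."""
    return NeighborDifferencer(graph).fit_transform(table)


def delta_columns(pairs: pd.DataFrame) -> list[str]:
    return [c for c in pairs.columns if c.startswith("delta_")]


def assign_modifier(pairs: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive the modifier flag from the ids; idempotent."""
    out = pairs.copy()
    out["modifier"] = (out["index_id"] < out["neighbor_id"]).astype(int)
    return out


def level2_index(pairs: pd.DataFrame) -> dict[str, np.ndarray]:
    """Mapping index_id -> positional row indices (the two-level nesting)."""
    return {
        str(j): np.asarray(idx)
        for j, idx in pairs.groupby("index_id", sort=False).indices.items()
    }


def describe_differences(pairs: pd.DataFrame,
                         convention: str = "two-stage",
                         ddof: int = 1) -> pd.DataFrame:
    """Per-variable descriptive statistics of between-neighbor differences.

    Conventions
    -----------
    ``all-ordered-pairs``
        Statistics over every ordered row.  Antisymmetry forces every mean
        to be exactly 0, so this convention is a consistency check rather
        than a summary.
    ``two-stage``
        Average within each index unit first, then take mean/SD across
        units ("average mean difference"); absolute statistics are computed
        over ordered rows.
    ``modifier-1-only``
        Statistics over the modifier = 1 rows (one direction per pair).

    ``ddof=1`` gives the sample SD (default); 0 the population SD.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")
    if len(pairs) == 0:
        raise ValueError("empty pair dataset")
    def _sd(v, d):
        return float(np.std(v, ddof=d)) if len(v) > d else float("nan")

    rows = []
    for col in delta_columns(pairs):
        x = pairs[col].to_numpy(float)
        if convention == "all-ordered-pairs":
            mean = float(x.mean())
            sd = _sd(x, ddof)
        elif convention == "modifier-1-only":
            xm = pairs.loc[pairs["modifier"] == 1, col].to_numpy(float)
            mean = float(xm.mean())
            sd = _sd(xm, ddof)
        else:  # two-stage
            per_unit = pairs.groupby("index_id", sort=False)[col].mean()
            mean = float(per_unit.mean())
            sd = _sd(per_unit.to_numpy(float), ddof)
        rows.append(
            {
                "variable": col.removeprefix("delta_"),
                "mean": mean,
                "sd": sd,
                "abs_max": float(np.abs(x).max()),
                "abs_mean": float(np.abs(x).mean()),
                "convention": convention,
            }
        )
    return pd.DataFrame(rows)


def flag_extreme_pairs(pairs: pd.DataFrame, ddof: int = 0) -> pd.Series:
    """Flag ordered pairs whose |outcome difference| is large relative to SD.

    ``two_sd`` when |dY| >= 2*SD, ``one_sd`` when SD <= |dY| < 2*SD, else
    ``none``.  SD is computed over all ordered pairs (population SD by
    default, matching a descriptive-map use).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 rows to compute an SD")
    dy = pairs["delta_outcome"].to_numpy(float)
    sd = float(dy.std(ddof=ddof))
    if sd == 0.0:
        warnings.warn("outcome differences have zero SD; no pairs flagged",
                      stacklevel=2)
        return pd.Series(["none"] * len(pairs), index=pairs.index, name="flag")
    a = np.abs(dy)
    flags = np.where(a >= 2 * sd, "two_sd", np.where(a >= sd, "one_sd", "none"))
    return pd.Series(flags, index=pairs.index, name="flag")


def validate_pairs(pairs: pd.DataFrame, graph: AdjacencyGraph) -> None:
    """Check every PairDataset invariant; raise on the first violation."""
    expected = graph.ordered_pairs()
    got = list(zip(pairs["index_id"], pairs["neighbor_id"]))
    if sorted(got) != sorted(expected):
        raise ValueError("rows do not enumerate each ordered adjacent pair exactly once")
    key = pairs.set_index(["index_id", "neighbor_id"])
    dcols = delta_columns(pairs)
    for (j, i) in graph.edges():
        fwd = key.loc[(j, i), dcols].to_numpy(float)
        rev = key.loc[(i, j), dcols].to_numpy(float)
        if not np.array_equal(fwd, -rev):
            raise ValueError(f"deltas of ({j},{i}) are not exact negations of ({i},{j})")
        m = int(key.loc[(j, i), "modifier"]) + int(key.loc[(i, j), "modifier"])
        if m != 1:
            raise ValueError(f"pair {{{j},{i}}} must have exactly one modifier=1 row")
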