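"""Impact coefficients for microbial guild quantification.

The contribution of a group of equivalent sequences ``s`` — the sequences
assigned to one (taxon, implementation, context) — to a guild is measured
by the impact coefficient

    k_s = A_s * (d_obs_s / d_exp_s) * u_s

where ``A_s`` is the summed normalized abundance (TPM) of the group,
``d_obs_s`` the observed richness (number of distinct unique sequences),
``d_exp_s`` the richness expected from the group's abundance, and
``u_s in [0, 1]`` the univocity of the cluster the sequences fall in
(binary here: functional clusters have u = 1, non-functional u = 0).

Expected richness corrects for the fact that sampling more reads from a
large, unsaturated pool of variants always yields more distinct variants.
Abundance and richness follow a power law per gene,

    d_exp = c * A ** gamma

whose constants (c, gamma) are obtained by ordinary least squares on the
log-log scale, pooled over all groups and contexts of the gene (per-group
constants would make d_obs/d_exp identically one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INCERTAE",
    "GROUP_COLUMNS",
    "SequenceGroup",
    "RichnessModel",
    "as_group_frame",
    "fit_richness_model",
    "expected_richness",
    "impact_coefficient",
    "build_impact_table",
    "aggregate_k",
    "fold_change",
]

#: Label for tree regions / groups outside every defined functional cluster.
INCERTAE = "incertae"

#: Canonical column order of a group table.
GROUP_COLUMNS = ("taxon", "implementation", "context", "abundance_tpm", "d_obs")

_LOG = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass(frozen=True)
class SequenceGroup:
    """A set of equivalent query sequences for one (taxon, implementation,
    context), with summed abundance and observed richness.

    ``unique_sequences`` may be given instead of ``d_obs``; the richness is
    then the cardinality of that set.
    """

    taxon: str
    implementation: str
    context: str
    abundance_tpm: float
    d_obs: int = 0
    unique_sequences: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.unique_sequences and self.d_obs == 0:
            object.__setattr__(self, "d_obs", len(self.unique_sequences))
        if self.unique_sequences and self.d_obs != len(self.unique_sequences):
            raise ValueError(
                f"d_obs={self.d_obs} does not match |unique_sequences|="
                f"{len(self.unique_sequences)} for group {self.key()}"
            )
        if not np.isfinite(self.abundance_tpm) or self.abundance_tpm < 0:
            raise ValueError(f"abundance must be finite and >= 0, got {self.abundance_tpm}")
        if self.abundance_tpm > 0 and self.d_obs < 1:
            raise ValueError(f"group {self.key()} has positive abundance but d_obs < 1")

    def key(self):
        return (self.taxon, self.implementation, self.context)


@dataclass(frozen=True)
class RichnessModel:
    """Fitted constants of the log-log richness-abundance relation."""

    c: float
    gamma: float
    r_squared: float
    n_points: int
    n_excluded: int = 0
    log_base: str = "e"

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"scale constant c must be positive, got {self.c}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")


def as_group_frame(groups) -> pd.DataFrame:
    """Coerce SequenceGroups / records / DataFrame to a canonical group table."""
    if isinstance(groups, pd.DataFrame):
        df = groups.copy()
    else:
        rows = []
        for g in groups:
            if isinstance(g, SequenceGroup):
                rows.append(
                    dict(
                        taxon=g.taxon,
                        implementation=g.implementation,
                        context=g.context,
                        abundance_tpm=g.abundance_tpm,
                        d_obs=g.d_obs,
                    )
                )
            else:
                rows.append(dict(g))
        df = pd.DataFrame(rows)
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"group table lacks columns: {missing}")
    return df


def fit_richness_model(groups, log_base: str = "e") -> RichnessModel:
    """Fit d = c * A**gamma by OLS of log(d_obs) on log(abundance).

    Groups with zero abundance carry no information about the power law and
    are excluded (their count is kept in ``n_excluded``). Requires at least
    three usable groups and a non-degenerate abundance spread.
    """
    if log_base not in _LOG:
        raise ValueError(f"log_base must be one of {sorted(_LOG)}, got {log_base!r}")
    df = as_group_frame(groups)
    a = df["abundance_tpm"].to_numpy(float)
    d = df["d_obs"].to_numpy(float)
    usable = (a > 0) & (d >= 1)
    n_excluded = int((~usable).sum())
    a, d = a[usable], d[usable]
    if a.size < 3:
        raise ValueError(
            f"insufficient points: need >= 3 groups with positive abundance "
            f"and d_obs >= 1, got {a.size}"
        )
    if np.unique(a).size < 2:
        raise ValueError("degenerate regressor: all abundances identical")
    base = _LOG[log_base]
    la, ld = np.log(a) / math.log(base), np.log(d) / math.log(base)
    fit = stats.linregress(la, ld)
    r2 = float(fit.rvalue**2)
    if not np.isfinite(r2):  # constant response
        r2 = 0.0
    return RichnessModel(
        c=float(base**fit.intercept),
        gamma=float(fit.slope),
        r_squared=r2,
        n_points=int(a.size),
        n_excluded=n_excluded,
        log_base=log_base,
    )


def expected_richness(model: RichnessModel, abundance_tpm):
    """Expected number of unique sequences at the given abundance: c * A**gamma."""
    a = np.asarray(abundance_tpm, float)
    if np.any(a <= 0):
        raise ValueError("expected richness is defined for positive abundance only")
    out = model.c * a**model.gamma
    return float(out) if np.isscalar(abundance_tpm) else out


def impact_coefficient(abundance_tpm: float, d_obs: float, d_exp: float, u: float) -> float:
    """k = A * (d_obs / d_exp) * u, the guild contribution of one group."""
    if d_exp <= 0:
        raise ValueError(f"d_exp must be positive, got {d_exp}")
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"univocity must lie in [0, 1], got {u}")
    if abundance_tpm < 0:
        raise ValueError(f"abundance must be >= 0, got {abundance_tpm}")
    return abundance_tpm * (d_obs / d_exp) * u


def build_impact_table(
    groups,
    model: RichnessModel,
    univocity: Mapping[str, float],
    incertae_label: str = INCERTAE,
) -> pd.DataFrame:
    """Apply the impact coefficient to every group.

    Groups whose implementation is the undefined (*incertae*) label get no
    k value — reported as missing, distinct from k = 0 of non-functional
    (u = 0) groups, which are retained and flagged.
    """
    df = as_group_frame(groups)
    defined = sorted(set(df["implementation"]) - {incertae_label})
    offenders = [lab for lab in defined if lab not in univocity]
    if offenders:
        raise KeyError(f"no univocity entry for clusters: {offenders}")
    d_exp = np.full(len(df), np.nan)
    pos = df["abundance_tpm"].to_numpy(float) > 0
    if pos.any():
        d_exp[pos] = expected_richness(model, df.loc[pos, "abundance_tpm"].to_numpy(float))
    out = df.copy()
    out["d_exp"] = d_exp
    u_col, k_col, status = [], [], []
    for row, de in zip(df.itertuples(index=False), d_exp):
        if row.implementation == incertae_label:
            u_col.append(np.nan)
            k_col.append(np.nan)
            status.append(INCERTAE)
            continue
        u = float(univocity[row.implementation])
        u_col.append(u)
        if row.abundance_tpm == 0:
            k_col.append(0.0)
        else:
            k_col.append(impact_coefficient(row.abundance_tpm, row.d_obs, de, u))
        status.append("functional" if u > 0 else "non_functional")
    out["u"] = u_col
    out["k"] = k_col
    out["status"] = status
    return out


def aggregate_k(table: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    """Sum k over the collapsed dimensions.

    ``by`` is a subset of {taxon, implementation, context}; the empty subset
    yields the grand total. Undefined (*incertae*) groups carry no k and are
    excluded; the total over defined groups is conserved under any grouping.
    """
    if len(table) == 0:
        raise ValueError("cannot aggregate an empty impact table")
    allowed = {"taxon", "implementation", "context"}
    unknown = [b for b in by if b not in allowed]
    if unknown:
        raise KeyError(f"unknown grouping keys: {unknown} (allowed: {sorted(allowed)})")
    defined = table[table["k"].notna()]
    if not by:
        return pd.DataFrame({"k": [float(defined["k"].sum())]})
    return defined.groupby(list(by), as_index=False)["k"].sum()


def _select(table: pd.DataFrame, selector: Mapping[str, object]) -> pd.DataFrame:
    mask = np.ones(len(table), bool)
    for col, val in selector.items():
        if col not in table.columns:
            raise KeyError(f"unknown selector column: {col}")
        vals = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
        mask &= table[col].isin(list(vals)).to_numpy()
    return table[mask]


def fold_change(
    table: pd.DataFrame,
    numerator: Mapping[str, object],
    denominator: Mapping[str, object],
    mode: str = "sum",
    model: RichnessModel | None = None,
) -> float:
    """Ratio of aggregated impact between two selections (e.g. two depth layers).

    ``mode="sum"`` (default) divides the summed k of the two selections.
    ``mode="pooled"`` instead re-applies the impact coefficient to each
    pooled selection (A and d_obs summed over its functional groups), which
    requires the fitted richness model.
    """
    num_df = _select(table, numerator)
    den_df = _select(table, denominator)
    if len(num_df) == 0 or len(den_df) == 0:
        raise ValueError("fold change requires non-empty numerator and denominator selections")
    if mode == "sum":
        num = float(num_df["k"].sum())
        den = float(den_df["k"].sum())
    elif mode == "pooled":
        if model is None:
            raise ValueError("pooled fold change requires the richness model")

        def pooled_k(df):
            func = df[df["u"] == 1]
            a = float(func["abundance_tpm"].sum())
            d = float(func["d_obs"].sum())
            if a <= 0:
                return 0.0
            return impact_coefficient(a, d, expected_richness(model, a), 1.0)

        num, den = pooled_k(num_df), pooled_k(den_df)
    else:
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    if den <= 0:
        raise ValueError("fold change denominator aggregates to zero")
    return num / den
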