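"""Group-relative diet specialization via the proportional similarity index.

For an individual i with diet proportions p_i and a population (here: a
Location x Sex x Year x Month group of scats) with mean diet q, the
proportional similarity index is

    PSi = 1 - 0.5 * sum_j |p_ij - q_j|

PSi = 1 means the individual eats exactly the population diet (generalist);
the smallest attainable value in a group of N individuals is 1/N (the
theoretical minimum, reached by a sole specialist on a resource nobody else
touches), so PSi is only comparable across groups after accounting for N.

The group diet q is the unweighted mean of member proportion vectors: each
scat weighs equally regardless of read depth, which is the only convention
under which the 1/N theoretical minimum is exact.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLOSURE_ATOL = 1e-9
LOGIT_CLAMP = 1e-6

SEASONS = {4: "Spring", 5: "Spring", 6: "Summer", 7: "Summer", 8: "Summer",
           9: "Fall", 10: "Fall", 11: "Fall"}

GroupKey = tuple  # (location, sex, year, month)


def psi(p: np.ndarray, q: np.ndarray) -> float:
    """Proportional similarity 1 - 0.5 * sum|p_j - q_j| of two diet vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("diet vectors are over different resource sets")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any() or abs(v.sum() - 1.0) > CLOSURE_ATOL:
            raise ValueError(f"{name} is not a proportion vector summing to 1")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def population_diet(members: pd.DataFrame) -> pd.Series:
    """Unweighted mean diet of a group (rows = member proportion vectors)."""
    if len(members) == 0:
        raise ValueError("empty group has no population diet")
    return members.mean(axis=0)


def theoretical_minimum(n: int) -> float:
    """Smallest attainable PSi in a group of n individuals: 1/n."""
    if n < 1:
        raise ValueError("group size must be >= 1")
    return 1.0 / n


def min_prey_density(members: pd.DataFrame) -> float:
    """Smallest nonzero prey proportion in any single scat of the group."""
    vals = members.to_numpy()
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("group has no positive proportions")
    return float(nz.min())


def shannon(q: pd.Series | np.ndarray) -> float:
    """Shannon-Weaver diversity H = -sum q ln q (nats, 0 ln 0 := 0)."""
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > CLOSURE_ATOL:
        raise ValueError("diversity input must sum to 1")
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def logit(x, clamp: float = LOGIT_CLAMP):
    """ln(x / (1-x)) with values clamped into [clamp, 1-clamp] (warns)."""
    arr = np.asarray(x, dtype=float)
    out_of_range = (arr <= 0) | (arr >= 1)
    if out_of_range.any():
        warnings.warn(f"{int(out_of_range.sum())} value(s) clamped to "
                      f"({clamp}, {1 - clamp}) before logit", stacklevel=2)
    arr = np.clip(arr, clamp, 1.0 - clamp)
    res = np.log(arr / (1.0 - arr))
    return float(res) if np.isscalar(x) or res.ndim == 0 else res


def season_of(month: int) -> str:
    """Spring = Apr-May, Summer = Jun-Aug, Fall = Sep-Nov; else out-of-window."""
    return SEASONS.get(int(month), "out-of-window")


@dataclass
class Group:
    """One Location x Sex x Year x Month bin of scats."""
    key: GroupKey
    members: pd.DataFrame          # species-level proportions, rows = samples
    q: pd.Series = field(init=False)
    psi_values: pd.Series = field(init=False)

    def __post_init__(self):
        self.q = population_diet(self.members)
        vals = self.members.to_numpy()
        qv = self.q.to_numpy()
        self.psi_values = pd.Series(
            1.0 - 0.5 * np.abs(vals - qv).sum(axis=1),
            index=self.members.index, name="psi")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def theoretical_min(self) -> float:
        return theoretical_minimum(self.n)

    @property
    def mean_psi(self) -> float:
        # A singleton group's sole member coincides with its own population
        # diet; PSi is 1 by the formula (the source tables print 0 for such
        # groups as a reporting convention; they are filtered before inference).
        return float(self.psi_values.mean())

    @property
    def shannon(self) -> float:
        return shannon(self.q)

    @property
    def min_prey_density(self) -> float:
        return min_prey_density(self.members)

    @property
    def season(self) -> str:
        return season_of(self.key[3])


def form_groups(props: pd.DataFrame, metadata: pd.DataFrame,
                sex_calls: pd.Series) -> dict[GroupKey, Group]:
    """Partition sexed samples into Location x Sex x Year x Month groups.

    Samples with excluded sex calls are dropped before grouping. Within a
    group the resource axis is the union of taxa its members actually eat.
    """
    sexed = sex_calls[sex_calls.isin(["male", "female"])]
    ids = [s for s in props.index if s in sexed.index and s in metadata.index]
    groups: dict[GroupKey, list] = {}
    for s in ids:
        m = metadata.loc[s]
        key = (m["location"], sexed[s].capitalize(), int(m["year"]), int(m["month"]))
        groups.setdefault(key, []).append(s)
    out = {}
    for key, members in groups.items():
        sub = props.loc[members]
        sub = sub.loc[:, (sub > 0).any(axis=0)]  # group-local resource axis
        out[key] = Group(key, sub)
    return out


def filter_groups(groups: dict[GroupKey, Group], min_n: int = 5
                  ) -> dict[GroupKey, bool]:
    """Retention flags: a group is retained iff N >= min_n (nothing deleted)."""
    return {key: g.n >= min_n for key, g in groups.items()}


def group_summary_table(groups: dict[GroupKey, Group], min_n: int = 5
                        ) -> pd.DataFrame:
    """Per-group summary mirroring the study's printed group table."""
    retained = filter_groups(groups, min_n)
    rows = []
    for key, g in groups.items():
        loc, sex, year, month = key
        rows.append({
            "location": loc, "month": month, "year": year,
            "season": g.season, "sex": sex,
            "min_prey_density": g.min_prey_density,
            "theoretical_min": g.theoretical_min, "n": g.n,
            "mean_psi": g.mean_psi, "use": retained[key],
            "shannon": g.shannon,
        })
    return pd.DataFrame(rows).sort_values(
        ["location", "year", "month", "sex"]).reset_index(drop=True)


def psi_table(groups: dict[GroupKey, Group], min_n: int = 5) -> pd.DataFrame:
    """Per-sample PSi (retained groups only) with its logit transform."""
    retained = filter_groups(groups, min_n)
    rows = []
    for key, g in groups.items():
        if not retained[key]:
            continue
        loc, sex, year, month = key
        for sid, v in g.psi_values.items():
            rows.append({"sample_id": sid, "location": loc, "sex": sex,
                         "year": year, "month": month, "season": g.season,
                         "sample_size": g.n, "psi": v})
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["logit_psi"] = logit(df["psi"].to_numpy())
    return df


def weighted_mean_psi(summary: pd.DataFrame) -> float:
    """Sample-weighted mean of group mean PSi over retained groups."""
    r = summary[summary["use"]]
    if len(r) == 0:
        raise ValueError("no retained groups")
    return float((r["n"] * r["mean_psi"]).sum() / r["n"].sum())


def bootstrap_mean_ci(values, n_resamples: int = 100_000, seed=None,
                      level: float = 0.95):
    """Percentile bootstrap CI of the mean.

    Returns (mean, half_width, lower, upper); half_width = (upper-lower)/2,
    matching the single-number confidence style of the source study.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to bootstrap")
    if n_resamples < 1000:
        raise ValueError("use at least 1,000 resamples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float((upper - lower) / 2), float(lower), float(upper)


def moment_stats(values) -> tuple[float, float]:
    """Moment skewness g1 = m3/m2^1.5 and non-excess kurtosis m4/m2^2."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least three values")
    d = v - v.mean()
    m2 = (d ** 2).mean()
    if m2 == 0:
        raise ValueError("zero variance: moments undefined")
    return float((d ** 3).mean() / m2 ** 1.5), float((d ** 4).mean() / m2 ** 2)
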