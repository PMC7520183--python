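"""Spearman rank correlations between diet composition and specialization.

Lower PSi means stronger specialization, so a *negative* rho between a prey
category's dietary proportion and PSi indicates that eating more of that
category goes with a more specialist diet.
"""
from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

EXACT_P_MAX_N = 10


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of mid-ranks) and two-sided p.

    The p-value uses the exact permutation distribution of rho for
    n <= 10 and the t approximation t = rho*sqrt((n-2)/(1-rho^2)) above.
    Constant input is an error: ranks carry no information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= EXACT_P_MAX_N:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _exact_perm_p(rx, ry, rho_obs) -> float:
    """P(|rho| >= |rho_obs|) under uniform permutation of one rank vector."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    count = total = 0
    for perm in permutations(range(len(rx))):
        r = (rx[list(perm)] * ry).sum() / denom
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def bonferroni_alpha(n_tests: int, base_alpha: float = 0.05) -> float:
    """Family-wise alpha split evenly over n_tests comparisons (4 decimals)."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return round(base_alpha / n_tests, 4)


def order_psi_correlations(order_props: pd.DataFrame, psi: pd.Series,
                           sex: pd.Series | None = None, subset: str = "all",
                           n_bonferroni_tests: int | None = None) -> pd.DataFrame:
    """Spearman correlation of each prey order's proportion against PSi.

    ``subset`` is 'all', 'female' or 'male' (filtered via ``sex``). All
    samples in the subset enter each correlation, zeros included;
    "occurrences" (samples where the order is present) is descriptive.
    Orders that are absent or constant in the subset are skipped with a
    warning. The juvenile/adult salmonid pseudo-orders inherit the same
    Bonferroni alpha as the base orders.
    """
    ids = order_props.index
    if subset != "all":
        if sex is None:
            raise ValueError("sex labels required for a sex subset")
        ids = ids[sex.loc[ids].str.lower() == subset]
    props = order_props.loc[ids]
    pvec = psi.loc[ids]
    if n_bonferroni_tests is None:
        from .diet import ADULT_ORDER, JUVENILE_ORDER
        n_bonferroni_tests = len(
            [c for c in props.columns if c not in (JUVENILE_ORDER, ADULT_ORDER)])
    alpha = bonferroni_alpha(n_bonferroni_tests)
    rows = []
    for order in props.columns:
        col = props[order]
        occurrences = int((col > 0).sum())
        try:
            rho, p = spearman(col.to_numpy(), pvec.to_numpy())
        except ValueError:
            warnings.warn(f"order {order!r} constant or absent in subset "
                          f"{subset!r}: skipped", stacklevel=2)
            continue
        rows.append({"variable": order, "subset": subset, "rho": rho, "p": p,
                     "n": len(col), "occurrences": occurrences,
                     "bonferroni_alpha": alpha, "significant": p < alpha})
    return pd.DataFrame(rows).sort_values("rho").reset_index(drop=True)


def benthic_psi_correlation(benthic: pd.Series, psi: pd.Series,
                            sex: pd.Series | None = None, subset: str = "all"
                            ) -> tuple[float, float]:
    """Spearman correlation of per-scat benthic diet fraction vs PSi."""
    ids = benthic.index
    if subset != "all":
        ids = ids[sex.loc[ids].str.lower() == subset]
    return spearman(benthic.loc[ids].to_numpy(), psi.loc[ids].to_numpy())


def sample_size_bias(summary: pd.DataFrame) -> tuple[float, float]:
    """Diagnostic rho of group mean PSi against group sample size.

    Run over retained groups. Smaller groups mechanically inflate PSi
    (their theoretical minimum 1/N is higher), so an unbiased comparison
    across groups would show rho near 0; a negative rho signals that group
    size still leaks into the specialization metric.
    """
    r = summary[summary["use"]] if "use" in summary.columns else summary
    if len(r) < 3:
        raise ValueError("need at least three retained groups")
    return spearman(r["mean_psi"].to_numpy(), r["n"].to_numpy())


def sex_ratio_analysis(summary: pd.DataFrame, require_both_retained: bool = True
                       ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Percent-female of each male/female group pair vs the pair's mean PSi.

    Pairs share (location, month, year). Percent female = N_f/(N_f+N_m);
    the pair's mean PSi is sample-weighted across the two groups.
    """
    df = summary
    if require_both_retained and "use" in df.columns:
        df = df[df["use"]]
    rows = []
    for (loc, yr, mo), sub in df.groupby(["location", "year", "month"]):
        sexes = set(sub["sex"])
        if {"Female", "Male"} <= sexes:
            f = sub[sub["sex"] == "Female"].iloc[0]
            m = sub[sub["sex"] == "Male"].iloc[0]
            n = f["n"] + m["n"]
            rows.append({
                "location": loc, "year": yr, "month": mo,
                "percent_female": f["n"] / n,
                "paired_mean_psi": (f["n"] * f["mean_psi"]
                                    + m["n"] * m["mean_psi"]) / n,
                "n_female": int(f["n"]), "n_male": int(m["n"])})
    pairs = pd.DataFrame(rows)
    if len(pairs) == 0:
        raise ValueError("no male/female group pairs found")
    try:
        rho_p = spearman(pairs["percent_female"].to_numpy(),
                         pairs["paired_mean_psi"].to_numpy())
    except ValueError as exc:  # < 3 pairs or a constant axis
        warnings.warn(f"sex-ratio correlation undefined: {exc}", stacklevel=2)
        rho_p = (float("nan"), float("nan"))
    return pairs, rho_p
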