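"""Synthetic scat-metabarcoding studies with known specialization structure.

The generative family is Dirichlet-multinomial: each group (one
Location x Sex x Year x Month bin) draws a base diet q0 ~ Dirichlet(alpha0)
over the taxon set, each member scat draws its individual diet
p_i ~ Dirichlet(c * q0), and reads are Multinomial(depth_i, p_i) with
lognormal depths floored at 100 reads. The single knob c controls
between-individual diet spread: large c makes every scat mirror q0
(generalists, PSi -> 1), small c makes scats diverge (specialists, low PSi).

Sex enters through sex-specific c (and an optional per-season multiplier),
so the generator can plant the kind of Sex x Season signal the analysis
stack is meant to detect. qPCR records are generated from the true sex with
a per-reaction dropout probability; a configurable fraction of extra scats
fails sexing entirely, mimicking the field success rate.

Every simulated study carries a truth record of its generative parameters;
recovery tests read the truth record, never re-derive it from outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as dio
from .specialization import season_of


def _default_template() -> pd.DataFrame:
    g = dio.load_group_summaries()
    return g[["location", "year", "month", "sex", "n"]].copy()


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate the source study: the group layout and sizes of its
    printed group table (111 groups, 1,099 sexed scats across 5 haul-outs,
    4 years, months April-November), read depths in the low thousands,
    ~75% sexing success, and a female/male specialization contrast with a
    summer-fall male shift toward generalism.
    """
    template: pd.DataFrame = field(default_factory=_default_template)
    annotation: pd.DataFrame = field(default_factory=dio.load_annotation_fixture)
    base_diet_concentration: float = 0.6     # alpha0, symmetric Dirichlet
    c_female: float = 4.0
    c_male: float = 8.0
    season_c_scale: dict = field(default_factory=lambda: {
        ("Male", "Summer"): 2.0, ("Male", "Fall"): 2.0})
    depth_mean_log: float = 7.5              # ~1,800 reads median
    depth_sigma_log: float = 0.6
    min_depth: int = 100
    qpcr_dropout: float = 0.10               # per-reaction, ZFX and ZFY alike
    excluded_fraction: float = 0.25          # scats with failed sexing
    juvenile_beta: tuple = (2.0, 2.0)        # hard-part juvenile fractions

    def validate(self) -> None:
        if self.base_diet_concentration <= 0:
            raise ValueError("alpha0 must be positive")
        if self.c_female <= 0 or self.c_male <= 0:
            raise ValueError("individual concentrations must be positive")
        if not 0 <= self.qpcr_dropout < 0.5:
            raise ValueError("dropout must be in [0, 0.5)")
        if not 0 <= self.excluded_fraction < 1:
            raise ValueError("excluded fraction must be in [0, 1)")
        if (self.template["n"] < 1).any():
            raise ValueError("template group sizes must be >= 1")


@dataclass
class SimulatedStudy:
    counts: pd.DataFrame
    metadata: pd.DataFrame
    qpcr: pd.DataFrame
    hard_parts: pd.DataFrame
    annotation: pd.DataFrame
    truth: dict


def simulate_group(q0: np.ndarray, c: float, n: int, rng: np.random.Generator,
                   depth_mean_log: float = 7.5, depth_sigma_log: float = 0.6,
                   min_depth: int = 100) -> np.ndarray:
    """Read-count matrix (n x K) for one group with base diet q0."""
    q0 = np.asarray(q0, dtype=float)
    if abs(q0.sum() - 1.0) > 1e-9 or n < 1:
        raise ValueError("q0 must sum to 1 and n must be >= 1")
    # Dirichlet via gammas: tolerates the tiny alphas a sparse q0 produces
    alphas = np.maximum(c * q0, 1e-12)
    g = rng.gamma(np.broadcast_to(alphas, (n, q0.size)))
    rows_bad = g.sum(axis=1) == 0
    g[rows_bad] = 1.0  # pathological underflow: fall back to uniform
    p = g / g.sum(axis=1, keepdims=True)
    depths = np.maximum(
        np.round(rng.lognormal(depth_mean_log, depth_sigma_log, n)),
        min_depth).astype(int)
    return np.vstack([rng.multinomial(d, pi) for d, pi in zip(depths, p)])


def _conditioned_pair(rng, dropout: float) -> tuple[bool, bool]:
    """Two Bernoulli(1-dropout) calls conditioned on at least one success."""
    while True:
        a, b = rng.random(2) >= dropout
        if a or b:
            return bool(a), bool(b)


def simulate_qpcr(true_sex: pd.Series, dropout: float,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Honest (unconditioned) four-reaction qPCR records from true sexes.

    Used by estimator-recovery tests: both ZFX and, for males, both ZFY
    reactions drop out independently with probability ``dropout``.
    """
    n = len(true_sex)
    zfx = rng.random((n, 2)) >= dropout
    male = (true_sex.str.lower() == "male").to_numpy()
    zfy = (rng.random((n, 2)) >= dropout) & male[:, None]
    return pd.DataFrame(
        {"zfx_1": zfx[:, 0], "zfx_2": zfx[:, 1],
         "zfy_1": zfy[:, 0], "zfy_2": zfy[:, 1]}, index=true_sex.index)


def simulate_study(config: SimulationConfig, seed=None) -> SimulatedStudy:
    """Generate a complete study the pipeline can ingest unmodified."""
    config.validate()
    rng = np.random.default_rng(seed)
    taxa = list(config.annotation.index)
    K = len(taxa)
    counts_rows, meta_rows, qpcr_rows, ids = [], [], [], []
    truth_groups = {}
    sid = 0
    for row in config.template.itertuples():
        season = season_of(row.month)
        c = config.c_female if row.sex == "Female" else config.c_male
        c *= config.season_c_scale.get((row.sex, season), 1.0)
        q0 = rng.dirichlet(np.full(K, config.base_diet_concentration))
        counts = simulate_group(
            q0, c, int(row.n), rng, config.depth_mean_log,
            config.depth_sigma_log, config.min_depth)
        truth_groups[(row.location, row.sex, row.year, row.month)] = c
        for i in range(int(row.n)):
            sid += 1
            sample = f"S{sid:05d}"
            ids.append(sample)
            counts_rows.append(counts[i])
            meta_rows.append({"sample_id": sample, "location": row.location,
                              "month": row.month, "year": row.year,
                              "true_sex": row.sex})
            zfx = _conditioned_pair(rng, config.qpcr_dropout)
            if row.sex == "Male":
                zfy = _conditioned_pair(rng, config.qpcr_dropout)
            else:
                zfy = (False, False)
            qpcr_rows.append({"sample_id": sample, "zfx_1": zfx[0],
                              "zfx_2": zfx[1], "zfy_1": zfy[0],
                              "zfy_2": zfy[1]})
    # extra scats whose sexing failed outright (no ZFX amplification)
    n_sexed = len(ids)
    ef = config.excluded_fraction
    n_fail = int(round(n_sexed * ef / (1.0 - ef))) if ef > 0 else 0
    tmpl = config.template.reset_index(drop=True)
    for _ in range(n_fail):
        sid += 1
        sample = f"S{sid:05d}"
        row = tmpl.iloc[int(rng.integers(len(tmpl)))]
        q0 = rng.dirichlet(np.full(K, config.base_diet_concentration))
        counts_rows.append(simulate_group(
            q0, config.c_female, 1, rng, config.depth_mean_log,
            config.depth_sigma_log, config.min_depth)[0])
        ids.append(sample)
        meta_rows.append({"sample_id": sample, "location": row["location"],
                          "month": int(row["month"]), "year": int(row["year"]),
                          "true_sex": "unknown"})
        zfy_contam = bool(rng.random() < 0.2)  # occasional ZFY-only pattern
        qpcr_rows.append({"sample_id": sample, "zfx_1": False, "zfx_2": False,
                          "zfy_1": zfy_contam, "zfy_2": False})
    counts = pd.DataFrame(np.vstack(counts_rows), index=pd.Index(ids, name="sample_id"),
                          columns=taxa)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    qpcr = pd.DataFrame(qpcr_rows).set_index("sample_id")[
        ["zfx_1", "zfx_2", "zfy_1", "zfy_2"]]
    hard_parts = _simulate_hard_parts(config, rng)
    truth = {
        "seed": -1 if seed is None else int(seed),
        "alpha0": config.base_diet_concentration,
        "c_female": config.c_female, "c_male": config.c_male,
        "qpcr_dropout": config.qpcr_dropout,
        "excluded_fraction": config.excluded_fraction,
        "n_sexed": n_sexed, "n_failed": n_fail,
        "n_groups": len(config.template),
    }
    for (loc, sex, yr, mo), c in truth_groups.items():
        truth[f"c[{loc},{sex},{yr},{mo}]"] = c
    return SimulatedStudy(counts, metadata, qpcr, hard_parts,
                          config.annotation, truth)


def _simulate_hard_parts(config: SimulationConfig, rng) -> pd.DataFrame:
    """Month- and season-scope juvenile fractions for each salmonid species."""
    a, b = config.juvenile_beta
    species = config.annotation.index[config.annotation["is_salmonid"]]
    rows = []
    cells = config.template[["location", "year", "month"]].drop_duplicates()
    for cell in cells.itertuples():
        for sp in species:
            if rng.random() < 0.7:  # month-level data not always available
                rows.append({"scope": "month", "sample_id": "",
                             "location": cell.location, "year": cell.year,
                             "month": cell.month, "season": "",
                             "species": sp,
                             "juvenile_fraction": rng.beta(a, b)})
    for season in ("Spring", "Summer", "Fall"):
        for sp in species:
            rows.append({"scope": "season", "sample_id": "", "location": None,
                         "year": None, "month": None, "season": season,
                         "species": sp, "juvenile_fraction": rng.beta(a, b)})
    return pd.DataFrame(rows)


def expected_psi_oracle(q0: np.ndarray, c: float, n: int, reps: int = 2000,
                        seed=None) -> float:
    """Monte Carlo E[group mean PSi] under the Dirichlet generative model.

    Simulates ``reps`` fresh groups and averages the group mean of
    1 - 0.5*sum|p_i - mean(p)| computed on exact individual diets (no read
    noise), the same statistic the specialization stack reports.
    """
    if reps < 1000:
        raise ValueError("use at least 1,000 replicates")
    rng = np.random.default_rng(seed)
    q0 = np.asarray(q0, dtype=float)
    alphas = np.maximum(c * q0, 1e-12)
    total = 0.0
    for _ in range(reps):
        g = rng.gamma(np.broadcast_to(alphas, (n, q0.size)))
        p = g / g.sum(axis=1, keepdims=True)
        q = p.mean(axis=0)
        total += float(np.mean(1.0 - 0.5 * np.abs(p - q).sum(axis=1)))
    return total / reps


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in truth.items():
            fh.write(f"{k}: {v}\n")


def load_truth(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            k, v = line.rstrip("\n").split(": ", 1)
            try:
                out[k] = int(v)
            except ValueError:
                try:
                    out[k] = float(v)
                except ValueError:
                    out[k] = v
    return out
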