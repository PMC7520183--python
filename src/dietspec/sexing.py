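"""Molecular sex assignment from replicated ZFX/ZFY qPCR calls.

Two reactions per probe are run for each scat. The depositor is called male
when at least one ZFY and at least one ZFX reaction amplified, female when
at least one ZFX but no ZFY reaction amplified. Samples with no ZFX
amplification are excluded (separately flagging those whose ZFY did
amplify, a pattern inconsistent with a clean template).

Because a male is called female when both ZFY reactions drop out, the
module also estimates the per-reaction ZFY dropout probability q from the
frequency of single-ZFY males and reports the implied male-to-female
false-negative rate q**2.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class SexCall(str, Enum):
    MALE = "male"
    FEMALE = "female"
    EXCLUDED_NO_ZFX = "excluded_no_zfx"
    EXCLUDED_ZFY_ONLY = "excluded_zfy_only"


@dataclass(frozen=True)
class QpcrRecord:
    """Amplification outcome of the four reactions for one scat."""
    sample_id: str
    zfx_1: bool
    zfx_2: bool
    zfy_1: bool
    zfy_2: bool


def call_sex(record: QpcrRecord) -> SexCall:
    """Classify one scat from its four amplification booleans (total function)."""
    zfx = record.zfx_1 or record.zfx_2
    zfy = record.zfy_1 or record.zfy_2
    if zfx and zfy:
        return SexCall.MALE
    if zfx:
        return SexCall.FEMALE
    if zfy:
        return SexCall.EXCLUDED_ZFY_ONLY
    return SexCall.EXCLUDED_NO_ZFX


def call_sex_table(qpcr: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`call_sex` over a qPCR table (index sample_id)."""
    zfx = qpcr["zfx_1"] | qpcr["zfx_2"]
    zfy = qpcr["zfy_1"] | qpcr["zfy_2"]
    out = pd.Series(SexCall.EXCLUDED_NO_ZFX.value, index=qpcr.index, name="sex_call")
    out[zfx & zfy] = SexCall.MALE.value
    out[zfx & ~zfy] = SexCall.FEMALE.value
    out[~zfx & zfy] = SexCall.EXCLUDED_ZFY_ONLY.value
    return out


def summarize_sexing(calls: pd.Series) -> dict:
    """Counts per call label plus the success rate (male+female)/total."""
    if len(calls) == 0:
        raise ValueError("no qPCR records to summarize")
    counts = {c.value: int((calls == c.value).sum()) for c in SexCall}
    n = len(calls)
    success = counts[SexCall.MALE.value] + counts[SexCall.FEMALE.value]
    counts["total"] = n
    counts["success_rate"] = success / n
    return counts


def estimate_false_negative_rate(
        qpcr: pd.DataFrame, method: str = "conditional") -> tuple[float, float]:
    """Estimate ZFY per-reaction dropout q and the two-reaction FN rate q**2.

    Among male-classified samples, let f be the fraction with exactly one
    positive ZFY reaction. Conditional on being classified male (>= 1 ZFY
    positive), f = 2q(1-q)/(1-q^2) = 2q/(1+q), inverted as q = f/(2-f)
    (default). ``method='unconditional'`` instead inverts the raw
    single-dropout probability 2q(1-q) = f.

    Returns (q_hat, fn_rate).
    """
    calls = call_sex_table(qpcr)
    males = qpcr[calls == SexCall.MALE.value]
    if len(males) == 0:
        raise ValueError("no male-classified samples: dropout not estimable")
    n_pos = males["zfy_1"].astype(int) + males["zfy_2"].astype(int)
    f = float((n_pos == 1).mean())
    if f >= 1.0:
        raise ValueError("every male shows one ZFY dropout: estimator "
                         "undefined at f = 1")
    if method == "conditional":
        q = f / (2.0 - f)
    elif method == "unconditional":
        if f > 0.5:
            raise ValueError("unconditional inversion needs f <= 0.5")
        q = (1.0 - np.sqrt(1.0 - 2.0 * f)) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return q, q * q
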