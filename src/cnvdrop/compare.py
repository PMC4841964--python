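"""Concordance between paired qPCR and ddPCR copy-number calls.

Summarises a set of per-sample call pairs with the least-squares r² of one
method on the other, and Bland-Altman-style agreement statistics on the
difference ddPCR − qPCR (mean, SD and 95 % limits of agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddpcr import Z_95
from .errors import CnvDropError


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    r_squared: float  # NaN when either axis has zero variance
    mean_difference: float  # ddPCR - qPCR
    sd_difference: float
    loa_low: float
    loa_high: float


def concordance(
    cn_qpcr, cn_ddpcr=None, min_pairs: int = 3
) -> ConcordanceResult:
    """Concordance statistics for paired calls.

    Accepts either two aligned sequences or a DataFrame with ``cn_qpcr``
    and ``cn_ddpcr`` columns.  The difference sign convention is fixed as
    ddPCR − qPCR, so a negative mean difference means ddPCR reads smaller.
    r² is reported as NaN when either axis is constant.
    """
    if cn_ddpcr is None:
        frame = pd.DataFrame(cn_qpcr)
        q = frame["cn_qpcr"].to_numpy(dtype=float)
        d = frame["cn_ddpcr"].to_numpy(dtype=float)
    else:
        q = np.asarray(cn_qpcr, dtype=float)
        d = np.asarray(cn_ddpcr, dtype=float)
    keep = ~(np.isnan(q) | np.isnan(d))
    q, d = q[keep], d[keep]
    if q.size != d.size:
        raise CnvDropError("paired vectors differ in length")
    if q.size < min_pairs:
        raise CnvDropError(f"need at least {min_pairs} pairs, got {q.size}")

    if np.ptp(q) == 0.0 or np.ptp(d) == 0.0:
        r2 = math.nan
    else:
        r2 = float(np.corrcoef(q, d)[0, 1] ** 2)

    diff = d - q
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return ConcordanceResult(
        n=int(q.size),
        r_squared=r2,
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - Z_95 * sd,
        loa_high=mean + Z_95 * sd,
    )
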