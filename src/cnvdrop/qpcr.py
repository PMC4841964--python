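"""Relative copy-number quantification from qPCR Ct replicates (ΔΔCT).

A sample's target-vs-reference cycle-threshold difference is compared to
that of a calibrator individual of known (diploid) copy number:

    ΔCt      = mean(Ct_target) - mean(Ct_reference)      per individual
    ΔΔCt     = ΔCt_sample - ΔCt_calibrator
    CN       = calibrator_cn * 2^(-ΔΔCt)

assuming perfect doubling per cycle.  The estimate is a composite of four
reactions (target and reference for both individuals), each run in
replicate, so the interval combines all four replicate standard errors in
quadrature on the ΔΔCt scale before exponentiation.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from .ddpcr import Z_95, CopyNumberCall
from .errors import CnvDropError, MissingDataError

#: Replicate-SD QC threshold, in cycles.
DEFAULT_REPLICATE_SD_THRESHOLD = 0.5

#: Perfect amplification efficiency (doubling per cycle) assumed by ΔΔCT.
EFFICIENCY = 2.0


@dataclass(frozen=True)
class CtReplicateSet:
    """Replicate Ct values for one sample/assay/dye combination.

    ``dye`` is ``"FAM"`` for the target CNV assay and ``"VIC"`` for the
    reference (housekeeper) assay; reactions are run in quadruplicate.
    """

    sample_id: str
    assay_id: str
    dye: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise CnvDropError("empty Ct replicate set")
        for ct in self.ct_values:
            if not 0.0 < ct < 45.0:
                raise CnvDropError(f"Ct value {ct} outside (0, 45)")

    @property
    def mean(self) -> float:
        return statistics.fmean(self.ct_values)

    @property
    def sd(self) -> float:
        if len(self.ct_values) < 2:
            return float("nan")
        return statistics.stdev(self.ct_values)

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(len(self.ct_values))

    def is_noisy(self, threshold: float = DEFAULT_REPLICATE_SD_THRESHOLD) -> bool:
        return len(self.ct_values) >= 2 and self.sd > threshold


def delta_delta_ct(
    sample: tuple[CtReplicateSet, CtReplicateSet],
    calibrator: tuple[CtReplicateSet, CtReplicateSet],
    calibrator_cn: int = 2,
    replicate_sd_threshold: float = DEFAULT_REPLICATE_SD_THRESHOLD,
) -> CopyNumberCall:
    """ΔΔCT copy-number estimate for one sample against a known calibrator.

    Parameters
    ----------
    sample, calibrator
        ``(target, reference)`` pairs of replicate sets — FAM then VIC.
    calibrator_cn
        Known copies per diploid genome of the calibrator individual.

    Returns
    -------
    CopyNumberCall
        With ``method="qPCR"``.  The 95 % interval combines the replicate
        standard errors of all four reactions in quadrature on the ΔΔCt
        scale.  Sets ``noisy_replicates`` when any replicate SD exceeds the
        threshold and ``no_ci`` when any set has fewer than two replicates.
    """
    s_t, s_r = sample
    c_t, c_r = calibrator
    for rs, want in ((s_t, "FAM"), (s_r, "VIC"), (c_t, "FAM"), (c_r, "VIC")):
        if rs is None:
            raise MissingDataError(f"missing {want} replicate set")

    dct_sample = s_t.mean - s_r.mean
    dct_cal = c_t.mean - c_r.mean
    ddct = dct_sample - dct_cal
    cn = calibrator_cn * EFFICIENCY ** (-ddct)

    flags = set()
    sets = (s_t, s_r, c_t, c_r)
    if any(rs.is_noisy(replicate_sd_threshold) for rs in sets):
        flags.add("noisy_replicates")

    if any(len(rs.ct_values) < 2 for rs in sets):
        flags.add("no_ci")
        ci_low = ci_high = cn
    else:
        se_ddct = math.sqrt(sum(rs.sem**2 for rs in sets))
        half = Z_95 * se_ddct * math.log(EFFICIENCY)  # to the ln scale
        ci_low, ci_high = cn * math.exp(-half), cn * math.exp(half)

    return CopyNumberCall(
        sample_id=s_t.sample_id,
        locus=_locus_of(s_t.assay_id),
        cn_estimate=cn,
        ci_low=ci_low,
        ci_high=ci_high,
        method="qPCR",
        qc_flags=frozenset(flags),
    )


def _locus_of(assay_id: str) -> str:
    from .ddpcr import ASSAY_LOCUS

    return ASSAY_LOCUS.get(assay_id, assay_id)
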