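"""Absolute copy-number quantification from droplet digital PCR counts.

In ddPCR the reaction is partitioned across thousands of oil droplets and,
after end-point amplification, each droplet is read as positive or negative
in two fluorescence channels: FAM for the target CNV assay and VIC for the
reference (housekeeper) assay.  Because template molecules distribute over
droplets at random, the mean number of copies per droplet follows the
Poisson occupancy model

    lambda = -ln(n_negative / n_accepted) = -ln(1 - p_hat),

and the copy number per diploid genome is the ratio of the target and
reference occupancies scaled by the reference ploidy,

    CN = 2 * lambda_target / lambda_reference.

The droplet volume cancels in the ratio and is only needed to express
absolute concentrations (copies/uL); it never influences the CN estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import (
    CnvDropError,
    EmptyWellError,
    MissingDataError,
    ReferenceFailureError,
    SaturationError,
)

#: Target assays and the CNV locus each one interrogates.  All three are
#: duplexed with the VIC-labelled C7orf28b housekeeper assay.
ASSAY_LOCUS = {
    "CNV-East": "CNV_14.3",
    "CNV-759": "CNV_16.1",
    "CNV-E": "CNV_16.1",
}

#: Accepted-droplet QC floor.  Wells below it are flagged, never rejected.
DEFAULT_MIN_DROPLETS = 8000

#: Nominal droplet volume in nanolitres, used only for copies/uL reporting.
DEFAULT_DROPLET_VOLUME_NL = 0.91

#: Two merged-assay calls further apart than this (in copies) are flagged.
DEFAULT_DISCORDANCE_THRESHOLD = 1.0

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class DropletWell:
    """One ddPCR well: accepted droplets and per-channel positive counts."""

    sample_id: str
    assay_id: str
    n_accepted: int
    n_pos_target: int
    n_pos_ref: int

    def __post_init__(self) -> None:
        if self.n_accepted < 0:
            raise CnvDropError(f"negative droplet count: {self.n_accepted}")
        for name in ("n_pos_target", "n_pos_ref"):
            n = getattr(self, name)
            if not 0 <= n <= self.n_accepted:
                raise CnvDropError(
                    f"{name}={n} outside [0, n_accepted={self.n_accepted}]"
                )

    @property
    def locus(self) -> str:
        try:
            return ASSAY_LOCUS[self.assay_id]
        except KeyError:
            raise CnvDropError(f"unknown assay id: {self.assay_id!r}") from None


@dataclass(frozen=True)
class CopyNumberCall:
    """A continuous copy-number estimate with its 95 % interval and QC flags."""

    sample_id: str
    locus: str
    cn_estimate: float
    ci_low: float
    ci_high: float
    method: str  # "ddPCR" or "qPCR"
    lambda_target: float | None = None
    lambda_ref: float | None = None
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.cn_estimate <= self.ci_high):
            raise CnvDropError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"estimate {self.cn_estimate}"
            )

    @property
    def sd(self) -> float:
        """Normal-approximation SD implied by the 95 % interval width."""
        return (self.ci_high - self.ci_low) / (2.0 * Z_95)


def poisson_lambda(n_accepted: int, n_positive: int) -> float:
    """Mean template copies per droplet from the fraction of negative droplets.

    Parameters
    ----------
    n_accepted
        Total accepted droplets in the well (> 0).
    n_positive
        Droplets positive in the channel of interest.

    Returns
    -------
    float
        ``lambda = -ln((n_accepted - n_positive) / n_accepted)``.

    Raises
    ------
    EmptyWellError
        If no droplets were accepted.
    SaturationError
        If every droplet is positive (lambda is unbounded).
    """
    if n_accepted <= 0:
        raise EmptyWellError("well has no accepted droplets")
    if not 0 <= n_positive <= n_accepted:
        raise CnvDropError(
            f"n_positive={n_positive} outside [0, {n_accepted}]"
        )
    if n_positive == n_accepted:
        raise SaturationError(
            "all droplets positive: occupancy not estimable"
        )
    return -math.log((n_accepted - n_positive) / n_accepted)


def _var_lambda(n_accepted: int, n_positive: int) -> float:
    # Delta-method variance of the occupancy estimate:
    # lambda = -ln(1-p), var(p) = p(1-p)/N  =>  var(lambda) = p / ((1-p) N).
    p = n_positive / n_accepted
    return p / ((1.0 - p) * n_accepted)


def copy_number_from_well(
    well: DropletWell,
    ploidy_copies: int = 2,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
) -> CopyNumberCall:
    """Copies per diploid genome for one duplex well.

    The estimate is ``ploidy_copies * lambda_target / lambda_ref``; the 95 %
    interval comes from the delta method applied to ``ln(lambda_t/lambda_r)``,
    so it is asymmetric on the copy-number scale and always positive.

    Raises
    ------
    ReferenceFailureError
        If the reference channel has no positive droplets.
    SaturationError
        If either channel is fully positive.
    EmptyWellError
        If the well has no accepted droplets.
    """
    lam_r = poisson_lambda(well.n_accepted, well.n_pos_ref)
    if lam_r == 0.0:
        raise ReferenceFailureError(
            f"reference channel empty in well for {well.sample_id}"
        )
    lam_t = poisson_lambda(well.n_accepted, well.n_pos_target)

    cn = ploidy_copies * lam_t / lam_r
    flags = set()
    if well.n_accepted < min_droplets:
        flags.add("low_droplets")

    if lam_t == 0.0:
        # No target template at all: the point estimate is an exact zero and
        # the log-ratio interval degenerates; report a one-sided interval from
        # the reference uncertainty alone.
        ci_low, ci_high = 0.0, 0.0
    else:
        var_ln = (
            _var_lambda(well.n_accepted, well.n_pos_target) / lam_t**2
            + _var_lambda(well.n_accepted, well.n_pos_ref) / lam_r**2
        )
        half = Z_95 * math.sqrt(var_ln)
        ci_low, ci_high = cn * math.exp(-half), cn * math.exp(half)

    return CopyNumberCall(
        sample_id=well.sample_id,
        locus=well.locus,
        cn_estimate=cn,
        ci_low=ci_low,
        ci_high=ci_high,
        method="ddPCR",
        lambda_target=lam_t,
        lambda_ref=lam_r,
        qc_flags=frozenset(flags),
    )


def copies_per_microlitre(
    lam: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Absolute template concentration implied by a per-droplet occupancy."""
    return lam / (droplet_volume_nl * 1e-3)


def merge_assay_calls(
    calls: list[CopyNumberCall],
    discordance_threshold: float = DEFAULT_DISCORDANCE_THRESHOLD,
) -> CopyNumberCall:
    """Combine duplicate-assay calls for one sample/locus.

    Calls are averaged with inverse-variance weights (variance from each
    call's interval width); the combined interval uses the pooled variance.
    If any two calls differ by more than ``discordance_threshold`` copies the
    result carries the ``assay_discordant`` flag.
    """
    if not calls:
        raise MissingDataError("merge_assay_calls requires at least one call")
    first = calls[0]
    if any(c.sample_id != first.sample_id or c.locus != first.locus for c in calls):
        raise CnvDropError("cannot merge calls across samples or loci")
    if len(calls) == 1:
        return first

    weights, estimates = [], []
    for c in calls:
        sd = c.sd
        weights.append(1.0 / (sd * sd) if sd > 0 else None)
        estimates.append(c.cn_estimate)
    if any(w is None for w in weights):
        weights = [1.0] * len(calls)  # degenerate CIs: plain mean

    wsum = sum(weights)
    mean = sum(w * e for w, e in zip(weights, estimates)) / wsum
    pooled_sd = math.sqrt(1.0 / wsum) if all(w > 0 for w in weights) else 0.0

    flags = set().union(*(c.qc_flags for c in calls))
    if max(estimates) - min(estimates) > discordance_threshold:
        flags.add("assay_discordant")

    return replace(
        first,
        cn_estimate=mean,
        ci_low=mean - Z_95 * pooled_sd,
        ci_high=mean + Z_95 * pooled_sd,
        lambda_target=None,
        lambda_ref=None,
        qc_flags=frozenset(flags),
    )
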