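"""Allele-level case/control association statistics for 2x2 tables.

All statistics operate on allele counts: rows are case vs control allele
pools, columns are the risk allele (CNV_16.1 allele 5) vs the alternative.
Reported are the odds ratio with a Woolf (log) confidence interval, the
risk ratio — the ratio of risk-allele carriage frequency among case
alleles to that among control alleles — with a Katz log interval, and the
two-tailed Fisher exact probability computed by full hypergeometric
enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .ddpcr import Z_95
from .errors import CnvDropError, MissingDataError

#: Relative tolerance when comparing point probabilities in the two-tailed
#: Fisher sum, to make ties robust to floating-point rounding.
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele counts: a, b = case risk/other allele; c, d = control."""

    a: int
    b: int
    c: int
    d: int
    group_labels: tuple[str, str] = ("case", "control")
    outcome_labels: tuple[str, str] = ("allele5", "allele1")

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise CnvDropError(f"cell {name}={v!r} must be a count >= 0")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


@dataclass(frozen=True)
class RatioEstimate:
    """A ratio statistic with its 95 % confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round(self.estimate, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def _continuity_corrected(t: ContingencyTable2x2) -> tuple[list[float], set[str]]:
    cells = [float(x) for x in t.cells]
    flags: set[str] = set()
    if 0 in t.cells:
        cells = [x + 0.5 for x in cells]  # Haldane–Anscombe
        flags.add("haldane_anscombe")
    return cells, flags


def odds_ratio(t: ContingencyTable2x2) -> RatioEstimate:
    """Odds ratio (a·d)/(b·c) with the Woolf log-scale 95 % interval.

    Tables with a zero cell get the Haldane–Anscombe +0.5 correction on
    every cell and carry the ``haldane_anscombe`` flag.
    """
    (a, b, c, d), flags = _continuity_corrected(t)
    if b * c == 0:
        raise CnvDropError("odds ratio undefined: b*c = 0 after correction")
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RatioEstimate(
        orr,
        orr * math.exp(-Z_95 * se),
        orr * math.exp(Z_95 * se),
        frozenset(flags),
    )


def risk_ratio(t: ContingencyTable2x2) -> RatioEstimate:
    """Risk ratio of risk-allele carriage, case vs control allele pools.

    ``RR = (a/(a+b)) / (c/(c+d))`` with the Katz log-method interval
    ``exp(ln RR ± 1.96·sqrt(b/(a(a+b)) + d/(c(c+d))))``.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise CnvDropError("risk ratio needs non-empty case and control pools")
    if t.c == 0:
        raise CnvDropError("risk ratio undefined: zero baseline risk")
    (a, b, c, d), flags = _continuity_corrected(t)
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(b / (a * (a + b)) + d / (c * (c + d)))
    return RatioEstimate(
        rr,
        rr * math.exp(-Z_95 * se),
        rr * math.exp(Z_95 * se),
        frozenset(flags),
    )


def fisher_exact_two_tailed(t: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact probability by full enumeration.

    Sums the hypergeometric point probabilities of every table sharing the
    observed margins whose probability does not exceed that of the observed
    table (within a relative tolerance of ``1 + 1e-7``).
    """
    a, b, c, d = t.cells
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0
    dist = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    total = float(pmf[pmf <= p_obs * (1.0 + FISHER_REL_TOL)].sum())
    return min(total, 1.0)


@dataclass(frozen=True)
class AssociationResult:
    """Full association read-out for one phenotype's 2x2 allele table."""

    phenotype: str
    control: str
    table: ContingencyTable2x2
    odds: RatioEstimate
    risk: RatioEstimate
    p_value: float


def associate(
    t: ContingencyTable2x2, phenotype: str = "", control: str = ""
) -> AssociationResult:
    """Odds ratio, risk ratio and Fisher p for one table."""
    return AssociationResult(
        phenotype=phenotype,
        control=control,
        table=t,
        odds=odds_ratio(t),
        risk=risk_ratio(t),
        p_value=fisher_exact_two_tailed(t),
    )


def build_tables_from_counts(
    allele_counts,
    control_group: str = "C1",
    risk_allele: int = 5,
    locus: str = "CNV_16.1",
    amyloidosis_uses_c3: bool = True,
    phenotypes: tuple[str, ...] | None = None,
) -> dict[str, ContingencyTable2x2]:
    """One case/control allele table per phenotype from a count tabulation.

    ``allele_counts`` is a DataFrame with ``(phenotype, status)`` columns and
    allele values as rows (the layout produced by
    :func:`cnvdrop.genotype.tabulate_counts` and by the packaged published
    counts).  The control pool is the SPAID-negative column for C1; when
    ``amyloidosis_uses_c3`` the amyloidosis phenotype is instead compared to
    the histopathology-confirmed amyloid-free column (C3), as only those
    controls were assessed for renal amyloid.
    """
    import warnings as _warnings

    al = allele_counts
    if hasattr(al, "allele_counts"):  # a Table1 or CountTables-like object
        al = al.allele_counts
    if isinstance(al, dict):
        al = al[locus]

    other = next(x for x in al.index if x != risk_allele)
    control_cols = {"C1": ("spaid", "-"), "C3": ("amyloidosis", "-")}
    if control_group not in control_cols:
        raise MissingDataError(
            f"control group {control_group!r} not derivable from counts"
        )

    if phenotypes is None:
        phenotypes = tuple(al.columns.get_level_values(0).unique())

    out: dict[str, ContingencyTable2x2] = {}
    for ph in phenotypes:
        control = control_group
        if ph == "amyloidosis" and amyloidosis_uses_c3:
            control = "C3"
        ctrl_col = control_cols[control]
        a = int(al.loc[risk_allele, (ph, "+")])
        b = int(al.loc[other, (ph, "+")])
        c = int(al.loc[risk_allele, ctrl_col])
        d = int(al.loc[other, ctrl_col])
        if a + b == 0:
            _warnings.warn(f"phenotype {ph!r} has no case alleles; omitted")
            continue
        if c + d == 0:
            raise MissingDataError(f"control counts missing for {ph!r}")
        out[ph] = ContingencyTable2x2(
            a, b, c, d,
            group_labels=(f"{ph}+", control),
            outcome_labels=(f"allele{risk_allele}", f"allele{other}"),
        )
    return out
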