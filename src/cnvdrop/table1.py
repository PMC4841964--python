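"""Published case/control genotype and allele counts for the SPAID cohorts.

These are the genotype counts per phenotype (affected ``+`` / unaffected
``-``) for the age-limited SPAID cohort and each sub-phenotype, at both CNV
loci, as reported by the originating study.  The SPAID-negative column
doubles as control group C1 (dogs older than 60 months with no signs of
disease); the amyloidosis-negative column is control group C3
(histopathology-confirmed amyloid-free).

Two consistency checks run at load time and raise on failure:

1. every genotype column sums to the published cohort size;
2. the published allele rows equal the linear map
   ``count(a) = 2 * n(a/a) + n(a/b)`` applied to the genotype rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import CnvDropError
from .genotype import PHENOTYPE_COLUMNS

#: (affected, unaffected) cohort sizes per phenotype column.
COHORT_SIZES = {
    "spaid": (155, 34),
    "fever": (114, 51),
    "arthritis": (79, 46),
    "vesicular": (44, 58),
    "otitis": (34, 71),
    "amyloidosis": (31, 17),
}

# Genotype counts, one row per diploid class; columns are the 12
# (phenotype, +/-) pairs in PHENOTYPE_COLUMNS order.
_GENOTYPE_ROWS = {
    "CNV_14.3": {
        2: [128, 15, 93, 30, 62, 28, 35, 36, 31, 43, 28, 13],
        4: [24, 17, 20, 19, 17, 15, 9, 19, 2, 25, 2, 4],
        6: [3, 2, 1, 2, 0, 3, 0, 3, 1, 3, 1, 0],
    },
    "CNV_16.1": {
        2: [3, 3, 1, 3, 0, 4, 0, 4, 1, 4, 1, 0],
        6: [25, 16, 21, 18, 17, 15, 9, 19, 2, 25, 3, 4],
        10: [127, 15, 92, 30, 62, 27, 35, 35, 31, 42, 27, 13],
    },
}

# Published allele rows, used purely to validate the linear map.
_ALLELE_ROWS = {
    "CNV_14.3": {
        1: [280, 47, 206, 79, 141, 71, 79, 91, 64, 111, 58, 30],
        3: [30, 21, 22, 23, 17, 21, 9, 25, 4, 31, 4, 4],
    },
    "CNV_16.1": {
        1: [31, 22, 23, 24, 17, 23, 9, 27, 4, 33, 5, 4],
        5: [279, 46, 205, 78, 141, 69, 79, 89, 64, 109, 57, 30],
    },
}

#: Per-chromosome allele values at each locus (diploid classes are the sums).
LOCUS_ALLELES = {"CNV_14.3": (1, 3), "CNV_16.1": (1, 5)}


@dataclass(frozen=True)
class Table1:
    """Validated published counts, as DataFrames per locus.

    Column index is ``(phenotype, status)`` with status ``+``/``-``; rows of
    ``genotype_counts[locus]`` are diploid classes, rows of
    ``allele_counts[locus]`` are per-chromosome allele values.
    """

    genotype_counts: dict[str, pd.DataFrame]
    allele_counts: dict[str, pd.DataFrame]

    def contingency(
        self, phenotype: str, risk_allele: int, locus: str = "CNV_16.1",
        control: str = "C1",
    ) -> tuple[int, int, int, int]:
        """(a, b, c, d) allele counts: case/control x risk/other allele."""
        al = self.allele_counts[locus]
        other = next(x for x in al.index if x != risk_allele)
        control_col = {"C1": ("spaid", "-"), "C3": ("amyloidosis", "-")}[control]
        a = int(al.loc[risk_allele, (phenotype, "+")])
        b = int(al.loc[other, (phenotype, "+")])
        c = int(al.loc[risk_allele, control_col])
        d = int(al.loc[other, control_col])
        return a, b, c, d


def load_table1() -> Table1:
    """Build and validate the published count tables.

    Raises
    ------
    CnvDropError
        If a genotype column does not sum to the published cohort size, or
        the published allele rows disagree with ``2*hom + het``.
    """
    cols = pd.MultiIndex.from_product(
        [PHENOTYPE_COLUMNS, ["+", "-"]], names=["phenotype", "status"]
    )
    genotype_counts, allele_counts = {}, {}
    for locus, rows in _GENOTYPE_ROWS.items():
        gt = pd.DataFrame.from_dict(rows, orient="index")
        gt.columns = cols
        gt = gt.sort_index()

        for ph, (n_pos, n_neg) in COHORT_SIZES.items():
            for status, expected in (("+", n_pos), ("-", n_neg)):
                got = int(gt[(ph, status)].sum())
                if got != expected:
                    raise CnvDropError(
                        f"{locus} {ph}{status}: genotype column sums to "
                        f"{got}, published cohort size is {expected}"
                    )

        lo, hi = LOCUS_ALLELES[locus]
        derived = pd.DataFrame(
            {
                "low": 2 * gt.loc[2 * lo] + gt.loc[lo + hi],
                "high": gt.loc[lo + hi] + 2 * gt.loc[2 * hi],
            }
        ).T
        derived.index = [lo, hi]
        published = pd.DataFrame.from_dict(
            _ALLELE_ROWS[locus], orient="index"
        ).sort_index()
        published.columns = cols
        if not (derived.sort_index().to_numpy() == published.to_numpy()).all():
            raise CnvDropError(
                f"{locus}: published allele rows disagree with 2*hom + het"
            )
        genotype_counts[locus] = gt
        allele_counts[locus] = published
    return Table1(genotype_counts, allele_counts)
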