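"""Discrete CNV genotype calling from continuous copy-number estimates.

Both Shar-Pei duplications behave as stable bi-allelic CNVs: each
chromosome carries a fixed number of tandem copies (CNV_14.3: 1 or 3;
CNV_16.1: 1 or 5), so diploid totals cluster at the pairwise sums
({2, 4, 6} and {2, 6, 10} respectively).  A continuous estimate is
resolved to the nearest diploid class and decomposed into an unordered
allele pair; cluster structure can also be re-discovered from a cohort of
calls without assuming the allele values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .ddpcr import CopyNumberCall
from .errors import CnvDropError, MissingDataError

#: Estimates further than this (copies) from every class centre are no-calls.
DEFAULT_MAX_CALL_DISTANCE = 1.5

#: "ambiguous" flag when runner-up weight / best weight exceeds this ratio.
DEFAULT_AMBIGUITY_RATIO = 0.2

#: Fallback SD (copies) when a call carries a degenerate interval.
_MIN_CALL_SD = 0.25

#: Cluster centres are snapped to integers only within this distance.
CENTRE_ROUNDING_TOLERANCE = 0.35

PHENOTYPE_COLUMNS = (
    "spaid",
    "fever",
    "arthritis",
    "vesicular",
    "otitis",
    "amyloidosis",
)


@dataclass(frozen=True)
class LocusModel:
    """Allele structure of one CNV locus.

    ``allele_copy_values`` are per-chromosome copy counts; the diploid
    genotype classes are all pairwise sums of those values.
    """

    locus: str
    allele_copy_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.allele_copy_values:
            raise CnvDropError("locus model needs at least one allele")
        object.__setattr__(
            self,
            "allele_copy_values",
            tuple(sorted(set(self.allele_copy_values))),
        )

    @property
    def genotype_classes(self) -> tuple[int, ...]:
        sums = {
            a + b
            for a, b in combinations_with_replacement(self.allele_copy_values, 2)
        }
        return tuple(sorted(sums))

    def alleles_for_total(self, total: int) -> tuple[int, int]:
        """Unordered allele pair (descending) summing to a diploid class."""
        for a, b in combinations_with_replacement(self.allele_copy_values, 2):
            if a + b == total:
                return (max(a, b), min(a, b))
        raise CnvDropError(
            f"total {total} not a genotype class of {self.locus}"
        )


#: The two Shar-Pei duplication loci with their published allele values.
BUILTIN_MODELS = {
    "CNV_14.3": LocusModel("CNV_14.3", (1, 3)),
    "CNV_16.1": LocusModel("CNV_16.1", (1, 5)),
}


@dataclass(frozen=True)
class CnvGenotype:
    """A called diploid genotype: total copy number and unordered alleles."""

    sample_id: str
    locus: str
    total_cn: int
    alleles: tuple[int, int]  # descending, e.g. (5, 1) printed "5|1"
    confidence: float = 1.0
    source: CopyNumberCall | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if sum(self.alleles) != self.total_cn:
            raise CnvDropError(
                f"alleles {self.alleles} do not sum to total {self.total_cn}"
            )
        object.__setattr__(
            self, "alleles", tuple(sorted(self.alleles, reverse=True))
        )

    @property
    def allele_string(self) -> str:
        return f"{self.alleles[0]}|{self.alleles[1]}"

    @classmethod
    def from_string(
        cls, sample_id: str, locus: str, text: str, **kw
    ) -> "CnvGenotype":
        a, b = (int(x) for x in text.split("|"))
        return cls(sample_id, locus, a + b, (a, b), **kw)


def call_genotype(
    call: CopyNumberCall,
    model: LocusModel,
    max_distance: float = DEFAULT_MAX_CALL_DISTANCE,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
) -> CnvGenotype | None:
    """Resolve a continuous estimate to the nearest diploid genotype class.

    The confidence is the normalised Gaussian weight of the estimate against
    the class centres, using the call's CI-derived SD.  Returns ``None``
    (no-call) when the estimate is further than ``max_distance`` from every
    class or sits at an exact midpoint between two classes.
    """
    if call.cn_estimate < 0:
        raise CnvDropError("negative copy-number estimate")
    classes = model.genotype_classes
    x = call.cn_estimate
    dists = [abs(x - c) for c in classes]
    order = sorted(range(len(classes)), key=dists.__getitem__)
    best = order[0]
    if dists[best] > max_distance:
        return None
    if len(classes) > 1 and math.isclose(
        dists[best], dists[order[1]], rel_tol=0.0, abs_tol=1e-9
    ):
        return None  # exact midpoint: surface the ambiguity, don't force it

    sd = max(call.sd, _MIN_CALL_SD)
    weights = [math.exp(-0.5 * (d / sd) ** 2) for d in dists]
    total_w = sum(weights)
    confidence = weights[best] / total_w if total_w > 0 else 1.0

    flags = set(call.qc_flags)
    if len(classes) > 1:
        runner = weights[order[1]]
        if weights[best] > 0 and runner / weights[best] > ambiguity_ratio:
            flags.add("ambiguous")

    total = classes[best]
    return CnvGenotype(
        sample_id=call.sample_id,
        locus=call.locus,
        total_cn=total,
        alleles=model.alleles_for_total(total),
        confidence=confidence,
        source=call,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of 1-D class discovery over a cohort of calls."""

    locus: str
    centres: tuple[float, ...]
    k: int
    silhouette: float
    warnings: tuple[str, ...] = ()

    def to_locus_model(self) -> LocusModel:
        """Decompose integer centres into two per-chromosome allele values.

        Three equally spaced centres ``{2a, a+b, 2b}`` decompose uniquely;
        anything else is rejected.
        """
        c = self.centres
        if any(abs(x - round(x)) > 1e-9 for x in c):
            raise CnvDropError("centres not integral; cannot derive alleles")
        ints = tuple(int(round(x)) for x in c)
        if len(ints) == 3 and ints[0] + ints[2] == 2 * ints[1]:
            a, b = ints[0] // 2, ints[2] // 2
            if 2 * a == ints[0] and 2 * b == ints[2]:
                return LocusModel(self.locus, (a, b))
        if len(ints) == 1 and ints[0] % 2 == 0:
            return LocusModel(self.locus, (ints[0] // 2,))
        raise CnvDropError(f"centres {ints} do not fit a bi-allelic model")


def discover_clusters(
    calls: list[CopyNumberCall] | np.ndarray,
    locus: str | None = None,
    k_range: range = range(2, 6),
    min_calls: int = 30,
) -> ClusterResult:
    """Discover discrete copy-number classes from a cohort of estimates.

    One-dimensional k-means over ``k_range``, with k chosen by the maximum
    silhouette score.  Centres within :data:`CENTRE_ROUNDING_TOLERANCE` of
    an integer are snapped to it; otherwise raw centres are reported with a
    warning.  Degenerate (all-identical) input yields a single-class model.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if isinstance(calls, np.ndarray):
        values = np.asarray(calls, dtype=float)
        locus = locus or "unknown"
    else:
        if not calls:
            raise MissingDataError("no calls supplied")
        values = np.array([c.cn_estimate for c in calls], dtype=float)
        locus = locus or calls[0].locus
    if values.size < min_calls:
        raise CnvDropError(
            f"need at least {min_calls} calls to discover clusters, "
            f"got {values.size}"
        )

    if np.ptp(values) == 0.0:
        centre = _snap(float(values[0]))
        return ClusterResult(
            locus, (centre[0],), 1, 1.0,
            ("degenerate input: single class",) + centre[1],
        )

    x = values.reshape(-1, 1)
    best = None
    for k in k_range:
        if k >= values.size:
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(x)
        score = silhouette_score(x, km.labels_)
        if best is None or score > best[0]:
            best = (score, k, np.sort(km.cluster_centers_.ravel()))
    score, k, centres = best

    snapped, warns = [], []
    for c in centres:
        v, w = _snap(float(c))
        snapped.append(v)
        warns.extend(w)
    return ClusterResult(locus, tuple(snapped), k, float(score), tuple(warns))


def _snap(centre: float) -> tuple[float, tuple[str, ...]]:
    nearest = round(centre)
    if abs(centre - nearest) <= CENTRE_ROUNDING_TOLERANCE:
        return float(nearest), ()
    return centre, (f"centre {centre:.3f} not near an integer; kept raw",)


@dataclass
class CountTables:
    """Genotype and allele counts per phenotype, split by case status.

    Both frames have a two-level column index ``(phenotype, status)`` with
    status ``"+"``/``"-"``; rows are genotype classes or allele values.
    """

    locus: str
    genotype_counts: pd.DataFrame
    allele_counts: pd.DataFrame
    unknown_samples: tuple[str, ...] = ()


def tabulate_counts(
    genotypes: list[CnvGenotype],
    phenotypes: pd.DataFrame,
    phenotype_columns: tuple[str, ...] = PHENOTYPE_COLUMNS,
) -> dict[str, CountTables]:
    """Genotype and allele counts per phenotype column, per locus.

    ``phenotypes`` is indexed (or indexable) by ``sample_id`` with one 1/0/NA
    column per phenotype.  Samples with no phenotype row are excluded and
    reported in ``unknown_samples``.  Allele counts obey the linear map
    ``count(a) = 2*n(a/a) + n(a/b)`` by construction.
    """
    pheno = phenotypes
    if "sample_id" in pheno.columns:
        pheno = pheno.set_index("sample_id")

    out: dict[str, CountTables] = {}
    for locus in sorted({g.locus for g in genotypes}):
        locus_gts = [g for g in genotypes if g.locus == locus]
        unknown = sorted(
            {g.sample_id for g in locus_gts} - set(pheno.index.astype(str))
        )
        if unknown:
            warnings.warn(
                f"{locus}: {len(unknown)} sample(s) without phenotype "
                f"excluded: {', '.join(unknown[:5])}"
                + ("..." if len(unknown) > 5 else "")
            )
        kept = [g for g in locus_gts if g.sample_id not in set(unknown)]

        classes = sorted({g.total_cn for g in kept})
        alleles = sorted({a for g in kept for a in g.alleles})
        cols = pd.MultiIndex.from_product(
            [phenotype_columns, ["+", "-"]], names=["phenotype", "status"]
        )
        gt = pd.DataFrame(0, index=classes, columns=cols)
        al = pd.DataFrame(0, index=alleles, columns=cols)
        for g in kept:
            row = pheno.loc[g.sample_id]
            for ph in phenotype_columns:
                val = row.get(ph)
                if pd.isna(val):
                    continue
                status = "+" if int(val) == 1 else "-"
                gt.loc[g.total_cn, (ph, status)] += 1
                for a in g.alleles:
                    al.loc[a, (ph, status)] += 1
        out[locus] = CountTables(locus, gt, al, tuple(unknown))
    return out
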