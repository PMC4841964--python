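"""Mendelian segregation checking and two-locus haplotype consistency.

Once the CNVs are resolved into discrete allele pairs they should behave
as ordinary bi-allelic markers: each offspring receives exactly one allele
from each parent.  The checker verifies that for every fully genotyped
trio, reports half-genotyped trios separately, and flags individuals whose
two-locus genotype pair cannot be assembled from the two canonical
haplotypes (CNV_14.3 allele 1 travelling with CNV_16.1 allele 5, and
allele 3 with allele 1) — such individuals carry a recombinant haplotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import CnvDropError
from .genotype import CnvGenotype

LOCI = ("CNV_14.3", "CNV_16.1")

#: Canonical haplotype phase: CNV_14.3 allele -> CNV_16.1 allele.
DEFAULT_PHASE = {1: 5, 3: 1}


@dataclass
class Individual:
    sample_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str | None = None
    genotypes: dict[str, CnvGenotype] = field(default_factory=dict)

    def alleles(self, locus: str) -> tuple[int, int] | None:
        g = self.genotypes.get(locus)
        return g.alleles if g is not None else None


class Pedigree:
    """A set of individuals with parent links; founders have no parents."""

    def __init__(self, individuals: list[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.sample_id in self.members:
                raise CnvDropError(f"duplicate individual {ind.sample_id}")
            self.members[ind.sample_id] = ind
        self._validate()

    def _validate(self) -> None:
        # parent ids must resolve or be founder markers (None)
        for ind in self.members.values():
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in self.members:
                    raise CnvDropError(
                        f"{ind.sample_id}: parent {pid} not in pedigree"
                    )
        # acyclicity by iterative DFS over parent links
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.members:
            if start in state:
                continue
            stack = [(start, iter(self._parents(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise CnvDropError(f"pedigree cycle through {p}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def _parents(self, sample_id: str) -> list[str]:
        ind = self.members[sample_id]
        return [p for p in (ind.sire_id, ind.dam_id) if p is not None]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.values())


@dataclass(frozen=True)
class MendelianViolation:
    offspring_id: str
    sire_id: str | None
    dam_id: str | None
    locus: str
    offspring_alleles: tuple[int, int]
    sire_alleles: tuple[int, int] | None
    dam_alleles: tuple[int, int] | None
    partial: bool = False  # True when only one parent was genotyped


@dataclass
class MendelReport:
    locus: str
    violations: list[MendelianViolation]
    partial_violations: list[MendelianViolation]
    n_trios_checked: int = 0
    n_half_checked: int = 0
    n_skipped: int = 0


def _trio_consistent(
    off: tuple[int, int], sire: tuple[int, int], dam: tuple[int, int]
) -> bool:
    x, y = off
    return (x in sire and y in dam) or (y in sire and x in dam)


def check_mendelian(ped: Pedigree, locus: str) -> MendelReport:
    """Verify one-allele-from-each-parent transmission at a locus.

    Fully genotyped trios are checked strictly; trios with exactly one
    genotyped parent are checked against that parent only (the offspring
    must share at least one allele with it) and reported separately; trios
    missing the offspring genotype or both parents are skipped and counted.
    """
    report = MendelReport(locus, [], [])
    for ind in ped:
        if ind.sire_id is None and ind.dam_id is None:
            continue
        off = ind.alleles(locus)
        sire = (
            ped.members[ind.sire_id].alleles(locus) if ind.sire_id else None
        )
        dam = ped.members[ind.dam_id].alleles(locus) if ind.dam_id else None
        if off is None or (sire is None and dam is None):
            report.n_skipped += 1
            continue
        if sire is not None and dam is not None:
            report.n_trios_checked += 1
            if not _trio_consistent(off, sire, dam):
                report.violations.append(
                    MendelianViolation(
                        ind.sample_id, ind.sire_id, ind.dam_id, locus,
                        off, sire, dam,
                    )
                )
        else:
            report.n_half_checked += 1
            parent = sire if sire is not None else dam
            if not any(a in parent for a in off):
                report.partial_violations.append(
                    MendelianViolation(
                        ind.sample_id, ind.sire_id, ind.dam_id, locus,
                        off, sire, dam, partial=True,
                    )
                )
    return report


def infer_phase(
    individuals: list[Individual],
) -> dict[int, int]:
    """Infer the dominant two-locus haplotype phase from co-segregation.

    Considers every one-to-one mapping between the CNV_14.3 and CNV_16.1
    allele values seen in the cohort and returns the one under which the
    largest number of doubly genotyped individuals are consistent (both
    genotype pairs decomposable into two phase-respecting haplotypes).
    Falls back to :data:`DEFAULT_PHASE` when nothing is doubly genotyped.
    """
    pairs = [
        (ind.alleles(LOCI[0]), ind.alleles(LOCI[1]))
        for ind in individuals
        if ind.alleles(LOCI[0]) is not None and ind.alleles(LOCI[1]) is not None
    ]
    if not pairs:
        return dict(DEFAULT_PHASE)
    a14 = sorted({a for p, _ in pairs for a in p})
    a16 = sorted({a for _, q in pairs for a in q})
    if len(a14) != 2 or len(a16) != 2:
        return dict(DEFAULT_PHASE)

    candidates = [
        {a14[0]: a16[0], a14[1]: a16[1]},
        {a14[0]: a16[1], a14[1]: a16[0]},
    ]
    best = max(
        candidates,
        key=lambda ph: sum(_pair_consistent(p, q, ph) for p, q in pairs),
    )
    return best


def _pair_consistent(
    p14: tuple[int, int], p16: tuple[int, int], phase: dict[int, int]
) -> bool:
    a, b = p14
    x, y = p16
    return (phase[a] == x and phase[b] == y) or (phase[a] == y and phase[b] == x)


@dataclass
class TwoLocusReport:
    """Frequency table over (total_14.3, total_16.1) pairs + recombinants."""

    phase: dict[int, int]
    pair_counts: Counter
    recombinant_ids: list[str]
    n_counted: int

    def pair_frequencies(self) -> dict[tuple[int, int], float]:
        if self.n_counted == 0:
            return {}
        return {
            pair: n / self.n_counted for pair, n in sorted(self.pair_counts.items())
        }


def detect_two_locus_pairs(
    ped_or_individuals, phase: dict[int, int] | None = None
) -> TwoLocusReport:
    """Tabulate two-locus genotype pairs and flag recombinant carriers.

    An individual is flagged when its pair of genotypes cannot be assembled
    from two haplotypes respecting the canonical phase.  The phase is
    inferred from the dominant co-segregation pattern unless given.
    """
    individuals = list(ped_or_individuals)
    if phase is None:
        phase = infer_phase(individuals)

    counts: Counter = Counter()
    recombinants: list[str] = []
    n = 0
    for ind in individuals:
        p14, p16 = ind.alleles(LOCI[0]), ind.alleles(LOCI[1])
        if p14 is None or p16 is None:
            continue
        n += 1
        counts[(sum(p14), sum(p16))] += 1
        if not _pair_consistent(p14, p16, phase):
            recombinants.append(ind.sample_id)
    return TwoLocusReport(dict(phase), counts, recombinants, n)


def read_ped(path, loci: tuple[str, ...] = LOCI) -> Pedigree:
    """Read a whitespace-separated PED-like file.

    Columns: family, id, sire, dam, sex, then one ``a|b`` genotype string
    per locus in ``loci`` order; ``0`` marks a missing parent or genotype.
    """
    individuals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 5 + len(loci):
                raise CnvDropError(
                    f"{path}:{line_no}: expected {5 + len(loci)} columns, "
                    f"got {len(fields)}"
                )
            _, sid, sire, dam, sex = fields[:5]
            genos = {}
            for locus, text in zip(loci, fields[5 : 5 + len(loci)]):
                if text != "0":
                    genos[locus] = CnvGenotype.from_string(sid, locus, text)
            individuals.append(
                Individual(
                    sample_id=sid,
                    sire_id=None if sire == "0" else sire,
                    dam_id=None if dam == "0" else dam,
                    sex=sex,
                    genotypes=genos,
                )
            )
    return Pedigree(individuals)
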