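"""Synthetic data generator for every stage of the CNV pipeline.

The generator emulates the study design end to end: duplex ddPCR wells in
which restriction-digested template partitions over ~13,000 droplets (with
on average ~6,000 of them containing the VIC-labelled housekeeper
product), qPCR Ct quadruplicates with Gaussian cycle noise, two-locus CNV
haplotypes transmitted through multi-generation pedigrees with rare
recombination, and case/control cohorts in which disease probability
rises with CNV_16.1 allele-5 dosage.

All randomness flows through a single :class:`numpy.random.Generator`
passed explicitly to each operation, so a fixed seed fully determines
every output; nested simulations simply consume the same stream in a
documented order.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ddpcr as dd
from .ddpcr import CopyNumberCall, DropletWell
from .genotype import BUILTIN_MODELS, CnvGenotype, LocusModel, call_genotype
from .pedigree import Individual, Pedigree
from .qpcr import CtReplicateSet, delta_delta_ct

#: Canonical haplotypes as (CNV_14.3 allele, CNV_16.1 allele).
HAP_CANONICAL_HIGH = (1, 5)  # travels with the disease-associated allele
HAP_CANONICAL_LOW = (3, 1)

LOCI = ("CNV_14.3", "CNV_16.1")


@dataclass
class SimulationConfig:
    """Defaults reflect the study conditions the pipeline is built for.

    Droplet counts centre on 13,000 accepted droplets with the diploid
    housekeeper occupying enough of them that ~6,000 are VIC-positive
    (occupancy 0.619 copies/droplet).  Ct noise of 0.15 cycles per
    replicate reproduces the qPCR regime in which estimates smear into a
    continuum while ddPCR stays clustered.  The canonical haplotype
    frequency of 0.8 yields two-locus pair frequencies of roughly
    64/32/4 % under random mating, and the dosage penetrances put the
    population allele-5 odds ratio for disease near 4.
    """

    n_droplets_mean: float = 13_000.0
    n_droplets_sd: float = 800.0
    droplet_volume_nl: float = dd.DEFAULT_DROPLET_VOLUME_NL
    lambda_ref_mean: float = 0.619  # diploid housekeeper copies per droplet
    lambda_ref_cv: float = 0.08  # well-to-well template-load variation
    ct_noise_sd: float = 0.15  # cycles, per replicate
    n_ct_replicates: int = 4
    ct_reference_base: float = 25.0  # housekeeper Ct at 10 ng template
    ct_target_base: float = 26.0  # target Ct at diploid copy number
    qpcr_efficiency: float = 2.0
    locus_models: dict[str, LocusModel] = field(
        default_factory=lambda: dict(BUILTIN_MODELS)
    )
    haplotype_freq: float = 0.80  # canonical (14.3:1, 16.1:5) haplotype
    recombination_rate: float = 0.01  # per meiosis, placeholder value
    #: P(SPAID) by CNV_16.1 allele-5 dosage 0/1/2.
    penetrance: tuple[float, float, float] = (0.18, 0.50, 0.82)
    #: P(sign | SPAID case) for each of the five clinical signs.
    sign_rates: dict[str, float] = field(
        default_factory=lambda: {
            "fever": 0.70,
            "arthritis": 0.50,
            "vesicular": 0.28,
            "otitis": 0.22,
            "amyloidosis": 0.20,
        }
    )

    def __post_init__(self) -> None:
        for name, p in (
            ("haplotype_freq", self.haplotype_freq),
            ("recombination_rate", self.recombination_rate),
            *((f"penetrance[{i}]", p) for i, p in enumerate(self.penetrance)),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


def simulate_well(
    cn_truth: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
    assay_id: str = "CNV-759",
) -> DropletWell:
    """One duplex ddPCR well at a known true copy number.

    The reference occupancy is drawn from the template load (lognormal
    jitter around the configured mean, shared by both channels so it
    cancels in the ratio); positives per channel are binomial with
    ``p = 1 - exp(-lambda)``.
    """
    if cn_truth < 0:
        raise ValueError("cn_truth must be >= 0")
    n = int(max(1, round(rng.normal(cfg.n_droplets_mean, cfg.n_droplets_sd))))
    sigma = math.sqrt(math.log(1.0 + cfg.lambda_ref_cv**2))
    lam_ref = cfg.lambda_ref_mean * rng.lognormal(-0.5 * sigma**2, sigma)
    lam_t = lam_ref * cn_truth / 2.0
    n_pos_ref = int(rng.binomial(n, -math.expm1(-lam_ref)))
    n_pos_target = int(rng.binomial(n, -math.expm1(-lam_t))) if lam_t > 0 else 0
    return DropletWell(
        sample_id=sample_id,
        assay_id=assay_id,
        n_accepted=n,
        n_pos_target=n_pos_target,
        n_pos_ref=n_pos_ref,
    )


def simulate_ct(
    cn_truth: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None,
    sample_id: str = "sim",
    assay_id: str = "CNV-759",
) -> tuple[CtReplicateSet, CtReplicateSet]:
    """Target (FAM) and reference (VIC) Ct quadruplicates for one sample.

    Cycle thresholds follow ``Ct = base - log_E(quantity/diploid)`` with
    i.i.d. Gaussian noise per replicate; ``rng=None`` or a zero noise SD
    yields noise-free values that invert exactly through ΔΔCT.
    """
    if cn_truth <= 0:
        raise ValueError("qPCR simulation needs cn_truth > 0")
    log_e = math.log(cfg.qpcr_efficiency)
    ct_t = cfg.ct_target_base - math.log(cn_truth / 2.0) / log_e
    ct_r = cfg.ct_reference_base
    k = cfg.n_ct_replicates
    if rng is None or cfg.ct_noise_sd == 0.0:
        t_vals = (ct_t,) * k
        r_vals = (ct_r,) * k
    else:
        t_vals = tuple(ct_t + rng.normal(0.0, cfg.ct_noise_sd, size=k))
        r_vals = tuple(ct_r + rng.normal(0.0, cfg.ct_noise_sd, size=k))
    return (
        CtReplicateSet(sample_id, assay_id, "FAM", t_vals),
        CtReplicateSet(sample_id, assay_id, "VIC", r_vals),
    )


# ---------------------------------------------------------------------------
# haplotypes, pedigrees and cohorts
# ---------------------------------------------------------------------------

Haplotype = tuple[int, int]  # (CNV_14.3 allele, CNV_16.1 allele)


def _draw_founder_haplotype(
    cfg: SimulationConfig, rng: np.random.Generator
) -> Haplotype:
    return (
        HAP_CANONICAL_HIGH
        if rng.random() < cfg.haplotype_freq
        else HAP_CANONICAL_LOW
    )


def _transmit(
    parent: tuple[Haplotype, Haplotype],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Haplotype:
    h1, h2 = parent
    first = h1 if rng.random() < 0.5 else h2
    if rng.random() < cfg.recombination_rate:
        other = h2 if first is h1 else h1
        return (first[0], other[1])  # crossover between the two loci
    return first


def _genotypes_from_haps(
    sample_id: str, haps: tuple[Haplotype, Haplotype]
) -> dict[str, CnvGenotype]:
    out = {}
    for i, locus in enumerate(LOCI):
        alleles = (haps[0][i], haps[1][i])
        out[locus] = CnvGenotype(
            sample_id, locus, sum(alleles), alleles, confidence=1.0
        )
    return out


@dataclass
class PedigreeSim:
    pedigree: Pedigree
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]


def simulate_pedigree(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    generations: int = 4,
    n_founder_couples: int = 4,
    mean_offspring: float = 3.0,
) -> PedigreeSim:
    """A multi-generation pedigree with true genotypes at both loci.

    Founders draw haplotypes at the population frequency; each offspring
    receives one (possibly recombined) haplotype per parent.  Each
    generation's offspring are mated to immigrant founders, so the pedigree
    both deepens and keeps realistic allele flow.
    """
    haps: dict[str, tuple[Haplotype, Haplotype]] = {}
    individuals: list[Individual] = []
    counter = 0

    def new_individual(sire, dam, h, sex):
        nonlocal counter
        counter += 1
        sid = f"P{counter:04d}"
        haps[sid] = h
        individuals.append(
            Individual(sid, sire, dam, sex, _genotypes_from_haps(sid, h))
        )
        return sid

    def founder(sex):
        h = (_draw_founder_haplotype(cfg, rng), _draw_founder_haplotype(cfg, rng))
        return new_individual(None, None, h, sex)

    couples = [(founder("M"), founder("F")) for _ in range(n_founder_couples)]
    for _ in range(generations - 1):
        next_couples = []
        for sire, dam in couples:
            n_off = max(1, int(rng.poisson(mean_offspring)))
            for _ in range(n_off):
                h = (
                    _transmit(haps[sire], cfg, rng),
                    _transmit(haps[dam], cfg, rng),
                )
                sex = "M" if rng.random() < 0.5 else "F"
                child = new_individual(sire, dam, h, sex)
                mate = founder("F" if sex == "M" else "M")
                next_couples.append(
                    (child, mate) if sex == "M" else (mate, child)
                )
        couples = next_couples
    return PedigreeSim(Pedigree(individuals), haps)


@dataclass
class CohortSim:
    """A case/control cohort with truth bookkeeping for oracle tests."""

    phenotypes: pd.DataFrame
    genotypes: list[CnvGenotype]  # truth, both loci, all individuals
    realised_or: float  # allele-level OR from the generator's own counts
    realised_table: tuple[int, int, int, int]  # a, b, c, d allele counts

    def truth_by_sample(self) -> dict[tuple[str, str], CnvGenotype]:
        return {(g.sample_id, g.locus): g for g in self.genotypes}


def simulate_cohort(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_cases: int = 155,
    n_controls: int = 34,
    max_draws: int = 500_000,
) -> CohortSim:
    """Sample a cohort with genotype-dependent disease risk.

    Individuals are drawn under random mating until the case and control
    quotas fill; disease status is Bernoulli in the CNV_16.1 allele-5
    dosage penetrance.  Cases draw each clinical sign at its conditional
    rate (at least one sign is guaranteed); controls are sign-free and, as
    in an age-restricted control group, at least 60 months old.  The
    realised allele-level odds ratio is recorded from the generator's own
    counts so downstream recovery can be checked against it.
    """
    rows, genotypes = [], []
    n_case = n_ctrl = 0
    a = b = c = d = 0  # case allele5, case allele1, control allele5, control allele1
    idx = 0
    draws = 0
    sign_names = ("fever", "arthritis", "vesicular", "otitis", "amyloidosis")
    while (n_case < n_cases or n_ctrl < n_controls) and draws < max_draws:
        draws += 1
        haps = (
            _draw_founder_haplotype(cfg, rng),
            _draw_founder_haplotype(cfg, rng),
        )
        dosage = sum(1 for h in haps if h[1] == 5)
        diseased = rng.random() < cfg.penetrance[dosage]
        if diseased and n_case >= n_cases:
            continue
        if not diseased and n_ctrl >= n_controls:
            continue
        idx += 1
        sid = f"D{idx:04d}"
        genotypes.extend(_genotypes_from_haps(sid, haps).values())

        row = {"sample_id": sid, "spaid": int(diseased)}
        if diseased:
            n_case += 1
            a += dosage
            b += 2 - dosage
            signs = {s: int(rng.random() < cfg.sign_rates[s]) for s in sign_names}
            if not any(signs.values()):
                signs["fever"] = 1  # a case must show at least one sign
            row.update(signs)
            row["age_months"] = int(rng.integers(12, 150))
            row["amyloid_histopath"] = signs["amyloidosis"]
        else:
            n_ctrl += 1
            c += dosage
            d += 2 - dosage
            row.update({s: 0 for s in sign_names})
            row["age_months"] = int(rng.integers(60, 150))
            # only some controls get post-mortem histopathology (C3-like)
            row["amyloid_histopath"] = 0
        rows.append(row)
    if n_case < n_cases or n_ctrl < n_controls:
        raise RuntimeError("cohort quotas not met within max_draws")

    realised_or = (
        (a * d) / (b * c) if b * c > 0 else math.inf
    )
    return CohortSim(
        phenotypes=pd.DataFrame(rows),
        genotypes=genotypes,
        realised_or=realised_or,
        realised_table=(a, b, c, d),
    )


# ---------------------------------------------------------------------------
# measurement of simulated individuals (composition helpers)
# ---------------------------------------------------------------------------

#: Which assays interrogate each locus in the simulated study design.
LOCUS_ASSAYS = {"CNV_14.3": ("CNV-East",), "CNV_16.1": ("CNV-759", "CNV-E")}


def measure_cohort_ddpcr(
    truth: list[CnvGenotype],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[CopyNumberCall]:
    """Simulate wells for every individual/locus and quantify them.

    CNV_16.1 is measured by both of its assays and the duplicate calls are
    merged, mirroring the duplicate-assay design.
    """
    calls = []
    for g in truth:
        per_assay = []
        for assay in LOCUS_ASSAYS[g.locus]:
            well = simulate_well(
                g.total_cn, cfg, rng, sample_id=g.sample_id, assay_id=assay
            )
            per_assay.append(dd.copy_number_from_well(well))
        calls.append(dd.merge_assay_calls(per_assay))
    return calls


def measure_cohort_qpcr(
    truth: list[CnvGenotype],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    calibrator_cn: int = 2,
) -> list[CopyNumberCall]:
    """Simulate Ct quadruplicates per individual and quantify via ΔΔCT.

    A fresh calibrator measurement (a diploid reference individual) is
    drawn per assay batch, so calibrator noise propagates to every sample
    in the batch as it does in practice.
    """
    calls = []
    by_locus: dict[str, tuple] = {}
    for g in truth:
        assay = LOCUS_ASSAYS[g.locus][0]
        if g.locus not in by_locus:
            by_locus[g.locus] = simulate_ct(
                calibrator_cn, cfg, rng, sample_id="calibrator", assay_id=assay
            )
        sample = simulate_ct(
            g.total_cn, cfg, rng, sample_id=g.sample_id, assay_id=assay
        )
        calls.append(
            delta_delta_ct(sample, by_locus[g.locus], calibrator_cn=calibrator_cn)
        )
    return calls


def genotype_calls(
    calls: list[CopyNumberCall],
    models: dict[str, LocusModel] | None = None,
) -> list[CnvGenotype | None]:
    """Apply the genotype caller to a list of calls with per-locus models."""
    models = models or BUILTIN_MODELS
    return [call_genotype(c, models[c.locus]) for c in calls]


def genotype_accuracy(
    truth: list[CnvGenotype], called: list[CnvGenotype | None]
) -> float:
    """Fraction of truth genotypes recovered exactly (no-calls count wrong)."""
    if len(truth) != len(called):
        raise ValueError("truth and called lists differ in length")
    hits = sum(
        1
        for t, g in zip(truth, called)
        if g is not None and g.total_cn == t.total_cn and g.alleles == t.alleles
    )
    return hits / len(truth)


def pair_frequency_counter(genotypes: list[CnvGenotype]) -> Counter:
    """Two-locus (total_14.3, total_16.1) pair counts from a genotype list."""
    by_sample: dict[str, dict[str, int]] = {}
    for g in genotypes:
        by_sample.setdefault(g.sample_id, {})[g.locus] = g.total_cn
    counts: Counter = Counter()
    for loci in by_sample.values():
        if set(LOCI) <= set(loci):
            counts[(loci[LOCI[0]], loci[LOCI[1]])] += 1
    return counts
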