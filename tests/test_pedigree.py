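"""Mendelian transmission checks and two-locus recombinant detection."""

import numpy as np
import pytest

from cnvdrop.errors import CnvDropError
from cnvdrop.genotype import CnvGenotype
from cnvdrop.pedigree import (
    DEFAULT_PHASE,
    Individual,
    Pedigree,
    check_mendelian,
    detect_two_locus_pairs,
    infer_phase,
    read_ped,
)
from cnvdrop.simulate import SimulationConfig, simulate_pedigree


def _ind(sid, sire=None, dam=None, g143=None, g161=None):
    genos = {}
    if g143:
        genos["CNV_14.3"] = CnvGenotype.from_string(sid, "CNV_14.3", g143)
    if g161:
        genos["CNV_16.1"] = CnvGenotype.from_string(sid, "CNV_16.1", g161)
    return Individual(sid, sire, dam, None, genos)


def _trio(sire_g, dam_g, off_g, locus="CNV_16.1"):
    key = "g161" if locus == "CNV_16.1" else "g143"
    ped = Pedigree(
        [
            _ind("sire", **{key: sire_g}),
            _ind("dam", **{key: dam_g}),
            _ind("kid", "sire", "dam", **{key: off_g}),
        ]
    )
    return check_mendelian(ped, locus)


class TestCheckMendelian:
    def test_consistent_trio(self):
        rep = _trio("3|1", "3|1", "3|3", locus="CNV_14.3")
        assert rep.n_trios_checked == 1 and not rep.violations

    def test_allele_absent_from_both_parents(self):
        rep = _trio("5|5", "5|5", "5|1")
        assert len(rep.violations) == 1
        v = rep.violations[0]
        assert v.offspring_id == "kid" and v.offspring_alleles == (5, 1)

    def test_homozygous_offspring_needs_allele_in_each_parent(self):
        rep = _trio("5|1", "5|5", "1|1")  # dam cannot donate a 1
        assert len(rep.violations) == 1

    def test_half_genotyped_checked_against_available_parent(self):
        ped = Pedigree(
            [
                _ind("sire", g161="5|5"),
                _ind("dam"),  # ungenotyped
                _ind("kid", "sire", "dam", g161="1|1"),
            ]
        )
        rep = check_mendelian(ped, "CNV_16.1")
        assert rep.n_half_checked == 1
        assert len(rep.partial_violations) == 1
        assert not rep.violations

    def test_missing_offspring_genotype_skipped(self):
        ped = Pedigree(
            [
                _ind("sire", g161="5|5"),
                _ind("dam", g161="5|1"),
                _ind("kid", "sire", "dam"),
            ]
        )
        rep = check_mendelian(ped, "CNV_16.1")
        assert rep.n_skipped == 1 and rep.n_trios_checked == 0

    def test_generation_one_cross_all_offspring_consistent(self):
        # a (14.3: 1|3, 16.1: 5|1) male crossed to a genotyped mate: every
        # offspring pair drawn one-from-each-parent must verify
        sire = _ind("sire", g143="1|3", g161="5|1")
        dam = _ind("dam", g143="1|1", g161="5|5")
        kids = [
            _ind("k1", "sire", "dam", g143="1|1", g161="5|5"),
            _ind("k2", "sire", "dam", g143="3|1", g161="5|1"),
            _ind("k3", "sire", "dam", g143="1|1", g161="5|1"),
            _ind("k4", "sire", "dam", g143="3|1", g161="5|5"),
        ]
        ped = Pedigree([sire, dam, *kids])
        for locus in ("CNV_14.3", "CNV_16.1"):
            assert not check_mendelian(ped, locus).violations


class TestPedigreeStructure:
    def test_unknown_parent_rejected(self):
        with pytest.raises(CnvDropError):
            Pedigree([_ind("kid", "nobody", None)])

    def test_cycle_rejected(self):
        a = _ind("a", "b", None)
        b = _ind("b", "a", None)
        with pytest.raises(CnvDropError):
            Pedigree([a, b])

    def test_duplicate_id_rejected(self):
        with pytest.raises(CnvDropError):
            Pedigree([_ind("a"), _ind("a")])


class TestTwoLocusPairs:
    def test_zero_recombination_only_canonical_pairs(self, rng):
        cfg = SimulationConfig(recombination_rate=0.0)
        sim = simulate_pedigree(cfg, rng, generations=4, n_founder_couples=5)
        report = detect_two_locus_pairs(sim.pedigree)
        assert set(report.pair_counts) <= {(2, 10), (4, 6), (6, 2)}
        assert report.recombinant_ids == []

    def test_non_canonical_pair_flagged(self):
        inds = [
            _ind("r1", g143="3|1", g161="1|1"),  # the (4, 2) carrier
            *[_ind(f"c{i}", g143="1|1", g161="5|5") for i in range(8)],
            *[_ind(f"h{i}", g143="3|1", g161="5|1") for i in range(4)],
        ]
        report = detect_two_locus_pairs(inds)
        assert report.phase == DEFAULT_PHASE
        assert report.recombinant_ids == ["r1"]
        assert report.pair_counts[(4, 2)] == 1

    def test_canonical_pair_not_flagged(self):
        inds = [_ind(f"c{i}", g143="1|1", g161="5|5") for i in range(40)]
        report = detect_two_locus_pairs(inds)
        assert report.recombinant_ids == []
        assert report.pair_counts == {(2, 10): 40}

    def test_recombination_produces_rare_flagged_pairs(self, rng):
        cfg = SimulationConfig(recombination_rate=0.05)
        flagged = 0
        for seed in range(6):
            sim = simulate_pedigree(
                cfg, np.random.default_rng(seed), generations=5,
                n_founder_couples=6,
            )
            flagged += len(detect_two_locus_pairs(sim.pedigree).recombinant_ids)
        assert flagged > 0

    def test_phase_inference_prefers_dominant_pattern(self):
        # flip the phase: allele 1 travelling with allele 1 everywhere
        inds = [_ind(f"x{i}", g143="1|1", g161="1|1") for i in range(10)]
        inds += [_ind(f"y{i}", g143="3|3", g161="5|5") for i in range(10)]
        assert infer_phase(inds) == {1: 1, 3: 5}


class TestInjectedCorruption:
    def test_incompatible_genotype_detected(self, rng):
        """Corrupting one offspring to an allele absent from both parents
        must surface as exactly one violation."""
        cfg = SimulationConfig(recombination_rate=0.0, haplotype_freq=1.0)
        sim = simulate_pedigree(cfg, rng, generations=3, n_founder_couples=3)
        # all genotypes are 5|5 at CNV_16.1; corrupt one childless
        # non-founder (last generation) to 1|1
        target = [ind for ind in sim.pedigree if ind.sire_id and ind.dam_id][-1]
        target.genotypes["CNV_16.1"] = CnvGenotype(
            target.sample_id, "CNV_16.1", 2, (1, 1)
        )
        rep = check_mendelian(sim.pedigree, "CNV_16.1")
        assert [v.offspring_id for v in rep.violations] == [target.sample_id]


def test_read_ped_round_trip(tmp_path):
    text = (
        "# family id sire dam sex CNV_14.3 CNV_16.1\n"
        "F1 sire 0 0 1 1|3 5|1\n"
        "F1 dam 0 0 2 1|1 5|5\n"
        "F1 kid sire dam 1 3|1 5|5\n"
        "F1 nogeno sire dam 2 0 0\n"
    )
    path = tmp_path / "fam.ped"
    path.write_text(text)
    ped = read_ped(path)
    assert len(ped) == 4
    assert ped.members["kid"].alleles("CNV_14.3") == (3, 1)
    assert ped.members["nogeno"].genotypes == {}
    assert not check_mendelian(ped, "CNV_16.1").violations
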