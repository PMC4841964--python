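"""Discrete genotype calling, class discovery and count tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvdrop.ddpcr import CopyNumberCall
from cnvdrop.errors import CnvDropError
from cnvdrop.genotype import (
    BUILTIN_MODELS,
    CnvGenotype,
    LocusModel,
    call_genotype,
    discover_clusters,
    tabulate_counts,
)

M143 = BUILTIN_MODELS["CNV_14.3"]
M161 = BUILTIN_MODELS["CNV_16.1"]


def _call(est, locus="CNV_16.1", sd=0.15):
    half = 1.959963984540054 * sd
    return CopyNumberCall("s", locus, est, est - half, est + half, "ddPCR")


class TestLocusModel:
    def test_genotype_classes_are_pairwise_sums(self):
        assert M143.genotype_classes == (2, 4, 6)
        assert M161.genotype_classes == (2, 6, 10)

    def test_allele_decomposition(self):
        assert M161.alleles_for_total(6) == (5, 1)
        assert M161.alleles_for_total(10) == (5, 5)
        assert M143.alleles_for_total(2) == (1, 1)
        with pytest.raises(CnvDropError):
            M161.alleles_for_total(4)


class TestCallGenotype:
    def test_near_heterozygote_calls_five_one(self):
        g = call_genotype(_call(5.9), M161)
        assert (g.total_cn, g.alleles, g.allele_string) == (6, (5, 1), "5|1")

    def test_exact_class_centre(self):
        g = call_genotype(_call(2.0, locus="CNV_14.3"), M143)
        assert g.total_cn == 2 and g.alleles == (1, 1)
        assert g.confidence > 0.99

    def test_no_call_when_far_from_every_class(self):
        # 4.05 on {2, 6, 10}: distances 2.05 and 1.95 both exceed 1.5
        assert call_genotype(_call(4.05), M161) is None

    def test_midpoint_tie_is_no_call(self):
        assert call_genotype(_call(4.0), M161) is None
        assert call_genotype(_call(3.0, locus="CNV_14.3"), M143) is None

    @given(
        centre=st.sampled_from([2, 6, 10]),
        delta=st.floats(min_value=-1.99, max_value=1.99),
    )
    def test_stable_within_half_minimum_gap(self, centre, delta):
        """Perturbing by < half the minimum inter-class gap never flips the call."""
        est = centre + delta
        if est < 0:
            est = 0.0
        g = call_genotype(_call(est), M161)
        if g is not None:
            assert g.total_cn == centre

    def test_idempotent_on_called_total(self):
        g = call_genotype(_call(6.12), M161)
        g2 = call_genotype(_call(float(g.total_cn)), M161)
        assert g2.total_cn == g.total_cn and g2.alleles == g.alleles

    def test_ambiguous_flag_between_classes(self):
        # wide interval: the runner-up class keeps substantial weight
        wide = CopyNumberCall("s", "CNV_16.1", 4.8, 1.0, 8.6, "qPCR")
        g = call_genotype(wide, M161)
        assert g is not None and "ambiguous" in g.flags

    def test_negative_estimate_rejected(self):
        with pytest.raises(CnvDropError):
            call_genotype(_call(-0.5), M161)


class TestDiscoverClusters:
    def test_recovers_published_classes_from_simulation(self, cfg, rng):
        from cnvdrop.ddpcr import copy_number_from_well
        from cnvdrop.simulate import simulate_well

        # mixture follows the dominant/intermediate/rare pair pattern
        truths = [2] * 10 + [6] * 60 + [10] * 130
        ests = np.array(
            [
                copy_number_from_well(simulate_well(cn, cfg, rng)).cn_estimate
                for cn in truths
            ]
        )
        res = discover_clusters(ests, locus="CNV_16.1")
        assert res.centres == (2.0, 6.0, 10.0)
        assert res.to_locus_model().allele_copy_values == (1, 5)

    def test_degenerate_input_single_class(self):
        res = discover_clusters(np.full(40, 2.0), locus="CNV_14.3")
        assert res.centres == (2.0,)
        assert res.k == 1 and res.warnings

    def test_non_integer_centres_kept_with_warning(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(2.5, 0.05, 40), rng.normal(7.4, 0.05, 40)])
        res = discover_clusters(vals, locus="x")
        assert len(res.warnings) == 2
        assert all(abs(c - round(c)) > 0.35 for c in res.centres)

    def test_too_few_calls_rejected(self):
        with pytest.raises(CnvDropError):
            discover_clusters(np.full(10, 2.0), locus="x")

    def test_qpcr_clustering_quality_lower_than_ddpcr(self, cfg, rng):
        from cnvdrop.ddpcr import copy_number_from_well
        from cnvdrop.qpcr import delta_delta_ct
        from cnvdrop.simulate import simulate_ct, simulate_well

        truths = [2] * 15 + [6] * 45 + [10] * 60
        dd = np.array(
            [
                copy_number_from_well(simulate_well(cn, cfg, rng)).cn_estimate
                for cn in truths
            ]
        )
        qp = np.array(
            [
                delta_delta_ct(
                    simulate_ct(cn, cfg, rng), simulate_ct(2, cfg, rng)
                ).cn_estimate
                for cn in truths
            ]
        )
        res_dd = discover_clusters(dd, locus="CNV_16.1")
        res_qp = discover_clusters(qp, locus="CNV_16.1")
        assert res_qp.silhouette < res_dd.silhouette


class TestTabulateCounts:
    def _genotypes(self):
        spec = [
            ("a", 10, 1), ("b", 10, 1), ("c", 6, 1), ("d", 6, 0),
            ("e", 2, 0), ("f", 10, None),
        ]
        gts, pheno_rows = [], []
        model = M161
        for sid, total, spaid in spec:
            gts.append(
                CnvGenotype(sid, "CNV_16.1", total, model.alleles_for_total(total))
            )
            pheno_rows.append({"sample_id": sid, "spaid": spaid})
        return gts, pd.DataFrame(pheno_rows)

    def test_counts_and_linear_map(self):
        gts, pheno = self._genotypes()
        tables = tabulate_counts(gts, pheno, phenotype_columns=("spaid",))
        t = tables["CNV_16.1"]
        assert t.genotype_counts.loc[10, ("spaid", "+")] == 2
        assert t.genotype_counts.loc[6, ("spaid", "+")] == 1
        assert t.genotype_counts.loc[2, ("spaid", "-")] == 1
        # allele counts obey count(a) = 2*hom + het in every column
        for col in t.allele_counts.columns:
            gt = t.genotype_counts[col]
            assert t.allele_counts.loc[5, col] == 2 * gt.get(10, 0) + gt.get(6, 0)
            assert t.allele_counts.loc[1, col] == 2 * gt.get(2, 0) + gt.get(6, 0)
        # the NA phenotype row contributes nowhere
        assert t.genotype_counts[("spaid", "+")].sum() == 3

    def test_unknown_samples_excluded_and_reported(self):
        gts, pheno = self._genotypes()
        gts.append(CnvGenotype("ghost", "CNV_16.1", 10, (5, 5)))
        with pytest.warns(UserWarning, match="ghost"):
            tables = tabulate_counts(gts, pheno, phenotype_columns=("spaid",))
        assert tables["CNV_16.1"].unknown_samples == ("ghost",)

    def test_empty_cohort_all_zero(self):
        pheno = pd.DataFrame({"sample_id": [], "spaid": []})
        tables = tabulate_counts([], pheno, phenotype_columns=("spaid",))
        assert tables == {}

    def test_simulated_cohort_matches_generator_bookkeeping(self, cfg, rng):
        from cnvdrop.association import build_tables_from_counts
        from cnvdrop.simulate import simulate_cohort

        cohort = simulate_cohort(cfg, rng, n_cases=60, n_controls=25)
        tables = tabulate_counts(cohort.genotypes, cohort.phenotypes)
        t = build_tables_from_counts(
            {l: v.allele_counts for l, v in tables.items()},
            amyloidosis_uses_c3=False,
        )["spaid"]
        assert t.cells == cohort.realised_table


def test_genotype_string_round_trip():
    g = CnvGenotype.from_string("s", "CNV_16.1", "1|5")
    assert g.alleles == (5, 1)  # canonical form sorts descending
    assert g.allele_string == "5|1"
    assert g.total_cn == 6
    with pytest.raises(CnvDropError):
        CnvGenotype("s", "CNV_16.1", 7, (5, 1))
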