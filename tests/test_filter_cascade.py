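"""The five-stage filtering cascade: per-stage predicates and the full funnel."""

import itertools

import numpy as np
import pytest

from famexome.filter_cascade import (
    CascadeConfig,
    MODE_EXOME_WIDE,
    control_keys_from_variants,
    exclude_common,
    exclude_in_controls,
    exclude_sex_chromosomes,
    keep_likely_functional,
    keep_shared_all_cases,
    restrict_to_genes,
    run_cascade,
)
from famexome.synthetic_data import (
    CausalSpec,
    simulate_family_variants,
    simulate_gene_models,
)
from famexome.variant_store import (
    AnnotatedVariant,
    CandidateGeneSet,
    FrequencyPanel,
    GenotypeCall,
    HET,
    HOM_REF,
    MISSING,
    VariantKey,
)

from conftest import small_config


def mkvar(chrom="1", pos=100, ref="A", alt="G", gene="DES", terms=("missense",),
          dts=None, genotypes=None):
    return AnnotatedVariant(
        VariantKey(chrom, pos, ref, alt), gene=gene,
        annotation_terms=frozenset(terms), distance_to_splice=dts,
        genotypes={s: GenotypeCall(g) for s, g in (genotypes or {}).items()})


CASES = ["c1", "c2", "c3"]
CONTROLS = ["k1", "k2", "k3"]
ALL_HET = {s: HET for s in CASES}


def config(**kw):
    kw.setdefault("case_ids", CASES)
    kw.setdefault("control_ids", CONTROLS)
    return CascadeConfig(**kw)


class TestConfigValidation:
    def test_empty_cases_rejected(self):
        with pytest.raises(ValueError):
            CascadeConfig(case_ids=[])

    def test_overlapping_cases_controls_rejected(self):
        with pytest.raises(ValueError):
            CascadeConfig(case_ids=["a"], control_ids=["a"])

    @pytest.mark.parametrize("cutoff", [0.0, -0.1, 1.5])
    def test_bad_freq_cutoff_rejected(self, cutoff):
        with pytest.raises(ValueError):
            CascadeConfig(case_ids=["a"], freq_cutoff=cutoff)


class TestGeneRestriction:
    def test_keeps_candidate_gene_variants_only(self):
        genes = CandidateGeneSet(frozenset({"DES"}))
        des = mkvar(gene="DES")
        other = mkvar(pos=200, gene="OR4F5")
        nogene = mkvar(pos=300, gene="", terms=("intergenic",))
        assert restrict_to_genes([des, other, nogene], genes) == [des]

    def test_count_matches_membership_oracle(self, small_sim):
        _, _, genes, variants, _, _ = small_sim
        survivors = restrict_to_genes(variants, genes)
        assert len(survivors) == sum(1 for v in variants if v.gene and v.gene in genes)


class TestControlAndSexExclusion:
    def test_variant_het_in_one_control_removed(self):
        v = mkvar(genotypes={**ALL_HET, "k1": HET})
        keys = control_keys_from_variants([v], CONTROLS)
        assert exclude_in_controls([v], keys) == []

    def test_empty_control_set_is_identity(self):
        v = mkvar()
        assert exclude_in_controls([v], set()) == [v]

    def test_set_difference_matches_brute_force(self, small_sim):
        sim_config, _, _, variants, _, _ = small_sim
        keys = control_keys_from_variants(variants, sim_config.control_ids)
        survivors = exclude_in_controls(variants, keys)
        assert {v.key for v in survivors} == {v.key for v in variants} - keys

    def test_chrx_removed_autosome_kept(self):
        chrx = mkvar(chrom="X")
        auto = mkvar(chrom="12", pos=200)
        chry = mkvar(chrom="Y", pos=300)
        assert exclude_sex_chromosomes([chrx, auto, chry]) == [auto]


class TestFrequencyExclusion:
    def _panels(self, *freq_maps):
        return [FrequencyPanel(name=f"p{i}", freqs=dict(f))
                for i, f in enumerate(freq_maps)]

    def test_common_in_either_panel_removed(self):
        v = mkvar()
        panels = self._panels({v.key: 0.02}, {})
        assert exclude_common([v], panels, 0.01) == []

    def test_below_cutoff_in_both_panels_retained(self):
        v = mkvar()
        panels = self._panels({v.key: 0.009}, {v.key: 0.009})
        assert exclude_common([v], panels, 0.01) == [v]

    def test_cutoff_boundary_is_inclusive_removal(self):
        v = mkvar()
        assert exclude_common([v], self._panels({v.key: 0.01}), 0.01) == []

    def test_absent_from_all_panels_retained(self):
        v = mkvar()
        assert exclude_common([v], self._panels({}, {}), 0.01) == [v]


class TestFunctionalFilter:
    def test_synonymous_near_splice_retained(self):
        v = mkvar(terms=("coding-synonymous",), dts=3)
        assert keep_likely_functional([v], config()) == [v]

    def test_intronic_near_splice_retained(self):
        """The non-canonical splice-site case: intronic term, 3 bp from the exon."""
        v = mkvar(terms=("intron",), dts=3)
        assert keep_likely_functional([v], config()) == [v]

    def test_deep_intronic_distance_11_removed(self):
        v = mkvar(terms=("intron",), dts=11)
        assert keep_likely_functional([v], config()) == []

    def test_coding_indel_retained_noncoding_indel_removed(self):
        coding = mkvar(ref="A", alt="AT", terms=("coding-indel",))
        utr = mkvar(pos=200, ref="A", alt="AT", terms=("3'utr",))
        assert keep_likely_functional([coding, utr], config()) == [coding]

    @pytest.mark.parametrize("term", ["nonsense", "stop-gain", "stop-lost",
                                      "frameshift", "missense"])
    def test_each_qualifying_term_suffices(self, term):
        v = mkvar(terms=(term,))
        assert keep_likely_functional([v], config()) == [v]


class TestSharedAllCases:
    def test_het_in_all_three_retained(self):
        v = mkvar(genotypes=ALL_HET)
        assert keep_shared_all_cases([v], CASES) == [v]

    def test_missing_in_one_case_removed(self):
        v = mkvar(genotypes={"c1": HET, "c2": HET, "c3": MISSING})
        assert keep_shared_all_cases([v], CASES) == []

    def test_hom_ref_in_one_case_removed(self):
        v = mkvar(genotypes={"c1": HET, "c2": HET, "c3": HOM_REF})
        assert keep_shared_all_cases([v], CASES) == []

    def test_random_matrix_matches_rowwise_conjunction(self, small_sim):
        sim_config, _, _, variants, _, _ = small_sim
        survivors = keep_shared_all_cases(variants, sim_config.case_ids)
        expected = [v for v in variants
                    if all(v.genotype(s).gt in (HET, "hom-alt")
                           for s in sim_config.case_ids)]
        assert [v.key for v in survivors] == [v.key for v in expected]


class TestRunCascade:
    def test_counts_non_increasing_and_causal_recovered(self, small_sim):
        sim_config, _, genes, variants, panels, truth = small_sim
        report = run_cascade(
            variants, config(case_ids=sim_config.case_ids,
                             control_ids=sim_config.control_ids),
            panels=panels, genes=genes)
        totals = [report.stage_counts[l].total for l in report.stage_labels]
        assert totals == sorted(totals, reverse=True)
        causal_key = next(t["key"] for t in truth if t["role"] == "causal")
        assert causal_key in {str(v.key) for v in report.survivors}

    def test_causal_missing_in_one_case_dropped_only_at_stage_v(self):
        """Loss of coverage in one case removes the variant at sharing, not before."""
        sim_config = small_config(seed=21)
        models, genes = simulate_gene_models(sim_config)
        variants, panels, truth = simulate_family_variants(sim_config, models, genes)
        causal_key = VariantKey.parse(next(t["key"] for t in truth if t["role"] == "causal"))
        for v in variants:
            if v.key == causal_key:
                v.genotypes[sim_config.case_ids[0]] = GenotypeCall(MISSING)
        report = run_cascade(
            variants, config(case_ids=sim_config.case_ids,
                             control_ids=sim_config.control_ids),
            panels=panels, genes=genes)
        assert causal_key in {v.key for v in report.per_stage_survivors["iv"]}
        assert causal_key not in {v.key for v in report.survivors}

    def test_zero_variants_gives_zero_counts(self):
        report = run_cascade([], config(), genes=CandidateGeneSet(frozenset({"DES"})))
        assert all(report.stage_counts[l].total == 0 for l in report.stage_labels)

    def test_low_depth_variant_survives_if_genotyped(self):
        """No depth threshold anywhere: 5 supporting reads still pass."""
        v = AnnotatedVariant(
            VariantKey("7", 128498529, "G", "A"), gene="FLNC",
            annotation_terms=frozenset({"nonsense"}),
            genotypes={"c1": GenotypeCall(HET, allele_depth=(8, 8), depth=16),
                       "c2": GenotypeCall(HET, allele_depth=(3, 2), depth=5),
                       "c3": GenotypeCall(HET, allele_depth=(10, 9), depth=19)})
        report = run_cascade([v], config(), genes=CandidateGeneSet(frozenset({"FLNC"})))
        assert report.survivors == [v]

    def test_stage_ii_order_robust(self, small_sim):
        sim_config, _, _, variants, _, _ = small_sim
        keys = control_keys_from_variants(variants, sim_config.control_ids)
        a = exclude_sex_chromosomes(exclude_in_controls(variants, keys))
        b = exclude_in_controls(exclude_sex_chromosomes(variants), keys)
        assert [v.key for v in a] == [v.key for v in b]

    def test_exome_wide_then_restrict_equals_candidate_mode(self, small_sim):
        sim_config, _, genes, variants, panels, _ = small_sim
        cand = run_cascade(
            variants, config(case_ids=sim_config.case_ids,
                             control_ids=sim_config.control_ids),
            panels=panels, genes=genes)
        wide = run_cascade(
            variants, config(case_ids=sim_config.case_ids,
                             control_ids=sim_config.control_ids,
                             mode=MODE_EXOME_WIDE),
            panels=panels)
        restricted = restrict_to_genes(wide.survivors, genes)
        assert {v.key for v in restricted} == {v.key for v in cand.survivors}

    def test_absent_case_sample_rejected_before_filtering(self):
        v = mkvar(genotypes={"c1": HET})
        with pytest.raises(ValueError, match="ghost"):
            run_cascade([v], config(case_ids=["ghost"], control_ids=[]),
                        genes=CandidateGeneSet(frozenset({"DES"})))

    def test_survivors_match_independent_predicate_intersection(self, small_sim):
        """Five independently applied predicates, intersected, equal the cascade."""
        sim_config, _, genes, variants, panels, _ = small_sim
        cases, controls = sim_config.case_ids, sim_config.control_ids
        keys = {v.key for v in variants
                if any(v.genotype(s).carries_alt for s in controls)}

        def survives(v):
            return (any(v.genotype(s).carries_alt for s in cases)
                    and v.gene and v.gene in genes
                    and v.key not in keys
                    and v.key.chrom not in ("X", "Y")
                    and not any((p.frequency(v.key) or 0.0) >= 0.01 for p in panels)
                    and (bool(v.annotation_terms & {"nonsense", "stop-gain", "stop-lost",
                                                    "frameshift", "missense"})
                         or (v.distance_to_splice is not None and v.distance_to_splice <= 10)
                         or (v.key.is_indel and bool(v.annotation_terms & {"coding-indel",
                                                                           "frameshift"})))
                    and all(v.genotype(s).carries_alt for s in cases))

        report = run_cascade(
            variants, config(case_ids=cases, control_ids=controls),
            panels=panels, genes=genes)
        assert {v.key for v in report.survivors} == {v.key for v in variants if survives(v)}
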