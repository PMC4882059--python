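"""Quantized site calling, genotype inference, site classification,
breakpoints, germline concordance and haplotype enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cd177conv import (
    ConversionGenotype,
    HaplotypeInconsistencyError,
    InsufficientSitesError,
    SampleReadProfile,
    SimulationConfig,
    call_genotype,
    call_site,
    classify_site,
    clopper_pearson,
    enumerate_haplotypes,
    germline_concordance,
    infer_breakpoint,
    simulate_cohort_reads,
    simulate_reads,
    simulate_transcripts,
)
from cd177conv.genotyping import adjust_for_error
from cd177conv.locus import EXON7_PSV_IDS
from cd177conv.simulate import ECTOPIC_EXON7, INTACT


def profile_at(levels: dict[str, float], depth: int = 9000,
               sample_id: str = "S0", tissue: str = "neutrophil"):
    counts = {
        sid: (depth - int(round(depth * f)), int(round(depth * f)))
        for sid, f in levels.items()
    }
    return SampleReadProfile(sample_id=sample_id, tissue=tissue, counts=counts)


def oracle_clopper_pearson(k: int, n: int, confidence: float):
    """Independent interval via direct binomial-cdf bisection."""
    alpha = 1 - confidence

    def solve(target, upper_tail):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            tail = (
                1 - sps.binom.cdf(k - 1, n, mid) if upper_tail
                else sps.binom.cdf(k, n, mid)
            )
            if upper_tail:
                if tail < target:
                    lo = mid
                else:
                    hi = mid
            else:
                if tail > target:
                    lo = mid
                else:
                    hi = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(alpha / 2, upper_tail=True)
    high = 1.0 if k == n else solve(alpha / 2, upper_tail=False)
    return low, high


class TestSiteCall:
    def test_pure_variant_reads_call_level_100(self):
        assert call_site(0, 9000, error_rate=0.0).level == 100

    def test_exact_midpoint_calls_level_50(self):
        assert call_site(4500, 4500).level == 50

    def test_deep_three_quarters_calls_level_75(self):
        # the exact binomial CI around 6790/9000 excludes 50 and 100
        call = call_site(2210, 6790, error_rate=0.005)
        lo, hi = oracle_clopper_pearson(6790, 9000, 0.99)
        assert (call.ci_low, call.ci_high) == pytest.approx((lo, hi), abs=1e-9)
        inside = [
            lvl for lvl in (0, 25, 50, 75, 100)
            if lo <= adjust_for_error(lvl / 100, 0.005) <= hi
        ]
        assert inside == [75]
        assert call.level == 75

    def test_ci_contains_point_estimate(self):
        call = call_site(100, 50)
        assert call.ci_low <= call.vaf <= call.ci_high

    def test_low_depth_is_ambiguous(self):
        # at depth 12 the CI spans several quantized levels
        assert call_site(7, 5).level is None

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            call_site(0, 0)

    @settings(max_examples=60)
    @given(n=st.integers(50, 5000), k=st.integers(0, 5000),
           conf=st.sampled_from([0.95, 0.99]))
    def test_interval_matches_enumeration_oracle(self, n, k, conf):
        k = min(k, n)
        lo, hi = clopper_pearson(k, n, conf)
        olo, ohi = oracle_clopper_pearson(k, n, conf)
        assert lo == pytest.approx(olo, abs=1e-7)
        assert hi == pytest.approx(ohi, abs=1e-7)

    @settings(max_examples=60)
    @given(depth=st.integers(100, 20000), k1=st.integers(0, 20000),
           k2=st.integers(0, 20000))
    def test_level_is_monotone_in_variant_count(self, depth, k1, k2):
        k1, k2 = sorted((min(k1, depth), min(k2, depth)))
        l1 = call_site(depth - k1, k1).level
        l2 = call_site(depth - k2, k2).level
        if l1 is not None and l2 is not None:
            assert l1 <= l2


class TestGenotypeCall:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.50, "ref_hom"), (0.75, "ectopic_het"), (1.00, "null")],
    )
    def test_exon7_levels_map_to_classes(self, model, fraction, expected):
        prof = profile_at({sid: fraction for sid in EXON7_PSV_IDS})
        call = call_genotype(prof, model, error_rate=0.0)
        assert call.exon7_class == expected
        assert call.gene_copies[7] == 4 - int(fraction * 4)

    def test_one_dropout_site_tolerated(self, model):
        levels = {sid: 0.75 for sid in EXON7_PSV_IDS[:4]}
        call = call_genotype(profile_at(levels), model, error_rate=0.0)
        assert call.exon7_class == "ectopic_het"

    def test_conflicting_levels_leave_sample_unresolved(self, model):
        levels = {sid: 0.75 for sid in EXON7_PSV_IDS}
        levels[EXON7_PSV_IDS[0]] = 0.50
        call = call_genotype(profile_at(levels), model, error_rate=0.0)
        assert call.exon7_class == "unresolved"
        assert "exon7_psv_discordant" in call.flags

    def test_missing_exon7_sites_rejected(self, model):
        prof = profile_at({"g.7497": 0.5, "g.7492": 0.5})
        with pytest.raises(InsufficientSitesError):
            call_genotype(prof, model)

    def test_per_exon_gene_copies_localize_tract(self, model):
        levels = {sid: 1.0 for sid in EXON7_PSV_IDS}
        levels.update({"g.1991": 0.5, "g.2368": 1.0, "g.2427": 1.0, "g.2431": 1.0})
        call = call_genotype(profile_at(levels), model, error_rate=0.0)
        assert call.gene_copies == {4: 2, 5: 0, 7: 0}

    def test_recovery_on_simulated_cohort(self, model):
        cfg = SimulationConfig(n_samples=1500, conversion_allele_freq=0.3, seed=9)
        _, truth, profiles = simulate_cohort_reads(cfg, model)
        calls = [call_genotype(p, model) for p in profiles]
        wrong = [
            (c.sample_id, c.exon7_class, t)
            for c, t in zip(calls, truth["exon7_class"])
            if c.exon7_class not in ("unresolved", t)
        ]
        assert wrong == []  # never a wrong confident class
        resolved = sum(c.exon7_class == t
                       for c, t in zip(calls, truth["exon7_class"]))
        assert resolved / len(calls) >= 0.999


class TestClassifySite:
    def test_exon2_site_is_snp_regardless_of_levels(self, model):
        site = model.site("g.242")
        assert classify_site(site, [50, 50], cdna_evidence={"G", "A"}) == "SNP"

    def test_exon8_variant_in_cdna_is_snp(self, model):
        site = model.site("g.7968")
        assert classify_site(site, [25, 50], cdna_evidence={"G", "A"}) == "SNP"

    def test_exon5_quarter_levels_absent_from_cdna_is_psv(self, model):
        site = model.site("g.2368")
        assert classify_site(site, [25, 50, 75], cdna_evidence={"G"}) == "PSV"

    def test_half_levels_only_and_no_cdna_variant_is_unknown(self, model):
        site = model.site("g.2368")
        assert classify_site(site, [50, None], cdna_evidence={"G"}) == "unknown"

    def test_catalog_recovered_from_simulated_evidence(self, model):
        """PSV/SNP labels are re-derivable from cohort gDNA levels + hi-subset
        cDNA of conversion carriers, provided the cohort contains carriers
        whose tracts cover each divergent exon."""
        from cd177conv.simulate import TRACT_EXON5_7, GeneAllele

        snp_dosage = {s.site_id: 1 for s in model.snp_sites()}
        cohort = [
            ConversionGenotype(INTACT, ECTOPIC_EXON7, snp_dosage=snp_dosage),
            ConversionGenotype(TRACT_EXON5_7, INTACT, snp_dosage=snp_dosage),
            ConversionGenotype(GeneAllele((4, 5, 6, 7)), INTACT,
                               snp_dosage=snp_dosage),
        ]
        cfg = SimulationConfig(seed=21)
        rng = np.random.default_rng(21)
        profiles = [
            simulate_reads(gt, model, cfg, rng=rng, sample_id=f"S{i}")
            for i, gt in enumerate(cohort)
        ]
        het = cohort[0]
        cdna = {
            sid: {t.bases[sid] for t in simulate_transcripts(het, "hi").transcripts}
            for sid in model.site_ids()
        }
        for site in model.sites:
            levels = [
                call_site(*p.counts[site.site_id], site_id=site.site_id).level
                for p in profiles
            ]
            got = classify_site(site, levels, cdna[site.site_id])
            assert got == site.site_class, site.site_id


class TestBreakpoints:
    def test_deficit_from_exon5_localizes_between_4_and_5(self):
        res = infer_breakpoint({4: 2, 5: 0, 7: 0})
        assert not res.complex_event
        assert [(i.left_exon, i.right_exon) for i in res.intervals] == [(4, 5)]

    def test_deficit_from_exon7_localizes_between_5_and_7(self):
        res = infer_breakpoint({4: 2, 5: 2, 7: 0})
        assert [(i.left_exon, i.right_exon) for i in res.intervals] == [(5, 7)]

    def test_uniform_counts_mean_no_breakpoint(self):
        res = infer_breakpoint({4: 2, 5: 2, 7: 2})
        assert res.intervals == () and not res.complex_event

    def test_heterozygote_deficit_uses_allele_scope(self):
        res = infer_breakpoint({4: 2, 5: 2, 7: 1}, scope="allele")
        assert res.intervals[0].scope == "allele"

    def test_restored_dosage_flags_complex_event(self):
        res = infer_breakpoint({4: 2, 5: 0, 7: 2})
        assert res.complex_event
        assert len(res.intervals) == 2

    def test_single_exon_rejected(self):
        with pytest.raises(ValueError, match="two"):
            infer_breakpoint({7: 0})


class TestGermlineConcordance:
    def test_identical_profiles_are_germline(self):
        neu = profile_at({sid: 0.75 for sid in EXON7_PSV_IDS})
        sal = profile_at({sid: 0.75 for sid in EXON7_PSV_IDS}, tissue="saliva")
        rep = germline_concordance(neu, sal, error_rate=0.0)
        assert rep.germline and rep.n_agree == rep.n_compared == 5

    def test_same_genotype_deep_profiles_concordant(self, model):
        gt = ConversionGenotype(INTACT, ECTOPIC_EXON7)
        cfg = SimulationConfig(seed=13)
        rng = np.random.default_rng(13)
        neu = simulate_reads(gt, model, cfg, rng=rng, tissue="neutrophil")
        sal = simulate_reads(gt, model, cfg, rng=rng, tissue="saliva")
        assert germline_concordance(neu, sal).germline

    def test_different_genotypes_flag_somatic_difference(self):
        neu = profile_at({sid: 0.75 for sid in EXON7_PSV_IDS})
        sal = profile_at({sid: 0.50 for sid in EXON7_PSV_IDS}, tissue="saliva")
        rep = germline_concordance(neu, sal, error_rate=0.0)
        assert not rep.germline
        assert "somatic_difference" in rep.flags

    def test_equal_tissue_labels_rejected(self):
        neu = profile_at({sid: 0.75 for sid in EXON7_PSV_IDS})
        with pytest.raises(ValueError, match="tissue"):
            germline_concordance(neu, neu)


def oracle_enumerate(ref4: int, ref7: int):
    """Raw enumeration over all base assignments to the four slots, filtered
    by the model constraints; independent of the implementation's pruning."""
    configs = set()
    for combo in itertools.product(["C", "G"], ["C", "G"], ["C", "G"], ["C", "G"]):
        for combo7 in itertools.product(["A", "T"], ["A", "T"], ["A", "T"], ["A", "T"]):
            g1, g2, p1, p2 = [
                (combo[i], combo7[i]) for i in range(4)
            ]
            if p1[1] != "T" or p2[1] != "T":
                continue  # pseudogene homozygous for the divergent exon-7 base
            if any(s[0] == "G" and s[1] == "A" for s in (g1, g2)):
                continue  # gene tract covering exon 4 extends through exon 7
            slots = (g1, g2, p1, p2)
            if 25 * sum(s[0] == "C" for s in slots) != ref4:
                continue
            if 25 * sum(s[1] == "A" for s in slots) != ref7:
                continue
            configs.add((tuple(sorted((g1, g2))), tuple(sorted((p1, p2)))))
    return configs


class TestHaplotypeEnumeration:
    def test_double_half_levels_have_unique_configuration(self):
        configs = enumerate_haplotypes(50, 50)
        assert len(configs) == 1
        cfg = configs[0]
        assert cfg.gene == (("C", "A"), ("C", "A"))
        assert cfg.pseudogene == (("G", "T"), ("G", "T"))

    def test_exon7_ref_absent_means_both_gene_slots_converted(self):
        for configs in (enumerate_haplotypes(50, 0), enumerate_haplotypes(100, 0)):
            for c in configs:
                assert all(slot[1] == "T" for slot in c.gene)

    def test_pseudogene_exon4_heterozygosity_explains_75_50(self):
        configs = enumerate_haplotypes(75, 50)
        assert any(
            sorted(s[0] for s in c.pseudogene) == ["C", "G"] for c in configs
        )

    def test_inconsistent_levels_rejected(self):
        with pytest.raises(HaplotypeInconsistencyError):
            enumerate_haplotypes(50, 75)  # 3 reference copies need 3 gene slots

    def test_matches_bruteforce_on_every_level_combination(self):
        levels = (0, 25, 50, 75, 100)
        for ref4 in levels:
            for ref7 in levels:
                expected = oracle_enumerate(ref4, ref7)
                try:
                    got = {
                        (c.gene, c.pseudogene)
                        for c in enumerate_haplotypes(ref4, ref7)
                    }
                except HaplotypeInconsistencyError:
                    got = set()
                assert got == expected, (ref4, ref7)
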