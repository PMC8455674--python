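import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import (
    ConfigurationError,
    GWASSummaryTable,
    HarmonizedInstrumentSet,
    InstrumentSelectionConfig,
    SelectionError,
    LDTable,
    SummaryAssociation,
    flag_overlap,
    generate_two_sample,
    greedy_clump,
    harmonize,
    is_palindromic,
    mean_f_statistic,
    scenario_presets,
    select_instruments,
    substitute_proxies,
)


def rec(rsid, ea="A", oa="G", beta=0.1, se=0.01, p=1e-10, eaf=0.3):
    return SummaryAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=p, eaf=eaf
    )


def table(*recs, trait_type="binary", name="t"):
    t = GWASSummaryTable(trait_name=name, trait_type=trait_type)
    for r in recs:
        t.add(r)
    return t


class TestConfig:
    def test_defaults_match_convention(self):
        cfg = InstrumentSelectionConfig()
        assert (cfg.p_threshold, cfg.clump_r2, cfg.proxy_r2, cfg.palindrome_maf_max) == (
            5e-8, 0.001, 0.8, 0.42,
        )

    def test_proxy_must_exceed_clump(self):
        with pytest.raises(ConfigurationError):
            InstrumentSelectionConfig(clump_r2=0.9, proxy_r2=0.5)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("p_threshold: 5.0e-6\nclump_r2: 0.001\n")
        cfg = InstrumentSelectionConfig.from_yaml(path)
        assert cfg.p_threshold == 5e-6 and cfg.proxy_r2 == 0.8


class TestSelectInstruments:
    @pytest.fixture
    def three_snp_table(self):
        return table(
            rec("rs1", p=1e-9), rec("rs2", p=4e-8), rec("rs3", p=6e-8),
        )

    def test_genome_wide_threshold(self, three_snp_table):
        got = select_instruments(three_snp_table, InstrumentSelectionConfig(p_threshold=5e-8))
        assert got == ["rs1", "rs2"]  # sorted ascending by p

    def test_relaxed_threshold_for_rare_outcomes(self, three_snp_table):
        got = select_instruments(three_snp_table, InstrumentSelectionConfig(p_threshold=5e-6))
        assert got == ["rs1", "rs2", "rs3"]

    def test_no_candidates_names_threshold(self, three_snp_table):
        with pytest.raises(SelectionError, match="5e-10"):
            select_instruments(three_snp_table, InstrumentSelectionConfig(p_threshold=5e-10))


class TestGreedyClump:
    def test_dominance_by_pvalue_order(self):
        ld = LDTable({("rs1", "rs2"): 0.5})
        assert greedy_clump(["rs1", "rs2"], ld, 0.001) == ["rs1"]

    def test_r2_strictly_below_threshold_kept(self):
        ld = LDTable({("rs1", "rs2"): 0.0005})
        assert greedy_clump(["rs1", "rs2"], ld, 0.001) == ["rs1", "rs2"]

    def test_unlinked_all_kept(self):
        rsids = [f"rs{i}" for i in range(7)]
        assert greedy_clump(rsids, LDTable(), 0.001) == rsids

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_dominance_oracle(self, seed):
        """On <=10 SNPs the greedy result equals the lexicographically first
        (in p-value order) maximal independent set, found by brute force."""
        rng = np.random.default_rng(seed)
        n = 8
        rsids = [f"rs{i}" for i in range(n)]
        ld = LDTable()
        for a, b in itertools.combinations(range(n), 2):
            if rng.random() < 0.4:
                ld.set(rsids[a], rsids[b], float(rng.uniform(0.1, 1.0)))
        thr = 0.05

        def independent(subset):
            return all(ld.r2(rsids[a], rsids[b]) < thr
                       for a, b in itertools.combinations(subset, 2))

        # dominance order: the lexicographically first maximal independent set
        all_maximal = []
        for size in range(1, n + 1):
            for s in itertools.combinations(range(n), size):
                if independent(s) and not any(
                    independent(tuple(sorted(s + (e,)))) for e in range(n) if e not in s
                ):
                    all_maximal.append(s)
        oracle = min(all_maximal)
        assert greedy_clump(rsids, ld, thr) == [rsids[i] for i in oracle]

    def test_output_pairwise_independent(self):
        exp, _, ld, _ = generate_two_sample(scenario_presets()["proxy_rich"])
        kept = greedy_clump(sorted(exp.records), ld, 0.001)
        for a, b in itertools.combinations(kept, 2):
            assert ld.r2(a, b) < 0.001


class TestSubstituteProxies:
    def test_threshold_and_tie_breaks(self):
        outcome = table(
            rec("rs10", p=1e-4), rec("rs11", p=1e-6), rec("rs12", p=1e-2),
        )
        ld = LDTable({
            ("rsA", "rs10"): 0.9, ("rsA", "rs11"): 0.9, ("rsA", "rs12"): 0.95,
            ("rsB", "rs10"): 0.6,
        })
        got = substitute_proxies(["rsA", "rsB", "rsC"], outcome, ld, 0.8)
        assert got["rsA"] == "rs12"          # highest r2 wins
        assert got["rsB"] is None            # best available below threshold
        assert got["rsC"] is None            # no LD information at all

    def test_pvalue_tie_break(self):
        outcome = table(rec("rs10", p=1e-4), rec("rs11", p=1e-6))
        ld = LDTable({("rsA", "rs10"): 0.9, ("rsA", "rs11"): 0.9})
        assert substitute_proxies(["rsA"], outcome, ld, 0.8)["rsA"] == "rs11"


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("a", "t", True)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


class TestHarmonize:
    CFG = InstrumentSelectionConfig()

    def test_direct_match_kept(self):
        h = harmonize([rec("rs1", "A", "G", beta=0.1)],
                      table(rec("rs1", "A", "G", beta=0.25)), self.CFG)
        assert h.Gamma_hat[0] == 0.25 and h.audit["rs1"] == "kept"

    def test_swapped_alleles_sign_flip(self):
        h = harmonize([rec("rs1", "A", "G")],
                      table(rec("rs1", "G", "A", beta=0.1, eaf=0.7)), self.CFG)
        assert h.Gamma_hat[0] == -0.1 and h.audit["rs1"] == "allele_flipped"

    def test_strand_complement_recovered(self):
        # exposure A/G vs outcome T/C: same variant on the other strand
        h = harmonize([rec("rs1", "A", "G")],
                      table(rec("rs1", "T", "C", beta=0.3)), self.CFG)
        assert h.Gamma_hat[0] == 0.3 and h.audit["rs1"] == "kept"

    def test_strand_complement_and_swap(self):
        h = harmonize([rec("rs1", "A", "G")],
                      table(rec("rs1", "C", "T", beta=0.3)), self.CFG)
        assert h.Gamma_hat[0] == -0.3

    def test_palindrome_low_maf_concordant(self):
        h = harmonize([rec("rs1", "A", "T", eaf=0.30)],
                      table(rec("rs1", "A", "T", beta=0.2, eaf=0.32)), self.CFG)
        assert h.Gamma_hat[0] == 0.2 and h.audit["rs1"] == "kept"

    def test_palindrome_discordant_frequency_flips(self):
        h = harmonize([rec("rs1", "A", "T", eaf=0.30)],
                      table(rec("rs1", "A", "T", beta=0.2, eaf=0.68)), self.CFG)
        assert h.Gamma_hat[0] == -0.2 and h.audit["rs1"] == "allele_flipped"

    def test_palindrome_high_maf_dropped(self):
        with pytest.raises(Exception):
            harmonize([rec("rs1", "A", "T", eaf=0.45)],
                      table(rec("rs1", "A", "T", eaf=0.44)), self.CFG)
        # with another keepable SNP present, the palindrome is audited as dropped
        h = harmonize(
            [rec("rs1", "A", "T", eaf=0.45), rec("rs2", "A", "G")],
            table(rec("rs1", "A", "T", eaf=0.44), rec("rs2", "A", "G")), self.CFG,
        )
        assert h.audit["rs1"] == "dropped_palindrome" and h.rsids == ["rs2"]

    def test_palindrome_missing_eaf_dropped(self):
        h = harmonize(
            [rec("rs1", "A", "T", eaf=None), rec("rs2", "A", "G")],
            table(rec("rs1", "A", "T", eaf=0.3), rec("rs2", "A", "G")), self.CFG,
        )
        assert h.audit["rs1"] == "dropped_palindrome"

    def test_one_sample_maf_switch(self):
        cfg = InstrumentSelectionConfig(palindrome_maf_both_samples=False)
        h = harmonize([rec("rs1", "A", "T", eaf=0.30)],
                      table(rec("rs1", "A", "T", beta=0.2, eaf=0.45)), cfg)
        assert h.rsids == ["rs1"]  # outcome MAF no longer vetoes

    def test_missing_without_proxy_dropped(self):
        h = harmonize(
            [rec("rs1"), rec("rs2", "T", "C")],
            table(rec("rs2", "T", "C")), self.CFG,
        )
        assert h.audit["rs1"] == "dropped_missing"

    def test_proxy_substituted(self):
        h = harmonize(
            [rec("rs1", "A", "G")],
            table(rec("rs99", "A", "G", beta=0.4)),
            self.CFG, proxy_map={"rs1": "rs99"},
        )
        assert h.Gamma_hat[0] == 0.4
        assert h.audit["rs1"] == "proxy_substituted"
        assert h.proxy_map == {"rs1": "rs99"}

    def test_audit_partition_covers_every_input(self):
        exp, out, ld, _ = generate_two_sample(scenario_presets()["palindrome_mix"])
        instr = list(exp.records.values())
        h = harmonize(instr, out, self.CFG)
        assert set(h.audit) == set(exp.records)
        n_kept = sum(a in ("kept", "allele_flipped", "proxy_substituted")
                     for a in h.audit.values())
        assert n_kept == h.J and len(h.audit) == len(instr)

    def test_orientation_invariance(self):
        """Flipping every outcome record's alleles, beta sign, and EAF leaves
        the harmonized set unchanged."""
        exp, out, ld, _ = generate_two_sample(scenario_presets()["palindrome_mix"])
        instr = list(exp.records.values())
        flipped = GWASSummaryTable(trait_name="t", trait_type="binary")
        for r in out.records.values():
            flipped.add(SummaryAssociation(
                rsid=r.rsid, effect_allele=r.other_allele, other_allele=r.effect_allele,
                beta=-r.beta, se=r.se, pvalue=r.pvalue,
                eaf=None if r.eaf is None else 1.0 - r.eaf,
            ))
        h1 = harmonize(instr, out, self.CFG)
        h2 = harmonize(instr, flipped, self.CFG)
        assert h1.rsids == h2.rsids
        np.testing.assert_allclose(h1.Gamma_hat, h2.Gamma_hat, atol=1e-15)


class TestFlagOverlap:
    def test_identical_and_linked_flagged(self):
        ld = LDTable({("rs2", "rs20"): 0.9, ("rs3", "rs30"): 0.5})
        got = flag_overlap(["rs1", "rs2", "rs3"], ["rs1", "rs20", "rs30"], ld, 0.8)
        assert got == ["rs1", "rs2"]

    def test_disjoint_unlinked_empty(self):
        assert flag_overlap(["rs1"], ["rs2"], LDTable(), 0.8) == []


class TestMeanF:
    def test_single_snp(self):
        s = HarmonizedInstrumentSet(
            rsids=["rs1"], gamma_hat=[0.1], sigma_x=[0.01], Gamma_hat=[0.2], sigma_y=[0.05]
        )
        f, per = mean_f_statistic(s)
        assert f == pytest.approx(100.0) and per[0] == pytest.approx(100.0)

    def test_mean_of_per_snp(self):
        s = HarmonizedInstrumentSet(
            rsids=["rs1", "rs2"],
            gamma_hat=[np.sqrt(50) * 0.01, np.sqrt(150) * 0.01],
            sigma_x=[0.01, 0.01], Gamma_hat=[0.0, 0.0], sigma_y=[0.05, 0.05],
        )
        f, per = mean_f_statistic(s)
        assert f == pytest.approx(100.0)
        assert per.min() <= f <= per.max()


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_mean_f_bounded_by_per_snp_extremes(seed):
    rng = np.random.default_rng(seed)
    J = int(rng.integers(1, 30))
    s = HarmonizedInstrumentSet(
        rsids=[f"rs{i}" for i in range(J)],
        gamma_hat=rng.normal(0.1, 0.05, J),
        sigma_x=rng.uniform(0.001, 0.05, J),
        Gamma_hat=rng.normal(0, 0.1, J),
        sigma_y=rng.uniform(0.005, 0.1, J),
    )
    f, per = mean_f_statistic(s)
    assert per.min() - 1e-12 <= f <= per.max() + 1e-12
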