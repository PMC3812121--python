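"""LD statistics, haplotype clustering, tag SNPs and haplotype association."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import hypergeom

from poolmap import synthetic as syn
from poolmap.haplotypes import (
    TagSet,
    cluster_major_haplotypes,
    conditional_independence_test,
    detect_recombinants,
    estimate_haplotype_frequencies,
    haplotype_fisher_test,
    joint_glm_test,
    ld_stats,
    select_tag_snps,
)
from poolmap.panel import HaplotypePanel


# ------------------------------------------------------------------ oracles
def ld_oracle(n_ab, n_a_b, n_b_a, n_ab_both):
    """LD from expanded gamete lists: r^2 via the sample correlation of the
    allele indicators, D' via the feasibility interval of the joint
    frequency given the margins."""
    a = [1] * n_ab + [1] * n_a_b + [0] * n_b_a + [0] * n_ab_both
    b = [1] * n_ab + [0] * n_a_b + [1] * n_b_a + [0] * n_ab_both
    a, b = np.array(a, float), np.array(b, float)
    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
    p_a, p_b, p_joint = a.mean(), b.mean(), (a * b).mean()
    d = p_joint - p_a * p_b
    lo = max(0.0, p_a + p_b - 1.0) - p_a * p_b
    hi = min(p_a, p_b) - p_a * p_b
    d_max = hi if d >= 0 else -lo
    return d, (abs(d) / d_max if d_max > 0 else 0.0), r2


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher P by summing hypergeometric outcomes no more likely
    than the observed table."""
    n, k, big_n = a + b, a + c, a + b + c + d
    rv = hypergeom(big_n, k, n)
    p_obs = rv.pmf(a)
    xs = np.arange(max(0, k - (big_n - n)), min(k, n) + 1)
    pmf = rv.pmf(xs)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def glm_oracle(df):
    """Direct binomial log-likelihood maximization (grid-started
    Nelder-Mead), independent of the IRLS fit."""
    y = df["status"].to_numpy(float)
    x = df[["dosage_risk", "dosage_prot"]].to_numpy(float)

    def nll(beta):
        eta = beta[0] + x @ beta[1:]
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    best, best_val = None, np.inf
    for b0 in np.linspace(-2, 2, 5):
        for br in np.linspace(-2, 2, 5):
            for bp in np.linspace(-2, 2, 5):
                v = nll([b0, br, bp])
                if v < best_val:
                    best, best_val = [b0, br, bp], v
    res = minimize(nll, best, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000})
    return res.x


# ----------------------------------------------------------------------- LD
class TestLDStats:
    def test_perfect_ld(self):
        res = ld_stats([[5, 0], [0, 5]])
        assert res.D_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_hand_computed_table(self):
        res = ld_stats([[4, 1], [1, 4]])
        assert res.D == pytest.approx(0.15)
        assert res.D_prime == pytest.approx(0.6)
        assert res.r2 == pytest.approx(0.36)

    def test_independence_gives_zero(self):
        res = ld_stats([[4, 4], [4, 4]])
        assert res.D == pytest.approx(0.0)
        assert res.r2 == pytest.approx(0.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_stats([[5, 5], [0, 0]])

    def test_matches_gamete_enumeration_oracle(self):
        """D, D' and r^2 agree with a brute-force computation from expanded
        gamete lists on all 2x2 tables with total <= 50 (both loci
        polymorphic)."""
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(600):
            counts = rng.multinomial(int(rng.integers(4, 51)), [0.25] * 4)
            n_ab, n_a_b, n_b_a, n_bb = (int(v) for v in counts)
            if min(n_ab + n_a_b, n_b_a + n_bb) == 0:
                continue
            if min(n_ab + n_b_a, n_a_b + n_bb) == 0:
                continue
            res = ld_stats([[n_ab, n_a_b], [n_b_a, n_bb]])
            d, dp, r2 = ld_oracle(n_ab, n_a_b, n_b_a, n_bb)
            assert res.D == pytest.approx(d, abs=1e-12)
            assert res.D_prime == pytest.approx(dp, abs=1e-9)
            assert res.r2 == pytest.approx(r2, abs=1e-9)
            # normalization invariants
            assert res.r2 <= res.D_prime + 1e-9
            if 0 in (n_ab, n_a_b, n_b_a, n_bb):
                assert res.D_prime == pytest.approx(1.0)
            checked += 1
        assert checked > 400


# ---------------------------------------------------------------- clustering
def _toy_panel(rows, positions=None):
    arr = np.array(rows, dtype=np.int8)
    n_sites = arr.shape[1]
    return HaplotypePanel(
        haplotypes=arr,
        site_ids=[f"s{j}" for j in range(n_sites)],
        positions=np.array(positions or range(1, n_sites + 1)),
    )


class TestClustering:
    def test_counts_forced_by_construction(self):
        rows = [[1, 0, 0]] * 20 + [[0, 1, 0]] * 12 + [[0, 0, 1]] * 6
        rows += [[1, 1, 0], [1, 0, 1]]  # two unique chromosomes
        groups, coverage = cluster_major_haplotypes(_toy_panel(rows))
        majors = [g for g in groups if g.is_major]
        assert [g.frequency for g in majors] == pytest.approx([0.5, 0.3, 0.15])
        assert coverage == pytest.approx(0.95)
        assert [g.label for g in majors] == ["hap1", "hap2", "hap3"]

    def test_all_identical_collapses_to_one_major(self):
        groups, coverage = cluster_major_haplotypes(_toy_panel([[0, 1]] * 10))
        assert len(groups) == 1
        assert groups[0].frequency == 1.0
        assert coverage == 1.0

    def test_boundary_group_retained_as_major(self):
        rows = [[1, 0]] * 19 + [[0, 1]] * 1  # 5% exactly
        groups, _ = cluster_major_haplotypes(_toy_panel(rows))
        assert all(g.is_major for g in groups)

    def test_synthetic_panel_majors_cover_77_percent(self, default_panel, major_groups):
        majors, coverage = major_groups
        assert len(majors) == 4
        assert coverage == pytest.approx(0.77, abs=1 / 186)


class TestTagSelection:
    def test_private_allele_is_perfect_tag(self):
        rows = [[1, 0]] * 4 + [[0, 0]] * 16
        panel = _toy_panel(rows)
        groups, _ = cluster_major_haplotypes(panel, freq_cutoff=0.05)
        target = next(g for g in groups if g.frequency == pytest.approx(0.2))
        tags = select_tag_snps(panel, target)
        assert "s0" in tags.snp_ids
        assert tags.r2_values[tags.snp_ids.index("s0")] == pytest.approx(1.0)

    def test_leaky_tag_below_cutoff_rejected(self):
        # allele on all 4 group chromosomes plus 1 of the 16 others: r^2 = 0.75
        rows = [[1, 1]] * 4 + [[1, 0]] * 1 + [[0, 0]] * 15
        panel = _toy_panel(rows)
        groups, _ = cluster_major_haplotypes(panel, freq_cutoff=0.05)
        target = next(
            g for g in groups if g.vector == (1, 1) and len(g.chromosome_indices) == 4
        )
        tags = select_tag_snps(panel, target)
        assert "s0" not in tags.snp_ids

    def test_unrelated_allele_rejected(self):
        rows = [[0, 1]] * 4 + [[1, 0]] * 8 + [[0, 0]] * 8
        panel = _toy_panel(rows)
        groups, _ = cluster_major_haplotypes(panel, freq_cutoff=0.05)
        target = next(g for g in groups if g.vector == (0, 1))
        tags = select_tag_snps(panel, target)
        assert "s0" not in tags.snp_ids


class TestFrequencyEstimation:
    def test_mean_of_tags(self):
        tags = TagSet("hap1", ("a", "b", "c"), (1.0, 1.0, 1.0), (1, 1, 1))
        est = estimate_haplotype_frequencies(tags, {"a": 0.12, "b": 0.14, "c": 0.13})
        assert est.frequency == pytest.approx(0.13)

    def test_singleton_tag(self):
        tags = TagSet("hap1", ("a",), (1.0,), (1,))
        assert estimate_haplotype_frequencies(tags, {"a": 0.2}).frequency == 0.2

    def test_orientation_flips_reference_linked_tags(self):
        tags = TagSet("hap1", ("a", "b"), (1.0, 1.0), (1, 0))
        est = estimate_haplotype_frequencies(tags, {"a": 0.2, "b": 0.8})
        assert est.frequency == pytest.approx(0.2)

    def test_outlier_visible_in_spread(self):
        tags = TagSet("hap1", ("a", "b", "c"), (1.0, 1.0, 1.0), (1, 1, 1))
        est = estimate_haplotype_frequencies(tags, {"a": 0.12, "b": 0.13, "c": 0.40})
        assert est.spread > 0.1
        assert est.per_tag["c"] == 0.40

    def test_empty_tag_set_rejected(self):
        with pytest.raises(ValueError):
            estimate_haplotype_frequencies(TagSet("h", (), (), ()), {})

    def test_exact_under_perfect_tags_and_zero_noise(self, default_panel, default_cohort):
        """With perfect private tags and zero pool noise, tag averaging
        returns the true haplotype frequency of each pool exactly."""
        panel = default_panel
        noise = syn.PoolNoiseConfig(se_case=0.0, se_control=0.0, seed=0)
        pool_af = syn.gen_pooled_af(panel, default_cohort, noise)
        var = syn.combine_pools(pool_af)
        groups, _ = cluster_major_haplotypes(panel)
        majors = [g for g in groups if g.is_major]
        risk = majors[panel.risk_hap]
        tags = select_tag_snps(panel, risk)
        af_case = dict(zip(var["variant_id"], var["af_case"]))
        est = estimate_haplotype_frequencies(tags, af_case)
        case_rows = default_cohort[default_cohort["status"] == 1]
        chroms = np.concatenate([case_rows["chrom1"], case_rows["chrom2"]])
        member = np.isin(chroms, risk.chromosome_indices)
        assert est.frequency == pytest.approx(member.mean(), abs=1e-12)


class TestHaplotypeFisher:
    def test_cross_product_odds_ratio_and_enumerated_p(self):
        res = haplotype_fisher_test(38 / 254, 254, 22 / 270, 270)
        assert res.odds_ratio == pytest.approx((38 * 248) / (216 * 22), rel=1e-12)
        assert round(res.odds_ratio, 2) == 1.98
        assert res.p_fisher == pytest.approx(
            fisher_two_sided_oracle(38, 216, 22, 248), rel=1e-9
        )
        lo, hi = res.ci95
        assert lo < res.odds_ratio < hi

    def test_null_table(self):
        res = haplotype_fisher_test(0.2, 100, 0.2, 100)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_fisher == 1.0

    def test_zero_frequency_flags_or_undefined(self):
        res = haplotype_fisher_test(0.0, 100, 0.1, 100)
        assert not res.or_defined
        assert math.isnan(res.odds_ratio)


class TestConditionalIndependence:
    CASE = {"hap1": 38, "hap2": 10, "other": 206}
    CTRL = {"hap1": 22, "hap2": 40, "other": 208}

    def test_excluding_competitor_shrinks_or(self):
        c_or, c_p = conditional_independence_test(self.CASE, self.CTRL, "hap1", "hap2")
        assert c_or == pytest.approx((38 * 208) / (206 * 22), rel=1e-12)
        assert c_or == pytest.approx(1.744, abs=5e-4)
        assert 0 < c_p < 1

    def test_zero_count_exclusion_is_noop(self):
        case = {"hap1": 38, "hap2": 0, "other": 216}
        ctrl = {"hap1": 22, "hap2": 0, "other": 248}
        c_or, c_p = conditional_independence_test(case, ctrl, "hap1", "hap2")
        unc = haplotype_fisher_test(38 / 254, 254, 22 / 270, 270)
        assert c_or == pytest.approx(unc.odds_ratio, rel=1e-12)
        assert c_p == pytest.approx(unc.p_fisher, rel=1e-9)

    def test_null_after_exclusion(self):
        case = {"hap1": 30, "hap2": 10, "other": 70}
        ctrl = {"hap1": 30, "hap2": 25, "other": 70}
        c_or, _ = conditional_independence_test(case, ctrl, "hap1", "hap2")
        assert c_or == pytest.approx(1.0)

    def test_target_equals_excluded_rejected(self):
        with pytest.raises(ValueError):
            conditional_independence_test(self.CASE, self.CTRL, "hap1", "hap1")


class TestRecombinants:
    @staticmethod
    def _table(rows):
        cols = ["individual_id", "rt1", "rt2", "rt3", "pt1", "pt2", "pt3"]
        return pd.DataFrame(rows, columns=cols)

    def test_dosage_rules(self):
        table = self._table(
            [
                ["ref_only", 0, 0, 0, 0, 0, 0],
                ["consistent", 1, 1, 1, 0, 0, 0],
                ["recombinant", 1, 1, 0, 0, 0, 0],
                ["prot_recomb", 0, 0, 0, 2, 1, 2],
            ]
        )
        recomb = detect_recombinants(table, ["rt1", "rt2", "rt3"], ["pt1", "pt2", "pt3"])
        assert recomb == ["recombinant", "prot_recomb"]

    def test_missing_dosage_rejected(self):
        table = self._table([["a", 1, np.nan, 1, 0, 0, 0]])
        with pytest.raises(ValueError):
            detect_recombinants(table, ["rt1", "rt2", "rt3"], ["pt1", "pt2", "pt3"])


class TestJointGLM:
    def test_identical_dosage_distributions_are_null(self):
        half = pd.DataFrame(
            {"dosage_risk": [0, 1, 2, 0, 1], "dosage_prot": [0, 0, 0, 1, 1]}
        )
        df = pd.concat(
            [half.assign(status=1), half.assign(status=0)], ignore_index=True
        )
        res = joint_glm_test(df)
        assert res["risk"]["or"] == pytest.approx(1.0, abs=1e-6)
        assert res["protective"]["or"] == pytest.approx(1.0, abs=1e-6)
        assert res["risk"]["p"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_likelihood_maximization(self):
        df = pd.DataFrame(
            {
                "status": [1, 1, 1, 0, 0, 0, 1, 0],
                "dosage_risk": [2, 1, 1, 0, 0, 1, 0, 0],
                "dosage_prot": [0, 0, 1, 1, 2, 0, 0, 1],
            }
        )
        res = joint_glm_test(df)
        beta = glm_oracle(df)
        assert math.log(res["risk"]["or"]) == pytest.approx(beta[1], abs=1e-4)
        assert math.log(res["protective"]["or"]) == pytest.approx(beta[2], abs=1e-4)

    def test_complete_separation_flagged(self):
        df = pd.DataFrame(
            {
                "status": [1] * 6 + [0] * 6,
                "dosage_risk": [2, 2, 2, 1, 1, 1, 0, 0, 0, 0, 0, 0],
                "dosage_prot": [0] * 12,
            }
        )
        res = joint_glm_test(df)
        assert res["separation"]

    def test_too_few_individuals_rejected(self):
        df = pd.DataFrame({"status": [1, 0], "dosage_risk": [1, 0], "dosage_prot": [0, 0]})
        with pytest.raises(ValueError):
            joint_glm_test(df)


class TestEndToEndRecovery:
    def test_direction_recovery_across_replicates(self, default_panel, major_groups):
        """Across 100 seeded replicates of the full pipeline (cohort, pooled
        estimates with default noise, tag averaging), the risk and protective
        haplotypes are recovered with the correct effect direction in >= 80%."""
        panel = default_panel
        majors, _ = major_groups
        tags_r = select_tag_snps(panel, majors[panel.risk_hap])
        tags_p = select_tag_snps(panel, majors[panel.protective_hap])
        ok = 0
        for i in range(100):
            coh = syn.gen_cohort(panel, syn.CohortConfig(seed=1000 + i))
            pool_af = syn.gen_pooled_af(panel, coh, syn.PoolNoiseConfig(seed=2000 + i))
            var = syn.combine_pools(pool_af)
            af_case = dict(zip(var["variant_id"], var["af_case"]))
            af_ctrl = dict(zip(var["variant_id"], var["af_control"]))
            risk_up = (
                estimate_haplotype_frequencies(tags_r, af_case).frequency
                > estimate_haplotype_frequencies(tags_r, af_ctrl).frequency
            )
            prot_down = (
                estimate_haplotype_frequencies(tags_p, af_case).frequency
                < estimate_haplotype_frequencies(tags_p, af_ctrl).frequency
            )
            ok += risk_up and prot_down
        assert ok >= 80
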