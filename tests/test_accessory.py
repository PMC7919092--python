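import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mspscreen.accessory import (
    call_carriage,
    carrier_abundance_test,
    fit_detection_model,
    module_counts,
    screen_all_modules,
    targeted_enrichment,
)
from mspscreen.io import ValidationError
from mspscreen.quantify import msp_abundance, tpm_normalize
from mspscreen.simulate import (
    CommunitySpec,
    ModuleSpec,
    MspSpec,
    generate_community,
    generate_metadata,
    simulate_counts,
)

from conftest import make_counts, make_gene_info, make_metadata


def fisher_oracle(a, b, c, d, alternative):
    """Fisher exact p by enumerating all 2x2 tables with fixed margins.

    Exact rational arithmetic; independent of any library routine.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    if alternative == "greater":
        p = sum(probs[k] for k in range(a, hi + 1))
    elif alternative == "less":
        p = sum(probs[k] for k in range(lo, a + 1))
    else:
        pa = probs[a]
        p = sum(v for v in probs.values() if v <= pa)
    return float(p)


def mk_module_counts(core, acc, sample_prefix="s"):
    idx = pd.Index([f"{sample_prefix}{i}" for i in range(len(core))], name="sample_id")
    return pd.DataFrame({"core_reads": core, "accessory_reads": acc}, index=idx)


class TestModuleCounts:
    def info(self):
        rows = [(f"c{i}", 500, "msp1", "core", i + 1, None) for i in range(35)]
        rows += [(f"a{i}", 400, "msp1", "accessory", None, "modA") for i in range(5)]
        return make_gene_info(rows)

    def test_sums_over_module_and_top30_core(self):
        gi = self.info()
        mat = np.zeros((40, 1), dtype=int)
        mat[:35] = 2  # every core gene, incl. 5 beyond the top 30
        mat[35:] = [[1], [0], [2], [0], [1]]
        counts = make_counts(mat, list(gi.frame.index), ["s1"])
        mc = module_counts(counts, gi, "msp1", "modA")
        assert mc.loc["s1", "core_reads"] == 60  # only core_rank <= 30
        assert mc.loc["s1", "accessory_reads"] == 4

    def test_zero_depth_sample_is_all_zero(self):
        gi = self.info()
        counts = make_counts(np.zeros((40, 1), dtype=int), list(gi.frame.index), ["s1"])
        mc = module_counts(counts, gi, "msp1", "modA")
        assert mc.loc["s1"].tolist() == [0, 0]

    def test_core_gene_in_explicit_accessory_list_rejected(self):
        gi = self.info()
        counts = make_counts(np.zeros((40, 1), dtype=int), list(gi.frame.index), ["s1"])
        with pytest.raises(ValidationError, match="core"):
            module_counts(counts, gi, "msp1", gene_ids=["c0", "a0"])

    def test_unknown_module_rejected(self):
        gi = self.info()
        counts = make_counts(np.zeros((40, 1), dtype=int), list(gi.frame.index), ["s1"])
        with pytest.raises(ValidationError, match="modX"):
            module_counts(counts, gi, "msp1", "modX")


class TestDetectionModel:
    def test_constant_ratio(self):
        mc = mk_module_counts([100, 200, 400], [25, 50, 100])
        model = fit_detection_model(mc, "m", "a")
        assert model.beta == pytest.approx(0.25)
        assert model.m_star == 4

    def test_median_ratio_then_ceiling(self):
        mc = mk_module_counts([10, 10, 10], [2, 3, 4])
        model = fit_detection_model(mc, "m", "a")
        assert model.beta == pytest.approx(0.3)
        assert model.m_star == 4

    def test_beta_at_least_one_gives_threshold_one(self):
        mc = mk_module_counts([10], [15])
        assert fit_detection_model(mc, "m", "a").m_star == 1

    def test_non_carriers_excluded_from_fit(self):
        mc = mk_module_counts([100, 100, 5], [25, 25, 0])
        assert fit_detection_model(mc, "m", "a").n_fit == 2

    def test_never_observed_module_rejected(self):
        mc = mk_module_counts([100, 100], [0, 0])
        with pytest.raises(ValidationError, match="never observed"):
            fit_detection_model(mc, "m", "a")

    def test_m_star_matches_brute_force_over_random_betas(self):
        rng = np.random.default_rng(0)
        for beta in rng.uniform(0.01, 2.0, 100):
            mc = mk_module_counts([10**7], [int(round(beta * 10**7))])
            model = fit_detection_model(mc, "m", "a")
            m = 1
            while model.beta * m < 1.0:
                m += 1
            assert model.m_star == m


class TestCallCarriage:
    def model(self, beta=1 / 16):
        mc = mk_module_counts([160], [10])
        return fit_detection_model(mc, "msp1", "modA")

    def test_covered_sample_with_signal_is_positive(self):
        model = self.model()
        assert model.m_star == 16
        calls = call_carriage(mk_module_counts([20], [3]), model)
        assert calls.frame["call"].iloc[0] == "positive"

    def test_low_coverage_discarded_despite_signal(self):
        calls = call_carriage(mk_module_counts([10], [2]), self.model())
        assert calls.frame["call"].iloc[0] == "undetermined"

    def test_covered_sample_without_signal_is_negative(self):
        calls = call_carriage(mk_module_counts([40], [0]), self.model())
        assert calls.frame["call"].iloc[0] == "negative"

    def test_detection_guarantee_at_threshold(self):
        # a carrier sampled at exactly m* core reads yields >= 1 accessory
        # read with probability >= 1 - exp(-1) under the Poisson model
        rng = np.random.default_rng(1)
        model = self.model()
        lam = model.beta * model.m_star
        draws = rng.poisson(lam, 10_000)
        freq = (draws >= 1).mean()
        target = 1 - math.exp(-1)
        mc_err = math.sqrt(target * (1 - target) / 10_000)
        assert freq >= target - 3 * mc_err


class TestTargetedEnrichment:
    def calls_from_cells(self, dp, dn, cp, cn, disease="IgG4-RD"):
        n_d, n_c = dp + dn, cp + cn
        cohorts = [disease] * n_d + ["control"] * n_c
        md = make_metadata(cohorts)
        core = [100] * (n_d + n_c)
        acc = [5] * dp + [0] * dn + [5] * cp + [0] * cn
        mc = mk_module_counts(core, acc)
        mc.index = md.frame.index
        model = fit_detection_model(mc, "msp1", "modA")
        return call_carriage(mc, model), md

    def test_odds_ratio_and_exact_p(self):
        calls, md = self.calls_from_cells(15, 5, 10, 10)
        res = targeted_enrichment(calls, md, "IgG4-RD")
        assert res.odds_ratio == pytest.approx(3.0)
        assert res.p == pytest.approx(fisher_oracle(15, 5, 10, 10, "greater"), abs=1e-12)

    def test_null_table_is_insignificant(self):
        calls, md = self.calls_from_cells(30, 30, 30, 30)
        res = targeted_enrichment(calls, md, "IgG4-RD")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p > 0.05

    def test_zero_control_cell_gives_infinite_or_with_corrected_log2(self):
        calls, md = self.calls_from_cells(8, 12, 0, 20)
        res = targeted_enrichment(calls, md, "IgG4-RD")
        assert math.isinf(res.odds_ratio)
        expected_log2 = math.log2((8.5 * 20.5) / (12.5 * 0.5))
        assert res.log2_odds_ratio == pytest.approx(expected_log2)
        assert res.p == pytest.approx(fisher_oracle(8, 12, 0, 20, "greater"), abs=1e-12)

    def test_all_undetermined_group_rejected(self):
        md = make_metadata(["IgG4-RD", "control"])
        mc = mk_module_counts([100, 2], [5, 0])
        mc.index = md.frame.index
        model = fit_detection_model(mc, "msp1", "modA")
        calls = call_carriage(mc, model)
        with pytest.raises(ValidationError):
            targeted_enrichment(calls, md, "IgG4-RD")


def carriage_scenario(p_control, p_disease, n_control, n_disease, seed, depth=3e4):
    md = generate_metadata(n_control, n_disease, 0, seed=seed)
    spec = CommunitySpec(
        [
            MspSpec(
                "msp1",
                n_core_genes=10,
                modules=[
                    ModuleSpec("modA", 4, {"control": p_control, "IgG4-RD": p_disease})
                ],
                base_log10=0.0,
            )
        ],
        sample_sigma=0.1,
    )
    gi, spec = generate_community(spec, seed + 1)
    counts, truth = simulate_counts(gi, md, spec, depth_mean=depth, seed=seed + 2)
    return counts, gi, md, truth


class TestScreen:
    def test_enriched_module_is_top_hit(self):
        md = generate_metadata(80, 80, 0, seed=3)
        msps = []
        for i in range(6):
            carr = {"default": 0.5}
            if i == 0:
                carr = {"control": 0.3, "IgG4-RD": 0.9}
            msps.append(
                MspSpec(
                    f"msp{i}",
                    n_core_genes=8,
                    modules=[ModuleSpec(f"mod{i}", 4, carr)],
                    base_log10=0.0,
                )
            )
        gi, spec = generate_community(CommunitySpec(msps, sample_sigma=0.1), seed=4)
        counts, _ = simulate_counts(gi, md, spec, depth_mean=1e5, seed=5)
        res = screen_all_modules(counts, gi, md, min_group_detected=20)
        best = res.sort_values("q").iloc[0]
        assert best["module_id"] == "mod0"
        assert best["q"] < 0.05
        assert best["log2_odds_ratio"] > 0

    def test_carriage_calls_recover_ground_truth(self):
        counts, gi, md, truth = carriage_scenario(0.5, 0.75, 60, 60, seed=6, depth=1e5)
        mc = module_counts(counts, gi, "msp1", "modA")
        model = fit_detection_model(mc, "msp1", "modA")
        calls = call_carriage(mc, model)
        det = calls.determined()
        true_carr = truth.carriage.loc[("msp1", "modA"), det.index]
        confusion = ((det["call"] == "positive").to_numpy(dtype=int) != true_carr.to_numpy()).mean()
        assert confusion <= 0.02

    def test_underdetected_msp_excluded(self):
        # coverage too low for any sample to be determined in one cohort
        counts, gi, md, _ = carriage_scenario(0.5, 0.5, 30, 30, seed=7, depth=1e4)
        res = screen_all_modules(counts, gi, md, min_group_detected=30)
        assert res.empty

    def test_screen_p_matches_oracle(self):
        counts, gi, md, _ = carriage_scenario(0.4, 0.7, 25, 25, seed=8, depth=1e5)
        res = screen_all_modules(counts, gi, md, min_group_detected=5)
        row = res.iloc[0]
        expected = fisher_oracle(
            int(row["disease_pos"]),
            int(row["disease_neg"]),
            int(row["control_pos"]),
            int(row["control_neg"]),
            "two-sided",
        )
        assert row["p"] == pytest.approx(expected, abs=1e-12)


class TestCarrierAbundanceTest:
    def dataset(self):
        counts, gi, md, truth = carriage_scenario(0.5, 0.5, 40, 40, seed=9, depth=1e5)
        table = msp_abundance(tpm_normalize(counts, gi), gi)
        mc = module_counts(counts, gi, "msp1", "modA")
        calls = call_carriage(mc, fit_detection_model(mc, "msp1", "modA"))
        return calls, table, md

    def test_exact_rank_sum_p_for_separated_groups(self):
        md = make_metadata(["control"] * 10)
        core = [100] * 10
        acc = [5] * 5 + [0] * 5
        mc = mk_module_counts(core, acc)
        mc.index = md.frame.index
        calls = call_carriage(mc, fit_detection_model(mc, "msp1", "modA"))
        abund = pd.DataFrame(
            [[10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]],
            index=pd.Index(["msp1"], name="msp_id"),
            columns=md.frame.index,
        )
        table = type(self.dataset()[1])(abundance=abund, rel_abundance=abund)
        stat, p = carrier_abundance_test(calls, table, md, "control", alternative="greater")
        assert p == pytest.approx(1 / 252)

    def test_p_matches_enumeration_oracle_small_case(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 4)
        y = rng.normal(0, 1, 4)
        u, p = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        pooled = np.concatenate([x, y])
        count = 0
        total = 0
        for idx in combinations(range(8), 4):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u_perm = sum((a > b) for a in xs for b in ys)
            count += u_perm >= u
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_null_carriage_gives_uniformish_p(self):
        calls, table, md = self.dataset()
        _, p = carrier_abundance_test(calls, table, md, "control")
        assert 0.0 < p <= 1.0

    def test_empty_class_rejected(self):
        md = make_metadata(["control"] * 4)
        mc = mk_module_counts([100] * 4, [5] * 4)
        mc.index = md.frame.index
        calls = call_carriage(mc, fit_detection_model(mc, "msp1", "modA"))
        abund = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=pd.Index(["msp1"], name="msp_id"), columns=md.frame.index
        )
        table = type(self.dataset()[1])(abundance=abund, rel_abundance=abund)
        with pytest.raises(ValidationError):
            carrier_abundance_test(calls, table, md, "control")
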