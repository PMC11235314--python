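"""Dependence rules, PWM learning/scanning and corroboration profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from m5cpipe.simulate import (SimConfig, simulate_methylome,
                              simulate_transcriptome)
from m5cpipe.writers import (
    BASES,
    build_pwm,
    classify_dependence_gain,
    classify_dependence_loss,
    combine_verdicts,
    methylation_expression_correlation,
    pairing_propensity_profile,
    read_meme,
    scan_and_assign,
    write_meme,
)


class TestDependenceRules:
    @pytest.mark.parametrize(
        "wt,ko,verdict",
        [
            (0.25, 0.08, "dependent"),
            (0.25, 0.12, "independent"),   # residual >= 0.10
            (0.14, 0.09, "independent"),   # decrease exactly 0.05, not > 0.05
        ],
    )
    def test_loss_examples(self, wt, ko, verdict):
        assert classify_dependence_loss(wt, ko) == verdict

    @pytest.mark.parametrize(
        "ctrl,oe,verdict",
        [
            (0.02, 0.15, "dependent"),
            (0.02, 0.06, "independent"),   # level <= 0.10
            (0.09, 0.12, "independent"),   # increase 0.03 < 0.05
            (0.07, 0.12, "dependent"),     # increase exactly 0.05 qualifies
        ],
    )
    def test_gain_examples(self, ctrl, oe, verdict):
        assert classify_dependence_gain(ctrl, oe) == verdict

    def test_low_coverage_is_uninformative(self):
        assert classify_dependence_loss(0.3, 0.0, 15, 100) == "uninformative"
        assert classify_dependence_gain(0.0, 0.3, 100, 19) == "uninformative"

    def test_lattice_matches_direct_transcription(self):
        """Exhaustive 0.01 grid against a literal transcription of the rules,
        written in exact integer (x100) units."""
        for ri, pi in itertools.product(range(101), range(101)):
            ref, pert = ri / 100, pi / 100
            loss = classify_dependence_loss(ref, pert)
            assert (loss == "dependent") == ((ri - pi) > 5 and pi < 10)
            gain = classify_dependence_gain(ref, pert)
            assert (gain == "dependent") == ((pi - ri) >= 5 and pi > 10)

    def test_or_combination_of_datasets(self):
        assert combine_verdicts("independent", "dependent") == "dependent"
        assert combine_verdicts("uninformative", "independent") == "independent"
        assert combine_verdicts("uninformative") == "uninformative"


class TestBuildPWM:
    def test_hand_counted_columns_without_pseudocount(self):
        pwm = build_pwm("X", ["CGGGAA", "CGGGAU", "CGGGUA", "CGGGAA"],
                        pseudocount=0.0)
        assert pwm.matrix[BASES.index("C"), 0] == pytest.approx(1.0)
        assert pwm.matrix[BASES.index("G"), 1] == pytest.approx(1.0)
        assert pwm.matrix[BASES.index("A"), 4] == pytest.approx(0.75)

    def test_pseudocount_smoothing(self):
        pwm = build_pwm("X", ["CGGGAA", "CGGGAU", "CGGGUA", "CGGGAA"],
                        pseudocount=0.25)
        assert pwm.matrix[BASES.index("C"), 0] == pytest.approx(4.25 / 5)
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-12)

    def test_dna_input_normalised_to_rna(self):
        pwm = build_pwm("X", ["CTCCAT", "CTCCAT"], pseudocount=0.0)
        assert pwm.matrix[BASES.index("U"), 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seqs", [[], ["CGGGAA"], ["CGGGAA", "CGGG"]])
    def test_bad_training_sets_rejected(self, seqs):
        with pytest.raises(ValueError):
            build_pwm("X", seqs)


class TestScanAndAssign:
    @pytest.fixture()
    def pwms(self):
        rng = np.random.default_rng(5)
        n6 = ["CUCCA" + rng.choice(list(BASES)) for _ in range(80)]
        n2 = ["C" + "".join(rng.choice(list(BASES), 5, p=[.04, .03, .9, .03]))
              for _ in range(80)]
        return {"NSUN2": build_pwm("NSUN2", n2), "NSUN6": build_pwm("NSUN6", n6)}

    def test_cucca_context_assigned_to_nsun6(self, pwms):
        assert scan_and_assign("CUCCAG", pwms) == "NSUN6"

    def test_far_from_both_pwms_is_other(self, pwms):
        assert scan_and_assign("AUAUAU", pwms, p_threshold=1e-3) == "other"

    def test_short_context_uninformative(self, pwms):
        assert scan_and_assign("CUCC", pwms) == "uninformative"

    def test_match_pvalue_equals_exhaustive_enumeration(self, pwms):
        """Oracle: brute-force sum over all 4^6 background 6-mers."""
        pwm = pwms["NSUN6"]
        for kmer in ["CUCCAG", "AUAUAU", "CGGGGG", "CUCCAA"]:
            s = pwm.score(kmer)
            brute = sum(
                np.prod([pwm.background[BASES.index(b)] for b in w])
                for w in map("".join, itertools.product(BASES, repeat=6))
                if pwm.score(w) >= s - 1e-9
            )
            assert pwm.match_pvalue(s) == pytest.approx(brute, rel=1e-9)

    def test_meme_round_trip(self, tmp_path, pwms):
        path = tmp_path / "writers.meme"
        write_meme(pwms.values(), path)
        back = read_meme(path)
        assert set(back) == set(pwms)
        for name in pwms:
            np.testing.assert_allclose(back[name].matrix, pwms[name].matrix,
                                       atol=1e-5)

    def test_recovery_on_simulated_motif_sites(self):
        """PWMs trained on simulated writer contexts recover held-out labels
        and rarely claim random contexts."""
        cfg = SimConfig(seed=21, n_transcripts=100, n_true_sites=500,
                        writer_mix={"NSUN2": 0.5, "NSUN6": 0.5})
        g, m = simulate_transcriptome(cfg)
        g, truth = simulate_methylome(g, m, cfg)
        truth["ctx"] = [g[r.chrom][r.pos0: r.pos0 + 6] for r in truth.itertuples()]
        n2 = truth[truth.writer == "NSUN2"].ctx.tolist()
        n6 = truth[truth.writer == "NSUN6"].ctx.tolist()
        pwms = {"NSUN2": build_pwm("NSUN2", n2[:150]),
                "NSUN6": build_pwm("NSUN6", n6[:150])}
        held = [(c, "NSUN2") for c in n2[150:]] + [(c, "NSUN6") for c in n6[150:]]
        acc = np.mean([scan_and_assign(c, pwms) == lab for c, lab in held])
        assert acc >= 0.9
        rng = np.random.default_rng(1)
        rand = ["".join(rng.choice(list(BASES), 6)) for _ in range(500)]
        claimed = np.mean([scan_and_assign(c, pwms) != "other" for c in rand])
        assert claimed <= 0.1


class TestPairingPropensity:
    def test_poly_a_windows_never_pair(self):
        profile, used, excl = pairing_propensity_profile(["A" * 21] * 5, window=10)
        assert used == 5 and excl == 0
        assert (profile == 0).all()

    def test_embedded_hairpin_stem_saturates(self):
        # 8-bp stem with a 5-nt loop at fixed offsets in every input
        hairpin = "GGGGGGGG" + "AAAAA" + "CCCCCCCC"
        seq = hairpin.center(21, "A")
        profile, _, _ = pairing_propensity_profile([seq] * 4, window=10)
        start = seq.index("G")
        assert (profile[start: start + 8] == 1.0).all()
        assert (profile[start + 8: start + 13] == 0.0).all()

    def test_short_sequences_excluded_with_count(self):
        profile, used, excl = pairing_propensity_profile(
            ["A" * 21, "A" * 15], window=10)
        assert used == 1 and excl == 1

    def test_no_usable_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            pairing_propensity_profile([], window=10)


class TestMethylationExpressionCorrelation:
    def _tables(self, levels_row, coverage_row, expr_row):
        samples = [f"s{i}" for i in range(len(levels_row))]
        levels = pd.DataFrame([levels_row], index=["site1"], columns=samples)
        cov = pd.DataFrame([coverage_row], index=["site1"], columns=samples)
        expr = pd.DataFrame([expr_row], index=["NSUN2"], columns=samples)
        return levels, cov, expr

    def test_proportional_levels_give_r_one(self):
        expr = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        lev = [0.1 * x for x in expr]
        levels, cov, e = self._tables(lev, [100] * 6, expr)
        out = methylation_expression_correlation(
            levels, cov, e, pd.Series({"site1": "NSUN2"}))
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_insufficient_coverage_excluded(self):
        levels, cov, e = self._tables([0.2] * 6, [100, 100, 100, 100, 10, 10],
                                      [1, 2, 3, 4, 5, 6])
        out = methylation_expression_correlation(
            levels, cov, e, pd.Series({"site1": "NSUN2"}))
        assert len(out) == 0  # coverage > 20 in only 4 samples

    def test_constant_vector_yields_missing_r(self):
        levels, cov, e = self._tables([0.2] * 6, [100] * 6, [3.0] * 6)
        out = methylation_expression_correlation(
            levels, cov, e, pd.Series({"site1": "NSUN2"}))
        assert len(out) == 1 and np.isnan(out.r.iloc[0])

    def test_correlation_sign_recovery(self):
        """Sites driven by an enzyme correlate positively with its expression
        and more strongly than other writers' sites."""
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(8)]
        expr = rng.uniform(1, 10, size=8)
        own = np.clip(0.05 * expr[None, :] + rng.normal(0, 0.05, (30, 8)), 0, 1)
        other = np.clip(rng.uniform(0.1, 0.5, (30, 1)) + rng.normal(0, 0.05, (30, 8)), 0, 1)
        levels = pd.DataFrame(np.vstack([own, other]), columns=samples,
                              index=[f"site{i}" for i in range(60)])
        cov = pd.DataFrame(100, index=levels.index, columns=samples)
        e = pd.DataFrame([expr], index=["NSUN2"], columns=samples)
        labels = pd.Series(["NSUN2"] * 30 + ["other"] * 30, index=levels.index)
        out = methylation_expression_correlation(levels, cov, e, labels)
        med = out.groupby("writer").r.median()
        assert med["NSUN2"] > 0
        assert med["NSUN2"] > med["other"]
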