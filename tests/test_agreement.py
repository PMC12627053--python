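"""Five-index agreement panel: examples, oracles, invariants, benchmarks."""

import numpy as np
import pytest

from facedamp.agreement import (
    AgreementPanel,
    PairedRatings,
    benchmark,
    bin_machine_intensity,
    cohens_kappa,
    gwets_ac1,
    group_mean_panel,
    icc_3_1,
    kripp_alpha_ordinal,
    panel,
    percent_agreement,
)
from facedamp.facs import MACHINE_AU_IDS, AUVector, ExpressionTrial

from .oracles import ac1_oracle, alpha_ordinal_oracle, icc_oracle, kappa_oracle


def ratings(pairs, q=6):
    return PairedRatings(tuple(pairs), n_categories=q)


class TestBinning:
    @pytest.mark.parametrize(
        "x, expected", [(1.5, 2), (5.7, 5), (0.49, 0), (0.5, 1), (2.4999, 2), (0.0, 0)]
    )
    def test_round_half_away_then_clamp(self, x, expected):
        assert bin_machine_intensity(x) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_machine_intensity(-0.1)


class TestPercentAgreement:
    def test_examples(self):
        assert percent_agreement(ratings([(1, 1)] * 17)) == 100.0
        mixed = [(0, 0)] * 43 + [(1, 0), (0, 1)]
        assert percent_agreement(ratings(mixed)) == pytest.approx(100 * 43 / 45)
        assert percent_agreement(ratings([(0, 1)] * 10)) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percent_agreement(ratings([]))


class TestKappa:
    def test_perfect_two_categories(self):
        assert cohens_kappa(ratings([(0, 0), (1, 1)] * 5)) == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        pairs = [(0, 0)] * 20 + [(0, 1)] * 5 + [(1, 0)] * 10 + [(1, 1)] * 15
        assert cohens_kappa(ratings(pairs, q=2)) == pytest.approx(0.4)

    def test_sparsity_paradox_example(self):
        """Two mismatched singletons among 43 zero pairs drive kappa below 0,
        yet raw agreement is 95.6% — the prevalence paradox."""
        pairs = [(0, 0)] * 43 + [(1, 0), (0, 1)]
        k = cohens_kappa(ratings(pairs, q=2))
        assert k == pytest.approx(-0.0227, abs=5e-4)

    def test_constant_raters_undefined(self):
        assert cohens_kappa(ratings([(0, 0)] * 10)) is None


class TestAC1:
    def test_perfect_mixed(self):
        assert gwets_ac1(ratings([(0, 0), (3, 3), (5, 5)])) == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        pairs = [(0, 0)] * 20 + [(0, 1)] * 5 + [(1, 0)] * 10 + [(1, 1)] * 15
        assert gwets_ac1(ratings(pairs, q=2)) == pytest.approx(0.4059, abs=5e-4)

    def test_stable_under_sparsity(self):
        pairs = [(0, 0)] * 43 + [(1, 0), (0, 1)]
        ac1 = gwets_ac1(ratings(pairs, q=2))
        kap = cohens_kappa(ratings(pairs, q=2))
        assert ac1 == pytest.approx(0.9535, abs=5e-4)
        assert ac1 > kap


class TestAlphaOrdinal:
    def test_identical_ratings(self):
        assert kripp_alpha_ordinal(ratings([(0, 0), (1, 1), (3, 3), (4, 4)])) == pytest.approx(1.0)

    def test_two_value_data_equals_nominal(self):
        """With only two observed adjacent categories the ordinal metric is a
        constant, so alpha reduces to its nominal form."""
        pairs = [(0, 0)] * 6 + [(0, 1)] * 2 + [(1, 1)] * 4
        a_ord = kripp_alpha_ordinal(ratings(pairs))
        # nominal alpha for 2 raters: 1 - D_o/D_e with 0/1 metric
        h = np.array([p[0] for p in pairs])
        m = np.array([p[1] for p in pairs])
        pooled = np.concatenate([h, m])
        n = len(pooled)
        d_o = np.mean(h != m)
        vals, counts = np.unique(pooled, return_counts=True)
        d_e = 1 - np.sum(counts * (counts - 1)) / (n * (n - 1))
        assert a_ord == pytest.approx(1 - d_o / d_e)

    def test_toy_set_against_pair_enumeration(self):
        h = [0, 1, 2, 3, 4, 1]
        m = [0, 1, 2, 3, 4, 2]  # one disagreement
        mine = kripp_alpha_ordinal(ratings(list(zip(h, m))))
        assert mine == pytest.approx(alpha_ordinal_oracle(h, m), abs=1e-12)


class TestICC:
    def test_perfect_agreement(self):
        h = [0, 1, 2, 3, 4]
        assert icc_3_1(h, h, "consistency") == pytest.approx(1.0)
        assert icc_3_1(h, h, "absolute") == pytest.approx(1.0)

    def test_constant_shift(self):
        h = [0, 1, 2, 3]
        m = [1, 2, 3, 4]
        assert icc_3_1(h, m, "consistency") == pytest.approx(1.0)
        assert icc_3_1(h, m, "absolute") < 1.0

    def test_matches_mixed_model_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            h = rng.normal(2, 1, n)
            m = 0.7 * h + rng.normal(0, 0.5, n)
            for variant in ("consistency", "absolute"):
                assert icc_3_1(h, m, variant) == pytest.approx(
                    icc_oracle(h, m, variant), abs=1e-10
                )


class TestPanel:
    def _trial(self, hvals, mvals):
        return ExpressionTrial(
            "P001",
            "happiness",
            AUVector(hvals),
            AUVector(mvals, rater="machine", au_id_set=MACHINE_AU_IDS),
            coded="happiness",
        )

    def test_identical_vectors_all_ones(self):
        vals = {6: 3, 12: 2, 25: 4}
        p = panel(self._trial(vals, {k: float(v) for k, v in vals.items()}))
        assert p.percent_agreement == 100.0
        assert p.kappa == pytest.approx(1.0)
        assert p.ac1 == pytest.approx(1.0)
        assert p.alpha_ordinal == pytest.approx(1.0)
        assert p.icc31 == pytest.approx(1.0)

    def test_kappa_bounded_by_observed_agreement(self, rng):
        for _ in range(50):
            h = {a: int(rng.integers(0, 6)) for a in MACHINE_AU_IDS}
            m = {a: float(np.clip(v + rng.normal(0, 1), 0, 5)) for a, v in h.items()}
            p = panel(self._trial({a: v for a, v in h.items() if v}, {a: v for a, v in m.items() if v}))
            if p.kappa is not None:
                assert p.kappa <= p.percent_agreement / 100.0 + 1e-12

    def test_missing_machine_vector_errors(self):
        t = ExpressionTrial("P001", "happiness", AUVector({6: 2, 12: 2, 25: 2}), coded="happiness")
        with pytest.raises(ValueError):
            panel(t)


class TestGroupMeanPanel:
    def _trials(self, n, group_map, emotion="happiness"):
        out = []
        for i in range(n):
            pid = f"P{i:03d}"
            vals = {6: 2 + (i % 2), 12: 2, 25: 3}
            out.append(
                ExpressionTrial(
                    pid,
                    emotion,
                    AUVector(vals),
                    AUVector({k: float(v) for k, v in vals.items()},
                             rater="machine", au_id_set=MACHINE_AU_IDS),
                    coded=emotion,
                )
            )
            group_map[pid] = "normotensive"
        return out

    def test_identical_panels_mean_equals_panel_sd_zero(self):
        groups = {}
        trials = self._trials(4, groups)
        tab = group_mean_panel(trials, groups)
        cell = tab[(tab.group == "normotensive") & (tab.emotion == "happiness")].iloc[0]
        assert cell["n"] == 4
        assert cell["percent_agreement_mean"] == pytest.approx(100.0)
        assert cell["kappa_mean"] == pytest.approx(1.0)

    def test_empty_cell_is_nan(self):
        groups = {}
        trials = self._trials(2, groups)
        tab = group_mean_panel(trials, groups)
        fear = tab[(tab.group == "normotensive") & (tab.emotion == "fear")].iloc[0]
        assert fear["n"] == 0
        assert np.isnan(fear["kappa_mean"])

    def test_single_trial_sd_zero(self):
        groups = {}
        trials = self._trials(1, groups)
        tab = group_mean_panel(trials, groups)
        cell = tab[(tab.group == "normotensive") & (tab.emotion == "happiness")].iloc[0]
        assert cell["n"] == 1
        assert cell["percent_agreement_sd"] == 0.0


class TestBenchmark:
    @pytest.mark.parametrize(
        "value, metric, label",
        [
            (0.68, "icc", "moderate"),
            (0.90, "icc", "good"),
            (0.95, "icc", "excellent"),
            (0.3, "icc", "poor"),
            (0.81, "kappa", "strong"),
            (0.61, "kappa", "acceptable"),
            (0.60, "ac1", "weak"),
            (0.667, "alpha", "unacceptable"),
            (0.70, "alpha", "acceptable"),
            (0.85, "alpha", "good"),
        ],
    )
    def test_bands(self, value, metric, label):
        assert benchmark(value, metric) == label

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            benchmark(0.5, "f1")


class TestOracleSweep:
    def test_all_indices_match_independent_oracles(self, rng):
        """Random small instances agree with library/brute-force routes."""
        for _ in range(200):
            n = int(rng.integers(3, 25))
            h = rng.integers(0, 6, n)
            m = np.clip(h + rng.integers(-2, 3, n), 0, 5)
            p = ratings(list(zip(h.tolist(), m.tolist())))
            k, ko = cohens_kappa(p), kappa_oracle(h, m)
            if k is None or ko is None:
                assert k == ko
            else:
                assert k == pytest.approx(ko, abs=1e-10)
            a, ao = gwets_ac1(p), ac1_oracle(h, m)
            assert a == pytest.approx(ao, abs=1e-10)
            al, alo = kripp_alpha_ordinal(p), alpha_ordinal_oracle(h.tolist(), m.tolist())
            if al is None or alo is None:
                assert al == alo
            else:
                assert al == pytest.approx(alo, abs=1e-10)
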