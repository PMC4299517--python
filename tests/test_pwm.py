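"""PWM encoding, fitting, prediction, and model-order comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tisfacs import pwm, sim, tis_space
from tisfacs.pwm import CONTRAST, N_POS
from tisfacs.sim import truth_efficiency_table


def _random_zero_margin_effects(rng):
    """Mono + pair effect tables with exactly zero margins."""
    mono = rng.normal(size=(N_POS, 4))
    mono -= mono.mean(axis=1, keepdims=True)
    pair = {}
    for i, j in itertools.combinations(range(N_POS), 2):
        t = rng.normal(size=(4, 4))
        t -= t.mean(axis=1, keepdims=True)
        t -= t.mean(axis=0, keepdims=True)
        pair[(i, j)] = t
    return mono, pair


class TestEncodeDesign:
    @pytest.mark.parametrize("order,ncols", [(1, 24), (2, 276), (3, 1788)])
    def test_column_counts(self, order, ncols):
        digits = tis_space.space_digits()[:64]
        x, keys = pwm.encode_design(digits, order)
        assert x.shape == (64, ncols)
        assert len(keys) == ncols

    def test_locality(self):
        a = tis_space.contexts_to_digits(["GCCACCAUGGG"])
        b = tis_space.contexts_to_digits(["UCCACCAUGGG"])  # differs at -6 only
        xa, _ = pwm.encode_design(a, 2)
        xb, _ = pwm.encode_design(b, 2)
        diff_cols = np.nonzero((xa != xb).any(axis=0))[0]
        keys = pwm.encode_design(a, 2)[1]
        for c in diff_cols:
            assert -6 in keys[c][2::2]

    def test_matches_brute_force_effect_sum(self):
        """The contrast design row, dotted with the contrast-basis
        coefficients of a zero-margin effect set, equals the direct sum of
        the full per-(base, position) effects — the one-hot oracle."""
        rng = np.random.default_rng(42)
        mono, pair = _random_zero_margin_effects(rng)
        beta = []
        for i in range(N_POS):
            beta.extend(mono[i, :3])
        for i, j in itertools.combinations(range(N_POS), 2):
            beta.extend(pair[(i, j)][:3, :3].ravel())
        beta = np.array(beta)
        ranks = rng.integers(0, tis_space.SPACE_SIZE, size=100)
        digits = tis_space.space_digits()[ranks]
        x, _ = pwm.encode_design(digits, 2)
        encoded = x @ beta
        direct = np.zeros(100)
        for i in range(N_POS):
            direct += mono[i, digits[:, i]]
        for (i, j), t in pair.items():
            direct += t[digits[:, i], digits[:, j]]
        assert np.allclose(encoded, direct, atol=1e-10)

    def test_decode_contrast_roundtrip(self):
        # CONTRAST columns sum to zero, so decoded effects have exact margins
        assert np.allclose(CONTRAST.sum(axis=0), 0.0)


class TestFitRecovery:
    def test_order1_noiseless_recovery(self, truth_mono):
        table = truth_efficiency_table(truth_mono)
        fit = pwm.fit_pwm(table, order=1)
        assert np.abs(fit.mono - truth_mono.mono).max() < 1e-6

    def test_order2_noiseless_recovery(self, truth_pairwise):
        table = truth_efficiency_table(truth_pairwise)
        fit = pwm.fit_pwm(table, order=2)
        assert np.abs(fit.mono - truth_pairwise.mono).max() < 1e-6
        for key, t in truth_pairwise.pair.items():
            assert np.abs(fit.pair[key] - t).max() < 1e-6

    def test_training_rows_exclude_upstream_aug(self, truth_mono):
        table = truth_efficiency_table(truth_mono)
        fit = pwm.fit_pwm(table, order=1)
        n_upstream = int(tis_space.space_upstream_aug_mask().sum())
        assert fit.metadata["n_excluded_upstream_aug"] == n_upstream
        assert fit.metadata["n_train"] == tis_space.SPACE_SIZE - n_upstream

    def test_sum_to_zero_margins_after_noisy_fit(self, small_pipeline):
        _, _, _, table = small_pipeline
        fit = pwm.fit_pwm(table, order=2)
        assert np.abs(fit.mono.sum(axis=1)).max() < 1e-9
        for t in fit.pair.values():
            assert np.abs(t.sum(axis=0)).max() < 1e-9
            assert np.abs(t.sum(axis=1)).max() < 1e-9

    def test_too_few_rows(self, truth_mono):
        table = truth_efficiency_table(truth_mono).head(100)
        with pytest.raises(pwm.FitError, match="training rows"):
            pwm.fit_pwm(table, order=1)

    def test_missing_level_reported(self, truth_mono):
        table = truth_efficiency_table(truth_mono)
        keep = table["tis"].str[0] != "A"  # drop every -6A context
        with pytest.raises(pwm.RankDeficiencyError, match="-6"):
            pwm.fit_pwm(table[keep], order=1)


class TestPrediction:
    def test_constant_model(self):
        model = pwm.PWMModel(order=1, intercept=np.log(76.9),
                             mono=np.zeros((N_POS, 4)))
        assert model.efficiency("GCCACCAUGGG") == pytest.approx(76.9)
        assert model.efficiency("AAAAAAAUGAA") == pytest.approx(76.9)

    def test_single_base_change_is_coefficient_difference(self, truth_mono):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_mono), order=1)
        a = np.log(fit.efficiency("GCCACCAUGGG"))
        b = np.log(fit.efficiency("UCCACCAUGGG"))
        i_g = tis_space.BASE_INDEX["G"]
        i_u = tis_space.BASE_INDEX["U"]
        assert a - b == pytest.approx(fit.mono[0, i_g] - fit.mono[0, i_u],
                                      abs=1e-9)

    def test_predictions_match_generator(self, truth_pairwise):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_pairwise), order=2)
        pred = fit.space_efficiencies()
        truth = truth_pairwise.true_efficiencies()
        ref = truth[tis_space.tis_rank("GCCACCAUGGG")]
        assert np.allclose(pred, 100.0 * truth / ref, rtol=1e-6)


class TestCoefficientReport:
    def test_zero_coefficient_reports_one(self):
        model = pwm.PWMModel(order=1, intercept=0.0,
                             mono=np.zeros((N_POS, 4)))
        report, intercept = pwm.coefficient_report(model)
        assert (report.to_numpy() == 1.0).all()
        assert intercept == 1.0

    def test_product_identity_order1(self, truth_mono):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_mono), order=1)
        report, intercept = pwm.coefficient_report(fit)
        ctx = "GCCACCAUGGG"
        product = intercept
        for pos in tis_space.VARIABLE_POSITIONS:
            base = ctx[tis_space.POSITION_OFFSETS[pos]]
            product *= report.loc[base, f"{pos:+d}"]
        assert product == pytest.approx(fit.efficiency(ctx), rel=1e-9)

    def test_geometric_mean_per_position_is_one(self, truth_mono):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_mono), order=1)
        report, _ = pwm.coefficient_report(fit)
        gm = np.exp(np.log(report.to_numpy()).mean(axis=0))
        assert np.allclose(gm, 1.0, atol=1e-9)


class TestReferenceTable:
    def test_covers_space_and_flags_extrapolation(self, truth_mono):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_mono), order=1)
        table = pwm.build_reference_table(fit)
        assert len(table) == tis_space.SPACE_SIZE
        assert (table["efficiency"] > 0).all()
        n_extrap = int((table["flag"] == "extrapolated").sum())
        assert n_extrap == int(tis_space.space_upstream_aug_mask().sum())

    def test_deterministic(self, truth_mono):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_mono), order=1)
        assert pwm.build_reference_table(fit).equals(
            pwm.build_reference_table(fit)
        )

    def test_lookup_backend_matches_model(self, truth_mono):
        fit = pwm.fit_pwm(truth_efficiency_table(truth_mono), order=1)
        lookup = pwm.EfficiencyLookup(pwm.build_reference_table(fit))
        for ctx in ("GCCACCAUGGG", "UAGCUCAUGCU", "AAAAAAAUGAA"):
            assert lookup.efficiency(ctx) == pytest.approx(
                fit.efficiency(ctx), rel=1e-12
            )


class TestModelOrderComparison:
    def test_heldout_r2_ordering(self, truth_pairwise):
        """With pairwise truth and measurement noise, the pairwise PWM beats
        the mononucleotide PWM out of sample, and the trinucleotide PWM
        (fitting absent higher-order structure) does not beat the pairwise
        one."""
        rng = np.random.default_rng(77)
        table = truth_efficiency_table(truth_pairwise).copy()
        table["efficiency"] *= np.exp(
            rng.normal(0.0, 0.25, size=len(table))
        )
        idx = rng.permutation(len(table))
        train = table.iloc[idx[:20_000]]
        test = table.iloc[idx[20_000:25_000]]
        test_digits = tis_space.contexts_to_digits(test["tis"])
        y = np.log(test["efficiency"].to_numpy())
        r2 = {}
        for order in (1, 2, 3):
            fit = pwm.fit_pwm(train, order=order)
            pred = fit.ln_predict_digits(test_digits)
            r2[order] = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2[2] > r2[1]
        assert r2[2] >= r2[3]
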