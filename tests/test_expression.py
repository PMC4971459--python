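"""Delta-delta-Ct quantification, tau, responsiveness and viability."""

import numpy as np
import pandas as pd
import pytest

from e3screen.expression import (
    SELECTIVE,
    SPECIFIC,
    UBIQUITOUS,
    delta_delta_ct,
    responsiveness,
    tissue_profile,
    viability,
)
from e3screen.synthetic import CtEffect, make_ct_table


def ct_table(rows):
    """rows: (sample, gene, ct) triplets, replicate numbering automatic."""
    recs = []
    counts = {}
    for sample, gene, ct in rows:
        counts[(sample, gene)] = counts.get((sample, gene), 0) + 1
        recs.append((sample, gene, counts[(sample, gene)], float(ct)))
    return pd.DataFrame(recs, columns=["sample", "gene", "replicate", "ct"])


class TestDeltaDeltaCt:
    def test_identical_dct_gives_fold_one(self):
        table = ct_table([
            ("cal", "T", 25), ("cal", "R", 20),
            ("s1", "T", 30), ("s1", "R", 25),
        ])
        folds = delta_delta_ct(table, "T", "R", "cal")
        assert folds["s1"].fold == pytest.approx(1.0)
        assert folds["cal"].fold == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "ddct,expected", [(-1.0, 2.0), (2.0, 0.25), (0.0, 1.0)]
    )
    def test_closed_form(self, ddct, expected):
        table = ct_table([
            ("cal", "T", 25), ("cal", "R", 20),
            ("s1", "T", 25 + ddct), ("s1", "R", 20),
        ])
        assert delta_delta_ct(table, "T", "R", "cal")["s1"].fold == pytest.approx(
            expected
        )

    def test_replicates_averaged_before_dct(self):
        table = ct_table([
            ("cal", "T", 24), ("cal", "T", 26), ("cal", "R", 20),
            ("s1", "T", 23), ("s1", "T", 25), ("s1", "R", 20),
        ])
        fc = delta_delta_ct(table, "T", "R", "cal")["s1"]
        assert fc.fold == pytest.approx(2.0)
        assert fc.replicate_folds == pytest.approx((4.0, 1.0))
        assert fc.mean == pytest.approx(2.5)

    def test_missing_reference_is_error(self):
        table = ct_table([("cal", "T", 25), ("cal", "R", 20), ("s1", "T", 25)])
        with pytest.raises(ValueError, match="s1"):
            delta_delta_ct(table, "T", "R", "cal")

    def test_missing_calibrator_is_error(self):
        table = ct_table([("s1", "T", 25), ("s1", "R", 20)])
        with pytest.raises(ValueError, match="cal"):
            delta_delta_ct(table, "T", "R", "cal")

    def test_planted_fold_recovered_within_noise(self):
        effects = [
            CtEffect("g", "control", 0.0, 1.0, 0.1, 4),
            CtEffect("g", "Tg", 6.0, 4.0, 0.1, 4),
        ]
        table, _ = make_ct_table(effects, "R", np.random.default_rng(5))
        fold = delta_delta_ct(table, "g", "R", "control_0h")["Tg_6h"].fold
        assert 3.5 <= fold <= 4.6

    def test_shift_equivariance(self):
        """Adding a constant to every Ct of a sample preserves folds only
        when applied to target and reference alike."""
        base = ct_table([
            ("cal", "T", 25), ("cal", "R", 20),
            ("s1", "T", 24), ("s1", "R", 20),
        ])
        fold0 = delta_delta_ct(base, "T", "R", "cal")["s1"].fold

        both = base.copy()
        both.loc[both["sample"] == "s1", "ct"] += 3.0
        assert delta_delta_ct(both, "T", "R", "cal")["s1"].fold == pytest.approx(fold0)

        target_only = base.copy()
        sel = (target_only["sample"] == "s1") & (target_only["gene"] == "T")
        target_only.loc[sel, "ct"] += 3.0
        shifted = delta_delta_ct(target_only, "T", "R", "cal")["s1"].fold
        assert shifted == pytest.approx(fold0 * 2.0 ** -3)


class TestTissueProfile:
    def test_single_tissue_expression_is_specific(self):
        folds = {f"t{i}": 0.0 for i in range(19)}
        folds["kidney"] = 12.0
        tau, cls = tissue_profile(folds)
        assert tau == pytest.approx(1.0) and cls == SPECIFIC

    def test_uniform_profile_is_ubiquitous(self):
        tau, cls = tissue_profile({f"t{i}": 3.0 for i in range(10)})
        assert tau == pytest.approx(0.0) and cls == UBIQUITOUS

    def test_kidney_dominant_profile_like_rnf183(self):
        rng = np.random.default_rng(9)
        folds = {f"t{i}": float(f) for i, f in enumerate(rng.normal(1.0, 0.1, 19))}
        folds["kidney"] = 50.0
        tau, cls = tissue_profile(folds)
        assert cls == SPECIFIC

    def test_limited_tissues_are_selective(self):
        folds = {f"t{i}": 0.2 for i in range(17)}
        folds.update({"brain": 10.0, "spine": 10.0, "nerve": 8.0})
        _, cls = tissue_profile(folds)
        assert cls == SELECTIVE

    def test_too_few_tissues_or_all_zero_error(self):
        with pytest.raises(ValueError):
            tissue_profile({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            tissue_profile({f"t{i}": 0.0 for i in range(6)})

    @pytest.mark.parametrize("seed", range(20))
    def test_concentration_monotonicity(self, seed):
        """Moving expression mass from a minor tissue onto the dominant
        one never decreases tau."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 5.0, size=12)
        folds = {f"t{i}": float(v) for i, v in enumerate(values)}
        tau0, _ = tissue_profile(folds)
        i_max = max(folds, key=folds.get)
        i_min = min(folds, key=folds.get)
        delta = folds[i_min] * 0.5
        folds[i_min] -= delta
        folds[i_max] += delta
        tau1, _ = tissue_profile(folds)
        assert tau1 >= tau0 - 1e-12


def stress_effects(peaks, sd=0.1, n=4, conditions=("Tg", "Tm")):
    effects = [CtEffect(g, "control", 0.0, 1.0, sd, n) for g in peaks]
    for cond in conditions:
        for gene, fold in peaks.items():
            effects.append(CtEffect(gene, cond, 6.0, fold, sd, n))
            effects.append(CtEffect(gene, cond, 24.0, 1.0, sd, n))
    return effects


class TestResponsiveness:
    def test_planted_two_fold_induction_is_responsive(self):
        table, _ = make_ct_table(
            stress_effects({"RNFT1": 2.0}), "GAPDH", np.random.default_rng(5)
        )
        (call,) = responsiveness(table, ["RNFT1"], "GAPDH")
        assert call.responsive
        for cond in ("Tg", "Tm"):
            fold6, p6 = call.per_condition[cond][6.0]
            assert fold6 > 1.5 and p6 < 0.05

    def test_single_condition_induction_is_not_responsive(self):
        effects = [CtEffect("g", "control", 0.0, 1.0, 0.1, 4)]
        effects += [CtEffect("g", "Tg", 6.0, 2.0, 0.1, 4)]
        effects += [CtEffect("g", "Tm", 6.0, 1.0, 0.1, 4)]
        table, _ = make_ct_table(effects, "GAPDH", np.random.default_rng(2))
        (call,) = responsiveness(table, ["g"], "GAPDH")
        assert not call.responsive

    def test_downregulation_is_not_responsive(self):
        table, _ = make_ct_table(
            stress_effects({"g": 0.25}), "GAPDH", np.random.default_rng(3)
        )
        (call,) = responsiveness(table, ["g"], "GAPDH")
        assert not call.responsive

    def test_fewer_than_three_replicates_rejected(self):
        table, _ = make_ct_table(
            stress_effects({"g": 2.0}, n=2), "GAPDH", np.random.default_rng(1)
        )
        with pytest.raises(ValueError, match="replicates"):
            responsiveness(table, ["g"], "GAPDH")

    def test_zero_variance_handled_as_exact_limit_with_warning(self):
        table, _ = make_ct_table(
            stress_effects({"g": 2.0}, sd=0.0), "GAPDH", np.random.default_rng(1)
        )
        with pytest.warns(RuntimeWarning):
            (call,) = responsiveness(table, ["g"], "GAPDH")
        assert call.responsive

    def test_null_type_one_error_controlled(self):
        """With no true effect the both-stressor requirement keeps the
        false 'responsive' rate well under alpha (200 replications here;
        the full 1000-replication bound runs in the acceptance suite)."""
        false_calls = 0
        n_rep = 200
        for seed in range(n_rep):
            table, _ = make_ct_table(
                stress_effects({"g": 1.0}, sd=0.2),
                "GAPDH",
                np.random.default_rng(10_000 + seed),
            )
            (call,) = responsiveness(table, ["g"], "GAPDH")
            false_calls += call.responsive
        assert false_calls / n_rep <= 0.05


class TestViability:
    def test_ratio_of_one_when_equal(self):
        assert viability(0.6, 0.6) == pytest.approx(1.0)

    def test_fold_over_mock(self):
        assert viability(0.3, 0.6, mock_ratio=0.5) == pytest.approx(1.0)

    def test_mapping_input(self):
        out = viability({"w1": 0.3, "w2": 0.6}, 0.6)
        assert out == {"w1": pytest.approx(0.5), "w2": pytest.approx(1.0)}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"od": -0.1, "vehicle_od": 0.5},
            {"od": 0.3, "vehicle_od": 0.0},
            {"od": 0.3, "vehicle_od": 0.6, "mock_ratio": 0.0},
        ],
    )
    def test_degenerate_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            viability(**kwargs)
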