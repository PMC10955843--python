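"""Young/old transfer grid and the 2x2 within-subject ANOVA."""

import numpy as np
import pandas as pd
import pytest

import qcla
from qcla.transfer_experiment import repeated_anova_2x2, run_transfer, summarize_fig3


def wide_frame(cube):
    """subjects x (age, condition) frame from an (n, 2, 2) array."""
    n = cube.shape[0]
    cols = pd.MultiIndex.from_product([["old", "young"], ["opposite", "same"]])
    data = cube.reshape(n, 4)
    idx = pd.MultiIndex.from_arrays([[f"q{i}" for i in range(n)], ["phq9"] * n])
    return pd.DataFrame(data, columns=cols, index=idx)


def anova_oracle(cube):
    """Hand-computed sums of squares for a 2x2 within-subject design."""
    n = cube.shape[0]
    g = cube.mean()
    S = cube.mean(axis=(1, 2))
    A = cube.mean(axis=(0, 2))
    B = cube.mean(axis=(0, 1))
    AB = cube.mean(axis=0)
    ss_a = 2 * n * ((A - g) ** 2).sum()
    ss_b = 2 * n * ((B - g) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + g) ** 2).sum()
    SA = cube.mean(axis=2)
    SB = cube.mean(axis=1)
    ss_ae = 2 * ((SA - S[:, None] - A[None, :] + g) ** 2).sum()
    ss_be = 2 * ((SB - S[:, None] - B[None, :] + g) ** 2).sum()
    resid = (cube - SA[:, :, None] - SB[:, None, :] - AB[None] +
             S[:, None, None] + A[None, :, None] + B[None, None, :] - g)
    ss_abe = (resid**2).sum()
    df = n - 1
    return {
        "age": ss_a / (ss_ae / df),
        "condition": ss_b / (ss_be / df),
        "age:condition": ss_ab / (ss_abe / df),
    }


class TestRepeatedAnova:
    def test_matches_hand_computed_fixture(self):
        # 4 subjects x 2 x 2, values chosen by hand
        cube = np.array([
            [[4.0, 6.0], [5.0, 9.0]],
            [[3.0, 5.0], [4.0, 8.0]],
            [[6.0, 7.0], [5.0, 10.0]],
            [[5.0, 8.0], [6.0, 11.0]],
        ])
        res = repeated_anova_2x2(wide_frame(cube))
        oracle = anova_oracle(cube)
        for effect in ("age", "condition", "age:condition"):
            assert res.F(effect) == pytest.approx(oracle[effect], abs=1e-10)
        assert res.effects.loc["age", "df_error"] == 3

    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        cube = rng.standard_normal((12, 2, 2))
        res = repeated_anova_2x2(wide_frame(cube))
        long = []
        for s in range(12):
            for i, a in enumerate(["old", "young"]):
                for j, b in enumerate(["opposite", "same"]):
                    long.append(dict(subject=s, age=a, cond=b, y=cube[s, i, j]))
        table = pg.rm_anova(
            data=pd.DataFrame(long), dv="y", within=["age", "cond"], subject="subject"
        ).set_index("Source")
        assert res.F("age") == pytest.approx(table.loc["age", "F"], rel=1e-6)
        assert res.F("condition") == pytest.approx(table.loc["cond", "F"], rel=1e-6)
        assert res.F("age:condition") == pytest.approx(table.loc["age * cond", "F"], rel=1e-6)
        assert res.p("age:condition") == pytest.approx(table.loc["age * cond", "p_unc"], rel=1e-6)

    def test_identical_cells_give_zero_f(self, rng):
        base = rng.standard_normal(10)
        cube = np.repeat(base, 4).reshape(10, 2, 2)
        res = repeated_anova_2x2(wide_frame(cube))
        for effect in ("age", "condition", "age:condition"):
            assert res.F(effect) == 0.0
            assert res.p(effect) == 1.0

    def test_ss_decomposition(self, rng):
        cube = rng.standard_normal((25, 2, 2)) * 3 + 1
        res = repeated_anova_2x2(wide_frame(cube))
        parts = res.ss_subjects + res.effects["SS"].sum() + res.effects["SS_error"].sum()
        assert parts == pytest.approx(res.ss_total, abs=1e-8)

    def test_unbalanced_design_rejected(self, rng):
        frame = wide_frame(rng.standard_normal((6, 2, 2)))
        frame.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="unbalanced"):
            repeated_anova_2x2(frame)

    def test_planted_interaction_power(self):
        """An old-specific same-group advantage of the generator's default
        size is detected in nearly every replicate."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            # paired contrast sd = 2*noise = 0.12, so d ~ 0.58: power ~ 0.997
            cube = _simulated_grid(rng, interaction=0.07)
            if repeated_anova_2x2(wide_frame(cube)).p("age:condition") < 0.05:
                hits += 1
        assert hits >= 0.9 * reps

    def test_fisher_z_option_runs(self, rng):
        cube = rng.uniform(-0.5, 0.8, size=(8, 2, 2))
        raw = repeated_anova_2x2(wide_frame(cube))
        z = repeated_anova_2x2(wide_frame(cube), fisher_z=True)
        assert np.isfinite(z.F("age:condition"))
        assert z.F("age") != raw.F("age")


def _simulated_grid(rng, interaction=0.0, age_effect=0.0, noise=0.06, n=68):
    """Per-model r values: subject heterogeneity + optional planted effects.

    ``interaction`` is an old-group same-vs-opposite advantage (the young
    cells are unaffected), the qualitative structure of the transfer
    experiment.
    """
    subj = 0.2 + 0.1 * rng.standard_normal(n)
    cube = np.empty((n, 2, 2))
    for i, age in enumerate(("old", "young")):
        for j, cond in enumerate(("opposite", "same")):
            mu = subj + (age_effect if age == "old" else 0)
            if age == "old" and cond == "same":
                mu = mu + interaction
            cube[:, i, j] = mu + noise * rng.standard_normal(n)
    return cube


class TestTransferNull:
    def test_null_interaction_rejection_rate_nominal(self):
        reps, hits = 300, 0
        for seed in range(reps):
            rng = np.random.default_rng(5000 + seed)
            cube = _simulated_grid(rng)
            if repeated_anova_2x2(wide_frame(cube)).p("age:condition") < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.08


@pytest.fixture(scope="module")
def small_transfer():
    """A scaled-down transfer run: both groups share vocabulary channels but
    carry group-specific trait expression (distinct planted mappings)."""
    config = qcla.GeneratorConfig(
        n_participants=600,
        shared_trait_loading=0.0,
        expressiveness_young=3.0,
        expressiveness_old=3.0,
        marker_rate=0.5,
        control_failure_rate=0.0,
    )
    cohort, truth = qcla.generate_cohort(config, seed=33)
    tokens = qcla.generate_reference_corpus(config, seed=34)
    space = qcla.build_space(tokens, d=120)
    split = qcla.median_split(cohort, "median")
    result = run_transfer(cohort, space, split, seed=35, grid=[8, 16])
    return result


class TestRunTransfer:
    def test_design_balance(self, small_transfer):
        counts = small_transfer.table.groupby(["question", "scale"]).size()
        assert (counts == 4).all()
        assert len(small_transfer.model_keys()) + len(small_transfer.dropped_keys) == 68

    def test_distinct_mappings_favor_same_group(self, small_transfer):
        """With trait expression flowing only through group-specific marker
        vocabulary, models transfer poorly: the same-group cell beats the
        opposite-group cell for most models."""
        w = small_transfer.wide("r")
        adv = ((w[("old", "same")] > w[("old", "opposite")]).mean()
               + (w[("young", "same")] > w[("young", "opposite")]).mean()) / 2
        assert adv >= 0.6
        summary = summarize_fig3(small_transfer).set_index(["age", "condition"])
        assert summary.loc[("old", "same"), "mean_r"] > summary.loc[("old", "opposite"), "mean_r"]
        assert summary.loc[("young", "same"), "mean_r"] > summary.loc[("young", "opposite"), "mean_r"]

    def test_summary_consistent_with_cells(self, small_transfer):
        summary = summarize_fig3(small_transfer).set_index(["age", "condition"])
        w = small_transfer.wide("r")
        assert summary.loc[("old", "same"), "mean_r"] == pytest.approx(
            float(w[("old", "same")].mean())
        )
        assert int(summary["n_models"].iloc[0]) == len(small_transfer.model_keys())

    def test_shuffled_scale_transfers_nothing(self, kept876, space):
        """Breaking the word-scale link (permuting one scale's values across
        participants) leaves nothing for the models to find."""
        rng = np.random.default_rng(77)
        records = [qcla.ParticipantRecord(
            id=r.id, age=r.age, gender=r.gender,
            scale_scores=dict(r.scale_scores), controls_passed=r.controls_passed,
            responses=r.responses,
        ) for r in kept876.records]
        shuffled = rng.permutation([r.scale_scores["phq9"] for r in records])
        for r, v in zip(records, shuffled):
            r.scale_scores["phq9"] = float(v)
        cohort = qcla.CohortTable(records, inventory=kept876.inventory)
        split = qcla.median_split(cohort, "median")
        from qcla.cohort import ALL_TEXTS

        inv = qcla.QuestionInventory(labels=("general",), words_requested={"general": 5})
        result = run_transfer(cohort, space, split, scales=("phq9",), inventory=inv,
                              seed=3, grid=[8])
        assert result.table["r"].abs().max() < 0.15
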