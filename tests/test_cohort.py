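"""Cohort reconstruction: printed margins, raking, sampling, encoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import borvm
from borvm.cohort import (
    AGE_BOUNDS,
    AGE_GROUPS,
    COHORT_COLUMNS,
    RakingError,
    encode_features,
    plant_signal,
    rake_all,
    rake_three_way,
    read_cohort_csv,
    sample_cohort,
    write_cohort_csv,
)


class TestPrintedMargins:
    def test_totals(self, spec):
        assert spec.total == 2518
        assert int(spec.poison_outcome.values.sum()) == spec.total
        assert int(spec.poison_outcome.loc["AlP", "died"]) == 622
        assert spec.poison_outcome.sum(axis=1).tolist() == [1330, 1188]
        assert spec.poison_outcome.sum(axis=0).tolist() == [1836, 682]

    def test_every_margin_sums_to_total(self, spec):
        for table in list(spec.margins_xo.values()) + list(spec.margins_xp.values()):
            assert int(table.values.sum()) == spec.total


def _ipf_oracle(m_xo, m_xp, joint, n_iter=5000):
    """Independent long-run alternating-projection raking, scalar loops."""
    L, P, O = m_xo.shape[0], joint.shape[0], joint.shape[1]
    px = m_xo.sum(axis=1) / joint.sum()
    t = np.array([[[px[l] * joint[p, o] for o in range(O)] for p in range(P)] for l in range(L)])
    for _ in range(n_iter):
        for l in range(L):
            for o in range(O):
                s = sum(t[l, p, o] for p in range(P))
                for p in range(P):
                    t[l, p, o] *= m_xo[l, o] / s
        for l in range(L):
            for p in range(P):
                s = sum(t[l, p, o] for o in range(O))
                for o in range(O):
                    t[l, p, o] *= m_xp[l, p] / s
        for p in range(P):
            for o in range(O):
                s = sum(t[l, p, o] for l in range(L))
                for l in range(L):
                    t[l, p, o] *= joint[p, o] / s
    return t


class TestRaking:
    def test_single_level_degenerates_to_joint(self, spec):
        joint = spec.poison_outcome
        m_xo = pd.DataFrame([joint.sum(axis=0)], index=["only"])
        m_xp = pd.DataFrame([joint.sum(axis=1)], index=["only"])
        table = rake_three_way(m_xo, m_xp, joint)
        np.testing.assert_array_equal(table.counts[0], joint.to_numpy())

    def test_silver_nitrate_outcome_margin_exact(self, spec):
        table = rake_three_way(
            spec.margins_xo["silver_nitrate"],
            spec.margins_xp["silver_nitrate"],
            spec.poison_outcome,
        )
        collapsed = table.collapse("poison")  # levels x outcome
        assert collapsed.tolist() == [[1145, 129], [691, 553]]

    def test_matches_alternating_projection_oracle(self, rng):
        # random compatible 2x2x2 margins built from a random positive table
        base = rng.uniform(1, 20, size=(2, 2, 2))
        m_xo, m_xp, joint = base.sum(axis=1), base.sum(axis=2), base.sum(axis=0)
        table = rake_three_way(
            pd.DataFrame(m_xo, index=["a", "b"]),
            pd.DataFrame(m_xp, index=["a", "b"]),
            pd.DataFrame(joint, index=["p0", "p1"]),
            tol=1e-12,
        )
        oracle = _ipf_oracle(m_xo, m_xp, joint)
        np.testing.assert_allclose(table.raked, oracle, atol=1e-8)

    def test_raked_tables_nonnegative_and_margins_exact(self, spec):
        for name, table in rake_all(spec).items():
            assert (table.raked >= 0).all(), name
            assert (table.counts >= 0).all(), name
            np.testing.assert_array_equal(
                table.collapse("poison"), spec.margins_xo[name].to_numpy()
            )
            np.testing.assert_array_equal(
                table.collapse("outcome"), spec.margins_xp[name].to_numpy()
            )
            np.testing.assert_array_equal(
                table.collapse("predictor"), spec.poison_outcome.to_numpy()
            )

    def test_incompatible_totals_rejected(self, spec):
        bad = spec.margins_xo["sex"] + 1
        with pytest.raises(ValueError, match="incompatible"):
            rake_three_way(bad, spec.margins_xp["sex"], spec.poison_outcome)

    def test_nonpositive_joint_rejected(self, spec):
        joint = spec.poison_outcome.copy()
        # keep the grand total unchanged so the positivity check is what fires
        joint.iloc[0, 1] += joint.iloc[0, 0]
        joint.iloc[0, 0] = 0
        with pytest.raises(ValueError, match="strictly positive"):
            rake_three_way(spec.margins_xo["sex"], spec.margins_xp["sex"], joint)

    def test_nonconvergence_raises_diagnostic(self, spec):
        with pytest.raises(RakingError) as err:
            rake_three_way(
                spec.margins_xo["age_group"],
                spec.margins_xp["age_group"],
                spec.poison_outcome,
                tol=1e-15,
                max_iter=1,
            )
        assert err.value.margin_error > 0


class TestSampleCohort:
    def test_exact_mode_poison_outcome_crosstab(self, exact_cohort):
        ct = pd.crosstab(exact_cohort["outcome"], exact_cohort["poison_type"])
        assert ct.loc["recovered", "AlP"] == 708
        assert ct.loc["recovered", "ZnP"] == 1128
        assert ct.loc["died", "AlP"] == 622
        assert ct.loc["died", "ZnP"] == 60

    def test_sampled_n_zero_empty(self, spec):
        cohort = sample_cohort(spec, mode="sampled", n=0, seed=0)
        assert len(cohort) == 0
        assert list(cohort.columns) == COHORT_COLUMNS

    def test_same_seed_identical(self, spec):
        a = sample_cohort(spec, mode="sampled", n=200, seed=42)
        b = sample_cohort(spec, mode="sampled", n=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, spec):
        a = sample_cohort(spec, mode="sampled", n=200, seed=1)
        b = sample_cohort(spec, mode="sampled", n=200, seed=2)
        assert not a.equals(b)

    def test_unknown_mode_and_negative_n(self, spec):
        with pytest.raises(ValueError, match="unknown mode"):
            sample_cohort(spec, mode="bootstrap")
        with pytest.raises(ValueError, match="non-negative"):
            sample_cohort(spec, mode="sampled", n=-1)

    def test_clinical_flags_track_outcome(self, exact_cohort):
        died = exact_cohort["outcome"] == "died"
        for col in ("blood_pressure", "pulse", "echo"):
            assert (exact_cohort.loc[died, col] == "abnormal").all()
            assert (exact_cohort.loc[~died, col] == "normal").all()

    def test_ages_within_group_bounds(self, exact_cohort):
        for group, (lo, hi) in AGE_BOUNDS.items():
            ages = exact_cohort.loc[exact_cohort["age_group"] == group, "age_years"]
            assert ages.between(lo, hi).all()

    def test_sampled_frequencies_match_raked_probabilities(self, spec):
        """Chi-square goodness of fit of sampled three-way cells, n=50000."""
        n = 50_000
        cohort = sample_cohort(spec, mode="sampled", n=n, seed=9)
        tables = rake_all(spec)
        for name, table in tables.items():
            obs = (
                pd.crosstab(
                    cohort[name], [cohort["poison_type"], cohort["outcome"]]
                )
                .reindex(
                    index=table.levels,
                    columns=pd.MultiIndex.from_product(
                        [table.poison_levels, table.outcome_levels]
                    ),
                    fill_value=0,
                )
                .to_numpy()
                .ravel()
            )
            expected = table.raked.reshape(len(table.levels), -1).ravel() / spec.total * n
            keep = expected > 0
            _, p = stats.chisquare(obs[keep], expected[keep] * obs[keep].sum() / expected[keep].sum())
            assert p > 0.001, name

    def test_cosmetic_fields_exact_counts(self, spec):
        cohort = sample_cohort(spec, mode="exact", seed=0, include_cosmetic=True)
        assert (cohort["residence"] == "rural").sum() == 2229
        assert (cohort["occupation"] == "student").sum() == 1324


class TestEncodeFeatures:
    def test_label_and_column_order(self, exact_cohort):
        X, y, names = encode_features(exact_cohort)
        assert names == ["age", "sex", "poison_type", "silver_nitrate", "cholinesterase", "mode"]
        assert y.sum() == 682
        died = exact_cohort["outcome"].to_numpy() == "died"
        np.testing.assert_array_equal(y.astype(bool), died)

    def test_minmax_bounds(self, exact_cohort):
        X, _, _ = encode_features(exact_cohort, scaling="minmax")
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_zscore_zero_variance_guard(self, exact_cohort):
        frozen = exact_cohort.copy()
        frozen["age_years"] = 30
        frozen["age_group"] = "30-40"
        X, _, _ = encode_features(frozen, scaling="zscore")
        assert (X[:, 0] == 0).all()

    def test_group_encoding(self, exact_cohort):
        X, _, _ = encode_features(exact_cohort, age_encoding="group", scaling="none")
        assert set(np.unique(X[:, 0])) <= set(range(len(AGE_GROUPS)))

    def test_unknown_category_names_record(self, exact_cohort):
        bad = exact_cohort.head(10).copy()
        bad.loc[3, "sex"] = "unknown"
        with pytest.raises(ValueError, match="record 3"):
            encode_features(bad)

    def test_empty_cohort_rejected(self, exact_cohort):
        with pytest.raises(ValueError, match="empty"):
            encode_features(exact_cohort.iloc[:0])


class TestPlantSignal:
    def test_rule_with_zero_noise(self, exact_cohort):
        planted = plant_signal(exact_cohort, noise=0.0, seed=0)
        rule = (planted["silver_nitrate"] == "positive") & (
            planted["cholinesterase"] == "abnormal"
        )
        np.testing.assert_array_equal(planted["outcome"] == "died", rule)

    def test_noise_rate_plausible(self, exact_cohort):
        planted = plant_signal(exact_cohort, noise=0.05, seed=0)
        rule = (planted["silver_nitrate"] == "positive") & (
            planted["cholinesterase"] == "abnormal"
        )
        flip_rate = ((planted["outcome"] == "died") != rule).mean()
        assert 0.02 < flip_rate < 0.08

    def test_clinical_flags_updated(self, exact_cohort):
        planted = plant_signal(exact_cohort, noise=0.05, seed=3)
        died = planted["outcome"] == "died"
        assert (planted.loc[died, "blood_pressure"] == "abnormal").all()
        assert (planted.loc[~died, "echo"] == "normal").all()


def test_csv_round_trip(tmp_path, spec):
    cohort = sample_cohort(spec, mode="sampled", n=100, seed=5)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(cohort, path)
    header = path.read_text().splitlines()[0]
    assert header == ",".join(COHORT_COLUMNS)
    back = read_cohort_csv(path)
    pd.testing.assert_frame_equal(back, cohort)
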