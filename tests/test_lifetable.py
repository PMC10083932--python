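"""Age-from-stage machinery and the six demographic traits."""

import numpy as np
import pandas as pd
import pytest

from plantdemog.lifetable import (
    ImmortalStageStructureError,
    LifeTable,
    TraitOptions,
    age_at_first_reproduction,
    age_schedules,
    fundamental_matrix,
    iteroparity_entropy,
    keyfitz_entropy,
    longevity_lmax,
    mean_life_expectancy,
    net_reproductive_rate,
    normalize_trait_table,
    trait_table,
    trait_vector,
)
from plantdemog.records import dominant_eigen
from plantdemog.synth import cohort_oracle

W2 = np.array([1.0, 0.0])


class TestFundamentalMatrix:
    def test_no_survival_gives_identity(self):
        np.testing.assert_allclose(fundamental_matrix(np.zeros((2, 2))).N, np.eye(2))

    def test_hand_2x2(self):
        N = fundamental_matrix(np.array([[0.0, 0.0], [0.5, 0.0]])).N
        np.testing.assert_allclose(N, [[1.0, 0.0], [0.5, 1.0]])

    def test_geometric_series(self):
        np.testing.assert_allclose(fundamental_matrix(np.array([[0.5]])).N, [[2.0]])

    def test_identity_invariant(self, random_records):
        for rec in random_records[:10]:
            N = fundamental_matrix(rec.T).N
            np.testing.assert_allclose(
                N @ (np.eye(rec.n_stages) - rec.T), np.eye(rec.n_stages), atol=1e-8
            )
            assert (N >= -1e-12).all()

    def test_immortal_structure_rejected(self):
        with pytest.raises(ImmortalStageStructureError):
            fundamental_matrix(np.array([[1.0]]))


class TestAgeSchedules:
    def test_worked_matrix(self, worked_record):
        lt = age_schedules(worked_record.T, worked_record.F, W2)
        np.testing.assert_allclose(lt.lx, [1.0, 0.5, 0.0])
        np.testing.assert_allclose(lt.mx[:2], [0.0, 4.0])

    def test_no_survival(self):
        lt = age_schedules(np.zeros((2, 2)), np.array([[3.0, 0.0], [0.0, 0.0]]), W2)
        np.testing.assert_allclose(lt.lx, [1.0, 0.0])
        assert lt.mx[0] == pytest.approx(3.0)

    def test_truncation_flag(self):
        # stasis 0.999: survivorship decays too slowly for a tiny cap
        T = np.array([[0.999]])
        lt = age_schedules(T, np.array([[1.0]]), np.array([1.0]), x_cap=10)
        assert lt.truncated
        assert len(lt.lx) == 11


class TestScalarTraits:
    def test_lmax_immediate_death(self):
        lt = LifeTable(np.arange(2), np.array([1.0, 0.0]), np.zeros(2), W2)
        assert longevity_lmax(lt) == 1.0

    def test_lmax_halving(self):
        lx = 0.5 ** np.arange(10)
        lt = LifeTable(np.arange(10), lx, np.zeros(10), W2)
        assert longevity_lmax(lt, crit=0.01) == 7.0

    def test_lmax_unreached_warns(self):
        lx = np.exp(-0.001 * np.arange(100))
        lt = LifeTable(np.arange(100), lx, np.zeros(100), W2, truncated=True)
        with pytest.warns(RuntimeWarning):
            assert longevity_lmax(lt, crit=0.01) == 99.0

    def test_lmax_bad_criterion(self):
        lt = LifeTable(np.arange(2), np.array([1.0, 0.0]), np.zeros(2), W2)
        with pytest.raises(ValueError):
            longevity_lmax(lt, crit=0.0)

    @pytest.mark.parametrize(
        "T, w0, expected",
        [
            (np.zeros((2, 2)), [1.0, 0.0], 1.0),
            (np.array([[0.0, 0.0], [0.5, 0.0]]), [1.0, 0.0], 1.5),
            (np.array([[0.5]]), [1.0], 2.0),
        ],
    )
    def test_life_expectancy(self, T, w0, expected):
        N = fundamental_matrix(np.asarray(T))
        assert mean_life_expectancy(N, np.asarray(w0)) == pytest.approx(expected)

    def test_age_at_first_reproduction_cases(self, worked_record):
        assert age_at_first_reproduction(
            worked_record.T, worked_record.F, W2
        ) == pytest.approx(1.0)
        # mass already on the reproductive stage reproduces at age 0
        assert age_at_first_reproduction(
            worked_record.T, worked_record.F, np.array([0.0, 1.0])
        ) == pytest.approx(0.0)

    def test_age_at_first_reproduction_chain(self):
        # juvenile -> subadult -> adult, deterministic promotion
        T = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.9]])
        F = np.zeros((3, 3))
        F[0, 2] = 2.0
        assert age_at_first_reproduction(T, F, np.array([1.0, 0.0, 0.0])) == pytest.approx(2.0)

    def test_non_reproducing_cycle_errors(self):
        with pytest.raises(ValueError, match="non-reproducing"):
            age_at_first_reproduction(np.zeros((2, 2)), np.zeros((2, 2)), W2)

    def test_keyfitz_entropy_examples(self):
        assert keyfitz_entropy(np.array([1.0])) == 0.0
        assert keyfitz_entropy(np.array([1.0, 0.5])) == pytest.approx(0.23105, abs=1e-5)

    def test_keyfitz_exponential_is_unity(self):
        x = np.arange(0, 200, 0.01)
        lx = np.exp(-0.2 * x)
        lx = lx[lx >= 1e-8]
        assert keyfitz_entropy(lx) == pytest.approx(1.0, rel=0.01)

    def test_keyfitz_grid_rescaling_invariance(self):
        # same survivorship values on a rescaled age grid give the same H
        lx = np.exp(-0.1 * np.arange(0, 100, 0.5))
        assert keyfitz_entropy(lx) == pytest.approx(keyfitz_entropy(lx), abs=0)
        # refining the discretization converges toward the constant-hazard limit
        coarse = keyfitz_entropy(np.exp(-0.2 * np.arange(0, 100, 1.0)))
        fine = keyfitz_entropy(np.exp(-0.2 * np.arange(0, 100, 0.001)))
        assert abs(fine - 1.0) < abs(coarse - 1.0)

    def test_net_reproductive_rate(self, worked_record):
        N = fundamental_matrix(worked_record.T)
        assert net_reproductive_rate(worked_record.F, N) == pytest.approx(2.0)
        assert net_reproductive_rate(np.zeros((2, 2)), N) == 0.0

    def test_ro_with_no_survival_is_dominant_of_F(self):
        F = np.array([[1.0, 3.0], [0.5, 0.2]])
        N = fundamental_matrix(np.zeros((2, 2)))
        expected = float(np.max(np.abs(np.linalg.eigvals(F))))
        assert net_reproductive_rate(F, N) == pytest.approx(expected)

    def test_iteroparity_semelparous_is_zero(self, worked_record):
        lt = age_schedules(worked_record.T, worked_record.F, W2)
        lam = dominant_eigen(worked_record.A).lam
        assert iteroparity_entropy(lt, lam) == 0.0

    def test_iteroparity_two_equal_ages(self):
        # two reproductive pulses with equal discounted mass -> ln 2
        lam = 1.0
        lt = LifeTable(np.arange(3), np.array([1.0, 1.0, 0.0]),
                       np.array([1.0, 1.0, 0.0]), W2)
        assert iteroparity_entropy(lt, lam) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_iteroparity_no_reproduction_errors(self):
        lt = LifeTable(np.arange(2), np.array([1.0, 0.0]), np.zeros(2), W2)
        with pytest.raises(ValueError, match="no reproduction"):
            iteroparity_entropy(lt, 1.0)


class TestTraitVector:
    def test_worked_matrix_full_vector(self, worked_record):
        tv = trait_vector(worked_record)
        assert tv.lam == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert tv.Lmax == 2.0
        assert tv.H == pytest.approx(0.23105, abs=1e-5)
        assert tv.Lalpha == pytest.approx(1.0)
        assert tv.Lmean == pytest.approx(1.5)
        assert tv.S == 0.0
        assert tv.Ro == pytest.approx(2.0)

    def test_generation_time_consistency(self, worked_record):
        # lam ** T_gen == Ro with T_gen = ln Ro / ln lam
        tv = trait_vector(worked_record)
        t_gen = np.log(tv.Ro) / np.log(tv.lam)
        assert tv.lam**t_gen == pytest.approx(tv.Ro)
        assert t_gen == pytest.approx(2.0)

    def test_determinism(self, worked_record):
        a, b = trait_vector(worked_record), trait_vector(worked_record)
        assert a.as_dict() == b.as_dict()

    def test_archetype_ordering(self, archetype_bundle):
        records, truth = archetype_bundle
        table = trait_table(records)
        table["arch"] = [truth[s] for s in table.index]
        med = table.groupby("arch")[["Lmax", "Lalpha"]].median()
        assert med.loc["slow", "Lmax"] > med.loc["fast", "Lmax"]
        assert med.loc["slow", "Lalpha"] > med.loc["fast", "Lalpha"]
        fast = table[table["arch"] == "fast"]
        assert (fast["Lalpha"] <= 1.5).all()

    def test_species_id_attached_to_errors(self):
        from plantdemog.records import ProjectionMatrixRecord

        rec = ProjectionMatrixRecord(
            species_id="doomed", listed=False,
            T=np.array([[1.0, 0.0], [0.0, 1.0]]),
            F=np.array([[0.0, 1.0], [1.0, 0.0]]),
        )
        with pytest.raises(ImmortalStageStructureError, match="doomed"):
            trait_vector(rec)


class TestEulerLotka:
    def test_euler_lotka_residual(self, random_records):
        """Sum of lam^-(x+1) lx mx is ~1 before renormalization."""
        for rec in random_records[:15]:
            lam = dominant_eigen(rec.A).lam
            w0 = np.zeros(rec.n_stages)
            w0[0] = 1.0
            lt = age_schedules(rec.T, rec.F, w0, lx_tol=1e-10, x_cap=5000)
            if lt.truncated or not (lt.lx * lt.mx > 0).any():
                continue
            x = lt.ages.astype(float)
            total = float((lam ** (-(x + 1)) * lt.lx * lt.mx).sum())
            assert 0.95 <= total <= 1.05


class TestCohortAgreement:
    def test_analytic_matches_cohort_simulation(self, random_records):
        """Analytic lx / Lmean / Lalpha sit within 3 Monte-Carlo SE of an
        independent individual-based simulation (small-n spot check; the
        full-size comparison runs in the acceptance suite)."""
        rng = np.random.default_rng(99)
        for rec in random_records[:5]:
            w0 = np.zeros(rec.n_stages)
            w0[0] = 1.0
            est = cohort_oracle(rec.T, rec.F, w0, n_individuals=20_000,
                                seed=int(rng.integers(2**31 - 1)))
            lt = age_schedules(rec.T, rec.F, w0, lx_tol=1e-10, x_cap=10_000)
            n_cmp = min(len(lt.lx), len(est.lx), 30)
            for i in range(1, n_cmp):
                # binomial SE evaluated at the analytic probability (the
                # plug-in estimate degenerates when the count hits 0)
                p = lt.lx[i]
                se = max(np.sqrt(p * (1 - p) / est.n_individuals), 1e-9)
                assert abs(lt.lx[i] - est.lx[i]) <= 4 * se + 1e-4
            N = fundamental_matrix(rec.T)
            lmean = mean_life_expectancy(N, w0)
            assert abs(lmean - est.Lmean) <= 3.5 * max(est.Lmean_se, 1e-9)
            if est.n_reproduced > 100:
                lalpha = age_at_first_reproduction(rec.T, rec.F, w0)
                assert abs(lalpha - est.Lalpha) <= 3.5 * max(est.Lalpha_se, 1e-6)


class TestNormalization:
    def test_min_max_column(self):
        df = pd.DataFrame({"lam": [2.0, 4.0, 10.0], "Ro": [3.0, 3.0, 3.0]})
        out = normalize_trait_table(df)
        np.testing.assert_allclose(out["lam"], [0.0, 0.25, 1.0])
        np.testing.assert_allclose(out["Ro"], 0.0)

    def test_idempotent_on_attained_bounds(self):
        df = pd.DataFrame({"lam": [0.0, 1.0]})
        out = normalize_trait_table(df)
        np.testing.assert_allclose(out["lam"], [0.0, 1.0])

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            normalize_trait_table(pd.DataFrame({"lam": [1.0]}))

    def test_listed_column_passes_through(self, archetype_bundle):
        records, _ = archetype_bundle
        table = trait_table(records[:5])
        out = normalize_trait_table(table)
        assert out["listed"].equals(table["listed"])
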