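import numpy as np
import pandas as pd
import pytest

from metabomix.chemmass import CompoundDatabase, get_adduct, mz_from_neutral
from metabomix.ident import (
    ErrorMixtureModel,
    assign_identifications,
    compute_posteriors,
    fit_error_mixture,
    match_candidates,
)

from conftest import make_peak_table, matches_from_errors


def _db(masses, formulas=None, ids=None, standards=None):
    n = len(masses)
    return CompoundDatabase.from_frame(
        pd.DataFrame(
            {
                "compound_id": ids or [f"C{i}" for i in range(n)],
                "formula": formulas or [f"C{i+1}H2O2" for i in range(n)],
                "neutral_mass": masses,
                "is_standard": standards or [False] * n,
            }
        )
    )


def _peak_at(neutral_mass):
    mz = mz_from_neutral(neutral_mass, get_adduct("[M+H]+"))
    return make_peak_table([mz], [5.0], [2000], [[1.0]], ["s1"])


class TestMatchCandidates:
    def test_best_and_second_best_ppm(self):
        db = _db([132.042259, 132.053000], formulas=["C5H8O4", "C5H9FO3"])
        matches = match_candidates(_peak_at(132.042900), db)
        m = matches[0]
        assert m.best.formula == "C5H8O4"
        assert m.best.ppm_error == pytest.approx(4.85, abs=0.05)
        assert m.second_best.formula == "C5H9FO3"
        assert m.second_best.ppm_error == pytest.approx(-76.5, abs=0.1)
        assert abs(m.best.ppm_error) <= abs(m.second_best.ppm_error)

    def test_single_entry_db_has_no_second_best(self):
        db = _db([132.042259])
        m = match_candidates(_peak_at(132.042900), db)[0]
        assert m.best is not None and m.second_best is None
        with pytest.raises(ValueError, match="too few"):
            fit_error_mixture([m], min_matches=1)

    def test_isomers_collapse_to_one_formula_candidate(self):
        db = _db(
            [132.042259, 132.042259, 132.060000],
            formulas=["C5H8O4", "C5H8O4", "C9H10N"],
            ids=["iso-a", "iso-b", "other"],
        )
        m = match_candidates(_peak_at(132.042300), db)[0]
        assert m.best.formula == "C5H8O4"
        assert set(m.best.compound_ids) == {"iso-a", "iso-b"}
        assert m.second_best.formula == "C9H10N"

    def test_best_outside_capture_window_is_dropped(self):
        db = _db([132.042259])
        far = 132.042259 * (1 + 80e-6)  # 80 ppm away
        m = match_candidates(_peak_at(far), db, capture_window_ppm=50.0)[0]
        assert m.best is None
        assert m.second_best is None or m.second_best.formula != ""

    def test_standard_flag_requires_tight_window(self):
        db = _db([132.042259], standards=[True])
        near = match_candidates(_peak_at(132.042259 * (1 + 5e-6)), db)[0]
        far = match_candidates(_peak_at(132.042259 * (1 + 30e-6)), db)[0]
        assert near.is_standard_match
        assert not far.is_standard_match and far.best is not None

    def test_empty_database_is_an_error(self):
        empty = CompoundDatabase(pd.DataFrame(columns=["compound_id", "formula", "neutral_mass",
                                                       "name", "class_label", "is_standard"]))
        with pytest.raises(ValueError, match="empty"):
            match_candidates(_peak_at(132.0), empty)


class TestErrorMixture:
    def _simulate_matches(self, rng, n, pi1, sd=2.0, null_w=50.0):
        k = rng.binomial(n, pi1)
        e_best = np.concatenate([rng.normal(0, sd, k), rng.uniform(-null_w, null_w, n - k)])
        e_second = rng.uniform(70, 3000, n) * rng.choice([-1, 1], n)
        keep = np.abs(e_best) <= np.abs(e_second)
        return matches_from_errors(e_best[keep], e_second[keep])

    def test_recovers_mixing_weight(self):
        rng = np.random.default_rng(11)
        model = fit_error_mixture(self._simulate_matches(rng, 2000, 0.6))
        assert model.pi1 == pytest.approx(0.6, abs=0.05)
        assert model.sigma1 == pytest.approx(2.0, abs=0.4)
        assert model.converged
        assert model.check_normalization()

    def test_all_null_gives_small_pi1(self):
        rng = np.random.default_rng(12)
        model = fit_error_mixture(self._simulate_matches(rng, 2000, 0.0))
        assert model.pi1 < 0.1

    def test_all_true_gives_large_pi1(self):
        rng = np.random.default_rng(13)
        n = 2000
        e_best = rng.normal(0, 1.0, n)
        e_second = rng.uniform(500, 3000, n) * rng.choice([-1, 1], n)
        model = fit_error_mixture(matches_from_errors(e_best, e_second))
        assert model.pi1 > 0.95

    def test_absolute_error_mode_pins_location_at_zero(self):
        rng = np.random.default_rng(21)
        matches = self._simulate_matches(rng, 2000, 0.6)
        model = fit_error_mixture(matches, error_mode="absolute")
        assert model.pi1 == pytest.approx(0.6, abs=0.06)
        assert abs(model.mu1) < 0.2
        with pytest.raises(ValueError, match="error_mode"):
            fit_error_mixture(matches, error_mode="huh")

    def test_degenerate_null_is_an_error(self):
        matches = matches_from_errors(np.zeros(100), np.full(100, 40.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_error_mixture(matches)

    def test_self_consistency_sum_of_posteriors(self):
        """E[sum of posteriors] = pi1 * n for a calibrated mixture."""
        rng = np.random.default_rng(14)
        matches = self._simulate_matches(rng, 3000, 0.6)
        model = fit_error_mixture(matches)
        posts = compute_posteriors(model, matches)
        assert sum(posts.values()) == pytest.approx(model.pi1 * len(posts), rel=0.05)


def _flat_model(pi1, f1_value_at_zero_sigma, f0_level):
    """Model with constant f0 and a Gaussian f1 for closed-form checks."""
    grid = np.linspace(-50, 50, 2001)
    return ErrorMixtureModel(
        pi1=pi1,
        mu1=0.0,
        sigma1=f1_value_at_zero_sigma,
        domain_ppm=50.0,
        grid=grid,
        f0_grid=np.full_like(grid, f0_level),
    )


class TestPosteriors:
    def test_symmetric_densities_give_half(self):
        # pick e where f1(e) equals the flat f0 level: posterior must be 1/2
        f0_level = 0.0997356
        model = _flat_model(0.5, 2.0, f0_level)
        e = 2.0 * np.sqrt(2 * np.log(0.199471 / f0_level))
        assert model.posterior(e) == pytest.approx(0.5, abs=1e-3)

    def test_pi1_zero_gives_zero_everywhere(self):
        model = _flat_model(0.0, 2.0, 0.01)
        assert np.all(model.posterior(np.linspace(-40, 40, 9)) == 0.0)

    def test_hand_computed_posterior(self):
        # pi1=0.7, f1(e)=0.39894 (standard normal at 0), f0(e)=0.05 -> 0.9490
        model = _flat_model(0.7, 1.0, 0.05)
        # sigma=1 truncated over +-50 is numerically the standard normal
        assert model.posterior(0.0) == pytest.approx(0.9490, abs=1e-4)

    def test_oracle_equivalence_closed_form(self):
        """Posterior formula agrees with direct arithmetic on the model's own
        densities to 1e-9."""
        model = _flat_model(0.37, 2.5, 0.013)
        e = np.linspace(-45, 45, 101)
        f1, f0 = model.f1(e), model.f0(e)
        direct = model.pi1 * f1 / (model.pi1 * f1 + (1 - model.pi1) * f0)
        assert np.allclose(model.posterior(e), direct, atol=1e-9)

    def test_posterior_bounds_and_monotonicity_in_f1(self):
        model = _flat_model(0.6, 2.0, 0.01)
        e = np.linspace(-50, 50, 401)
        post = model.posterior(e)
        assert np.all((post >= 0) & (post <= 1))
        # at fixed f0, posterior increases with f1, i.e. decreases with |e|
        half = post[e >= 0]
        assert np.all(np.diff(half) <= 1e-12)

    def test_vanishing_densities_warn_and_return_zero(self):
        model = _flat_model(0.6, 2.0, 0.01)
        assert model.posterior(60.0) == 0.0  # outside the modeled domain


class TestAssignment:
    def _matches_with_posteriors(self, db, posts):
        matches = []
        from metabomix.ident import Candidate, MatchResult

        ft = db.formula_table()
        for i, (formula, post) in enumerate(posts):
            row = ft[ft["formula"] == formula].iloc[0]
            best = Candidate(tuple(row["compound_ids"]), formula, "[M+H]+", 1.0, 100.0, 100.0)
            matches.append(MatchResult(f"P{i}", best, None))
        return matches, {f"P{i}": p for i, (_, p) in enumerate(posts)}

    def test_threshold_and_isomer_rules(self, tiny_db):
        posts = [
            ("C5H8O4", 0.85),   # unique formula -> assigned
            ("C4H8O2", 0.85),   # two isomers -> removed
            ("C6H12O6", 0.79),  # below threshold -> unassigned
            ("C6H12O6", 0.80),  # threshold inclusive -> assigned
        ]
        matches, posteriors = self._matches_with_posteriors(tiny_db, posts)
        idents, summary = assign_identifications(matches, posteriors, tiny_db, threshold=0.8)
        statuses = [i.status for i in idents]
        assert statuses == ["assigned", "ambiguous_isomer_removed", "unassigned", "assigned"]
        assert summary["n_identified"] == 2.0

    def test_standard_gets_full_confidence(self):
        db = _db([132.042259], standards=[True])
        matches = match_candidates(_peak_at(132.042259 * (1 + 3e-6)), db)
        idents, _ = assign_identifications(matches, {}, db)
        assert idents[0].status == "standard"
        assert idents[0].posterior == 1.0

    def test_invalid_threshold(self, tiny_db):
        with pytest.raises(ValueError, match="threshold"):
            assign_identifications([], {}, tiny_db, threshold=1.01)
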