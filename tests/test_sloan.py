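"""Sloan near-neutral model: transition law, occurrence curve, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metaneutral import (
    OtuTable,
    SloanParams,
    classify_species,
    compare_class_proportions,
    fit_sloan,
    predicted_occurrence,
    transition_probabilities,
)
from metaneutral.sloan import transition_stay_direct


class TestTransitionProbabilities:
    def test_hand_example(self):
        # N_T=10, N_i=3, m=0.1, p=0.2:
        # gain = 0.7*(0.1*0.2 + 0.9*3/9), loss = 0.3*(0.1*0.8 + 0.9*7/9)
        p_gain, p_loss, p_stay = transition_probabilities(
            3, SloanParams(10, 0.1), 0.2
        )
        assert p_gain == pytest.approx(0.224)
        assert p_loss == pytest.approx(0.234)
        assert p_stay == pytest.approx(1 - 0.224 - 0.234)

    def test_full_community_cannot_gain(self):
        p_gain, _, _ = transition_probabilities(10, SloanParams(10, 0.3), 0.5)
        assert p_gain == 0.0

    def test_empty_community_cannot_lose(self):
        _, p_loss, _ = transition_probabilities(0, SloanParams(10, 0.3), 0.5)
        assert p_loss == 0.0

    def test_abundance_above_community_size_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            transition_probabilities(11, SloanParams(10, 0.3), 0.5)

    @given(
        n_t=st.integers(2, 5000),
        frac=st.floats(0, 1),
        m=st.floats(1e-6, 1 - 1e-6),
        p=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_probabilities_sum_to_one_and_stay_matches_direct_form(
        self, n_t, frac, m, p
    ):
        n_i = int(round(frac * n_t))
        params = SloanParams(n_t, m)
        p_gain, p_loss, p_stay = transition_probabilities(n_i, params, p)
        assert 0 <= p_gain <= 1 and 0 <= p_loss <= 1 and 0 <= p_stay <= 1
        assert p_gain + p_loss + p_stay == pytest.approx(1.0, abs=1e-12)
        assert p_stay == pytest.approx(
            transition_stay_direct(n_i, params, p), abs=1e-12
        )


class TestPredictedOccurrence:
    def test_symmetric_beta_at_midpoint(self):
        assert predicted_occurrence(0.5, 10.0, 0.5) == pytest.approx(0.5)

    def test_vanishing_detection_limit(self):
        assert predicted_occurrence(0.3, 20.0, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_oracle(self, rng):
        # Beta(2, 18) upper tail beyond 0.01, 1e6 draws
        draws = rng.beta(2.0, 18.0, size=10**6)
        mc = (draws > 0.01).mean()
        se = np.sqrt(mc * (1 - mc) / 10**6)
        assert predicted_occurrence(0.1, 20.0, 0.01) == pytest.approx(mc, abs=3 * se)

    def test_monotone_in_source_frequency(self):
        grid = np.linspace(0.01, 0.99, 50)
        vals = predicted_occurrence(grid, 25.0, 0.02)
        assert np.all(np.diff(vals) >= 0)
        interior = vals < 1 - 1e-9  # strictly increasing until saturation
        assert np.all(np.diff(vals[interior]) > 0)

    def test_degenerate_frequencies_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert predicted_occurrence(0.0, 10.0, 0.1) == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert predicted_occurrence(1.0, 10.0, 0.1) == 1.0


def _tables_from_occurrence(p_source, ntm_true, n_dest, depth=5000, d=None):
    """Source table approximating p_source; destination presence pattern
    placed exactly at the neutral occurrence prediction computed from the
    REALIZED source frequencies, up to the n_dest sample grid."""
    n_taxa = len(p_source)
    d = 1.0 / depth if d is None else d
    src = np.round(np.asarray(p_source) * depth).astype(int)[:, None] * np.ones(
        3, dtype=int
    )
    p_realized = src[:, 0] / src[:, 0].sum()
    pred = predicted_occurrence(p_realized, ntm_true, d)
    dest = np.zeros((n_taxa, n_dest), dtype=int)
    for i in range(n_taxa):
        k = int(round(pred[i] * n_dest))
        dest[i, :k] = 1
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    source = OtuTable(src, taxa, ("a", "b", "c"))
    destination = OtuTable(dest, taxa, tuple(f"d{j}" for j in range(n_dest)))
    return source, destination


class TestFitSloan:
    def test_noiseless_self_consistency(self, rng):
        p_source = np.geomspace(2e-4, 0.05, 60)
        source, dest = _tables_from_occurrence(p_source, 50.0, n_dest=400)
        # hold the detection limit at the value used to build the data
        fit = fit_sloan(source, dest, d=1.0 / 5000)
        assert fit.NTm == pytest.approx(50.0, rel=0.05)
        assert fit.R2 > 0.99

    def test_parameter_recovery_on_synthetic_data(self, rng):
        from metaneutral import sample_local_stationary, sample_metacommunity

        errors = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            meta = sample_metacommunity(40.0, 500, r)
            depth = 10_000
            src = np.column_stack([r.multinomial(depth, meta) for _ in range(20)])
            dst = np.column_stack(
                [sample_local_stationary(meta, 30.0, depth, r) for _ in range(60)]
            )
            taxa = tuple(f"t{i}" for i in range(500))
            fit = fit_sloan(
                OtuTable(src, taxa, tuple(f"s{j}" for j in range(20))),
                OtuTable(dst, taxa, tuple(f"d{j}" for j in range(60))),
            )
            errors.append(abs(fit.NTm / 30.0 - 1))
        assert max(errors) <= 0.15

    def test_too_few_usable_species_rejected(self):
        taxa = ("a", "b", "c")
        src = OtuTable(np.array([[5], [0], [0]]), taxa, ("s",))
        dst = OtuTable(np.ones((3, 3), dtype=int), taxa, ("d1", "d2", "d3"))
        with pytest.raises(ValueError, match="need >= 5"):
            fit_sloan(src, dst)

    def test_source_absent_taxa_unclassifiable(self, rng):
        p_source = np.geomspace(1e-3, 0.05, 30)
        source, dest = _tables_from_occurrence(p_source, 40.0, n_dest=50)
        # zero out one source row but keep it in the destination
        counts = source.counts.copy()
        counts[0] = 0
        dest_counts = dest.counts.copy()
        dest_counts[0, :5] = 1
        source = OtuTable(counts, source.taxon_ids, source.sample_ids)
        dest = OtuTable(dest_counts, dest.taxon_ids, dest.sample_ids)
        fit = fit_sloan(source, dest)
        row = fit.per_species.set_index("taxon").loc["t0"]
        assert row["label"] == "unclassifiable"


class TestClassifySpecies:
    def test_observed_equals_predicted_is_neutral(self):
        pred = np.array([0.2, 0.5, 0.9])
        labels, lower, upper = classify_species(pred, pred.copy(), 30)
        assert list(labels) == ["neutral"] * 3
        assert np.all(lower <= pred) and np.all(pred <= upper)

    def test_strict_exceedance_is_above(self):
        labels, lower, upper = classify_species(
            np.array([0.25]), np.array([1.0]), 12
        )
        assert upper[0] < 1.0 and labels[0] == "above"

    def test_shortfall_is_below(self):
        labels, _, _ = classify_species(np.array([0.9]), np.array([0.05]), 12)
        assert labels[0] == "below"

    def test_shrinking_alpha_nests_toward_neutral(self, rng):
        """Widening the band (alpha -> 0) can only move labels to neutral."""
        pred = rng.random(100)
        obs = rng.integers(0, 11, size=100) / 10
        previous = None
        for alpha in (0.5, 0.05, 1e-4, 1e-12):
            labels, _, _ = classify_species(pred, obs, 10, alpha=alpha)
            flagged = {i for i, lab in enumerate(labels) if lab != "neutral"}
            if previous is not None:
                assert flagged <= previous
            previous = flagged
        assert len(previous) < 100  # the widest band clears most species

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            classify_species(np.array([0.5]), np.array([0.5]), 1)


def _fit_with_counts(neutral, above, below):
    """Minimal SloanFit stand-in carrying only class counts."""
    import pandas as pd

    from metaneutral.sloan import SloanFit

    labels = ["neutral"] * neutral + ["above"] * above + ["below"] * below
    frame = pd.DataFrame(
        {
            "taxon": [f"t{i}" for i in range(len(labels))],
            "p_source": 0.1,
            "observed": 0.5,
            "predicted": 0.5,
            "lower95": 0.4,
            "upper95": 0.6,
            "label": labels,
        }
    )
    return SloanFit(
        m_hat=0.01, NTm=10, N_T=1000, d=1e-3, R2=0.5,
        n_dest_samples=10, alpha=0.05, per_species=frame,
    )


class TestCompareClassProportions:
    def test_identical_counts_give_p_one(self):
        fit = _fit_with_counts(90, 5, 5)
        res = compare_class_proportions(fit, fit)
        assert np.allclose(res["p_value"], 1.0)
        assert np.allclose(res["odds_ratio"], 1.0)

    def test_against_exhaustive_hypergeometric_enumeration(self):
        # 90/10 vs 10/90: two-sided Fisher p from first principles
        fit_a = _fit_with_counts(90, 10, 0)
        fit_b = _fit_with_counts(10, 90, 0)
        res = compare_class_proportions(fit_a, fit_b).set_index("label")
        n, K, drawn = 200, 100, 100  # total, neutral total, size of group A
        probs = np.array([stats.hypergeom.pmf(k, n, K, drawn) for k in range(101)])
        observed_p = probs[90]
        p_exact = probs[probs <= observed_p * (1 + 1e-9)].sum()
        assert res.loc["neutral", "p_value"] == pytest.approx(p_exact, rel=1e-6)

    def test_balanced_odds_ratio_is_one(self):
        fit = _fit_with_counts(50, 50, 0)
        res = compare_class_proportions(fit, fit).set_index("label")
        assert res.loc["neutral", "odds_ratio"] == pytest.approx(1.0)
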