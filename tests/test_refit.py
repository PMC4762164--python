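"""The forward-selection refit algorithm, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar, nnls

from sigrefit.catalog import ContextMatrix
from sigrefit.contexts import CONTEXT_ORDER
from sigrefit.refit import (
    DEFAULT_CONFIG,
    RefitConfig,
    RefitError,
    RefitResult,
    batch_refit,
    filter_candidates,
    forward_step,
    reconstruct,
    results_to_frame,
    seed_signature,
    signature_prevalence,
    which_signatures,
)
from sigrefit.signatures import SignatureSet, subset_signatures
from sigrefit.simulate import synthetic_signature_set


def _profile(df_rows: np.ndarray) -> np.ndarray:
    return np.asarray(df_rows, dtype=float)


def _sse(t, recon):
    d = np.asarray(t) - np.asarray(recon)
    return float(d @ d)


class TestFilterCandidates:
    def _peaked_set(self):
        peaked = np.full(96, 0.75 / 95)
        peaked[0] = 0.25                     # 25% of mass at A[C>A]A
        uniform = np.full(96, 1 / 96)
        return SignatureSet(
            pd.DataFrame([peaked, uniform], index=["Peaked", "Uniform"],
                         columns=list(CONTEXT_ORDER))
        )

    def test_peaked_signature_excluded_when_tumor_lacks_its_context(self):
        S = self._peaked_set()
        t = np.full(96, 1 / 95)
        t[0] = 0.0
        retained, excluded = filter_candidates(t, S, 0.20)
        assert excluded == ["Peaked"]
        assert retained == ["Uniform"]

    def test_uniform_signature_never_excluded(self):
        S = self._peaked_set()
        t = np.zeros(96)
        t[-1] = 1.0
        retained, _ = filter_candidates(t, S, 0.20)
        assert "Uniform" in retained

    def test_strictly_positive_tumor_excludes_nothing(self, sig_set):
        t = np.full(96, 1 / 96)
        retained, excluded = filter_candidates(t, sig_set, 0.20)
        assert retained == sig_set.names
        assert excluded == []

    def test_boundary_is_strict_at_the_threshold(self):
        """Exactly 20% at a zero-mass context is kept; 20.1% is excluded."""
        at = np.full(96, 0.8 / 95)
        at[0] = 0.20
        above = np.full(96, 0.799 / 95)
        above[0] = 0.201
        S = SignatureSet(pd.DataFrame([at, above], index=["At", "Above"],
                                      columns=list(CONTEXT_ORDER)))
        t = np.full(96, 1 / 95)
        t[0] = 0.0
        retained, excluded = filter_candidates(t, S, 0.20)
        assert retained == ["At"]
        assert excluded == ["Above"]


class TestSeedSignature:
    def test_exact_member_is_its_own_seed(self, sig_set):
        for i, name in enumerate(sig_set.names):
            assert seed_signature(sig_set.row(name), sig_set) == i

    def test_matches_brute_force_scan(self, sig_set):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.dirichlet(np.ones(96))
            best = min(range(sig_set.k),
                       key=lambda i: _sse(t, sig_set.values[i]))
            assert seed_signature(t, sig_set) == best

    def test_single_signature_set(self, sig_set):
        one = subset_signatures(sig_set, [sig_set.names[4]])
        assert seed_signature(np.full(96, 1 / 96), one) == 0


class TestForwardStep:
    def test_recovers_exact_member_in_one_step(self, sig_set):
        t = sig_set.row(sig_set.names[0])
        i, wi, sse = forward_step(t, sig_set, np.zeros(sig_set.k))
        assert i == 0
        assert wi == pytest.approx(1.0, abs=1e-12)
        assert sse == pytest.approx(0.0, abs=1e-15)

    def test_closed_form_agrees_with_bounded_numeric_search(self, sig_set):
        """The quadratic minimizer must match a golden-section search to 1e-6."""
        rng = np.random.default_rng(21)
        V = sig_set.values
        for _ in range(25):
            t = rng.dirichlet(np.ones(96))
            w = rng.uniform(0, 0.5, size=sig_set.k)
            i, wi, _ = forward_step(t, sig_set, w)
            others = t - (w @ V - w[i] * V[i])

            def f(x, i=i, others=others):
                return _sse(others, x * V[i])

            numeric = minimize_scalar(f, bounds=(0, 10), method="bounded",
                                      options={"xatol": 1e-10})
            assert wi == pytest.approx(max(0.0, numeric.x), abs=1e-6)

    def test_step_never_increases_sse(self, sig_set):
        rng = np.random.default_rng(3)
        V = sig_set.values
        for _ in range(50):
            t = rng.dirichlet(np.ones(96))
            w = rng.uniform(0, 1, size=sig_set.k)
            before = _sse(t, w @ V)
            i, wi, after = forward_step(t, sig_set, w)
            assert after <= before + 1e-15


class TestWhichSignatures:
    def test_exact_member_recovery_one_hot(self, sig_set):
        for name in sig_set.names:
            r = which_signatures(sig_set.row(name), sig_set)
            assert r.weights[name] >= 0.99
            assert r.unknown == pytest.approx(0.0, abs=1e-6)
            assert r.sse < 1e-10

    def test_disjoint_support_half_half(self, disjoint_sigs):
        t = 0.5 * disjoint_sigs.row("SigA") + 0.5 * disjoint_sigs.row("SigB")
        r = which_signatures(t, disjoint_sigs)
        assert r.weights["SigA"] == pytest.approx(0.5, abs=1e-6)
        assert r.weights["SigB"] == pytest.approx(0.5, abs=1e-6)

    def test_final_sse_within_nnls_oracle_bound(self):
        """Forward selection must reach the NNLS optimum to within 1e-3."""
        for seed in range(30):
            S = synthetic_signature_set(k=8, seed=seed, n_variants=1)
            rng = np.random.default_rng(1000 + seed)
            m = int(rng.integers(1, 5))
            chosen = rng.choice(8, size=m, replace=False)
            while True:
                w = rng.dirichlet(np.ones(m))
                if w.min() >= 0.1:
                    break
            t = w @ S.values[chosen]
            r = which_signatures(t, S)
            _, resid = nnls(S.values.T, t)
            assert r.sse <= resid**2 + 1e-3

    def test_cutoff_boundary_mass_goes_to_unknown(self, disjoint_sigs):
        """A normalized weight of 0.059 is excluded at the 6% cutoff, 0.061 kept."""
        below = 0.941 * disjoint_sigs.row("SigA") + 0.059 * disjoint_sigs.row("SigB")
        r = which_signatures(below, disjoint_sigs)
        assert r.weights["SigB"] == 0.0
        assert r.unknown == pytest.approx(0.059, abs=1e-6)
        above = 0.939 * disjoint_sigs.row("SigA") + 0.061 * disjoint_sigs.row("SigB")
        r = which_signatures(above, disjoint_sigs)
        assert r.weights["SigB"] == pytest.approx(0.061, abs=1e-6)
        assert r.unknown == pytest.approx(0.0, abs=1e-6)

    def test_stopping_threshold_halts_refinement(self, sig_set):
        """A loose relative threshold stops after the seed's first refinements."""
        rng = np.random.default_rng(0)
        w_true = rng.dirichlet(np.ones(sig_set.k))
        t = w_true @ sig_set.values
        coarse = which_signatures(t, sig_set, RefitConfig(error_threshold=0.5))
        fine = which_signatures(t, sig_set, RefitConfig(error_threshold=1e-9))
        assert coarse.iterations < fine.iterations
        assert fine.sse <= coarse.sse

    def test_sse_non_increasing_across_iterations(self, sig_set):
        """Replay the iteration with the public pieces; SSE must be monotone."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            t = rng.dirichlet(np.ones(96))
            retained, _ = filter_candidates(t, sig_set, 0.20)
            S_sub = subset_signatures(sig_set, retained)
            w = np.zeros(S_sub.k)
            w[seed_signature(t, S_sub)] = 1.0
            sse = _sse(t, w @ S_sub.values)
            for _step in range(200):
                i, wi, sse_new = forward_step(t, S_sub, w)
                assert sse_new <= sse + 1e-15
                w[i] = wi
                if sse - sse_new < 1e-12:
                    break
                sse = sse_new

    def test_scale_invariance_of_fraction_input(self, sig_set):
        """Identical fractions from 1e3 or 1e6 mutations refit identically."""
        counts_small = np.zeros(96)
        counts_small[::4] = 40          # 24 contexts x 40 = 960 mutations
        t_small = counts_small / counts_small.sum()
        t_big = (counts_small * 1000) / (counts_small * 1000).sum()
        r1 = which_signatures(t_small, sig_set)
        r2 = which_signatures(t_big, sig_set)
        assert r1.weights == r2.weights

    def test_low_mutation_count_warns(self, sig_set, caplog):
        t = sig_set.row(sig_set.names[0])
        with caplog.at_level("WARNING", logger="sigrefit.refit"):
            which_signatures(t, sig_set, n_mutations=49)
        assert any("49" in rec.message for rec in caplog.records)
        caplog.clear()
        with caplog.at_level("WARNING", logger="sigrefit.refit"):
            which_signatures(t, sig_set, n_mutations=50)
        assert not caplog.records

    def test_profile_not_summing_to_one_rejected(self, sig_set):
        with pytest.raises(RefitError, match="sums to"):
            which_signatures(np.full(96, 0.5 / 96), sig_set)

    def test_empty_candidate_set_is_an_error(self):
        peaked = np.full(96, 0.5 / 95)
        peaked[0] = 0.5
        S = SignatureSet(pd.DataFrame([peaked], index=["OnlyPeaked"],
                                      columns=list(CONTEXT_ORDER)))
        t = np.full(96, 1 / 95)
        t[0] = 0.0
        with pytest.raises(RefitError, match="no candidate"):
            which_signatures(t, S)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_result_contract_on_random_profiles(self, sig_set, seed):
        """Weights >= cutoff or 0; non-negative; weights + unknown sum to 1."""
        t = np.random.default_rng(seed).dirichlet(np.full(96, 0.5))
        try:
            r = which_signatures(t, sig_set)
        except RefitError:
            return                      # empty candidate set is a legal outcome
        values = np.array(list(r.weights.values()))
        assert (values >= 0).all()
        assert all(v == 0.0 or v >= DEFAULT_CONFIG.weight_cutoff for v in values)
        assert values.sum() + r.unknown == pytest.approx(1.0, abs=1e-9)
        assert r.sse == pytest.approx(float(r.residual @ r.residual), abs=1e-12)
        np.testing.assert_allclose(
            r.reconstructed, reconstruct(r.weights, sig_set), atol=1e-12
        )


class TestReconstruct:
    def test_one_hot_returns_the_row(self, sig_set):
        name = sig_set.names[1]
        np.testing.assert_allclose(
            reconstruct({name: 1.0}, sig_set), sig_set.row(name), atol=1e-15
        )

    def test_zero_weights_zero_vector(self, sig_set):
        assert reconstruct({}, sig_set) == pytest.approx(np.zeros(96))

    def test_half_half_is_elementwise_mean(self, sig_set):
        a, b = sig_set.names[:2]
        np.testing.assert_allclose(
            reconstruct({a: 0.5, b: 0.5}, sig_set),
            (sig_set.row(a) + sig_set.row(b)) / 2,
            atol=1e-15,
        )

    def test_unknown_label_rejected(self, sig_set):
        with pytest.raises(KeyError):
            reconstruct({"Nope": 1.0}, sig_set)

    def test_negative_weight_rejected(self, sig_set):
        with pytest.raises(RefitError):
            reconstruct({sig_set.names[0]: -0.1}, sig_set)


class TestBatchRefit:
    def _matrix(self, sig_set, rows: dict[str, np.ndarray]) -> ContextMatrix:
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CONTEXT_ORDER))
        return ContextMatrix(df, mode="fractions")

    def test_single_row_equals_direct_call(self, sig_set):
        t = sig_set.row(sig_set.names[0])
        T = self._matrix(sig_set, {"only": t})
        out = batch_refit(T, sig_set)
        direct = which_signatures(t, sig_set, sample_id="only")
        assert out["only"].weights == direct.weights

    def test_row_permutation_permutes_results(self, sig_set):
        rows = {f"s{i}": sig_set.row(sig_set.names[i]) for i in range(3)}
        T1 = self._matrix(sig_set, rows)
        T2 = self._matrix(sig_set, dict(reversed(list(rows.items()))))
        out1 = batch_refit(T1, sig_set)
        out2 = batch_refit(T2, sig_set)
        for s in rows:
            assert out1[s].weights == out2[s].weights

    def test_pure_tumors_give_prevalence_one_for_used_signatures(self, sig_set):
        used = sig_set.names[:4]
        rows = {f"s{i}": sig_set.row(used[i % 4]) for i in range(20)}
        out = batch_refit(self._matrix(sig_set, rows), sig_set)
        prev = signature_prevalence(out)
        for name in sig_set.names:
            assert prev[name] == (1 / 4 if name in used else 0.0)

    def test_counts_mode_rejected(self, sig_set):
        df = pd.DataFrame(np.ones((1, 96)), index=["s"], columns=list(CONTEXT_ORDER))
        with pytest.raises(RefitError):
            batch_refit(ContextMatrix(df, mode="counts"), sig_set)

    def test_per_sample_failure_does_not_abort_cohort(self):
        peaked = np.full(96, 0.5 / 95)
        peaked[0] = 0.5
        S = SignatureSet(pd.DataFrame([peaked], index=["P"], columns=list(CONTEXT_ORDER)))
        bad = np.full(96, 1 / 95)
        bad[0] = 0.0
        out = batch_refit(
            self._matrix(S, {"good": peaked, "bad": bad}), S
        )
        assert isinstance(out["good"], RefitResult)
        assert isinstance(out["bad"], RefitError)

    def test_results_frame_contains_unknown_and_sse_rows(self, sig_set):
        T = self._matrix(sig_set, {"s": sig_set.row(sig_set.names[0])})
        frame = results_to_frame(batch_refit(T, sig_set))
        kinds = set(frame["signature"])
        assert "unknown" in kinds and "sse" in kinds
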