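import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from btcprof.channels import (
    SBS96_LABELS,
    channel_index,
    channel_label,
    channel_of_substitution,
)
from btcprof.signatures import (
    MutationCatalog,
    SignatureSet,
    attribute_signature,
    build_context_matrix,
    cosine_match,
    cosine_similarity,
    load_reference_catalog,
    nmf_decompose,
    refit_exposures,
    select_rank,
)

from conftest import make_variants


class TestChannelAxis:
    def test_axis_shape_and_extremes(self):
        assert len(SBS96_LABELS) == 96
        assert channel_label(0) == "A[C>A]A"
        assert channel_label(95) == "T[T>G]T"
        assert channel_index("A[C>T]C") == 33

    def test_purine_substitutions_fold_to_pyrimidine_strand(self):
        # G>T in context AGC reverse-complements to C>A in GCT
        assert channel_of_substitution("G", "T", "AGC") == channel_index("G[C>A]T")
        assert channel_of_substitution("C", "T", "ACG") == channel_index("A[C>T]G")

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            channel_of_substitution("C", "T", "AAG")


class TestBuildContextMatrix:
    def test_single_variant(self):
        variants = make_variants([{"sample_id": "A", "context_channel": 33}])
        cat = build_context_matrix(variants)
        assert cat.sample_ids == ["A"]
        assert cat.counts[33, 0] == 1
        assert cat.counts.sum() == 1

    def test_excluded_sample_absent(self):
        variants = make_variants(
            [
                {"sample_id": "A", "context_channel": 1},
                {"sample_id": "H", "context_channel": 2},
            ]
        )
        cat = build_context_matrix(variants, exclude_samples={"H"})
        assert cat.sample_ids == ["A"]

    def test_column_equals_known_histogram(self):
        rng = np.random.default_rng(3)
        channels = rng.integers(0, 96, size=1000)
        variants = make_variants(
            [{"sample_id": "A", "context_channel": int(c)} for c in channels]
        )
        cat = build_context_matrix(variants)
        np.testing.assert_array_equal(cat.counts[:, 0], np.bincount(channels, minlength=96))

    def test_empty_catalog_warns(self):
        variants = make_variants([{"sample_id": "A", "context_channel": None}])
        with pytest.warns(UserWarning, match="empty"):
            build_context_matrix(variants, samples=["A"])


class TestNmf:
    def test_rank_one_exact_recovery(self, toy_reference):
        profile = toy_reference["SBS22"].to_numpy()
        loads = np.array([200, 500, 1000, 80.0])
        V = np.round(np.outer(profile, loads) * 10)
        cat = MutationCatalog(V.astype(int), ["a", "b", "c", "d"])
        fitted = nmf_decompose(cat, 1, seed=0, n_restarts=5)
        assert cosine_similarity(fitted.profiles[:, 0], profile) >= 0.999

    def test_single_sample_profile_is_normalized_column(self):
        rng = np.random.default_rng(1)
        v = rng.integers(0, 50, size=96)
        cat = MutationCatalog(v[:, None], ["only"])
        fitted = nmf_decompose(cat, 1, seed=0, n_restarts=3)
        np.testing.assert_allclose(fitted.profiles[:, 0], v / v.sum(), atol=1e-4)

    def test_fitted_set_invariants(self, planted_catalog):
        catalog, _, _ = planted_catalog
        fitted = nmf_decompose(catalog, 3, seed=1, n_restarts=8, max_iter=300)
        np.testing.assert_allclose(fitted.profiles.sum(axis=0), 1.0, atol=1e-9)
        assert (fitted.exposures >= 0).all()
        assert np.isfinite(fitted.reconstruction_error)

    def test_matches_sklearn_objective(self, planted_catalog):
        """Independent cross-check: our KL multiplicative updates reach an
        objective comparable to scikit-learn's mu/KL solver."""
        from sklearn.decomposition import NMF as SkNMF

        catalog, _, _ = planted_catalog
        V = catalog.counts.astype(float)
        ours = nmf_decompose(catalog, 3, seed=2, n_restarts=8, max_iter=400)
        sk = SkNMF(
            n_components=3, beta_loss="kullback-leibler", solver="mu",
            init="random", random_state=0, max_iter=600, tol=1e-6,
        )
        W = sk.fit_transform(V)
        H = sk.components_
        WH = np.maximum(W @ H, 1e-12)
        mask = V > 0
        sk_obj = float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())
        assert ours.reconstruction_error <= sk_obj * 1.05

    def test_all_zero_catalog_rejected(self):
        cat = MutationCatalog(np.zeros((96, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            nmf_decompose(cat, 1, seed=0)

    def test_invalid_k_rejected(self, planted_catalog):
        catalog, _, _ = planted_catalog
        with pytest.raises(ValueError):
            nmf_decompose(catalog, 0, seed=0)


class TestSelectRank:
    def test_singleton_range(self, planted_catalog):
        catalog, _, _ = planted_catalog
        assert select_rank(catalog, [2], n_restarts=3, seed=0).k == 2

    def test_rank_one_catalog(self, toy_reference):
        profile = toy_reference["SBS1"].to_numpy()
        V = np.round(np.outer(profile, np.full(20, 3000.0)))
        cat = MutationCatalog(V.astype(int), [f"s{i}" for i in range(20)])
        sel = select_rank(cat, [1, 2, 3], n_restarts=4, seed=0)
        assert sel.k == 1

    def test_degenerate_catalog_returns_min(self):
        cat = MutationCatalog(np.zeros((96, 3), dtype=int), ["a", "b", "c"])
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_rank(cat, [2, 3], seed=0).k == 2


class TestCosine:
    def test_identity_match(self, toy_reference):
        profiles = toy_reference[["SBS22"]].to_numpy()
        matches = cosine_match(profiles, toy_reference)
        assert matches[0][0] == "SBS22"
        assert matches[0][1] == pytest.approx(1.0)

    def test_orthogonal_point_masses(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[0], v[1] = 1.0, 1.0
        assert cosine_similarity(u, v) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity(np.zeros(96), np.ones(96))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(0, 10), min_size=4, max_size=4),
        scale=st.floats(0.01, 100),
    )
    def test_symmetric_scale_invariant_bounded(self, data, scale):
        u = np.array(data[:2] + [1.0, 0.0])
        v = np.array(data[2:] + [0.0, 1.0])
        c = cosine_similarity(u, v)
        assert 0.0 <= c <= 1.0
        assert cosine_similarity(v, u) == pytest.approx(c)
        assert cosine_similarity(u * scale, v) == pytest.approx(c, abs=1e-9)


class TestAttribution:
    @staticmethod
    def _signature_set(P, n):
        return SignatureSet(
            profiles=P, exposures=np.zeros((P.shape[1], n)), k=P.shape[1],
            reconstruction_error=0.0, sample_ids=[f"s{i}" for i in range(n)],
        )

    def test_pure_target_sample_is_positive(self, toy_reference):
        P = toy_reference[["SBS1", "SBS22", "SBS40"]].to_numpy()
        rng = np.random.default_rng(0)
        counts = rng.multinomial(200, P[:, 1])[:, None]
        cat = MutationCatalog(counts, ["pure"])
        att = attribute_signature(cat, self._signature_set(P, 1), 1, n_null=200, seed=1)
        assert bool(att["positive"].iloc[0])
        assert att["exposure_fraction"].iloc[0] > 0.8

    def test_positive_iff_q_below_threshold(self, toy_reference):
        P = toy_reference[["SBS1", "SBS22", "SBS40"]].to_numpy()
        rng = np.random.default_rng(1)
        counts = np.column_stack(
            [rng.multinomial(150, P[:, 1]), rng.multinomial(150, P[:, 0])]
        )
        cat = MutationCatalog(counts, ["a", "b"])
        att = attribute_signature(cat, self._signature_set(P, 2), 1, n_null=150, seed=2)
        assert (att["positive"] == (att["q_value"] < 0.05)).all()

    def test_n_null_zero_rejected(self, toy_reference):
        P = toy_reference[["SBS1", "SBS22"]].to_numpy()
        cat = MutationCatalog(np.ones((96, 1), dtype=int), ["a"])
        with pytest.raises(ValueError, match="n_null"):
            attribute_signature(cat, self._signature_set(P, 1), 0, n_null=0, seed=0)

    def test_small_n_null_warns(self, toy_reference):
        P = toy_reference[["SBS1", "SBS22"]].to_numpy()
        cat = MutationCatalog(np.ones((96, 1), dtype=int), ["a"])
        with pytest.warns(UserWarning, match="unstable"):
            attribute_signature(cat, self._signature_set(P, 1), 0, n_null=50, seed=0)


def test_refit_exposures_recovers_mixture(toy_reference):
    P = toy_reference[["SBS1", "SBS22", "SBS40"]].to_numpy()
    true = np.array([0.2, 0.5, 0.3])
    v = 10_000 * (P @ true)
    e = refit_exposures(P, v)
    np.testing.assert_allclose(e / e.sum(), true, atol=0.01)


def test_reference_catalog_loads_and_is_normalized(toy_reference):
    assert list(toy_reference.index) == list(SBS96_LABELS)
    np.testing.assert_allclose(toy_reference.sum(axis=0), 1.0, atol=1e-6)
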