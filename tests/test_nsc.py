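"""Nearest-shrunken-centroid estimator: fit, shrinkage, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import partsig.nsc as nsc


def _random_problem(rng, genes=40, per_class=(8, 10, 6)):
    labels = np.repeat([f"C{i}" for i in range(len(per_class))], per_class)
    x = rng.normal(size=(genes, labels.size))
    return x, labels


class TestFit:
    def test_equal_class_means_give_zero_d(self):
        x = np.array([[1.0, 1.0, 2.0, 2.0, 1.0, 1.0, 2.0, 2.0]])
        labels = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])
        model = nsc.fit(x, labels)
        np.testing.assert_allclose(model.d[0], 0.0, atol=1e-12)

    def test_one_gene_toy_hand_computed(self):
        # class A = {0, 0}, class B = {2, 2}: zero pooled SD, so d is
        # driven entirely by s0; equal class sizes give mirror-image d
        x = np.array([[0.0, 0.0, 2.0, 2.0]])
        labels = np.array(["A", "A", "B", "B"])
        model = nsc.fit(x, labels, s0=0.5)
        m_k = np.sqrt(1 / 2 - 1 / 4)
        expected = (1.0 - 2.0) / (m_k * 0.5)  # (class A mean - grand)/...
        assert model.pooled_sd[0] == 0.0
        assert model.d[0, 0] == pytest.approx(expected, abs=1e-12)
        assert model.d[0, 1] == pytest.approx(-expected, abs=1e-12)

    def test_centroids_match_groupby_loop(self, rng):
        x, labels = _random_problem(rng)
        model = nsc.fit(x, labels)
        for j, c in enumerate(model.classes):
            np.testing.assert_allclose(model.centroids[:, j],
                                       x[:, labels == c].mean(axis=1),
                                       atol=1e-12)
        np.testing.assert_allclose(model.overall_centroid, x.mean(axis=1),
                                   atol=1e-12)

    def test_small_class_rejected(self):
        x = np.ones((3, 4))
        with pytest.raises(ValueError, match="fewer than 2"):
            nsc.fit(x, np.array(["A", "A", "A", "B"]))

    def test_all_zero_variance_rejected(self):
        x = np.ones((3, 6))
        with pytest.raises(ValueError, match="zero within-class variance"):
            nsc.fit(x, np.array(["A"] * 3 + ["B"] * 3))


class TestShrink:
    def test_delta_zero_is_identity(self, rng):
        x, labels = _random_problem(rng)
        model = nsc.shrink(nsc.fit(x, labels), 0.0)
        np.testing.assert_allclose(model.d_shrunk, model.d, atol=1e-12)
        np.testing.assert_allclose(model.shrunk_centroids, model.centroids,
                                   atol=1e-10)

    def test_full_shrinkage_collapses_to_overall(self, rng):
        x, labels = _random_problem(rng)
        fitted = nsc.fit(x, labels)
        model = nsc.shrink(fitted, np.abs(fitted.d).max() + 0.1)
        assert model.n_nonzero_genes == 0
        for j in range(len(model.classes)):
            np.testing.assert_allclose(model.shrunk_centroids[:, j],
                                       model.overall_centroid, atol=1e-10)

    def test_gene_count_monotone_in_delta(self, rng):
        x, labels = _random_problem(rng, genes=100)
        fitted = nsc.fit(x, labels)
        counts = [nsc.shrink(fitted, d).n_nonzero_genes
                  for d in np.linspace(0, np.abs(fitted.d).max(), 15)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_delta_rejected(self, rng):
        x, labels = _random_problem(rng)
        with pytest.raises(ValueError, match="non-negative"):
            nsc.shrink(nsc.fit(x, labels), -0.5)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000),
           delta=st.floats(0.0, 5.0, allow_nan=False,
                           allow_subnormal=False))
    def test_soft_threshold_contracts(self, seed, delta):
        """|d'| <= |d| element-wise, strictly in L1 when delta > 0."""
        rng = np.random.default_rng(seed)
        x, labels = _random_problem(rng, genes=20)
        model = nsc.shrink(nsc.fit(x, labels), delta)
        assert (np.abs(model.d_shrunk) <= np.abs(model.d) + 1e-12).all()
        assert np.array_equal(model.d_shrunk == 0,
                              np.abs(model.d) <= delta)
        if delta > 1e-9 and np.abs(model.d).max() > 0:
            assert np.abs(model.d_shrunk).sum() < np.abs(model.d).sum()


class TestClassify:
    def test_centroid_sample_goes_to_its_class(self, rng):
        x, labels = _random_problem(rng)
        model = nsc.shrink(nsc.fit(x, labels, priors="uniform"), 0.3)
        for j, c in enumerate(model.classes):
            pred, _ = nsc.classify(model, model.shrunk_centroids[:, j])
            assert pred == c

    def test_fully_shrunk_predicts_largest_class(self, rng):
        x, labels = _random_problem(rng, per_class=(4, 20, 6))
        fitted = nsc.fit(x, labels, priors="empirical")
        model = nsc.shrink(fitted, np.abs(fitted.d).max() + 1)
        pred, _ = nsc.classify(model, x)
        assert (pred == "C1").all()

    def test_discriminant_matches_hand_sum(self, rng):
        x = rng.normal(size=(3, 8))
        labels = np.array(["A"] * 4 + ["B"] * 4)
        model = nsc.shrink(nsc.fit(x, labels), 0.2)
        sample = rng.normal(size=3)
        _, scores = nsc.classify(model, sample)
        for j in range(2):
            expected = sum(
                (sample[g] - model.shrunk_centroids[g, j]) ** 2
                / (model.pooled_sd[g] + model.s0) ** 2
                for g in range(3)
            ) - 2 * np.log(model.priors[j])
            assert scores[j] == pytest.approx(expected, abs=1e-12)

    def test_missing_genes_rejected(self, rng):
        x, labels = _random_problem(rng, genes=5)
        model = nsc.shrink(nsc.fit(x, labels), 0.0)
        with pytest.raises(ValueError):
            nsc.classify(model, np.array([1.0, 2.0]))
        bad = np.full(5, np.nan)
        with pytest.raises(ValueError, match="missing"):
            nsc.classify(model, bad)

    def test_equals_plain_nearest_centroid_when_unshrunken(self, rng):
        """delta=0, uniform priors, s0=0 reduces to nearest centroid in
        per-gene standardized space (independent oracle, 20 instances)."""
        for _ in range(20):
            x, labels = _random_problem(rng, genes=15, per_class=(6, 7, 5))
            model = nsc.shrink(nsc.fit(x, labels, priors="uniform", s0=0.0),
                               0.0)
            test = rng.normal(size=(15, 9))
            pred, _ = nsc.classify(model, test)
            # oracle: argmin_k sum_g ((x - mean_gk)/sd_g)^2
            sds = model.pooled_sd
            dists = np.stack([
                (((test - model.centroids[:, [j]]) / sds[:, None]) ** 2
                 ).sum(axis=0)
                for j in range(len(model.classes))
            ])
            np.testing.assert_array_equal(
                pred, model.classes[np.argmin(dists, axis=0)])

    def test_gene_permutation_equivariance(self, rng):
        x, labels = _random_problem(rng, genes=12)
        perm = rng.permutation(12)
        m1 = nsc.shrink(nsc.fit(x, labels), 0.4)
        m2 = nsc.shrink(nsc.fit(x[perm], labels), 0.4)
        np.testing.assert_allclose(m1.d_shrunk[perm], m2.d_shrunk,
                                   atol=1e-12)
        sample = rng.normal(size=12)
        p1, s1 = nsc.classify(m1, sample)
        p2, s2 = nsc.classify(m2, sample[perm])
        assert p1 == p2
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestSignature:
    def test_fully_shrunk_gives_all_background(self, rng):
        x, labels = _random_problem(rng)
        fitted = nsc.fit(x, labels)
        model = nsc.shrink(fitted, np.abs(fitted.d).max() + 1)
        profile = nsc.extract_signature(model)
        assert (profile.categories == nsc.BACKGROUND).all()
        assert all(len(t) == 0 for t in profile.per_class.values())

    def test_requires_shrunken_model(self, rng):
        x, labels = _random_problem(rng)
        with pytest.raises(ValueError, match="shrunken"):
            nsc.extract_signature(nsc.fit(x, labels))

    def test_signature_table_roundtrip(self, rng, tmp_path):
        from partsig import io

        x, labels = _random_problem(rng)
        model = nsc.shrink(nsc.fit(x, labels), 0.5)
        profile = nsc.extract_signature(model)
        io.write_signature(profile, tmp_path / "sig.tsv")
        back = io.read_signature(tmp_path / "sig.tsv")
        assert len(back) == sum(len(t) for t in profile.per_class.values())

    def test_model_bundle_roundtrip(self, rng, tmp_path):
        from partsig import io

        x, labels = _random_problem(rng)
        model = nsc.shrink(nsc.fit(x, labels), 0.5)
        io.save_model(model, tmp_path / "model.json")
        back = io.load_model(tmp_path / "model.json")
        np.testing.assert_allclose(back.d_shrunk, model.d_shrunk, atol=1e-12)
        sample = rng.normal(size=x.shape[0])
        assert nsc.classify(back, sample)[0] == nsc.classify(model, sample)[0]
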