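"""Feature selection and binary gene-pair encoding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmsffpe import (
    FeatureGeneSet,
    align_features,
    encode_gene_pairs,
    log_transform,
    select_feature_genes,
    zscore_by_gene,
)
from cmsffpe.features import pair_ids
from cmsffpe.pipeline import encode_cohort


def brute_force_pairs(z: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Reference double loop over pairs and samples."""
    genes = sorted(genes)
    cols = {}
    for a, b in itertools.combinations(genes, 2):
        cols[f"({a},{b})"] = [
            1 if z.loc[a, s] > z.loc[b, s] else 0 for s in z.columns
        ]
    return pd.DataFrame(cols, index=z.columns)


class TestLogTransform:
    def test_known_points(self, tiny_expr):
        out = log_transform(pd.DataFrame({"s": [0.0, 1.0, 7.0]}, index=list("abc")))
        assert out["s"].tolist() == [0.0, 1.0, 3.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [-0.5]}, index=["a"]))


class TestZscore:
    def test_two_sample_hand_value(self):
        z = zscore_by_gene(pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["g"]))
        assert z.loc["g"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_gene_maps_to_zero(self):
        z = zscore_by_gene(
            pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 9.0]},
                         index=["flat", "var"])
        )
        assert (z.loc["flat"] == 0).all()

    def test_moments(self, rng):
        x = pd.DataFrame(rng.uniform(0, 50, (20, 30)))
        z = zscore_by_gene(x)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_single_sample_refused(self):
        with pytest.raises(ValueError, match="cohort"):
            zscore_by_gene(pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"]))


class TestSelectFeatureGenes:
    def test_strict_threshold(self):
        tins = pd.DataFrame(
            {"s1": [20.0, 25.0], "s2": [20.0, 25.0], "s3": [20.0, 25.0]},
            index=["at20", "above"],
        )
        kept = select_feature_genes(["at20", "above"], tins, threshold=20.0)
        assert list(kept) == ["above"]  # exactly 20 is excluded

    def test_matches_brute_force_filter(self, rng):
        genes = [f"g{i:03d}" for i in range(500)]
        tins = pd.DataFrame(
            rng.uniform(0, 60, size=(500, 7)), index=genes,
            columns=[f"s{j}" for j in range(7)],
        )
        kept = select_feature_genes(genes, tins, threshold=20.0)
        expected = sorted(
            g for g in genes if float(np.median(np.sort(tins.loc[g].to_numpy()))) > 20.0
        )
        assert list(kept) == expected

    def test_absent_candidates_dropped(self, caplog):
        tins = pd.DataFrame({"s1": [50.0], "s2": [50.0]}, index=["known"])
        kept = select_feature_genes(["known", "ghost"], tins)
        assert list(kept) == ["known"]

    def test_threshold_monotonicity(self, rng):
        genes = [f"g{i}" for i in range(100)]
        tins = pd.DataFrame(rng.uniform(0, 50, (100, 5)), index=genes)
        loose = set(select_feature_genes(genes, tins, threshold=10.0))
        tight = set(select_feature_genes(genes, tins, threshold=25.0))
        assert tight <= loose

    def test_empty_result_is_error(self):
        tins = pd.DataFrame({"s1": [5.0], "s2": [5.0]}, index=["g"])
        with pytest.raises(ValueError, match="no candidate gene has median TIN"):
            select_feature_genes(["g"], tins)


class TestEncodeGenePairs:
    def test_pair_count_law(self, rng):
        for m in (2, 3, 10, 17):
            genes = sorted(f"g{i:02d}" for i in range(m))
            z = pd.DataFrame(rng.normal(size=(m, 4)), index=genes,
                             columns=[f"s{j}" for j in range(4)])
            feats = encode_gene_pairs(z, genes)
            assert feats.shape == (4, m * (m - 1) // 2)

    def test_ties_encode_zero(self):
        z = pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 2.0]}, index=["a", "b"])
        feats = encode_gene_pairs(z, ["a", "b"])
        assert feats.loc["s1", "(a,b)"] == 0 and feats.loc["s2", "(a,b)"] == 0

    def test_matches_brute_force(self, rng):
        genes = sorted(f"g{i:02d}" for i in range(10))
        z = pd.DataFrame(rng.normal(size=(10, 20)), index=genes,
                         columns=[f"s{j:02d}" for j in range(20)])
        fast = encode_gene_pairs(z, genes)
        slow = brute_force_pairs(z, genes)
        pd.testing.assert_frame_equal(fast.astype(int), slow.astype(int))

    def test_missing_gene_mentions_align(self, tiny_expr):
        z = zscore_by_gene(tiny_expr)
        with pytest.raises(KeyError, match="align_features"):
            encode_gene_pairs(z, ["g0", "zzz"])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_affine_invariance(self, seed):
        # per-gene strictly increasing affine transforms leave features bit-identical
        rng = np.random.default_rng(seed)
        genes = sorted(f"g{i}" for i in range(6))
        x = pd.DataFrame(rng.uniform(0, 100, (6, 8)), index=genes,
                         columns=[f"s{j}" for j in range(8)])
        a = rng.uniform(0.1, 5.0, size=(6, 1))
        b = rng.uniform(-10, 10, size=(6, 1))
        base = encode_gene_pairs(zscore_by_gene(x), genes)
        warped = encode_gene_pairs(zscore_by_gene(x * a + b), genes)
        assert base.equals(warped)

    def test_sample_permutation_equivariance(self, rng):
        genes = sorted(f"g{i}" for i in range(5))
        x = pd.DataFrame(rng.uniform(0, 10, (5, 12)), index=genes,
                         columns=[f"s{j}" for j in range(12)])
        perm = rng.permutation(x.columns)
        base = encode_gene_pairs(zscore_by_gene(x), genes)
        permuted = encode_gene_pairs(zscore_by_gene(x[perm]), genes)
        pd.testing.assert_frame_equal(permuted, base.loc[perm])


class TestAlignFeatures:
    def test_all_present(self, tiny_expr):
        genes = sorted(tiny_expr.index)
        out, report = align_features(tiny_expr, genes)
        assert list(out.index) == genes and report.missing == ()

    def test_padding_behaviour(self, rng):
        genes = sorted(f"g{i}" for i in range(10))
        x = pd.DataFrame(rng.uniform(1, 50, (9, 6)), index=genes[:9],
                         columns=[f"s{j}" for j in range(6)])
        out, report = align_features(x, genes, max_missing_frac=0.2)
        assert report.missing == ("g9",)
        assert (out.loc["g9"] == 0).all()
        # padded gene z-scores to 0, so pairs against it reduce to 1[z_other > 0]
        feats = encode_gene_pairs(zscore_by_gene(out), genes)
        z8 = zscore_by_gene(out).loc["g8"]
        expected = (z8 > 0.0).astype(int).to_numpy()
        assert (feats["(g8,g9)"].to_numpy() == expected).all()

    def test_too_many_missing(self, rng):
        genes = sorted(f"g{i}" for i in range(10))
        x = pd.DataFrame(rng.uniform(1, 50, (7, 4)), index=genes[:7])
        with pytest.raises(ValueError, match="missing"):
            align_features(x, genes, max_missing_frac=0.2)


class TestFeatureGeneSet:
    def test_must_be_sorted_unique(self):
        with pytest.raises(ValueError):
            FeatureGeneSet(("b", "a"), 20.0, 2)
        with pytest.raises(ValueError):
            FeatureGeneSet(("a", "a"), 20.0, 2)

    def test_pair_ids_order_is_lexicographic(self):
        assert pair_ids(["a", "b", "c"]) == ["(a,b)", "(a,c)", "(b,c)"]


def test_encode_cohort_platform_shift_invariance(small_cohort):
    """The whole cohort path is invariant to per-gene positive scaling of input."""
    genes = sorted(small_cohort.candidate_genes[:12])
    expr = small_cohort.ff_expr
    base = encode_cohort(expr, genes, log=False)
    rng = np.random.default_rng(0)
    scale = pd.Series(rng.uniform(0.5, 3.0, size=expr.shape[0]), index=expr.index)
    warped = encode_cohort(expr.mul(scale, axis=0), genes, log=False)
    assert base.equals(warped)
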