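"""Vote fusion against brute force; distribution and similarity analyses."""

import numpy as np
import pandas as pd
import pytest

from otpred.alphabet import MISMATCH_GROUPS, MISMATCH_TOKENS, PositionConvention, token_index
from otpred.train import SeedRun
from otpred.updatelens import (
    DeltaStack,
    cross_dataset_concordance,
    delta_stack,
    group_similarity_summary,
    pair_similarity,
    position_stats,
    vote_fuse,
)


def brute_force_fuse(deltas):
    """Independent per-cell reference implementation of the voting rules."""
    n, L, W = deltas.shape
    T = np.zeros((L, W), dtype=int)
    fusion = np.zeros((L, W))
    support = np.zeros((L, W), dtype=int)
    for i in range(L):
        for j in range(W):
            t = [1 if deltas[s, i, j] > 0 else -1 for s in range(n)]
            total = sum(t)
            if total >= 1:
                T[i, j] = 1
            elif total <= -1:
                T[i, j] = -1
            else:
                continue
            agreeing = [deltas[s, i, j] for s in range(n) if t[s] == T[i, j]]
            support[i, j] = len(agreeing)
            fusion[i, j] = float(np.mean(agreeing))
    return T, fusion, support


def stack_from(deltas, m_init=None):
    m_init = m_init if m_init is not None else np.zeros(deltas.shape[1:])
    return DeltaStack(deltas=deltas, seeds=tuple(range(1, len(deltas) + 1)), m_init=m_init)


def make_run(seed, m_init, m_update):
    return SeedRun(seed=seed, model=None, m_init=m_init, m_update=m_update)


class TestDeltaStack:
    def test_exact_subtraction(self, rng):
        init = rng.normal(size=(24, 16))
        ups = [init + rng.normal(size=(24, 16)) for _ in range(3)]
        st = delta_stack([make_run(s, init, u) for s, u in enumerate(ups, 1)])
        for d, u in zip(st.deltas, ups):
            np.testing.assert_array_equal(d, u - init)

    def test_mismatched_inits_rejected(self, rng):
        a = rng.normal(size=(24, 16))
        b = a + 1.0
        with pytest.raises(ValueError, match="initial"):
            delta_stack([make_run(1, a, a), make_run(2, b, b)])

    def test_frozen_runs_give_zero_stack(self, rng):
        init = rng.normal(size=(24, 16))
        st = delta_stack([make_run(s, init, init.copy()) for s in (1, 2)])
        assert (st.deltas == 0).all()


class TestVoteFuse:
    def test_hand_worked_cell(self):
        """Across 5 seeds (+0.2, +0.4, +0.6, -0.1, -0.3): majority up."""
        deltas = np.array([0.2, 0.4, 0.6, -0.1, -0.3]).reshape(5, 1, 1)
        fused = vote_fuse(stack_from(deltas))
        assert fused.T[0, 0] == 1
        assert fused.support[0, 0] == 3
        assert fused.delta_fusion[0, 0] == pytest.approx(0.4)

    def test_unanimous_mean(self):
        deltas = np.array([0.1, 0.2, 0.3, 0.4, 0.5]).reshape(5, 1, 1)
        fused = vote_fuse(stack_from(deltas))
        assert fused.support[0, 0] == 5
        assert fused.delta_fusion[0, 0] == pytest.approx(0.3)

    def test_even_tie_yields_no_consensus(self):
        deltas = np.array([0.5, 0.1, -0.2, -0.9]).reshape(4, 1, 1)
        fused = vote_fuse(stack_from(deltas))
        assert fused.T[0, 0] == 0
        assert fused.delta_fusion[0, 0] == 0.0

    def test_zero_delta_counts_as_decrease(self):
        deltas = np.array([0.0, 0.0, 0.4]).reshape(3, 1, 1)
        fused = vote_fuse(stack_from(deltas))
        assert fused.T[0, 0] == -1
        assert fused.delta_fusion[0, 0] == pytest.approx(0.0)

    def test_single_seed_degenerates_to_identity(self, rng):
        init = rng.normal(size=(24, 16))
        up = init + rng.normal(size=(24, 16))
        fused = vote_fuse(delta_stack([make_run(1, init, up)]))
        np.testing.assert_allclose(fused.delta_fusion, up - init)
        np.testing.assert_allclose(fused.m_fusion, up)

    def test_matches_brute_force_on_random_stacks(self, rng):
        """200 random stacks, n in {1, 3, 5}, exact agreement."""
        for _ in range(200):
            n = int(rng.choice([1, 3, 5]))
            deltas = np.round(rng.normal(size=(n, 6, 16)), 2)
            fused = vote_fuse(stack_from(deltas))
            T, fusion, support = brute_force_fuse(deltas)
            np.testing.assert_array_equal(fused.T, T)
            np.testing.assert_array_equal(fused.support, support)
            np.testing.assert_allclose(fused.delta_fusion, fusion, atol=1e-12)

    def test_fusion_within_agreeing_range(self, rng):
        deltas = rng.normal(size=(5, 24, 16))
        fused = vote_fuse(stack_from(deltas))
        agree = np.where(deltas > 0, 1, -1) == fused.T[None]
        lo = np.where(agree, deltas, np.inf).min(axis=0)
        hi = np.where(agree, deltas, -np.inf).max(axis=0)
        ok = fused.T != 0
        assert np.all(fused.delta_fusion[ok] >= lo[ok] - 1e-12)
        assert np.all(fused.delta_fusion[ok] <= hi[ok] + 1e-12)

    def test_m_fusion_identity(self, rng):
        init = rng.normal(size=(24, 16))
        deltas = rng.normal(size=(3, 24, 16))
        fused = vote_fuse(stack_from(deltas, m_init=init))
        np.testing.assert_allclose(fused.m_fusion, init + fused.delta_fusion)


class TestPositionStats:
    def test_constant_embedding_zero_variance(self, conv):
        df = position_stats(np.full((24, 16), 0.7), conv)
        assert df["variance"].abs().max() == pytest.approx(0.0, abs=1e-15)
        assert set(df["bio_pos"]) == set(range(1, 21))
        assert len(df) == 20 * 12

    def test_passthrough_of_table_values(self, conv, mtp_prior):
        df = position_stats(mtp_prior.matrix, conv, stage="origin")
        row = df[(df.bio_pos == 7) & (df.token == "AC")]
        assert row["value"].iloc[0] == pytest.approx(mtp_prior.value(7, "AC"))

    def test_mean_difference_between_constructed_embeddings(self, conv):
        a = np.full((24, 16), 1.0)
        b = np.full((24, 16), 1.0)
        b[conv.row_of_bio(20) - 1, :] = 2.0  # lift position 20
        da = position_stats(a, conv)
        db = position_stats(b, conv)
        mean_a = da[da.bio_pos == 20]["mean"].iloc[0]
        mean_b = db[db.bio_pos == 20]["mean"].iloc[0]
        assert abs(mean_b - mean_a) == pytest.approx(1.0)


class TestPairSimilarity:
    def test_alpha_zero_reduces_to_pearson(self, rng, conv):
        emb = rng.normal(size=(24, 16))
        sim = pair_similarity(emb, conv, region="all", alpha=0.0)
        pd.testing.assert_frame_equal(sim.phi, sim.pearson)

    def test_alpha_one_max_distance_pair_is_zero(self, rng, conv):
        emb = rng.normal(size=(24, 16))
        sim = pair_similarity(emb, conv, region="all", alpha=1.0)
        off = ~np.eye(12, dtype=bool)
        assert np.nanmin(sim.phi.to_numpy()[off]) == pytest.approx(0.0, abs=1e-12)

    def test_identical_vectors_full_similarity(self, conv):
        emb = np.zeros((24, 16))
        values = np.linspace(0.0, 1.0, 20)
        for t in MISMATCH_TOKENS:
            emb[1:21, token_index(t) - 1] = values * (2 if t == "TG" else 1)
        # AC and AG have identical profiles; their distance 0 is the minimum
        emb[:, token_index("AG") - 1] = emb[:, token_index("AC") - 1]
        sim = pair_similarity(emb, conv, region="all", alpha=0.5)
        assert sim.phi.loc["AC", "AG"] == pytest.approx(1.0)

    def test_zero_variance_profile_flagged_nan(self, conv):
        emb = np.zeros((24, 16))
        for t in MISMATCH_TOKENS:
            emb[1:21, token_index(t) - 1] = np.linspace(0, 1, 20)
        emb[:, token_index("CA") - 1] = 0.3  # constant profile
        sim = pair_similarity(emb, conv, region="seed")
        assert np.isnan(sim.phi.loc["CA", "AC"])

    def test_symmetry_and_diagonal(self, rng, conv):
        emb = rng.normal(size=(24, 16))
        sim = pair_similarity(emb, conv, region="nonseed", alpha=0.5)
        phi = sim.phi.to_numpy()
        np.testing.assert_allclose(phi, phi.T, atol=1e-12)
        norm0 = sim.norm_euclid.to_numpy()[np.eye(12, dtype=bool)]
        np.testing.assert_allclose(
            np.diag(phi), 0.5 * 1.0 + 0.5 * (1.0 - norm0), atol=1e-12
        )

    def test_token_permutation_equivariance(self, rng, conv):
        emb = rng.normal(size=(24, 16))
        perm = tuple(reversed(MISMATCH_TOKENS))
        sim_a = pair_similarity(emb, conv, tokens=MISMATCH_TOKENS)
        sim_b = pair_similarity(emb, conv, tokens=perm)
        reindexed = sim_b.phi.loc[list(MISMATCH_TOKENS), list(MISMATCH_TOKENS)]
        np.testing.assert_allclose(sim_a.phi.to_numpy(), reindexed.to_numpy(), atol=1e-12)


class TestGroupSummary:
    def test_counts(self, rng, conv):
        emb = rng.normal(size=(24, 16))
        summary = group_similarity_summary(pair_similarity(emb, conv))
        intra = summary[summary.group_a == summary.group_b]
        inter = summary[summary.group_a != summary.group_b]
        assert len(intra) == 4 and (intra.n_pairs == 3).all()
        assert len(inter) == 6 and (inter.n_pairs == 9).all()

    def test_matches_brute_force_average(self, rng, conv):
        emb = rng.normal(size=(24, 16))
        sim = pair_similarity(emb, conv)
        summary = group_similarity_summary(sim)
        a, b = MISMATCH_GROUPS["rA"], MISMATCH_GROUPS["rC"]
        manual = np.mean([sim.phi.loc[x, y] for x in a for y in b])
        got = summary[(summary.group_a == "rA") & (summary.group_b == "rC")]["mean_phi"]
        assert got.iloc[0] == pytest.approx(manual)


class TestCrossDatasetConcordance:
    @staticmethod
    def _fused(delta):
        from otpred.updatelens import FusedUpdate

        return FusedUpdate(
            T=np.sign(delta).astype(int),
            delta_fusion=delta,
            m_fusion=delta,
            support=np.full(delta.shape, 3),
            n=5,
        )

    def test_identical_updates_fully_concordant(self, rng):
        d = rng.normal(size=(24, 16))
        corr, ranking = cross_dataset_concordance({"a": self._fused(d), "b": self._fused(d.copy())})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert set(ranking.dataset) == {"a", "b"}

    def test_negated_updates_anticorrelated(self, rng):
        d = rng.normal(size=(24, 16))
        corr, _ = cross_dataset_concordance({"a": self._fused(d), "b": self._fused(-d)})
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_planted_ranking_structure(self, rng):
        """Three datasets: two near-identical, one independent; the odd one ranks last."""
        base = rng.normal(size=(24, 16))
        near = base + 0.01 * rng.normal(size=(24, 16))
        indep = rng.normal(size=(24, 16))
        corr, ranking = cross_dataset_concordance(
            {"x": self._fused(base), "y": self._fused(near), "z": self._fused(indep)}
        )
        assert ranking.dataset.iloc[-1] == "z"
        assert corr.loc["x", "y"] > 0.9
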