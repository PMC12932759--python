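"""The recognition network: forward operations, gradients and training.

The batched forward/backward implementation is checked against (a) a pure
loop-based oracle with no vectorization and (b) central finite differences,
so the training code cannot silently drift from the stated architecture.
"""

import math

import numpy as np
import pytest

from neoprecis._aa import AA_INDEX, AA_ORDER, blosum62_matrix, one_hot, random_peptides
from neoprecis.core_motifs import BindingMotif, CorePeptidePair
from neoprecis.immuno_model import (
    STAGE1_TRAINABLE,
    ImmunoModelParams,
    TrainConfig,
    backward_batch,
    binding_covariate,
    component_scores,
    crd,
    embed_residues,
    encode_triplets,
    forward_batch,
    geometric_representation,
    motif_enrich,
    pool_peptide,
    predict,
    train_stage1,
    train_stage2,
    triplet_losses,
)

from conftest import FixedRankPredictor


# --- loop-based oracle (no vectorization, pure python floats) -------------

def oracle_crd(params, wt, mt, motif_rows, mhc_class="I"):
    """Dense-arithmetic re-implementation of the CRD forward pass with
    explicit loops; independent of the einsum path it checks."""
    B = blosum62_matrix().tolist()
    L, d_a, d_p, K = params.L, params.d_a, params.d_p, params.K

    def embed(rows):
        out = []
        for i in range(L):
            z = [sum(rows[i][t] * B[t][d] for t in range(20)) for d in range(20)]
            out.append([
                sum(z[t] * params.embed_w[t][e] for t in range(20)) + params.embed_b[e]
                for e in range(d_a)
            ])
        return out

    def onehot_rows(pep):
        return [[1.0 if AA_ORDER[t] == pep[i] else 0.0 for t in range(20)]
                for i in range(L)]

    E_wt, E_mt = embed(onehot_rows(wt)), embed(onehot_rows(mt))
    E_motif = embed([list(r) for r in motif_rows])

    def enrich(E_pep):
        out = []
        for i in range(L):
            H = []
            for k in range(K):
                Ck_i = [
                    sum(E_motif[i][d] * params.conv[k][d][e] for d in range(d_a))
                    for e in range(d_a)
                ]
                H.append(sum(Ck_i[e] * E_pep[i][e] for e in range(d_a)))
            out.append([sum(params.proj[p][k] * H[k] for k in range(K))
                        for p in range(d_p)])
        return out

    w = params.pos_w(mhc_class)
    def pool(E):
        return [sum(w[i] * E[i][p] for i in range(L)) for p in range(d_p)]

    v_wt, v_mt = pool(enrich(E_wt)), pool(enrich(E_mt))
    u = [v_mt[p] - v_wt[p] for p in range(d_p)]
    d = math.sqrt(sum(x * x for x in u))
    direction = [x / (d + params.epsilon) for x in u]
    x = v_wt + direction
    h = [math.tanh(sum(params.scale_w1[j][t] * x[t] for t in range(2 * d_p))
                   + params.scale_b1[j]) for j in range(params.hidden)]
    s = sum(params.scale_w2[j] * h[j] for j in range(params.hidden)) + params.scale_b2
    return d * (1.0 / (1.0 + math.exp(-s)))


def random_pair(rng):
    wt = "".join(AA_ORDER[j] for j in rng.integers(0, 20, 9))
    i = int(rng.integers(9))
    sub = AA_ORDER[(AA_INDEX[wt[i]] + 1 + int(rng.integers(19))) % 20]
    return wt, wt[:i] + sub + wt[i + 1:]


class TestElementaryOps:
    def test_embedding_selects_blosum_columns(self, params):
        p = params.copy()
        sel = np.zeros((20, 2))
        sel[0, 0] = sel[1, 1] = 1.0  # first two BLOSUM62 columns (A, R)
        p.set_tensor("embed_w", sel)
        p.set_tensor("embed_b", np.zeros(2))
        E = embed_residues(one_hot("AAAAAAAAA"), p)
        assert np.allclose(E, [[4.0, -1.0]] * 9)  # BLOSUM62 row A at (A, R)

    def test_zero_input_gives_replicated_bias(self, params):
        E = embed_residues(np.zeros((9, 20)), params)
        assert np.allclose(E, np.tile(params.embed_b, (9, 1)))

    def test_motif_row_embeds_to_midpoint(self, params):
        # f_embed is affine, so a 0.5 A + 0.5 C frequency row lands at the
        # midpoint of the A and C embeddings
        row = np.zeros((1, 20))
        row[0, AA_INDEX["A"]] = row[0, AA_INDEX["C"]] = 0.5
        ea = embed_residues(one_hot("A"), params)
        ec = embed_residues(one_hot("C"), params)
        assert np.allclose(embed_residues(row, params), (ea + ec) / 2)

    def test_non_finite_input_rejected(self, params):
        bad = np.full((9, 20), np.nan)
        with pytest.raises(ValueError):
            embed_residues(bad, params)

    def test_zero_motif_annihilates_enrichment(self, params):
        E_pep = np.random.default_rng(0).normal(size=(9, 2))
        assert np.allclose(motif_enrich(E_pep, np.zeros((9, 2)), params), 0.0)

    def test_motif_enrich_matches_loop_oracle(self, params):
        rng = np.random.default_rng(5)
        E_pep, E_motif = rng.normal(size=(9, 2)), rng.normal(size=(9, 2))
        fast = motif_enrich(E_pep, E_motif, params)
        slow = np.zeros((9, 2))
        for i in range(9):
            H = np.empty(8)
            for k in range(8):
                Ck = E_motif @ params.conv[k]
                H[k] = float(Ck[i] @ E_pep[i])
            slow[i] = params.proj @ H
        assert np.allclose(fast, slow, atol=1e-10)

    def test_pooling_selector_uniform_zero(self):
        E = np.arange(18, dtype=float).reshape(9, 2)
        onehot3 = np.eye(9)[2]
        assert np.allclose(pool_peptide(E, onehot3), E[2])
        assert np.allclose(pool_peptide(E, np.full(9, 1 / 9)), E.mean(axis=0))
        assert np.allclose(pool_peptide(E, np.zeros(9)), 0.0)

    @pytest.mark.parametrize(
        "v_wt,v_mt,exp_d,exp_dir",
        [
            ((0, 0), (3, 4), 5.0, (0.6, 0.8)),
            ((1, 1), (1, 1), 0.0, (0.0, 0.0)),
            ((1, 1), (1, 2), 1.0, (0.0, 1.0)),
        ],
    )
    def test_geometric_representation(self, v_wt, v_mt, exp_d, exp_dir):
        origin, direction, d = geometric_representation(np.array(v_wt), np.array(v_mt))
        assert np.allclose(origin, v_wt)
        assert d == pytest.approx(exp_d)
        assert np.allclose(direction, exp_dir, atol=1e-7)

    def test_crd_zero_distance_and_forced_half(self, params):
        assert crd(np.zeros(2), np.zeros(2), 0.0, params) == 0.0
        p = params.copy()
        p.set_tensor("scale_w2", np.zeros(8))
        p.set_tensor("scale_b2", np.zeros(()))
        assert crd(np.ones(2), np.ones(2), 2.0, p) == pytest.approx(1.0)  # sigma(0) = 1/2

    def test_crd_strictly_below_distance(self, params):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = float(rng.uniform(0.1, 5))
            c = crd(rng.normal(size=2), rng.normal(size=2), d, params)
            assert 0 < c < d


class TestPredict:
    def motif(self, allele="M", cls="I"):
        rng = np.random.default_rng(9)
        return BindingMotif(allele, cls, rng.dirichlet(np.ones(20), size=9))

    def test_zero_classifier_gives_half(self, params):
        p = params.copy()
        p.set_tensor("out_w", np.zeros(2))
        p.set_tensor("out_b", np.zeros(()))
        pair = CorePeptidePair("AAAAAAAAA", "AAAAAAAAC", "M", "I")
        assert predict(pair, self.motif(), 0.3, p).probability == pytest.approx(0.5)

    def test_self_pair_probability_from_binding_only(self, params):
        pair = CorePeptidePair("KLVALGINA", "KLVALGINA", "M", "I")
        trace = predict(pair, self.motif(), 0.7, params)
        assert trace.crd == pytest.approx(0.0)
        expected = 1 / (1 + np.exp(-(params.out_w[1] * 0.7 + params.out_b)))
        assert trace.probability == pytest.approx(expected)

    def test_allele_mismatch_rejected(self, params):
        pair = CorePeptidePair("AAAAAAAAA", "AAAAAAAAC", "OTHER", "I")
        with pytest.raises(ValueError):
            predict(pair, self.motif(), 0.0, params)

    def test_trace_invariants(self, params):
        pair = CorePeptidePair("AAAAAAAAA", "AAAAAAAAC", "M", "I")
        t = predict(pair, self.motif(), 0.5, params)
        assert t.distance == pytest.approx(np.linalg.norm(t.v_mt - t.v_wt))
        assert 0 <= t.crd <= t.distance
        assert 0 < t.probability < 1


class TestOracleEquivalence:
    def test_forward_matches_loop_oracle(self, params):
        rng = np.random.default_rng(12)
        for _ in range(25):
            wt, mt = random_pair(rng)
            motif = rng.dirichlet(np.ones(20), size=9)
            cache = forward_batch(
                params, one_hot(wt)[None], one_hot(mt)[None], motif[None], "I"
            )
            assert cache.crd[0] == pytest.approx(
                oracle_crd(params, wt, mt, motif.tolist()), abs=1e-10
            )

    def test_gradients_match_finite_differences(self, params):
        rng = np.random.default_rng(3)
        pairs = [random_pair(rng) for _ in range(4)]
        Xw = np.stack([one_hot(w) for w, _ in pairs])
        Xm = np.stack([one_hot(m) for _, m in pairs])
        M = rng.dirichlet(np.ones(20), size=(4, 9))
        dcrd = rng.normal(size=4)
        grads = backward_batch(params, forward_batch(params, Xw, Xm, M, "I"), dcrd)

        def loss(p):
            return float(np.sum(dcrd * forward_batch(p, Xw, Xm, M, "I").crd))

        eps = 1e-6
        for name in STAGE1_TRAINABLE:
            t = np.asarray(getattr(params, name), dtype=float)
            flat = t.reshape(-1)
            # probe a deterministic subset of entries per tensor
            for idx in range(0, flat.size, max(1, flat.size // 6)):
                p2, p3 = params.copy(), params.copy()
                f2, f3 = np.array(flat), np.array(flat)
                f2[idx] += eps
                f3[idx] -= eps
                p2.set_tensor(name, f2.reshape(t.shape))
                p3.set_tensor(name, f3.reshape(t.shape))
                num = (loss(p2) - loss(p3)) / (2 * eps)
                ana = np.asarray(grads[name]).reshape(-1)[idx]
                assert ana == pytest.approx(num, abs=1e-6, rel=1e-5), name


class TestComponentScores:
    def motif(self):
        return BindingMotif("M", "I", np.random.default_rng(2).dirichlet(np.ones(20), size=9))

    def test_self_pair_all_zero(self, params):
        pair = CorePeptidePair("KLVALGINA", "KLVALGINA", "M", "I")
        assert component_scores(pair, self.motif(), params) == {
            "SubDist": 0.0, "SubPosDist": 0.0, "GeoDist": 0.0, "CRD": 0.0
        }

    def test_uniform_weights_divide_subdist_by_nine(self, params):
        p = params.copy()
        p.set_tensor("pos_w_i", np.full(9, 1 / 9))
        pair = CorePeptidePair("AAAAAAAAA", "AAAAAAAAC", "M", "I")
        comp = component_scores(pair, self.motif(), p)
        assert comp["SubPosDist"] == pytest.approx(comp["SubDist"] / 9)

    def test_geodist_is_predict_distance(self, params):
        pair = CorePeptidePair("AAAAAAAAA", "AAAAAAAAC", "M", "I")
        comp = component_scores(pair, self.motif(), params)
        trace = predict(pair, self.motif(), 0.0, params)
        assert comp["GeoDist"] == pytest.approx(trace.distance)
        assert comp["CRD"] == pytest.approx(trace.crd)
        assert 0 <= comp["CRD"] <= comp["GeoDist"]


@pytest.fixture(scope="module")
def trained(world):
    """Stage-1 training artifacts shared by the training tests."""
    from neoprecis.synthetic_data import SyntheticConfig, gen_tcr_binding_table
    from neoprecis.triplet_curation import make_triplets

    records, _ = gen_tcr_binding_table(SyntheticConfig(seed=1), world)
    triplets = make_triplets(records, world.predictor, seed=1)
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(triplets))
    n_train = int(0.8 * len(triplets))
    train = [triplets[i] for i in idx[:n_train]]
    held = [triplets[i] for i in idx[n_train:]]
    params0 = ImmunoModelParams.initialize(seed=1)
    config = TrainConfig(epochs=40, lr=0.005, seed=1)
    params1, history = train_stage1(train, world.motifs, params0, config,
                                    predictor=world.predictor)
    return {"params0": params0, "params1": params1, "history": history,
            "train": train, "held": held}


class TestStage1Training:
    def test_heldout_loss_decreases(self, world, trained):
        enc = encode_triplets(trained["held"], world.motifs, world.predictor)
        before = triplet_losses(trained["params0"], enc).mean()
        after = triplet_losses(trained["params1"], enc).mean()
        assert after < before

    def test_heldout_ks_separation(self, world, trained):
        # cross-reactive pairs should sit at smaller geometric distances
        # than negatives on held-out triplets (scaled separation analogue)
        from scipy.stats import ks_2samp

        enc = encode_triplets(trained["held"], world.motifs, world.predictor)
        d_pos, d_neg = [], []
        for cls, b in enc.items():
            d_pos.append(forward_batch(trained["params1"], b["a"], b["p"], b["m"], cls).d)
            d_neg.append(forward_batch(trained["params1"], b["a"], b["n"], b["m"], cls).d)
        stat = ks_2samp(np.concatenate(d_pos), np.concatenate(d_neg),
                        alternative="greater").statistic
        assert stat > 0.3

    def test_determinism_under_fixed_seed(self, world, trained):
        config = TrainConfig(epochs=3, lr=0.005, seed=5)
        p0 = ImmunoModelParams.initialize(seed=1)
        r1, _ = train_stage1(trained["train"][:200], world.motifs, p0, config,
                             predictor=world.predictor)
        r2, _ = train_stage1(trained["train"][:200], world.motifs, p0, config,
                             predictor=world.predictor)
        for name, t in r1.tensors().items():
            assert np.array_equal(t, r2.tensors()[name]), name

    def test_missing_motif_skips_triplet(self, world, trained):
        from neoprecis.triplet_curation import Triplet

        odd = Triplet("AAAAAAAAA", "AAAAAAAAC", "AAAAAAAAW", "UNKNOWN", "I")
        enc = encode_triplets([odd] + trained["train"][:5], world.motifs, world.predictor)
        assert sum(len(b["a"]) for b in enc.values()) == 5


class TestStage2Training:
    def make_labeled(self, world, params, n=200, seed=0):
        """Labels from thresholding sigma(3 CRD - 1), i.e. CRD > 1/3, under
        the given upstream parameters — a parameter-recovery setting."""
        from neoprecis.core_motifs import make_core_pair
        from neoprecis.triplet_curation import LabeledEpitope

        rng = np.random.default_rng(seed)
        alleles = world.alleles("I")
        out = []
        for _ in range(n):
            allele = alleles[rng.integers(len(alleles))]
            wt, mt = random_pair(rng)
            pair, pred = make_core_pair(wt, mt, allele, world.predictor)
            trace = predict(pair, world.motifs[allele],
                            binding_covariate(pred, "I"), params)
            label = int(1 / (1 + np.exp(-(3 * trace.crd - 1))) > 0.5)
            split = "train" if rng.random() < 0.8 else "val"
            out.append(LabeledEpitope(wt, mt, allele, "I", label, split))
        return out

    def test_frozen_tensors_unchanged_and_auroc(self, world, trained):
        from sklearn.metrics import roc_auc_score
        from neoprecis.core_motifs import make_core_pair

        params1 = trained["params1"]
        labeled = self.make_labeled(world, params1, n=250, seed=4)
        val = [e for e in labeled if e.split == "val"]
        assert len(set(e.label for e in val)) == 2
        params2, history = train_stage2(
            labeled, world.motifs, world.predictor, params1,
            TrainConfig(epochs=60, lr=0.05, seed=0),
        )
        for name in ("embed_w", "embed_b", "conv", "proj", "pos_w_i", "pos_w_ii"):
            assert np.array_equal(
                np.asarray(getattr(params1, name)), np.asarray(getattr(params2, name))
            ), name
        probs = []
        for e in val:
            pair, pred = make_core_pair(e.wt_peptide, e.mt_peptide, e.allele,
                                        world.predictor)
            probs.append(predict(pair, world.motifs[e.allele],
                                 binding_covariate(pred, "I"), params2).probability)
        auroc = roc_auc_score([e.label for e in val], probs)
        assert auroc > 0.8

    def test_single_class_labels_rejected(self, world, trained):
        labeled = self.make_labeled(world, trained["params1"], n=30, seed=1)
        degenerate = [type(e)(e.wt_peptide, e.mt_peptide, e.allele, e.mhc_class, 1, e.split)
                      for e in labeled]
        with pytest.raises(ValueError):
            train_stage2(degenerate, world.motifs, world.predictor, trained["params1"])


def test_checkpoint_round_trip(tmp_path, params):
    path = tmp_path / "model.npz"
    params.save(path)
    back = ImmunoModelParams.load(path)
    for name, t in params.tensors().items():
        assert np.array_equal(t, back.tensors()[name]), name
    assert back.margin == params.margin and back.epsilon == params.epsilon
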