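"""Topology HMM: recursions vs. enumeration, grammar, windows, training."""

import itertools
import math

import numpy as np
import pytest

from anchorscreen import topology_hmm as th
from anchorscreen.topology_hmm import (
    AA20,
    AA_INDEX,
    GROUP_GLOBULAR,
    GROUP_HELIX,
    GROUP_INSIDE,
    GROUP_OUTSIDE,
    LABEL_MEM,
    LABEL_OUT,
    ResiduePosterior,
    TopologyError,
    TopologyModel,
    build_model,
    default_model,
    model_from_text,
    model_to_text,
    posterior_decode,
    sample_sequence,
    sequence_likelihood,
    sequence_likelihood_backward,
    summarize_topology,
    train_emissions,
    viterbi_topology,
)

from conftest import enumerate_paths, segments_to_labels


# ---------------------------------------------------------------------------
# default model construction
# ---------------------------------------------------------------------------


class TestDefaultModel:
    def test_passes_structural_invariants(self):
        model = default_model()
        model.validate()  # row sums, grammar, helix length bounds
        assert model.helix_min_len == 15
        assert model.helix_max_len == 25

    def test_helix_emissions_follow_hydropathy(self):
        model = default_model()
        helix = next(
            model.emissions[i] for i in range(model.n_states)
            if model.groups[i] == GROUP_HELIX
        )
        assert helix[AA_INDEX["L"]] > helix[AA_INDEX["D"]]
        assert helix[AA_INDEX["I"]] > helix[AA_INDEX["K"]]

    def test_positive_inside_rule_in_emissions(self):
        model = default_model()
        inside = next(
            model.emissions[i] for i in range(model.n_states)
            if model.groups[i] == GROUP_INSIDE
        )
        outside = next(
            model.emissions[i] for i in range(model.n_states)
            if model.groups[i] == GROUP_OUTSIDE
        )
        for aa in "KR":
            assert inside[AA_INDEX[aa]] > outside[AA_INDEX[aa]]

    def test_no_direct_inside_outside_transition(self):
        model = default_model()
        for i in range(model.n_states):
            for j in range(model.n_states):
                if model.transitions[i, j] > 0:
                    assert {model.labels[i], model.labels[j]} != {"inside", "outside"}

    def test_helix_length_bounds_are_checked(self):
        with pytest.raises(TopologyError):
            build_model(helix_min_len=4)
        with pytest.raises(TopologyError):
            build_model(helix_min_len=15, helix_max_len=10)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestLikelihood:
    def test_single_residue_closed_form(self, toy2_model):
        # log P = log( sum_s init(s) * emit(s, K) )
        expected = math.log(
            toy2_model.initial[0] * toy2_model.emissions[0, AA_INDEX["K"]]
            + toy2_model.initial[1] * toy2_model.emissions[1, AA_INDEX["K"]]
        )
        assert sequence_likelihood(toy2_model, "K") == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seq", ["KALLD", "DDDDD", "LKDAS", "AAAAA"])
    def test_matches_path_enumeration(self, toy3_model, seq):
        total, _, _ = enumerate_paths(toy3_model, seq)
        assert sequence_likelihood(toy3_model, seq) == pytest.approx(
            math.log(total), rel=1e-9
        )

    def test_forward_and_backward_agree(self, toy3_model):
        for seq in ("KALLDSA", "LLLLLLLL", "KDKDKDKD"):
            assert sequence_likelihood(toy3_model, seq) == pytest.approx(
                sequence_likelihood_backward(toy3_model, seq), rel=1e-9
            )
        model = default_model()
        seq = "MKKLLLLLLLLLLASADQRNST"
        assert sequence_likelihood(model, seq) == pytest.approx(
            sequence_likelihood_backward(model, seq), rel=1e-9
        )

    def test_invariant_under_consistent_state_relabelling(self, toy3_model):
        perm = [2, 0, 1]
        inv = np.argsort(perm)
        m = toy3_model
        permuted = TopologyModel(
            states=[m.states[i] for i in perm],
            labels=[m.labels[i] for i in perm],
            groups=[m.groups[i] for i in perm],
            transitions=m.transitions[np.ix_(perm, perm)],
            emissions=m.emissions[perm],
            initial=m.initial[perm],
            helix_min_len=m.helix_min_len,
            helix_max_len=m.helix_max_len,
        )
        for seq in ("KALLD", "DKLSA"):
            assert sequence_likelihood(m, seq) == pytest.approx(
                sequence_likelihood(permuted, seq), rel=1e-12
            )

    def test_ambiguous_residues_emit_background_average(self, toy3_model):
        col = toy3_model.emission_column("X")
        assert np.allclose(col, toy3_model.emissions.mean(axis=1))
        assert np.isfinite(sequence_likelihood(toy3_model, "KXBZU"))

    def test_empty_sequence_rejected(self, toy3_model):
        with pytest.raises(TopologyError):
            sequence_likelihood(toy3_model, "")


# ---------------------------------------------------------------------------
# posterior decoding and Viterbi
# ---------------------------------------------------------------------------


def _all_sequences(alphabet: str, max_len: int):
    for L in range(1, max_len + 1):
        for combo in itertools.product(alphabet, repeat=L):
            yield "".join(combo)


class TestDecodingAgainstEnumeration:
    def test_exhaustive_small_sequences(self, toy3_model):
        """Posterior and Viterbi agree with brute force on every sequence of
        length <= 6 over a two-letter alphabet (the exhaustive contract)."""
        for seq in _all_sequences("AD", 6):
            total, post_ref, best_path = enumerate_paths(toy3_model, seq)
            assert sequence_likelihood(toy3_model, seq) == pytest.approx(
                math.log(total), rel=1e-9
            )
            post = posterior_decode(toy3_model, seq)
            assert np.allclose(post.p_in, post_ref["inside"], atol=1e-9)
            assert np.allclose(post.p_mem, post_ref["membrane"], atol=1e-9)
            assert np.allclose(post.p_out, post_ref["outside"], atol=1e-9)
            segs = viterbi_topology(toy3_model, seq)
            labels = segments_to_labels(segs, len(seq))
            assert labels == [toy3_model.labels[s] for s in best_path]

    def test_posterior_rows_sum_to_one_random_models(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            emis = {
                g: rng.dirichlet(np.ones(len(AA20)))
                for g in (GROUP_INSIDE, "cap", GROUP_HELIX, GROUP_OUTSIDE,
                          GROUP_GLOBULAR)
            }
            model = build_model(emis)
            seq = "".join(rng.choice(list(AA20), size=rng.integers(5, 60)))
            post = posterior_decode(model, seq)
            assert np.allclose(post.p_in + post.p_mem + post.p_out, 1.0, atol=1e-9)


class TestDecodingBehaviour:
    def test_all_outside_degenerate_model(self):
        E = np.tile(np.full(len(AA20), 1 / len(AA20)), (2, 1))
        model = TopologyModel(
            states=["out", "glob"],
            labels=[LABEL_OUT, LABEL_OUT],
            groups=[GROUP_OUTSIDE, GROUP_GLOBULAR],
            transitions=np.array([[0.9, 0.1], [0.2, 0.8]]),
            emissions=E,
            initial=np.array([1.0, 0.0]),
            helix_min_len=5,
            helix_max_len=25,
        )
        seq = "MKTAYIAKQR"
        post = posterior_decode(model, seq)
        assert np.allclose(post.p_out, 1.0)
        assert viterbi_topology(model, seq) == [("outside", 1, len(seq))]

    def test_long_polyleucine_no_underflow(self):
        model = default_model()
        seq = "L" * 2000
        post = posterior_decode(model, seq)
        assert np.all(np.isfinite(post.p_mem))
        assert np.allclose(post.p_in + post.p_mem + post.p_out, 1.0, atol=1e-9)

    def test_viterbi_helix_segments_respect_min_length(self):
        model = default_model()
        # core helix only (caps fold into the membrane label, so a decoded
        # membrane segment is at least min_len + 4 caps long)
        seq = "MKKR" + "DEKR" * 3 + "LIVLLIVALIVLLIVALIV" + "DESTQNDESTQNDESTQN"
        segs = viterbi_topology(model, seq)
        for lab, start, end in segs:
            if lab == LABEL_MEM:
                assert end - start + 1 >= model.helix_min_len

    def test_planted_hydrophobic_stretch_decodes_as_one_helix(self):
        model = default_model()
        loop_in = "MKKRDSKRED"
        helix = "LIVLLIVALIVLLIVALIV"  # 19 residues
        loop_out = "DSTQNGEDSTQNGEDSTQNGE" * 3
        seq = loop_in + helix + loop_out
        segs = viterbi_topology(model, seq)
        mem = [s for s in segs if s[0] == LABEL_MEM]
        assert len(mem) == 1
        start, end = mem[0][1], mem[0][2]
        overlap = min(end, len(loop_in) + 19) - max(start, len(loop_in) + 1) + 1
        assert overlap >= 15

    def test_monotone_in_helix_leucine_emission(self):
        seq = "L" * 60
        means = []
        for boost in (1.0, 1.5, 2.0, 3.0):
            emis = th._group_emissions()
            helix = emis[GROUP_HELIX].copy()
            helix[AA_INDEX["L"]] *= boost
            emis[GROUP_HELIX] = helix / helix.sum()
            model = build_model(emis)
            post = posterior_decode(model, seq)
            means.append(float(post.p_mem.mean()))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# summary windows
# ---------------------------------------------------------------------------


class TestSummarize:
    def _post(self, p_in, p_mem, p_out):
        return ResiduePosterior(np.asarray(p_in, float), np.asarray(p_mem, float),
                                np.asarray(p_out, float))

    def test_all_outside_posterior(self):
        L = 30
        post = self._post([0] * L, [0] * L, [1] * L)
        summ = summarize_topology(post, [("outside", 1, L)])
        assert summ.out_first_w == 1.0
        assert summ.out_last_w == 1.0
        assert summ.prob_n_in == 0.0
        assert summ.n_helices == 0

    def test_short_sequence_uses_all_residues(self):
        post = self._post([1] * 10, [0] * 10, [0] * 10)
        summ = summarize_topology(post, [("inside", 1, 10)], window=20)
        assert summ.out_first_w == 0.0
        assert summ.out_last_w == 0.0

    def test_invalid_window_rejected(self):
        post = self._post([1], [0], [0])
        with pytest.raises(TopologyError):
            summarize_topology(post, [("inside", 1, 1)], window=0)

    def test_segments_tile_sequence(self):
        model = default_model()
        seq = "MKKR" + "LIVLLIVALIVLLIVALIV" + "DSTQNGE" * 10
        segs = viterbi_topology(model, seq)
        covered = []
        for lab, start, end in segs:
            covered.extend(range(start, end + 1))
        assert covered == list(range(1, len(seq) + 1))

    def test_type_ii_topology_statistics(self):
        """N-in single-helix proteins report prob_n_in and out_last > 0.5."""
        from anchorscreen.synthetic_fixtures import PlantSpec, generate_protein
        rec, truth = generate_protein(PlantSpec("n_anchored", length=250, seed=11))
        model = default_model()
        post = posterior_decode(model, rec.sequence)
        segs = viterbi_topology(model, rec.sequence)
        summ = summarize_topology(post, segs)
        assert summ.prob_n_in > 0.5
        assert summ.out_last_w > 0.5

    def test_max_aggregate_available(self):
        post = self._post([0.5] * 25, [0.25] * 25, [0.25] * 25)
        post.p_out[3] = 0.9
        summ = summarize_topology(post, [("inside", 1, 25)], agg="max")
        assert summ.out_first_w == pytest.approx(0.9)


# ---------------------------------------------------------------------------
# supervised re-estimation and serialization
# ---------------------------------------------------------------------------


class TestTraining:
    def test_recovers_emissions_from_sampled_data(self):
        model = default_model()
        rng = np.random.default_rng(3)
        data = [sample_sequence(model, 150, rng) for _ in range(200)]
        trained = train_emissions(model, data)
        ref = {}
        for g, row in zip(model.groups, model.emissions):
            ref.setdefault(g, row)
        got = {}
        for g, row in zip(trained.groups, trained.emissions):
            got.setdefault(g, row)
        for g in ref:
            assert np.max(np.abs(ref[g] - got[g])) < 0.05, g

    def test_single_residue_training_is_smoothed_and_valid(self):
        model = default_model()
        trained = train_emissions(model, [("L", [GROUP_HELIX])])
        trained.validate()
        helix = next(trained.emissions[i] for i in range(trained.n_states)
                     if trained.groups[i] == GROUP_HELIX)
        assert np.all(helix > 0)  # add-one floor
        assert helix[AA_INDEX["L"]] == helix.max()

    def test_unknown_label_rejected(self):
        model = default_model()
        with pytest.raises(TopologyError):
            train_emissions(model, [("L", ["no-such-state-group"])])

    def test_retraining_on_own_expected_counts_is_near_fixed_point(self):
        # sampling from the model and retraining changes emissions only by
        # sampling noise + smoothing
        model = default_model()
        rng = np.random.default_rng(7)
        data = [sample_sequence(model, 300, rng) for _ in range(300)]
        trained = train_emissions(model, data)
        assert np.max(np.abs(trained.emissions - model.emissions)) < 0.05


class TestSerialization:
    def test_round_trip(self):
        model = default_model()
        text = model_to_text(model)
        back = model_from_text(text)
        assert back.states == model.states
        assert np.allclose(back.transitions, model.transitions)
        assert np.allclose(back.emissions, model.emissions)
        assert np.allclose(back.initial, model.initial)
        assert sequence_likelihood(back, "MKKLLLLLLLLLLASADQ") == pytest.approx(
            sequence_likelihood(model, "MKKLLLLLLLLLLASADQ"), rel=1e-12
        )
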