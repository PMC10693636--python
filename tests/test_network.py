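"""Network architecture, loss functions and training machinery."""

import numpy as np
import pytest

from tcnovo import chem, losses, model, training
from tcnovo.model import ModelConfig, receptive_field
from tcnovo.nn import TCNBlock, Tensor


class TestReceptiveField:
    def test_degenerate_kernel(self):
        for n in (1, 3, 5):
            assert receptive_field(1, n) == 1

    def test_hand_arithmetic(self):
        assert receptive_field(3, 1) == 5
        assert receptive_field(5, 5) == 1 + 2 * 4 * 31

    @pytest.mark.parametrize("k,n", [(3, 1), (3, 2), (3, 3), (5, 1), (5, 2), (5, 3)])
    def test_formula_matches_gradient_support_probe(self, k, n):
        """The nonzero input-gradient span of a built block on a centered
        output equals the closed-form receptive field."""
        rf = receptive_field(k, n)
        L = 2 * rf  # long enough that the support is not clipped
        rng = np.random.default_rng(99)
        block = TCNBlock(n_in=1, n_channels=4, kernel_size=k,
                         n_dilated_layers=n, rng=rng)
        # positive weights keep every path alive through the ReLUs
        for p in block.parameters():
            p.data = np.abs(p.data) + 0.01
        x = Tensor(np.abs(rng.normal(1.0, 0.1, (1, L, 1))), requires_grad=True)
        out = block(x)
        center = L // 2
        # select the center position's summed activation
        mask = np.zeros((1, L, 4), dtype=np.float32)
        mask[0, center, :] = 1.0
        (out * Tensor(mask)).sum().backward()
        support = np.nonzero(np.abs(x.grad[0, :, 0]) > 1e-12)[0]
        width = support.max() - support.min() + 1
        assert width == rf


class TestModelConfig:
    def test_channel_growth_ratio(self):
        ch = ModelConfig().channels
        ratios = [b / a for a, b in zip(ch, ch[1:])]
        assert all(1.33 <= r <= 1.5 for r in ratios)

    def test_divisibility_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(input_length=1000)
        with pytest.raises(ValueError):
            ModelConfig(channels=(64, 64))

    def test_scaled_channels_floor(self):
        cfg = ModelConfig.desk_scale(scale=0.01)
        assert min(cfg.scaled_channels()) == 8


@pytest.fixture(scope="module")
def tiny():
    cfg = ModelConfig(input_length=1024, scale=0.05, layers_per_block=1,
                      kernel_size=3, fusion_channels=32, meta_channels=8)
    return cfg, model.build_model(cfg, seed=1)


class TestForwardContract:

    def test_softmax_columns_sum_to_one(self, tiny, rng):
        cfg, net = tiny
        x = rng.random((3, 1024, 4)).astype(np.float32)
        meta = rng.random((3, 10)).astype(np.float32)
        probs = net.forward(x, meta)["probs"].data
        assert probs.shape == (3, 32, 23)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert probs.min() >= 0

    def test_forward_deterministic(self, tiny, rng):
        cfg, net = tiny
        x = rng.random((2, 1024, 4)).astype(np.float32)
        meta = rng.random((2, 10)).astype(np.float32)
        p1 = net.forward(x, meta)["probs"].data
        p2 = net.forward(x, meta)["probs"].data
        np.testing.assert_array_equal(p1, p2)

    def test_aux_head_shapes(self, tiny, rng):
        cfg, net = tiny
        out = net.forward(rng.random((2, 1024, 4)).astype(np.float32),
                          rng.random((2, 10)).astype(np.float32))
        assert out["tryptic"].shape == (2, 1)
        assert out["length"].shape == (2, 30)
        assert out["presence"].shape == (2, 20)
        assert out["composition"].shape == (2, 20)
        assert out["pairs"].shape == (2, 400)

    def test_wrong_input_length_rejected(self, tiny, rng):
        cfg, net = tiny
        with pytest.raises(ValueError):
            net.forward(rng.random((1, 512, 4)), rng.random((1, 10)))

    def test_checkpoint_round_trip(self, tiny, tmp_path, rng):
        cfg, net = tiny
        from tcnovo.encoding import EncodingConfig
        from tcnovo.model import load_checkpoint, save_checkpoint
        path = tmp_path / "ckpt"
        save_checkpoint(net, path, EncodingConfig.desk_scale())
        net2, ecfg = load_checkpoint(path)
        assert ecfg.bin_width == 1.0
        x = rng.random((1, 1024, 4)).astype(np.float32)
        meta = rng.random((1, 10)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x, meta)["probs"].data,
                                      net2.forward(x, meta)["probs"].data)


def one_hot_probs(peptides, fill=1e-9):
    targets, mask = losses.encode_targets(peptides)
    m = np.full((len(peptides), 32, 23), fill, dtype=np.float64)
    np.put_along_axis(m, targets[..., None], 1.0, axis=-1)
    m /= m.sum(axis=-1, keepdims=True)
    return Tensor(m.astype(np.float32)), targets, mask


class TestMaskedCE:
    def test_one_hot_correct_is_zero(self):
        probs, targets, mask = one_hot_probs(["ACK", "GDE"])
        assert losses.masked_ce_loss(probs, targets, mask).item() == pytest.approx(
            0.0, abs=1e-5)

    def test_uniform_is_log23(self):
        targets, mask = losses.encode_targets(["ACDEFK"])
        probs = Tensor(np.full((1, 32, 23), 1 / 23, dtype=np.float32))
        assert losses.masked_ce_loss(probs, targets, mask).item() == pytest.approx(
            np.log(23), rel=1e-4)

    def test_matches_brute_force(self, rng):
        peptides = ["ACK", "GGDEK", "WYV"]
        targets, mask = losses.encode_targets(peptides)
        m = rng.random((3, 32, 23))
        m /= m.sum(axis=-1, keepdims=True)
        expected = np.mean([
            -np.log(m[i, j, targets[i, j]])
            for i in range(3) for j in range(32) if mask[i, j]])
        got = losses.masked_ce_loss(Tensor(m.astype(np.float32)), targets, mask)
        assert got.item() == pytest.approx(expected, rel=1e-4)


class TestMassMAE:
    def test_one_hot_correct_is_zero(self):
        probs, _, _ = one_hot_probs(["ACK", "GDE"])
        masses = np.array([chem.peptide_mono_mass("ACK"),
                           chem.peptide_mono_mass("GDE")])
        assert losses.mass_mae_loss(probs, masses).item() == pytest.approx(
            0.0, abs=1e-2)

    def test_single_substitution_closed_form(self):
        probs, _, _ = one_hot_probs(["AAK"])
        true_mass = np.array([chem.peptide_mono_mass("GAK")])
        expected = chem.RESIDUE_MASS["A"] - chem.RESIDUE_MASS["G"]
        assert losses.mass_mae_loss(probs, true_mass).item() == pytest.approx(
            expected, abs=1e-2)

    def test_matches_brute_force_expectation(self, rng):
        m = rng.random((2, 32, 23))
        m /= m.sum(axis=-1, keepdims=True)
        true = np.array([800.0, 1200.0])
        expected_masses = (m * chem.CLASS_MASS).sum(axis=(1, 2)) + chem.WATER
        expected = np.abs(expected_masses - true).mean()
        got = losses.mass_mae_loss(Tensor(m.astype(np.float32)), true)
        assert got.item() == pytest.approx(expected, rel=1e-4)


class TestAuxiliary:
    def test_targets_consistency(self):
        aux = losses.build_aux_targets(["ACKA", "GGK"])
        # composition (normalized) sums to 1; presence = composition > 0
        np.testing.assert_allclose(aux["composition"].sum(axis=1), 1.0)
        np.testing.assert_array_equal(aux["presence"],
                                      (aux["composition"] > 0).astype(np.float32))
        assert aux["tryptic"][1, 0] == 1.0 and aux["tryptic"][0, 0] == 0.0
        assert list(aux["length"]) == [3, 2]
        # pair (G,G) and (G,K) set for "GGK"
        gi = losses.AA_INDEX["G"]
        ki = losses.AA_INDEX["K"]
        assert aux["pairs"][1, gi * 20 + gi] == 1.0
        assert aux["pairs"][1, gi * 20 + ki] == 1.0
        assert aux["pairs"][1].sum() == 2.0

    def test_bce_closed_form_ln2(self, rng):
        # 0.5 predictions vs any binary target -> BCE = ln 2
        logits = Tensor(np.zeros((4, 20), dtype=np.float32))
        target = (rng.random((4, 20)) < 0.5).astype(np.float32)
        out = losses.auxiliary_losses(
            {"tryptic": Tensor(np.zeros((4, 1), np.float32)),
             "length": Tensor(np.zeros((4, 30), np.float32)),
             "presence": logits, "composition": Tensor(np.zeros((4, 20), np.float32)),
             "pairs": Tensor(np.zeros((4, 400), np.float32))},
            {"tryptic": target[:, :1], "length": np.zeros(4, np.int64),
             "presence": target, "composition": target,
             "pairs": np.zeros((4, 400), np.float32)})
        assert out["presence"].item() == pytest.approx(np.log(2), rel=1e-4)
        assert out["length"].item() == pytest.approx(np.log(30), rel=1e-4)

    def test_perfect_predictions_near_zero(self):
        peps = ["ACK", "GGK"]
        aux_t = losses.build_aux_targets(peps)
        big = 30.0
        logits = {
            "tryptic": Tensor((aux_t["tryptic"] * 2 - 1) * big),
            "length": Tensor(losses.one_hot(aux_t["length"], 30) * big),
            "presence": Tensor((aux_t["presence"] * 2 - 1) * big),
            "composition": Tensor(aux_t["composition"]),
            "pairs": Tensor((aux_t["pairs"] * 2 - 1) * big),
        }
        out = losses.auxiliary_losses(logits, aux_t)
        for task, val in out.items():
            assert val.item() == pytest.approx(0.0, abs=1e-3), task


class TestTotalLoss:
    def test_zero_for_perfect_everything(self):
        peps = ["ACK"]
        probs, targets, mask = one_hot_probs(peps)
        aux_t = losses.build_aux_targets(peps)
        big = 30.0
        outputs = {
            "probs": probs,
            "tryptic": Tensor((aux_t["tryptic"] * 2 - 1) * big),
            "length": Tensor(losses.one_hot(aux_t["length"], 30) * big),
            "presence": Tensor((aux_t["presence"] * 2 - 1) * big),
            "composition": Tensor(aux_t["composition"]),
            "pairs": Tensor((aux_t["pairs"] * 2 - 1) * big),
        }
        masses = np.array([chem.peptide_mono_mass("ACK")])
        total, comps = losses.total_loss(
            outputs, targets, mask, masses, aux_t, mae_weight=1e-4,
            aux_weights={"tryptic": 0.1, "length": 0.1, "presence": 0.1,
                         "composition": 0.1, "pairs": 0.1})
        assert total.item() == pytest.approx(0.0, abs=1e-3)

    def test_c_zero_reduces_to_ce_plus_aux(self, rng):
        peps = ["ACDK"]
        targets, mask = losses.encode_targets(peps)
        m = rng.random((1, 32, 23))
        m /= m.sum(axis=-1, keepdims=True)
        probs = Tensor(m.astype(np.float32))
        outputs = {"probs": probs}
        masses = np.array([chem.peptide_mono_mass("ACDK")])
        total, comps = losses.total_loss(
            outputs, targets, mask, masses, losses.build_aux_targets(peps),
            mae_weight=0.0, aux_weights={})
        assert total.item() == pytest.approx(comps["masked_ce"], rel=1e-5)


class TestSplitByPeptide:
    def test_group_integrity_and_disjointness(self, rng):
        from conftest import random_peptides
        base = random_peptides(rng, 200, lengths=(6, 10))
        # each peptide repeated a few times (multiple spectra per peptide)
        peptides = [p for p in base for _ in range(5)]
        tr, va, te = training.split_by_peptide(peptides, (0.8, 0.1, 0.1), seed=3)
        sets = [set(peptides[i] for i in idx) for idx in (tr, va, te)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])
        assert len(tr) + len(va) + len(te) == len(peptides)
        # a peptide's 5 spectra land wholly in one split
        for pep in base[:20]:
            hits = [bool([i for i in idx if peptides[i] == pep])
                    for idx in (tr, va, te)]
            assert sum(hits) == 1

    def test_fraction_approximation(self, rng):
        from conftest import random_peptides
        peptides = random_peptides(rng, 10000, lengths=(6, 12))
        fr = (0.956, 0.018, 0.025)  # the full-scale split proportions
        tr, va, te = training.split_by_peptide(peptides, fr, seed=11)
        n = len(peptides)
        for idx, f in zip((tr, va, te), fr):
            assert abs(len(idx) / n - f) < 0.01

    def test_deterministic(self, rng):
        from conftest import random_peptides
        peptides = random_peptides(rng, 100)
        a = training.split_by_peptide(peptides, (0.8, 0.1, 0.1), seed=5)
        b = training.split_by_peptide(peptides, (0.8, 0.1, 0.1), seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestTrainingLoop:
    def test_loss_decreases_on_tiny_problem(self):
        """Smoke: a small model memorizes 60 synthetic spectra."""
        from tcnovo import encoding, simulator
        scfg = simulator.SimulatorConfig.recovery_benchmark()
        recs = simulator.generate_dataset(scfg, 60, seed=3)
        ecfg = encoding.EncodingConfig.desk_scale()
        peps = [r.peptide for r in recs]
        data = training.TrainingData.from_records(
            [r.spectrum for r in recs], peps, ecfg)
        mcfg = ModelConfig(input_length=2048, scale=0.04, layers_per_block=1,
                           kernel_size=3, fusion_channels=64, meta_channels=8)
        net = model.build_model(mcfg, seed=3)
        tcfg = training.TrainingConfig.desk_scale(epochs=3, batch_size=16,
                                                  learning_rate=3e-3, seed=3)
        result = training.train(net, data, data.subset(np.arange(20)), tcfg)
        totals = [row["total"] for row in result.history]
        assert totals[-1] < totals[0]
        assert 0 <= result.best_epoch < 3
        assert all(np.isfinite(t) for t in totals)
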