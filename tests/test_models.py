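"""Model-layer tests: encodings, config validation, training determinism,
overfit sanity (memorization oracle), batching invariance, checkpoint
round trips, and the Sec-from-Cys warm start."""

import numpy as np
import pytest

from secproxy import chem, synth_gen
from secproxy.entities import Peptide, PrecursorIon, SpectralLibrary
from secproxy.models import api, encoding
from secproxy.models.nets import CHANNELS
from secproxy.synth_gen import SynthConfig


class TestEncoding:
    def test_ptm_composition_vector(self):
        cam = chem.get_modification("CAM")
        pep = Peptide("ACDK", ((2, cam),))
        ptm = encoding.encode_ptm(pep)
        expected = np.zeros(8)
        expected[:4] = [2, 3, 1, 1]  # C, H, N, O
        np.testing.assert_array_equal(ptm[1], expected)
        assert np.all(ptm[[0, 2, 3]] == 0)

    def test_sec_is_distinct_token(self):
        t_cys = encoding.encode_tokens(Peptide("ACDK"))
        t_sec = encoding.encode_tokens(Peptide("AUDK"))
        assert t_cys[1] != t_sec[1]
        assert np.array_equal(t_cys[[0, 2, 3]], t_sec[[0, 2, 3]])

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError, match="X"):
            encoding.encode_tokens(Peptide("AXDK"))

    def test_meta_differs_only_in_charge(self):
        m2 = encoding.encode_meta(2)
        m3 = encoding.encode_meta(3)
        assert not np.array_equal(m2, m3)
        assert np.array_equal(m2[4:], m3[4:])  # NCE + instrument shared

    def test_selenium_channel(self):
        dese = chem.get_modification("deSe")
        pep = Peptide("AUDK", ((2, dese),))
        ptm = encoding.encode_ptm(pep)
        assert ptm[1, encoding.ELEMENT_CHANNELS.index("Se")] == -1
        assert ptm[1, encoding.ELEMENT_CHANNELS.index("H")] == -2


class TestModelConfig:
    def test_defaults_are_reference_recipe(self):
        c = api.ModelConfig("ms2")
        assert (c.hidden_dim, c.n_layers, c.fc_dim) == (256, 4, 128)
        assert (c.epochs, c.warmup_epochs, c.batch_size) == (20, 5, 256)
        assert c.learning_rate == pytest.approx(1e-5)
        assert c.dropout == pytest.approx(0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            api.ModelConfig("nope")
        with pytest.raises(ValueError):
            api.ModelConfig("rt", warmup_epochs=30, epochs=20)
        with pytest.raises(ValueError):
            api.ModelConfig("rt", lstm_dim=0)

    def test_desk_scale_keeps_recipe(self):
        c = api.ModelConfig.desk_scale("ccs")
        assert c.hidden_dim < 256
        assert (c.epochs, c.warmup_epochs, c.learning_rate) == (20, 5, 1e-5)

    def test_channel_layout(self):
        assert len(CHANNELS) == 8
        assert {c[0] for c in CHANNELS} == {"b", "y"}
        assert {c[1] for c in CHANNELS} == {1, 2}
        assert sum(c[2] == "modloss" for c in CHANNELS) == 4


@pytest.fixture(scope="module")
def tiny_library():
    lib, _ = synth_gen.generate_cys_library(SynthConfig(n_peptides=24, seed=5))
    return lib


def tiny_config(task):
    return api.ModelConfig.desk_scale(
        task, hidden_dim=32, conv_channels=16, lstm_dim=16, fc_dim=32, seed=1
    )


class TestTraining:
    def test_finetune_curve_length_and_determinism(self, tiny_library):
        curves = []
        for _ in range(2):
            b = api.ModelBundle(tiny_config("rt"))
            curve = api.finetune(b, tiny_library, seed=3)
            curves.append(curve)
            assert len(curve) == b.config.epochs == 20
        assert curves[0] == curves[1]

    def test_empty_training_set_errors(self):
        b = api.ModelBundle(tiny_config("rt"))
        with pytest.raises(ValueError, match="empty"):
            api.finetune(b, SpectralLibrary())

    def test_training_reduces_loss(self, tiny_library):
        b = api.ModelBundle(tiny_config("ms2"))
        curve = api.pretrain(b, tiny_library, epochs=15, learning_rate=2e-3, seed=2)
        assert curve[-1] < curve[0]

    def test_overfit_memorizes_targets(self):
        """After an overfit run on 10 peptides, predictions reproduce the
        training targets with PCC > 0.99."""
        lib, _ = synth_gen.generate_cys_library(
            SynthConfig(n_peptides=10, seed=6, sigma_ms2=0.0)
        )
        b = api.ModelBundle(tiny_config("ms2"))
        api.pretrain(b, lib, epochs=200, warmup_epochs=10, learning_rate=3e-3, seed=4)
        model = api.MS2Model(b)
        precs = [PrecursorIon(e.peptide, e.charge, e.precursor_mz) for e in lib]
        for entry, pred in zip(lib, model.predict(precs)):
            obs = {f.key: f.intensity for f in entry.fragments}
            keys = sorted(obs)
            x = [pred.get(k, 0.0) for k in keys]
            y = [obs[k] for k in keys]
            assert np.corrcoef(x, y)[0, 1] > 0.99


@pytest.fixture(scope="module")
def trained(tiny_library):
    bundles = {}
    for task in ("ms2", "rt", "ccs"):
        b = api.ModelBundle(tiny_config(task))
        api.pretrain(b, tiny_library, epochs=5, learning_rate=1e-3, seed=7)
        bundles[task] = b
    return bundles


class TestPrediction:
    def test_batching_invariance(self, trained, tiny_library):
        e = tiny_library.entries[0]
        prec = PrecursorIon(e.peptide, e.charge, e.precursor_mz)
        model = api.MS2Model(trained["ms2"])
        single = model.predict_matrices([prec])[0]
        batch = model.predict_matrices([prec] * 7)
        for m in batch:
            np.testing.assert_allclose(m, single, atol=1e-5)

    def test_outputs_normalized_and_modloss_zero(self, trained, tiny_library):
        precs = [
            PrecursorIon(e.peptide, e.charge, e.precursor_mz) for e in tiny_library
        ]
        for m in api.MS2Model(trained["ms2"]).predict_matrices(precs):
            assert m.min() >= 0 and m.max() == pytest.approx(1.0)
            assert np.all(m[:, 4:] == 0)  # modloss channels

    def test_duplicate_peptides_identical_outputs(self, trained, tiny_library):
        peps = [tiny_library.entries[0].peptide] * 3
        out = api.RTModel(trained["rt"]).predict(peps)
        assert out[0] == out[1] == out[2]

    def test_ccs_strictly_positive(self, trained, tiny_library):
        precs = [
            PrecursorIon(e.peptide, e.charge, e.precursor_mz) for e in tiny_library
        ]
        assert np.all(api.CCSModel(trained["ccs"]).predict(precs) > 0)

    def test_too_long_peptide_errors(self, trained):
        seq = "A" * 100 + "CK"
        pep = Peptide(seq)
        with pytest.raises(ValueError, match="max length"):
            api.MS2Model(trained["ms2"]).predict_matrices([PrecursorIon(pep, 2, 500.0)])

    def test_save_load_bit_identical(self, trained, tiny_library, tmp_path):
        path = tmp_path / "rt.npz"
        trained["rt"].save(path)
        loaded = api.ModelBundle.load(path)
        peps = [e.peptide for e in tiny_library]
        a = api.RTModel(trained["rt"]).predict(peps)
        b = api.RTModel(loaded).predict(peps)
        np.testing.assert_array_equal(a, b)
        assert loaded.loss_curve == trained["rt"].loss_curve


class TestWarmStart:
    def test_sec_twin_identical_after_warm_start(self):
        """With the U representation copied from C and identical
        modifications, a peptide and its Sec twin get identical
        predictions — the proxy hypothesis in weight space."""
        cam = chem.get_modification("CAM")
        cys = Peptide("ACDEFK", ((2, cam),))
        sec = Peptide("AUDEFK", ((2, cam),))
        for task in ("rt", "ms2"):
            b = api.ModelBundle(tiny_config(task))
            b.warm_start_sec_from_cys()
            if task == "rt":
                out = api.RTModel(b).predict([cys, sec])
                assert out[0] == pytest.approx(out[1], abs=1e-6)
            else:
                prec_c = PrecursorIon(cys, 2, 400.0)
                prec_u = PrecursorIon(sec, 2, 400.0)
                mc, mu = api.MS2Model(b).predict_matrices([prec_c, prec_u])
                np.testing.assert_allclose(mc, mu, atol=1e-5)
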