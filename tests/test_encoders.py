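import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from keyslice.ct_volume import PreprocessSpec, WindowSpec, apply_window
from keyslice.encoders import (
    OracleEncoder,
    TinyTrainableEncoder,
    encode_text,
    encode_volume,
    get_model,
    register_model,
    tokenize,
)
from keyslice.errors import ConfigError, InputError
from keyslice.slice_selection import select_for_sentence
from keyslice.synthetic import concept_intensities
from keyslice.curation import DEFAULT_ORGANS

WINDOW = WindowSpec()
CODES = concept_intensities()


def make_oracle(vocab=("heart", "liver", "spleen", "kidney")):
    return OracleEncoder(list(vocab), CODES, window=WINDOW)


def phantom_slice(concepts, size=32):
    """Slice containing a small constant-intensity patch per concept."""
    img = np.full((size, size), -1000.0)
    for i, c in enumerate(concepts):
        r = 2 + 7 * i
        img[r : r + 5, 2:10] = CODES[c]
    return apply_window(img, WINDOW)


class TestOracleText:
    def test_single_concept_is_one_hot(self):
        enc = make_oracle()
        v = enc.encode_text("This CT image includes the heart")
        expected = np.zeros(4)
        expected[0] = 1.0
        np.testing.assert_allclose(v, expected)

    def test_deterministic(self):
        enc = make_oracle()
        s = "A cystic lesion near the liver and spleen"
        np.testing.assert_array_equal(enc.encode_text(s), enc.encode_text(s))

    def test_truncation_to_77_tokens(self):
        enc = make_oracle()
        filler = " ".join(f"word{i}" for i in range(100))
        long_sentence = filler + " heart"  # concept beyond token 77
        first77 = " ".join(tokenize(long_sentence)[:77])
        np.testing.assert_array_equal(
            enc.encode_text(long_sentence), enc.encode_text(first77)
        )
        # and the concept was indeed dropped by truncation
        assert "heart" not in tokenize(first77)

    def test_empty_sentence_rejected(self):
        with pytest.raises(InputError):
            encode_text(make_oracle(), "   ")

    def test_multiword_concept_matched_as_token_sequence(self):
        enc = OracleEncoder(["adrenal gland", "kidney"], CODES, window=WINDOW)
        v = enc.encode_text("The adrenal gland is unremarkable.")
        np.testing.assert_allclose(v, [1.0, 0.0])


class TestOracleImage:
    def test_single_concept_one_hot(self):
        enc = make_oracle()
        v = enc.encode_image(phantom_slice(["liver"]))
        np.testing.assert_allclose(v, [0.0, 1.0, 0.0, 0.0])

    def test_two_concepts_normalized_sum(self):
        enc = make_oracle()
        v = enc.encode_image(phantom_slice(["liver", "heart"]))
        np.testing.assert_allclose(v, [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0, 0.0])

    def test_empty_slice_uniform_fallback(self):
        enc = make_oracle()
        v = enc.encode_image(np.zeros((16, 16)))
        np.testing.assert_allclose(v, np.full(4, 0.5))  # 1/sqrt(4)

    def test_cosine_structure_exhaustive_up_to_4_concepts(self):
        vocab = ["heart", "liver", "spleen", "kidney"]
        enc = make_oracle(vocab)
        for size in range(1, 5):
            for planted in itertools.combinations(vocab, size):
                img_emb = enc.encode_image(phantom_slice(planted))
                for concept in vocab:
                    cos = float(img_emb @ enc.encode_text(concept))
                    expected = 1 / np.sqrt(size) if concept in planted else 0.0
                    assert cos == pytest.approx(expected, abs=1e-9)


class TestEncodeVolume:
    def test_matches_per_slice_loop_and_order(self, oracle, cohort):
        sid = cohort.studies()[0]
        vol = cohort.volumes[sid]
        mat = encode_volume(oracle, vol, cohort.preprocess)
        assert mat.shape == (vol.n_slices, oracle.dim)
        np.testing.assert_allclose(np.linalg.norm(mat, axis=1), 1.0, atol=1e-6)
        from keyslice.ct_volume import preprocess_slice

        for i in range(vol.n_slices):
            row = oracle.encode_image(preprocess_slice(vol.slices[i], cohort.preprocess))
            np.testing.assert_array_equal(mat[i], row)


WORDS = st.lists(
    st.sampled_from(["heart", "liver", "mass", "lesion", "the", "ct", "image", "x9"]),
    min_size=1,
    max_size=20,
)


class TestUnitNorm:
    @given(words=WORDS)
    def test_text_unit_norm_both_encoders(self, words):
        sentence = " ".join(words)
        for model in (make_oracle(), TinyTrainableEncoder(seed=0)):
            assert np.linalg.norm(model.encode_text(sentence)) == pytest.approx(1.0, abs=1e-6)

    @given(seed=st.integers(0, 500))
    def test_image_unit_norm_both_encoders(self, seed):
        img = np.random.default_rng(seed).uniform(0, 1, (32, 32))
        for model in (make_oracle(), TinyTrainableEncoder(seed=0)):
            assert np.linalg.norm(model.encode_image(img)) == pytest.approx(1.0, abs=1e-6)


class TestTinyEncoder:
    def test_truncation_contract(self):
        model = TinyTrainableEncoder(seed=0)
        long_sentence = " ".join(f"tok{i}" for i in range(200))
        first77 = " ".join(tokenize(long_sentence)[:77])
        np.testing.assert_allclose(
            model.encode_text(long_sentence), model.encode_text(first77)
        )

    def test_save_load_round_trip(self, tmp_path):
        model = TinyTrainableEncoder(seed=3)
        model.save(tmp_path / "ckpt.npz")
        back = TinyTrainableEncoder.load(tmp_path / "ckpt.npz")
        s = "a mass is seen"
        np.testing.assert_allclose(model.encode_text(s), back.encode_text(s))
        img = np.random.default_rng(0).uniform(0, 1, (64, 64))
        np.testing.assert_allclose(model.encode_image(img), back.encode_image(img))


class TestRegistry:
    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError):
            get_model("no-such-backbone")

    def test_duck_typed_adapter_accepted_downstream(self, cohort):
        class ConstantModel:
            dim = 3
            max_tokens = 77

            def encode_text(self, sentence):
                return np.array([1.0, 0.0, 0.0])

            def encode_image(self, image):
                v = np.array([1.0, float(image.mean()), 0.0])
                return v / np.linalg.norm(v)

        register_model("constant", ConstantModel)
        model = get_model("constant")
        sid = cohort.studies()[0]
        sel = select_for_sentence(
            model, cohort.volumes[sid], "anything", spec=cohort.preprocess
        )
        assert 0 <= sel.key_index < cohort.volumes[sid].n_slices
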