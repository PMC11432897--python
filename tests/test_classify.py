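import numpy as np
import pytest

from lexasd.classify import (
    ClassifierConfig,
    TrainedClassifier,
    embed_tags,
    predict_proba,
    train_classifier,
)
from lexasd.corpus import Dataset, Document

FAST_DNN = dict(embedding_dim=8, hidden_dim=8, epochs=5, batch_size=4, seed=0)


def _freq_doc(schema, doc_id, label, col, freq, L=10):
    tags = np.zeros((L, schema.tag_count), dtype=np.uint8)
    tags[: int(freq * L), col] = 1
    tokens = [f"w{i}" for i in range(L)]
    return Document(id=doc_id, label=label, task="interview", tokens=tokens,
                    tags=tags, annotation_source="manual")


@pytest.fixture(scope="module")
def separable(schema=None):
    from lexasd.schema import default_schema

    schema = default_schema()
    docs = [_freq_doc(schema, f"as{i}", "AS", 0, 0.9) for i in range(5)]
    docs += [_freq_doc(schema, f"n{i}", "nonAS", 0, 0.1) for i in range(5)]
    return Dataset(docs)


class TestEmbedTags:
    def test_no_active_tags_gives_zero_row(self, rng):
        table = rng.normal(size=(147, 4))
        mat = np.zeros((3, 147), dtype=np.uint8)
        assert not embed_tags(mat, table).any()

    def test_single_tag_returns_its_row(self, rng):
        table = rng.normal(size=(147, 4))
        mat = np.zeros((1, 147), dtype=np.uint8)
        mat[0, 31] = 1
        assert np.allclose(embed_tags(mat, table)[0], table[31])

    def test_two_tags_sum_elementwise(self, rng):
        table = rng.normal(size=(147, 4))
        mat = np.zeros((1, 147), dtype=np.uint8)
        mat[0, [3, 77]] = 1
        assert np.allclose(embed_tags(mat, table)[0], table[3] + table[77])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="incompatible"):
            embed_tags(np.zeros((2, 10)), rng.normal(size=(147, 4)))


class TestTagLinear:
    def test_separable_data_perfect_training_accuracy(self, separable):
        clf = train_classifier(separable, ClassifierConfig(variant="tag_linear"))
        preds = [predict_proba(clf, d) >= 0.5 for d in separable]
        truth = [d.label == "AS" for d in separable]
        assert preds == truth
        assert clf.coefficients[0] > 0  # higher tag-0 frequency -> AS

    def test_single_class_training_rejected(self, schema):
        docs = [_freq_doc(schema, f"a{i}", "AS", 0, 0.5) for i in range(4)]
        with pytest.raises(ValueError, match="single class"):
            train_classifier(Dataset(docs), ClassifierConfig(variant="tag_linear"))

    def test_order_invariance(self, separable, schema):
        clf = train_classifier(separable, ClassifierConfig(variant="tag_linear"))
        doc = separable[0]
        perm = np.random.default_rng(0).permutation(doc.n_tokens)
        shuffled = Document(id="s", label="AS", task="interview",
                            tokens=[doc.tokens[i] for i in perm],
                            tags=doc.tags[perm], annotation_source="manual")
        assert predict_proba(clf, doc) == pytest.approx(
            predict_proba(clf, shuffled), abs=1e-12
        )

    def test_zero_vector_predicts_sigmoid_intercept(self, separable, schema):
        clf = train_classifier(separable, ClassifierConfig(variant="tag_linear"))
        zero = Document(id="z", label="unknown", task="interview",
                        tokens=["w", "v"],
                        tags=np.zeros((2, schema.tag_count), dtype=np.uint8),
                        annotation_source="manual")
        expected = 1.0 / (1.0 + np.exp(-clf.intercept))
        assert predict_proba(clf, zero) == pytest.approx(expected, abs=1e-12)


class TestDnnVariants:
    @pytest.mark.parametrize("variant", ["tag_dnn", "text_dnn", "text_tag_dnn"])
    def test_seed_reproducibility(self, tiny_tagged_dataset, variant):
        cfg = ClassifierConfig(variant=variant, **FAST_DNN)
        c1 = train_classifier(tiny_tagged_dataset, cfg)
        c2 = train_classifier(tiny_tagged_dataset, cfg)
        for key in c1.params:
            assert np.array_equal(c1.params[key], c2.params[key])

    @pytest.mark.parametrize("variant", ["tag_dnn", "text_dnn", "text_tag_dnn"])
    def test_probability_range_and_purity(self, tiny_tagged_dataset, variant):
        cfg = ClassifierConfig(variant=variant, **FAST_DNN)
        clf = train_classifier(tiny_tagged_dataset, cfg)
        doc = tiny_tagged_dataset[0]
        p1 = predict_proba(clf, doc)
        p2 = predict_proba(clf, doc)
        assert 0.0 <= p1 <= 1.0 and p1 == p2

    def test_tag_variant_requires_tags(self, tiny_tagged_dataset):
        cfg = ClassifierConfig(variant="tag_dnn", **FAST_DNN)
        clf = train_classifier(tiny_tagged_dataset, cfg)
        untagged = Document(id="u", label="AS", task="interview", tokens=["w"])
        with pytest.raises(ValueError, match="requires a tag matrix"):
            predict_proba(clf, untagged)

    def test_tag_dnn_is_order_sensitive(self, tiny_tagged_dataset):
        cfg = ClassifierConfig(variant="tag_dnn", embedding_dim=8, hidden_dim=8,
                               epochs=15, batch_size=4, seed=0)
        clf = train_classifier(tiny_tagged_dataset, cfg)
        changed = 0
        for doc in tiny_tagged_dataset:
            reversed_doc = Document(
                id=doc.id, label=doc.label, task=doc.task,
                tokens=doc.tokens[::-1], tags=doc.tags[::-1],
                annotation_source="manual",
            )
            if abs(predict_proba(clf, doc) - predict_proba(clf, reversed_doc)) > 1e-9:
                changed += 1
        assert changed > 0  # unlike the frequency model, order matters


class TestDegeneracy:
    """With one input stream frozen at zero, the combined model must compute
    exactly what the corresponding single-stream model computes."""

    def _restricted(self, combined, rows, variant):
        d = combined.config.embedding_dim
        params = {
            "out_W": combined.params["out_W"], "out_b": combined.params["out_b"],
        }
        for dirn in ("fwd", "bwd"):
            params[f"{dirn}_W"] = combined.params[f"{dirn}_W"][rows]
            params[f"{dirn}_U"] = combined.params[f"{dirn}_U"]
            params[f"{dirn}_b"] = combined.params[f"{dirn}_b"]
        if variant == "tag_dnn":
            params["tag_table"] = combined.params["tag_table"]
        else:
            params["emb"] = combined.params["emb"]
        cfg = ClassifierConfig(variant=variant, embedding_dim=d,
                               hidden_dim=combined.config.hidden_dim)
        return TrainedClassifier(variant=variant, config=cfg, n_tags=147,
                                 params=params, vocab=combined.vocab)

    def test_zero_word_table_reduces_to_tag_dnn(self, tiny_tagged_dataset):
        cfg = ClassifierConfig(variant="text_tag_dnn", **FAST_DNN)
        combined = train_classifier(tiny_tagged_dataset, cfg)
        d = cfg.embedding_dim
        combined.params["emb"][:] = 0.0
        reduced = self._restricted(combined, slice(0, d), "tag_dnn")
        for doc in list(tiny_tagged_dataset)[:3]:
            assert predict_proba(combined, doc) == pytest.approx(
                predict_proba(reduced, doc), abs=1e-12
            )

    def test_zero_tag_table_reduces_to_text_dnn(self, tiny_tagged_dataset):
        cfg = ClassifierConfig(variant="text_tag_dnn", **FAST_DNN)
        combined = train_classifier(tiny_tagged_dataset, cfg)
        d = cfg.embedding_dim
        combined.params["tag_table"][:] = 0.0
        reduced = self._restricted(combined, slice(d, 2 * d), "text_dnn")
        for doc in list(tiny_tagged_dataset)[:3]:
            assert predict_proba(combined, doc) == pytest.approx(
                predict_proba(reduced, doc), abs=1e-12
            )
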