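"""Saving and loading trained models.

A model is a directory holding ``params.npz`` (all numpy parameters) and
``meta.json`` (config, vocabulary, variant, seed snapshot).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .annotator import AnnotatorConfig, AnnotatorModel
from .classify import ClassifierConfig, TrainedClassifier


def _save(path, params: dict, meta: dict) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **params)
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def _load(path) -> tuple[dict, dict]:
    path = Path(path)
    with np.load(path / "params.npz") as npz:
        params = {k: npz[k] for k in npz.files}
    meta = json.loads((path / "meta.json").read_text())
    return params, meta


def save_annotator(model: AnnotatorModel, path) -> None:
    meta = {
        "kind": "annotator",
        "config": dataclasses.asdict(model.config),
        "vocab": model.vocab,
        "n_tags": model.n_tags,
    }
    _save(path, model.params, meta)


def load_annotator(path) -> AnnotatorModel:
    params, meta = _load(path)
    if meta.get("kind") != "annotator":
        raise ValueError(f"{path} does not hold an annotator model")
    return AnnotatorModel(
        config=AnnotatorConfig(**meta["config"]),
        vocab=meta["vocab"],
        params=params,
        n_tags=meta["n_tags"],
    )


def save_classifier(model: TrainedClassifier, path) -> None:
    params = {}
    if model.params is not None:
        params |= model.params
    if model.coef is not None:
        params["linear_coef"] = model.coef
        params["linear_intercept"] = np.array([model.intercept])
    meta = {
        "kind": "classifier",
        "variant": model.variant,
        "config": dataclasses.asdict(model.config),
        "vocab": model.vocab,
        "n_tags": model.n_tags,
    }
    _save(path, params, meta)


def load_classifier(path) -> TrainedClassifier:
    params, meta = _load(path)
    if meta.get("kind") != "classifier":
        raise ValueError(f"{path} does not hold a classifier model")
    coef = params.pop("linear_coef", None)
    intercept = params.pop("linear_intercept", None)
    return TrainedClassifier(
        variant=meta["variant"],
        config=ClassifierConfig(**meta["config"]),
        n_tags=meta["n_tags"],
        coef=coef,
        intercept=float(intercept[0]) if intercept is not None else None,
        params=params or None,
        vocab=meta["vocab"],
    )
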