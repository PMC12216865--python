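"""Model checkpoints: npz parameter archives with a JSON config header."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from ._nn import MLP
from .autoencoder import BAEConfig, BAEModel
from .contrastive import CLConfig, CLModel


def _pack(prefix: str, mlp: MLP, store: dict) -> None:
    store[f"{prefix}__sizes"] = np.array(mlp.sizes)
    for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
        store[f"{prefix}__w{i}"] = w
        store[f"{prefix}__b{i}"] = b


def _unpack(prefix: str, data) -> MLP:
    sizes = data[f"{prefix}__sizes"].tolist()
    mlp = MLP(sizes, np.random.default_rng(0))
    n = len(sizes) - 1
    mlp.weights = [data[f"{prefix}__w{i}"] for i in range(n)]
    mlp.biases = [data[f"{prefix}__b{i}"] for i in range(n)]
    return mlp


def save_model(model: CLModel | BAEModel, path: str | Path) -> None:
    path = Path(path)
    store: dict = {}
    meta = {
        "config": asdict(model.config),
        "history": model.history,
        "cp_feature_names": model.cp_feature_names,
    }
    if isinstance(model, CLModel):
        meta["model_type"] = "contrastive"
        _pack("cp_encoder", model.cp_encoder, store)
        _pack("tx_encoder", model.tx_encoder, store)
        _pack("cp_projection", model.cp_projection, store)
        _pack("tx_projection", model.tx_projection, store)
    elif isinstance(model, BAEModel):
        meta["model_type"] = "bae"
        _pack("encoder", model.encoder, store)
        _pack("cp_decoder", model.cp_decoder, store)
        _pack("tx_decoder", model.tx_decoder, store)
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    store["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **store)


def load_model(path: str | Path) -> CLModel | BAEModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    cfg_dict = meta["config"]
    for key in ("cp_hidden_sizes", "tx_hidden_sizes", "encoder_hidden",
                "cp_decoder_hidden", "tx_decoder_hidden"):
        if key in cfg_dict:
            cfg_dict[key] = tuple(cfg_dict[key])
    if meta["model_type"] == "contrastive":
        return CLModel(
            _unpack("cp_encoder", data),
            _unpack("tx_encoder", data),
            _unpack("cp_projection", data),
            _unpack("tx_projection", data),
            CLConfig(**cfg_dict),
            meta["history"],
            meta["cp_feature_names"],
        )
    if meta["model_type"] == "bae":
        return BAEModel(
            _unpack("encoder", data),
            _unpack("cp_decoder", data),
            _unpack("tx_decoder", data),
            BAEConfig(**cfg_dict),
            meta["history"],
            meta["cp_feature_names"],
        )
    raise ValueError(f"unknown model_type {meta['model_type']!r}")
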