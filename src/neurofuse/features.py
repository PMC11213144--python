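"""Model metadata and per-layer feature matrices.

Deep-network features enter the pipeline as files: one matrix of shape
(events, dims) per layer per model, plus metadata describing each model's
modality class and whether its weights are trained.  Running the networks
themselves is out of scope.  Two linearly-integrated baselines are built
here: MultiConcat (column-wise concatenation of a vision and a language
model's features) and MultiLin (the same concatenation pushed through a
fixed linear projection).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

MODALITIES = ("vision", "language", "multimodal", "linear_integration")
ENCODER_SIDES = ("vision_encoder", "language_encoder")

_SIDE_TO_MODALITY = {"vision_encoder": "vision", "language_encoder": "language"}


@dataclass(frozen=True)
class ModelSpec:
    """Identity and modality metadata for one feature-producing model."""

    name: str
    architecture_family: str = ""
    declared_modality: str = ""
    trained: bool = True
    encoder_side: str | None = None

    def __post_init__(self) -> None:
        if self.declared_modality and self.declared_modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.declared_modality!r}")
        if self.encoder_side is not None and self.encoder_side not in ENCODER_SIDES:
            raise ValueError(f"unknown encoder_side {self.encoder_side!r}")


def effective_modality(spec: ModelSpec) -> str:
    """Modality class a model acts as, given its training state.

    Contrastively-trained multimodal models (dual-encoder designs such as
    SLIP-Combo / SLIP-CLIP, marked by ``encoder_side``) lose their multimodal
    status when randomly initialized: the cross-modal alignment lives in the
    trained weights, so an untrained encoder is unimodal on its own side.
    Architecturally multimodal models (cross-attention designs: ALBEF, BLIP,
    Flava) consume both modalities regardless of training, so random
    initialization does not change their multimodal status.
    """
    if not spec.declared_modality:
        raise ValueError(f"model {spec.name!r} has no declared_modality")
    if spec.declared_modality == "multimodal" and not spec.trained:
        if spec.encoder_side is not None:
            return _SIDE_TO_MODALITY[spec.encoder_side]
        return "multimodal"  # architecturally multimodal
    return spec.declared_modality


@dataclass
class FeatureSet:
    """Per-layer (events x dims) feature matrices for one model."""

    model: ModelSpec
    layers: dict[str, np.ndarray]
    event_ids: Sequence[str]

    def __post_init__(self) -> None:
        n = len(self.event_ids)
        for layer_id, mat in self.layers.items():
            mat = np.asarray(mat)
            if mat.ndim != 2:
                raise ValueError(f"layer {layer_id!r} is not a matrix")
            if mat.shape[0] != n:
                raise ValueError(
                    f"layer {layer_id!r} has {mat.shape[0]} events, "
                    f"event_ids has {n}"
                )
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"layer {layer_id!r} contains non-finite entries")
            self.layers[layer_id] = mat

    @property
    def layer_ids(self) -> list[str]:
        return list(self.layers)

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    def matrices(self) -> list[np.ndarray]:
        return list(self.layers.values())


def save_feature_set(store_path, fs: FeatureSet) -> None:
    """Append one model's features to an HDF5 feature store."""
    with h5py.File(store_path, "a") as f:
        if fs.model.name in f:
            del f[fs.model.name]
        g = f.create_group(fs.model.name)
        g.attrs["name"] = fs.model.name
        g.attrs["architecture_family"] = fs.model.architecture_family
        g.attrs["declared_modality"] = fs.model.declared_modality
        g.attrs["trained"] = bool(fs.model.trained)
        g.attrs["encoder_side"] = fs.model.encoder_side or ""
        g.create_dataset("event_ids", data=np.array(fs.event_ids, dtype="S"))
        lg = g.create_group("layers")
        for layer_id, mat in fs.layers.items():
            lg.create_dataset(layer_id, data=mat)


def load_feature_set(
    store_path, model_name: str, event_ids: Sequence[str] | None = None
) -> FeatureSet:
    """Load one model's features; optionally validate the event axis.

    ``event_ids``, when given, must match the stored axis exactly (same
    events, same order); a mismatch raises naming both counts.
    """
    with h5py.File(store_path, "r") as f:
        if model_name not in f:
            raise KeyError(f"model {model_name!r} not in store")
        g = f[model_name]
        spec = ModelSpec(
            name=str(g.attrs["name"]),
            architecture_family=str(g.attrs["architecture_family"]),
            declared_modality=str(g.attrs["declared_modality"]),
            trained=bool(g.attrs["trained"]),
            encoder_side=str(g.attrs["encoder_side"]) or None,
        )
        stored_ids = [s.decode() for s in g["event_ids"][()]]
        if event_ids is not None:
            if len(event_ids) != len(stored_ids):
                raise ValueError(
                    f"event axis mismatch for {model_name!r}: store has "
                    f"{len(stored_ids)} events, dataset has {len(event_ids)}"
                )
            if list(event_ids) != stored_ids:
                raise ValueError(f"event ids differ for {model_name!r}")
        layers = {layer_id: g["layers"][layer_id][()] for layer_id in g["layers"]}
    return FeatureSet(model=spec, layers=layers, event_ids=stored_ids)


def list_models(store_path) -> list[str]:
    with h5py.File(store_path, "r") as f:
        return list(f)


def write_manifest(path, specs: Sequence[ModelSpec]) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "architecture_family": s.architecture_family,
                "declared_modality": s.declared_modality,
                "trained": s.trained,
                "encoder_side": s.encoder_side or "",
            }
            for s in specs
        ]
    ).to_csv(path, index=False)


def read_manifest(path) -> list[ModelSpec]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        ModelSpec(
            name=str(r.name),
            architecture_family=str(r.architecture_family),
            declared_modality=str(r.declared_modality),
            trained=bool(r.trained),
            encoder_side=str(r.encoder_side) or None,
        )
        for r in frame.itertuples()
    ]


def _paired_layers(n_a: int, n_b: int) -> list[tuple[int, int]]:
    """Depth-fraction layer pairing: layer i/N of each parent is matched."""
    n_out = max(n_a, n_b)
    pairs = []
    for i in range(n_out):
        frac = i / (n_out - 1) if n_out > 1 else 0.0
        pairs.append((round(frac * (n_a - 1)), round(frac * (n_b - 1))))
    return pairs


def build_multiconcat(
    vision_fs: FeatureSet, language_fs: FeatureSet, name: str = "multiconcat"
) -> FeatureSet:
    """Concatenate vision and language features column-wise (vision first).

    Layers of the two parents are paired by matching depth fraction, so the
    output has max(n_vision_layers, n_language_layers) layers.
    """
    if list(vision_fs.event_ids) != list(language_fs.event_ids):
        raise ValueError(
            f"event axis mismatch: vision has {vision_fs.n_events} events, "
            f"language has {language_fs.n_events}"
        )
    v_ids, l_ids = vision_fs.layer_ids, language_fs.layer_ids
    layers = {}
    for i, (vi, li) in enumerate(_paired_layers(len(v_ids), len(l_ids))):
        layers[f"concat{i}"] = np.concatenate(
            [vision_fs.layers[v_ids[vi]], language_fs.layers[l_ids[li]]], axis=1
        )
    spec = ModelSpec(
        name=name,
        architecture_family="linear_integration",
        declared_modality="linear_integration",
        trained=True,
    )
    return FeatureSet(model=spec, layers=layers, event_ids=list(vision_fs.event_ids))


def build_multilin(
    concat_fs: FeatureSet, projection: np.ndarray, name: str = "multilin"
) -> FeatureSet:
    """Map every concatenated layer through a fixed linear projection.

    The projection is an input artifact (in synthetic runs a seeded random
    orthonormal map); training it is out of scope.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.ndim != 2:
        raise ValueError("projection must be a matrix (d_in, d_out)")
    layers = {}
    for layer_id, mat in concat_fs.layers.items():
        if mat.shape[1] != projection.shape[0]:
            raise ValueError(
                f"projection expects {projection.shape[0]} input dims, layer "
                f"{layer_id!r} has {mat.shape[1]}"
            )
        layers[layer_id.replace("concat", "lin")] = mat @ projection
    spec = ModelSpec(
        name=name,
        architecture_family="linear_integration",
        declared_modality="linear_integration",
        trained=True,
    )
    return FeatureSet(model=spec, layers=layers, event_ids=list(concat_fs.event_ids))


def random_orthonormal_projection(d_in: int, d_out: int, seed: int) -> np.ndarray:
    """Seeded random matrix with orthonormal columns, shape (d_in, d_out)."""
    if d_out > d_in:
        raise ValueError("d_out must be <= d_in")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((d_in, d_out)))
    return q
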