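"""Serialization of probing instances and result tables.

Instances round-trip through a self-describing JSON document (header plus
pmf grid or weight matrix).  Deterministic instances can alternatively be
written as a tab-separated edge list with ``regulator  position  weight``
columns, which is also the on-disk form of TF-gene networks converted to
probing instances.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ProbingInstance

__all__ = [
    "instance_to_json",
    "instance_from_json",
    "instance_to_tsv",
    "instance_from_tsv",
]


def instance_to_json(instance: ProbingInstance, path: str | Path) -> None:
    doc: dict = {
        "n_regulators": instance.n_regulators,
        "n_positions": instance.n_positions,
        "support_max": instance.support_max,
        "setting": instance.setting,
        "seed": instance.seed,
        "deterministic": instance.deterministic,
    }
    if instance._pmfs is not None:
        doc["pmfs"] = instance._pmfs.tolist()
    else:
        doc["weights"] = instance._weights.tolist()
    Path(path).write_text(json.dumps(doc))


def instance_from_json(path: str | Path) -> ProbingInstance:
    doc = json.loads(Path(path).read_text())
    if "pmfs" in doc:
        inst = ProbingInstance(
            pmfs=np.array(doc["pmfs"], dtype=float),
            setting=doc.get("setting"),
            seed=doc.get("seed"),
        )
    else:
        inst = ProbingInstance(
            weights=np.array(doc["weights"], dtype=float),
            setting=doc.get("setting"),
            seed=doc.get("seed"),
        )
    if inst.n_regulators != doc["n_regulators"] or inst.n_positions != doc["n_positions"]:
        raise ValueError("instance header inconsistent with stored grid")
    return inst


def instance_to_tsv(instance: ProbingInstance, path: str | Path) -> None:
    """Write a deterministic instance as a dense edge-list TSV."""
    W = instance.point_weights
    a, b = np.indices(W.shape)
    df = pd.DataFrame(
        {"regulator": a.ravel(), "position": b.ravel(), "weight": W.ravel()}
    )
    df.to_csv(path, sep="\t", index=False)


def instance_from_tsv(path: str | Path) -> ProbingInstance:
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "position", "weight"}
    if not required <= set(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    if (df["weight"] < 0).any():
        raise ValueError("edge weights must be non-negative")
    n_a = int(df["regulator"].max()) + 1
    n_b = int(df["position"].max()) + 1
    W = np.zeros((n_a, n_b))
    W[df["regulator"].to_numpy(int), df["position"].to_numpy(int)] = df["weight"].to_numpy(float)
    return ProbingInstance.from_weights(W)
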