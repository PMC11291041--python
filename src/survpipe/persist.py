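"""Text-only model persistence: parameter arrays + a JSON model card.

A saved model (or bag) is a directory of JSON files — no binary formats —
so artifacts survive text-only archiving and stay diffable.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from survpipe import __version__
from survpipe._mlp import MLP
from survpipe.bagging import ModelBag, ParametricConfig
from survpipe.cohort import ColumnProvenance
from survpipe.hazard import DiscretizationGrid, HazardModel, HazardNetConfig
from survpipe.parametric import RoystonParmarModel


def _prov_to_json(prov):
    return None if prov is None else [dataclasses.asdict(p) for p in prov]


def _prov_from_json(doc):
    return None if doc is None else [ColumnProvenance(**p) for p in doc]


def _model_to_json(model) -> dict:
    if isinstance(model, HazardModel):
        return {
            "family": "pchazard",
            "net": model.net.state(),
            "grid": model.grid.cuts.tolist(),
            "config": dataclasses.asdict(model.config),
            "encode_stats": _prov_to_json(model.encode_stats),
        }
    if isinstance(model, RoystonParmarModel):
        return {
            "family": "spline",
            "gamma": model.gamma.tolist(),
            "beta": model.beta.tolist(),
            "internal_knots": model.internal_knots.tolist(),
            "boundary_knots": list(model.boundary_knots),
            "log_likelihood": model.log_likelihood,
            "monotone_violation": model.monotone_violation,
            "time_mesh": model.time_mesh.tolist(),
        }
    raise TypeError(f"cannot serialise {type(model).__name__}")


def _model_from_json(doc: dict):
    if doc["family"] == "pchazard":
        cfg = doc["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        return HazardModel(
            net=MLP.from_state(doc["net"]),
            grid=DiscretizationGrid(cuts=np.asarray(doc["grid"])),
            config=HazardNetConfig(**cfg),
            encode_stats=_prov_from_json(doc["encode_stats"]),
        )
    return RoystonParmarModel(
        gamma=np.asarray(doc["gamma"]),
        beta=np.asarray(doc["beta"]),
        internal_knots=np.asarray(doc["internal_knots"]),
        boundary_knots=tuple(doc["boundary_knots"]),
        log_likelihood=doc["log_likelihood"],
        monotone_violation=doc["monotone_violation"],
        time_mesh=np.asarray(doc["time_mesh"]),
    )


def save_bag(bag: ModelBag, directory: str, extra_card: dict | None = None) -> None:
    os.makedirs(directory, exist_ok=True)
    card = {
        "software_version": __version__,
        "bag_size": bag.size,
        "member_seeds": bag.member_seeds,
        "config": dataclasses.asdict(bag.config),
        "family": "pchazard" if isinstance(bag.config, HazardNetConfig) else "spline",
        "encode_stats": _prov_to_json(bag.encode_stats),
        **(extra_card or {}),
    }
    with open(os.path.join(directory, "model_card.json"), "w") as fh:
        json.dump(card, fh, indent=2)
    for i, member in enumerate(bag.members):
        with open(os.path.join(directory, f"member_{i:02d}.json"), "w") as fh:
            json.dump(_model_to_json(member), fh)


def load_bag(directory: str) -> ModelBag:
    with open(os.path.join(directory, "model_card.json")) as fh:
        card = json.load(fh)
    if card["family"] == "pchazard":
        cfg = card["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        config = HazardNetConfig(**cfg)
    else:
        config = ParametricConfig(**card["config"])
    members = []
    for i in range(card["bag_size"]):
        with open(os.path.join(directory, f"member_{i:02d}.json")) as fh:
            members.append(_model_from_json(json.load(fh)))
    return ModelBag(
        members=members,
        member_seeds=card["member_seeds"],
        config=config,
        encode_stats=_prov_from_json(card["encode_stats"]),
    )
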