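"""The identified-model container and its lossless JSON (de)serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hankel import ARXParams
from .hill import HillParams

__all__ = ["IdentifiedModel"]


@dataclass
class IdentifiedModel:
    """One output molecule's identified NARX model.

    ``inputs`` is the chosen input set, each with its Hill nonlinearity in
    ``hill`` and its numerator coefficients inside ``arx``.  ``provenance``
    records the config snapshot and seeds that produced the fit, so the model
    can be regenerated from inputs alone.
    """

    output: str
    inputs: list[str]
    hill: dict[str, HillParams]
    arx: ARXParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.hill) != set(self.arx.inputs) or set(self.inputs) != set(self.hill):
            raise ValueError("inputs, hill keys and arx.inputs must agree")

    def to_dict(self) -> dict:
        return {
            "output": self.output,
            "inputs": list(self.inputs),
            "hill": {k: {"n": p.n, "K": p.K} for k, p in self.hill.items()},
            "arx": {
                "a": self.arx.a.tolist(),
                "b": {k: v.tolist() for k, v in self.arx.b.items()},
                "m_y": self.arx.m_y,
                "m_u": self.arx.m_u,
                "inputs": list(self.arx.inputs),
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IdentifiedModel":
        arx = ARXParams(
            a=np.asarray(d["arx"]["a"], dtype=float),
            b={k: np.asarray(v, dtype=float) for k, v in d["arx"]["b"].items()},
            m_y=int(d["arx"]["m_y"]),
            m_u=int(d["arx"]["m_u"]),
            inputs=list(d["arx"]["inputs"]),
        )
        hill = {k: HillParams(n=v["n"], K=v["K"]) for k, v in d["hill"].items()}
        return cls(
            output=d["output"],
            inputs=list(d["inputs"]),
            hill=hill,
            arx=arx,
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "IdentifiedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
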