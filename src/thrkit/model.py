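"""Backbone model container shared by blocks, assemblies and file I/O.

A :class:`BackboneModel` is a list of chains; each chain is an ordered list
of segments (helices or placeholder loops) carrying per-residue backbone
coordinates plus bookkeeping labels (repeat index, helix name, loop flag).
Residue numbering is assigned sequentially per chain when writing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .geometry import RigidTransform


@dataclass
class Segment:
    """A run of consecutive residues with one label set.

    ``coords`` has shape (n_res, 4, 3) in N/CA/C/O order.
    """

    coords: np.ndarray
    helix: str = ""
    repeat: int = 0
    kind: str = "helix"  # "helix" | "loop"
    flags: Dict[str, bool] = field(default_factory=dict)

    @property
    def n_res(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1, :]

    def transformed(self, t: RigidTransform) -> "Segment":
        return Segment(
            t.apply(self.coords.reshape(-1, 3)).reshape(self.coords.shape),
            helix=self.helix,
            repeat=self.repeat,
            kind=self.kind,
            flags=dict(self.flags),
        )


@dataclass
class Chain:
    chain_id: str
    segments: List[Segment] = field(default_factory=list)

    @property
    def n_res(self) -> int:
        return sum(s.n_res for s in self.segments)

    @property
    def ca(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 3))
        return np.concatenate([s.ca for s in self.segments])

    @property
    def coords(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 4, 3))
        return np.concatenate([s.coords for s in self.segments])

    def transformed(self, t: RigidTransform) -> "Chain":
        return Chain(self.chain_id, [s.transformed(t) for s in self.segments])


@dataclass
class BackboneModel:
    """Chains of backbone residues plus free-form assembly metadata."""

    chains: List[Chain] = field(default_factory=list)
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_res(self) -> int:
        return sum(c.n_res for c in self.chains)

    def ca_coords(self) -> np.ndarray:
        if not self.chains:
            return np.empty((0, 3))
        return np.concatenate([c.ca for c in self.chains])

    def ca_index(self) -> List[Tuple[int, int]]:
        """(chain index, residue index within chain) per CA, in ca_coords order."""
        out: List[Tuple[int, int]] = []
        for ci, chain in enumerate(self.chains):
            for ri in range(chain.n_res):
                out.append((ci, ri))
        return out

    def transformed(self, t: RigidTransform) -> "BackboneModel":
        return BackboneModel([c.transformed(t) for c in self.chains], dict(self.meta))

    def iter_segments(self) -> Iterator[Tuple[Chain, Segment]]:
        for chain in self.chains:
            for seg in chain.segments:
                yield chain, seg

    def merged(self, other: "BackboneModel") -> "BackboneModel":
        """Concatenate chains of two models, reassigning chain ids."""
        chains = [c for c in self.chains] + [c for c in other.chains]
        out = BackboneModel(chains, dict(self.meta))
        out.reassign_chain_ids()
        return out

    def reassign_chain_ids(self) -> None:
        for i, chain in enumerate(self.chains):
            chain.chain_id = chain_id_for(i)


_ONE_LETTER = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [
    chr(c) for c in range(ord("a"), ord("z") + 1)
]


def chain_id_for(i: int) -> str:
    """Chain id sequence A..Z, a..z, then two-letter AA, AB, ...."""
    if i < len(_ONE_LETTER):
        return _ONE_LETTER[i]
    i -= len(_ONE_LETTER)
    hi, lo = divmod(i, len(_ONE_LETTER))
    if hi >= len(_ONE_LETTER):
        raise ValueError("too many chains")
    return _ONE_LETTER[hi] + _ONE_LETTER[lo]
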