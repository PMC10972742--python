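"""Coordinate file output/input (PDB and mmCIF) via gemmi.

Backbone-only models are written as poly-alanine with occupancy 1.00 and
B-factor 0.00 at standard 1e-3 A coordinate precision.  Chain ids run
A..Z, a..z; models with more than 52 chains require mmCIF (two-letter ids).
The per-residue segment annotation (repeat index) goes into the PDB segid
column; mmCIF output does not carry it (blueprints, not coordinate files,
are the annotated source of truth).
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import gemmi
import numpy as np

from ..constants import ATOM_ORDER
from ..model import BackboneModel, Chain, Segment

logger = logging.getLogger(__name__)

_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


class StructureIOError(IOError):
    pass


def _format_from_path(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f in ("pdb", "cif", "mmcif"):
            return "pdb" if f == "pdb" else "mmcif"
        raise StructureIOError(f"unknown format {fmt!r}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        return "pdb"
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    raise StructureIOError(f"cannot infer format from extension {ext!r}")


def write_structure(model: BackboneModel, path: str, fmt: Optional[str] = None) -> None:
    """Write a backbone model to PDB or mmCIF (format from ``fmt`` or the
    file extension)."""
    if model.n_res == 0:
        raise StructureIOError("refusing to write an empty model")
    fmt_ = _format_from_path(path, fmt)
    if fmt_ == "pdb" and model.n_chains > 52:
        raise StructureIOError(
            f"{model.n_chains} chains exceed the PDB 52-chain id space; write mmCIF"
        )
    st = gemmi.Structure()
    st.name = str(model.meta.get("architecture", "thrkit model"))
    gm = gemmi.Model("1")
    serial = 1
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        resseq = 0
        for seg in chain.segments:
            for i in range(seg.n_res):
                resseq += 1
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(resseq, " ")
                res.segment = f"R{seg.repeat}" if seg.kind == "helix" else "LOOP"
                for k, aname in enumerate(ATOM_ORDER):
                    at = gemmi.Atom()
                    at.name = aname
                    at.element = gemmi.Element(_ELEMENTS[aname])
                    x, y, z = seg.coords[i, k]
                    at.pos = gemmi.Position(float(x), float(y), float(z))
                    at.occ = 1.0
                    at.b_iso = 0.0
                    at.serial = serial
                    serial += 1
                    res.add_atom(at)
                gc.add_residue(res)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    if fmt_ == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def read_structure(path: str) -> BackboneModel:
    """Read backbone (N, CA, C, O) coordinates from a PDB/mmCIF file.

    Non-backbone atoms are ignored (with a logged count); residues missing
    any backbone atom are skipped with a warning.
    """
    if not os.path.exists(path):
        raise StructureIOError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureIOError(f"{path} contains no models")
    gm = st[0]
    model = BackboneModel()
    ignored = 0
    skipped = 0
    for gc in gm:
        coords = []
        for res in gc:
            atoms = {}
            for at in res:
                if at.name in ATOM_ORDER:
                    atoms[at.name] = [at.pos.x, at.pos.y, at.pos.z]
                else:
                    ignored += 1
            if len(atoms) < len(ATOM_ORDER):
                skipped += 1
                logger.warning(
                    "residue %s %s/%s missing backbone atoms; skipped",
                    gc.name, res.seqid.num, res.name,
                )
                continue
            coords.append([atoms[a] for a in ATOM_ORDER])
        if not coords:
            continue
        seg = Segment(np.asarray(coords, dtype=float))
        model.chains.append(Chain(gc.name, [seg]))
    if ignored:
        logger.info("ignored %d non-backbone atoms in %s", ignored, path)
    if model.n_res == 0:
        raise StructureIOError(f"{path} contains no parseable backbone residues")
    return model
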