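"""Ideal straight alpha-helix constants.

Every helix this package builds is the same ideal straight alpha-helix:
rise 1.5 A per residue, twist +100 deg per residue (right-handed), CA atoms
on a cylinder of radius 2.3 A about the helix axis.  The remaining backbone
atoms (N, C, O) lie on their own coaxial cylinders; their parameters were
obtained once by constructing a poly-backbone from ideal internal
coordinates (bond lengths N-CA 1.458, CA-C 1.525, C-N 1.329, C-O 1.231 A;
trans peptide, omega = 180 deg) and solving the free torsions/angles
(phi = -57.484, psi = -47.313, tau N-CA-C = 108.783, CA-C-N = 119.093 deg)
so that the resulting helix has exactly the rise/twist/radius above.  The
cylindrical parameters of that solution are frozen here; rebuilding atoms
from them reproduces the internal-coordinate chain to ~1e-12 A, so bond
lengths are exactly the ideals listed.

All angles in degrees, lengths in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Tuple

#: Backbone atom order used throughout the package.
ATOM_ORDER: Tuple[str, str, str, str] = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class IdealHelixParams:
    """Frozen geometric definition of the ideal straight alpha-helix.

    ``atom_cylinders`` maps atom name -> (radius, phase offset relative to
    the CA of the same residue in degrees, z offset relative to the CA).
    """

    rise: float = 1.5
    twist: float = 100.0
    ca_radius: float = 2.3
    atom_cylinders: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: MappingProxyType(
            {
                "N": (1.572373205101, -26.360680029925, -0.918814776743),
                "CA": (2.300000000000, 0.000000000000, 0.000000000000),
                "C": (1.646908124918, 27.757418365963, 1.013573472308),
                "O": (1.847388870163, 22.422411753641, 2.217238245792),
            }
        )
    )
    # ideal covalent geometry realized by the cylinders above
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231


#: The single source of helix geometry for the whole package.
IDEAL_HELIX = IdealHelixParams()

#: Geometric identity tolerance (rotations in rad / lengths in A).
GEOM_TOL = 1e-6
#: Coordinate-file round-trip tolerance (PDB precision).
FILE_TOL = 1e-3
#: Default CA-CA hard-sphere clash cutoff for backbone-only models.
CLASH_CUTOFF = 3.5
#: Probe radius used when reporting ring outside/inside diameters.
DIAMETER_PROBE = 2.0
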