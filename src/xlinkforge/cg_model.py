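"""Two-center coarse-grained protein representation and cross-link geometry.

Each residue is reduced to its alpha-carbon position and the centroid of its
side-chain heavy atoms (the "side-chain center", SC).  A chemical cross-link
between residues *i* and *j* is described by anchor points X_i and X_j placed
on the respective Ca -> SC axes; the internal coordinates of the linked
fragment are the anchor-anchor distance d_XiXj, the two virtual-bond angles
theta_Xi (Ca_i...X_i...X_j) and theta_Xj (Ca_j...X_j...X_i) and the
virtual-bond dihedral gamma (Ca_i...X_i...X_j...Ca_j).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Cross-product-norm tolerance (A^2) below which a dihedral is undefined.
COLLINEAR_TOL = 1e-8

#: Sentinel returned for an undefined (degenerate) dihedral angle.
GAMMA_UNDEFINED = float("nan")

#: Names of backbone heavy atoms (everything else heavy is side chain;
#: CB is included in the side chain, per the two-center convention).
_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CGResidue:
    """One coarse-grained residue: Ca position plus side-chain center.

    ``index`` is the author (PDB) residue number, preserved for cross-link
    matching; ``icode`` keeps any insertion code so insertion-coded residues
    remain distinguishable.  For glycine (and residues whose side-chain atoms
    are all missing) ``sc == ca`` by convention.
    """

    index: int
    aa: str
    ca: np.ndarray
    sc: np.ndarray
    icode: str = ""

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.sc = np.asarray(self.sc, dtype=float)
        if self.ca.shape != (3,) or self.sc.shape != (3,):
            raise ValueError("ca and sc must be 3-vectors")

    @property
    def sc_axis_length(self) -> float:
        """|sc - ca| in Angstrom (0 for glycine)."""
        return float(np.linalg.norm(self.sc - self.ca))


@dataclass
class CGChain:
    """An ordered single chain of :class:`CGResidue`.

    Author numbering must be strictly increasing; consecutive Ca-Ca
    distances outside (2.0, 4.5) A trigger a warning (broken or non-protein
    geometry) but are tolerated, since decoys and toy fixtures may violate
    them deliberately.
    """

    residues: list[CGResidue]
    chain_id: str = "A"
    _pos: dict[int, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("chain must contain at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        self._pos = {r.index: p for p, r in enumerate(self.residues)}
        d = np.linalg.norm(np.diff(self.ca_coords(), axis=0), axis=1)
        bad = (d <= 2.0) | (d >= 4.5)
        if bad.any():
            warnings.warn(
                f"{bad.sum()} consecutive Ca-Ca distances outside (2.0, 4.5) A",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def position(self, index: int) -> int:
        """Internal 0-based position of the residue with author number ``index``."""
        try:
            return self._pos[index]
        except KeyError:
            raise KeyError(f"index error: residue {index} not in chain "
                           f"{self.chain_id!r}") from None

    def residue(self, index: int) -> CGResidue:
        return self.residues[self.position(index)]

    def __contains__(self, index: int) -> bool:
        return index in self._pos

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def sc_coords(self) -> np.ndarray:
        return np.array([r.sc for r in self.residues])

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class XLGeometry:
    """Internal coordinates of a cross-linked residue pair (Fig.-style anchors).

    Angles are in radians; ``gamma`` lies in (-pi, pi] or is NaN when the
    four points are (nearly) collinear and the dihedral is undefined.
    """

    d_xixj: float
    theta_xi: float
    theta_xj: float
    gamma: float
    d_xi: float
    d_xj: float

    @property
    def gamma_defined(self) -> bool:
        return not math.isnan(self.gamma)


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex ``b``, in [0, pi]."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Right-handed (IUPAC) dihedral p0-p1-p2-p3 in (-pi, pi].

    Returns :data:`GAMMA_UNDEFINED` (NaN) when either bonded triple is
    collinear within :data:`COLLINEAR_TOL`.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < COLLINEAR_TOL or np.linalg.norm(n2) < COLLINEAR_TOL:
        return GAMMA_UNDEFINED
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.atan2(y, x)
    # atan2 yields [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention
    return ang if ang != -math.pi else math.pi


def wrap_angle(gamma: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (rad) into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(gamma, float), 2.0 * np.pi)


def anchor_point(res: CGResidue, d_x: float,
                 fallback_axis: np.ndarray | None = None) -> np.ndarray:
    """Point at distance ``d_x`` from Ca along the Ca -> SC axis.

    Offsets larger than |sc - ca| are allowed (anchor beyond the SC center).
    For a zero-length axis (glycine) a ``fallback_axis`` must be supplied
    unless ``d_x`` is 0.
    """
    axis = res.sc - res.ca
    n = np.linalg.norm(axis)
    if d_x == 0.0:
        return res.ca.copy()
    if n == 0.0:
        if fallback_axis is None:
            raise ValueError(
                f"degenerate axis: residue {res.index} has sc == ca and no "
                f"fallback axis was supplied")
        axis = np.asarray(fallback_axis, float)
        n = np.linalg.norm(axis)
        if n == 0.0:
            raise ValueError("degenerate axis: zero-length fallback")
    return res.ca + d_x * axis / n


def xlink_geometry(chain: CGChain, i: int, j: int,
                   d_xi: float, d_xj: float) -> XLGeometry:
    """All cross-link internal coordinates for residues ``i`` and ``j``.

    ``i`` and ``j`` are author residue numbers.  The dihedral is reported as
    NaN (undefined sentinel) for collinear arrangements; the angles are still
    returned.
    """
    if i == j:
        raise ValueError("cross-link endpoints must differ")
    ri, rj = chain.residue(i), chain.residue(j)
    xi = anchor_point(ri, d_xi)
    xj = anchor_point(rj, d_xj)
    d = float(np.linalg.norm(xj - xi))
    try:
        theta_i = bond_angle(ri.ca, xi, xj)
    except ValueError:          # anchor at Ca: angle undefined
        theta_i = GAMMA_UNDEFINED
    try:
        theta_j = bond_angle(rj.ca, xj, xi)
    except ValueError:
        theta_j = GAMMA_UNDEFINED
    gamma = dihedral_angle(ri.ca, xi, xj, rj.ca)
    return XLGeometry(d_xixj=d, theta_xi=theta_i, theta_xj=theta_j,
                      gamma=gamma, d_xi=d_xi, d_xj=d_xj)


def ca_distance(chain: CGChain, i: int, j: int) -> float:
    """Ca-Ca distance (A) between author-numbered residues ``i`` and ``j``."""
    return float(np.linalg.norm(chain.residue(i).ca - chain.residue(j).ca))


def sc_distance(chain: CGChain, i: int, j: int) -> float:
    """Side-chain-center distance (A) between residues ``i`` and ``j``."""
    return float(np.linalg.norm(chain.residue(i).sc - chain.residue(j).sc))


def backbone_dihedral(chain: CGChain, i: int) -> float:
    """Backbone virtual-bond dihedral gamma over Ca(i)..Ca(i+3), radians.

    ``i`` is the author number of the first residue of the quadruplet; the
    next three residues in chain order are used.
    """
    p = chain.position(i)
    if p + 3 >= len(chain):
        raise KeyError(f"index error: backbone dihedral at {i} needs three "
                       f"following residues")
    r = chain.residues
    return dihedral_angle(r[p].ca, r[p + 1].ca, r[p + 2].ca, r[p + 3].ca)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_structure(path, chain_id: str | None = None,
                   model_index: int = 0) -> CGChain:
    """Parse a PDB file into a :class:`CGChain`.

    One CG residue is produced per standard amino-acid residue possessing a
    Ca atom; ``sc`` is the centroid of the side-chain heavy atoms (CB and
    beyond).  Residues without any side-chain heavy atom fall back to the
    glycine convention ``sc = ca`` (with a warning for non-glycine).  For
    disordered atoms Biopython's default altloc selection (highest occupancy)
    is used.

    Parameters
    ----------
    path : str or Path
        PDB file.
    chain_id : str, optional
        Chain to extract; default: first chain of the model.
    model_index : int
        0-based model number for multi-model files.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("xl", str(path))
    models = list(structure)
    if not 0 <= model_index < len(models):
        raise ValueError(f"model {model_index} not found ({len(models)} models)")
    model = models[model_index]
    if chain_id is None:
        chains = list(model)
        if not chains:
            raise ValueError("chain not found: file contains no chains")
        chain = chains[0]
        chain_id = chain.id
    else:
        if not model.has_id(chain_id):
            raise ValueError(f"chain not found: {chain_id!r}")
        chain = model[chain_id]

    residues: list[CGResidue] = []
    for res in chain:
        if not is_aa(res, standard=True):
            continue
        if "CA" not in res:
            warnings.warn(f"residue {res.id[1]} has no Ca atom; skipped",
                          stacklevel=2)
            continue
        aa = _THREE_TO_ONE.get(res.get_resname().strip(), "X")
        ca = np.asarray(res["CA"].get_coord(), dtype=float)
        side = [np.asarray(atom.get_coord(), dtype=float)
                for atom in res
                if atom.element != "H" and atom.get_id() not in _BACKBONE_ATOMS]
        if side:
            sc = np.mean(side, axis=0)
        else:
            if aa != "G":
                warnings.warn(
                    f"residue {res.id[1]} ({aa}) has no side-chain heavy "
                    f"atoms; using sc = ca", stacklevel=2)
            sc = ca.copy()
        residues.append(CGResidue(index=res.id[1], aa=aa, ca=ca, sc=sc,
                                  icode=res.id[2].strip()))
    if not residues:
        raise ValueError(f"chain {chain_id!r} contains no standard residues "
                         f"with Ca atoms")
    return CGChain(residues=residues, chain_id=str(chain_id))


def write_cg_pdb(chain: CGChain, path) -> None:
    """Write a minimal CG PDB for visualization: Ca as CA, SC as pseudo-atom.

    The SC pseudo-atom is emitted as a second record named ``SC`` in the same
    residue; glycine gets no SC record.  Intended for inspection only; use
    :func:`xlinkforge.fixtures.write_pdb` to emit files that
    :func:`read_structure` re-ingests losslessly.
    """
    with open(path, "w") as fh:
        serial = 1
        for r in chain:
            resname = ONE_TO_THREE.get(r.aa, "UNK")
            fh.write(_atom_record(serial, "CA", resname, chain.chain_id,
                                  r.index, r.ca, element="C"))
            serial += 1
            if r.sc_axis_length > 0:
                fh.write(_atom_record(serial, "SC", resname, chain.chain_id,
                                      r.index, r.sc, element="C"))
                serial += 1
        fh.write("TER\nEND\n")


def _atom_record(serial, name, resname, chain_id, resseq, xyz, element="C"):
    return (f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain_id:1s}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")


# ---------------------------------------------------------------------------
# Cartesian gradients of the internal coordinates
# (used by the toy refiner; all verified against finite differences in tests)
# ---------------------------------------------------------------------------

def distance_gradient(p: np.ndarray, q: np.ndarray):
    """Gradients of |p - q| with respect to p and q."""
    u = p - q
    d = np.linalg.norm(u)
    if d == 0.0:
        raise ValueError("degenerate distance: coincident points")
    g = u / d
    return g, -g


def angle_gradient(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Gradients of the angle a-b-c with respect to a, b and c."""
    u = a - b
    v = c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cosang = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sinang = math.sqrt(max(1.0 - cosang * cosang, 0.0))
    if sinang < 1e-10:
        raise ValueError("degenerate angle gradient: collinear points")
    ga = (cosang * uh - vh) / (nu * sinang)
    gc = (cosang * vh - uh) / (nv * sinang)
    gb = -(ga + gc)
    return ga, gb, gc


def dihedral_gradient(p0, p1, p2, p3):
    """Gradients of the dihedral p0-p1-p2-p3 with respect to the four points."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    if n1sq < COLLINEAR_TOL ** 2 or n2sq < COLLINEAR_TOL ** 2:
        raise ValueError("degenerate dihedral gradient: collinear points")
    nb2 = np.linalg.norm(b2)
    g0 = -nb2 / n1sq * n1
    g3 = nb2 / n2sq * n2
    s12 = np.dot(b1, b2) / (nb2 * nb2)
    s32 = np.dot(b3, b2) / (nb2 * nb2)
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = -(1.0 + s32) * g3 + s12 * g0
    return g0, g1, g2, g3


def anchor_jacobians(res: CGResidue, d_x: float):
    """Jacobians dX/dca and dX/dsc of the anchor X = ca + d_x * unit(sc - ca).

    Both are symmetric 3x3 matrices; dX/dca + dX/dsc = I.
    """
    v = res.sc - res.ca
    n = np.linalg.norm(v)
    if n == 0.0:
        if d_x == 0.0:
            return np.eye(3), np.zeros((3, 3))
        raise ValueError("degenerate axis: cannot differentiate anchor")
    u = v / n
    proj = (np.eye(3) - np.outer(u, u)) * (d_x / n)
    return np.eye(3) - proj, proj
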