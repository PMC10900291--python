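"""Synthetic input generators: ideal/perturbed CG helices, toy PDB files,
Boltzmann samples from known potentials, and cross-link sets with a
controlled fraction of false (over-length) restraints.

These generators are first-class: they define the study conditions under
which the restraint machinery is exercised and validated.  An ideal helix
with the default rise (1.5 A/residue) and twist (100 deg/residue) has
consecutive Ca-Ca distances of ~3.8 A and interior backbone virtual-bond
dihedrals of ~+50 deg, inside the helical restraint window (30-70 deg).
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_model import CGChain, CGResidue, ONE_TO_THREE
from .restraints import REAGENTS, ReagentSpec
from .xlink_planner import CrossLink, CrossLinkSet
from .pmf_fit import R_KCAL

logger = logging.getLogger(__name__)


@dataclass
class HelixSpec:
    """Geometry of an ideal CG helix.

    rise (A/residue), twist (deg/residue) and radius (A) place the Ca atoms
    on a helical lattice; side-chain centers sit ``sc_offset`` A radially
    outward.  ``sequence`` assigns residue types (cycled if shorter than
    ``n_res``); the default all-lysine sequence keeps every residue
    cross-linkable by the lysine-specific reagents.
    """

    n_res: int = 20
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    sc_offset: float = 2.0
    sequence: str = "K"

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise ValueError("helix needs at least 4 residues")
        if min(self.rise, self.radius, self.sc_offset) <= 0:
            raise ValueError("helix geometry must be positive")


@dataclass
class DecoySpec:
    """Decoy construction: hinge rotations plus Gaussian coordinate noise."""

    base: CGChain
    hinge_indices: list = field(default_factory=list)
    rotation_magnitudes: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n = len(self.base)
        for h in self.hinge_indices:
            p = self.base.position(h)
            if p == 0 or p >= n - 1:
                raise ValueError(f"hinge {h} must be interior")
        if len(self.rotation_magnitudes) != len(self.hinge_indices):
            raise ValueError("one rotation magnitude per hinge required")


def ideal_helix(spec: HelixSpec | None = None, **kwargs) -> CGChain:
    """Build an ideal CG helix; see :class:`HelixSpec` for the lattice."""
    if spec is None:
        spec = HelixSpec(**kwargs)
    phi = math.radians(spec.twist)
    residues = []
    for k in range(spec.n_res):
        radial = np.array([math.cos(k * phi), math.sin(k * phi), 0.0])
        ca = spec.radius * radial + np.array([0.0, 0.0, k * spec.rise])
        sc = ca + spec.sc_offset * radial
        aa = spec.sequence[k % len(spec.sequence)]
        residues.append(CGResidue(index=k + 1, aa=aa, ca=ca,
                                  sc=ca.copy() if aa == "G" else sc))
    return CGChain(residues=residues, chain_id="A")


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + math.sin(angle_rad) * K
            + (1 - math.cos(angle_rad)) * K @ K)


def perturb(spec: DecoySpec) -> CGChain:
    """Apply hinge rotations and Gaussian noise to a chain (seeded).

    Each hinge rotates everything downstream of it about a random axis
    through the hinge Ca.  With no hinges and zero noise this is the
    identity.
    """
    rng = np.random.default_rng(spec.seed)
    ca = spec.base.ca_coords().copy()
    sc = spec.base.sc_coords().copy()
    for h, mag in zip(spec.hinge_indices, spec.rotation_magnitudes):
        p = spec.base.position(h)
        axis = rng.normal(size=3)
        R = _rotation_matrix(axis, math.radians(mag))
        pivot = ca[p]
        ca[p + 1:] = (ca[p + 1:] - pivot) @ R.T + pivot
        sc[p + 1:] = (sc[p + 1:] - pivot) @ R.T + pivot
    if spec.noise_sd > 0:
        ca = ca + rng.normal(scale=spec.noise_sd, size=ca.shape)
        sc = sc + rng.normal(scale=spec.noise_sd, size=sc.shape)
    residues = [CGResidue(index=r.index, aa=r.aa, ca=ca[k], sc=sc[k],
                          icode=r.icode)
                for k, r in enumerate(spec.base.residues)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # decoys may break ideal geometry
        return CGChain(residues=residues, chain_id=spec.base.chain_id)


def boltzmann_sample(potential, T: float, n: int, seed: int,
                     step: float = 1.0, x0: float = 0.0,
                     bounds: tuple | None = None) -> np.ndarray:
    """Metropolis samples of a 1-D coordinate under a known potential.

    Single chain, uniform +/- ``step`` proposals, 10% burn-in discarded.
    ``potential(x)`` returns kcal/mol; proposals outside ``bounds`` are
    rejected.  The acceptance rate is logged.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rt = R_KCAL * T
    rng = np.random.default_rng(seed)
    total = int(math.ceil(n / 0.9))
    x = float(x0)
    e = float(potential(x))
    out = np.empty(total)
    accepted = 0
    steps = rng.uniform(-step, step, size=total)
    logu = np.log(rng.uniform(size=total))
    for k in range(total):
        xp = x + steps[k]
        if bounds is None or (bounds[0] <= xp <= bounds[1]):
            ep = float(potential(xp))
            if ep - e <= -rt * logu[k]:
                x, e = xp, ep
                accepted += 1
        out[k] = x
    logger.info("boltzmann_sample: acceptance rate %.3f", accepted / total)
    return out[total - n:]


def make_xlink_fixture(chain: CGChain, reagent: str | ReagentSpec,
                       n_true: int, n_false: int, seed: int,
                       false_margin: float = 5.0) -> CrossLinkSet:
    """A cross-link set with controlled true/false composition.

    True links are type-allowed pairs whose Ca-Ca distance is within the
    reagent's maximum span; false links exceed that span by more than
    ``false_margin`` A (over-length restraints, capturable only through
    distortion).  Pairs are drawn without replacement from the candidates.
    """
    spec = REAGENTS[reagent] if isinstance(reagent, str) else reagent
    rng = np.random.default_rng(seed)
    true_cands, false_cands = [], []
    residues = chain.residues
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ra, rb = residues[a], residues[b]
            if not spec.allows(ra.aa, rb.aa):
                continue
            d = float(np.linalg.norm(ra.ca - rb.ca))
            excess = d - spec.max_ca_span(ra.aa, rb.aa)
            if excess <= 0:
                true_cands.append((ra.index, rb.index))
            elif excess > false_margin:
                false_cands.append((ra.index, rb.index))
    if len(true_cands) < n_true or len(false_cands) < n_false:
        raise ValueError(
            f"cannot construct fixture: {len(true_cands)} satisfied and "
            f"{len(false_cands)} over-length candidates available")
    links = []
    for pool, count in ((true_cands, n_true), (false_cands, n_false)):
        for idx in rng.choice(len(pool), size=count, replace=False):
            i, j = pool[idx]
            links.append(CrossLink(i=i, j=j, reagent=spec.name))
    return CrossLinkSet(links=links, protein_id=chain.chain_id)


# ---------------------------------------------------------------------------
# toy PDB output (re-ingestable by cg_model.read_structure)
# ---------------------------------------------------------------------------

def write_pdb(chains, path) -> None:
    """Write CG chains as a minimal all-atom-style PDB.

    Each residue gets a CA record at the Ca position and, for non-glycine,
    a single CB record at the side-chain center; the centroid convention
    then reproduces ``sc`` exactly on re-reading (to PDB coordinate
    precision, 1e-3 A).  Pass a list of chains to emit a multi-model file.
    """
    models = chains if isinstance(chains, (list, tuple)) else [chains]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m, chain in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for r in chain:
                resname = ONE_TO_THREE.get(r.aa, "ALA")
                fh.write(_record(serial, "CA", resname, chain.chain_id,
                                 r.index, r.ca))
                serial += 1
                if r.aa != "G" and r.sc_axis_length > 0:
                    fh.write(_record(serial, "CB", resname, chain.chain_id,
                                     r.index, r.sc))
                    serial += 1
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _record(serial, name, resname, chain_id, resseq, xyz):
    return (f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain_id:1s}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}           C\n")
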