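import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xlinkforge import CGChain, CGResidue, ideal_helix


@pytest.fixture
def helix20():
    return ideal_helix(n_res=20)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def make_chain(ca_sc_pairs, aas=None, start_index=1):
    """Build a CGChain from explicit (ca, sc) coordinate pairs.

    Geometry warnings (toy chains break ideal Ca-Ca spacing) are
    suppressed.
    """
    aas = aas or "K" * len(ca_sc_pairs)
    residues = [CGResidue(index=start_index + k, aa=aas[k],
                          ca=np.asarray(ca, float), sc=np.asarray(sc, float))
                for k, (ca, sc) in enumerate(ca_sc_pairs)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CGChain(residues=residues, chain_id="A")


def rigid_transform_chain(chain, seed=0, translation=(5.0, -3.0, 11.0)):
    """Apply a random proper rotation plus translation to a chain."""
    R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    t = np.asarray(translation, float)
    residues = [CGResidue(index=r.index, aa=r.aa, ca=R @ r.ca + t,
                          sc=R @ r.sc + t, icode=r.icode)
                for r in chain.residues]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CGChain(residues=residues, chain_id=chain.chain_id)


def mirror_chain(chain):
    """Reflect a chain through the xy-plane (improper transform)."""
    M = np.diag([1.0, 1.0, -1.0])
    residues = [CGResidue(index=r.index, aa=r.aa, ca=M @ r.ca, sc=M @ r.sc,
                          icode=r.icode)
                for r in chain.residues]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CGChain(residues=residues, chain_id=chain.chain_id)
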