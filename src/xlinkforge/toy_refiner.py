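"""Restrained minimization on a CG chain: an end-to-end exercise of the
restraint gradients.

The full modeling energy combines a physical force field with the
cross-link and dihedral penalty terms; reimplementing a force field is out
of scope here, so a per-site harmonic tether to the starting coordinates
stands in for it.  This isolates the restraint-gradient behavior: a
satisfied flat-bottom restraint exerts no force, a moderately violated one
pulls side chains inside its upper boundary, and a grossly violated one
sits on the bounded plateau and leaves the structure untouched.

Minimization is plain gradient descent with Armijo backtracking, so the
energy trace is monotone non-increasing by construction.  All Cartesian
gradients are analytic (chain rule through the anchor-point geometry) and
are validated against finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import cg_model
from .cg_model import (CGChain, CGResidue, XLGeometry, anchor_jacobians,
                       anchor_point, angle_gradient, dihedral_angle,
                       dihedral_gradient, distance_gradient)
from .restraints import (dihedral_penalty, lorentz_energy, mdbased_energy,
                         resolve_potential, statistical_energy)


@dataclass
class RefineConfig:
    """Minimizer settings: tether weight kcal/(mol A^2), initial step (A),
    iteration cap, energy-decrease tolerance (kcal/mol), seed."""

    tether_weight: float = 1.0
    step_size: float = 0.1
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tether_weight, self.step_size, self.max_iter,
               self.tol) <= 0:
            raise ValueError("all refine settings must be positive")


def _chain_coords(chain: CGChain) -> np.ndarray:
    """Stack (n, 2, 3): ca rows then sc rows per residue."""
    return np.stack([chain.ca_coords(), chain.sc_coords()], axis=1)


def _coords_chain(chain: CGChain, coords: np.ndarray) -> CGChain:
    residues = [CGResidue(index=r.index, aa=r.aa, ca=coords[k, 0],
                          sc=coords[k, 1], icode=r.icode)
                for k, r in enumerate(chain.residues)]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CGChain(residues=residues, chain_id=chain.chain_id)


def restraint_energy_gradient(chain: CGChain, coords: np.ndarray, xlinks,
                              potentials, dihedral_restraints=()):
    """Energy and Cartesian gradient of all restraint terms at ``coords``.

    ``coords`` has shape (n, 2, 3): per residue, Ca then SC.  Returns
    (energy, gradient of the same shape).
    """
    grad = np.zeros_like(coords)
    energy = 0.0
    pos = {r.index: k for k, r in enumerate(chain.residues)}

    for link in xlinks:
        kind, params = resolve_potential(link, potentials)
        a, b = pos[link.i], pos[link.j]
        conf = link.confidence
        if kind == "lorentz":
            p, q = coords[a, 1], coords[b, 1]
            d = float(np.linalg.norm(p - q))
            e, dEdd = lorentz_energy(d, params)
            gp, gq = distance_gradient(p, q)
            grad[a, 1] += conf * dEdd * gp
            grad[b, 1] += conf * dEdd * gq
        elif kind == "statistical":
            p, q = coords[a, 0], coords[b, 0]
            d = float(np.linalg.norm(p - q))
            e, dEdd = statistical_energy(d, params)
            gp, gq = distance_gradient(p, q)
            grad[a, 0] += conf * dEdd * gp
            grad[b, 0] += conf * dEdd * gq
        elif kind == "mdbased":
            e = _mdbased_cartesian(coords, a, b, params, conf, grad, chain)
        else:
            raise ValueError(f"parameter error: unknown potential kind "
                             f"{kind!r}")
        energy += conf * e if kind != "mdbased" else e

    for first_index, restraint in dihedral_restraints:
        k = pos[first_index]
        pts = [coords[k + m, 0] for m in range(4)]
        gamma = dihedral_angle(*pts)
        if math.isnan(gamma):
            continue
        e, dEdg = dihedral_penalty(math.degrees(gamma), restraint)
        energy += e
        if dEdg != 0.0:
            for m, g in enumerate(dihedral_gradient(*pts)):
                grad[k + m, 0] += dEdg * g
    return energy, grad


def _mdbased_cartesian(coords, a, b, params, conf, grad, chain):
    """MD-based term: analytic chain rule through the anchor geometry."""
    ca_i, sc_i = coords[a, 0], coords[a, 1]
    ca_j, sc_j = coords[b, 0], coords[b, 1]
    res_i = CGResidue(index=0, aa="X", ca=ca_i, sc=sc_i)
    res_j = CGResidue(index=1, aa="X", ca=ca_j, sc=sc_j)
    xi = anchor_point(res_i, params.d_xi)
    xj = anchor_point(res_j, params.d_xj)
    d = float(np.linalg.norm(xj - xi))
    geom = XLGeometry(
        d_xixj=d,
        theta_xi=cg_model.bond_angle(ca_i, xi, xj),
        theta_xj=cg_model.bond_angle(ca_j, xj, xi),
        gamma=dihedral_angle(ca_i, xi, xj, ca_j),
        d_xi=params.d_xi, d_xj=params.d_xj)
    e, (dEdd, dEti, dEtj, dEdg) = mdbased_energy(geom, params)
    e *= conf

    # accumulate dE/d{ca_i, X_i, X_j, ca_j} then push X-gradients through
    # the anchor Jacobians onto (ca, sc)
    g_cai = np.zeros(3)
    g_caj = np.zeros(3)
    g_xi = np.zeros(3)
    g_xj = np.zeros(3)

    gd_xi, gd_xj = distance_gradient(xi, xj)
    g_xi += dEdd * gd_xi
    g_xj += dEdd * gd_xj

    ga, gb, gc = angle_gradient(ca_i, xi, xj)        # theta_i at X_i
    g_cai += dEti * ga
    g_xi += dEti * gb
    g_xj += dEti * gc

    ga, gb, gc = angle_gradient(ca_j, xj, xi)        # theta_j at X_j
    g_caj += dEtj * ga
    g_xj += dEtj * gb
    g_xi += dEtj * gc

    g0, g1, g2, g3 = dihedral_gradient(ca_i, xi, xj, ca_j)
    g_cai += dEdg * g0
    g_xi += dEdg * g1
    g_xj += dEdg * g2
    g_caj += dEdg * g3

    J_ca_i, J_sc_i = anchor_jacobians(res_i, params.d_xi)
    J_ca_j, J_sc_j = anchor_jacobians(res_j, params.d_xj)
    grad[a, 0] += conf * (g_cai + J_ca_i @ g_xi)
    grad[a, 1] += conf * (J_sc_i @ g_xi)
    grad[b, 0] += conf * (g_caj + J_ca_j @ g_xj)
    grad[b, 1] += conf * (J_sc_j @ g_xj)
    return e


def restrained_minimize(chain: CGChain, xlinks, potentials,
                        dihedral_restraints=(),
                        cfg: RefineConfig | None = None):
    """Minimize tether + restraint energy by backtracking gradient descent.

    Returns ``(refined_chain, energy_trace)``; the trace (one entry per
    accepted iterate, starting energy first) is monotone non-increasing.
    Terminates when an iteration lowers the energy by less than ``cfg.tol``
    or when no productive step can be found.
    """
    cfg = cfg or RefineConfig()
    missing = [(l.i, l.j) for l in xlinks
               if l.i not in chain or l.j not in chain]
    if missing:
        raise ValueError(f"mapping error: cross-link residues not in chain: "
                         f"{missing}")
    x0 = _chain_coords(chain)
    x = x0.copy()

    def energy_grad(xc):
        e_r, g_r = restraint_energy_gradient(chain, xc, xlinks, potentials,
                                             dihedral_restraints)
        diff = xc - x0
        e = e_r + 0.5 * cfg.tether_weight * float((diff * diff).sum())
        g = g_r + cfg.tether_weight * diff
        return e, g

    e, g = energy_grad(x)
    if not np.isfinite(g).all():
        raise RuntimeError(_nan_diagnostic(chain, x, xlinks, potentials))
    trace = [e]
    step = cfg.step_size
    for _ in range(cfg.max_iter):
        gnorm2 = float((g * g).sum())
        if gnorm2 == 0.0:
            break
        # Armijo backtracking along -g
        alpha = step / max(math.sqrt(gnorm2), 1e-12)
        accepted = False
        for _ in range(40):
            xt = x - alpha * g
            et, gt = energy_grad(xt)
            if not np.isfinite(et) or not np.isfinite(gt).all():
                alpha *= 0.5
                continue
            if et <= e - 1e-4 * alpha * gnorm2:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        improvement = e - et
        x, e, g = xt, et, gt
        trace.append(e)
        step = min(alpha * math.sqrt(gnorm2) * 1.5, 10.0 * cfg.step_size)
        if improvement < cfg.tol:
            break
    return _coords_chain(chain, x), trace


def _nan_diagnostic(chain, coords, xlinks, potentials) -> str:
    """Name the restraint term that produced a non-finite gradient."""
    for link in xlinks:
        try:
            restraint_energy_gradient(chain, coords, [link], potentials)
        except (ValueError, FloatingPointError) as exc:
            return (f"NaN gradient: cross-link {link.i}-{link.j} "
                    f"({link.reagent}): {exc}")
        e, g = restraint_energy_gradient(chain, coords, [link], potentials)
        if not (np.isfinite(e) and np.isfinite(g).all()):
            return (f"NaN gradient: cross-link {link.i}-{link.j} "
                    f"({link.reagent})")
    return "NaN gradient in restraint terms"
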