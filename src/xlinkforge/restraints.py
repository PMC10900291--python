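"""Cross-link and dihedral restraint potentials with analytic first derivatives.

Three restraint families are provided:

* **Lorentz-like** flat-bottom potentials on the side-chain-center distance:
  zero inside [d_l, d_u], a bounded quartic-Lorentzian wall outside that
  saturates at the well depth ``A``, so a grossly violated restraint exerts
  no force (robustness against false cross-links).
* **Statistical** pseudopotentials on the Ca-Ca distance, the negative
  log of a skew-normal distance density with cross-link-specific shape
  parameters (a, b, c, sigma), scaled by RT and a confidence weight ``A``.
* **MD-based** distance-and-orientation potentials on the cross-link
  internal coordinates (d_XiXj, theta_Xi, theta_Xj, gamma): a sum of
  Gaussian terms in the distance and in each angle plus a cosine series
  in the dihedral, with coefficients fitted to potentials of mean force
  (see :mod:`xlinkforge.pmf_fit`).

A quartic flat-bottom penalty on backbone virtual-bond dihedral angles is
also provided (helical window 30-70 deg, extended window 120-240 deg), and
:func:`total_restraint_energy` assembles the composite penalty over a chain.

Units: kcal/mol, Angstrom, radians internally; restraint windows for
dihedrals are specified in degrees at the API boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import log_ndtr

from .cg_model import (CGChain, XLGeometry, backbone_dihedral, ca_distance,
                       sc_distance, xlink_geometry)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: kcal/(mol K) at T = 298 K -> RT = 0.591 kcal/mol (statistical potential).
RT_298 = 0.591


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------

@dataclass
class LorentzParams:
    """Flat-bottom Lorentz-like restraint parameters.

    d_l, d_u : flat-bottom boundaries (A); sigma : wall thickness (A);
    A : well depth / asymptotic plateau (kcal/mol).
    """

    d_l: float
    d_u: float
    sigma: float
    A: float

    def __post_init__(self) -> None:
        if not (0 <= self.d_l < self.d_u):
            raise ValueError("parameter error: require 0 <= d_l < d_u")
        if self.sigma <= 0 or self.A <= 0:
            raise ValueError("parameter error: sigma and A must be positive")


@dataclass
class StatisticalParams:
    """Skew-normal statistical potential parameters (Ca-distance based).

    ``b`` is the location (A), ``sigma`` the scale (A) and ``c`` the skewness
    of the distance density; ``a`` is its amplitude.  ``A`` is the confidence
    weight (dimensionless, 15 by default) and ``RT`` = 0.591 kcal/mol
    (T = 298 K) by default.
    """

    b: float
    c: float
    sigma: float
    a: float = 1.0
    A: float = 15.0
    RT: float = RT_298

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("parameter error: sigma must be positive")
        if self.a <= 0:
            raise ValueError("parameter error: amplitude a must be positive")


@dataclass
class MDBasedParams:
    """Coefficients of the MD-based (PMF-fitted) cross-link potential.

    ``dist_terms`` and the two ``angle_terms`` arrays hold Gaussian terms as
    (coefficient kcal/mol, center A or rad, width A or rad) triples;
    ``dihedral_terms`` holds cosine terms as (coefficient, phase rad,
    integer order) triples.  ``d_xi``/``d_xj`` are the Ca -> anchor offsets.
    """

    d_xi: float
    d_xj: float
    dist_terms: np.ndarray
    angle_terms_i: np.ndarray
    angle_terms_j: np.ndarray
    dihedral_terms: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dist_terms", "angle_terms_i", "angle_terms_j",
                     "dihedral_terms"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.shape[0] < 1 or arr.shape[1] != 3:
                raise ValueError(
                    f"parameter error: {name} must be an (N, 3) array, N >= 1")
            setattr(self, name, arr)
        for name in ("dist_terms", "angle_terms_i", "angle_terms_j"):
            if np.any(getattr(self, name)[:, 2] <= 0):
                raise ValueError(f"parameter error: {name} widths must be > 0")
        orders = self.dihedral_terms[:, 2]
        if np.any(orders < 1) or np.any(orders != np.round(orders)):
            raise ValueError("parameter error: dihedral orders must be "
                             "positive integers")


@dataclass
class DihedralRestraint:
    """Flat-bottom window restraint on a backbone virtual-bond dihedral.

    gamma_l, gamma_u : window boundaries in degrees (window taken modulo
    360); w_dih : quartic force constant, kcal/(mol rad^4), 50 by default.
    The helical window is (30, 70) deg and the extended window (120, 240).
    """

    gamma_l: float
    gamma_u: float
    w_dih: float = 50.0

    def __post_init__(self) -> None:
        if self.w_dih < 0:
            raise ValueError("parameter error: w_dih must be >= 0")
        if (self.gamma_u - self.gamma_l) % 360.0 == 0.0:
            raise ValueError("parameter error: empty dihedral window")


HELICAL_WINDOW = (30.0, 70.0)
EXTENDED_WINDOW = (120.0, 240.0)

#: Default Ca -> side-chain-end reach (A) used for maximum Ca-Ca spans
#: in violation analysis (lysine value; overridable per residue type).
DEFAULT_SC_REACH = 6.4
SC_REACH = {"K": 6.4, "C": 2.8, "S": 2.4, "T": 2.6, "M": 5.2, "E": 4.9,
            "D": 3.7}


@dataclass(frozen=True)
class ReagentSpec:
    """A cross-linking reagent: residue-pair specificity and distance bounds.

    ``pair_specificity`` is a frozenset of frozensets of 1-letter codes
    ('*' is a wildcard side); ``None`` means nonspecific (any pair).
    ``d_u`` is the upper flat-bottom boundary set by the maximum dimension
    of the reagent molecule; ``d_l`` defaults to 2.5 A.
    """

    name: str
    pair_specificity: frozenset | None
    d_u: float
    d_l: float = 2.5

    def allows(self, aa_i: str, aa_j: str) -> bool:
        if self.pair_specificity is None:
            return True
        pair = frozenset((aa_i, aa_j))
        for spec in self.pair_specificity:
            if pair == spec:
                return True
            if "*" in spec:
                other = next(iter(spec - {"*"}), "*")
                if other == "*" or other in pair:
                    return True
        return False

    def max_ca_span(self, aa_i: str = "K", aa_j: str = "K") -> float:
        """Maximum Ca-Ca distance bridgeable by this reagent (A)."""
        return (self.d_u + SC_REACH.get(aa_i, DEFAULT_SC_REACH)
                + SC_REACH.get(aa_j, DEFAULT_SC_REACH))


def _pairs(*pairs) -> frozenset:
    return frozenset(frozenset(p) for p in pairs)


#: Built-in reagent registry.  Homobifunctional NHS esters (DSG, DSA, BS3)
#: bridge lysine pairs; SDA binds Lys with its NHS arm and Ser/Cys/Met/Thr/Glu
#: with the photoactivatable diazirine; ABAS binds Lys plus (nonspecifically)
#: any residue via the aryl azide; TATA's azide arms are nonspecific.
#: "SS" models a natural disulfide bridge treated as a restraint.
REAGENTS: dict[str, ReagentSpec] = {
    "TATA": ReagentSpec("TATA", None, d_u=4.0),
    "SDA": ReagentSpec("SDA", _pairs(*[("K", x) for x in "SCMTE"]), d_u=5.0),
    "ABAS": ReagentSpec("ABAS", _pairs(("K", "*")), d_u=6.0),
    "DSG": ReagentSpec("DSG", _pairs(("K", "K")), d_u=6.0),
    "DSA": ReagentSpec("DSA", _pairs(("K", "K")), d_u=7.0),
    "BS3": ReagentSpec("BS3", _pairs(("K", "K")), d_u=12.0),
    "SS": ReagentSpec("SS", _pairs(("C", "C")), d_u=4.5),
}

#: The four published (sigma, A) Lorentz parameter variants.
LORENTZ_PRESETS: dict[str, tuple[float, float]] = {
    "LR(5,8)": (5.0, 8.0),
    "LR(15,8)": (15.0, 8.0),
    "LR(5,20)": (5.0, 20.0),
    "LR(15,20)": (15.0, 20.0),
}

#: Disulfide-bridge Lorentz restraint: d_l 2.5, d_u 4.5, sigma 5, A 10.
DISULFIDE_LORENTZ = LorentzParams(d_l=2.5, d_u=4.5, sigma=5.0, A=10.0)


def lorentz_preset(preset: str, reagent: str | ReagentSpec = "DSA",
                   d_l: float | None = None) -> LorentzParams:
    """Build :class:`LorentzParams` from a named (sigma, A) preset.

    The flat-bottom boundaries come from the reagent specification
    (d_l = 2.5 A, d_u = reagent upper boundary) unless overridden.
    """
    try:
        sigma, A = LORENTZ_PRESETS[preset]
    except KeyError:
        raise ValueError(f"parameter error: unknown preset {preset!r}; "
                         f"choose from {sorted(LORENTZ_PRESETS)}") from None
    spec = REAGENTS[reagent] if isinstance(reagent, str) else reagent
    return LorentzParams(d_l=spec.d_l if d_l is None else d_l,
                         d_u=spec.d_u, sigma=sigma, A=A)


# ---------------------------------------------------------------------------
# potential evaluation
# ---------------------------------------------------------------------------

def lorentz_energy(d, p: LorentzParams):
    """Bounded flat-bottom wall on a distance; returns (energy, dE/dd).

    Zero on [d_l, d_u].  For an excess x = d - d_u (or d_l - d below the
    bottom) the wall is A x^4 / (x^4 + sigma^4): continuous and once
    differentiable at the boundaries, strictly increasing in the excess,
    bounded by A with a vanishing gradient at gross violation.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("domain error: distance must be >= 0")
    x = np.where(d > p.d_u, d - p.d_u, np.where(d < p.d_l, p.d_l - d, 0.0))
    s4 = p.sigma ** 4
    x4 = x ** 4
    energy = p.A * x4 / (x4 + s4)
    dE_dx = 4.0 * p.A * s4 * x ** 3 / (x4 + s4) ** 2
    grad = np.where(d > p.d_u, dE_dx, -dE_dx)
    if energy.ndim == 0:
        return float(energy), float(grad)
    return energy, grad


def statistical_energy(d, p: StatisticalParams):
    """Statistical (skew-normal) pseudopotential on a Ca distance.

    ``E(d) = -A RT ln q(d)`` with
    ``q(d) = 2 a phi((d - b)/sigma) * Phi(c (d - b)/sigma) * sigma`` up to the
    standard-normal normalization (an additive constant in the energy);
    phi/Phi are the standard normal pdf/cdf.  Finite, continuous and once
    differentiable for d > 0; pointwise proportional to the confidence
    weight ``A``.  Returns (energy, dE/dd).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("domain error: distance must be > 0")
    t = (d - p.b) / p.sigma
    u = p.c * t
    # log q up to constants: ln a - t^2/2 + ln 2 + ln Phi(u)
    logq = math.log(p.a) + math.log(2.0) - 0.5 * t * t + log_ndtr(u)
    energy = -p.A * p.RT * logq
    # hazard ratio phi(u)/Phi(u), computed in log space for stability
    lam = np.exp(-0.5 * u * u - _LOG_SQRT_2PI - log_ndtr(u))
    dlogq_dd = (-t + p.c * lam) / p.sigma
    grad = -p.A * p.RT * dlogq_dd
    if energy.ndim == 0:
        return float(energy), float(grad)
    return energy, grad


def gaussian_terms(x, terms: np.ndarray):
    """Sum of Gaussian basis terms: V = sum a_k exp(-(x-c_k)^2 / (2 w_k^2)).

    Returns (V, dV/dx); vectorized over ``x``.
    """
    x = np.asarray(x, dtype=float)
    a = terms[:, 0][:, None]
    c = terms[:, 1][:, None]
    w = terms[:, 2][:, None]
    z = (np.atleast_1d(x)[None, :] - c) / w
    g = a * np.exp(-0.5 * z * z)
    V = g.sum(axis=0)
    dV = (-g * z / w).sum(axis=0)
    if x.ndim == 0:
        return float(V[0]), float(dV[0])
    return V, dV


def cosine_terms(gamma, terms: np.ndarray):
    """Cosine series: V = sum a_k cos(n_k (gamma - phi_k)); 2pi-periodic.

    Returns (V, dV/dgamma); vectorized over ``gamma``.
    """
    gamma = np.asarray(gamma, dtype=float)
    a = terms[:, 0][:, None]
    phi = terms[:, 1][:, None]
    n = terms[:, 2][:, None]
    arg = n * (np.atleast_1d(gamma)[None, :] - phi)
    V = (a * np.cos(arg)).sum(axis=0)
    dV = (-a * n * np.sin(arg)).sum(axis=0)
    if gamma.ndim == 0:
        return float(V[0]), float(dV[0])
    return V, dV


def mdbased_energy(g: XLGeometry, p: MDBasedParams):
    """MD-based cross-link penalty: distance + two angle + dihedral components.

    Returns ``(energy, gradient)`` with the gradient over
    (d_XiXj, theta_Xi, theta_Xj, gamma) as a length-4 array.  The dihedral
    component is exactly 2pi-periodic.  Raises on an undefined dihedral.
    """
    if not g.gamma_defined:
        raise ValueError("degenerate geometry: dihedral undefined")
    vd, dvd = gaussian_terms(g.d_xixj, p.dist_terms)
    vi, dvi = gaussian_terms(g.theta_xi, p.angle_terms_i)
    vj, dvj = gaussian_terms(g.theta_xj, p.angle_terms_j)
    vg, dvg = cosine_terms(g.gamma, p.dihedral_terms)
    energy = vd + vi + vj + vg
    return energy, np.array([dvd, dvi, dvj, dvg])


def mdbased_components(g: XLGeometry, p: MDBasedParams) -> dict[str, float]:
    """Per-coordinate breakdown of the MD-based penalty (energies only)."""
    return {
        "distance": gaussian_terms(g.d_xixj, p.dist_terms)[0],
        "angle_i": gaussian_terms(g.theta_xi, p.angle_terms_i)[0],
        "angle_j": gaussian_terms(g.theta_xj, p.angle_terms_j)[0],
        "dihedral": cosine_terms(g.gamma, p.dihedral_terms)[0],
    }


def dihedral_penalty(gamma_deg: float, r: DihedralRestraint):
    """Flat-bottom quartic penalty on a virtual-bond dihedral.

    ``gamma_deg`` is the dihedral in degrees; zero inside the window
    [gamma_l, gamma_u] (modulo 360) and ``w_dih * excess^4`` outside, with
    the excess measured in radians along the shorter angular path to the
    window.  Returns (energy kcal/mol, dE/dgamma in kcal/(mol rad)).
    """
    if not math.isfinite(gamma_deg):
        raise ValueError("domain error: gamma must be finite")
    width = (r.gamma_u - r.gamma_l) % 360.0
    rel = (gamma_deg - r.gamma_l) % 360.0
    if rel <= width:
        return 0.0, 0.0
    past_upper = rel - width          # degrees beyond the upper boundary
    below_lower = 360.0 - rel         # degrees short of the lower boundary
    if past_upper <= below_lower:
        excess = math.radians(past_upper)
        sign = 1.0
    else:
        excess = math.radians(below_lower)
        sign = -1.0
    energy = r.w_dih * excess ** 4
    grad = sign * 4.0 * r.w_dih * excess ** 3
    return energy, grad


# ---------------------------------------------------------------------------
# composite restraint energy
# ---------------------------------------------------------------------------

def resolve_potential(link, potentials):
    """Map a cross-link to its (kind, params) assignment.

    ``potentials`` is either a single ``(kind, params)`` tuple applied to all
    links, or a dict keyed by reagent name (with optional ``"*"`` default).
    """
    if isinstance(potentials, tuple):
        return potentials
    try:
        return potentials[link.reagent]
    except KeyError:
        if "*" in potentials:
            return potentials["*"]
        raise ValueError(f"parameter error: no potential assigned to "
                         f"reagent {link.reagent!r}") from None


def total_restraint_energy(chain: CGChain, xlinks, potentials,
                           dihedral_restraints=()):
    """Composite restraint penalty: sum of cross-link and dihedral terms.

    The force-field term of the full modeling energy is outside this
    package's scope and contributes zero here (the toy refiner supplies a
    harmonic-tether surrogate).  Each cross-link is evaluated with its
    assigned potential family -- Lorentz on the SC-SC distance, statistical
    on the Ca-Ca distance, MD-based on the full anchor geometry -- and
    scaled by the link's confidence.  ``dihedral_restraints`` is an iterable
    of ``(first_residue_author_index, DihedralRestraint)`` pairs applied to
    backbone virtual-bond dihedrals.

    Returns ``(total, breakdown)`` where breakdown is a list of per-term
    records; the breakdown energies sum to the total exactly.
    """
    breakdown = []
    missing = [(l.i, l.j) for l in xlinks
               if l.i not in chain or l.j not in chain]
    if missing:
        raise ValueError(f"mapping error: cross-link residues not in chain: "
                         f"{missing}")
    total = 0.0
    for link in xlinks:
        kind, params = resolve_potential(link, potentials)
        if kind == "lorentz":
            d = sc_distance(chain, link.i, link.j)
            e, _ = lorentz_energy(d, params)
            coord = d
        elif kind == "statistical":
            d = ca_distance(chain, link.i, link.j)
            e, _ = statistical_energy(d, params)
            coord = d
        elif kind == "mdbased":
            g = xlink_geometry(chain, link.i, link.j, params.d_xi, params.d_xj)
            e, _ = mdbased_energy(g, params)
            coord = g.d_xixj
        else:
            raise ValueError(f"parameter error: unknown potential kind "
                             f"{kind!r}")
        e *= link.confidence
        total += e
        breakdown.append({"term": "xlink", "i": link.i, "j": link.j,
                          "reagent": link.reagent, "kind": kind,
                          "coordinate": coord, "energy": e})
    for first_index, restraint in dihedral_restraints:
        gamma = backbone_dihedral(chain, first_index)
        e, _ = dihedral_penalty(math.degrees(gamma), restraint)
        total += e
        breakdown.append({"term": "dihedral", "i": first_index,
                          "coordinate": math.degrees(gamma), "energy": e})
    return total, breakdown


# ---------------------------------------------------------------------------
# JSON parameter files
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1
_KINDS = {"lorentz": LorentzParams, "statistical": StatisticalParams,
          "mdbased": MDBasedParams}


def save_params(assignments: dict, path) -> None:
    """Write potential assignments {reagent: (kind, params)} to JSON."""
    entries = []
    for reagent, (kind, params) in assignments.items():
        d = asdict(params)
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                d[key] = val.tolist()
        entries.append({"reagent": reagent, "potential_type": kind,
                        "params": d})
    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, "potentials": entries},
                  fh, indent=2)


def load_params(path) -> dict:
    """Read potential assignments from a JSON parameter file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"parameter error: unsupported schema version "
                         f"{doc.get('schema_version')!r}")
    out = {}
    for entry in doc["potentials"]:
        kind = entry["potential_type"]
        if kind not in _KINDS:
            raise ValueError(f"parameter error: unknown potential type "
                             f"{kind!r}")
        out[entry["reagent"]] = (kind, _KINDS[kind](**entry["params"]))
    return out
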