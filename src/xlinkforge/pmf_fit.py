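"""Potentials of mean force by Boltzmann inversion and analytic-form fitting.

The derivation pipeline mirrors how distance-and-orientation cross-link
potentials are obtained from conformational samples of a cross-linked model
compound: histogram each internal coordinate, invert the histogram to a PMF,
``W_i = -RT ln h_i`` (empty bins masked, minimum shifted to zero), then fit
the analytic restraint forms -- a Gaussian sum for distances and angles, a
cosine series for dihedrals -- by nonlinear least squares.  The dihedral
form is linear in its coefficients for fixed harmonic orders, so that fit is
solved exactly; the Gaussian forms use a multi-start trust-region
least-squares solver.

In the original workflow the samples come from all-atom MD; here any sample
array can be ingested (e.g. a TSV of snapshot coordinates), and
:func:`xlinkforge.fixtures.boltzmann_sample` provides a documented Metropolis
sampler on a known potential for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .cg_model import XLGeometry, wrap_angle
from .restraints import MDBasedParams, cosine_terms, gaussian_terms

#: Universal gas constant, kcal/(mol K).
R_KCAL = 1.9872e-3

#: Default bin counts: 50 for distances, 36 for angles (5 deg),
#: 72 for dihedrals (5 deg).
DEFAULT_BINS = {"distance": 50, "angle": 36, "dihedral": 72}

#: Convergence tolerance on the scaled gradient norm of the fit.
FIT_GTOL = 1e-8


@dataclass
class HistogramTable:
    """Binned samples of one internal coordinate."""

    variable: str            # "distance" | "angle" | "dihedral"
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges length mismatch")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("histogram counts must be non-negative with a "
                             "positive total")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PMFTable:
    """Potential of mean force on histogram bins; masked bins were empty."""

    midpoints: np.ndarray
    W: np.ndarray            # kcal/mol; NaN on masked bins
    T: float                 # Kelvin
    mask: np.ndarray         # True where the bin is excluded (empty)
    variable: str = "distance"

    @property
    def rt(self) -> float:
        return R_KCAL * self.T


@dataclass
class FitResult:
    """Outcome of fitting an analytic potential form to a PMF."""

    params: np.ndarray       # (n_terms, 3) term triples
    offset: float            # fitted additive constant (kcal/mol)
    form: str
    residual_norm: float
    n_iterations: int
    converged: bool
    cost_trace: list = field(default_factory=list)

    def evaluate(self, x) -> np.ndarray:
        """Fitted potential (including the additive offset) at ``x``."""
        basis = cosine_terms if self.form == "dihedral" else gaussian_terms
        return basis(x, self.params)[0] + self.offset


# ---------------------------------------------------------------------------
# histogramming and Boltzmann inversion
# ---------------------------------------------------------------------------

def histogram(samples, n_bins: int | None = None, range=None,
              variable: str = "distance") -> HistogramTable:
    """Bin samples of one coordinate.

    Dihedral samples are wrapped into (-pi, pi] before binning, so values
    near +pi and -pi fall into the two edge bins, which are periodic
    neighbors (the fit basis is periodic, so no seam is introduced).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("no samples")
    if variable not in DEFAULT_BINS:
        raise ValueError(f"unknown variable {variable!r}")
    if n_bins is None:
        n_bins = DEFAULT_BINS[variable]
    if variable == "dihedral":
        samples = wrap_angle(samples)
        if range is None:
            range = (-np.pi, np.pi)
    counts, edges = np.histogram(samples, bins=n_bins, range=range)
    return HistogramTable(variable=variable, bin_edges=edges, counts=counts)


def pmf_from_histogram(h: HistogramTable, T: float = 300.0) -> PMFTable:
    """Boltzmann inversion: W_i = -RT ln h_i, shifted so min W = 0.

    Empty bins are masked (excluded), not pseudo-counted: the inversion is
    undefined at zero counts and invented counts would pollute the fit.
    Because the result is shifted, scaling all counts uniformly leaves the
    PMF unchanged.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    counts = np.asarray(h.counts, dtype=float)
    mask = counts <= 0
    if mask.all():
        raise ValueError("no data: all bins empty")
    W = np.full(counts.shape, np.nan)
    rt = R_KCAL * T
    W[~mask] = -rt * np.log(counts[~mask])
    W[~mask] -= W[~mask].min()
    return PMFTable(midpoints=h.midpoints, W=W, T=T, mask=mask,
                    variable=h.variable)


# ---------------------------------------------------------------------------
# least-squares fitting of the analytic forms
# ---------------------------------------------------------------------------

def _unpack(theta, n_terms):
    return float(theta[0]), theta[1:].reshape(n_terms, 3)


def _gaussian_design(x, theta, n_terms):
    """Design matrix [1, g_1 .. g_n] of the Gaussian basis at nonlinear
    parameters theta = [(center_k, width_k) ...]."""
    A = np.empty((x.size, n_terms + 1))
    A[:, 0] = 1.0
    for k in range(n_terms):
        c, w = theta[2 * k], theta[2 * k + 1]
        z = (x - c) / w
        A[:, k + 1] = np.exp(-0.5 * z * z)
    return A


def _default_inits(x, W, n_terms, rng=None):
    """Starting (center, width) sets for the Gaussian-sum fit.

    Amplitudes are profiled out linearly (variable projection), so only the
    nonlinear parameters need seeding: the top-scoring combinations from an
    exhaustive linear-subfit scan over a candidate (center, width) grid,
    plus greedy matching-pursuit starts (peak-pick on the residual,
    subtract, repeat, at two width scales) and evenly spread centers at two
    width scales.
    """
    lo, hi = x.min(), x.max()
    span = max(hi - lo, 1e-9)
    centers = np.linspace(lo + 0.1 * span, hi - 0.1 * span, n_terms)
    width0 = span / (3.0 * n_terms)

    cand = [(c, w) for c in np.linspace(lo, hi, 10)
            for w in (span / 20, span / 8, span / 3)]

    def _score(theta):
        A = _gaussian_design(x, np.asarray(theta), len(theta) // 2)
        r = A @ np.linalg.lstsq(A, W, rcond=None)[0] - W
        return float(np.dot(r, r))

    def combinatorial(top_k=6):
        # Seed by exact linear subfits over candidate (center, width) pairs:
        # exhaustively for <= 2 terms (keeping the top_k scoring combos,
        # since near-degenerate PMFs have several competitive basins),
        # greedily one term at a time beyond that.
        if n_terms <= 2:
            import itertools as it
            scored = []
            for combo in it.combinations_with_replacement(cand, n_terms):
                trial = [v for cw in combo for v in cw]
                scored.append((_score(trial), trial))
            scored.sort(key=lambda t: t[0])
            return [np.asarray(t) for _, t in scored[:top_k]]
        theta: list[float] = []
        for _ in range(n_terms):
            best, best_res = None, np.inf
            for c, w in cand:
                rn = _score(theta + [c, w])
                if rn < best_res:
                    best, best_res = (c, w), rn
            theta.extend(best)
        return [np.asarray(theta)]

    def greedy(width):
        theta = []
        resid = W - np.median(W)
        for _ in range(n_terms):
            k = int(np.argmax(np.abs(resid)))
            amp, c = resid[k], x[k]
            theta.extend([c, width])
            resid = resid - amp * np.exp(-0.5 * ((x - c) / width) ** 2)
        return np.asarray(theta)

    def spread(width):
        return np.asarray([v for c in centers for v in (c, width)])

    inits = combinatorial() + [greedy(width0), greedy(width0 / 2.0),
                               spread(width0), spread(2.0 * width0)]
    if rng is not None:
        for base in list(inits[:2]):
            inits.append(base + rng.normal(scale=0.05 * span,
                                           size=base.size))
    return inits


def _fit_dihedral_linear(x, W, n_terms, sqrt_w):
    """Exact linear least squares for the cosine series.

    ``c0 + sum_k (alpha_k cos kx + beta_k sin kx)`` is linear in its
    coefficients; the (alpha, beta) pairs are converted to the
    (amplitude, phase, order) triples of the restraint basis.
    """
    cols = [np.ones_like(x)]
    for k in range(1, n_terms + 1):
        cols.append(np.cos(k * x))
        cols.append(np.sin(k * x))
    A = np.stack(cols, axis=1) * sqrt_w[:, None]
    coef, *_ = np.linalg.lstsq(A, W * sqrt_w, rcond=None)
    offset = coef[0]
    terms = []
    for k in range(1, n_terms + 1):
        alpha, beta = coef[2 * k - 1], coef[2 * k]
        amp = float(np.hypot(alpha, beta))
        phase = float(np.arctan2(beta, alpha)) / k if amp > 0 else 0.0
        terms.append((amp, phase, float(k)))
    terms = np.asarray(terms)
    resid = (cosine_terms(x, terms)[0] + offset - W) * sqrt_w
    return FitResult(params=terms, offset=float(offset), form="dihedral",
                     residual_norm=float(np.linalg.norm(resid)),
                     n_iterations=1, converged=True,
                     cost_trace=[float(0.5 * np.dot(resid, resid))])


def fit_potential(pmf: PMFTable, form: str, n_terms: int = 2,
                  init: np.ndarray | None = None,
                  weights: np.ndarray | None = None,
                  seed: int | None = None) -> FitResult:
    """Fit the analytic restraint form to a PMF by weighted least squares.

    Parameters
    ----------
    pmf : PMFTable
        Masked bins are excluded from the fit.
    form : {"distance", "angle", "dihedral"}
        Chooses the basis: Gaussian sum for distance/angle, cosine series
        (exactly periodic) for dihedral.
    n_terms : int
        Number of basis terms; an additive constant is always included
        (the PMF zero point is arbitrary).
    init : array, optional
        A user starting point ``[offset, (a, c, w) * n_terms]`` for the
        Gaussian forms; otherwise a set of default initializations is tried
        (grid-scanned plus heuristic starts) and the best residual kept.
    weights : array, optional
        Per-bin weights on the unmasked bins (uniform by default; pass the
        bin counts for Boltzmann weighting).
    seed : int, optional
        Adds one jittered starting point drawn from this seed.

    Objective decrease across accepted iterations is recorded in
    ``cost_trace``; ``converged`` reflects the 1e-8 gradient-norm tolerance.
    """
    if form not in ("distance", "angle", "dihedral"):
        raise ValueError(f"unknown form {form!r}")
    good = ~pmf.mask
    x = np.asarray(pmf.midpoints, float)[good]
    W = np.asarray(pmf.W, float)[good]
    n_free = 1 + (2 if form == "dihedral" else 3) * n_terms
    if x.size < n_free + 1:
        raise ValueError(f"insufficient bins: {x.size} unmasked bins for "
                         f"{n_free} free parameters")
    if weights is None:
        sqrt_w = np.ones_like(x)
    else:
        weights = np.asarray(weights, float)
        if weights.shape == pmf.mask.shape:
            weights = weights[good]
        sqrt_w = np.sqrt(weights)

    if form == "dihedral":
        return _fit_dihedral_linear(x, W, n_terms, sqrt_w)

    # Gaussian sum by variable projection: amplitudes and the offset are
    # linear given (center, width), so they are profiled out exactly and the
    # trust-region solver works on the nonlinear parameters only.  The
    # objective is the same weighted sum of squares.
    span = max(x.max() - x.min(), 1e-9)
    n_nl = 2 * n_terms
    lb = np.full(n_nl, -np.inf)
    ub = np.full(n_nl, np.inf)
    for k in range(n_terms):
        lb[2 * k] = x.min() - span       # centers within an expanded domain
        ub[2 * k] = x.max() + span
        lb[2 * k + 1] = 1e-4 * span      # widths bounded away from zero
        ub[2 * k + 1] = 10.0 * span
    Wn = W * sqrt_w

    def solve_linear(theta):
        A = _gaussian_design(x, theta, n_terms) * sqrt_w[:, None]
        beta, *_ = np.linalg.lstsq(A, Wn, rcond=None)
        return beta, A @ beta - Wn

    trace: list[float] = []
    best_cost = np.inf

    def residuals(theta):
        nonlocal best_cost
        _, r = solve_linear(theta)
        cost = 0.5 * float(np.dot(r, r))
        if cost < best_cost:             # accepted-descent trace
            best_cost = cost
            trace.append(cost)
        return r

    if init is not None:
        init = np.asarray(init, float)
        _, terms0 = _unpack(init, n_terms)
        starts = [terms0[:, 1:].ravel()]
    else:
        rng = np.random.default_rng(seed) if seed is not None else None
        starts = _default_inits(x, W, n_terms, rng)
    def run(theta0):
        theta0 = np.clip(theta0, lb + 1e-12, ub - 1e-12)
        return least_squares(residuals, theta0, bounds=(lb, ub),
                             method="trf", gtol=1e-14, xtol=1e-15,
                             ftol=1e-15, max_nfev=400 * theta0.size)

    best = None
    for theta0 in starts:
        res = run(theta0)
        if best is None or res.cost < best.cost:
            best = res
    # deterministic perturbation polish: rescale each width, nudge each
    # center by one width, and re-solve; escapes the shallow basins of
    # strongly overlapping terms
    for _ in range(3):
        if best.cost < 1e-16:
            break
        improved = False
        th = best.x
        for k in range(n_terms):
            perturbed = []
            for fac in (0.5, 2.0):
                t2 = th.copy()
                t2[2 * k + 1] *= fac
                perturbed.append(t2)
            for dc in (-1.0, 1.0):
                t2 = th.copy()
                t2[2 * k] += dc * th[2 * k + 1]
                perturbed.append(t2)
            for t2 in perturbed:
                res = run(t2)
                if res.cost < best.cost * 0.99:
                    best = res
                    improved = True
        if not improved:
            break
    beta, resid = solve_linear(best.x)
    terms = np.column_stack([beta[1:],
                             best.x[0::2],
                             best.x[1::2]])
    return FitResult(params=terms, offset=float(beta[0]), form=form,
                     residual_norm=float(np.linalg.norm(resid)),
                     n_iterations=int(best.nfev),
                     converged=bool(best.status in (1, 2, 3, 4)),
                     cost_trace=trace)


# ---------------------------------------------------------------------------
# end-to-end derivation of MD-based parameters
# ---------------------------------------------------------------------------

def derive_mdbased_params(ensemble, n_bins: dict | None = None,
                          T: float = 300.0, n_terms: dict | None = None,
                          weights: str = "uniform") -> MDBasedParams:
    """Histogram -> PMF -> fit for each cross-link internal coordinate.

    ``ensemble`` is a sequence of :class:`~xlinkforge.cg_model.XLGeometry`
    samples (at least 100).  Anchor offsets are taken as the ensemble means.
    Per-coordinate fit residuals and convergence flags are stored in the
    returned parameters' ``provenance``.  ``weights="boltzmann"`` weights
    each bin by its count.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 100:
        raise ValueError("need at least 100 geometry samples")
    n_bins = {**DEFAULT_BINS, **(n_bins or {})}
    n_terms = {**{"distance": 2, "angle": 2, "dihedral": 2}, **(n_terms or {})}

    coords = {
        "distance": np.array([g.d_xixj for g in ensemble]),
        "angle_i": np.array([g.theta_xi for g in ensemble]),
        "angle_j": np.array([g.theta_xj for g in ensemble]),
        "dihedral": np.array([g.gamma for g in ensemble]),
    }
    forms = {"distance": "distance", "angle_i": "angle", "angle_j": "angle",
             "dihedral": "dihedral"}
    fits = {}
    provenance = {"T": T}
    for name, samples in coords.items():
        form = forms[name]
        h = histogram(samples, n_bins[form], variable=form)
        pmf = pmf_from_histogram(h, T=T)
        wt = h.counts[~pmf.mask] if weights == "boltzmann" else None
        fit = fit_potential(pmf, form, n_terms=n_terms[form], weights=wt)
        fits[name] = fit
        provenance[name] = {"residual_norm": fit.residual_norm,
                            "converged": fit.converged,
                            "offset": fit.offset}
    return MDBasedParams(
        d_xi=float(np.mean([g.d_xi for g in ensemble])),
        d_xj=float(np.mean([g.d_xj for g in ensemble])),
        dist_terms=fits["distance"].params,
        angle_terms_i=fits["angle_i"].params,
        angle_terms_j=fits["angle_j"].params,
        dihedral_terms=fits["dihedral"].params,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# sample table I/O
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["d_xixj", "theta_xi", "theta_xj", "gamma"]


def read_samples(path, d_xi: float = 3.0, d_xj: float = 3.0):
    """Read an ensemble of internal-coordinate snapshots from TSV.

    Expected columns: ``d_xixj  theta_xi  theta_xj  gamma`` (angles in
    radians), one row per snapshot.  Returns a list of XLGeometry.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return [XLGeometry(d_xixj=row.d_xixj, theta_xi=row.theta_xi,
                       theta_xj=row.theta_xj, gamma=row.gamma,
                       d_xi=d_xi, d_xj=d_xj)
            for row in df.itertuples()]


def write_samples(ensemble, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"d_xixj": [g.d_xixj for g in ensemble],
         "theta_xi": [g.theta_xi for g in ensemble],
         "theta_xj": [g.theta_xj for g in ensemble],
         "gamma": [g.gamma for g in ensemble]}
    ).to_csv(path, sep="\t", index=False)
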