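"""Cross-link set handling: planning, the topological-length descriptor,
and violation censuses.

A cross-link's *topological length* L is the difference of the sequence
indices of its two residues; the sum over a set, Sigma-L, measures how much
long-range contact information the set carries.  Empirically, restraint sets
with Sigma-L strictly greater than 150 consistently improve coarse-grained
model quality, so :func:`predict_improvement` classifies a set as
high-capacity on that rule.

The violation census compares each link's Ca-Ca distance in a reference
structure against the maximum Ca-Ca span its reagent can bridge; links in
excess are *false restraints* (capturable only through fluctuations or
distortion).  False restraints are reported, never deleted: the toolkit does
not curate cross-link data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cg_model
from .cg_model import CGChain
from .restraints import REAGENTS, ReagentSpec

logger = logging.getLogger(__name__)

SIGMA_L_THRESHOLD = 150


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossLink:
    """One cross-link: author residue indices, reagent name, confidence."""

    i: int
    j: int
    reagent: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("cross-link endpoints must differ")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def key(self):
        """Unordered identity (i, j, reagent)."""
        return (frozenset((self.i, self.j)), self.reagent)


@dataclass
class CrossLinkSet:
    """A set of cross-links for one protein; duplicates are rejected."""

    links: list[CrossLink]
    protein_id: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for link in self.links:
            if link.key in seen:
                raise ValueError(f"duplicate cross-link {link.i}-{link.j} "
                                 f"({link.reagent})")
            seen.add(link.key)

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)


@dataclass
class ViolationReport:
    """Per-link distance excesses and threshold counts for one structure."""

    per_link: list[dict]
    unresolved: list[CrossLink]
    margins: tuple
    counts: dict = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {m: sum(1 for rec in self.per_link
                              if rec["excess"] > m)
                       for m in self.margins}

    @property
    def n_total(self) -> int:
        return len(self.per_link)

    def n_over(self, margin: float) -> int:
        return sum(1 for rec in self.per_link if rec["excess"] > margin)


@dataclass
class ImprovementPrediction:
    """Sigma-L based classification of a cross-link set's capacity."""

    classification: str      # "high-capacity" | "low-capacity"
    sigma_l: int
    n_links: int
    max_length: int
    threshold: int = SIGMA_L_THRESHOLD


# ---------------------------------------------------------------------------
# topological length
# ---------------------------------------------------------------------------

def topological_length(link: CrossLink, convention: str = "index_difference") -> int:
    """Topological length of a link: |j - i| residues.

    ``convention="loop_size"`` counts the closed loop inclusively
    (|j - i| + 1), the alternative reading of "closing a loop of N
    residues"; the index-difference convention is the default.
    """
    L = abs(link.j - link.i)
    if convention == "loop_size":
        return L + 1
    if convention != "index_difference":
        raise ValueError(f"unknown convention {convention!r}")
    return L


def sigma_L(xset: CrossLinkSet, convention: str = "index_difference") -> int:
    """Sum of topological lengths over the set (order-independent, additive)."""
    return sum(topological_length(l, convention) for l in xset)


def predict_improvement(xset: CrossLinkSet,
                        threshold: int = SIGMA_L_THRESHOLD) -> ImprovementPrediction:
    """Classify a cross-link set by the strict Sigma-L > threshold rule."""
    s = sigma_L(xset)
    lengths = [topological_length(l) for l in xset]
    return ImprovementPrediction(
        classification="high-capacity" if s > threshold else "low-capacity",
        sigma_l=s,
        n_links=len(xset),
        max_length=max(lengths) if lengths else 0,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# surface exposure on the CG sphere model
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sc_accessibility(chain: CGChain, probe: float = 1.4, r_ca: float = 2.0,
                     r_sc: float = 3.0, n_points: int = 256) -> np.ndarray:
    """Relative side-chain-sphere accessibility for every residue.

    Shrake-Rupley-style: test points on the probe-inflated SC sphere are
    occluded by any other probe-inflated Ca/SC sphere.  The result is
    normalized by the accessibility of the same SC sphere occluded only by
    its own residue's Ca sphere (the fully extended, fully exposed
    reference), so an unburied side chain scores ~1 and a core side chain
    ~0.  Glycine (sc == ca) is scored on a sphere centered at ca.
    """
    from scipy.spatial import cKDTree

    pts = _sphere_points(n_points)
    ca = chain.ca_coords()
    sc = chain.sc_coords()
    centers = np.vstack([ca, sc])
    radii = np.concatenate([np.full(len(ca), r_ca + probe),
                            np.full(len(sc), r_sc + probe)])
    tree = cKDTree(centers)
    r_test = r_sc + probe
    reach = radii.max() + r_test
    out = np.empty(len(chain))
    for k in range(len(chain)):
        test = sc[k] + r_test * pts
        neighbors = tree.query_ball_point(sc[k], reach)
        own_sc = len(ca) + k
        occluded = np.zeros(n_points, dtype=bool)
        own_ca_occl = np.zeros(n_points, dtype=bool)
        for idx in neighbors:
            if idx == own_sc:
                continue
            hit = (np.linalg.norm(test - centers[idx], axis=1) < radii[idx])
            if idx == k:                       # own Ca sphere
                own_ca_occl |= hit
            occluded |= hit
        denom = np.count_nonzero(~own_ca_occl)
        out[k] = (np.count_nonzero(~occluded) / denom) if denom else 0.0
    return out


# ---------------------------------------------------------------------------
# planning and the violation census
# ---------------------------------------------------------------------------

def find_crosslinkable_pairs(chain: CGChain, reagent: str | ReagentSpec,
                             exposure_threshold: float = 0.2,
                             exposure: np.ndarray | None = None) -> CrossLinkSet:
    """All cross-linkable residue pairs for a reagent on a structure.

    A pair qualifies when (a) the reagent's residue-type specificity allows
    it, (b) the side-chain-center distance does not exceed the reagent's
    upper boundary d_u and (c) both side chains are exposed (relative
    CG-sphere accessibility >= ``exposure_threshold``).  A precomputed
    exposure array can be passed to avoid recomputation.
    """
    spec = REAGENTS[reagent] if isinstance(reagent, str) else reagent
    if exposure is None:
        exposure = sc_accessibility(chain)
    links = []
    residues = chain.residues
    for a, b in itertools.combinations(range(len(residues)), 2):
        ra, rb = residues[a], residues[b]
        if not spec.allows(ra.aa, rb.aa):
            continue
        if np.linalg.norm(ra.sc - rb.sc) > spec.d_u:
            continue
        if exposure[a] < exposure_threshold or exposure[b] < exposure_threshold:
            continue
        links.append(CrossLink(i=ra.index, j=rb.index, reagent=spec.name))
    if not links:
        logger.info("no cross-linkable %s pairs found on chain %s",
                    spec.name, chain.chain_id)
    return CrossLinkSet(links=links, protein_id=chain.chain_id)


def violation_report(chain: CGChain, xset: CrossLinkSet,
                     margins=(5.0, 10.0)) -> ViolationReport:
    """Census of links whose Ca-Ca distance exceeds the reagent's max span.

    ``excess = ca_distance - max_length`` where max_length is the reagent's
    maximum Ca-Ca span (upper boundary plus both side-chain reaches).
    Links with unresolvable residue indices are listed separately and
    excluded from the counts.
    """
    per_link, unresolved = [], []
    for link in xset:
        if link.i not in chain or link.j not in chain:
            logger.warning("cross-link %s-%s not resolvable in chain",
                           link.i, link.j)
            unresolved.append(link)
            continue
        spec = REAGENTS[link.reagent]
        aa_i = chain.residue(link.i).aa
        aa_j = chain.residue(link.j).aa
        d = cg_model.ca_distance(chain, link.i, link.j)
        max_len = spec.max_ca_span(aa_i, aa_j)
        per_link.append({"i": link.i, "j": link.j, "reagent": link.reagent,
                         "ca_distance": d, "max_length": max_len,
                         "excess": d - max_len})
    return ViolationReport(per_link=per_link, unresolved=unresolved,
                           margins=tuple(margins))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

XLINK_COLUMNS = ["protein", "res_i", "res_j", "reagent", "confidence"]


def read_xlinks(path) -> CrossLinkSet:
    """Read a cross-link table (TSV with header).

    Columns: ``protein  res_i  res_j  reagent  confidence``; the confidence
    column is optional (default 1.0).  Malformed rows are reported with
    their line number.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["protein", "res_i", "res_j", "reagent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cross-link table missing columns: {missing}")
    if "confidence" not in df.columns:
        df["confidence"] = 1.0
    links = []
    protein = ""
    for row in df.itertuples():
        line = row.Index + 2          # 1-based, after the header line
        try:
            links.append(CrossLink(i=int(row.res_i), j=int(row.res_j),
                                   reagent=str(row.reagent),
                                   confidence=float(row.confidence)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed cross-link row at line {line}: "
                             f"{exc}") from None
        protein = str(row.protein)
    try:
        return CrossLinkSet(links=links, protein_id=protein)
    except ValueError as exc:
        raise ValueError(f"invalid cross-link table: {exc}") from None


def write_xlinks(xset: CrossLinkSet, path) -> None:
    pd.DataFrame(
        {"protein": [xset.protein_id] * len(xset),
         "res_i": [l.i for l in xset],
         "res_j": [l.j for l in xset],
         "reagent": [l.reagent for l in xset],
         "confidence": [l.confidence for l in xset]}
    ).to_csv(path, sep="\t", index=False)
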