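"""Community-structure responses: Hellinger composition matrix and the
composition/dispersion decomposition of functional or phylogenetic structure.

The taxonomic response is the Hellinger-transformed site-by-species matrix.
For functional (or phylogenetic) structure, a single species score vector u
is extracted by principal-coordinates analysis of the functional (or
cophenetic) distance matrix; the abundance matrix is linked to u cell-wise
(a Hadamard product of weights and scores) and the resulting total-variation
matrix is redistributed into a per-site weighted mean (composition, the
community-weighted mean position on u) and a per-site weighted spread
(dispersion, the weighted standard deviation around that mean).  Cell
weights default to abundance times a species-occurrence multiplier, which
down-weights species that are rare and infrequent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DegenerateDistanceError, InputError
from .traits import DistanceMatrix

#: selectable cell-weight schemes for the decomposition
WEIGHT_SCHEMES = ("abundance_occurrence", "presence_occurrence", "abundance")


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Sites x species count matrix for one season."""

    counts: pd.DataFrame
    season: str | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise InputError("abundance matrix has negative entries")
        if not np.allclose(vals, np.round(vals)):
            raise InputError("abundance matrix has non-integer entries")
        if np.any(vals.sum(axis=1) == 0):
            empty = list(self.counts.index[vals.sum(axis=1) == 0])
            raise InputError(f"sites with no individuals: {empty}")

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "site_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, season: str | None = None) -> "AbundanceMatrix":
        return cls(counts=pd.read_csv(path, index_col=0), season=season)


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

@dataclass
class StructureResponse:
    """One response object for variation partitioning.

    ``kind`` is ``"taxonomic_composition"`` (matrix-valued: the Hellinger
    matrix), ``"composition"`` or ``"dispersion"`` (vector-valued per site).
    """

    kind: str
    sites: list[str]
    matrix: pd.DataFrame | None = None
    values: pd.Series | None = None
    site_weights: pd.Series | None = None
    provenance: str | None = None  # "functional" | "phylogenetic" | None
    meta: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        """Response as an (n_sites x q) array, q = 1 for vector responses."""
        if self.matrix is not None:
            return self.matrix.to_numpy(dtype=float)
        return self.values.to_numpy(dtype=float)[:, None]


@dataclass
class SpeciesScores:
    """First principal-coordinate axis of a species distance matrix."""

    ids: list[str]
    scores: pd.Series
    eigenvalue: float
    provenance: str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def hellinger(Y: AbundanceMatrix) -> StructureResponse:
    """Hellinger transform: sqrt of row proportions of the count matrix.

    Rows of the result have unit sum of squares, so Euclidean distances on
    it are Hellinger distances between community profiles.
    """
    counts = Y.counts.to_numpy(dtype=float)
    row_tot = counts.sum(axis=1, keepdims=True)
    H = np.sqrt(counts / row_tot)
    mat = pd.DataFrame(H, index=Y.counts.index, columns=Y.counts.columns)
    return StructureResponse(kind="taxonomic_composition", sites=Y.sites,
                             matrix=mat, meta={"season": Y.season})


def species_scores(D: DistanceMatrix) -> SpeciesScores:
    """Principal-coordinates scores on the largest positive axis of ``D``.

    Gower-centres -0.5 * D^2, takes the eigenvector of the largest positive
    eigenvalue scaled by sqrt(eigenvalue).  Sign convention: the entry of
    largest magnitude is positive (ties broken toward the earlier species).
    """
    d = D.values
    n = d.shape[0]
    if n < 2:
        raise DegenerateDistanceError("need at least 2 species for an ordination axis")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d * d) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(B)
    lam = eigvals[-1]
    if lam <= 1e-10:
        raise DegenerateDistanceError(
            "distance matrix has no positive principal-coordinate eigenvalue"
        )
    v = eigvecs[:, -1]
    u = v * np.sqrt(lam)
    k = int(np.argmax(np.round(np.abs(u), 12)))  # deterministic under ties
    if u[k] < 0:
        u = -u
    prov = "functional" if D.provenance == "gower" else "phylogenetic"
    return SpeciesScores(ids=list(D.ids),
                         scores=pd.Series(u, index=list(D.ids)),
                         eigenvalue=float(lam), provenance=prov)


def cell_weights(Y: AbundanceMatrix, scheme: str = "abundance_occurrence") -> pd.DataFrame:
    """Cell weights w_ij for the decomposition.

    The species multiplier o_j is the number of sites a species occupies;
    multiplying by it damps the influence of infrequent species.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise InputError(f"unknown weighting scheme {scheme!r}; options: {WEIGHT_SCHEMES}")
    counts = Y.counts.to_numpy(dtype=float)
    occ = (counts > 0).sum(axis=0)  # o_j: number of occupied sites
    if scheme == "abundance_occurrence":
        w = counts * occ[None, :]
    elif scheme == "presence_occurrence":
        w = (counts > 0).astype(float) * occ[None, :]
    else:  # abundance only
        w = counts.copy()
    return pd.DataFrame(w, index=Y.counts.index, columns=Y.counts.columns)


def decompose(
    Y: AbundanceMatrix,
    u: SpeciesScores,
    weighting: str = "abundance_occurrence",
) -> tuple[StructureResponse, StructureResponse]:
    """Split total functional/phylogenetic variation into composition and
    dispersion components.

    With normalised cell weights w~_ij (summing to 1 within each site), the
    per-site weighted second moment of the species scores obeys

        sum_j w~_ij u_j^2  =  m_i^2 + s_i^2,

    where m_i is the weighted mean score (composition) and s_i the weighted
    standard deviation (dispersion).  A one-species site has s_i = 0
    exactly.
    """
    if list(Y.counts.columns) != list(u.ids):
        if set(Y.counts.columns) != set(u.ids):
            raise InputError("abundance matrix and species scores use different species")
        u = SpeciesScores(ids=Y.species,
                          scores=u.scores.reindex(Y.counts.columns),
                          eigenvalue=u.eigenvalue, provenance=u.provenance)
    w = cell_weights(Y, weighting).to_numpy(dtype=float)
    tot = w.sum(axis=1)
    if np.any(tot <= 0):
        bad = list(Y.counts.index[tot <= 0])
        raise InputError(f"sites with zero total weight: {bad}")
    uv = u.scores.to_numpy(dtype=float)
    wt = w / tot[:, None]
    m = wt @ uv
    var = np.maximum(wt @ (uv * uv) - m * m, 0.0)
    s = np.sqrt(var)

    site_w = pd.Series(tot, index=Y.counts.index)
    meta = {"season": Y.season, "weighting": weighting, "axis_eigenvalue": u.eigenvalue}
    comp = StructureResponse(kind="composition", sites=Y.sites,
                             values=pd.Series(m, index=Y.counts.index),
                             site_weights=site_w, provenance=u.provenance,
                             meta=dict(meta))
    disp = StructureResponse(kind="dispersion", sites=Y.sites,
                             values=pd.Series(s, index=Y.counts.index),
                             site_weights=site_w, provenance=u.provenance,
                             meta=dict(meta, variance=pd.Series(var, index=Y.counts.index)))
    return comp, disp


def decomposition_summary(
    comp: StructureResponse, disp: StructureResponse
) -> dict[str, float]:
    """Share of total trait variation carried by composition vs dispersion.

    Redistributes the site-weighted total sum of squares of the species
    scores into a between-site component (squared deviations of the
    community means m_i from their weighted grand mean) and a within-site
    component (the weighted variances s_i^2).  A dispersion share near 1
    means the communities spread widely along the trait axis while their
    weighted means barely differ between sites.  The raw between-site
    variances of the m and s vectors are included as diagnostics.
    """
    w = comp.site_weights.to_numpy(dtype=float)
    w = w / w.sum()
    m = comp.values.to_numpy(dtype=float)
    s = disp.values.to_numpy(dtype=float)
    ss_comp = float(np.sum(w * (m - np.sum(w * m)) ** 2))
    ss_disp = float(np.sum(w * s * s))
    total = ss_comp + ss_disp
    return {
        "composition_ss": ss_comp,
        "dispersion_ss": ss_disp,
        "composition_share": ss_comp / total if total > 0 else float("nan"),
        "dispersion_share": ss_disp / total if total > 0 else float("nan"),
        "composition_between_site_variance": ss_comp,
        "dispersion_between_site_variance": float(
            np.sum(w * (s - np.sum(w * s)) ** 2)),
    }
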