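"""Variation partitioning by full and partial redundancy analysis.

The variance of a response (Hellinger matrix, or a composition/dispersion
vector) is split into four fractions with respect to an environmental
predictor block E and a spatial predictor block S:

    [a] unique environment   = adjR2(E+S) - adjR2(S)
    [b] spatially structured environment = adjR2(E) + adjR2(S) - adjR2(E+S)
    [c] unique space         = adjR2(E+S) - adjR2(E)
    [d] residual             = 1 - adjR2(E+S)

Adjusted R-squared uses the Ezekiel correction, which is unbiased under
irrelevant added predictors and may be negative; negative fractions are
reported raw and clamped to zero for display.  Significance of the unique
fractions is assessed by permutation: whole response rows for the taxonomic
(matrix) response (reduced-model residual permutation is available but is
conservative when the reduced model is large relative to the site count),
and a double permutation (site rows of the tested predictor block, and
species entries of the trait score vector) with a conservative max-p
combination for trait-based responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import InputError, UndefinedStatisticError
from .structure import AbundanceMatrix, SpeciesScores, StructureResponse, decompose

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Predictor sets and fits
# ---------------------------------------------------------------------------

@dataclass
class PredictorSet:
    """A block of per-site predictor columns (environment or space)."""

    role: str  # "environment" | "space"
    data: pd.DataFrame
    scale: str | None = None
    season: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("environment", "space"):
            raise InputError(f"unknown predictor role {self.role!r}")
        if self.data.isna().any().any():
            raise InputError(f"{self.role} predictors contain missing values")
        if self.data.shape[1]:
            var = self.data.var(axis=0, ddof=0)
            dead = list(var.index[var == 0])
            if dead:
                raise InputError(f"zero-variance {self.role} columns: {dead}")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_predictors(self) -> int:
        return self.data.shape[1]


@dataclass
class RegressionFit:
    response_kind: str
    roles: tuple[str, ...]
    r2: float
    adj_r2: float
    n: int
    p: int
    weighted: bool
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class PartitionResult:
    """Fractions [a], [b], [c], [d] with adjusted R2 bookkeeping."""

    fractions: dict[str, float]          # raw adjusted-scale fractions
    clamped: dict[str, float]            # negatives interpreted as zeros
    totals: dict[str, float]             # adjusted [ab], [bc], [abc]
    fits: dict[str, RegressionFit]
    p_values: dict[str, float] = field(default_factory=dict)
    codes: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def set_p(self, fraction: str, p: float) -> None:
        self.p_values[fraction] = p
        self.codes[fraction] = significance_code(p)

    def to_row(self) -> dict:
        row = dict(self.meta)
        for k in ("a", "b", "c", "d"):
            row[k] = self.fractions[k]
            row[f"{k}_clamped"] = self.clamped[k]
        for k, v in self.totals.items():
            row[f"adj_{k}"] = v
        for k, v in self.p_values.items():
            row[f"p_{k}"] = v
            row[f"sig_{k}"] = self.codes[k]
        return row


# ---------------------------------------------------------------------------
# Core regression machinery
# ---------------------------------------------------------------------------

def _drop_collinear(X: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Return a full-column-rank design (centred) and the kept/dropped names."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0)), [], []
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    q, r, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    dropped = [X.columns[i] for i in sorted(piv[rank:])]
    if dropped:
        warnings.warn(f"dropping collinear predictor columns: {dropped}")
    return Xc[:, keep], [X.columns[i] for i in keep], dropped


def _fitted_ss(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Sum of squares of the projection of centred Y onto span(Xc)."""
    if Xc.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return float(np.sum((Xc @ beta) ** 2))


def _weighted_design(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Absorb the intercept by weighted centring, then scale by sqrt(w)."""
    w = w / w.sum()
    sw = np.sqrt(w)
    yc = (y - np.sum(w * y)) * sw
    Xc = (X - np.sum(w[:, None] * X, axis=0)) * sw[:, None]
    return yc, Xc


def fit_r2(
    response: StructureResponse,
    X: pd.DataFrame,
    site_weights: "pd.Series | None" = None,
) -> RegressionFit:
    """R-squared of a (weighted) least-squares fit with intercept.

    Matrix responses get the redundancy-analysis R2: fitted sum of squares
    over total sum of squares across all columns after column centring.
    Vector responses are fitted by weighted least squares when site weights
    are given (unweighted otherwise), with R2 on the weighted scale.
    """
    n = len(response.sites)
    if X.shape[0] != n:
        raise InputError("predictor rows do not match response sites")
    Xc, kept, dropped = _drop_collinear(X)
    p = Xc.shape[1]
    if p >= n - 1:
        raise InputError(f"too many predictors (p={p}) for n={n} sites")

    if response.matrix is not None:
        Y = response.matrix.to_numpy(dtype=float)
        Yc = Y - Y.mean(axis=0)
        ss_tot = float(np.sum(Yc * Yc))
        if ss_tot == 0:
            raise UndefinedStatisticError("response has zero total variance")
        r2 = _fitted_ss(Yc, Xc) / ss_tot
        weighted = False
    else:
        y = response.values.to_numpy(dtype=float)
        if site_weights is None:
            site_weights = response.site_weights
        if site_weights is not None:
            w = site_weights.to_numpy(dtype=float)
            weighted = True
        else:
            w = np.ones(n)
            weighted = False
        yc, Xw = _weighted_design(y, Xc, w)
        ss_tot = float(yc @ yc)
        if ss_tot == 0:
            raise UndefinedStatisticError("response has zero (weighted) variance")
        r2 = _fitted_ss(yc[:, None], Xw) / ss_tot

    r2 = min(max(r2, 0.0), 1.0)
    return RegressionFit(
        response_kind=response.kind, roles=(), r2=r2,
        adj_r2=adjust_r2(r2, n, p), n=n, p=p, weighted=weighted,
        dropped_columns=dropped,
    )


def adjust_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel-adjusted R2: 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise InputError(f"adjusted R2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

def _check_alignment(response: StructureResponse, E: PredictorSet, S: PredictorSet):
    for block in (E, S):
        if list(block.data.index) != list(response.sites):
            if set(block.data.index) != set(response.sites):
                raise InputError(f"{block.role} predictor sites do not match response")
            block.data = block.data.reindex(response.sites)


def partition(
    response: StructureResponse,
    E: PredictorSet,
    S: PredictorSet,
    site_weights: "pd.Series | None" = None,
) -> PartitionResult:
    """Partition response variation into fractions [a], [b], [c], [d].

    Three (partial) fits are run: both blocks together ([abc]), environment
    alone ([ab]) and space alone ([bc]); each R2 is Ezekiel-adjusted with
    its own predictor count and the fractions follow by the inclusion-
    exclusion identities.  Negative raw fractions are kept (they signal
    correlated predictors with opposing effects) alongside zero-clamped
    copies for display.
    """
    _check_alignment(response, E, S)
    both = pd.concat([E.data, S.data], axis=1)
    fit_abc = fit_r2(response, both, site_weights)
    fit_ab = fit_r2(response, E.data, site_weights)
    fit_bc = fit_r2(response, S.data, site_weights)
    abc, ab, bc = fit_abc.adj_r2, fit_ab.adj_r2, fit_bc.adj_r2
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    d = 1.0 - abc
    fractions = {"a": a, "b": b, "c": c, "d": d}
    clamped = {k: max(v, 0.0) for k, v in fractions.items()}
    meta = {
        "response": response.kind,
        "provenance": response.provenance,
        "season": response.meta.get("season") or E.season,
        "scale": E.scale,
        "n": fit_abc.n,
    }
    return PartitionResult(
        fractions=fractions, clamped=clamped,
        totals={"ab": ab, "bc": bc, "abc": abc},
        fits={"abc": fit_abc, "ab": fit_ab, "bc": fit_bc},
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _projector(Xc: np.ndarray) -> np.ndarray:
    if Xc.shape[1] == 0:
        return np.zeros((Xc.shape[0], Xc.shape[0]))
    return Xc @ np.linalg.pinv(Xc)


def _partial_f(ssf_full, ssf_red, ss_tot, p_extra, n, p_full) -> float:
    num = (ssf_full - ssf_red) / p_extra
    den = (ss_tot - ssf_full) / (n - p_full - 1)
    if den <= 0:
        return np.inf
    return num / den


def test_taxonomic(
    Yhel: StructureResponse,
    E: PredictorSet,
    S: PredictorSet,
    nperm: int = 1000,
    seed: int | None = None,
    permute: str = "rows",
) -> dict[str, float]:
    """Permutation p-values for the unique fractions of a matrix response.

    The test statistic is the partial pseudo-F of adding the tested block to
    the other block's model.  ``permute="rows"`` (default) permutes whole
    response rows; ``permute="residuals"`` permutes rows of the reduced-model
    residuals instead, which is only advisable when the reduced model is
    small relative to the number of sites.
    """
    if Yhel.matrix is None:
        raise InputError("test_taxonomic needs a matrix-valued response")
    if nperm < 99:
        raise InputError("nperm must be at least 99")
    if permute not in ("residuals", "rows"):
        raise InputError(f"unknown permutation scheme {permute!r}")
    _check_alignment(Yhel, E, S)
    Y = Yhel.matrix.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=0)
    n = Yc.shape[0]
    rng = np.random.default_rng(seed)

    out = {}
    for frac, tested, other in (("a", E, S), ("c", S, E)):
        Xt, *_ = _drop_collinear(tested.data)
        Xo, *_ = _drop_collinear(other.data)
        Xf = np.hstack([Xt, Xo])
        p_full = np.linalg.matrix_rank(Xf) if Xf.shape[1] else 0
        if p_full >= n - 1:
            raise InputError(f"too many predictors (p={p_full}) for n={n} sites")
        p_extra = max(p_full - Xo.shape[1], 1)
        P_full = _projector(Xf)
        P_red = _projector(Xo)

        def f_stat(Ymat: np.ndarray) -> float:
            ss_tot = float(np.sum(Ymat * Ymat))
            ssf_full = float(np.sum((P_full @ Ymat) ** 2))
            ssf_red = float(np.sum((P_red @ Ymat) ** 2))
            return _partial_f(ssf_full, ssf_red, ss_tot, p_extra, n, p_full)

        obs = f_stat(Yc)
        fitted_red = P_red @ Yc
        resid_red = Yc - fitted_red
        hits = 0
        for _ in range(nperm):
            idx = rng.permutation(n)
            if permute == "residuals":
                Yp = fitted_red + resid_red[idx]
            else:
                Yp = Yc[idx]
            if f_stat(Yp) >= obs:
                hits += 1
        out[frac] = (hits + 1) / (nperm + 1)
    return out


def _univariate_f(y: np.ndarray, X_test: np.ndarray, X_other: np.ndarray,
                  w: np.ndarray) -> float:
    """Weighted partial pseudo-F for adding X_test over X_other."""
    n = y.shape[0]
    Xf = np.hstack([X_test, X_other])
    yc, Xfw = _weighted_design(y, Xf, w)
    _, Xow = _weighted_design(y, X_other, w)
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        raise UndefinedStatisticError("zero-variance response in permutation test")
    ssf_full = _fitted_ss(yc[:, None], Xfw)
    ssf_red = _fitted_ss(yc[:, None], Xow) if X_other.shape[1] else 0.0
    p_full = Xf.shape[1]
    return _partial_f(ssf_full, ssf_red, ss_tot, X_test.shape[1], n, p_full)


def test_trait(
    Y: AbundanceMatrix,
    u: SpeciesScores,
    E: PredictorSet,
    S: PredictorSet,
    response: str = "dispersion",
    weighting: str = "abundance_occurrence",
    nperm: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Double-permutation p-values for trait-based responses.

    Two null distributions are built for each tested fraction: one by
    permuting site rows of the tested predictor block, one by permuting the
    species score vector across species and recomputing the composition/
    dispersion decomposition each time.  The combined p-value is the
    maximum of the two (both permutation schemes must find the observed
    statistic extreme).  Keys: ``"a"``, ``"c"`` for the unique fractions
    and ``"env_model"`` for the whole environmental model [ab].
    """
    if nperm < 99:
        raise InputError("nperm must be at least 99")
    if response not in ("dispersion", "composition"):
        raise InputError(f"unknown trait response {response!r}")
    if np.ptp(u.scores.to_numpy(dtype=float)) == 0:
        raise UndefinedStatisticError(
            "species scores are constant: dispersion is identically zero"
        )
    comp, disp = decompose(Y, u, weighting)
    resp = disp if response == "dispersion" else comp
    y = resp.values.to_numpy(dtype=float)
    if np.var(y) == 0:
        raise UndefinedStatisticError(
            f"{response} response has zero variance across sites"
        )
    for block in (E, S):
        if list(block.data.index) != list(resp.sites):
            if set(block.data.index) != set(resp.sites):
                raise InputError(f"{block.role} predictor sites do not match response")
            block.data = block.data.reindex(resp.sites)
    w = resp.site_weights.to_numpy(dtype=float)
    Xe, *_ = _drop_collinear(E.data)
    Xs, *_ = _drop_collinear(S.data)
    n = y.shape[0]
    none = np.empty((n, 0))
    rng = np.random.default_rng(seed)
    uv = u.scores.to_numpy(dtype=float)

    # normalised cell weights reproduce the decomposition for permuted scores
    from .structure import cell_weights

    wc = cell_weights(Y, weighting).to_numpy(dtype=float)
    wt = wc / wc.sum(axis=1, keepdims=True)

    def permuted_response(up: np.ndarray) -> np.ndarray:
        m = wt @ up
        if response == "composition":
            return m
        return np.sqrt(np.maximum(wt @ (up * up) - m * m, 0.0))

    tests = {
        "a": (Xe, Xs),
        "c": (Xs, Xe),
        "env_model": (Xe, none),
    }
    # one shared set of permutations per scheme, reused across fractions
    site_perms = [rng.permutation(n) for _ in range(nperm)]
    species_resps = [permuted_response(rng.permutation(uv)) for _ in range(nperm)]

    out = {}
    for name, (X_test, X_other) in tests.items():
        obs = _univariate_f(y, X_test, X_other, w)
        # (i) permute site rows of the tested predictor block
        hits_site = 0
        for idx in site_perms:
            if _univariate_f(y, X_test[idx], X_other, w) >= obs:
                hits_site += 1
        p_site = (hits_site + 1) / (nperm + 1)
        # (ii) permute species scores, recomputing the decomposition
        hits_sp = 0
        for yp in species_resps:
            if np.var(yp) == 0:
                continue  # degenerate draw cannot be extreme
            if _univariate_f(yp, X_test, X_other, w) >= obs:
                hits_sp += 1
        p_species = (hits_sp + 1) / (nperm + 1)
        out[name] = max(p_site, p_species)
        out[f"{name}_site"] = p_site
        out[f"{name}_species"] = p_species
    return out


def significance_code(p: float) -> str:
    """Symbol for a p-value: ** (P<=0.01), * (0.05>=P>0.01), @ (0.10>=P>0.05)."""
    if not (0.0 <= p <= 1.0):
        raise InputError(f"p-value {p} outside [0, 1]")
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.10:
        return "@"
    return ""
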