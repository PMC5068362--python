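"""Species trait tables and species-by-species distance matrices.

Functional distances use the Gower metric on mixed binary/mensural
attributes, weighted so that every niche axis carries equal total weight
regardless of how many attributes describe it.  Phylogenetic distances are
cophenetic (patristic) distances read off a tree with branch lengths.
Missing mensural attributes are imputed by ordinary least squares on body
mass within the species' subfamily; missing binary attributes are copied
from a congener.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .errors import ImputationError, InputError

logger = logging.getLogger(__name__)

BINARY = "binary"
MENSURAL = "mensural"


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species-by-attribute table with niche-axis grouping.

    Parameters
    ----------
    data:
        species (rows) x attributes (columns); binary columns hold {0, 1,
        NaN}, mensural columns nonnegative reals or NaN.
    axis:
        attribute -> niche-axis label.
    kind:
        attribute -> ``"binary"`` or ``"mensural"``.
    mass_attr:
        name of the body-mass column (the imputation predictor).
    subfamily, genus:
        optional per-species taxonomy labels, needed only for imputation.
    """

    data: pd.DataFrame
    axis: pd.Series
    kind: pd.Series
    mass_attr: str | None = None
    subfamily: pd.Series | None = None
    genus: pd.Series | None = None

    def __post_init__(self) -> None:
        self.axis = pd.Series(self.axis).reindex(self.data.columns)
        self.kind = pd.Series(self.kind).reindex(self.data.columns)
        if self.axis.isna().any():
            missing = list(self.axis[self.axis.isna()].index)
            raise InputError(f"attributes without an axis label: {missing}")
        bad = set(self.kind.unique()) - {BINARY, MENSURAL}
        if bad:
            raise InputError(f"unknown attribute kinds: {sorted(bad)}")
        if self.mass_attr is not None and self.mass_attr not in self.data.columns:
            raise InputError(f"mass attribute {self.mass_attr!r} not in table")
        for col in self.data.columns:
            vals = self.data[col].dropna()
            if self.kind[col] == BINARY:
                if not vals.isin([0, 1]).all():
                    raise InputError(f"binary attribute {col!r} has values outside {{0,1}}")
            else:
                if (vals < 0).any():
                    raise InputError(f"mensural attribute {col!r} has negative values")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def axes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.axis:
            seen.setdefault(a, None)
        return list(seen)

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def copy(self) -> "TraitTable":
        return replace(
            self,
            data=self.data.copy(),
            axis=self.axis.copy(),
            kind=self.kind.copy(),
            subfamily=None if self.subfamily is None else self.subfamily.copy(),
            genus=None if self.genus is None else self.genus.copy(),
        )

    # -- CSV round trip: 3 header rows (attribute, axis, kind) ------------
    def to_csv(self, path) -> None:
        kinds = self.kind.copy()
        if self.mass_attr is not None:
            kinds[self.mass_attr] = kinds[self.mass_attr] + ":mass"
        cols = pd.MultiIndex.from_arrays(
            [self.data.columns, self.axis.values, kinds.values],
            names=["attribute", "axis", "kind"],
        )
        out = self.data.copy()
        out.columns = cols
        if self.subfamily is not None:
            out[("subfamily", "taxonomy", "label")] = self.subfamily
        if self.genus is not None:
            out[("genus", "taxonomy", "label")] = self.genus
        out.index.name = "species"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        raw.index.name = None
        subfamily = genus = None
        mass_attr = None
        names, axes, kinds, cols = [], [], [], []
        for key in raw.columns:
            name, ax, kd = key
            if kd == "label":
                if name == "subfamily":
                    subfamily = raw[key]
                elif name == "genus":
                    genus = raw[key]
                continue
            if kd.endswith(":mass"):
                kd = kd[: -len(":mass")]
                mass_attr = name
            names.append(name)
            axes.append(ax)
            kinds.append(kd)
            cols.append(raw[key])
        data = pd.concat(cols, axis=1)
        data.columns = names
        return cls(
            data=data,
            axis=pd.Series(axes, index=names),
            kind=pd.Series(kinds, index=names),
            mass_attr=mass_attr,
            subfamily=subfamily,
            genus=genus,
        )


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric species dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    provenance: str = "gower"  # "gower" | "cophenetic"
    axes_used: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InputError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise InputError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, provenance: str = "gower") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=list(df.index), values=df.values, provenance=provenance)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    table: TraitTable
    report: pd.DataFrame  # columns: species, attribute, kind, value, source


def impute_traits(
    traits: TraitTable,
    phylo_distances: DistanceMatrix | None = None,
) -> ImputationResult:
    """Fill missing trait cells.

    Mensural gaps are predicted from the least-squares regression of the
    attribute on body mass, fitted on same-subfamily species with known
    values (intercept included).  Binary gaps are copied from a congener;
    among several congeners with known values the one at smallest
    cophenetic distance wins (alphabetical first if no phylogeny is given).
    Observed cells are never altered.
    """
    if traits.n_missing() == 0:
        return ImputationResult(table=traits.copy(), report=_empty_report())
    if traits.mass_attr is None:
        raise ImputationError("imputation requires a flagged mass attribute")
    if traits.data[traits.mass_attr].isna().any():
        raise ImputationError("mass attribute must be complete before imputation")

    out = traits.copy()
    rows = []
    mass = traits.data[traits.mass_attr]
    for attr in traits.attributes:
        col = traits.data[attr]
        for sp in col.index[col.isna()]:
            if traits.kind[attr] == MENSURAL:
                value, source = _impute_mensural(traits, sp, attr, mass)
            else:
                value, source = _impute_binary(traits, sp, attr, phylo_distances)
            out.data.loc[sp, attr] = value
            rows.append(
                {"species": sp, "attribute": attr, "kind": traits.kind[attr],
                 "value": value, "source": source}
            )
    report = pd.DataFrame(rows) if rows else _empty_report()
    logger.info("imputed %d trait cells", len(report))
    return ImputationResult(table=out, report=report)


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(columns=["species", "attribute", "kind", "value", "source"])


def _impute_mensural(traits: TraitTable, sp: str, attr: str, mass: pd.Series):
    if traits.subfamily is None:
        raise ImputationError(
            f"cannot impute mensural cell ({sp!r}, {attr!r}): no subfamily labels"
        )
    same = traits.subfamily[traits.subfamily == traits.subfamily[sp]].index
    known = [s for s in same if s != sp and not pd.isna(traits.data.loc[s, attr])]
    if len(known) < 2:
        raise ImputationError(
            f"cannot impute mensural cell ({sp!r}, {attr!r}): "
            f"fewer than 2 same-subfamily species with known values"
        )
    x = mass.loc[known].to_numpy(dtype=float)
    y = traits.data.loc[known, attr].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    value = float(intercept + slope * mass[sp])
    value = max(value, 0.0)  # mensural attributes are nonnegative by contract
    return value, f"ols_on_mass[subfamily={traits.subfamily[sp]},n={len(known)}]"


def _impute_binary(traits: TraitTable, sp: str, attr: str,
                   phylo: DistanceMatrix | None):
    if traits.genus is None:
        raise ImputationError(
            f"cannot impute categorical cell ({sp!r}, {attr!r}): no genus labels"
        )
    congeners = [
        s for s in traits.genus[traits.genus == traits.genus[sp]].index
        if s != sp and not pd.isna(traits.data.loc[s, attr])
    ]
    if not congeners:
        raise ImputationError(
            f"cannot impute categorical cell ({sp!r}, {attr!r}): "
            f"no congener with a known value"
        )
    if phylo is not None and sp in phylo.ids:
        dist = phylo.to_frame()
        usable = [c for c in congeners if c in phylo.ids]
        if usable:
            congeners = sorted(usable, key=lambda c: (dist.loc[sp, c], c))
        else:
            congeners = sorted(congeners)
    else:
        congeners = sorted(congeners)
    donor = congeners[0]
    logger.debug("categorical cell (%s, %s) copied from congener %s", sp, attr, donor)
    return float(traits.data.loc[donor, attr]), f"congener[{donor}]"


# ---------------------------------------------------------------------------
# Gower distances
# ---------------------------------------------------------------------------

def gower(traits: TraitTable, axes: list[str] | None = None) -> DistanceMatrix:
    """Weighted Gower dissimilarity on mixed binary/mensural attributes.

    Each attribute gets weight ``1 / (n_axes_used * n_attrs_in_its_axis)``
    so every niche axis contributes total weight ``1 / n_axes_used`` and
    the full-table distance is bounded in [0, 1].  Mensural contributions
    are absolute differences scaled by the observed range over the analysed
    species; binary contributions are 0/1 mismatches.  Zero-range mensural
    attributes are dropped with a warning and the weights renormalised.
    Any remaining missing cells are handled by pairwise deletion with
    weight renormalisation (the pipeline imputes first, so this path is
    defensive).
    """
    if axes is None:
        use_axes = traits.axes
    else:
        unknown = set(axes) - set(traits.axes)
        if unknown:
            raise InputError(f"unknown niche axes requested: {sorted(unknown)}")
        use_axes = list(axes)
    attrs = [a for a in traits.attributes if traits.axis[a] in use_axes]
    if not attrs:
        raise InputError("no attributes in the requested axes")

    n_axes = len(use_axes)
    axis_counts = {ax: sum(1 for a in attrs if traits.axis[a] == ax) for ax in use_axes}

    X = traits.data[attrs].to_numpy(dtype=float)
    n = X.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k, attr in enumerate(attrs):
        w = 1.0 / (n_axes * axis_counts[traits.axis[attr]])
        col = X[:, k]
        if traits.kind[attr] == MENSURAL:
            rng = np.nanmax(col) - np.nanmin(col)
            if rng == 0 or np.isnan(rng):
                warnings.warn(
                    f"mensural attribute {attr!r} has zero range; "
                    f"excluded from Gower with weight renormalisation"
                )
                continue
            diff = np.abs(col[:, None] - col[None, :]) / rng
        else:
            diff = (col[:, None] != col[None, :]).astype(float)
        ok = ~(np.isnan(col)[:, None] | np.isnan(col)[None, :])
        num += np.where(ok, w * np.nan_to_num(diff), 0.0)
        den += np.where(ok, w, 0.0)
    if np.any(den == 0):
        raise InputError("some species pairs share no comparable attribute")
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=traits.species, values=d,
                          provenance="gower", axes_used=use_axes)


# ---------------------------------------------------------------------------
# Cophenetic distances
# ---------------------------------------------------------------------------

def cophenetic(
    tree: "dendropy.Tree | str",
    species: list[str] | None = None,
    substitutions: dict[str, str] | None = None,
) -> DistanceMatrix:
    """Patristic distances between (possibly substituted) tree tips.

    Entry (i, j) is the sum of branch lengths on the path between the tips
    representing species i and j.  A species absent from the tree may be
    mapped to a congener tip via ``substitutions``; two species mapped to
    the same tip get distance 0 with a logged warning.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    subs = substitutions or {}
    tip_names = {t.label for t in tree.taxon_namespace}
    if species is None:
        species = sorted(tip_names)

    mapping: dict[str, str] = {}
    unmapped = []
    for sp in species:
        tip = subs.get(sp, sp)
        if tip not in tip_names:
            unmapped.append(sp)
        else:
            mapping[sp] = tip
    if unmapped:
        raise InputError(f"species not on the tree and not substituted: {unmapped}")

    used = pd.Series(list(mapping.values()))
    for tip, cnt in used.value_counts().items():
        if cnt > 1:
            dup = [s for s, t in mapping.items() if t == tip]
            logger.warning(
                "species %s share tree tip %r; their pairwise distance is 0", dup, tip
            )

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = mapping[species[i]], mapping[species[j]]
            if ti == tj:
                continue
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[ti], taxa[tj])
    return DistanceMatrix(ids=list(species), values=d, provenance="cophenetic")


def read_substitutions(path) -> dict[str, str]:
    """Read a 2-column CSV mapping analysis species -> tree tip."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError("substitution map needs 2 columns: species, tip")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
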