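"""End-to-end orchestration: load data, build responses and predictors, and
run variation partitioning for every season x focal scale x response.

The run also emits two side tables: a decomposition summary giving the share
of between-site variation carried by composition versus dispersion for the
functional and phylogenetic axes, and Moran's I spatial-autocorrelation
tables for the structure vectors and for every environmental column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CommdecompError, ConfigurationError
from .spatial import build_connectivity, mem_basis, moran_i
from .structure import (AbundanceMatrix, decompose, decomposition_summary,
                        hellinger, species_scores)
from .traits import DistanceMatrix, TraitTable, cophenetic, gower, impute_traits, \
    read_substitutions
from .varpart import PredictorSet, partition, test_taxonomic, test_trait

logger = logging.getLogger(__name__)

RESPONSES = (
    "taxonomic",
    "functional_composition", "functional_dispersion",
    "phylogenetic_composition", "phylogenetic_dispersion",
    "per_axis_dispersion",
)


@dataclass
class RunConfig:
    """Paths and settings for one full analysis."""

    abundance: dict[str, str]          # season -> CSV path
    traits: str
    tree: str                          # Newick path
    coordinates: str                   # CSV: site_id, x, y
    predictors: dict[str, str]         # focal scale label -> CSV path
    seasons: list[str] = field(default_factory=list)
    scales: list[str] = field(default_factory=list)
    responses: list[str] = field(default_factory=lambda: list(RESPONSES))
    substitutions: str | None = None   # species -> tree tip CSV
    nperm: int = 1000
    seed: int = 0
    weighting: str = "abundance_occurrence"
    mem_predictors: int = 1            # how many leading MEMs form block S
    taxonomic_permute: str = "rows"

    def __post_init__(self) -> None:
        if not self.seasons:
            self.seasons = sorted(self.abundance)
        if not self.scales:
            self.scales = sorted(self.predictors)
        if not self.scales:
            raise ConfigurationError("no focal scales configured")
        if self.nperm < 99:
            raise ConfigurationError("nperm must be at least 99")
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ConfigurationError(f"unknown responses: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") \
                else json.load(fh)
        cfg = cls(**raw)
        base = path.parent
        # resolve paths relative to the config file
        cfg.abundance = {k: str(base / v) for k, v in cfg.abundance.items()}
        cfg.predictors = {k: str(base / v) for k, v in cfg.predictors.items()}
        cfg.traits = str(base / cfg.traits)
        cfg.tree = str(base / cfg.tree)
        cfg.coordinates = str(base / cfg.coordinates)
        if cfg.substitutions:
            cfg.substitutions = str(base / cfg.substitutions)
        return cfg


def validate_inputs(config: RunConfig) -> pd.DataFrame:
    """Itemised consistency report (never raises; report-only)."""
    items = []

    def add(item, status, message=""):
        items.append({"item": item, "status": status, "message": message})

    paths = {"traits": config.traits, "tree": config.tree,
             "coordinates": config.coordinates}
    paths.update({f"abundance[{s}]": p for s, p in config.abundance.items()})
    paths.update({f"predictors[{s}]": p for s, p in config.predictors.items()})
    missing = {k: p for k, p in paths.items() if not Path(p).exists()}
    for k, p in paths.items():
        add(f"path:{k}", "FAIL" if k in missing else "PASS",
            f"missing file {p}" if k in missing else p)
    if missing:
        return pd.DataFrame(items)

    traits = TraitTable.from_csv(config.traits)
    coords = pd.read_csv(config.coordinates, index_col=0)
    tree_tips = _tree_tips(config.tree)
    subs = read_substitutions(config.substitutions) if config.substitutions else {}
    for season, path in config.abundance.items():
        Y = pd.read_csv(path, index_col=0)
        vals = Y.to_numpy()
        add(f"counts_integral[{season}]",
            "PASS" if np.allclose(vals, np.round(vals)) and (vals >= 0).all()
            else "FAIL")
        missing_tr = sorted(set(Y.columns) - set(traits.species))
        add(f"species_in_traits[{season}]",
            "FAIL" if missing_tr else "PASS",
            f"species missing from traits: {missing_tr}" if missing_tr else "")
        on_tree = {subs.get(sp, sp) for sp in Y.columns}
        missing_ph = sorted(on_tree - tree_tips)
        add(f"species_on_tree[{season}]",
            "FAIL" if missing_ph else "PASS",
            f"tips missing from tree: {missing_ph}" if missing_ph else "")
        if set(Y.index) == set(coords.index):
            note = "" if list(Y.index) == list(coords.index) \
                else "site order differs; will be aligned by id"
            add(f"sites_in_coordinates[{season}]", "PASS", note)
        else:
            diff = sorted(set(Y.index) ^ set(coords.index))
            add(f"sites_in_coordinates[{season}]", "FAIL",
                f"site sets differ: {diff}")
        for scale, ppath in config.predictors.items():
            pred = pd.read_csv(ppath, index_col=0)
            ok = set(Y.index) <= set(pred.index)
            add(f"sites_in_predictors[{season},{scale}]",
                "PASS" if ok else "FAIL",
                "" if ok else f"missing sites: {sorted(set(Y.index) - set(pred.index))}")
    return pd.DataFrame(items)


def _tree_tips(path) -> set[str]:
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return {t.label for t in tree.taxon_namespace}


@dataclass
class RunReport:
    results: pd.DataFrame              # one row per season x scale x response
    decomposition: pd.DataFrame        # composition vs dispersion shares
    moran: pd.DataFrame                # spatial autocorrelation tables
    errors: list[dict]
    provenance: dict


def run(config: RunConfig, outdir=None) -> RunReport:
    """Execute the full partitioning analysis described by ``config``."""
    traits = TraitTable.from_csv(config.traits)
    subs = read_substitutions(config.substitutions) if config.substitutions else None
    coords = pd.read_csv(config.coordinates, index_col=0)

    abund = {s: AbundanceMatrix.from_csv(p, season=s)
             for s, p in config.abundance.items()}
    species = abund[config.seasons[0]].species
    sites = abund[config.seasons[0]].sites

    D_phylo = cophenetic(Path(config.tree).read_text(), species=species,
                         substitutions=subs)
    imputed = impute_traits(traits, phylo_distances=D_phylo)
    traits_full = imputed.table
    if list(traits_full.species) != species:
        traits_full = dataclasses.replace(
            traits_full, data=traits_full.data.reindex(species))
    D_fun = gower(traits_full)
    u_fun = species_scores(D_fun)
    u_phy = species_scores(D_phylo)

    coords = coords.reindex(sites)
    conn = build_connectivity(coords)
    basis = mem_basis(conn)
    S_cols = basis.predictors(config.mem_predictors)

    predictor_tables = {
        scale: pd.read_csv(path, index_col=0).reindex(sites)
        for scale, path in config.predictors.items()
    }

    results, errors, decomp_rows, moran_rows = [], [], [], []
    rng_root = np.random.SeedSequence(config.seed)
    combo_idx = 0

    # decomposition summary + Moran tables (per season, scale-independent)
    for season in config.seasons:
        Y = abund[season]
        for prov, u in (("functional", u_fun), ("phylogenetic", u_phy)):
            comp, disp = decompose(Y, u, config.weighting)
            row = {"season": season, "provenance": prov}
            row.update(decomposition_summary(comp, disp))
            decomp_rows.append(row)
            for kind, resp in (("composition", comp), ("dispersion", disp)):
                stat, p = moran_i(resp.values.reindex(conn.ids), conn,
                                  nperm=config.nperm,
                                  seed=int(np.random.SeedSequence(
                                      [config.seed, 101, combo_idx]).generate_state(1)[0] % 2**31))
                moran_rows.append({"season": season, "variable": f"{prov}_{kind}",
                                   "moran_i": stat, "p": p})
                combo_idx += 1
    for scale, table in predictor_tables.items():
        for col in table.columns:
            try:
                stat, p = moran_i(table[col].reindex(conn.ids), conn,
                                  nperm=config.nperm,
                                  seed=int(np.random.SeedSequence(
                                      [config.seed, 102, combo_idx]).generate_state(1)[0] % 2**31))
                moran_rows.append({"season": f"scale={scale}", "variable": col,
                                   "moran_i": stat, "p": p})
            except CommdecompError as exc:
                moran_rows.append({"season": f"scale={scale}", "variable": col,
                                   "moran_i": np.nan, "p": np.nan,
                                   "error": str(exc)})
            combo_idx += 1

    # main partitioning loop
    job = 0
    for season in sorted(config.seasons):
        Y = abund[season]
        Yhel = hellinger(Y)
        for scale in sorted(config.scales):
            E = PredictorSet(role="environment", data=predictor_tables[scale],
                             scale=scale, season=season)
            S = PredictorSet(role="space", data=S_cols.copy(), scale=scale,
                             season=season)
            for response in sorted(config.responses):
                job += 1
                seed = int(np.random.SeedSequence(
                    [config.seed, 200, job]).generate_state(1)[0] % 2**31)
                try:
                    rows = _run_one(response, Y, Yhel, u_fun, u_phy,
                                    traits_full, E, S, config, seed)
                    results.extend(rows)
                except CommdecompError as exc:
                    logger.warning("combination (%s, %s, %s) failed: %s",
                                   season, scale, response, exc)
                    errors.append({"season": season, "scale": scale,
                                   "response": response, "error": str(exc)})

    report = RunReport(
        results=pd.DataFrame(results),
        decomposition=pd.DataFrame(decomp_rows),
        moran=pd.DataFrame(moran_rows),
        errors=errors,
        provenance={
            "seed": config.seed, "nperm": config.nperm,
            "weighting": config.weighting,
            "mem_predictors": config.mem_predictors,
            "mem_threshold": conn.threshold,
            "imputed_cells": len(imputed.report),
            "dropped_columns": sorted(
                {c for r in results for c in r.get("dropped_columns", [])}),
        },
    )
    if outdir is not None:
        _write_report(report, outdir)
    return report


def _run_one(response, Y, Yhel, u_fun, u_phy, traits_full, E, S, config, seed):
    """One season x scale x response combination -> list of result rows."""
    if response == "taxonomic":
        res = partition(Yhel, E, S)
        pvals = test_taxonomic(Yhel, E, S, nperm=config.nperm, seed=seed,
                               permute=config.taxonomic_permute)
        for k, p in pvals.items():
            res.set_p(k, p)
        return [_result_row(res)]

    if response == "per_axis_dispersion":
        rows = []
        for i, ax in enumerate(traits_full.axes):
            D_ax = gower(traits_full, axes=[ax])
            u_ax = species_scores(D_ax)
            comp, disp = decompose(Y, u_ax, config.weighting)
            res = partition(disp, E, S)
            pvals = test_trait(Y, u_ax, E, S, response="dispersion",
                               weighting=config.weighting,
                               nperm=config.nperm, seed=seed + i)
            for k in ("a", "c", "env_model"):
                res.set_p(k, pvals[k])
            res.meta["response"] = f"dispersion[{ax}]"
            rows.append(_result_row(res))
        return rows

    prov, kind = response.split("_")
    u = u_fun if prov == "functional" else u_phy
    comp, disp = decompose(Y, u, config.weighting)
    resp = comp if kind == "composition" else disp
    res = partition(resp, E, S)
    pvals = test_trait(Y, u, E, S, response=kind,
                       weighting=config.weighting,
                       nperm=config.nperm, seed=seed)
    for k in ("a", "c", "env_model"):
        res.set_p(k, pvals[k])
    return [_result_row(res)]


def _result_row(res) -> dict:
    row = res.to_row()
    row["dropped_columns"] = sorted(
        {c for f in res.fits.values() for c in f.dropped_columns})
    return row


def _write_report(report: RunReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    res = report.results.copy()
    if not res.empty:
        res["dropped_columns"] = res["dropped_columns"].map(";".join)
        num = res.select_dtypes(include=[np.number]).columns
        res[num] = res[num].round(3)
    res.to_csv(out / "results.csv", index=False)
    report.results.to_json(out / "results.json", orient="records", indent=1)
    report.decomposition.round(6).to_csv(out / "decomposition_summary.csv",
                                         index=False)
    report.moran.round(6).to_csv(out / "moran_tables.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=1, default=str)
    if report.errors:
        with open(out / "errors.json", "w") as fh:
            json.dump(report.errors, fh, indent=1)


def plot_fractions(results: pd.DataFrame, path) -> None:
    """Stacked-bar chart of clamped fractions per response row."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if results.empty:
        raise ConfigurationError("no results to plot")
    labels = [
        f"{r.get('season', '')}/{r.get('scale', '')}/{r.get('response', '')}"
        for _, r in results.iterrows()
    ]
    frac = results[["a_clamped", "b_clamped", "c_clamped", "d_clamped"]].to_numpy()
    fig, ax = plt.subplots(figsize=(8, max(3, 0.4 * len(labels))))
    left = np.zeros(len(labels))
    for k, (name, color) in enumerate(zip("abcd", ["#31688e", "#35b779",
                                                   "#fde725", "#d0d0d0"])):
        ax.barh(labels, frac[:, k], left=left, label=f"[{name}]", color=color)
        left += frac[:, k]
    ax.set_xlabel("adjusted fraction of variation (clamped at 0)")
    ax.legend(loc="lower right", ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
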