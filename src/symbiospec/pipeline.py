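"""End-to-end orchestration: simulate -> delimit -> tables -> analyses.

Each step is a thin composition of the library modules; the CLI and the
worked examples call these functions.  All outputs are deterministic given
the run configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ForestMeta, ThallusRecord
from .delimit import delimit_phylogroups, pairwise_distance_matrix, select_threshold
from .drivers import rda, richness_gradient_lm, screen_predictors, variation_partition
from .interactions import build_table, InteractionTable
from .io import RunConfig, write_alignment, write_forest_table, write_thallus_table
from .metrics import chao1, efficiency_test, partner_richness, specialization_table
from .mixedmodels import (
    ModelSpec,
    fit_gaussian_lmm,
    fit_poisson_glmm,
    morans_i,
    r2_nakagawa,
    vif,
    wald_type3,
)
from .ranges import partner_limitation, range_table, richness_vs_range_lm
from .simulate import CommunityConfig, SyntheticCommunity, generate_community
from .turnover import turnover_table

ENV_PREDICTORS = ["bio01", "bio06", "bio14", "dbh"]


def delimit_alignment(alignment, band=(0.001, 0.01)):
    """Distance matrix -> barcode-gap threshold -> partition."""
    matrix = pairwise_distance_matrix(alignment)
    threshold = select_threshold(matrix, band)
    partition = delimit_phylogroups(matrix, threshold)
    return matrix, threshold, partition


def relabel_records(
    records: list[ThallusRecord], assignments: dict[str, str]
) -> list[ThallusRecord]:
    """Replace phylogroup labels with delimited ones (keyed by thallus id)."""
    return [
        dataclasses.replace(r, phylogroup=assignments[r.thallus_id])
        for r in records
    ]


def forest_frame(forests: list[ForestMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in forests]).set_index("forest")


def model_frame(
    table: InteractionTable,
    spec_df: pd.DataFrame,
    forests: pd.DataFrame,
    records: list[ThallusRecord],
) -> pd.DataFrame:
    """Join local metric rows with forest covariates and species traits."""
    local = spec_df[spec_df["scope"] != "regional"].copy()
    local = local.rename(columns={"scope": "forest", "partner_richness": "richness"})
    traits = {}
    for r in records:
        traits.setdefault(r.species, (r.guild, r.repro_mode))
    local["guild"] = local["species"].map(lambda s: traits[s][0])
    local["repro_mode"] = local["species"].map(lambda s: traits[s][1])
    return local.join(forests, on="forest")


def fit_driver_models(model_df: pd.DataFrame) -> dict:
    """The three GLMMs with their diagnostics."""
    out = {}
    vifs = vif(model_df[ENV_PREDICTORS])
    coords = model_df[["latitude", "longitude"]].to_numpy()
    for response in ("richness", "simpson", "dprime"):
        spec = ModelSpec.for_response(response)
        fit = (
            fit_poisson_glmm(spec, model_df)
            if spec.family == "poisson"
            else fit_gaussian_lmm(spec, model_df)
        )
        r2m, r2c = r2_nakagawa(fit)
        moran = morans_i(fit.residuals, coords)
        out[response] = {
            "family": spec.family,
            "transformation": spec.transformation,
            "n": fit.n,
            "converged": fit.converged,
            "coefficients": fit.params.to_dict(),
            "se": fit.bse.to_dict(),
            "random_variances": fit.vc,
            "residual_variance": fit.resid_var,
            "anova_type3": wald_type3(fit).to_dict(orient="records"),
            "r2_marginal": r2m,
            "r2_conditional": r2c,
            "vif": vifs.to_dict(),
            "morans_i": moran,
        }
    return out


def analyze(
    records: list[ThallusRecord],
    forests: list[ForestMeta],
    run_config: RunConfig,
) -> dict:
    """All downstream analyses on fully labeled records."""
    table = build_table(records)
    fdf = forest_frame(forests)
    coords = {f: (fdf.loc[f, "latitude"], fdf.loc[f, "longitude"]) for f in fdf.index}

    spec_df = specialization_table(
        table, run_config.min_regional_sequences, run_config.min_local_sequences
    )
    turn_df, turn_summary = turnover_table(
        table, run_config.min_regional_sequences, run_config.min_local_sequences
    )

    forest_mat = table.forest_matrix().reindex(fdf.index, fill_value=0)
    forest_richness = (forest_mat > 0).sum(axis=1)
    richness_lm = richness_gradient_lm(
        forest_richness.to_numpy(), fdf["latitude"].to_numpy()
    )

    # forest-level sampling efficiency: observed richness vs Chao1
    forest_chao = np.array([chao1(forest_mat.loc[f].to_numpy()) for f in fdf.index])
    t, df_, p = efficiency_test(forest_richness.to_numpy(float), forest_chao)
    efficiency = {"t": t, "df": df_, "p_value": p, "n_forests": len(fdf)}

    retained = screen_predictors(fdf[ENV_PREDICTORS], r_threshold=0.7)
    X = fdf[retained]
    rda_res = rda(forest_mat, X)
    varpart = variation_partition(
        forest_mat, X, groups={c: [c] for c in retained}
    )

    model_df = model_frame(table, spec_df, fdf, records)
    glmm = fit_driver_models(model_df)

    ranges_df = range_table(table, coords)
    range_lm = richness_vs_range_lm(table, coords, run_config.min_regional_sequences)
    limitation = partner_limitation(table, coords)

    return {
        "table": table,
        "specialization": spec_df,
        "turnover": turn_df,
        "turnover_summary": turn_summary,
        "forest_richness": forest_richness,
        "richness_gradient_lm": richness_lm,
        "sampling_efficiency": efficiency,
        "retained_predictors": retained,
        "rda": rda_res,
        "varpart": varpart,
        "glmm": glmm,
        "model_frame": model_df,
        "ranges": ranges_df,
        "richness_vs_range_lm": range_lm,
        "partner_limitation": limitation,
    }


def run_synthetic_pipeline(
    run_config: RunConfig, community_config: CommunityConfig | None = None
) -> dict:
    """Simulate a community, delimit from sequences, run every analysis."""
    if community_config is None:
        community_config = CommunityConfig(seed=run_config.seed)
    community = generate_community(community_config)
    matrix, threshold, partition = delimit_alignment(
        community.alignment, run_config.threshold_band
    )
    records = relabel_records(community.records, partition.assignments)
    results = analyze(records, community.forests, run_config)
    results.update(
        {
            "community": community,
            "distance_matrix": matrix,
            "threshold": threshold,
            "partition": partition,
        }
    )
    return results


def _float_fmt(x) -> str:
    return f"{x:.6g}" if isinstance(x, float) else str(x)


def write_outputs(results: dict, run_config: RunConfig, outdir: str | Path) -> None:
    """Serialize result tables (TSV, 6 significant digits) and JSON summaries."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# symbiospec {__version__} seed={run_config.seed} "
        f"threshold_band={run_config.threshold_band[0]},{run_config.threshold_band[1]} "
        f"min_regional={run_config.min_regional_sequences} "
        f"min_local={run_config.min_local_sequences}\n"
    )

    def tsv(df: pd.DataFrame, name: str, index=False) -> None:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index, float_format="%.6g")

    tsv(results["specialization"], "specialization.tsv")
    tsv(results["turnover"], "turnover.tsv")
    tsv(results["turnover_summary"], "turnover_summary.tsv")
    tsv(results["ranges"], "ranges.tsv")
    tsv(results["partner_limitation"], "partner_limitation.tsv")
    tsv(results["table"].counts, "interactions.tsv")

    summary = {
        "seed": run_config.seed,
        "version": __version__,
        "threshold": results.get("threshold"),
        "n_phylogroups": results.get("partition").n_groups
        if results.get("partition")
        else None,
        "richness_gradient_lm": results["richness_gradient_lm"],
        "sampling_efficiency": results["sampling_efficiency"],
        "retained_predictors": results["retained_predictors"],
        "rda_proportion_constrained": results["rda"].proportion_constrained,
        "varpart": {
            k: results["varpart"][k]
            for k in ("unique", "unique_plus_shared", "total_adj_r2")
        },
        "glmm": results["glmm"],
        "richness_vs_range_lm": results["richness_vs_range_lm"],
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )


def write_simulation(community: SyntheticCommunity, outdir: str | Path) -> None:
    """Write the raw synthetic inputs (and the ground truth) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(community.alignment, out / "alignment.fasta")
    blank = [dataclasses.replace(r, phylogroup="") for r in community.records]
    write_thallus_table(blank, out / "thalli.tsv")
    write_thallus_table(community.records, out / "thalli_true.tsv")
    write_forest_table(community.forests, out / "forests.tsv")
    community.pools.to_csv(out / "pools.tsv", sep="\t", float_format="%.6g")
    from .simulate import config_to_json

    config_to_json(community.config, out / "community_config.json")
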