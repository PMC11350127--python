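"""End-to-end orchestration: simulate -> spatial adjust -> epistasis + linkage.

``run_pipeline`` chains the stages in analysis order, writes every stage
artefact (with the config hash and seed as provenance) into the output
directory and returns the report bundle as a dictionary.  The routing
follows the analysis design: plant-level spatially corrected values feed
the CSL epistasis decomposition, genotype-level shrunken means feed the
RIL linkage scan.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import breeding, epistasis, io, linkage, pheno, spatial
from .config import RunConfig
from .panel import enumerate_panel, interaction_term, main_term


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the default synthetic experiment end to end.

    Stages: enumerate the CSL panel and simulate a RIL panel; lay out and
    simulate the phenotyping experiment; spatially adjust; run the staged
    epistasis decomposition on corrected plant values; run CIM on RIL
    shrunken means.  Every stage writes its artefact before the next starts,
    so a failure leaves partial outputs in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"config": config.to_dict(), "config_hash": config.hash(),
                    "stages": {}}
    config.to_yaml(outdir / "config.yaml")
    trace_path = outdir / "trace.jsonl"
    trace_fh = open(trace_path, "w")

    def log(stage: str, **payload):
        trace_fh.write(json.dumps({"stage": stage, **payload}) + "\n")
        trace_fh.flush()

    try:
        # ---- stage: simulate genotypes
        panel = enumerate_panel(config.n_chrom)
        genotypes = {g.label(): g for g in panel}
        io.write_csl_panel(panel, outdir / "csl_panel.tsv")
        marker_map = breeding.MarkerMap.default(config.n_chrom)
        io.write_map(marker_map, outdir / "marker_map.csv")
        rils = breeding.ril_panel(config.n_rils, marker_map, rng)
        io.write_recombinant_panel(rils, marker_map, outdir / "ril_panel.tsv")
        log("simulate-genotypes", n_csl=len(panel), n_ril=len(rils))
        report["stages"]["genotypes"] = {
            "n_csl": len(panel), "n_ril": len(rils),
            "n_markers": marker_map.n_markers,
        }

        # ---- stage: simulate phenotypes
        if config.trait == "flowering_time":
            model = pheno.EffectModel.flowering_time_default()
        else:
            model = pheno.EffectModel.stem_length_default()
        spec = pheno.default_csl_ril_spec(
            csl_lines=list(genotypes),
            ril_lines=[r.line_id for r in rils],
            csl_reps=config.csl_reps,
            ril_reps=config.ril_reps,
        )
        layout = pheno.make_layout(
            spec, grid=(config.grid_rows, config.grid_cols),
            n_blocks=config.n_blocks, rng=rng,
        )
        surface = pheno.spatial_surface(
            layout, amplitude=config.surface_amplitude * model.sigma_e, rng=rng
        )
        records, truth = pheno.simulate_experiment(
            layout, genotypes, model, trait=config.trait,
            block_sd=config.block_sd, surface=surface, rng=rng,
        )
        # RIL plants share the field; give them trait values from two QTLs
        ril_truth_qtls = [(2, 40.0, 3.0 * model.sigma_e),
                          (5, 50.0, 1.5 * model.sigma_e)]
        ril_geno_vals = pheno.simulate_ril_phenotypes(
            rils, marker_map, ril_truth_qtls, mu=model.mu, sigma_e=0.0,
        )
        ril_rows = []
        filled = layout.filled()
        for idx, rec in filled.iterrows():
            line = rec["line_id"]
            if line not in ril_geno_vals.index:
                continue
            yv = (
                float(ril_geno_vals[line])
                + truth["block_effects"][rec["block"]]
                + float(surface.loc[idx])
                + rng.normal(0.0, model.sigma_e)
            )
            ril_rows.append(
                {"line_id": line, "block": int(rec["block"]),
                 "row": int(rec["row"]), "col": int(rec["col"]),
                 "trait": config.trait, "value": yv}
            )
        records = pd.concat([records, pd.DataFrame(ril_rows)], ignore_index=True)
        io.write_phenotypes(records, outdir / "phenotypes.csv")
        io.write_report(
            {"genotype_values": truth["genotype_values"],
             "block_effects": truth["block_effects"],
             "ril_qtls": ril_truth_qtls, "seed": config.seed},
            outdir / "truth.json",
        )
        log("simulate-phenotypes", n_records=len(records))
        report["stages"]["phenotypes"] = {"n_records": len(records)}

        # ---- stage: spatial adjustment
        populations = {g: "CSL" for g in genotypes}
        populations.update({r.line_id: "RIL" for r in rils})
        if config.run_spatial:
            adjusted = spatial.fit_spatial(records, populations,
                                           trait=config.trait,
                                           seed=config.seed)
            plant_table = spatial.corrected_table(adjusted, "plant")
            geno_table = spatial.corrected_table(adjusted, "genotype")
            plant_table.to_csv(outdir / "corrected_plants.csv", index=False)
            geno_table.to_csv(outdir / "genotype_means.csv", index=False)
            io.write_report(adjusted.varcomp, outdir / "variance_components.json")
            y_col = "corrected"
            log("adjust-spatial", varcomp=adjusted.varcomp)
            report["stages"]["spatial"] = {"varcomp": adjusted.varcomp}
        else:
            plant_table = records.copy()
            plant_table["corrected"] = plant_table["value"]
            geno_table = (
                plant_table.groupby("line_id")["corrected"].mean()
                .rename("shrunken_mean").reset_index()
            )
            geno_table["population"] = geno_table["line_id"].map(populations)
            y_col = "corrected"

        # ---- stage: epistasis decomposition on CSL plants
        if config.run_epistasis:
            csl_rows = plant_table[plant_table["line_id"].isin(genotypes)]
            y = csl_rows[y_col].to_numpy(dtype=float)
            geno_list = [genotypes[l] for l in csl_rows["line_id"]]
            sel = epistasis.run_selection(
                y, geno_list, alpha3=config.alpha3, alpha2=config.alpha2
            )
            for step in sel.trace:
                log("map-epistasis", dropped=step.dropped, p=step.pvalue)
            ep_report = {
                "selected_terms": sel.terms(),
                "mains": sel.mains,
                "S2": [list(t) for t in sel.S2],
                "S3": [list(t) for t in sel.S3],
                "r2_full": sel.r2_full,
                "r2_main_only": sel.r2_main_only,
                "overall_p": sel.overall_p,
                "coefficients": sel.coef.reset_index()
                .rename(columns={"index": "term"}),
            }
            io.write_report(ep_report, outdir / "epistasis_report.json")
            for name, table in sel.class_means.items():
                table.to_csv(
                    outdir / f"effect_plot_{name.replace(':', '_')}.csv",
                    index=False,
                )
            report["stages"]["epistasis"] = {
                "selected_terms": sel.terms(),
                "r2_full": sel.r2_full,
                "r2_main_only": sel.r2_main_only,
            }

        # ---- stage: RIL linkage scan on shrunken means
        if config.run_linkage:
            ril_means = geno_table[
                geno_table["line_id"].str.startswith("RIL")
            ].set_index("line_id")["shrunken_mean"]
            predictors = linkage.genetic_predictors(
                rils, marker_map, step_cm=config.cim_step_cm
            )
            scan_res = linkage.cim_iterate(
                ril_means, predictors, alpha=config.alpha_gw,
                marker_map=marker_map, window_cm=config.cim_window_cm,
                min_sep_cm=config.cim_min_sep_cm,
            )
            scan_res.profile.to_csv(outdir / "ril_scan_profile.csv", index=False)
            scan_res.qtls.to_csv(outdir / "ril_qtls.csv", index=False)
            log("map-qtl", n_qtls=len(scan_res.qtls),
                threshold=scan_res.threshold)
            report["stages"]["linkage"] = {
                "threshold": scan_res.threshold,
                "qtls": scan_res.qtls.to_dict(orient="records"),
            }
    except Exception as exc:  # annotate which stage failed, keep artefacts
        log("error", message=str(exc))
        trace_fh.close()
        raise
    trace_fh.close()
    io.write_report(report, outdir / "report.json")
    return report
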