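"""End-to-end pipeline: simulate -> harmonize -> W-score -> interaction ->
PLS -> enrichment -> tissue, with a JSON run manifest.

Each stage reads the previous stage's TSV outputs from the run directory,
so stages can be re-run or disabled individually; a disabled stage simply
expects its outputs to exist already. All randomness derives from the
single global seed via fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combat import combat_fit, combat_apply
from .enrich import gsea_preranked, weighted_set_cover, write_gmt, read_gmt
from .io import config_hash, read_matrix_tsv, read_tsv, write_tsv
from .pls import (bootstrap_gene_weights, lv_significance, pls_fit,
                  region_score_correlation, spin_permutations)
from .synthdata import (CohortConfig, ExpressionConfig, PLANTED_SET_NAME,
                        generate_cohort, generate_expression, generate_geometry,
                        generate_genesets, generate_tissue_table,
                        true_interaction_map)
from .tissue import TissueTable, brain_enrichment_compare
from .wscore import (compute_wscores, fit_normative, regional_atrophy_test,
                     sex_interaction_estimates)

STAGES = ("simulate", "harmonize", "wscore", "interaction", "atrophy",
          "pls", "gsea", "tissue")

# fixed per-stage seed offsets (all well below 2**31 when added to a CLI seed)
_STAGE_SEED_OFFSET = {name: 1000 + i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Nested configuration of a full synthetic-pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    expression: ExpressionConfig = field(default_factory=lambda: ExpressionConfig(n_genes=2000))
    n_random_sets: int = 50
    geneset_size_range: tuple[int, int] = (10, 200)
    n_components: int = 3
    n_spin: int = 1000
    n_boot: int = 500
    #: 2000 (not 1000) so the sign-stratified add-one p floor, multiplied by
    #: the BH factor over ~25 positive-NES terms, stays below q = 0.05
    gsea_n_perm: int = 2000
    gsea_min_size: int = 5
    gsea_max_size: int = 2000
    setcover_k: int = 10
    n_tissues: int = 54
    n_brain_tissues: int = 13
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["atrophy_regions"] = sorted(d["cohort"]["atrophy_regions"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "atrophy_regions" in c:
                c["atrophy_regions"] = frozenset(c["atrophy_regions"])
            if "age_range" in c:
                c["age_range"] = tuple(c["age_range"])
            if "atrophy_gradient" in c:
                c["atrophy_gradient"] = tuple(c["atrophy_gradient"])
            kwargs["cohort"] = CohortConfig(**c)
        if "expression" in kwargs:
            kwargs["expression"] = ExpressionConfig(**kwargs["expression"])
        if "geneset_size_range" in kwargs:
            kwargs["geneset_size_range"] = tuple(kwargs["geneset_size_range"])
        if "stages" in kwargs:
            stages = {s: True for s in STAGES}
            stages.update(kwargs["stages"])
            kwargs["stages"] = stages
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return int(cfg.seed) + _STAGE_SEED_OFFSET[stage]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.as_dict())
    manifest = {"version": __version__, "seed": cfg.seed, "config": cfg.as_dict(),
                "config_hash": chash, "stages": []}

    def record(stage, t0, inputs, outputs, **extra):
        manifest["stages"].append({
            "stage": stage, "inputs": inputs, "outputs": outputs,
            "seed": _stage_seed(cfg, stage), "wall_time_s": round(time.time() - t0, 3),
            **extra})

    def wtsv(df, name, stage, index=True):
        write_tsv(df, out / name, stage=stage, seed=cfg.seed, cfg_hash=chash,
                  index=index)

    try:
        if cfg.stages.get("simulate", True):
            t0 = time.time()
            seed = _stage_seed(cfg, "simulate")
            geom = generate_geometry(cfg.cohort.n_regions, seed)
            cohort_cfg = dataclasses.replace(cfg.cohort, seed=seed + 1)
            participants, thickness = generate_cohort(cohort_cfg, geom)
            interaction = true_interaction_map(cohort_cfg, geom)
            expr_cfg = dataclasses.replace(cfg.expression, seed=seed + 2)
            expr, planted = generate_expression(expr_cfg, geom, interaction)
            genesets = generate_genesets(list(expr.columns), planted,
                                         cfg.n_random_sets,
                                         cfg.geneset_size_range, seed + 3)
            tissue_tab = generate_tissue_table(list(expr.columns),
                                               cfg.n_tissues, cfg.n_brain_tissues,
                                               brain_enriched_genes=planted,
                                               seed=seed + 4)
            wtsv(geom, "geometry.tsv", "simulate", index=False)
            wtsv(participants, "participants.tsv", "simulate")
            wtsv(thickness, "thickness.tsv", "simulate")
            wtsv(expr, "expression.tsv", "simulate")
            write_gmt(genesets, out / "genesets.gmt")
            wtsv(tissue_tab.tpm, "tissues.tsv", "simulate")
            wtsv(tissue_tab.is_brain.rename("is_brain").to_frame(),
                 "tissue_labels.tsv", "simulate")
            with open(out / "planted_genes.json", "w") as fh:
                json.dump({"planted": planted, "set_name": PLANTED_SET_NAME}, fh)
            record("simulate", t0, [], ["geometry.tsv", "participants.tsv",
                                        "thickness.tsv", "expression.tsv",
                                        "genesets.gmt", "tissues.tsv",
                                        "tissue_labels.tsv"])

        def need(*stages):
            return any(cfg.stages.get(s, True) for s in stages)

        if need("harmonize", "wscore", "interaction", "atrophy", "pls",
                "gsea", "tissue"):
            participants = read_tsv(out / "participants.tsv")
        if need("harmonize", "wscore"):
            thickness = read_matrix_tsv(out / "thickness.tsv")
        if need("pls"):
            geom = read_tsv(out / "geometry.tsv", index_col=None)

        if cfg.stages.get("harmonize", True):
            t0 = time.time()
            model = combat_fit(thickness, participants)
            adjusted = combat_apply(model, thickness, participants)
            wtsv(adjusted, "thickness_combat.tsv", "harmonize")
            model.to_json(out / "combat_model.json")
            record("harmonize", t0, ["thickness.tsv", "participants.tsv"],
                   ["thickness_combat.tsv", "combat_model.json"])

        if cfg.stages.get("wscore", True):
            adjusted = read_matrix_tsv(out / "thickness_combat.tsv")
            t0 = time.time()
            controls = participants[participants["group"] == "control"]
            patients = participants[participants["group"] == "patient"]
            norm = fit_normative(adjusted.loc[controls.index], controls)
            w = compute_wscores(adjusted.loc[patients.index], patients, norm)
            wtsv(w, "wscores.tsv", "wscore")
            record("wscore", t0, ["thickness_combat.tsv"], ["wscores.tsv"],
                   n_controls=len(controls), n_patients=len(patients))

        if need("interaction", "atrophy"):
            wscores = read_matrix_tsv(out / "wscores.tsv")
            patients = participants.loc[wscores.index]

        if cfg.stages.get("interaction", True):
            t0 = time.time()
            effects = sex_interaction_estimates(wscores, patients["sex"])
            wtsv(effects, "interaction.tsv", "interaction")
            record("interaction", t0, ["wscores.tsv"], ["interaction.tsv"])

        if cfg.stages.get("atrophy", True):
            t0 = time.time()
            stats_rows = {}
            for subset in ("M", "F", "all"):
                res = regional_atrophy_test(wscores, patients["sex"], subset)
                wtsv(res, f"atrophy_{subset}.tsv", "atrophy")
                stats_rows[subset] = {k: res.attrs[k] for k in
                                      ("n_patients", "n_sig_p", "n_sig_q",
                                       "prop_sig_p", "prop_sig_q")}
            with open(out / "atrophy_counts.json", "w") as fh:
                json.dump(stats_rows, fh, indent=2)
            record("atrophy", t0, ["wscores.tsv"],
                   ["atrophy_M.tsv", "atrophy_F.tsv", "atrophy_all.tsv",
                    "atrophy_counts.json"], counts=stats_rows)

        if cfg.stages.get("pls", True):
            t0 = time.time()
            seed = _stage_seed(cfg, "pls")
            expr = read_matrix_tsv(out / "expression.tsv")
            effects = read_tsv(out / "interaction.tsv")
            beta = effects["beta"].to_numpy()
            model = pls_fit(expr, beta, n_components=cfg.n_components)
            nulls = spin_permutations(geom, cfg.n_spin, seed)
            p_spin = lv_significance(model, expr, beta, nulls)
            boot = bootstrap_gene_weights(expr, beta, component_set=(1,),
                                          n_boot=cfg.n_boot, seed=seed + 1)
            comp = pd.DataFrame({
                "component": np.arange(1, cfg.n_components + 1),
                "var_explained": model.var_explained,
                "cumulative": model.cumulative_var,
                "p_spin": p_spin,
                "score_r": [region_score_correlation(model, beta, c)[0]
                            for c in range(1, cfg.n_components + 1)],
            }).set_index("component")
            scores = pd.DataFrame(model.scores, index=expr.index,
                                  columns=[f"t{c}" for c in range(1, cfg.n_components + 1)])
            ratios = boot.ranked_scores(1).to_frame()
            wtsv(comp, "components.tsv", "pls")
            wtsv(scores, "scores.tsv", "pls")
            wtsv(ratios, "gene_ratios.tsv", "pls")
            record("pls", t0, ["expression.tsv", "interaction.tsv", "geometry.tsv"],
                   ["components.tsv", "scores.tsv", "gene_ratios.tsv"])

        if cfg.stages.get("gsea", True):
            t0 = time.time()
            seed = _stage_seed(cfg, "gsea")
            ranked = read_tsv(out / "gene_ratios.tsv")["bootstrap_ratio"]
            collection = read_gmt(out / "genesets.gmt")
            res = gsea_preranked(ranked, collection, cfg.gsea_min_size,
                                 cfg.gsea_max_size, cfg.gsea_n_perm, seed)
            sig = res[res["q"] < 0.05]
            reduced = weighted_set_cover(sig, k=cfg.setcover_k)
            wtsv(res, "enrichment.tsv", "gsea")
            with open(out / "enrichment_reduced.json", "w") as fh:
                json.dump({"selected_terms": reduced}, fh)
            record("gsea", t0, ["gene_ratios.tsv", "genesets.gmt"],
                   ["enrichment.tsv", "enrichment_reduced.json"],
                   n_significant=int((res["q"] < 0.05).sum()))

        if cfg.stages.get("tissue", True):
            t0 = time.time()
            ranked = read_tsv(out / "gene_ratios.tsv")["bootstrap_ratio"]
            tpm = read_tsv(out / "tissues.tsv")
            labels = read_tsv(out / "tissue_labels.tsv")["is_brain"].astype(bool)
            table = TissueTable(tpm=tpm, is_brain=labels)
            top_gene = ranked.index[0]
            mid_gene = ranked.index[len(ranked) // 2]
            counts, chi2, p = brain_enrichment_compare(table, top_gene, mid_gene)
            result = {"gene_top": top_gene, "gene_reference": mid_gene,
                      "counts": counts.tolist(), "chi2": chi2, "p": p}
            with open(out / "tissue_enrichment.json", "w") as fh:
                json.dump(result, fh, indent=2)
            record("tissue", t0, ["gene_ratios.tsv", "tissues.tsv"],
                   ["tissue_enrichment.json"], **result)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        done = {s["stage"] for s in manifest["stages"]}
        current = next((s for s in STAGES
                        if cfg.stages.get(s, True) and s not in done), "unknown")
        raise StageError(current, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
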