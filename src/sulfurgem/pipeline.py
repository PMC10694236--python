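"""End-to-end orchestration of the draft -> final-model curation workflow.

Stage order is fixed: merge the two annotation drafts, repair
energy-generating cycles against the directionality reference, extend with
the curated sulfur-oxidation core, install biomass and gap-fill blocked
precursors, extend for phenotype-array false negatives, and finally
enumerate sulfur-oxidation pathways.  Each stage writes its model and a
machine-readable report; a failure halts with the stage name while earlier
outputs are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curation, io, phenotype, sulfur
from .core import MetabolicModel, model_stats
from .fba import Medium, fba

log = logging.getLogger("sulfurgem")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    model_a: str | None = None
    model_b: str | None = None
    directionality_reference: str | None = None
    universal_db: str | None = None
    biomass_composition: str | None = None
    panel: str | None = None
    sulfur_uptake: float = sulfur.SULFUR_UPTAKE_DEFAULT
    ou_threshold: float = phenotype.OU_THRESHOLD
    growth_threshold: float = phenotype.GROWTH_THRESHOLD
    gapfill_threshold: float = curation.GAPFILL_THRESHOLD
    output_dir: str = "pipeline_out"
    seed: int = 0
    medium_uptake: dict = field(default_factory=dict)
    medium_closed: list = field(default_factory=list)
    #: exchanges additionally closed while testing carbon sources, e.g. the
    #: growth substrate itself when carbon and energy source coincide
    phenotype_closed: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @property
    def medium(self) -> Medium:
        return Medium(dict(self.medium_uptake), set(self.medium_closed))

    @property
    def phenotype_medium(self) -> Medium:
        return Medium(dict(self.medium_uptake),
                      set(self.medium_closed) | set(self.phenotype_closed))


def _write_stage(outdir: Path, name: str, model: MetabolicModel,
                 report: curation.CurationReport | None) -> None:
    io.write_model(model, outdir / f"{name}.json")
    if report is not None:
        (outdir / f"{name}.report.json").write_text(json.dumps(report.to_dict(), indent=1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written as JSON + TSV)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    medium = config.medium

    def record(name: str, model: MetabolicModel) -> None:
        stats = model_stats(model)
        summary["stages"][name] = {
            "n_genes": stats.n_genes,
            "n_metabolites": stats.n_metabolites,
            "n_reactions": stats.n_reactions,
        }
        log.info("stage %s: %d metabolites, %d reactions", name,
                 stats.n_metabolites, stats.n_reactions)

    stage = "merge"
    try:
        a = io.read_model(config.model_a)
        b = io.read_model(config.model_b)
        draft, merge_report = curation.merge_models(a, b)
        _write_stage(outdir, "draft", draft, merge_report)
        record("draft", draft)

        stage = "fix-energy"
        model_01 = draft
        repair_report = curation.CurationReport(stage="energy-cycle-repair")
        if config.directionality_reference:
            reference = curation.DirectionalityReference.from_tsv(
                config.directionality_reference
            )
            model_01, repair_report = curation.repair_energy_cycles(draft, reference)
        _write_stage(outdir, "model_01", model_01, repair_report)
        record("model_01", model_01)
        summary["stages"]["model_01"]["modified_reversibilities"] = len(
            repair_report.modified_reversibilities
        )

        stage = "sulfur-core"
        core = sulfur.build_sulfur_core()
        try:
            model_02, core_report = curation.merge_models(model_01, core)
        except curation.MergeConflictError:
            model_02, core_report = model_01, curation.CurationReport(stage="sulfur-core")
            core_report.notes.append("sulfur core conflicts with draft ids; skipped")
        _write_stage(outdir, "model_02", model_02, core_report)
        record("model_02", model_02)

        stage = "gapfill"
        model_03 = model_02
        gap_report = curation.CurationReport(stage="precursor-gapfill")
        if config.biomass_composition:
            composition = curation.BiomassComposition.from_tsv(config.biomass_composition)
            model_03 = curation.install_biomass(model_02, composition)
            gap_report.precursor_status = curation.check_precursors(
                model_03, composition, medium
            )
            if config.universal_db:
                db = curation.UniversalReactionDB.from_tsv(config.universal_db)
                for met_id, status in sorted(gap_report.precursor_status.items()):
                    if status != "blocked":
                        continue
                    from .fba import ensure_demand

                    demand = ensure_demand(model_03, met_id)
                    added, model_03 = curation.gapfill(
                        model_03, db, demand, medium, threshold=config.gapfill_threshold
                    )
                    gap_report.added_reactions.extend(added)
                gap_report.precursor_status = curation.check_precursors(
                    model_03, composition, medium
                )
        _write_stage(outdir, "model_03", model_03, gap_report)
        record("model_03", model_03)

        stage = "biolog"
        model_04 = model_03
        pheno_report = curation.CurationReport(stage="phenotype-extension")
        if config.panel:
            panel = phenotype.call_phenotypes(
                phenotype.PhenotypePanel.from_tsv(config.panel), config.ou_threshold
            )
            if config.universal_db:
                db = curation.UniversalReactionDB.from_tsv(config.universal_db)
                model_04, pheno_report = phenotype.extend_for_phenotypes(
                    model_03, panel, db, config.phenotype_medium
                )
            table, simulated = phenotype.concordance(model_04, panel, config.phenotype_medium)
            summary["concordance"] = table.to_dict()
            simulated.to_tsv(outdir / "concordance.tsv")
        _write_stage(outdir, "model_04", model_04, pheno_report)
        record("model_04", model_04)

        stage = "sulfur-paths"
        pathways = []
        if sulfur.SULFUR_EXCHANGE in model_04.reactions:
            pathways = sulfur.enumerate_pathways(model_04, config.sulfur_uptake)
        summary["pathways"] = pathway_table(pathways).to_dict(orient="records")
    except StageError:
        raise
    except Exception as exc:  # halt with stage name, keep earlier outputs
        raise StageError(stage, exc) from exc

    write_report(summary, outdir)
    return summary


def pathway_table(pathways: list[sulfur.SulfurPathway]) -> pd.DataFrame:
    """Ranked pathway table mirroring the four-column energetics schema."""
    return pd.DataFrame(
        [
            {
                "pathway": p.label,
                "active_reactions": ";".join(p.active_reactions),
                "nadh_nadph_rate": p.energetics.nadh_nadph_rate,
                "atp_rate": p.energetics.atp_rate,
                "co2_uptake": p.energetics.co2_uptake,
                "growth_rate": p.energetics.growth_rate,
            }
            for p in pathways
        ],
        columns=["pathway", "active_reactions", "nadh_nadph_rate", "atp_rate",
                 "co2_uptake", "growth_rate"],
    )


def write_report(summary: dict, outdir: Path) -> None:
    """Write the JSON summary and its field-for-field TSV mirrors."""
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    stages = pd.DataFrame(
        [{"stage": k, **v} for k, v in summary.get("stages", {}).items()]
    )
    stages.to_csv(outdir / "stages.tsv", sep="\t", index=False)
    pd.DataFrame(summary.get("pathways", []),
                 columns=["pathway", "active_reactions", "nadh_nadph_rate", "atp_rate",
                          "co2_uptake", "growth_rate"]).to_csv(
        outdir / "pathways.tsv", sep="\t", index=False
    )
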