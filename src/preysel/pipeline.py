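"""End-to-end orchestration: read inputs, run every stage, write a bundle.

Stage order follows the analysis flow of a multiple-choice predation study:
selectivity -> diet/predation-pressure overlaps -> clustering and ordination
-> food-web modularity -> prey vulnerability -> (optional) literature
synthesis.  Outputs are TSV matrices with labels plus JSON result bundles,
and a manifest recording seeds and options so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiment import (
    read_controls, read_literature, read_predators, read_prey, read_trials,
)
from .literature import (
    microhabitat_fisher, microhabitat_table, preference_glm, rank_matrix_occupancy,
    score_preferences,
)
from .modularity import find_modules, scale_weights
from .overlap import (
    diet_overlap_matrix, nmds, predation_pressure_overlap_matrix,
    to_dissimilarity, ward_cluster,
)
from .selectivity import build_profile, compare_stages
from .vulnerability import mortality_table, vulnerability_tests

log = logging.getLogger("preysel")

#: ontogenetic ordering used to orient stage contrasts (later > earlier)
STAGE_ORDER = {"L1": 0, "L2": 1, "L3": 2, "F-2": 3, "F-1": 4, "F-0": 5, "adult": 6}


@dataclass
class RunConfig:
    trials: str
    prey: str
    controls: str
    predators: str | None = None
    literature: str | None = None
    outdir: str = "results"
    seed: int = 0
    nmds_restarts: int = 20
    modularity_restarts: int = 50
    ward_variant: str = "ward.D"
    welch: bool = True
    depletion_correction: bool = True
    round_digits: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_matrix(df: pd.DataFrame, path: Path, digits: int | None) -> None:
    out = df.round(digits) if digits is not None else df
    out.to_csv(path, sep="\t")


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    digits = config.round_digits

    log.info("reading inputs")
    roster = read_prey(config.prey)
    trials = read_trials(config.trials, roster)
    controls = read_controls(config.controls, roster)
    predators = read_predators(config.predators) if config.predators else None

    stage_ids = list(dict.fromkeys(t.predator_stage_id for t in trials))
    prey_ids = [p.id for p in roster]

    # --- selectivity -------------------------------------------------------
    log.info("selectivity: %d predator stages", len(stage_ids))
    profiles = [
        build_profile(s, trials, controls, config.depletion_correction)
        for s in stage_ids
    ]
    rows = []
    breadth_rows = []
    for prof in profiles:
        test = prof.test()
        for j, prey in enumerate(prof.prey_ids):
            rows.append(
                (prof.predator_stage_id, prey, prof.mean_alpha[j], prof.se_alpha[j],
                 prof.mean_electivity[j], prof.se_electivity[j], test.t[j],
                 test.p_raw[j], test.p_holm[j], bool(test.significant[j]))
            )
        breadth_rows.append((prof.predator_stage_id, prof.diet_breadth))
    sel = pd.DataFrame(
        rows,
        columns=["predator_stage_id", "prey_id", "mean_alpha", "se_alpha",
                 "mean_electivity", "se_electivity", "t", "p_raw", "p_holm",
                 "significant"],
    )
    sel_out = sel.round(digits) if digits is not None else sel
    sel_out.to_csv(out / "selectivity.tsv", sep="\t", index=False)
    pd.DataFrame(breadth_rows, columns=["predator_stage_id", "diet_breadth"]).to_csv(
        out / "breadth.tsv", sep="\t", index=False
    )

    # --- ontogenetic stage contrasts --------------------------------------
    by_species: dict[str, list] = {}
    if predators:
        for p in predators:
            by_species.setdefault(p.species, []).append(p)
    ods_rows = []
    prof_by_id = {p.predator_stage_id: p for p in profiles}
    for species, stages in by_species.items():
        staged = [s for s in stages if s.id in prof_by_id]
        staged.sort(key=lambda s: STAGE_ORDER.get(s.stage, 99))
        for i in range(len(staged)):
            for j in range(i + 1, len(staged)):
                earlier, later = staged[i], staged[j]
                contrast = compare_stages(
                    prof_by_id[later.id], prof_by_id[earlier.id], welch=config.welch
                )
                for k, prey in enumerate(contrast.prey_ids):
                    ods_rows.append(
                        (species, later.id, earlier.id, prey, contrast.t[k],
                         contrast.p[k], bool(contrast.missing[k]))
                    )
    if ods_rows:
        pd.DataFrame(
            ods_rows,
            columns=["species", "later_stage", "earlier_stage", "prey_id",
                     "t", "p", "missing"],
        ).to_csv(out / "ontogenetic_shifts.tsv", sep="\t", index=False)

    # --- overlaps, clustering, ordination ---------------------------------
    log.info("overlap matrices and structure")
    diet_overlap = diet_overlap_matrix(profiles)
    mort = mortality_table(trials, controls)
    pressure_overlap = predation_pressure_overlap_matrix(mort.mean)
    _write_matrix(diet_overlap, out / "overlap_diet.tsv", digits)
    _write_matrix(pressure_overlap, out / "overlap_pressure.tsv", digits)

    d_diet = to_dissimilarity(diet_overlap)
    d_pressure = to_dissimilarity(pressure_overlap)
    _write_matrix(d_diet, out / "dissimilarity_diet.tsv", digits)
    _write_matrix(d_pressure, out / "dissimilarity_pressure.tsv", digits)

    tree_pred = ward_cluster(d_diet, config.ward_variant)
    tree_prey = ward_cluster(d_pressure, config.ward_variant)
    (out / "dendrogram_predators.nwk").write_text(tree_pred.to_newick() + "\n")
    (out / "dendrogram_prey.nwk").write_text(tree_prey.to_newick() + "\n")

    ord_pred = nmds(d_diet, restarts=config.nmds_restarts, seed=config.seed)
    ord_prey = nmds(d_pressure, restarts=config.nmds_restarts, seed=config.seed)
    ord_pred.to_frame().to_csv(out / "ordination_predators.tsv", sep="\t")
    ord_prey.to_frame().to_csv(out / "ordination_prey.tsv", sep="\t")

    # --- modularity (both interaction-strength measures) ------------------
    log.info("bipartite modularity")
    alpha_raw = pd.DataFrame(
        [p.mean_alpha for p in profiles],
        index=[p.predator_stage_id for p in profiles],
        columns=prey_ids,
    )
    webs = {
        "manly_alpha": scale_weights(alpha_raw, measure="manly_alpha"),
        "mortality": scale_weights(mort.mean.T, measure="mortality"),
    }
    modules_json = {}
    mod_rows = []
    for measure, web in webs.items():
        part = find_modules(
            web, restarts=config.modularity_restarts, seed=config.seed
        )
        modules_json[measure] = {
            "Q": part.q,
            "n_modules": part.n_modules,
            "seed": config.seed,
            "restarts": config.modularity_restarts,
            "modules": [
                {"predators": sorted(r), "prey": sorted(c)}
                for r, c in part.module_members()
            ],
        }
        frame = part.to_frame()
        frame.insert(0, "measure", measure)
        mod_rows.append(frame)
    with open(out / "modules.json", "w") as fh:
        json.dump(modules_json, fh, indent=2)
    pd.concat(mod_rows).to_csv(out / "modules.tsv", sep="\t", index=False)

    # --- vulnerability -----------------------------------------------------
    log.info("prey vulnerability")
    _write_matrix(mort.to_frame(), out / "mortality.tsv", digits)
    glms = vulnerability_tests(trials, controls)
    vuln = {
        prey: {
            "F": res.f_statistic, "df_num": res.df_num, "df_den": res.df_den,
            "p": res.p_value, "dispersion": res.dispersion,
            "separation": res.separation_flag,
        }
        for prey, res in glms.items()
    }
    with open(out / "vulnerability_glm.json", "w") as fh:
        json.dump(vuln, fh, indent=2)

    # --- literature synthesis (optional) -----------------------------------
    lit_summary = None
    if config.literature:
        log.info("literature synthesis")
        records = read_literature(config.literature)
        scored = score_preferences(records)
        scored.per_taxon.to_csv(out / "preference_scores.tsv", sep="\t", index=False)
        glm = preference_glm(scored, seed=config.seed)
        _, frac_empty = rank_matrix_occupancy(records)
        table = microhabitat_table(records)
        fisher_p = microhabitat_fisher(table)
        lit_summary = {
            "n_experiments": scored.n_experiments,
            "n_excluded_single_taxon": scored.n_excluded,
            "glm_F": glm.overall.f_statistic,
            "glm_p": glm.overall.p_value,
            "dispersion": glm.overall.dispersion,
            "rank_matrix_fraction_empty": frac_empty,
            "microhabitat_table": table.tolist(),
            "fisher_one_tailed_p": fisher_p,
            "letters": glm.letters,
        }
        with open(out / "preference_glm.json", "w") as fh:
            json.dump(
                {
                    "F": glm.overall.f_statistic,
                    "p": glm.overall.p_value,
                    "dispersion": glm.overall.dispersion,
                    "adjustment": glm.adjustment,
                    "boundary_taxa": list(glm.boundary_taxa),
                    "letters": glm.letters,
                },
                fh, indent=2,
            )
        glm.contrasts.to_csv(out / "preference_contrasts.tsv", sep="\t", index=False)
        with open(out / "fisher.json", "w") as fh:
            json.dump({"table": table.tolist(), "p_one_tailed": fisher_p}, fh, indent=2)
    else:
        log.info("no literature table configured; literature stage skipped")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_trials": len(trials),
        "stages": stage_ids,
        "prey": prey_ids,
        "nmds_stress": {"predators": ord_pred.stress, "prey": ord_prey.stress},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "profiles": profiles,
        "diet_overlap": diet_overlap,
        "pressure_overlap": pressure_overlap,
        "predator_tree": tree_pred,
        "prey_tree": tree_prey,
        "ordination": {"predators": ord_pred, "prey": ord_prey},
        "modules": modules_json,
        "mortality": mort,
        "vulnerability": vuln,
        "literature": lit_summary,
        "manifest": manifest,
    }
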