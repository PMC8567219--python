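"""End-to-end orchestration: simulate -> parse -> normalize -> filter ->
assemble -> integrate/classify -> motifs, plus the independent M-Track
branch, from a single config with a fixed seed.

Every stage writes a tab-delimited artifact with stable float formatting, so
a rerun with the same config is byte-identical.  ``demo()`` runs the default
stated world: three setups (stress response, phosphatase-subunit deletion,
endosulfine-deletion stress response), planted Set1/Set2/static/decreased
sites, lognormal ratio noise (sd 0.3 in log2), a mixing offset, a negative
per-proline conversion factor and one orientation-swapped replicate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import classify, evidence_io, motifs, mtrack, normalize, simulate, sites
from .errors import PhosphoflowError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the demo's stated world."""

    seed: int = 0
    # proteome / evidence generation
    n_proteins: int = 60
    protein_length_range: tuple[int, int] = (250, 450)
    n_evidence: int = 4000
    mixing_offset_m: float = 0.4
    proline_factor_c: float = -0.25
    noise_sd: float = 0.3
    setups: tuple[str, ...] = ("SR", "cdc55", "SR_igo1igo2")
    replicates: tuple[str, ...] = ("r1", "r2", "r3")
    label_swap: Mapping[str, bool] = field(default_factory=lambda: {"r2": True})
    frac_low_localization: float = 0.15
    # planted site classes
    n_set1: int = 60
    n_set2: int = 30
    n_static: int = 80
    n_decreased: int = 15
    stp_bias: float = 0.8
    # thresholds / settings
    min_isoform_prob: float = 0.70
    rules: classify.ClassRules = field(default_factory=classify.ClassRules)
    motif_min_seq: int = 20
    motif_p_cutoff: float = 0.01
    # M-Track branch
    mtrack_n_baits: int = 10
    mtrack_n_replicates: int = 4
    mtrack_curve_degree: int = 2
    mtrack_effects: Mapping[str, float] = field(
        default_factory=lambda: {"B01": 2.0, "B02": 2.0, "B03": 2.0}
    )
    mtrack_noise_sd: float = 0.3
    # stage toggles
    run_islands: bool = True
    run_motifs: bool = True
    run_mtrack: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PhosphoflowError(f"unknown config keys: {sorted(unknown)}")
        if "rules" in raw:
            raw["rules"] = classify.ClassRules(**raw["rules"])
        for key in ("protein_length_range", "setups", "replicates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all enabled stages in order, writing artifacts to ``outdir``.

    Returns the run report (also written as ``run_report.json``): per-stage
    record counts, dropped-row counts and all fitted normalization factors.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # --- simulate -----------------------------------------------------------
    proteome = simulate.generate_proteome(
        config.n_proteins, config.protein_length_range, seed=config.seed
    )
    effect_table, true_labels = simulate.plan_site_effects(
        proteome,
        n_set1=config.n_set1,
        n_set2=config.n_set2,
        n_static=config.n_static,
        n_decreased=config.n_decreased,
        setups=config.setups,
        seed=config.seed + 1,
        stp_bias=config.stp_bias,
    )
    sim_config = simulate.SimulationConfig(
        n_proteins=config.n_proteins,
        protein_length_range=config.protein_length_range,
        n_evidence=config.n_evidence,
        mixing_offset_m=config.mixing_offset_m,
        proline_factor_c=config.proline_factor_c,
        noise_sd=config.noise_sd,
        site_effect_table=effect_table,
        setups=config.setups,
        replicates=config.replicates,
        frac_low_localization=config.frac_low_localization,
        label_swap=dict(config.label_swap),
        seed=config.seed + 2,
    )
    evidence, truth = simulate.simulate_evidence(sim_config, proteome)
    evidence_io.write_fasta(proteome, out / "proteome.fasta")
    evidence_io.write_evidence_table(evidence, out / "evidence.tsv")
    simulate.write_ground_truth(truth, out / "ground_truth.tsv")
    report["stages"]["simulate"] = {
        "n_evidence": len(evidence),
        "n_sites_planted": len(true_labels),
    }

    # --- parse --------------------------------------------------------------
    records, parse_report = evidence_io.read_evidence(
        out / "evidence.tsv", dialect="simple"
    )
    if parse_report.row_errors:
        raise PhosphoflowError(
            f"parse: {len(parse_report.row_errors)} row-level errors"
        )
    report["stages"]["parse"] = {
        "n_rows": parse_report.n_rows,
        "n_records": parse_report.n_records,
        "n_dropped_missing_ratio": parse_report.n_dropped_missing_ratio,
    }

    # --- normalize ----------------------------------------------------------
    models = normalize.fit_groups(records, swap_map=config.label_swap)
    normalize.apply_normalization(records, models, swap_map=config.label_swap)
    report["stages"]["normalize"] = {
        f"{setup}/{rep}": {
            "m": model.mixing_factor_m,
            "c": model.proline_factor_c,
            "n_reference": model.n_reference_peptides,
            "n_one_proline": model.n_one_proline,
            "n_two_proline": model.n_two_proline,
        }
        for (setup, rep), model in sorted(models.items())
    }

    # --- localization filter + site assembly --------------------------------
    retained = sites.filter_localization(records, config.min_isoform_prob)
    n_phospho = sum(1 for r in records if r.is_phosphorylated)
    n_retained_phospho = sum(1 for r in retained if r.is_phosphorylated)
    site_list = sites.assemble_sites(retained, proteome)
    evidence_io.write_site_table(site_list, out / "sites.tsv")
    report["stages"]["sites"] = {
        "n_phospho_records": n_phospho,
        "n_discarded_localization": n_phospho - n_retained_phospho,
        "n_sites": len({s.identity for s in site_list}),
    }

    if config.run_islands:
        islands = sites.build_phosphoislands(retained, proteome)
        with open(out / "islands.tsv", "w") as fh:
            fh.write("protein\tpositions\tspan\tn_sites\tucg_log2\tucg_n\n")
            for isl in islands:
                pos = ";".join(map(str, isl.positions))
                ucg = "" if isl.ucg_log2 is None else f"{isl.ucg_log2:.10g}"
                fh.write(
                    f"{isl.protein_id}\t{pos}\t{isl.span[0]}-{isl.span[1]}\t"
                    f"{len({s.identity for s in isl.member_sites})}\t{ucg}\t{isl.ucg_n}\n"
                )
        report["stages"]["islands"] = {"n_islands": len(islands)}

    # --- integrate + classify -----------------------------------------------
    by_setup = {
        setup: [s for s in site_list if s.setup == setup] for setup in config.setups
    }
    matrix = classify.merge_setups(by_setup)
    labels = classify.assign_sets(matrix, config.rules)
    matrix_out = matrix.copy()
    matrix_out["set_label"] = labels.fillna("")
    matrix_out.to_csv(out / "matrix.tsv", sep="\t", float_format="%.10g")
    fractions = classify.summarize_fractions(
        matrix.drop(columns="residues"), config.rules
    )
    fractions.to_csv(out / "summary.tsv", sep="\t", float_format="%.10g")
    report["stages"]["integrate"] = {
        "n_matrix_sites": len(matrix),
        "n_set1": int((labels == classify.SET1).sum()),
        "n_set2": int((labels == classify.SET2).sum()),
        "fractions": {
            setup: {k: row[k] for k in ("induced_pct", "decreased_pct", "static_pct")}
            for setup, row in fractions.iterrows()
        },
    }

    # --- motifs -------------------------------------------------------------
    if config.run_motifs:
        rules = config.rules
        fg_mask = (matrix[rules.sr_setup] >= rules.up_log2) & (
            matrix[rules.sr_igo_setup] <= rules.down_log2
        )
        bg_mask = matrix[rules.sr_setup].notna() & matrix[rules.sr_igo_setup].notna()
        fg_ids = [
            (prot, int(p))
            for (prot, pos) in matrix.index[fg_mask]
            for p in pos.split(";")
        ]
        bg_ids = [
            (prot, int(p))
            for (prot, pos) in matrix.index[bg_mask]
            for p in pos.split(";")
        ]
        fg_windows = motifs.extract_windows(fg_ids, proteome)
        bg_windows = motifs.extract_windows(bg_ids, proteome)
        found = []
        for central in ("S", "T"):
            found.extend(
                motifs.motifx(
                    fg_windows,
                    bg_windows,
                    central=central,
                    min_seq=config.motif_min_seq,
                    p_cutoff=config.motif_p_cutoff,
                )
            )
        with open(out / "motifs.tsv", "w") as fh:
            fh.write("motif\tfg_matches\tbg_matches\tscore\tfold_enrichment\n")
            for mres in found:
                fh.write(
                    f"{mres.motif}\t{mres.fg_matches}\t{mres.bg_matches}\t"
                    f"{mres.score:.6g}\t{mres.fold_enrichment:.6g}\n"
                )
        t_or, t_p = motifs.threonine_enrichment(fg_windows, bg_windows)
        report["stages"]["motifs"] = {
            "n_foreground_windows": len(fg_windows),
            "n_background_windows": len(bg_windows),
            "motifs": [m.motif for m in found],
            "threonine_odds_ratio": t_or,
            "threonine_p": t_p,
        }

    # --- M-Track branch -----------------------------------------------------
    if config.run_mtrack:
        dens, true_effects = simulate.simulate_densitometry(
            n_baits=config.mtrack_n_baits,
            n_replicates=config.mtrack_n_replicates,
            curve_degree=config.mtrack_curve_degree,
            effect_map=config.mtrack_effects,
            seed=config.seed + 3,
            noise_sd=config.mtrack_noise_sd,
        )
        dens.to_csv(out / "densitometry.tsv", sep="\t", index=False,
                    float_format="%.10g")
        prox = mtrack.correct_and_score(dens)
        prox = mtrack.rescale_to_control(prox)
        results = mtrack.test_baits(prox)
        mtrack.results_to_frame(results).to_csv(
            out / "proximity.tsv", sep="\t", index=False, float_format="%.10g"
        )
        report["stages"]["mtrack"] = {
            "n_baits_tested": len(results),
            "significant_q05": sorted(
                r.bait for r in results if r.q_value < 0.05
            ),
            "true_effect_baits": sorted(
                b for b, e in true_effects.items() if e != 0
            ),
        }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def demo(outdir, seed: int = 0) -> dict:
    """Run the default synthetic world end to end; deterministic per seed."""
    return run_pipeline(PipelineConfig(seed=seed), outdir)
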