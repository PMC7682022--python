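"""End-to-end workflow: simulate -> emulate -> score -> summarize.

Each stage writes plain-text artifacts (VCF, TSV, JSON) into a workspace
directory and can be re-run from those files, so the command-line subcommands
compose. A fixed master seed makes the whole run bit-reproducible; per-stage
seeds are spawned from it in a fixed order and recorded in the manifests.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy as acc
from . import contribution as contrib
from . import io as pio
from . import simulate as sim
from . import variability as var
from .config import ProcessConfig, RunConfig
from .containers import Cohort, HaplotypePanel, ReplicateSet, merge_panels
from .emulator import EmulatorConfig, emulate_hmm, emulate_parametric
from .scoring import TierDefinition, make_percentile_frame

log = logging.getLogger("prsvar")


@dataclass
class SimulatedData:
    cohort: Cohort
    panel: HaplotypePanel
    reference_panel: HaplotypePanel
    model: pd.DataFrame
    typed_mask: np.ndarray


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def stage_simulate(config: RunConfig, workspace=None) -> SimulatedData:
    """Generate panel, cohort, score model, and typed mask; optionally persist."""
    seeds = _stage_seeds(config.master_seed, 8)
    ancestral = sim.draw_ancestral_frequencies(
        config.n_variants, config.maf_range, rng_seed=seeds[0]
    )
    variants = sim.default_variant_table(config.n_variants)
    panels = []
    for i, (pop, _) in enumerate(sorted(config.populations.items())):
        freqs = sim.derive_population_frequencies(
            ancestral, config.fst.get(pop, 0.0), rng_seed=seeds[1] + i, label=pop
        )
        panels.append(
            sim.simulate_haplotype_panel(
                freqs,
                config.panel_haplotypes_per_population,
                config.block_length,
                rng_seed=seeds[2] + i,
                block_ld=config.block_ld,
                variants=variants,
            )
        )
    panel = merge_panels(panels)
    cohort = sim.simulate_cohort(panel, dict(sorted(config.populations.items())), seeds[3])
    model = sim.generate_prs_model(
        variants=variants,
        weight_scale=config.weight_scale,
        n_high_weight=config.n_high_weight,
        high_weight_multiplier=config.high_weight_multiplier,
        rng_seed=seeds[4],
    )
    typed_mask = sim.assign_typed_mask(config.n_variants, config.fraction_typed, seeds[5])
    reference = (
        panel.subset_population(config.reference_population)
        if config.reference_population
        else panel
    )
    log.info(
        "simulated %d samples x %d variants (%d typed)",
        cohort.truth.n_samples,
        config.n_variants,
        int(typed_mask.sum()),
    )
    data = SimulatedData(cohort, panel, reference, model, typed_mask)
    if workspace is not None:
        _write_simulated(data, config, Path(workspace))
    return data


def _write_simulated(data: SimulatedData, config: RunConfig, ws: Path) -> None:
    ws.mkdir(parents=True, exist_ok=True)
    pio.write_dosage_vcf(data.cohort.truth, ws / "truth.vcf")
    pio.write_scoring_file(data.model, ws / "scoring.tsv")
    pio.write_ancestry(data.cohort.truth.samples, data.cohort.ancestry, ws / "ancestry.tsv")
    pio.write_panel(data.panel, ws / "panel.tsv")
    n, _, m = data.cohort.haplotypes.shape
    hap_panel = HaplotypePanel(
        data.cohort.haplotypes.reshape(2 * n, m),
        data.cohort.truth.variants,
        np.repeat(data.cohort.ancestry, 2),
    )
    pio.write_panel(hap_panel, ws / "cohort_haplotypes.tsv")
    (ws / "simulate_manifest.json").write_text(
        json.dumps(
            {
                "typed_mask": data.typed_mask.astype(int).tolist(),
                "reference_population": config.reference_population,
                "master_seed": config.master_seed,
            },
            indent=2,
        )
    )


def load_simulated(workspace) -> SimulatedData:
    ws = Path(workspace)
    truth = pio.read_dosage_vcf(ws / "truth.vcf")
    model = pio.read_scoring_file(ws / "scoring.tsv")
    ancestry = pio.read_ancestry(ws / "ancestry.tsv").loc[truth.samples].to_numpy()
    panel = pio.read_panel(ws / "panel.tsv", truth.variants)
    hap_panel = pio.read_panel(ws / "cohort_haplotypes.tsv", truth.variants)
    haplotypes = hap_panel.alleles.reshape(truth.n_samples, 2, truth.n_variants)
    manifest = json.loads((ws / "simulate_manifest.json").read_text())
    typed_mask = np.asarray(manifest["typed_mask"], dtype=bool)
    ref_pop = manifest.get("reference_population")
    reference = panel.subset_population(ref_pop) if ref_pop else panel
    cohort = Cohort(truth, ancestry, haplotypes)
    return SimulatedData(cohort, panel, reference, model, typed_mask)


def emulate_process(
    data: SimulatedData, process: ProcessConfig, k: int, master_seed: int
) -> ReplicateSet:
    if process.mode == "parametric":
        cfg = EmulatorConfig(
            mode="parametric",
            r2_target=process.r2_target,
            sigma_run=process.sigma_run,
            k=k,
        )
        reps = emulate_parametric(data.cohort.truth, data.typed_mask, cfg, master_seed)
    else:
        cfg = EmulatorConfig(mode="hmm", k=k, rho=process.rho, theta=process.theta)
        reps = emulate_hmm(
            data.cohort,
            data.typed_mask,
            data.reference_panel,
            cfg,
            mode=process.hmm_mode,
            master_seed=master_seed,
        )
    reps.process = process.name
    return reps


def stage_emulate(
    config: RunConfig, data: SimulatedData, workspace=None
) -> dict[str, ReplicateSet]:
    seeds = _stage_seeds(config.master_seed + 1, len(config.processes))
    out = {}
    for seed, process in zip(seeds, config.processes):
        reps = emulate_process(data, process, config.k, seed)
        out[process.name] = reps
        log.info("emulated process %s: K=%d replicates", process.name, reps.k)
        if workspace is not None:
            pio.write_replicate_set(reps, Path(workspace) / f"replicates_{process.name}")
    return out


def analyze_process(
    config: RunConfig, data: SimulatedData, reps: ReplicateSet, workspace=None
) -> dict:
    """Score, rank, and summarize one process's replicate set."""
    tiers = TierDefinition(config.tier_lower, config.tier_upper)
    frame = make_percentile_frame(
        data.cohort.truth, reps, data.model, data.cohort.ancestry, config.rank_against
    )
    results = {
        "frame": frame,
        "range_table": var.percentile_range_table(frame, config.range_thresholds),
        "deviation_bins": var.deviation_by_bin(frame, config.n_bins),
        "reclassification": var.reclassification_matrix(frame, tiers),
        "highrisk": var.highrisk_reclassification(frame, config.refined_tiers),
        "r2_mean": acc.per_individual_r2_summary(reps, data.cohort.truth, "mean"),
        "r2_min": acc.per_individual_r2_summary(reps, data.cohort.truth, "min"),
        "maf_binned": acc.maf_binned_accuracy(reps, data.cohort.truth),
        "gini_pve": contrib.contribution_quadrants(
            contrib.gini_pve_table(reps, data.model, data.cohort.truth)
        ),
    }
    if workspace is not None:
        outdir = Path(workspace) / f"analysis_{reps.process}"
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_frame().to_csv(outdir / "percentiles.tsv", sep="\t", index=False)
        results["range_table"].to_csv(outdir / "range_table.tsv", sep="\t")
        results["deviation_bins"].to_csv(outdir / "deviation_bins.tsv", sep="\t", index=False)
        results["reclassification"]["replicate_vs_mean"].to_csv(
            outdir / "tier_matrix_replicate_vs_mean.tsv", sep="\t"
        )
        results["reclassification"]["replicate_vs_wgs"].to_csv(
            outdir / "tier_matrix_replicate_vs_wgs.tsv", sep="\t"
        )
        results["highrisk"].to_csv(outdir / "highrisk_reclassification.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "sample": frame.samples,
                "r2_mean": results["r2_mean"],
                "r2_min": results["r2_min"],
            }
        ).to_csv(outdir / "per_individual_r2.tsv", sep="\t", index=False)
        results["maf_binned"].to_csv(outdir / "maf_binned_accuracy.tsv", sep="\t", index=False)
        results["gini_pve"].to_csv(outdir / "gini_pve.tsv", sep="\t", index=False)
        meta = dict(results["reclassification"]["metadata"])
        meta.update({"process": reps.process, "seeds": list(map(int, reps.seeds))})
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return results


def run_pipeline(config: RunConfig, workspace) -> dict:
    """Run every stage and write all reports plus a run manifest."""
    ws = Path(workspace)
    ws.mkdir(parents=True, exist_ok=True)
    if config.k < 2:
        raise ValueError("variability analysis requires K >= 2 replicates")
    data = stage_simulate(config, ws)
    replicate_sets = stage_emulate(config, data, ws)
    results = {
        name: analyze_process(config, data, reps, ws)
        for name, reps in replicate_sets.items()
    }
    ld = acc.best_tag_ld(data.cohort.truth, data.typed_mask)
    pd.DataFrame({"id": ld["ids"], "best_r2": ld["best_r2"]}).to_csv(
        ws / "best_tag_ld.tsv", sep="\t", index=False
    )
    manifest = {
        "config": config.to_dict(),
        "processes": list(replicate_sets),
        "ld_fractions": ld["fractions"],
        "conventions": {
            "percentile": "midrank within ancestry group",
            "tiers": f"low < {config.tier_lower}, high > {config.tier_upper}",
            "dosage": "ALT-allele expected count in [0, 2]",
        },
    }
    (ws / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
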