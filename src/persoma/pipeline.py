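"""End-to-end orchestration on synthetic data: simulate a genome pair and
tumor truth, derive per-caller callsets, build somatic SV consensus on both
assemblies, cross-map SNVs and SVs, and emit category reports."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .core_model import write_fasta, write_vcf
from .flank_mapper import SeedIndex
from .reporting import classification_report
from .snv_crossmap import crossmap_snvs
from .sv_toolkit import (DEFAULT_MERGE_CRITERIA, crossmap_svs,
                         merge_sv_callsets, select_somatic_sv_joint,
                         subtract_germline_svs)
from .synthetic_data import (CallerProfile, SimulationConfig,
                             simulate_caller_callset,
                             simulate_joint_genotyped_sv_vcf, simulate_truth)

logger = logging.getLogger(__name__)


def run_pipeline(config: dict, outdir: Path) -> dict:
    """Run the full synthetic comparison; returns the summary dict that is
    also written to ``outdir/summary.json``."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim = SimulationConfig(
        seed=seed,
        n_scaffolds=int(config.get("n_scaffolds", 2)),
        scaffold_length_bp=int(config.get("scaffold_length_bp", 300_000)),
        somatic_snv_count=int(config.get("somatic_snv_count", 50)))
    logger.info("simulation seed=%d scaffold_length=%d", seed,
                sim.scaffold_length_bp)
    reference, personal, truth = simulate_truth(sim)
    write_fasta(reference, outdir / "reference.fasta")
    write_fasta(personal, outdir / "personal.fasta")

    jitter = float(config.get("breakpoint_jitter_sd_bp", 30.0))
    callers = [CallerProfile(name, jitter_sd_bp=jitter)
               for name in config.get("callers", ["callerA", "callerB"])]

    # somatic SVs: joint genotyping + two-rule selection + germline subtraction
    all_truth = truth.germline_variants + truth.somatic_variants
    sv_results = {}
    for target, genome in (("reference", reference), ("personal", personal)):
        joint = simulate_joint_genotyped_sv_vcf(all_truth, target_assembly=target,
                                                seed=seed)
        selected = select_somatic_sv_joint(joint)
        germline_svs = [r for r in joint
                        if r.sample("normal") and r.sample("normal").genotype
                        in ("0/1", "1/1")]
        somatic = subtract_germline_svs(selected, germline_svs)
        write_vcf(joint, outdir / f"joint.{target}.vcf",
                  scaffold_lengths=genome.lengths())
        per_caller = {c.name: simulate_caller_callset(
            [v for v in truth.somatic_variants if v.kind == "sv"],
            target, c, seed=seed) for c in callers}
        consensus = merge_sv_callsets(per_caller)
        sv_results[target] = {
            "joint_selected_somatic": len(somatic),
            "consensus_svs": len(consensus),
            "consensus": consensus,
        }

    # somatic SNV crossmap reference -> personal
    source_snvs = [v for v in (simulate_caller_callset(
        [t for t in truth.somatic_variants if t.kind == "snv"],
        "reference", CallerProfile("consensus"), seed=seed))]
    target_snvs = [v for v in (simulate_caller_callset(
        [t for t in truth.somatic_variants if t.kind == "snv"],
        "personal", CallerProfile("consensus"), seed=seed))]
    target_index = SeedIndex(personal)
    results, snv_summary = crossmap_snvs(source_snvs, reference, personal,
                                         target_snvs,
                                         target_index=target_index)
    report = classification_report(snv_summary.category_counts)

    # personal-based consensus SVs lacking a reference-based counterpart
    personal_reps = [c.representative for c in sv_results["personal"]["consensus"]]
    reference_reps = [c.representative for c in sv_results["reference"]["consensus"]]
    back_mapped = crossmap_svs(personal_reps, personal, reference,
                               reference_reps,
                               merge_criteria=DEFAULT_MERGE_CRITERIA)
    personal_specific = sum(1 for r in back_mapped
                            if r.final_status != "matched")

    summary = {
        "seed": seed,
        "snv_crossmap": {
            "counts": snv_summary.category_counts,
            "percentages": {k: round(v, 2)
                            for k, v in report.raw_percentages.items()},
            "step1_selected": snv_summary.step1_selected,
        },
        "somatic_sv": {t: {k: v for k, v in r.items() if k != "consensus"}
                       for t, r in sv_results.items()},
        "personal_specific_consensus_svs": personal_specific,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
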