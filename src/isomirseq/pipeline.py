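"""End-to-end orchestration: simulate inputs, run all stages, write tables.

The pipeline runs preprocess -> align -> isomiR call -> quantify -> stats ->
seed/target -> enrichment, logging read-accounting tallies per stage so
conservation violations surface in normal runs. All outputs are plain TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import isomir, preprocess, quantify, simulate, stats, targets
from .config import PipelineConfig
from .reference import (ArmAnnotation, HairpinReference, load_arm_annotations,
                        load_hairpins, make_arm, write_arm_annotations,
                        write_hairpins)

log = logging.getLogger(__name__)

CONDITIONS = ("Young", "SEN", "SEN+M")


# ---------------------------------------------------------------- synthetic dataset

def default_synthetic_references(seed: int = 0
                                 ) -> tuple[dict[str, HairpinReference],
                                            dict[str, ArmAnnotation]]:
    """Two synthetic hairpins (one double-arm, one single-arm) with flanks.

    Sequences are drawn from the seed; arm placement mimics miRBase
    precursors: a 22-nt 5p arm near the 5' end, a 22-nt 3p arm near the 3'
    end, separated by a loop.
    """
    rng = np.random.default_rng([seed, 9001])

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    hairpins, arms = {}, {}
    specs = [("syn-mir-1", True), ("syn-mir-2", False)]
    offset = 1000
    for hid, both_arms in specs:
        body = list(rand_seq(72))
        # pin the bases flanking each arm's 3' end so planted uridine tails
        # are genuinely non-templated (continuation is never T)
        for arm_end0 in (27, 67):     # 0-based exclusive ends of 5p/3p arms
            body[arm_end0 - 1] = "G"  # arm's final base
            if arm_end0 < len(body):
                body[arm_end0] = "A"  # first continuation base
        body = "".join(body)
        flank = "A" + rand_seq(9)
        hp = HairpinReference(hid, body, "chrS", "+", offset,
                              offset + len(body) - 1, flank)
        offset += 500
        hairpins[hid] = hp
        base = hid.replace("mir", "miR")
        a5 = make_arm(f"{base}-5p", f"SYNMAT{len(arms):04d}", hp, 6, 27)
        arms[a5.accession] = a5
        if both_arms:
            a3 = make_arm(f"{base}-3p", f"SYNMAT{len(arms):04d}", hp, 46, 67)
            arms[a3.accession] = a3
    return hairpins, arms


def default_spectra(condition: str) -> dict[str, list[simulate.SpectrumEntry]]:
    """Per-condition isomiR spectra for the default synthetic study.

    Conditions differ in the canonical share and uridylation rate so the
    proportion z-tests and category statistics have real signal; the 5'
    isomiR of syn-miR-1-5p gives the seed-shift stage something to find.
    """
    E = simulate.SpectrumEntry
    base = {
        "Young":  {"canon": 0.70, "del1": 0.15, "uri": 0.05, "shift": 0.05,
                   "mixed": 0.05},
        "SEN":    {"canon": 0.55, "del1": 0.20, "uri": 0.12, "shift": 0.08,
                   "mixed": 0.05},
        "SEN+M":  {"canon": 0.62, "del1": 0.18, "uri": 0.08, "shift": 0.07,
                   "mixed": 0.05},
    }[condition]
    return {
        "syn-miR-1-5p": [
            E(0, 0, "", base["canon"]),
            E(0, -1, "", base["del1"]),
            E(0, 0, "T", base["uri"]),
            E(2, 0, "", base["shift"]),
            E(1, -2, "", base["mixed"]),
        ],
        "syn-miR-1-3p": [
            E(0, 0, "", 0.8),
            E(0, 1, "", 0.1),
            E(0, -1, "TT", 0.1),
        ],
        "syn-miR-2-5p": [
            E(0, 0, "", 0.9),
            E(-1, 0, "", 0.1),
        ],
    }


def simulate_dataset(config: PipelineConfig, out_dir: str | Path,
                     force: bool = False) -> dict:
    """Write the full synthetic dataset (references, 9 FASTQ, sample sheet,
    UTRs, GMT, truth tables) and a checksum manifest. Returns the manifest.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty (use force/--force)")
    out.mkdir(parents=True, exist_ok=True)

    hairpins, arms = default_synthetic_references(config.seed)
    write_hairpins(hairpins, out / "hairpins.fasta", pre_extended=True)
    write_arm_annotations(arms, out / "arms.gff3")

    sheet_rows = []
    truths = []
    for ci, cond in enumerate(CONDITIONS):
        spectra = default_spectra(cond)
        spec_cfg = simulate.IsomiRSpectrumConfig(
            spectra,
            reads_per_sample=config.reads_per_sample,
            sequencing_error_rate=config.sequencing_error_rate,
            adapter=config.adapter,
            rng_seed=config.seed * 10 + ci,
        )
        cond_tag = cond.replace("+", "")
        samples = [f"{cond_tag}_{r}" for r in (1, 2, 3)]
        _, truth = simulate.simulate_reads(spec_cfg, hairpins, arms,
                                           samples=samples, out_dir=out)
        truths.append(truth)
        for s in samples:
            sheet_rows.append({"sample": s, "condition": cond,
                               "fastq": f"{s}.fastq"})
    pd.concat(truths, ignore_index=True).to_csv(
        out / "truth_isomirs.tsv", sep="\t", index=False)
    pd.DataFrame(sheet_rows).to_csv(out / "samples.tsv", sep="\t", index=False)

    planted_seed = targets.arm_seed(
        next(a for a in arms.values() if a.name == "syn-miR-1-5p"),
        hairpins["syn-mir-1"])
    utrs, gene_sets, utr_truth = simulate.simulate_utrs_and_genesets(
        n_genes=60,
        seeds_to_plant={planted_seed: [f"G{i:04d}" for i in range(1, 11)]},
        sites_per_gene=1, rng_seed=config.seed, utr_len=200, n_sets=4)
    simulate.write_utr_fasta(utrs, out / "utrs.fasta")
    simulate.write_gmt(gene_sets, out / "genesets.gmt")
    utr_truth.to_csv(out / "truth_utr_sites.tsv", sep="\t", index=False)

    manifest = {"seed": config.seed,
                "reads_per_sample": config.reads_per_sample,
                "files": {}}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest["files"][path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------- per-sample stage

def process_sample(fastq_path: str | Path, config: PipelineConfig,
                   hairpins: Mapping[str, HairpinReference],
                   arms: Mapping[str, ArmAnnotation],
                   ) -> tuple[list[preprocess.ArmAlignment],
                              preprocess.FilterTally, preprocess.AlignTally]:
    """Trim, filter, collapse, align, and arm-assign one sample's reads."""
    trimmed = []
    for seq, qual in preprocess.parse_fastq(fastq_path):
        insert, found = preprocess.trim_adapter(seq, config.adapter,
                                                config.min_overlap)
        trimmed.append((insert, qual[:len(insert)]))
    collapsed, ftally = preprocess.collapse_and_filter(
        trimmed, config.min_len, config.max_len, config.min_mean_quality)
    max_mm = 0 if config.strict_denominator else config.max_mismatch
    aligned, atally = preprocess.align_sample(
        collapsed, hairpins, arms, max_mm,
        config.cap_5p, config.cap_3p, config.min_templated)
    return aligned, ftally, atally


# ---------------------------------------------------------------- full run

def run_pipeline(config: PipelineConfig, input_dir: str | Path | None = None
                 ) -> Path:
    """Execute every stage and write result tables under ``output_dir``."""
    base = Path(input_dir) if input_dir else Path(".")
    out = Path(config.output_dir)

    # upfront validation: fail before alignment starts
    for label, p in (("hairpin FASTA", config.hairpin_fasta),
                     ("arm GFF3", config.arm_gff3),
                     ("sample sheet", config.sample_sheet)):
        if not (base / p).exists():
            raise FileNotFoundError(f"{label} not found: {base / p}")
    if not config.skip_targets:
        for label, p in (("UTR FASTA", config.utr_fasta),
                         ("GMT", config.gmt)):
            if p and not (base / p).exists():
                raise FileNotFoundError(f"{label} not found: {base / p}")
    out.mkdir(parents=True, exist_ok=True)

    hairpins = load_hairpins(base / config.hairpin_fasta,
                             flank_len=config.flank_len)
    arms = load_arm_annotations(base / config.arm_gff3, hairpins)
    log.info("loaded %d hairpins, %d arms", len(hairpins), len(arms))

    sheet = pd.read_csv(base / config.sample_sheet, sep="\t")
    conditions = dict(zip(sheet["sample"], sheet["condition"]))
    samples = list(sheet["sample"])

    sample_alignments: dict[str, list] = {}
    tally_rows = []
    for _, row in sheet.iterrows():
        aligned, ft, at = process_sample(base / row["fastq"], config,
                                         hairpins, arms)
        sample_alignments[row["sample"]] = aligned
        assert ft.conserved() and at.conserved(), \
            f"read accounting broken for {row['sample']}"
        log.info("%s: %d in, %d kept, %d assigned", row["sample"],
                 ft.input, ft.kept, at.assigned)
        tally_rows.append({
            "sample": row["sample"], "input": ft.input,
            "untrimmed": ft.untrimmed, "too_short": ft.too_short,
            "too_long": ft.too_long, "low_quality": ft.low_quality,
            "kept": ft.kept, "unaligned": at.unaligned,
            "ambiguous": at.ambiguous, "unassigned": at.unassigned,
            "assigned": at.assigned,
        })
    pd.DataFrame(tally_rows).to_csv(out / "read_tallies.tsv", sep="\t",
                                    index=False)

    records = isomir.build_isomir_table(sample_alignments, hairpins, samples)
    isomir.isomir_frame(records, samples).to_csv(out / "isomirs.tsv", sep="\t")

    policy = "strict" if config.strict_denominator else "le1mm"
    cm = quantify.rpm_normalize(records, conditions, samples, policy)
    cm.rpm.to_csv(out / "isomir_rpm.tsv", sep="\t")
    arm_cm = quantify.arm_abundance(cm, records)
    arm_cm.rpm.to_csv(out / "arm_rpm.tsv", sep="\t")

    ptable = quantify.proportion_table(records, conditions, config.pool)
    present = set(conditions.values())
    if {"SEN", "SEN+M"} <= present:
        ptable = quantify.add_proportion_ztests(ptable)
    ptable.to_csv(out / "proportions.tsv", sep="\t", index=False)

    if {"SEN", "SEN+M"} <= present:
        de = stats.de_test(cm, "SEN", "SEN+M", config.fc_threshold,
                           config.fdr_threshold)
        de.to_csv(out / "de_isomirs.tsv", sep="\t")
        de_arm = stats.de_test(arm_cm, "SEN", "SEN+M", config.fc_threshold,
                               config.fdr_threshold)
        de_arm.to_csv(out / "de_arms.tsv", sep="\t")

        cats = list(isomir.CATEGORIES)
        pooled = {}
        for cond in ("SEN", "SEN+M"):
            cond_samples = cm.condition_samples(cond)
            pooled[cond] = [
                sum(r.counts.get(s, 0) for s in cond_samples
                    for r in records if r.category == cat)
                for cat in cats
            ]
        p_global = stats.global_category_test(pooled["SEN"], pooled["SEN+M"],
                                              config.global_test)
        (out / "global_category_test.json").write_text(json.dumps(
            {"test": config.global_test, "p": p_global,
             "categories": cats, "SEN": pooled["SEN"],
             "SEN+M": pooled["SEN+M"]}, indent=2) + "\n")

    if set(CONDITIONS) <= present:
        trend = stats.lrt_trend(arm_cm, CONDITIONS, config.fdr_threshold)
        trend.to_csv(out / "trend_arms.tsv", sep="\t")
        trend_iso = stats.lrt_trend(cm, CONDITIONS, config.fdr_threshold)
        trend_iso.to_csv(out / "trend_isomirs.tsv", sep="\t")

    qc = stats.qc_summary(cm.rpm)
    qc.pearson.to_csv(out / "qc_pearson.tsv", sep="\t")
    coords = qc.pca_coords.copy()
    coords.to_csv(out / "qc_pca.tsv", sep="\t")
    (out / "qc_variance_fractions.json").write_text(json.dumps(
        [float(v) for v in qc.variance_fractions]) + "\n")

    if not config.skip_targets and config.utr_fasta and config.gmt:
        _run_targets(config, base, out, hairpins, arms, records)
    return out


def _run_targets(config: PipelineConfig, base: Path, out: Path,
                 hairpins, arms, records) -> None:
    """Seed extraction, collision scan, target prediction, Venn, enrichment."""
    utrs = targets.load_utrs(base / config.utr_fasta)
    gene_sets = targets.load_gmt(base / config.gmt)
    arm_by_name = {a.name: a for a in arms.values()}

    canonical_index = {
        a.name: targets.arm_seed(a, hairpins[a.hairpin_id])
        for a in arms.values()
    }
    seed_rows = []
    target_sets: dict[str, set[str]] = {}
    isomir_seeds = []
    shifted_arms = sorted({r.name for r in records if r.start_offset != 0
                           and sum(r.counts.values()) > 0})
    for name in sorted(canonical_index):
        ts = targets.predict_targets(canonical_index[name], utrs,
                                     config.site_types, source=f"{name}|0|0")
        target_sets[f"{name}|0|0"] = ts.genes
        seed_rows.append({"source": f"{name}|0|0",
                          "seed": canonical_index[name],
                          "n_targets": len(ts.genes)})
    for name in shifted_arms:
        arm = arm_by_name[name]
        offsets = sorted({r.start_offset for r in records
                          if r.name == name and r.start_offset != 0})
        for s in offsets:
            seed = targets.arm_seed(arm, hairpins[arm.hairpin_id], s)
            source = f"{name}|{isomir.format_label(s, 0)}"
            isomir_seeds.append(targets.SeedInfo(source, seed))
            ts = targets.predict_targets(seed, utrs, config.site_types,
                                         source=source)
            target_sets[source] = ts.genes
            seed_rows.append({"source": source, "seed": seed,
                              "n_targets": len(ts.genes)})
    pd.DataFrame(seed_rows).to_csv(out / "seeds.tsv", sep="\t", index=False)

    collisions = targets.seed_collisions(isomir_seeds, canonical_index)
    pd.DataFrame(collisions, columns=["isomir", "canonical_arm"]).to_csv(
        out / "seed_collisions.tsv", sep="\t", index=False)

    for name in shifted_arms:
        keys = [k for k in target_sets if k.startswith(name + "|")]
        if 2 <= len(keys) <= 3:
            venn = targets.target_overlap({k: target_sets[k] for k in keys})
            venn.to_csv(out / f"venn_{name}.tsv", sep="\t", index=False)

    pooled = set().union(*target_sets.values()) if target_sets else set()
    if pooled:
        enr = targets.enrich(pooled, gene_sets)
        enr.to_csv(out / "enrichment.tsv", sep="\t")

    rows = []
    for source, genes in sorted(target_sets.items()):
        for g in sorted(genes):
            rows.append({"source": source, "gene": g})
    pd.DataFrame(rows, columns=["source", "gene"]).to_csv(
        out / "target_genes.tsv", sep="\t", index=False)
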