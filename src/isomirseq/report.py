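"""Assemble a plain-markdown summary of a completed results directory."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def missing_artifacts(results_dir: str | Path) -> list[str]:
    required = ["read_tallies.tsv", "isomirs.tsv", "isomir_rpm.tsv",
                "arm_rpm.tsv", "proportions.tsv"]
    d = Path(results_dir)
    return [f for f in required if not (d / f).exists()]


def build_report(results_dir: str | Path) -> str:
    """Render the summary markdown; deterministic for identical inputs."""
    d = Path(results_dir)
    missing = missing_artifacts(d)
    if missing:
        raise FileNotFoundError(
            "results directory incomplete; missing: " + ", ".join(missing))
    lines = ["# isomiR pipeline report", ""]

    tallies = pd.read_csv(d / "read_tallies.tsv", sep="\t")
    lines += ["## Read accounting", "", tallies.to_markdown(index=False), ""]

    iso = pd.read_csv(d / "isomirs.tsv", sep="\t", index_col=0)
    sample_cols = [c for c in iso.columns
                   if c not in ("accession", "name", "label", "nta",
                                "category", "uridylated")]
    cat_totals = iso.groupby("category")[sample_cols].sum().sum(axis=1)
    total = int(cat_totals.sum())
    lines += ["## IsomiR category distribution (all samples pooled)", ""]
    for cat, n in cat_totals.sort_values(ascending=False).items():
        pct = 100.0 * n / total if total else float("nan")
        lines.append(f"- {cat}: {int(n)} reads ({pct:.2f}%)")
    lines.append("")

    props = pd.read_csv(d / "proportions.tsv", sep="\t")
    lines += ["## Per-condition isomiR proportions", "",
              props.round(2).to_markdown(index=False), ""]

    gct = d / "global_category_test.json"
    if gct.exists():
        info = json.loads(gct.read_text())
        lines += [f"Global category homogeneity ({info['test']}): "
                  f"p = {info['p']:.4g}", ""]

    de_path = d / "de_isomirs.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t", index_col=0)
        called = de[de["called"] == True]  # noqa: E712
        lines += ["## Differential expression (SEN+M vs SEN)", "",
                  f"{len(called)} of {de['p'].notna().sum()} isomiRs called "
                  f"(FDR < 0.05, |FC| >= 1.5)", ""]
        if len(called):
            lines += [called.round(4).to_markdown(), ""]

    trend_path = d / "trend_arms.tsv"
    if trend_path.exists():
        trend = pd.read_csv(trend_path, sep="\t", index_col=0)
        lines += ["## Trend shapes (Young -> SEN -> SEN+M, arm level)", ""]
        for shape, grp in trend.groupby("shape"):
            lines.append(f"- {shape}: {', '.join(sorted(grp.index))}")
        lines.append("")
    else:
        lines += ["## Trend shapes", "", "_section skipped: no trend table_", ""]

    enr_path = d / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t", index_col=0)
        lines += ["## Gene-set enrichment (pooled targets)", "",
                  enr.round(4).to_markdown(), ""]
    else:
        lines += ["## Gene-set enrichment", "",
                  "_section skipped: no enrichment table_", ""]
    return "\n".join(lines) + "\n"
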