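"""RPM normalization, arm-level aggregation, and isomiR proportion tables.

The RPM denominator follows the arm-aligned rule: only reads that survived
trimming/filtering and were assigned to a miRNA arm enter the per-sample
denominator. With isomiR features covering all arms this equals the column
sum of the raw isomiR count matrix, so RPM columns sum to one million.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .isomir import CATEGORIES, IsomiRRecord

CONDITIONS = ("Young", "SEN", "SEN+M")


@dataclass
class CountMatrix:
    """Features x samples raw counts with an RPM view.

    ``conditions`` maps sample -> condition label; ``denominators`` are the
    per-sample arm-aligned read totals used for RPM.
    """

    raw: pd.DataFrame
    conditions: dict[str, str]
    denominators: pd.Series | None = None
    denominator_policy: str = "le1mm"
    _rpm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.denominators is None:
            self.denominators = self.raw.sum(axis=0).astype(float)
        self.denominators = self.denominators.reindex(self.raw.columns)
        zero = self.denominators[self.denominators <= 0]
        if len(zero):
            raise ValueError(
                "zero RPM denominator for sample(s): " + ", ".join(zero.index)
            )

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def rpm(self) -> pd.DataFrame:
        if self._rpm is None:
            self._rpm = self.raw.div(self.denominators, axis=1) * 1e6
        return self._rpm

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions.get(s) == condition]


def rpm_normalize(records: Sequence[IsomiRRecord],
                  conditions: Mapping[str, str],
                  samples: Sequence[str] | None = None,
                  denominator_policy: str = "le1mm") -> CountMatrix:
    """IsomiR-level count matrix with RPM filled.

    ``denominator_policy`` records whether arm assignment allowed one
    mismatch ("le1mm") or none ("strict"); the policy is applied upstream at
    alignment time and carried here as provenance.
    """
    if samples is None:
        samples = sorted({s for r in records for s in r.counts})
    data = {s: [r.counts.get(s, 0) for r in records] for s in samples}
    raw = pd.DataFrame(data, index=[r.feature_id for r in records], dtype=int)
    raw.index.name = "isomir"
    return CountMatrix(raw, dict(conditions),
                       denominator_policy=denominator_policy)


def arm_abundance(isomir_matrix: CountMatrix,
                  records: Sequence[IsomiRRecord]) -> CountMatrix:
    """Aggregate isomiR counts to arms (arm abundance = sum over isoforms)."""
    arm_of = {r.feature_id: r.name for r in records}
    groups = isomir_matrix.raw.groupby(
        isomir_matrix.raw.index.map(arm_of)).sum()
    groups.index.name = "arm"
    return CountMatrix(groups.sort_index(), isomir_matrix.conditions,
                       isomir_matrix.denominators.copy(),
                       isomir_matrix.denominator_policy)


@dataclass
class ProportionRow:
    name: str
    condition: str
    total: int
    counts: dict[str, int]          # per exclusive category
    uridylated: int

    def percentages(self, ndigits: int | None = None) -> dict[str, float]:
        out = {}
        for cat in CATEGORIES:
            v = 100.0 * self.counts.get(cat, 0) / self.total if self.total else float("nan")
            out[cat] = round(v, ndigits) if ndigits is not None else v
        return out

    def uridylation_pct(self, ndigits: int | None = None) -> float:
        v = 100.0 * self.uridylated / self.total if self.total else float("nan")
        return round(v, ndigits) if ndigits is not None else v


def proportion_table(records: Sequence[IsomiRRecord],
                     conditions: Mapping[str, str],
                     pool: str = "sum") -> pd.DataFrame:
    """Per-arm, per-condition category proportion table.

    Replicates within a condition are pooled by summing counts (default) or
    by averaging per-replicate proportions (``pool="mean"``). Exclusive
    category percentages sum to 100 per arm x condition; 3' uridylation is a
    cross-cutting percentage over the same denominator. Full precision is
    kept; round for reporting.
    """
    if pool not in ("sum", "mean"):
        raise ValueError("pool must be 'sum' or 'mean'")
    by_cond: dict[str, list[str]] = {}
    for s, c in conditions.items():
        by_cond.setdefault(c, []).append(s)
    order = [c for c in CONDITIONS if c in by_cond] + sorted(
        set(by_cond) - set(CONDITIONS))

    arms = sorted({r.name for r in records})
    rows = []
    for arm in arms:
        mine = [r for r in records if r.name == arm]
        for cond in order:
            samples = sorted(by_cond[cond])
            if pool == "sum":
                cat_counts = {cat: 0 for cat in CATEGORIES}
                uri = 0
                total = 0
                for r in mine:
                    c = sum(r.counts.get(s, 0) for s in samples)
                    cat_counts[r.category] += c
                    if r.uridylated:
                        uri += c
                    total += c
                pct = {cat: (100.0 * cat_counts[cat] / total if total else np.nan)
                       for cat in CATEGORIES}
                uri_pct = 100.0 * uri / total if total else np.nan
            else:
                per = []
                totals = []
                for s in samples:
                    t = sum(r.counts.get(s, 0) for r in mine)
                    totals.append(t)
                    if t:
                        per.append({
                            **{cat: 100.0 * sum(r.counts.get(s, 0) for r in mine
                                                if r.category == cat) / t
                               for cat in CATEGORIES},
                            "uri": 100.0 * sum(r.counts.get(s, 0) for r in mine
                                               if r.uridylated) / t,
                        })
                total = sum(totals)
                if per:
                    pct = {cat: float(np.mean([p[cat] for p in per]))
                           for cat in CATEGORIES}
                    uri_pct = float(np.mean([p["uri"] for p in per]))
                    cat_counts = {cat: sum(
                        sum(r.counts.get(s, 0) for s in samples)
                        for r in mine if r.category == cat) for cat in CATEGORIES}
                    uri = sum(sum(r.counts.get(s, 0) for s in samples)
                              for r in mine if r.uridylated)
                else:
                    pct = {cat: np.nan for cat in CATEGORIES}
                    uri_pct = np.nan
                    cat_counts = {cat: 0 for cat in CATEGORIES}
                    uri = 0
            row = {"name": arm, "condition": cond, "total": total}
            row.update({f"pct_{cat}": pct[cat] for cat in CATEGORIES})
            row["pct_uridylation"] = uri_pct
            row.update({f"n_{cat}": cat_counts[cat] for cat in CATEGORIES})
            row["n_uridylated"] = uri
            rows.append(row)
    return pd.DataFrame(rows)


def add_proportion_ztests(table: pd.DataFrame, cond_a: str = "SEN",
                          cond_b: str = "SEN+M") -> pd.DataFrame:
    """Append two-proportion z-test p-values per arm x category between two
    conditions; unadjusted, the convention for published proportion rows."""
    from .stats import ztest_proportions

    cols = [c for c in table.columns if c.startswith("pct_")]
    out_rows = []
    for name, grp in table.groupby("name", sort=True):
        a = grp[grp.condition == cond_a]
        b = grp[grp.condition == cond_b]
        row = {"name": name, "condition": f"p({cond_a} vs {cond_b})",
               "total": np.nan}
        if len(a) == 1 and len(b) == 1:
            na, nb = int(a.total.iloc[0]), int(b.total.iloc[0])
            for col in cols:
                ncol = "n_" + col[4:] if col != "pct_uridylation" else "n_uridylated"
                if na and nb:
                    row[col] = ztest_proportions(
                        int(a[ncol].iloc[0]), na, int(b[ncol].iloc[0]), nb)
                else:
                    row[col] = np.nan
        out_rows.append(row)
    pvals = pd.DataFrame(out_rows)
    return pd.concat([table, pvals], ignore_index=True).sort_values(
        ["name", "condition"], kind="stable", ignore_index=True)


def population_doublings(final_count: float, initial_count: float) -> float:
    """Population doublings over one passage: (log10 F - log10 I)/log10 2."""
    if final_count <= 0 or initial_count <= 0:
        raise ValueError("cell counts must be positive")
    return (math.log10(final_count) - math.log10(initial_count)) / math.log10(2)


def cumulative_population_doublings(passages: Iterable[tuple[float, float]]
                                    ) -> float:
    """Running sum of per-passage population doublings."""
    return sum(population_doublings(f, i) for f, i in passages)
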