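"""Synthetic small-RNA data with full ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_reads` — per-sample FASTQ of adapter-carrying isomiR reads
  following a configured per-arm offset/NTA spectrum, with optional
  substitution errors;
* :func:`simulate_counts` — negative-binomial count matrices for a 3
  conditions x 3 replicates design with planted linear or U-shaped /
  inverted-U effects;
* :func:`simulate_utrs_and_genesets` — 3'UTR sequences with planted seed
  match sites and GMT gene sets of known composition.

All randomness flows from explicit integer seeds; identical seeds produce
byte-identical artifacts. Count allocation of spectrum fractions is
deterministic by default (largest remainder), so recovered proportions can
be compared exactly; multinomial sampling is available for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isomir import classify, format_label, is_uridylated
from .quantify import CountMatrix
from .reference import ArmAnnotation, HairpinReference, normalize_seq

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"   # TruSeq small-RNA 3' adapter
CAP_5P, CAP_3P = 4, 6
PATTERNS = ("linear-up", "linear-down", "U", "inverted-U")


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------- reads

@dataclass(frozen=True)
class SpectrumEntry:
    start_offset: int
    end_offset: int
    nta: str
    fraction: float

    def __post_init__(self):
        object.__setattr__(self, "nta", normalize_seq(self.nta))
        if abs(self.start_offset) > CAP_5P or abs(self.end_offset) > CAP_3P:
            raise SimulationError(
                f"offsets ({self.start_offset},{self.end_offset}) exceed caps "
                f"({CAP_5P},{CAP_3P})")
        if not 0 <= self.fraction <= 1:
            raise SimulationError("fraction must be in [0, 1]")


@dataclass
class IsomiRSpectrumConfig:
    """Per-arm isomiR spectra plus sequencing parameters.

    ``spectra`` maps arm name -> list of entries whose fractions sum to 1.
    With ``protect_ends`` (default) substitution errors never hit the first
    or last base of the templated region, keeping truth labels unambiguous.
    """

    spectra: dict[str, list[SpectrumEntry]]
    reads_per_sample: int = 10000
    sequencing_error_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    allocation: str = "largest_remainder"   # or "multinomial"
    protect_ends: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.reads_per_sample < 1:
            raise SimulationError("reads_per_sample must be positive")
        if self.allocation not in ("largest_remainder", "multinomial"):
            raise SimulationError("allocation must be largest_remainder or "
                                  "multinomial")
        for arm, entries in self.spectra.items():
            tot = sum(e.fraction for e in entries)
            if abs(tot - 1.0) > 1e-9:
                raise SimulationError(
                    f"arm {arm!r}: fractions sum to {tot}, expected 1")


def isoform_sequence(arm: ArmAnnotation, hairpin: HairpinReference,
                     start_offset: int, end_offset: int) -> str:
    """Templated isoform sequence for the given terminal offsets.

    3' extensions may run into the genomic flank (still templated); a 5'
    start before the hairpin or a 3' end beyond the flank is a config error.
    """
    lo = arm.start0 + start_offset
    hi = arm.end0 + end_offset
    if lo < 0 or hi > len(hairpin.extended) or hi <= lo:
        raise SimulationError(
            f"isoform ({start_offset},{end_offset}) of arm {arm.name!r} "
            f"escapes hairpin+flank bounds")
    return hairpin.extended[lo:hi]


def largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Integer allocation of ``total`` by the largest-remainder method.

    Deterministic: ties on the fractional part are broken by entry order.
    """
    exact = [f * total for f in fractions]
    base = [int(x) for x in exact]
    short = total - sum(base)
    order = sorted(range(len(exact)),
                   key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def simulate_reads(
    config: IsomiRSpectrumConfig,
    hairpins: Mapping[str, HairpinReference],
    arms: Mapping[str, ArmAnnotation],
    samples: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate per-sample reads and the ground-truth isomiR table.

    Each read is the templated isoform sequence plus its NTA tail plus the
    3' adapter, at constant high quality. Returns
    ``({sample: [(sequence, quality), ...]}, truth)`` where ``truth`` has one
    row per (sample, arm, label, nta) with the planted read count; with
    ``out_dir`` the reads are also written as ``<sample>.fastq``.
    """
    from .isomir import resolve_tail
    from .preprocess import trim_adapter

    arm_by_name = {a.name: a for a in arms.values()}
    effective: dict[tuple[str, int], tuple[int, int, str]] = {}
    for arm_name, entries in config.spectra.items():
        if arm_name not in arm_by_name:
            raise SimulationError(f"unknown arm {arm_name!r} in spectrum")
        arm = arm_by_name[arm_name]
        hp = hairpins[arm.hairpin_id]
        for ei, e in enumerate(entries):  # validate before writing anything
            templated = isoform_sequence(arm, hp, e.start_offset, e.end_offset)
            insert = templated + e.nta
            trimmed, found = trim_adapter(insert + config.adapter,
                                          config.adapter)
            if not found or trimmed != insert:
                raise SimulationError(
                    f"insert for arm {arm_name!r} entry {ei} collides with "
                    f"the adapter prefix; choose a different adapter or arm")
            # a planted tail prefix matching the genomic continuation is a
            # templated extension: record the effective ground-truth label
            continuation = hp.extended[arm.end0 + e.end_offset:]
            extra, eff_nta = resolve_tail(e.nta, continuation)
            effective[(arm_name, ei)] = (e.start_offset,
                                         e.end_offset + extra, eff_nta)
    if samples is None:
        samples = ["sample_1"]

    reads_out: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for si, sample in enumerate(samples):
        rng = np.random.default_rng([config.rng_seed, si])
        sample_reads: list[tuple[str, str]] = []
        for arm_name in sorted(config.spectra):
            arm = arm_by_name[arm_name]
            hp = hairpins[arm.hairpin_id]
            entries = config.spectra[arm_name]
            fracs = [e.fraction for e in entries]
            if config.allocation == "largest_remainder":
                counts = largest_remainder(fracs, config.reads_per_sample)
            else:
                counts = rng.multinomial(config.reads_per_sample, fracs).tolist()
            per_label: dict[tuple[int, int, str], int] = {}
            for ei, (e, n) in enumerate(zip(entries, counts)):
                if n == 0:
                    continue
                templated = isoform_sequence(arm, hp, e.start_offset,
                                             e.end_offset)
                for _ in range(n):
                    t = templated
                    if config.sequencing_error_rate > 0:
                        t = _mutate(t, config.sequencing_error_rate,
                                    config.protect_ends, rng)
                    insert = t + e.nta
                    seq = insert + config.adapter
                    sample_reads.append((seq, "I" * len(seq)))
                key = effective[(arm_name, ei)]
                per_label[key] = per_label.get(key, 0) + n
            for (s_off, e_off, nta), n in sorted(per_label.items()):
                truth_rows.append({
                    "sample": sample,
                    "accession": arm.accession,
                    "name": arm_name,
                    "label": format_label(s_off, e_off),
                    "start_offset": s_off,
                    "end_offset": e_off,
                    "nta": nta,
                    "category": classify(s_off, e_off, nta),
                    "uridylated": is_uridylated(nta),
                    "count": n,
                })
        reads_out[sample] = sample_reads
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample in samples:
            write_fastq(reads_out[sample], out_dir / f"{sample}.fastq",
                        prefix=sample)
    return reads_out, truth


_BASES = "ACGT"


def _mutate(seq: str, rate: float, protect_ends: bool,
            rng: np.random.Generator) -> str:
    """Per-base substitution, capped at one substitution per read.

    With ``protect_ends`` the first and last templated base are exempt, so a
    substitution can never masquerade as a terminal offset or NTA change.
    """
    chars = list(seq)
    lo = 1 if protect_ends else 0
    hi = len(chars) - 1 if protect_ends else len(chars)
    for i in range(lo, hi):
        if rng.random() < rate:
            choices = [b for b in _BASES if b != chars[i]]
            chars[i] = choices[rng.integers(3)]
            break
    return "".join(chars)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path,
                prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads, 1):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------- counts

@dataclass(frozen=True)
class PlantedEffect:
    feature: str
    pattern: str
    fold_changes: tuple[float, float]

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise SimulationError(f"unknown pattern {self.pattern!r}")
        f1, f2 = self.fold_changes
        if f1 <= 0 or f2 <= 0:
            raise SimulationError("fold-changes must be strictly positive")
        ok = {
            "linear-up": f1 >= 1 and f2 >= 1,
            "linear-down": f1 <= 1 and f2 <= 1,
            "U": f1 < 1 < f2,
            "inverted-U": f2 < 1 < f1,
        }[self.pattern]
        if not ok:
            raise SimulationError(
                f"fold-changes {self.fold_changes} inconsistent with "
                f"pattern {self.pattern!r}")


@dataclass
class CountSimConfig:
    """NB count simulation: 3 conditions x n replicates with planted trends.

    Baseline means are log-normal (``baseline_log_mean``/``sd`` on the
    natural-log scale); ``dispersion`` is the NB2 alpha (variance =
    mu + alpha mu^2), scalar or per-feature. Effects multiply the condition
    means transition-by-transition: means = (m, m*f1, m*f1*f2).
    """

    n_features: int = 2000
    conditions: tuple[str, ...] = ("Young", "SEN", "SEN+M")
    n_replicates: int = 3
    baseline_log_mean: float = np.log(200.0)
    baseline_log_sd: float = 1.0
    dispersion: float | Sequence[float] = 0.05
    effects: list[PlantedEffect] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise SimulationError("need >= 2 replicates per condition")
        if self.n_features < 1:
            raise SimulationError("n_features must be positive")


def simulate_counts(config: CountSimConfig
                    ) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the count matrix and return it with the per-feature truth table.

    Truth columns: feature, pattern ('none' for nulls), fold-change per
    transition, and the per-condition true means.
    """
    rng = np.random.default_rng(config.rng_seed)
    features = [f"feat_{i:05d}" for i in range(config.n_features)]
    feat_idx = {f: i for i, f in enumerate(features)}
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                         config.n_features)
    disp = np.broadcast_to(np.asarray(config.dispersion, dtype=float),
                           (config.n_features,)).copy()

    n_cond = len(config.conditions)
    mult = np.ones((config.n_features, n_cond))
    truth_pattern = ["none"] * config.n_features
    truth_fc = [(1.0, 1.0)] * config.n_features
    for eff in config.effects:
        if eff.feature not in feat_idx:
            raise SimulationError(f"unknown feature {eff.feature!r} in effects")
        i = feat_idx[eff.feature]
        f1, f2 = eff.fold_changes
        mult[i] = [1.0, f1, f1 * f2][:n_cond]
        truth_pattern[i] = eff.pattern
        truth_fc[i] = eff.fold_changes

    means = base[:, None] * mult
    cols, data, conditions = [], [], {}
    for ci, cond in enumerate(config.conditions):
        for rep in range(1, config.n_replicates + 1):
            name = f"{cond}_{rep}"
            cols.append(name)
            conditions[name] = cond
            mu = means[:, ci]
            pos = disp > 1e-12
            draw = np.empty(config.n_features, dtype=np.int64)
            if pos.any():
                r = 1.0 / disp[pos]
                p = r / (r + mu[pos])
                draw[pos] = rng.negative_binomial(r, p)
            if (~pos).any():
                draw[~pos] = rng.poisson(mu[~pos])
            data.append(draw)
    raw = pd.DataFrame(np.column_stack(data), index=features, columns=cols)
    raw.index.name = "feature"
    truth = pd.DataFrame({
        "feature": features,
        "pattern": truth_pattern,
        "fc1": [fc[0] for fc in truth_fc],
        "fc2": [fc[1] for fc in truth_fc],
        **{f"mean_{c}": means[:, i] for i, c in enumerate(config.conditions)},
    }).set_index("feature")
    return CountMatrix(raw, conditions), truth


# ---------------------------------------------------------------- UTRs & gene sets

def simulate_utrs_and_genesets(
    n_genes: int,
    seeds_to_plant: Mapping[str, Sequence[str]],
    sites_per_gene: int = 1,
    rng_seed: int = 0,
    utr_len: int = 300,
    n_sets: int = 5,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    max_retries: int = 200,
) -> tuple[dict[str, str], dict[str, set[str]], pd.DataFrame]:
    """UTRs with planted 8mer seed-match sites plus GMT-style gene sets.

    ``seeds_to_plant`` maps a 7-mer seed to the gene IDs that must carry
    ``sites_per_gene`` sites for it; every other UTR is rejection-sampled to
    contain no site (of any class) for any planted seed. Genes are named
    ``G0001``.. and, unless ``gene_sets`` is given, partitioned into
    ``n_sets`` contiguous blocks ``set_1``..  Returns
    ``(utrs, gene_sets, truth)`` with truth rows (gene, seed, n_sites).
    """
    from .targets import scan_utr, site_motifs

    for seed in seeds_to_plant:
        if len(normalize_seq(seed)) != 7:
            raise SimulationError(f"planted seed {seed!r} must be a 7-mer")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    assigned: dict[str, str] = {}
    for seed, gene_list in seeds_to_plant.items():
        for g in gene_list:
            if g not in set(genes):
                raise SimulationError(f"gene {g!r} outside universe")
            if g in assigned:
                raise SimulationError(f"gene {g!r} planted for two seeds")
            assigned[g] = seed

    rng = np.random.default_rng(rng_seed)
    all_seeds = list(seeds_to_plant)

    def clean_backbone(length: int) -> str:
        for _ in range(max_retries):
            s = "".join(rng.choice(list("ACGT"), size=length))
            if all(sum(scan_utr(s, sd).values()) == 0 for sd in all_seeds):
                return s
        raise SimulationError(
            "could not rejection-sample a site-free UTR backbone; "
            "alphabet too constrained")

    utrs: dict[str, str] = {}
    truth_rows = []
    for g in genes:
        backbone = clean_backbone(utr_len)
        seed = assigned.get(g)
        if seed is None:
            utrs[g] = backbone
            continue
        site = site_motifs(seed)["8mer"]
        for _ in range(max_retries):
            pieces = list(backbone)
            positions = sorted(
                rng.choice(utr_len - len(site), size=sites_per_gene,
                           replace=False))
            utr = backbone
            for pos in positions:
                utr = utr[:pos] + site + utr[pos + len(site):]
            own = sum(scan_utr(utr, seed).values())
            others_clean = all(
                sum(scan_utr(utr, sd).values()) == 0
                for sd in all_seeds if sd != seed)
            if own >= sites_per_gene and others_clean:
                break
            backbone = clean_backbone(utr_len)
        else:
            raise SimulationError(f"could not plant sites in gene {g!r}")
        utrs[g] = utr
        truth_rows.append({"gene": g, "seed": seed, "n_sites": sites_per_gene})

    if gene_sets is None:
        out_sets: dict[str, set[str]] = {}
        block = max(1, n_genes // n_sets)
        for i in range(n_sets):
            members = genes[i * block:(i + 1) * block] if i < n_sets - 1 \
                else genes[(n_sets - 1) * block:]
            out_sets[f"set_{i + 1}"] = set(members)
    else:
        out_sets = {k: set(v) for k, v in gene_sets.items()}
    truth = pd.DataFrame(truth_rows, columns=["gene", "seed", "n_sites"])
    return utrs, out_sets, truth


def write_utr_fasta(utrs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(utrs):
            fh.write(f">{gene}\n{utrs[gene]}\n")


def write_gmt(gene_sets: Mapping[str, set[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
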