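"""Seed sequences, seed-match target prediction, and gene-set enrichment.

A miRNA's *seed* is mature positions 2-8 (7 nt); 5'-shifted isomiRs move
this window along the templated precursor sequence and can therefore adopt
an entirely different target repertoire — including, occasionally, the seed
of another annotated miRNA (a *seed collision*).

Target sites on a 3'UTR follow the TargetScan site classes:

* 7mer-m8 — Watson-Crick match to seed positions 2-8;
* 7mer-A1 — match to positions 2-7 followed by an adenine opposite
  position 1 (the A is required on the UTR regardless of the miRNA base);
* 8mer — both: the position 2-8 match followed by the A.

Site search is on the given UTR strand only, in DNA space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from scipy import stats as sps

from .reference import ArmAnnotation, HairpinReference, normalize_seq, revcomp
from .stats import bh_adjust

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
SEED_LEN = 7


class SeedError(ValueError):
    pass


def seed_of(mature_sequence: str, start_offset: int = 0,
            upstream: str = "") -> str:
    """Seed (positions 2-8) of a 5'-shifted mature sequence.

    ``start_offset`` moves the 5' terminus along the precursor: +1 drops the
    archetype's first base, -1 prepends one templated base, supplied via
    ``upstream`` (hairpin sequence immediately 5' of the archetype).
    """
    seq = normalize_seq(mature_sequence)
    up = normalize_seq(upstream)
    if start_offset >= 0:
        shifted = seq[start_offset:]
    else:
        need = -start_offset
        if len(up) < need:
            raise SeedError(
                f"offset {start_offset} needs {need} upstream base(s), "
                f"got {len(up)}")
        shifted = up[len(up) - need:] + seq
    if len(shifted) < SEED_LEN + 1:
        raise SeedError("shifted sequence too short to contain a seed")
    return shifted[1:1 + SEED_LEN]


def arm_seed(arm: ArmAnnotation, hairpin: HairpinReference,
             start_offset: int = 0) -> str:
    """Seed of an arm's isoform at the given 5' offset, templated bases for
    negative offsets taken from the hairpin."""
    upstream = hairpin.sequence[:arm.start0]
    return seed_of(arm.archetype_seq, start_offset, upstream)


@dataclass(frozen=True)
class SeedInfo:
    source: str                     # e.g. "miR-217-5p|+2|0"
    seed: str
    site_types: tuple[str, ...] = SITE_TYPES

    def __post_init__(self):
        if len(self.seed) != SEED_LEN:
            raise SeedError("seed must be exactly 7 nt")


def seed_collisions(isomir_seeds: Iterable[SeedInfo],
                    canonical_index: Mapping[str, str]) -> list[tuple[str, str]]:
    """Exact 7-mer collisions between isomiR seeds and canonical arm seeds.

    ``canonical_index`` maps arm name -> canonical seed. Self-pairs (an
    isomiR matching its own parent arm's seed) are excluded; the parent is
    taken as the part of ``source`` before the first ``|``.
    """
    by_seed: dict[str, list[str]] = {}
    for arm_name, seed in canonical_index.items():
        by_seed.setdefault(normalize_seq(seed), []).append(arm_name)
    out = []
    for info in isomir_seeds:
        parent = info.source.split("|", 1)[0]
        for arm_name in sorted(by_seed.get(normalize_seq(info.seed), [])):
            if arm_name != parent:
                out.append((info.source, arm_name))
    return sorted(out)


# ---------------------------------------------------------------- target scan

def site_motifs(seed: str) -> dict[str, str]:
    """UTR-side match motifs for the three canonical site classes."""
    seed = normalize_seq(seed)
    if len(seed) != SEED_LEN:
        raise SeedError("seed must be exactly 7 nt")
    m8 = revcomp(seed)               # complement of positions 2-8
    a1 = revcomp(seed[:6]) + "A"     # complement of positions 2-7, then A
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": a1}


def scan_utr(utr: str, seed: str,
             enabled: Sequence[str] = SITE_TYPES) -> dict[str, int]:
    """Count qualifying sites per enabled site type in one UTR.

    An 8mer occurrence also satisfies 7mer-m8 and 7mer-A1 by construction;
    counts are per-type occurrences, not mutually exclusive.
    """
    utr = normalize_seq(utr)
    motifs = site_motifs(seed)
    counts = {}
    for t in enabled:
        if t not in motifs:
            raise SeedError(f"unknown site type {t!r}")
        motif = motifs[t]
        n = 0
        start = utr.find(motif)
        while start != -1:
            n += 1
            start = utr.find(motif, start + 1)
        counts[t] = n
    return counts


@dataclass
class TargetSet:
    source: str
    genes: set[str] = field(default_factory=set)
    site_counts: dict[str, int] = field(default_factory=dict)


def predict_targets(seed: str, utrs: Mapping[str, str],
                    enabled: Sequence[str] = SITE_TYPES,
                    source: str = "") -> TargetSet:
    """Genes whose 3'UTR carries >= 1 qualifying site for the seed."""
    ts = TargetSet(source or seed)
    for gene, utr in utrs.items():
        counts = scan_utr(utr, seed, enabled)
        total = sum(counts.values())
        if total > 0:
            ts.genes.add(gene)
            ts.site_counts[gene] = total
    return ts


def load_utrs(fasta_path: str | Path) -> dict[str, str]:
    """3'UTR FASTA -> {gene: sequence} (DNA-normalized)."""
    out = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out[rec.id] = normalize_seq(str(rec.seq))
    return out


# ---------------------------------------------------------------- set algebra

def target_overlap(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exact region counts of the 2- or 3-set Venn partition.

    Rows are membership patterns (one column per input set, boolean) with
    the count of genes in exactly that region; counts sum to the union size.
    For more than 3 sets a pairwise intersection matrix is returned instead.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two target sets")
    if len(names) > 3:
        return pd.DataFrame(
            [[len(sets[a] & sets[b]) for b in names] for a in names],
            index=names, columns=names)
    union = set().union(*sets.values())
    rows = []
    n = len(names)
    for mask in range(1, 2**n):
        pattern = [(mask >> i) & 1 == 1 for i in range(n)]
        region = union.copy()
        for i, inside in enumerate(pattern):
            region = region & sets[names[i]] if inside else region - sets[names[i]]
        rows.append({**{names[i]: pattern[i] for i in range(n)},
                     "count": len(region)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- enrichment

def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich(targets: set[str], gene_sets: Mapping[str, set[str]],
           universe: set[str] | None = None) -> pd.DataFrame:
    """One-sided Fisher exact gene-set enrichment with BH correction.

    The universe defaults to the union of all gene-set members; targets are
    intersected with it. Returned columns: set size, hits, ratio
    (hits / set size), p, fdr, sorted by p then name.
    """
    if not gene_sets:
        raise ValueError("no gene sets given")
    if universe is None:
        universe = set().union(*gene_sets.values())
    if not universe:
        raise ValueError("empty universe")
    targ = targets & universe
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        if not members:
            raise ValueError(f"gene set {name!r} empty within universe")
        k = len(members & targ)
        table = [[k, len(members) - k],
                 [len(targ) - k, len(universe) - len(members) - (len(targ) - k)]]
        _, p = sps.fisher_exact(table, alternative="greater")
        rows.append({"set": name, "size": len(members), "hits": k,
                     "ratio": k / len(members), "p": float(p)})
    df = pd.DataFrame(rows).set_index("set")
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"], kind="stable")
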