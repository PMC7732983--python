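"""Adapter trimming, read collapsing/filtering, and ungapped hairpin alignment.

The aligner is deliberately restrictive, matching how isomiR studies map
small-RNA reads: contiguous, ungapped, at most one internal substitution,
and unambiguous (reads whose best hit is tied across different hairpins are
discarded). A read's 3' bases that cannot be explained by the hairpin or its
genomic flank become the *tail* — the candidate non-templated addition.

A 3'-terminal mismatch is never spent as the one allowed substitution: it is
indistinguishable from a non-templated addition, so it is shunted into the
tail and resolved downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from .reference import ArmAnnotation, HairpinReference, arms_by_hairpin, normalize_seq

DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 28
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_MISMATCH = 1
DEFAULT_CAP_5P = 4
DEFAULT_CAP_3P = 6
DEFAULT_MIN_TEMPLATED = 15


@dataclass(frozen=True)
class TrimmedRead:
    sequence: str
    count: int = 1
    passed_filter: bool = True
    adapter_found: bool = True

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("read count must be >= 1")


@dataclass(frozen=True)
class ArmAlignment:
    """A read placed on a hairpin, optionally assigned to a mature arm."""

    read: TrimmedRead
    hairpin_id: str
    start_pos: int          # 1-based position within hairpin of templated 5' end
    templated_len: int
    mismatches: int
    tail: str               # 3' bases not explained by hairpin+flank
    arm: ArmAnnotation | None = None
    ambiguous: bool = False

    def __post_init__(self):
        if self.mismatches > 1:
            raise ValueError("at most one mismatch is representable")
        if self.templated_len + len(self.tail) != len(self.read.sequence):
            raise ValueError("templated_len + tail must cover the read")

    @property
    def start0(self) -> int:
        return self.start_pos - 1

    @property
    def templated_end0(self) -> int:
        """0-based exclusive end of the templated region within hairpin+flank."""
        return self.start0 + self.templated_len


def trim_adapter(read_seq: str, adapter: str,
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> tuple[str, bool]:
    """Remove a 3' adapter; returns (insert, adapter_found).

    The earliest position where the read suffix matches a prefix of the
    adapter is trimmed: either an exact match of length >= ``min_overlap``,
    or a full-length adapter occurrence with <= 10% mismatches.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read_seq = normalize_seq(read_seq)
    adapter = normalize_seq(adapter)
    n, m = len(read_seq), len(adapter)
    allowed_full = m // 10
    for i in range(0, n):
        ov = min(n - i, m)
        if ov < min_overlap:
            break
        window = read_seq[i:i + ov]
        prefix = adapter[:ov]
        if window == prefix:
            return read_seq[:i], True
        if ov == m:
            mm = sum(a != b for a, b in zip(window, prefix))
            if mm <= allowed_full:
                return read_seq[:i], True
    return read_seq, False


@dataclass
class FilterTally:
    """Read accounting through trimming and filtering."""
    input: int = 0
    untrimmed: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    kept: int = 0

    def conserved(self) -> bool:
        return self.input == (self.kept + self.too_short + self.too_long
                              + self.low_quality)


def collapse_and_filter(
    reads: Iterable[tuple[str, str | None]] | Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mean_quality: float = 20.0,
) -> tuple[list[TrimmedRead], FilterTally]:
    """Collapse identical trimmed sequences and apply length/quality filters.

    ``reads`` yields either bare sequences or ``(sequence, quality_string)``
    pairs (phred+33). Returns collapsed reads sorted by (-count, sequence)
    and the accounting tally.
    """
    counts: dict[str, int] = {}
    tally = FilterTally()
    for item in reads:
        seq, qual = item if isinstance(item, tuple) else (item, None)
        tally.input += 1
        if len(seq) < min_len:
            tally.too_short += 1
            continue
        if len(seq) > max_len:
            tally.too_long += 1
            continue
        if qual is not None and qual:
            mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
            if mean_q < min_mean_quality:
                tally.low_quality += 1
                continue
        tally.kept += 1
        seq = normalize_seq(seq)
        counts[seq] = counts.get(seq, 0) + 1
    collapsed = [TrimmedRead(seq, c) for seq, c in counts.items()]
    collapsed.sort(key=lambda r: (-r.count, r.sequence))
    return collapsed, tally


def parse_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (sequence, quality-string) pairs from FASTQ."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield str(rec.seq), qual


def _best_split(read: str, ref: str, pos: int, max_mismatch: int,
                min_templated: int) -> tuple[int, int] | None:
    """Best (templated_len, mismatches) for a read anchored at ``pos`` in ref.

    Valid splits have <= ``max_mismatch`` substitutions inside the templated
    region and a final templated base matching the reference (3'-terminal
    mismatches belong to the tail). Among valid splits the one with fewest
    mismatches wins, then the longest templated region (shortest tail): an
    exact placement with a genuine NTA tail must not lose to a longer
    placement that spends the mismatch budget absorbing tail bases.
    """
    limit = min(len(read), len(ref) - pos)
    if limit < min_templated:
        return None
    mm = 0
    mism_prefix = []
    for k in range(limit):
        if read[k] != ref[pos + k]:
            mm += 1
        mism_prefix.append(mm)
    best: tuple[int, int] | None = None
    for L in range(limit, min_templated - 1, -1):
        m = mism_prefix[L - 1]
        if read[L - 1] == ref[pos + L - 1] and m <= max_mismatch:
            if best is None or m < best[1]:
                best = (L, m)
            if m == 0:
                break
    return best


def align_ungapped(
    read: TrimmedRead,
    hairpins: Mapping[str, HairpinReference],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_templated: int = DEFAULT_MIN_TEMPLATED,
) -> list[ArmAlignment]:
    """All candidate ungapped placements of a read on the hairpin set.

    Candidates are ranked by (mismatches, tail length, hairpin id, position);
    the returned list is sorted by that rank. Use :func:`resolve_candidates`
    to apply the unambiguity rule.
    """
    seq = read.sequence
    out: list[ArmAlignment] = []
    for hid in sorted(hairpins):
        hp = hairpins[hid]
        ref = hp.extended
        for pos in range(len(hp.sequence)):
            split = _best_split(seq, ref, pos, max_mismatch, min_templated)
            if split is None:
                continue
            L, mm = split
            out.append(ArmAlignment(read, hid, pos + 1, L, mm, seq[L:]))
    out.sort(key=lambda a: (a.mismatches, len(a.tail), a.hairpin_id, a.start_pos))
    return out


def resolve_candidates(candidates: Sequence[ArmAlignment],
                       arms_index: Mapping[str, list[ArmAnnotation]] | None = None,
                       ) -> ArmAlignment | None:
    """Pick the unique best placement, or mark ambiguity.

    Reads whose best (mismatches, tail length) rank is achieved on more than
    one hairpin are ambiguous and return an alignment flagged as such; ties
    within one hairpin keep the placement nearest an annotated arm start
    (then smallest position).
    """
    if not candidates:
        return None
    best_rank = (candidates[0].mismatches, len(candidates[0].tail))
    top = [c for c in candidates
           if (c.mismatches, len(c.tail)) == best_rank]
    hairpin_ids = {c.hairpin_id for c in top}
    if len(hairpin_ids) > 1:
        return replace(top[0], ambiguous=True)
    if len(top) == 1 or arms_index is None:
        return top[0]
    arm_starts = [a.arm_start for a in arms_index.get(top[0].hairpin_id, [])]
    if not arm_starts:
        return top[0]
    return min(top, key=lambda c: (min(abs(c.start_pos - s) for s in arm_starts),
                                   c.start_pos))


def assign_to_arm(alignment: ArmAlignment,
                  arms: Sequence[ArmAnnotation],
                  cap_5p: int = DEFAULT_CAP_5P,
                  cap_3p: int = DEFAULT_CAP_3P) -> ArmAlignment | None:
    """Assign an alignment to the nearest arm of its hairpin.

    The arm whose archetype 5' end is nearest the read's templated 5' start
    wins; the assignment stands only if both terminal offsets are within the
    caps (|5'| <= ``cap_5p``, |3'| <= ``cap_3p``), else ``None``.
    """
    mine = [a for a in arms if a.hairpin_id == alignment.hairpin_id]
    if not mine:
        return None
    arm = min(mine, key=lambda a: (abs(alignment.start_pos - a.arm_start),
                                   a.arm_start))
    start_offset = alignment.start_pos - arm.arm_start
    end_offset = (alignment.start_pos + alignment.templated_len - 1) - arm.arm_end
    if abs(start_offset) > cap_5p or abs(end_offset) > cap_3p:
        return None
    return replace(alignment, arm=arm)


@dataclass
class AlignTally:
    """Per-sample accounting over the alignment and assignment stages."""
    input: int = 0
    unaligned: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    assigned: int = 0

    def conserved(self) -> bool:
        return self.input == (self.unaligned + self.ambiguous
                              + self.unassigned + self.assigned)


def align_sample(
    collapsed: Sequence[TrimmedRead],
    hairpins: Mapping[str, HairpinReference],
    arms: Mapping[str, ArmAnnotation],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    cap_5p: int = DEFAULT_CAP_5P,
    cap_3p: int = DEFAULT_CAP_3P,
    min_templated: int = DEFAULT_MIN_TEMPLATED,
) -> tuple[list[ArmAlignment], AlignTally]:
    """Align and arm-assign one sample's collapsed reads."""
    arms_index = arms_by_hairpin(arms)
    assigned: list[ArmAlignment] = []
    tally = AlignTally()
    for read in collapsed:
        tally.input += read.count
        cands = align_ungapped(read, hairpins, max_mismatch, min_templated)
        best = resolve_candidates(cands, arms_index)
        if best is None:
            tally.unaligned += read.count
            continue
        if best.ambiguous:
            tally.ambiguous += read.count
            continue
        placed = assign_to_arm(best, arms_index.get(best.hairpin_id, []),
                               cap_5p, cap_3p)
        if placed is None:
            tally.unassigned += read.count
            continue
        tally.assigned += read.count
        assigned.append(placed)
    return assigned, tally
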