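"""IsomiR nomenclature, classification, and table construction.

An isomiR is identified by its parent arm plus a signed-offset label ``s|e``:
``s`` is the shift of the 5' terminus relative to the archetype's (positive =
rightward, i.e. toward the 3' end of the hairpin), ``e`` the shift of the
*templated* 3' terminus. The archetype is ``0|0``. Non-templated 3' additions
(NTA) are kept as a separate tail string; a tail made entirely of uridines is
flagged as uridylation.

Six exclusive categories partition all records: canonical, 5' deletion,
5' addition, 3' deletion, 3' addition, and mixed (any combination of a 5'
and a 3' modification, or an NTA on top of a templated 3' change). A pure
NTA on canonical ends (0,0,tail) counts as a 3' addition by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import ArmAlignment
from .reference import ArmAnnotation, HairpinReference, normalize_seq

CATEGORIES = (
    "canonical",
    "3p_addition",
    "3p_deletion",
    "5p_deletion",
    "5p_addition",
    "mixed",
)

_LABEL_RE = re.compile(r"^(0|[+-]\d+)\|(0|[+-]\d+)$")


def format_label(start_offset: int, end_offset: int) -> str:
    """Signed-offset label, e.g. ``+1|-2``; zero is unsigned (``0|0``)."""
    def fmt(v: int) -> str:
        return "0" if v == 0 else f"{v:+d}"
    return f"{fmt(start_offset)}|{fmt(end_offset)}"


def parse_label(label: str) -> tuple[int, int]:
    """Inverse of :func:`format_label`."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed isomiR label {label!r}")
    return int(m.group(1)), int(m.group(2))


def compute_offsets(alignment: ArmAlignment, arm: ArmAnnotation | None = None
                    ) -> tuple[int, int]:
    """Signed 5'/3' offsets of an arm-assigned alignment.

    Rightward (3'-ward on the hairpin) is positive: a read starting one base
    right of the archetype's 5' end has ``start_offset`` +1; a templated end
    two bases left of the archetype's 3' end has ``end_offset`` -2.
    """
    arm = arm or alignment.arm
    if arm is None:
        raise ValueError("alignment is not assigned to an arm")
    start_offset = alignment.start_pos - arm.arm_start
    end_offset = (alignment.start_pos + alignment.templated_len - 1) - arm.arm_end
    return start_offset, end_offset


def resolve_tail(tail: str, reference_continuation: str) -> tuple[int, str]:
    """Split an aligner tail into (templated extension, NTA).

    Maximal-prefix rule: the longest prefix of ``tail`` matching the
    reference continuation beyond the templated end is absorbed as templated
    3' extension; the remaining suffix is non-templated. If the reference
    continuation is exhausted first, the rest of the tail is NTA by
    definition.
    """
    tail = normalize_seq(tail)
    ref = normalize_seq(reference_continuation)
    k = 0
    while k < len(tail) and k < len(ref) and tail[k] == ref[k]:
        k += 1
    return k, tail[k:]


def is_uridylated(nta: str) -> bool:
    """NTA composed exclusively of one or more uridines."""
    nta = normalize_seq(nta)
    return bool(nta) and set(nta) == {"T"}


def classify(start_offset: int, end_offset: int, nta: str) -> str:
    """Six-way exclusive category of an isomiR.

    The 3' terminus counts as modified if the templated end shifted or an
    NTA is present; a record that is modified at both termini — or carries
    an NTA on top of a templated 3' shift — is mixed.
    """
    has_nta = bool(nta)
    three_mod = end_offset != 0 or has_nta
    if start_offset == 0 and not three_mod:
        return "canonical"
    if start_offset != 0 and three_mod:
        return "mixed"
    if end_offset != 0 and has_nta:
        return "mixed"
    if start_offset > 0:
        return "5p_deletion"
    if start_offset < 0:
        return "5p_addition"
    if end_offset < 0:
        return "3p_deletion"
    return "3p_addition"  # e>0 templated, or pure NTA on canonical ends


@dataclass(frozen=True)
class IsomiRKey:
    accession: str
    name: str
    start_offset: int
    end_offset: int
    nta: str

    @property
    def label(self) -> str:
        return format_label(self.start_offset, self.end_offset)


@dataclass
class IsomiRRecord:
    """One distinct isoform with per-sample counts."""

    accession: str
    name: str
    start_offset: int
    end_offset: int
    nta: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return format_label(self.start_offset, self.end_offset)

    @property
    def category(self) -> str:
        return classify(self.start_offset, self.end_offset, self.nta)

    @property
    def uridylated(self) -> bool:
        return is_uridylated(self.nta)

    @property
    def feature_id(self) -> str:
        nta_part = f"|{self.nta}" if self.nta else ""
        return f"{self.name}|{self.label}{nta_part}"


def call_isomir(alignment: ArmAlignment,
                hairpin: HairpinReference) -> tuple[IsomiRKey, int]:
    """Resolve one arm-assigned alignment into (isomiR key, read count).

    The aligner already maximises the templated region, but the maximal-
    prefix rule is re-applied against the hairpin+flank continuation so the
    contract holds regardless of the aligner's split.
    """
    arm = alignment.arm
    if arm is None:
        raise ValueError("alignment is not assigned to an arm")
    start_offset, end_offset = compute_offsets(alignment)
    continuation = hairpin.extended[alignment.templated_end0:]
    extra, nta = resolve_tail(alignment.tail, continuation)
    key = IsomiRKey(arm.accession, arm.name, start_offset, end_offset + extra, nta)
    return key, alignment.read.count


def build_isomir_table(
    sample_alignments: Mapping[str, Sequence[ArmAlignment]],
    hairpins: Mapping[str, HairpinReference],
    samples: Sequence[str] | None = None,
) -> list[IsomiRRecord]:
    """Aggregate per-sample assigned alignments into isomiR records.

    One record per distinct (arm, 5' offset, templated 3' offset, NTA);
    counts summed per sample; deterministic ordering by accession then
    label then NTA.
    """
    samples = list(samples) if samples is not None else sorted(sample_alignments)
    acc: dict[IsomiRKey, dict[str, int]] = {}
    for sample in samples:
        for aln in sample_alignments.get(sample, ()):
            key, count = call_isomir(aln, hairpins[aln.hairpin_id])
            per = acc.setdefault(key, {s: 0 for s in samples})
            per[sample] += count
    records = [
        IsomiRRecord(k.accession, k.name, k.start_offset, k.end_offset, k.nta,
                     dict(counts))
        for k, counts in acc.items()
    ]
    records.sort(key=lambda r: (r.accession, r.start_offset, r.end_offset, r.nta))
    return records


def isomir_frame(records: Iterable[IsomiRRecord],
                 samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabular view: one row per isomiR, annotation columns + count columns."""
    records = list(records)
    if samples is None:
        samples = sorted({s for r in records for s in r.counts})
    rows = []
    for r in records:
        row = {
            "accession": r.accession,
            "name": r.name,
            "label": r.label,
            "nta": r.nta,
            "category": r.category,
            "uridylated": r.uridylated,
        }
        for s in samples:
            row[s] = r.counts.get(s, 0)
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["accession", "name", "label", "nta", "category", "uridylated",
                 *samples],
    )
    df.index = [r.feature_id for r in records]
    df.index.name = "isomir"
    return df
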