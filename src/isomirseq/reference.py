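"""Hairpin references and mature-arm annotations.

A *hairpin* is a miRNA precursor sequence; each hairpin carries one or two
annotated mature *arms* (5p/3p). IsomiR classification additionally needs the
genomic bases immediately downstream of the hairpin's 3' end (the *flank*),
because a 3'-terminal read extension is only "templated" if it matches the
genome continuation; otherwise it is a non-templated addition (NTA).

Conventions
-----------
* Sequences are stored uppercase in DNA space (U -> T); comparison logic is
  DNA-only.  Output can be re-projected to RNA where the input used RNA.
* File interfaces are 1-based inclusive (FASTA headers, GFF3); in-memory
  arithmetic is 0-based half-open, converted only in readers/writers.
* Hairpin sequence and flank are always stored in mature (5'->3')
  orientation; minus-strand genomic extraction reverse-complements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_FLANK_LEN = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


def normalize_seq(seq: str) -> str:
    """Uppercase and project RNA to DNA space (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HairpinReference:
    """One precursor with its downstream genomic flank.

    ``start``/``end`` are 1-based inclusive genomic coordinates; ``flank3``
    holds the genomic bases immediately 3' of the hairpin in mature
    orientation (reverse-complemented for minus-strand hairpins).
    """

    id: str
    sequence: str
    chrom: str = "."
    strand: str = "+"
    start: int = 1
    end: int = 0
    flank3: str = ""
    rna_input: bool = False

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        object.__setattr__(self, "flank3", normalize_seq(self.flank3))
        end = self.end if self.end else self.start + len(self.sequence) - 1
        object.__setattr__(self, "end", end)
        if self.strand not in "+-":
            raise ReferenceError(f"hairpin {self.id}: strand must be + or -")
        if len(self.sequence) != self.end - self.start + 1:
            raise ReferenceError(
                f"hairpin {self.id}: sequence length {len(self.sequence)} != "
                f"genomic span {self.end - self.start + 1}"
            )
        bad = set(self.sequence + self.flank3) - set("ACGTN")
        if bad:
            raise ReferenceError(
                f"hairpin {self.id}: invalid characters {sorted(bad)}"
            )

    @property
    def extended(self) -> str:
        """Hairpin plus 3' flank, the aligner's templated search space."""
        return self.sequence + self.flank3

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ArmAnnotation:
    """One mature arm located within its hairpin.

    ``arm_start``/``arm_end`` are 1-based inclusive positions within the
    hairpin sequence; ``archetype_seq`` is the annotated mature sequence
    (the "0|0" isoform).
    """

    name: str
    accession: str
    hairpin_id: str
    arm_start: int
    arm_end: int
    archetype_seq: str

    def __post_init__(self):
        object.__setattr__(self, "archetype_seq", normalize_seq(self.archetype_seq))
        if not (1 <= self.arm_start < self.arm_end):
            raise ReferenceError(
                f"arm {self.name}: require 1 <= arm_start < arm_end "
                f"(got {self.arm_start}, {self.arm_end})"
            )

    @property
    def start0(self) -> int:
        """0-based start within hairpin."""
        return self.arm_start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end within hairpin."""
        return self.arm_end

    def __len__(self) -> int:
        return self.arm_end - self.arm_start + 1


def make_arm(name: str, accession: str, hairpin: HairpinReference,
             arm_start: int, arm_end: int) -> ArmAnnotation:
    """Build an arm, deriving and checking the archetype from the hairpin."""
    if arm_end > len(hairpin.sequence):
        raise ReferenceError(
            f"arm {name}: end {arm_end} outside hairpin {hairpin.id} "
            f"of length {len(hairpin.sequence)}"
        )
    archetype = hairpin.sequence[arm_start - 1:arm_end]
    return ArmAnnotation(name, accession, hairpin.id, arm_start, arm_end, archetype)


def load_hairpins(
    fasta_path: str | Path,
    genome_flank_source: str | Path | Mapping[str, str] | None = None,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> dict[str, HairpinReference]:
    """Load hairpins from FASTA and attach 3' flanks.

    ``genome_flank_source`` is one of:

    * ``None`` — records are *pre-extended*: the last ``flank_len`` bases of
      each FASTA record are treated as flank, the rest as hairpin;
    * a mapping ``{hairpin_id: flank}`` with per-hairpin flank strings;
    * a genome FASTA path — flanks extracted by coordinates parsed from the
      record description (``chrom:start-end(strand)``) via pyfaidx.

    Raises :class:`ReferenceError` for duplicate IDs, malformed records, or
    missing flanks (listing the offending hairpin IDs).
    """
    records = {}
    coords: dict[str, tuple[str, int, int, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ReferenceError(f"duplicate hairpin ID {rec.id!r} in {fasta_path}")
        seq = str(rec.seq)
        if not seq:
            raise ReferenceError(f"empty sequence for record {rec.id!r}")
        records[rec.id] = seq
        loc = _parse_location(rec.description)
        if loc is not None:
            coords[rec.id] = loc

    hairpins: dict[str, HairpinReference] = {}
    missing: list[str] = []
    for hid, seq in records.items():
        rna = "U" in seq.upper()
        chrom, start, end, strand = coords.get(hid, (".", 1, 0, "+"))
        if genome_flank_source is None:
            if len(seq) <= flank_len:
                missing.append(hid)
                continue
            body, flank = seq[:-flank_len], seq[-flank_len:]
            end = start + len(body) - 1 if end else 0
            hairpins[hid] = HairpinReference(hid, body, chrom, strand, start,
                                             end if end else 0, flank, rna)
        elif isinstance(genome_flank_source, Mapping):
            flank = genome_flank_source.get(hid)
            if flank is None or len(normalize_seq(flank)) != flank_len:
                missing.append(hid)
                continue
            hairpins[hid] = HairpinReference(hid, seq, chrom, strand, start,
                                             end if end else 0, flank, rna)
        else:
            if hid not in coords:
                missing.append(hid)
                continue
            chrom, start, end, strand = coords[hid]
            flank = _extract_flank(genome_flank_source, chrom, start, end,
                                   strand, flank_len)
            if flank is None:
                missing.append(hid)
                continue
            hairpins[hid] = HairpinReference(hid, seq, chrom, strand, start,
                                             end, flank, rna)
    if missing:
        raise ReferenceError(
            "no 3' flank available for hairpin(s): " + ", ".join(sorted(missing))
        )
    return hairpins


def _parse_location(description: str) -> tuple[str, int, int, str] | None:
    """Parse ``chrom:start-end(strand)`` from a FASTA description, if present."""
    for token in description.split():
        if ":" in token and "-" in token.split(":", 1)[1]:
            chrom, span = token.split(":", 1)
            strand = "+"
            if span.endswith("(+)") or span.endswith("(-)"):
                strand = span[-2]
                span = span[:-3]
            try:
                start_s, end_s = span.split("-")
                return chrom, int(start_s), int(end_s), strand
            except ValueError:
                continue
    return None


def _extract_flank(genome_fasta: str | Path, chrom: str, start: int, end: int,
                   strand: str, flank_len: int) -> str | None:
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    if chrom not in genome:
        return None
    chrom_len = len(genome[chrom])
    if strand == "+":
        lo, hi = end, min(end + flank_len, chrom_len)  # 0-based half-open [end, ...)
        if hi - lo < flank_len:
            return None
        return normalize_seq(str(genome[chrom][lo:hi]))
    lo, hi = max(start - 1 - flank_len, 0), start - 1
    if hi - lo < flank_len:
        return None
    return revcomp(normalize_seq(str(genome[chrom][lo:hi])))


def load_arm_annotations(
    gff3_path: str | Path,
    hairpins: Mapping[str, HairpinReference],
) -> dict[str, ArmAnnotation]:
    """Load mature-arm annotations from a miRBase-dialect GFF3.

    Accepts ``miRNA`` features whose seqid is either a loaded hairpin ID
    (coordinates 1-based within the hairpin) or a chromosome name
    (genomic coordinates, converted via the hairpin named in the
    ``Derives_from`` attribute). Returns arms keyed by accession.
    """
    chrom_index: dict[str, list[HairpinReference]] = {}
    for hp in hairpins.values():
        chrom_index.setdefault(hp.chrom, []).append(hp)

    arms: dict[str, ArmAnnotation] = {}
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ReferenceError(f"{gff3_path}:{lineno}: expected 9 columns")
            seqid, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            if ftype != "miRNA":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            name = attrs.get("Name")
            accession = attrs.get("ID")
            if not name or not accession:
                raise ReferenceError(
                    f"{gff3_path}:{lineno}: miRNA feature needs ID= and Name="
                )
            start, end = int(start_s), int(end_s)
            if seqid in hairpins:
                hp = hairpins[seqid]
                arm_start, arm_end = start, end
            else:
                parent = attrs.get("Derives_from")
                hp = hairpins.get(parent) if parent else _locate_hairpin(
                    chrom_index.get(seqid, []), start, end)
                if hp is None:
                    raise ReferenceError(
                        f"{gff3_path}:{lineno}: arm {name!r} references no "
                        f"loaded hairpin (seqid {seqid!r})"
                    )
                if hp.strand == "+":
                    arm_start = start - hp.start + 1
                    arm_end = end - hp.start + 1
                else:
                    arm_start = hp.end - end + 1
                    arm_end = hp.end - start + 1
            if not (1 <= arm_start <= arm_end <= len(hp.sequence)):
                raise ReferenceError(
                    f"{gff3_path}:{lineno}: arm {name!r} coordinates "
                    f"({arm_start},{arm_end}) outside hairpin {hp.id!r} "
                    f"of length {len(hp.sequence)} (1-based inclusive)"
                )
            if accession in arms:
                raise ReferenceError(
                    f"{gff3_path}:{lineno}: duplicate accession {accession!r}"
                )
            arms[accession] = make_arm(name, accession, hp, arm_start, arm_end)
    return arms


def _locate_hairpin(candidates: Iterable[HairpinReference], start: int,
                    end: int) -> HairpinReference | None:
    for hp in candidates:
        if hp.start <= start and end <= hp.end:
            return hp
    return None


def write_hairpins(hairpins: Mapping[str, HairpinReference],
                   fasta_path: str | Path, pre_extended: bool = True) -> None:
    """Write hairpins to FASTA; with ``pre_extended`` the flank is appended
    so :func:`load_hairpins` round-trips without a genome."""
    with open(fasta_path, "w") as fh:
        for hid in sorted(hairpins):
            hp = hairpins[hid]
            seq = hp.extended if pre_extended else hp.sequence
            if hp.rna_input:
                seq = seq.replace("T", "U")
            loc = f"{hp.chrom}:{hp.start}-{hp.end}({hp.strand})"
            fh.write(f">{hid} {loc}\n{seq}\n")


def write_arm_annotations(arms: Mapping[str, ArmAnnotation],
                          gff3_path: str | Path) -> None:
    """Write arms as hairpin-relative miRNA features (GFF3)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for acc in sorted(arms):
            arm = arms[acc]
            fh.write(
                f"{arm.hairpin_id}\t.\tmiRNA\t{arm.arm_start}\t{arm.arm_end}"
                f"\t.\t+\t.\tID={arm.accession};Name={arm.name}\n"
            )


def arms_by_hairpin(arms: Mapping[str, ArmAnnotation]
                    ) -> dict[str, list[ArmAnnotation]]:
    """Group arms by hairpin ID, ordered by position."""
    out: dict[str, list[ArmAnnotation]] = {}
    for arm in arms.values():
        out.setdefault(arm.hairpin_id, []).append(arm)
    for lst in out.values():
        lst.sort(key=lambda a: a.arm_start)
    return out
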