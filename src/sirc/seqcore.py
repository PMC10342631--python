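"""Core genomic types and readers/writers for FASTA, GFF3, BED and TSV tables.

All in-memory coordinates are 0-based half-open intervals on the forward
strand; GFF3 emission converts to the 1-based inclusive convention on output
and back on input.  Genome sequences are held as uppercase strings over the
alphabet ``{A, C, G, T, N}``; any other IUPAC ambiguity code is mapped to
``N`` when a FASTA file is loaded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "Interval",
    "SircRecord",
    "AnnotationInterval",
    "load_genome",
    "write_genome",
    "write_sirc_gff",
    "read_sirc_gff",
    "read_annotations",
    "write_feature_table",
]

_IUPAC_EXTRA = "RYSWKMBDHVU"
_TO_N = str.maketrans(_IUPAC_EXTRA, "N" * len(_IUPAC_EXTRA))
_VALID_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: an uppercase DNA string over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not _VALID_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(
                f"record {self.name!r} contains non-nucleotide characters: {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SircRecord:
    """A detected cassette: 2-8 equal-length direct-repeat units separated by
    diverse spacers, plus derived per-cassette statistics.

    ``features`` carries the derived statistics emitted in the TSV feature
    table (gc_percent, dust, trifonov, palindrome_arm, copy numbers, ...).
    """

    interval: Interval
    units: list[Interval]
    spacers: list[Interval]
    dr_consensus: str
    features: dict[str, object] = field(default_factory=dict)
    sirc_id: str = ""

    def __post_init__(self) -> None:
        if len(self.units) < 2:
            raise ValueError("a cassette needs at least 2 repeat units")
        if len(self.spacers) != len(self.units) - 1:
            raise ValueError("expected one spacer between consecutive units")
        chroms = {u.chrom for u in self.units} | {s.chrom for s in self.spacers}
        if chroms != {self.interval.chrom}:
            raise ValueError("units/spacers must share the cassette chromosome")
        for a, b in zip(self.units, self.units[1:]):
            if a.end > b.start:
                raise ValueError("units must be sorted and non-overlapping")
        for sp, a, b in zip(self.spacers, self.units, self.units[1:]):
            if not (a.end <= sp.start and sp.end <= b.start):
                raise ValueError("spacer must lie between its flanking units")
        if (
            self.interval.start != self.units[0].start
            or self.interval.end != self.units[-1].end
        ):
            raise ValueError("cassette span must cover first unit to last unit")
        if not self.sirc_id:
            self.sirc_id = (
                f"SIRC_{self.interval.chrom}_{self.interval.start}_{self.interval.end}"
            )

    @property
    def n_units(self) -> int:
        return len(self.units)

    def sequence(self, genome: Mapping[str, str] | str) -> str:
        seq = genome if isinstance(genome, str) else genome[self.interval.chrom]
        return seq[self.interval.start : self.interval.end]

    def unit_sequences(self, genome: Mapping[str, str] | str) -> list[str]:
        seq = genome if isinstance(genome, str) else genome[self.interval.chrom]
        return [seq[u.start : u.end] for u in self.units]

    def spacer_sequences(self, genome: Mapping[str, str] | str) -> list[str]:
        seq = genome if isinstance(genome, str) else genome[self.interval.chrom]
        return [seq[s.start : s.end] for s in self.spacers]


@dataclass(frozen=True)
class AnnotationInterval:
    """A typed genomic feature (e.g. MITE, MGE, mRNA, exon, pseudogene)."""

    interval: Interval
    category: str

    def __post_init__(self) -> None:
        if not self.category:
            raise ValueError("annotation category must be non-empty")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(fasta_path: str | Path) -> list[GenomeSequence]:
    """Load a FASTA file; uppercase, map ambiguity codes other than N to N.

    Record order follows the file.  Raises on missing files, empty records
    and characters that are not IUPAC nucleotide codes.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: list[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().translate(_TO_N)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if not _VALID_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(
                f"record {rec.id!r} contains non-nucleotide characters: {bad}"
            )
        out.append(GenomeSequence(rec.id, seq))
    return out


def write_genome(seqs: Iterable[GenomeSequence], fasta_path: str | Path,
                 width: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.name, description="") for s in seqs]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def genome_dict(seqs: Iterable[GenomeSequence]) -> dict[str, str]:
    """Name -> sequence mapping used throughout the scanning modules."""
    return {s.name: s.seq for s in seqs}


# ---------------------------------------------------------------------------
# GFF3 for cassettes
# ---------------------------------------------------------------------------

_SOURCE = "sirc"


def _gff_attrs(pairs: Mapping[str, object]) -> str:
    return ";".join(f"{k}={quote(str(v), safe='')}" for k, v in pairs.items())


def write_sirc_gff(records: Sequence[SircRecord], path: str | Path) -> None:
    """Write cassettes as GFF3: one parent feature per cassette with child
    features for every repeat unit and spacer (1-based inclusive coords)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = {"ID": rec.sirc_id, "dr_consensus": rec.dr_consensus}
            for k, v in rec.features.items():
                attrs[k] = v
            iv = rec.interval
            fh.write(
                "\t".join(
                    [iv.chrom, _SOURCE, "repeat_cassette", str(iv.start + 1),
                     str(iv.end), ".", iv.strand, ".", _gff_attrs(attrs)]
                ) + "\n"
            )
            for i, u in enumerate(rec.units):
                fh.write(
                    "\t".join(
                        [u.chrom, _SOURCE, "repeat_unit", str(u.start + 1),
                         str(u.end), ".", u.strand, ".",
                         _gff_attrs({"ID": f"{rec.sirc_id}.unit{i}",
                                     "Parent": rec.sirc_id})]
                    ) + "\n"
                )
            for i, s in enumerate(rec.spacers):
                fh.write(
                    "\t".join(
                        [s.chrom, _SOURCE, "spacer", str(s.start + 1),
                         str(s.end), ".", s.strand, ".",
                         _gff_attrs({"ID": f"{rec.sirc_id}.spacer{i}",
                                     "Parent": rec.sirc_id})]
                    ) + "\n"
                )


def _parse_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for piece in text.strip().split(";"):
        if not piece:
            continue
        key, _, val = piece.partition("=")
        out[key] = unquote(val)
    return out


def read_sirc_gff(path: str | Path) -> list[SircRecord]:
    """Re-parse a GFF3 file produced by :func:`write_sirc_gff`."""
    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start, end, _, strand, _, attr_text = cols
            iv = Interval(chrom, int(start) - 1, int(end), strand)
            attrs = _parse_attrs(attr_text)
            if ftype == "repeat_cassette":
                feats = {
                    k: v for k, v in attrs.items()
                    if k not in ("ID", "dr_consensus")
                }
                parents[attrs["ID"]] = {
                    "interval": iv,
                    "dr_consensus": attrs.get("dr_consensus", ""),
                    "features": feats,
                    "units": [],
                    "spacers": [],
                }
                order.append(attrs["ID"])
            elif ftype in ("repeat_unit", "spacer"):
                parent = attrs.get("Parent")
                if parent not in parents:
                    raise ValueError(f"{path}:{lineno}: orphan child feature")
                key = "units" if ftype == "repeat_unit" else "spacers"
                parents[parent][key].append(iv)
    out = []
    for pid in order:
        p = parents[pid]
        out.append(
            SircRecord(
                interval=p["interval"],
                units=sorted(p["units"]),
                spacers=sorted(p["spacers"]),
                dr_consensus=p["dr_consensus"],
                features=p["features"],
                sirc_id=pid,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Annotations (GFF3 or BED in, 0-based half-open out)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path,
                     category_field: str | None = None) -> list[AnnotationInterval]:
    """Read genomic feature intervals from GFF3 or BED.

    The dialect is detected from the extension (``.bed`` vs ``.gff``/
    ``.gff3``) or, failing that, the first data line.  For GFF3 the category
    defaults to the feature-type column; pass ``category_field`` to take it
    from a named attribute instead.  For BED the name column is the category.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    fmt = None
    if path.suffix.lower() == ".bed":
        fmt = "bed"
    elif path.suffix.lower() in (".gff", ".gff3"):
        fmt = "gff"
    else:
        for line in lines:
            if line.startswith("##gff-version"):
                fmt = "gff"
                break
            if line and not line.startswith("#"):
                fmt = "gff" if len(line.split("\t")) == 9 else "bed"
                break
    out: list[AnnotationInterval] = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        try:
            if fmt == "bed":
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                category = cols[3] if len(cols) > 3 else "feature"
                strand = cols[5] if len(cols) > 5 else "."
                out.append(
                    AnnotationInterval(Interval(chrom, start, end, strand), category)
                )
            else:
                chrom, _, ftype = cols[0], cols[1], cols[2]
                start, end = int(cols[3]) - 1, int(cols[4])
                strand = cols[6] if cols[6] in ("+", "-") else "."
                category = ftype
                if category_field:
                    attrs = _parse_attrs(cols[8])
                    category = attrs.get(category_field, ftype)
                out.append(
                    AnnotationInterval(Interval(chrom, start, end, strand), category)
                )
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return out


def write_annotations_bed(annotations: Sequence[AnnotationInterval],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            iv = ann.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.category}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# TSV feature table
# ---------------------------------------------------------------------------

def write_feature_table(records: Sequence[SircRecord], path: str | Path) -> None:
    """One row per cassette; columns are the union of feature-map keys."""
    import pandas as pd

    rows = []
    for rec in records:
        row: dict[str, object] = {
            "sirc_id": rec.sirc_id,
            "chrom": rec.interval.chrom,
            "start": rec.interval.start,
            "end": rec.interval.end,
            "n_units": rec.n_units,
            "dr_length": len(rec.dr_consensus),
            "dr_consensus": rec.dr_consensus,
        }
        row.update(rec.features)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
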