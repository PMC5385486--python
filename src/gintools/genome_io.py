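"""Sequence and annotation I/O with a single internal coordinate convention.

All intervals inside the package are 0-based half-open ``[start, end)``.
GenBank and GFF3 use 1-based inclusive coordinates; conversion happens only
at the file boundary (``file_start == internal_start + 1``,
``file_end == internal_end``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CdsFeature",
    "AnnotatedGenome",
    "GenomeValidationError",
    "read_genome",
    "write_genome",
    "extract_cds_protein",
    "at_fraction",
]

_DNA_ALPHABET = set("ACGTN")


class GenomeValidationError(ValueError):
    """A genome or feature violates the package's structural invariants."""


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a replicon.

    ``interval`` is 0-based half-open on the forward strand regardless of
    the coding strand; ``strand`` is ``'+'`` or ``'-'``.
    """

    feature_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    locus_tag: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < 3:
            raise GenomeValidationError(
                f"CDS {self.feature_id!r}: interval shorter than one codon"
            )
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"CDS {self.feature_id!r}: strand must be '+' or '-'"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "CdsFeature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class AnnotatedGenome:
    """A replicon sequence plus its ordered CDS features."""

    id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    topology: Literal["linear", "circular"] = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise GenomeValidationError(
                f"genome {self.id!r}: disallowed characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted"
            )
        for feat in self.features:
            if not (0 <= feat.start < feat.end <= len(self.sequence)):
                raise GenomeValidationError(
                    f"CDS {feat.feature_id!r} interval [{feat.start}, {feat.end}) "
                    f"outside sequence bounds [0, {len(self.sequence)})"
                )
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedGenome):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and self.features == other.features
            and self.topology == other.topology
        )

    def feature_by_id(self, feature_id: str) -> CdsFeature:
        for feat in self.features:
            if feat.feature_id == feature_id:
                return feat
        raise KeyError(f"no CDS with feature_id {feature_id!r}")

    def subsequence(self, start: int, end: int) -> str:
        """Forward-strand slice; wraps across the origin on circular replicons."""
        if start <= end and end <= len(self.sequence):
            return self.sequence[start:end]
        if self.topology == "circular":
            end_mod = end % len(self.sequence)
            return self.sequence[start:] + self.sequence[:end_mod]
        raise GenomeValidationError(
            f"slice [{start}, {end}) outside linear genome of length {len(self)}"
        )


def read_genome(path: str | Path, format: str = "genbank",
                gff3: str | Path | None = None) -> AnnotatedGenome:
    """Read a genome with CDS annotation from standard files.

    Parameters
    ----------
    path
        GenBank flat file, or FASTA when ``format='fasta+gff3'``.
    format
        ``'genbank'`` or ``'fasta+gff3'``.
    gff3
        Companion GFF3 path for the ``fasta+gff3`` format; if omitted the
        genome is returned without features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        record = SeqIO.read(str(path), "genbank")
        topology = record.annotations.get("topology", "linear")
        features = []
        for i, feat in enumerate(record.features):
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            fid = (quals.get("locus_tag") or quals.get("protein_id")
                   or [f"cds_{i}"])[0]
            features.append(CdsFeature(
                feature_id=fid,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="+" if feat.location.strand != -1 else "-",
                locus_tag=(quals.get("locus_tag") or [""])[0],
            ))
        return AnnotatedGenome(id=record.id, sequence=str(record.seq),
                               features=features,
                               topology="circular" if topology == "circular" else "linear")
    if format == "fasta+gff3":
        record = SeqIO.read(str(path), "fasta")
        features = _read_gff3_cds(gff3, record.id) if gff3 else []
        return AnnotatedGenome(id=record.id, sequence=str(record.seq),
                               features=features)
    raise ValueError(f"unknown format {format!r}")


def _read_gff3_cds(path: str | Path, seqid: str | None = None) -> list[CdsFeature]:
    # GFF3 columns: seqid source type start end score strand phase attributes
    # (1-based inclusive). Only CDS rows are materialized.
    features = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GenomeValidationError(f"malformed GFF3 line: {line!r}")
        if cols[2] != "CDS":
            continue
        if seqid is not None and cols[0] != seqid:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        fid = attrs.get("ID") or attrs.get("locus_tag") or f"cds_{len(features)}"
        features.append(CdsFeature(
            feature_id=fid,
            start=int(cols[3]) - 1,
            end=int(cols[4]),
            strand=cols[6] if cols[6] in "+-" else "+",
            locus_tag=attrs.get("locus_tag", ""),
        ))
    return features


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path,
                 gff3_path: str | Path | None = None) -> None:
    """Write FASTA and (optionally) GFF3 for the genome's CDS features."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
            for feat in genome.features:
                attrs = f"ID={feat.feature_id}"
                if feat.locus_tag:
                    attrs += f";locus_tag={feat.locus_tag}"
                fh.write("\t".join([
                    genome.id, "gintools", "CDS",
                    str(feat.start + 1), str(feat.end),
                    ".", feat.strand, "0", attrs,
                ]) + "\n")


def extract_cds_protein(genome: AnnotatedGenome, feature_id: str) -> str:
    """Translate a CDS (strand-corrected, standard code, stop trimmed)."""
    feat = genome.feature_by_id(feature_id)
    nt = genome.sequence[feat.start:feat.end]
    if feat.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        warnings.warn(
            f"internal stop codon in CDS {feature_id!r}; translation truncated",
            stacklevel=2,
        )
        aa = aa.split("*")[0]
    return aa


def at_fraction(seq: str, window: int | None = None) -> float | list[float]:
    """A+T fraction of a sequence, whole or in non-overlapping windows.

    ``N`` bases are excluded from both numerator and denominator; an
    all-``N`` stretch yields ``nan`` for that window.
    """
    if not seq:
        raise ValueError("at_fraction of empty sequence")
    seq = seq.upper()

    def _frac(s: str) -> float:
        denom = len(s) - s.count("N")
        if denom == 0:
            return float("nan")
        return (s.count("A") + s.count("T")) / denom

    if window is None:
        return _frac(seq)
    if window <= 0:
        raise ValueError("window must be positive")
    return [_frac(seq[i:i + window]) for i in range(0, len(seq), window)]
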