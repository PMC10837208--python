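"""Readers and writers for the standard formats the pipeline touches.

FASTA in/out (via Biopython), biallelic-SNP extraction from VCF v4.x text
(via pysam), two-locus F2 genotype count tables (TSV), sample->population
maps (TSV), Newick quartet output, and a small key-value configuration
loader.  Coordinate conventions: positions are 1-based in every user-facing
structure (VCF in, tables out); genomic windows use 0-based half-open
``[start, end)`` arithmetic internally.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("ricebarrier")

_MISSING = -1  #: sentinel for a missing haploid call

SEQ_ALPHABET = frozenset("ACGTN-")


def setup_logging(level: str = "INFO") -> None:
    """Configure line-oriented logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ricebarrier")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, level.upper()))


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence over {A, C, G, T, N, -}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise ValueError(f"invalid characters in sequence {self.id!r}: {sorted(bad)}")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with per-sample pairs of haploid calls.

    Calls are 0 (ref), 1 (alt) or -1 (missing); ``pos`` is 1-based as in VCF.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    def allele_counts(self) -> tuple[int, int]:
        """(alt-allele count, called-allele count) over all samples."""
        k = n = 0
        for a, b in self.calls:
            for h in (a, b):
                if h != _MISSING:
                    n += 1
                    k += h
        return k, n

    @property
    def genotyped_fraction(self) -> float:
        """Fraction of samples with at least one called haplotype."""
        if not self.calls:
            return 0.0
        called = sum(1 for a, b in self.calls if a != _MISSING or b != _MISSING)
        return called / len(self.calls)


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population label (P1/P2/P3/O for quartets; case/control)."""

    labels: Mapping[str, str]

    def samples(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def require_quartet(self) -> None:
        for role in ("P1", "P2", "P3", "O"):
            if not self.samples(role):
                raise ValueError(f"quartet analysis requires samples labelled {role}")


# Genotype-class vocabularies for the two-locus F2 tables.  Locus 1 alleles
# are written W1 (recurrent parent) / G1 (donor); locus 2 W2 / G2, following
# the reference cross where both loci segregate W vs G.
MARGINAL1_CLASSES = ("W1W1", "W1G1", "G1G1")
MARGINAL2_CLASSES = ("W2W2", "W2G2", "G2G2")
JOINT_CLASSES = tuple(f"{a}_{b}" for a in MARGINAL1_CLASSES for b in MARGINAL2_CLASSES)


@dataclass(frozen=True)
class CountsTable:
    """Genotype-class counts from an F2 population.

    ``kind`` is one of ``marginal1``, ``marginal2`` or ``joint`` and is
    inferred from the class names on construction.
    """

    classes: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.counts):
            raise ValueError("classes and counts must have equal length")
        for c in self.counts:
            if not isinstance(c, int) or c < 0:
                raise ValueError(f"counts must be non-negative integers, got {c!r}")
        if sum(self.counts) <= 0:
            raise ValueError("total count must be > 0")
        valid = set(MARGINAL1_CLASSES) | set(MARGINAL2_CLASSES) | set(JOINT_CLASSES)
        for name in self.classes:
            if name not in valid:
                raise ValueError(
                    f"unknown genotype class {name!r}; valid names: "
                    f"{MARGINAL1_CLASSES + MARGINAL2_CLASSES} or joint pairs like "
                    f"{JOINT_CLASSES[:2]}"
                )
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate genotype class names")

    @property
    def kind(self) -> str:
        s = set(self.classes)
        if s <= set(MARGINAL1_CLASSES):
            return "marginal1"
        if s <= set(MARGINAL2_CLASSES):
            return "marginal2"
        return "joint"

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.classes, self.counts))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are upper-cased and line wrapping is removed.  Raises
    :class:`FormatError` naming the offending line for empty files or
    content appearing before the first header.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: expected FASTA header at line {lineno}")
        break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` wrapped at ``width`` columns."""
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_BASES = frozenset("ACGT")


def read_vcf_sites(
    path: str | Path,
    samples: Sequence[str] | None = None,
) -> list[VariantSite]:
    """Extract biallelic SNP records from a VCF v4.x file.

    Multi-allelic and indel records are skipped (count logged).  ``./.`` and
    ``.`` genotypes become missing calls; phased and unphased separators are
    both accepted.  ``samples`` restricts and orders the call columns.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        if samples is not None:
            missing = [s for s in samples if s not in header_samples]
            if missing:
                raise LookupError(f"{path}: samples not in VCF header: {missing}")
            use = list(samples)
        else:
            use = header_samples

        sites: list[VariantSite] = []
        skipped = 0
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref is None:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if ref not in _SNP_BASES or alt not in _SNP_BASES:
                skipped += 1
                continue
            calls = []
            for s in use:
                gt = rec.samples[s].get("GT")
                if gt is None:
                    pair = (_MISSING, _MISSING)
                else:
                    pair = tuple(_MISSING if a is None else int(a) for a in gt)
                    if len(pair) == 1:
                        pair = (pair[0], _MISSING)
                calls.append(pair)
            sites.append(VariantSite(rec.chrom, rec.pos, ref, alt, tuple(calls)))
    if skipped:
        logger.info("read_vcf_sites: skipped %d non-biallelic-SNP records", skipped)
    return sites


def write_vcf_sites(
    sites: Sequence[VariantSite],
    sample_names: Sequence[str],
    path: str | Path,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write sites as a minimal uncompressed VCF v4.2 text file."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    for s in sites:
        gts = []
        for a, b in s.calls:
            fmt = lambda h: "." if h == _MISSING else str(h)
            gts.append(f"{fmt(a)}/{fmt(b)}")
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_counts_table(path: str | Path) -> CountsTable:
    """Read a TSV of (class, count) rows into a :class:`CountsTable`."""
    path = Path(path)
    classes: list[str] = []
    counts: list[int] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty counts table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 2 columns at line {lineno}")
            name, raw = parts
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(f"{path}: non-integer count {raw!r} at line {lineno}") from None
            classes.append(name)
            counts.append(value)
    return CountsTable(tuple(classes), tuple(counts))


def write_counts_table(table: CountsTable, path: str | Path) -> None:
    lines = ["class\tcount"]
    lines += [f"{c}\t{n}" for c, n in zip(table.classes, table.counts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column sample<TAB>label TSV (no header)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 2 columns at line {lineno}")
            sample, label = parts
            if sample in labels:
                raise ValueError(f"{path}: sample {sample!r} listed twice")
            labels[sample] = label
    return PopulationMap(labels)


def quartet_newick(sister: tuple[str, str], other: str, outgroup: str) -> str:
    """Serialize a quartet topology as a Newick string."""
    a, b = sorted(sister)
    return f"(({a},{b}),{other},{outgroup});"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a nestable key-value config file.

    Lines are ``key = value``; sections open with ``[name]`` and nest with
    dots (``[a.b]``).  Values are parsed as int, float, bool or string.
    """
    cfg: dict = {}
    section = cfg
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = cfg
            for part in line[1:-1].split("."):
                section = section.setdefault(part.strip(), {})
            continue
        if "=" not in line:
            raise FormatError(f"config line {lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        section[key] = _parse_scalar(raw)
    return cfg


def _parse_scalar(raw: str):
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw
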