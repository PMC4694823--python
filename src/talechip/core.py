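"""Genomic domain types and readers/writers.

All coordinates inside the package are 0-based, half-open (BED-native).
Conversion to/from 1-based formats (GTF) happens only in readers/writers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pyfaidx

STRANDS = {"+", "-", "."}

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-seq peak with a summit.

    The score is the enrichment of immunoprecipitated over input reads as
    emitted by MACS-style callers; the summit is the position of maximal
    enrichment (absolute coordinate).
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.score < 0:
            raise ValueError(f"negative peak score {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to a single transcription unit.

    tss is the strand-aware 5' end: interval.start on '+', interval.end - 1
    on '-'.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class PeakSet:
    """A labelled collection of peaks, e.g. Meis1 binding in M cells."""

    label: str
    peaks: list[Peak] = field(default_factory=list)
    genome_id: str | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]


class Genome:
    """In-memory random-access genome sequence.

    Sequences are stored uppercased as bytearrays so that the synthetic-data
    generator can write motif instances in place.
    """

    def __init__(self, sequences: dict[str, str | bytes | bytearray], genome_id: str = "genome"):
        self.genome_id = genome_id
        self._seq: dict[str, bytearray] = {}
        for chrom, seq in sequences.items():
            if isinstance(seq, str):
                seq = seq.encode()
            self._seq[chrom] = bytearray(bytes(seq).upper())

    @property
    def chroms(self) -> list[str]:
        return list(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seq:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seq[chrom]) or end <= start:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside contig of length "
                f"{len(self._seq[chrom])}"
            )
        seq = self._seq[chrom][start:end]
        if strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq.decode()

    def fetch_interval(self, interval: GenomicInterval) -> str:
        strand = interval.strand if interval.strand == "-" else "+"
        return self.fetch(interval.chrom, interval.start, interval.end, strand)

    def embed(self, chrom: str, start: int, seq: str) -> None:
        """Overwrite genome sequence in place (synthetic-data generator)."""
        if start < 0 or start + len(seq) > len(self._seq[chrom]):
            raise ValueError(f"embedding outside contig {chrom}")
        self._seq[chrom][start : start + len(seq)] = seq.upper().encode()

    def sequence(self, chrom: str) -> str:
        return self._seq[chrom].decode()

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seq.items():
                fh.write(f">{chrom}\n")
                s = seq.decode()
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


def read_fasta(path: str | Path, genome_id: str | None = None) -> Genome:
    """Load a FASTA file into a Genome (sequences uppercased)."""
    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return Genome(sequences, genome_id=genome_id or Path(path).stem)


# ---------------------------------------------------------------------------
# BED peaks

SUMMIT_DIALECTS = ("offset", "absolute", "midpoint")


def read_bed(path: str | Path, summit_dialect: str = "midpoint", label: str | None = None,
             genome_id: str | None = None) -> PeakSet:
    """Read peaks from a BED3/BED5(+summit) file.

    Columns: chrom, start, end [, name, score, summit]. The summit column is
    interpreted per ``summit_dialect``: 'offset' (relative to start, MACS
    convention), 'absolute' (genome coordinate) or 'midpoint' (ignore the
    column and use the interval midpoint, also the default when the column is
    absent).
    """
    if summit_dialect not in SUMMIT_DIALECTS:
        raise ValueError(f"summit_dialect must be one of {SUMMIT_DIALECTS}")
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            if len(fields) > 5 and summit_dialect != "midpoint":
                raw = int(fields[5])
                summit = start + raw if summit_dialect == "offset" else raw
            else:
                summit = (start + end) // 2
            try:
                peaks.append(Peak(GenomicInterval(chrom, start, end), summit, score, name))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return PeakSet(label or Path(path).stem, peaks, genome_id=genome_id)


def write_bed(peak_set: PeakSet, path: str | Path, summit_dialect: str = "offset") -> None:
    """Write peaks as BED5+summit (summit encoded per dialect)."""
    if summit_dialect not in ("offset", "absolute"):
        raise ValueError("write_bed emits 'offset' or 'absolute' summit columns")
    with open(path, "w") as fh:
        for p in peak_set:
            summit = p.summit - p.start if summit_dialect == "offset" else p.summit
            score = f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t{summit}\n")


def write_regions_bed(regions: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_regions_bed(path: str | Path) -> list[GenomicInterval]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            regions.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return regions


# ---------------------------------------------------------------------------
# Gene annotation

_GTF_GENE_ID = re.compile(r'gene_id[ =]+"?([^";]+)"?')


def read_gene_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from a TSV (chrom/start/end/strand/gene_id header) or
    GTF-lite file; multiple rows per gene_id are collapsed to the union of
    their extents (one transcription unit per gene).

    Format is inferred from the extension unless ``fmt`` ('tsv' or 'gtf') is
    given. GTF coordinates (1-based inclusive) are converted on read.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff", ".gff3") else "tsv"
    rows: list[tuple[str, str, int, int, str]] = []  # gene_id, chrom, start, end, strand
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            idx = {c.lower(): i for i, c in enumerate(header)}
            for col in ("gene_id", "chrom", "start", "end", "strand"):
                if col not in idx:
                    raise ValueError(f"{path}: missing column {col!r}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((f[idx["gene_id"]], f[idx["chrom"]],
                             int(f[idx["start"]]), int(f[idx["end"]]),
                             f[idx["strand"]]))
    elif fmt == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise ValueError(f"{path}: line {lineno}: fewer than 9 GTF columns")
                m = _GTF_GENE_ID.search(f[8])
                if m is None:
                    raise ValueError(f"{path}: line {lineno}: no gene_id attribute")
                # GTF is 1-based inclusive
                rows.append((m.group(1), f[0], int(f[3]) - 1, int(f[4]), f[6]))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    for gene_id, chrom, start, end, strand in rows:
        if strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {gene_id}: unknown strand {strand!r}")
        by_gene.setdefault(gene_id, []).append((chrom, start, end, strand))

    genes = []
    for gene_id, parts in by_gene.items():
        chroms = {c for c, *_ in parts}
        strands = {s for *_, s in parts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{path}: gene {gene_id} spans multiple chromosomes/strands")
        start = min(s for _, s, _, _ in parts)
        end = max(e for _, _, e, _ in parts)
        genes.append(GeneModel(gene_id, GenomicInterval(parts[0][0], start, end), parts[0][3]))
    return genes


def write_gene_annotation(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.strand}\n")
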