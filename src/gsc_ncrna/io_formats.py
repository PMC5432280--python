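"""Readers and writers for every on-disk representation used by the pipeline.

Formats
-------
FASTA            genome sequences (``Genome``)
GTF              transcript models, exon features only, 1-based inclusive on
                 disk, 0-based half-open in memory
split-alignment  bespoke 8-column TSV holding the two exact-match segments of
                 one read (``SplitAlignment``); the ``chrom`` column holds one
                 name when both segments share a chromosome and
                 ``"chrom1,chrom2"`` otherwise
count table      TSV, ``transcript_id`` index column + one column per library
edge list        Cytoscape-loadable TSV (source, target, weight, sign)

All coordinates are 0-based half-open internally; conversion to/from the GTF
convention happens only inside :func:`read_gtf` / :func:`write_gtf`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .errors import FormatError

AUTOSOME = "autosome"
X_CHROM = "X"

#: chromosome names treated as X-linked unless a config override is given
DEFAULT_X_NAMES = frozenset({"chrX", "X"})

BIOTYPES = frozenset(
    {
        "coding",
        "known_lncRNA",
        "rRNA",
        "tRNA",
        "snRNA",
        "snoRNA",
        "pre_miRNA",
        "pseudogene",
        "unknown",
    }
)

HOUSEKEEPING_BIOTYPES = frozenset(
    {"rRNA", "tRNA", "snRNA", "snoRNA", "pre_miRNA", "pseudogene"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Chromosome sequences plus an autosome/X label per chromosome."""

    seqs: Dict[str, str]
    chrom_class: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.seqs.items():
            if not seq:
                raise FormatError(f"empty sequence for chromosome {name!r}")
            if name not in self.chrom_class:
                raise FormatError(f"chromosome {name!r} has no chrom_class entry")

    def fetch(self, chrom: str, start: int, end: int) -> Optional[str]:
        """Return genome[start:end) or None when the window leaves the chrom."""
        seq = self.seqs.get(chrom)
        if seq is None or start < 0 or end > len(seq) or start > end:
            return None
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs


@dataclass
class TranscriptModel:
    """One transcript: ordered non-overlapping exons on a single chromosome."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    biotype: str = "unknown"
    read_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise FormatError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < 0:
                raise FormatError(
                    f"bad exon ({s},{e}) in transcript {self.transcript_id}"
                )
            if prev_end is not None and s < prev_end:
                raise FormatError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
            prev_end = e
        if self.biotype not in BIOTYPES:
            raise FormatError(f"unknown biotype {self.biotype!r}")
        if self.read_coverage < 0:
            raise FormatError("read_coverage must be non-negative")

    # -- geometry helpers -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcript 5' end."""
        return self.start if self.strand == "+" else self.end

    def introns(self) -> List[Tuple[int, int]]:
        """Genomic intron intervals (0-based half-open, ascending)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def intron_chain(self) -> Tuple[int, ...]:
        """Ordered internal splice coordinates; empty for monoexonic models."""
        chain: List[int] = []
        for s, e in self.introns():
            chain.extend((s, e))
        return tuple(chain)

    def sequence(self, genome: Genome) -> str:
        """Spliced sequence in transcript orientation."""
        parts = []
        for s, e in self.exons:
            piece = genome.fetch(self.chrom, s, e)
            if piece is None:
                raise FormatError(
                    f"exon ({s},{e}) of {self.transcript_id} outside {self.chrom}"
                )
            parts.append(piece)
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class SplitAlignment:
    """Two exact-match genomic segments of one read (seg1 = 5' read part)."""

    read_id: str
    sample_id: str
    chrom1: str
    chrom2: str
    strand: str
    seg1: Tuple[int, int]
    seg2: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r} in read {self.read_id}")
        for name, (s, e) in (("seg1", self.seg1), ("seg2", self.seg2)):
            if s >= e or s < 0:
                raise FormatError(
                    f"malformed {name} ({s},{e}) in read {self.read_id}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, x_names: Iterable[str] = DEFAULT_X_NAMES) -> Genome:
    """Load a genome FASTA; sequences are uppercased.

    Chromosomes whose name is in ``x_names`` are labelled X-linked, everything
    else is an autosome.
    """
    x_names = set(x_names)
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    chrom_class = {
        name: (X_CHROM if name in x_names else AUTOSOME) for name in seqs
    }
    return Genome(seqs=seqs, chrom_class=chrom_class)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.seqs:
            fh.write(f">{name}\n")
            seq = genome.seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> List[TranscriptModel]:
    """Parse exon features of a GTF into transcript models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Recognised attributes: ``gene_id``, ``transcript_id``, ``biotype``
    (default ``unknown``) and ``cov`` (mean read coverage, default 0).
    """
    per_tx: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            if not tid:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            gid = attrs.get("gene_id", tid)
            entry = per_tx.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": attrs.get("biotype", "unknown"),
                    "cov": float(attrs["cov"]) if "cov" in attrs else 0.0,
                },
            )
            if tid not in order:
                order.append(tid)
            entry["exons"].append((start_i - 1, end_i))
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=per_tx[tid]["gene_id"],
            chrom=per_tx[tid]["chrom"],
            strand=per_tx[tid]["strand"],
            exons=per_tx[tid]["exons"],
            biotype=per_tx[tid]["biotype"],
            read_coverage=per_tx[tid]["cov"],
        )
        for tid in order
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as exon features (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}"; cov "{t.read_coverage:g}";'
                )
                fh.write(
                    f"{t.chrom}\tgsc_ncrna\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# split-alignment TSV
# ---------------------------------------------------------------------------

_SPLIT_HEADER = [
    "read_id",
    "sample_id",
    "chrom",
    "strand",
    "seg1_start",
    "seg1_end",
    "seg2_start",
    "seg2_end",
]


def read_split_alignments(path) -> List[SplitAlignment]:
    """Read the split-alignment TSV in file order; no filtering is applied."""
    out: List[SplitAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SPLIT_HEADER:
            raise FormatError(f"{path}: unexpected split-alignment header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns")
            read_id, sample_id, chrom, strand = fields[:4]
            try:
                s1s, s1e, s2s, s2e = (int(x) for x in fields[4:])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            chrom1, _, chrom2 = chrom.partition(",")
            chrom2 = chrom2 or chrom1
            try:
                aln = SplitAlignment(
                    read_id=read_id,
                    sample_id=sample_id,
                    chrom1=chrom1,
                    chrom2=chrom2,
                    strand=strand,
                    seg1=(s1s, s1e),
                    seg2=(s2s, s2e),
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(aln)
    return out


def write_split_alignments(alignments: Sequence[SplitAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SPLIT_HEADER) + "\n")
        for a in alignments:
            chrom = a.chrom1 if a.chrom1 == a.chrom2 else f"{a.chrom1},{a.chrom2}"
            fh.write(
                f"{a.read_id}\t{a.sample_id}\t{chrom}\t{a.strand}\t"
                f"{a.seg1[0]}\t{a.seg1[1]}\t{a.seg2[0]}\t{a.seg2[1]}\n"
            )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate transcript ids")
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def write_edge_list(edges: Iterable, path) -> None:
    """Write a Cytoscape-loadable edge TSV, sorted by (source, target).

    Accepts any iterable of objects/tuples exposing source, target, weight and
    sign (dataclasses use their first four fields).
    """
    rows = []
    for edge in edges:
        if all(hasattr(edge, a) for a in ("source", "target", "weight", "sign")):
            vals = (edge.source, edge.target, edge.weight, edge.sign)
        elif dataclasses.is_dataclass(edge):
            vals = dataclasses.astuple(edge)[:4]
        else:
            vals = tuple(edge)[:4]
        source, target, weight, sign = vals
        rows.append((str(source), str(target), float(weight), str(sign)))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tsign\n")
        for source, target, weight, sign in rows:
            fh.write(f"{source}\t{target}\t{weight:.6f}\t{sign}\n")
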