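"""Backsplice (circRNA) junction calling from split-read alignments.

The caller consumes alignments in which each read contributed two exact-match
genomic segments (seg1 = 5' part of the read, seg2 = 3' part).  Stages:

1. :func:`dedup_alignments`   — collapse PCR duplicates.
2. :func:`detect_candidates`  — reversed-dual-segment rule with a 100 kb
   outer-span cutoff; identical raw junctions merge with read support.
3. :func:`refine_splice_sites` — coupled GT/AG window search (+/- 10 nt) that
   snaps raw breakpoints onto the true splice sites or rejects the candidate.
4. :func:`annotate_circrnas`  — hosting gene assignment, exonic/intronic/
   intergenic classes, first/last-exon usage and strand relation.
5. :func:`summarize_circ_stats` — class/strand/terminal-exon tallies.

Coordinates follow the package convention: a junction is the half-open
interval [acceptor_pos, donor_pos) on the reference; on the plus strand the
donor GT sits at genome[donor_pos:donor_pos+2] and the acceptor AG at
genome[acceptor_pos-2:acceptor_pos]; minus-strand junctions show the
reverse-complement motifs ("AC" left of the acceptor boundary, "CT" right of
the donor boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import FormatError
from .io_formats import Genome, SplitAlignment, TranscriptModel

MAX_SPAN_BP = 100_000
MOTIF_WINDOW = 10


@dataclass(frozen=True)
class RawJunction:
    """Unrefined candidate: raw acceptor = seg2_start, raw donor = seg1_end."""

    chrom: str
    strand: str
    acceptor: int
    donor: int
    support: int


@dataclass(frozen=True)
class BackspliceJunction:
    chrom: str
    strand: str
    acceptor_pos: int  # circle 5' boundary (leftmost, 0-based start)
    donor_pos: int  # circle 3' boundary (rightmost, 0-based exclusive end)
    motif: str  # donor dinucleotide + acceptor dinucleotide, strand-oriented
    support: int
    shift_applied: int

    def __post_init__(self) -> None:
        if not self.acceptor_pos < self.donor_pos:
            raise FormatError("junction requires acceptor_pos < donor_pos")
        if self.donor_pos - self.acceptor_pos > MAX_SPAN_BP:
            raise FormatError("junction span exceeds 100 kb")


@dataclass
class CircRNARecord:
    junction: BackspliceJunction
    hosting_gene_id: Optional[str] = None
    circ_class: str = "intergenic"  # exonic | intronic | intergenic
    uses_first_exon: bool = False
    uses_last_exon: bool = False
    derived_strand_relation: Optional[str] = None  # sense | antisense | None


# ---------------------------------------------------------------------------
# stage 1: PCR-duplicate removal
# ---------------------------------------------------------------------------

def dedup_alignments(alignments: Sequence[SplitAlignment]) -> List[SplitAlignment]:
    """Collapse rows identical in (sample_id, chroms, strand, seg1, seg2).

    The read_id is ignored in the key; the first occurrence is kept.
    """
    seen = set()
    out: List[SplitAlignment] = []
    for a in alignments:
        key = (a.sample_id, a.chrom1, a.chrom2, a.strand, a.seg1, a.seg2)
        if key in seen:
            continue
        seen.add(key)
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# stage 2: reversed-dual-segment candidates
# ---------------------------------------------------------------------------

def detect_candidates(alignments: Sequence[SplitAlignment]) -> List[RawJunction]:
    """Emit raw junctions from reads whose segments map in reversed order.

    A candidate requires: both segments on one chromosome and strand, the 3'
    read segment genomically upstream of the 5' one (seg2_end <= seg1_start),
    and an outer span seg1_end - seg2_start of at most 100 kb.  Identical raw
    junctions merge, accumulating read support.  Output is sorted by genomic
    position for determinism.
    """
    tally: Dict[Tuple[str, str, int, int], int] = {}
    for a in alignments:
        if a.chrom1 != a.chrom2:
            continue
        seg1_start, seg1_end = a.seg1
        seg2_start, seg2_end = a.seg2
        if seg2_end > seg1_start:  # genomic order or overlapping: linear read
            continue
        if seg1_end - seg2_start > MAX_SPAN_BP:
            continue
        key = (a.chrom1, a.strand, seg2_start, seg1_end)
        tally[key] = tally.get(key, 0) + 1
    return [
        RawJunction(chrom=c, strand=st, acceptor=acc, donor=don, support=n)
        for (c, st, acc, don), n in sorted(tally.items())
    ]


# ---------------------------------------------------------------------------
# stage 3: GT/AG refinement
# ---------------------------------------------------------------------------

def _shift_candidates(window: int) -> List[int]:
    """Shifts ordered by preference: smallest |shift|, 0 first, then negative."""
    order = [0]
    for mag in range(1, window + 1):
        order.extend((-mag, mag))
    return order


def _motif_at(genome: Genome, chrom: str, acceptor: int, donor: int, strand: str) -> bool:
    if strand == "+":
        return (
            genome.fetch(chrom, donor, donor + 2) == "GT"
            and genome.fetch(chrom, acceptor - 2, acceptor) == "AG"
        )
    return (
        genome.fetch(chrom, acceptor - 2, acceptor) == "AC"
        and genome.fetch(chrom, donor, donor + 2) == "CT"
    )


def refine_splice_sites(
    raw: RawJunction, genome: Genome, window: int = MOTIF_WINDOW
) -> Optional[BackspliceJunction]:
    """Snap a raw junction onto the nearest GT/AG pair, or reject it.

    Both breakpoints carry the same alignment-ambiguity offset, so the donor
    and acceptor shifts are coupled (one shared delta in [-window, +window]).
    Preference among valid deltas: smallest magnitude, exact zero first, then
    the negative one.  Windows that leave the chromosome count as no-hit.
    """
    if raw.chrom not in genome:
        return None
    for delta in _shift_candidates(window):
        acc = raw.acceptor + delta
        don = raw.donor + delta
        if acc < 2 or not acc < don:
            continue
        if don - acc > MAX_SPAN_BP:
            continue
        if _motif_at(genome, raw.chrom, acc, don, raw.strand):
            return BackspliceJunction(
                chrom=raw.chrom,
                strand=raw.strand,
                acceptor_pos=acc,
                donor_pos=don,
                motif="GTAG",
                support=raw.support,
                shift_applied=delta,
            )
    return None


def call_junctions(
    alignments: Sequence[SplitAlignment],
    genome: Genome,
    min_support: int = 1,
    window: int = MOTIF_WINDOW,
) -> List[BackspliceJunction]:
    """dedup -> detect -> refine; merge junctions that refine to one site."""
    refined: Dict[Tuple[str, str, int, int], BackspliceJunction] = {}
    for raw in detect_candidates(dedup_alignments(alignments)):
        junc = refine_splice_sites(raw, genome, window=window)
        if junc is None:
            continue
        key = (junc.chrom, junc.strand, junc.acceptor_pos, junc.donor_pos)
        prev = refined.get(key)
        if prev is not None:
            junc = BackspliceJunction(
                chrom=junc.chrom,
                strand=junc.strand,
                acceptor_pos=junc.acceptor_pos,
                donor_pos=junc.donor_pos,
                motif=junc.motif,
                support=prev.support + junc.support,
                shift_applied=min(
                    prev.shift_applied, junc.shift_applied, key=abs
                ),
            )
        refined[key] = junc
    return [
        j for _, j in sorted(refined.items()) if j.support >= min_support
    ]


# ---------------------------------------------------------------------------
# stage 4: annotation against gene models
# ---------------------------------------------------------------------------

def _gene_spans(
    annotation: Sequence[TranscriptModel],
) -> Dict[str, Tuple[str, str, int, int]]:
    """gene_id -> (chrom, strand, span_start, span_end) over all transcripts."""
    spans: Dict[str, Tuple[str, str, int, int]] = {}
    for t in annotation:
        cur = spans.get(t.gene_id)
        if cur is None:
            spans[t.gene_id] = (t.chrom, t.strand, t.start, t.end)
        else:
            chrom, strand, s, e = cur
            spans[t.gene_id] = (chrom, strand, min(s, t.start), max(e, t.end))
    return spans


def _terminal_exon_usage(
    junc: BackspliceJunction, t: TranscriptModel
) -> Optional[Tuple[bool, bool]]:
    """(uses_first_exon, uses_last_exon) in transcript orientation, or None
    when the junction boundaries do not both sit on exon edges of ``t``."""
    starts = {s for s, _ in t.exons}
    ends = {e for _, e in t.exons}
    if junc.acceptor_pos not in starts or junc.donor_pos not in ends:
        return None
    if t.strand == "+":
        uses_first = junc.acceptor_pos == t.exons[0][0]
        uses_last = junc.donor_pos == t.exons[-1][1]
    else:
        uses_first = junc.donor_pos == t.exons[-1][1]
        uses_last = junc.acceptor_pos == t.exons[0][0]
    return uses_first, uses_last


def annotate_circrnas(
    junctions: Sequence[BackspliceJunction],
    annotation: Sequence[TranscriptModel],
) -> List[CircRNARecord]:
    """Assign hosting genes and classes to refined junctions.

    Hosting gene: the gene whose span contains the junction interval; ties go
    to the largest reciprocal overlap, then lexicographic gene_id.  Class is
    exonic when both boundaries coincide with exon boundaries of one
    transcript of the host, intronic when the interval lies wholly inside one
    intron, intergenic when no gene hosts the junction.
    """
    spans = _gene_spans(annotation)
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in annotation:
        by_gene.setdefault(t.gene_id, []).append(t)

    records: List[CircRNARecord] = []
    for junc in junctions:
        length = junc.donor_pos - junc.acceptor_pos
        best: Optional[Tuple[float, str]] = None
        for gid, (chrom, _strand, gs, ge) in spans.items():
            if chrom != junc.chrom:
                continue
            if gs <= junc.acceptor_pos and junc.donor_pos <= ge:
                # containment => overlap = junction length; reciprocal overlap
                # = length / gene span (junction side is 1 for every host)
                recip = length / (ge - gs)
                key = (-recip, gid)
                if best is None or key < best:
                    best = key
        rec = CircRNARecord(junction=junc)
        if best is not None:
            gid = best[1]
            rec.hosting_gene_id = gid
            _, gstrand, _, _ = spans[gid]
            rec.derived_strand_relation = (
                "sense" if junc.strand == gstrand else "antisense"
            )
            rec.circ_class = "intergenic"
            for t in sorted(by_gene[gid], key=lambda t: t.transcript_id):
                usage = _terminal_exon_usage(junc, t)
                if usage is not None:
                    rec.circ_class = "exonic"
                    rec.uses_first_exon, rec.uses_last_exon = usage
                    break
            if rec.circ_class != "exonic":
                for t in by_gene[gid]:
                    for is_, ie in t.introns():
                        if is_ <= junc.acceptor_pos and junc.donor_pos <= ie:
                            rec.circ_class = "intronic"
                            break
                    if rec.circ_class == "intronic":
                        break
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# stage 5: summary statistics
# ---------------------------------------------------------------------------

def summarize_circ_stats(records: Sequence[CircRNARecord]) -> Dict[str, object]:
    """Counts and percentages over a circRNA record set.

    Percentages are plain ``count / total * 100`` floats; callers round to
    the precision they need.  An empty input sets ``undefined_fractions``.
    """
    n = len(records)
    n_exonic = sum(1 for r in records if r.circ_class == "exonic")
    n_intronic = sum(1 for r in records if r.circ_class == "intronic")
    n_intergenic = sum(1 for r in records if r.circ_class == "intergenic")
    n_sense = sum(1 for r in records if r.derived_strand_relation == "sense")
    n_antisense = sum(
        1 for r in records if r.derived_strand_relation == "antisense"
    )
    n_missed = sum(
        1 for r in records if not (r.uses_first_exon or r.uses_last_exon)
    )
    n_hosts = len(
        {r.hosting_gene_id for r in records if r.hosting_gene_id is not None}
    )
    summary: Dict[str, object] = {
        "n_total": n,
        "n_exonic": n_exonic,
        "n_intronic": n_intronic,
        "n_intergenic": n_intergenic,
        "n_sense": n_sense,
        "n_antisense": n_antisense,
        "n_missed_first_or_last": n_missed,
        "n_hosting_genes": n_hosts,
        "undefined_fractions": n == 0,
    }
    if n:
        summary["pct_sense"] = 100.0 * n_sense / n
        summary["pct_antisense"] = 100.0 * n_antisense / n
        summary["pct_missed_first_or_last"] = 100.0 * n_missed / n
    else:
        summary["pct_sense"] = summary["pct_antisense"] = None
        summary["pct_missed_first_or_last"] = None
    return summary


def extract_circ_sequence(
    record: CircRNARecord,
    annotation: Sequence[TranscriptModel],
    genome: Genome,
) -> Optional[str]:
    """Spliced circle sequence (transcript orientation) for an exonic record.

    Uses the first transcript of the hosting gene whose exon boundaries match
    both junction ends; returns None for non-exonic records.
    """
    if record.circ_class != "exonic" or record.hosting_gene_id is None:
        return None
    junc = record.junction
    for t in sorted(
        (t for t in annotation if t.gene_id == record.hosting_gene_id),
        key=lambda t: t.transcript_id,
    ):
        if _terminal_exon_usage(junc, t) is None:
            continue
        circ_exons = [
            (s, e)
            for s, e in t.exons
            if junc.acceptor_pos <= s and e <= junc.donor_pos
        ]
        seq = "".join(genome.fetch(t.chrom, s, e) or "" for s, e in circ_exons)
        from .io_formats import revcomp

        return seq if t.strand == "+" else revcomp(seq)
    return None


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def circ_records_to_rows(records: Sequence[CircRNARecord]) -> List[dict]:
    rows = []
    for r in records:
        j = r.junction
        rows.append(
            {
                "chrom": j.chrom,
                "start": j.acceptor_pos,
                "end": j.donor_pos,
                "strand": j.strand,
                "motif": j.motif,
                "support": j.support,
                "shift": j.shift_applied,
                "hosting_gene": r.hosting_gene_id or ".",
                "circ_class": r.circ_class,
                "uses_first_exon": int(r.uses_first_exon),
                "uses_last_exon": int(r.uses_last_exon),
                "strand_relation": r.derived_strand_relation or ".",
            }
        )
    return rows
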