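"""Multi-step lncRNA identification cascade and positional classification.

Cascade order (first failing rule is recorded as the reject reason):

1. structure      — monoexonic OR spliced length < 200 bp
2. evidence       — read coverage < 3 OR FPKM < 0.01 in every library
3. known match    — intron chain congruent with a known lncRNA => known;
                    >= 1 bp same-strand overlap with a housekeeping RNA
                    (rRNA/tRNA/snRNA/snoRNA/pre-miRNA/pseudogene) => reject;
                    intron chain congruent with a known mRNA => reject
4. coding score   — two intersected ORF rules (longest forward-frame ORF
                    >= 300 bp; ORF fraction >= 0.5); a transcript is kept as
                    noncoding only when BOTH rules call it noncoding

Survivors are classified positionally against coding gene models as sense,
antisense, bidirectional (divergent 5' ends within a configurable window on
the opposite strand) or intergenic, with that precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import ConfigError
from .io_formats import (
    HOUSEKEEPING_BIOTYPES,
    Genome,
    TranscriptModel,
)

MIN_LENGTH_BP = 200
MIN_COVERAGE = 3.0
MIN_FPKM = 0.01
ORF_LENGTH_CODING_BP = 300
ORF_FRACTION_CODING = 0.5
BIDIRECTIONAL_WINDOW_BP = 1000

REJECT_REASONS = (
    "short_or_monoexonic",
    "low_coverage",
    "low_fpkm",
    "housekeeping_overlap",
    "mrna_match",
    "coding_potential",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptVerdict:
    transcript_id: str
    status: str  # rejected | known_lncRNA | novel_lncRNA
    reject_reason: Optional[str] = None
    positional_class: Optional[str] = None
    max_orf_bp: Optional[int] = None
    orf_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.status == "rejected") != (self.reject_reason is not None):
            raise ValueError("reject_reason must be set iff status is rejected")


# ---------------------------------------------------------------------------
# step 1-2: structure and evidence filters
# ---------------------------------------------------------------------------

def _max_fpkm(fpkm, transcript_id: str) -> float:
    if isinstance(fpkm, pd.DataFrame):
        if transcript_id not in fpkm.index:
            raise ConfigError(f"no FPKM for transcript {transcript_id}")
        return float(fpkm.loc[transcript_id].max())
    try:
        return float(fpkm[transcript_id])
    except KeyError as exc:
        raise ConfigError(f"no FPKM for transcript {transcript_id}") from exc


def filter_structure(
    transcripts: Sequence[TranscriptModel],
    fpkm,
    min_length_bp: int = MIN_LENGTH_BP,
    min_coverage: float = MIN_COVERAGE,
    min_fpkm: float = MIN_FPKM,
) -> Dict[str, Optional[str]]:
    """Apply the structure and evidence filters.

    Returns transcript_id -> reject reason (or None for survivors).  ``fpkm``
    is a transcripts x libraries DataFrame or a mapping to the per-transcript
    maximum FPKM over libraries; a transcript is FPKM-rejected only when its
    maximum over all libraries is below the cutoff.
    """
    out: Dict[str, Optional[str]] = {}
    for t in transcripts:
        if t.n_exons == 1 or t.spliced_length < min_length_bp:
            out[t.transcript_id] = "short_or_monoexonic"
        elif t.read_coverage < min_coverage:
            out[t.transcript_id] = "low_coverage"
        elif _max_fpkm(fpkm, t.transcript_id) < min_fpkm:
            out[t.transcript_id] = "low_fpkm"
        else:
            out[t.transcript_id] = None
    return out


# ---------------------------------------------------------------------------
# step 3: known-transcript matching
# ---------------------------------------------------------------------------

def _exon_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    if a.chrom != b.chrom:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def match_known(
    transcripts: Sequence[TranscriptModel],
    known_db: Sequence[TranscriptModel],
) -> Dict[str, Optional[str]]:
    """Match candidates against a reference annotation.

    Returns transcript_id -> one of ``"known_lncRNA"``,
    ``"housekeeping_overlap"``, ``"mrna_match"`` or None (still a candidate).
    Splice-site congruence means an identical ordered intron chain on the same
    chromosome and strand; monoexonic entries have an empty chain and never
    match.
    """
    lnc_chains = set()
    mrna_chains = set()
    housekeeping: List[TranscriptModel] = []
    for k in known_db:
        chain = k.intron_chain()
        if k.biotype == "known_lncRNA" and chain:
            lnc_chains.add((k.chrom, k.strand, chain))
        elif k.biotype == "coding" and chain:
            mrna_chains.add((k.chrom, k.strand, chain))
        elif k.biotype in HOUSEKEEPING_BIOTYPES:
            housekeeping.append(k)

    out: Dict[str, Optional[str]] = {}
    for t in transcripts:
        key = (t.chrom, t.strand, t.intron_chain())
        if t.intron_chain() and key in lnc_chains:
            out[t.transcript_id] = "known_lncRNA"
            continue
        hk_hit = any(
            h.strand == t.strand and _exon_overlap_bp(t, h) >= 1
            for h in housekeeping
        )
        if hk_hit:
            out[t.transcript_id] = "housekeeping_overlap"
            continue
        if t.intron_chain() and key in mrna_chains:
            out[t.transcript_id] = "mrna_match"
            continue
        out[t.transcript_id] = None
    return out


# ---------------------------------------------------------------------------
# step 4: coding-potential stand-in
# ---------------------------------------------------------------------------

def coding_potential(transcript_seq: str) -> Tuple[int, float, bool]:
    """Longest forward-frame ORF statistics and a two-rule coding call.

    The longest ATG..stop ORF across the three forward frames is measured in
    bp including the stop codon.  The transcript is coding when the ORF is at
    least 300 bp *or* covers at least half the transcript; i.e. it is kept as
    noncoding only when both rules agree.  Codons containing non-ACGT
    characters never start or stop an ORF.
    """
    seq = transcript_seq.upper()
    n = len(seq)
    best = 0
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    fraction = best / n if n else 0.0
    is_coding = best >= ORF_LENGTH_CODING_BP or fraction >= ORF_FRACTION_CODING
    return best, fraction, is_coding


# ---------------------------------------------------------------------------
# positional classification
# ---------------------------------------------------------------------------

def classify_position(
    transcript: TranscriptModel,
    coding_annotation: Sequence[TranscriptModel],
    bidirectional_window: int = BIDIRECTIONAL_WINDOW_BP,
) -> str:
    """Classify a surviving lncRNA relative to coding gene models.

    Precedence: sense (exon overlap, same strand) > antisense (exon overlap,
    opposite strand) > bidirectional (no overlap, 5' ends within the window on
    opposite strands) > intergenic.
    """
    sense = antisense = bidirectional = False
    for c in coding_annotation:
        if c.chrom != transcript.chrom:
            continue
        if _exon_overlap_bp(transcript, c) >= 1:
            if c.strand == transcript.strand:
                sense = True
            else:
                antisense = True
        elif (
            c.strand != transcript.strand
            and abs(c.tss - transcript.tss) <= bidirectional_window
        ):
            bidirectional = True
    if sense:
        return "sense"
    if antisense:
        return "antisense"
    if bidirectional:
        return "bidirectional"
    return "intergenic"


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    transcripts: Sequence[TranscriptModel],
    genome: Genome,
    known_db: Sequence[TranscriptModel],
    fpkm,
    bidirectional_window: int = BIDIRECTIONAL_WINDOW_BP,
    min_length_bp: int = MIN_LENGTH_BP,
    min_coverage: float = MIN_COVERAGE,
    min_fpkm: float = MIN_FPKM,
) -> List[TranscriptVerdict]:
    """Apply the full cascade; verdict order follows the input order.

    ``known_db`` supplies known lncRNAs, housekeeping RNAs and known mRNAs
    (biotype ``coding``); its coding entries double as the annotation for the
    positional classification of survivors.
    """
    structural = filter_structure(
        transcripts, fpkm,
        min_length_bp=min_length_bp,
        min_coverage=min_coverage,
        min_fpkm=min_fpkm,
    )
    survivors = [t for t in transcripts if structural[t.transcript_id] is None]
    matches = match_known(survivors, known_db)
    coding_models = [k for k in known_db if k.biotype == "coding"]

    verdicts: List[TranscriptVerdict] = []
    for t in transcripts:
        reason = structural[t.transcript_id]
        if reason is not None:
            verdicts.append(
                TranscriptVerdict(t.transcript_id, "rejected", reject_reason=reason)
            )
            continue
        match = matches[t.transcript_id]
        if match == "known_lncRNA":
            verdicts.append(
                TranscriptVerdict(
                    t.transcript_id,
                    "known_lncRNA",
                    positional_class=classify_position(
                        t, coding_models, bidirectional_window
                    ),
                )
            )
            continue
        if match in ("housekeeping_overlap", "mrna_match"):
            verdicts.append(
                TranscriptVerdict(t.transcript_id, "rejected", reject_reason=match)
            )
            continue
        orf_bp, orf_frac, is_coding = coding_potential(t.sequence(genome))
        if is_coding:
            verdicts.append(
                TranscriptVerdict(
                    t.transcript_id,
                    "rejected",
                    reject_reason="coding_potential",
                    max_orf_bp=orf_bp,
                    orf_fraction=orf_frac,
                )
            )
            continue
        verdicts.append(
            TranscriptVerdict(
                t.transcript_id,
                "novel_lncRNA",
                positional_class=classify_position(
                    t, coding_models, bidirectional_window
                ),
                max_orf_bp=orf_bp,
                orf_fraction=orf_frac,
            )
        )
    return verdicts


def summarize_lncrnas(
    verdicts: Sequence[TranscriptVerdict],
    transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> Dict[str, object]:
    """Counts per status/reason/positional class, plus novel-lncRNA means."""
    by_status: Dict[str, int] = {
        "rejected": 0,
        "known_lncRNA": 0,
        "novel_lncRNA": 0,
    }
    by_reason: Dict[str, int] = {r: 0 for r in REJECT_REASONS}
    by_class: Dict[str, int] = {
        "sense": 0,
        "antisense": 0,
        "bidirectional": 0,
        "intergenic": 0,
    }
    for v in verdicts:
        by_status[v.status] += 1
        if v.reject_reason:
            by_reason[v.reject_reason] += 1
        if v.positional_class:
            by_class[v.positional_class] += 1

    summary: Dict[str, object] = {
        "by_status": by_status,
        "by_reject_reason": by_reason,
        "by_positional_class": by_class,
    }
    novel_orfs = [
        v.max_orf_bp
        for v in verdicts
        if v.status == "novel_lncRNA" and v.max_orf_bp is not None
    ]
    summary["mean_novel_orf_bp"] = (
        sum(novel_orfs) / len(novel_orfs) if novel_orfs else None
    )
    if transcripts is not None:
        models = {t.transcript_id: t for t in transcripts}
        by_chrom: Dict[str, int] = {}
        lengths = []
        for v in verdicts:
            if v.status == "rejected":
                continue
            t = models.get(v.transcript_id)
            if t is None:
                continue
            by_chrom[t.chrom] = by_chrom.get(t.chrom, 0) + 1
            if v.status == "novel_lncRNA":
                lengths.append(t.spliced_length)
        summary["lncrnas_by_chrom"] = dict(sorted(by_chrom.items()))
        summary["mean_novel_length_bp"] = (
            sum(lengths) / len(lengths) if lengths else None
        )
    return summary
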