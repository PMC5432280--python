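"""Seeded synthetic data with planted ground truth for every pipeline stage.

The generator emits a small multi-chromosome genome (autosomes + optional X),
a reference annotation (coding genes, known lncRNAs, housekeeping RNAs), an
"assembled" annotation (everything the cascade sees, including junk destined
for each reject reason), split-read alignments supporting planted backsplice
junctions plus decoys, an NB count matrix with planted sex-biased /
co-expressed / ceRNA structure, and miRNAs whose seed sites are written into
the planted sponge and target sequences (background occurrences scrubbed).

Construction guarantees, relied on by the acceptance tests:

* every intron starts GT and ends AG on the template strand;
* planted circRNA junctions use internal exons except a configurable count
  on the first exon, and their boundaries carry the backsplice motif;
* planted lncRNA sequences are noncoding under the two-rule ORF score and
  coding transcripts carry a planted ORF that satisfies it;
* with a fixed seed every artifact is byte-identical across runs (separate
  deterministic random streams per stage keep the stage functions
  independently callable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import ExpressionTable
from .io_formats import Genome, SplitAlignment, TranscriptModel, revcomp
from .lncrna_pipeline import coding_potential
from .networks import MiRNA

MIN_SEGMENT_LEN = 20
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
#: 12-mer with a stop codon in every forward frame and no ATG
STOP_CASSETTE = "ATAAATAAATAA"


# ---------------------------------------------------------------------------
# configuration & truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 1
    n_autosomes: int = 2
    include_X: bool = True
    chrom_length_bp: int = 400_000
    n_coding_genes: int = 30
    n_lnc_per_class: int = 3
    n_circ_junctions: int = 10
    n_circ_first_exon: int = 0
    n_housekeeping: int = 4
    frac_lnc_known: float = 0.25
    n_libraries_per_condition: int = 3
    nb_dispersion: float = 0.1
    fold_change_planted: float = 4.0
    frac_male_biased: float = 0.1
    frac_female_biased: float = 0.1
    frac_male_biased_on_X: float = 0.05
    frac_female_biased_on_X: float = 0.5
    read_len: int = 100
    circ_read_depth: int = 5
    pcr_dup_rate: float = 0.0
    breakpoint_jitter: int = 0
    n_decoy_linear: int = 20
    n_decoy_interchrom: int = 5
    n_coexpressed_pairs: int = 3
    n_cerna_triples: int = 2
    n_mirnas: int = 4
    base_log_mean: float = 4.0
    base_log_sigma: float = 1.0
    coexpr_dispersion: float = 5e-4
    coexpr_base_mean: float = 4000.0

    def validate(self) -> None:
        ints = dict(
            n_autosomes=self.n_autosomes,
            chrom_length_bp=self.chrom_length_bp,
            n_coding_genes=self.n_coding_genes,
            n_lnc_per_class=self.n_lnc_per_class,
            n_circ_junctions=self.n_circ_junctions,
            n_circ_first_exon=self.n_circ_first_exon,
            n_housekeeping=self.n_housekeeping,
            n_libraries_per_condition=self.n_libraries_per_condition,
            read_len=self.read_len,
            circ_read_depth=self.circ_read_depth,
            n_mirnas=self.n_mirnas,
        )
        for name, val in ints.items():
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name, val in dict(
            frac_lnc_known=self.frac_lnc_known,
            frac_male_biased=self.frac_male_biased,
            frac_female_biased=self.frac_female_biased,
            frac_male_biased_on_X=self.frac_male_biased_on_X,
            frac_female_biased_on_X=self.frac_female_biased_on_X,
            pcr_dup_rate=self.pcr_dup_rate,
        ).items():
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.coexpr_dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.fold_change_planted <= 0:
            raise ConfigError("fold_change_planted must be positive")
        if self.read_len < 2 * MIN_SEGMENT_LEN:
            raise ConfigError(
                f"read_len must be >= {2 * MIN_SEGMENT_LEN} "
                "(two exact-match segments of >= 20 bp)"
            )
        if self.n_circ_first_exon > self.n_circ_junctions:
            raise ConfigError("n_circ_first_exon exceeds n_circ_junctions")
        needed = self.n_circ_junctions + 3 * self.n_lnc_per_class
        if self.n_coding_genes < needed:
            raise ConfigError(
                f"n_coding_genes={self.n_coding_genes} too small: need "
                f">= {needed} (circ hosts + lncRNA companions)"
            )
        if self.n_cerna_triples and self.n_mirnas < self.n_cerna_triples:
            raise ConfigError("need at least one miRNA per ceRNA triple")
        if self._n_circ_sponges() and self.n_circ_junctions < 1:
            raise ConfigError("ceRNA circRNA sponge needs n_circ_junctions >= 1")
        if self.n_cerna_triples and self.n_lnc_per_class < 1:
            raise ConfigError("ceRNA lncRNA sponges need intergenic lncRNAs")

    def _n_circ_sponges(self) -> int:
        return sum(1 for i in range(self.n_cerna_triples) if i % 2 == 1)

    def libraries(self) -> Dict[str, str]:
        libs: Dict[str, str] = {}
        for cond in ("SSC", "FGSC"):
            for i in range(1, self.n_libraries_per_condition + 1):
                libs[f"{cond}_{i}"] = cond
        return libs


@dataclass
class PlantedTruth:
    """Ground truth for the planted structures (ids resolve in the emitted
    annotation; junction motifs hold by construction)."""

    circ_junctions: List[dict] = field(default_factory=list)
    sex_biased: Dict[str, str] = field(default_factory=dict)
    coexpressed_pairs: List[dict] = field(default_factory=list)
    cerna_triples: List[dict] = field(default_factory=list)
    lnc_classes: Dict[str, str] = field(default_factory=dict)
    known_lnc_ids: List[str] = field(default_factory=list)
    novel_lnc_ids: List[str] = field(default_factory=list)
    coding_ids: List[str] = field(default_factory=list)
    housekeeping_ids: List[str] = field(default_factory=list)
    junk_ids: Dict[str, str] = field(default_factory=dict)  # id -> expected reason
    mirnas: Dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Genome
    known_transcripts: List[TranscriptModel]
    assembled_transcripts: List[TranscriptModel]
    truth: PlantedTruth
    mirnas: List[MiRNA]


# ---------------------------------------------------------------------------
# low-level sequence helpers
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _seq_without(rng: np.random.Generator, n: int, forbidden: Sequence[str]) -> str:
    """Random sequence containing none of the forbidden substrings."""
    seq = list(_random_seq(rng, n))
    for _ in range(200):
        text = "".join(seq)
        hit = None
        for motif in forbidden:
            idx = text.find(motif)
            if idx >= 0 and (hit is None or idx < hit[0]):
                hit = (idx, motif)
        if hit is None:
            return text
        idx, motif = hit
        pos = idx + len(motif) // 2
        current = seq[pos]
        choices = [b for b in _BASES if b != current]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    raise ConfigError("could not scrub forbidden motifs from random sequence")


def _orf_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _tx_positions(exons: Sequence[Tuple[int, int]], strand: str) -> List[int]:
    """Genomic position of every transcript base, 5'->3'."""
    pos: List[int] = []
    for s, e in exons:
        pos.extend(range(s, e))
    if strand == "-":
        pos.reverse()
    return pos


class _ChromBuffer:
    """Mutable chromosome with a protected-position set."""

    def __init__(self, name: str, seq: str) -> None:
        self.name = name
        self.buf = bytearray(seq, "ascii")
        self.protected: Set[int] = set()

    def write(self, start: int, text: str, protect: bool = False) -> None:
        if start < 0 or start + len(text) > len(self.buf):
            raise ConfigError(f"write outside chromosome {self.name}")
        self.buf[start : start + len(text)] = text.encode("ascii")
        if protect:
            self.protected.update(range(start, start + len(text)))

    def protect(self, start: int, end: int) -> None:
        self.protected.update(range(start, end))

    def __str__(self) -> str:
        return self.buf.decode("ascii")


@dataclass
class _GeneInfo:
    transcript: TranscriptModel
    orf_tx_start: Optional[int] = None  # spliced coords, None for noncoding
    orf_tx_end: Optional[int] = None
    role: str = "plain"


class _Builder:
    """Stateful genome/annotation constructor (single use)."""

    def __init__(self, config: SimulationConfig) -> None:
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng([config.seed, 101])
        self.chroms: Dict[str, _ChromBuffer] = {}
        self.cursors: Dict[str, int] = {}
        self.genes: Dict[str, _GeneInfo] = {}
        self.lncs: Dict[str, TranscriptModel] = {}
        self.known: List[TranscriptModel] = []
        self.assembled: List[TranscriptModel] = []
        self.truth = PlantedTruth()
        self.mirnas: List[MiRNA] = []

    # -- genome scaffold ---------------------------------------------------
    def _init_chroms(self) -> None:
        names = [f"chr{i + 1}" for i in range(self.cfg.n_autosomes)]
        if self.cfg.include_X:
            names.append("chrX")
        for name in names:
            self.chroms[name] = _ChromBuffer(
                name, _random_seq(self.rng, self.cfg.chrom_length_bp)
            )
            self.cursors[name] = 2000

    def _alloc(self, chrom: str, width: int) -> int:
        """Reserve `width` bp on `chrom` after a random spacing gap."""
        gap = int(self.rng.integers(3000, 5000))
        start = self.cursors[chrom] + gap
        if start + width > self.cfg.chrom_length_bp - 1000:
            raise ConfigError(
                f"chromosome {chrom} too short for requested gene count"
            )
        self.cursors[chrom] = start + width
        return start

    # -- transcript sequence plumbing ---------------------------------------
    def _write_tx(self, t: TranscriptModel, spliced: str) -> None:
        buf = self.chroms[t.chrom]
        genomic = spliced if t.strand == "+" else revcomp(spliced)
        offset = 0
        for s, e in t.exons:
            buf.write(s, genomic[offset : offset + (e - s)])
            offset += e - s

    def _read_tx(self, t: TranscriptModel) -> str:
        buf = self.chroms[t.chrom]
        parts = [str(buf)[s:e] for s, e in t.exons]
        seq = "".join(parts)
        return seq if t.strand == "+" else revcomp(seq)

    def _write_tx_base(self, t: TranscriptModel, tpos: int, base: str) -> None:
        gpos = _tx_positions(t.exons, t.strand)[tpos]
        buf = self.chroms[t.chrom]
        buf.write(gpos, base if t.strand == "+" else revcomp(base))

    def _tx_base_editable(self, t: TranscriptModel, tpos: int) -> bool:
        gpos = _tx_positions(t.exons, t.strand)[tpos]
        return gpos not in self.chroms[t.chrom].protected

    def _write_introns(self, t: TranscriptModel) -> None:
        buf = self.chroms[t.chrom]
        for is_, ie in t.introns():
            if t.strand == "+":
                buf.write(is_, "GT", protect=True)
                buf.write(ie - 2, "AG", protect=True)
            else:
                buf.write(is_, "CT", protect=True)
                buf.write(ie - 2, "AC", protect=True)

    # -- coding genes --------------------------------------------------------
    def _build_coding_gene(
        self,
        idx: int,
        chrom: str,
        role: str,
        strand: str,
        n_exons: Optional[int] = None,
        exon_len: Optional[int] = None,
    ) -> _GeneInfo:
        rng = self.rng
        if n_exons is None:
            n_exons = int(rng.integers(4, 9))
        if exon_len is not None:
            exon_lens = [exon_len] * n_exons
        else:
            exon_lens = [int(x) for x in rng.integers(150, 300, size=n_exons)]
        if role in ("companion_sense", "companion_antisense"):
            exon_lens[0 if strand == "+" else -1] = 250  # roomy terminal UTR exon
        intron_lens = [int(x) for x in rng.integers(250, 600, size=n_exons - 1)]
        width = sum(exon_lens) + sum(intron_lens)
        start = self._alloc(chrom, width)

        exons: List[Tuple[int, int]] = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < n_exons - 1:
                pos += intron_lens[i]
        gid = f"gene{idx:04d}"
        t = TranscriptModel(
            transcript_id=f"tx{idx:04d}",
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            biotype="coding",
            read_coverage=float(rng.integers(5, 50)),
        )
        self._write_introns(t)

        # transcript sequence: ATG/CAT-free 5' UTR, planted ORF, random tail
        L = t.spliced_length
        l0 = (exons[0][1] - exons[0][0]) if strand == "+" else (
            exons[-1][1] - exons[-1][0]
        )
        u = min(l0 + 3, L - 351)
        orf_len = int(min(L - u - 48, max(303, 0.55 * L)) // 3) * 3
        if role == "cerna_circ_host":
            # ORF confined inside the circle chunk, clear of the junction edges
            u = 760
            orf_len = 501
        utr5 = _seq_without(rng, u, ["ATG", "CAT"])
        orf = _orf_seq(rng, orf_len // 3)
        tail = _random_seq(rng, L - u - orf_len)
        self._write_tx(t, utr5 + orf + tail)

        info = _GeneInfo(
            transcript=t, orf_tx_start=u, orf_tx_end=u + orf_len, role=role
        )
        self.genes[gid] = info
        self.known.append(t)
        asm = TranscriptModel(
            transcript_id=t.transcript_id,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=list(exons),
            biotype="unknown",
            read_coverage=t.read_coverage,
        )
        self.assembled.append(asm)
        self.truth.coding_ids.append(t.transcript_id)
        return info

    # -- circRNA planting ----------------------------------------------------
    def _plant_circ(self, info: _GeneInfo, first_exon: bool, forced=None) -> dict:
        t = info.transcript
        n = t.n_exons
        rng = self.rng
        if forced is not None:
            i, j = forced
        elif first_exon:
            i, j = 0, int(rng.integers(1, n - 1))
        else:
            i = int(rng.integers(1, n - 1))
            j = int(rng.integers(i, n - 1))
        acceptor = donor = None
        while True:
            # transcript exon indices -> genomic exon indices
            if t.strand == "+":
                gi, gj = i, j
            else:
                gi, gj = n - 1 - j, n - 1 - i
            acceptor = t.exons[gi][0]
            donor = t.exons[gj][1]
            if donor - acceptor >= self.cfg.read_len + 2:
                break
            if j < n - 2:
                j += 1
            elif i > (0 if first_exon else 1):
                i -= 1
            else:
                raise ConfigError(
                    "gene too small to host a circle longer than read_len"
                )
        if first_exon:
            # no upstream intron: write the acceptor-side motif by hand
            buf = self.chroms[t.chrom]
            motif = "AG" if t.strand == "+" else "CT"
            if t.strand == "+":
                buf.write(acceptor - 2, motif, protect=True)
            else:
                buf.write(donor, motif, protect=True)
        circ_exons = t.exons[gi : gj + 1]
        circ_len = sum(e - s for s, e in circ_exons)
        rec = {
            "circ_id": f"circ_{t.chrom}_{acceptor}_{donor}",
            "chrom": t.chrom,
            "strand": t.strand,
            "acceptor": acceptor,
            "donor": donor,
            "hosting_gene": t.gene_id,
            "host_transcript": t.transcript_id,
            "exon_indices": list(range(i, j + 1)),
            "uses_first_exon": first_exon,
            "uses_last_exon": False,
            "circ_length": circ_len,
        }
        self.truth.circ_junctions.append(rec)
        return rec

    def _circ_sequence(self, rec: dict) -> str:
        """Circle sequence in transcript orientation (exons of the circle)."""
        t = self.genes[rec["hosting_gene"]].transcript
        n = t.n_exons
        idx = rec["exon_indices"]
        if t.strand == "+":
            gidx = idx
        else:
            gidx = [n - 1 - i for i in reversed(idx)]
        seq = "".join(str(self.chroms[t.chrom])[s:e] for s, e in (t.exons[g] for g in gidx))
        return seq if t.strand == "+" else revcomp(seq)

    def _circ_tx_window(self, rec: dict) -> Tuple[TranscriptModel, int, int]:
        """Host transcript plus the circle's [start, end) in spliced coords."""
        t = self.genes[rec["hosting_gene"]].transcript
        lens = [e - s for s, e in t.exons]
        if t.strand == "-":
            lens.reverse()
        start = sum(lens[: rec["exon_indices"][0]])
        end = start + rec["circ_length"]
        return t, start, end

    # -- lncRNAs ---------------------------------------------------------------
    def _register_lnc(self, t: TranscriptModel, positional_class: str) -> None:
        self.lncs[t.transcript_id] = t
        self.truth.lnc_classes[t.transcript_id] = positional_class
        self.assembled.append(t)

    def _build_companion_lnc(self, idx: int, info: _GeneInfo, kind: str) -> None:
        """sense/antisense/bidirectional lncRNA tied to a plus-strand host."""
        host = info.transcript
        assert host.strand == "+"
        s0, e0 = host.exons[0]
        i0s, i0e = host.introns()[0]
        rng = self.rng
        tid = f"lnc{idx:04d}"
        if kind == "sense":
            exon_a = (s0 + 10, s0 + 110)  # inside the ATG/CAT-free host UTR exon
            exon_b = (i0s + 40, i0s + 40 + 140)
            if exon_b[1] > i0e - 10:
                exon_b = (i0s + 10, i0e - 10)
            t = TranscriptModel(
                tid, f"lncgene{idx:04d}", host.chrom, "+",
                [exon_a, exon_b], "unknown", float(rng.integers(3, 20)),
            )
            self._write_introns(t)
            self.chroms[t.chrom].write(
                exon_b[0] + 2,
                _seq_without(rng, exon_b[1] - exon_b[0] - 4, ["ATG"]),
            )
        elif kind == "antisense":
            exon_a = (s0 + 10, s0 + 110)
            exon_b = (s0 - 400, s0 - 250)
            t = TranscriptModel(
                tid, f"lncgene{idx:04d}", host.chrom, "-",
                [exon_b, exon_a], "unknown", float(rng.integers(3, 20)),
            )
            self._write_introns(t)
            self.chroms[t.chrom].write(
                exon_b[0] + 2,
                revcomp(_seq_without(rng, exon_b[1] - exon_b[0] - 4, ["ATG"])),
            )
        elif kind == "bidirectional":
            exon_b = (s0 - 600, s0 - 450)
            exon_a = (s0 - 250, s0 - 100)
            t = TranscriptModel(
                tid, f"lncgene{idx:04d}", host.chrom, "-",
                [exon_b, exon_a], "unknown", float(rng.integers(3, 20)),
            )
            self._write_introns(t)
            for s, e in (exon_a, exon_b):
                self.chroms[t.chrom].write(
                    s + 2, revcomp(_seq_without(rng, e - s - 4, ["ATG"]))
                )
        else:  # pragma: no cover
            raise ValueError(kind)
        self._register_lnc(t, kind)

    def _build_intergenic_lnc(self, idx: int, chrom: str) -> TranscriptModel:
        rng = self.rng
        # reserve extra flanks so no coding TSS sits within the bidirectional
        # window and no exon overlap is possible
        start = self._alloc(chrom, 3900) + 1500
        exon_a = (start, start + 200)
        exon_b = (start + 500, start + 800)
        tid = f"lnc{idx:04d}"
        t = TranscriptModel(
            tid, f"lncgene{idx:04d}", chrom, "+",
            [exon_a, exon_b], "unknown", float(rng.integers(3, 20)),
        )
        self._write_introns(t)
        for s, e in t.exons:
            self.chroms[chrom].write(s, _seq_without(rng, e - s, ["ATG"]))
        self._register_lnc(t, "intergenic")
        return t

    # -- housekeeping + junk ----------------------------------------------------
    def _build_housekeeping(self, idx: int, chrom: str) -> TranscriptModel:
        biotypes = ["rRNA", "tRNA", "snRNA", "snoRNA"]
        start = self._alloc(chrom, 120)
        t = TranscriptModel(
            f"hk{idx:04d}", f"hkgene{idx:04d}", chrom, "+",
            [(start, start + 120)], biotypes[idx % len(biotypes)], 0.0,
        )
        self.known.append(t)
        self.truth.housekeeping_ids.append(t.transcript_id)
        return t

    def _build_junk(self, chrom: str, hk: Optional[TranscriptModel]) -> None:
        rng = self.rng
        # monoexonic, long enough otherwise
        start = self._alloc(chrom, 500)
        t1 = TranscriptModel(
            "junk_mono", "junkgene1", chrom, "+",
            [(start, start + 500)], "unknown", 10.0,
        )
        # two exons but < 200 bp spliced
        start = self._alloc(chrom, 500)
        t2 = TranscriptModel(
            "junk_short", "junkgene2", chrom, "+",
            [(start, start + 80), (start + 330, start + 420)], "unknown", 10.0,
        )
        self._write_introns(t2)
        # low coverage
        start = self._alloc(chrom, 800)
        t3 = TranscriptModel(
            "junk_lowcov", "junkgene3", chrom, "+",
            [(start, start + 200), (start + 500, start + 750)], "unknown", 1.0,
        )
        self._write_introns(t3)
        # low FPKM (counts forced to zero downstream)
        start = self._alloc(chrom, 800)
        t4 = TranscriptModel(
            "junk_lowfpkm", "junkgene4", chrom, "+",
            [(start, start + 200), (start + 500, start + 750)], "unknown", 10.0,
        )
        self._write_introns(t4)
        # novel transcript with a genuine ORF -> coding_potential reject
        start = self._alloc(chrom, 1200)
        t5 = TranscriptModel(
            "junk_coding", "junkgene5", chrom, "+",
            [(start, start + 400), (start + 700, start + 1100)], "unknown", 10.0,
        )
        self._write_introns(t5)
        self._write_tx(
            t5,
            _seq_without(rng, 40, ["ATG"]) + _orf_seq(rng, 220) + _random_seq(rng, 100),
        )
        junk = [t1, t2, t3, t4, t5]
        reasons = {
            "junk_mono": "short_or_monoexonic",
            "junk_short": "short_or_monoexonic",
            "junk_lowcov": "low_coverage",
            "junk_lowfpkm": "low_fpkm",
            "junk_coding": "coding_potential",
        }
        if hk is not None:
            # same-strand overlap with a housekeeping RNA
            hs, he = hk.exons[0]
            t6 = TranscriptModel(
                "junk_hk_overlap", "junkgene6", hk.chrom, hk.strand,
                [(hs - 150, he - 60), (he + 200, he + 400)], "unknown", 10.0,
            )
            self._write_introns(t6)
            junk.append(t6)
            reasons["junk_hk_overlap"] = "housekeeping_overlap"
        self.assembled.extend(junk)
        self.truth.junk_ids.update(reasons)

    # -- miRNA seed sites --------------------------------------------------------
    def _make_mirnas(self) -> None:
        self.mirnas = simulate_mirnas(self.cfg)
        self.truth.mirnas = {m.mirna_id: m.sequence for m in self.mirnas}

    def _plant_site_in_tx(self, t: TranscriptModel, tpos: int, mir: MiRNA) -> None:
        site = mir.seed_match_dna + "A"  # 8mer site, transcript orientation
        for k, base in enumerate(site):
            self._write_tx_base(t, tpos + k, base)
        buf = self.chroms[t.chrom]
        for gpos in _tx_positions(t.exons, t.strand)[tpos : tpos + 8]:
            buf.protect(gpos, gpos + 1)

    def _plant_cerna(self, target_pool: List[_GeneInfo]) -> None:
        cfg = self.cfg
        lnc_sponges = [
            self.lncs[i]
            for i, c in sorted(self.truth.lnc_classes.items())
            if c == "intergenic"
        ]
        circ_recs = [
            r for r in self.truth.circ_junctions if not r["uses_first_exon"]
        ]
        li = 0
        for n in range(cfg.n_cerna_triples):
            mir = self.mirnas[n]
            target = target_pool[n % len(target_pool)]
            mt = target.transcript
            # site in the 3' UTR, 10 bp after the stop codon
            tpos_m = target.orf_tx_end + 10
            if tpos_m + 8 > mt.spliced_length:
                raise ConfigError("target 3' UTR too short for a seed site")
            self._plant_site_in_tx(mt, tpos_m, mir)
            if n % 2 == 1 and circ_recs:
                rec = next(
                    r for r in circ_recs if r["hosting_gene"] in self.genes
                    and self.genes[r["hosting_gene"]].role == "cerna_circ_host"
                )
                host, cstart, cend = self._circ_tx_window(rec)
                site = mir.seed_match_dna + "A"
                # junction-spanning: last 4 nt of the circle + first 4 nt
                for k in range(4):
                    self._write_tx_base(host, cend - 4 + k, site[k])
                for k in range(4):
                    self._write_tx_base(host, cstart + k, site[4 + k])
                buf = self.chroms[host.chrom]
                gp = _tx_positions(host.exons, host.strand)
                for tp in list(range(cend - 4, cend)) + list(range(cstart, cstart + 4)):
                    buf.protect(gp[tp], gp[tp] + 1)
                self.truth.cerna_triples.append(
                    {
                        "sponge_id": rec["circ_id"],
                        "sponge_kind": "circRNA",
                        "mirna_id": mir.mirna_id,
                        "mrna_id": mt.transcript_id,
                        "sponge_sites": [rec["circ_length"] - 4],
                        "mrna_sites": [tpos_m],
                    }
                )
            else:
                sponge = lnc_sponges[li % len(lnc_sponges)]
                li += 1
                tpos_s = 30
                self._plant_site_in_tx(sponge, tpos_s, mir)
                self.truth.cerna_triples.append(
                    {
                        "sponge_id": sponge.transcript_id,
                        "sponge_kind": "lncRNA",
                        "mirna_id": mir.mirna_id,
                        "mrna_id": mt.transcript_id,
                        "sponge_sites": [tpos_s],
                        "mrna_sites": [tpos_m],
                    }
                )

    def _scrub_seed_matches(self) -> None:
        """Remove spurious seed-core matches from every emitted sequence.

        Scans every coding transcript and lncRNA linearly, and every planted
        circle across its backsplice junction, for 6-mer matches to the core
        (reverse complement of miRNA nucleotides 2-7) of any simulated miRNA.
        Non-planted occurrences are disrupted by mutating one editable base;
        ORF start/stop codons, intron motifs and planted sites are never
        touched, and no new in-frame stop codon is introduced.
        """
        if not self.mirnas:
            return
        cores = {m.seed_match_dna[1:] for m in self.mirnas}
        # planted core positions: transcript-coordinate 6-mer starts to skip
        planted: Dict[str, Set[int]] = {}
        circ_windows = {
            rec["circ_id"]: self._circ_tx_window(rec)
            for rec in self.truth.circ_junctions
        }
        for triple in self.truth.cerna_triples:
            for sid, pos_list in (
                (triple["sponge_id"], triple["sponge_sites"]),
                (triple["mrna_id"], triple["mrna_sites"]),
            ):
                if sid in circ_windows:
                    host, cstart, cend = circ_windows[sid]
                    clen = cend - cstart
                    for p in pos_list:  # circle coords, 8mer start
                        core_q = (p + 1) % clen
                        planted.setdefault(host.transcript_id, set()).add(
                            cstart + core_q
                        )
                else:
                    planted.setdefault(sid, set()).update(p + 1 for p in pos_list)

        def scrub_tx(t: TranscriptModel, orf=None, circ_window=None) -> None:
            skip = planted.get(t.transcript_id, set())
            for _round in range(15):
                seq = self._read_tx(t)
                hit: Optional[List[int]] = None
                for q in range(len(seq) - 5):
                    if seq[q : q + 6] in cores and q not in skip:
                        hit = list(range(q, q + 6))
                        break
                if hit is None and circ_window is not None:
                    cstart, cend = circ_window
                    clen = cend - cstart
                    circ_seq = seq[cstart:cend]
                    ext = circ_seq + circ_seq[:6]
                    for q in range(clen - 5, clen):  # junction-spanning only
                        if ext[q : q + 6] in cores and (cstart + q) not in skip:
                            hit = [
                                cstart + ((q + k) % clen) for k in range(6)
                            ]
                            break
                if hit is None:
                    return
                if not self._fix_core(t, hit, orf):
                    raise ConfigError("unable to scrub a spurious seed site")
            raise ConfigError("seed-site scrubbing did not converge")

        for info in self.genes.values():
            window = None
            for rec in self.truth.circ_junctions:
                if rec["hosting_gene"] == info.transcript.gene_id:
                    _, cstart, cend = circ_windows[rec["circ_id"]]
                    window = (cstart, cend)
                    break
            scrub_tx(
                info.transcript,
                orf=(info.orf_tx_start, info.orf_tx_end),
                circ_window=window,
            )
        for t in self.lncs.values():
            scrub_tx(t)

    def _fix_core(self, t: TranscriptModel, positions: List[int], orf) -> bool:
        """Mutate one editable base among the given spliced positions."""
        seq = self._read_tx(t)
        order = [2, 3, 1, 4, 0, 5]
        for offset in order:
            tpos = positions[offset]
            if tpos >= t.spliced_length:
                continue
            if not self._tx_base_editable(t, tpos):
                continue
            in_orf = (
                orf is not None
                and orf[0] is not None
                and orf[0] <= tpos < orf[1]
            )
            if in_orf:
                o_start, o_end = orf
                if o_start <= tpos < o_start + 3 or o_end - 3 <= tpos < o_end:
                    continue  # never touch the start or stop codon
            current = seq[tpos]
            for base in "CGTA":
                if base == current:
                    continue
                if in_orf:
                    codon_i = orf[0] + 3 * ((tpos - orf[0]) // 3)
                    codon = list(seq[codon_i : codon_i + 3])
                    codon[tpos - codon_i] = base
                    if "".join(codon) in _STOPS:
                        continue
                self._write_tx_base(t, tpos, base)
                return True
        return False

    def _force_noncoding_lncs(self) -> None:
        """Backstop: break any chance ORF in a planted lncRNA."""
        for t in self.lncs.values():
            for _ in range(20):
                seq = self._read_tx(t)
                orf_bp, frac, is_coding = coding_potential(seq)
                if not is_coding:
                    break
                start = self._find_max_orf_start(seq)
                fixed = False
                for codon_i in range(start + 3, start + orf_bp - 3, 3):
                    if all(
                        self._tx_base_editable(t, codon_i + k) for k in range(3)
                    ):
                        for k, b in enumerate("TAA"):
                            self._write_tx_base(t, codon_i + k, b)
                        fixed = True
                        break
                if not fixed:
                    raise ConfigError(
                        f"cannot force lncRNA {t.transcript_id} noncoding"
                    )
            else:
                raise ConfigError("noncoding enforcement did not converge")

    @staticmethod
    def _find_max_orf_start(seq: str) -> int:
        best_len, best_start = 0, 0
        n = len(seq)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOPS:
                    if i + 3 - start > best_len:
                        best_len, best_start = i + 3 - start, start
                    start = None
        return best_start

    # -- main ---------------------------------------------------------------
    def build(self) -> SimulationResult:
        cfg = self.cfg
        self._init_chroms()
        self._make_mirnas()
        chrom_names = list(self.chroms)

        n_companions = 3 * cfg.n_lnc_per_class
        roles: List[str] = []
        for i in range(cfg.n_circ_junctions):
            if i == 0 and cfg._n_circ_sponges():
                roles.append("cerna_circ_host")
            else:
                roles.append("circ_host")
        for i in range(cfg.n_lnc_per_class):
            roles.extend(["companion_sense", "companion_antisense", "companion_bidirectional"])
        while len(roles) < cfg.n_coding_genes:
            roles.append("plain")

        infos: List[_GeneInfo] = []
        for idx, role in enumerate(roles):
            chrom = chrom_names[idx % len(chrom_names)]
            if role.startswith("companion"):
                strand = "+"
            elif role == "cerna_circ_host":
                strand = "+"
            else:
                strand = "+" if idx % 2 == 0 else "-"
            kwargs = {}
            if role == "cerna_circ_host":
                kwargs = dict(n_exons=8, exon_len=250)
            elif role.startswith("companion"):
                kwargs = dict(n_exons=int(self.rng.integers(5, 9)))
            infos.append(
                self._build_coding_gene(idx, chrom, role, strand, **kwargs)
            )

        # circRNA junctions (one per host gene)
        remaining_first = cfg.n_circ_first_exon
        circ_hosts = [g for g in infos if g.role in ("circ_host", "cerna_circ_host")]
        for info in circ_hosts:
            if info.role == "cerna_circ_host":
                self._plant_circ(info, first_exon=False, forced=(2, 5))
            elif remaining_first > 0:
                self._plant_circ(info, first_exon=True)
                remaining_first -= 1
            else:
                self._plant_circ(info, first_exon=False)

        # companion lncRNAs
        lnc_idx = 0
        for info in infos:
            if info.role == "companion_sense":
                self._build_companion_lnc(lnc_idx, info, "sense")
                lnc_idx += 1
            elif info.role == "companion_antisense":
                self._build_companion_lnc(lnc_idx, info, "antisense")
                lnc_idx += 1
            elif info.role == "companion_bidirectional":
                self._build_companion_lnc(lnc_idx, info, "bidirectional")
                lnc_idx += 1
        for i in range(cfg.n_lnc_per_class):
            self._build_intergenic_lnc(lnc_idx, chrom_names[i % len(chrom_names)])
            lnc_idx += 1

        # known vs novel lncRNAs (per class, the first fraction are known)
        by_class: Dict[str, List[str]] = {}
        for tid, cls in sorted(self.truth.lnc_classes.items()):
            by_class.setdefault(cls, []).append(tid)
        for cls, tids in sorted(by_class.items()):
            n_known = int(round(cfg.frac_lnc_known * len(tids)))
            for tid in tids[:n_known]:
                src = self.lncs[tid]
                self.known.append(
                    TranscriptModel(
                        transcript_id=f"known_{tid}",
                        gene_id=f"known_{src.gene_id}",
                        chrom=src.chrom,
                        strand=src.strand,
                        exons=list(src.exons),
                        biotype="known_lncRNA",
                        read_coverage=0.0,
                    )
                )
                self.truth.known_lnc_ids.append(tid)
            for tid in tids[n_known:]:
                self.truth.novel_lnc_ids.append(tid)
        self.truth.known_lnc_ids.sort()
        self.truth.novel_lnc_ids.sort()

        # housekeeping genes + junk transcripts
        hk_first: Optional[TranscriptModel] = None
        for i in range(cfg.n_housekeeping):
            hk = self._build_housekeeping(i, chrom_names[i % len(chrom_names)])
            if hk_first is None:
                hk_first = hk
        self._build_junk(chrom_names[0], hk_first)

        # ceRNA planting and sequence hygiene
        if cfg.n_cerna_triples:
            plain = [g for g in infos if g.role == "plain"]
            target_pool = plain if plain else infos
            self._plant_cerna(target_pool)
        self._scrub_seed_matches()
        self._force_noncoding_lncs()

        genome = Genome(
            seqs={name: str(buf) for name, buf in self.chroms.items()},
            chrom_class={
                name: ("X" if name == "chrX" else "autosome")
                for name in self.chroms
            },
        )
        return SimulationResult(
            config=cfg,
            genome=genome,
            known_transcripts=self.known,
            assembled_transcripts=self.assembled,
            truth=self.truth,
            mirnas=self.mirnas,
        )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Full deterministic build of genome, annotations, truth and miRNAs."""
    return _Builder(config).build()


def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> Tuple[Genome, List[TranscriptModel], PlantedTruth]:
    res = simulate_all(config)
    return res.genome, res.assembled_transcripts, res.truth


def simulate_mirnas(config: SimulationConfig) -> List[MiRNA]:
    """The miRNA set used by the genome builder (same seeded stream).

    Seed cores (reverse complement of nucleotides 2-7) are forced distinct so
    a planted site for one miRNA can never be read as a site for another.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 909])
    out: List[MiRNA] = []
    cores: Set[str] = set()
    while len(out) < config.n_mirnas:
        seq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=22))
        mir = MiRNA(mirna_id=f"mir{len(out) + 1:03d}", sequence=seq)
        core = mir.seed_match_dna[1:]
        if core in cores:
            continue
        cores.add(core)
        out.append(mir)
    return out


def simulate_backsplice_reads(
    genome: Genome, truth: PlantedTruth, config: SimulationConfig
) -> List[SplitAlignment]:
    """Backsplice-supporting reads for every planted junction, plus decoys.

    Each junction gets ``circ_read_depth`` reads whose 5' segment ends at the
    donor and whose 3' segment starts at the acceptor.  Linear decoys place
    the segments in genomic order; inter-chromosomal decoys use two
    chromosomes; PCR duplicates are byte-identical copies injected at
    ``pcr_dup_rate``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    libs = sorted(config.libraries())
    chroms = sorted(genome.seqs)
    rows: List[SplitAlignment] = []
    ridx = 0
    for rec in truth.circ_junctions:
        acceptor, donor = rec["acceptor"], rec["donor"]
        for _ in range(config.circ_read_depth):
            l1 = int(
                rng.integers(
                    MIN_SEGMENT_LEN, config.read_len - MIN_SEGMENT_LEN + 1
                )
            )
            l2 = config.read_len - l1
            delta = (
                int(rng.integers(-config.breakpoint_jitter, config.breakpoint_jitter + 1))
                if config.breakpoint_jitter
                else 0
            )
            rows.append(
                SplitAlignment(
                    read_id=f"bsj{ridx:06d}",
                    sample_id=libs[int(rng.integers(0, len(libs)))],
                    chrom1=rec["chrom"],
                    chrom2=rec["chrom"],
                    strand=rec["strand"],
                    seg1=(donor - l1 + delta, donor + delta),
                    seg2=(acceptor + delta, acceptor + delta + l2),
                )
            )
            ridx += 1
    for i in range(config.n_decoy_linear):
        chrom = chroms[i % len(chroms)]
        limit = len(genome.seqs[chrom]) - 2000
        x = int(rng.integers(1000, limit))
        gap = int(rng.integers(100, 800))
        rows.append(
            SplitAlignment(
                read_id=f"lin{i:06d}",
                sample_id=libs[int(rng.integers(0, len(libs)))],
                chrom1=chrom,
                chrom2=chrom,
                strand="+" if i % 2 == 0 else "-",
                seg1=(x, x + 50),
                seg2=(x + 50 + gap, x + 100 + gap),
            )
        )
    if len(chroms) > 1:
        for i in range(config.n_decoy_interchrom):
            c1 = chroms[i % len(chroms)]
            c2 = chroms[(i + 1) % len(chroms)]
            x = int(rng.integers(1000, len(genome.seqs[c1]) - 2000))
            y = int(rng.integers(1000, len(genome.seqs[c2]) - 2000))
            rows.append(
                SplitAlignment(
                    read_id=f"ic{i:06d}",
                    sample_id=libs[int(rng.integers(0, len(libs)))],
                    chrom1=c1,
                    chrom2=c2,
                    strand="+",
                    seg1=(x, x + 50),
                    seg2=(y, y + 50),
                )
            )
    if config.pcr_dup_rate > 0:
        duplicated: List[SplitAlignment] = []
        for row in rows:
            duplicated.append(row)
            while rng.random() < config.pcr_dup_rate:
                duplicated.append(row)
        rows = duplicated
    return rows


def simulate_counts(
    annotation: Sequence[TranscriptModel],
    truth: PlantedTruth,
    config: SimulationConfig,
    select_biased: bool = True,
) -> ExpressionTable:
    """NB fragment counts with planted bias and co-expression structure.

    Rows cover every annotated transcript plus every planted circRNA.  Sex
    bias multiplies the favored condition's means by the planted fold change;
    female-biased ids are drawn from the X chromosome with probability
    ``frac_female_biased_on_X`` (male-biased symmetrically with their own,
    usually small, X fraction).  Co-expressed and ceRNA pairs share a latent
    per-library factor so their expression correlates near +/-1.

    Calling this mutates ``truth`` (fills sex_biased / coexpressed_pairs
    membership) unless those fields are already populated.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 303])
    select_rng = np.random.default_rng([config.seed, 304])
    libs = config.libraries()
    lib_names = sorted(libs, key=lambda l: (libs[l] != "SSC", l))
    n_lib = len(lib_names)
    male_libs = np.array([libs[l] == "SSC" for l in lib_names])

    ids = [t.transcript_id for t in annotation]
    chrom_of = {t.transcript_id: t.chrom for t in annotation}
    lengths = {t.transcript_id: float(t.spliced_length) for t in annotation}
    for rec in truth.circ_junctions:
        ids.append(rec["circ_id"])
        chrom_of[rec["circ_id"]] = rec["chrom"]
        lengths[rec["circ_id"]] = float(rec["circ_length"])

    # reserve pair members before drawing the general biased sets
    pair_specs: List[dict] = []
    reserved: Set[str] = set()
    if select_biased and not truth.coexpressed_pairs:
        lnc_pool = [i for i in sorted(truth.novel_lnc_ids) if i not in reserved]
        mrna_pool = [i for i in sorted(truth.coding_ids) if i not in reserved]
        for k in range(config.n_coexpressed_pairs):
            if not lnc_pool or not mrna_pool:
                break
            lnc = lnc_pool.pop(0)
            mrna = mrna_pool.pop()
            sign = "positive" if k % 2 == 0 else "negative"
            truth.coexpressed_pairs.append(
                {"noncoding_id": lnc, "mrna_id": mrna, "sign": sign}
            )
    for pair in truth.coexpressed_pairs:
        pair_specs.append(dict(pair))
        reserved.update((pair["noncoding_id"], pair["mrna_id"]))
    for triple in truth.cerna_triples:
        pair_specs.append(
            {
                "noncoding_id": triple["sponge_id"],
                "mrna_id": triple["mrna_id"],
                "sign": "positive",
            }
        )
        reserved.update((triple["sponge_id"], triple["mrna_id"]))

    if select_biased and not truth.sex_biased:
        eligible = [
            i
            for i in ids
            if i not in reserved and i not in truth.junk_ids
        ]
        x_ids = sorted(i for i in eligible if chrom_of[i] == "chrX")
        auto_ids = sorted(i for i in eligible if chrom_of[i] != "chrX")
        n_male = int(round(config.frac_male_biased * len(eligible)))
        n_female = int(round(config.frac_female_biased * len(eligible)))
        for direction, n_pick, frac_x in (
            ("male", n_male, config.frac_male_biased_on_X),
            ("female", n_female, config.frac_female_biased_on_X),
        ):
            for _ in range(n_pick):
                use_x = bool(select_rng.random() < frac_x) and bool(x_ids)
                pool = x_ids if use_x else (auto_ids or x_ids)
                if not pool:
                    break
                tid = pool.pop(int(select_rng.integers(0, len(pool))))
                truth.sex_biased[tid] = direction
        # pair members are biased through their shared latent factor: the
        # noncoding side follows the male direction, the mRNA side follows it
        # for positive pairs and flips for negative ones
        for pair in pair_specs:
            truth.sex_biased.setdefault(pair["noncoding_id"], "male")
            truth.sex_biased.setdefault(
                pair["mrna_id"],
                "male" if pair["sign"] == "positive" else "female",
            )

    fc = config.fold_change_planted
    means = {}
    for tid in ids:
        base = float(np.exp(rng.normal(config.base_log_mean, config.base_log_sigma)))
        mu = np.full(n_lib, base)
        direction = truth.sex_biased.get(tid)
        if direction == "male":
            mu = np.where(male_libs, mu * fc, mu)
        elif direction == "female":
            mu = np.where(male_libs, mu, mu * fc)
        means[tid] = mu
    if "junk_lowfpkm" in lengths:
        means["junk_lowfpkm"] = np.zeros(n_lib)

    # shared latent factor per pair (bias folded into the factor keeps the
    # relation exactly linear, so the planted PCC survives on the raw scale)
    pair_disp = {}
    for pair in pair_specs:
        u = np.clip(rng.lognormal(mean=0.0, sigma=0.4, size=n_lib), 0.3, 1.4)
        w = np.where(male_libs, u * fc, u)
        b_nc = config.coexpr_base_mean * float(rng.uniform(0.8, 1.2))
        b_m = config.coexpr_base_mean * float(rng.uniform(0.8, 1.2))
        means[pair["noncoding_id"]] = b_nc * w
        if pair["sign"] == "positive":
            means[pair["mrna_id"]] = b_m * w
        else:
            ceiling = fc * 1.4 + 0.3
            means[pair["mrna_id"]] = b_m * (ceiling - w)
        pair_disp[pair["noncoding_id"]] = config.coexpr_dispersion
        pair_disp[pair["mrna_id"]] = config.coexpr_dispersion

    counts = np.zeros((len(ids), n_lib), dtype=np.int64)
    for r, tid in enumerate(ids):
        mu = means[tid]
        d = pair_disp.get(tid, config.nb_dispersion)
        n_param = 1.0 / d
        with np.errstate(divide="ignore"):
            p_param = np.where(mu > 0, n_param / (n_param + mu), 1.0)
        counts[r] = np.where(
            mu > 0, rng.negative_binomial(n_param, p_param), 0
        )

    df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"), columns=lib_names)
    # one shared library size (>= every column sum): per-library FPKM then
    # differs from counts by a global constant, so planted linear relations
    # between rows survive on the FPKM scale
    lib_size = float(10 ** np.ceil(np.log10(df.values.sum(axis=0).max() + 1)))
    return ExpressionTable(
        counts=df,
        effective_length_bp=lengths,
        conditions=dict(libs),
        library_size={lib: lib_size for lib in lib_names},
    )


def circ_sequences(result: SimulationResult) -> Dict[str, str]:
    """Circle sequences (transcript orientation) keyed by planted circ id."""
    genome = result.genome
    models = {t.transcript_id: t for t in result.assembled_transcripts}
    out: Dict[str, str] = {}
    for rec in result.truth.circ_junctions:
        t = models[rec["host_transcript"]]
        n = t.n_exons
        idx = rec["exon_indices"]
        if t.strand == "+":
            gidx = idx
        else:
            gidx = [n - 1 - i for i in reversed(idx)]
        seq = "".join(
            genome.seqs[t.chrom][t.exons[g][0] : t.exons[g][1]] for g in gidx
        )
        out[rec["circ_id"]] = seq if t.strand == "+" else revcomp(seq)
    return out
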