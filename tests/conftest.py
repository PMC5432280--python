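import dataclasses
from typing import Dict, List

import pytest

from gsc_ncrna.io_formats import Genome, TranscriptModel
from gsc_ncrna.synthetic_data import (
    SimulationConfig,
    SimulationResult,
    simulate_all,
    simulate_backsplice_reads,
    simulate_counts,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_result(sim_config) -> SimulationResult:
    return simulate_all(sim_config)


@pytest.fixture(scope="session")
def sim_reads(sim_result, sim_config):
    return simulate_backsplice_reads(sim_result.genome, sim_result.truth, sim_config)


@pytest.fixture(scope="session")
def sim_table(sim_result, sim_config):
    return simulate_counts(
        sim_result.assembled_transcripts, sim_result.truth, sim_config
    )


# ---------------------------------------------------------------------------
# hand-built lncRNA cascade fixture (12 transcripts, verdicts derived by hand)
# ---------------------------------------------------------------------------

_UNIT = "ACGGTCCTA"  # no ATG on either strand (also CAT-free)


@dataclasses.dataclass
class CascadeCase:
    genome: Genome
    known: List[TranscriptModel]
    transcripts: List[TranscriptModel]
    fpkm: Dict[str, float]
    expected: Dict[str, tuple]  # tid -> (status, reject_reason, positional_class)


def _cascade_genome() -> Genome:
    n = 20007
    seq = list((_UNIT * (n // len(_UNIT) + 1))[:n])
    # plant a 603 bp ORF for t08 across its two exons:
    # exon1 (18000,18400) holds spliced [0,400), exon2 (18600,19000) the rest;
    # the ORF occupies spliced [10, 613)
    orf = "ATG" + "GCA" * 199 + "TAA"
    seq[18010:18400] = orf[:390]
    seq[18600 : 18600 + 213] = orf[390:]
    return Genome(seqs={"chr1": "".join(seq)}, chrom_class={"chr1": "autosome"})


@pytest.fixture(scope="session")
def cascade_case() -> CascadeCase:
    genome = _cascade_genome()
    known = [
        TranscriptModel(
            "kcod", "gkcod", "chr1", "+",
            [(1000, 1200), (1500, 1700), (2000, 2200)], "coding", 0.0,
        ),
        TranscriptModel(
            "klnc", "gklnc", "chr1", "+",
            [(5000, 5200), (5500, 5700)], "known_lncRNA", 0.0,
        ),
        TranscriptModel("ktrna", "gktrna", "chr1", "+", [(8000, 8080)], "tRNA", 0.0),
        TranscriptModel(
            "kmrna2", "gkmrna2", "chr1", "+",
            [(12000, 12200), (12500, 12700)], "coding", 0.0,
        ),
    ]
    transcripts = [
        TranscriptModel("t01", "g01", "chr1", "+", [(14000, 14500)], "unknown", 5.0),
        TranscriptModel(
            "t02", "g02", "chr1", "+", [(14800, 14870), (15000, 15080)], "unknown", 5.0
        ),
        TranscriptModel(
            "t03", "g03", "chr1", "+",
            [(15200, 15400), (15600, 15800), (16000, 16200)], "unknown", 1.0,
        ),
        TranscriptModel(
            "t04", "g04", "chr1", "+",
            [(16400, 16600), (16800, 17000), (17200, 17400)], "unknown", 5.0,
        ),
        TranscriptModel(
            "t05", "g05", "chr1", "+", [(4900, 5200), (5500, 5800)], "unknown", 5.0
        ),
        TranscriptModel(
            "t06", "g06", "chr1", "+", [(7950, 8030), (8200, 8400)], "unknown", 5.0
        ),
        TranscriptModel(
            "t07", "g07", "chr1", "+", [(11900, 12200), (12500, 12800)], "unknown", 5.0
        ),
        TranscriptModel(
            "t08", "g08", "chr1", "+", [(18000, 18400), (18600, 19000)], "unknown", 5.0
        ),
        TranscriptModel(
            "t09", "g09", "chr1", "+", [(1100, 1250), (1350, 1450)], "unknown", 5.0
        ),
        TranscriptModel(
            "t10", "g10", "chr1", "-", [(2050, 2150), (2300, 2400)], "unknown", 5.0
        ),
        TranscriptModel(
            "t11", "g11", "chr1", "-", [(200, 350), (500, 650)], "unknown", 5.0
        ),
        TranscriptModel(
            "t12", "g12", "chr1", "+", [(9500, 9700), (9900, 10100)], "unknown", 5.0
        ),
    ]
    fpkm = {t.transcript_id: 1.0 for t in transcripts}
    fpkm["t04"] = 0.001
    expected = {
        "t01": ("rejected", "short_or_monoexonic", None),
        "t02": ("rejected", "short_or_monoexonic", None),
        "t03": ("rejected", "low_coverage", None),
        "t04": ("rejected", "low_fpkm", None),
        "t05": ("known_lncRNA", None, "intergenic"),
        "t06": ("rejected", "housekeeping_overlap", None),
        "t07": ("rejected", "mrna_match", None),
        "t08": ("rejected", "coding_potential", None),
        "t09": ("novel_lncRNA", None, "sense"),
        "t10": ("novel_lncRNA", None, "antisense"),
        "t11": ("novel_lncRNA", None, "bidirectional"),
        "t12": ("novel_lncRNA", None, "intergenic"),
    }
    return CascadeCase(genome, known, transcripts, fpkm, expected)
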