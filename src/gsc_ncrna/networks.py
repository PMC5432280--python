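"""Coding-noncoding co-expression network and miRNA seed-site ceRNA network.

The co-expression network tests every (noncoding, coding) pair with Pearson
correlation across libraries and keeps edges at |PCC| >= 0.99, p < 0.01 and
BH FDR < 0.01 (FDR computed over all tested pairs).  Coding genes with
several transcripts are collapsed to their per-library median first.

The ceRNA network re-implements canonical seed matching: a site is a target
match to the reverse complement of miRNA nucleotides 2-8, classified as
8mer / 7mer-m8 / 7mer-A1.  A (sponge, miRNA, mRNA) link is emitted when both
sequences carry at least one site for the same miRNA and the sponge-mRNA
expression correlation passes the gate (default |PCC| >= 0.9).  circRNA
sponge sequences are scanned circularly so junction-spanning sites are found.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .io_formats import revcomp

PCC_EDGE_MIN = 0.99
EDGE_P_MAX = 0.01
EDGE_FDR_MAX = 0.01
CERNA_PCC_MIN = 0.9
SEED_START = 1  # 0-based: miRNA nucleotides 2..8
SEED_END = 8


@dataclass(frozen=True)
class CoexpressionEdge:
    noncoding_id: str
    mrna_id: str
    pcc: float
    p_value: float
    fdr: float
    sign: str  # positive | negative

    # duck-typed view consumed by io_formats.write_edge_list
    @property
    def source(self) -> str:
        return self.noncoding_id

    @property
    def target(self) -> str:
        return self.mrna_id

    @property
    def weight(self) -> float:
        return self.pcc


@dataclass(frozen=True)
class MiRNA:
    mirna_id: str
    sequence: str  # 22-nt RNA, 5'->3'

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGU"):
            raise ConfigError(f"miRNA {self.mirna_id} is not RNA: {seq}")
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (7 nt, RNA)."""
        return self.sequence[SEED_START:SEED_END]

    @property
    def seed_match_dna(self) -> str:
        """Reverse complement of the seed in DNA alphabet (target-strand)."""
        return revcomp(self.seed.replace("U", "T"))


@dataclass(frozen=True)
class SeedSite:
    target_id: str
    position: int  # 0-based start of the site on the target
    site_type: str  # 8mer | 7mer_m8 | 7mer_A1


@dataclass
class CeRNALink:
    sponge_id: str
    mirna_id: str
    mrna_id: str
    sponge_sites: List[SeedSite]
    mrna_sites: List[SeedSite]
    expr_pcc: float


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_cc(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with a two-sided t-test p (n - 2 df).

    Constant vectors make the coefficient undefined: (nan, nan) is returned
    and such pairs are excluded from networks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ConfigError("pearson_cc needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pairwise_pcc(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs PCC and two-sided t-test p between rows of a and rows of b."""
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def build_cnc_network(
    noncoding_fpkm: pd.DataFrame,
    mrna_fpkm: pd.DataFrame,
    top_k_mrnas: Optional[int] = None,
    gene_map: Optional[Mapping[str, str]] = None,
    pcc_min: float = PCC_EDGE_MIN,
    p_max: float = EDGE_P_MAX,
    fdr_max: float = EDGE_FDR_MAX,
) -> List[CoexpressionEdge]:
    """Build the coding-noncoding co-expression network.

    ``noncoding_fpkm`` and ``mrna_fpkm`` are expression matrices (rows = ids,
    columns = shared libraries), already restricted to the sex-biased lists.
    When ``gene_map`` is given, coding transcripts are collapsed to genes by
    the per-library median.  FDR is BH over all tested pairs; constant rows
    are excluded.  ``top_k_mrnas`` keeps only the k most significant coding
    genes (by their best pair p-value) before emitting edges.
    """
    shared = [c for c in noncoding_fpkm.columns if c in mrna_fpkm.columns]
    if len(shared) < 3:
        raise ConfigError("need >= 3 shared libraries")
    nc = noncoding_fpkm[shared]
    mr = mrna_fpkm[shared]
    if gene_map is not None:
        genes = pd.Index([gene_map[t] for t in mr.index], name="gene_id")
        mr = mr.groupby(genes).median()

    nc = nc.loc[nc.std(axis=1, ddof=0) > 0]
    mr = mr.loc[mr.std(axis=1, ddof=0) > 0]
    if nc.empty or mr.empty:
        return []

    r, p = _pairwise_pcc(nc.values.astype(float), mr.values.astype(float))
    fdr = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)

    keep = (np.abs(r) >= pcc_min) & (p < p_max) & (fdr < fdr_max)
    edges: List[CoexpressionEdge] = []
    for i, j in zip(*np.nonzero(keep)):
        edges.append(
            CoexpressionEdge(
                noncoding_id=str(nc.index[i]),
                mrna_id=str(mr.index[j]),
                pcc=float(r[i, j]),
                p_value=float(p[i, j]),
                fdr=float(fdr[i, j]),
                sign="positive" if r[i, j] > 0 else "negative",
            )
        )
    if top_k_mrnas is not None and edges:
        best_p: Dict[str, float] = {}
        for j, gid in enumerate(mr.index):
            best_p[str(gid)] = float(np.min(p[:, j]))
        ranked = sorted(best_p, key=lambda g: (best_p[g], g))
        kept = set(ranked[:top_k_mrnas])
        edges = [e for e in edges if e.mrna_id in kept]
    edges.sort(key=lambda e: (e.noncoding_id, e.mrna_id))
    return edges


# ---------------------------------------------------------------------------
# seed-site scanning
# ---------------------------------------------------------------------------

def find_seed_sites(
    target_seq_dna: str,
    mirna: MiRNA,
    target_id: str = "",
    circular: bool = False,
) -> List[SeedSite]:
    """Scan a target (DNA alphabet, transcript orientation) for seed sites.

    A site anchors on a 6-mer match to the reverse complement of miRNA
    nucleotides 2-7; the m8 extension (reverse complement of nucleotide 8
    immediately 5' on the target) and the A1 anchor (an A immediately 3')
    classify it as 8mer, 7mer_m8 or 7mer_A1.  Bare 6-mers are not reported.
    Overlapping sites are all reported.  Circular targets are scanned across
    the junction and positions are reported modulo the sequence length.
    """
    seq = target_seq_dna.upper()
    n = len(seq)
    match7 = mirna.seed_match_dna  # [m8][core 6-mer], 5'->3' on the target
    m8_base = match7[0]
    core6 = match7[1:]
    if n < 6:
        return []
    scan = seq + seq[:7] if circular else seq
    limit = n if circular else n - 5
    sites: List[SeedSite] = []
    for q in range(limit):
        if scan[q : q + 6] != core6:
            continue
        if circular:
            prev = scan[q - 1] if q > 0 else seq[-1]
        else:
            prev = scan[q - 1] if q > 0 else None
        nxt = scan[q + 6] if q + 6 < len(scan) else None
        m8 = prev == m8_base
        a1 = nxt == "A"
        if m8 and a1:
            site_type = "8mer"
        elif m8:
            site_type = "7mer_m8"
        elif a1:
            site_type = "7mer_A1"
        else:
            continue
        start = q - 1 if m8 else q
        if circular:
            start %= n
        sites.append(SeedSite(target_id=target_id, position=start, site_type=site_type))
    return sites


def build_cerna_network(
    sponges: Mapping[str, str],
    mrnas: Mapping[str, str],
    mirnas: Sequence[MiRNA],
    fpkm: pd.DataFrame,
    circular_ids: Optional[Set[str]] = None,
    pcc_threshold: float = CERNA_PCC_MIN,
) -> List[CeRNALink]:
    """Emit (sponge, miRNA, mRNA) links sharing a seed site.

    ``sponges`` maps lncRNA/circRNA ids to sequences (DNA, transcript
    orientation); ids in ``circular_ids`` are scanned circularly.  A link
    needs at least one site for the same miRNA on both molecules plus a
    passing expression-correlation gate; output order is deterministic.
    """
    circular_ids = circular_ids or set()
    sponge_sites: Dict[Tuple[str, str], List[SeedSite]] = {}
    for sid in sorted(sponges):
        for mir in mirnas:
            hits = find_seed_sites(
                sponges[sid], mir, target_id=sid, circular=sid in circular_ids
            )
            if hits:
                sponge_sites[(sid, mir.mirna_id)] = hits
    mrna_sites: Dict[Tuple[str, str], List[SeedSite]] = {}
    for mid in sorted(mrnas):
        for mir in mirnas:
            hits = find_seed_sites(mrnas[mid], mir, target_id=mid)
            if hits:
                mrna_sites[(mid, mir.mirna_id)] = hits

    links: List[CeRNALink] = []
    for sid in sorted(sponges):
        for mir in mirnas:
            s_hits = sponge_sites.get((sid, mir.mirna_id))
            if not s_hits:
                continue
            for mid in sorted(mrnas):
                m_hits = mrna_sites.get((mid, mir.mirna_id))
                if not m_hits:
                    continue
                if sid not in fpkm.index or mid not in fpkm.index:
                    continue
                r, _ = pearson_cc(fpkm.loc[sid].values, fpkm.loc[mid].values)
                if np.isnan(r) or abs(r) < pcc_threshold:
                    continue
                links.append(
                    CeRNALink(
                        sponge_id=sid,
                        mirna_id=mir.mirna_id,
                        mrna_id=mid,
                        sponge_sites=s_hits,
                        mrna_sites=m_hits,
                        expr_pcc=r,
                    )
                )
    links.sort(key=lambda l: (l.sponge_id, l.mirna_id, l.mrna_id))
    return links


def read_mirna_fasta(path) -> List[MiRNA]:
    """Load miRNAs from FASTA (RNA alphabet; T is tolerated and converted)."""
    from Bio import SeqIO

    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append(
            MiRNA(mirna_id=record.id, sequence=str(record.seq).upper().replace("T", "U"))
        )
    return out
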