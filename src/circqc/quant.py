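"""BSJ pseudo-sequences, read counting, ambiguity screening and the
treat/mock depletion classification.

A circRNA candidate is quantified through its junction *pseudo-sequence*:
the last 50 exonic-strand nucleotides ending at the donor site
concatenated with the first 50 starting at the acceptor site, so that a
read spanning the back-splice junction aligns contiguously to it.  A
read counts for a BSJ when its best local alignment covers ≥80% of the
pseudo-sequence (at ≥95% identity over the aligned columns by default)
and extends ≥10 nt into both sides of the junction.  Expression is BSJ
reads per million raw reads (RPM); a candidate with ≥2 mock reads is
*not-depleted* when treated/mock RPM ≥ 1 and *depleted* otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import KmerIndex, local_align
from .io import Annotation, revcomp

logger = logging.getLogger(__name__)

DONOR_FLANK = 50
ACCEPTOR_FLANK = 50


@dataclass(frozen=True)
class CircCandidate:
    """One BSJ event (1-based genomic coordinates).

    ``acceptor_pos`` is the first exonic base of the circle (upstream
    acceptor splice site) and ``donor_pos`` the last exonic base
    (downstream donor); on the + strand donor_pos > acceptor_pos, on the
    − strand donor_pos < acceptor_pos.
    """

    circ_id: str
    chrom: str
    acceptor_pos: int
    donor_pos: int
    strand: str
    gene_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.circ_id}: strand must be + or -")
        if self.strand == "+" and self.donor_pos <= self.acceptor_pos:
            raise ValueError(f"{self.circ_id}: + strand requires donor_pos > acceptor_pos")
        if self.strand == "-" and self.donor_pos >= self.acceptor_pos:
            raise ValueError(f"{self.circ_id}: - strand requires donor_pos < acceptor_pos")


@dataclass(frozen=True)
class PseudoSeq:
    """Junction pseudo-sequence; bases 1..junction_index are donor-side."""

    circ_id: str
    sequence: str
    junction_index: int


@dataclass
class PairQuant:
    circ_id: str
    mock_count: int
    treated_count: int
    mock_total: int
    treated_total: int
    mock_rpm: float = field(init=False)
    treated_rpm: float = field(init=False)
    ratio: float = field(init=False)
    depletion_class: str = field(init=False)
    min_mock_reads: int = 2

    def __post_init__(self):
        if self.mock_total <= 0 or self.treated_total <= 0:
            raise ValueError("raw read totals must be positive")
        self.mock_rpm = self.mock_count * 1e6 / self.mock_total
        self.treated_rpm = self.treated_count * 1e6 / self.treated_total
        self.ratio = (self.treated_rpm / self.mock_rpm) if self.mock_rpm > 0 else float("nan")
        if self.mock_count < self.min_mock_reads:
            self.depletion_class = "excluded"
        elif self.ratio >= 1.0:
            self.depletion_class = "not-depleted"
        else:
            self.depletion_class = "depleted"


@dataclass
class AmbiguityFlag:
    circ_id: str
    has_colinear_explanation: bool
    has_multiple_hits: bool

    @property
    def ambiguous(self) -> bool:
        return self.has_colinear_explanation or self.has_multiple_hits


# ---------------------------------------------------------------------------
# pseudo-sequence construction
# ---------------------------------------------------------------------------

def build_pseudo_seq(candidate: CircCandidate, genome: dict[str, str],
                     donor_flank: int = DONOR_FLANK,
                     acceptor_flank: int = ACCEPTOR_FLANK) -> PseudoSeq:
    """Concatenate the donor-side and acceptor-side BSJ flanks, 5'→3' on
    the transcript; flanks truncated by a chromosome edge shorten the
    pseudo-sequence and shift the junction index accordingly."""
    if candidate.chrom not in genome:
        raise KeyError(f"{candidate.circ_id}: chromosome {candidate.chrom} not in genome")
    chrom = genome[candidate.chrom]
    n = len(chrom)
    for pos in (candidate.acceptor_pos, candidate.donor_pos):
        if not 1 <= pos <= n:
            raise ValueError(f"{candidate.circ_id}: coordinate {pos} outside chromosome")
    if candidate.strand == "+":
        d_start = max(1, candidate.donor_pos - donor_flank + 1)
        donor_side = chrom[d_start - 1:candidate.donor_pos]
        a_end = min(n, candidate.acceptor_pos + acceptor_flank - 1)
        acceptor_side = chrom[candidate.acceptor_pos - 1:a_end]
    else:
        d_end = min(n, candidate.donor_pos + donor_flank - 1)
        donor_side = revcomp(chrom[candidate.donor_pos - 1:d_end])
        a_start = max(1, candidate.acceptor_pos - acceptor_flank + 1)
        acceptor_side = revcomp(chrom[a_start - 1:candidate.acceptor_pos])
    if len(donor_side) < donor_flank or len(acceptor_side) < acceptor_flank:
        warnings.warn(f"{candidate.circ_id}: BSJ flank truncated by chromosome edge "
                      f"({len(donor_side)}+{len(acceptor_side)} nt)", stacklevel=2)
    return PseudoSeq(candidate.circ_id, donor_side + acceptor_side, len(donor_side))


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

@dataclass
class MatchParams:
    min_cover_frac: float = 0.8
    min_span: int = 10
    min_identity: float = 0.95
    check_revcomp: bool = True
    match: int = 1
    mismatch: int = -1
    gap: int = -2


def _alignment_passes(ref_start: int, ref_end: int, matches: int, columns: int,
                      pseudo: PseudoSeq, p: MatchParams) -> bool:
    plen = len(pseudo.sequence)
    coverage = ref_end - ref_start + 1
    if coverage < p.min_cover_frac * plen:
        return False
    if columns > 0 and matches / columns < p.min_identity:
        return False
    left_span = pseudo.junction_index - ref_start + 1
    right_span = ref_end - pseudo.junction_index
    return left_span >= p.min_span and right_span >= p.min_span


def _oriented_match(seq: str, pseudo: PseudoSeq, p: MatchParams) -> bool:
    # exact-substring fast path (identity 1, coverage = read length)
    start = 0
    while True:
        pos = pseudo.sequence.find(seq, start)
        if pos < 0:
            break
        if _alignment_passes(pos + 1, pos + len(seq), len(seq), len(seq), pseudo, p):
            return True
        start = pos + 1
    aln = local_align(seq, pseudo.sequence, p.match, p.mismatch, p.gap)
    if aln is None:
        return False
    return _alignment_passes(aln.ref_start, aln.ref_end, aln.matches, aln.columns, pseudo, p)


def read_matches_bsj(seq: str, pseudo: PseudoSeq, params: MatchParams | None = None) -> bool:
    """Does one read satisfy the BSJ counting rule for this pseudo-sequence?"""
    p = params or MatchParams()
    if _oriented_match(seq, pseudo, p):
        return True
    return p.check_revcomp and _oriented_match(revcomp(seq), pseudo, p)


def count_bsj_reads(reads, pseudo: PseudoSeq, min_cover_frac: float = 0.8,
                    min_span: int = 10, **kwargs) -> int:
    """Count reads supporting a BSJ; each read counts at most once."""
    p = MatchParams(min_cover_frac=min_cover_frac, min_span=min_span, **kwargs)
    n = 0
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        n += read_matches_bsj(seq, pseudo, p)
    return n


class PseudoIndex:
    """Seed-and-verify read assignment across many pseudo-sequences.

    A read is tested against a pseudo-sequence only when the two share
    an exact k-mer.  With the default criteria (coverage ≥ 0.8 × 100 nt
    at identity ≥ 0.95, i.e. ≤ 4 non-matching columns over ≥ 80) any
    passing alignment must contain an exact run ≥ 16 nt, so a 12-mer
    seed filter cannot miss a countable read.
    """

    def __init__(self, pseudos: dict[str, PseudoSeq], params: MatchParams | None = None,
                 seed_k: int = 12):
        self.pseudos = pseudos
        self.params = params or MatchParams()
        self.index = KmerIndex({cid: ps.sequence for cid, ps in pseudos.items()}, seed_k)
        self.seed_k = seed_k

    def assign(self, seq: str, unique: bool = False) -> set[str]:
        """circ_ids whose counting rule this read satisfies."""
        cands = self.index.names_with_seed(seq, step=4)
        if self.params.check_revcomp:
            cands |= self.index.names_with_seed(revcomp(seq), step=4)
        hits = {cid for cid in cands
                if read_matches_bsj(seq, self.pseudos[cid], self.params)}
        if unique and len(hits) > 1:
            return set()
        return hits


class LinearReadFilter:
    """Exact-match filter emulating 'STAR-unmapped reads only': a read
    that matches the linear genome exactly (either strand) cannot be
    junction evidence and is excluded before pseudo-sequence matching."""

    def __init__(self, genome: dict[str, str], k: int = 31):
        self.genome = genome
        self.k = k
        self._anchors: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._anchors.setdefault(seq[i:i + k], []).append((chrom, i))

    def _oriented_linear(self, seq: str) -> bool:
        if len(seq) < self.k:
            return False
        for chrom, pos in self._anchors.get(seq[:self.k], ()):
            if self.genome[chrom][pos:pos + len(seq)] == seq:
                return True
        return False

    def is_linear(self, seq: str) -> bool:
        return self._oriented_linear(seq) or self._oriented_linear(revcomp(seq))


# ---------------------------------------------------------------------------
# ambiguity screen
# ---------------------------------------------------------------------------

def _cluster_loci(hits: list[tuple[str, int, int]], width: int) -> list[tuple[str, int, int]]:
    """Cluster seed hits by (name, diagonal); return (name, lo, hi) windows."""
    from collections import defaultdict
    by_key: dict[tuple[str, int], list[int]] = defaultdict(list)
    for name, rpos, qpos in hits:
        by_key[(name, (rpos - qpos) // width)].append(rpos - qpos)
    out = []
    for (name, _), diags in by_key.items():
        out.append((name, min(diags), max(diags)))
    # merge adjacent buckets on the same name
    merged: list[tuple[str, int, int]] = []
    for name, lo, hi in sorted(out):
        if merged and merged[-1][0] == name and lo - merged[-1][2] <= width:
            merged[-1] = (name, merged[-1][1], max(hi, merged[-1][2]))
        else:
            merged.append((name, lo, hi))
    return merged


class GenomeIndex:
    """Shared k-mer index over the (forward-strand) genome."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.genome = genome
        self.k = k
        self.index = KmerIndex(genome, k)

    def near_matches(self, query: str, min_cover: int, identity_thresh: float,
                     pad: int = 30) -> list[tuple[str, int, int]]:
        """Distinct genomic loci where query (either strand) aligns with
        ≥ min_cover aligned reference bases at ≥ identity_thresh."""
        loci: list[tuple[str, int, int]] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            hits = self.index.hits(q, step=4)
            for chrom, lo, hi in _cluster_loci(hits, len(q)):
                w_lo = max(0, lo - pad)
                w_hi = min(len(self.genome[chrom]), hi + len(q) + pad)
                aln = local_align(q, self.genome[chrom][w_lo:w_hi])
                if aln is None or aln.columns == 0:
                    continue
                cover = aln.ref_end - aln.ref_start + 1
                if cover >= min_cover and aln.matches / aln.columns >= identity_thresh:
                    loci.append((chrom, strand == "-", w_lo + aln.ref_start))
        # deduplicate loci closer than the query length
        loci.sort()
        dedup: list[tuple[str, int, int]] = []
        for chrom, rc, pos in loci:
            if dedup and dedup[-1][0] == chrom and dedup[-1][1] == rc \
                    and abs(pos - dedup[-1][2]) < len(query):
                continue
            dedup.append((chrom, rc, pos))
        return dedup


def screen_ambiguity(candidate: CircCandidate, pseudo: PseudoSeq,
                     genome: dict[str, str], annotation: Annotation | None = None,
                     identity_thresh: float = 0.9,
                     max_colinear_window: int | None = None,
                     genome_index: GenomeIndex | None = None,
                     transcript_seqs: dict[str, str] | None = None,
                     transcript_index: KmerIndex | None = None) -> AmbiguityFlag:
    """Flag candidates with an alternative colinear explanation or
    multiple genomic matches (simplified seed-and-verify screen).

    *Colinear explanation*: the full pseudo-sequence aligns to a single
    contiguous genomic window (≤ ``max_colinear_window``, default twice
    its length) or to an annotated transcript's spliced sequence at
    ≥ ``identity_thresh`` identity over ≥ 80% of its length.
    *Multiple hits*: either 50-nt half matches ≥ 2 distinct genomic loci
    at ≥ ``identity_thresh`` over ≥ 90% of the half.
    """
    gidx = genome_index or GenomeIndex(genome)
    plen = len(pseudo.sequence)
    window = max_colinear_window or 2 * plen

    colinear = False
    for chrom, _rc, _pos in gidx.near_matches(pseudo.sequence,
                                              min_cover=int(np.ceil(0.8 * plen)),
                                              identity_thresh=identity_thresh,
                                              pad=window - plen):
        colinear = True
        break
    if not colinear and annotation is not None:
        if transcript_seqs is None:
            transcript_seqs = {t.transcript_id: t.spliced_sequence(genome)
                               for t in annotation.transcripts()}
        tidx = transcript_index or KmerIndex(transcript_seqs, 16)
        names = tidx.names_with_seed(pseudo.sequence, step=4) \
            | tidx.names_with_seed(revcomp(pseudo.sequence), step=4)
        for name in names:
            for q in (pseudo.sequence, revcomp(pseudo.sequence)):
                aln = local_align(q, transcript_seqs[name])
                if aln is None or aln.columns == 0:
                    continue
                cover = aln.ref_end - aln.ref_start + 1
                if cover >= 0.8 * plen and aln.matches / aln.columns >= identity_thresh:
                    colinear = True
                    break
            if colinear:
                break

    multiple = False
    ji = pseudo.junction_index
    for half in (pseudo.sequence[:ji], pseudo.sequence[ji:]):
        if len(half) < gidx.k:
            continue
        loci = gidx.near_matches(half, min_cover=int(np.ceil(0.9 * len(half))),
                                 identity_thresh=identity_thresh)
        if len(loci) >= 2:
            multiple = True
            break
    return AmbiguityFlag(candidate.circ_id, colinear, multiple)


# ---------------------------------------------------------------------------
# pair quantification
# ---------------------------------------------------------------------------

def candidates_from_frame(df: pd.DataFrame) -> list[CircCandidate]:
    return [CircCandidate(r.circ_id, r.chrom, int(r.acceptor_pos), int(r.donor_pos),
                          r.strand, getattr(r, "gene_id", ""))
            for r in df.itertuples(index=False)]


def quantify_pair(candidates, genome: dict[str, str],
                  mock_reads, mock_total: int,
                  treated_reads, treated_total: int,
                  min_mock_reads: int = 2,
                  params: MatchParams | None = None,
                  unique_assignment: bool = False,
                  exclude_linear: bool = True,
                  linear_filter: LinearReadFilter | None = None) -> pd.DataFrame:
    """Count BSJ reads for every candidate in both samples and classify.

    ``candidates`` is a candidate DataFrame or list of CircCandidate;
    reads are (id, sequence) pairs or bare sequences.  Reads matching
    the linear genome exactly are excluded first (``exclude_linear``),
    emulating alignment of genome-unmapped reads only; raw totals stay
    the RPM denominators either way.  Returns one row per candidate
    with counts, RPM, treat/mock ratio and depletion class.
    """
    if mock_total <= 0 or treated_total <= 0:
        raise ValueError("raw read totals must be positive")
    if isinstance(candidates, pd.DataFrame):
        candidates = candidates_from_frame(candidates)
    pseudos = {c.circ_id: build_pseudo_seq(c, genome) for c in candidates}
    index = PseudoIndex(pseudos, params)
    lin = (linear_filter or LinearReadFilter(genome)) if exclude_linear else None

    def tally(reads) -> dict[str, int]:
        counts = dict.fromkeys(pseudos, 0)
        for read in reads:
            seq = read[1] if isinstance(read, tuple) else read
            if lin is not None and lin.is_linear(seq):
                continue
            for cid in index.assign(seq, unique=unique_assignment):
                counts[cid] += 1
        return counts

    mock_counts = tally(mock_reads)
    treated_counts = tally(treated_reads)
    rows = []
    for cid in pseudos:
        pq = PairQuant(cid, mock_counts[cid], treated_counts[cid],
                       mock_total, treated_total, min_mock_reads=min_mock_reads)
        rows.append({"circ_id": cid, "mock_count": pq.mock_count,
                     "treated_count": pq.treated_count,
                     "mock_total": pq.mock_total, "treated_total": pq.treated_total,
                     "mock_rpm": pq.mock_rpm, "treated_rpm": pq.treated_rpm,
                     "ratio": pq.ratio, "depletion_class": pq.depletion_class})
    logger.info("quantified %d candidates: %d mock-detected, %d analyzable (≥%d mock reads)",
                len(rows), sum(c > 0 for c in mock_counts.values()),
                sum(c >= min_mock_reads for c in mock_counts.values()), min_mock_reads)
    return pd.DataFrame(rows)


def check_pair_inclusion(quant: pd.DataFrame, min_mock_circ: int = 600,
                         min_overlap_frac: float = 1 / 3,
                         min_detect_reads: int = 1) -> dict:
    """Sample-pair inclusion rule: > min_mock_circ candidates detected in
    mock AND more than min_overlap_frac of them also detected in treated."""
    mock_det = quant["mock_count"] >= min_detect_reads
    n_mock = int(mock_det.sum())
    n_overlap = int((mock_det & (quant["treated_count"] >= min_detect_reads)).sum())
    frac = n_overlap / n_mock if n_mock else 0.0
    passed = (n_mock > min_mock_circ) and (frac > min_overlap_frac)
    return {"pass": bool(passed), "n_mock_detected": n_mock,
            "n_overlap": n_overlap, "overlap_frac": frac}
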