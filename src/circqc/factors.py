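"""Per-candidate reliability factors.

Factors fall into four families: identification (BSJ read count,
multi-tool detection, full-length reconstruction), conservation
(species/tissue/sample counts, evolutionary rates around the junction),
biogenesis (annotated boundaries, same-isoform support, alternative
splicing, reverse-complementary sequences in the flanking regions,
RBP binding near the junction) and function (junction-spanning
G-quadruplex/miRNA/RBP sites and the count of functional features).
The *supporting-factor count* summarises seven thresholded indicators
per candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Annotation, ScoreTrack, revcomp
from .quant import CircCandidate

logger = logging.getLogger(__name__)

SPAN_MINIMA = {"G4": 5, "miRNA": 5, "RBP": 2}

SUPPORTING_FACTORS = ["multi_tool", "full_length", "n_samples", "both_annotated",
                      "same_isoform", "both_AS", "n_functional_features"]

FUNCTIONAL_FEATURE_COLUMNS = [
    "feat_ribosome", "feat_tis", "feat_ires", "feat_m6a", "feat_orf",
    "feat_orf_score", "feat_ms_peptide", "feat_mirna_span", "feat_rbp_span",
]


@dataclass(frozen=True)
class SiteInterval:
    """A predicted site on the 100-nt BSJ pseudo-sequence (1-based)."""

    circ_id: str
    kind: str  # G4 | miRNA | RBP
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.circ_id}: invalid site interval [{self.start},{self.end}]")


# ---------------------------------------------------------------------------
# annotation agreement and alternative splicing
# ---------------------------------------------------------------------------

def _locus_transcripts(candidate: CircCandidate, annotation: Annotation):
    txs = []
    seen = set()
    gene = annotation.genes.get(candidate.gene_id)
    if gene is not None:
        for t in gene.transcripts.values():
            txs.append(t)
            seen.add(t.transcript_id)
    for pos in (candidate.donor_pos, candidate.acceptor_pos):
        for g in annotation.genes_overlapping(candidate.chrom, pos):
            for t in g.transcripts.values():
                if t.transcript_id not in seen:
                    txs.append(t)
                    seen.add(t.transcript_id)
    return [t for t in txs if t.strand == candidate.strand and t.chrom == candidate.chrom]


def annotate_boundaries(candidate: CircCandidate, annotation: Annotation,
                        ) -> tuple[bool, bool, bool, bool]:
    """(donor_annotated, acceptor_annotated, both_annotated, same_isoform).

    A donor is annotated when it equals an exon 3' boundary (strand
    aware) of any transcript at the locus; the acceptor analogously for
    exon 5' boundaries.  same_isoform requires one transcript to carry
    both boundaries.
    """
    txs = _locus_transcripts(candidate, annotation)
    donor_ok = any(candidate.donor_pos in t.donor_sites() for t in txs)
    acceptor_ok = any(candidate.acceptor_pos in t.acceptor_sites() for t in txs)
    both = donor_ok and acceptor_ok
    same_iso = both and any(candidate.donor_pos in t.donor_sites()
                            and candidate.acceptor_pos in t.acceptor_sites()
                            for t in txs)
    return donor_ok, acceptor_ok, both, same_iso


def _site_is_AS(pos: int, kind: str, txs, use_partner_rule: bool = True,
                use_skip_rule: bool = True) -> bool:
    """AS when, within one gene's transcript set, (a) the site pairs with
    ≥2 distinct intron partner sites or (b) it is unused in a transcript
    whose span covers it.  Only annotated sites can be AS, and the rules
    are evaluated gene by gene so an overlapping neighbour gene cannot
    make a constitutive site look alternative."""
    from collections import defaultdict

    def used(t):
        return pos in (t.donor_sites() if kind == "donor" else t.acceptor_sites())

    by_gene = defaultdict(list)
    for t in txs:
        by_gene[t.gene_id].append(t)
    for gene_txs in by_gene.values():
        if not any(used(t) for t in gene_txs):
            continue
        if use_partner_rule:
            partners = set()
            for t in gene_txs:
                for don, acc in t.introns():
                    if kind == "donor" and don == pos:
                        partners.add(acc)
                    elif kind == "acceptor" and acc == pos:
                        partners.add(don)
            if len(partners) >= 2:
                return True
        if use_skip_rule:
            for t in gene_txs:
                lo, hi = t.span
                if lo <= pos <= hi and not used(t):
                    return True
    return False


def annotate_AS(candidate: CircCandidate, annotation: Annotation,
                use_partner_rule: bool = True, use_skip_rule: bool = True,
                ) -> tuple[bool, bool, bool]:
    """(donor_AS, acceptor_AS, both_AS) for the candidate's splice sites."""
    txs = _locus_transcripts(candidate, annotation)
    d = _site_is_AS(candidate.donor_pos, "donor", txs, use_partner_rule, use_skip_rule)
    a = _site_is_AS(candidate.acceptor_pos, "acceptor", txs, use_partner_rule, use_skip_rule)
    return d, a, d and a


# ---------------------------------------------------------------------------
# reverse-complementary sequences (RCS)
# ---------------------------------------------------------------------------

def _window_hashes(seq: str, L: int) -> np.ndarray:
    """Polynomial rolling hashes (mod 2^64) of all L-mers of seq."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.uint64)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    base = 1099511628211
    pw, acc = [], 1
    for _ in range(L):
        pw.append(acc)
        acc = (acc * base) % (1 << 64)
    powers = np.array(pw, dtype=np.uint64)
    from numpy.lib.stride_tricks import sliding_window_view
    windows = sliding_window_view(codes, L)
    return (windows * powers[::-1]).sum(axis=1, dtype=np.uint64)


def _maximal_rc_matches(a: str, b: str, min_len: int) -> set[tuple[int, int, int]]:
    """Maximal exact matches ≥ min_len between a and revcomp(b),
    reported as (start_in_a, start_in_revcomp_b, length), 0-based.
    Anchoring uses rolling hashes; every anchor is verified by direct
    string comparison before extension, so collisions cannot create
    spurious matches."""
    rb = revcomp(b)
    if len(a) < min_len or len(rb) < min_len:
        return set()
    ha = _window_hashes(a, min_len)
    hb = _window_hashes(rb, min_len)
    anchors: dict[int, list[int]] = {}
    common = set(ha.tolist()) & set(hb.tolist())
    if not common:
        return set()
    for j, h in enumerate(hb.tolist()):
        if h in common:
            anchors.setdefault(h, []).append(j)
    out: set[tuple[int, int, int]] = set()
    seen_diag: set[tuple[int, int]] = set()
    for i, h in enumerate(ha.tolist()):
        for j in anchors.get(h, ()):
            if a[i:i + min_len] != rb[j:j + min_len]:  # hash collision
                continue
            diag = i - j
            # extend left
            li, lj = i, j
            while li > 0 and lj > 0 and a[li - 1] == rb[lj - 1]:
                li, lj = li - 1, lj - 1
            key = (diag, li)
            if key in seen_diag:
                continue
            seen_diag.add(key)
            # extend right
            ri, rj = i + min_len, j + min_len
            while ri < len(a) and rj < len(rb) and a[ri] == rb[rj]:
                ri, rj = ri + 1, rj + 1
            out.add((li, lj, ri - li))
    return out


def _rc_matches_within(f: str, min_len: int) -> int:
    """Count unordered hairpin pairs within a single flank: maximal
    segments x, y (x before y) with y = revcomp(x), length ≥ min_len."""
    matches = _maximal_rc_matches(f, f, min_len)
    n = len(f)
    pairs = set()
    for i, j, length in matches:
        # j indexes revcomp(f); map back to a forward-strand segment
        y_start = n - j - length
        lo, hi = sorted((i, y_start))
        if lo == hi:  # self reverse-palindrome, not a pair
            continue
        pairs.add((lo, hi, length))
    return len(pairs)


def count_rcs(candidate: CircCandidate, genome: dict[str, str],
              window: int = 20_000, min_len: int = 30,
              within_aggregate: str = "sum") -> tuple[int, int]:
    """(rcs_across, rcs_within): maximal exact reverse-complement match
    pairs ≥ min_len between the two BSJ flanking regions (±window nt),
    and within each individual flank (summed by default).

    Flanks are genomic: the upstream flank lies 5' of the acceptor and
    the downstream flank 3' of the donor (strand-aware), truncated at
    chromosome ends.
    """
    chrom = genome[candidate.chrom]
    n = len(chrom)
    if candidate.strand == "+":
        up = chrom[max(0, candidate.acceptor_pos - 1 - window):candidate.acceptor_pos - 1]
        down = chrom[candidate.donor_pos:min(n, candidate.donor_pos + window)]
    else:
        up = revcomp(chrom[candidate.acceptor_pos:min(n, candidate.acceptor_pos + window)])
        down = revcomp(chrom[max(0, candidate.donor_pos - 1 - window):candidate.donor_pos - 1])
    across = len(_maximal_rc_matches(up, down, min_len))
    withins = [_rc_matches_within(up, min_len), _rc_matches_within(down, min_len)]
    within = sum(withins) if within_aggregate == "sum" else max(withins)
    return across, within


# ---------------------------------------------------------------------------
# RBP flanks, junction-spanning sites, evolutionary rates
# ---------------------------------------------------------------------------

def rbp_flank_overlap(candidate: CircCandidate, clip_sites: pd.DataFrame,
                      flank: int = 1000) -> tuple[bool, float]:
    """(rbp_flank, rbp_min_dist): does any CLIP interval fall within
    ±flank nt of either BSJ coordinate, and the minimum distance from a
    site edge to the nearer coordinate (0 when overlapping it).

    ``clip_sites`` has 1-based inclusive columns chrom/start/end.
    Returns (False, nan) for an empty site table.
    """
    sites = clip_sites[clip_sites["chrom"] == candidate.chrom]
    if not len(sites):
        return False, float("nan")
    dists = []
    for pos in (candidate.donor_pos, candidate.acceptor_pos):
        inside = (sites["start"] <= pos) & (pos <= sites["end"])
        d = np.where(inside, 0, np.minimum(np.abs(sites["start"] - pos),
                                           np.abs(sites["end"] - pos)))
        dists.append(d.min())
    min_dist = float(min(dists))
    return min_dist <= flank, min_dist


def span_filter(sites: list[SiteInterval], junction_index: int = 50,
                min_span: dict[str, int] | None = None,
                pseudo_len: int = 100) -> dict[str, bool]:
    """Per-kind flags: does ≥1 site span the junction by ≥ min_span[kind]
    on both sides?  Defaults G4=5, miRNA=5, RBP=2."""
    minima = dict(SPAN_MINIMA)
    if min_span:
        minima.update(min_span)
    flags = dict.fromkeys(minima, False)
    for s in sites:
        if s.end > pseudo_len:
            raise ValueError(f"{s.circ_id}: site [{s.start},{s.end}] outside "
                             f"pseudo-sequence 1..{pseudo_len}")
        if s.kind not in minima:
            raise ValueError(f"unknown site kind {s.kind!r}")
        need = minima[s.kind]
        left = junction_index - s.start + 1
        right = s.end - junction_index
        if left >= need and right >= need:
            flags[s.kind] = True
    return flags


EVO_REGIONS = ["acceptor_exon", "acceptor_intron", "donor_exon", "donor_intron"]


def evo_rate_regions(candidate: CircCandidate, track: ScoreTrack,
                     region_len: int = 10) -> dict[str, float]:
    """Mean conservation score over the four 10-nt windows around the
    BSJ: just inside/outside the acceptor and just inside/outside the
    donor, strand-aware.  Missing bases are skipped; a fully missing
    region yields NaN."""
    a, d = candidate.acceptor_pos, candidate.donor_pos
    L = region_len
    if candidate.strand == "+":
        windows = {"acceptor_exon": (a, a + L - 1), "acceptor_intron": (a - L, a - 1),
                   "donor_exon": (d - L + 1, d), "donor_intron": (d + 1, d + L)}
    else:
        windows = {"acceptor_exon": (a - L + 1, a), "acceptor_intron": (a + 1, a + L),
                   "donor_exon": (d, d + L - 1), "donor_intron": (d - L, d - 1)}
    out = {}
    for name, (lo, hi) in windows.items():
        mean, n_cov = track.window_mean(candidate.chrom, lo, hi)
        out[name] = mean
        out[f"{name}_n"] = n_cov
    return out


# ---------------------------------------------------------------------------
# functional features, supporting factors, G4 detector
# ---------------------------------------------------------------------------

def count_functional_features(flags) -> int:
    """Number of true indicators among the nine functional features
    (seven coding-potential evidence types plus junction-spanning miRNA
    and RBP sites); missing values count as false."""
    vals = list(flags.values()) if isinstance(flags, dict) else list(flags)
    if len(vals) != 9:
        raise ValueError(f"expected 9 feature indicators, got {len(vals)}")
    return int(sum(bool(v) and not pd.isna(v) for v in vals))


def count_supporting_factors(row, cutoff_counts: int = 3) -> int:
    """Count of the seven supporting reliability indicators: multi-tool,
    full-length, ≥cutoff samples, both boundaries annotated, same
    isoform, both sites AS, ≥cutoff functional features."""
    get = row.get if hasattr(row, "get") else row.__getitem__
    n = 0
    for flag in ("multi_tool", "full_length", "both_annotated", "same_isoform", "both_AS"):
        v = get(flag)
        n += bool(v) and not pd.isna(v)
    for count_col in ("n_samples", "n_functional_features"):
        v = get(count_col)
        n += (not pd.isna(v)) and v >= cutoff_counts
    return n


def find_g4(seq: str, min_g_run: int = 2, max_loop: int = 36, max_total: int = 30,
            ) -> list[tuple[int, int]]:
    """Optional built-in G-quadruplex detector: four runs of ≥min_g_run
    G separated by loops ≤max_loop nt, total span ≤max_total nt.
    Returns 1-based (start, end) intervals (presence only, no score)."""
    import re
    pat = re.compile(
        "(G{%d,})" % min_g_run + ("([ACGTN]{0,%d}?)(G{%d,})" % (max_loop, min_g_run)) * 3)
    out = []
    for m in pat.finditer(seq):
        if m.end() - m.start() <= max_total:
            out.append((m.start() + 1, m.end()))
    return out


# ---------------------------------------------------------------------------
# the factor matrix
# ---------------------------------------------------------------------------

def build_factor_matrix(candidates: pd.DataFrame, annotation: Annotation | None = None,
                        genome: dict[str, str] | None = None,
                        clip_sites: pd.DataFrame | None = None,
                        conservation: ScoreTrack | None = None,
                        site_table: pd.DataFrame | None = None,
                        bsj_read_counts: pd.Series | None = None,
                        rcs_window: int = 20_000, rcs_min_len: int = 30,
                        rbp_flank: int = 1000, cutoff_counts: int = 3,
                        compute_g4: bool = False) -> pd.DataFrame:
    """Assemble every examined factor per candidate into one table.

    Identification/conservation columns (n_tools, full_length,
    n_samples, tissue_specificity_index, splice-site strengths,
    functional-feature flags) pass through from the candidate table;
    annotation, AS, RCS, RBP, junction-span and evolutionary-rate
    factors are computed when their inputs are supplied, otherwise left
    missing (candidates drop only from analyses that use the missing
    factor).
    """
    from .quant import build_pseudo_seq, candidates_from_frame

    cands = candidates_from_frame(candidates)
    df = candidates.set_index("circ_id", drop=False).copy()

    if "n_tools" in df.columns and "multi_tool" not in df.columns:
        df["multi_tool"] = df["n_tools"] >= 2
    if bsj_read_counts is not None:
        df["bsj_read_count"] = bsj_read_counts.reindex(df.index)

    if annotation is not None:
        ann_rows = []
        for c in cands:
            don, acc, both, same = annotate_boundaries(c, annotation)
            d_as, a_as, both_as = annotate_AS(c, annotation)
            ann_rows.append({"circ_id": c.circ_id, "donor_annotated": don,
                             "acceptor_annotated": acc, "both_annotated": both,
                             "same_isoform": same, "donor_AS": d_as,
                             "acceptor_AS": a_as, "both_AS": both_as})
        df = df.join(pd.DataFrame(ann_rows).set_index("circ_id"))

    if genome is not None:
        rcs_rows = []
        for c in cands:
            across, within = count_rcs(c, genome, rcs_window, rcs_min_len)
            rcs_rows.append({"circ_id": c.circ_id, "rcs_across": across,
                             "rcs_within": within, "rcs_diff": across - within})
        df = df.join(pd.DataFrame(rcs_rows).set_index("circ_id"))

    if clip_sites is not None:
        rbp_rows = []
        for c in cands:
            flag, dist = rbp_flank_overlap(c, clip_sites, rbp_flank)
            rbp_rows.append({"circ_id": c.circ_id, "rbp_flank": flag,
                             "rbp_min_dist": dist})
        df = df.join(pd.DataFrame(rbp_rows).set_index("circ_id"))

    if conservation is not None:
        evo_rows = []
        for c in cands:
            evo_rows.append({"circ_id": c.circ_id,
                             **{f"evo_{k}": v
                                for k, v in evo_rate_regions(c, conservation).items()}})
        df = df.join(pd.DataFrame(evo_rows).set_index("circ_id"))

    span_flags = {}
    if site_table is not None:
        for c in cands:
            rows = site_table[site_table["circ_id"] == c.circ_id]
            sites = [SiteInterval(c.circ_id, r.kind, int(r.start), int(r.end))
                     for r in rows.itertuples(index=False)]
            span_flags[c.circ_id] = span_filter(sites)
    if compute_g4 and genome is not None and not span_flags:
        for c in cands:
            ps = build_pseudo_seq(c, genome)
            g4 = find_g4(ps.sequence)
            sites = [SiteInterval(c.circ_id, "G4", s, e) for s, e in g4]
            span_flags[c.circ_id] = span_filter(sites, junction_index=ps.junction_index,
                                                pseudo_len=len(ps.sequence))
    if span_flags:
        sf = pd.DataFrame(span_flags).T
        sf.columns = [f"{k.lower()}_span" for k in sf.columns]
        df = df.join(sf)
        for kind in ("mirna", "rbp"):
            col = f"feat_{kind}_span"
            if col in df.columns:
                df[col] = df[f"{kind}_span"]

    feat_cols = [c for c in FUNCTIONAL_FEATURE_COLUMNS if c in df.columns]
    if len(feat_cols) == 9 and "n_functional_features" not in candidates.columns:
        df["n_functional_features"] = df[feat_cols].fillna(False).astype(bool).sum(axis=1)
    elif "n_functional_features" not in df.columns:
        logger.warning("functional feature flags incomplete (%d/9); "
                       "n_functional_features left missing", len(feat_cols))
        df["n_functional_features"] = np.nan

    needed = {"multi_tool", "full_length", "n_samples", "both_annotated",
              "same_isoform", "both_AS", "n_functional_features"}
    if needed <= set(df.columns):
        df["n_supporting_factors"] = [
            count_supporting_factors(row, cutoff_counts)
            for _, row in df[list(needed)].iterrows()]
    return df.reset_index(drop=True)
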