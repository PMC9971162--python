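"""Readers, writers and in-memory containers for the toy genomics formats.

Conventions
-----------
All genomic coordinates are **1-based inclusive** internally, matching
GTF and the candidate tables this package consumes and emits.  BED and
bedGraph inputs (0-based half-open) are converted on read.  Output
tables carry a comment header naming the coordinate convention; readers
skip ``#`` comment lines.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_RC)[::-1]


class FormatError(ValueError):
    """Raised when an input record violates a format contract."""


# ---------------------------------------------------------------------------
# annotation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise FormatError(f"exon end {self.end} < start {self.start}")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def sort_exons(self) -> None:
        self.exons.sort(key=lambda e: e.start)

    # strand-aware splice-site sets -------------------------------------
    def donor_sites(self) -> set[int]:
        """Genomic positions acting as exon 3' (donor-side) boundaries."""
        if self.strand == "+":
            return {e.end for e in self.exons}
        return {e.start for e in self.exons}

    def acceptor_sites(self) -> set[int]:
        """Genomic positions acting as exon 5' (acceptor-side) boundaries."""
        if self.strand == "+":
            return {e.start for e in self.exons}
        return {e.end for e in self.exons}

    def introns(self) -> list[tuple[int, int]]:
        """(donor_site, acceptor_site) pairs of consecutive introns, 5'→3'."""
        ex = sorted(self.exons, key=lambda e: e.start)
        pairs = []
        for a, b in zip(ex, ex[1:]):
            if self.strand == "+":
                pairs.append((a.end, b.start))
            else:
                pairs.append((b.start, a.end))
        if self.strand == "-":
            pairs = [(d, a) for (d, a) in pairs]
        return pairs

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        chrom = genome[self.chrom]
        seq = "".join(chrom[e.start - 1:e.end] for e in sorted(self.exons, key=lambda e: e.start))
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts.values()]
        ends = [t.span[1] for t in self.transcripts.values()]
        return min(starts), max(ends)


class Annotation:
    """Gene/transcript/exon models keyed by gene, with locus lookups."""

    def __init__(self, genes: dict[str, Gene] | None = None):
        self.genes: dict[str, Gene] = genes or {}

    def add_exon(self, gene_id: str, transcript_id: str, chrom: str, strand: str,
                 start: int, end: int) -> None:
        gene = self.genes.setdefault(gene_id, Gene(gene_id, chrom, strand))
        tx = gene.transcripts.setdefault(
            transcript_id, Transcript(transcript_id, gene_id, chrom, strand))
        tx.exons.append(Exon(start, end))

    def finalize(self) -> "Annotation":
        for g in self.genes.values():
            for t in g.transcripts.values():
                t.sort_exons()
        return self

    def transcripts(self):
        for g in self.genes.values():
            yield from g.transcripts.values()

    def genes_overlapping(self, chrom: str, pos: int) -> list[Gene]:
        out = []
        for g in self.genes.values():
            if g.chrom != chrom or not g.transcripts:
                continue
            s, e = g.span
            if s <= pos <= e:
                out.append(g)
        return out


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> Annotation:
    """Parse exon features of a GTF (1-based inclusive) into an Annotation.

    Raises FormatError naming the offending line on malformed records.
    """
    ann = Annotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: exon end {end_i} < start {start_i}")
            if start_i < 1:
                raise FormatError(f"{path}:{lineno}: coordinates are 1-based; got start {start_i}")
            a = _parse_gtf_attrs(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise FormatError(f"{path}:{lineno}: missing gene_id/transcript_id attribute")
            ann.add_exon(a["gene_id"], a["transcript_id"], chrom, strand, start_i, end_i)
    return ann.finalize()


def write_gtf(ann: Annotation, path: str | Path, source: str = "circqc") -> None:
    with open(path, "w") as fh:
        fh.write("#!coordinates: 1-based inclusive\n")
        for gene in ann.genes.values():
            s, e = gene.span
            fh.write("\t".join([gene.chrom, source, "gene", str(s), str(e), ".",
                                gene.strand, ".", f'gene_id "{gene.gene_id}";']) + "\n")
            for tx in gene.transcripts.values():
                ts, te = tx.span
                attr = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write("\t".join([gene.chrom, source, "transcript", str(ts), str(te),
                                    ".", gene.strand, ".", attr]) + "\n")
                for ex in tx.exons:
                    fh.write("\t".join([gene.chrom, source, "exon", str(ex.start),
                                        str(ex.end), ".", gene.strand, ".", attr]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ reads as (id, sequence) pairs."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = ["circ_id", "chrom", "acceptor_pos", "donor_pos", "strand", "gene_id"]

_TABLE_HEADER = "# coordinates: 1-based inclusive; counts: reads; rpm: reads per million raw reads\n"


def write_table(df: pd.DataFrame, path: str | Path, header: str = _TABLE_HEADER) -> None:
    """Write a TSV with a comment line naming units and coordinate convention."""
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_candidates(path: str | Path, genome: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a candidate circRNA table (TSV, 1-based BSJ coordinates).

    Validates the strand/orientation invariant (donor downstream of
    acceptor on the transcript) and, when a genome is supplied, that the
    coordinates lie inside their chromosome.
    """
    df = read_table(path)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"candidate table missing columns: {missing}")
    bad_plus = (df["strand"] == "+") & (df["donor_pos"] <= df["acceptor_pos"])
    bad_minus = (df["strand"] == "-") & (df["donor_pos"] >= df["acceptor_pos"])
    bad = df.loc[bad_plus | bad_minus, "circ_id"]
    if len(bad):
        raise FormatError(
            "backsplice orientation violated (donor must be downstream of "
            f"acceptor): {', '.join(map(str, bad.head(5)))}")
    if genome is not None:
        for _, row in df.iterrows():
            if row["chrom"] not in genome:
                raise FormatError(f"{row['circ_id']}: chromosome {row['chrom']} not in genome")
            clen = len(genome[row["chrom"]])
            for col in ("acceptor_pos", "donor_pos"):
                if not 1 <= row[col] <= clen:
                    raise FormatError(
                        f"{row['circ_id']}: {col}={row[col]} outside chromosome (1..{clen})")
    return df


def write_candidates(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED (0-based half-open) file; returns 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs ≥3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty/negative interval")
            name = parts[3] if len(parts) > 3 else f"site{lineno}"
            rows.append((chrom, start + 1, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# per-base score track (conservation)
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Sparse per-base score track, 1-based positions."""

    def __init__(self, scores: dict[str, dict[int, float]] | None = None):
        self._scores = scores or {}

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ScoreTrack":
        scores: dict[str, dict[int, float]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split()[:4]
                d = scores.setdefault(chrom, {})
                for pos in range(int(start) + 1, int(end) + 1):  # 0-based half-open → 1-based
                    d[pos] = float(value)
        return cls(scores)

    @classmethod
    def constant(cls, genome: dict[str, str], value: float) -> "ScoreTrack":
        return cls({c: dict.fromkeys(range(1, len(s) + 1), value) for c, s in genome.items()})

    def get(self, chrom: str, pos: int) -> float:
        return self._scores.get(chrom, {}).get(pos, np.nan)

    def window_mean(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Mean over covered bases of [start, end]; returns (mean, n_covered)."""
        vals = [self._scores.get(chrom, {}).get(p) for p in range(start, end + 1)]
        vals = [v for v in vals if v is not None]
        if not vals:
            return np.nan, 0
        return float(np.mean(vals)), len(vals)


def read_bedgraph(path: str | Path) -> ScoreTrack:
    return ScoreTrack.from_bedgraph(path)


def read_labelset(path: str | Path) -> set[str]:
    """One circ_id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
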