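"""Synthetic genome, circRNA candidates and mock/treated read pairs.

The generator emulates the statistical structure the reliability
analysis assumes:

* a toy multi-gene genome with single-isoform genes, exon-skipping genes
  and alternative-donor/acceptor genes, so the annotation-derived
  factors (annotated boundaries, same isoform, alternative splicing)
  have both positive and negative cases by construction;
* a candidate set that mixes true circRNAs and artifacts, with factor
  values drawn **class-conditionally** so that the log-odds of being a
  true circRNA is (approximately, exactly for unconstrained factors)
  the linear combination specified by ``factor_effects``;
* paired mock/treated read sets in which back-splice-junction (BSJ)
  molecules survive the treatment with a class-dependent retention
  probability, while linear background reads fill the library.

Everything is driven by a single master seed; each stage draws from its
own child stream so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Annotation, revcomp


class SimulationError(ValueError):
    pass


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


DEFAULT_FACTOR_EFFECTS: dict[str, float] = {
    # per-unit logistic coefficients on the log-odds of being a true circRNA
    "bsj_read_count": 0.12,
    "multi_tool": 1.2,
    "full_length": 2.0,
    "n_samples": 0.5,
    "both_annotated": 1.2,
    "same_isoform": 1.0,
    "both_AS": 0.8,
    "n_functional_features": 0.4,
}

DEFAULT_FACTOR_BASE: dict[str, float] = {
    # artifact-class base rates / rate parameters
    "multi_tool": 0.35,
    "full_length": 0.15,
    "n_samples_lambda": 1.2,       # n_samples = 1 + Poisson(lambda)
    "both_annotated": 0.35,
    "same_isoform": 0.45,          # conditional on both_annotated
    "both_AS": 0.35,               # conditional on both_annotated
    "n_functional_features": 0.12,  # Binomial(9, p) success prob
}

FUNCTIONAL_FEATURES = [
    "feat_ribosome", "feat_tis", "feat_ires", "feat_m6a", "feat_orf",
    "feat_orf_score", "feat_ms_peptide", "feat_mirna_span", "feat_rbp_span",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Depletion follows the three treatment-group design (1: RNase R,
    2: A-tailing + RNase R, 3: non-poly(A) selection); each group maps
    to ``(retain_prob_true, retain_prob_artifact)`` — the probability
    that a mock BSJ molecule survives into the treated library for true
    circRNAs and artifacts respectively.  Treated libraries are smaller
    than mock libraries because linear RNA is digested, so a retained
    circRNA gains in RPM.
    """

    genome_n_chroms: int = 2
    chrom_len: int = 120_000
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (80, 260)
    intron_len: tuple[int, int] = (150, 900)
    isoform_fraction: float = 0.6
    companion_fraction: float = 0.5
    n_circ_true: int = 150
    n_circ_artifact: int = 150
    depletion_model: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.9, 0.1), 2: (0.85, 0.08), 3: (0.8, 0.15)})
    factor_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_EFFECTS))
    factor_base: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_BASE))
    mean_mock_reads: float = 12.0
    library_size_mock: int = 60_000
    library_size_treated: int = 30_000
    read_len: int = 90
    chimera_fraction: float = 0.3
    perturb_range: tuple[int, int] = (2, 10)
    seed: int = 0

    def validate(self) -> None:
        for g, (pt, pa) in self.depletion_model.items():
            if not (0 <= pt <= 1 and 0 <= pa <= 1):
                raise SimulationError(f"retain probabilities for group {g} outside [0,1]")
        if not 0 < self.read_len <= 100:
            raise SimulationError("read_len must be in (0, 100] so reads fit in pseudo-sequences")
        if self.chrom_len < 2000:
            raise SimulationError("chrom_len too small")
        for k, v in self.factor_base.items():
            if k != "n_samples_lambda" and not 0 < v < 1:
                raise SimulationError(f"factor_base[{k}] must be in (0,1)")

    def rng(self, stage: int) -> np.random.Generator:
        """One child stream per logical stage (0: reference, 1: candidates, 2+: reads)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stage + 1)[stage])


@dataclass
class TruthRecord:
    circ_id: str
    is_true_circ: bool
    generating_factor_values: dict[str, float]
    expected_class: str  # "not-depleted" | "depleted"


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

@dataclass
class _BoundaryEntry:
    """One realizable BSJ boundary pair with construction-known flags."""
    gene_id: str
    chrom: str
    strand: str
    acceptor: int
    donor: int
    same_isoform: bool
    donor_AS: bool
    acceptor_AS: bool


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def simulate_reference(config: SimConfig) -> tuple[dict[str, str], Annotation]:
    """Generate a random genome and a multi-isoform annotation.

    Gene archetypes: single-isoform, exon-skipping (second isoform skips
    one internal exon) and double-alternative (second isoform uses an
    alternative acceptor on one exon and an alternative donor on a
    downstream exon).  A fraction ``isoform_fraction`` of genes carry a
    second isoform, split between the two multi-isoform archetypes.
    """
    config.validate()
    rng = config.rng(0)
    genome = {f"chr{i + 1}": _rand_seq(rng, config.chrom_len)
              for i in range(config.genome_n_chroms)}
    ann = Annotation()

    margin = 200  # keep BSJ flanks inside the chromosome
    chroms = list(genome)
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    placed = 0
    for chrom in chroms:
        cursor = margin
        for _ in range(per_chrom):
            if placed >= config.n_genes:
                break
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
            intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1,
                                       max(n_ex - 1, 0))
            glen = int(exon_lens.sum() + intron_lens.sum())
            if cursor + glen > config.chrom_len - margin:
                break
            gid = f"gene{placed + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            starts, pos = [], cursor
            for i in range(n_ex):
                starts.append(pos)
                pos += int(exon_lens[i])
                if i < n_ex - 1:
                    pos += int(intron_lens[i])
            exons = [(s + 1, s + int(l)) for s, l in zip(starts, exon_lens)]  # 1-based inclusive
            for (es, ee) in exons:
                ann.add_exon(gid, f"{gid}.t1", chrom, strand, es, ee)
            archetype = "single"
            if rng.random() < config.isoform_fraction and n_ex >= 3:
                archetype = "skip" if rng.random() < 0.5 else "alt"
                if archetype == "skip":
                    k = int(rng.integers(1, n_ex - 1))  # internal exon index
                    for i, (es, ee) in enumerate(exons):
                        if i != k:
                            ann.add_exon(gid, f"{gid}.t2", chrom, strand, es, ee)
                    ann.genes[gid].transcripts[f"{gid}.t2"].skip_exon = k  # type: ignore[attr-defined]
                else:
                    # second isoform shifts both splice sites of internal exon 1
                    d1 = int(rng.integers(10, 26))
                    d2 = int(rng.integers(10, 26))
                    for i, (es, ee) in enumerate(exons):
                        if i == 1:
                            es, ee = es + d2, ee - d1
                        ann.add_exon(gid, f"{gid}.t2", chrom, strand, es, ee)
                    ann.genes[gid].alt_exon = 1  # type: ignore[attr-defined]
            elif rng.random() < config.companion_fraction and n_ex >= 2:
                # interleaved companion gene: one exon inside each host
                # intron, same strand — overlapping but isoform-disjoint
                archetype = "pairgene"
                cgid = f"{gid}c"
                for i in range(n_ex - 1):
                    intron_lo = exons[i][1] + 1
                    intron_hi = exons[i + 1][0] - 1
                    space = intron_hi - intron_lo + 1
                    if space < 110:
                        continue
                    clen = int(rng.integers(60, min(101, space - 50)))
                    cstart = intron_lo + int(rng.integers(25, space - clen - 25))
                    ann.add_exon(cgid, f"{cgid}.t1", chrom, strand, cstart, cstart + clen - 1)
                if cgid in ann.genes:
                    ann.genes[gid].companion = cgid  # type: ignore[attr-defined]
                else:
                    archetype = "single"
            ann.genes[gid].archetype = archetype  # type: ignore[attr-defined]
            cursor += glen + int(rng.integers(300, 800))
            placed += 1
    if placed < config.n_genes:
        raise SimulationError(
            f"chrom_len={config.chrom_len} too small to place {config.n_genes} genes "
            f"(placed {placed})")
    return genome, ann.finalize()


# ---------------------------------------------------------------------------
# boundary catalog with construction-known flags
# ---------------------------------------------------------------------------

def _gene_catalog(ann: Annotation) -> list[_BoundaryEntry]:
    entries: list[_BoundaryEntry] = []
    for gene in ann.genes.values():
        t1 = gene.transcripts.get(f"{gene.gene_id}.t1")
        t2 = gene.transcripts.get(f"{gene.gene_id}.t2")
        if t1 is None:
            continue
        exons = sorted(t1.exons, key=lambda e: e.start)
        archetype = getattr(gene, "archetype", "single")
        plus = gene.strand == "+"

        # construction-known AS site sets (genomic positions)
        as_donor: set[int] = set()
        as_acceptor: set[int] = set()
        if archetype == "skip" and t2 is not None:
            k = getattr(t2, "skip_exon")
            ek = exons[k]
            # skipped exon's own boundaries are unused in t2 (rule: skipped);
            # the flanking intron partners change (alternative pairing)
            if plus:
                as_donor |= {ek.end, exons[k - 1].end}
                as_acceptor |= {ek.start, exons[k + 1].start}
            else:
                as_donor |= {ek.start, exons[k + 1].start}
                as_acceptor |= {ek.end, exons[k - 1].end}
        elif archetype == "alt" and t2 is not None:
            alt_exons = sorted(t2.exons, key=lambda e: e.start)
            e1, a1 = exons[1], alt_exons[1]  # original vs shifted internal exon
            # alternative usage of exon 1's sites makes both its variants AS
            # (unused-in-covering-isoform rule) and gives the neighbouring
            # intron partners two pairings each (alternative-pairing rule)
            if plus:
                as_donor |= {exons[0].end, e1.end, a1.end}
                as_acceptor |= {e1.start, a1.start, exons[2].start}
            else:
                as_donor |= {e1.start, a1.start, exons[2].start}
                as_acceptor |= {exons[0].end, e1.end, a1.end}

        seen: set[tuple[int, int]] = set()

        def make(acceptor: int, donor: int, same_iso: bool,
                 donor_as: bool | None = None, acc_as: bool | None = None) -> None:
            if (acceptor, donor) in seen:
                return
            seen.add((acceptor, donor))
            entries.append(_BoundaryEntry(
                gene.gene_id, gene.chrom, gene.strand, acceptor, donor, same_iso,
                donor in as_donor if donor_as is None else donor_as,
                acceptor in as_acceptor if acc_as is None else acc_as))

        # same-transcript exon pairs (acceptor of exon i, donor of exon j, i ≤ j)
        for tx in (t1, t2):
            if tx is None:
                continue
            tex = sorted(tx.exons, key=lambda e: e.start)
            for i in range(len(tex)):
                for j in range(i, len(tex)):
                    if plus:
                        make(tex[i].start, tex[j].end, True)
                    else:
                        make(tex[j].end, tex[i].start, True)
        # cross-isoform pairs for the double-alternative archetype:
        # acceptor used by one isoform only, donor by the other only
        if archetype == "alt" and t2 is not None:
            alt_exons = sorted(t2.exons, key=lambda e: e.start)
            e1, a1 = exons[1], alt_exons[1]
            if plus:
                make(e1.start, a1.end, False)
                make(a1.start, e1.end, False)
            else:
                make(e1.end, a1.start, False)
                make(a1.end, e1.start, False)
        # cross-gene pairs with an interleaved companion gene: annotated
        # boundaries, no shared transcript, all sites constitutive
        companion = getattr(gene, "companion", None)
        if companion is not None:
            ct = next(iter(ann.genes[companion].transcripts.values()))
            cex = sorted(ct.exons, key=lambda e: e.start)
            for he in exons:
                for ce in cex:
                    if plus:
                        if ce.end > he.start:
                            make(he.start, ce.end, False, donor_as=False, acc_as=False)
                        if he.end > ce.start:
                            make(ce.start, he.end, False, donor_as=False, acc_as=False)
                    else:
                        if ce.start < he.end:
                            make(he.end, ce.start, False, donor_as=False, acc_as=False)
                        if he.start < ce.end:
                            make(ce.end, he.start, False, donor_as=False, acc_as=False)
    return entries


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

def simulate_candidates(config: SimConfig, annotation: Annotation,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a candidate table and its truth table.

    Truth labels fill the exact ``n_circ_true`` / ``n_circ_artifact``
    quotas.  Factor values are sampled class-conditionally so that each
    factor's implied logistic coefficient equals ``factor_effects``
    (naive-Bayes construction); coordinates then realize the sampled
    annotation flags (annotated boundaries from the gene catalog,
    perturbed or chimeric boundaries otherwise).
    """
    config.validate()
    rng = config.rng(1)
    catalog = _gene_catalog(annotation)
    if not catalog:
        raise SimulationError("no annotated exons available to build candidates")
    rng.shuffle(catalog)  # type: ignore[arg-type]
    eff, base = config.factor_effects, config.factor_base

    n_total = config.n_circ_true + config.n_circ_artifact
    labels = np.array([True] * config.n_circ_true + [False] * config.n_circ_artifact)
    rng.shuffle(labels)

    # boundary-site sets for keeping perturbed artifacts off annotated sites
    all_sites: dict[str, set[int]] = {}
    for tx in annotation.transcripts():
        s = all_sites.setdefault(tx.chrom, set())
        s |= tx.donor_sites() | tx.acceptor_sites()

    used_coords: set[tuple[str, int, int]] = set()
    cat_pool = {
        (si, as_): [e for e in catalog
                    if e.same_isoform == si and (e.donor_AS and e.acceptor_AS) == as_]
        for si in (True, False) for as_ in (True, False)
    }
    genes = list(annotation.genes.values())

    def bern(p0: float, beta: float, z: int) -> bool:
        return bool(rng.random() < _sigmoid(_logit(p0) + beta * z))

    def draw_entry(same_iso: bool, both_as: bool) -> _BoundaryEntry | None:
        order = {(True, True): [(True, True), (True, False)],
                 (True, False): [(True, False), (True, True)],
                 (False, True): [(False, True), (False, False), (True, True)],
                 (False, False): [(False, False), (False, True), (True, False)]}[
                     (same_iso, both_as)]
        for key in order:
            pool = cat_pool[key]
            while pool:
                e = pool.pop()
                if (e.chrom, e.acceptor, e.donor) not in used_coords:
                    return e
        return None

    def perturbed_coords() -> tuple[str, str, str, int, int]:
        lo, hi = config.perturb_range
        for _ in range(200):
            g = genes[rng.integers(len(genes))]
            tx = next(iter(g.transcripts.values()))
            exons = sorted(tx.exons, key=lambda e: e.start)
            i = int(rng.integers(len(exons)))
            j = int(rng.integers(i, len(exons)))
            if g.strand == "+":
                acc, don = exons[i].start, exons[j].end
            else:
                acc, don = exons[j].end, exons[i].start
            shift_a = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
            shift_d = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
            acc2, don2 = acc + shift_a, don + shift_d
            ok_orient = don2 > acc2 if g.strand == "+" else don2 < acc2
            if (ok_orient and acc2 not in all_sites.get(g.chrom, set())
                    and don2 not in all_sites.get(g.chrom, set())
                    and (g.chrom, acc2, don2) not in used_coords):
                return g.gene_id, g.chrom, g.strand, acc2, don2
        raise SimulationError("could not place a perturbed artifact candidate")

    # chimeras draw annotated sites from AS-free genes only, so their
    # construction-known AS flags stay false
    plain_genes = [g for g in genes
                   if getattr(g, "archetype", "single") in ("single", "pairgene")]

    def chimera_coords() -> tuple[str, str, str, int, int]:
        for _ in range(200):
            ga = plain_genes[rng.integers(len(plain_genes))]
            gb = plain_genes[rng.integers(len(plain_genes))]
            if ga.gene_id == gb.gene_id or ga.chrom != gb.chrom or ga.strand != gb.strand:
                continue
            if getattr(ga, "companion", None) == gb.gene_id:
                continue
            ta = next(iter(ga.transcripts.values()))
            tb = next(iter(gb.transcripts.values()))
            acc = sorted(rng.choice(sorted(ta.acceptor_sites()), 1))[0]
            don = sorted(rng.choice(sorted(tb.donor_sites()), 1))[0]
            ok_orient = don > acc if ga.strand == "+" else don < acc
            if ok_orient and (ga.chrom, int(acc), int(don)) not in used_coords:
                return f"{ga.gene_id}|{gb.gene_id}", ga.chrom, ga.strand, int(acc), int(don)
        raise SimulationError("could not place a chimeric artifact candidate")

    rows, truth_rows = [], []
    group0 = sorted(config.depletion_model)[0]
    lib_ratio = config.library_size_mock / config.library_size_treated
    for idx, z_true in enumerate(labels):
        z = int(z_true)
        cid = f"circ{idx + 1:05d}"
        multi_tool = bern(base["multi_tool"], eff.get("multi_tool", 0.0), z)
        n_tools = (2 + int(rng.binomial(2, 0.5))) if multi_tool else 1
        full_length = bern(base["full_length"], eff.get("full_length", 0.0), z)
        lam_ns = base["n_samples_lambda"] * np.exp(eff.get("n_samples", 0.0) * z)
        n_samples = 1 + int(rng.poisson(lam_ns))
        q_ff = _sigmoid(_logit(base["n_functional_features"])
                        + eff.get("n_functional_features", 0.0) * z)
        feats = rng.random(9) < q_ff
        both_annotated = bern(base["both_annotated"], eff.get("both_annotated", 0.0), z)
        same_isoform = both_annotated and bern(base["same_isoform"], eff.get("same_isoform", 0.0), z)
        both_as = both_annotated and bern(base["both_AS"], eff.get("both_AS", 0.0), z)

        if both_annotated:
            if (not same_isoform and not both_as
                    and rng.random() < config.chimera_fraction):
                # two-gene chimera: annotated constitutive sites, no
                # shared transcript — a (False, False) realization
                gene_id, chrom, strand, acc, don = chimera_coords()
                donor_as = acceptor_as = False
            else:
                entry = draw_entry(same_isoform, both_as)
                if entry is None:
                    raise SimulationError(
                        "gene catalog exhausted; increase n_genes or chrom_len")
                gene_id, chrom, strand = entry.gene_id, entry.chrom, entry.strand
                acc, don = entry.acceptor, entry.donor
                same_isoform = entry.same_isoform
                donor_as, acceptor_as = entry.donor_AS, entry.acceptor_AS
                both_as = donor_as and acceptor_as
        else:
            same_isoform = False
            donor_as = acceptor_as = both_as = False
            gene_id, chrom, strand, acc, don = perturbed_coords()
        used_coords.add((chrom, acc, don))

        lam_mock = config.mean_mock_reads * np.exp(
            eff.get("bsj_read_count", 0.0) * (z - 0.5))
        n_species = 1 + int(rng.binomial(6, 0.15 + 0.1 * z))
        n_tissues = 1 + int(rng.binomial(18, 0.1 + 0.08 * z))
        tsi = float(rng.beta(2.0 + 2.0 * (1 - z), 2.0))

        retain = config.depletion_model[group0][0 if z_true else 1]
        expected = "not-depleted" if retain * lib_ratio >= 1.0 else "depleted"

        row = {
            "circ_id": cid, "chrom": chrom, "acceptor_pos": acc, "donor_pos": don,
            "strand": strand, "gene_id": gene_id,
            "n_tools": n_tools, "multi_tool": multi_tool, "full_length": full_length,
            "n_samples": n_samples, "n_species": n_species, "n_tissues": n_tissues,
            "tissue_specificity_index": round(tsi, 4),
        }
        row.update({name: bool(v) for name, v in zip(FUNCTIONAL_FEATURES, feats)})
        rows.append(row)
        gen_values = {
            "bsj_read_count_lambda": lam_mock, "multi_tool": multi_tool,
            "full_length": full_length, "n_samples": n_samples,
            "both_annotated": both_annotated, "same_isoform": same_isoform,
            "both_AS": both_as, "donor_AS": donor_as, "acceptor_AS": acceptor_as,
            "n_functional_features": int(feats.sum()),
        }
        truth_rows.append({
            "circ_id": cid, "is_true_circ": bool(z_true), "expected_class": expected,
            **{f"gen_{k}": v for k, v in gen_values.items()},
        })
    candidates = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return candidates, truth


def truth_records(truth: pd.DataFrame) -> list[TruthRecord]:
    """View a truth table as TruthRecord objects (one per candidate)."""
    recs = []
    for _, r in truth.iterrows():
        gen = {c[4:]: r[c] for c in truth.columns if c.startswith("gen_")}
        recs.append(TruthRecord(r["circ_id"], bool(r["is_true_circ"]), gen,
                                r["expected_class"]))
    return recs


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_read_pairs(candidates: pd.DataFrame, truth: pd.DataFrame, config: SimConfig,
                        genome: dict[str, str], group: int = 1, pair_index: int = 0,
                        ) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, int]]:
    """Generate one mock/treated read pair.

    Mock BSJ-spanning reads per candidate are Poisson with the
    candidate's generating rate; treated reads are a Binomial survival
    subsample (retention probability by truth class and treatment
    group).  Linear background reads — random genomic substrings — fill
    both libraries to their configured raw totals, which are returned
    as the RPM denominators.
    """
    from .quant import build_pseudo_seq, CircCandidate  # local import to avoid cycle

    config.validate()
    if group not in config.depletion_model:
        raise SimulationError(f"treatment group {group} not in depletion_model")
    rng = config.rng(2 + pair_index)
    retain_true, retain_art = config.depletion_model[group]
    is_true = dict(zip(truth["circ_id"], truth["is_true_circ"]))
    lam = dict(zip(truth["circ_id"], truth["gen_bsj_read_count_lambda"]))

    L = config.read_len
    mock_reads: list[tuple[str, str]] = []
    treated_reads: list[tuple[str, str]] = []
    for _, row in candidates.iterrows():
        cand = CircCandidate(row["circ_id"], row["chrom"], int(row["acceptor_pos"]),
                             int(row["donor_pos"]), row["strand"], row["gene_id"])
        pseudo = build_pseudo_seq(cand, genome)
        plen = len(pseudo.sequence)
        if plen < L:
            continue
        # start offsets keeping the read junction-spanning by ≥10 nt on both
        # sides (0-based starts)
        lo = max(0, pseudo.junction_index - L + 10)
        hi = min(plen - L, pseudo.junction_index - 10)
        if hi < lo:
            continue
        n_mock = int(rng.poisson(lam[row["circ_id"]]))
        if n_mock == 0:
            continue
        starts = rng.integers(lo, hi + 1, n_mock)
        reads_i = [pseudo.sequence[s:s + L] for s in starts]
        for k, seq in enumerate(reads_i):
            mock_reads.append((f"m_{row['circ_id']}_{k}", seq))
        p_keep = retain_true if is_true[row["circ_id"]] else retain_art
        keep = rng.random(n_mock) < p_keep
        for k in np.flatnonzero(keep):
            treated_reads.append((f"t_{row['circ_id']}_{k}", reads_i[k]))

    chroms = list(genome)
    def background(n: int, prefix: str) -> list[tuple[str, str]]:
        out = []
        for k in range(n):
            c = chroms[rng.integers(len(chroms))]
            s = int(rng.integers(0, len(genome[c]) - L))
            seq = genome[c][s:s + L]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            out.append((f"{prefix}_bg{k}", seq))
        return out

    n_bg_mock = config.library_size_mock - len(mock_reads)
    n_bg_tr = config.library_size_treated - len(treated_reads)
    if n_bg_mock < 0 or n_bg_tr < 0:
        raise SimulationError("library size smaller than generated BSJ reads; "
                              "increase library_size or lower mean_mock_reads")
    mock_reads += background(n_bg_mock, "m")
    treated_reads += background(n_bg_tr, "t")
    totals = {"mock_total": config.library_size_mock,
              "treated_total": config.library_size_treated}
    return mock_reads, treated_reads, totals


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["depletion_model"] = {int(k): list(v) for k, v in config.depletion_model.items()}
    return d
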