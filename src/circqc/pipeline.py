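"""End-to-end pipeline: simulate → quantify → annotate → test → rcve → report.

Each stage writes TSV/JSON outputs into the run directory and is
skipped on rerun when its outputs already exist and are newer than its
inputs.  Stage boundaries are auditable: the log records candidate
counts entering and surviving every filter (ambiguity screen, ≥2 mock
reads), mirroring the attrition accounting the analysis design calls
for.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .factors import build_factor_matrix
from .model import CircReliabilityModel, DEFAULT_FACTORS, rank_across_pairs
from .quant import (GenomeIndex, MatchParams, build_pseudo_seq, candidates_from_frame,
                    check_pair_inclusion, quantify_pair, screen_ambiguity)
from .simulate import SimConfig, config_to_dict, simulate_candidates, simulate_read_pairs, simulate_reference
from .stats import bh_adjust, fet_enrichment, significance_summary, trend_table, wrst_enrichment

logger = logging.getLogger(__name__)

BINARY_FACTORS = ["multi_tool", "full_length", "both_annotated", "same_isoform", "both_AS"]
QUANT_FACTORS = ["bsj_read_count", "n_samples", "n_functional_features"]


@dataclass
class RunConfig:
    """Pipeline configuration; threshold defaults are the published
    analysis values (≥2 mock reads, 80% coverage, 10-nt junction span,
    ±20 kb RCS window, ±1 kb RBP flanks, 5/5/2-nt site spans,
    supporting-factor cutoff 3, FDR α 0.05, pair inclusion >600 mock
    circRNAs and >1/3 treated overlap)."""

    outdir: str = "circqc_run"
    seed: int = 0
    # simulation-driven run (the default demo); set simulate=None and the
    # genome/annotation/candidates/pair paths to analyze external data
    simulate: dict | None = field(default_factory=dict)
    n_pairs: int = 3
    genome: str | None = None
    annotation: str | None = None
    candidates: str | None = None
    pairs: list = field(default_factory=list)  # [{pair_id, group, mock, treated, mock_total, treated_total}]
    # thresholds
    min_mock_reads: int = 2
    min_cover_frac: float = 0.8
    min_span: int = 10
    min_identity: float = 0.95
    rcs_window: int = 20_000
    rbp_flank: int = 1000
    span_minima: dict = field(default_factory=lambda: {"G4": 5, "miRNA": 5, "RBP": 2})
    cutoff_counts: int = 3
    alpha: float = 0.05
    min_mock_circ: int = 600
    min_overlap_frac: float = 1 / 3
    ambiguity_screen: bool = True
    enforce_inclusion: bool = False
    pseudo_r2: str = "mcfadden"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return min(p.stat().st_mtime for p in outputs) >= newest_in


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s: failed: %s", self.name, exc)
            return False
        logger.info("stage %s: done in %.1fs", self.name, time.time() - self.t0)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable run summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    # echo the config, but only on change so an unchanged rerun can skip stages
    cfg_text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    cfg_path = out / "config.yaml"
    if not cfg_path.exists() or cfg_path.read_text() != cfg_text:
        cfg_path.write_text(cfg_text)

    # ----- stage: simulate (or load external inputs) --------------------
    if config.simulate is not None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
        genome_path = out / "genome.fa"
        gtf_path = out / "annotation.gtf"
        cand_path = out / "candidates.tsv"
        truth_path = out / "truth.tsv"
        groups = sorted(sim_cfg.depletion_model)
        pair_specs = [{"pair_id": f"pair{i + 1}", "group": groups[i % len(groups)]}
                      for i in range(config.n_pairs)]
        read_paths = [(out / f"{p['pair_id']}_mock.fa", out / f"{p['pair_id']}_treated.fa")
                      for p in pair_specs]
        sim_outputs = [genome_path, gtf_path, cand_path, truth_path] \
            + [p for pr in read_paths for p in pr]
        if not _fresh(sim_outputs, [out / "config.yaml"]):
            with _Stage("simulate"):
                genome, ann = simulate_reference(sim_cfg)
                candidates, truth = simulate_candidates(sim_cfg, ann)
                qio.write_fasta(genome, genome_path)
                qio.write_gtf(ann, gtf_path)
                qio.write_candidates(candidates, cand_path)
                qio.write_table(truth, truth_path)
                with open(out / "sim_config.yaml", "w") as fh:
                    yaml.safe_dump(config_to_dict(sim_cfg), fh, sort_keys=False)
                for i, (spec, (mp, tp)) in enumerate(zip(pair_specs, read_paths)):
                    mock, treated, totals = simulate_read_pairs(
                        candidates, truth, sim_cfg, genome, group=spec["group"],
                        pair_index=i)
                    qio.write_fasta(dict(mock), mp)
                    qio.write_fasta(dict(treated), tp)
                    spec.update(totals)
        else:
            logger.info("stage simulate: outputs fresh, skipped")
        for spec, (mp, tp) in zip(pair_specs, read_paths):
            spec.setdefault("mock_total", sim_cfg.library_size_mock)
            spec.setdefault("treated_total", sim_cfg.library_size_treated)
            spec["mock"], spec["treated"] = str(mp), str(tp)
        genome = qio.read_fasta(genome_path)
        annotation = qio.read_gtf(gtf_path)
        candidates = qio.read_candidates(cand_path, genome)
    else:
        if not (config.genome and config.annotation and config.candidates and config.pairs):
            raise ValueError("non-simulated runs need genome, annotation, candidates and pairs")
        genome = qio.read_fasta(config.genome)
        annotation = qio.read_gtf(config.annotation)
        candidates = qio.read_candidates(config.candidates, genome)
        pair_specs = list(config.pairs)
    logger.info("loaded %d candidates", len(candidates))

    params = MatchParams(min_cover_frac=config.min_cover_frac, min_span=config.min_span,
                         min_identity=config.min_identity)

    # ----- stage: ambiguity screen --------------------------------------
    amb_path = out / "ambiguity.tsv"
    if config.ambiguity_screen:
        if not _fresh([amb_path], [out / "candidates.tsv"]):
            with _Stage("ambiguity"):
                gidx = GenomeIndex(genome)
                tx_seqs = {t.transcript_id: t.spliced_sequence(genome)
                           for t in annotation.transcripts()}
                from ._align import KmerIndex
                tidx = KmerIndex(tx_seqs, 16)
                rows = []
                for cand in candidates_from_frame(candidates):
                    ps = build_pseudo_seq(cand, genome)
                    flag = screen_ambiguity(cand, ps, genome, annotation,
                                            genome_index=gidx, transcript_seqs=tx_seqs,
                                            transcript_index=tidx)
                    rows.append({"circ_id": cand.circ_id,
                                 "has_colinear_explanation": flag.has_colinear_explanation,
                                 "has_multiple_hits": flag.has_multiple_hits,
                                 "ambiguous": flag.ambiguous})
                qio.write_table(pd.DataFrame(rows), amb_path)
        amb = qio.read_table(amb_path)
        n0 = len(candidates)
        keep_ids = set(amb.loc[~amb["ambiguous"], "circ_id"])
        candidates = candidates[candidates["circ_id"].isin(keep_ids)].reset_index(drop=True)
        logger.info("ambiguity screen: %d → %d candidates", n0, len(candidates))

    # ----- stage: quantify ----------------------------------------------
    quants = {}
    inclusion = {}
    for spec in pair_specs:
        pid = spec["pair_id"]
        qpath = out / f"quant_{pid}.tsv"
        if not _fresh([qpath], [Path(spec["mock"]), Path(spec["treated"])]):
            with _Stage(f"quantify:{pid}"):
                mock = qio.read_reads(spec["mock"])
                treated = qio.read_reads(spec["treated"])
                q = quantify_pair(candidates, genome, mock, int(spec["mock_total"]),
                                  treated, int(spec["treated_total"]),
                                  min_mock_reads=config.min_mock_reads, params=params)
                qio.write_table(q, qpath)
        quants[pid] = qio.read_table(qpath)
        inc = check_pair_inclusion(quants[pid], config.min_mock_circ,
                                   config.min_overlap_frac)
        inclusion[pid] = inc
        with open(out / f"inclusion_{pid}.json", "w") as fh:
            json.dump(inc, fh, indent=2)
        if not inc["pass"]:
            msg = f"pair {pid} fails the inclusion rule: {inc}"
            if config.enforce_inclusion:
                raise ValueError(msg)
            logger.warning("%s (continuing; enforce_inclusion=False)", msg)

    # ----- stage: annotate ----------------------------------------------
    fpath = out / "factors.tsv"
    if not _fresh([fpath], [out / "candidates.tsv"]):
        with _Stage("annotate"):
            factors = build_factor_matrix(candidates, annotation, genome,
                                          rcs_window=config.rcs_window,
                                          rbp_flank=config.rbp_flank,
                                          cutoff_counts=config.cutoff_counts)
            qio.write_table(factors, fpath)
    factors = qio.read_table(fpath)

    # ----- stage: test ---------------------------------------------------
    results_path = out / "enrichment.tsv"
    trend_path = out / "trend.tsv"
    with _Stage("test"):
        res_rows, trend_frames = [], []
        for pid, quant in quants.items():
            merged = quant.merge(factors, on="circ_id")
            merged["bsj_read_count"] = merged["mock_count"]
            cls = merged.set_index("circ_id")["depletion_class"]
            m = merged.set_index("circ_id")
            for fac in BINARY_FACTORS:
                if fac in m.columns and m[fac].notna().any():
                    res_rows.append(fet_enrichment(cls, m[fac], pid, fac).to_dict())
            for fac in QUANT_FACTORS:
                if fac in m.columns and m[fac].notna().any():
                    res_rows.append(wrst_enrichment(cls, m[fac], "greater", pid, fac,
                                                    seed=config.seed).to_dict())
                    trend_frames.append(trend_table(cls, m[fac], pair_id=pid,
                                                    factor_name=fac))
        results = bh_adjust(pd.DataFrame(res_rows))
        qio.write_table(results, results_path)
        if trend_frames:
            qio.write_table(pd.concat(trend_frames, ignore_index=True), trend_path)
        summary_tbl = significance_summary(results, config.alpha)
        qio.write_table(summary_tbl, out / "significance_summary.tsv")

    # ----- stage: rcve ----------------------------------------------------
    with _Stage("rcve"):
        fits = []
        for pid, quant in quants.items():
            merged = quant.merge(factors, on="circ_id")
            merged["bsj_read_count"] = merged["mock_count"]
            model = CircReliabilityModel.from_dataframe(
                merged, factors=[f for f in DEFAULT_FACTORS if f in merged.columns],
                pair_id=pid)
            fits.append(model.fit(pseudo_r2=config.pseudo_r2))
        rcve_df = pd.concat([f.to_frame() for f in fits], ignore_index=True)
        qio.write_table(rcve_df, out / "rcve.tsv")
        ranks, avg_rank = rank_across_pairs(fits)
        qio.write_table(ranks.reset_index(), out / "rcve_ranks.tsv")
        qio.write_table(avg_rank.reset_index(), out / "rcve_average_rank.tsv")

    # ----- stage: report --------------------------------------------------
    with _Stage("report"):
        important = summary_tbl.loc[summary_tbl["important"], "factor"].tolist()
        summary = {
            "n_candidates": int(len(candidates)),
            "pairs": {pid: {"inclusion": inclusion[pid],
                            "n_not_depleted": int((q["depletion_class"] == "not-depleted").sum()),
                            "n_depleted": int((q["depletion_class"] == "depleted").sum()),
                            "n_excluded": int((q["depletion_class"] == "excluded").sum())}
                      for pid, q in quants.items()},
            "important_factors": important,
            "rcve_average_rank": {k: float(v) for k, v in avg_rank.items()},
            "r2_all": {f.pair_id: f.r2_all for f in fits},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        lines = [f"circqc run summary ({len(candidates)} candidates, "
                 f"{len(quants)} sample pair(s))", ""]
        for pid, info in summary["pairs"].items():
            lines.append(f"{pid}: not-depleted {info['n_not_depleted']}, depleted "
                         f"{info['n_depleted']}, excluded {info['n_excluded']}, "
                         f"inclusion pass={info['inclusion']['pass']}")
        lines += ["", "important factors (FDR < %.2f in every pair):" % config.alpha]
        lines += [f"  - {f}" for f in important] or ["  (none)"]
        lines += ["", "factor importance by average RCVE rank:"]
        lines += [f"  {i + 1}. {k} (avg rank {v:.2f})"
                  for i, (k, v) in enumerate(avg_rank.items())]
        (out / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
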