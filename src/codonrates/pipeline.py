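"""End-to-end orchestration: sequences -> ORFs -> orthologues -> filtered
codon alignments -> distances -> clade rates -> category statistics.

Runs either on a synthetic study (the generator supplies sequences,
orthologue truth and annotations) or on user FASTA files with an externally
supplied 1:1 orthologue list or the built-in RBH search.  Every stage
writes its table to the output directory, logs its bookkeeping counts, and
a machine-readable manifest records the seed, configuration hash and
per-stage counts so a run can be audited or resumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from joblib import Parallel, delayed

from . import __version__
from .alignment import AlignScoring, ColumnPolicy, align_codons, filter_columns
from .categories import (across_category_heterogeneity,
                         compare_categories_between_clades,
                         ranked_segmentation_test, logistic_trend_test,
                         read_annotation_table, results_frame)
from .distances import (PairwiseEstimate, d4_distance, estimates_table,
                        gy94_ml_estimate, ng86_estimate)
from .io import SequenceRecord, read_fasta, write_tsv
from .orfs import (NoOrfError, OrfRecord, ReferenceHit, find_orfs,
                   select_orf_by_homology, select_orf_by_reference_frame)
from .orthology import (local_align_search, read_blast_tabular,
                        read_ortholog_list, reciprocal_best_hits)
from .rates import (ANGIOSPERM_FILTER, ANGIOSPERM_SCENARIO, CONIFER_FILTER,
                    CONIFER_SCENARIO, DivergenceScenario, FilterPolicy,
                    apply_filters, apportion_lineage_rates, bootstrap_ci,
                    clade_summary, fold_change_frame, fold_change_table,
                    substitution_rate)
from .simulate import Study, StudyConfig, generate_study

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage
        self.detail = detail


@dataclass(frozen=True)
class CladeRunConfig:
    """Inputs and policies for one clade (a two-species comparison)."""

    name: str
    fasta_1: Optional[str] = None
    fasta_2: Optional[str] = None
    ortholog_list: Optional[str] = None  # TSV id_a/id_b; None -> built-in RBH
    hits_ab: Optional[str] = None  # precomputed BLAST tabular (authoritative)
    hits_ba: Optional[str] = None
    scenario: DivergenceScenario = CONIFER_SCENARIO
    filter_policy: FilterPolicy = CONIFER_FILTER
    orf_strategy_2: Literal["longest", "reference_frame"] = "longest"


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str
    seed: int = 0
    estimator: Literal["GY94-ML", "NG86"] = "GY94-ML"
    threads: int = 1
    study: Optional[StudyConfig] = None  # synthetic mode when set
    clades: tuple[CladeRunConfig, ...] = ()
    annotations: Optional[str] = None  # TSV; synthetic study supplies its own
    column_policy: ColumnPolicy = ColumnPolicy()
    rbh_e_max: float = 1e-20
    run_enrichment: bool = True
    n_bootstrap: int = 1000


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-clade stages
# ---------------------------------------------------------------------------


def _protein(codon_seq: str) -> str:
    return str(Seq(codon_seq).translate())


def _select_orfs_flcdna(records: list[SequenceRecord]) -> dict[str, OrfRecord]:
    """Full-length-cDNA strategy: start-to-stop ORFs, longest-ORF fallback
    (no external similarity hits in this mode)."""
    out = {}
    dropped = 0
    for rec in records:
        orfs = find_orfs(rec, min_codons=10)
        try:
            sel = select_orf_by_homology(orfs, [], fallback_longest=True)
        except NoOrfError:
            dropped += 1
            continue
        if sel is not None:
            out[rec.id] = sel[0]
    logger.info("FLcDNA ORF selection: %d of %d sequences yielded an ORF",
                len(out), len(records))
    return out


def _reference_frame_hit(record: SequenceRecord, ref_protein: str,
                         aligner: PairwiseAligner) -> Optional[ReferenceHit]:
    """Locate the coding frame of a fragment by aligning its three forward
    frame translations against a reference protein."""
    best = None
    for offset in range(3):
        m = (len(record.seq) - offset) // 3
        if m < 10:
            continue
        prot = _protein(record.seq[offset : offset + 3 * m])
        score = aligner.score(prot, ref_protein)
        if best is None or score > best[0]:
            aln = aligner.align(prot, ref_protein)[0]
            blocks = aln.aligned[0]
            start_aa, end_aa = int(blocks[0][0]), int(blocks[-1][1])
            best = (score, ReferenceHit(offset + 3 * start_aa,
                                        offset + 3 * end_aa, offset + 1))
    return None if best is None else best[1]


def _select_orfs_fragments(records: list[SequenceRecord],
                           partner_orfs: dict[str, str],
                           pair_of: dict[str, str]) -> dict[str, OrfRecord]:
    """EST-fragment strategy: pick the ORF (open-ended allowed) sharing the
    frame of the best hit against the partner's ORF."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    out = {}
    for rec in records:
        partner = pair_of.get(rec.id)
        ref = partner_orfs.get(partner) if partner else None
        if ref is None:
            continue
        hit = _reference_frame_hit(rec, _protein(ref), aligner)
        if hit is None:
            continue
        orfs = find_orfs(rec, min_codons=10, include_open_ended=True)
        sel = select_orf_by_reference_frame(rec, hit, orfs)
        if sel is not None:
            out[rec.id] = sel
    logger.info("fragment ORF selection: %d of %d fragments had an ORF in "
                "the reference frame", len(out), len(records))
    return out


def _infer_pairs_rbh(orfs_1: dict[str, OrfRecord], orfs_2: dict[str, OrfRecord],
                     clade: CladeRunConfig, e_max: float) -> list[tuple[str, str]]:
    if clade.hits_ab and clade.hits_ba:
        hits_ab = read_blast_tabular(clade.hits_ab)
        hits_ba = read_blast_tabular(clade.hits_ba)
    else:
        prots_1 = [(k, _protein(o.coding_codons())) for k, o in sorted(orfs_1.items())]
        prots_2 = [(k, _protein(o.coding_codons())) for k, o in sorted(orfs_2.items())]
        hits_ab = local_align_search(prots_1, prots_2, e_max=e_max)
        hits_ba = local_align_search(prots_2, prots_1, e_max=e_max)
    pairs = reciprocal_best_hits(hits_ab, hits_ba, e_max=e_max)
    return [(p.id_a, p.id_b) for p in pairs]


def _estimate_pair(pair_id: str, orf_a: str, orf_b: str, estimator: str,
                   policy: ColumnPolicy) -> PairwiseEstimate:
    aln = filter_columns(align_codons(orf_a, orf_b, pair_id), policy)
    if aln.discarded:
        return PairwiseEstimate(pair_id, estimator, "failed")
    est = gy94_ml_estimate(aln) if estimator == "GY94-ML" else ng86_estimate(aln)
    d4, n4d = d4_distance(aln)
    return dataclasses.replace(est, d4=d4, n4D=n4d)


@dataclass
class CladeResult:
    name: str
    estimates: list[PairwiseEstimate]
    kept: list[PairwiseEstimate]
    discard_ledger: pd.DataFrame
    summary: object
    n_input_pairs: int


def run_clade(
    records_1: list[SequenceRecord],
    records_2: list[SequenceRecord],
    clade: CladeRunConfig,
    config: PipelineConfig,
    pairs: Optional[list[tuple[str, str]]] = None,
) -> CladeResult:
    orfs_1 = _select_orfs_flcdna(records_1)
    if clade.orf_strategy_2 == "reference_frame":
        if pairs is None:
            raise StageError("orfs", f"{clade.name}: reference-frame ORF "
                             "selection needs an orthologue list")
        pair_of = {b: a for a, b in pairs}
        partner = {k: o.coding_codons() for k, o in orfs_1.items()}
        orfs_2 = _select_orfs_fragments(records_2, partner, pair_of)
    else:
        orfs_2 = _select_orfs_flcdna(records_2)

    if pairs is None:
        pairs = _infer_pairs_rbh(orfs_1, orfs_2, clade, config.rbh_e_max)
        logger.info("%s: RBH found %d orthologue pairs", clade.name, len(pairs))
    usable = [(a, b) for a, b in pairs if a in orfs_1 and b in orfs_2]
    logger.info("%s: %d of %d pairs have ORFs on both sides",
                clade.name, len(usable), len(pairs))

    jobs = [(f"{a}|{b}", orfs_1[a].coding_codons(), orfs_2[b].coding_codons())
            for a, b in usable]
    runner = Parallel(n_jobs=max(config.threads, 1))
    estimates = runner(
        delayed(_estimate_pair)(pid, oa, ob, config.estimator, config.column_policy)
        for pid, oa, ob in jobs
    )
    kept, ledger = apply_filters(estimates, clade.filter_policy)
    logger.info("%s: %d estimated, %d kept after saturation filters",
                clade.name, len(estimates), len(kept))
    summary = clade_summary(kept, clade.name) if kept else None
    return CladeResult(clade.name, list(estimates), kept, ledger, summary,
                       len(pairs))


# ---------------------------------------------------------------------------
# whole-pipeline run
# ---------------------------------------------------------------------------


def _rates_rows(result: CladeResult, scenario: DivergenceScenario,
                n_boot: int, seed: int) -> list[dict]:
    rows = []
    per_gene = {
        "synonymous": [e.dS for e in result.kept if e.dS is not None],
        "fourfold": [e.d4 for e in result.kept if e.d4 is not None],
        "nonsynonymous": [e.dN for e in result.kept if e.dN is not None],
    }
    for site_class, values in per_gene.items():
        if len(values) < 2:
            continue
        import zlib

        mean, lo, hi = bootstrap_ci(values, n_reps=n_boot,
                                    seed=(seed + zlib.crc32(site_class.encode()))
                                    % (2**31 - 1))
        rate = substitution_rate(mean, scenario, site_class)
        row = {
            "clade": result.name,
            "site_class": site_class,
            "mean_d": mean,
            "mu": rate.mu,
            "mu_low": rate.mu_low,
            "mu_high": rate.mu_high,
            "mu_ci_low": substitution_rate(lo, scenario).mu,
            "mu_ci_high": substitution_rate(hi, scenario).mu,
        }
        if scenario.rho > 1:
            mu_slow, mu_fast = apportion_lineage_rates(mean, scenario)
            row["mu_slow"] = mu_slow
            row["mu_fast"] = mu_fast
        rows.append(row)
    return rows


@dataclass
class PipelineResult:
    outdir: str
    clades: dict[str, CladeResult]
    rates: pd.DataFrame
    fold_changes: Optional[pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    if config.study is None and not config.clades:
        raise StageError("config", "neither a synthetic study nor clade inputs given")
    for clade in config.clades:
        for path in (clade.fasta_1, clade.fasta_2, clade.ortholog_list,
                     clade.hits_ab, clade.hits_ba):
            if path is not None and not os.path.exists(path):
                raise StageError("config", f"missing input file: {path}")
    os.makedirs(config.outdir, exist_ok=True)

    study: Optional[Study] = None
    annotations = None
    clade_inputs = []
    if config.study is not None:
        study = generate_study(config.study, config.seed)
        study.write(os.path.join(config.outdir, "inputs"))
        defaults = {
            0: (CONIFER_SCENARIO, CONIFER_FILTER),
            1: (ANGIOSPERM_SCENARIO, ANGIOSPERM_FILTER),
        }
        for i, (name, data) in enumerate(study.clades.items()):
            scenario, filt = defaults.get(i, (CONIFER_SCENARIO, CONIFER_FILTER))
            over = {c.name: c for c in config.clades}
            run_cfg = over.get(name, CladeRunConfig(name=name, scenario=scenario,
                                                    filter_policy=filt))
            clade_inputs.append((run_cfg, data.records_1, data.records_2,
                                 data.pairs))
        ann_map: dict[str, set] = {}
        for _, row in study.annotations.iterrows():
            ann_map.setdefault(row["gene_id"], set()).add(row["go_slim_term"])
        annotations = ann_map
    else:
        for clade in config.clades:
            recs_1 = read_fasta(clade.fasta_1)
            recs_2 = read_fasta(clade.fasta_2)
            pairs = (read_ortholog_list(clade.ortholog_list)
                     if clade.ortholog_list else None)
            clade_inputs.append((clade, recs_1, recs_2, pairs))
        if config.annotations:
            annotations = read_annotation_table(config.annotations)

    results: dict[str, CladeResult] = {}
    rate_rows = []
    for run_cfg, recs_1, recs_2, pairs in clade_inputs:
        res = run_clade(recs_1, recs_2, run_cfg, config, pairs)
        results[run_cfg.name] = res
        write_tsv(estimates_table(res.estimates),
                  os.path.join(config.outdir, f"{run_cfg.name}_estimates.tsv"))
        write_tsv(res.discard_ledger,
                  os.path.join(config.outdir, f"{run_cfg.name}_discards.tsv"))
        if res.summary is not None:
            rate_rows += _rates_rows(res, run_cfg.scenario, config.n_bootstrap,
                                     config.seed)

    rates_frame = pd.DataFrame(rate_rows)
    write_tsv(rates_frame, os.path.join(config.outdir, "rates.tsv"))

    folds = None
    names = list(results)
    if len(names) >= 2 and results[names[0]].summary and results[names[1]].summary:
        cfg_by_name = {c[0].name: c[0] for c in clade_inputs}
        folds = fold_change_frame(
            fold_change_table(results[names[0]].summary, results[names[1]].summary,
                              cfg_by_name[names[0]].scenario,
                              cfg_by_name[names[1]].scenario)
        )
        write_tsv(folds, os.path.join(config.outdir, "fold_changes.tsv"))

    enrichment: dict[str, pd.DataFrame] = {}
    if config.run_enrichment and annotations and results:
        first = results[names[0]]
        omega = {e.pair_id.split("|")[0]: e.omega for e in first.kept
                 if e.omega is not None and e.dN is not None and e.dN > 0}
        if len(omega) >= 10:
            seg = ranked_segmentation_test(omega, annotations)
            logit = logistic_trend_test(omega, annotations)
            enrichment["segmentation"] = results_frame(seg)
            enrichment["logistic"] = results_frame(logit)
            try:
                het = across_category_heterogeneity(omega, annotations)
                enrichment["heterogeneity"] = results_frame([het])
            except ValueError:
                pass
        if len(names) >= 2:
            second = results[names[1]]
            omega_b = {e.pair_id.split("|")[0]: e.omega for e in second.kept
                       if e.omega is not None}
            if omega and omega_b:
                mw = compare_categories_between_clades(omega, omega_b, annotations)
                enrichment["between_clades"] = results_frame(mw)
        for name, frame in enrichment.items():
            write_tsv(frame, os.path.join(config.outdir, f"enrichment_{name}.tsv"))

    manifest = {
        "package": "codonrates",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "estimator": config.estimator,
        "clades": {
            name: {
                "input_pairs": res.n_input_pairs,
                "estimated": len(res.estimates),
                "kept": len(res.kept),
                "discarded": int(len(res.discard_ledger)),
            }
            for name, res in results.items()
        },
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(config.outdir, results, rates_frame, folds,
                          enrichment, manifest)
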