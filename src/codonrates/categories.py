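"""Annotation transfer and category-level selection statistics.

Genes receive flat GO-slim-like term sets from their best reference hit
(no ontology propagation).  Three kinds of category-level tests are
provided over per-gene evolutionary values (typically dN/dS or a 4D-site
rate):

* per-category two-clade comparison (Mann-Whitney U),
* across-category heterogeneity (Kruskal-Wallis H),
* ranked gene-set association - a Fisher-exact segmentation test over a
  collection of partitions of the omega-ranked gene list, and a logistic
  trend variant - with Benjamini-Hochberg FDR control across categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    terms: frozenset[str]
    source_evalue: Optional[float] = None


@dataclass(frozen=True)
class CategoryTestResult:
    term: str
    n_in: int
    n_out: int
    statistic: Optional[float]
    p: Optional[float]
    p_adj: Optional[float] = None
    direction: str = "none"  # high | low | a-high | b-high | none
    note: str = ""


# ---------------------------------------------------------------------------
# annotation transfer
# ---------------------------------------------------------------------------


def transfer_annotations(
    best_hits: Mapping[str, tuple[str, float]],
    reference_annotations: Mapping[str, set[str] | frozenset[str]],
    e_max: float = 1e-5,
) -> list[GeneAnnotation]:
    """Copy the reference gene's term set to each gene whose best hit passes
    the e-value threshold; everything else gets an empty term set."""
    out = []
    for gene_id, (ref_id, evalue) in sorted(best_hits.items()):
        terms: frozenset[str] = frozenset()
        if evalue <= e_max:
            ref_terms = reference_annotations.get(ref_id)
            if ref_terms is None:
                logger.warning("reference gene %s missing from annotation table",
                               ref_id)
            else:
                terms = frozenset(ref_terms)
        out.append(GeneAnnotation(gene_id, terms, evalue))
    return out


def read_annotation_table(path) -> dict[str, set[str]]:
    """TSV with gene_id, go_slim_term (+ optional description) columns."""
    frame = pd.read_csv(path, sep="\t")
    if not {"gene_id", "go_slim_term"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns gene_id, go_slim_term")
    out: dict[str, set[str]] = {}
    for gene, term in zip(frame["gene_id"], frame["go_slim_term"]):
        out.setdefault(str(gene), set()).add(str(term))
    return out


def _terms_of(annotations: Mapping[str, set[str] | frozenset[str]]) -> list[str]:
    terms: set[str] = set()
    for t in annotations.values():
        terms |= set(t)
    return sorted(terms)


def _bh_adjust(results: list[CategoryTestResult]) -> list[CategoryTestResult]:
    tested = [r for r in results if r.p is not None]
    if tested:
        _, p_adj, _, _ = multipletests([r.p for r in tested], method="fdr_bh")
        adj = {r.term: float(q) for r, q in zip(tested, p_adj)}
    else:
        adj = {}
    return [replace(r, p_adj=adj.get(r.term)) if r.p is not None else r
            for r in results]


# ---------------------------------------------------------------------------
# two-clade category comparison
# ---------------------------------------------------------------------------


def compare_categories_between_clades(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
    annotations: Mapping[str, set[str] | frozenset[str]],
    alpha: float = 0.05,
    min_genes: int = 2,
    exact_max_n: int = 20,
) -> list[CategoryTestResult]:
    """Two-sided Mann-Whitney U on per-gene values between clades, per
    category; exact null distribution for small groups, tie-corrected
    normal approximation otherwise."""
    results = []
    for term in _terms_of(annotations):
        ga = [v for g, v in values_a.items() if term in annotations.get(g, ())]
        gb = [v for g, v in values_b.items() if term in annotations.get(g, ())]
        if len(ga) < min_genes or len(gb) < min_genes:
            results.append(CategoryTestResult(term, len(ga) + len(gb), 0, None,
                                              None, note="below_min_size"))
            continue
        method = "exact" if max(len(ga), len(gb)) <= exact_max_n else "asymptotic"
        try:
            res = stats.mannwhitneyu(ga, gb, alternative="two-sided", method=method)
        except ValueError:
            # exact method refuses ties; fall back to the corrected normal
            res = stats.mannwhitneyu(ga, gb, alternative="two-sided",
                                     method="asymptotic")
        med_a, med_b = float(np.median(ga)), float(np.median(gb))
        if med_a > med_b:
            direction = "a-high"
        elif med_b > med_a:
            direction = "b-high"
        else:
            direction = "none"
        results.append(
            CategoryTestResult(term, len(ga), len(gb), float(res.statistic),
                               float(res.pvalue), direction=direction)
        )
    return _bh_adjust(results)


# ---------------------------------------------------------------------------
# across-category heterogeneity
# ---------------------------------------------------------------------------


def across_category_heterogeneity(
    values: Mapping[str, float],
    annotations: Mapping[str, set[str] | frozenset[str]],
    min_genes: int = 2,
) -> CategoryTestResult:
    """Kruskal-Wallis H across categories (tie-corrected, chi-squared p with
    k-1 df).  A gene with several terms contributes to each of them."""
    groups = []
    n_total = 0
    for term in _terms_of(annotations):
        g = [v for gid, v in values.items() if term in annotations.get(gid, ())]
        if len(g) >= min_genes:
            groups.append(g)
            n_total += len(g)
    if len(groups) < 2:
        raise ValueError("need at least 2 categories with enough genes")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return CategoryTestResult("(all)", n_total, 0, 0.0, 1.0,
                                  note="constant_values")
    h, p = stats.kruskal(*groups)
    return CategoryTestResult("(all)", n_total, 0, float(h), float(p))


# ---------------------------------------------------------------------------
# ranked gene-set association
# ---------------------------------------------------------------------------


def _ranked_genes(values: Mapping[str, float]) -> list[str]:
    """Gene ids ranked by value descending; ties broken by gene id for
    determinism."""
    return [g for g, _ in sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))]


def _partition_cuts(n: int, n_partitions: int) -> list[int]:
    cuts = sorted({min(max(round(k * n / (n_partitions + 1)), 1), n - 1)
                   for k in range(1, n_partitions + 1)})
    return [int(c) for c in cuts]


def ranked_segmentation_test(
    values: Mapping[str, float],
    annotations: Mapping[str, set[str] | frozenset[str]],
    n_partitions: int = 30,
    fdr_alpha: float = 0.05,
) -> list[CategoryTestResult]:
    """Fisher exact tests at a collection of thresholds along the ranked
    gene list.  Benjamini-Hochberg FDR is applied jointly over every
    (category, partition) test - the partitions are many and mutually
    dependent, so per-category minimum raw p-values are not calibrated on
    their own - and each category reports its best partition together with
    the adjusted p.  The direction says whether the category concentrates
    at the high- or low-value end of the ranking."""
    ranked = _ranked_genes(values)
    n = len(ranked)
    if n < 2:
        raise ValueError("need at least 2 ranked genes")
    cuts = _partition_cuts(n, n_partitions)
    membership = {g: annotations.get(g, frozenset()) for g in ranked}
    results = []
    all_tests: list[tuple[int, float]] = []  # (result index, raw partition p)
    for term in _terms_of(annotations):
        member = np.array([term in membership[g] for g in ranked])
        n_in = int(member.sum())
        if n_in == 0:
            results.append(CategoryTestResult(term, 0, n, None, None,
                                              note="absent_from_ranking"))
            continue
        best_p, best_dir, best_stat = None, "none", None
        term_ps = []
        for cut in cuts:
            in_top = int(member[:cut].sum())
            table = [[in_top, n_in - in_top],
                     [cut - in_top, (n - cut) - (n_in - in_top)]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            term_ps.append(float(p))
            if best_p is None or p < best_p:
                top_frac = in_top / cut
                bot_frac = (n_in - in_top) / (n - cut)
                best_p = float(p)
                best_dir = "high" if top_frac > bot_frac else "low"
                best_stat = float(odds) if np.isfinite(odds) else float("inf")
        idx = len(results)
        results.append(CategoryTestResult(term, n_in, n - n_in, best_stat,
                                          best_p, direction=best_dir))
        all_tests.extend((idx, p) for p in term_ps)
    if all_tests:
        _, p_adj, _, _ = multipletests([p for _, p in all_tests], method="fdr_bh")
        best_adj: dict[int, float] = {}
        for (idx, _), q in zip(all_tests, p_adj):
            best_adj[idx] = min(best_adj.get(idx, 1.0), float(q))
        results = [replace(r, p_adj=best_adj[i]) if i in best_adj else r
                   for i, r in enumerate(results)]
    return results


def logistic_trend_test(
    values: Mapping[str, float],
    annotations: Mapping[str, set[str] | frozenset[str]],
    fdr_alpha: float = 0.05,
) -> list[CategoryTestResult]:
    """Per category, membership probability modelled as a logistic function
    of rank percentile (1 = top of the ranking); Wald test on the slope.
    Complete separation falls back to a lightly penalised fit (four
    half-weight pseudo-observations at the percentile extremes), noted in
    the result."""
    import statsmodels.api as sm

    ranked = _ranked_genes(values)
    n = len(ranked)
    if n < 3:
        raise ValueError("need at least 3 ranked genes")
    pct = 1.0 - (np.arange(n) + 0.5) / n  # 1 at the top (highest values)
    results = []
    for term in _terms_of(annotations):
        y = np.array([term in annotations.get(g, ()) for g in ranked], dtype=float)
        n_in = int(y.sum())
        if n_in == 0 or n_in == n:
            results.append(CategoryTestResult(term, n_in, n - n_in, None, None,
                                              note="degenerate_membership"))
            continue
        x = sm.add_constant(pct)
        slope = p = None
        note = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
                if fit.mle_retvals.get("converged", False) and \
                        abs(fit.params[1]) < 50:
                    slope = float(fit.params[1])
                    p = float(fit.pvalues[1])
            except Exception:
                pass
            if p is None or not np.isfinite(p):
                y_aug = np.concatenate([y, [1, 0, 1, 0]])
                x_aug = sm.add_constant(np.concatenate([pct, [0, 0, 1, 1]]))
                w = np.concatenate([np.ones(n), [0.5] * 4])
                glm = sm.GLM(y_aug, x_aug, family=sm.families.Binomial(),
                             freq_weights=w).fit()
                slope = float(glm.params[1])
                p = float(glm.pvalues[1])
                note = "penalized"
        direction = "high" if slope > 0 else ("low" if slope < 0 else "none")
        results.append(CategoryTestResult(term, n_in, n - n_in, slope, p,
                                          direction=direction, note=note))
    return _bh_adjust(results)


def results_frame(results: Sequence[CategoryTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": r.term, "n_in": r.n_in, "statistic": r.statistic, "p": r.p,
          "p_adj": r.p_adj, "direction": r.direction, "note": r.note}
         for r in results],
        columns=["term", "n_in", "statistic", "p", "p_adj", "direction", "note"],
    )
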