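"""From per-gene distances to absolute substitution rates and clade tables.

The headline arithmetic: saturation filtering, the rate formula
``mu = d / (2T)`` with a fossil divergence-time range, optional asymmetric
apportionment of the rate between the two lineages (between-lineage ratio
rho, e.g. a slow tree lineage at one sixth of a fast annual lineage),
clade summary statistics, a fold-change table, and gene-level percentile
bootstrap confidence intervals.

The per-gene dN/dS summary is the mean of per-gene ratios, not the ratio of
mean dN to mean dS: the two differ markedly when dS varies across genes,
and the per-gene mean is the quantity the clade tables report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import substream
from .distances import PairwiseEstimate


@dataclass(frozen=True)
class FilterPolicy:
    """Saturation filter. Defaults follow the slow-clade settings; the
    fast-clade policy raises max_dS and adds a dN guard."""

    max_dS: float = 0.5
    max_dN: Optional[float] = None
    drop_undefined_ratio: bool = True

    def __post_init__(self):
        if self.max_dS <= 0 or (self.max_dN is not None and self.max_dN <= 0):
            raise ValueError("filter thresholds must be > 0")


CONIFER_FILTER = FilterPolicy(max_dS=0.5, max_dN=None)
ANGIOSPERM_FILTER = FilterPolicy(max_dS=4.0, max_dN=5.0)


def apply_filters(
    estimates: Sequence[PairwiseEstimate], policy: FilterPolicy
) -> tuple[list[PairwiseEstimate], pd.DataFrame]:
    """Drop saturated / degenerate genes; one reason per dropped gene, first
    matching rule wins: failed, undefined_ratio, max_dS, max_dN."""
    kept = []
    ledger_rows = []
    for e in estimates:
        reason = None
        if e.status == "failed":
            reason = "failed"
        elif policy.drop_undefined_ratio and e.status == "undefined_ratio":
            reason = "undefined_ratio"
        elif e.dS is not None and e.dS > policy.max_dS:
            reason = "max_dS"
        elif policy.max_dN is not None and e.dN is not None and e.dN > policy.max_dN:
            reason = "max_dN"
        if reason is None:
            kept.append(e)
        else:
            ledger_rows.append({"pair_id": e.pair_id, "reason": reason})
    ledger = pd.DataFrame(ledger_rows, columns=["pair_id", "reason"])
    return kept, ledger


@dataclass(frozen=True)
class DivergenceScenario:
    """Calibration: working divergence time T (years), fossil range
    [T_low, T_high], and between-lineage rate ratio rho (fast/slow, >= 1;
    1 = symmetric rates)."""

    T: float
    T_low: float
    T_high: float
    rho: float = 1.0

    def __post_init__(self):
        if not (0 < self.T_low <= self.T <= self.T_high):
            raise ValueError("need 0 < T_low <= T <= T_high")
        if self.rho < 1:
            raise ValueError("rho must be >= 1 (orient the pair fast/slow)")


#: working calibrations used throughout: 140 (120-160) My for the
#: spruce-pine split, 110 (105-115) My for the Arabidopsis-poplar split
CONIFER_SCENARIO = DivergenceScenario(140e6, 120e6, 160e6, rho=1.0)
ANGIOSPERM_SCENARIO = DivergenceScenario(110e6, 105e6, 115e6, rho=6.0)


@dataclass(frozen=True)
class RateEstimate:
    """Absolute substitution rate, per site per year."""

    mu: float
    mu_low: float
    mu_high: float
    site_class: str = ""
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self):
        if not (self.mu_low <= self.mu <= self.mu_high):
            raise ValueError("rate range must bracket the working-time rate")


def substitution_rate(d: float, scenario: DivergenceScenario,
                      site_class: str = "") -> RateEstimate:
    """mu = d / (2T); the range comes from the divergence-time range."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return RateEstimate(
        mu=d / (2.0 * scenario.T),
        mu_low=d / (2.0 * scenario.T_high),
        mu_high=d / (2.0 * scenario.T_low),
        site_class=site_class,
    )


def apportion_lineage_rates(d: float, scenario: DivergenceScenario) -> tuple[float, float]:
    """(mu_slow, mu_fast) when the two lineages evolve at ratio rho.

    Conservation: (mu_slow + mu_fast) * T == d exactly.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    rho = scenario.rho
    mu_slow = d / ((1.0 + rho) * scenario.T)
    return mu_slow, rho * mu_slow


@dataclass(frozen=True)
class CladeSummary:
    name: str
    n_genes: int
    mean_dS: float
    mean_d4: Optional[float]
    mean_dN: float
    mean_omega: float
    frac_omega_gt1: float


def clade_summary(kept: Sequence[PairwiseEstimate], name: str = "") -> CladeSummary:
    """Arithmetic means over kept genes; omega is the mean of per-gene
    ratios over genes where it is defined."""
    if not kept:
        raise ValueError("empty estimate set")
    ds = [e.dS for e in kept if e.dS is not None]
    dn = [e.dN for e in kept if e.dN is not None]
    d4 = [e.d4 for e in kept if e.d4 is not None]
    omega = [e.omega for e in kept if e.omega is not None]
    if not ds or not dn or not omega:
        raise ValueError("no defined distances in the kept set")
    return CladeSummary(
        name=name,
        n_genes=len(kept),
        mean_dS=float(np.mean(ds)),
        mean_d4=float(np.mean(d4)) if d4 else None,
        mean_dN=float(np.mean(dn)),
        mean_omega=float(np.mean(omega)),
        frac_omega_gt1=float(np.mean([w > 1.0 for w in omega])),
    )


@dataclass(frozen=True)
class FoldChange:
    quantity: str
    ratio: Optional[float]  # unrounded b/a (None on zero denominator)
    fold: Optional[float]  # rounded to 1 decimal, always >= 1
    label: Optional[str]  # "x:1" when b > a, "1:x" when a > b


def _fold_row(quantity: str, a: Optional[float], b: Optional[float]) -> FoldChange:
    if a is None or b is None or a == 0:
        return FoldChange(quantity, None, None, None)
    r = b / a
    if r == 0:
        return FoldChange(quantity, r, None, None)
    if r >= 1:
        fold = round(r, 1)
        label = f"{fold}:1"
    else:
        fold = round(1.0 / r, 1)
        label = f"1:{fold}"
    return FoldChange(quantity, r, fold, label)


def fold_change_table(
    summary_a: CladeSummary,
    summary_b: CladeSummary,
    scenario_a: DivergenceScenario,
    scenario_b: DivergenceScenario,
) -> list[FoldChange]:
    """Fold changes of clade B over clade A for the distance means, the
    absolute rates at the working times, and mean dN/dS (reported 1:x when
    clade A is larger)."""
    mu = lambda d, sc: None if d is None else d / (2.0 * sc.T)
    rows = [
        _fold_row("dS", summary_a.mean_dS, summary_b.mean_dS),
        _fold_row("d4", summary_a.mean_d4, summary_b.mean_d4),
        _fold_row("dN", summary_a.mean_dN, summary_b.mean_dN),
        _fold_row("muS", mu(summary_a.mean_dS, scenario_a), mu(summary_b.mean_dS, scenario_b)),
        _fold_row("mu4D", mu(summary_a.mean_d4, scenario_a), mu(summary_b.mean_d4, scenario_b)),
        _fold_row("muN", mu(summary_a.mean_dN, scenario_a), mu(summary_b.mean_dN, scenario_b)),
        _fold_row("omega", summary_a.mean_omega, summary_b.mean_omega),
    ]
    return rows


def fold_change_frame(rows: Iterable[FoldChange]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"quantity": r.quantity, "ratio": r.ratio, "fold": r.fold,
          "label": r.label} for r in rows],
        columns=["quantity", "ratio", "fold", "label"],
    )


def bootstrap_ci(
    values: Sequence[float],
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Gene-level percentile bootstrap of the mean: (mean, ci_low, ci_high)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = substream(seed, "bootstrap_ci")
    idx = rng.integers(0, values.size, size=(n_reps, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)
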