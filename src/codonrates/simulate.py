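"""Synthetic data with known truth for every pipeline stage.

Orthologous codon pairs are simulated under the reversible codon model in
:mod:`codonrates.model`: an ancestral sequence is drawn from the stationary
codon distribution and two lineages evolve independently for ``t/2`` each,
using exact matrix-exponential transition probabilities per codon site (no
Gillespie simulation), so a fixed seed gives byte-identical output.

Coding sequences can then be wrapped into cDNA-like records (random UTRs,
optional 5'/3' truncation emulating EST-cluster fragments), and whole
two-clade studies can be generated with decoy paralogues and planted
functional categories, mirroring a slow-evolving conifer-like clade and a
fast-evolving angiosperm-like clade with a saturated-dS tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import model
from ._seeds import substream
from .io import SequenceRecord

STOP_FOR_WRAP = "TAA"


# ---------------------------------------------------------------------------
# pair simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimRegime:
    """Generative truth for one codon pair.

    t_codon is the total pairwise divergence in expected substitutions per
    codon (each lineage evolves for half of it); kappa the
    transition/transversion rate ratio; omega the dN/dS rate ratio.
    """

    n_codons: int
    t_codon: float
    kappa: float
    omega: float
    codon_freqs: np.ndarray | None = None
    seed: int = 0

    def frequencies(self) -> np.ndarray:
        if self.codon_freqs is None:
            return model.uniform_sense_frequencies()
        return model.validate_frequencies(np.asarray(self.codon_freqs, float))

    def validate(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        for name in ("t_codon", "kappa", "omega"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.t_codon < 0:
            raise ValueError("t_codon must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        self.frequencies()


def expected_distances(regime: SimRegime) -> tuple[float, float]:
    """(dN, dS) implied by the generating matrix at the regime's t.

    Uses the mutational-opportunity site definition: the synonymous fraction
    of stationary flow at (kappa, omega), normalised by the same fraction at
    omega = 1.
    """
    pi = regime.frequencies()
    rho_s = model.synonymous_flow_fraction(pi, regime.kappa, regime.omega)
    rho_s1 = model.synonymous_flow_fraction(pi, regime.kappa, 1.0)
    ds = regime.t_codon * rho_s / (3.0 * rho_s1)
    dn = regime.t_codon * (1.0 - rho_s) / (3.0 * (1.0 - rho_s1))
    return dn, ds


def divergence_for_ds(ds: float, kappa: float, omega: float,
                      pi: np.ndarray | None = None) -> float:
    """Invert dS(t) to the branch length t producing a target dS."""
    if pi is None:
        pi = model.uniform_sense_frequencies()
    rho_s = model.synonymous_flow_fraction(pi, kappa, omega)
    rho_s1 = model.synonymous_flow_fraction(pi, kappa, 1.0)
    return ds * 3.0 * rho_s1 / rho_s


def _sample_codons(rng: np.random.Generator, pi: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(model.N_SENSE, size=n, p=pi)


def _evolve(rng: np.random.Generator, ancestor: np.ndarray,
            eig: model._Eigensystem, t: float) -> np.ndarray:
    p = eig.probabilities(t)
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(ancestor.size)
    return (u[:, np.newaxis] > cum[ancestor]).sum(axis=1)


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(model.SENSE_CODONS[i] for i in idx)


def simulate_codon_pair(regime: SimRegime) -> tuple[str, str, dict]:
    """Simulate one orthologous codon-sequence pair.

    Returns gap-free, stop-free nucleotide strings of length 3*n_codons and
    a truth record with the generating parameters and model-expected dN/dS.
    """
    regime.validate()
    pi = regime.frequencies()
    rng = substream(regime.seed, "simulate_codon_pair")
    ancestor = _sample_codons(rng, pi, regime.n_codons)
    if regime.t_codon == 0:
        a = b = ancestor
    else:
        eig = model.eigensystem(pi, regime.kappa, regime.omega)
        half = regime.t_codon / 2.0
        a = _evolve(rng, ancestor, eig, half)
        b = _evolve(rng, ancestor, eig, half)
    dn, ds = expected_distances(regime)
    truth = {
        "t": regime.t_codon,
        "kappa": regime.kappa,
        "omega": regime.omega,
        "dN_true": dn,
        "dS_true": ds,
        "n_codons": regime.n_codons,
    }
    return _indices_to_seq(a), _indices_to_seq(b), truth


# ---------------------------------------------------------------------------
# cDNA wrapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WrappedCdna:
    """A cDNA-like sequence with the planted ORF's coordinates (0-based,
    half-open, on the emitted sequence; the ORF may be truncated)."""

    seq: str
    orf_start: int
    orf_end: int
    truncated_5p: bool = False
    truncated_3p: bool = False


def _random_utr(rng: np.random.Generator, length: int) -> str:
    """Random UTR with every ATG occurrence broken (so the planted ORF stays
    the unique maximal ORF in its frame)."""
    if length == 0:
        return ""
    nts = list(rng.choice(list("ACGT"), size=length))
    s = "".join(nts)
    pos = s.find("ATG")
    while pos != -1:
        nts[pos + 1] = rng.choice(list("ACG"))
        s = "".join(nts)
        pos = s.find("ATG", pos)
    return s


def wrap_as_cdna(
    codon_seq: str,
    utr5_len: int = 0,
    utr3_len: int = 0,
    truncate_fraction: float = 0.0,
    seed: int = 0,
    truncate_end: Literal["5p", "3p", None] = None,
) -> WrappedCdna:
    """Embed a stop-free coding body in a cDNA-like record.

    The body gets an ATG start and a TAA stop; random UTRs (free of ATG, so
    no longer ORF can arise upstream) are attached; an optional truncation
    removes a fraction of the record from one end, possibly cutting into the
    start or stop codon as in EST-cluster consensus sequences.
    """
    if utr5_len < 0 or utr3_len < 0:
        raise ValueError("UTR lengths must be >= 0")
    if not 0 <= truncate_fraction < 1:
        raise ValueError("truncate_fraction must be in [0, 1)")
    if len(codon_seq) % 3 != 0:
        raise ValueError("codon_seq length must be a multiple of 3")
    rng = substream(seed, "wrap_as_cdna")
    orf = "ATG" + codon_seq + STOP_FOR_WRAP
    utr5 = _random_utr(rng, utr5_len)
    utr3 = _random_utr(rng, utr3_len)
    seq = utr5 + orf + utr3
    start, end = len(utr5), len(utr5) + len(orf)
    cut5 = cut3 = False
    if truncate_fraction > 0:
        n_cut = int(round(truncate_fraction * len(seq)))
        endsel = truncate_end or rng.choice(["5p", "3p"])
        if endsel == "5p":
            seq = seq[n_cut:]
            start, end = start - n_cut, end - n_cut
            if start < 0:
                # a mid-codon cut: advance to the first complete codon
                start = (3 - ((-start) % 3)) % 3
            cut5 = n_cut > 0
        else:
            seq = seq[: len(seq) - n_cut]
            end = min(end, len(seq))
            end = start + 3 * ((end - start) // 3)  # trim any partial codon
            cut3 = n_cut > 0
        if end - start < 3:
            raise ValueError("truncation would leave less than one codon of ORF")
    return WrappedCdna(seq, start, end, cut5, cut3)


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WrapConfig:
    utr5_len: int = 60
    utr3_len: int = 40
    truncate_fraction: float = 0.0
    truncate_end: Literal["5p", "3p", None] = None


@dataclass(frozen=True)
class CladeConfig:
    """Generative regime for one two-species clade comparison.

    mean_ds / ds_shape parameterise a gamma distribution of per-gene dS for
    the unsaturated body of genes; a configurable fraction of genes is drawn
    from a saturated tail above ``saturated_ds_offset``.  mean_omega /
    omega_shape give the per-gene dN/dS distribution.
    """

    name: str
    n_pairs: int
    n_codons: int = 170
    mean_ds: float = 0.19
    ds_shape: float = 2.0
    saturated_fraction: float = 0.0
    saturated_ds_offset: float = 4.0
    saturated_ds_mean_excess: float = 2.5
    mean_omega: float = 0.31
    omega_shape: float = 1.5
    kappa: float = 2.0
    n_decoys: int = 0
    decoy_extra_t: float = 2.0
    wrap_1: WrapConfig | None = None
    wrap_2: WrapConfig | None = None

    def validate(self) -> None:
        if self.n_pairs < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        for name in ("mean_ds", "ds_shape", "mean_omega", "omega_shape", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.saturated_fraction < 1:
            raise ValueError("saturated_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PlantedCategory:
    """A functional term planted on clade-1 genes with rescaled omega."""

    name: str
    n_genes: int
    omega_multiplier: float


@dataclass(frozen=True)
class StudyConfig:
    clades: tuple[CladeConfig, ...]
    planted: tuple[PlantedCategory, ...] = ()
    n_background_terms: int = 8
    max_omega: float = 5.0

    def validate(self) -> None:
        if len(self.clades) == 0:
            raise ValueError("at least one clade required")
        names = [c.name for c in self.clades]
        if len(set(names)) != len(names):
            raise ValueError("clade names must be unique")
        for c in self.clades:
            c.validate()
        total_planted = sum(p.n_genes for p in self.planted)
        if self.planted and total_planted > self.clades[0].n_pairs:
            raise ValueError("planted categories exceed clade-1 gene count")


@dataclass
class CladeData:
    config: CladeConfig
    records_1: list[SequenceRecord]
    records_2: list[SequenceRecord]
    pairs: list[tuple[str, str]]
    orf_truth: dict[str, tuple[int, int]]  # id -> planted ORF coords


@dataclass
class Study:
    """Everything the pipeline consumes, with generative truth attached."""

    config: StudyConfig
    clades: dict[str, CladeData]
    truth: pd.DataFrame
    annotations: pd.DataFrame

    def write(self, outdir) -> None:
        import os

        from .io import write_fasta, write_tsv

        os.makedirs(outdir, exist_ok=True)
        for name, clade in self.clades.items():
            write_fasta(clade.records_1, os.path.join(outdir, f"{name}_sp1.fasta"))
            write_fasta(clade.records_2, os.path.join(outdir, f"{name}_sp2.fasta"))
            pairs = pd.DataFrame(clade.pairs, columns=["id_a", "id_b"])
            write_tsv(pairs, os.path.join(outdir, f"{name}_orthologues.tsv"))
        write_tsv(self.truth, os.path.join(outdir, "truth.tsv"))
        write_tsv(self.annotations, os.path.join(outdir, "annotations.tsv"))


def _draw_ds(rng: np.random.Generator, cfg: CladeConfig) -> tuple[float, bool]:
    saturated = rng.random() < cfg.saturated_fraction
    if saturated:
        ds = cfg.saturated_ds_offset + rng.gamma(2.0, cfg.saturated_ds_mean_excess / 2.0)
    else:
        ds = rng.gamma(cfg.ds_shape, cfg.mean_ds / cfg.ds_shape)
        ds = min(ds, cfg.saturated_ds_offset * 0.98)  # keep body below the tail
    return float(ds), saturated


def generate_study(config: StudyConfig, seed: int) -> Study:
    """Generate a full multi-clade study; deterministic for a fixed seed."""
    config.validate()
    truth_rows = []
    clades: dict[str, CladeData] = {}
    ann_rows = []
    bg_terms = [f"GO:BG{i:02d}" for i in range(config.n_background_terms)]

    for ci, cfg in enumerate(config.clades):
        rng = substream(seed, f"study/{cfg.name}")
        planted_map: dict[int, str] = {}
        if ci == 0 and config.planted:
            order = rng.permutation(cfg.n_pairs)
            k = 0
            for cat in config.planted:
                for g in order[k : k + cat.n_genes]:
                    planted_map[int(g)] = cat.name
                k += cat.n_genes
        mult = {p.name: p.omega_multiplier for p in config.planted}

        recs1, recs2, pairs = [], [], []
        orf_truth: dict[str, tuple[int, int]] = {}
        ancestors: list[np.ndarray] = []
        pi = model.uniform_sense_frequencies()
        for g in range(cfg.n_pairs):
            n_codons = int(rng.integers(int(0.7 * cfg.n_codons), int(1.3 * cfg.n_codons) + 1))
            ds, saturated = _draw_ds(rng, cfg)
            omega = float(rng.gamma(cfg.omega_shape, cfg.mean_omega / cfg.omega_shape))
            category = planted_map.get(g, "")
            if category:
                omega *= mult[category]
            omega = float(np.clip(omega, 1e-3, config.max_omega))
            t = divergence_for_ds(ds, cfg.kappa, omega, pi)
            pair_seed = int(rng.integers(0, 2**31 - 1))
            regime = SimRegime(n_codons, t, cfg.kappa, omega, None, pair_seed)
            seq_a, seq_b, row = simulate_codon_pair(regime)
            id_a = f"{cfg.name}_{g:04d}_a"
            id_b = f"{cfg.name}_{g:04d}_b"
            ancestors.append((seq_a, pair_seed))
            for sid, seq, wrap in ((id_a, seq_a, cfg.wrap_1), (id_b, seq_b, cfg.wrap_2)):
                if wrap is None:
                    recs = SequenceRecord(sid, "ATG" + seq + STOP_FOR_WRAP)
                    orf_truth[sid] = (0, len(recs.seq))
                else:
                    w = wrap_as_cdna(seq, wrap.utr5_len, wrap.utr3_len,
                                     wrap.truncate_fraction,
                                     seed=pair_seed + (0 if sid == id_a else 1),
                                     truncate_end=wrap.truncate_end)
                    recs = SequenceRecord(sid, w.seq)
                    orf_truth[sid] = (w.orf_start, w.orf_end)
                (recs1 if sid == id_a else recs2).append(recs)
            pairs.append((id_a, id_b))
            row.update({"pair_id": f"{cfg.name}_{g:04d}", "clade": cfg.name,
                        "category": category, "saturated": saturated})
            truth_rows.append(row)
            terms = [category] if (ci == 0 and category) else []
            n_bg = int(rng.integers(1, 3))
            terms += list(rng.choice(bg_terms, size=n_bg, replace=False))
            for term in terms:
                ann_rows.append({"gene_id": id_a, "go_slim_term": term,
                                 "description": f"synthetic annotation {term}"})

        # decoys: paralogue-like unpaired sequences in species 2, evolved from
        # existing genes at much larger divergence so they lose RBH contests
        for d in range(cfg.n_decoys):
            src_seq, src_seed = ancestors[int(rng.integers(0, len(ancestors)))]
            idx = np.array([model.CODON_INDEX[src_seq[i : i + 3]]
                            for i in range(0, len(src_seq), 3)])
            eig = model.eigensystem(pi, cfg.kappa, 0.5)
            drng = substream(seed, f"study/{cfg.name}/decoy{d}")
            mutated = _evolve(drng, idx, eig, cfg.decoy_extra_t)
            sid = f"{cfg.name}_decoy{d:03d}_b"
            recs2.append(SequenceRecord(sid, "ATG" + _indices_to_seq(mutated) + STOP_FOR_WRAP))
            orf_truth[sid] = (0, len(recs2[-1].seq))

        clades[cfg.name] = CladeData(cfg, recs1, recs2, pairs, orf_truth)

    truth = pd.DataFrame(truth_rows, columns=["pair_id", "clade", "t", "kappa",
                                              "omega", "dN_true", "dS_true",
                                              "n_codons", "category", "saturated"])
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "go_slim_term",
                                                  "description"])
    return Study(config, clades, truth, annotations)


def conifer_like(n_pairs: int = 300, **overrides) -> CladeConfig:
    """Slow-evolving clade: low dS (mean 0.19), elevated omega (mean 0.31)."""
    defaults = dict(name="conifer", n_pairs=n_pairs, n_codons=170,
                    mean_ds=0.19, ds_shape=2.0, saturated_fraction=0.0,
                    mean_omega=0.31, omega_shape=1.5, kappa=2.0)
    defaults.update(overrides)
    return CladeConfig(**defaults)


def angiosperm_like(n_pairs: int = 300, **overrides) -> CladeConfig:
    """Fast-evolving clade: high dS (unsaturated body mean 2.2, 25% of genes
    in a saturated dS > 4 tail), low omega (mean 0.09)."""
    defaults = dict(name="angiosperm", n_pairs=n_pairs, n_codons=129,
                    mean_ds=2.2, ds_shape=8.0, saturated_fraction=0.25,
                    saturated_ds_offset=4.0, saturated_ds_mean_excess=2.5,
                    mean_omega=0.09, omega_shape=1.5, kappa=2.0)
    defaults.update(overrides)
    return CladeConfig(**defaults)
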