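"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emits a complete, desk-scale stand-in for the real inputs:

- several overlapping mark target-gene datasets (true targets dropped from
  each dataset independently with a configurable dropout probability, so
  2-of-3 integration is exercised);
- class-labelled paralog pairs whose expression profiles are bivariate
  normal with class-dependent correlation and level;
- coding-sequence pairs evolved from random ancestors to target dN and dS;
- 500-bp upstream regions with shared motif blocks planted at
  class-dependent probability;

plus a ground-truth table so recovery can be tested end to end.  All
randomness derives from one master seed; identical configs give
byte-identical outputs.

Codon pairs are produced by planting Poisson-distributed *observed*
difference counts with mean ``p * sites``, where ``p`` is the inverse
Jukes-Cantor transform of the target distance, at distinct nucleotide
positions split between the two descendant branches.  Each planted change
is classified (synonymous/nonsynonymous, against the branch's current
codon) and never creates a stop codon.  Distinct positions keep the
observed difference counts equal to the planted ones, so the
Nei-Gojobori + Jukes-Cantor estimate is unbiased for the target at the
divergences simulated here, while the Poisson counts retain honest
sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import io as mdio
from ._seeds import stage_rng
from .coding_divergence import _syn_sites
from .expression_divergence import ExpressionMatrix
from .mark_classes import MARK_CLASSES, MarkDataset

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_mark_datasets",
    "generate_expression",
    "random_sense_cds",
    "evolve_codon_pair",
    "generate_upstream_pairs",
    "generate_dataset",
]

_BASES = "ACGT"


def _class_dict(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(MARK_CLASSES) - set(value)
        if missing:
            raise ValueError(f"missing classes in config mapping: {sorted(missing)}")
        return {c: value[c] for c in MARK_CLASSES}
    return {c: value for c in MARK_CLASSES}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic universe (defaults are the desk-scale study
    conditions; see docs/methods.md for the rationale of each value)."""

    n_pairs: Mapping[str, int] = field(
        default_factory=lambda: {"both": 300, "mixed": 300, "none": 300})
    rho: Mapping[str, float] = field(
        default_factory=lambda: {"both": 0.6, "mixed": 0.2, "none": 0.45})
    level_mean: Mapping[str, float] = field(
        default_factory=lambda: {"both": 6.0, "mixed": 6.3, "none": 7.5})
    level_sd: float = 0.8
    noise_sd: float = 1.0
    n_samples: int = 100
    n_background_genes: int = 4000
    background_level_mean: float = 7.0
    background_target_fraction: float = 0.2
    dn_target: Mapping[str, float] = field(
        default_factory=lambda: {"both": 0.20, "mixed": 0.22, "none": 0.14})
    ds_target: Mapping[str, float] = field(
        default_factory=lambda: {"both": 0.8, "mixed": 0.7, "none": 0.6})
    n_codons: int = 200
    motif_prob: Mapping[str, float] = field(
        default_factory=lambda: {"both": 0.40, "mixed": 0.20, "none": 0.25})
    motif_length: int = 25
    promoter_length: int = 500
    n_mark_datasets: int = 3
    dataset_dropout: float = 0.1
    measurable_fraction: float = 0.72
    level_rho_slope: float = 0.0
    master_seed: int = 17

    def __post_init__(self) -> None:
        self.n_pairs = {c: int(v) for c, v in _class_dict(self.n_pairs).items()}
        self.rho = _class_dict(self.rho)
        self.level_mean = _class_dict(self.level_mean)
        self.dn_target = _class_dict(self.dn_target)
        self.ds_target = _class_dict(self.ds_target)
        self.motif_prob = _class_dict(self.motif_prob)
        if any(v < 0 for v in self.n_pairs.values()):
            raise ValueError("negative pair count")
        if sum(self.n_pairs.values()) == 0:
            raise ValueError("no pairs requested")
        if not all(0 <= r < 1 for r in self.rho.values()):
            raise ValueError("rho must be in [0, 1)")
        if not all(0 <= p <= 1 for p in self.motif_prob.values()):
            raise ValueError("motif_prob must be in [0, 1]")
        if not 0 <= self.dataset_dropout <= 1:
            raise ValueError("dataset_dropout must be in [0, 1]")
        if self.motif_length > self.promoter_length:
            raise ValueError("motif_length exceeds promoter_length")
        if self.n_mark_datasets < 1:
            raise ValueError("need at least one mark dataset")

    def to_dict(self) -> dict:
        return {
            "n_pairs": dict(self.n_pairs), "rho": dict(self.rho),
            "level_mean": dict(self.level_mean), "level_sd": self.level_sd,
            "noise_sd": self.noise_sd, "n_samples": self.n_samples,
            "n_background_genes": self.n_background_genes,
            "background_level_mean": self.background_level_mean,
            "background_target_fraction": self.background_target_fraction,
            "dn_target": dict(self.dn_target), "ds_target": dict(self.ds_target),
            "n_codons": self.n_codons, "motif_prob": dict(self.motif_prob),
            "motif_length": self.motif_length,
            "promoter_length": self.promoter_length,
            "n_mark_datasets": self.n_mark_datasets,
            "dataset_dropout": self.dataset_dropout,
            "measurable_fraction": self.measurable_fraction,
            "level_rho_slope": self.level_rho_slope,
            "master_seed": self.master_seed,
        }


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimulationConfig
    mark_datasets: list[MarkDataset]
    true_targets: set[str]
    pairs: list[tuple[str, str]]
    expression: ExpressionMatrix
    cds: dict[str, str]
    proteins: dict[str, str]
    upstream: dict[str, str]
    measurable_genes: set[str]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Emit every file the analysis modules read, plus truth and config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, ds in enumerate(self.mark_datasets, start=1):
            mdio.write_gene_list(outdir / f"marks_{k}.txt", sorted(ds.gene_ids))
        mdio.write_pair_list(outdir / "pairs.tsv", self.pairs)
        mdio.write_fasta(outdir / "cds.fasta", self.cds)
        mdio.write_fasta(outdir / "proteins.fasta", self.proteins)
        mdio.write_expression_matrix(outdir / "expression.tsv", self.expression)
        mdio.write_fasta(outdir / "upstream.fasta", self.upstream)
        mdio.write_gene_list(outdir / "measurable_genes.txt",
                             sorted(self.measurable_genes))
        self.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# gene naming

def _agi_like_ids(n: int, prefix_offset: int = 0) -> list[str]:
    """Deterministic AGI-style identifiers (AT1G00010, ...)."""
    out = []
    for k in range(n):
        idx = k + prefix_offset
        chrom = idx % 5 + 1
        num = (idx // 5 + 1) * 10
        out.append(f"AT{chrom}G{num:05d}")
    return out


def _pair_table(config: SimulationConfig) -> pd.DataFrame:
    """Pair ids, member genes and true classes, in a fixed deterministic order."""
    n_total = sum(config.n_pairs.values())
    gene_ids = _agi_like_ids(2 * n_total)
    rows = []
    k = 0
    for cls in MARK_CLASSES:
        for _ in range(config.n_pairs[cls]):
            a, b = gene_ids[2 * k], gene_ids[2 * k + 1]
            rows.append({"pair_id": "|".join(sorted((a, b))), "gene_a": a,
                         "gene_b": b, "true_class": cls})
            k += 1
    return pd.DataFrame(rows)


def _background_ids(config: SimulationConfig) -> list[str]:
    n_pair_genes = 2 * sum(config.n_pairs.values())
    return _agi_like_ids(config.n_background_genes, prefix_offset=n_pair_genes)


# ---------------------------------------------------------------------------
# mark datasets

def generate_mark_datasets(config: SimulationConfig
                           ) -> tuple[list[MarkDataset], set[str]]:
    """Mark datasets with per-dataset dropout, plus the true target set.

    True targets: both genes of every ``both`` pair, gene_a of every
    ``mixed`` pair, and a random fraction of background genes.  Each true
    target enters each dataset independently with probability
    ``1 - dataset_dropout``.
    """
    rng = stage_rng(config.master_seed, "marks")
    table = _pair_table(config)
    targets: set[str] = set()
    for row in table.itertuples():
        if row.true_class == "both":
            targets.update((row.gene_a, row.gene_b))
        elif row.true_class == "mixed":
            targets.add(row.gene_a)
    background = _background_ids(config)
    n_bg_targets = int(round(config.background_target_fraction * len(background)))
    if n_bg_targets:
        targets.update(rng.choice(background, size=n_bg_targets, replace=False))
    ordered = sorted(targets)
    datasets = []
    for k in range(config.n_mark_datasets):
        keep = rng.random(len(ordered)) >= config.dataset_dropout
        members = [g for g, kept in zip(ordered, keep) if kept]
        datasets.append(MarkDataset.from_iterable(f"synthetic_{k + 1}", members))
    return datasets, targets


# ---------------------------------------------------------------------------
# expression

def generate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix plus the pair/truth table used to build it.

    Each pair's two profiles are bivariate normal across samples: common
    per-pair level (drawn around the class level mean), correlation
    ``rho_class`` (optionally coupled to level through
    ``level_rho_slope``), unit-free intensity on a log-like scale.
    Background genes are mutually independent.
    """
    rng = stage_rng(config.master_seed, "expression")
    table = _pair_table(config).copy()
    n_samples = config.n_samples
    rows: dict[str, np.ndarray] = {}
    rho_used, level_used = [], []
    for row in table.itertuples():
        cls = row.true_class
        level = config.level_mean[cls] + config.level_sd * rng.standard_normal()
        rho = config.rho[cls] + config.level_rho_slope * (level - config.level_mean[cls])
        rho = float(np.clip(rho, 0.0, 0.99))
        z1 = rng.standard_normal(n_samples)
        z2 = rng.standard_normal(n_samples)
        x = level + config.noise_sd * z1
        y = level + config.noise_sd * (rho * z1 + math.sqrt(1.0 - rho ** 2) * z2)
        rows[row.gene_a] = x
        rows[row.gene_b] = y
        rho_used.append(rho)
        level_used.append(level)
    for gene in _background_ids(config):
        rows[gene] = (config.background_level_mean
                      + config.noise_sd * rng.standard_normal(n_samples))
    table["rho_used"] = rho_used
    table["level_used"] = level_used
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"sample_{s + 1}" for s in range(n_samples)])
    return ExpressionMatrix(data=df), table


# ---------------------------------------------------------------------------
# coding sequences

@lru_cache(maxsize=1)
def _mutation_fates(table_id: int = 1) -> dict[tuple[str, int, str], str]:
    """(codon, position, new_base) -> 'syn' | 'nonsyn' | 'stop'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    aa = table.forward_table
    fates = {}
    for codon in aa:
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt in stops:
                    fate = "stop"
                elif aa[alt] == aa[codon]:
                    fate = "syn"
                else:
                    fate = "nonsyn"
                fates[(codon, pos, base)] = fate
    return fates


def random_sense_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random CDS: ATG start then random non-stop codons."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    table = CodonTable.unambiguous_dna_by_id[1]
    sense = sorted(table.forward_table)
    idx = rng.integers(len(sense), size=n_codons - 1)
    return "ATG" + "".join(sense[i] for i in idx)


def _inverse_jc(d: float) -> float:
    """Observable difference proportion for a Jukes-Cantor distance."""
    if d < 0 or not math.isfinite(d):
        raise ValueError(f"divergence target must be finite and >= 0, got {d}")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_codon_pair(ancestral_cds: str, ds_target: float, dn_target: float,
                      seed: int | np.random.Generator) -> tuple[str, str, str, str]:
    """Two descendant CDS at target pairwise dN/dS, plus their proteins.

    Returns (cds_a, cds_b, protein_a, protein_b).  See the module docstring
    for the planting scheme.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cds = ancestral_cds.upper()
    if len(cds) % 3:
        raise ValueError("ancestral CDS length not divisible by 3")
    table = CodonTable.unambiguous_dna_by_id[1]
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if any(c in table.stop_codons for c in codons):
        raise ValueError("ancestral CDS contains internal stop codons")
    s_anc = sum(_syn_sites(c, 1) for c in codons)
    n_anc = 3 * len(codons) - s_anc
    p_s = _inverse_jc(ds_target)
    p_n = _inverse_jc(dn_target)
    n_syn_total = int(rng.poisson(p_s * s_anc))
    n_non_total = int(rng.poisson(p_n * n_anc))
    branches = [list(codons), list(codons)]
    syn_per_branch = int(rng.binomial(n_syn_total, 0.5))
    non_per_branch = int(rng.binomial(n_non_total, 0.5))
    needs = [[syn_per_branch, non_per_branch],
             [n_syn_total - syn_per_branch, n_non_total - non_per_branch]]
    fates = _mutation_fates(1)
    mutated: set[int] = set()
    n_positions = len(cds)
    max_attempts = 1000 * (n_syn_total + n_non_total + 1) + 10 * n_positions
    attempts = 0
    for branch, (need_syn, need_non) in zip(branches, needs):
        while need_syn or need_non:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not place requested substitutions; targets too "
                    "dense for the sequence length")
            pos = int(rng.integers(n_positions))
            if pos in mutated:
                continue
            ci, off = divmod(pos, 3)
            codon = branch[ci]
            base = _BASES[int(rng.integers(4))]
            if base == codon[off]:
                continue
            fate = fates[(codon, off, base)]
            if fate == "stop":
                continue
            if fate == "syn" and need_syn:
                need_syn -= 1
            elif fate == "nonsyn" and need_non:
                need_non -= 1
            else:
                continue
            branch[ci] = codon[:off] + base + codon[off + 1:]
            mutated.add(pos)
    cds_a, cds_b = "".join(branches[0]), "".join(branches[1])
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())
    return cds_a, cds_b, prot_a, prot_b


def _generate_coding(config: SimulationConfig, table: pd.DataFrame
                     ) -> tuple[dict[str, str], dict[str, str]]:
    rng = stage_rng(config.master_seed, "coding")
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    for row in table.itertuples():
        ancestor = random_sense_cds(config.n_codons, rng)
        ca, cb, pa, pb = evolve_codon_pair(
            ancestor, config.ds_target[row.true_class],
            config.dn_target[row.true_class], rng)
        cds[row.gene_a], cds[row.gene_b] = ca, cb
        proteins[row.gene_a], proteins[row.gene_b] = pa, pb
    return cds, proteins


# ---------------------------------------------------------------------------
# upstream regions

def generate_upstream_pairs(config: SimulationConfig
                            ) -> tuple[dict[str, str], pd.DataFrame]:
    """Upstream regions for pair and background genes, plus planting truth.

    Each pair's two regions are independent random sequences; with
    probability ``motif_prob[class]`` a shared block of ``motif_length``
    is copied between them at independent random offsets.
    """
    rng = stage_rng(config.master_seed, "upstream")
    table = _pair_table(config).copy()
    plen, mlen = config.promoter_length, config.motif_length
    regions: dict[str, str] = {}

    def random_region() -> str:
        return "".join(np.array(list(_BASES))[rng.integers(4, size=plen)])

    planted = []
    for row in table.itertuples():
        sa, sb = random_region(), random_region()
        plant = bool(rng.random() < config.motif_prob[row.true_class])
        if plant:
            off_a = int(rng.integers(plen - mlen + 1))
            off_b = int(rng.integers(plen - mlen + 1))
            motif = sa[off_a:off_a + mlen]
            sb = sb[:off_b] + motif + sb[off_b + mlen:]
        planted.append(plant)
        regions[row.gene_a] = sa
        regions[row.gene_b] = sb
    for gene in _background_ids(config):
        regions[gene] = random_region()
    table["motif_planted"] = planted
    table["motif_length"] = np.where(planted, mlen, 0)
    return regions, table


# ---------------------------------------------------------------------------
# whole dataset

def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate every input the pipeline reads, plus the ground-truth table."""
    config = config or SimulationConfig()
    datasets, targets = generate_mark_datasets(config)
    expression, expr_table = generate_expression(config)
    cds, proteins = _generate_coding(config, _pair_table(config))
    upstream, up_table = generate_upstream_pairs(config)
    rng = stage_rng(config.master_seed, "mask")
    all_genes = sorted(expression.gene_ids)
    n_measurable = int(round(config.measurable_fraction * len(all_genes)))
    measurable = set(rng.choice(all_genes, size=n_measurable, replace=False))
    truth = expr_table.merge(
        up_table[["pair_id", "motif_planted", "motif_length"]], on="pair_id")
    truth["dn_target"] = [config.dn_target[c] for c in truth["true_class"]]
    truth["ds_target"] = [config.ds_target[c] for c in truth["true_class"]]
    pairs = list(zip(truth["gene_a"], truth["gene_b"]))
    return SyntheticDataset(
        config=config, mark_datasets=datasets, true_targets=targets,
        pairs=pairs, expression=expression, cds=cds, proteins=proteins,
        upstream=upstream, measurable_genes=measurable, truth=truth,
    )
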