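"""End-to-end orchestration: classify, coding divergence, expression, upstream, report.

The pipeline composes the analysis modules over files in the interchange
formats of :mod:`markdiv.io`, writes one TSV/JSON output set per stage into
the output directory, and assembles a machine-readable ``report.json`` plus
a human-readable ``report.md``.  Every stage derives its RNG from the
master seed and a stage label, so a rerun with the same inputs and seed is
value-identical, and each stage is independently reproducible.

Exclusions (pairs missing from an input, undefined correlations, saturated
or high-dS estimates) are counted per stage and reconcile against the input
pair count in the report.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as mdio
from ._seeds import stage_seed
from .coding_divergence import divergence_for_pairs, filter_estimates
from .expression_divergence import (apply_measurability_mask,
                                    class_distribution_summary, fisher_transform,
                                    joint_levels_and_quintiles,
                                    level_correlation_regression,
                                    pair_correlations, random_pair_null)
from .mark_classes import (MARK_CLASSES, MarkDataset, ParalogPair, class_counts,
                           classify_pairs, integrate_marks, subset_by_function,
                           target_set)
from .upstream_divergence import (conserved_fractions, dsm_score,
                                  hypergeometric_enrichment, percentile_cutoff,
                                  proportion_test, random_pair_null_dsm)

__all__ = ["RunConfig", "ValidationError", "run_pipeline"]

log = logging.getLogger("markdiv")


class ValidationError(ValueError):
    """Invalid run configuration; the CLI maps this to exit code 2."""


@dataclass
class RunConfig:
    """Inputs, parameters and seed of one pipeline run.

    Parameter defaults are the calibrated analysis values: 2-of-3 mark
    support, dS cutoff 5.0, 10,000 null draws, 5th-percentile conservation
    cutoff, 18-bp minimum match, 500-bp promoters, five level bins.
    """

    pairs: str
    mark_lists: Sequence[str]
    cds_fasta: str
    protein_fasta: str
    expression: str
    upstream: str
    outdir: str
    function_genes: str | None = None
    reference_conserved: str | None = None
    measurable_genes: str | None = None
    exclude_id_substring: str | None = None
    min_support: int = 2
    ks_max: float = 5.0
    n_null_draws: int = 10_000
    percentile: float = 5.0
    min_match_length: int = 18
    promoter_length: int = 500
    n_quantiles: int = 5
    master_seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def validate(self) -> None:
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if self.min_match_length < 1:
            raise ValidationError("min_match_length must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValidationError("percentile must be in (0, 100)")
        if self.n_null_draws < 1:
            raise ValidationError("n_null_draws must be >= 1")
        if self.ks_max <= 0:
            raise ValidationError("ks_max must be positive")
        if self.promoter_length < self.min_match_length:
            raise ValidationError("promoter_length below min_match_length")
        if self.n_quantiles < 2:
            raise ValidationError("n_quantiles must be >= 2")
        required = [self.pairs, self.cds_fasta, self.protein_fasta,
                    self.expression, self.upstream, *self.mark_lists]
        for opt in (self.function_genes, self.reference_conserved,
                    self.measurable_genes):
            if opt is not None:
                required.append(opt)
        for path in required:
            if not Path(path).exists():
                raise ValidationError(f"missing input file: {path}")

    def to_dict(self) -> dict:
        return {
            "pairs": str(self.pairs), "mark_lists": [str(p) for p in self.mark_lists],
            "cds_fasta": str(self.cds_fasta), "protein_fasta": str(self.protein_fasta),
            "expression": str(self.expression), "upstream": str(self.upstream),
            "outdir": str(self.outdir), "function_genes": self.function_genes,
            "reference_conserved": self.reference_conserved,
            "measurable_genes": self.measurable_genes,
            "exclude_id_substring": self.exclude_id_substring,
            "min_support": self.min_support, "ks_max": self.ks_max,
            "n_null_draws": self.n_null_draws, "percentile": self.percentile,
            "min_match_length": self.min_match_length,
            "promoter_length": self.promoter_length,
            "n_quantiles": self.n_quantiles, "master_seed": self.master_seed,
        }


def _by_class(pairs: Sequence[ParalogPair], values: Mapping[str, float]
              ) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {c: [] for c in MARK_CLASSES}
    for p in pairs:
        v = values.get(p.pair_id)
        if v is not None:
            out[p.mark_class].append(v)
    return {c: v for c, v in out.items() if v}


def _stage_classify(config: RunConfig, outdir: Path) -> tuple[list[ParalogPair], dict]:
    datasets = [MarkDataset.from_iterable(Path(p).stem, mdio.read_gene_list(p))
                for p in config.mark_lists]
    calls = integrate_marks(datasets, min_support=config.min_support)
    targets = target_set(calls)
    raw_pairs = mdio.read_pair_list(config.pairs)
    pairs = classify_pairs(raw_pairs, targets)
    support = {c.gene_id: c.support for c in calls}
    mdio.write_classified_pairs(outdir / "classified_pairs.tsv", pairs, support)
    tally = class_counts(pairs)
    summary = {
        "n_pairs": len(pairs),
        "n_targets": len(targets),
        "classes": {c: {"count": t.count, "fraction": t.fraction}
                    for c, t in tally.items()},
    }
    return pairs, summary


def _stage_divergence(config: RunConfig, pairs: Sequence[ParalogPair],
                      outdir: Path) -> dict:
    proteins = mdio.read_fasta(config.protein_fasta)
    cds = mdio.read_fasta(config.cds_fasta)
    estimates, skipped = divergence_for_pairs(pairs, proteins, cds)
    kept, discarded = filter_estimates(estimates, ks_max=config.ks_max)
    mdio.write_divergence_table(outdir / "divergence.tsv", kept + discarded)
    dn = {e.pair_id: e.dn for e in kept}
    ds = {e.pair_id: e.ds for e in kept}
    dn_by_class = _by_class(pairs, dn)
    ds_by_class = _by_class(pairs, ds)
    summary = {
        "n_estimated": len(estimates),
        "n_kept": len(kept),
        "n_discarded": len(discarded),
        "n_skipped_missing_sequence": len(skipped),
        "discard_reasons": {},
        "dn_medians": {c: float(np.median(v)) for c, v in dn_by_class.items()},
        "ds_medians": {c: float(np.median(v)) for c, v in ds_by_class.items()},
        "dn_ks": class_distribution_summary(dn_by_class)["ks"] if len(dn_by_class) > 1 else {},
    }
    for e in discarded:
        summary["discard_reasons"][e.status] = summary["discard_reasons"].get(e.status, 0) + 1
    return summary


def _stage_expression(config: RunConfig, pairs: Sequence[ParalogPair],
                      outdir: Path) -> dict:
    matrix = mdio.read_expression_matrix(config.expression)
    analyzed = list(pairs)
    retention = None
    if config.measurable_genes:
        mask = set(mdio.read_gene_list(config.measurable_genes))
        analyzed, retention = apply_measurability_mask(analyzed, mask)
    correlations, skipped = pair_correlations(analyzed, matrix)
    defined = [c for c in correlations if c.defined]
    r_values = {c.pair_id: c.r for c in defined}
    r_by_class = _by_class(analyzed, r_values)
    summary_classes = class_distribution_summary(r_by_class)
    null = random_pair_null(matrix, n_draws=config.n_null_draws,
                            seed=stage_seed(config.master_seed, "expression_null"))
    mdio.write_null_distribution(outdir / "expression_null.tsv", null)

    # expression levels: joint sums, equal-size level bins, per-bin medians
    level_pairs = [p for p in analyzed
                   if p.gene_a in matrix and p.gene_b in matrix]
    levels = joint_levels_and_quintiles(level_pairs, matrix,
                                        n_bins=config.n_quantiles)
    level_by_id = {l.pair_id: l for l in levels}
    level_values = {l.pair_id: l.joint_level for l in levels}
    level_by_class = _by_class(analyzed, level_values)
    per_bin: dict[str, dict[str, float]] = {}
    for b in range(1, config.n_quantiles + 1):
        ids = {l.pair_id for l in levels if l.quintile == b}
        sub = {c: [r_values[p.pair_id] for p in analyzed
                   if p.mark_class == c and p.pair_id in ids and p.pair_id in r_values]
               for c in MARK_CLASSES}
        per_bin[str(b)] = {c: float(np.median(v)) for c, v in sub.items() if v}

    # level vs transformed correlation regression
    xs, ys = [], []
    for pid, r in r_values.items():
        z = fisher_transform(r)
        if pid in level_values and math.isfinite(z):
            xs.append(level_values[pid])
            ys.append(z)
    regression = None
    if len(xs) >= 3 and np.std(xs) > 0:
        fit = level_correlation_regression(xs, ys)
        regression = {"slope": float(fit.slope), "intercept": float(fit.intercept),
                      "r_value": float(fit.rvalue), "p_value": float(fit.pvalue),
                      "n_points": len(xs)}

    with open(outdir / "expression_pairs.tsv", "w") as fh:
        fh.write("pair_id\tmark_class\tr\tjoint_level\tquintile\n")
        for p in analyzed:
            r = r_values.get(p.pair_id)
            lv = level_by_id.get(p.pair_id)
            fh.write(f"{p.pair_id}\t{p.mark_class}"
                     f"\t{'' if r is None else f'{r:.6f}'}"
                     f"\t{'' if lv is None else f'{lv.joint_level:.4f}'}"
                     f"\t{'' if lv is None else lv.quintile}\n")

    summary = {
        "n_input_pairs": len(pairs),
        "n_after_mask": len(analyzed),
        "retention_pct": retention,
        "n_skipped_missing_gene": len(skipped),
        "n_undefined_r": len(correlations) - len(defined),
        "classes": summary_classes["classes"],
        "ks": summary_classes["ks"],
        "null_median": null.median,
        "null_n_draws": null.n_draws,
        "null_seed": null.seed,
        "level_medians": {c: float(np.median(v)) for c, v in level_by_class.items()},
        "level_ks": class_distribution_summary(level_by_class)["ks"] if len(level_by_class) > 1 else {},
        "per_level_bin_median_r": per_bin,
        "level_regression": regression,
    }

    if config.function_genes:
        tf = set(mdio.read_gene_list(config.function_genes))
        tf_pairs = subset_by_function(analyzed, tf, mode="both_members")
        tf_by_class = _by_class(tf_pairs, r_values)
        if tf_by_class:
            summary["function_subset"] = class_distribution_summary(tf_by_class)
    return summary


def _stage_upstream(config: RunConfig, pairs: Sequence[ParalogPair],
                    outdir: Path) -> dict:
    regions_full = mdio.read_fasta(config.upstream)
    plen = config.promoter_length
    regions = {g: s[-plen:] for g, s in regions_full.items()}
    results = []
    pair_genes = {}
    analyzed = []
    skipped = 0
    for p in pairs:
        if p.gene_a not in regions or p.gene_b not in regions:
            skipped += 1
            continue
        res = dsm_score(regions[p.gene_a], regions[p.gene_b],
                        config.min_match_length, pair_id=p.pair_id)
        results.append(res)
        pair_genes[p.pair_id] = (p.gene_a, p.gene_b)
        analyzed.append(p)
    mdio.write_motif_table(outdir / "shared_motifs.tsv", results, pair_genes)
    null = random_pair_null_dsm(regions, n_draws=config.n_null_draws,
                                seed=stage_seed(config.master_seed, "dsm_null"),
                                min_match_length=config.min_match_length)
    mdio.write_null_distribution(outdir / "dsm_null.tsv", null)
    cutoff = percentile_cutoff(null, config.percentile)
    dsm_values = {r.pair_id: r.dsm for r in results}
    dsm_by_class = _by_class(analyzed, dsm_values)
    summaries = conserved_fractions(dsm_by_class, cutoff)
    by_class = {s.mark_class: s for s in summaries}
    tests = {}
    for ca, cb in (("both", "mixed"), ("both", "none"), ("mixed", "none")):
        if ca in by_class and cb in by_class:
            chi2, p = proportion_test(by_class[ca].n_conserved, by_class[ca].n_pairs,
                                      by_class[cb].n_conserved, by_class[cb].n_pairs)
            tests[f"{ca}_vs_{cb}"] = {"chi2": chi2, "p_value": p}
    summary = {
        "n_input_pairs": len(pairs),
        "n_analyzed": len(analyzed),
        "n_skipped_missing_region": skipped,
        "cutoff": cutoff,
        "percentile": config.percentile,
        "null_seed": null.seed,
        "classes": {s.mark_class: {"n_pairs": s.n_pairs,
                                   "n_conserved": s.n_conserved,
                                   "fraction": s.fraction}
                    for s in summaries},
        "proportion_tests": tests,
    }
    if config.reference_conserved:
        ref = set(mdio.read_gene_list(config.reference_conserved))
        if config.exclude_id_substring:
            ref = {g for g in ref if config.exclude_id_substring not in g}
        universe = len(analyzed)
        ref_pairs = {p.pair_id for p in analyzed
                     if p.gene_a in ref or p.gene_b in ref}
        enrichment = {}
        for cls in MARK_CLASSES:
            members = [p for p in analyzed if p.mark_class == cls]
            hits = sum(1 for p in members if p.pair_id in ref_pairs)
            if members and ref_pairs:
                enrichment[cls] = {
                    "hits": hits, "class_size": len(members),
                    "p_value": hypergeometric_enrichment(
                        hits, len(members), len(ref_pairs), universe),
                }
        summary["reference_enrichment"] = enrichment
    return summary


def _render_report_md(report: dict) -> str:
    lines = ["# Mark-stratified paralog divergence report", ""]
    cls = report["classify"]["classes"]
    lines += ["## Pair classification", "",
              "| class | pairs | fraction |", "|---|---|---|"]
    for c in MARK_CLASSES:
        t = cls[c]
        lines.append(f"| {c} | {t['count']} | {100 * t['fraction']:.0f}% |")
    lines += ["", "## Expression divergence (Pearson r)", "",
              "| class | n | median r |", "|---|---|---|"]
    for c, row in report["expression"]["classes"].items():
        lines.append(f"| {c} | {row['n']} | {row['median']:.2f} |")
    lines.append(f"\nrandom-pair null median: "
                 f"{report['expression']['null_median']:.2f} "
                 f"({report['expression']['null_n_draws']} draws)")
    lines += ["", "## Coding divergence (kept estimates)", "",
              "| class | median dN | median dS |", "|---|---|---|"]
    dn = report["divergence"]["dn_medians"]
    ds = report["divergence"]["ds_medians"]
    for c in dn:
        lines.append(f"| {c} | {dn[c]:.3f} | {ds[c]:.3f} |")
    up = report["upstream"]
    lines += ["", "## Upstream conservation (dSM)", "",
              f"cutoff (p{up['percentile']:.0f} of null): {up['cutoff']:.4f}", "",
              "| class | n | conserved | fraction |", "|---|---|---|---|"]
    for c, row in up["classes"].items():
        lines.append(f"| {c} | {row['n_pairs']} | {row['n_conserved']} "
                     f"| {100 * row['fraction']:.0f}% |")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, *, resume: bool = False) -> dict:
    """Run all stages and return the analysis report (also written to disk).

    With ``resume=True`` a stage whose summary JSON already exists in the
    output directory is loaded instead of recomputed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))

    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    try:
        report: dict = {"master_seed": config.master_seed,
                        "config": config.to_dict()}
        pairs = None

        def run_stage(name: str, fn):
            stage_file = outdir / f"stage_{name}.json"
            if resume and stage_file.exists():
                log.info("stage %s: loaded cached summary", name)
                return json.loads(stage_file.read_text())
            t0 = time.monotonic()
            out = fn()
            stage_file.write_text(json.dumps(out, indent=2, sort_keys=True))
            log.info("stage %s: %.2fs", name, time.monotonic() - t0)
            return out

        classify_file = outdir / "classified_pairs.tsv"
        if resume and classify_file.exists() and (outdir / "stage_classify.json").exists():
            pairs = mdio.read_classified_pairs(classify_file)
            report["classify"] = json.loads((outdir / "stage_classify.json").read_text())
        else:
            pairs, summary = _stage_classify(config, outdir)
            (outdir / "stage_classify.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True))
            report["classify"] = summary

        report["divergence"] = run_stage(
            "divergence", lambda: _stage_divergence(config, pairs, outdir))
        report["expression"] = run_stage(
            "expression", lambda: _stage_expression(config, pairs, outdir))
        report["upstream"] = run_stage(
            "upstream", lambda: _stage_upstream(config, pairs, outdir))

        mdio.write_json(outdir / "report.json", report)
        (outdir / "report.md").write_text(_render_report_md(report))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
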