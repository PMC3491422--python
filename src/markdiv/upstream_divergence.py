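"""Shared-motif divergence of upstream regulatory regions.

Two 500-bp upstream regions are compared by their *shared motifs*: maximal
perfect matches of at least ``min_match_length`` nucleotides (default 18)
on the forward strand.  The shared-motif divergence score is

    dSM = 1 - (covered_a + covered_b) / (len_a + len_b)

where ``covered_x`` is the number of positions of sequence *x* lying inside
any shared motif.  dSM is 0 for identical sequences and 1 when no match of
the minimum length exists.  A conservation cutoff is calibrated as the 5th
percentile (nearest rank) of a seeded random-pair null; per-class conserved
fractions are compared with a Yates-corrected two-proportion chi-square
test, and overlap with external conserved-region gene sets with an
upper-tail hypergeometric test.

``N`` bases never match.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .expression_divergence import NullDistribution

__all__ = [
    "SharedMotif",
    "DSMResult",
    "ConservationSummary",
    "find_shared_motifs",
    "dsm_score",
    "random_pair_null_dsm",
    "percentile_cutoff",
    "calibrate_parameters",
    "conserved_fractions",
    "proportion_test",
    "hypergeometric_enrichment",
]


@dataclass(frozen=True)
class SharedMotif:
    """A maximal perfect match between two sequences (0-based half-open)."""

    start_a: int
    start_b: int
    length: int

    @property
    def end_a(self) -> int:
        return self.start_a + self.length

    @property
    def end_b(self) -> int:
        return self.start_b + self.length


@dataclass(frozen=True)
class DSMResult:
    pair_id: str
    dsm: float
    covered_a: int
    covered_b: int
    motifs: tuple[SharedMotif, ...]


@dataclass(frozen=True)
class ConservationSummary:
    mark_class: str
    n_pairs: int
    n_conserved: int

    @property
    def fraction(self) -> float:
        return self.n_conserved / self.n_pairs if self.n_pairs else 0.0


def _match(x: str, y: str) -> bool:
    return x == y and x != "N"


def find_shared_motifs(seq_a: str, seq_b: str, min_match_length: int = 18
                       ) -> list[SharedMotif]:
    """All maximal exact matches of length >= ``min_match_length``.

    Forward strand only; positions holding ``N`` never match.  Seeded by a
    k-mer index of ``seq_b`` and extended along diagonals, which finds every
    maximal match (any match of length >= l contains an l-mer seed).
    Output sorted by (start_a, start_b).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if min_match_length < 1:
        raise ValueError("min_match_length must be >= 1")
    a, b = seq_a.upper(), seq_b.upper()
    la, lb = len(a), len(b)
    l = min_match_length
    if la < l or lb < l:
        return []
    index: dict[str, list[int]] = {}
    for j in range(lb - l + 1):
        kmer = b[j:j + l]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    diagonals: set[int] = set()
    for i in range(la - l + 1):
        kmer = a[i:i + l]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            diagonals.add(j - i)
    motifs: list[SharedMotif] = []
    for d in diagonals:
        i = max(0, -d)
        j = i + d
        run = 0
        while i <= la and j <= lb:
            if i < la and j < lb and _match(a[i], b[j]):
                run += 1
            else:
                if run >= l:
                    motifs.append(SharedMotif(start_a=i - run, start_b=j - run,
                                              length=run))
                run = 0
            i += 1
            j += 1
    motifs.sort(key=lambda m: (m.start_a, m.start_b))
    return motifs


def _coverage(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    covered = 0
    cur_start = cur_end = None
    for s, e in ivs:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def dsm_score(seq_a: str, seq_b: str, min_match_length: int = 18, *,
              pair_id: str = "") -> DSMResult:
    """Shared-motif divergence of two sequences (symmetric, in [0, 1])."""
    motifs = find_shared_motifs(seq_a, seq_b, min_match_length)
    covered_a = _coverage((m.start_a, m.end_a) for m in motifs)
    covered_b = _coverage((m.start_b, m.end_b) for m in motifs)
    dsm = 1.0 - (covered_a + covered_b) / (len(seq_a) + len(seq_b))
    return DSMResult(pair_id=pair_id, dsm=dsm, covered_a=covered_a,
                     covered_b=covered_b, motifs=tuple(motifs))


# -- fast path for nulls: integer k-mer fingerprints ------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_set(seq: str, l: int) -> frozenset[int]:
    """Integer-encoded l-mers of a sequence (k-mers containing N excluded)."""
    out = set()
    for i in range(len(seq) - l + 1):
        kmer = seq[i:i + l]
        code = 0
        ok = True
        for ch in kmer:
            v = _BASE_CODE.get(ch)
            if v is None:
                ok = False
                break
            code = (code << 2) | v
        if ok:
            out.add(code)
    return frozenset(out)


def random_pair_null_dsm(regions: Mapping[str, str], n_draws: int = 10_000,
                         seed: int = 0, min_match_length: int = 18
                         ) -> NullDistribution:
    """dSM null over randomly combined distinct-gene region pairs (seeded).

    Pairs without any shared l-mer (the overwhelming majority for unrelated
    promoters) short-circuit to dSM = 1 via cached k-mer fingerprints.
    """
    genes = sorted(regions)
    if len(genes) < 2:
        raise ValueError("need at least 2 upstream regions")
    rng = np.random.default_rng(seed)
    kmer_cache: dict[str, frozenset[int]] = {}

    def kmers(g: str) -> frozenset[int]:
        ks = kmer_cache.get(g)
        if ks is None:
            ks = _kmer_set(regions[g].upper(), min_match_length)
            kmer_cache[g] = ks
        return ks

    values = np.empty(n_draws, dtype=float)
    n_genes = len(genes)
    for t in range(n_draws):
        i = int(rng.integers(n_genes))
        j = int(rng.integers(n_genes))
        while j == i:
            j = int(rng.integers(n_genes))
        ga, gb = genes[i], genes[j]
        if kmers(ga).isdisjoint(kmers(gb)):
            values[t] = 1.0
        else:
            values[t] = dsm_score(regions[ga], regions[gb], min_match_length).dsm
    return NullDistribution(statistic="dsm", values=values,
                            n_draws=n_draws, seed=seed)


def percentile_cutoff(null: NullDistribution, percentile: float = 5.0) -> float:
    """Nearest-rank empirical percentile of the null (lower = more similar)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    values = np.sort(np.asarray(null.values, dtype=float))
    if values.size == 0:
        raise ValueError("empty null distribution")
    k = int(np.ceil(percentile / 100.0 * values.size))
    return float(values[max(k, 1) - 1])


def calibrate_parameters(pairs: Sequence, regions: Mapping[str, str],
                         l_values: Sequence[int],
                         promoter_lengths: Sequence[int],
                         *, n_random: int = 1000, seed: int = 0):
    """Signal/noise table over candidate match lengths and promoter lengths.

    For each combination, counts pairs with at least one shared motif among
    the true paralog pairs (signal) and among random gene pairs (the
    false-positive proxy).  Promoters are truncated to their proximal
    (3'-most) ``promoter_length`` bases.  Returns a pandas DataFrame sorted
    by descending signal/noise ratio.
    """
    import pandas as pd

    if not l_values or not promoter_lengths:
        raise ValueError("need at least one candidate per calibration axis")
    rows = []
    genes = sorted(regions)
    rng = np.random.default_rng(seed)
    random_pairs = []
    for _ in range(n_random):
        i = int(rng.integers(len(genes)))
        j = int(rng.integers(len(genes)))
        while j == i:
            j = int(rng.integers(len(genes)))
        random_pairs.append((genes[i], genes[j]))
    for plen in promoter_lengths:
        trimmed = {g: s[-plen:] for g, s in regions.items()}
        for l in l_values:
            def hits(pair_list) -> int:
                n = 0
                for ga, gb in pair_list:
                    if ga not in trimmed or gb not in trimmed:
                        continue
                    if find_shared_motifs(trimmed[ga], trimmed[gb], l):
                        n += 1
                return n

            signal = hits([(p.gene_a, p.gene_b) for p in pairs])
            noise = hits(random_pairs)
            signal_rate = signal / max(len(pairs), 1)
            noise_rate = noise / max(n_random, 1)
            ratio = signal_rate / noise_rate if noise_rate > 0 else float("inf")
            rows.append({"min_match_length": l, "promoter_length": plen,
                         "signal_pairs": signal, "noise_pairs": noise,
                         "signal_rate": signal_rate, "noise_rate": noise_rate,
                         "ratio": ratio})
    table = pd.DataFrame(rows)
    return table.sort_values("ratio", ascending=False, kind="stable").reset_index(drop=True)


def conserved_fractions(dsm_by_class: Mapping[str, Sequence[float]],
                        cutoff: float) -> list[ConservationSummary]:
    """Per-class counts and fractions of pairs with dSM below the cutoff."""
    out = []
    for cls, values in dsm_by_class.items():
        arr = np.asarray(values, dtype=float)
        out.append(ConservationSummary(mark_class=cls, n_pairs=int(arr.size),
                                       n_conserved=int((arr < cutoff).sum())))
    return out


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sample equality-of-proportions test with Yates continuity correction.

    Pooled 2x2 chi-square with one degree of freedom, two-sided; returns
    (statistic, p_value).  Degenerate tables (pooled proportion 0 or 1, or
    equal observed proportions) give statistic 0 and p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("trial counts must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes outside [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or x1 * n2 == x2 * n1:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def hypergeometric_enrichment(hits_in_class: int, class_size: int,
                              hits_total: int, universe: int) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= hits_in_class).

    ``universe`` genes (or pairs) of which ``hits_total`` carry the feature;
    a class of ``class_size`` drawn without replacement contains
    ``hits_in_class`` of them.
    """
    if not (0 <= hits_in_class <= min(class_size, hits_total)):
        raise ValueError("inconsistent hit counts")
    if max(class_size, hits_total) > universe:
        raise ValueError("counts exceed universe")
    return float(stats.hypergeom.sf(hits_in_class - 1, universe, hits_total,
                                    class_size))
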