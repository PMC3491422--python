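"""Pairwise coding-sequence divergence: dN and dS by Nei-Gojobori counting.

The route mirrors classical practice for paralog pairs:

1. global protein alignment with affine gap penalties (BLOSUM62, gap open
   10.0, gap extend 0.5, terminal gaps free);
2. protein-guided back-translation, so the nucleotide alignment gaps in
   whole codons;
3. Nei-Gojobori (1986) counting of synonymous (S) and nonsynonymous (N)
   sites and differences, with Jukes-Cantor multiple-hit correction
   ``d = -(3/4) ln(1 - (4/3) p)``;
4. a reliability filter that discards saturated estimates and pairs with
   dS above a cutoff (default 5.0).

Site counting follows the standard convention: each codon position
contributes exactly one site, split by the fraction of possible
single-nucleotide changes that are synonymous, with changes creating stop
codons excluded from the tally.  Codons that contain gaps, ambiguity codes
or stops in either sequence are dropped pairwise, so N + S always equals
three times the number of compared codons.  Multi-difference codons are
averaged over all orderings of single steps, excluding orderings that pass
through a stop codon (falling back to all orderings if every path is
blocked, which cannot happen in the standard code for sense endpoints at
one or two differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "ProteinAlignment",
    "CodonAlignment",
    "DivergenceEstimate",
    "align_proteins",
    "backtranslate",
    "nei_gojobori",
    "jukes_cantor",
    "filter_estimates",
    "divergence_for_pairs",
]

_BASES = "ACGT"

# status codes for DivergenceEstimate
STATUS_OK = "ok"
STATUS_HIGH_KS = "discarded_high_ks"
STATUS_INVALID_KS = "discarded_invalid_ks"
STATUS_SATURATED = "undefined_saturation"


class SequenceInputError(ValueError):
    """Bad sequence input (empty, unknown residue, length mismatch)."""


@dataclass(frozen=True)
class ProteinAlignment:
    """A global pairwise protein alignment (gapped rows plus score)."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise SequenceInputError("aligned rows differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise SequenceInputError("column gapped in both rows")


@dataclass(frozen=True)
class CodonAlignment:
    """A codon-aware nucleotide alignment; gaps come in whole codons."""

    pair_id: str
    aligned_cds_a: str
    aligned_cds_b: str

    def __post_init__(self) -> None:
        if len(self.aligned_cds_a) != len(self.aligned_cds_b):
            raise SequenceInputError("aligned CDS rows differ in length")
        if len(self.aligned_cds_a) % 3:
            raise SequenceInputError("aligned CDS length not divisible by 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        a, b = self.aligned_cds_a, self.aligned_cds_b
        return [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]


@dataclass
class DivergenceEstimate:
    """Nei-Gojobori site/difference counts and corrected distances for one pair."""

    pair_id: str
    n_sites: float          # nonsynonymous sites N
    s_sites: float          # synonymous sites S
    n_diffs: float          # nonsynonymous differences Nd
    s_diffs: float          # synonymous differences Sd
    p_n: float
    p_s: float
    dn: float | None        # None when saturated (p >= 3/4)
    ds: float | None
    n_codons: int           # comparable (gap-free, unambiguous, non-stop) codons
    status: str = STATUS_OK


# ---------------------------------------------------------------------------
# protein alignment

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYBZX")


def _make_aligner(matrix: str | object, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    # terminal gaps are free (needle-style semi-global behaviour)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align_proteins(seq_a: str, seq_b: str, *, matrix: str = "BLOSUM62",
                   gap_open: float = 10.0, gap_extend: float = 0.5) -> ProteinAlignment:
    """Optimal global affine-gap protein alignment.

    Scoring contract: substitution scores from ``matrix`` (default BLOSUM62);
    an internal gap of length L costs ``gap_open + (L - 1) * gap_extend``;
    terminal gaps are free.  The returned score is the dynamic-programming
    optimum; the reported alignment is the aligner's first (deterministic)
    traceback among co-optimal ones.
    """
    if not seq_a or not seq_b:
        raise SequenceInputError("empty protein sequence")
    if gap_open <= 0 or gap_extend <= 0:
        raise SequenceInputError("gap penalties must be positive")
    for name, seq in (("a", seq_a), ("b", seq_b)):
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise SequenceInputError(f"unknown residues in sequence {name}: {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    return ProteinAlignment(aligned_a=str(best[0]), aligned_b=str(best[1]),
                            score=float(alignments.score))


# ---------------------------------------------------------------------------
# back-translation

def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    """Translate one codon; ambiguous or gapped codons give 'X', stops '*'."""
    if any(b not in _BASES for b in codon):
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def _strip_terminal_stop(cds: str, protein: str, table: CodonTable.CodonTable) -> str:
    if len(cds) == 3 * (len(protein) + 1) and cds[-3:].upper() in table.stop_codons:
        return cds[:-3]
    return cds


def backtranslate(pa: ProteinAlignment, cds_a: str, cds_b: str, *,
                  pair_id: str = "", table_id: int = 1) -> CodonAlignment:
    """Expand a protein alignment into a codon alignment of the two CDS.

    Each aligned residue maps to its source codon; gap columns map to
    ``---``.  A terminal stop codon on either CDS is trimmed.  The codons
    must translate to the aligned residues (X accepts any codon).
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    rows = []
    for label, aligned, cds in (("a", pa.aligned_a, cds_a), ("b", pa.aligned_b, cds_b)):
        cds = cds.upper().replace("U", "T")
        protein = aligned.replace("-", "")
        cds = _strip_terminal_stop(cds, protein, table)
        if len(cds) != 3 * len(protein):
            raise SequenceInputError(
                f"{pair_id or 'pair'}: CDS {label} length {len(cds)} does not match "
                f"{len(protein)} aligned residues"
            )
        out, k = [], 0
        for residue in aligned:
            if residue == "-":
                out.append("---")
                continue
            codon = cds[3 * k:3 * k + 3]
            k += 1
            translated = _translate_codon(codon, table)
            if residue != translated and residue != "X" and translated != "X":
                raise SequenceInputError(
                    f"{pair_id or 'pair'}: codon {codon} (#{k}) of CDS {label} "
                    f"translates to {translated}, aligned residue is {residue}"
                )
            out.append(codon)
        rows.append("".join(out))
    return CodonAlignment(pair_id=pair_id, aligned_cds_a=rows[0], aligned_cds_b=rows[1])


# ---------------------------------------------------------------------------
# Nei-Gojobori counting

@lru_cache(maxsize=None)
def _codon_tools(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    aa = dict(table.forward_table)
    return table, stops, aa


@lru_cache(maxsize=None)
def _syn_sites(codon: str, table_id: int) -> float:
    """Synonymous site count of one sense codon (0..3).

    Each position contributes its fraction of synonymous changes among the
    possible single-nucleotide changes not creating a stop codon.
    """
    _, stops, aa = _codon_tools(table_id)
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in stops:
                continue
            non_stop += 1
            if aa[alt] == aa[codon]:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str, table_id: int) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over mutational pathways.

    Orderings of the single-nucleotide steps are weighted equally; orderings
    whose intermediate codons are stops are excluded.  If every ordering is
    blocked, all orderings are used (degenerate safeguard).
    """
    _, stops, aa = _codon_tools(table_id)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            # stop codons form their own class, so steps touching one are
            # nonsynonymous; such orderings are excluded unless all are
            if aa.get(nxt, "*") == aa.get(cur, "*"):
                syn += 1
            else:
                nonsyn += 1
            if nxt in stops:
                hit_stop = True
            cur = nxt
        (blocked if hit_stop else valid).append((syn, nonsyn))
    paths = valid or blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor correction; ``None`` when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion below 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _comparable(codon_a: str, codon_b: str, stops: frozenset[str]) -> bool:
    for codon in (codon_a, codon_b):
        if "-" in codon:
            return False
        if any(b not in _BASES for b in codon):
            return False
        if codon in stops:
            return False
    return True


def nei_gojobori(ca: CodonAlignment, *, table_id: int = 1) -> DivergenceEstimate:
    """Nei-Gojobori (1986) dN/dS for one codon alignment.

    Codons with gaps, ambiguity codes, or stops in either row are excluded
    pairwise.  Raises when no codon pair is comparable.  Saturation
    (p >= 3/4) flags the affected distance as undefined rather than raising.
    """
    _, stops, _ = _codon_tools(table_id)
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for codon_a, codon_b in ca.codon_pairs():
        if not _comparable(codon_a, codon_b, stops):
            continue
        n_codons += 1
        s_a = _syn_sites(codon_a, table_id)
        s_b = _syn_sites(codon_b, table_id)
        S += 0.5 * (s_a + s_b)
        N += 3.0 - 0.5 * (s_a + s_b)
        sd, nd = _pathway_diffs(codon_a, codon_b, table_id)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise SequenceInputError(f"{ca.pair_id or 'pair'}: no comparable codons")
    p_s = Sd / S if S > 0 else 0.0
    p_n = Nd / N if N > 0 else 0.0
    ds = jukes_cantor(p_s)
    dn = jukes_cantor(p_n)
    status = STATUS_OK if (ds is not None and dn is not None) else STATUS_SATURATED
    return DivergenceEstimate(
        pair_id=ca.pair_id, n_sites=N, s_sites=S, n_diffs=Nd, s_diffs=Sd,
        p_n=p_n, p_s=p_s, dn=dn, ds=ds, n_codons=n_codons, status=status,
    )


def filter_estimates(estimates: Iterable[DivergenceEstimate], ks_max: float = 5.0
                     ) -> tuple[list[DivergenceEstimate], list[DivergenceEstimate]]:
    """Partition estimates into (kept, discarded) by the dS reliability filter.

    Estimates with undefined dS (saturation — the analogue of the invalid
    estimates real aligner/codeml pipelines produce) are discarded with
    reason ``discarded_invalid_ks``; dS above ``ks_max`` with
    ``discarded_high_ks``.  Reason codes are written onto the estimates.
    """
    kept: list[DivergenceEstimate] = []
    discarded: list[DivergenceEstimate] = []
    for est in estimates:
        if est.ds is None or est.dn is None:
            est.status = STATUS_INVALID_KS
            discarded.append(est)
        elif est.ds > ks_max:
            est.status = STATUS_HIGH_KS
            discarded.append(est)
        else:
            est.status = STATUS_OK
            kept.append(est)
    return kept, discarded


# ---------------------------------------------------------------------------
# convenience driver

def divergence_for_pairs(pairs: Sequence, proteins: Mapping[str, str],
                         cds: Mapping[str, str], *, matrix: str = "BLOSUM62",
                         gap_open: float = 10.0, gap_extend: float = 0.5,
                         table_id: int = 1) -> tuple[list[DivergenceEstimate], list[str]]:
    """Estimate dN/dS for many pairs; returns (estimates, skipped pair ids).

    Pairs with a gene missing from either FASTA mapping are skipped and
    reported, mirroring annotation-coverage loss in real data.
    """
    estimates: list[DivergenceEstimate] = []
    skipped: list[str] = []
    for pair in pairs:
        a, b = pair.gene_a, pair.gene_b
        if a not in proteins or b not in proteins or a not in cds or b not in cds:
            skipped.append(pair.pair_id)
            continue
        pa = align_proteins(proteins[a], proteins[b], matrix=matrix,
                            gap_open=gap_open, gap_extend=gap_extend)
        calign = backtranslate(pa, cds[a], cds[b], pair_id=pair.pair_id,
                               table_id=table_id)
        estimates.append(nei_gojobori(calign, table_id=table_id))
    return estimates, skipped
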