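"""Integration of chromatin-mark target-gene datasets and paralog-pair classification.

Genome-wide surveys of a histone mark (here, H3K27me3 in *Arabidopsis
thaliana* seedlings) each report a list of target genes.  Because the
individual surveys differ in method and material, a combined target set is
built by *minimum support*: a gene counts as a target when it appears in at
least ``min_support`` of the input datasets (2 of 3 by default).  Treating
mark presence as a binary gene property, every paralog pair then falls into
exactly one of three classes:

``both``
    both paralogs are mark targets,
``mixed``
    exactly one paralog is a target,
``none``
    neither is.

Gene identifiers are opaque, case-sensitive strings (AGI codes are stable);
an optional normalization helper can uppercase them and strip ``.1``-style
version suffixes for sloppier inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MARK_CLASSES",
    "MarkDataset",
    "MarkCall",
    "ParalogPair",
    "ClassTally",
    "normalize_gene_id",
    "integrate_marks",
    "target_set",
    "classify_pair",
    "classify_pairs",
    "class_counts",
    "subset_by_function",
]

#: The three mark classes, in the conventional reporting order.
MARK_CLASSES = ("both", "mixed", "none")


class ConfigurationError(ValueError):
    """Invalid analysis configuration (e.g. empty dataset list)."""


class InvalidPairError(ValueError):
    """A paralog pair violating its invariants (e.g. gene paired with itself)."""


@dataclass(frozen=True)
class MarkDataset:
    """One genome-wide survey of mark target genes."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        # empty datasets are permitted: a survey can contribute no calls
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    @classmethod
    def from_iterable(cls, name: str, gene_ids: Iterable[str]) -> "MarkDataset":
        ids = list(gene_ids)
        if len(ids) != len(set(ids)):
            dupes = sorted(g for g, c in Counter(ids).items() if c > 1)
            raise ConfigurationError(
                f"mark dataset {name!r} contains duplicate gene ids: {dupes[:5]}"
            )
        return cls(name=name, gene_ids=frozenset(ids))


@dataclass(frozen=True)
class MarkCall:
    """Combined call for one gene: in how many datasets it appears."""

    gene_id: str
    support: int
    is_target: bool


@dataclass(frozen=True)
class ParalogPair:
    """An unordered pair of paralogous genes, optionally class-labelled."""

    gene_a: str
    gene_b: str
    mark_class: str | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise InvalidPairError(f"gene paired with itself: {self.gene_a!r}")
        if self.mark_class is not None and self.mark_class not in MARK_CLASSES:
            raise InvalidPairError(f"unknown mark class {self.mark_class!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Order-independent pair key (sorted id tuple)."""
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]

    @property
    def pair_id(self) -> str:
        return "|".join(self.key)


@dataclass(frozen=True)
class ClassTally:
    count: int
    fraction: float


def normalize_gene_id(gene_id: str, *, uppercase: bool = False,
                      strip_version: bool = False) -> str:
    """Optionally uppercase and strip a trailing ``.N`` version suffix.

    Off by default throughout the package: identifiers are treated as opaque.
    """
    out = gene_id.strip()
    if strip_version:
        head, sep, tail = out.rpartition(".")
        if sep and tail.isdigit():
            out = head
    if uppercase:
        out = out.upper()
    return out


def integrate_marks(datasets: Sequence[MarkDataset], min_support: int = 2) -> list[MarkCall]:
    """Combine mark datasets into per-gene calls by minimum support.

    A gene is a target iff it occurs in at least ``min_support`` datasets.
    Returns one :class:`MarkCall` per gene seen in any dataset, sorted by id.
    """
    if not datasets:
        raise ConfigurationError("no mark datasets given")
    if not 1 <= min_support <= len(datasets):
        raise ConfigurationError(
            f"min_support={min_support} outside [1, {len(datasets)}]"
        )
    support: Counter[str] = Counter()
    for ds in datasets:
        support.update(ds.gene_ids)
    return [
        MarkCall(gene_id=g, support=s, is_target=s >= min_support)
        for g, s in sorted(support.items())
    ]


def target_set(calls: Iterable[MarkCall]) -> set[str]:
    """The set of gene ids called as targets."""
    return {c.gene_id for c in calls if c.is_target}


def classify_pair(pair: tuple[str, str], targets: set[str]) -> str:
    """Class of one pair given the combined target set.

    Genes absent from every dataset are non-targets (support 0); the
    classification is symmetric in the two genes.
    """
    a, b = pair
    if a == b:
        raise InvalidPairError(f"gene paired with itself: {a!r}")
    n = (a in targets) + (b in targets)
    return ("none", "mixed", "both")[n]


def classify_pairs(pairs: Iterable[tuple[str, str]], targets: set[str]) -> list[ParalogPair]:
    """Classify many pairs, preserving input order."""
    return [
        ParalogPair(gene_a=a, gene_b=b, mark_class=classify_pair((a, b), targets))
        for a, b in pairs
    ]


def class_counts(pairs: Sequence[ParalogPair]) -> dict[str, ClassTally]:
    """Counts and fractions per mark class (fractions of all input pairs)."""
    total = len(pairs)
    counts = Counter(p.mark_class for p in pairs)
    if None in counts:
        raise InvalidPairError("class_counts requires classified pairs")
    return {
        cls: ClassTally(count=counts.get(cls, 0),
                        fraction=(counts.get(cls, 0) / total) if total else 0.0)
        for cls in MARK_CLASSES
    }


def subset_by_function(pairs: Iterable[ParalogPair], function_genes: set[str],
                       mode: str = "both_members") -> list[ParalogPair]:
    """Restrict pairs to a functional gene set (e.g. GO-annotated TFs).

    ``mode='both_members'`` keeps pairs whose two genes are both in the set;
    ``mode='any_member'`` keeps pairs with at least one member in the set.
    Class labels are unchanged.
    """
    if mode not in ("both_members", "any_member"):
        raise ConfigurationError(f"unknown subset mode {mode!r}")
    if mode == "both_members":
        return [p for p in pairs
                if p.gene_a in function_genes and p.gene_b in function_genes]
    return [p for p in pairs
            if p.gene_a in function_genes or p.gene_b in function_genes]
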