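"""Name dictionaries, abstract scanning, and co-occurrence tallies.

The unit of evidence throughout the package is a single abstract: a gene
*i* and a GO term *j* "co-occur" when at least one surface name of each
appears in the same abstract.  A corpus is summarised by four counts --
the number of abstracts mentioning gene *i* (``n_i``), GO term *j*
(``n_j``), both together (``n_ij``), and at least one gene or GO term
overall (``n_total``).  These are the sufficient statistics for every
association measure downstream (:mod:`golink.association`).

Dictionaries map a stable term identifier (an HGNC symbol or a
``GO:NNNNNNN`` accession) to a set of surface names.  Because everyday
English words double as gene symbols and GO term names ("learning",
"growth", short symbols like "IL"), dictionaries are filtered against a
stop-word list and a minimum name length before any scanning happens.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TermDictionary",
    "AbstractRecord",
    "CooccurrenceCounts",
    "normalize_name",
    "tokenize",
    "default_stopwords",
    "filter_dictionary",
    "scan_abstract",
    "scan_corpus",
    "tally_counts",
]

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


def normalize_name(name: str) -> str:
    """Collapse internal whitespace and strip the ends of a surface name."""
    return " ".join(name.split())


def tokenize(text: str) -> list[str]:
    """Lower-case *text* and split it on runs of non-alphanumeric characters.

    This is the matching normalization used by :func:`scan_abstract`: a
    surface name matches iff its own token sequence occurs as consecutive
    tokens of the abstract.  The rule is deterministic and case-insensitive;
    hyphens, slashes and punctuation all act as token boundaries.
    """
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def default_stopwords() -> frozenset[str]:
    """The bundled common-English stop-word list (lower-cased)."""
    text = resources.files("golink.data").joinpath("stopwords.txt").read_text()
    words = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@dataclass
class TermDictionary:
    """A mapping from term identifiers to their surface names.

    Parameters
    ----------
    kind
        Either ``"gene"`` or ``"go"``.
    entries
        Mapping ``term_id -> iterable of surface names``.  Names are
        whitespace-normalized on construction; empty names are rejected.
        A term may own an empty name set (it then never matches anything
        during scanning) -- this keeps identifier spaces stable across
        filtering.
    """

    kind: str
    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "go"):
            raise ValueError(f"dictionary kind must be 'gene' or 'go', got {self.kind!r}")
        cleaned: dict[str, frozenset[str]] = {}
        for term_id, names in self.entries.items():
            norm = frozenset(normalize_name(n) for n in names)
            if "" in norm:
                raise ValueError(f"empty surface name for term {term_id!r}")
            cleaned[term_id] = norm
        self.entries = cleaned

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __contains__(self, term_id: object) -> bool:
        return term_id in self.entries

    def names(self, term_id: str) -> frozenset[str]:
        return self.entries[term_id]


@dataclass(frozen=True)
class AbstractRecord:
    """The gene and GO mention sets extracted from one abstract."""

    abstract_id: str
    genes: frozenset[str] = frozenset()
    gos: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "gos", frozenset(self.gos))

    @property
    def is_empty(self) -> bool:
        return not self.genes and not self.gos


def filter_dictionary(
    dictionary: TermDictionary,
    stopwords: Iterable[str] | None = None,
    min_len: int = 3,
) -> TermDictionary:
    """Drop surface names that are too short or are common English words.

    Scanning for one-letter or two-letter symbols, or for names that double
    as everyday words ("learning" is both English and GO:0007612), floods
    the counts with false positives; such names are removed before any
    matching.  Term identifiers are always preserved: a term whose names are
    all filtered away survives with an empty name set (and is logged), so
    that the identifier space is stable regardless of the stop-word list.

    Parameters
    ----------
    dictionary
        The dictionary to filter; it is not modified.
    stopwords
        Words to remove, compared case-insensitively against whole surface
        names.  Defaults to the bundled common-English list.
    min_len
        Minimum surviving name length in characters (default 3).
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if stopwords is None:
        stop = default_stopwords()
    else:
        stop = {s.lower() for s in stopwords}
    filtered: dict[str, frozenset[str]] = {}
    emptied = []
    for term_id, names in dictionary.entries.items():
        kept = frozenset(n for n in names if len(n) >= min_len and n.lower() not in stop)
        if names and not kept:
            emptied.append(term_id)
        filtered[term_id] = kept
    if emptied:
        logger.warning(
            "%d %s term(s) lost every surface name during filtering and will "
            "never match: %s",
            len(emptied),
            dictionary.kind,
            ", ".join(sorted(emptied)[:10]) + ("..." if len(emptied) > 10 else ""),
        )
    return TermDictionary(dictionary.kind, filtered)


class _TokenMatcher:
    """Index of a dictionary's surface names as token sequences."""

    def __init__(self, dictionary: TermDictionary):
        # first token -> [(token tuple, term_id), ...]
        self._index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for term_id, names in dictionary.entries.items():
            for name in names:
                toks = tuple(tokenize(name))
                if toks:
                    self._index.setdefault(toks[0], []).append((toks, term_id))

    def match(self, tokens: Sequence[str]) -> frozenset[str]:
        hits: set[str] = set()
        for i, tok in enumerate(tokens):
            for seq, term_id in self._index.get(tok, ()):
                if term_id not in hits and tuple(tokens[i : i + len(seq)]) == seq:
                    hits.add(term_id)
        return frozenset(hits)


def scan_abstract(
    text: str,
    gene_dict: TermDictionary,
    go_dict: TermDictionary,
    abstract_id: str = "",
) -> AbstractRecord:
    """Report which dictionary terms occur in *text*.

    A term is present iff one of its surface names occurs as a whole-token
    sequence under :func:`tokenize` (case-insensitive; multi-word names must
    appear as consecutive tokens).  Each term is reported at most once.
    Dictionaries are expected to be pre-filtered with
    :func:`filter_dictionary`.
    """
    tokens = tokenize(text)
    return AbstractRecord(
        abstract_id=abstract_id,
        genes=_TokenMatcher(gene_dict).match(tokens),
        gos=_TokenMatcher(go_dict).match(tokens),
    )


def scan_corpus(
    abstracts: Iterable[tuple[str, str]],
    gene_dict: TermDictionary,
    go_dict: TermDictionary,
) -> list[AbstractRecord]:
    """Scan many ``(abstract_id, text)`` pairs, building the matchers once."""
    gene_matcher = _TokenMatcher(gene_dict)
    go_matcher = _TokenMatcher(go_dict)
    records = []
    for abstract_id, text in abstracts:
        tokens = tokenize(text)
        records.append(
            AbstractRecord(
                abstract_id=abstract_id,
                genes=gene_matcher.match(tokens),
                gos=go_matcher.match(tokens),
            )
        )
    return records


@dataclass
class CooccurrenceCounts:
    """Marginal and joint abstract counts for a corpus.

    ``n_total`` counts abstracts mentioning at least one gene *or* GO term;
    abstracts with no mention at all never enter any statistic.  ``n_joint``
    stores only gene-GO pairs observed together at least once -- the absence
    of a pair means "no abstract mentions both".  ``n_gene_joint`` stores the
    analogous gene-gene co-mention counts that feed the co-occurrence-only
    baseline similarity.
    """

    n_total: int
    n_gene: dict[str, int] = field(default_factory=dict)
    n_go: dict[str, int] = field(default_factory=dict)
    n_joint: dict[tuple[str, str], int] = field(default_factory=dict)
    n_gene_joint: dict[tuple[str, str], int] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise ``ValueError`` if any count invariant is violated."""
        if self.n_total < 0:
            raise ValueError("n_total must be non-negative")
        for name, margins in (("gene", self.n_gene), ("GO", self.n_go)):
            for term, n in margins.items():
                if not (0 <= n <= self.n_total):
                    raise ValueError(
                        f"{name} margin for {term!r} is {n}, outside [0, n_total={self.n_total}]"
                    )
        for (g, t), n in self.n_joint.items():
            if n < 1:
                raise ValueError(f"stored joint count for ({g}, {t}) must be >= 1, got {n}")
            if n > min(self.n_gene.get(g, 0), self.n_go.get(t, 0)):
                raise ValueError(
                    f"joint count for ({g}, {t}) exceeds a margin: "
                    f"n_ij={n}, n_i={self.n_gene.get(g, 0)}, n_j={self.n_go.get(t, 0)}"
                )
        for (a, b), n in self.n_gene_joint.items():
            if a >= b:
                raise ValueError(f"gene pair ({a}, {b}) must be stored in sorted order")
            if n < 1 or n > min(self.n_gene.get(a, 0), self.n_gene.get(b, 0)):
                raise ValueError(f"gene-gene joint count for ({a}, {b}) is inconsistent: {n}")


def tally_counts(records: Iterable[AbstractRecord]) -> CooccurrenceCounts:
    """Count marginal and joint abstract incidences over *records*.

    Raises ``ValueError`` naming the offending identifier if two records
    share an ``abstract_id``.  Records mentioning nothing are ignored
    entirely (they do not contribute to ``n_total``).
    """
    seen: set[str] = set()
    n_total = 0
    n_gene: Counter[str] = Counter()
    n_go: Counter[str] = Counter()
    n_joint: Counter[tuple[str, str]] = Counter()
    n_gene_joint: Counter[tuple[str, str]] = Counter()
    for rec in records:
        if rec.abstract_id in seen:
            raise ValueError(f"duplicate abstract_id: {rec.abstract_id!r}")
        seen.add(rec.abstract_id)
        if rec.is_empty:
            continue
        n_total += 1
        for g in rec.genes:
            n_gene[g] += 1
        for t in rec.gos:
            n_go[t] += 1
        for g in rec.genes:
            for t in rec.gos:
                n_joint[(g, t)] += 1
        genes = sorted(rec.genes)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                n_gene_joint[(a, b)] += 1
    counts = CooccurrenceCounts(
        n_total=n_total,
        n_gene=dict(n_gene),
        n_go=dict(n_go),
        n_joint=dict(n_joint),
        n_gene_joint=dict(n_gene_joint),
    )
    counts.validate()
    return counts
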