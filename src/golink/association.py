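"""Gene-GO and gene-gene association statistics.

The strength of the association between gene *i* and GO term *j* is
measured by an upper-tail hypergeometric test on the co-occurrence counts,
with a mid-p continuity correction:

.. math::

    p_{ij} \\;=\\; P(X > n_{ij}) \\; + \\; \\tfrac12\\, P(X = n_{ij}),
    \\qquad X \\sim \\mathrm{HG}(n_{\\cdot\\cdot},\\, n_{\\cdot j},\\, n_{i\\cdot}),

where the population is the :math:`n_{\\cdot\\cdot}` abstracts mentioning at
least one gene or GO term, the :math:`n_{\\cdot j}` abstracts mentioning the
GO term are the "successes", and the :math:`n_{i\\cdot}` abstracts mentioning
the gene are the "draws".  Counting only half the mass of the observed
outcome reduces the conservatism of the discrete test.  Conditioning on the
margins automatically discounts heavily-studied genes and promiscuous GO
terms.

Two genes are then compared through their :math:`-\\log p` association
profiles.  With :math:`w_{ij} = -\\log \\max(p_{ij}, 10^{-6})` (zero when the
pair was never observed together), the gene-gene similarity is the cosine

.. math::

    \\gamma_{i,i'} \\;=\\;
    \\frac{\\sum_j w_{ij} w_{i'j}}
         {\\sqrt{\\sum_j w_{ij}^2}\\,\\sqrt{\\sum_j w_{i'j}^2}} \\in [0, 1],

taken over the GO terms associated with at least one of the two genes.  The
:math:`10^{-6}` truncation keeps a handful of astronomically small p-values
from dominating the profile; :math:`\\gamma` depends only on ratios of
weights and is therefore invariant to the base of the logarithm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, norm

__all__ = [
    "PValueMatrix",
    "WeightProfile",
    "SimilarityMatrix",
    "hypergeom_midp",
    "hypergeom_midp_many",
    "hypergeom_midp_exact",
    "build_pvalue_matrix",
    "weight_profile",
    "cosine_similarity",
    "similarity_matrix",
    "similarity_percentiles",
    "cooccurrence_similarity",
    "probit_transform",
    "select_top_go",
    "DEFAULT_FLOOR",
]

DEFAULT_FLOOR = 1e-6
_PROBIT_CLAMP = (1e-6, 1.0 - 1e-6)
_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# mid-p hypergeometric test
# ---------------------------------------------------------------------------

def _check_margins(n_ij: int, n_i: int, n_j: int, n_tot: int) -> None:
    if n_tot < 1:
        raise ValueError(f"total abstract count n_tot={n_tot} must be >= 1")
    if not 0 <= n_i <= n_tot:
        raise ValueError(f"gene margin n_i={n_i} outside [0, n_tot={n_tot}]")
    if not 0 <= n_j <= n_tot:
        raise ValueError(f"GO margin n_j={n_j} outside [0, n_tot={n_tot}]")
    if not 0 <= n_ij <= min(n_i, n_j):
        raise ValueError(
            f"joint count n_ij={n_ij} outside [0, min(n_i={n_i}, n_j={n_j})]"
        )


def hypergeom_midp_many(
    n_ij: Sequence[int] | np.ndarray,
    n_i: Sequence[int] | np.ndarray,
    n_j: Sequence[int] | np.ndarray,
    n_tot: Sequence[int] | np.ndarray | int,
) -> np.ndarray:
    """Vectorized mid-p upper-tail hypergeometric test.

    The tail :math:`P(X > k) + \\frac12 P(X = k)` is assembled in log space
    from ``scipy.stats.hypergeom.logpmf`` terms via a grouped log-sum-exp,
    which stays accurate when individual terms underflow and is exact to
    floating precision at small margins.  Results are clipped away from zero
    so the "0 < p" invariant survives even astronomically small tails.
    """
    k = np.atleast_1d(np.asarray(n_ij, dtype=np.int64))
    a = np.atleast_1d(np.asarray(n_i, dtype=np.int64))
    b = np.atleast_1d(np.asarray(n_j, dtype=np.int64))
    N = np.broadcast_to(np.atleast_1d(np.asarray(n_tot, dtype=np.int64)), k.shape)
    if not (k.shape == a.shape == b.shape):
        raise ValueError("n_ij, n_i, n_j must have identical shapes")
    if k.size == 0:
        return np.empty(0)

    kmax = np.minimum(a, b)
    lengths = kmax - k + 1  # one term per k' in [k, kmax]
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    total = int(lengths.sum())
    offsets = np.arange(total) - np.repeat(starts, lengths)
    ks = np.repeat(k, lengths) + offsets

    logp = hypergeom.logpmf(ks, np.repeat(N, lengths), np.repeat(b, lengths),
                            np.repeat(a, lengths))
    logp[starts] -= math.log(2.0)  # the k' = k term carries weight 1/2

    # grouped log-sum-exp over each pair's tail
    seg_max = np.maximum.reduceat(logp, starts)
    seg_max = np.where(np.isfinite(seg_max), seg_max, 0.0)
    scaled = np.exp(logp - np.repeat(seg_max, lengths))
    sums = np.add.reduceat(scaled, starts)
    out = np.exp(seg_max + np.log(sums))
    return np.clip(out, _TINY, 1.0)


def hypergeom_midp(n_ij: int, n_i: int, n_j: int, n_tot: int) -> float:
    """Mid-p upper-tail probability for one gene-GO pair.

    Parameters are the joint count ``n_ij``, the gene margin ``n_i``, the
    GO margin ``n_j``, and the total ``n_tot`` of abstracts with at least
    one mention.  Margins are validated; violations raise ``ValueError``
    naming the offending margin.

    >>> round(hypergeom_midp(4, 4, 5, 10), 9)   # upper tail empty
    0.011904762
    >>> hypergeom_midp(2, 4, 5, 10)
    0.5
    """
    _check_margins(n_ij, n_i, n_j, n_tot)
    return float(hypergeom_midp_many([n_ij], [n_i], [n_j], [n_tot])[0])


def hypergeom_midp_exact(n_ij: int, n_i: int, n_j: int, n_tot: int) -> Fraction:
    """Exact rational-arithmetic mid-p value (reference implementation).

    Enumerates the hypergeometric PMF with integer binomial coefficients and
    returns the mid-p tail as a :class:`fractions.Fraction`.  Exact but slow;
    used to validate :func:`hypergeom_midp` at small margins.
    """
    _check_margins(n_ij, n_i, n_j, n_tot)
    denom = math.comb(n_tot, n_i)
    kmax = min(n_i, n_j)
    tail = 0
    for kk in range(n_ij + 1, kmax + 1):
        tail += math.comb(n_j, kk) * math.comb(n_tot - n_j, n_i - kk)
    here = math.comb(n_j, n_ij) * math.comb(n_tot - n_j, n_i - n_ij)
    return Fraction(2 * tail + here, 2 * denom)


# ---------------------------------------------------------------------------
# p-value matrix
# ---------------------------------------------------------------------------

@dataclass
class PValueMatrix:
    """Sparse gene x GO matrix of mid-p association p-values.

    A pair is stored iff its joint count was at least one; absence encodes
    "no abstract mentions this gene-GO pair" and is treated as a missing
    value (weight zero, or p = 1, depending on the consumer's rule).
    """

    genes: tuple[str, ...]
    gos: tuple[str, ...]
    p: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.gos = tuple(self.gos)
        self._gene_set = frozenset(self.genes)
        self._go_set = frozenset(self.gos)
        by_gene: dict[str, dict[str, float]] = {}
        for (g, t), val in self.p.items():
            if not 0.0 < val <= 1.0:
                raise ValueError(f"p-value for ({g}, {t}) outside (0, 1]: {val}")
            if g not in self._gene_set or t not in self._go_set:
                raise ValueError(f"stored pair ({g}, {t}) outside the index sets")
            by_gene.setdefault(g, {})[t] = val
        self._by_gene = by_gene

    @property
    def gene_set(self) -> frozenset[str]:
        return self._gene_set

    @property
    def go_set(self) -> frozenset[str]:
        return self._go_set

    def get(self, gene: str, go: str) -> float | None:
        """Stored p-value, or ``None`` when the pair was never observed."""
        return self.p.get((gene, go))

    def profile(self, gene: str) -> dict[str, float]:
        """All stored ``go -> p`` entries for *gene* (empty dict if none)."""
        return dict(self._by_gene.get(gene, {}))


def build_pvalue_matrix(counts) -> PValueMatrix:
    """Apply the mid-p test to every stored joint count of *counts*.

    Exactly the pairs with ``n_ij >= 1`` appear in the result; their margins
    are taken from the same tally, so the matrix and the counts can never
    disagree.
    """
    pairs = sorted(counts.n_joint)
    if pairs:
        k = [counts.n_joint[pr] for pr in pairs]
        a = [counts.n_gene[pr[0]] for pr in pairs]
        b = [counts.n_go[pr[1]] for pr in pairs]
        vals = hypergeom_midp_many(k, a, b, counts.n_total)
        p = {pr: float(v) for pr, v in zip(pairs, vals)}
    else:
        p = {}
    return PValueMatrix(
        genes=tuple(sorted(counts.n_gene)),
        gos=tuple(sorted(counts.n_go)),
        p=p,
    )


# ---------------------------------------------------------------------------
# weight profiles and cosine similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightProfile:
    """A gene's truncated ``-log p`` association profile over GO terms.

    Only nonzero weights are stored; GO terms never observed with the gene
    contribute zero.  With the default floor of ``1e-6`` every stored weight
    lies in ``(0, -log(1e-6)]``.
    """

    gene: str
    weights: Mapping[str, float]

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


def weight_profile(
    pmat: PValueMatrix,
    gene: str,
    floor: float = DEFAULT_FLOOR,
    log_base: float | None = None,
) -> WeightProfile:
    """Build the ``-log max(p, floor)`` profile of *gene*.

    ``log_base=None`` means the natural logarithm (the package default; the
    choice only rescales profiles uniformly and cancels in the cosine).
    """
    if not 0.0 < floor < 1.0:
        raise ValueError(f"floor must be in (0, 1), got {floor}")
    scale = 1.0 if log_base is None else math.log(log_base)
    weights = {}
    for go, p in pmat.profile(gene).items():
        w = -math.log(max(p, floor)) / scale
        if w > 0.0:
            weights[go] = w
    return WeightProfile(gene=gene, weights=weights)


def cosine_similarity(a: WeightProfile, b: WeightProfile) -> float:
    """Cosine of two weight profiles over the union of their supports.

    Weights are non-negative, so the value lies in ``[0, 1]``.  If either
    profile is all-zero the similarity is undefined; this function returns
    0.0 for that case (callers that need the distinction should check the
    norms, as :func:`similarity_matrix` does).
    """
    na, nb = a.norm(), b.norm()
    if na == 0.0 or nb == 0.0:
        return 0.0
    small, large = (a.weights, b.weights) if len(a.weights) <= len(b.weights) else (b.weights, a.weights)
    dot = sum(w * large.get(go, 0.0) for go, w in small.items())
    return min(dot / (na * nb), 1.0)


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene cosine similarities.

    ``undefined`` flags genes whose weight profile is all-zero: their rows
    and columns are stored as 0 (including the diagonal) so that network
    thresholding never produces edges for unstudied genes, but they remain
    distinguishable from genuinely orthogonal pairs.
    """

    genes: tuple[str, ...]
    values: np.ndarray
    undefined: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("similarities must lie in [0, 1]")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def gamma(self, gene_a: str, gene_b: str) -> float:
        return float(self.values[self._index[gene_a], self._index[gene_b]])

    def is_defined(self, gene: str) -> bool:
        return gene not in self.undefined

    def pair_values(self, include_undefined: bool = False) -> np.ndarray:
        """Upper-triangle similarities, one value per unordered gene pair.

        By default pairs involving an undefined (all-zero-profile) gene are
        excluded; these are placeholders, not measurements.
        """
        n = len(self.genes)
        iu, ju = np.triu_indices(n, k=1)
        vals = self.values[iu, ju]
        if include_undefined or not self.undefined:
            return vals
        defined = np.array([g not in self.undefined for g in self.genes])
        keep = defined[iu] & defined[ju]
        return vals[keep]


def similarity_matrix(
    pmat: PValueMatrix,
    genes: Sequence[str] | None = None,
    floor: float = DEFAULT_FLOOR,
    log_base: float | None = None,
) -> SimilarityMatrix:
    """All pairwise profile cosines for *genes* (default: every gene).

    The diagonal is 1 for genes with at least one nonzero weight and 0 for
    all-zero profiles, which are flagged ``undefined``.  Unknown gene ids
    raise ``ValueError`` listing every offender.
    """
    if genes is None:
        genes = pmat.genes
    genes = list(genes)
    unknown = [g for g in genes if g not in pmat.gene_set]
    if unknown:
        raise ValueError(f"unknown gene id(s): {', '.join(sorted(unknown))}")
    go_index = {t: j for j, t in enumerate(pmat.gos)}
    W = np.zeros((len(genes), len(pmat.gos)))
    for i, g in enumerate(genes):
        prof = weight_profile(pmat, g, floor=floor, log_base=log_base)
        for go, w in prof.weights.items():
            W[i, go_index[go]] = w
    norms = np.linalg.norm(W, axis=1)
    defined = norms > 0.0
    safe = np.where(defined, norms, 1.0)
    U = W / safe[:, None]
    S = U @ U.T
    S[~defined, :] = 0.0
    S[:, ~defined] = 0.0
    np.fill_diagonal(S, np.where(defined, 1.0, 0.0))
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(
        genes=tuple(genes),
        values=S,
        undefined=frozenset(g for g, d in zip(genes, defined) if not d),
    )


def similarity_percentiles(
    values: Sequence[float] | np.ndarray,
    qs: Sequence[float],
    method: str = "linear",
) -> list[float]:
    """Empirical percentiles of a similarity distribution.

    ``method`` is passed to :func:`numpy.quantile`; the default is linear
    interpolation between order statistics (the classical "type 7" rule).
    Output is monotone non-decreasing in ``q``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take percentiles of an empty value set")
    for q in qs:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"percentile level {q} outside [0, 1]")
    return [float(v) for v in np.quantile(arr, list(qs), method=method)]


def cooccurrence_similarity(counts) -> SimilarityMatrix:
    """Baseline gene-gene similarity from direct co-mentions only.

    The cosine of two genes' 0/1 abstract-incidence vectors reduces to
    :math:`n_{ii'} / \\sqrt{n_{i\\cdot} n_{i'\\cdot}}`.  Genes with a zero
    margin are flagged undefined.  This deliberately ignores GO terms and
    serves as the comparison point for the GO-guided similarity.
    """
    genes = tuple(sorted(counts.n_gene))
    index = {g: i for i, g in enumerate(genes)}
    margins = np.array([counts.n_gene[g] for g in genes], dtype=float)
    defined = margins > 0
    S = np.zeros((len(genes), len(genes)))
    for (a, b), n in counts.n_gene_joint.items():
        i, j = index[a], index[b]
        if defined[i] and defined[j]:
            S[i, j] = S[j, i] = n / math.sqrt(margins[i] * margins[j])
    np.fill_diagonal(S, np.where(defined, 1.0, 0.0))
    S = np.clip(S, 0.0, 1.0)
    return SimilarityMatrix(
        genes=genes,
        values=S,
        undefined=frozenset(g for g, d in zip(genes, defined) if not d),
    )


# ---------------------------------------------------------------------------
# downstream transforms
# ---------------------------------------------------------------------------

def probit_transform(p):
    """Standard-normal quantile of a p-value, clamped to ``[1e-6, 1 - 1e-6]``.

    Missing values (``None`` or NaN) are treated as p = 1 before clamping,
    matching the "no evidence" convention used everywhere else.  The result
    is unbounded-looking and roughly normal, which makes p-value matrices
    amenable to ordinary clustering and PCA.  Scalars return a float; array
    input returns an array of the same shape.
    """
    scalar = np.isscalar(p) or p is None
    if p is None:
        p = 1.0
    arr = np.asarray(p, dtype=float)
    arr = np.where(np.isnan(arr), 1.0, arr)
    if np.any((arr <= 0.0) | (arr > 1.0)):
        raise ValueError("p-values must lie in (0, 1] (or be missing)")
    out = norm.ppf(np.clip(arr, *_PROBIT_CLAMP))
    return float(out) if scalar else out


def select_top_go(
    pmat: PValueMatrix,
    genes: Iterable[str],
    k: int,
) -> list[str]:
    """The *k* GO terms with the smallest average p over a gene set.

    Missing gene-GO pairs count as p = 1 in the average.  Only GO terms with
    at least one stored pair for the gene set are candidates (all others tie
    at exactly 1).  Ties are broken lexicographically by GO id, and the
    result does not depend on the order of *genes*.  If *k* exceeds the
    number of candidates all of them are returned, with a warning.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("gene set must be non-empty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    unknown = [g for g in genes if g not in pmat.gene_set]
    if unknown:
        raise ValueError(f"unknown gene id(s): {', '.join(unknown)}")
    totals: dict[str, float] = {}
    for g in genes:
        for go, p in pmat.profile(g).items():
            totals[go] = totals.get(go, 0.0) + (p - 1.0)  # relative to all-missing
    n = len(genes)
    ranked = sorted(totals, key=lambda go: ((n + totals[go]) / n, go))
    if k > len(ranked):
        warnings.warn(
            f"requested {k} GO terms but only {len(ranked)} have any stored "
            "p-value for the gene set; returning all of them",
            stacklevel=2,
        )
        k = len(ranked)
    return ranked[:k]


def average_go_pvalues(pmat: PValueMatrix, genes: Iterable[str]) -> dict[str, float]:
    """Average p per GO term over *genes*, missing entries counted as 1."""
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("gene set must be non-empty")
    totals: dict[str, float] = {go: 0.0 for go in pmat.gos}
    for g in genes:
        prof = pmat.profile(g)
        for go in pmat.gos:
            totals[go] += prof.get(go, 1.0)
    n = len(genes)
    return {go: t / n for go, t in totals.items()}
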