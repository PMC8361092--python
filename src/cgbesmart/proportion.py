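"""Chain-factorized joint distribution over C-to-G edit patterns.

Editing of each substrate C is modeled as a Bernoulli variable X_i with
marginal p(X_i = 1) supplied by the efficiency model.  Dependence between
edits is restricted to adjacent substrate positions and summarized by the
odds ratio

    c = p11 * p00 / (p01 * p10),

estimated from pooled training counts.  Given the marginals and the adjacent
odds ratios, each pairwise joint is the unique bivariate Bernoulli with those
margins and that odds ratio (Plackett construction), the conditionals
p(X_i | X_{i-1}) follow, and the full outcome distribution is the forward
chain p(X_1) * prod_i p(X_i | X_{i-1}).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import EditPattern, OutcomeTable, TargetSite, ValidationError

#: c estimates are clipped here to guard against smoothing artifacts.
C_CAP = (1e-4, 1e4)
#: Marginals at exactly 0 or 1 are clipped into the open interval.
MARGINAL_CLIP = 1e-9
#: Exact enumeration refuses chains longer than this.
N_MAX_EXACT = 12


class SmoothingError(ValueError):
    """A pairwise cell was zero; apply add-one smoothing upstream first."""


@dataclass(frozen=True)
class PairwiseCounts:
    """Joint probabilities of a pair of binary edit indicators."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        cells = (self.p11, self.p10, self.p01, self.p00)
        if any(c < 0 for c in cells):
            raise ValidationError(f"negative pairwise cell in {cells}")
        if abs(sum(cells) - 1.0) > 1e-12:
            raise ValidationError(f"pairwise cells sum to {sum(cells)!r}, not 1")

    @property
    def p_a(self) -> float:
        """Marginal of the first (left) position."""
        return self.p11 + self.p10

    @property
    def p_b(self) -> float:
        """Marginal of the second (right) position."""
        return self.p11 + self.p01


def estimate_c(pair: PairwiseCounts) -> float:
    """Odds ratio c = p11*p00 / (p01*p10) of a pairwise table."""
    if min(pair.p11, pair.p10, pair.p01, pair.p00) <= 0.0:
        raise SmoothingError(
            "zero cell in pairwise counts; add-one smoothing must be applied "
            "before estimating c"
        )
    return (pair.p11 * pair.p00) / (pair.p01 * pair.p10)


def joint_from_marginals(p_a: float, p_b: float, c: float) -> PairwiseCounts:
    """Unique bivariate Bernoulli with margins ``(p_a, p_b)`` and odds ratio ``c``.

    For c == 1 this is the independence product.  Otherwise p11 solves the
    quadratic ``c (p_a - p11)(p_b - p11) = p11 (1 - p_a - p_b + p11)``; the
    admissible root is the one inside the Frechet bounds
    ``max(0, p_a + p_b - 1) < p11 < min(p_a, p_b)``.
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValidationError(f"marginals must lie in (0,1), got ({p_a}, {p_b})")
    if not c > 0.0:
        raise ValidationError(f"odds ratio must be positive, got {c}")

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    if abs(c - 1.0) < 1e-12:
        p11 = p_a * p_b
    else:
        # Plackett closed form: (c-1) x^2 - [1 + (c-1)(pa+pb)] x + c pa pb = 0
        s = 1.0 + (c - 1.0) * (p_a + p_b)
        disc = s * s - 4.0 * c * (c - 1.0) * p_a * p_b
        if disc >= 0.0:
            root = math.sqrt(disc)
            p11 = (s - root) / (2.0 * (c - 1.0))
        else:
            p11 = math.nan
        if not (lo < p11 < hi):
            # numerically marginal discriminant: bisection on the monotone
            # map p11 -> odds ratio
            p11 = _bisect_p11(p_a, p_b, c, lo, hi)
    if not (lo <= p11 <= hi):
        raise ArithmeticError(
            f"no admissible p11 for margins ({p_a}, {p_b}), c={c}"
        )
    p11 = min(max(p11, lo), hi)
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p_a - p_b + p11
    # clamp tiny negatives from rounding
    return PairwiseCounts(p11, max(p10, 0.0), max(p01, 0.0), max(p00, 0.0))


def _bisect_p11(p_a: float, p_b: float, c: float, lo: float, hi: float) -> float:
    def odds(x: float) -> float:
        return (x * (1.0 - p_a - p_b + x)) / ((p_a - x) * (p_b - x))

    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        if odds(mid) < c:
            a = mid
        else:
            b = mid
        if b - a < 1e-15:
            break
    return 0.5 * (a + b)


@dataclass
class ChainModel:
    """First-order chain over the substrate C positions of one site.

    ``positions`` are protospacer positions left-to-right; ``marginals`` are
    p(X_i = 1); ``cond_given_prev`` holds, per adjacent pair, the pair
    (p(X_i=1 | X_{i-1}=0), p(X_i=1 | X_{i-1}=1)).
    """

    positions: tuple[int, ...]
    marginals: tuple[float, ...]
    cond_given_prev: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n < 1:
            raise ValidationError("chain needs at least one position")
        if len(self.marginals) != n or len(self.cond_given_prev) != n - 1:
            raise ValidationError("chain component lengths inconsistent")

    @property
    def n(self) -> int:
        return len(self.positions)

    def pattern_probability(self, edited: Sequence[int]) -> float:
        """Probability of the binary pattern ``edited`` (0/1 per position)."""
        x = list(edited)
        p = self.marginals[0] if x[0] else 1.0 - self.marginals[0]
        for i in range(1, self.n):
            q1 = self.cond_given_prev[i - 1][x[i - 1]]
            p *= q1 if x[i] else 1.0 - q1
        return p

    def propagated_marginals(self) -> np.ndarray:
        """Forward-recursed marginals (must equal the inputs)."""
        out = np.empty(self.n)
        out[0] = self.marginals[0]
        for i in range(1, self.n):
            q0, q1 = self.cond_given_prev[i - 1]
            out[i] = q0 * (1.0 - out[i - 1]) + q1 * out[i - 1]
        return out

    def sample(self, n_reads: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``n_reads`` binary edit vectors (works for any chain length)."""
        x = np.empty((n_reads, self.n), dtype=np.int8)
        u = rng.random((n_reads, self.n))
        x[:, 0] = u[:, 0] < self.marginals[0]
        for i in range(1, self.n):
            q0, q1 = self.cond_given_prev[i - 1]
            q = np.where(x[:, i - 1] == 1, q1, q0)
            x[:, i] = u[:, i] < q
        return x


def build_chain(
    positions: Sequence[int],
    marginals: Sequence[float],
    correlations: Sequence[float],
) -> ChainModel:
    """Assemble a chain from marginals and adjacent odds ratios.

    Marginals at exactly 0 or 1 are clipped into the open unit interval
    (degenerate Bernoullis have no finite odds ratio).
    """
    positions = tuple(int(p) for p in positions)
    if len(marginals) != len(positions):
        raise ValidationError("one marginal per position required")
    if len(correlations) != max(len(positions) - 1, 0):
        raise ValidationError("need n-1 adjacent odds ratios for n positions")
    clipped = tuple(
        min(max(float(m), MARGINAL_CLIP), 1.0 - MARGINAL_CLIP) for m in marginals
    )
    conds = []
    for i, c in enumerate(correlations):
        pair = joint_from_marginals(clipped[i], clipped[i + 1], float(c))
        q1 = pair.p11 / pair.p_a
        q0 = pair.p01 / (1.0 - pair.p_a)
        conds.append((q0, q1))
    return ChainModel(positions, clipped, tuple(conds))


def outcome_proportions(
    chain: ChainModel, n_max: int = N_MAX_EXACT
) -> dict[EditPattern, float]:
    """Exact outcome distribution over all 2^n edit patterns.

    Patterns are keyed by :class:`EditPattern` (C-to-G at the edited
    positions; the empty pattern is REF).  Raises for chains longer than
    ``n_max`` — use :meth:`ChainModel.sample` for those.
    """
    if chain.n > n_max:
        raise ValidationError(
            f"chain length {chain.n} exceeds exact-enumeration limit {n_max}; "
            "use ChainModel.sample for long chains"
        )
    out: dict[EditPattern, float] = {}
    for bits in itertools.product((0, 1), repeat=chain.n):
        prob = chain.pattern_probability(bits)
        pattern = EditPattern.from_positions(
            p for p, b in zip(chain.positions, bits) if b
        )
        out[pattern] = prob
    return out


# ---------------------------------------------------------------------------
# Estimating c from pooled training tables
# ---------------------------------------------------------------------------


def pairwise_counts_from_tables(
    tables: Iterable[OutcomeTable],
    sites: Mapping[str, TargetSite],
) -> dict[tuple[int, int], np.ndarray]:
    """Pool read counts over adjacent substrate-C pairs, by absolute position.

    For every site, consecutive substrate Cs (a, b) contribute each read to
    one of the four cells (X_a, X_b).  Indel reads are ignored; a position
    counts as edited only for the modeled C-to-G conversion.  Returns, per
    ordered absolute position pair, the 2x2 count array ``[[n00, n01],
    [n10, n11]]``.
    """
    pooled: dict[tuple[int, int], np.ndarray] = {}
    for table in tables:
        site = sites.get(table.site_id)
        if site is None:
            raise ValidationError(f"no site record for table {table.site_id!r}")
        subs = site.substrate_positions()
        if len(subs) < 2:
            continue
        pairs = list(zip(subs[:-1], subs[1:]))
        for pattern, n in table.counts.items():
            if pattern.is_indel or n == 0:
                continue
            g = pattern.g_positions() if pattern.kind == "substitution" else frozenset()
            for a, b in pairs:
                cell = pooled.setdefault((a, b), np.zeros((2, 2), dtype=np.int64))
                cell[int(a in g), int(b in g)] += n
    return pooled


def estimate_adjacent_correlations(
    tables: Iterable[OutcomeTable],
    sites: Mapping[str, TargetSite],
    cap: tuple[float, float] = C_CAP,
) -> dict[tuple[int, int], float]:
    """Pooled odds-ratio estimate per adjacent absolute-position pair.

    Upstream add-one smoothing of the training table normally guarantees
    nonzero cells; a zero cell raises :class:`SmoothingError`.  Estimates are
    capped to ``cap`` to guard against smoothing artifacts.
    """
    out: dict[tuple[int, int], float] = {}
    for key, cells in pairwise_counts_from_tables(tables, sites).items():
        total = cells.sum()
        pair = PairwiseCounts(
            p11=cells[1, 1] / total,
            p10=cells[1, 0] / total,
            p01=cells[0, 1] / total,
            p00=cells[0, 0] / total,
        )
        c = estimate_c(pair)
        out[key] = min(max(c, cap[0]), cap[1])
    return out


def chain_for_site(
    site: TargetSite,
    marginals: Mapping[int, float],
    correlations: Mapping[tuple[int, int], float],
    default_c: float | None = None,
) -> ChainModel:
    """Chain over a site's substrate Cs from per-position marginals and the
    pooled correlation map.

    Adjacent pairs never observed in training fall back to ``default_c``;
    when that is None, the median of the pooled estimates is used (the
    correlation is a property of the editor, so the pooled central value is
    a better prior than independence), or 1.0 if no estimate exists.
    """
    if default_c is None:
        default_c = float(np.median(list(correlations.values()))) if correlations else 1.0
    positions = [p for p in site.substrate_positions() if p in marginals]
    if not positions:
        raise ValidationError(f"site {site.site_id!r} has no substrate C with a marginal")
    margs = [marginals[p] for p in positions]
    cs = [
        correlations.get((a, b), default_c)
        for a, b in zip(positions[:-1], positions[1:])
    ]
    return build_chain(positions, margs, cs)
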