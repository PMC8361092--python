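"""Read classification, strand normalization, and training-table assembly.

Per-site statistics follow the amplicon-sequencing conventions: on-target
efficiency is the number of reads containing only the intended mutations
divided by all reads (indel reads included in the denominator); indel
frequency is the fraction of reads containing indels.

Training tables are assembled replicate-wise: indel reads are discarded
first, replicates with fewer than ``min_reads`` remaining reads are dropped,
surviving replicates are summed per genotype, and add-one smoothing is
applied to every edited outcome in the site's outcome space so no outcome has
zero probability.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .io_tables import (
    EDIT_BASES,
    EditPattern,
    OutcomeTable,
    TargetSite,
    ValidationError,
)
from .synthetic import reverse_complement

logger = logging.getLogger(__name__)

MIN_READS_DEFAULT = 100
#: Positions 1-23 (protospacer + PAM); a gap inside this region marks an indel.
INDEL_REGION = (1, 23)
WINDOW_POSITIONS = frozenset({4, 5, 6, 7})


@dataclass
class ReadCall:
    """Classification of a single read against its target site."""

    kind: str  # substitution | unedited | indel
    substitutions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "unedited", "indel"):
            raise ValidationError(f"unknown read-call kind {self.kind!r}")
        if self.kind == "indel" and self.substitutions:
            raise ValidationError("indel calls carry no substitutions")
        for p, b in self.substitutions.items():
            if not 1 <= p <= 20:
                raise ValidationError(f"substitution position {p} outside 1-20")
            if b not in EDIT_BASES:
                raise ValidationError(f"substitution base {b!r} invalid")

    def to_pattern(self) -> EditPattern:
        if self.kind == "indel":
            return EditPattern.indel()
        if not self.substitutions:
            return EditPattern.ref()
        return EditPattern.substitution(self.substitutions)


@dataclass(frozen=True)
class Read:
    """A raw read with its (possibly unknown) orientation."""

    read_id: str
    sequence: str
    orientation: str = "forward"  # forward | reverse | unknown


def orient_to_forward(read: Read, site: TargetSite) -> Read:
    """Return the read in the frame where the protospacer reads 5'->3'.

    Reverse reads are reverse-complemented (idempotent: the returned read is
    marked forward).  On the forward frame only C is a substrate nucleotide;
    positions called in the reverse frame map through ``p -> 21 - p``.
    """
    if read.orientation == "forward":
        return read
    if read.orientation == "reverse":
        return Read(read.read_id, reverse_complement(read.sequence), "forward")
    raise ValidationError(f"read {read.read_id!r}: unknown orientation")


def flip_positions(positions: Iterable[int]) -> set[int]:
    """Remap protospacer positions called in the reverse frame (p -> 21-p)."""
    return {21 - p for p in positions}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    # ends-free: reads may cover only part of the amplicon and vice versa
    aligner.end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def classify_read(read: Read | str, site: TargetSite) -> ReadCall:
    """Classify one (forward-frame) read against the site reference.

    A global affine-gap alignment (match 2, mismatch -2, open -6, extend -1)
    is computed read-vs-amplicon; any gap inside protospacer+PAM positions
    1-23 classifies the read as indel.  Otherwise per-position comparison over
    protospacer positions 1-20 yields the substitution map, recorded at
    reference-C positions (the substrate nucleotide).
    """
    seq = read.sequence if isinstance(read, Read) else read
    if set(seq) - set("ACGT"):
        raise ValidationError("read contains non-ACGT symbols")
    ref = site.sequence
    if seq == ref:
        return ReadCall("unedited")

    alignment = _ALIGNER.align(seq, ref)[0]
    # aligned columns: read (query here is 'seq' as target of align()?) --
    # we aligned (seq, ref): seq is "target", ref is "query" in Biopython
    # terms; use the coordinate blocks to map ref index -> read index.
    ref_to_read: dict[int, int] = {}
    seq_blocks, ref_blocks = alignment.aligned
    for (s0, s1), (r0, r1) in zip(seq_blocks, ref_blocks):
        for k in range(r1 - r0):
            ref_to_read[r0 + k] = s0 + k

    lo = site.seq_index(INDEL_REGION[0])
    hi = site.seq_index(INDEL_REGION[1])
    covered = [i for i in range(lo, hi + 1) if i in ref_to_read]
    if len(covered) < (hi - lo + 1):
        # a ref position in the region is deleted or not covered
        if not covered or covered[0] > lo or covered[-1] < hi:
            raise ValidationError(
                f"read does not cover protospacer positions 1-20 of site {site.site_id!r}"
            )
        return ReadCall("indel")
    # insertion inside the region: read indices not consecutive
    read_idx = [ref_to_read[i] for i in range(lo, hi + 1)]
    if any(b - a != 1 for a, b in zip(read_idx[:-1], read_idx[1:])):
        return ReadCall("indel")

    substitutions: dict[int, str] = {}
    for pos in range(1, 21):
        i = site.seq_index(pos)
        base = seq[ref_to_read[i]]
        if base != ref[i] and ref[i] == "C" and base in EDIT_BASES:
            substitutions[pos] = base
    if substitutions:
        return ReadCall("substitution", substitutions)
    return ReadCall("unedited")


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------


def on_target_efficiency(
    calls: Sequence[ReadCall], intended_edits: Iterable[tuple[int, str]]
) -> float:
    """Fraction of reads containing exactly the intended mutations.

    The numerator counts reads whose substitution set equals
    ``intended_edits`` (no bystanders); the denominator is all reads,
    including indel reads.
    """
    if not calls:
        raise ValidationError("empty call list")
    intended = set(intended_edits)
    if not intended:
        raise ValidationError("intended_edits must be non-empty")
    hits = sum(
        1
        for c in calls
        if c.kind == "substitution" and set(c.substitutions.items()) == intended
    )
    return hits / len(calls)


def indel_frequency(calls: Sequence[ReadCall]) -> float:
    """Fraction of reads containing indels."""
    if not calls:
        raise ValidationError("empty call list")
    return sum(1 for c in calls if c.kind == "indel") / len(calls)


def calls_from_table(table: OutcomeTable) -> list[ReadCall]:
    """Expand an outcome table into per-read calls (for the statistics above)."""
    calls = []
    for pattern, n in table.counts.items():
        if pattern.is_indel:
            call = ReadCall("indel")
        elif pattern.is_ref:
            call = ReadCall("unedited")
        else:
            call = ReadCall("substitution", dict(pattern.edits))
        calls.extend([call] * n)
    return calls


# ---------------------------------------------------------------------------
# Training-table assembly
# ---------------------------------------------------------------------------


def smoothing_outcome_space(site: TargetSite, max_order: int = 2) -> set[EditPattern]:
    """Edited outcomes receiving the add-one count for one site: all C-to-G
    patterns over the site's substrate Cs with up to ``max_order``
    simultaneous edits.  Patterns observed beyond that order are already
    nonzero and receive no extra count."""
    space: set[EditPattern] = set()
    subs = site.substrate_positions()
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(subs, order):
            space.add(EditPattern.from_positions(combo))
    return space


def assemble_training_table(
    tables: Iterable[OutcomeTable],
    sites: Mapping[str, TargetSite],
    min_reads: int = MIN_READS_DEFAULT,
    max_order: int = 2,
) -> tuple[dict[str, OutcomeTable], pd.DataFrame]:
    """Filter, sum, and smooth replicate outcome tables into training data.

    Steps, in order: (1) indel reads discarded; (2) replicates with fewer
    than ``min_reads`` remaining reads dropped; (3) surviving replicates
    summed per genotype; (4) add-one smoothing over the site's edited outcome
    space; (5) per-position efficiency label = smoothed count of reads edited
    (C-to-G) at the position / smoothed total.

    Sites with no surviving replicate are omitted (logged, not an error).
    Returns the summed+smoothed tables and a labels frame with columns
    ``site_id, position, efficiency, coverage`` (coverage = unsmoothed summed
    read count, used by the >100x coverage filter).
    """
    by_site: dict[str, list[OutcomeTable]] = defaultdict(list)
    for t in tables:
        by_site[t.site_id].append(t)

    out_tables: dict[str, OutcomeTable] = {}
    rows = []
    n_dropped_sites = 0
    for site_id, reps in by_site.items():
        site = sites.get(site_id)
        if site is None:
            raise ValidationError(f"no site record for outcome table {site_id!r}")
        surviving = []
        for rep in reps:
            clean = rep.without_indels()
            if clean.total < min_reads:
                logger.info(
                    "site %s replicate %s dropped: %d < %d reads",
                    site_id, rep.replicate_id, clean.total, min_reads,
                )
                continue
            surviving.append(clean)
        if not surviving:
            n_dropped_sites += 1
            logger.info("site %s dropped: no replicate with >= %d reads", site_id, min_reads)
            continue

        summed: dict[EditPattern, int] = defaultdict(int)
        for rep in surviving:
            for pattern, n in rep.counts.items():
                summed[pattern] += n
        coverage = sum(summed.values())

        for pattern in smoothing_outcome_space(site, max_order):
            summed[pattern] += 1
        summed.setdefault(EditPattern.ref(), 0)
        table = OutcomeTable(site_id, dict(summed), "pooled")
        out_tables[site_id] = table

        smoothed_total = table.total
        for pos in site.substrate_positions():
            edited = sum(
                n
                for pattern, n in table.counts.items()
                if pattern.kind == "substitution" and pos in pattern.g_positions()
            )
            rows.append((site_id, pos, edited / smoothed_total, coverage))
    if n_dropped_sites:
        logger.info("%d sites dropped by the %d-read filter", n_dropped_sites, min_reads)

    labels = pd.DataFrame(rows, columns=["site_id", "position", "efficiency", "coverage"])
    return out_tables, labels


def window_filter(
    labels: pd.DataFrame,
    positions: frozenset[int] = WINDOW_POSITIONS,
    min_coverage: int = 100,
) -> pd.DataFrame:
    """Retain (site, position) labels inside the editing window (positions
    4-7) with coverage strictly above ``min_coverage``."""
    mask = labels["position"].isin(positions) & (labels["coverage"] > min_coverage)
    return labels.loc[mask].reset_index(drop=True)
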