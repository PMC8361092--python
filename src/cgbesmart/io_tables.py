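"""Domain types and tabular file formats shared by all stages.

Coordinates are 1-based throughout: protospacer positions run 1-20 with the
PAM at positions 21-23, matching the usual CRISPR convention of numbering
from the PAM-distal end.  Sites are stored as given; strand normalization of
reads happens in :mod:`cgbesmart.quantify`, never here.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
#: Flank required on each side of every protospacer position, set by the
#: largest prediction window (11 nt -> 5 nt each side).
FLANK = 5
PROTOSPACER_LEN = 20
PAM_LEN = 3

STRANDS = ("forward", "reverse")

#: Bases an edited C can be observed as.  C-to-G is the modeled outcome;
#: A and T are bystander conversions tracked by quantification only.
EDIT_BASES = frozenset("AGT")


class ValidationError(ValueError):
    """An input violated a domain invariant (never silently repaired)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSite:
    """One guide/target pair: protospacer + PAM with symmetric flanks.

    ``protospacer_start`` is the 1-based offset of protospacer position 1
    within ``sequence``.  The sequence must carry at least 5 nt of context on
    each side of every protospacer position (so position 1 needs a 5-nt left
    flank and position 20 is followed by the PAM plus 2 more nt).
    """

    site_id: str
    sequence: str
    protospacer_start: int
    strand: str = "forward"

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValidationError("site_id must be non-empty")
        if set(self.sequence) - VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValidationError(
                f"site {self.site_id!r}: sequence contains non-ACGT symbols {bad}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"site {self.site_id!r}: strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if self.protospacer_start < FLANK + 1:
            raise ValidationError(
                f"site {self.site_id!r}: needs >= {FLANK} nt left flank "
                f"(protospacer_start={self.protospacer_start})"
            )
        # rightmost position touched by an 11-nt window centered at position 20
        needed = self.protospacer_start - 1 + PROTOSPACER_LEN + PAM_LEN + (FLANK - PAM_LEN)
        if len(self.sequence) < needed:
            raise ValidationError(
                f"site {self.site_id!r}: sequence too short ({len(self.sequence)} nt, "
                f"needs {needed}) for {FLANK} nt right context"
            )

    # -- coordinate helpers -------------------------------------------------

    def seq_index(self, position: int) -> int:
        """0-based index into ``sequence`` of protospacer ``position``."""
        return self.protospacer_start - 1 + position - 1

    def base_at(self, position: int) -> str:
        """Base at a protospacer position (may reach into flanks/PAM)."""
        idx = self.seq_index(position)
        if idx < 0 or idx >= len(self.sequence):
            raise ValidationError(
                f"site {self.site_id!r}: position {position} outside sequence"
            )
        return self.sequence[idx]

    @property
    def protospacer(self) -> str:
        i = self.protospacer_start - 1
        return self.sequence[i : i + PROTOSPACER_LEN]

    @property
    def pam(self) -> str:
        i = self.protospacer_start - 1 + PROTOSPACER_LEN
        return self.sequence[i : i + PAM_LEN]

    def substrate_positions(self) -> tuple[int, ...]:
        """Protospacer positions (1-20) whose reference base is C."""
        proto = self.protospacer
        return tuple(p for p in range(1, PROTOSPACER_LEN + 1) if proto[p - 1] == "C")


REF_TOKEN = "REF"
INDEL_TOKEN = "INDEL"
_EDIT_RE = re.compile(r"^(\d+)([AGT])$")


@dataclass(frozen=True)
class EditPattern:
    """The outcome class of a single read.

    ``kind`` is one of ``substitution`` (one or more C conversions),
    ``ref`` (unedited) or ``indel``.  ``edits`` maps protospacer position to
    the observed base, stored sorted by position so patterns are canonical and
    hashable.  Only C-to-G edits enter the modeled outcome space; C-to-A/T
    bystanders are representable for quantification.
    """

    kind: str
    edits: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "ref", "indel"):
            raise ValidationError(f"unknown pattern kind {self.kind!r}")
        if self.kind != "substitution":
            if self.edits:
                raise ValidationError(f"{self.kind} pattern carries no edits")
            return
        if not self.edits:
            raise ValidationError("substitution pattern must carry >=1 edit")
        positions = [p for p, _ in self.edits]
        if len(set(positions)) != len(positions):
            raise ValidationError("duplicate positions in edit pattern")
        for p, b in self.edits:
            if not 1 <= p <= PROTOSPACER_LEN:
                raise ValidationError(f"edit position {p} outside 1-{PROTOSPACER_LEN}")
            if b not in EDIT_BASES:
                raise ValidationError(f"edit base {b!r} not in {sorted(EDIT_BASES)}")
        if tuple(sorted(self.edits)) != self.edits:
            raise ValidationError("edits must be sorted by position (use .substitution())")

    # -- constructors -------------------------------------------------------

    @classmethod
    def ref(cls) -> "EditPattern":
        return cls("ref")

    @classmethod
    def indel(cls) -> "EditPattern":
        return cls("indel")

    @classmethod
    def substitution(cls, edits: Mapping[int, str] | Iterable[tuple[int, str]]) -> "EditPattern":
        items = edits.items() if isinstance(edits, Mapping) else edits
        return cls("substitution", tuple(sorted(items)))

    @classmethod
    def from_positions(cls, positions: Iterable[int]) -> "EditPattern":
        """C-to-G pattern at the given positions; REF for the empty set."""
        pos = sorted(positions)
        if not pos:
            return cls.ref()
        return cls("substitution", tuple((p, "G") for p in pos))

    # -- predicates ---------------------------------------------------------

    @property
    def is_ref(self) -> bool:
        return self.kind == "ref"

    @property
    def is_indel(self) -> bool:
        return self.kind == "indel"

    def g_positions(self) -> frozenset[int]:
        """Positions carrying the modeled C-to-G conversion."""
        return frozenset(p for p, b in self.edits if b == "G")

    def has_bystander(self) -> bool:
        return any(b != "G" for _, b in self.edits)

    # -- serialization ------------------------------------------------------

    def token(self) -> str:
        if self.is_ref:
            return REF_TOKEN
        if self.is_indel:
            return INDEL_TOKEN
        return "+".join(f"{p}{b}" for p, b in self.edits)

    @classmethod
    def parse(cls, token: str) -> "EditPattern":
        token = token.strip()
        if token == REF_TOKEN:
            return cls.ref()
        if token == INDEL_TOKEN:
            return cls.indel()
        edits = []
        for part in token.split("+"):
            m = _EDIT_RE.match(part)
            if m is None:
                raise ParseError(f"unknown pattern token {token!r}")
            edits.append((int(m.group(1)), m.group(2)))
        return cls.substitution(edits)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


@dataclass
class OutcomeTable:
    """Per-site read counts keyed by edit pattern, for one replicate."""

    site_id: str
    counts: dict[EditPattern, int] = field(default_factory=dict)
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        for pattern, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"site {self.site_id!r}: negative count {n} for {pattern.token()}"
                )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def without_indels(self) -> "OutcomeTable":
        return OutcomeTable(
            self.site_id,
            {p: n for p, n in self.counts.items() if not p.is_indel},
            self.replicate_id,
        )


@dataclass(frozen=True)
class PositionEfficiency:
    """Predicted or observed C-to-G efficiency at one protospacer position."""

    site_id: str
    position: int
    value: float

    def __post_init__(self) -> None:
        if not 1 <= self.position <= PROTOSPACER_LEN:
            raise ValidationError(f"position {self.position} outside 1-{PROTOSPACER_LEN}")
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError(f"efficiency {self.value} outside [0,1]")


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["site_id", "sequence", "protospacer_start", "strand"]


def read_site_table(path: str | Path) -> list[TargetSite]:
    """Read a TSV of target sites; every row is validated, order preserved."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pandas raises many flavours
        raise ParseError(f"{path}: cannot parse site table: {exc}") from exc
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = int(row.protospacer_start)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path} line {i}: protospacer_start {row.protospacer_start!r} not an integer"
            ) from exc
        sites.append(
            TargetSite(
                site_id=str(row.site_id),
                sequence=str(row.sequence).upper(),
                protospacer_start=start,
                strand=str(row.strand),
            )
        )
    return sites


def write_site_table(path: str | Path, sites: Iterable[TargetSite]) -> None:
    df = pd.DataFrame(
        [(s.site_id, s.sequence, s.protospacer_start, s.strand) for s in sites],
        columns=_SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Outcome tables
# ---------------------------------------------------------------------------

_OUTCOME_COLUMNS = ["site_id", "replicate", "pattern", "count"]


def write_outcome_table(path: str | Path, tables: Iterable[OutcomeTable]) -> None:
    """Write outcome tables canonically (sorted patterns, stable row order)."""
    rows = []
    for t in tables:
        for pattern in sorted(t.counts, key=_pattern_sort_key):
            rows.append((t.site_id, t.replicate_id, pattern.token(), t.counts[pattern]))
    df = pd.DataFrame(rows, columns=_OUTCOME_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _pattern_sort_key(p: EditPattern) -> tuple:
    order = {"ref": 0, "indel": 1, "substitution": 2}
    return (order[p.kind], p.edits)


def read_outcome_table(path: str | Path) -> list[OutcomeTable]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "replicate": str, "pattern": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse outcome table: {exc}") from exc
    missing = [c for c in _OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    tables: dict[tuple[str, str], OutcomeTable] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            count = int(row.count)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: count {row.count!r} not an integer") from exc
        if count < 0:
            raise ValidationError(f"{path} line {i}: negative count {count}")
        pattern = EditPattern.parse(str(row.pattern))
        key = (str(row.site_id), str(row.replicate))
        table = tables.setdefault(key, OutcomeTable(key[0], {}, key[1]))
        table.counts[pattern] = table.counts.get(pattern, 0) + count
    return list(tables.values())


# ---------------------------------------------------------------------------
# Predictions and proportions
# ---------------------------------------------------------------------------


def write_predictions(path: str | Path, values: Iterable[PositionEfficiency]) -> None:
    rows = sorted((v.site_id, v.position, v.value) for v in values)
    df = pd.DataFrame(rows, columns=["site_id", "position", "efficiency"])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def read_predictions(path: str | Path) -> list[PositionEfficiency]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    return [
        PositionEfficiency(str(r.site_id), int(r.position), float(r.efficiency))
        for r in df.itertuples(index=False)
    ]


def write_proportions(path: str | Path, props: Mapping[str, Mapping[EditPattern, float]]) -> None:
    rows = []
    for site_id in sorted(props):
        for pattern in sorted(props[site_id], key=_pattern_sort_key):
            rows.append((site_id, pattern.token(), props[site_id][pattern]))
    df = pd.DataFrame(rows, columns=["site_id", "pattern", "probability"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_proportions(path: str | Path) -> dict[str, dict[EditPattern, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "pattern": str})
    out: dict[str, dict[EditPattern, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.site_id), {})[EditPattern.parse(str(r.pattern))] = float(r.probability)
    return out


# ---------------------------------------------------------------------------
# Raw reads
# ---------------------------------------------------------------------------


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from FASTA/FASTQ, plain or gzipped.

    The read id's first ``:``-separated field names the target site, the
    convention used by the bundled simulator (demultiplexing by sample
    barcode is out of scope).
    """
    path = Path(path)
    name = path.name.lower()
    fmt = "fastq" if (".fastq" in name or ".fq" in name) else "fasta"
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()
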