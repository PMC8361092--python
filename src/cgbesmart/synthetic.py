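"""Synthetic sgRNA-library generator.

Emulates a paired guide/target amplicon screen: each site is a uniform-random
20-nt protospacer with an NGG PAM at positions 21-23 and 10-nt flanks.  True
per-position C-to-G efficiencies follow a logistic model with a boost inside
the editing window (protospacer positions 4-7) and sequence-context (motif)
terms defaulting to an A/T preference at the positions flanking the targeted
C (the "WCW" preference of the optimized C-to-G editors).  Reads carry
negative-binomial coverage, indels, rare C-to-A/T bystanders, and correlated
co-editing of adjacent substrate Cs generated from the same margins+odds-ratio
pairwise joint the proportion model infers — so the generator doubles as the
inference oracle.

Every simulated quantity is reproducible from ``SimConfig.seed``; each site
draws from its own stream keyed by (seed, crc32(site_id)) so per-site results
do not depend on site order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_tables import EditPattern, OutcomeTable, TargetSite, ValidationError
from .proportion import build_chain

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _default_motif_effects() -> dict[tuple[int, str], float]:
    # A/T immediately up- and downstream of the targeted C raise efficiency
    return {(-1, "A"): 0.8, (-1, "T"): 0.8, (1, "A"): 0.8, (1, "T"): 0.8}


@dataclass
class SimConfig:
    """Study conditions of the simulated library.

    Logit-scale effects: true efficiency at a substrate C is
    ``sigmoid(baseline + position_effect * [pos in 4-7] + motif terms)``.
    Coverage per replicate is negative binomial with the given mean and
    dispersion (gamma shape; variance = mean + mean^2/dispersion).
    """

    n_sites: int
    seed: int
    baseline: float = -2.5
    position_effect: float = 1.5
    window: tuple[int, int] = (4, 7)
    motif_effects: dict[tuple[int, str], float] = field(default_factory=_default_motif_effects)
    coverage_mean: float = 1000.0
    coverage_dispersion: float = 10.0
    indel_rate: float = 0.05
    bystander_rate: float = 0.02
    c_true: float = 4.0
    replicates: int = 2
    reverse_fraction: float = 0.1
    pam: str = "NGG"
    flank: int = 10

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("indel_rate", "bystander_rate", "reverse_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if not self.c_true > 0:
            raise ValidationError("c_true must be positive")
        if self.coverage_mean < 1:
            raise ValidationError("coverage mean must be >= 1")


@dataclass
class SimTruth:
    """Ground truth exported alongside every simulated dataset.

    ``efficiencies`` maps (site_id, protospacer position) to the true p*;
    ``correlations`` is the planted adjacent odds ratio (shared by all pairs);
    ``indel_rate`` the per-read indel probability.  Sufficient to score every
    recovery experiment without re-running the generator.
    """

    efficiencies: dict[tuple[str, int], float]
    correlations: float
    indel_rate: float
    bystander_rate: float

    def site_marginals(self, site_id: str) -> dict[int, float]:
        return {
            pos: p for (sid, pos), p in self.efficiencies.items() if sid == site_id
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, pos, p, self.correlations, self.indel_rate)
            for (sid, pos), p in sorted(self.efficiencies.items())
        ]
        return pd.DataFrame(
            rows, columns=["site_id", "position", "p_true", "c_true", "indel_rate"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def _site_rng(seed: int, site_id: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(site_id.encode()), *extra])


def _true_efficiency(config: SimConfig, site: TargetSite, position: int) -> float:
    logit = config.baseline
    if config.window[0] <= position <= config.window[1]:
        logit += config.position_effect
    for (offset, base), w in config.motif_effects.items():
        if site.base_at(position + offset) == base:
            logit += w
    return float(expit(logit))


def simulate_library(config: SimConfig) -> tuple[list[TargetSite], SimTruth]:
    """Draw random target sites and their true per-position efficiencies."""
    sites: list[TargetSite] = []
    efficiencies: dict[tuple[str, int], float] = {}
    for i in range(config.n_sites):
        site_id = f"site{i:05d}"
        rng = _site_rng(config.seed, site_id, 0)
        proto = "".join(rng.choice(list("ACGT"), size=20))
        pam = "".join(
            rng.choice(list("ACGT")) if b == "N" else b for b in config.pam
        )
        flank_l = "".join(rng.choice(list("ACGT"), size=config.flank))
        flank_r = "".join(rng.choice(list("ACGT"), size=config.flank))
        site = TargetSite(
            site_id=site_id,
            sequence=flank_l + proto + pam + flank_r,
            protospacer_start=config.flank + 1,
            strand="forward",
        )
        sites.append(site)
        for pos in site.substrate_positions():
            efficiencies[(site_id, pos)] = _true_efficiency(config, site, pos)
    truth = SimTruth(
        efficiencies=efficiencies,
        correlations=config.c_true,
        indel_rate=config.indel_rate,
        bystander_rate=config.bystander_rate,
    )
    return sites, truth


def _draw_coverage(rng: np.random.Generator, config: SimConfig) -> int:
    # negative binomial via gamma-Poisson mixture
    shape = config.coverage_dispersion
    lam = rng.gamma(shape, config.coverage_mean / shape)
    return max(int(rng.poisson(lam)), 1)


def simulate_site_reads(
    site: TargetSite,
    truth: SimTruth,
    config: SimConfig,
    replicate: int,
) -> OutcomeTable:
    """Outcome table for one site/replicate.

    Non-indel reads get correlated C-to-G edits sampled along the adjacent
    chain with the planted odds ratio; with probability ``bystander_rate`` a
    read converts one of its unedited substrate Cs to A or T instead.
    """
    rng = _site_rng(config.seed, site.site_id, 1, replicate)
    n_total = _draw_coverage(rng, config)
    n_indel = int(rng.binomial(n_total, config.indel_rate))
    n_clean = n_total - n_indel

    subs = site.substrate_positions()
    counts: dict[EditPattern, int] = {}
    if n_indel:
        counts[EditPattern.indel()] = n_indel
    if n_clean == 0:
        return OutcomeTable(site.site_id, counts, f"rep{replicate}")

    if subs:
        margs = [truth.efficiencies[(site.site_id, p)] for p in subs]
        if all(m <= 0.0 for m in margs):
            edits = np.zeros((n_clean, len(subs)), dtype=np.int8)
        else:
            chain = build_chain(subs, margs, [truth.correlations] * (len(subs) - 1))
            edits = chain.sample(n_clean, rng)
    else:
        edits = np.zeros((n_clean, 0), dtype=np.int8)

    bystander = rng.random(n_clean) < config.bystander_rate
    bys_base = rng.random(n_clean) < 0.5  # A vs T
    bys_pick = rng.random(n_clean)

    # plain reads aggregate vectorized; rare bystander reads loop
    plain = edits[~bystander]
    if plain.size:
        rows, reps = np.unique(plain, axis=0, return_counts=True)
        for row, n in zip(rows, reps):
            pattern = EditPattern.from_positions(
                subs[j] for j in range(len(subs)) if row[j]
            )
            counts[pattern] = counts.get(pattern, 0) + int(n)
    elif plain.shape[0]:
        # no substrate C at all: every clean read is REF
        counts[EditPattern.ref()] = counts.get(EditPattern.ref(), 0) + plain.shape[0]

    for r in np.flatnonzero(bystander):
        pattern_edits = {subs[j]: "G" for j in range(len(subs)) if edits[r, j]}
        unedited = [p for p in subs if p not in pattern_edits]
        if unedited:
            p = unedited[int(bys_pick[r] * len(unedited))]
            pattern_edits[p] = "A" if bys_base[r] else "T"
        if pattern_edits:
            pattern = EditPattern.substitution(pattern_edits)
        else:
            pattern = EditPattern.ref()
        counts[pattern] = counts.get(pattern, 0) + 1
    return OutcomeTable(site.site_id, counts, f"rep{replicate}")


def simulate_reads(
    sites: list[TargetSite], truth: SimTruth, config: SimConfig
) -> list[OutcomeTable]:
    """Outcome tables for every site and replicate."""
    return [
        simulate_site_reads(site, truth, config, rep)
        for site in sites
        for rep in range(1, config.replicates + 1)
    ]


def simulate_read_sequences(
    site: TargetSite, table: OutcomeTable, config: SimConfig
) -> Iterator[tuple[str, str, str]]:
    """Expand an outcome table into raw read sequences.

    Yields ``(read_id, sequence, orientation)``; a configurable fraction of
    sites is emitted reverse-complemented to exercise strand normalization.
    Indel reads carry a 1-nt deletion at protospacer position 10.
    """
    rng = _site_rng(config.seed, site.site_id, 2)
    reverse = rng.random() < config.reverse_fraction
    k = 0
    for pattern, n in sorted(table.counts.items(), key=lambda kv: kv[0].token()):
        for _ in range(n):
            seq = list(site.sequence)
            if pattern.is_indel:
                del seq[site.seq_index(10)]
            else:
                for pos, base in pattern.edits:
                    seq[site.seq_index(pos)] = base
            read = "".join(seq)
            orientation = "forward"
            if reverse:
                read = reverse_complement(read)
                orientation = "reverse"
            yield f"{site.site_id}:{table.replicate_id}:{k}", read, orientation
            k += 1


def binomial_labels(
    truth: SimTruth, n_reads: int, seed: int
) -> dict[tuple[str, int], float]:
    """Binomial-noise efficiency labels at fixed coverage (k/N per position)."""
    rng = np.random.default_rng([seed, 0xB10])
    return {
        key: rng.binomial(n_reads, p) / n_reads
        for key, p in sorted(truth.efficiencies.items())
    }
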