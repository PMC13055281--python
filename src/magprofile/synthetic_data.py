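"""Synthetic communities with known ground truth, and the packaged
19-MAG reference fixture.

The simulator emulates the statistical structure the abundance estimator
assumes: a K-taxon community whose relative cell abundances are Dirichlet-
distributed, genome lengths log-uniform, and read counts multinomial with
per-taxon probability proportional to abundance x true genome length — the
"longer genomes attract more reads" bias the length correction removes.
Each taxon's recovered bin is imperfect: completeness and contamination are
drawn uniformly, and the *observed* bin size is the true length pushed
through the inverse of the correction formula, so applying the correction
recovers the true length exactly. A configurable fraction of reads is
emitted with sub-threshold mapping quality (MAPQ 30 vs 60) uniformly across
taxa, exercising the count filter without biasing the estimates.

All randomness flows through one seeded numpy Generator; the same seed
yields bit-identical outputs.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ValidationError
from .io_formats import Lineage, parse_lineage
from .mag_model import MagRecord, true_genome_length
from .taxonomy import CommunityProfile

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_community",
    "simulate_sites",
    "table2_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sequencing experiment.

    Defaults mirror the magnitude of the study system: 19 selected bins,
    genome lengths of a few Mb, completeness in the range the >= 90%
    selection filter admits, and single-digit contamination.
    """

    seed: int = 0
    n_taxa: int = 19
    total_reads: int = 1_000_000
    abundance_concentration: float = 1.0  # symmetric Dirichlet parameter
    genome_length_range: tuple[float, float] = (2.5e6, 8.0e6)  # bp, log-uniform
    completeness_range: tuple[float, float] = (90.0, 100.0)  # percent
    contamination_range: tuple[float, float] = (0.0, 10.0)  # percent
    frac_ambiguous: float = 0.0  # share of reads emitted below the MAPQ threshold
    lineage_pool: Sequence[Lineage] | None = None

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValidationError(f"n_taxa must be >= 1, got {self.n_taxa}")
        if self.total_reads < 0:
            raise ValidationError(f"total_reads must be >= 0, got {self.total_reads}")
        if self.abundance_concentration <= 0:
            raise ValidationError("abundance_concentration must be > 0")
        lo, hi = self.genome_length_range
        if not 0 < lo <= hi:
            raise ValidationError(f"invalid genome_length_range {self.genome_length_range}")
        lo, hi = self.completeness_range
        if not 0 < lo <= hi <= 100:
            raise ValidationError(f"invalid completeness_range {self.completeness_range}")
        lo, hi = self.contamination_range
        if not 0 <= lo <= hi < 100:
            raise ValidationError(f"invalid contamination_range {self.contamination_range}")
        if not 0 <= self.frac_ambiguous < 1:
            raise ValidationError(f"frac_ambiguous must be in [0, 1), got {self.frac_ambiguous}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-taxon truth behind one simulated community."""

    taxon_ids: tuple[str, ...]
    abundance: np.ndarray  # relative cell abundances, sum to 1
    true_length: np.ndarray  # bp
    completeness: np.ndarray  # percent
    contamination: np.ndarray  # percent
    expected_share: np.ndarray = field(init=False)  # read-sampling probabilities

    def __post_init__(self):
        weights = self.abundance * self.true_length
        object.__setattr__(self, "expected_share", weights / weights.sum())

    def expected_percentages(self) -> np.ndarray:
        """The analytic expectation of the corrected estimator's output.

        Reads are drawn with probability proportional to abundance x true
        length; dividing the counts by true length undoes the length
        weighting, so the estimator converges on the relative cell
        abundances: 100 x a_i / sum a_j.
        """
        return 100.0 * self.abundance / self.abundance.sum()

    def expected_read_share(self) -> np.ndarray:
        """The uncorrected read shares, 100 x a_i L_i / sum a_j L_j — what a
        length-naive estimator converges on instead."""
        return 100.0 * self.expected_share


def _default_lineage(i: int) -> Lineage:
    return Lineage(domain="Bacteria", phylum=f"Phylum{i + 1:02d}")


def simulate_community(
    config: SimulationConfig,
) -> tuple[GroundTruth, list[MagRecord], Iterator[tuple[str, str, int]]]:
    """Draw one community and its sequencing experiment.

    Returns the ground truth, the recovered MAG records (``mapped`` already
    holds the MAPQ >= 60 count), and a lazily generated per-read stream of
    ``(read_id, ref_id, mapq)`` in which a ``frac_ambiguous`` binomial share
    of each taxon's reads carries MAPQ 30 and the rest MAPQ 60.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_taxa
    abundance = rng.dirichlet(np.full(k, config.abundance_concentration))
    lo, hi = config.genome_length_range
    true_length = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
    completeness = rng.uniform(*config.completeness_range, size=k)
    contamination = rng.uniform(*config.contamination_range, size=k)
    taxon_ids = tuple(f"TAX{i + 1:03d}" for i in range(k))
    truth = GroundTruth(taxon_ids, abundance, true_length, completeness, contamination)

    counts = rng.multinomial(config.total_reads, truth.expected_share)
    ambiguous = rng.binomial(counts, config.frac_ambiguous)
    confident = counts - ambiguous

    if config.lineage_pool is not None:
        pool = list(config.lineage_pool)
        lineages = [pool[i] for i in rng.integers(0, len(pool), size=k)]
    else:
        lineages = [_default_lineage(i) for i in range(k)]

    # observed bin size = inverse of the length correction
    size = true_length * (1.0 + contamination / 100.0) * completeness / 100.0
    mags = [
        MagRecord(
            mag_id=taxon_ids[i],
            size=float(size[i]),
            completeness=float(completeness[i]),
            contamination=float(contamination[i]),
            lineage=lineages[i],
            mapped=int(confident[i]),
        )
        for i in range(k)
    ]

    def stream() -> Iterator[tuple[str, str, int]]:
        for i, tid in enumerate(taxon_ids):
            for j in range(int(confident[i])):
                yield (f"{tid}_r{j + 1}", tid, 60)
            for j in range(int(ambiguous[i])):
                yield (f"{tid}_a{j + 1}", tid, 30)

    return truth, mags, stream()


def simulate_sites(
    seed: int,
    n_sites: int,
    label_pool: Sequence[str] | None = None,
    concentration: float = 1.0,
):
    """Dirichlet site profiles over a shared label pool, scaled to 100.

    A low ``concentration`` produces near-disjoint sites (dissimilarities
    near 1); a high one produces near-identical sites.
    """
    from .community_compare import SiteCollection
    import pandas as pd

    if n_sites < 2:
        raise ValidationError(f"n_sites must be >= 2, got {n_sites}")
    if concentration <= 0:
        raise ValidationError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    labels = list(label_pool) if label_pool else [f"Phylum{i + 1:02d}" for i in range(12)]
    profiles = 100.0 * rng.dirichlet(np.full(len(labels), concentration), size=n_sites)
    sites = [f"site{i + 1}" for i in range(n_sites)]
    return SiteCollection(pd.DataFrame(profiles, index=sites, columns=labels))


def table2_fixture() -> tuple[list[MagRecord], CommunityProfile]:
    """The packaged 19-MAG reference table.

    Returns the MAG records (sizes, quality metrics, lineages; ``mapped``
    is 0 — the fixture predates read counts) and the printed per-MAG
    community percentages keyed by MAG id. The printed values sum to 99.99,
    not 100, and are returned exactly as printed. Lineage interior ranks
    are reconstructed from standard GTDB placements of the printed names
    (see the data file header).
    """
    mags: list[MagRecord] = []
    pcts: dict[str, float] = {}
    path = resources.files("magprofile.data").joinpath("bno_table2.tsv")
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            mags.append(
                MagRecord(
                    mag_id=row["mag_id"],
                    size=float(row["size_bp"]),
                    completeness=float(row["completeness"]),
                    contamination=float(row["contamination"]),
                    lineage=parse_lineage(row["classification"]),
                    mapped=0,
                )
            )
            pcts[row["mag_id"]] = float(row["percentage"])
    return mags, CommunityProfile(pcts)
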