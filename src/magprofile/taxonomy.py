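"""Mixed-rank aggregation of per-MAG percentages into a community profile.

Display convention: phylum level in general, class level inside designated
phyla (by default the Proteobacteria/Pseudomonadota, whose classes differ
ecologically far more than most phyla do), and domain level for Archaea.
Labels whose aggregated total falls below a cutoff (default 0.5%) are
pooled into an "Other" category; the cutoff applies to the aggregated label
total, not to individual MAGs, so two 0.3% MAGs of one phylum survive at
0.6%.

GTDB names can then be harmonized to LPSN/validly-published names through a
synonym map (:data:`DEFAULT_SYNONYMS`); renaming two labels onto one merges
them by summation, which is also how GTDB's alphabetic phylum splits
(e.g. Myxococcota_A) are folded back.

GTDB folds the historical Betaproteobacteria into Gammaproteobacteria as
the order Burkholderiales. Studies that report the three-way
Alpha/Beta/Gamma split can opt into :data:`BETAPROTEOBACTERIA_SPLIT`, a
(class, order)-keyed relabel map that is off by default because it
deliberately departs from GTDB semantics.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import ValidationError
from .io_formats import Lineage

__all__ = [
    "AggregationPolicy",
    "CommunityProfile",
    "DEFAULT_SYNONYMS",
    "BETAPROTEOBACTERIA_SPLIT",
    "display_label",
    "aggregate",
    "adjust_names",
]

#: GTDB -> LPSN phylum name harmonization, including GTDB's alphabetic
#: splits which LPSN does not recognize.
DEFAULT_SYNONYMS: dict[str, str] = {
    "Proteobacteria": "Pseudomonadota",
    "Cyanobacteria": "Cyanobacteriota",
    "Firmicutes": "Bacillota",
    "Firmicutes_A": "Bacillota",
    "Actinobacteriota": "Actinomycetota",
    "Myxococcota_A": "Myxococcota",
    "Desulfobacterota_A": "Desulfobacterota",
}

#: Optional (class, order) -> display label preset restoring the historical
#: three-way proteobacterial split.
BETAPROTEOBACTERIA_SPLIT: dict[tuple[str, str], str] = {
    ("Gammaproteobacteria", "Burkholderiales"): "Betaproteobacteria",
}


@dataclass(frozen=True)
class AggregationPolicy:
    class_split_phyla: frozenset[str] = frozenset({"Proteobacteria", "Pseudomonadota"})
    domain_collapse: frozenset[str] = frozenset({"Archaea"})
    cutoff: float = 0.5  # percent; aggregated labels below it pool into other_label
    other_label: str = "Other"
    unclassified_label: str = "Unclassified"
    class_relabel_map: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValidationError(f"cutoff must be >= 0, got {self.cutoff}")


class CommunityProfile(Mapping):
    """An ordered label -> percentage mapping.

    Ordering is descending by percentage, ties broken lexicographically,
    with the "Other" pool always last. The stored total is whatever the
    caller supplied (printed tables often sum to 99.99); use
    :meth:`normalized` to rescale to exactly 100.
    """

    def __init__(self, values, other_label: str = "Other"):
        pairs = list(values.items()) if isinstance(values, Mapping) else list(values)
        for label, pct in pairs:
            if pct < 0:
                raise ValidationError(f"negative percentage for {label!r}: {pct}")
        if len({label for label, _ in pairs}) != len(pairs):
            raise ValidationError("duplicate labels in profile")
        self._other = other_label
        pairs.sort(key=lambda kv: (kv[0] == other_label, -kv[1], kv[0]))
        self._data: dict[str, float] = dict(pairs)

    def __getitem__(self, label: str) -> float:
        return self._data[label]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}: {v:.4g}" for k, v in self._data.items())
        return f"CommunityProfile({{{inner}}})"

    @property
    def other_label(self) -> str:
        return self._other

    @property
    def total(self) -> float:
        return sum(self._data.values())

    def normalized(self, total: float = 100.0) -> "CommunityProfile":
        """Rescale so the percentages sum to ``total`` exactly."""
        current = self.total
        if current <= 0:
            raise ValidationError("cannot normalize an all-zero profile")
        return CommunityProfile(
            {k: v * total / current for k, v in self._data.items()}, self._other
        )


def display_label(lineage: Lineage, policy: AggregationPolicy | None = None) -> str:
    """Map a 7-rank lineage to its mixed-rank display label."""
    policy = policy or AggregationPolicy()
    if not lineage.domain:
        raise ValidationError(f"lineage has no domain: {lineage}")
    if lineage.domain in policy.domain_collapse:
        return lineage.domain
    if not lineage.phylum:
        return policy.unclassified_label
    if lineage.phylum in policy.class_split_phyla:
        relabelled = policy.class_relabel_map.get((lineage.class_, lineage.order))
        if relabelled is not None:
            return relabelled
        return lineage.class_ or policy.unclassified_label
    return lineage.phylum


def aggregate(
    members: Iterable[tuple[Lineage, float]], policy: AggregationPolicy | None = None
) -> CommunityProfile:
    """Sum per-MAG percentages under the mixed-rank display labels and pool
    sub-cutoff labels into the policy's "Other" category.

    ``members`` is an iterable of (lineage, percentage) pairs, e.g.
    :meth:`~magprofile.mag_model.AbundanceTable.labelled`. Total mass is
    conserved exactly (up to float addition order).
    """
    policy = policy or AggregationPolicy()
    totals: dict[str, float] = {}
    for lineage, pct in members:
        label = display_label(lineage, policy)
        totals[label] = totals.get(label, 0.0) + pct
    named = {k: v for k, v in totals.items() if v >= policy.cutoff or k == policy.other_label}
    below = [v for k, v in totals.items() if k not in named]
    if below or policy.other_label in totals:
        named[policy.other_label] = named.get(policy.other_label, 0.0) + sum(below)
    return CommunityProfile(named, policy.other_label)


def _resolve(synonyms: Mapping[str, str], label: str) -> str:
    seen = {label}
    while label in synonyms:
        label = synonyms[label]
        if label in seen:
            raise ValidationError(f"cyclic synonym map at {label!r}")
        seen.add(label)
    return label


def adjust_names(
    profile: CommunityProfile, synonym_map: Mapping[str, str] | None = None
) -> CommunityProfile:
    """Rename profile labels through a (transitively resolved) synonym map;
    labels that collide after renaming are merged by summation."""
    synonyms = DEFAULT_SYNONYMS if synonym_map is None else synonym_map
    out: dict[str, float] = {}
    for label, pct in profile.items():
        new = _resolve(synonyms, label)
        out[new] = out.get(new, 0.0) + pct
    return CommunityProfile(out, profile.other_label)
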