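"""Cross-site community comparison by Bray-Curtis dissimilarity.

Sites from different studies are compiled into one table over the union of
taxon labels (absent labels imputed as 0, exact string matching — name
harmonization is the synonym map's job, done upstream). Pairwise
dissimilarity between sites A and B is

    BC(A, B) = sum_i |p_iA - p_iB| / sum_i (p_iA + p_iB)

where p_iX is the percentage of taxon i at site X. BC is 0 for identical
profiles, 1 for disjoint supports, symmetric, and scale-invariant; it is a
semimetric (the triangle inequality is not guaranteed and not asserted).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .io_formats import SiteProfileRow
from .taxonomy import CommunityProfile

__all__ = [
    "SiteCollection",
    "DissimilarityMatrix",
    "bray_curtis",
    "build_collection",
    "dissimilarity_matrix",
    "nearest_sites",
]


def bray_curtis(profile_a: Mapping[str, float], profile_b: Mapping[str, float]) -> float:
    """Bray-Curtis dissimilarity between two label -> abundance mappings.

    Labels missing from one profile count as 0 there. Raises
    :class:`DegenerateInputError` when both profiles are all-zero.
    """
    # sorted union: summation order is then independent of argument order,
    # making symmetry exact in floating point
    labels = sorted(set(profile_a) | set(profile_b))
    num = 0.0
    den = 0.0
    for label in labels:
        a = float(profile_a.get(label, 0.0))
        b = float(profile_b.get(label, 0.0))
        if a < 0 or b < 0:
            raise ValidationError(f"negative abundance for {label!r}")
        num += abs(a - b)
        den += a + b
    if den == 0:
        raise DegenerateInputError("both profiles are all-zero; dissimilarity undefined")
    return num / den


@dataclass
class SiteCollection:
    """Named site profiles over a shared label union.

    ``table`` is a sites x labels DataFrame with no missing values.
    """

    table: pd.DataFrame

    @property
    def sites(self) -> list[str]:
        return list(self.table.index)

    @property
    def labels(self) -> list[str]:
        return list(self.table.columns)

    def profile(self, site: str) -> CommunityProfile:
        if site not in self.table.index:
            raise KeyError(site)
        row = self.table.loc[site]
        return CommunityProfile({label: float(v) for label, v in row.items()})


def build_collection(rows: Iterable[SiteProfileRow], normalize: bool = True) -> SiteCollection:
    """Pivot long-format rows into a zero-filled sites x labels table.

    With ``normalize`` each site is rescaled to sum to exactly 100 (a
    warning is logged when an input total deviates from 100 by more than
    1%). A site with total 0 is an error.
    """
    import logging

    rows = list(rows)
    if not rows:
        raise ValidationError("no site-profile rows")
    df = pd.DataFrame([(r.site, r.taxon_label, r.percentage) for r in rows],
                      columns=["site", "label", "pct"])
    table = df.pivot_table(index="site", columns="label", values="pct",
                           aggfunc="sum", fill_value=0.0)
    # preserve first-appearance order of sites and labels
    site_order = list(dict.fromkeys(r.site for r in rows))
    label_order = list(dict.fromkeys(r.taxon_label for r in rows))
    table = table.reindex(index=site_order, columns=label_order, fill_value=0.0)
    totals = table.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"site(s) with zero total abundance: {', '.join(zero.index)}")
    if normalize:
        off = totals[(totals - 100.0).abs() > 1.0]
        for site, tot in off.items():
            logging.getLogger(__name__).warning(
                "site %s sums to %.4g; renormalizing to 100", site, tot
            )
        table = table.div(totals, axis=0) * 100.0
    return SiteCollection(table)


class DissimilarityMatrix:
    """Symmetric Bray-Curtis matrix with a zero diagonal."""

    def __init__(self, sites: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sites), len(sites)):
            raise ValidationError("matrix shape does not match site count")
        if not np.array_equal(values, values.T):
            raise ValidationError("matrix must be exactly symmetric")
        if np.any(np.diag(values) != 0):
            raise ValidationError("matrix diagonal must be exactly zero")
        if np.any((values < 0) | (values > 1)):
            raise ValidationError("dissimilarities must lie in [0, 1]")
        self._sites = list(sites)
        self._index = {s: i for i, s in enumerate(self._sites)}
        if len(self._index) != len(self._sites):
            raise ValidationError("duplicate site names")
        self._values = values

    @classmethod
    def from_values(cls, sites: Sequence[str], values) -> "DissimilarityMatrix":
        return cls(sites, np.asarray(values, dtype=float))

    @property
    def sites(self) -> list[str]:
        return list(self._sites)

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self._values[self._index[a], self._index[b]])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DissimilarityMatrix)
            and self._sites == other._sites
            and np.array_equal(self._values, other._values)
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._sites, columns=self._sites)


def dissimilarity_matrix(collection: SiteCollection) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis over a site collection (>= 2 sites)."""
    sites = collection.sites
    if len(sites) < 2:
        raise ValidationError("need at least 2 sites for a dissimilarity matrix")
    n = len(sites)
    values = np.zeros((n, n))
    rows = [collection.table.loc[s].to_dict() for s in sites]
    for i in range(n):
        for j in range(i + 1, n):
            d = bray_curtis(rows[i], rows[j])
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(sites, values)


def nearest_sites(
    matrix: DissimilarityMatrix, query: str, k: int
) -> list[tuple[str, float]]:
    """The ``k`` sites closest to ``query``, ascending by dissimilarity;
    ties broken lexicographically by site name."""
    if query not in matrix.sites:
        raise KeyError(f"unknown site {query!r}")
    others = [s for s in matrix.sites if s != query]
    if not 1 <= k <= len(others):
        raise ValidationError(f"k must be in [1, {len(others)}], got {k}")
    ranked = sorted(others, key=lambda s: (matrix[query, s], s))
    return [(s, matrix[query, s]) for s in ranked[:k]]


def plot_matrix(matrix: DissimilarityMatrix, ax=None):
    """Minimal matrix heatmap (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.5 * len(matrix.sites),) * 2)
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.sites)), matrix.sites, rotation=90)
    ax.set_yticks(range(len(matrix.sites)), matrix.sites)
    ax.figure.colorbar(im, ax=ax, label="Bray-Curtis dissimilarity")
    return ax
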