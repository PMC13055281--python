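"""Readers and writers for the plain-text tables the pipeline touches.

Every external file is UTF-8, tab-separated text; lines starting with ``#``
are comments. Column matching is by case-insensitive header name with a
configurable alias map, because the upstream QC / classification tools vary
their headers across releases ("Bin Id" vs "bin_id" vs "user_genome").
Numbers are parsed with a dot decimal separator regardless of locale, and
percent fields accept a trailing ``%`` sign.

Downstream modules consume only the parsed domain rows defined here, never
raw files.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "Lineage",
    "QualityRow",
    "TaxonomyRow",
    "CountRow",
    "SiteProfileRow",
    "parse_lineage",
    "read_quality_table",
    "read_taxonomy_table",
    "read_counts",
    "read_site_profiles",
    "read_profile",
    "write_profile",
    "read_matrix",
    "write_matrix",
]

RANKS = ("domain", "phylum", "class_", "order", "family", "genus", "species")
RANK_PREFIXES = ("d", "p", "c", "o", "f", "g", "s")


class Lineage(NamedTuple):
    """A seven-rank GTDB-style taxonomy; empty strings are placeholders
    (an unresolved rank such as ``g__`` with no name)."""

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __str__(self) -> str:
        return ";".join(f"{p}__{name}" for p, name in zip(RANK_PREFIXES, self))


def parse_lineage(text: str) -> Lineage:
    """Parse ``d__...;p__...;...;s__...`` into a :class:`Lineage`.

    Rank prefixes are stripped; empty names are retained as empty strings.
    Raises :class:`FormatError` on a wrong field count or unknown prefix.
    """
    fields = [f.strip() for f in text.split(";")]
    if len(fields) != 7:
        raise FormatError(
            f"expected 7 semicolon-delimited ranks, got {len(fields)}: {text!r}"
        )
    names = []
    for expected, field in zip(RANK_PREFIXES, fields):
        prefix, sep, name = field.partition("__")
        if sep != "__" or prefix != expected:
            raise FormatError(
                f"expected rank prefix {expected}__ in field {field!r} of {text!r}"
            )
        names.append(name.strip())
    return Lineage(*names)


@dataclass(frozen=True)
class QualityRow:
    """One genome bin's QC estimates (CheckM-style), in percent."""

    bin_id: str
    completeness: float  # (0, 100]
    contamination: float  # >= 0; > 100 possible for badly merged bins


@dataclass(frozen=True)
class TaxonomyRow:
    bin_id: str
    lineage: Lineage


@dataclass(frozen=True)
class CountRow:
    """Mapped-read count for one reference (a MAG or a contig)."""

    ref_id: str
    ref_length: int | None
    mapped: int


@dataclass(frozen=True)
class SiteProfileRow:
    """One (site, taxon) percentage from a compiled cross-study table."""

    site: str
    taxon_label: str
    percentage: float


# Default header aliases, all matched case-insensitively.
QUALITY_ALIASES: dict[str, tuple[str, ...]] = {
    "bin_id": ("bin_id", "bin id", "genome", "user_genome", "mag", "mag_id", "name"),
    "completeness": ("completeness", "completeness (%)", "comp"),
    "contamination": ("contamination", "contamination (%)", "cont"),
}
TAXONOMY_ALIASES: dict[str, tuple[str, ...]] = {
    "bin_id": ("bin_id", "bin id", "genome", "user_genome", "mag", "mag_id", "name"),
    "lineage": ("classification", "lineage", "taxonomy", "gtdb taxonomy", "gtdb_taxonomy"),
}
SITE_ALIASES: dict[str, tuple[str, ...]] = {
    "site": ("site", "study", "sample"),
    "taxon_label": ("taxon", "taxon_label", "label", "phylum", "group"),
    "percentage": ("percentage", "percent", "abundance", "pct"),
}


def _lines(path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _resolve_columns(
    header: Sequence[str],
    aliases: Mapping[str, tuple[str, ...]],
    overrides: Mapping[str, str] | None,
) -> dict[str, int]:
    """Map canonical field name -> column index, case-insensitively."""
    lowered = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    for field, names in aliases.items():
        candidates = (overrides[field].lower(),) if overrides and field in overrides else tuple(
            n.lower() for n in names
        )
        for cand in candidates:
            if cand in lowered:
                out[field] = lowered.index(cand)
                break
        else:
            raise FormatError(
                f"missing mandatory column {field!r} "
                f"(accepted headers: {', '.join(candidates)}; got: {', '.join(header)})"
            )
    return out


def _parse_percent(text: str, lineno: int, field: str) -> float:
    text = text.strip()
    if text.endswith("%"):
        text = text[:-1].strip()
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"non-numeric {field} value {text!r}", lineno) from None


def _parse_count(text: str, lineno: int, field: str) -> int:
    try:
        value = int(text.strip())
    except ValueError:
        raise ParseError(f"non-integer {field} value {text!r}", lineno) from None
    if value < 0:
        raise ValidationError(f"line {lineno}: negative {field} {value}")
    return value


def read_quality_table(path, columns: Mapping[str, str] | None = None) -> list[QualityRow]:
    """Read a CheckM-style quality table (bin id, completeness %, contamination %).

    ``columns`` overrides the header name used for any canonical field,
    e.g. ``{"bin_id": "Bin Id"}``. Row order is preserved.
    """
    rows: list[QualityRow] = []
    seen: set[str] = set()
    idx: dict[str, int] | None = None
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if idx is None:
            idx = _resolve_columns(fields, QUALITY_ALIASES, columns)
            continue
        bin_id = fields[idx["bin_id"]].strip()
        if not bin_id:
            raise ValidationError(f"line {lineno}: empty bin id")
        if bin_id in seen:
            raise ValidationError(f"line {lineno}: duplicate bin id {bin_id!r}")
        seen.add(bin_id)
        completeness = _parse_percent(fields[idx["completeness"]], lineno, "completeness")
        contamination = _parse_percent(fields[idx["contamination"]], lineno, "contamination")
        if completeness <= 0:
            raise ValidationError(f"line {lineno}: completeness must be > 0, got {completeness}")
        if contamination < 0:
            raise ValidationError(f"line {lineno}: contamination must be >= 0, got {contamination}")
        rows.append(QualityRow(bin_id, completeness, contamination))
    if idx is None:
        raise FormatError(f"{path}: empty file, no header found")
    return rows


def read_taxonomy_table(path, columns: Mapping[str, str] | None = None) -> list[TaxonomyRow]:
    """Read a GTDB-Tk-style classification summary (genome id, 7-rank lineage)."""
    rows: list[TaxonomyRow] = []
    seen: set[str] = set()
    idx: dict[str, int] | None = None
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if idx is None:
            idx = _resolve_columns(fields, TAXONOMY_ALIASES, columns)
            continue
        bin_id = fields[idx["bin_id"]].strip()
        if bin_id in seen:
            raise ValidationError(f"line {lineno}: duplicate bin id {bin_id!r}")
        seen.add(bin_id)
        try:
            lineage = parse_lineage(fields[idx["lineage"]])
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        rows.append(TaxonomyRow(bin_id, lineage))
    if idx is None:
        raise FormatError(f"{path}: empty file, no header found")
    return rows


def read_counts(path, dialect: str = "aggregated") -> list[CountRow]:
    """Read mapped-read counts.

    ``aggregated``: two headerless columns (ref id, mapped count).
    ``idxstats``: the four-column per-reference summary of alignment
    toolchains (ref, length, mapped, unmapped); the ``*`` unmapped-summary
    line is dropped and the unmapped column ignored.
    """
    if dialect not in ("aggregated", "idxstats"):
        raise FormatError(f"unknown counts dialect {dialect!r}")
    rows: list[CountRow] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if dialect == "idxstats":
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: idxstats needs 4 columns, got {len(fields)}")
            if fields[0] == "*":
                continue
            rows.append(
                CountRow(
                    fields[0].strip(),
                    _parse_count(fields[1], lineno, "length"),
                    _parse_count(fields[2], lineno, "mapped"),
                )
            )
        else:
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: aggregated needs 2 columns, got {len(fields)}")
            rows.append(CountRow(fields[0].strip(), None, _parse_count(fields[1], lineno, "mapped")))
    return rows


def read_site_profiles(path, columns: Mapping[str, str] | None = None) -> list[SiteProfileRow]:
    """Read a long-format cross-study table (site, taxon label, percentage)."""
    rows: list[SiteProfileRow] = []
    seen: set[tuple[str, str]] = set()
    idx: dict[str, int] | None = None
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if idx is None:
            idx = _resolve_columns(fields, SITE_ALIASES, columns)
            continue
        site = fields[idx["site"]].strip()
        label = fields[idx["taxon_label"]].strip()
        pct = _parse_percent(fields[idx["percentage"]], lineno, "percentage")
        if pct < 0:
            raise ValidationError(f"line {lineno}: negative percentage {pct}")
        key = (site, label)
        if key in seen:
            raise ValidationError(f"line {lineno}: duplicate (site, taxon) pair {key!r}")
        seen.add(key)
        rows.append(SiteProfileRow(site, label, pct))
    if idx is None:
        raise FormatError(f"{path}: empty file, no header found")
    return rows


def _fmt(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def write_profile(profile, path, precision: int = 2) -> None:
    """Write a community profile as a two-column TSV, labels sorted
    lexicographically for deterministic output."""
    buf = io.StringIO()
    buf.write("label\tpercentage\n")
    for label in sorted(profile):
        buf.write(f"{label}\t{_fmt(profile[label], precision)}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_profile(path):
    """Read a profile written by :func:`write_profile`."""
    from .taxonomy import CommunityProfile

    idx = None
    pairs: list[tuple[str, float]] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if idx is None:
            idx = True  # header
            continue
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: profile rows need 2 columns")
        pairs.append((fields[0], _parse_percent(fields[1], lineno, "percentage")))
    return CommunityProfile(pairs)


def write_matrix(matrix, path, precision: int = 2) -> None:
    """Write a dissimilarity matrix as a full square TSV with a site-name
    header row and column."""
    sites = list(matrix.sites)
    buf = io.StringIO()
    buf.write("site\t" + "\t".join(sites) + "\n")
    for a in sites:
        buf.write(a + "\t" + "\t".join(_fmt(matrix[a, b], precision) for b in sites) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`."""
    from .community_compare import DissimilarityMatrix

    sites: list[str] | None = None
    values: list[list[float]] = []
    row_names: list[str] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if sites is None:
            sites = [f.strip() for f in fields[1:]]
            continue
        row_names.append(fields[0].strip())
        values.append([_parse_percent(f, lineno, "dissimilarity") for f in fields[1:]])
    if sites is None:
        raise FormatError(f"{path}: empty file, no header found")
    if row_names != sites:
        raise FormatError(f"{path}: matrix row names do not match header columns")
    return DissimilarityMatrix.from_values(sites, values)
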