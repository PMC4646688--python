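"""Synteny-based locus reconstruction, geometry and to-scale maps.

Protease loci are identified in genome annotations not by the protease
genes themselves (whose names vary wildly between assemblies) but by
conserved non-protease *bordering marker genes*: e.g. the mammalian
chymase locus sits between RIPK3/NYNRIN/CBLN3/SDR39U1 on one side and
STXBP6 on the other.  Given gene records and a locus definition this
module finds the locus (the run of genes between the innermost matched
left and right markers), computes gene sizes and intergenic distances,
flags marker strand inversions against a reference orientation, and
renders base-pair-proportional SVG maps in which protease genes are
drawn at double height.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted on read and write, BED passes through unchanged.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

from gasp.errors import AnnotationParseError, InputError

logger = logging.getLogger(__name__)

CATEGORIES = {"protease", "marker", "other"}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, 0-based half-open coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    category: str = "other"
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"{self.gene_id}: require 0 <= start < end, got [{self.start},{self.end})")
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.category not in CATEGORIES:
            raise InputError(f"{self.gene_id}: unknown category {self.category!r}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LocusDefinition:
    """Marker genes delimiting a locus; at least one list non-empty."""

    name: str
    left_markers: tuple[str, ...] = ()
    right_markers: tuple[str, ...] = ()
    center_markers: tuple[str, ...] = ()
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.left_markers or self.right_markers or self.center_markers):
            raise InputError(f"locus {self.name!r}: all marker lists empty")

    def canonical(self, name: str) -> str:
        """Alias-resolved, upper-cased marker name."""
        up = name.upper()
        return {k.upper(): v.upper() for k, v in self.aliases.items()}.get(up, up)

    def side_of(self, name: str) -> str | None:
        canon = self.canonical(name)
        if canon in {self.canonical(m) for m in self.left_markers}:
            return "left"
        if canon in {self.canonical(m) for m in self.right_markers}:
            return "right"
        if canon in {self.canonical(m) for m in self.center_markers}:
            return "center"
        return None


@dataclass
class LocusMap:
    """An identified locus: ordered genes plus derived geometry."""

    definition_name: str
    contig: str
    genes: list[GeneRecord]
    split: bool = False
    inversion_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def intergenic_distances(self) -> list[int]:
        return [
            max(0, b.start - a.end)
            for a, b in zip(self.genes, self.genes[1:])
        ]

    @property
    def marker_count(self) -> int:
        return sum(1 for g in self.genes if g.category == "marker")

    @property
    def span(self) -> int:
        if not self.genes:
            return 0
        return self.genes[-1].end - self.genes[0].start


def load_locus_definitions(path: str | Path | None = None) -> dict[str, LocusDefinition]:
    """Load locus definitions + alias table (packaged defaults when None)."""
    if path is None:
        text = (resources.files("gasp") / "data" / "locus_definitions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    aliases = raw.get("aliases", {}) or {}
    out: dict[str, LocusDefinition] = {}
    for name, spec in raw.get("definitions", {}).items():
        left = tuple(spec.get("left_markers", []) or [])
        right = tuple(spec.get("right_markers", []) or [])
        center = tuple(spec.get("center_markers", []) or [])
        if not (left or right or center):
            logger.warning("locus definition %r has no markers; skipped", name)
            continue
        out[name] = LocusDefinition(
            name=name,
            left_markers=left,
            right_markers=right,
            center_markers=center,
            aliases=aliases,
        )
    return out


# ---------------------------------------------------------------------------
# Annotation reading


def _gene_id_from_gff(feature) -> str:
    for key in ("Name", "gene_name", "ID", "gene_id"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return f"{feature.seqid}:{feature.start}-{feature.end}"


def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneRecord]:
    """Read gene records from GFF3 or BED.

    ``fmt`` is ``"gff3"`` or ``"bed"``; inferred from the suffix when
    omitted.  Coordinates are normalised to 0-based half-open (GFF3 is
    1-based inclusive on disk).  Malformed lines and records whose end
    does not exceed their start are rejected and logged with their line
    number; a file yielding no valid record raises
    :class:`AnnotationParseError`.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff3"
    fmt = fmt.lower()
    if fmt not in {"gff3", "bed"}:
        raise InputError(f"unknown annotation format {fmt!r}")

    records: list[GeneRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if fmt == "gff3":
                    rec = _parse_gff3_line(line, feature_types)
                else:
                    rec = _parse_bed_line(line)
            except Exception as exc:
                n_rejected += 1
                logger.warning("%s line %d rejected: %s", path.name, lineno, exc)
                continue
            if rec is not None:
                records.append(rec)
    if not records:
        raise AnnotationParseError(f"{path}: no valid records ({n_rejected} rejected)")
    return records


def _parse_gff3_line(line: str, feature_types: Sequence[str]) -> GeneRecord | None:
    if len(line.split("\t")) != 9:
        raise InputError(f"expected 9 tab-separated fields, got {len(line.split(chr(9)))}")
    feature = feature_from_line(line)
    if feature_types and feature.featuretype not in feature_types:
        return None
    start = int(feature.start) - 1  # GFF3 1-based inclusive -> 0-based half-open
    end = int(feature.end)
    if end <= start:
        raise InputError(f"non-positive span [{start},{end})")
    strand = feature.strand if feature.strand in {"+", "-"} else "+"
    attrs = {k: v[0] if len(v) == 1 else list(v) for k, v in feature.attributes.items()}
    category = attrs.get("category", "other")
    if category not in CATEGORIES:
        category = "other"
    return GeneRecord(
        gene_id=_gene_id_from_gff(feature),
        contig=feature.seqid,
        start=start,
        end=end,
        strand=strand,
        category=category,
        attributes=attrs,
    )


def _parse_bed_line(line: str) -> GeneRecord:
    fields = line.split("\t")
    if len(fields) < 3:
        raise InputError(f"BED line has {len(fields)} fields, need >= 3")
    contig, start_s, end_s = fields[0], fields[1], fields[2]
    start, end = int(start_s), int(end_s)
    if end <= start:
        raise InputError(f"non-positive span [{start},{end})")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{contig}:{start}-{end}"
    strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "+"
    return GeneRecord(
        gene_id=name, contig=contig, start=start, end=end, strand=strand, category="other"
    )


def write_gff3(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = dict(rec.attributes)
            attrs.setdefault("ID", rec.gene_id)
            attrs.setdefault("Name", rec.gene_id)
            attrs["category"] = rec.category
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{rec.contig}\tgasp\tgene\t{rec.start + 1}\t{rec.end}\t.\t{rec.strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# Locus identification


def _categorise(genes: Sequence[GeneRecord], definition: LocusDefinition) -> list[GeneRecord]:
    """Mark genes matching the definition's markers as category 'marker'."""
    out = []
    for g in genes:
        if definition.side_of(g.gene_id) is not None and g.category != "marker":
            out.append(replace(g, category="marker"))
        else:
            out.append(g)
    return out


def identify_locus(
    genes: Sequence[GeneRecord],
    definition: LocusDefinition,
) -> list[LocusMap]:
    """Find candidate loci for a marker definition.

    Returns candidate :class:`LocusMap` objects ranked by matched-marker
    count (then by contig/position for determinism).  For left/right
    definitions a candidate is the run of genes between the *innermost*
    matched left and right markers on one contig, markers inclusive.
    When the two sides resolve only to different contigs the candidates
    are partial maps flagged ``split=True`` (marker to contig end).  For
    centre-only definitions the candidate spans all matched centre
    markers, extended outward over contiguous protease genes.

    No marker matched at all returns an empty list with a logged
    diagnostic, not an exception.
    """
    genes = _categorise(genes, definition)
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start, g.end, g.gene_id)):
        by_contig.setdefault(g.contig, []).append(g)

    candidates: list[LocusMap] = []
    any_left = any_right = False
    for contig, cgenes in sorted(by_contig.items()):
        sides = [definition.side_of(g.gene_id) if g.category == "marker" else None for g in cgenes]
        left_idx = [i for i, s in enumerate(sides) if s == "left"]
        right_idx = [i for i, s in enumerate(sides) if s == "right"]
        center_idx = [i for i, s in enumerate(sides) if s == "center"]
        any_left |= bool(left_idx)
        any_right |= bool(right_idx)

        if left_idx and right_idx:
            # innermost pair: the left/right marker pair with the
            # smallest gap between them (orientation-agnostic);
            # deterministic tie-break on position
            pairs = [sorted((l, r)) for l in left_idx for r in right_idx if l != r]
            if not pairs:  # one gene matched on both sides
                pairs = [[min(left_idx), max(right_idx)]]
            lo, hi = min(pairs, key=lambda p: (p[1] - p[0], p[0]))
            candidates.append(
                LocusMap(definition.name, contig, cgenes[lo : hi + 1], split=False)
            )
        elif center_idx:
            lo, hi = min(center_idx), max(center_idx)
            while lo > 0 and cgenes[lo - 1].category == "protease":
                lo -= 1
            while hi + 1 < len(cgenes) and cgenes[hi + 1].category == "protease":
                hi += 1
            candidates.append(
                LocusMap(definition.name, contig, cgenes[lo : hi + 1], split=False)
            )
        elif left_idx:
            lo = max(left_idx)
            candidates.append(LocusMap(definition.name, contig, cgenes[lo:], split=True))
        elif right_idx:
            hi = min(right_idx)
            candidates.append(LocusMap(definition.name, contig, cgenes[: hi + 1], split=True))

    if not candidates:
        logger.warning(
            "locus %r: no marker gene matched among %d genes", definition.name, len(genes)
        )
        return []
    # a split is only real when the two sides never co-occur on a contig
    has_full = any(not c.split for c in candidates)
    if has_full:
        candidates = [c for c in candidates if not c.split]
    candidates.sort(key=lambda c: (-c.marker_count, c.contig, c.genes[0].start if c.genes else 0))
    return candidates


# ---------------------------------------------------------------------------
# Geometry


@dataclass(frozen=True)
class LocusGeometry:
    """Gene sizes and intergenic gaps of one locus."""

    gene_ids: tuple[str, ...]
    sizes: tuple[int, ...]
    distances: tuple[int, ...]  # gap before gene i+1; clamped at 0
    overlap_flags: tuple[bool, ...]  # True where consecutive genes overlap
    span: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, (gid, size) in enumerate(zip(self.gene_ids, self.sizes)):
            rows.append(
                {
                    "gene_id": gid,
                    "size": size,
                    "gap_to_next": self.distances[i] if i < len(self.distances) else pd.NA,
                    "overlaps_next": self.overlap_flags[i] if i < len(self.overlap_flags) else pd.NA,
                }
            )
        return pd.DataFrame(rows, columns=["gene_id", "size", "gap_to_next", "overlaps_next"])


def compute_geometry(locus: LocusMap) -> LocusGeometry:
    """Gene sizes and clamped intergenic distances for a locus map.

    Overlapping consecutive genes get distance 0 plus an overlap flag.
    """
    if not locus.genes:
        raise InputError("empty locus")
    sizes = tuple(g.size for g in locus.genes)
    distances = []
    overlaps = []
    for a, b in zip(locus.genes, locus.genes[1:]):
        gap = b.start - a.end
        distances.append(max(0, gap))
        overlaps.append(gap < 0)
    return LocusGeometry(
        gene_ids=tuple(g.gene_id for g in locus.genes),
        sizes=sizes,
        distances=tuple(distances),
        overlap_flags=tuple(overlaps),
        span=locus.span,
    )


def detect_inversion(
    locus: LocusMap,
    reference_orientation: Mapping[str, str],
) -> dict[str, bool]:
    """Flag markers whose strand differs from a reference orientation.

    Markers absent from ``reference_orientation`` are skipped with a
    warning.  The flags are also stored on ``locus.inversion_flags``.
    """
    ref = {k.upper(): v for k, v in reference_orientation.items()}
    if not any(g.category == "marker" and g.gene_id.upper() in ref for g in locus.genes):
        raise InputError("no reference orientation provided for any marker in the locus")
    flags: dict[str, bool] = {}
    for g in locus.genes:
        if g.category != "marker":
            continue
        expected = ref.get(g.gene_id.upper())
        if expected is None:
            logger.warning("marker %s has no reference orientation; skipped", g.gene_id)
            continue
        flags[g.gene_id] = g.strand != expected
    locus.inversion_flags = flags
    return flags


# ---------------------------------------------------------------------------
# SVG rendering


@dataclass(frozen=True)
class MapStyle:
    """Rendering style for to-scale locus maps.

    ``px_per_bp`` sets the horizontal scale; marker/other genes are
    ``gene_height`` px tall and protease genes exactly twice that.
    """

    px_per_bp: float = 0.001
    gene_height: float = 12.0
    row_gap: float = 30.0
    margin: float = 20.0
    arrow_px: float = 5.0
    colors: Mapping[str, str] = field(
        default_factory=lambda: {"protease": "#3b6fb6", "marker": "#777777", "other": "#bbbbbb"}
    )
    font_size: float = 9.0


def _fmt(x: float) -> str:
    # deterministic compact float formatting
    if x == int(x):
        return str(int(x))
    return f"{x:.6g}"


def _gene_glyph(gene: GeneRecord, x0: float, y_base: float, style: MapStyle) -> ET.Element:
    h = style.gene_height * (2.0 if gene.category == "protease" else 1.0)
    w = gene.size * style.px_per_bp
    x = style.margin + (gene.start - x0) * style.px_per_bp
    y = y_base - h
    arrow = min(style.arrow_px, w / 2.0)
    if gene.strand == "+":
        pts = [
            (x, y),
            (x + w - arrow, y),
            (x + w, y + h / 2.0),
            (x + w - arrow, y + h),
            (x, y + h),
        ]
    else:
        pts = [
            (x + w, y),
            (x + arrow, y),
            (x, y + h / 2.0),
            (x + arrow, y + h),
            (x + w, y + h),
        ]
    poly = ET.Element(
        "polygon",
        {
            "points": " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in pts),
            "fill": style.colors.get(gene.category, "#bbbbbb"),
            "stroke": "#222222",
            "stroke-width": "0.5",
        },
    )
    title = ET.SubElement(poly, "title")
    title.text = f"{gene.gene_id} [{gene.start},{gene.end}) {gene.strand} ({gene.category})"
    return poly


def render_scale_map(
    loci: Sequence[LocusMap],
    style: MapStyle | None = None,
) -> str:
    """Render loci as a to-scale SVG document (one row per locus).

    Glyph widths are proportional to gene length (``px_per_bp``),
    protease glyphs are exactly twice the height of marker/other
    glyphs, and strand is shown by the arrowed end of each glyph.
    Output is deterministic for fixed input and style.  Empty or
    zero-span loci are skipped with a warning.
    """
    style = style or MapStyle()
    drawable = []
    for locus in loci:
        if not locus.genes or locus.span <= 0:
            logger.warning("locus %r skipped: zero length", locus.definition_name)
            continue
        drawable.append(locus)
    if not drawable:
        raise InputError("no drawable loci")

    row_h = 2 * style.gene_height + style.row_gap
    width = (
        2 * style.margin
        + max(l.span for l in drawable) * style.px_per_bp
    )
    height = style.margin + row_h * len(drawable) + style.margin
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": _fmt(math.ceil(width)),
            "height": _fmt(math.ceil(height)),
            "version": "1.1",
        },
    )
    for row, locus in enumerate(drawable):
        y_base = style.margin + row_h * (row + 1) - style.row_gap / 2.0
        x0 = locus.genes[0].start
        label = ET.SubElement(
            svg,
            "text",
            {
                "x": _fmt(style.margin),
                "y": _fmt(y_base - 2 * style.gene_height - 4),
                "font-size": _fmt(style.font_size),
                "font-family": "sans-serif",
            },
        )
        label.text = f"{locus.definition_name} | {locus.contig}" + (
            " (split)" if locus.split else ""
        )
        baseline = ET.SubElement(
            svg,
            "line",
            {
                "x1": _fmt(style.margin),
                "y1": _fmt(y_base),
                "x2": _fmt(style.margin + locus.span * style.px_per_bp),
                "y2": _fmt(y_base),
                "stroke": "#444444",
                "stroke-width": "1",
            },
        )
        for gene in locus.genes:
            svg.append(_gene_glyph(gene, x0, y_base, style))
    return ET.tostring(svg, encoding="unicode")
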