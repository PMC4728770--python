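"""User-facing artifacts: colored sequence graphics, raw tables, PyMOL scripts.

A :class:`ColorDocument` is the renderer-independent description of the
output: one block per chain holding the color-annotated sequence, followed by
one entry per bound compound, plus the frame parameters needed to decode
colors back to coordinates.  From it four artifacts are produced:

* ``render_svg``  — a colorized FASTA-like sequence figure (SVG 1.1),
* ``render_raster`` — the same figure as a PNG, drawn from the same layout,
* ``write_raw``   — a TSV with per-entity integer and continuous channels and
  the frame header, self-sufficient for coordinate reconstruction,
* ``write_pml``   — a PyMOL script painting the original structure residue by
  residue with its embedding color.

All renderers are pure functions of (document, style): identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .embedding import Embedding, EmbeddingFrame, RGBColor, rgb_to_point
from .representative import EntityRef
from .structure_io import Structure

__all__ = [
    "ColorDocument",
    "ChainBlock",
    "ResidueEntry",
    "CompoundEntry",
    "RenderArtifact",
    "Style",
    "RasterBackendMissingError",
    "build_document",
    "render_svg",
    "render_raster",
    "write_raw",
    "write_pml",
    "load_raw",
    "decode_raw",
]

_NA = "NA"
_BLANK_ICODE = "."  # placeholder for an empty insertion code in text output


class RasterBackendMissingError(RuntimeError):
    """No raster backend is importable; the SVG path remains usable."""


@dataclass(frozen=True)
class ResidueEntry:
    letter: str
    author_number: int
    insertion_code: str
    color: RGBColor | None


@dataclass(frozen=True)
class ChainBlock:
    chain_id: str
    header: str
    entries: tuple[ResidueEntry, ...]


@dataclass(frozen=True)
class CompoundEntry:
    name3: str
    chain_id: str
    author_number: int
    insertion_code: str
    color: RGBColor | None


@dataclass(frozen=True)
class ColorDocument:
    structure_id: str
    blocks: tuple[ChainBlock, ...]
    compounds: tuple[CompoundEntry, ...]
    frame: EmbeddingFrame
    mode_name: str


@dataclass(frozen=True)
class RenderArtifact:
    format: str  # svg | raster | raw_tsv | pml
    payload: bytes
    filename: str


@dataclass(frozen=True)
class Style:
    """Layout configuration shared by the SVG and raster renderers."""

    wrap: int = 60          # residues per sequence row
    tile_w: int = 12        # px
    tile_h: int = 18        # px
    margin: int = 12
    header_h: int = 22
    ruler_h: int = 12
    row_gap: int = 2
    block_gap: int = 10
    font_size: int = 12
    small_font: int = 9
    scale: float = 1.0      # raster only


def build_document(structure: Structure, embedding: Embedding) -> ColorDocument:
    """Assemble the ordered, color-annotated document for one structure.

    Raises ``ValueError`` if the embedding was not produced from this
    structure (an entity is missing from the color map).
    """
    blocks = []
    for chain in structure.chains:
        entries = []
        for residue in chain.residues:
            ref = EntityRef(
                residue.chain_id,
                residue.author_number,
                residue.insertion_code,
                residue.name3,
                False,
            )
            if ref not in embedding.colors:
                raise ValueError(
                    f"embedding does not cover residue {ref}: "
                    "structure/embedding mismatch"
                )
            entries.append(
                ResidueEntry(
                    residue.letter,
                    residue.author_number,
                    residue.insertion_code,
                    embedding.colors[ref],
                )
            )
        header = f">{structure.identifier}_{chain.chain_id} ({len(entries)} residues)"
        blocks.append(ChainBlock(chain.chain_id, header, tuple(entries)))

    compounds = []
    for compound in structure.compounds:
        ref = EntityRef(
            compound.chain_id,
            compound.author_number,
            compound.insertion_code,
            compound.name3,
            True,
        )
        if ref not in embedding.colors:
            raise ValueError(
                f"embedding does not cover compound {ref}: "
                "structure/embedding mismatch"
            )
        compounds.append(
            CompoundEntry(
                compound.name3,
                compound.chain_id,
                compound.author_number,
                compound.insertion_code,
                embedding.colors[ref],
            )
        )

    return ColorDocument(
        structure_id=structure.identifier,
        blocks=tuple(blocks),
        compounds=tuple(compounds),
        frame=embedding.frame,
        mode_name=embedding.mode.value,
    )


# ---------------------------------------------------------------------------
# shared layout: a flat list of drawing primitives consumed by both renderers

@dataclass(frozen=True)
class _Rect:
    x: float
    y: float
    w: float
    h: float
    fill: tuple[int, int, int] | None  # None -> hatched "unmapped" tile


@dataclass(frozen=True)
class _Text:
    x: float
    y: float  # baseline
    s: str
    size: int
    anchor: str = "start"  # start | middle | end
    color: tuple[int, int, int] = (0, 0, 0)


@dataclass
class _Layout:
    width: float = 0.0
    height: float = 0.0
    rects: list[_Rect] = field(default_factory=list)
    texts: list[_Text] = field(default_factory=list)


def _glyph_color(color: RGBColor) -> tuple[int, int, int]:
    # black on light tiles, white on dark ones
    return (0, 0, 0) if color.luminance > 0.5 else (255, 255, 255)


def _layout(doc: ColorDocument, style: Style) -> _Layout:
    lay = _Layout()
    m = style.margin
    y = float(m)
    for block in doc.blocks:
        lay.texts.append(_Text(m, y + style.font_size, block.header, style.font_size))
        y += style.header_h
        for start in range(0, len(block.entries), style.wrap):
            row = block.entries[start : start + style.wrap]
            # ruler: position labels every 10 residues, right-aligned on the tile
            for offset in range(len(row)):
                pos = start + offset + 1
                if pos % 10 == 0:
                    x_right = m + (offset + 1) * style.tile_w
                    lay.texts.append(
                        _Text(x_right, y + style.small_font, str(pos),
                              style.small_font, anchor="end", color=(90, 90, 90))
                    )
            y += style.ruler_h
            for offset, entry in enumerate(row):
                x = m + offset * style.tile_w
                fill = entry.color.integer if entry.color is not None else None
                lay.rects.append(_Rect(x, y, style.tile_w, style.tile_h, fill))
                glyph_color = (
                    _glyph_color(entry.color) if entry.color is not None else (90, 90, 90)
                )
                lay.texts.append(
                    _Text(x + style.tile_w / 2, y + style.tile_h - 4, entry.letter,
                          style.font_size, anchor="middle", color=glyph_color)
                )
            y += style.tile_h + style.row_gap
        y += style.block_gap

    if doc.compounds:
        lay.texts.append(
            _Text(m, y + style.font_size,
                  f"compounds ({len(doc.compounds)})", style.font_size)
        )
        y += style.header_h
        for comp in doc.compounds:
            fill = comp.color.integer if comp.color is not None else None
            lay.rects.append(_Rect(m, y, 2 * style.tile_w, style.tile_h, fill))
            icode = comp.insertion_code or ""
            rgb = (
                "RGB({},{},{})".format(*comp.color.integer)
                if comp.color is not None
                else _NA
            )
            label = f"{comp.name3} {comp.chain_id}/{comp.author_number}{icode} {rgb}"
            lay.texts.append(
                _Text(m + 2 * style.tile_w + 6, y + style.tile_h - 4,
                      label, style.font_size)
            )
            y += style.tile_h + style.row_gap
        y += style.block_gap

    frame = doc.frame
    legend = (
        f"mode={doc.mode_name}  s_max={frame.s_max_effective:.2f} A"
        f"{' (floored)' if frame.floor_applied else ''}"
        "  centroid=({:.2f}, {:.2f}, {:.2f})".format(*frame.centroid)
    )
    lay.texts.append(_Text(m, y + style.small_font, legend, style.small_font,
                           color=(60, 60, 60)))
    y += style.header_h

    lay.width = 2 * m + style.wrap * style.tile_w
    lay.height = y + m
    return lay


# ---------------------------------------------------------------------------
# SVG

_HATCH_DEFS = (
    '<defs><pattern id="unmapped" width="6" height="6" '
    'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
    '<rect width="6" height="6" fill="#ffffff"/>'
    '<line x1="0" y1="0" x2="0" y2="6" stroke="#bbbbbb" stroke-width="2"/>'
    "</pattern></defs>"
)

_ANCHOR_SVG = {"start": "start", "middle": "middle", "end": "end"}


def _fmt(value: float) -> str:
    text = f"{value:.2f}"
    return text[:-3] if text.endswith(".00") else text


def render_svg(doc: ColorDocument, style: Style = Style()) -> RenderArtifact:
    """Render the document to a deterministic standalone SVG."""
    lay = _layout(doc, style)
    out = io.StringIO()
    out.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    out.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(lay.width)}" height="{_fmt(lay.height)}" '
        f'viewBox="0 0 {_fmt(lay.width)} {_fmt(lay.height)}">\n'
    )
    out.write(_HATCH_DEFS + "\n")
    out.write(
        f'<rect x="0" y="0" width="{_fmt(lay.width)}" height="{_fmt(lay.height)}" '
        'fill="#ffffff"/>\n'
    )
    for rect in lay.rects:
        fill = (
            "#{:02x}{:02x}{:02x}".format(*rect.fill)
            if rect.fill is not None
            else "url(#unmapped)"
        )
        out.write(
            f'<rect x="{_fmt(rect.x)}" y="{_fmt(rect.y)}" width="{_fmt(rect.w)}" '
            f'height="{_fmt(rect.h)}" fill="{fill}"/>\n'
        )
    for text in lay.texts:
        color = "#{:02x}{:02x}{:02x}".format(*text.color)
        escaped = (
            text.s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        )
        out.write(
            f'<text x="{_fmt(text.x)}" y="{_fmt(text.y)}" '
            f'font-family="DejaVu Sans Mono, monospace" font-size="{text.size}" '
            f'text-anchor="{_ANCHOR_SVG[text.anchor]}" fill="{color}">'
            f"{escaped}</text>\n"
        )
    out.write("</svg>\n")
    return RenderArtifact(
        format="svg",
        payload=out.getvalue().encode("utf-8"),
        filename=f"{doc.structure_id}.svg",
    )


# ---------------------------------------------------------------------------
# raster (PNG)

def render_raster(doc: ColorDocument, style: Style = Style()) -> RenderArtifact:
    """Render the document to a PNG at ``style.scale`` pixels per SVG unit.

    Drawn from the same layout as the SVG, so tile geometry matches exactly;
    pixel dimensions are the SVG viewbox multiplied by the scale.
    """
    try:
        from PIL import Image, ImageDraw, ImageFont
    except ImportError as exc:  # pragma: no cover
        raise RasterBackendMissingError(
            "raster backend missing: Pillow is not importable; "
            "SVG output remains available"
        ) from exc

    lay = _layout(doc, style)
    scale = style.scale
    size = (int(round(lay.width * scale)), int(round(lay.height * scale)))
    image = Image.new("RGB", size, (255, 255, 255))
    draw = ImageDraw.Draw(image)

    for rect in lay.rects:
        box = (
            int(round(rect.x * scale)),
            int(round(rect.y * scale)),
            int(round((rect.x + rect.w) * scale)) - 1,
            int(round((rect.y + rect.h) * scale)) - 1,
        )
        if rect.fill is not None:
            draw.rectangle(box, fill=rect.fill)
        else:
            draw.rectangle(box, fill=(255, 255, 255), outline=(187, 187, 187))
            draw.line((box[0], box[3], box[2], box[1]), fill=(187, 187, 187))

    fonts: dict[int, object] = {}

    def font_for(points: int):
        px = max(int(round(points * scale)), 1)
        if px not in fonts:
            try:
                fonts[px] = ImageFont.load_default(size=px)
            except TypeError:  # older Pillow: fixed-size bitmap font
                fonts[px] = ImageFont.load_default()
        return fonts[px]

    for text in lay.texts:
        font = font_for(text.size)
        anchor = {"start": "ls", "middle": "ms", "end": "rs"}[text.anchor]
        draw.text(
            (text.x * scale, text.y * scale),
            text.s,
            fill=text.color,
            font=font,
            anchor=anchor,
        )

    buffer = io.BytesIO()
    image.save(buffer, format="PNG")
    return RenderArtifact(
        format="raster",
        payload=buffer.getvalue(),
        filename=f"{doc.structure_id}.png",
    )


# ---------------------------------------------------------------------------
# raw TSV

_RAW_COLUMNS = (
    "chain_id\tauthor_number\tinsertion_code\tentity\tentity_class\t"
    "R\tG\tB\tc_red\tc_green\tc_blue"
)


def write_raw(doc: ColorDocument) -> RenderArtifact:
    """Write the per-entity color table as TSV.

    The header comments carry the frame parameters (centroid, spans,
    effective span), so the file alone suffices to decode every color back
    to its representative coordinate.  Unmapped entities carry ``NA`` in all
    channel columns.
    """
    frame = doc.frame
    lines = [
        "# seqcerosene raw color data",
        f"# structure_id\t{doc.structure_id}",
        f"# mode\t{doc.mode_name}",
        "# centroid\t{:.6f} {:.6f} {:.6f}".format(*frame.centroid),
        "# spans\t{:.6f} {:.6f} {:.6f}".format(*frame.spans),
        f"# s_max_raw\t{frame.s_max_raw:.6f}",
        f"# s_max_effective\t{frame.s_max_effective:.6f}",
        f"# floor_applied\t{'true' if frame.floor_applied else 'false'}",
        "# " + _RAW_COLUMNS.replace("\t", ", "),
        _RAW_COLUMNS,
    ]

    def row(chain_id, number, icode, entity, klass, color):
        if color is None:
            channels = [_NA] * 6
        else:
            channels = [str(c) for c in color.integer] + [
                f"{c:.6f}" for c in color.continuous
            ]
        return "\t".join(
            [chain_id, str(number), icode or _BLANK_ICODE, entity, klass, *channels]
        )

    for block in doc.blocks:
        for entry in block.entries:
            lines.append(
                row(block.chain_id, entry.author_number, entry.insertion_code,
                    entry.letter, "polymer_residue", entry.color)
            )
    for comp in doc.compounds:
        lines.append(
            row(comp.chain_id, comp.author_number, comp.insertion_code,
                comp.name3, "compound", comp.color)
        )

    payload = ("\n".join(lines) + "\n").encode("utf-8")
    return RenderArtifact(
        format="raw_tsv", payload=payload, filename=f"{doc.structure_id}.tsv"
    )


@dataclass(frozen=True)
class RawRow:
    chain_id: str
    author_number: int
    insertion_code: str
    entity: str
    entity_class: str
    integer: tuple[int, int, int] | None
    continuous: tuple[float, float, float] | None


def load_raw(text: str) -> tuple[EmbeddingFrame, list[RawRow]]:
    """Parse a raw TSV back into its frame and rows (inverse of write_raw)."""
    headers: dict[str, str] = {}
    rows: list[RawRow] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                headers[parts[0]] = parts[1]
            continue
        fields = line.split("\t")
        if fields[0] == "chain_id":  # column header
            continue
        chain_id, number, icode, entity, klass = fields[:5]
        channels = fields[5:11]
        if channels[0] == _NA:
            integer = continuous = None
        else:
            integer = tuple(int(c) for c in channels[:3])
            continuous = tuple(float(c) for c in channels[3:])
        rows.append(
            RawRow(chain_id, int(number),
                   "" if icode == _BLANK_ICODE else icode,
                   entity, klass, integer, continuous)
        )
    centroid = np.array([float(v) for v in headers["centroid"].split()])
    spans = tuple(float(v) for v in headers["spans"].split())
    frame = EmbeddingFrame(
        centroid=centroid,
        spans=spans,
        s_max_raw=float(headers["s_max_raw"]),
        s_max_effective=float(headers["s_max_effective"]),
        floor_applied=headers["floor_applied"] == "true",
    )
    return frame, rows


def decode_raw(text: str, use_integer: bool = False) -> list[np.ndarray | None]:
    """Reconstruct representative coordinates from a raw TSV, in row order."""
    frame, rows = load_raw(text)
    coords: list[np.ndarray | None] = []
    for row in rows:
        channels = row.integer if use_integer else row.continuous
        coords.append(None if channels is None else rgb_to_point(channels, frame))
    return coords


# ---------------------------------------------------------------------------
# PyMOL PML

def _sanitize(name: str) -> str:
    return "".join(c if c.isalnum() or c == "_" else "_" for c in name)


def write_pml(doc: ColorDocument, structure: Structure) -> RenderArtifact:
    """Write a PyMOL script coloring the original structure entity by entity.

    One ``set_color`` (channels scaled to [0, 1], three decimals) and one
    ``color`` statement per mappable entity, addressed by chain and author
    residue number (with insertion code where present).  Unmapped entities
    are skipped.
    """
    sid = _sanitize(doc.structure_id)
    lines = [
        f"# seqcerosene per-residue coloring for {doc.structure_id} "
        f"(mode={doc.mode_name})",
        "bg_color white",
    ]

    def emit(prefix, chain_id, number, icode, color, extra_sel=""):
        if color is None:
            return
        name = f"seqc_{sid}_{prefix}{_sanitize(chain_id)}_{number}{icode}"
        r, g, b = (round(c / 255.0, 3) for c in color.integer)
        lines.append(f"set_color {name}, [{r:.3f}, {g:.3f}, {b:.3f}]")
        resi = f"{number}{icode}"
        lines.append(
            f"color {name}, (chain {chain_id} and resi {resi}{extra_sel})"
        )

    for block in doc.blocks:
        for entry in block.entries:
            emit("", block.chain_id, entry.author_number,
                 entry.insertion_code, entry.color)
    for comp in doc.compounds:
        emit("het_", comp.chain_id, comp.author_number, comp.insertion_code,
             comp.color, extra_sel=f" and resn {comp.name3}")

    payload = ("\n".join(lines) + "\n").encode("utf-8")
    return RenderArtifact(
        format="pml", payload=payload, filename=f"{doc.structure_id}.pml"
    )
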