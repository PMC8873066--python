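"""Data model and I/O for instrument-table setups.

A *setup* is the spatial arrangement of surgical instruments on a
simulated table surface of 1920 x 1080 pixels.  Each placed instrument
carries a canonical identity token (used for cross-table matching), a
free-text label, a position in screen pixels and an orientation angle in
degrees.

Coordinate convention: origin at the top-left corner of the surface,
x grows rightward, y grows downward.  Angles are counter-clockwise
positive and normalized to ``[0, 360)`` on ingest.

Two on-disk formats are supported:

* an XML dialect — root ``<setups>``, children ``<setup id clinic>``,
  grandchildren ``<instrument id label x y angle/>`` — with a
  configurable :class:`XmlDialect` mapping so files using different
  element/attribute names can be read without code changes;
* a flat CSV with columns
  ``setup_id,clinic_id,instrument_id,label,x,y,angle``.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "SURFACE_WIDTH",
    "SURFACE_HEIGHT",
    "InstrumentPlacement",
    "TableSetup",
    "SetupCollection",
    "XmlDialect",
    "SetupValidationError",
    "SetupParseError",
    "read_setups_xml",
    "write_setups_xml",
    "read_setups_csv",
    "write_setups_csv",
]

SURFACE_WIDTH = 1920.0
SURFACE_HEIGHT = 1080.0

CSV_COLUMNS = ("setup_id", "clinic_id", "instrument_id", "label", "x", "y", "angle")


class SetupValidationError(ValueError):
    """A setup or placement violates a domain invariant."""


class SetupParseError(ValueError):
    """An input file could not be parsed into setups."""


def normalize_angle(angle: float) -> float:
    """Map any angle in degrees onto ``[0, 360)``."""
    a = float(angle) % 360.0
    # Python's % can return 360.0 for tiny negative inputs due to rounding.
    return 0.0 if a == 360.0 else a


@dataclass(frozen=True)
class InstrumentPlacement:
    """One instrument instance placed on a table.

    Parameters
    ----------
    instrument_id
        Canonical identity token; instruments with equal ids are
        considered the same instrument when two tables are compared.
    label
        Free-text display name (not used by the metric).
    x, y
        Position in screen pixels, inside the 1920 x 1080 surface.
    angle
        Orientation in degrees; normalized to ``[0, 360)``.
    """

    instrument_id: str
    label: str
    x: float
    y: float
    angle: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        object.__setattr__(self, "angle", normalize_angle(self.angle))

    def validate(self, setup_id: str = "?") -> None:
        if not (0.0 <= self.x <= SURFACE_WIDTH):
            raise SetupValidationError(
                f"setup {setup_id!r}, instrument {self.instrument_id!r}: "
                f"x={self.x} outside [0, {SURFACE_WIDTH:g}]"
            )
        if not (0.0 <= self.y <= SURFACE_HEIGHT):
            raise SetupValidationError(
                f"setup {setup_id!r}, instrument {self.instrument_id!r}: "
                f"y={self.y} outside [0, {SURFACE_HEIGHT:g}]"
            )


@dataclass(frozen=True)
class TableSetup:
    """A named table setup belonging to a clinic.

    ``placements`` may be empty (a valid degenerate setup).  Duplicate
    ``instrument_id`` values are permitted — the table simulation allows
    stacking several instances of the same instrument.
    """

    setup_id: str
    clinic_id: str
    placements: tuple[InstrumentPlacement, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "placements", tuple(self.placements))

    def validate(self) -> None:
        for p in self.placements:
            p.validate(self.setup_id)

    def __len__(self) -> int:
        return len(self.placements)


@dataclass
class SetupCollection:
    """An ordered list of setups, e.g. all participants of a study."""

    setups: list[TableSetup] = field(default_factory=list)

    @property
    def clinics(self) -> list[str]:
        """Clinic ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.setups:
            seen.setdefault(s.clinic_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.setups)

    def __iter__(self) -> Iterator[TableSetup]:
        return iter(self.setups)

    def __getitem__(self, setup_id: str) -> TableSetup:
        for s in self.setups:
            if s.setup_id == setup_id:
                return s
        raise KeyError(setup_id)

    def setup_ids(self) -> list[str]:
        return [s.setup_id for s in self.setups]

    def by_clinic(self) -> dict[str, list[TableSetup]]:
        out: dict[str, list[TableSetup]] = {}
        for s in self.setups:
            out.setdefault(s.clinic_id, []).append(s)
        return out

    def validate(self, require_unique_ids: bool = True) -> None:
        if require_unique_ids:
            ids = self.setup_ids()
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise SetupValidationError(f"duplicate setup_id(s): {sorted(dupes)}")
        for s in self.setups:
            s.validate()


@dataclass(frozen=True)
class XmlDialect:
    """Element/attribute name mapping for the setups XML format.

    The default names define this package's own dialect.  Deposited data
    sets using other names can be adapted by constructing a dialect with
    the observed names, e.g.
    ``XmlDialect(instrument_tag="item", x_attr="xpos", y_attr="ypos")``.
    """

    root_tag: str = "setups"
    setup_tag: str = "setup"
    setup_id_attr: str = "id"
    clinic_attr: str = "clinic"
    instrument_tag: str = "instrument"
    instrument_id_attr: str = "id"
    label_attr: str = "label"
    x_attr: str = "x"
    y_attr: str = "y"
    angle_attr: str = "angle"


DEFAULT_DIALECT = XmlDialect()


def _float_attr(elem: ET.Element, name: str, context: str) -> float:
    raw = elem.get(name)
    if raw is None:
        raise SetupParseError(f"{context}: missing attribute {name!r}")
    try:
        return float(raw)
    except ValueError as exc:
        raise SetupParseError(f"{context}: attribute {name}={raw!r} is not numeric") from exc


def read_setups_xml(
    path: str | Path,
    dialect: XmlDialect = DEFAULT_DIALECT,
    validate: bool = True,
) -> SetupCollection:
    """Read a :class:`SetupCollection` from an XML file.

    Raises :class:`SetupParseError` on malformed XML (with the line
    number reported by the parser) and :class:`SetupValidationError`
    when a placement lies outside the surface bounds.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SetupParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != dialect.root_tag:
        raise SetupParseError(
            f"{path}: expected root element <{dialect.root_tag}>, found <{root.tag}>"
        )
    setups: list[TableSetup] = []
    for setup_elem in root.findall(dialect.setup_tag):
        setup_id = setup_elem.get(dialect.setup_id_attr)
        if setup_id is None:
            raise SetupParseError(f"{path}: <{dialect.setup_tag}> without {dialect.setup_id_attr!r}")
        clinic_id = setup_elem.get(dialect.clinic_attr, "")
        placements = []
        for inst in setup_elem.findall(dialect.instrument_tag):
            iid = inst.get(dialect.instrument_id_attr)
            if iid is None:
                raise SetupParseError(
                    f"{path}, setup {setup_id!r}: "
                    f"<{dialect.instrument_tag}> without {dialect.instrument_id_attr!r}"
                )
            ctx = f"{path}, setup {setup_id!r}, instrument {iid!r}"
            placements.append(
                InstrumentPlacement(
                    instrument_id=iid,
                    label=inst.get(dialect.label_attr, iid),
                    x=_float_attr(inst, dialect.x_attr, ctx),
                    y=_float_attr(inst, dialect.y_attr, ctx),
                    angle=_float_attr(inst, dialect.angle_attr, ctx),
                )
            )
        setups.append(TableSetup(setup_id=setup_id, clinic_id=clinic_id, placements=placements))
    collection = SetupCollection(setups)
    if validate:
        collection.validate()
    return collection


def _format_num(v: float) -> str:
    # repr round-trips doubles exactly; integral values print compactly.
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def write_setups_xml(
    collection: SetupCollection,
    path: str | Path,
    dialect: XmlDialect = DEFAULT_DIALECT,
) -> None:
    """Write ``collection`` to ``path``; round-trips exactly through
    :func:`read_setups_xml`."""
    root = ET.Element(dialect.root_tag)
    for s in collection:
        setup_elem = ET.SubElement(
            root,
            dialect.setup_tag,
            {dialect.setup_id_attr: s.setup_id, dialect.clinic_attr: s.clinic_id},
        )
        for p in s.placements:
            ET.SubElement(
                setup_elem,
                dialect.instrument_tag,
                {
                    dialect.instrument_id_attr: p.instrument_id,
                    dialect.label_attr: p.label,
                    dialect.x_attr: _format_num(p.x),
                    dialect.y_attr: _format_num(p.y),
                    dialect.angle_attr: _format_num(p.angle),
                },
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def read_setups_csv(path: str | Path, validate: bool = True) -> SetupCollection:
    """Read a collection from CSV with header ``setup_id,clinic_id,
    instrument_id,label,x,y,angle``.

    Consecutive rows sharing a ``setup_id`` form one setup; placement
    order follows row order.  A setup with an empty placement list can
    be encoded as a row with blank instrument fields.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SetupParseError(f"{path}: missing column(s) {missing}")
        order: list[str] = []
        clinic_of: dict[str, str] = {}
        placements: dict[str, list[InstrumentPlacement]] = {}
        for lineno, row in enumerate(reader, start=2):
            sid = row["setup_id"]
            if sid is None or sid == "":
                raise SetupParseError(f"{path}, row {lineno}: empty setup_id")
            if sid not in clinic_of:
                order.append(sid)
                clinic_of[sid] = row["clinic_id"]
                placements[sid] = []
            if row["instrument_id"] == "" and row["x"] == "":
                continue  # marker row for an empty setup
            try:
                x, y, angle = (float(row[c]) for c in ("x", "y", "angle"))
            except (TypeError, ValueError) as exc:
                raise SetupParseError(f"{path}, row {lineno}: non-numeric coordinate") from exc
            placements[sid].append(
                InstrumentPlacement(
                    instrument_id=row["instrument_id"],
                    label=row["label"],
                    x=x,
                    y=y,
                    angle=angle,
                )
            )
    collection = SetupCollection(
        [TableSetup(sid, clinic_of[sid], placements[sid]) for sid in order]
    )
    if validate:
        collection.validate()
    return collection


def write_setups_csv(collection: SetupCollection, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in collection:
            if not s.placements:
                writer.writerow([s.setup_id, s.clinic_id, "", "", "", "", ""])
            for p in s.placements:
                writer.writerow(
                    [
                        s.setup_id,
                        s.clinic_id,
                        p.instrument_id,
                        p.label,
                        _format_num(p.x),
                        _format_num(p.y),
                        _format_num(p.angle),
                    ]
                )
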