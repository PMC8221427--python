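"""Reading and writing annotations, detection files and images.

Ground truth lives in PASCAL VOC XML as emitted by the LabelImg annotation
tool: coordinates there are 1-based and inclusive.  On read they are
converted to the package-internal 0-based half-open convention
(``xmin -> xmin - 1``, ``xmax`` unchanged), which preserves box width and
height exactly; :func:`write_voc_xml` applies the inverse so that
write-then-read is the identity.

Detections travel as a small comma-delimited text format with the header
``image_id,xmin,ymin,xmax,ymax,score`` -- one row per detection, scores
serialized at 6 decimal places.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from lxml import etree
from PIL import Image

from .geometry import Box, Detection

__all__ = [
    "AnnotationSet",
    "DetectionFile",
    "read_voc_xml",
    "write_voc_xml",
    "read_detections",
    "write_detections",
    "read_image",
    "write_image",
]

DETECTION_HEADER = ["image_id", "xmin", "ymin", "xmax", "ymax", "score"]


@dataclass
class AnnotationSet:
    """Ground-truth objects of one image.

    ``objects`` pairs a class name (``"tassel"`` in this package, though any
    nonempty name is accepted) with a :class:`~tasselkit.geometry.Box` in
    internal 0-based half-open coordinates.
    """

    image_id: str
    image_width: int
    image_height: int
    objects: list[tuple[str, Box]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, box in self.objects:
            if not name:
                raise ValueError("empty class name in annotation")
            if not (
                0 <= box.xmin
                and box.xmax <= self.image_width
                and 0 <= box.ymin
                and box.ymax <= self.image_height
            ):
                raise ValueError(
                    f"box {box} outside image "
                    f"{self.image_width}x{self.image_height} of {self.image_id!r}"
                )

    @property
    def boxes(self) -> list[Box]:
        return [b for _, b in self.objects]


@dataclass
class DetectionFile:
    """Detections for one or more images, in file row order."""

    rows: list[tuple[str, Detection]] = field(default_factory=list)

    def for_image(self, image_id: str) -> list[Detection]:
        return [d for i, d in self.rows if i == image_id]

    @property
    def image_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for i, _ in self.rows:
            seen.setdefault(i)
        return list(seen)


class VocParseError(ValueError):
    """Raised when a VOC XML file is structurally incomplete."""


def _req(parent: etree._Element, tag: str, path: Union[str, Path]) -> str:
    el = parent.find(tag)
    if el is None or el.text is None:
        raise VocParseError(f"{path}: missing <{tag}> under <{parent.tag}>")
    return el.text.strip()


def read_voc_xml(path: Union[str, Path]) -> AnnotationSet:
    """Parse one LabelImg-dialect VOC XML file.

    VOC's 1-based inclusive pixel coordinates are mapped to 0-based
    half-open boxes.  A file with no ``<object>`` elements is legal and
    yields an empty annotation set (a tassel-free image).
    """
    path = Path(path)
    root = etree.parse(str(path)).getroot()
    size = root.find("size")
    if size is None:
        raise VocParseError(f"{path}: missing <size> element")
    width = int(_req(size, "width", path))
    height = int(_req(size, "height", path))
    filename = _req(root, "filename", path)
    image_id = Path(filename).stem

    objects: list[tuple[str, Box]] = []
    for obj in root.findall("object"):
        name = _req(obj, "name", path)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocParseError(f"{path}: <object> without <bndbox>")
        xmin = int(_req(bnd, "xmin", path)) - 1
        ymin = int(_req(bnd, "ymin", path)) - 1
        xmax = int(_req(bnd, "xmax", path))
        ymax = int(_req(bnd, "ymax", path))
        if xmax <= xmin or ymax <= ymin:
            raise VocParseError(
                f"{path}: degenerate bndbox ({xmin + 1}, {ymin + 1}, {xmax}, {ymax})"
            )
        objects.append((name, Box(xmin, ymin, xmax, ymax)))

    return AnnotationSet(image_id, width, height, objects)


def write_voc_xml(ann: AnnotationSet, path: Union[str, Path]) -> None:
    """Write an annotation set as canonical LabelImg-dialect VOC XML.

    Inverse of :func:`read_voc_xml`; coordinates are emitted 1-based
    inclusive, so a read/write round-trip on a canonical file is
    byte-identical.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = f"{ann.image_id}.png"
    etree.SubElement(root, "path").text = f"images/{ann.image_id}.png"
    source = etree.SubElement(root, "source")
    etree.SubElement(source, "database").text = "Unknown"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.image_width)
    etree.SubElement(size, "height").text = str(ann.image_height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for name, box in ann.objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = name
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(box.xmin) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(box.ymin) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(box.xmax))
        etree.SubElement(bnd, "ymax").text = str(int(box.ymax))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, encoding="utf-8")


def read_detections(path: Union[str, Path]) -> DetectionFile:
    """Read a detection CSV (``image_id,xmin,ymin,xmax,ymax,score``)."""
    path = Path(path)
    rows: list[tuple[str, Detection]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != DETECTION_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(DETECTION_HEADER)!r}, "
                f"got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            try:
                image_id = row[0]
                box = Box(float(row[1]), float(row[2]), float(row[3]), float(row[4]))
                det = Detection(box, float(row[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append((image_id, det))
    return DetectionFile(rows)


def _fmt_coord(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_detections(dfile: DetectionFile, path: Union[str, Path]) -> None:
    """Write a detection CSV; scores at 6 decimal places, row order kept."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTION_HEADER)
        for image_id, det in dfile.rows:
            b = det.box
            writer.writerow(
                [
                    image_id,
                    _fmt_coord(b.xmin),
                    _fmt_coord(b.ymin),
                    _fmt_coord(b.xmax),
                    _fmt_coord(b.ymax),
                    f"{det.score:.6f}",
                ]
            )


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path: Union[str, Path]) -> None:
    """Save an (H, W, 3) uint8 RGB array as PNG/JPEG (by extension)."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(str(path))
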