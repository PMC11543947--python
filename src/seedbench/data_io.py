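"""Readers/writers: COCO-style JSON annotations, PNG images, dataset
manifests, and a best-effort adapter for the deposited real dataset.

COCO subset
-----------
``images``: id, file_name, width, height; ``annotations``: id, image_id,
bbox, category_id, optional score; ``categories``: one entry (seedling).
The bbox convention is ``[x, y, width, height]`` with a top-left origin —
stated explicitly because the in-memory :class:`~seedbench.geometry.Box`
uses (min_x, min_y, max_x, max_y).  Writing is deterministic (sorted keys,
consecutive ids from 1) so files diff stably; read(write(x)) is the
identity for the documented fields.

Nothing in this module performs a network download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import Box
from .synth import BenchmarkLayout, DomainParams, ImageRecord, ImageSet

__all__ = [
    "DatasetManifest",
    "ManifestSet",
    "read_coco",
    "write_coco",
    "load_manifest",
    "save_benchmark",
    "load_benchmark",
    "zenodo_adapter",
    "ZENODO_DOI",
]

ZENODO_DOI = "10.5281/zenodo.11055599"
ROLES = ("train", "id_test", "ood_test")


@dataclass
class ManifestSet:
    set_id: str
    role: str
    annotations: Path
    images_dir: Path
    seed: int | None = None
    params: dict | None = None


@dataclass
class DatasetManifest:
    name: str
    sets: list[ManifestSet] = field(default_factory=list)

    def by_role(self, role: str) -> list[ManifestSet]:
        return [s for s in self.sets if s.role == role]


def write_coco(records: Sequence[ImageRecord], path, *,
               images_dir=None, write_images: bool = False) -> None:
    """Write records as COCO-style JSON; optionally also write PNG pixels.

    Image and annotation ids are consecutive from 1 in input order; output
    bytes are deterministic for identical records.
    """
    path = Path(path)
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(records, start=1):
        h, w = rec.pixels.shape[:2] if rec.pixels is not None else (0, 0)
        file_name = f"{rec.image_id.replace('/', '_')}.png"
        images.append({"id": img_id, "file_name": file_name,
                       "width": int(w), "height": int(h)})
        for b in rec.annotations:
            entry = {"id": ann_id, "image_id": img_id,
                     "bbox": [b.min_x, b.min_y,
                              b.max_x - b.min_x, b.max_y - b.min_y],
                     "category_id": 1}
            if b.confidence is not None:
                entry["score"] = b.confidence
            annotations.append(entry)
            ann_id += 1
        if write_images and rec.pixels is not None:
            out = Path(images_dir) if images_dir else path.parent
            out.mkdir(parents=True, exist_ok=True)
            iio.imwrite(out / file_name, rec.pixels)
    doc = {"images": images, "annotations": annotations,
           "categories": [{"id": 1, "name": "seedling"}]}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_coco(path, *, images_dir=None, load_images: bool = True,
              domain_id: str = "") -> list[ImageRecord]:
    """Load a COCO-style JSON file back into ImageRecords.

    Box invariants are enforced on load; a zero-area bbox raises a
    descriptive error naming the annotation id.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed JSON ({e})") from e
    for key in ("images", "annotations"):
        if key not in doc:
            raise ValueError(f"{path}: missing '{key}' section")
    by_image: dict[int, list[Box]] = {img["id"]: [] for img in doc["images"]}
    for ann in doc["annotations"]:
        try:
            x, y, w, h = ann["bbox"]
            img_id = ann["image_id"]
        except (KeyError, ValueError) as e:
            raise ValueError(
                f"{path}: annotation {ann.get('id', '?')} malformed: {e}") from e
        if w <= 0 or h <= 0:
            raise ValueError(f"{path}: annotation {ann.get('id', '?')} has "
                             f"non-positive extent (bbox={ann['bbox']})")
        if img_id not in by_image:
            raise ValueError(f"{path}: annotation {ann.get('id', '?')} "
                             f"references unknown image {img_id}")
        by_image[img_id].append(Box(x, y, x + w, y + h, ann.get("score")))
    records = []
    for img in doc["images"]:
        pixels = None
        if load_images:
            base = Path(images_dir) if images_dir else path.parent
            img_path = base / img["file_name"]
            if img_path.exists():
                pixels = np.asarray(iio.imread(img_path))
        records.append(ImageRecord(
            image_id=Path(img["file_name"]).stem,
            pixels=pixels,
            annotations=tuple(by_image[img["id"]]),
            domain_id=domain_id))
    return records


def load_manifest(path) -> DatasetManifest:
    """Load and validate a YAML dataset manifest; relative paths resolve
    against the manifest's directory."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    root = path.parent
    sets, seen = [], set()
    for entry in doc.get("sets", []):
        sid, role = entry.get("id"), entry.get("role")
        if sid in seen:
            raise ValueError(f"duplicate set id '{sid}'")
        seen.add(sid)
        if role not in ROLES:
            raise ValueError(f"set '{sid}': role '{role}' not in {ROLES}")
        ann = root / entry["annotations"]
        if not ann.exists():
            raise FileNotFoundError(f"set '{sid}': missing annotations "
                                    f"file {ann}")
        images_dir = root / entry.get("images_dir", sid)
        if not images_dir.exists():
            raise FileNotFoundError(f"set '{sid}': missing images dir "
                                    f"{images_dir}")
        sets.append(ManifestSet(sid, role, ann, images_dir,
                                entry.get("seed"), entry.get("params")))
    return DatasetManifest(name=doc.get("name", path.stem), sets=sets)


def save_benchmark(layout: BenchmarkLayout, out_dir) -> Path:
    """Write a benchmark to disk (PNG tiles + per-set COCO JSON + manifest);
    returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in layout.all_sets():
        set_dir = out / s.set_id
        write_coco(s.images, out / f"{s.set_id}.json",
                   images_dir=set_dir, write_images=True)
        entry = {"id": s.set_id, "role": s.role,
                 "annotations": f"{s.set_id}.json",
                 "images_dir": s.set_id}
        if s.params is not None:
            entry["seed"] = int(s.params.seed)
            entry["params"] = {k: (v if isinstance(v, int) else float(v))
                               for k, v in vars(s.params).items()}
        entries.append(entry)
    manifest = out / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"name": out.name, "sets": entries},
                                       sort_keys=False))
    return manifest


def load_benchmark(manifest_path) -> BenchmarkLayout:
    """Read a saved benchmark back into memory."""
    manifest = load_manifest(manifest_path)
    layout = BenchmarkLayout([], [], [])
    dest = {"train": layout.train_sets, "id_test": layout.id_test_sets,
            "ood_test": layout.ood_test_sets}
    for ms in manifest.sets:
        records = read_coco(ms.annotations, images_dir=ms.images_dir,
                            domain_id=ms.set_id)
        params = DomainParams(**ms.params) if ms.params else None
        dest[ms.role].append(ImageSet(ms.set_id, records, params, ms.role))
    return layout


def zenodo_adapter(root_dir) -> DatasetManifest:
    """EXPERIMENTAL best-effort adapter for the deposited canola seedling
    dataset (DOI 10.5281/zenodo.11055599).

    The archive must be downloaded and unpacked manually; this function
    never fetches anything and never writes into ``root_dir``.  It maps
    subdirectories containing a COCO-style JSON plus images into manifest
    sets, inferring roles from directory names containing "train",
    "id" / "id_test", or "ood".
    """
    root = Path(root_dir)
    if not root.exists():
        raise FileNotFoundError(
            f"{root} not found. Download the dataset archive manually from "
            f"https://doi.org/{ZENODO_DOI} and unpack it there.")
    sets = []
    found = []
    for sub in sorted(p for p in root.rglob("*") if p.is_dir()):
        jsons = sorted(sub.glob("*.json"))
        images = [p for p in sub.iterdir()
                  if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif")]
        found.append(f"{sub} ({len(jsons)} json, {len(images)} images)")
        if not jsons or not images:
            continue
        name = sub.name.lower()
        if "ood" in name:
            role = "ood_test"
        elif "id" in name and "test" in name:
            role = "id_test"
        elif "train" in name:
            role = "train"
        else:
            continue
        sets.append(ManifestSet(sub.name, role, jsons[0], sub))
    if not sets:
        listing = "\n  ".join(found) if found else "(empty directory)"
        raise ValueError(
            f"unrecognised dataset layout under {root}; found:\n  {listing}")
    return DatasetManifest(name=root.name, sets=sets)
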