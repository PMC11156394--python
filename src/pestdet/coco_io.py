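"""COCO-JSON dataset container and serialisation.

Internally every box is (x1, y1, x2, y2), 0-based continuous corner
coordinates; the COCO (x, y, w, h) dialect exists only inside the JSON
files written and read here.  Images are uint8 RGB arrays (H, W, 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class AnnotationRecord:
    """One ground-truth instance."""

    image_id: int
    class_id: int
    bbox: tuple[float, float, float, float]  # x1, y1, x2, y2
    iscrowd: int = 0

    def __post_init__(self):
        x1, y1, x2, y2 = self.bbox
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate bbox {self.bbox}")

    @property
    def area(self) -> float:
        x1, y1, x2, y2 = self.bbox
        return (x2 - x1) * (y2 - y1)


@dataclass
class DetectionDataset:
    """In-memory detection dataset: images keyed by id + flat annotations."""

    images: dict[int, np.ndarray] = field(default_factory=dict)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    n_classes: int = 0
    category_names: list[str] | None = None

    def add_image(self, image: np.ndarray,
                  annotations: list[AnnotationRecord] | None = None,
                  image_id: int | None = None) -> int:
        if image_id is None:
            image_id = max(self.images, default=-1) + 1
        if image_id in self.images:
            raise ValueError(f"duplicate image id {image_id}")
        self.images[image_id] = image
        for ann in annotations or []:
            if ann.image_id != image_id:
                ann = replace(ann, image_id=image_id)
            self.annotations.append(ann)
        return image_id

    def annotations_for(self, image_id: int) -> list[AnnotationRecord]:
        return [a for a in self.annotations if a.image_id == image_id]

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_classes, dtype=np.int64)
        for a in self.annotations:
            counts[a.class_id] += 1
        return counts

    def gt_arrays(self, image_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(boxes (N,4), labels (N,)) for one image."""
        anns = self.annotations_for(image_id)
        if not anns:
            return np.zeros((0, 4)), np.zeros(0, dtype=np.int64)
        boxes = np.array([a.bbox for a in anns], dtype=np.float64)
        labels = np.array([a.class_id for a in anns], dtype=np.int64)
        return boxes, labels

    # -- COCO JSON ---------------------------------------------------------

    def to_coco_dict(self, file_names: dict[int, str] | None = None) -> dict:
        cats = self.category_names or [f"class_{i}" for i in range(self.n_classes)]
        images = []
        for img_id, arr in sorted(self.images.items()):
            h, w = arr.shape[:2]
            entry = {"id": img_id, "width": w, "height": h}
            if file_names:
                entry["file_name"] = file_names[img_id]
            images.append(entry)
        annotations = []
        for i, a in enumerate(self.annotations):
            x1, y1, x2, y2 = a.bbox
            annotations.append({
                "id": i,
                "image_id": a.image_id,
                "category_id": a.class_id,
                "bbox": [x1, y1, x2 - x1, y2 - y1],
                "area": a.area,
                "iscrowd": a.iscrowd,
            })
        categories = [{"id": i, "name": name} for i, name in enumerate(cats)]
        return {"images": images, "annotations": annotations,
                "categories": categories}

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        try:
            img_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create dataset directory {img_dir}: {exc}") from exc
        file_names = {}
        for img_id, arr in sorted(self.images.items()):
            name = f"{img_id:06d}.png"
            file_names[img_id] = f"images/{name}"
            Image.fromarray(arr).save(img_dir / name)
        coco = self.to_coco_dict(file_names)
        path = out_dir / "annotations.json"
        path.write_text(json.dumps(coco))
        return out_dir

    @classmethod
    def from_coco_dict(cls, coco: dict,
                       images: dict[int, np.ndarray]) -> "DetectionDataset":
        validate_coco(coco)
        anns = []
        for a in coco["annotations"]:
            x, y, w, h = a["bbox"]
            anns.append(AnnotationRecord(
                image_id=a["image_id"], class_id=a["category_id"],
                bbox=(x, y, x + w, y + h), iscrowd=a.get("iscrowd", 0)))
        cats = sorted(coco["categories"], key=lambda c: c["id"])
        return cls(images=images, annotations=anns, n_classes=len(cats),
                   category_names=[c["name"] for c in cats])

    @classmethod
    def load(cls, root: str | Path) -> "DetectionDataset":
        root = Path(root)
        path = root / "annotations.json"
        if not path.exists():
            raise FileNotFoundError(f"no annotations.json under {root}")
        coco = json.loads(path.read_text())
        images = {}
        for entry in coco["images"]:
            img_path = root / entry.get("file_name", f"images/{entry['id']:06d}.png")
            if not img_path.exists():
                raise FileNotFoundError(f"missing image file {img_path}")
            images[entry["id"]] = np.asarray(Image.open(img_path).convert("RGB"))
        return cls.from_coco_dict(coco, images)


def validate_coco(coco: dict) -> None:
    """Check referential integrity of a COCO dict; raises ValueError."""
    for key in ("images", "annotations", "categories"):
        if key not in coco:
            raise ValueError(f"COCO dict missing '{key}' section")
    image_ids = {e["id"] for e in coco["images"]}
    cat_ids = {c["id"] for c in coco["categories"]}
    for a in coco["annotations"]:
        if a["image_id"] not in image_ids:
            raise ValueError(f"annotation {a['id']} references missing image "
                             f"{a['image_id']}")
        if a["category_id"] not in cat_ids:
            raise ValueError(f"annotation {a['id']} references missing category "
                             f"{a['category_id']}")
        if a["bbox"][2] <= 0 or a["bbox"][3] <= 0:
            raise ValueError(f"annotation {a['id']} has non-positive extent")


def write_results_json(detections: dict[int, "object"], path: str | Path) -> None:
    """Write per-image BoxSets as a COCO results array."""
    out = []
    for image_id, dets in detections.items():
        for box, score, label in zip(dets.boxes, dets.scores, dets.labels):
            x1, y1, x2, y2 = (float(v) for v in box)
            out.append({"image_id": int(image_id), "category_id": int(label),
                        "bbox": [x1, y1, x2 - x1, y2 - y1],
                        "score": float(score)})
    Path(path).write_text(json.dumps(out))
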