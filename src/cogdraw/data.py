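"""Manifest parsing, image loading/resizing, augmentation, stratified splits.

Images are handled internally in *ink-positive* form: background 0, full
ink 1, replicated to three channels (CHW).  With this convention the
pad-then-random-crop training augmentation literally adds nothing at the
borders, and total ink mass can only shift or fall off the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labels import hard_label
from .synthetic import MANIFEST_COLUMNS, TASKS

IMAGE_SIZE = 256
#: full-scale augmentation pads 256 -> 280, i.e. a +-12 px random shift
MAX_SHIFT_FRACTION = 12 / 256

__all__ = ["SubjectRecord", "SplitAssignment", "load_manifest",
           "load_and_resize", "augment", "stratified_split", "split_sizes",
           "records_to_arrays"]


@dataclass
class SubjectRecord:
    subject_id: str
    image_paths: dict[str, Path]
    moca_score: int
    mask_paths: dict[str, Path] = field(default_factory=dict)
    severity: float | None = None


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive subject-to-partition map."""

    assignment: dict[str, str]        # subject_id -> train/validation/test
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": list(self.assignment),
             "partition": list(self.assignment.values()),
             "seed": self.seed})


def load_manifest(path) -> list[SubjectRecord]:
    """Read a cohort manifest CSV into subject records.

    Required columns: subject_id, {clock,cube,trail}_path, moca_score.
    Mask columns are optional.  Rows with unparsable scores or missing
    image files raise errors naming the offending subject.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["subject_id", "moca_score"] + [f"{t}_path" for t in TASKS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    root = path.parent
    records = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            score = int(row["moca_score"])
        except (TypeError, ValueError):
            raise ValueError(
                f"subject {sid}: unparsable moca_score {row['moca_score']!r}")
        if not 0 <= score <= 30:
            raise ValueError(f"subject {sid}: moca_score {score} outside [0, 30]")
        paths = {}
        for t in TASKS:
            p = root / str(row[f"{t}_path"]) if not Path(
                str(row[f"{t}_path"])).is_absolute() else Path(str(row[f"{t}_path"]))
            if not p.exists():
                raise FileNotFoundError(f"subject {sid}: missing image {p}")
            paths[t] = p
        mask_paths = {}
        for t in TASKS:
            col = f"{t}_mask_path"
            if col in df.columns and isinstance(row[col], str):
                mp = root / row[col]
                if mp.exists():
                    mask_paths[t] = mp
        records.append(SubjectRecord(
            subject_id=sid, image_paths=paths, moca_score=score,
            mask_paths=mask_paths,
            severity=float(row["severity"]) if "severity" in df.columns else None))
    return records


def _to_ink_chw(img: Image.Image, size: int) -> np.ndarray:
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img.convert("L"), dtype=np.float32) / 255.0
    ink = 1.0 - arr
    return np.repeat(ink[None], 3, axis=0)


def load_and_resize(record: SubjectRecord, size: int = IMAGE_SIZE) -> np.ndarray:
    """Load a record's three drawings as a (3 tasks, 3 ch, size, size) array.

    Any input resolution is plainly rescaled (bilinear) to ``size``; the
    grayscale drawing is replicated to three channels and mapped to the
    networks' ink-positive [0, 1] input range.
    """
    out = np.empty((len(TASKS), 3, size, size), dtype=np.float32)
    for t, task in enumerate(TASKS):
        with Image.open(record.image_paths[task]) as img:
            out[t] = _to_ink_chw(img, size)
    return out


def augment(image: np.ndarray, rng: np.random.Generator,
            max_shift: int | None = None) -> np.ndarray:
    """Random-crop translation augmentation.

    Zero-pads the image by ``max_shift`` on every side and crops back to
    the original size with the crop center at a uniformly random location
    of the padded canvas — equivalently, a uniform integer translation of
    at most ``max_shift`` pixels per axis with zero fill.  At 256x256 the
    default pad of 12 px reproduces the 280x280-pad-then-crop scheme.
    Operates on (..., H, W) arrays with H == W.
    """
    h, w = image.shape[-2:]
    if h != w:
        raise ValueError(f"augment expects a square image, got {h}x{w}")
    if max_shift is None:
        max_shift = int(round(h * MAX_SHIFT_FRACTION))
    dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
    out = np.zeros_like(image)
    ys_src = slice(max(0, -dy), h - max(0, dy))
    xs_src = slice(max(0, -dx), w - max(0, dx))
    ys_dst = slice(max(0, dy), h - max(0, -dy))
    xs_dst = slice(max(0, dx), w - max(0, -dx))
    out[..., ys_dst, xs_dst] = image[..., ys_src, xs_src]
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_sizes(n_class: int, fractions=(0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    """(train, validation, test) sizes for one stratum.

    Validation and test sizes are round-half-up nearest integers of
    ``n_class * fraction``; train receives the remainder.  With 651
    healthy / 267 MCI at 15% this yields test strata of 98 and 40.
    """
    f_train, f_val, f_test = fractions
    n_test = _round_half_up(n_class * f_test)
    n_val = _round_half_up(n_class * f_val)
    n_train = n_class - n_val - n_test
    if n_train < 0:
        raise ValueError("fractions allocate more subjects than available")
    return n_train, n_val, n_test


def stratified_split(records: list[SubjectRecord],
                     fractions=(0.70, 0.15, 0.15),
                     seed: int = 0, cutoff: int = 25) -> SplitAssignment:
    """Random stratified 3-way split by hard diagnostic label.

    Deterministic under ``seed``; each class is permuted independently and
    carved into train/validation/test by :func:`split_sizes`.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    degenerate = any(f == 1.0 for f in fractions)
    for label in (0, 1):
        ids = [r.subject_id for r in records
               if hard_label(r.moca_score, cutoff) == label]
        if not ids:
            continue
        if len(ids) < 3 and not degenerate:
            raise ValueError(
                f"class {label} has only {len(ids)} subjects; "
                "cannot populate train/validation/test")
        n_train, n_val, n_test = split_sizes(len(ids), fractions)
        order = rng.permutation(len(ids))
        for k, idx in enumerate(order):
            if k < n_train:
                part = "train"
            elif k < n_train + n_val:
                part = "validation"
            else:
                part = "test"
            assignment[ids[idx]] = part
    # keep manifest order for readability/determinism of emitted CSVs
    ordered = {r.subject_id: assignment[r.subject_id] for r in records
               if r.subject_id in assignment}
    return SplitAssignment(assignment=ordered, seed=seed)


def records_to_arrays(records: list[SubjectRecord], size: int = IMAGE_SIZE
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into (X, scores): X has shape (n, 3 tasks, 3, size, size)."""
    X = np.stack([load_and_resize(r, size) for r in records])
    scores = np.array([r.moca_score for r in records])
    return X, scores
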