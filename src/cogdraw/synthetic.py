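"""Synthetic drawing-test cohorts with ground-truth anomaly masks.

Emulates the three pen-and-paper screening drawings used for cognitive
assessment — a clock face, a Necker-cube copy, and a number/letter
trail-making path — as dark anti-aliased strokes on a white canvas.
Each subject receives a severity in [0, 1]; severity drives both

* the number (and size) of localized defects injected into each drawing
  (extra or misplaced strokes, missing digits, broken cube edges, wrong or
  omitted trail connections), each logged with a binary pixel mask, and
* a MoCA-like screening score ``clip(round(30 - 12*severity + eps), 0, 30)``
  so that severity 0.5 sits at the score cutoff of 25 used for labeling.

Because the base drawings carry no class information, the healthy-vs-MCI
signal of a generated cohort is confined to the anomaly masks by
construction, which is what makes the masks usable as ground-truth
"expert" regions of interest for interpretability scoring.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line

TASKS = ("clock", "cube", "trail")

#: anomaly catalog, per task (order is part of the generator contract)
ANOMALY_CATALOG = {
    "clock": ("misplaced_hand", "missing_digit", "duplicated_digit"),
    "cube": ("broken_edge", "stray_edge"),
    "trail": ("wrong_connection", "omitted_connection"),
}

DEFAULT_MAX_ANOMALIES = 4
DEFAULT_SCORE_SLOPE = 12.0
DEFAULT_TRAIL_NODES = 8


@dataclass(frozen=True)
class StrokeParams:
    thickness: int = 1          # extra dilation steps beyond the 1-px line
    blur_sigma: float = 0.5     # anti-aliasing blur applied to new strokes


@dataclass
class AnomalySpec:
    """One injected defect: what, where, and how heavy."""

    task_kind: str
    anomaly_kind: str
    location: tuple[int, int, int, int]   # bounding box (r0, c0, r1, c1)
    severity_weight: float

    def __post_init__(self):
        if self.severity_weight < 0:
            raise ValueError("severity_weight must be >= 0")


@dataclass
class SyntheticSubject:
    subject_id: str
    images: dict[str, np.ndarray]
    anomaly_masks: dict[str, np.ndarray]
    severity: float
    moca_like_score: int
    specs: dict[str, list[AnomalySpec]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level raster helpers (ink canvas: float in [0,1], ink = 1, paper = 0)
# ---------------------------------------------------------------------------

def _stroke_mask(shape, segments, thickness: int) -> np.ndarray:
    """Binary mask of 1-px segments thickened by ``thickness`` pixels."""
    m = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in segments:
        rr, cc = line(int(round(r0)), int(round(c0)),
                      int(round(r1)), int(round(c1)))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        m[rr[ok], cc[ok]] = True
    if thickness > 0:
        from scipy.ndimage import binary_dilation
        m = binary_dilation(m, iterations=thickness)
    return m


def _disk_mask(shape, center, radius) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk((center[0], center[1]), radius, shape=shape)
    m[rr, cc] = True
    return m


def _paint(ink: np.ndarray, mask: np.ndarray, sigma: float) -> None:
    soft = gaussian_filter(mask.astype(np.float32), sigma) if sigma > 0 else mask
    np.maximum(ink, np.clip(soft * 1.6, 0, 1), out=ink)


def _erase(ink: np.ndarray, mask: np.ndarray) -> None:
    ink[mask] = 0.0


def _ink_to_image(ink: np.ndarray) -> np.ndarray:
    return np.clip(255 * (1.0 - ink), 0, 255).astype(np.uint8)


def _image_to_ink(image: np.ndarray) -> np.ndarray:
    return 1.0 - image.astype(np.float32) / 255.0


# ---------------------------------------------------------------------------
# deterministic scene geometry (canvas-size relative)
# ---------------------------------------------------------------------------

def _clock_geometry(s: int):
    c = s / 2.0
    radius = 0.42 * s
    digit_r = 0.34 * s
    # digit k sits at angle (k/12)*360 deg measured clockwise from 12 o'clock
    digits = [(c - digit_r * np.cos(np.deg2rad(k * 30.0)),
               c + digit_r * np.sin(np.deg2rad(k * 30.0)))
              for k in range(1, 13)]
    hands = {  # classic "ten past eleven": hour toward 11, minute toward 2
        "hour": (np.deg2rad(11 * 30.0), 0.20 * s),
        "minute": (np.deg2rad(2 * 30.0), 0.32 * s),
    }
    return {"center": (c, c), "radius": radius, "digits": digits,
            "digit_blob_r": max(2.0, 0.025 * s), "hands": hands}


def _cube_geometry(s: int):
    a0, a1 = 0.22 * s, 0.58 * s
    d = 0.20 * s
    front = [(a0, a0), (a0, a1), (a1, a1), (a1, a0)]
    back = [(r - d * 0.8, c + d) for (r, c) in front]
    edges = []
    for i in range(4):
        edges.append((front[i], front[(i + 1) % 4]))
        edges.append((back[i], back[(i + 1) % 4]))
        edges.append((front[i], back[i]))
    return {"edges": edges}


_TRAIL_LAYOUT = [(0.80, 0.15), (0.55, 0.28), (0.78, 0.45), (0.45, 0.52),
                 (0.68, 0.75), (0.35, 0.82), (0.15, 0.65), (0.18, 0.30),
                 (0.40, 0.12), (0.60, 0.92)]


def _trail_geometry(s: int, n_nodes: int = DEFAULT_TRAIL_NODES):
    if n_nodes > len(_TRAIL_LAYOUT):
        raise ValueError(f"at most {len(_TRAIL_LAYOUT)} trail nodes supported")
    nodes = [(r * s, c * s) for r, c in _TRAIL_LAYOUT[:n_nodes]]
    return {"nodes": nodes, "node_r": max(2.0, 0.04 * s)}


def _connection_endpoints(p, q, radius):
    """Trim a node-to-node segment so it starts/ends at the node boundaries."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    v = q - p
    n = np.linalg.norm(v)
    if n < 2 * radius:
        return tuple(p), tuple(q)
    u = v / n
    return tuple(p + u * radius), tuple(q - u * radius)


# ---------------------------------------------------------------------------
# public generator operations
# ---------------------------------------------------------------------------

def make_base_drawing(task_kind: str, canvas_size: int = 256,
                      stroke_params: StrokeParams | None = None,
                      rng_seed: int = 0, n_trail_nodes: int = DEFAULT_TRAIL_NODES,
                      return_layers: bool = False):
    """Render an idealized (defect-free) drawing for one task.

    Returns a uint8 grayscale raster (white paper 255, dark ink); with
    ``return_layers=True`` also returns a dict of binary element layers
    (e.g. the ``nodes`` layer of the trail drawing) for structural checks.
    """
    if task_kind not in TASKS:
        raise ValueError(f"unknown task_kind {task_kind!r}; valid: {TASKS}")
    if canvas_size < 64:
        raise ValueError("canvas_size must be >= 64")
    sp = stroke_params or StrokeParams()
    rng = np.random.default_rng(rng_seed)
    s = canvas_size
    shape = (s, s)
    ink = np.zeros(shape, dtype=np.float32)
    layers: dict[str, np.ndarray] = {}

    if task_kind == "clock":
        g = _clock_geometry(s)
        # face: circle approximated by a polygon of short segments
        t = np.linspace(0, 2 * np.pi, 120)
        pts = [(g["center"][0] + g["radius"] * np.sin(a),
                g["center"][1] + g["radius"] * np.cos(a)) for a in t]
        face = _stroke_mask(shape, list(zip(pts[:-1], pts[1:])), sp.thickness)
        _paint(ink, face, sp.blur_sigma)
        digit_layer = np.zeros(shape, dtype=bool)
        for (r, c) in g["digits"]:
            jr, jc = rng.uniform(-1, 1, 2) * 0.004 * s
            digit_layer |= _disk_mask(shape, (r + jr, c + jc), g["digit_blob_r"])
        _paint(ink, digit_layer, sp.blur_sigma)
        hand_layer = np.zeros(shape, dtype=bool)
        for ang, length in g["hands"].values():
            end = (g["center"][0] - length * np.cos(ang),
                   g["center"][1] + length * np.sin(ang))
            hand_layer |= _stroke_mask(shape, [(g["center"], end)], sp.thickness)
        _paint(ink, hand_layer, sp.blur_sigma)
        layers = {"face": face, "digits": digit_layer, "hands": hand_layer}

    elif task_kind == "cube":
        g = _cube_geometry(s)
        edge_layer = _stroke_mask(shape, g["edges"], sp.thickness)
        _paint(ink, edge_layer, sp.blur_sigma)
        layers = {"edges": edge_layer}

    else:  # trail
        g = _trail_geometry(s, n_trail_nodes)
        node_layer = np.zeros(shape, dtype=bool)
        for (r, c) in g["nodes"]:
            node_layer |= _disk_mask(shape, (r, c), g["node_r"])
        conn_layer = np.zeros(shape, dtype=bool)
        for p, q in zip(g["nodes"][:-1], g["nodes"][1:]):
            a, b = _connection_endpoints(p, q, g["node_r"])
            conn_layer |= _stroke_mask(shape, [(a, b)], sp.thickness)
        _paint(ink, node_layer, sp.blur_sigma)
        _paint(ink, conn_layer, sp.blur_sigma)
        layers = {"nodes": node_layer, "connections": conn_layer}

    image = _ink_to_image(ink)
    if return_layers:
        return image, layers
    return image


def _sample_anomaly(task_kind: str, kind: str, s: int, rng: np.random.Generator,
                    scale: float, used: dict, sp: StrokeParams):
    """Build (add_mask, erase_mask) for one defect; either may be None."""
    shape = (s, s)
    band = max(1, int(round(0.02 * s)))

    def pick_unused(key, n):
        pool = [i for i in range(n) if i not in used.setdefault(key, set())]
        if not pool:
            used[key] = set()
            pool = list(range(n))
        i = int(rng.choice(pool))
        used[key].add(i)
        return i

    if task_kind == "clock":
        g = _clock_geometry(s)
        if kind == "misplaced_hand":
            ang = rng.uniform(0, 2 * np.pi)
            length = (0.22 + 0.12 * scale) * s
            end = (g["center"][0] - length * np.cos(ang),
                   g["center"][1] + length * np.sin(ang))
            return _stroke_mask(shape, [(g["center"], end)], sp.thickness + 1), None
        if kind == "missing_digit":
            i = pick_unused("digit", 12)
            r = g["digit_blob_r"] + 2 + 2 * scale
            return None, _disk_mask(shape, g["digits"][i], r)
        # duplicated_digit
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.10, 0.26) * s
        pos = (g["center"][0] - rad * np.cos(ang), g["center"][1] + rad * np.sin(ang))
        return _disk_mask(shape, pos, g["digit_blob_r"] * (1 + 0.5 * scale)), None

    if task_kind == "cube":
        g = _cube_geometry(s)
        if kind == "broken_edge":
            i = pick_unused("edge", len(g["edges"]))
            (p, q) = g["edges"][i]
            p, q = np.asarray(p), np.asarray(q)
            lo, hi = 0.5 - (0.15 + 0.15 * scale), 0.5 + (0.15 + 0.15 * scale)
            a, b = p + lo * (q - p), p + hi * (q - p)
            return None, _stroke_mask(shape, [(tuple(a), tuple(b))], band + 1)
        # stray_edge
        p = rng.uniform(0.15, 0.85, 2) * s
        ang = rng.uniform(0, 2 * np.pi)
        length = (0.12 + 0.12 * scale) * s
        q = (p[0] + length * np.sin(ang), p[1] + length * np.cos(ang))
        q = (float(np.clip(q[0], 0, s - 1)), float(np.clip(q[1], 0, s - 1)))
        return _stroke_mask(shape, [(tuple(p), q)], sp.thickness + 1), None

    # trail
    g = _trail_geometry(s)
    nodes = g["nodes"]
    if kind == "wrong_connection":
        n = len(nodes)
        pairs = [(i, j) for i in range(n) for j in range(i + 2, n)]
        i, j = pairs[int(rng.integers(len(pairs)))]
        a, b = _connection_endpoints(nodes[i], nodes[j], g["node_r"])
        return _stroke_mask(shape, [(a, b)], sp.thickness + 1), None
    # omitted_connection
    i = pick_unused("conn", len(nodes) - 1)
    p, q = np.asarray(nodes[i]), np.asarray(nodes[i + 1])
    a = p + 0.18 * (q - p)
    b = p + 0.82 * (q - p)
    return None, _stroke_mask(shape, [(tuple(a), tuple(b))], band + 1)


def inject_anomalies(image: np.ndarray, task_kind: str, severity: float,
                     rng_seed: int = 0,
                     max_anomalies: int = DEFAULT_MAX_ANOMALIES,
                     stroke_params: StrokeParams | None = None):
    """Inject severity-scaled defects into a drawing.

    The number of defects is Binomial(max_anomalies, severity) and defect
    sizes grow mildly with severity, so both count and magnitude increase
    monotonically in expectation.  Returns ``(image, mask, specs)`` where
    ``mask`` is a boolean array covering every modified pixel — or, for
    omissions, the locus where the erased element should have been — and
    ``specs`` logs each applied defect.  Severity 0 returns the input
    untouched with an empty mask.
    """
    if task_kind not in TASKS:
        raise ValueError(f"unknown task_kind {task_kind!r}; valid: {TASKS}")
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    sp = stroke_params or StrokeParams()
    rng = np.random.default_rng(rng_seed)
    s = image.shape[0]
    mask = np.zeros(image.shape, dtype=bool)
    specs: list[AnomalySpec] = []
    n = int(rng.binomial(max_anomalies, severity))
    if n == 0:
        return image.copy(), mask, specs

    ink = _image_to_ink(image)
    catalog = ANOMALY_CATALOG[task_kind]
    used: dict = {}
    scale = severity
    for _ in range(n):
        kind = catalog[int(rng.integers(len(catalog)))]
        add_m, erase_m = _sample_anomaly(task_kind, kind, s, rng, scale, used, sp)
        region = add_m if add_m is not None else erase_m
        if add_m is not None:
            _paint(ink, add_m, sp.blur_sigma)
        if erase_m is not None:
            _erase(ink, erase_m)
        mask |= region
        rr, cc = np.nonzero(region)
        specs.append(AnomalySpec(
            task_kind=task_kind, anomaly_kind=kind,
            location=(int(rr.min()), int(cc.min()), int(rr.max()), int(cc.max())),
            severity_weight=float(region.sum())))
    return _ink_to_image(ink), mask, specs


def severity_to_moca(severity: float, noise_sd: float = 0.0,
                     rng_seed: int = 0, slope: float = DEFAULT_SCORE_SLOPE) -> int:
    """MoCA-like score: ``clip(round(30 - slope*severity + eps), 0, 30)``.

    ``eps ~ Normal(0, noise_sd)``; with the default slope of 12 a severity
    of 0.5 lands exactly at score 24, just below the MCI cutoff of 25.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    eps = 0.0
    if noise_sd > 0:
        eps = np.random.default_rng(rng_seed).normal(0.0, noise_sd)
    return int(np.clip(np.rint(30.0 - slope * severity + eps), 0, 30))


def _resolve_severities(severity_distribution, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    if severity_distribution is None or severity_distribution == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if isinstance(severity_distribution, (int, float)):
        return np.full(n, float(severity_distribution))
    if callable(severity_distribution):
        return np.asarray(severity_distribution(rng, n), dtype=float)
    arr = np.asarray(severity_distribution, dtype=float)
    if arr.shape != (n,):
        raise ValueError("severity array must have one value per subject")
    return arr


def simulate_subject(subject_id: str, severity: float, rng_seed: int,
                     canvas_size: int = 256, noise_sd: float = 1.0,
                     max_anomalies: int = DEFAULT_MAX_ANOMALIES) -> SyntheticSubject:
    """Generate one subject's three drawings, masks and score in memory."""
    ss = np.random.SeedSequence(rng_seed)
    task_seeds = ss.generate_state(2 * len(TASKS) + 1)
    images, masks, specs = {}, {}, {}
    for t, task in enumerate(TASKS):
        base = make_base_drawing(task, canvas_size, rng_seed=int(task_seeds[2 * t]))
        img, mask, sp = inject_anomalies(base, task, severity,
                                         rng_seed=int(task_seeds[2 * t + 1]),
                                         max_anomalies=max_anomalies)
        images[task], masks[task], specs[task] = img, mask, sp
    score = severity_to_moca(severity, noise_sd, rng_seed=int(task_seeds[-1]))
    return SyntheticSubject(subject_id=subject_id, images=images,
                            anomaly_masks=masks, severity=float(severity),
                            moca_like_score=score, specs=specs)


def simulate_cohort(n_subjects: int, severity_distribution="uniform",
                    rng_seed: int = 0, canvas_size: int = 256,
                    noise_sd: float = 1.0,
                    max_anomalies: int = DEFAULT_MAX_ANOMALIES
                    ) -> list[SyntheticSubject]:
    """In-memory cohort generation (no files); deterministic under the seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng([rng_seed, 0xC0])
    severities = _resolve_severities(severity_distribution, n_subjects, rng)
    return [simulate_subject(f"S{i:04d}", severities[i],
                             rng_seed=int(np.random.SeedSequence(
                                 [rng_seed, 1 + i]).generate_state(1)[0] % (2**31)),
                             canvas_size=canvas_size, noise_sd=noise_sd,
                             max_anomalies=max_anomalies)
            for i in range(n_subjects)]


MANIFEST_COLUMNS = ["subject_id", "clock_path", "cube_path", "trail_path",
                    "clock_mask_path", "cube_mask_path", "trail_mask_path",
                    "moca_score", "severity"]


def generate_cohort(n_subjects: int, severity_distribution="uniform",
                    out_dir: str | os.PathLike = ".", rng_seed: int = 0,
                    canvas_size: int = 256, noise_sd: float = 1.0,
                    max_anomalies: int = DEFAULT_MAX_ANOMALIES) -> pd.DataFrame:
    """Generate a cohort on disk: PNG images + masks and a CSV manifest.

    Re-running with identical arguments reproduces byte-identical files.
    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``); image paths are relative to ``out_dir``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    subjects = simulate_cohort(n_subjects, severity_distribution, rng_seed,
                               canvas_size, noise_sd, max_anomalies)
    rows = []
    for subj in subjects:
        row = {"subject_id": subj.subject_id,
               "moca_score": subj.moca_like_score,
               "severity": subj.severity}
        for task in TASKS:
            img_rel = f"images/{subj.subject_id}_{task}.png"
            mask_rel = f"masks/{subj.subject_id}_{task}_mask.png"
            Image.fromarray(subj.images[task]).save(out / img_rel)
            Image.fromarray(
                (subj.anomaly_masks[task] * 255).astype(np.uint8)).save(out / mask_rel)
            row[f"{task}_path"] = img_rel
            row[f"{task}_mask_path"] = mask_rel
        rows.append(row)
    manifest = pd.DataFrame(rows)[MANIFEST_COLUMNS]
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
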