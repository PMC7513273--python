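"""Synthetic X-ray angiogram simulator.

Generates short grayscale sequences that mimic what the segmentation method
exploits in clinical angiographic video:

* a branching tubular vessel tree, darker than the surrounding tissue
  (the contrast agent absorbs X-rays),
* contrast arrival — branches become opaque one after another, so early
  frames show a partially filled (or empty) tree,
* quasi-periodic cardiac motion: the whole tree is displaced by a sinusoid
  with a period of roughly one heartbeat at 10–15 fps,
* low signal-to-noise ratio: Poisson (photon) noise followed by Gaussian
  read-out noise,
* transient per-frame occlusions: with some probability a random visible
  vessel segment is blanked in a frame's *image* while the ground-truth mask
  keeps it — the temporal redundancy that a multi-frame model can use and a
  single-frame model cannot.

Everything is a deterministic function of the spec (including its seed):
identical specs give bit-identical sequences.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

_N_MAX = 2
MIN_FRAME_COUNT = 2 * _N_MAX + 1


@dataclasses.dataclass
class VesselTreeSpec:
    """Parametric description of one synthetic clip.

    Lengths are pixels, times seconds, intensities in [0, 1].  When
    ``branch_control_points`` is None the tree geometry is drawn from
    ``seed``; when ``contrast_arrival`` is None arrival frames are assigned
    by branch depth (contrast reaches the root first).  ``poisson_scale`` or
    ``gaussian_sigma`` of 0 disables that noise source; ``occlusion_rate`` is
    the per-frame probability that one visible vessel segment is blanked in
    the rendered image (never in the mask).
    """

    seed: int = 0
    image_size: int = 96
    n_branches: int = 5
    branch_control_points: Optional[Sequence[Sequence[Sequence[float]]]] = None
    radius_root: float = 3.0
    radius_taper: float = 0.75
    frame_count: int = 16
    frame_rate: float = 12.5
    motion_amplitude: float = 2.0
    motion_period: float = 0.9
    contrast_arrival: Optional[Sequence[int]] = None
    vessel_intensity: float = 0.25
    background_intensity: float = 0.75
    gaussian_sigma: float = 0.08
    poisson_scale: float = 60.0
    occlusion_rate: float = 0.3

    def __post_init__(self):
        if self.n_branches < 1:
            raise ValueError(f"n_branches must be >= 1, got {self.n_branches}")
        if self.frame_count < MIN_FRAME_COUNT:
            raise ValueError(
                f"frame_count must be >= {MIN_FRAME_COUNT} (window depth "
                f"2N+1 with N up to {_N_MAX}), got {self.frame_count}")
        if self.radius_root <= 0:
            raise ValueError(f"radius_root must be > 0, got {self.radius_root}")
        if not (0 < self.radius_taper <= 1):
            raise ValueError(
                f"radius_taper must be in (0, 1], got {self.radius_taper}")
        if self.image_size < 8:
            raise ValueError(f"image_size too small: {self.image_size}")
        for name in ("vessel_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.vessel_intensity >= self.background_intensity:
            raise ValueError(
                "vessel_intensity must be below background_intensity "
                "(vessels are darker on X-ray angiograms)")
        if not (0.0 <= self.occlusion_rate <= 1.0):
            raise ValueError(
                f"occlusion_rate must be in [0, 1], got {self.occlusion_rate}")
        if self.branch_control_points is not None:
            lim = self.image_size - 1
            for bi, pts in enumerate(self.branch_control_points):
                arr = np.asarray(pts, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                    raise ValueError(
                        f"branch_control_points[{bi}] must be >= 2 points of "
                        f"(x, y); got shape {arr.shape}")
                if (arr < 0).any() or (arr > lim).any():
                    raise ValueError(
                        f"branch_control_points[{bi}] out of image bounds "
                        f"[0, {lim}]")
        if self.contrast_arrival is not None:
            if len(self.contrast_arrival) != self.n_branches:
                raise ValueError(
                    "contrast_arrival must list one frame index per branch")


@dataclasses.dataclass
class Branch:
    """Dense centerline polyline of one vessel branch."""

    points: np.ndarray          # (K, 2) in (x, y) pixel coordinates
    radius: float
    parent: int                 # -1 for the root
    depth: int                  # 0 for the root


@dataclasses.dataclass
class SyntheticSequence:
    frames: np.ndarray          # (T, S, S) float32 in [0, 1]
    masks: np.ndarray           # (T, S, S) uint8 in {0, 1}
    spec: VesselTreeSpec

    def __post_init__(self):
        t = self.spec.frame_count
        s = self.spec.image_size
        if self.frames.shape != (t, s, s) or self.masks.shape != (t, s, s):
            raise ValueError("frames/masks shape inconsistent with spec")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _densify(points: np.ndarray, step: float = 0.4) -> np.ndarray:
    """Resample a control polygon as a smooth dense polyline (~step px)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = float(seg.sum())
    n = max(2, int(np.ceil(arclen / step)))
    if len(points) == 2:
        u = np.linspace(0.0, 1.0, n)
        return points[0] + u[:, None] * (points[1] - points[0])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # guard against duplicate control points
    s = np.maximum.accumulate(s + np.arange(len(s)) * 1e-9)
    cs = CubicSpline(s, points, axis=0, bc_type="natural")
    return cs(np.linspace(0.0, s[-1], n))


def _random_walk(rng: np.random.Generator, start: np.ndarray,
                 direction: np.ndarray, size: int, n_steps: int,
                 step_len: float) -> np.ndarray:
    """Control points meandering from ``start`` along ``direction``."""
    pts = [start.copy()]
    d = direction / (np.linalg.norm(direction) + 1e-12)
    p = start.copy()
    for _ in range(n_steps):
        ang = rng.normal(0.0, 0.35)
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        d = rot @ d
        p = p + d * step_len
        p = np.clip(p, 1.0, size - 2.0)
        pts.append(p.copy())
    return np.asarray(pts)


def generate_vessel_tree(spec: VesselTreeSpec) -> List[Branch]:
    """Static tree geometry (dense centerlines + radii), from the spec alone.

    Deterministic in ``spec.seed``.  Generated trees are rooted at a point on
    the image border and children sprout from a random location along their
    parent with tapered radii.
    """
    size = spec.image_size
    if spec.branch_control_points is not None:
        branches = []
        for bi, pts in enumerate(spec.branch_control_points):
            dense = np.clip(_densify(np.asarray(pts, dtype=float)),
                            0.0, size - 1.0)
            branches.append(Branch(points=dense,
                                   radius=spec.radius_root
                                   * spec.radius_taper ** bi,
                                   parent=bi - 1, depth=bi))
        return branches[:spec.n_branches]

    rng = np.random.default_rng([int(spec.seed), 11])
    # root: enter from a random border point, heading inward
    side = int(rng.integers(4))
    u = rng.uniform(0.15, 0.85) * (size - 1)
    if side == 0:
        start, direction = np.array([u, 0.0]), np.array([0.0, 1.0])
    elif side == 1:
        start, direction = np.array([u, size - 1.0]), np.array([0.0, -1.0])
    elif side == 2:
        start, direction = np.array([0.0, u]), np.array([1.0, 0.0])
    else:
        start, direction = np.array([size - 1.0, u]), np.array([-1.0, 0.0])
    step = size / 5.0
    ctrl = _random_walk(rng, start, direction, size, n_steps=4, step_len=step)
    branches = [Branch(points=_densify(ctrl), radius=spec.radius_root,
                       parent=-1, depth=0)]
    ctrl_polys = [ctrl]
    for _ in range(1, spec.n_branches):
        pi = int(rng.integers(len(branches)))
        parent_ctrl = ctrl_polys[pi]
        seg = int(rng.integers(1, len(parent_ctrl)))
        anchor = parent_ctrl[seg]
        tangent = parent_ctrl[seg] - parent_ctrl[seg - 1]
        ang = rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        direction = rot @ (tangent / (np.linalg.norm(tangent) + 1e-12))
        depth = branches[pi].depth + 1
        radius = max(0.8, spec.radius_root * spec.radius_taper ** depth)
        ctrl = _random_walk(rng, anchor, direction, size,
                            n_steps=3, step_len=step * 0.8)
        branches.append(Branch(points=_densify(ctrl), radius=radius,
                               parent=pi, depth=depth))
        ctrl_polys.append(ctrl)
    return branches


def _distance_maps(branches: List[Branch], size: int) -> np.ndarray:
    """Per-branch maps of distance from each pixel to the centerline."""
    ys, xs = np.mgrid[0:size, 0:size]
    grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    maps = np.empty((len(branches), size, size), np.float32)
    for i, br in enumerate(branches):
        tree = cKDTree(br.points)
        d, _ = tree.query(grid, k=1)
        maps[i] = d.reshape(size, size).astype(np.float32)
    return maps


def rasterize_tree(branches: List[Branch], size: int) -> np.ndarray:
    """Binary union of tube footprints (no motion, all branches filled)."""
    dist = _distance_maps(branches, size)
    mask = np.zeros((size, size), bool)
    for i, br in enumerate(branches):
        mask |= dist[i] <= max(br.radius - 0.5, 0.5)
    return mask


def _shift2d(a: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Integer shift with constant fill (no wrap-around)."""
    out = np.full_like(a, fill)
    src_y = slice(max(0, -dy), a.shape[0] - max(0, dy))
    src_x = slice(max(0, -dx), a.shape[1] - max(0, dx))
    dst_y = slice(max(0, dy), a.shape[0] - max(0, -dy))
    dst_x = slice(max(0, dx), a.shape[1] - max(0, -dx))
    out[dst_y, dst_x] = a[src_y, src_x]
    return out


def _default_arrivals(spec: VesselTreeSpec,
                      branches: List[Branch]) -> np.ndarray:
    spacing = max(1, spec.frame_count // 8)
    return np.array([1 + b.depth * spacing for b in branches], dtype=int)


def render_sequence(spec: VesselTreeSpec) -> SyntheticSequence:
    """Render frames and ground-truth masks for one clip."""
    size = spec.image_size
    branches = generate_vessel_tree(spec)
    dist = _distance_maps(branches, size)
    arrivals = (np.asarray(spec.contrast_arrival, dtype=int)
                if spec.contrast_arrival is not None
                else _default_arrivals(spec, branches))

    rng_motion = np.random.default_rng([int(spec.seed), 23])
    rng_occ = np.random.default_rng([int(spec.seed), 31])
    rng_noise = np.random.default_rng([int(spec.seed), 47])
    phase = rng_motion.uniform(0.0, 2.0 * np.pi)
    period_frames = max(spec.motion_period * spec.frame_rate, 1e-6)

    # slowly varying background clutter, static over the clip
    rng_bg = np.random.default_rng([int(spec.seed), 59])
    coarse = rng_bg.normal(0.0, 1.0, size=(size // 8 + 1, size // 8 + 1))
    yy, xx = np.mgrid[0:size, 0:size]
    clutter = coarse[yy // 8, xx // 8] * 0.03

    frames = np.empty((spec.frame_count, size, size), np.float32)
    masks = np.empty((spec.frame_count, size, size), np.uint8)
    for t in range(spec.frame_count):
        arg = 2.0 * np.pi * t / period_frames + phase
        dx = int(np.rint(spec.motion_amplitude * np.sin(arg)))
        dy = int(np.rint(spec.motion_amplitude * np.sin(arg + 0.5 * np.pi) * 0.6))
        arrived = [i for i in range(len(branches)) if arrivals[i] <= t]
        mask = np.zeros((size, size), bool)
        vis = np.zeros((size, size), bool)
        occlude = (len(arrived) > 0
                   and rng_occ.uniform() < spec.occlusion_rate)
        occ_branch = int(rng_occ.integers(len(arrived))) if arrived else 0
        occ_u = rng_occ.uniform(0.1, 0.9)
        occ_frac = rng_occ.uniform(0.25, 0.55)
        for j, i in enumerate(arrived):
            # pixel centers within radius - 0.5 => stroke width 2*radius px
            thr = max(branches[i].radius - 0.5, 0.5)
            tube = _shift2d(dist[i], dy, dx, np.inf) <= thr
            mask |= tube
            if occlude and j == occ_branch:
                pts = branches[i].points
                k = len(pts)
                lo = int(occ_u * k)
                hi = min(k, lo + max(2, int(occ_frac * k)))
                sub = cKDTree(pts[lo:hi])
                ygrid, xgrid = np.nonzero(tube)
                # query only tube pixels, shifted back to static coordinates
                q = np.column_stack([xgrid - dx, ygrid - dy]).astype(float)
                d, _ = sub.query(q, k=1)
                keep = d > thr + 0.5
                vis[ygrid[keep], xgrid[keep]] = True
            else:
                vis |= tube
        frame = np.where(vis, spec.vessel_intensity,
                         spec.background_intensity + clutter)
        if spec.poisson_scale > 0:
            lam = np.clip(frame, 0.0, None) * spec.poisson_scale
            frame = rng_noise.poisson(lam) / spec.poisson_scale
        if spec.gaussian_sigma > 0:
            frame = frame + rng_noise.normal(0.0, spec.gaussian_sigma,
                                             size=frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0).astype(np.float32)
        masks[t] = mask.astype(np.uint8)
    return SyntheticSequence(frames=frames, masks=masks, spec=spec)


def simulate_dataset(n_clips: int, base_spec: Optional[VesselTreeSpec] = None,
                     seed: int = 0, **overrides) -> List[SyntheticSequence]:
    """Render ``n_clips`` independent clips with seeds derived from ``seed``."""
    base = base_spec or VesselTreeSpec(**overrides)
    if base_spec is not None and overrides:
        base = dataclasses.replace(base, **overrides)
    clip_seeds = np.random.default_rng([int(seed), 7]).integers(
        0, 2 ** 31 - 1, size=n_clips)
    return [render_sequence(dataclasses.replace(base, seed=int(s)))
            for s in clip_seeds]


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_dataset(sequences: Sequence[SyntheticSequence],
                  out_dir: Union[str, Path]) -> pd.DataFrame:
    """Write clips as 8-bit PNG frames/masks plus a CSV manifest.

    Layout: ``<out>/<clip_id>/frames/0000.png`` and ``.../masks/0000.png``;
    masks are 0/255.  Returns the manifest (also written to
    ``<out>/manifest.csv``); an empty sequence list yields an empty manifest
    and no clip directories.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, seq in enumerate(sequences):
        clip_id = f"clip_{ci:03d}"
        fdir = out / clip_id / "frames"
        mdir = out / clip_id / "masks"
        fdir.mkdir(parents=True, exist_ok=True)
        mdir.mkdir(parents=True, exist_ok=True)
        for t in range(seq.spec.frame_count):
            img = np.rint(seq.frames[t] * 255).astype(np.uint8)
            Image.fromarray(img).save(fdir / f"{t:04d}.png")
            Image.fromarray(seq.masks[t] * np.uint8(255)).save(
                mdir / f"{t:04d}.png")
        rows.append({"clip_id": clip_id,
                     "frame_rate": seq.spec.frame_rate,
                     "n_frames": seq.spec.frame_count,
                     "frames_dir": str(fdir),
                     "masks_dir": str(mdir)})
    manifest = pd.DataFrame(
        rows, columns=["clip_id", "frame_rate", "n_frames", "frames_dir",
                       "masks_dir"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def visible_fraction(seq: SyntheticSequence,
                     window: int = 1) -> tuple:
    """Measure occlusion complementarity on a rendered clip.

    Returns ``(single, pooled)``: the mean fraction of mask pixels that look
    like vessel (below the vessel/background midpoint) in the frame itself,
    and in at least one frame of the +/-``window`` neighbourhood.  For clips
    with per-frame occlusions, pooled > single — the redundancy the temporal
    fusion layer exploits.
    """
    mid = 0.5 * (seq.spec.vessel_intensity + seq.spec.background_intensity)
    dark = seq.frames < mid
    t_count = seq.spec.frame_count
    singles, pooled = [], []
    for t in range(t_count):
        m = seq.masks[t].astype(bool)
        if not m.any():
            continue
        lo, hi = max(0, t - window), min(t_count, t + window + 1)
        any_dark = dark[lo:hi].any(axis=0)
        singles.append(dark[t][m].mean())
        pooled.append(any_dark[m].mean())
    return float(np.mean(singles)), float(np.mean(pooled))
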