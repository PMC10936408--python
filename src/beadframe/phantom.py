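"""Ground-truthed synthetic samples rendered through simulated instruments.

A phantom is a 3D block of substrate containing fluorescent spherical beads
(~90 um diameter) surrounding a central "tissue" region made of smooth
anisotropic bumps, plus optional small bright fragments that act as
false-positive confusers for bead detection. The block is sectioned into
slices of configurable thickness and imaged by a simulated serial
two-photon-style instrument: overlapping tiles with stage-positioning errors,
per-slice drift of the whole stage, flatfield and polynomial distortion
fields, additive dark level, and Poisson counting noise.

Everything is a pure function of ``(config, seed)``, and every renderer
emits the ground truth it used (bead centers, per-slice offsets, tile
positions, transforms, cell labels), which downstream tests use as oracles.

The default geometry is deliberately down-scaled (8x8 tiles of 128 px at
2 um/px, 20 slices) so full-chain runs complete in seconds; the native
instrument scale (0.56 um/px, 2,080 px tiles) is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .beadmodel import OpticsParams, bead_profile, projected_radius
from .geometry import AffineTransform, Orientation

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "Tile",
    "generate_phantom",
    "render_scene",
    "render_stpt_slice",
    "render_second_modality",
    "render_probability_map",
    "true_bead_catalog",
]


@dataclass
class Tile:
    """One instrument field of view.

    ``reported_origin`` is the stage position the (simulated) microscope
    recorded, in px of the stage frame; ``true_origin`` (ground truth, only
    known for synthetic tiles) is where the tile actually sits.
    Origins are (x, y).
    """

    data: np.ndarray
    confidence: np.ndarray
    reported_origin: tuple[float, float]
    tile_id: int
    true_origin: tuple[float, float] | None = None
    grid_pos: tuple[int, int] | None = None


@dataclass
class PhantomConfig:
    # block / instrument geometry
    pixel_scale_um: float = 2.0
    tile_size_px: int = 128
    n_tiles: tuple[int, int] = (8, 8)       # (nx, ny)
    tile_overlap: float = 0.10
    slice_thickness_um: float = 15.0
    n_slices: int = 20
    # beads
    n_beads: int = 120
    bead_radius_um: float = 45.0
    bead_radius_sd_um: float = 2.0
    bead_amplitude: float = 250.0           # counts per um of attenuated chord
    # tissue
    n_blobs: int = 5
    blob_amplitude: float = 900.0
    tissue_radius_frac: float = 0.30        # tissue sits in this central fraction
    # confusers
    n_fragments: int = 0
    fragment_amplitude: float = 900.0
    # substrate autofluorescence texture (0 -> featureless substrate)
    texture_amplitude: float = 0.0
    texture_scale_um: float = 40.0
    # instrumental effects
    positioning_error_um: float = 7.5       # SD of reported-vs-true tile offsets
    drift_per_slice_um: tuple[float, float] = (1.5, 0.1)
    slice_jitter_um: float = 0.5
    dark_level: float = 10.0
    flatfield_amplitude: float = 0.0        # 0 -> unit flatfield
    distortion_amplitude_px: float = 0.0    # corner displacement of injected field
    poisson_noise: bool = True
    # optics of the bead model
    optics: OpticsParams = field(default_factory=OpticsParams)
    # precision of bead centroids when emitting jittered (fitted-like) catalogs
    centroid_jitter_px: float = 0.25

    @property
    def tile_stride_px(self) -> float:
        return self.tile_size_px * (1.0 - self.tile_overlap)

    @property
    def stage_size_px(self) -> tuple[int, int]:
        nx, ny = self.n_tiles
        w = int(round(self.tile_stride_px * (nx - 1) + self.tile_size_px))
        h = int(round(self.tile_stride_px * (ny - 1) + self.tile_size_px))
        return w, h

    @property
    def block_size_um(self) -> tuple[float, float, float]:
        w, h = self.stage_size_px
        return (w * self.pixel_scale_um, h * self.pixel_scale_um,
                self.n_slices * self.slice_thickness_um)


@dataclass
class PhantomSample:
    """A generated sample: bead/blob tables plus the stored ground truth."""

    config: PhantomConfig
    seed: int
    beads: pd.DataFrame          # bead_id, x_um, y_um, z_um, radius_um
    blobs: pd.DataFrame          # x_um, y_um, z_um, sx, sy, sz, amplitude, theta
    fragments: pd.DataFrame      # like blobs but small
    slice_offsets_um: np.ndarray  # (n_slices, 2) true stage drift per slice
    flatfield: np.ndarray | None
    distortion: "object | None" = None   # preprocess.DistortionModel
    texture_params: np.ndarray | None = None  # (n, 4): kx, ky, phase, amp

    @property
    def n_slices(self) -> int:
        return self.config.n_slices


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0,
                     **overrides) -> PhantomSample:
    """Draw a phantom sample; identical ``(config, seed)`` give identical output."""
    cfg = replace(config, **overrides) if config is not None else PhantomConfig(**overrides)
    bw, bh, bd = cfg.block_size_um
    if 2 * cfg.bead_radius_um >= bd:
        raise ValueError("bead diameter exceeds block thickness: impossible geometry")
    rng = np.random.default_rng([seed, 0x0BEAD])

    # tissue blobs concentrated in the center of the block
    cx, cy = bw / 2, bh / 2
    tissue_r = cfg.tissue_radius_frac * min(bw, bh)
    blobs = []
    for _ in range(cfg.n_blobs):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.5 * tissue_r)
        blobs.append(dict(
            x_um=cx + rad * np.cos(ang), y_um=cy + rad * np.sin(ang),
            z_um=rng.uniform(0.2 * bd, 0.8 * bd),
            sx=rng.uniform(0.25, 0.6) * tissue_r,
            sy=rng.uniform(0.25, 0.6) * tissue_r,
            sz=rng.uniform(0.3, 0.8) * bd,
            amplitude=cfg.blob_amplitude * rng.uniform(0.6, 1.0),
            theta=rng.uniform(0, np.pi),
        ))
    blobs = pd.DataFrame(blobs, columns=["x_um", "y_um", "z_um", "sx", "sy",
                                         "sz", "amplitude", "theta"])

    # beads in the substrate: keep clear of the tissue and of the stage edge
    margin = cfg.bead_radius_um + 4 * cfg.bead_radius_sd_um
    beads = []
    while len(beads) < cfg.n_beads:
        x = rng.uniform(margin, bw - margin)
        y = rng.uniform(margin, bh - margin)
        if np.hypot(x - cx, y - cy) < tissue_r + margin:
            continue
        r = rng.normal(cfg.bead_radius_um, cfg.bead_radius_sd_um)
        if r <= 5:
            continue
        # centers span the full block depth so every slice (including the
        # first and last) sees a comparable bead density; beads protruding
        # from the block top were simply cut by early sections
        z = rng.uniform(1.0, bd - 1.0)
        beads.append(dict(bead_id=len(beads), x_um=x, y_um=y, z_um=z, radius_um=r))
    beads = pd.DataFrame(beads)

    # small bright fragments: spurious near-point sources in the substrate
    fragments = []
    for _ in range(cfg.n_fragments):
        while True:
            x = rng.uniform(margin, bw - margin)
            y = rng.uniform(margin, bh - margin)
            if np.hypot(x - cx, y - cy) >= tissue_r + margin:
                break
        fragments.append(dict(
            x_um=x, y_um=y, z_um=rng.uniform(0.05 * bd, 0.95 * bd),
            sx=rng.uniform(4, 10), sy=rng.uniform(4, 10),
            sz=rng.uniform(4, 12),
            amplitude=cfg.fragment_amplitude * rng.uniform(0.5, 1.2),
            theta=rng.uniform(0, np.pi),
        ))
    fragments = pd.DataFrame(fragments, columns=blobs.columns)

    # per-slice stage drift: linear trend plus jitter
    k = np.arange(cfg.n_slices)[:, None]
    drift = k * np.asarray(cfg.drift_per_slice_um)[None, :]
    drift = drift + rng.normal(0, cfg.slice_jitter_um, size=(cfg.n_slices, 2))
    drift[0] = 0.0

    flat = None
    if cfg.flatfield_amplitude > 0:
        flat = _smooth_flatfield(cfg.tile_size_px, cfg.flatfield_amplitude,
                                 np.random.default_rng([seed, 0xF1A7]))

    dist = None
    if cfg.distortion_amplitude_px > 0:
        from .preprocess import DistortionModel
        dist = DistortionModel.synthetic(cfg.tile_size_px,
                                         cfg.distortion_amplitude_px,
                                         seed=seed)

    texture = None
    if cfg.texture_amplitude > 0:
        trng = np.random.default_rng([seed, 0x7E87])
        n_waves = 24
        ang = trng.uniform(0, 2 * np.pi, n_waves)
        wavelength = cfg.texture_scale_um * trng.uniform(0.5, 2.0, n_waves)
        kk = 2 * np.pi / wavelength
        texture = np.column_stack([
            kk * np.cos(ang), kk * np.sin(ang),
            trng.uniform(0, 2 * np.pi, n_waves),
            cfg.texture_amplitude / np.sqrt(n_waves) * trng.uniform(0.5, 1.5, n_waves),
        ])

    return PhantomSample(config=cfg, seed=seed, beads=beads, blobs=blobs,
                         fragments=fragments, slice_offsets_um=drift,
                         flatfield=flat, distortion=dist, texture_params=texture)


def _smooth_flatfield(size: int, amplitude: float, rng) -> np.ndarray:
    """A smooth multiplicative response field, median-normalized to 1."""
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    f = np.ones((size, size))
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 2.0, 2)
        px, py = rng.uniform(0, 2 * np.pi, 2)
        f += amplitude / 4 * np.cos(2 * np.pi * fx * xx + px) * np.cos(2 * np.pi * fy * yy + py)
    # vignetting-like radial term
    rr = np.hypot(xx - 0.5, yy - 0.5)
    f -= amplitude * 0.5 * rr ** 2
    return f / np.median(f)


# ---------------------------------------------------------------------------
# scene evaluation


def _surface_depth_um(cfg: PhantomConfig, z_index: int) -> float:
    return z_index * cfg.slice_thickness_um


def scene_at(sample: PhantomSample, x_um, y_um, z_index: int) -> np.ndarray:
    """Evaluate the noiseless emitted scene at arbitrary stage coordinates (um).

    The scene of slice ``z_index`` is what the excited layer below the
    current optical surface emits: sliced beads (via the physical bead
    model), tissue blobs, and fragments. Per-slice stage drift shifts the
    whole scene in the stage frame.
    """
    cfg = sample.config
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    dx, dy = sample.slice_offsets_um[z_index]
    # stage coords -> block coords
    bx = x - dx
    by = y - dy
    zsurf = _surface_depth_um(cfg, z_index)
    out = np.zeros(np.broadcast(bx, by).shape, dtype=float)

    for b in sample.beads.itertuples():
        depth = b.z_um - zsurf
        if not (-b.radius_um < depth - cfg.optics.zs < b.radius_um + cfg.optics.dz):
            continue
        m = (np.abs(bx - b.x_um) < b.radius_um + 2) & (np.abs(by - b.y_um) < b.radius_um + 2)
        if not m.any():
            continue
        out[m] += bead_profile(bx[m], by[m], b.x_um, b.y_um, b.radius_um, depth,
                               cfg.bead_amplitude, 0.0, cfg.optics,
                               pixel_scale_um=1.0)

    if sample.texture_params is not None:
        # substrate autofluorescence: a fixed sum of random plane waves,
        # offset-positive so counts stay non-negative
        tx = np.zeros_like(out)
        for kx, ky, ph, amp in sample.texture_params:
            tx += amp * np.cos(kx * bx + ky * by + ph)
        total_amp = np.abs(sample.texture_params[:, 3]).sum()
        out += np.clip(tx + 0.6 * total_amp, 0.0, None)

    zmid = zsurf + cfg.optics.z_mid
    for tbl in (sample.blobs, sample.fragments):
        for g in tbl.itertuples():
            c, s = np.cos(g.theta), np.sin(g.theta)
            u = (bx - g.x_um) * c + (by - g.y_um) * s
            v = -(bx - g.x_um) * s + (by - g.y_um) * c
            zq = ((zmid - g.z_um) / g.sz) ** 2
            if zq > 12:
                continue
            q = (u / g.sx) ** 2 + (v / g.sy) ** 2 + zq
            out += g.amplitude * np.exp(-0.5 * np.clip(q, None, 60.0))
    return out


def render_scene(sample: PhantomSample, z_index: int,
                 downsample: int = 1) -> np.ndarray:
    """Render the full noiseless stage scene of a slice (rows = y)."""
    cfg = sample.config
    w, h = cfg.stage_size_px
    step = downsample
    ys = (np.arange(0, h, step) + 0.5 * (step - 1)) * cfg.pixel_scale_um
    xs = (np.arange(0, w, step) + 0.5 * (step - 1)) * cfg.pixel_scale_um
    xx, yy = np.meshgrid(xs, ys)
    return scene_at(sample, xx, yy, z_index)


def tile_grid_origins(cfg: PhantomConfig) -> list[tuple[int, float, float, int, int]]:
    """Nominal tile origins (tile_id, x_px, y_px, ix, iy) on the stage."""
    nx, ny = cfg.n_tiles
    out = []
    tid = 0
    for iy in range(ny):
        for ix in range(nx):
            out.append((tid, ix * cfg.tile_stride_px, iy * cfg.tile_stride_px, ix, iy))
            tid += 1
    return out


def render_stpt_slice(sample: PhantomSample, z_index: int,
                      apply_flatfield: bool = True,
                      apply_distortion: bool = True,
                      noise: bool | None = None) -> list[Tile]:
    """Render one slice as a set of overlapping raw tiles.

    The reported stage positions are the nominal grid positions; the true
    positions are perturbed by the stage positioning error (the microscope
    *reports* the commanded grid, the stage *lands* slightly off), so
    reported-vs-true offsets have SD ``positioning_error_um``.
    Intensities are ``flatfield x distorted(scene) + dark`` with Poisson
    counting noise.
    """
    cfg = sample.config
    if not 0 <= z_index < cfg.n_slices:
        raise ValueError(f"z_index {z_index} outside block (0..{cfg.n_slices - 1})")
    if noise is None:
        noise = cfg.poisson_noise
    rng = np.random.default_rng([sample.seed, 0x7117E5, z_index])
    ts = cfg.tile_size_px
    err_px = cfg.positioning_error_um / cfg.pixel_scale_um

    tiles: list[Tile] = []
    for tid, ox, oy, ix, iy in tile_grid_origins(cfg):
        true_ox = ox + rng.normal(0, err_px)
        true_oy = oy + rng.normal(0, err_px)
        yy, xx = np.mgrid[0:ts, 0:ts].astype(float)
        if apply_distortion and sample.distortion is not None:
            # raw pixel (i,j) actually looked at distorted scene position
            xx, yy = sample.distortion.distort(xx, yy)
        sx = (xx + true_ox) * cfg.pixel_scale_um
        sy = (yy + true_oy) * cfg.pixel_scale_um
        clean = scene_at(sample, sx, sy, z_index)
        if apply_flatfield and sample.flatfield is not None:
            clean = clean * sample.flatfield
        clean = clean + cfg.dark_level
        data = rng.poisson(np.clip(clean, 0, None)).astype(float) if noise else clean
        tiles.append(Tile(data=data, confidence=np.ones((ts, ts)),
                          reported_origin=(ox, oy), tile_id=tid,
                          true_origin=(true_ox, true_oy), grid_pos=(ix, iy)))
    return tiles


def true_bead_catalog(sample: PhantomSample, z_index: int,
                      min_proj_radius_um: float = 4.0,
                      jitter_px: float = 0.0,
                      rng=None) -> pd.DataFrame:
    """Ground-truth bead catalog of a slice in stage-frame pixels.

    With ``jitter_px > 0``, centers are perturbed by isotropic Gaussian
    noise, emulating the precision of the profile fitter.
    """
    cfg = sample.config
    zmid = _surface_depth_um(cfg, z_index) + cfg.optics.z_mid
    dx, dy = sample.slice_offsets_um[z_index]
    rows = []
    for b in sample.beads.itertuples():
        r = projected_radius(b.radius_um, b.z_um - zmid)
        if r < min_proj_radius_um:
            continue
        rows.append(dict(bead_id=b.bead_id,
                         x=(b.x_um + dx) / cfg.pixel_scale_um,
                         y=(b.y_um + dy) / cfg.pixel_scale_um,
                         r_proj_um=float(r), radius_um=b.radius_um,
                         depth_um=b.z_um - zmid))
    cat = pd.DataFrame(rows, columns=["bead_id", "x", "y", "r_proj_um",
                                      "radius_um", "depth_um"])
    if jitter_px > 0 and len(cat):
        if rng is None:
            rng = np.random.default_rng([sample.seed, 0xCA7, z_index])
        cat[["x", "y"]] += rng.normal(0, jitter_px, size=(len(cat), 2))
    return cat


# ---------------------------------------------------------------------------
# second modality (slide-scanner-like whole-slice rendering)


def render_second_modality(sample: PhantomSample, z_index: int,
                           orientation: Orientation | None = None,
                           affine_perturbation: AffineTransform | None = None,
                           noise: float = 0.0,
                           out_shape: tuple[int, int] | None = None,
                           seed: int | None = None):
    """Render a whole-slice image under a known flip + affine perturbation.

    Returns ``(image, truth)`` where ``truth`` is a dict with the recorded
    ground-truth transform ``slide_to_stage`` (slide px -> stage px), the
    orientation, and the slide-frame bead catalog. ``z_index`` may be any
    physical slice of the block; rendering a plane the volume never imaged
    (``z_index < 0``) produces an orphan slide with valid ground truth but
    no matching volume slice.
    """
    cfg = sample.config
    orientation = orientation or Orientation()
    w, h = cfg.stage_size_px
    out_shape = out_shape or (h, w)
    oh, ow = out_shape

    flip = orientation.as_affine(ow, oh)
    pert = affine_perturbation or AffineTransform.identity()
    # slide px -> stage px: undo the flip, then the perturbation
    slide_to_stage = pert.compose(flip)
    slide_to_stage = AffineTransform(slide_to_stage.linear, slide_to_stage.translation,
                                     src_frame="slide", dst_frame="stage")

    yy, xx = np.mgrid[0:oh, 0:ow].astype(float)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    stage_px = slide_to_stage.apply(pts)
    img = scene_at(sample,
                   stage_px[:, 0].reshape(oh, ow) * cfg.pixel_scale_um,
                   stage_px[:, 1].reshape(oh, ow) * cfg.pixel_scale_um,
                   max(z_index, 0)).astype(float)
    if z_index < 0:
        # orphan physical slice: content the volume never imaged
        rng0 = np.random.default_rng([sample.seed, 0x0FA2])
        img = rng0.gamma(2.0, 20.0, size=img.shape)
    if noise > 0:
        rng = np.random.default_rng([seed if seed is not None else sample.seed,
                                     0x51DE, max(z_index, 0)])
        img = img + rng.normal(0, noise, size=img.shape)

    stage_to_slide = slide_to_stage.invert()
    if z_index >= 0:
        cat = true_bead_catalog(sample, z_index)
        if len(cat):
            sl = stage_to_slide.apply(cat[["x", "y"]].to_numpy())
            cat = cat.assign(x=sl[:, 0], y=sl[:, 1])
            inside = (cat.x >= 0) & (cat.x < ow) & (cat.y >= 0) & (cat.y < oh)
            cat = cat[inside].reset_index(drop=True)
    else:
        cat = pd.DataFrame(columns=["bead_id", "x", "y", "r_proj_um",
                                    "radius_um", "depth_um"])
    truth = dict(slide_to_stage=slide_to_stage, orientation=orientation,
                 bead_catalog=cat, z_index=z_index)
    return img, truth


# ---------------------------------------------------------------------------
# probability-map fixture for the cell segmentation module


def render_probability_map(n_cells: int = 200, shape: tuple[int, int] = (600, 600),
                           nucleus_radius_px: float = 8.0,
                           cell_radius_px: float = 14.0,
                           min_separation_px: float | None = None,
                           noise: float = 0.05, seed: int = 0):
    """Synthesize a 3-channel (background, nucleus, cytoplasm) probability map.

    Nuclei are rendered as smooth super-Gaussian peaks, cytoplasm as annuli
    out to the cell radius; channels sum to 1 per pixel. Returns
    ``(prob_map, truth)`` with ground-truth cell/nucleus label images and
    the center table.
    """
    rng = np.random.default_rng([seed, 0xCE11])
    h, w = shape
    # moderate nuclear overlap: centers may sit closer than two radii
    min_sep = min_separation_px if min_separation_px is not None else 1.5 * nucleus_radius_px

    centers: list[tuple[float, float]] = []
    attempts = 0
    pad = nucleus_radius_px + 2
    while len(centers) < n_cells and attempts < 300 * n_cells:
        attempts += 1
        x = rng.uniform(pad, w - pad)
        y = rng.uniform(pad, h - pad)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep ** 2 for cx, cy in centers):
            centers.append((x, y))
    centers_arr = np.array(centers)
    n = len(centers_arr)

    from scipy.spatial import cKDTree
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(centers_arr)
    dist, idx = tree.query(pix, k=1)
    dist = dist.reshape(h, w)
    idx = idx.reshape(h, w)

    cell_labels = np.where(dist <= cell_radius_px, idx + 1, 0).astype(np.int32)
    nucleus_labels = np.where(dist <= nucleus_radius_px, idx + 1, 0).astype(np.int32)

    # smooth class scores -> probabilities
    p_nuc = np.exp(-(dist / nucleus_radius_px) ** 4)
    ring = np.exp(-((dist - 0.5 * (nucleus_radius_px + cell_radius_px))
                    / (0.6 * (cell_radius_px - nucleus_radius_px))) ** 2)
    p_cyt = np.clip(ring * (dist > 0.6 * nucleus_radius_px), 0, 1) * (dist <= cell_radius_px + 2)
    p_bg = np.clip(1.0 - p_nuc - p_cyt, 0.05, None)
    probs = np.stack([p_bg, p_nuc, p_cyt]).astype(float)
    if noise > 0:
        probs = np.clip(probs + rng.normal(0, noise, size=probs.shape), 1e-6, None)
    probs /= probs.sum(axis=0, keepdims=True)

    truth = dict(centers=centers_arr, cell_labels=cell_labels,
                 nucleus_labels=nucleus_labels, n_cells=n)
    return probs, truth
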