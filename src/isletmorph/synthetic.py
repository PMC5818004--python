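"""Ground-truthed synthetic microscopy scenes.

Generates blurred, noisy renderings of the anatomy the analysis pipeline
is built for: an ellipsoidal exocrine "pancreas" blob in the red channel
containing spherical endocrine cells in the green channel; 4D series in
which cell centres move under an attraction-plus-noise motion model; and
2D cells bearing thin (< 2 µm) filopodia whose lengths follow piecewise
linear extension/retraction programs.  Every renderer returns the exact
geometry it drew (before blur and noise) so downstream segmentation,
tracking, morphometry and kinetics can be validated against known truth.

Noise model: Poisson shot noise on the signal plus additive Gaussian
read noise — the standard fluorescence imaging model.  The point spread
function is approximated by an anisotropic Gaussian; this is sufficient
to exercise segmentation tolerance and makes no attempt at optical
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .image import VolumetricImage

__all__ = [
    "SceneSpec",
    "MotionSpec",
    "FilopodiumSpec",
    "GroundTruth",
    "sample_cell_centers",
    "render_scene",
    "simulate_motion",
    "render_cell_frames",
    "star_polygon",
    "rasterize_polygon",
    "filopodium_lengths",
    "render_filopodium_frames",
    "sample_filopodium_cohort",
]


@dataclass
class SceneSpec:
    """Geometry, optics and noise of one synthetic two-channel stack.

    All lengths in µm; ``grid_shape`` and ``voxel_size`` are axis order
    ``(z, y, x)`` and may be anisotropic (confocal z-step > xy pixel).
    ``noise_gaussian_sd`` is additive read noise (intensity units);
    ``noise_poisson_scale`` is the photon count per intensity unit for
    shot noise (``None`` disables it).  ``psf_sigma`` of zero disables
    blurring.
    """

    grid_shape: tuple[int, int, int] = (40, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)
    pancreas_center: tuple[float, float, float] | None = None
    pancreas_semiaxes: tuple[float, float, float] = (14.0, 36.0, 16.0)
    n_cells: int = 8
    cell_radius_range: tuple[float, float] = (2.5, 4.0)
    psf_sigma: tuple[float, float, float] = (1.0, 0.4, 0.4)
    noise_gaussian_sd: float = 2.0
    noise_poisson_scale: float | None = 1.0
    red_amplitude: float = 100.0
    green_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pancreas_center is None:
            self.pancreas_center = tuple(
                n * s / 2 for n, s in zip(self.grid_shape, self.voxel_size)
            )
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(a <= 0 for a in self.pancreas_semiaxes):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.cell_radius_range[0] <= 0 or self.cell_radius_range[1] < self.cell_radius_range[0]:
            raise ValueError("cell_radius_range must be positive and ordered")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


@dataclass
class MotionSpec:
    """Attraction-plus-diffusion motion of cell centres.

    Each Euler step moves every centre a fraction ``attraction_rate*dt``
    toward the instantaneous group centroid and adds isotropic Gaussian
    noise of standard deviation ``diffusion_sd*sqrt(dt)`` per axis — a
    minimal stand-in for the observed coalescence of tracked endocrine
    cells.
    """

    attraction_rate: float = 0.05  # 1/min toward the group centroid
    diffusion_sd: float = 0.3  # µm per sqrt(min)
    dt: float = 3.0  # min
    n_frames: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attraction_rate < 0:
            raise ValueError("attraction_rate must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class FilopodiumSpec:
    """Piecewise-linear length program of one thin protrusion.

    ``segments`` is a list of ``(duration_min, rate_um_per_min)`` pairs;
    positive rates extend, negative rates retract.  The implied length
    trajectory must never go negative and the diameter must stay below
    the 2 µm bound that defines a filopodium here.
    """

    base: tuple[float, ...] = (0.0, 0.0)
    direction: tuple[float, ...] = (0.0, 1.0)
    segments: tuple[tuple[float, float], ...] = ((1.0, 3.2), (1.0, -2.9))
    diameter: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.diameter < 2.0):
            raise ValueError("filopodium diameter must be in (0, 2) µm")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be a nonzero vector")
        self.direction = tuple(d / n)
        length = 0.0
        for dur, rate in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            length += dur * rate
            if length < -1e-9:
                raise ValueError("length program goes negative")


@dataclass
class GroundTruth:
    """Exact geometry behind a rendered scene, recorded before blur/noise."""

    cell_centers: np.ndarray | None = None  # (n, 3) µm, or (T, n, 3) per frame
    cell_radii: np.ndarray | None = None  # µm
    islet_volumes: list[float] = field(default_factory=list)  # analytic, µm³
    pancreas_mask: np.ndarray | None = None
    cell_labels: np.ndarray | None = None  # voxelized spheres, integer labels
    filopodium_lengths: np.ndarray | None = None  # per frame, µm
    body_radius: float | None = None  # µm (2D cell fixtures)
    protrusions: list[dict] = field(default_factory=list)
    seed: int | None = None


def _grids(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def sample_cell_centers(spec: SceneSpec, margin: float = 1.0) -> np.ndarray:
    """Draw ``n_cells`` centres uniformly inside the pancreas ellipsoid.

    ``margin`` shrinks the admissible ellipsoid by the cell radius plus
    this many µm so whole cells stay inside the blob.
    """
    rng = np.random.default_rng(spec.seed)
    rmax = spec.cell_radius_range[1]
    c = np.asarray(spec.pancreas_center)
    semi = np.asarray(spec.pancreas_semiaxes) - (rmax + margin)
    if np.any(semi <= 0):
        raise ValueError("pancreas too small for the requested cell radii")
    out = []
    while len(out) < spec.n_cells:
        u = rng.uniform(-1, 1, size=3)
        if np.sum(u**2) <= 1.0:
            out.append(c + semi * u)
    return np.array(out).reshape(spec.n_cells, 3)


def _apply_noise(signal: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = signal
    if spec.noise_poisson_scale:
        scale = float(spec.noise_poisson_scale)
        out = rng.poisson(np.clip(out, 0, None) * scale).astype(float) / scale
    if spec.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.noise_gaussian_sd, size=out.shape)
    return out


def render_scene(
    spec: SceneSpec,
    centers: np.ndarray | None = None,
    radii: np.ndarray | float | None = None,
) -> tuple[VolumetricImage, VolumetricImage, GroundTruth]:
    """Render the two-channel stack: red ellipsoid blob, green cell spheres.

    Returns ``(red, green, truth)``.  ``truth`` carries the voxelized
    pancreas mask, per-cell labelled sphere masks and the analytic
    sphere volumes ``(4/3)πr³`` — all recorded before PSF blur and noise
    are applied.  Identical spec (and centres) produce bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    if centers is None:
        centers = sample_cell_centers(spec)
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if radii is None:
        radii = np.random.default_rng(spec.seed + 1).uniform(
            *spec.cell_radius_range, size=len(centers)
        )
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(centers),)).copy()
    if np.any(radii <= 0):
        raise ValueError("cell radii must be positive")
    extent = np.array([n * s for n, s in zip(spec.grid_shape, spec.voxel_size)])
    for i, ctr in enumerate(centers):
        if np.any(ctr < 0) or np.any(ctr > extent):
            raise ValueError(f"cell {i} centre {tuple(ctr)} lies outside the grid {tuple(extent)}")

    zz, yy, xx = _grids(spec.grid_shape, spec.voxel_size)
    c = spec.pancreas_center
    a = spec.pancreas_semiaxes
    pancreas = (
        ((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2 + ((xx - c[2]) / a[2]) ** 2
    ) <= 1.0

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    for i, (ctr, r) in enumerate(zip(centers, radii), start=1):
        sphere = ((zz - ctr[0]) ** 2 + (yy - ctr[1]) ** 2 + (xx - ctr[2]) ** 2) <= r**2
        labels[sphere] = i

    red = pancreas.astype(float) * spec.red_amplitude
    green = (labels > 0).astype(float) * spec.green_amplitude
    if any(s > 0 for s in spec.psf_sigma):
        sig_vox = np.asarray(spec.psf_sigma) / np.asarray(spec.voxel_size)
        red = ndimage.gaussian_filter(red, sig_vox)
        green = ndimage.gaussian_filter(green, sig_vox)
    red = _apply_noise(red, spec, rng)
    green = _apply_noise(green, spec, rng)

    truth = GroundTruth(
        cell_centers=centers,
        cell_radii=radii,
        islet_volumes=[(4.0 / 3.0) * np.pi * float(r) ** 3 for r in radii],
        pancreas_mask=pancreas,
        cell_labels=labels,
        seed=spec.seed,
    )
    red_im = VolumetricImage(red, spec.voxel_size, channel_label="red")
    green_im = VolumetricImage(green, spec.voxel_size, channel_label="green")
    return red_im, green_im, truth


def simulate_motion(motion: MotionSpec, initial_centers: np.ndarray) -> np.ndarray:
    """Euler-integrate attraction-plus-noise motion of cell centres.

    Update per step: ``x <- x + attraction_rate * (centroid - x) * dt
    + N(0, diffusion_sd² * dt)``.  Returns an array of shape
    ``(n_frames, n_cells, 3)`` whose first frame is the initial state.
    With zero noise every centre's distance to the (fixed) centroid is
    multiplied by ``1 - attraction_rate*dt`` each step, so the convex
    hull contracts by exactly that linear factor per frame.
    """
    x = np.asarray(initial_centers, dtype=float).reshape(-1, 3)
    if len(x) < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(motion.seed)
    frames = [x.copy()]
    for _ in range(motion.n_frames - 1):
        centroid = x.mean(axis=0)
        x = x + motion.attraction_rate * (centroid - x) * motion.dt
        if motion.diffusion_sd > 0:
            x = x + rng.normal(0.0, motion.diffusion_sd * np.sqrt(motion.dt), size=x.shape)
        frames.append(x.copy())
    return np.array(frames)


def render_cell_frames(
    body_radius: float = 5.0,
    n_protrusions: int = 0,
    protrusion_length: float = 4.0,
    protrusion_width: float = 1.0,
    pixel_size: float = 0.2,
    shape: tuple[int, int] | None = None,
    n_frames: int = 1,
    angle_offset: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a disk-bodied cell with ``n_protrusions`` radial spikes.

    All lengths in µm.  Returns ``(masks, truth)`` where ``masks`` has
    shape ``(n_frames, ny, nx)`` (frames are identical; the series form
    feeds per-frame morphometry).  Protrusions are thin rectangles of
    the given width reaching ``protrusion_length`` beyond the body
    boundary, evenly spaced in angle.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    reach = body_radius + (protrusion_length if n_protrusions else 0.0)
    if shape is None:
        n = int(np.ceil(2 * (reach + 2.0) / pixel_size))
        shape = (n, n)
    extent = np.array(shape) * pixel_size
    center = extent / 2.0
    if reach > min(center):
        raise ValueError("protrusion reaches beyond the grid")

    yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * pixel_size,
        (np.arange(shape[1]) + 0.5) * pixel_size,
        indexing="ij",
    )
    dy, dx = yy - center[0], xx - center[1]
    mask = dy**2 + dx**2 <= body_radius**2
    protrusions = []
    for k in range(n_protrusions):
        theta = angle_offset + 2 * np.pi * k / n_protrusions
        u = np.array([np.sin(theta), np.cos(theta)])  # (y, x) direction
        along = dy * u[0] + dx * u[1]
        across = -dy * u[1] + dx * u[0]
        spike = (
            (along >= 0)
            & (along <= body_radius + protrusion_length)
            & (np.abs(across) <= protrusion_width / 2.0)
        )
        mask |= spike
        protrusions.append(
            {"angle": theta, "length": protrusion_length, "width": protrusion_width}
        )
    masks = np.repeat(mask[None], n_frames, axis=0)
    truth = GroundTruth(body_radius=body_radius, protrusions=protrusions)
    return masks, truth


def star_polygon(
    n_arms: int = 5,
    r_outer: float = 10.0,
    r_inner: float = 4.0,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float = -np.pi / 2,
) -> np.ndarray:
    """Vertex list (y, x in µm) of a regular star, outer/inner radii alternating."""
    angles = phase + np.pi * np.arange(2 * n_arms) / n_arms
    radii = np.where(np.arange(2 * n_arms) % 2 == 0, r_outer, r_inner)
    return np.column_stack([center[0] + radii * np.sin(angles), center[1] + radii * np.cos(angles)])


def rasterize_polygon(
    vertices: np.ndarray, pixel_size: float, pad: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask of a polygon given in µm; returns (mask, shifted vertices µm)."""
    v = np.asarray(vertices, dtype=float)
    lo = v.min(axis=0) - pad
    v_shift = v - lo
    shape = tuple(np.ceil((v_shift.max(axis=0) + pad) / pixel_size).astype(int))
    rr, cc = draw_polygon(v_shift[:, 0] / pixel_size - 0.5, v_shift[:, 1] / pixel_size - 0.5, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask, v_shift


def filopodium_lengths(
    spec: FilopodiumSpec, frame_times: np.ndarray, initial_length: float = 0.0
) -> np.ndarray:
    """Length (µm) at each frame time (min) under the piecewise-linear program.

    The length is the running integral of the segment rates starting
    from ``initial_length``; after the last segment the length holds.
    """
    times = np.asarray(frame_times, dtype=float)
    # breakpoints and lengths at them
    bp_t = [0.0]
    bp_l = [initial_length]
    for dur, rate in spec.segments:
        bp_t.append(bp_t[-1] + dur)
        bp_l.append(bp_l[-1] + dur * rate)
    lengths = np.interp(times, bp_t, bp_l)
    if np.any(lengths < -1e-9):
        raise ValueError("length program goes negative at a sampled time")
    return np.clip(lengths, 0.0, None)


def render_filopodium_frames(
    spec: FilopodiumSpec,
    frame_times: np.ndarray,
    body_radius: float = 4.0,
    pixel_size: float = 0.2,
    shape: tuple[int, int] | None = None,
    initial_length: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """2D mask series of a disk cell with one filopodium of programmed length.

    The filopodium is a thin rectangle from the body boundary along
    ``spec.direction``; its length per frame follows the spec's segment
    program.  Returns ``(masks, truth)`` with the exact lengths in
    ``truth.filopodium_lengths``.
    """
    lengths = filopodium_lengths(spec, frame_times, initial_length)
    reach = body_radius + float(lengths.max())
    if shape is None:
        n = int(np.ceil(2 * (reach + 2.0) / pixel_size))
        shape = (n, n)
    extent = np.array(shape) * pixel_size
    center = extent / 2.0
    if reach > min(center):
        raise ValueError("filopodium reaches beyond the grid")
    yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * pixel_size,
        (np.arange(shape[1]) + 0.5) * pixel_size,
        indexing="ij",
    )
    dy, dx = yy - center[0], xx - center[1]
    body = dy**2 + dx**2 <= body_radius**2
    u = np.asarray(spec.direction[-2:], dtype=float)
    u = u / np.linalg.norm(u)
    along = dy * u[0] + dx * u[1]
    across = -dy * u[1] + dx * u[0]
    masks = []
    for L in lengths:
        m = body.copy()
        if L > 0:
            m |= (
                (along >= 0)
                & (along <= body_radius + L)
                & (np.abs(across) <= spec.diameter / 2.0)
            )
        masks.append(m)
    truth = GroundTruth(filopodium_lengths=lengths, body_radius=body_radius)
    return np.array(masks), truth


def sample_filopodium_cohort(
    n: int = 41,
    seed: int = 0,
    frame_interval: float = 0.25,
    mean_extension: float = 3.2,
    mean_retraction: float = 2.9,
    between_sd: float = 1.0,
    within_sd: float = 0.4,
    length_log_mu: float = 1.755,
    length_log_sigma: float = 0.656,
):
    """Simulate a cohort of filopodium length traces with known kinetics.

    Each filopodium draws its characteristic extension and retraction
    speeds from normal distributions around the cohort means (µm/min,
    truncated at 0.5), a maximal length from a lognormal (defaults put
    ~75% of maxima below 9 µm and a small tail beyond 15 µm), then
    extends to that length and retracts back, with per-interval rate
    noise of ``within_sd`` µm/min on top (default 0.4, i.e. ~0.1 µm of
    length jitter per 15 s frame — the scale the rate dead-band is
    built to suppress).  Frame interval defaults to 15 s.  Returns
    ``(traces, cohort_truth)`` where ``cohort_truth`` records both the
    drawn per-filopodium speeds and the realized per-phase rates (the
    phase-final step is truncated at the length bounds, so realized
    rates are the exact ground truth for recovery checks).
    """
    from .filopodia import trace_from_lengths

    rng = np.random.default_rng(seed)
    traces = []
    truth = {
        "extension_rates": [],
        "retraction_rates": [],
        "realized_extension_rates": [],
        "realized_retraction_rates": [],
        "max_lengths": [],
    }
    for i in range(n):
        re_i = max(0.5, rng.normal(mean_extension, between_sd))
        rr_i = max(0.5, rng.normal(mean_retraction, between_sd))
        lmax = float(rng.lognormal(length_log_mu, length_log_sigma))
        lengths = [0.0]
        ext_steps, ret_steps = [], []
        # extension phase up to lmax, then retraction back to zero; the
        # phase-final steps are truncated at the bounds, so the realized
        # per-phase rates (recorded below) are the ground truth a
        # phase-aware observer would measure
        while lengths[-1] < lmax:
            step = rng.normal(re_i, within_sd) * frame_interval
            new = min(lmax, max(0.0, lengths[-1] + step))
            ext_steps.append(new - lengths[-1])
            lengths.append(new)
        while lengths[-1] > 0.0:
            step = rng.normal(rr_i, within_sd) * frame_interval
            new = max(0.0, lengths[-1] - step)
            ret_steps.append(lengths[-1] - new)
            lengths.append(new)
        times = np.arange(len(lengths)) * frame_interval
        traces.append(trace_from_lengths(np.array(lengths), times, filopodium_id=i))
        truth["extension_rates"].append(re_i)
        truth["retraction_rates"].append(rr_i)
        pos = [s for s in ext_steps if s > 0]
        neg = [s for s in ret_steps if s > 0]
        truth["realized_extension_rates"].append(
            np.mean(pos) / frame_interval if pos else np.nan
        )
        truth["realized_retraction_rates"].append(
            np.mean(neg) / frame_interval if neg else np.nan
        )
        truth["max_lengths"].append(lmax)
    return traces, {k: np.array(v) for k, v in truth.items()}
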