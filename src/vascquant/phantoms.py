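"""Digital phantoms with known ground truth.

Three phantom families feed the pipeline:

* multi-b-value DWI volumes whose voxels follow the two-compartment
  (IVIM-style) biexponential decay
  ``S(b) = s0 * (f * exp(-b*d_star) + (1-f) * exp(-b*d))``,
* paired pre/post-contrast CT volumes in Hounsfield units with an
  enhancing parenchyma and a hypodense necrotic core,
* 2-D histology renderings: dark stained structures on bright tissue
  (microvessel counting) and bright fluorescent beads on dark background.

Every generator is deterministic for a fixed seed and reports the ground
truth it embedded (tissue maps, necrotic masks, structure counts), so the
quantification modules can be tested for exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

# Tissue class labels shared by the DWI and CT phantoms.
BACKGROUND = 0
VIABLE = 1
NECROSIS = 2
STROMA = 3

CLASS_NAMES = {BACKGROUND: "background", VIABLE: "viable",
               NECROSIS: "necrosis", STROMA: "stroma"}

#: b-values of the emulated acquisition protocol, s/mm^2.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0,
                    500.0, 750.0, 1000.0)

LOW_B_SUBSET = (50.0, 100.0, 150.0)
HIGH_B_SUBSET = (500.0, 750.0, 1000.0)


@dataclass(frozen=True)
class IVIMParams:
    """Two-compartment diffusion parameters of one tissue class.

    Parameters
    ----------
    s0 : float
        Baseline (b=0) signal, arbitrary units, > 0.
    f : float
        Perfusion (pseudo-diffusion) volume fraction in [0, 1].
    d : float
        Tissue diffusion coefficient, mm^2/s, >= 0.
    d_star : float
        Pseudo-diffusion coefficient of the microvascular compartment,
        mm^2/s.  Must satisfy ``d_star >= d`` whenever ``f > 0``: the
        perfusion compartment decays faster than true diffusion.
    """

    s0: float
    f: float
    d: float
    d_star: float = 0.0

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"perfusion fraction f must be in [0, 1], got {self.f}")
        if self.d < 0:
            raise ValueError(f"d must be non-negative, got {self.d}")
        if self.f > 0 and self.d_star < self.d:
            raise ValueError(
                f"d_star ({self.d_star}) must be >= d ({self.d}) when f > 0")


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Biexponential IVIM signal at diffusion weighting ``b`` (s/mm^2).

    Evaluates ``s0 * (f * exp(-b*d_star) + (1-f) * exp(-b*d))``; strictly
    decreasing in ``b`` when ``d > 0``.  ``b`` may be a scalar or array.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    out = params.s0 * (params.f * np.exp(-b_arr * params.d_star)
                       + (1.0 - params.f) * np.exp(-b_arr * params.d))
    if np.isscalar(b) or b_arr.ndim == 0:
        return float(out)
    return out


@dataclass
class DWIPhantomSpec:
    """Recipe for a multi-b-value DWI phantom volume."""

    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]  # mm per axis
    b_values: Sequence[float] = DEFAULT_B_VALUES
    tissue_map: np.ndarray | None = None       # per-voxel class labels
    class_params: Mapping[int, IVIMParams] = field(default_factory=dict)
    noise_model: Literal["none", "gaussian", "rician"] = "none"
    noise_sigma: float = 0.0                   # signal units, per acquisition
    n_averages: int = 1                        # magnitude averages per b-value
    seed: int = 0

    def validate(self) -> None:
        if len(self.b_values) == 0:
            raise ValueError("b_values must be non-empty")
        b = np.asarray(self.b_values, dtype=float)
        if np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be non-negative and strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.tissue_map is None:
            raise ValueError("tissue_map is required")
        if tuple(self.tissue_map.shape) != tuple(self.grid_shape):
            raise ValueError("tissue_map shape must equal grid_shape")
        labels = set(np.unique(self.tissue_map).tolist())
        labels.discard(BACKGROUND)
        missing = labels - set(self.class_params)
        if missing:
            raise ValueError(f"no IVIM parameters for class labels {sorted(missing)}")


def generate_dwi_phantom(spec: DWIPhantomSpec):
    """Render a DWI phantom; returns ``(BValueStack, class_params)``.

    With ``noise_model='none'`` every voxel equals :func:`ivim_signal`
    exactly and background voxels carry signal 0.  Rician noise replaces
    the signal by ``sqrt((S+n1)^2 + n2^2)`` with i.i.d. Gaussian ``n1, n2``
    (magnitude-MR statistics); Gaussian noise adds ``n1`` only.  The
    delivered image is the mean of ``n_averages`` independent noisy
    acquisitions, emulating trace averaging over diffusion directions and
    signal averages (the noiseless signal itself is direction-free, so
    averaging only affects the noise level).  One root seed is split per
    b-value so partial regeneration is stable.
    """
    from vascquant.dwi import BValueStack  # local import to avoid a cycle

    spec.validate()
    b = np.asarray(spec.b_values, dtype=float)
    signal = np.zeros(spec.grid_shape + (len(b),), dtype=float)
    for label, params in spec.class_params.items():
        mask = spec.tissue_map == label
        if not mask.any():
            continue
        signal[mask, :] = ivim_signal(params, b)

    if spec.noise_model != "none" and spec.noise_sigma > 0:
        if spec.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
        child_seeds = np.random.SeedSequence(spec.seed).spawn(len(b))
        for k in range(len(b)):
            rng = np.random.default_rng(child_seeds[k])
            clean = signal[..., k].copy()
            acc = np.zeros_like(clean)
            for _ in range(max(1, spec.n_averages)):
                n1 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
                if spec.noise_model == "rician":
                    n2 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
                    acc += np.hypot(clean + n1, n2)
                else:
                    acc += clean + n1
            # magnitude images are non-negative; clip the additive model too
            signal[..., k] = np.maximum(acc / max(1, spec.n_averages), 0.0)

    stack = BValueStack(signal=signal, b_values=b,
                        voxel_spacing=np.asarray(spec.voxel_spacing, float))
    return stack, dict(spec.class_params)


def generate_piecewise_phantom(d_high: float, excess_low: float,
                               b_values: Sequence[float] = DEFAULT_B_VALUES,
                               grid_shape: tuple[int, int, int] = (4, 4, 2),
                               s0: float = 100.0,
                               low_subset: Sequence[float] = LOW_B_SUBSET,
                               high_subset: Sequence[float] = HIGH_B_SUBSET):
    """Exact-recovery fixture for the low-b/high-b ADC subtraction.

    Signals at the high-b subset follow ``exp(-b*d_high)``; at the low-b
    subset they follow ``exp(-b*(d_high+excess_low))``, so the downstream
    high-b fit recovers ``d_high`` and the low-minus-high subtraction
    recovers ``excess_low`` exactly.  Remaining b-values (0, 200-300) are
    filled from the high-b exponential; they are carried but unused.
    """
    from vascquant.dwi import BValueStack

    if d_high < 0 or excess_low < 0:
        raise ValueError("d_high and excess_low must be non-negative")
    b = np.asarray(b_values, dtype=float)
    if not set(low_subset) <= set(b.tolist()) or not set(high_subset) <= set(b.tolist()):
        raise ValueError("b_values must contain both the low-b and high-b subsets")
    decay = np.exp(-b * d_high)
    low = np.isin(b, np.asarray(low_subset, float))
    decay[low] = np.exp(-b[low] * (d_high + excess_low))
    signal = np.broadcast_to(s0 * decay, grid_shape + (len(b),)).copy()
    return BValueStack(signal=signal, b_values=b,
                       voxel_spacing=np.ones(3))


@dataclass
class CTPhantomSpec:
    """Recipe for a paired pre/post-contrast CT phantom (HU)."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_spacing: tuple[float, float, float] = (0.42, 0.42, 0.75)  # mm
    class_mean_hu_pre: Mapping[str, float] = field(
        default_factory=lambda: {"background": -1000.0, "viable": 31.0,
                                 "necrosis": 25.0})
    class_mean_hu_post: Mapping[str, float] = field(
        default_factory=lambda: {"background": -1000.0, "viable": 115.0,
                                 "necrosis": 20.0})
    necrotic_fraction: float = 0.0
    semi_axes_frac: float = 0.38  # tumour half-axes as fraction of the grid
    noise_sigma: float = 0.0  # HU
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.necrotic_fraction <= 1.0:
            raise ValueError(
                f"necrotic_fraction must be in [0, 1], got {self.necrotic_fraction}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for m in (self.class_mean_hu_pre, self.class_mean_hu_post):
            for key in ("background", "viable", "necrosis"):
                if key not in m:
                    raise ValueError(f"missing HU mean for class {key!r}")


def _ellipsoid_mask(shape, semi_axes_frac=0.38) -> np.ndarray:
    """Centred ellipsoid occupying ``semi_axes_frac`` of each half-axis."""
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=float)
    for c, n in zip(coords, shape):
        half = (n - 1) / 2.0
        a = max(semi_axes_frac * n, 1.0)
        r2 += ((c - half) / a) ** 2
    return r2 <= 1.0


def _scaled_centre_distance(shape) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=float)
    for c, n in zip(coords, shape):
        half = (n - 1) / 2.0
        r2 += ((c - half) / max(n, 1)) ** 2
    return np.sqrt(r2)


def grow_necrotic_core(contour: np.ndarray, fraction: float) -> np.ndarray:
    """Central core covering ``round(fraction * |contour|)`` voxels.

    Contour voxels are ranked by scaled distance from the volume centre and
    the innermost ones are labelled necrotic, so the realised voxel count
    matches the target fraction to within rounding (ties broken by voxel
    order, which is deterministic).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    idx = np.flatnonzero(contour.ravel())
    n_target = int(round(fraction * idx.size))
    mask = np.zeros(contour.size, dtype=bool)
    if n_target > 0:
        dist = _scaled_centre_distance(contour.shape).ravel()[idx]
        order = np.argsort(dist, kind="stable")
        mask[idx[order[:n_target]]] = True
    return mask.reshape(contour.shape)


def generate_ct_phantom(spec: CTPhantomSpec):
    """Pre/post-contrast HU volumes with an embedded necrotic core.

    Returns ``(pre, post, contour, necrotic_mask)``.  The necrotic-labelled
    fraction of tumour voxels equals ``spec.necrotic_fraction`` to within
    one voxel's rounding; output is seeded-deterministic.
    """
    spec.validate()
    contour = _ellipsoid_mask(spec.grid_shape, spec.semi_axes_frac)
    necrotic = grow_necrotic_core(contour, spec.necrotic_fraction)

    pre = np.full(spec.grid_shape, spec.class_mean_hu_pre["background"], float)
    post = np.full(spec.grid_shape, spec.class_mean_hu_post["background"], float)
    viable = contour & ~necrotic
    pre[viable] = spec.class_mean_hu_pre["viable"]
    post[viable] = spec.class_mean_hu_post["viable"]
    pre[necrotic] = spec.class_mean_hu_pre["necrosis"]
    post[necrotic] = spec.class_mean_hu_post["necrosis"]

    if spec.noise_sigma > 0:
        s_pre, s_post = np.random.SeedSequence(spec.seed).spawn(2)
        pre += np.random.default_rng(s_pre).normal(0, spec.noise_sigma, spec.grid_shape)
        post += np.random.default_rng(s_post).normal(0, spec.noise_sigma, spec.grid_shape)
    return pre, post, contour, necrotic


@dataclass
class HistoPhantomSpec:
    """Recipe for a 2-D stained-structure (or bead) rendering."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.953125  # um/pixel; 512 px * this = 1 mm
    n_structures: int = 0
    structure_radius_range: tuple[float, float] = (3.0, 6.0)  # pixels
    seed: int = 0
    allow_overlap: bool = False
    max_attempts_per_structure: int = 2000

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")
        lo, hi = self.structure_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid structure_radius_range")


class PlacementError(RuntimeError):
    """Non-overlapping placement failed: image too small for the request."""


def _place_disks(shape, n, radius_range, rng, allow_overlap, max_attempts):
    """Rejection-sample ``n`` disk centres/radii; disjoint unless allowed."""
    placed: list[tuple[float, float, float]] = []
    lo, hi = radius_range
    for _ in range(n):
        for _attempt in range(max_attempts):
            r = rng.uniform(lo, hi)
            cy = rng.uniform(r, shape[0] - 1 - r)
            cx = rng.uniform(r, shape[1] - 1 - r)
            # margin 2 px keeps rendered disks disconnected even under
            # 8-connectivity (diagonal gap sqrt(2) < 2)
            if allow_overlap or all(
                    (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2.0) ** 2
                    for py, px, pr in placed):
                placed.append((cy, cx, r))
                break
        else:
            raise PlacementError(
                f"could not place structure {len(placed) + 1} of {n} without "
                f"overlap after {max_attempts} attempts")
    return placed


def _render_disks(shape, disks, foreground, background):
    img = np.full(shape, background, dtype=float)
    for cy, cx, r in disks:
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        patch = img[y0:y1, x0:x1]
        patch[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = foreground
    return img


def generate_histology_image(spec: HistoPhantomSpec):
    """Stained-structure slide with exact ground-truth count.

    Dark (CD-31-like) blobs on a bright tissue background; returns
    ``(image, n_structures)``.  Non-overlap is enforced by rejection
    sampling so connected-component counting recovers the count exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    disks = _place_disks(spec.image_shape, spec.n_structures,
                         spec.structure_radius_range, rng,
                         spec.allow_overlap, spec.max_attempts_per_structure)
    image = _render_disks(spec.image_shape, disks, foreground=0.15, background=0.92)
    return image, spec.n_structures


def generate_bead_fovs(counts: Sequence[int],
                       image_shape: tuple[int, int] = (256, 256),
                       bead_radius: float = 2.0,
                       seed: int = 0):
    """Fluorescent-bead fields of view with known per-FOV counts.

    Bright beads on dark background (fluorescence microscopy polarity);
    returns ``(images, list(counts))``.
    """
    if len(counts) == 0:
        raise ValueError("at least one field of view is required")
    images = []
    child = np.random.SeedSequence(seed).spawn(len(counts))
    for k, c in enumerate(counts):
        rng = np.random.default_rng(child[k])
        disks = _place_disks(image_shape, int(c), (bead_radius, bead_radius),
                             rng, allow_overlap=False, max_attempts=2000)
        images.append(_render_disks(image_shape, disks,
                                    foreground=0.95, background=0.05))
    return images, [int(c) for c in counts]


def bead_counts_for_mean(mean: float, n_fov: int = 10) -> list[int]:
    """Integer per-FOV counts whose arithmetic mean equals ``mean`` exactly.

    Requires ``mean * n_fov`` to be (numerically) an integer; counts are
    spread as evenly as possible.
    """
    total = mean * n_fov
    total_int = int(round(total))
    if abs(total - total_int) > 1e-9:
        raise ValueError(f"mean {mean} is not attainable with {n_fov} integer counts")
    base, extra = divmod(total_int, n_fov)
    return [base + 1] * extra + [base] * (n_fov - extra)


# --------------------------------------------------------------------------
# Cohort generation: 2 cell lines x (co- / non-co-transplanted)
# --------------------------------------------------------------------------

#: Per-group study conditions.  Diffusion coefficients of the viable rim and
#: necrotic core are set to the cohort's reported minimal/maximal ADC_diff
#: levels; the co-transplanted group carries a higher perfusion fraction, a
#: higher necrotic fraction, a denser viable rim, larger tumours, higher
#: microvessel density and higher bead embolisation.  Class HU means are
#: calibrated so that the necrosis/parenchyma *mixture* at the group's
#: necrotic fraction reproduces the reported whole-tumour means (30.5/120 HU
#: co, 32/111 HU non-co pre/post): the reported values are measured over the
#: entire contour, hypodense lacunas included.
DEFAULT_GROUP_PARAMS = {
    "co": {
        "viable": IVIMParams(s0=100.0, f=0.10, d=166e-6, d_star=12e-3),
        "necrosis": IVIMParams(s0=100.0, f=0.02, d=1695e-6, d_star=12e-3),
        "stroma": IVIMParams(s0=100.0, f=0.22, d=900e-6, d_star=12e-3),
        "necrotic_fraction": 0.40,
        "tumour_size_frac": 0.44,
        "hu_pre": {"background": -1000.0, "viable": 34.2, "necrosis": 25.0},
        "hu_post": {"background": -1000.0, "viable": 186.7, "necrosis": 20.0},
        "mvd_mean": 171.0, "mvd_sd": 19.0,
        "beads_mean": 1.3,
        "tof_probs": (0.10, 0.35, 0.55),
    },
    "non-co": {
        "viable": IVIMParams(s0=100.0, f=0.06, d=346e-6, d_star=12e-3),
        "necrosis": IVIMParams(s0=100.0, f=0.02, d=1320e-6, d_star=12e-3),
        "stroma": IVIMParams(s0=100.0, f=0.12, d=800e-6, d_star=12e-3),
        "necrotic_fraction": 0.18,
        "tumour_size_frac": 0.36,
        "hu_pre": {"background": -1000.0, "viable": 33.1, "necrosis": 27.0},
        "hu_post": {"background": -1000.0, "viable": 130.5, "necrosis": 22.0},
        "mvd_mean": 111.0, "mvd_sd": 11.0,
        "beads_mean": 1.1,
        "tof_probs": (0.45, 0.45, 0.10),
    },
}


@dataclass
class CohortSpec:
    """Stratified cohort: ``n_per_group`` animals per (cell line, group)."""

    n_per_group: int = 3
    cell_lines: tuple[str, ...] = ("H1299", "A549")
    groups: tuple[str, ...] = ("co", "non-co")
    group_params: Mapping[str, dict] = field(
        default_factory=lambda: DEFAULT_GROUP_PARAMS)
    dwi_grid_shape: tuple[int, int, int] = (12, 12, 6)
    dwi_voxel_spacing: tuple[float, float, float] = (1.8, 1.8, 1.8)
    ct_grid_shape: tuple[int, int, int] = (24, 24, 12)
    noise_model: Literal["none", "gaussian", "rician"] = "rician"
    snr: float = 50.0            # b=0 SNR per acquisition; sigma = s0 / snr
    dwi_n_averages: int = 6      # 3 orthogonal directions x 2 signal averages
    ct_noise_sigma: float = 2.0  # HU
    subject_cv: float = 0.08     # inter-animal coefficient of variation
    n_bead_fovs: int = 10
    render_histology: bool = True  # off: keep count truth, skip rendering
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g in self.groups:
            if g not in self.group_params:
                raise ValueError(f"missing parameterisation for group {g!r}")


@dataclass
class AnimalBundle:
    """All synthetic modalities for one animal, plus embedded ground truth."""

    animal_id: str
    cell_line: str
    group: str
    dwi_stack: object                 # BValueStack
    tissue_map: np.ndarray
    dwi_truth: dict                   # class label -> IVIMParams
    tumour_mask: np.ndarray           # DWI-grid tumour ROI (viable+necrosis+stroma)
    ct_pre: np.ndarray
    ct_post: np.ndarray
    ct_contour: np.ndarray
    ct_necrotic_mask: np.ndarray
    necrotic_fraction_truth: float
    histology_image: np.ndarray | None  # None when rendering is disabled
    histology_pixel_size: float       # um/pixel
    mvd_truth_count: int
    bead_images: list
    bead_counts_truth: list
    tof_score: int


def _jitter(rng, value, cv):
    """Multiplicative lognormal-ish subject variability, mean ~= value."""
    return value * float(np.exp(rng.normal(0.0, cv)))


def generate_cohort(spec: CohortSpec) -> list[AnimalBundle]:
    """Simulate the stratified cohort (cell line x transplantation group).

    Per animal the group-level parameters receive multiplicative
    inter-subject jitter (coefficient of variation ``subject_cv``), then a
    DWI phantom (necrotic core, stromal shell, viable rim), a CT phantom
    sharing the animal's necrotic fraction, a CD-31 slide, and a set of
    bead fields of view are rendered.  Deterministic for a fixed seed.
    """
    spec.validate()
    bundles: list[AnimalBundle] = []
    root = np.random.SeedSequence(spec.seed)
    n_animals = spec.n_per_group * len(spec.cell_lines) * len(spec.groups)
    seeds = root.spawn(n_animals)
    k = 0
    for cell_line in spec.cell_lines:
        for group in spec.groups:
            gp = spec.group_params[group]
            for i in range(spec.n_per_group):
                ss = seeds[k]
                k += 1
                rng = np.random.default_rng(ss)
                animal_id = f"{cell_line}-{group}-{i + 1:02d}"

                # --- per-animal parameter draw ------------------------------
                cls = {}
                for label, key in ((VIABLE, "viable"), (NECROSIS, "necrosis"),
                                   (STROMA, "stroma")):
                    p: IVIMParams = gp[key]
                    cls[label] = IVIMParams(
                        s0=p.s0,
                        f=min(1.0, _jitter(rng, p.f, spec.subject_cv)) if p.f > 0 else 0.0,
                        d=_jitter(rng, p.d, spec.subject_cv),
                        d_star=p.d_star)
                nf = float(np.clip(_jitter(rng, gp["necrotic_fraction"],
                                           spec.subject_cv), 0.0, 1.0))
                size_frac = float(np.clip(
                    _jitter(rng, gp.get("tumour_size_frac", 0.40),
                            spec.subject_cv), 0.22, 0.48))

                # --- DWI phantom -------------------------------------------
                tumour = _ellipsoid_mask(spec.dwi_grid_shape, size_frac)
                core = grow_necrotic_core(tumour, nf)
                # stromal shell: outer part of what remains after the core
                rest = tumour & ~core
                stroma_shell = grow_necrotic_core(rest, 0.5)  # inner half of rest
                tmap = np.full(spec.dwi_grid_shape, BACKGROUND, np.uint8)
                tmap[rest & ~stroma_shell] = VIABLE
                tmap[stroma_shell] = STROMA
                tmap[core] = NECROSIS
                sigma = (cls[VIABLE].s0 / spec.snr) if spec.noise_model != "none" else 0.0
                dwi_spec = DWIPhantomSpec(
                    grid_shape=spec.dwi_grid_shape,
                    voxel_spacing=spec.dwi_voxel_spacing,
                    tissue_map=tmap, class_params=cls,
                    noise_model=spec.noise_model, noise_sigma=sigma,
                    n_averages=spec.dwi_n_averages,
                    seed=int(rng.integers(2 ** 31)))
                stack, truth = generate_dwi_phantom(dwi_spec)

                # --- CT phantom --------------------------------------------
                ct_spec = CTPhantomSpec(
                    grid_shape=spec.ct_grid_shape,
                    class_mean_hu_pre=gp["hu_pre"],
                    class_mean_hu_post=gp["hu_post"],
                    necrotic_fraction=nf,
                    semi_axes_frac=size_frac,
                    noise_sigma=spec.ct_noise_sigma,
                    seed=int(rng.integers(2 ** 31)))
                pre, post, contour, necro = generate_ct_phantom(ct_spec)

                # --- histology ---------------------------------------------
                n_mvd = max(0, int(round(rng.normal(gp["mvd_mean"], gp["mvd_sd"]))))
                hspec = HistoPhantomSpec(n_structures=n_mvd,
                                         seed=int(rng.integers(2 ** 31)))
                bead_counts = rng.poisson(gp["beads_mean"],
                                          spec.n_bead_fovs).tolist()
                bead_seed = int(rng.integers(2 ** 31))
                if spec.render_histology:
                    himg, _ = generate_histology_image(hspec)
                    bimgs, bcounts = generate_bead_fovs(bead_counts,
                                                        seed=bead_seed)
                else:
                    himg, bimgs, bcounts = None, [], [int(c) for c in bead_counts]

                tof = int(rng.choice(3, p=np.asarray(gp["tof_probs"])))

                bundles.append(AnimalBundle(
                    animal_id=animal_id, cell_line=cell_line, group=group,
                    dwi_stack=stack, tissue_map=tmap, dwi_truth=truth,
                    tumour_mask=tumour,
                    ct_pre=pre, ct_post=post, ct_contour=contour,
                    ct_necrotic_mask=necro,
                    necrotic_fraction_truth=float(necro.sum()) / float(contour.sum()),
                    histology_image=himg,
                    histology_pixel_size=hspec.pixel_size,
                    mvd_truth_count=n_mvd,
                    bead_images=bimgs, bead_counts_truth=bcounts,
                    tof_score=tof))
    return bundles
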