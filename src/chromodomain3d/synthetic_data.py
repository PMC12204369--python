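"""Ground-truthed synthetic multi-channel Z-stacks.

The generator emulates the structure the analysis assumes: one
ellipsoidal nucleus per field (DAPI channel well above the 500 ADU
gate inside, background outside), H3K27ac chromatin domains drawn from
two morphology populations — "closed" domains are compact spheres,
"open" domains are curved tubes (random-walk spines with circular
cross-section) of larger volume and lower analytic sphericity — and an
ER channel whose within-domain voxel intensities are coupled to the
H3K27ac intensities at a tunable Pearson correlation ρ.

Imaging realism: a Gaussian PSF blurs the noiseless structure fields,
camera noise is added afterwards, and the ER channel can carry a known
integer lateral shift for the registration stage to recover.  The ρ
mixing is applied to the *blurred* standardized H3K27ac field with a
blurred independent field of the same spectrum, so the realized
within-domain correlation over the true domain support equals ρ up to
camera noise — this is the generator's contract and what recovery
tests measure.

Stacks are produced at native (anisotropic, 0.15 μm Z) spacing so the
pipeline's Z-interpolation stage is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from chromodomain3d.channel_alignment import translate_slide
from chromodomain3d.image_io import ImageStack, write_stack


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of one synthetic cell; defaults are the study conditions."""

    seed: int = 0
    shape_zyx: tuple[int, int, int] = (12, 256, 256)
    spacing_um: tuple[float, float, float] = (0.15, 0.06, 0.06)
    # nucleus geometry and DAPI levels (ADU)
    nucleus_semiaxes_um: tuple[float, float, float] = (0.8, 6.0, 6.0)
    dapi_inside: float = 800.0
    dapi_outside: float = 100.0
    # domain population
    n_domains: int = 20
    open_fraction: float = 0.2
    closed_radius_um: tuple[float, float] = (0.15, 0.28)   # uniform range
    open_radius_um: tuple[float, float] = (0.12, 0.18)
    open_length_um: tuple[float, float] = (1.2, 2.2)
    min_separation_vox: int = 2
    domain_margin_um: float = 0.1  # clearance kept between domains and the envelope
    # normalized radial band (0 = nuclear centre, 1 = envelope) domains are
    # placed in; peripheral bands emulate lamina-proximal heterochromatin
    radial_range: tuple[float, float] = (0.0, 1.0)
    # intensities (ADU)
    h3k27ac_level: float = 3000.0
    h3k27ac_sigma: float = 800.0
    er_level: float = 600.0
    er_sigma: float = 200.0
    er_floor_sigma: float = 100.0
    er_background: float = 300.0
    # extranuclear background: nonspecific staining makes it brighter and
    # more heterogeneous than the clean nucleoplasm floor, which is what
    # lets a top-percentile background threshold clear the nucleoplasm
    background_mean: float = 150.0
    cyto_extra_sigma: float = 40.0
    cyto_scale_px: float = 3.0
    cyto_clear_um: float = 1.5  # perinuclear shell kept free of bright cytoplasm
    nuclear_floor: float = 100.0
    background_sigma: float = 20.0  # white camera noise, all channels
    # coupling and optics
    rho: float = 0.5
    psf_sigma_um: tuple[float, float, float] = (0.075, 0.05, 0.05)
    channel_shift: tuple[int, int] = (0, 0)  # (dy, dx) applied to ER

    def __post_init__(self) -> None:
        if not (0.0 <= self.open_fraction <= 1.0):
            raise ValueError("open_fraction must be in [0, 1]")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [-1, 1]")
        if self.n_domains < 0:
            raise ValueError("n_domains must be >= 0")
        if any(s <= 0 for s in self.spacing_um + self.nucleus_semiaxes_um):
            raise ValueError("geometry must be positive")


@dataclass
class GroundTruthDomain:
    """True geometry and coupling of one generated domain."""

    id: int
    morphology: str  # "open" | "closed"
    center_um: tuple[float, float, float]
    radius_um: float
    length_um: float  # 0 for closed
    spine_um: np.ndarray | None  # (k, 3) physical spine points for tubes
    rho: float
    voxels_native: np.ndarray  # (n, 3) native-grid (z, y, x)
    volume_um3: float  # rasterized voxel count x native voxel volume
    sphericity_analytic: float


@dataclass
class SyntheticGroundTruth:
    spec: SyntheticSpec
    nucleus_center_um: tuple[float, float, float]
    nucleus_semiaxes_um: tuple[float, float, float]
    nucleus_mask_native: np.ndarray
    domains: list[GroundTruthDomain] = field(default_factory=list)

    @property
    def channel_shift(self) -> tuple[int, int]:
        return self.spec.channel_shift


CHANNEL_NAMES = ["DAPI", "H3K27ac", "ER"]

#: per-condition generator presets; paper-style condition names map onto
#: the two morphology mixtures the comparisons contrast
_OPEN_RICH = {"open_fraction": 0.8, "rho": 0.8, "radial_range": (0.0, 0.75)}
_CLOSED_RICH = {"open_fraction": 0.1, "rho": 0.3, "radial_range": (0.55, 1.0)}
CONDITION_PRESETS: dict[str, dict] = {
    "open_rich": dict(_OPEN_RICH),
    "closed_rich": dict(_CLOSED_RICH),
    "E2": dict(_OPEN_RICH),
    "ED": dict(_CLOSED_RICH),
    "TAM": dict(_CLOSED_RICH),
    "FULV": dict(_CLOSED_RICH),
}


def tube_sphericity(radius: float, length: float) -> float:
    """Analytic φ of a straight tube with hemispherically-flat ends."""
    v = np.pi * radius**2 * length
    s = 2 * np.pi * radius * length + 2 * np.pi * radius**2
    return float(np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / s)


def analytic_domain_shape_stats(spec: SyntheticSpec) -> dict:
    """Closed-form expected volume and sphericity per morphology class."""
    r_c = np.mean(spec.closed_radius_um)
    r_o = np.mean(spec.open_radius_um)
    l_o = np.mean(spec.open_length_um)
    return {
        "closed": {
            "volume_um3": float(4.0 / 3.0 * np.pi * r_c**3),
            "sphericity": 1.0,
        },
        "open": {
            "volume_um3": float(np.pi * r_o**2 * l_o),
            "sphericity": tube_sphericity(r_o, l_o),
        },
    }


def _grid_coords_um(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def rasterize_ellipsoid(
    center_um, semiaxes_um, shape, spacing
) -> np.ndarray:
    zz, yy, xx = _grid_coords_um(shape, spacing)
    c, s = np.asarray(center_um), np.asarray(semiaxes_um)
    q = (
        ((zz - c[0]) / s[0]) ** 2
        + ((yy - c[1]) / s[1]) ** 2
        + ((xx - c[2]) / s[2]) ** 2
    )
    return q <= 1.0


def _paint_balls(mask: np.ndarray, points_um: np.ndarray, radius_um: float,
                 spacing: tuple[float, float, float]) -> None:
    """OR balls of physical radius around each point into `mask`."""
    sp = np.asarray(spacing)
    shape = np.asarray(mask.shape)
    for p in np.atleast_2d(points_um):
        lo = np.maximum(np.floor((p - radius_um) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((p + radius_um) / sp).astype(int) + 1, shape)
        if (lo >= hi).any():
            continue
        axes = [np.arange(l, h) * s - pc for l, h, s, pc in zip(lo, hi, sp, p)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
        ball = zz**2 + yy**2 + xx**2 <= radius_um**2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball


def rasterize_domain_support(
    domain: GroundTruthDomain,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Domain support on an arbitrary grid (e.g. the interpolated one)."""
    mask = np.zeros(shape, dtype=bool)
    if domain.morphology == "closed":
        pts = np.asarray(domain.center_um)[np.newaxis]
    else:
        pts = domain.spine_um
    _paint_balls(mask, pts, domain.radius_um, spacing)
    return mask


def _sample_center(rng, center, semiaxes, margin_um,
                   radial_range=(0.0, 1.0)) -> np.ndarray | None:
    """Uniform point inside the ellipsoid shrunk by `margin_um` per axis,
    restricted to the normalized radial band `radial_range`."""
    s = np.asarray(semiaxes) - margin_um
    if (s <= 0).any():
        return None
    lo, hi = radial_range
    for _ in range(500):
        u = rng.uniform(-1, 1, size=3)
        if lo**2 <= (u**2).sum() <= hi**2:
            return np.asarray(center) + u * s
    return None


def _sample_spine(rng, center, semiaxes, length: float, margin_um: float,
                  radial_range=(0.0, 1.0), step_um: float = 0.08) -> np.ndarray | None:
    """Persistent random-walk spine kept inside the shrunken nucleus."""
    s = np.asarray(semiaxes) - margin_um
    if (s <= 0).any():
        return None
    start = _sample_center(rng, center, semiaxes, margin_um, radial_range)
    if start is None:
        return None
    d = rng.standard_normal(3)
    d[0] *= 0.2  # nuclei are thin along Z; tubes run mostly in-plane
    d /= np.linalg.norm(d)
    pts = [start]
    n_steps = max(int(round(length / step_um)), 1)
    for _ in range(n_steps):
        d = d + 0.35 * rng.standard_normal(3) * np.array([0.2, 1.0, 1.0])
        d /= np.linalg.norm(d)
        nxt = pts[-1] + d * step_um
        if (((nxt - center) / s) ** 2).sum() > 1.0:
            return None  # wandered out; caller retries
        pts.append(nxt)
    return np.asarray(pts)


def _place_domains(rng, spec: SyntheticSpec, nucleus_center) -> list[GroundTruthDomain]:
    shape, spacing = spec.shape_zyx, spec.spacing_um
    occupancy = np.zeros(shape, dtype=bool)
    sep = np.ones((3, 3, 3), dtype=bool)
    n_open = int(round(spec.n_domains * spec.open_fraction))
    classes = ["open"] * n_open + ["closed"] * (spec.n_domains - n_open)
    domains: list[GroundTruthDomain] = []
    voxvol = float(np.prod(spacing))

    for i, morph in enumerate(classes):
        placed = False
        for _ in range(300):
            if morph == "closed":
                radius = rng.uniform(*spec.closed_radius_um)
                center = _sample_center(rng, nucleus_center, spec.nucleus_semiaxes_um,
                                        radius + spec.domain_margin_um,
                                        spec.radial_range)
                if center is None:
                    break
                spine, length = None, 0.0
                pts = center[np.newaxis]
            else:
                radius = rng.uniform(*spec.open_radius_um)
                length = rng.uniform(*spec.open_length_um)
                spine = _sample_spine(rng, nucleus_center, spec.nucleus_semiaxes_um,
                                      length, radius + spec.domain_margin_um,
                                      spec.radial_range)
                if spine is None:
                    continue
                center = spine.mean(axis=0)
                pts = spine
            support = np.zeros(shape, dtype=bool)
            _paint_balls(support, pts, radius, spacing)
            if not support.any():
                continue
            halo = ndimage.binary_dilation(support, structure=sep,
                                           iterations=spec.min_separation_vox)
            if (halo & occupancy).any():
                continue
            occupancy |= support
            vox = np.argwhere(support)
            domains.append(
                GroundTruthDomain(
                    id=i + 1,
                    morphology=morph,
                    center_um=tuple(float(v) for v in center),
                    radius_um=float(radius),
                    length_um=float(length),
                    spine_um=spine,
                    rho=spec.rho,
                    voxels_native=vox,
                    volume_um3=float(len(vox) * voxvol),
                    sphericity_analytic=1.0 if morph == "closed"
                    else tube_sphericity(radius, length),
                )
            )
            placed = True
            break
        if not placed and morph == "closed":
            raise RuntimeError(
                f"could not place domain {i + 1}/{spec.n_domains} without overlap"
            )
        if not placed and morph == "open":
            raise RuntimeError(
                f"could not place open domain {i + 1}/{spec.n_domains} inside the nucleus"
            )
    return domains


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def generate_cell(spec: SyntheticSpec) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render one synthetic cell; deterministic given ``spec.seed``.

    Channel order is DAPI, H3K27ac, ER.  The ER within-domain
    intensities are ``er_level + er_sigma * (ρ·ĥ + sqrt(1-ρ²)·ŵ)``
    where ĥ is the blurred H3K27ac field standardized over the domain
    support and ŵ an equally blurred independent field, so the
    realized support correlation is ρ up to camera noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape_zyx, spec.spacing_um
    center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))

    nucleus = rasterize_ellipsoid(center, spec.nucleus_semiaxes_um, shape, spacing)
    if not nucleus.any():
        raise ValueError("nucleus ellipsoid does not intersect the field")
    domains = _place_domains(rng, spec, np.asarray(center))

    dapi = np.full(shape, spec.dapi_outside, dtype=np.float64)
    dapi[nucleus] = spec.dapi_inside
    # H3K27ac: bright heterogeneous extranuclear background, dim clean
    # nucleoplasm floor, strong signal inside domains
    h3k = np.full(shape, spec.nuclear_floor, dtype=np.float64)
    if spec.cyto_extra_sigma > 0:
        cyto = ndimage.gaussian_filter(
            rng.standard_normal(shape), (1.0, spec.cyto_scale_px, spec.cyto_scale_px)
        )
        sd = cyto.std()
        if sd > 0:
            cyto *= spec.cyto_extra_sigma / sd
        cyto = np.abs(cyto)
        # bright nonspecific cytoplasm stays clear of the nuclear envelope,
        # so the perinuclear shell that the dilated nucleus mask swallows
        # is dim relative to the sampled background tail
        far = ~rasterize_ellipsoid(
            center,
            tuple(s + spec.cyto_clear_um for s in spec.nucleus_semiaxes_um),
            shape, spacing,
        )
        cyto *= far
    else:
        cyto = np.zeros(shape)
    h3k[~nucleus] = spec.background_mean + cyto[~nucleus]
    for d in domains:
        idx = tuple(d.voxels_native.T)
        h3k[idx] = spec.h3k27ac_level + spec.h3k27ac_sigma * rng.standard_normal(
            len(d.voxels_native)
        )

    sigma_vox = tuple(s / sp for s, sp in zip(spec.psf_sigma_um, spacing))
    dapi_b = ndimage.gaussian_filter(dapi, sigma_vox)
    h3k_b = ndimage.gaussian_filter(h3k, sigma_vox)
    # independent field with the H3K27ac texture spectrum, for the ρ mix
    w_b = ndimage.gaussian_filter(
        rng.standard_normal(shape) * spec.h3k27ac_sigma, sigma_vox
    )

    # ER: diffuse nucleoplasmic pool at the same mean level as in the
    # domains (so the domain edge carries no ER intensity step), focal
    # rho-coupled fluctuations inside domains
    er = np.full(shape, spec.er_background, dtype=np.float64)
    er[nucleus] = spec.er_level + spec.er_floor_sigma * rng.standard_normal(
        int(nucleus.sum())
    )
    for d in domains:
        idx = tuple(d.voxels_native.T)
        h1 = _standardize(h3k_b[idx])
        w1 = _standardize(w_b[idx])
        # Gram-Schmidt: remove the chance correlation of the independent
        # field with h over this (small, blur-correlated) support, so the
        # realized support correlation is exactly rho
        w_perp = _standardize(w1 - float(np.mean(h1 * w1)) * h1)
        mix = d.rho * h1 + np.sqrt(1.0 - d.rho**2) * w_perp
        er[idx] = spec.er_level + spec.er_sigma * mix

    if spec.background_sigma > 0:
        dapi_b = dapi_b + spec.background_sigma * rng.standard_normal(shape)
        h3k_b = h3k_b + spec.background_sigma * rng.standard_normal(shape)
        er = er + spec.background_sigma * rng.standard_normal(shape)
    dapi_b = np.clip(dapi_b, 0, None)
    h3k_b = np.clip(h3k_b, 0, None)
    er = np.clip(er, 0, None)

    dy, dx = spec.channel_shift
    if (dy, dx) != (0, 0):
        for z in range(shape[0]):
            er[z] = translate_slide(er[z], dy, dx)

    stack = ImageStack(
        voxels=np.stack([dapi_b, h3k_b, er]).astype(np.float32),
        spacing=spacing,
        channel_names=list(CHANNEL_NAMES),
    )
    truth = SyntheticGroundTruth(
        spec=spec,
        nucleus_center_um=center,
        nucleus_semiaxes_um=spec.nucleus_semiaxes_um,
        nucleus_mask_native=nucleus,
        domains=domains,
    )
    return stack, truth


def expected_detected_support(
    domain: GroundTruthDomain,
    spec: SyntheticSpec,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    threshold: float,
    dilation_iters: int = 2,
) -> np.ndarray:
    """Noise-free expectation of what the detector should segment.

    The deterministic part of the imaging model (support -> PSF blur ->
    intensity gate) plus the detector's own morphological refinement is
    replayed on the analysis grid; recovery tests compare detected
    domains against this expectation so they measure noise robustness
    and labeling fidelity, not the known diffraction/refinement halo.
    """
    from chromodomain3d.domain_detection import refine_component

    support = rasterize_domain_support(domain, shape, spacing)
    sigma_vox = tuple(s / sp for s, sp in zip(spec.psf_sigma_um, spacing))
    signal = spec.nuclear_floor + (
        spec.h3k27ac_level - spec.nuclear_floor
    ) * ndimage.gaussian_filter(support.astype(np.float64), sigma_vox)
    return refine_component(signal > threshold, dilation_iters)


def measured_support_correlation(
    stack: ImageStack,
    domain: GroundTruthDomain,
    channel_a: str = "H3K27ac",
    channel_b: str = "ER",
    z_stride: int = 1,
) -> float:
    """Pearson r over the domain's true (native-grid) support voxels.

    `stack` should be channel-aligned.  On a Z-interpolated stack pass
    ``z_stride=3``: real slides are preserved at stride 3, so the
    native support voxels are sampled exactly, without the blurred
    edge voxels a re-rasterized support would add.
    """
    coords = domain.voxels_native.copy()
    coords[:, 0] *= z_stride
    idx = tuple(coords.T)
    a = stack.channel(channel_a)[idx].astype(np.float64)
    b = stack.channel(channel_b)[idx].astype(np.float64)
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float((a @ b) / denom) if denom else float("nan")


def _spec_for(condition: str, base: SyntheticSpec, overrides: dict | None) -> SyntheticSpec:
    params = dict(CONDITION_PRESETS.get(condition, {}))
    if overrides:
        params.update(overrides)
    return replace(base, **params)


def generate_experiment(
    out_dir: str | Path,
    conditions: list[str],
    n_cells: int = 3,
    n_batches: int = 2,
    seed: int = 0,
    base_spec: SyntheticSpec = SyntheticSpec(),
    per_condition: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Write a deterministic file tree of stacks plus manifest and truth.

    Per-cell seeds are derived from ``seed`` with a spawn key, so the
    same seed reproduces every stack bit-for-bit.  Returns the manifest
    (path, batch, cell, condition, genotype) and writes it together
    with a per-domain ground-truth CSV to `out_dir`.
    """
    out = Path(out_dir)
    (out / "stacks").mkdir(parents=True, exist_ok=True)
    rows, truth_rows = [], []
    for bi in range(n_batches):
        for ci, cond in enumerate(conditions):
            for cell in range(n_cells):
                child = np.random.SeedSequence(seed, spawn_key=(bi, ci, cell))
                cell_seed = int(child.generate_state(1)[0] % (2**31))
                spec = _spec_for(cond, base_spec, (per_condition or {}).get(cond))
                spec = replace(spec, seed=cell_seed)
                stack, truth = generate_cell(spec)
                rel = f"stacks/b{bi}_{cond}_c{cell}.tif"
                write_stack(stack, out / rel)
                rows.append({
                    "path": rel,
                    "batch": f"batch{bi}",
                    "cell": f"cell{cell}",
                    "condition": cond,
                    "genotype": "WT",
                    "seed": cell_seed,
                    "shift_dy": spec.channel_shift[0],
                    "shift_dx": spec.channel_shift[1],
                })
                for d in truth.domains:
                    truth_rows.append({
                        "batch": f"batch{bi}",
                        "cell": f"cell{cell}",
                        "condition": cond,
                        "domain_id": d.id,
                        "morphology": d.morphology,
                        "rho": d.rho,
                        "volume_um3": d.volume_um3,
                        "sphericity_analytic": d.sphericity_analytic,
                        "center_z_um": d.center_um[0],
                        "center_y_um": d.center_um[1],
                        "center_x_um": d.center_um[2],
                    })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    meta = {"seed": seed, "conditions": conditions,
            "n_cells": n_cells, "n_batches": n_batches}
    (out / "experiment.json").write_text(json.dumps(meta, indent=2))
    return manifest
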