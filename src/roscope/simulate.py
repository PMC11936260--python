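"""Synthetic two-channel confocal z-stacks of single microglia.

Each generated stack emulates one confocal acquisition of a single HMC3
microglial cell carrying a Lifeact (actin) reporter and loaded with a
fluorogenic ROS dye: an "actin" channel with a bright cortical rim outlining
the cell body, and a "ros" channel of punctate spots whose number scales with
the cell's oxidative state.  Conditions (LPS, GP120, Abeta42) and treatment
(CBD vs control) modulate the ROS signal through an :class:`EffectDesign`,
and every cell carries a :class:`GroundTruth` record (true mask, noiseless
integrated ROS, puncta count) so downstream segmentation and statistics can
be validated against known answers.

Default acquisition geometry: 1024x1024 px slices, 18-20 slices per stack at
0.5 um z-step.  Pixels are stored as 16-bit unsigned integers, the common
confocal bit depth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

logger = logging.getLogger("roscope.simulate")

CONDITIONS = ("LPS", "GP120", "Abeta42")
TREATMENTS = ("CBD", "control")
MOTIFS = ("peripheral", "perinuclear", "diffuse")

MAX_PIXEL = 65535  # 16-bit storage


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SceneParams:
    """Optical and biological parameters of one synthetic scene.

    Lengths are in micrometers; intensities in 16-bit camera counts.
    ``n_slices=None`` draws the slice count uniformly from 18-20, the
    acquisition depth the pipeline assumes.
    """

    image_size_px: int = 1024
    n_slices: int | None = None
    z_step_um: float = 0.5
    pixel_size_um: float = 0.25
    cell_radius_um: tuple[float, float] = (8.0, 12.0)
    cortex_width_um: float = 1.0
    puncta_rate: float = 30.0
    puncta_density_per_um3: float | None = None  # overrides puncta_rate when set
    puncta_intensity_mu: float = 8.5  # log-amplitude; exp(8.5) ~ 4900 counts
    puncta_intensity_sigma: float = 0.4
    puncta_sigma_um: float = 0.4
    background_level: float = 100.0
    read_noise_sigma: float = 10.0
    shot_noise: bool = True
    z_attenuation: float = 0.98
    actin_amplitude: float = 3000.0
    cell_z_fill: float = 0.8  # z semi-axis of the cell as fraction of stack depth
    outline_irregularity: float = 0.06  # max radial-harmonic amplitude
    aspect_jitter: float = 0.15  # max fractional x/y radius asymmetry

    def validate(self) -> None:
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")
        if self.n_slices is not None and not (1 <= self.n_slices <= 64):
            raise ValueError("n_slices must lie in [1, 64]")
        for name in ("z_step_um", "pixel_size_um", "cortex_width_um",
                     "puncta_sigma_um", "puncta_intensity_sigma", "cell_z_fill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.cell_radius_um
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("cell_radius_um must be a positive (lo, hi) range")
        if self.puncta_rate < 0:
            raise ValueError("puncta_rate must be nonnegative")
        if self.puncta_density_per_um3 is not None and self.puncta_density_per_um3 < 0:
            raise ValueError("puncta_density_per_um3 must be nonnegative")
        if self.background_level < 0 or self.read_noise_sigma < 0:
            raise ValueError("background_level and read_noise_sigma must be nonnegative")
        if not 0 < self.z_attenuation <= 1:
            raise ValueError("z_attenuation must lie in (0, 1]")
        if self.outline_irregularity < 0 or self.aspect_jitter < 0:
            raise ValueError("outline_irregularity and aspect_jitter must be nonnegative")
        if self.puncta_sigma_um >= lo:
            raise ValueError("puncta wider than cell: puncta_sigma_um must be "
                             "smaller than the minimum cell radius")


@dataclass
class ConditionEffect:
    """Per-condition modulation of the ROS signal.

    ``baseline`` multiplies both the expected puncta count and the puncta
    log-amplitude scale; ``cbd_multiplier`` m scales the expected puncta count
    of CBD-treated cells (m < 1: CBD reduces ROS; m = 1: no CBD effect, the
    GP120-like null).  ``motif`` controls where puncta sit inside the cell so
    the three conditions remain distinguishable by an image classifier.
    """

    baseline: float = 1.0
    cbd_multiplier: float = 1.0
    motif: str = "diffuse"

    def validate(self) -> None:
        if self.baseline <= 0 or self.cbd_multiplier <= 0:
            raise ValueError("effect multipliers must be positive")
        if self.motif not in MOTIFS:
            raise ValueError(f"motif must be one of {MOTIFS}")


@dataclass
class EffectDesign:
    """Group structure of a simulated experiment.

    ``n_cells`` maps (condition, treatment) to the number of cells generated
    for that group; ``effects`` maps each condition to its
    :class:`ConditionEffect`.
    """

    effects: dict[str, ConditionEffect] = field(default_factory=dict)
    n_cells: dict[tuple[str, str], int] = field(default_factory=dict)

    def validate(self) -> None:
        for (cond, treat), n in self.n_cells.items():
            if treat not in TREATMENTS:
                raise ValueError(f"unknown treatment {treat!r}")
            if n < 0:
                raise ValueError("group sizes must be nonnegative")
            if cond not in self.effects:
                raise ValueError(f"no ConditionEffect given for condition {cond!r}")
        for eff in self.effects.values():
            eff.validate()

    @property
    def total_cells(self) -> int:
        return sum(self.n_cells.values())

    @classmethod
    def default(cls, n_per_group: int | None = None) -> "EffectDesign":
        """The study-like design: CBD reduces ROS under LPS and Abeta42 but
        not under GP120, with distinct spatial motifs per condition.

        With ``n_per_group=None`` the group sizes follow the acquisition
        counts of the emulated experiment (66-138 cells per group).
        """
        effects = {
            "LPS": ConditionEffect(baseline=1.3, cbd_multiplier=0.6, motif="peripheral"),
            "GP120": ConditionEffect(baseline=1.2, cbd_multiplier=1.0, motif="perinuclear"),
            "Abeta42": ConditionEffect(baseline=1.3, cbd_multiplier=0.65, motif="diffuse"),
        }
        if n_per_group is None:
            n_cells = {
                ("LPS", "CBD"): 124, ("LPS", "control"): 130,
                ("GP120", "CBD"): 66, ("GP120", "control"): 118,
                ("Abeta42", "CBD"): 122, ("Abeta42", "control"): 138,
            }
        else:
            n_cells = {(c, t): n_per_group for c in CONDITIONS for t in TREATMENTS}
        return cls(effects=effects, n_cells=n_cells)

    @classmethod
    def two_group(cls, condition: str = "LPS", n: int = 10,
                  cbd_multiplier: float = 0.6, baseline: float = 1.0,
                  motif: str = "peripheral") -> "EffectDesign":
        """A single-condition CBD-vs-control design (binary experiments)."""
        return cls(
            effects={condition: ConditionEffect(baseline=baseline,
                                                cbd_multiplier=cbd_multiplier,
                                                motif=motif)},
            n_cells={(condition, "CBD"): n, (condition, "control"): n},
        )


@dataclass
class ZStack:
    """A two-channel 3D image (Z x Y x X) with physical calibration."""

    actin: np.ndarray
    ros: np.ndarray
    pixel_size_um: float
    z_step_um: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.actin.shape != self.ros.shape:
            raise ValueError("actin and ros channels must share a shape")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.actin.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"actin": self.actin, "ros": self.ros}[name]
        except KeyError:
            raise ValueError(f"unknown channel {name!r}; expected 'actin' or 'ros'") from None


@dataclass
class GroundTruth:
    """Generator-side truth for one cell: what measurement should recover."""

    cell_id: str
    condition: str
    treatment: str
    mask: np.ndarray | None  # boolean (Z, Y, X) volume; may be dropped to save memory
    true_area_um2: float
    true_integrated_ros: float
    puncta_count: int
    seed: int

    def to_record(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "condition": self.condition,
            "treatment": self.treatment,
            "true_area_um2": float(self.true_area_um2),
            "true_integrated_ros": float(self.true_integrated_ros),
            "puncta_count": int(self.puncta_count),
            "seed": int(self.seed),
        }


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _cell_geometry(params: SceneParams, rng: np.random.Generator, n_slices: int):
    """Boundary-perturbed ellipsoid mask plus per-slice edge distances (um)."""
    size = params.image_size_px
    px = params.pixel_size_um
    r_um = rng.uniform(*params.cell_radius_um)
    aj = params.aspect_jitter
    rx = r_um / px * rng.uniform(1 - aj, 1 + aj)
    ry = r_um / px * rng.uniform(1 - aj, 1 + aj)
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size

    # low-order radial harmonics perturb the outline for a non-circular look
    orders = np.arange(2, 6)
    amps = rng.uniform(0.0, params.outline_irregularity, orders.size)
    phases = rng.uniform(0.0, 2 * np.pi, orders.size)

    yy, xx = np.mgrid[0:size, 0:size]
    dx = (xx - cx) / rx
    dy = (yy - cy) / ry
    theta = np.arctan2(dy, dx)
    pert = 1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, orders, phases))
    rho = np.hypot(dx, dy) / pert  # normalized in-plane radius; 1 at the membrane

    zc = (n_slices - 1) / 2
    rz = max(params.cell_z_fill * n_slices, 0.5)
    mask = np.empty((n_slices, size, size), dtype=bool)
    edge_um = np.zeros((n_slices, size, size), dtype=np.float32)
    for z in range(n_slices):
        fz2 = 1.0 - ((z - zc) / rz) ** 2
        if fz2 <= 0:
            mask[z] = False
            continue
        mask[z] = rho <= np.sqrt(fz2)
        if mask[z].any():
            edge_um[z] = ndimage.distance_transform_edt(mask[z]) * px
    return mask, rho, edge_um, r_um


def _motif_weights(motif: str, rho_vals: np.ndarray, edge_vals: np.ndarray,
                   r_um: float) -> np.ndarray:
    if motif == "peripheral":
        w = np.exp(-edge_vals / max(0.15 * r_um, 1e-6))
    elif motif == "perinuclear":
        w = np.exp(-((rho_vals - 0.35) ** 2) / (2 * 0.15**2))
    elif motif == "diffuse":
        w = np.ones_like(rho_vals)
    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown motif {motif!r}")
    s = w.sum()
    if s <= 0:
        w = np.ones_like(rho_vals)
        s = w.sum()
    return w / s


def _render_puncta(shape, coords, offsets, amplitudes, sigma_xy_px, sigma_z_sl):
    """Accumulate 3D Gaussian spots; returns the noiseless float image."""
    n_sl, size, _ = shape
    img = np.zeros(shape, dtype=np.float64)
    wxy = int(np.ceil(3 * sigma_xy_px))
    wz = int(np.ceil(3 * sigma_z_sl))
    for (z0, y0, x0), (oz, oy, ox), amp in zip(coords, offsets, amplitudes):
        zc, yc, xc = z0 + oz, y0 + oy, x0 + ox
        zlo, zhi = max(0, z0 - wz), min(n_sl, z0 + wz + 1)
        ylo, yhi = max(0, y0 - wxy), min(size, y0 + wxy + 1)
        xlo, xhi = max(0, x0 - wxy), min(size, x0 + wxy + 1)
        zz = np.arange(zlo, zhi, dtype=np.float64) - zc
        yy = np.arange(ylo, yhi, dtype=np.float64) - yc
        xx = np.arange(xlo, xhi, dtype=np.float64) - xc
        gz = np.exp(-0.5 * (zz / sigma_z_sl) ** 2)
        gy = np.exp(-0.5 * (yy / sigma_xy_px) ** 2)
        gx = np.exp(-0.5 * (xx / sigma_xy_px) ** 2)
        img[zlo:zhi, ylo:yhi, xlo:xhi] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(img, 0, MAX_PIXEL)).astype(np.uint16)


def _add_noise(clean: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    bg = params.background_level
    if params.shot_noise:
        # scalar-rate draw over the background, per-voxel rates only where signal sits
        signal = rng.poisson(bg, clean.shape).astype(np.float64) if bg > 0 \
            else np.zeros(clean.shape)
        lit = clean > 0
        if lit.any():
            signal[lit] = rng.poisson(clean[lit] + bg)
    else:
        signal = clean + bg
    if params.read_noise_sigma > 0:
        signal = signal + rng.normal(0.0, params.read_noise_sigma, signal.shape)
    return _quantize(signal)


def generate_cell_stack(params: SceneParams, seed: int, *,
                        condition: str = "LPS", treatment: str = "control",
                        effect: ConditionEffect | None = None,
                        cell_id: str = "") -> tuple[ZStack, GroundTruth]:
    """Render one labeled cell as a two-channel stack plus its ground truth.

    The output is a pure function of (params, effect, seed): the same inputs
    reproduce the stack bit for bit.  ``true_integrated_ros`` is the sum of
    the quantized noiseless ROS channel inside the cell mask, before
    background and noise are added, so it is exactly recoverable from a
    noiseless render.
    """
    params.validate()
    effect = effect or ConditionEffect()
    effect.validate()
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")

    rng = np.random.default_rng(seed)
    n_slices = params.n_slices if params.n_slices is not None else int(rng.integers(18, 21))

    mask, rho, edge_um, r_um = _cell_geometry(params, rng, n_slices)
    atten = params.z_attenuation ** np.arange(n_slices, dtype=np.float64)

    # actin: bright cortical rim over a dimmer cell body
    rim = (edge_um <= params.cortex_width_um) & mask
    actin_clean = np.where(mask, 0.25 * params.actin_amplitude, 0.0)
    actin_clean[rim] = params.actin_amplitude
    actin_clean *= atten[:, None, None]

    # ros: Poisson number of log-normal puncta placed by the condition motif;
    # CBD scales the expected count through the effect multiplier m.
    # puncta_density_per_um3 ties the expected count to the cell volume
    # (constant organelle density), making puncta density size-invariant.
    if params.puncta_density_per_um3 is not None:
        voxel_um3 = params.pixel_size_um**2 * params.z_step_um
        base_count = params.puncta_density_per_um3 * float(mask.sum()) * voxel_um3
    else:
        base_count = params.puncta_rate
    rate = base_count * effect.baseline
    if treatment == "CBD":
        rate *= effect.cbd_multiplier
    k = int(rng.poisson(rate))
    coords = np.argwhere(mask)
    ros_clean = np.zeros_like(actin_clean)
    if k > 0 and coords.shape[0] > 0:
        zi, yi, xi = coords[:, 0], coords[:, 1], coords[:, 2]
        w = _motif_weights(effect.motif, rho[yi, xi], edge_um[zi, yi, xi], r_um)
        pick = rng.choice(coords.shape[0], size=k, p=w)
        offsets = rng.uniform(-0.5, 0.5, (k, 3))
        amps = effect.baseline * np.exp(
            rng.normal(params.puncta_intensity_mu, params.puncta_intensity_sigma, k))
        ros_clean = _render_puncta(mask.shape, coords[pick], offsets, amps,
                                   params.puncta_sigma_um / params.pixel_size_um,
                                   params.puncta_sigma_um / params.z_step_um)
        ros_clean[~mask] = 0.0  # ROS is intracellular: clip tails at the membrane
        ros_clean *= atten[:, None, None]

    ros_clean_q = _quantize(ros_clean)
    true_integrated = float(ros_clean_q[mask].sum(dtype=np.float64))

    actin = _add_noise(actin_clean, params, rng)
    ros = _add_noise(ros_clean, params, rng)

    stack = ZStack(actin=actin, ros=ros, pixel_size_um=params.pixel_size_um,
                   z_step_um=params.z_step_um, cell_id=cell_id)
    footprint_px = int(mask.any(axis=0).sum())
    truth = GroundTruth(
        cell_id=cell_id, condition=condition, treatment=treatment, mask=mask,
        true_area_um2=footprint_px * params.pixel_size_um**2,
        true_integrated_ros=true_integrated, puncta_count=k, seed=seed,
    )
    return stack, truth


def cnn_benchmark(n_per_group: int = 10, cbd_multiplier: float = 0.5,
                  image_size_px: int = 256) -> tuple[SceneParams, EffectDesign]:
    """Scene + design for the slice-classification benchmark.

    A strongly class-separated two-group experiment: 20-slice stacks of one
    large spread cell (radius 15-25 um) filling the field, dense sharp ROS
    puncta (constant density of 0.27 per um^3, i.e. ~3000 per average control
    cell, sigma 0.25 um) on a dark confocal background, and a CBD group whose
    expected puncta count is scaled by ``cbd_multiplier``.  Tying the count
    to cell volume keeps the per-slice puncta density independent of cell
    size, so density is a pure treatment readout.  With the default 10 cells per group this yields
    exactly 400 slices.  The puncta-density contrast is the class cue: it
    survives per-slice min-max normalization and histogram equalization,
    which erase absolute intensity.
    """
    scene = SceneParams(image_size_px=image_size_px, n_slices=20,
                        cell_radius_um=(19.0, 21.0),
                        puncta_density_per_um3=0.27,
                        puncta_sigma_um=0.25, puncta_intensity_sigma=0.2,
                        background_level=5.0, read_noise_sigma=2.0,
                        z_attenuation=1.0, cell_z_fill=1.5,
                        outline_irregularity=0.02, aspect_jitter=0.05)
    design = EffectDesign.two_group("LPS", n=n_per_group,
                                    cbd_multiplier=cbd_multiplier, motif="diffuse")
    return scene, design


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def write_stack(stack: ZStack, path: str, two_files: bool = False) -> list[str]:
    """Write a stack as multi-page TIFF: (Z, 2, Y, X) channel-interleaved, or
    one file per channel when ``two_files``."""
    if two_files:
        base, ext = os.path.splitext(path)
        paths = [f"{base}_actin{ext}", f"{base}_ros{ext}"]
        tifffile.imwrite(paths[0], stack.actin)
        tifffile.imwrite(paths[1], stack.ros)
        return paths
    arr = np.stack([stack.actin, stack.ros], axis=1)  # (Z, C, Y, X)
    tifffile.imwrite(path, arr)
    return [path]


def load_stack(path: str, pixel_size_um: float, z_step_um: float,
               cell_id: str = "") -> ZStack:
    """Read a channel-interleaved (Z, 2, Y, X) TIFF written by write_stack."""
    arr = tifffile.imread(path)
    if arr.ndim != 4 or arr.shape[1] != 2:
        raise ValueError(f"expected a (Z, 2, Y, X) stack in {path}, got shape {arr.shape}")
    return ZStack(actin=arr[:, 0], ros=arr[:, 1], pixel_size_um=pixel_size_um,
                  z_step_um=z_step_um, cell_id=cell_id)


def generate_dataset(params: SceneParams, design: EffectDesign, seed: int,
                     out_dir: str | None = None, two_files: bool = False,
                     keep_masks: bool | None = None,
                     ) -> tuple[pd.DataFrame, list[GroundTruth], list[ZStack] | None]:
    """Generate one stack per cell for every group in the design.

    With ``out_dir`` set, writes one multi-page TIFF per cell plus
    ``manifest.csv`` and ``ground_truth.json`` and drops the stacks from
    memory; otherwise returns the stacks in memory.  Group sizes match the
    design exactly and per-cell seeds derive deterministically from ``seed``.
    """
    params.validate()
    design.validate()
    if keep_masks is None:
        keep_masks = out_dir is None
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    truths: list[GroundTruth] = []
    stacks: list[ZStack] | None = [] if out_dir is None else None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    groups = sorted(design.n_cells.items(), key=lambda kv: (CONDITIONS.index(kv[0][0])
                                                            if kv[0][0] in CONDITIONS
                                                            else len(CONDITIONS),
                                                            kv[0][1]))
    idx = 0
    for (condition, treatment), n in groups:
        effect = design.effects[condition]
        for _ in range(n):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell_id = f"cell_{idx:04d}_{condition}_{treatment}"
            stack, truth = generate_cell_stack(
                params, cell_seed, condition=condition, treatment=treatment,
                effect=effect, cell_id=cell_id)
            path = ""
            if out_dir is not None:
                path = os.path.join(out_dir, f"{cell_id}.tif")
                write_stack(stack, path, two_files=two_files)
            else:
                stacks.append(stack)
            if not keep_masks:
                truth.mask = None
            truths.append(truth)
            rows.append({"cell_id": cell_id, "path": path, "condition": condition,
                         "treatment": treatment, "n_slices": stack.n_slices,
                         "seed": cell_seed})
            idx += 1

    manifest = pd.DataFrame(rows, columns=["cell_id", "path", "condition",
                                           "treatment", "n_slices", "seed"])
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump([t.to_record() for t in truths], fh, indent=1)
    return manifest, truths, stacks
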