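"""Slice-level dataset preparation for the CNN classifiers.

Each 3D stack is expanded into its individual 2D optical sections (treating
every z-slice as an independent training image gives roughly a twenty-fold
increase in data for 18-20-slice stacks).  Each slice is then min-max
normalized to 8-bit, converted to grayscale, resized to 256x256 with area
interpolation, and contrast-enhanced by classic histogram equalization.
The processed slices are partitioned 72/8/20 into train/validation/test by
largest-remainder apportionment, stratified by (condition, treatment), with
a grouping policy: ``by_cell`` (default) keeps all slices of one cell in a
single partition to prevent leakage; ``by_slice`` splits at the slice level.

Rounding convention throughout: round half to even, then clip to [0, 255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from .simulate import ZStack

logger = logging.getLogger("roscope.preprocess")

PARTITIONS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.72, 0.08, 0.20)

# luminance weights for collapsing RGB inputs (ITU-R 709, as used by skimage)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class ProcessedSlice:
    """One 8-bit 256x256 grayscale training image with its labels."""

    pixels: np.ndarray
    treatment: str = ""
    condition: str = ""
    cell_id: str = ""
    z_index: int = 0

    def validate(self, out_size: int = 256) -> None:
        if self.pixels.shape != (out_size, out_size):
            raise ValueError(f"expected {out_size}x{out_size} pixels, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit")


@dataclass
class RawSlice:
    """A single optical section tagged with its provenance."""

    pixels: np.ndarray
    z_index: int
    cell_id: str = ""
    condition: str = ""
    treatment: str = ""


# ---------------------------------------------------------------------------
# per-slice operations
# ---------------------------------------------------------------------------


def slice_stack(stack: ZStack, channel: str = "ros", *, condition: str = "",
                treatment: str = "") -> list[RawSlice]:
    """Split a stack into its 2D z-slices, order preserved (the augmentation)."""
    data = stack.channel(channel)
    if data.shape[0] == 0:
        raise ValueError("empty stack")
    return [RawSlice(pixels=data[z], z_index=z, cell_id=stack.cell_id,
                     condition=condition, treatment=treatment)
            for z in range(data.shape[0])]


def minmax_normalize(img) -> np.ndarray:
    """Min-max rescale to 8 bits: new = (old - min) / (max - min) * 255.

    The minimum maps to 0 and the maximum to 255.  A constant image cannot be
    rescaled and maps to all zeros (logged).
    """
    arr = np.asarray(img, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite pixels")
    mn, mx = arr.min(), arr.max()
    if mx == mn:
        logger.warning("constant image: min-max normalization returns zeros")
        return np.zeros(arr.shape, dtype=np.uint8)
    out = (arr - mn) / (mx - mn) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def equalize_hist(img8: np.ndarray) -> np.ndarray:
    """Classic 8-bit histogram equalization via CDF remapping.

    out(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255), with cdf_min the
    CDF at the lowest occupied intensity.  A constant image is returned
    unchanged (its single bin cannot be spread).
    """
    img8 = np.asarray(img8)
    if img8.dtype != np.uint8 or img8.ndim != 2:
        raise ValueError("equalize_hist expects a 2D 8-bit image")
    hist = np.bincount(img8.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = img8.size
    cdf_min = int(cdf[np.nonzero(hist)[0][0]])
    if n == cdf_min:
        return img8.copy()
    lut = np.clip(np.rint((cdf - cdf_min) / (n - cdf_min) * 255.0), 0, 255).astype(np.uint8)
    return lut[img8]


def _to_gray(img8: np.ndarray) -> np.ndarray:
    if img8.ndim == 2:
        return img8
    if img8.ndim == 3 and img8.shape[-1] in (3, 4):
        gray = img8[..., :3].astype(np.float64) @ _LUMA
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot convert shape {img8.shape} to grayscale")


def _resize_area(img8: np.ndarray, out_size: int) -> np.ndarray:
    h, w = img8.shape
    if (h, w) == (out_size, out_size):
        return img8
    if h % out_size == 0 and w % out_size == 0:
        small = transform.downscale_local_mean(img8.astype(np.float64),
                                               (h // out_size, w // out_size))
    else:
        small = transform.resize(img8.astype(np.float64), (out_size, out_size),
                                 anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(small), 0, 255).astype(np.uint8)


def preprocess_slice(img, out_size: int = 256, *, treatment: str = "",
                     condition: str = "", cell_id: str = "",
                     z_index: int = 0) -> ProcessedSlice:
    """Normalize -> grayscale -> area resize -> equalize, in that order."""
    if isinstance(img, RawSlice):
        treatment = treatment or img.treatment
        condition = condition or img.condition
        cell_id = cell_id or img.cell_id
        z_index = img.z_index
        img = img.pixels
    g8 = minmax_normalize(img)
    g8 = _to_gray(g8)
    g8 = _resize_area(g8, out_size)
    g8 = equalize_hist(g8)
    out = ProcessedSlice(pixels=g8, treatment=treatment, condition=condition,
                         cell_id=cell_id, z_index=z_index)
    out.validate(out_size)
    return out


def preprocess_stack(stack: ZStack, condition: str = "", treatment: str = "",
                     channel: str = "ros", out_size: int = 256) -> list[ProcessedSlice]:
    """slice_stack + preprocess_slice for every section of one stack."""
    return [preprocess_slice(s, out_size)
            for s in slice_stack(stack, channel, condition=condition, treatment=treatment)]


# ---------------------------------------------------------------------------
# train/validation/test split
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    """Assignment of every slice to train/val/test."""

    fractions: tuple[float, float, float]
    seed: int
    grouping: str
    assignment: list[str] = field(default_factory=list)  # one partition name per slice

    def indices(self, partition: str) -> np.ndarray:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return np.flatnonzero(np.asarray(self.assignment) == partition)

    def sizes(self) -> dict[str, int]:
        return {p: int(self.indices(p).size) for p in PARTITIONS}


def largest_remainder(total: int, fractions) -> list[int]:
    """Apportion ``total`` into integer parts proportional to ``fractions``."""
    quotas = np.asarray(fractions, dtype=np.float64) * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:short]] += 1
    return counts.tolist()


def split_dataset(slices, fractions=DEFAULT_FRACTIONS, seed: int = 0,
                  grouping: str = "by_cell") -> DatasetSplit:
    """Stratified largest-remainder split, reproducible under a fixed seed.

    Strata are (condition, treatment) groups.  Under ``by_cell`` all slices of
    a parent cell share one partition (assigned greedily to the partition with
    the largest remaining slice deficit); under ``by_slice`` slices are
    assigned independently.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if grouping not in ("by_cell", "by_slice"):
        raise ValueError(f"unknown grouping policy {grouping!r}")

    rng = np.random.default_rng(seed)
    n = len(slices)
    assignment = [""] * n

    strata: dict[tuple[str, str], list[int]] = {}
    for i, s in enumerate(slices):
        strata.setdefault((s.condition, s.treatment), []).append(i)

    for key in sorted(strata):
        idx = np.asarray(strata[key])
        targets = largest_remainder(idx.size, fractions)
        if grouping == "by_slice":
            perm = rng.permutation(idx.size)
            bounds = np.cumsum([0] + targets)
            for p, lo, hi in zip(PARTITIONS, bounds[:-1], bounds[1:]):
                for j in perm[lo:hi]:
                    assignment[idx[j]] = p
        else:
            cells: dict[str, list[int]] = {}
            for i in idx:
                cells.setdefault(slices[i].cell_id, []).append(int(i))
            sizes = {c: len(v) for c, v in cells.items()}
            if max(sizes.values()) > max(targets):
                raise ValueError(
                    "a cell has more slices than the largest partition target; "
                    "adjust the split fractions or use grouping='by_slice'")
            order = rng.permutation(sorted(cells))
            deficit = dict(zip(PARTITIONS, targets))
            for cell in order:
                part = max(PARTITIONS, key=lambda p: deficit[p])
                for i in cells[cell]:
                    assignment[i] = part
                deficit[part] -= sizes[cell]

    split = DatasetSplit(fractions=fractions, seed=seed, grouping=grouping,
                         assignment=assignment)
    if grouping == "by_cell":
        seen: dict[str, str] = {}
        for s, p in zip(slices, split.assignment):
            if seen.setdefault(s.cell_id, p) != p:  # pragma: no cover - guard
                raise AssertionError("by_cell split leaked a cell across partitions")
    return split
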