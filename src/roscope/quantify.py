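"""Per-cell ROS quantification with ImageJ semantics plus Welch group tests.

The actin channel outlines the cell: the mask is the largest connected
component of the Otsu-thresholded maximum projection after morphological
closing and hole filling.  The five per-cell measures (area, mean, max,
integrated density, raw integrated density) follow the ImageJ conventions:
RawIntDen is the raw sum of ROS pixel intensities inside the cell, IntDen is
mean x calibrated area.  Intensity statistics are computed by default on the
z-summed projection of the masked ROS signal, so RawIntDen equals the total
3D masked voxel sum while the ImageJ identities (raw = mean x area_px,
IntDen = mean x area_um2, max >= mean) hold at machine precision; a "voxel"
mode computes mean/max over the 3D voxel set instead.

Group differences are assessed with Welch's two-tailed t-test
(Welch-Satterthwaite degrees of freedom), the convention for comparing
challenge-vehicle against challenge-CBD groups of unequal variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, measure, morphology

from .simulate import ZStack, load_stack  # noqa: F401  (ZStack is part of this surface)

logger = logging.getLogger("roscope.quantify")

MEASURE_NAMES = ("area_um2", "mean", "max", "int_den", "raw_int_den")


class NoCellFoundError(ValueError):
    """Raised when segmentation finds no foreground component."""


@dataclass
class CellMask:
    """Boolean cell volume plus its 2D footprint and calibrated area."""

    volume: np.ndarray  # (Z, Y, X) bool
    footprint: np.ndarray  # (Y, X) bool
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.footprint.any():
            raise NoCellFoundError("empty cell mask")

    @property
    def area_px(self) -> int:
        return int(self.footprint.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @classmethod
    def from_footprint(cls, footprint: np.ndarray, n_slices: int,
                       pixel_size_um: float) -> "CellMask":
        volume = np.broadcast_to(footprint, (n_slices, *footprint.shape)).copy()
        return cls(volume=volume, footprint=footprint.astype(bool), pixel_size_um=pixel_size_um)


@dataclass
class CellMeasures:
    """The five per-cell ROS measures (ImageJ conventions)."""

    mean: float
    max: float
    raw_int_den: float
    int_den: float
    area_um2: float
    area_px: int

    def as_dict(self) -> dict:
        return {"area_um2": self.area_um2, "mean": self.mean, "max": self.max,
                "int_den": self.int_den, "raw_int_den": self.raw_int_den}


@dataclass
class GroupComparison:
    """Welch two-sample comparison between two labeled groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    t: float
    df: float
    p: float
    stars: str


def _significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# segmentation and measurement
# ---------------------------------------------------------------------------


def segment_cell(stack_or_actin, method: str = "otsu", threshold: float | None = None,
                 *, pixel_size_um: float | None = None, closing_radius: int = 2) -> CellMask:
    """Outline the cell from the actin channel.

    Thresholds the maximum projection (Otsu by default, or a fixed value),
    applies morphological closing, keeps the largest connected component and
    fills its holes.  Deterministic; raises :class:`NoCellFoundError` when no
    foreground component exists.
    """
    if isinstance(stack_or_actin, ZStack):
        actin = stack_or_actin.actin
        if pixel_size_um is None:
            pixel_size_um = stack_or_actin.pixel_size_um
    else:
        actin = np.asarray(stack_or_actin)
    if pixel_size_um is None:
        pixel_size_um = 1.0
    if actin.size == 0:
        raise ValueError("empty actin channel")
    if actin.ndim == 2:
        actin = actin[None]
    if actin.ndim != 3:
        raise ValueError("actin channel must be 2D or 3D (Z, Y, X)")

    proj = actin.max(axis=0).astype(np.float64)
    if method == "otsu":
        if np.ptp(proj) == 0:
            raise NoCellFoundError("uniform actin projection: no cell found")
        thr = filters.threshold_otsu(proj)
    elif method == "fixed-threshold":
        if threshold is None:
            raise ValueError("fixed-threshold segmentation requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    binary = proj > thr
    if closing_radius > 0:
        binary = morphology.closing(binary, morphology.disk(closing_radius))
    if not binary.any():
        raise NoCellFoundError("no pixels above threshold: no cell found")
    labels = measure.label(binary)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    footprint = ndimage.binary_fill_holes(labels == largest)
    return CellMask.from_footprint(footprint, actin.shape[0], pixel_size_um)


def measure_cell(ros_or_stack, mask: CellMask, pixel_size_um: float | None = None,
                 mode: str = "projection", background_correct: bool = False) -> CellMeasures:
    """Compute the five per-cell measures of the ROS channel inside the mask.

    ``mode="projection"`` (default) computes intensity statistics on the
    z-summed masked projection; ``mode="voxel"`` on the 3D masked voxel set
    (there raw_int_den = mean x n_voxels rather than mean x area_px).
    ``background_correct`` subtracts the per-slice median intensity outside
    the footprint before summing, the standard offset correction when the
    camera baseline is nonzero.
    """
    if isinstance(ros_or_stack, ZStack):
        ros = ros_or_stack.ros
        if pixel_size_um is None:
            pixel_size_um = ros_or_stack.pixel_size_um
    else:
        ros = np.asarray(ros_or_stack)
    if pixel_size_um is None:
        pixel_size_um = mask.pixel_size_um
    if ros.ndim == 2:
        ros = ros[None]
    if ros.shape[1:] != mask.footprint.shape or ros.shape[0] != mask.volume.shape[0]:
        raise ValueError("ROS channel and mask are not aligned")
    if not mask.footprint.any():
        raise ValueError("empty mask")

    ros = ros.astype(np.float64)
    if background_correct:
        outside = ~mask.footprint
        if outside.any():
            bg = np.array([np.median(sl[outside]) for sl in ros])
            ros = ros - bg[:, None, None]

    area_px = mask.area_px
    area_um2 = area_px * pixel_size_um**2
    if mode == "projection":
        vals = ros.sum(axis=0)[mask.footprint]
    elif mode == "voxel":
        vals = ros[mask.volume]
    else:
        raise ValueError(f"unknown measure mode {mode!r}")

    mean = float(vals.mean())
    mx = float(vals.max())
    if mode == "projection":
        raw = mean * area_px  # identical to vals.sum() up to the order of summation
        int_den = mean * area_um2
    else:
        raw = float(vals.sum())
        int_den = (raw / vals.size) * area_um2
    return CellMeasures(mean=mean, max=mx, raw_int_den=raw, int_den=int_den,
                        area_um2=area_um2, area_px=area_px)


def measure_dataset(stacks, manifest: pd.DataFrame | None = None, *,
                    method: str = "otsu", mode: str = "projection",
                    background_correct: bool = False) -> pd.DataFrame:
    """Segment and measure every stack; returns one row per cell.

    ``stacks`` is a sequence of :class:`ZStack`; labels are joined from the
    manifest on cell_id when given.
    """
    rows = []
    for stack in stacks:
        cm = segment_cell(stack, method=method)
        meas = measure_cell(stack, cm, mode=mode, background_correct=background_correct)
        rows.append({"cell_id": stack.cell_id, **meas.as_dict()})
    df = pd.DataFrame(rows)
    if manifest is not None:
        df = df.merge(manifest[["cell_id", "condition", "treatment"]], on="cell_id", how="left")
    return df


def measure_file_dataset(manifest: pd.DataFrame, pixel_size_um: float,
                         z_step_um: float, **kwargs) -> pd.DataFrame:
    """measure_dataset over TIFF files listed in a manifest."""
    stacks = (load_stack(row.path, pixel_size_um, z_step_um, cell_id=row.cell_id)
              for row in manifest.itertuples())
    return measure_dataset(stacks, manifest, **kwargs)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def welch_test(values_a, values_b, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Welch's two-tailed t-test for unequal variances.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-tailed p from Student's
    t distribution.  When both variances are zero: p = 1 if the means agree
    (t = 0), else p = 0 (documented convention for degenerate input).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")

    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        df = float(na + nb - 2)
        if ma == mb:
            t, p = 0.0, 1.0
        else:
            t = np.inf if ma > mb else -np.inf
            p = 0.0
    else:
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(2 * stats.t.sf(abs(t), df))
    return GroupComparison(label_a=labels[0], label_b=labels[1], n_a=na, n_b=nb,
                           mean_a=float(ma), mean_b=float(mb), var_a=float(va),
                           var_b=float(vb), t=float(t), df=float(df), p=p,
                           stars=_significance_stars(p))


def compare_groups(measures: pd.DataFrame, measure_name: str,
                   manifest: pd.DataFrame | None = None,
                   holm: bool = False) -> tuple[dict[str, GroupComparison], pd.DataFrame]:
    """CBD-vs-control Welch comparison per condition for one measure.

    Returns the comparisons keyed by condition plus a summary table with
    group means and SEMs (bar-chart data).  Conditions missing a group or
    with fewer than 2 cells per group are skipped with a warning.  ``holm``
    applies a Holm step-down correction across conditions (off by default:
    per-measure p-values are reported uncorrected).
    """
    if measure_name not in measures.columns:
        raise ValueError(f"unknown measure {measure_name!r}")
    df = measures
    if "condition" not in df.columns or "treatment" not in df.columns:
        if manifest is None:
            raise ValueError("measures lack labels and no manifest was given")
        df = df.merge(manifest[["cell_id", "condition", "treatment"]], on="cell_id")

    comparisons: dict[str, GroupComparison] = {}
    rows = []
    for condition, grp in df.groupby("condition", sort=True):
        cbd = grp.loc[grp.treatment == "CBD", measure_name].to_numpy()
        ctl = grp.loc[grp.treatment == "control", measure_name].to_numpy()
        if cbd.size < 2 or ctl.size < 2:
            warnings.warn(f"condition {condition!r}: missing or undersized group, "
                          "comparison skipped", stacklevel=2)
            continue
        comp = welch_test(cbd, ctl, labels=(f"{condition}-CBD", f"{condition}-control"))
        comparisons[str(condition)] = comp
        rows.append({
            "condition": condition, "measure": measure_name,
            "n_cbd": comp.n_a, "n_control": comp.n_b,
            "mean_cbd": comp.mean_a, "mean_control": comp.mean_b,
            "sem_cbd": float(np.sqrt(comp.var_a / comp.n_a)),
            "sem_control": float(np.sqrt(comp.var_b / comp.n_b)),
            "t": comp.t, "df": comp.df, "p": comp.p, "stars": comp.stars,
        })
    summary = pd.DataFrame(rows)
    if holm and not summary.empty:
        order = np.argsort(summary["p"].to_numpy())
        m = len(order)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * summary["p"].iloc[i]))
            adj[i] = running
        summary["p_holm"] = adj
    return comparisons, summary


def compare_all_measures(measures: pd.DataFrame,
                         manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Welch comparisons for every standard measure; one row per (condition, measure)."""
    tables = []
    for name in MEASURE_NAMES:
        if name in measures.columns:
            _, summary = compare_groups(measures, name, manifest)
            tables.append(summary)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
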