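"""Mesophyll anatomy from labeled 3D leaf volumes.

Works on integer class grids (one voxel label per tissue) such as those
produced by semantic segmentation of synchrotron microCT scans of leaves.
Conventions: arrays are indexed (slice, row, column); the row axis runs
adaxial -> abaxial; volumes are axis-aligned with an isotropic voxel edge
(default 0.65 um). The mesophyll volume V_mes is palisade + spongy + IAS;
veins and bundle-sheath extensions are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

__all__ = [
    "DEFAULT_LEGEND",
    "DEFAULT_VOXEL_EDGE",
    "LabeledVolume",
    "AnatomyTraits",
    "AnatomyError",
    "tissue_volumes",
    "interface_surface_area",
    "leaf_thickness",
    "anatomy_traits",
    "segmentation_f1",
]

#: Canonical class legend for labeled leaf volumes.
DEFAULT_LEGEND = {
    "background": 0,
    "adaxial_epidermis": 1,
    "abaxial_epidermis": 2,
    "palisade": 3,
    "spongy": 4,
    "ias": 5,
    "bundle_sheath_extension": 6,
    "vein": 7,
}

#: Scan resolution in um per voxel edge.
DEFAULT_VOXEL_EDGE = 0.65

MESOPHYLL_CLASSES = ("palisade", "spongy", "ias")


class AnatomyError(ValueError):
    """Invalid labeled volume or undefined trait."""


@dataclass
class LabeledVolume:
    """A 3D integer class grid with voxel size and class legend."""

    grid: np.ndarray
    voxel_edge: float = DEFAULT_VOXEL_EDGE
    legend: dict = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise AnatomyError("grid must be a non-empty 3D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise AnatomyError("grid must hold integer class labels")
        if not self.voxel_edge > 0:
            raise AnatomyError("voxel_edge must be positive")
        present = set(np.unique(self.grid).tolist())
        known = set(self.legend.values())
        if not present <= known:
            raise AnatomyError(
                f"grid contains labels absent from legend: {sorted(present - known)}")

    def mask(self, *class_names: str) -> np.ndarray:
        ids = [self.legend[c] for c in class_names]
        return np.isin(self.grid, ids)


@dataclass
class AnatomyTraits:
    """Per-leaf mesophyll traits.

    Surface areas are per unit mesophyll volume (um2 um-3, i.e. the
    classical Sm when multiplied through by mesophyll volume per leaf
    area); theta_ias and the volume ratios are dimensionless; l_leaf in um.
    """

    sa_mes_total: float
    sa_mes_p: float
    sa_mes_s: float
    theta_ias: float
    p_to_m: float
    s_to_m: float
    s_to_p: float
    l_leaf: float

    def as_dict(self) -> dict:
        return {
            "sa_mes_total": self.sa_mes_total, "sa_mes_p": self.sa_mes_p,
            "sa_mes_s": self.sa_mes_s, "theta_ias": self.theta_ias,
            "p_to_m": self.p_to_m, "s_to_m": self.s_to_m,
            "s_to_p": self.s_to_p, "l_leaf": self.l_leaf,
        }


def tissue_volumes(vol: LabeledVolume) -> dict:
    """Voxel counts and physical volumes (um3) per mesophyll class.

    V_mes = V_palisade + V_spongy + V_IAS; vein and bundle-sheath voxels do
    not contribute.
    """
    for cls in MESOPHYLL_CLASSES:
        if cls not in vol.legend:
            raise AnatomyError(f"legend lacks required class {cls!r}")
    counts = np.bincount(vol.grid.ravel(), minlength=max(vol.legend.values()) + 1)
    voxvol = vol.voxel_edge ** 3
    n_p = int(counts[vol.legend["palisade"]])
    n_s = int(counts[vol.legend["spongy"]])
    n_i = int(counts[vol.legend["ias"]])
    return {
        "v_p": n_p * voxvol, "v_s": n_s * voxvol, "v_ias": n_i * voxvol,
        "v_mes": (n_p + n_s + n_i) * voxvol,
        "counts": {name: int(counts[idx]) if idx < counts.size else 0
                   for name, idx in vol.legend.items()},
    }


def _face_count(a: np.ndarray, b: np.ndarray) -> int:
    """Number of shared voxel faces between disjoint masks a and b."""
    total = 0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)
        total += int(np.count_nonzero(a[lo] & b[hi]))
        total += int(np.count_nonzero(b[lo] & a[hi]))
    return total


#: Gaussian pre-smoothing (voxels) applied before marching cubes; chosen so
#: voxelized spheres of radius >= 8 voxels are recovered within ~1%.
MESH_SMOOTH_SIGMA = 0.8


def _mesh_area(mask: np.ndarray, spacing: float,
               sigma: float = MESH_SMOOTH_SIGMA) -> float:
    """Isosurface area of a smoothed binary mask, closed by zero padding.

    Marching cubes on the raw 0/1 mask still reproduces the voxel
    staircase (~8% high on spheres); a light Gaussian smoothing first
    removes that curvature bias.
    """
    if not mask.any():
        return 0.0
    padded = np.pad(mask.astype(np.float32), 2)
    if sigma > 0:
        padded = gaussian_filter(padded, sigma)
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5,
                                              spacing=(spacing,) * 3)
    return float(measure.mesh_surface_area(verts, faces))


def interface_surface_area(
    vol: LabeledVolume,
    cell_classes: set | frozenset = frozenset({"palisade", "spongy"}),
    method: str = "face",
    boundary: str = "ias",
) -> float:
    """Surface area (um2) of the mesophyll cell / airspace interface.

    ``boundary='ias'`` (default) measures the cell surface exposed to the
    intercellular airspace -- the exposure surface that Sm quantifies.
    ``boundary='all'`` instead measures the total boundary of the cell
    classes against every other class (cell walls shared with epidermis,
    veins etc. included).

    ``method='face'`` counts shared voxel faces x voxel_edge^2 (exact on the
    voxel grid, but overestimates smooth interfaces by a staircase factor of
    about 1.5); ``method='mesh'`` uses a marching-cubes isosurface, which
    tracks smooth interfaces to within a few percent. For the 'ias' boundary
    the mesh area uses the identity
    A(cell|ias) = [A(cell|rest) + A(ias|rest) - A(cell+ias|rest)] / 2,
    exact for face counting and a good approximation for meshed surfaces.
    """
    if not cell_classes:
        raise AnatomyError("cell_classes must be non-empty")
    if not set(cell_classes) <= {"palisade", "spongy"}:
        raise AnatomyError("cell_classes must be a subset of {'palisade', 'spongy'}")
    cells = vol.mask(*cell_classes)
    if boundary == "ias":
        other = vol.mask("ias")
    elif boundary == "all":
        other = ~cells
    else:
        raise AnatomyError(f"unknown boundary {boundary!r}")

    if method == "face":
        return _face_count(cells, other) * vol.voxel_edge ** 2
    if method == "mesh":
        if boundary == "all":
            return _mesh_area(cells, vol.voxel_edge)
        a_cell = _mesh_area(cells, vol.voxel_edge)
        a_ias = _mesh_area(other, vol.voxel_edge)
        a_both = _mesh_area(cells | other, vol.voxel_edge)
        return max(0.0, 0.5 * (a_cell + a_ias - a_both))
    raise AnatomyError(f"unknown method {method!r}")


def leaf_thickness(
    vol: LabeledVolume,
    n_columns: int = 5,
    n_slices: int = 6,
    seed: int | None = 0,
    exhaustive: bool = False,
    max_resample: int = 200,
) -> float:
    """Mean leaf thickness (um) from sampled cross-section lines.

    Mirrors line-tool measurements on cross-section images: ``n_slices``
    slices are sampled, and on each ``n_columns`` columns; per column the
    thickness is the inclusive row span from the outermost adaxial-epidermis
    voxel to the outermost abaxial-epidermis voxel, times the voxel edge.
    ``exhaustive=True`` instead averages every column (in every slice) that
    intersects both epidermes, and is the deterministic oracle for the
    sampled estimate.
    """
    ad = vol.mask("adaxial_epidermis")
    ab = vol.mask("abaxial_epidermis")
    if not ad.any() or not ab.any():
        raise AnatomyError("volume lacks an epidermis class; thickness undefined")
    nz, ny, nx = vol.grid.shape

    def column_thickness(z: int, x: int) -> float | None:
        a = np.flatnonzero(ad[z, :, x])
        b = np.flatnonzero(ab[z, :, x])
        if a.size == 0 or b.size == 0:
            return None
        top = a.min()
        bottom = b.max()
        if bottom < top:
            return None
        return (bottom - top + 1) * vol.voxel_edge

    if exhaustive:
        vals = [t for z in range(nz) for x in range(nx)
                if (t := column_thickness(z, x)) is not None]
        if not vals:
            raise AnatomyError("no column intersects both epidermes")
        return float(np.mean(vals))

    rng = np.random.default_rng(seed)
    slices = rng.choice(nz, size=min(n_slices, nz), replace=False)
    vals = []
    for z in slices:
        got, tries = 0, 0
        while got < n_columns and tries < max_resample:
            x = int(rng.integers(nx))
            t = column_thickness(int(z), x)
            tries += 1
            if t is not None:
                vals.append(t)
                got += 1
        if got == 0:
            raise AnatomyError(f"slice {z} has no column crossing both epidermes")
    return float(np.mean(vals))


def anatomy_traits(
    vol: LabeledVolume,
    surface_method: str = "face",
    n_columns: int = 5,
    n_slices: int = 6,
    seed: int | None = 0,
    exhaustive_thickness: bool = False,
) -> AnatomyTraits:
    """All mesophyll traits for one labeled leaf volume."""
    v = tissue_volumes(vol)
    if v["v_mes"] <= 0:
        raise AnatomyError("mesophyll volume is zero; traits undefined")
    if v["v_p"] <= 0:
        raise AnatomyError("palisade volume is zero; S:P undefined")
    sa_p = interface_surface_area(vol, {"palisade"}, method=surface_method)
    sa_s = interface_surface_area(vol, {"spongy"}, method=surface_method)
    l_leaf = leaf_thickness(vol, n_columns=n_columns, n_slices=n_slices,
                            seed=seed, exhaustive=exhaustive_thickness)
    return AnatomyTraits(
        sa_mes_total=(sa_p + sa_s) / v["v_mes"],
        sa_mes_p=sa_p / v["v_mes"],
        sa_mes_s=sa_s / v["v_mes"],
        theta_ias=v["v_ias"] / v["v_mes"],
        p_to_m=v["v_p"] / v["v_mes"],
        s_to_m=v["v_s"] / v["v_mes"],
        s_to_p=v["v_s"] / v["v_p"],
        l_leaf=l_leaf,
    )


def segmentation_f1(pred: LabeledVolume, truth: LabeledVolume) -> dict:
    """Per-class voxelwise F1 = 2TP / (2TP + FP + FN) of a predicted label map.

    Classes absent from both volumes are omitted from the result.
    """
    if pred.grid.shape != truth.grid.shape:
        raise AnatomyError("prediction and truth grids differ in shape")
    if pred.legend != truth.legend:
        raise AnatomyError("prediction and truth legends differ")
    p = pred.grid.ravel()
    t = truth.grid.ravel()
    out = {}
    for name, idx in truth.legend.items():
        pm = p == idx
        tm = t == idx
        denom = pm.sum() + tm.sum()
        if denom == 0:
            continue
        tp = np.count_nonzero(pm & tm)
        out[name] = 2.0 * tp / denom
    return out
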