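"""Synthetic study inputs: A-Ci curves, leaf voxel phantoms, trait tables.

Three generators exercise the full pipeline without any measured data:

* :func:`simulate_aci` produces FvCB-consistent CO2 response curves by
  solving the coupled stomatal/mesophyll supply and biochemical demand
  system at the chamber setpoints of the measurement protocol, with
  additive Gaussian noise on An;
* :func:`gen_leaf_phantom` builds a labeled leaf volume whose airspace is
  made of analytic primitives (cylindrical channels through the palisade,
  spherical bubbles in the spongy layer) so every tissue volume and
  cell-airspace interface area has a closed form;
* :func:`gen_bm_traits` simulates Brownian-motion trait evolution on a
  phylogeny with an optional additive leaf-habit effect, the null and
  alternative generator for the phylogenetic ANOVA.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .anatomy3d import DEFAULT_LEGEND, DEFAULT_VOXEL_EDGE, LabeledVolume
from .gas_exchange import (
    CA_SETPOINTS_BASE,
    CA_SETPOINTS_EXTRA,
    AciCurve,
    FluorescenceConfig,
    FvcbParams,
    GasExchangeError,
)

__all__ = [
    "SimSpec",
    "PhantomSpec",
    "PhantomError",
    "simulate_aci",
    "solve_operating_point",
    "gen_leaf_phantom",
    "phantom_spec_for_habit",
    "full_protocol_setpoints",
    "gen_bm_traits",
    "default_oak_tree",
    "DEFAULT_HABIT_MAP",
    "SPECIES_PARAMS",
]


class PhantomError(ValueError):
    """Infeasible phantom geometry."""


# ---------------------------------------------------------------------------
# A-Ci curve simulation


@dataclass(frozen=True)
class SimSpec:
    """Forward-simulation settings for one leaf's CO2 response curves.

    ``gs`` is held constant across setpoints (no stomatal dynamics), and
    noise is additive Gaussian on An only; Ci is reported as solved.
    """

    params: FvcbParams
    ca_setpoints: tuple = CA_SETPOINTS_BASE
    gs: float = 0.3
    ppfd: float = 1500.0
    leaf_temp: float = 30.0
    noise_sd: float = 0.5
    replicates: int = 1
    seed: int = 0
    species: str = "sim"
    tree_id: str = "t1"
    habit: str = "deciduous"
    year: int = 2022
    with_fluorescence: bool = True

    def __post_init__(self) -> None:
        sp = tuple(self.ca_setpoints)
        if any(s <= 0 for s in sp) or list(sp) != sorted(sp):
            raise GasExchangeError("ca_setpoints must be positive and sorted")
        if self.noise_sd < 0:
            raise GasExchangeError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise GasExchangeError("replicates must be >= 1")
        if not self.gs > 0:
            raise GasExchangeError("gs must be positive")


def full_protocol_setpoints() -> tuple:
    """All 13 chamber CO2 setpoints of the extended protocol, sorted."""
    return tuple(sorted(CA_SETPOINTS_BASE + CA_SETPOINTS_EXTRA))


def solve_operating_point(params: FvcbParams, ca: float, gs: float) -> tuple[float, float]:
    """Steady-state (an, ci) where supply gs*(ca-ci) meets biochemical demand.

    Chloroplast CO2 follows cc = ci - an/gm (cc = ci for unbounded gm). The
    root is bracketed in ci; no root means a non-physical parameter set.
    """
    gm = params.gm

    def resid(ci: float) -> float:
        an = gs * (ca - ci)
        cc = ci if gm is None else ci - an / gm
        cc = max(cc, -params.km * 0.99)
        rd = params.rd
        a_c = params.vcmax * (cc - params.gamma_star) / (cc + params.km) - rd
        a_j = params.jmax * (cc - params.gamma_star) / (4 * cc + 8 * params.gamma_star) - rd
        a = min(a_c, a_j)
        if params.tpu is not None:
            a = min(a, 3 * params.tpu - rd)
        return an - a

    lo = 1e-9
    hi = ca + (params.rd + 2.0) / gs
    flo, fhi = resid(lo), resid(hi)
    if flo * fhi > 0:
        raise GasExchangeError(
            f"no operating point in ({lo:g}, {hi:g}) at ca={ca}; "
            "non-physical parameter combination")
    ci = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14)
    return gs * (ca - ci), ci


def _phi_psii_for(params: FvcbParams, an: float, ci: float, ppfd: float,
                  config: FluorescenceConfig) -> float:
    """PhiPSII consistent with the variable-J relation at the solved point."""
    cc = ci if params.gm is None else ci - an / params.gm
    if cc <= params.gamma_star:
        return np.nan
    j = 4.0 * (an + params.rd) * (cc + 2.0 * params.gamma_star) / (cc - params.gamma_star)
    phi = j / (ppfd * config.alpha * config.beta)
    return phi if 0 <= phi <= 1 else np.nan


def simulate_aci(spec: SimSpec) -> list[AciCurve]:
    """Simulate ``spec.replicates`` A-Ci curves for one leaf.

    Each curve solves the coupled system exactly at every setpoint, then
    adds N(0, noise_sd) to An. When ``with_fluorescence``, PhiPSII is
    emitted consistent with the true gm via the variable-J relation (NaN
    where Cc <= Gamma*), using the habit's absorbance.
    """
    rng = np.random.default_rng(spec.seed)
    setpoints = np.asarray(spec.ca_setpoints, dtype=float)
    an0 = np.empty_like(setpoints)
    ci0 = np.empty_like(setpoints)
    for i, ca in enumerate(setpoints):
        an0[i], ci0[i] = solve_operating_point(spec.params, float(ca), spec.gs)
    fconf = FluorescenceConfig.for_habit(spec.habit)
    phi0 = np.array([
        _phi_psii_for(spec.params, a, c, spec.ppfd, fconf)
        for a, c in zip(an0, ci0)
    ]) if spec.with_fluorescence else None

    curves = []
    for rep in range(spec.replicates):
        an = an0 + rng.normal(0.0, spec.noise_sd, size=an0.size) if spec.noise_sd > 0 \
            else an0.copy()
        curves.append(AciCurve(
            ca_setpoint=setpoints.copy(), an=an, ci=ci0.copy(),
            gs=np.full_like(setpoints, spec.gs),
            ppfd=np.full_like(setpoints, spec.ppfd),
            leaf_temp=np.full_like(setpoints, spec.leaf_temp),
            phi_psii=None if phi0 is None else phi0.copy(),
            species=spec.species,
            tree_id=spec.tree_id if spec.replicates == 1 else f"{spec.tree_id}r{rep + 1}",
            habit=spec.habit, year=spec.year,
        ))
    return curves


# ---------------------------------------------------------------------------
# Leaf voxel phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of an analytic leaf phantom.

    The leaf fills the grid: adaxial epidermis, palisade, spongy and
    abaxial epidermis slabs stacked along the row axis. Airspace is carved
    as IAS primitives with closed-form volume and area: vertical cylindrical
    channels (radius ``channel_radius``, square lattice ``channel_spacing``)
    spanning the palisade depth, and non-touching spheres (radii uniform in
    ``sphere_radius_range``) inside the spongy layer, placed by rejection
    sampling until the whole-mesophyll porosity reaches ``target_porosity``.
    Defaults give a ~150 um thick leaf at the scan resolution of 0.65 um
    with porosity in the range observed for oak leaves.
    """

    shape: tuple = (96, 231, 96)          # (slices, rows, columns)
    voxel_edge: float = DEFAULT_VOXEL_EDGE
    epidermis_voxels: int = 15
    palisade_voxels: int = 120
    spongy_voxels: int = 81
    channel_radius: int = 6
    channel_spacing: int = 19
    sphere_radius_range: tuple = (8, 12)
    target_porosity: float = 0.23
    include_veins: bool = False
    seed: int = 0
    max_attempts: int = 200_000

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if 2 * self.epidermis_voxels + self.palisade_voxels + self.spongy_voxels != ny:
            raise PhantomError("layer depths must sum to the row extent of the grid")
        if not 0 <= self.target_porosity < 1:
            raise PhantomError("target_porosity must be in [0, 1)")
        r0, r1 = self.sphere_radius_range
        if not (0 < r0 <= r1):
            raise PhantomError("invalid sphere_radius_range")
        if self.target_porosity > 0 and self.channel_radius > 0 \
                and self.channel_spacing <= 2 * self.channel_radius:
            raise PhantomError("channel_spacing must exceed the channel diameter")


def _sphere_mask(shape, center, r):
    z0, y0, x0 = center
    zlo, zhi = int(np.floor(z0 - r)), int(np.ceil(z0 + r)) + 1
    ylo, yhi = int(np.floor(y0 - r)), int(np.ceil(y0 + r)) + 1
    xlo, xhi = int(np.floor(x0 - r)), int(np.ceil(x0 + r)) + 1
    z, y, x = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
    m = (z - z0) ** 2 + (y - y0) ** 2 + (x - x0) ** 2 <= r * r
    return (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi)), m


def gen_leaf_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, dict]:
    """Build a labeled leaf phantom and its closed-form ground truth.

    Returns the volume and a truth dict with analytic tissue volumes (um3),
    cell-IAS interface areas (um2), porosity/ratio values and leaf
    thickness (um). Cylinder channels contribute lateral area to the
    palisade interface and one end-cap disk (against the solid spongy
    matrix) to the spongy interface; spheres contribute their full surface
    to the spongy interface. Raises :class:`PhantomError` when the target
    porosity cannot be reached by non-touching spheres.
    """
    nz, ny, nx = spec.shape
    L = DEFAULT_LEGEND
    e, dp, ds = spec.epidermis_voxels, spec.palisade_voxels, spec.spongy_voxels
    grid = np.empty(spec.shape, dtype=np.uint8)
    grid[:, :e, :] = L["adaxial_epidermis"]
    grid[:, e:e + dp, :] = L["palisade"]
    grid[:, e + dp:e + dp + ds, :] = L["spongy"]
    grid[:, e + dp + ds:, :] = L["abaxial_epidermis"]

    vox = spec.voxel_edge
    v_mes_layers = (dp + ds) * nz * nx            # voxel units
    target_ias = spec.target_porosity * v_mes_layers

    n_channels = 0
    if spec.target_porosity > 0 and spec.channel_radius > 0:
        r = spec.channel_radius
        margin = r + 1
        zs = np.arange(margin, nz - margin + 1, spec.channel_spacing)
        xs = np.arange(margin, nx - margin + 1, spec.channel_spacing)
        zz, xx = np.mgrid[0:nz, 0:nx]
        for cz in zs:
            for cx in xs:
                disk = (zz - cz) ** 2 + (xx - cx) ** 2 <= r * r
                grid[:, e:e + dp, :][np.broadcast_to(disk[:, None, :], (nz, dp, nx))] \
                    = L["ias"]
                n_channels += 1
    v_channels = n_channels * np.pi * spec.channel_radius ** 2 * dp
    if v_channels > target_ias + 0.5 * np.pi * spec.channel_radius ** 2 * dp \
            and spec.target_porosity > 0 and n_channels > 0:
        raise PhantomError(
            "palisade channels alone exceed the target porosity; widen spacing")

    truth_veins = {"v_vein": 0.0, "v_bse": 0.0}
    vein_keepout = None
    if spec.include_veins:
        # small rectangular vein + bundle-sheath block mid-spongy, away from IAS
        vz = slice(nz // 2 - 5, nz // 2 + 5)
        vy = slice(e + dp + ds // 2 - 4, e + dp + ds // 2 + 4)
        vx = slice(2, nx - 2)
        grid[vz, vy, vx] = L["bundle_sheath_extension"]
        iz = slice(nz // 2 - 3, nz // 2 + 3)
        iy = slice(e + dp + ds // 2 - 2, e + dp + ds // 2 + 2)
        grid[iz, iy, vx] = L["vein"]
        truth_veins["v_bse"] = (10 * 8 - 6 * 4) * (nx - 4) * vox ** 3
        truth_veins["v_vein"] = 6 * 4 * (nx - 4) * vox ** 3
        vein_keepout = (nz // 2 - 5, nz // 2 + 5, e + dp + ds // 2 - 4,
                        e + dp + ds // 2 + 4)

    # spongy spheres by rejection sampling; non-touching so areas stay exact
    rng = np.random.default_rng(spec.seed)
    r0, r1 = spec.sphere_radius_range
    min_vol = 4.0 / 3.0 * np.pi * r0 ** 3
    centers: list[tuple[float, float, float]] = []
    radii: list[float] = []
    v_spheres = 0.0
    attempts = 0
    while v_spheres + v_channels + 0.5 * min_vol < target_ias:
        if attempts >= spec.max_attempts:
            raise PhantomError(
                f"could not reach target porosity {spec.target_porosity} with "
                f"non-touching spheres after {attempts} attempts")
        attempts += 1
        remaining = target_ias - v_channels - v_spheres
        r_hi = min(r1, (remaining * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0))
        if r_hi < r0:
            break
        r = rng.uniform(r0, r_hi)
        cz = rng.uniform(r + 1, nz - r - 2)
        cy = rng.uniform(e + dp + r + 1, e + dp + ds - r - 2)
        cx = rng.uniform(r + 1, nx - r - 2)
        if vein_keepout is not None:
            z0, z1_, y0, y1_ = vein_keepout
            if (z0 - r - 1 < cz < z1_ + r + 1) and (y0 - r - 1 < cy < y1_ + r + 1):
                continue
        ok = True
        for (oz, oy, ox), orad in zip(centers, radii):
            if (cz - oz) ** 2 + (cy - oy) ** 2 + (cx - ox) ** 2 < (r + orad + 2.0) ** 2:
                ok = False
                break
        if not ok:
            continue
        sl, m = _sphere_mask(spec.shape, (cz, cy, cx), r)
        grid[sl][m] = L["ias"]
        centers.append((cz, cy, cx))
        radii.append(r)
        v_spheres += 4.0 / 3.0 * np.pi * r ** 3

    radii_arr = np.asarray(radii)
    v_ias = (v_channels + v_spheres) * vox ** 3
    v_p = (dp * nz * nx - v_channels) * vox ** 3
    v_s = ds * nz * nx * vox ** 3 - v_spheres * vox ** 3 \
        - truth_veins["v_vein"] - truth_veins["v_bse"]
    v_mes = v_p + v_s + v_ias
    sa_p = n_channels * 2.0 * np.pi * spec.channel_radius * dp * vox ** 2
    sa_s = (np.sum(4.0 * np.pi * radii_arr ** 2)
            + n_channels * np.pi * spec.channel_radius ** 2) * vox ** 2

    truth = {
        "v_p": v_p, "v_s": v_s, "v_ias": v_ias, "v_mes": v_mes,
        "theta_ias": v_ias / v_mes, "p_to_m": v_p / v_mes, "s_to_m": v_s / v_mes,
        "s_to_p": v_s / v_p if v_p > 0 else np.nan,
        "sa_p": sa_p, "sa_s": sa_s, "sa_total": sa_p + sa_s,
        "sa_mes_total": (sa_p + sa_s) / v_mes,
        "l_leaf": ny * vox,
        "n_channels": n_channels, "n_spheres": len(radii),
        "sphere_radii": radii_arr,
        **truth_veins,
    }
    return LabeledVolume(grid=grid, voxel_edge=vox), truth


def phantom_spec_for_habit(habit: str, seed: int = 0) -> PhantomSpec:
    """Phantom geometry emulating the habit-typical mesophyll organisation.

    Deciduous leaves get a palisade-dominant, low-porosity mesophyll;
    evergreen leaves a spongier, more porous one (denser channel lattice,
    thinner palisade). Both keep the same leaf thickness class (~150 um).
    """
    if habit == "deciduous":
        return PhantomSpec(seed=seed)
    if habit == "evergreen":
        return PhantomSpec(palisade_voxels=104, spongy_voxels=97,
                           channel_spacing=14, target_porosity=0.32, seed=seed)
    raise ValueError(f"unknown habit {habit!r}")


# ---------------------------------------------------------------------------
# Brownian-motion trait evolution


def default_oak_tree() -> dendropy.Tree:
    """Synthetic 6-species oak phylogeny: three deciduous/evergreen sister pairs.

    An ultrametric stand-in (depth 35 My) for the pruned study phylogeny;
    branch lengths are invented but of realistic magnitude for oak
    divergences.
    """
    newick = ("((Quercus_kelloggii:10,Quercus_agrifolia:10):25,"
              "((Quercus_lobata:12,Quercus_rugosa:12):15,"
              "(Quercus_douglasii:14,Quercus_suber:14):13):8);")
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


#: Leaf habit of each synthetic study species.
DEFAULT_HABIT_MAP = {
    "Quercus_kelloggii": "deciduous",
    "Quercus_lobata": "deciduous",
    "Quercus_douglasii": "deciduous",
    "Quercus_agrifolia": "evergreen",
    "Quercus_rugosa": "evergreen",
    "Quercus_suber": "evergreen",
}

#: Species-level true biochemical parameters and anatomy targets used by the
#: study-scale simulation. Deciduous leaves get the higher capacities and a
#: denser (less porous, palisade-rich) mesophyll, evergreen the reverse,
#: with magnitudes in the range reported for oaks.
SPECIES_PARAMS: dict[str, dict] = {
    "deciduous": {
        "vcmax": 73.0, "jmax": 109.0, "tpu": 8.0, "rd": 0.88, "gm": 0.25,
        "theta_ias": 0.23, "p_to_m": 0.484, "l_leaf": 150.0, "lma": 9.0,
    },
    "evergreen": {
        "vcmax": 40.0, "jmax": 60.0, "tpu": 4.4, "rd": 0.71, "gm": 0.18,
        "theta_ias": 0.32, "p_to_m": 0.358, "l_leaf": 160.0, "lma": 11.0,
    },
}


def gen_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    habit_effect: float,
    habit_map: dict[str, str],
    seed: int | None = 0,
    trait_names: Sequence[str] = ("trait",),
) -> pd.DataFrame:
    """Brownian-motion tip values with an additive habit effect.

    Each trait evolves independently from a root state of 0 with Gaussian
    increments of variance ``sigma2`` x branch length; ``habit_effect`` is
    added to every deciduous tip. Returns a species x trait table with the
    habit factor.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(tips) - set(habit_map)
    if missing:
        raise ValueError(f"habit_map lacks tips: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in trait_names:
        state: dict = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                state[node] = 0.0
                continue
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 > 0 and bl > 0 else 0.0
            state[node] = state[parent] + step
        vals = {l.taxon.label: state[l] for l in tree.leaf_node_iter()}
        cols[name] = [
            vals[t] + (habit_effect if habit_map[t] == "deciduous" else 0.0)
            for t in tips
        ]
    out = pd.DataFrame({"species": tips,
                        "habit": [habit_map[t] for t in tips], **cols})
    return out
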