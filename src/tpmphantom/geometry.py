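"""Procedural generation of the 3D scattering microphantom.

The phantom is a biomimetic test object for tomographic phase microscopy:
a cell-like imaging target (truncated ellipsoid with resolution line
groups, a nucleus with nucleoli and a slow refractive-index gradient)
embedded in a multiple-scattering cube built from pseudo-randomly spaced
rectangular rods whose orientation alternates from layer to layer.

All lengths are micrometres, refractive indices are dimensionless.
Coordinate convention: axis order ``(x, y, z)`` with ``z`` the optical
axis; voxel ``i`` is centred at ``origin + (i + 0.5) * pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "CellTargetSpec",
    "RodLayerLayout",
    "LineGroup",
    "RIVolume",
    "sample_rod_layouts",
    "rasterize_scattering_cube",
    "build_cell_target",
    "line_group_layouts",
    "compose_phantom",
    "compute_fill_factor",
    "generate_phantom",
    "beer_lambert_transmittance",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RIVolume:
    """A refractive-index field on a regular voxel grid.

    Attributes
    ----------
    values : (nx, ny, nz) float array of absolute refractive index.
    voxel_pitch : physical voxel size per axis, µm.
    origin : physical position of the lower corner of voxel (0,0,0), µm;
        voxel centres sit at ``origin + (index + 0.5) * voxel_pitch``.
    """

    values: np.ndarray
    voxel_pitch: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_pitch = np.broadcast_to(
            np.asarray(self.voxel_pitch, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.broadcast_to(
            np.asarray(self.origin, dtype=np.float64), (3,)
        ).copy()
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.voxel_pitch <= 0):
            raise ValueError("voxel_pitch must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical centre coordinates of the voxels along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_pitch[axis]

    def copy(self) -> "RIVolume":
        return RIVolume(self.values.copy(), self.voxel_pitch.copy(), self.origin.copy())

    def same_grid(self, other: "RIVolume", atol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.voxel_pitch, other.voxel_pitch, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class RodLayerLayout:
    """One layer of parallel rods.

    ``orientation`` is the axis the rods extend along (``"x-aligned"``
    rods run along x and are positioned by their y centre coordinate).
    """

    z_center: float
    orientation: str  # "x-aligned" | "y-aligned"
    rod_positions: np.ndarray  # lateral centre coordinates, µm

    def __post_init__(self) -> None:
        if self.orientation not in ("x-aligned", "y-aligned"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        self.rod_positions = np.asarray(self.rod_positions, dtype=np.float64)


@dataclass
class LineGroup:
    """A resolution line group: parallel bars at one spatial frequency."""

    frequency_lpmm: float
    bar_centers: np.ndarray  # x centre of each bar, µm
    bar_width: float  # µm (= half period)
    y_center: float
    bar_length: float
    z_center: float
    bar_thickness: float

    @property
    def period_um(self) -> float:
        return 1000.0 / self.frequency_lpmm

    @property
    def gap_centers(self) -> np.ndarray:
        c = np.asarray(self.bar_centers)
        return 0.5 * (c[1:] + c[:-1])


@dataclass
class PhantomSpec:
    """Design parameters of the scattering cube.

    Defaults follow the printed design: a 60 × 60 × 40 µm cube of
    0.5 × 1.8 µm rods with edge-to-edge gaps drawn uniformly from
    0.7–3 µm, layers stacked every 1.4 µm with alternating orientation,
    ~25 % polymer fill, and a maximal RI contrast of 0.03 above the
    immersion medium (n = 1.5123, matching the index oil used to mount
    the printed structure).
    """

    cube_size: tuple[float, float, float] = (60.0, 60.0, 40.0)
    rod_width: float = 0.5
    rod_height: float = 1.8
    rod_gap_range: tuple[float, float] = (0.7, 3.0)
    layer_pitch: float = 1.4
    clearance: float = 0.5
    fill_factor_nominal: float = 0.25
    n_background: float = 1.5123
    delta_ri_max: float = 0.03
    ri_accuracy: float = 5e-4  # fabrication metadata, not used numerically
    polymer_ri: float | None = None  # default n_background + delta_ri_max
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.rod_gap_range
        if lo <= 0 or hi < lo:
            raise ValueError("rod_gap_range must satisfy 0 < lo <= hi")
        if self.layer_pitch <= 0 or self.rod_width <= 0 or self.rod_height <= 0:
            raise ValueError("rod dimensions and layer_pitch must be positive")
        if self.delta_ri_max <= 0:
            raise ValueError("delta_ri_max must be positive")
        if self.polymer_ri is not None:
            off = self.polymer_ri - self.n_background
            if not (0.0 <= off <= self.delta_ri_max):
                raise ValueError("polymer RI offset outside [0, delta_ri_max]")
        if any(s <= 0 for s in self.cube_size):
            raise ValueError("cube_size must be positive")

    @property
    def polymer_ri_effective(self) -> float:
        if self.polymer_ri is not None:
            return self.polymer_ri
        return self.n_background + self.delta_ri_max

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellTargetSpec:
    """Parameters of the cell-like imaging target.

    The target is a truncated ellipsoid (flat face on the substrate side)
    carrying a bar resolution test of increasing spatial frequency
    (finest group 1667 lp/mm, i.e. a 0.6 µm period), a nucleus with
    suspended nucleoli, and a region of slow RI variation.  All feature
    geometry is expressed in coordinates relative to the ellipsoid
    centre; RI offsets are relative to the background medium and must
    not exceed the phantom's ``delta_ri_max``.
    """

    ellipsoid_size: tuple[float, float, float] = (30.0, 25.0, 12.0)
    truncation: float = 0.1  # fraction of total height removed at the bottom
    line_group_frequencies: tuple[float, ...] = (417.0, 595.0, 833.0, 1190.0, 1667.0)
    bars_per_group: int = 4
    bar_length: float = 2.0
    bar_thickness: float = 1.0
    line_row_y: float = -4.0
    line_row_z: float = 0.0
    group_margin: float = 0.8
    nucleus_center: tuple[float, float, float] = (0.0, 5.0, 0.0)
    nucleus_semiaxes: tuple[float, float, float] = (5.0, 4.0, 3.0)
    nucleoli_centers: tuple[tuple[float, float, float], ...] = (
        (-2.0, 5.0, -1.0),
        (2.0, 5.0, 1.0),
    )
    nucleoli_radii: tuple[float, ...] = (1.0, 1.0)
    gradient_center: tuple[float, float, float] = (-8.0, 1.0, 0.0)
    gradient_size: tuple[float, float, float] = (6.0, 4.0, 4.0)
    # RI offsets above background, each must lie in (0, delta_ri_max]
    cytoplasm_offset: float = 0.010
    nucleus_offset: float = 0.015
    nucleolus_offset: float = 0.030
    line_offset: float = 0.025
    gradient_max_offset: float = 0.020

    def validate(self, spec: PhantomSpec) -> None:
        freqs = np.asarray(self.line_group_frequencies, dtype=float)
        if len(freqs) == 0 or np.any(np.diff(freqs) <= 0):
            raise ValueError("line_group_frequencies must be strictly increasing")
        offsets = {
            "cytoplasm": self.cytoplasm_offset,
            "nucleus": self.nucleus_offset,
            "nucleolus": self.nucleolus_offset,
            "line": self.line_offset,
            "gradient": self.gradient_max_offset,
        }
        for name, off in offsets.items():
            if not (0.0 < off <= spec.delta_ri_max):
                raise ValueError(
                    f"{name} RI offset {off} outside (0, {spec.delta_ri_max}]"
                )
        if not 0.0 <= self.truncation < 1.0:
            raise ValueError("truncation must be in [0, 1)")
        for i, s in enumerate(self.ellipsoid_size):
            if s > spec.cube_size[i]:
                raise ValueError("ellipsoid does not fit inside the cube")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# rod layers
# ---------------------------------------------------------------------------

def sample_rod_layouts(spec: PhantomSpec, rng_seed: int | None = None) -> list[RodLayerLayout]:
    """Draw the pseudo-random rod layouts of every scattering layer.

    Layers are stacked every ``layer_pitch`` starting at
    ``z = rod_height / 2`` (so no rod protrudes from the cube) and
    alternate orientation.  Within a layer, edge-to-edge gaps between
    neighbouring rods are i.i.d. uniform over ``rod_gap_range``.
    Deterministic for a fixed seed.
    """
    spec.validate()
    if rng_seed is None:
        rng_seed = spec.seed
    rng = np.random.default_rng(rng_seed)
    lx, ly, lz = spec.cube_size
    w, h = spec.rod_width, spec.rod_height
    if lz < h or lz < spec.layer_pitch:
        raise ValueError("degenerate cube: smaller than one rod layer")

    layouts: list[RodLayerLayout] = []
    z = h / 2.0
    k = 0
    while z + h / 2.0 <= lz + 1e-12:
        orientation = "x-aligned" if k % 2 == 0 else "y-aligned"
        extent = ly if orientation == "x-aligned" else lx
        # first rod's left edge randomised over one width so that the cube
        # face cuts rods at a random phase
        positions = []
        edge = rng.uniform(-w, 0.0)
        while edge < extent:
            positions.append(edge + w / 2.0)
            edge += w + rng.uniform(*spec.rod_gap_range)
        layouts.append(RodLayerLayout(z, orientation, np.asarray(positions)))
        z += spec.layer_pitch
        k += 1
    return layouts


def rasterize_scattering_cube(
    layouts: Sequence[RodLayerLayout],
    spec: PhantomSpec,
    voxel_pitch: float | Sequence[float],
    origin: Sequence[float] | None = None,
) -> RIVolume:
    """Voxelize rod layers into an RI volume.

    A voxel is polymer iff its centre lies inside a rod's rectangular
    cross-section (half-open intervals) extruded along the rod axis.
    Polymer voxels take ``spec.polymer_ri_effective``; the rest stay at
    ``n_background``.
    """
    spec.validate()
    pitch = np.broadcast_to(np.asarray(voxel_pitch, dtype=float), (3,)).copy()
    if max(pitch[0], pitch[1]) > spec.rod_width / 2.0 + 1e-12:
        raise ValueError(
            "undersampled geometry: lateral voxel pitch must be <= rod_width/2"
        )
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(np.ceil(s / p - 1e-9)) for s, p in zip(spec.cube_size, pitch))
    occupancy = np.zeros(shape, dtype=bool)
    coords = [origin[a] + (np.arange(shape[a]) + 0.5) * pitch[a] for a in range(3)]

    w, h = spec.rod_width, spec.rod_height
    for layer in layouts:
        z_sel = (coords[2] >= layer.z_center - h / 2.0) & (
            coords[2] < layer.z_center + h / 2.0
        )
        if not np.any(z_sel):
            continue
        across_axis = 1 if layer.orientation == "x-aligned" else 0
        c = coords[across_axis]
        lateral = np.zeros(len(c), dtype=bool)
        for pos in layer.rod_positions:
            lateral |= (c >= pos - w / 2.0) & (c < pos + w / 2.0)
        if layer.orientation == "x-aligned":
            occupancy[np.ix_(np.ones(shape[0], bool), lateral, z_sel)] = True
        else:
            occupancy[np.ix_(lateral, np.ones(shape[1], bool), z_sel)] = True

    values = np.full(shape, spec.n_background, dtype=np.float64)
    values[occupancy] = spec.polymer_ri_effective
    return RIVolume(values, pitch, origin)


# ---------------------------------------------------------------------------
# cell target
# ---------------------------------------------------------------------------

def line_group_layouts(cspec: CellTargetSpec, spec: PhantomSpec) -> list[LineGroup]:
    """Deterministic placement of the resolution line groups.

    Groups are laid out coarse-to-fine along +x, centred as a row at
    ``(line_row_y, line_row_z)`` relative to the ellipsoid centre; the
    bars extend along y.  Bar width equals half the group period and the
    gaps between bars equal the bar width.
    """
    cspec.validate(spec)
    cube_center = np.asarray(spec.cube_size) / 2.0
    widths = []
    for f in cspec.line_group_frequencies:
        bw = 0.5 * 1000.0 / f
        widths.append((2 * cspec.bars_per_group - 1) * bw)
    total = sum(widths) + cspec.group_margin * (len(widths) - 1)
    x_left = -total / 2.0
    groups: list[LineGroup] = []
    for f, gw in zip(cspec.line_group_frequencies, widths):
        bw = 0.5 * 1000.0 / f
        centers = x_left + bw / 2.0 + np.arange(cspec.bars_per_group) * 2.0 * bw
        groups.append(
            LineGroup(
                frequency_lpmm=f,
                bar_centers=centers + cube_center[0],
                bar_width=bw,
                y_center=cspec.line_row_y + cube_center[1],
                bar_length=cspec.bar_length,
                z_center=cspec.line_row_z + cube_center[2],
                bar_thickness=cspec.bar_thickness,
            )
        )
        x_left += gw + cspec.group_margin
    return groups


def build_cell_target(
    cspec: CellTargetSpec,
    spec: PhantomSpec,
    voxel_pitch: float | Sequence[float],
    shape: tuple[int, int, int] | None = None,
    origin: Sequence[float] | None = None,
) -> RIVolume:
    """Rasterize the cell-like target, centred in the phantom cube.

    Returns absolute RI: ``n_background`` outside the (truncated)
    ellipsoid, background + feature offsets inside.  Feature precedence
    where regions overlap: nucleoli > nucleus > line bars > gradient >
    cytoplasm.
    """
    cspec.validate(spec)
    pitch = np.broadcast_to(np.asarray(voxel_pitch, dtype=float), (3,)).copy()
    if shape is None:
        shape = tuple(
            int(np.ceil(s / p - 1e-9)) for s, p in zip(spec.cube_size, pitch)
        )
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, dtype=float)
    cube_center = np.asarray(spec.cube_size) / 2.0

    # voxel-centre coordinates relative to the ellipsoid centre
    x = origin[0] + (np.arange(shape[0]) + 0.5) * pitch[0] - cube_center[0]
    y = origin[1] + (np.arange(shape[1]) + 0.5) * pitch[1] - cube_center[1]
    z = origin[2] + (np.arange(shape[2]) + 0.5) * pitch[2] - cube_center[2]
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    a, b, c = (s / 2.0 for s in cspec.ellipsoid_size)
    body = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    z_cut = -c + cspec.truncation * 2.0 * c  # flat face on the substrate side
    body &= Z >= z_cut

    offsets = np.zeros(shape, dtype=np.float64)
    offsets[body] = cspec.cytoplasm_offset

    # slow RI gradient: linear ramp along x inside a box
    gc = np.asarray(cspec.gradient_center)
    gs = np.asarray(cspec.gradient_size) / 2.0
    in_box = (
        (np.abs(X - gc[0]) <= gs[0])
        & (np.abs(Y - gc[1]) <= gs[1])
        & (np.abs(Z - gc[2]) <= gs[2])
        & body
    )
    ramp = (X - (gc[0] - gs[0])) / (2.0 * gs[0])
    ramp = np.clip(ramp, 0.0, 1.0) * cspec.gradient_max_offset
    offsets[in_box] = np.broadcast_to(ramp, shape)[in_box]

    # resolution line groups
    for grp in line_group_layouts(cspec, spec):
        gy = grp.y_center - cube_center[1]
        gz = grp.z_center - cube_center[2]
        in_row = (
            (np.abs(Y - gy) <= grp.bar_length / 2.0)
            & (np.abs(Z - gz) <= grp.bar_thickness / 2.0)
            & body
        )
        bar_x = np.zeros(shape[0], dtype=bool)
        for bc in grp.bar_centers - cube_center[0]:
            bar_x |= (x >= bc - grp.bar_width / 2.0) & (x < bc + grp.bar_width / 2.0)
        offsets[in_row & bar_x[:, None, None]] = cspec.line_offset

    # nucleus
    nc = np.asarray(cspec.nucleus_center)
    na_, nb, ncz = cspec.nucleus_semiaxes
    nucleus = (
        ((X - nc[0]) / na_) ** 2 + ((Y - nc[1]) / nb) ** 2 + ((Z - nc[2]) / ncz) ** 2
        <= 1.0
    ) & body
    offsets[nucleus] = cspec.nucleus_offset

    # nucleoli
    for center, r in zip(cspec.nucleoli_centers, cspec.nucleoli_radii):
        cc = np.asarray(center)
        sph = ((X - cc[0]) ** 2 + (Y - cc[1]) ** 2 + (Z - cc[2]) ** 2 <= r**2) & body
        offsets[sph] = cspec.nucleolus_offset

    if offsets.max(initial=0.0) > spec.delta_ri_max + 1e-12:
        raise ValueError("a cell-target feature exceeds delta_ri_max")
    return RIVolume(spec.n_background + offsets, pitch, origin)


# ---------------------------------------------------------------------------
# composition and metrics
# ---------------------------------------------------------------------------

def compose_phantom(
    cube: RIVolume,
    cell: RIVolume,
    clearance: float,
    n_background: float | None = None,
) -> RIVolume:
    """Embed the cell target in the scattering cube.

    Rod voxels are suppressed wherever they come within ``clearance``
    (Euclidean, µm) of any cell-target voxel; cell RI overwrites rods
    inside the target.
    """
    if not cube.same_grid(cell):
        raise ValueError("grid mismatch between scattering cube and cell target")
    if n_background is None:
        n_background = min(cube.values.min(), cell.values.min())
    cell_mask = cell.values > n_background + 1e-12
    rod_mask = cube.values > n_background + 1e-12

    out = np.full_like(cube.values, n_background)
    if np.any(cell_mask) and clearance > 0:
        dist = ndimage.distance_transform_edt(
            ~cell_mask, sampling=tuple(cube.voxel_pitch)
        )
        keep = rod_mask & (dist >= clearance)
    else:
        keep = rod_mask
    out[keep] = cube.values[keep]
    out[cell_mask] = cell.values[cell_mask]
    return RIVolume(out, cube.voxel_pitch.copy(), cube.origin.copy())


def compute_fill_factor(
    volume: RIVolume,
    region: Sequence[Sequence[float]] | None = None,
    n_background: float | None = None,
    exclude: np.ndarray | None = None,
) -> float:
    """Fraction of voxels above background RI within ``region``.

    ``region`` is ``((x0, x1), (y0, y1), (z0, z1))`` in µm (half-open on
    voxel centres); ``None`` means the whole volume.  ``exclude`` is an
    optional boolean mask of voxels to leave out of the count (e.g. the
    cell-target region when measuring the scattering cube's nominal
    fill).
    """
    if n_background is None:
        n_background = float(volume.values.min())
    sel = np.ones(volume.shape, dtype=bool)
    if region is not None:
        for a, (lo, hi) in enumerate(region):
            c = volume.axis_coords(a)
            keep1d = (c >= lo) & (c < hi)
            sl = [None, None, None]
            sl[a] = slice(None)
            sel &= keep1d[tuple(sl)]
    if exclude is not None:
        sel &= ~exclude
    n_tot = int(sel.sum())
    if n_tot == 0:
        raise ValueError("empty region")
    n_poly = int(np.count_nonzero(volume.values[sel] > n_background + 1e-12))
    return n_poly / n_tot


def generate_phantom(
    spec: PhantomSpec,
    cspec: CellTargetSpec | None = None,
    voxel_pitch: float | Sequence[float] = 0.1,
    seed: int | None = None,
) -> RIVolume:
    """Full phantom: scattering cube with the cell target composed in."""
    layouts = sample_rod_layouts(spec, spec.seed if seed is None else seed)
    cube = rasterize_scattering_cube(layouts, spec, voxel_pitch)
    if cspec is None:
        return cube
    cell = build_cell_target(cspec, spec, voxel_pitch)
    return compose_phantom(cube, cell, spec.clearance, spec.n_background)


def pad_volume(
    volume: RIVolume, shape: tuple[int, int, int], fill: float
) -> RIVolume:
    """Embed a volume centred in a larger grid filled with ``fill``.

    Used to surround the phantom cube with immersion medium so the
    simulated field of view extends beyond the object.
    """
    out = np.full(shape, fill, dtype=np.float64)
    off = []
    for a in range(3):
        if shape[a] < volume.shape[a]:
            raise ValueError("target shape smaller than volume")
        off.append((shape[a] - volume.shape[a]) // 2)
    out[
        off[0] : off[0] + volume.shape[0],
        off[1] : off[1] + volume.shape[1],
        off[2] : off[2] + volume.shape[2],
    ] = volume.values
    origin = volume.origin - np.asarray(off) * volume.voxel_pitch
    return RIVolume(out, volume.voxel_pitch.copy(), origin)


def beer_lambert_transmittance(extinction_per_mm: float, thickness_um: float) -> float:
    """Ballistic transmittance exp(-µ d) through a slab of thickness d."""
    return float(np.exp(-extinction_per_mm * thickness_um * 1e-3))


def scaled_spec(spec: PhantomSpec, cube_size: tuple[float, float, float]) -> PhantomSpec:
    """A reduced-size variant of a phantom spec for desk-scale work.

    The cube shrinks but rod cross-section, gaps and layer pitch are kept
    so the scattering micro-structure stays resolvable at the same voxel
    pitch (fewer rods and layers, identical local statistics).
    """
    return replace(spec, cube_size=cube_size)
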