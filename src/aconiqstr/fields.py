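"""Molecular-field descriptors on a rectangular lattice.

Two descriptor families are computed for a set of pre-aligned molecules:

* CoMFA-style interaction energies — a Lennard-Jones 6-12 steric term and a
  Coulomb electrostatic term between every lattice point and a probe atom
  (sp3 carbon, +1 e by default), truncated at an energy cap.
* CoMSIA-style similarity indices — Gaussian-attenuated sums of per-atom
  property weights (steric, electrostatic, hydrophobic, donor, acceptor),
  which decay smoothly and need no cap.

Columns that barely vary across the molecule set carry no regression signal
and are removed by a minimum-standard-deviation column filter before PLS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molecules import AlignedMolecule
from .params import COULOMB_CONSTANT, PROBE_CHARGE, PROBE_EPSILON, PROBE_RADIUS

COMFA_FIELDS = ("steric", "electrostatic")
COMSIA_FIELDS = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")

DEFAULT_SPACING = 2.0
DEFAULT_MARGIN = 4.0
DEFAULT_CAP = 30.0
DEFAULT_ALPHA = 0.3
DEFAULT_FILTER = 2.0


@dataclass(frozen=True)
class ProbeSpec:
    radius: float = PROBE_RADIUS
    epsilon: float = PROBE_EPSILON
    charge: float = PROBE_CHARGE


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectangular lattice: origin, isotropic spacing, counts."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 points per axis")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All lattice points, x-major (index = ix*ny*nz + iy*nz + iz)."""
        nx, ny, nz = self.dims
        idx = np.array(list(itertools.product(range(nx), range(ny), range(nz))))
        return self.origin + idx * self.spacing

    def translated(self, vector) -> "GridSpec":
        return GridSpec(self.origin + np.asarray(vector, dtype=float), self.spacing, self.dims)


@dataclass
class FieldBlock:
    """Molecules x descriptor-columns matrix with per-column provenance.

    ``column_meta`` holds one (grid_index, field_name) pair per retained
    column; ``dropped_columns`` records the metadata of columns removed by
    filtration so the lattice layout stays reconstructible.
    """

    matrix: np.ndarray
    column_meta: list[tuple[int, str]]
    molecule_ids: list[str]
    grid: GridSpec | None = None
    dropped_columns: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.column_meta):
            raise ValueError("column_meta length must equal column count")
        if self.matrix.shape[0] != len(self.molecule_ids):
            raise ValueError("one row per molecule required")
        overlap = set(self.column_meta) & set(self.dropped_columns)
        if overlap:
            raise ValueError(f"columns both present and dropped: {sorted(overlap)[:3]}")

    @property
    def field_names(self) -> list[str]:
        seen: list[str] = []
        for _, name in self.column_meta:
            if name not in seen:
                seen.append(name)
        return seen

    def columns_for(self, field_name: str) -> np.ndarray:
        idx = [j for j, (_, name) in enumerate(self.column_meta) if name == field_name]
        if not idx:
            raise KeyError(f"unknown field {field_name!r}")
        return np.asarray(idx)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{name}@{gi}" for gi, name in self.column_meta]
        return pd.DataFrame(self.matrix, index=self.molecule_ids, columns=cols)

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "id"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FieldBlock":
        frame = pd.read_csv(path, index_col=0)
        meta = []
        for col in frame.columns:
            name, _, gi = col.rpartition("@")
            meta.append((int(gi), name))
        return cls(frame.to_numpy(float), meta, [str(i) for i in frame.index])


def build_grid(molecules: list[AlignedMolecule], spacing: float = DEFAULT_SPACING,
               margin: float = DEFAULT_MARGIN) -> GridSpec:
    """Bounding box of all atoms, expanded by ``margin`` per side, discretized
    at ``spacing``; each axis keeps at least two lattice planes."""
    if not molecules:
        raise ValueError("need at least one molecule to build a grid")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = np.maximum(np.floor((hi - lo) / spacing + 1e-9).astype(int) + 1, 2)
    return GridSpec(lo, spacing, tuple(dims))


def comfa_fields(molecule: AlignedMolecule, grid: GridSpec,
                 probe: ProbeSpec = ProbeSpec(), cap: float = DEFAULT_CAP
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Steric (LJ 6-12) and electrostatic (Coulomb, unit-positive probe)
    probe energies at every lattice point, truncated to [-cap, +cap].

    Electrostatic values at sterically excluded points (steric at +cap) are
    returned as NaN; :func:`comfa_block` replaces them by the column mean
    over the non-excluded molecules, the classical treatment that keeps the
    electrostatic column well-defined inside molecular volume.
    """
    pts = grid.points()
    diff = pts[:, None, :] - molecule.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    r = np.maximum(r, 1e-12)

    r_min = molecule.vdw_radius + probe.radius  # Lorentz-style arithmetic mixing
    eps = np.sqrt(molecule.vdw_epsilon * probe.epsilon)
    ratio6 = (r_min[None, :] / r) ** 6
    steric = (eps[None, :] * (ratio6**2 - 2.0 * ratio6)).sum(axis=1)
    steric = np.clip(steric, -cap, cap)

    elec = (COULOMB_CONSTANT * probe.charge * molecule.charges[None, :] / r).sum(axis=1)
    elec = np.clip(elec, -cap, cap)
    elec[steric >= cap] = np.nan
    return steric, elec


def comsia_fields(molecule: AlignedMolecule, grid: GridSpec,
                  alpha: float = DEFAULT_ALPHA) -> dict[str, np.ndarray]:
    """Gaussian similarity indices A(j) = -sum_i w_probe * w_i exp(-alpha r^2)
    for the five property fields; probe weights are unity."""
    weights = {
        "steric": molecule.vdw_radius**3,
        "electrostatic": molecule.charges,
        "hydrophobic": None,
        "donor": None,
        "acceptor": None,
    }
    for prop in ("hydrophobic", "donor", "acceptor"):
        if prop not in molecule.props:
            raise ValueError(f"{molecule.id}: missing CoMSIA property table {prop!r}")
        weights[prop] = np.asarray(molecule.props[prop], dtype=float)

    pts = grid.points()
    diff = pts[:, None, :] - molecule.coords[None, :, :]
    gauss = np.exp(-alpha * (diff**2).sum(axis=2))
    return {name: -(gauss * w[None, :]).sum(axis=1) for name, w in weights.items()}


def comfa_block(molecules: list[AlignedMolecule], grid: GridSpec,
                probe: ProbeSpec = ProbeSpec(), cap: float = DEFAULT_CAP) -> FieldBlock:
    sterics, elecs = [], []
    for mol in molecules:
        s, e = comfa_fields(mol, grid, probe, cap)
        sterics.append(s)
        elecs.append(e)
    steric = np.vstack(sterics)
    elec = np.vstack(elecs)
    # mean-of-molecules placeholder at sterically excluded points
    excluded = np.isnan(elec)
    n_ok = (~excluded).sum(axis=0)
    col_sum = np.where(excluded, 0.0, elec).sum(axis=0)
    col_mean = np.divide(col_sum, n_ok, out=np.zeros_like(col_sum), where=n_ok > 0)
    elec = np.where(np.isnan(elec), col_mean[None, :], elec)

    matrix = np.hstack([steric, elec])
    meta = [(j, "steric") for j in range(grid.n_points)]
    meta += [(j, "electrostatic") for j in range(grid.n_points)]
    return FieldBlock(matrix, meta, [m.id for m in molecules], grid=grid)


def comsia_block(molecules: list[AlignedMolecule], grid: GridSpec,
                 alpha: float = DEFAULT_ALPHA) -> FieldBlock:
    per_field = {name: [] for name in COMSIA_FIELDS}
    for mol in molecules:
        vals = comsia_fields(mol, grid, alpha)
        for name in COMSIA_FIELDS:
            per_field[name].append(vals[name])
    blocks, meta = [], []
    for name in COMSIA_FIELDS:
        blocks.append(np.vstack(per_field[name]))
        meta += [(j, name) for j in range(grid.n_points)]
    return FieldBlock(np.hstack(blocks), meta, [m.id for m in molecules], grid=grid)


def column_filter(block: FieldBlock, threshold: float = DEFAULT_FILTER) -> FieldBlock:
    """Drop columns whose standard deviation across molecules falls below
    ``threshold`` (energy units for CoMFA fields). Column order is preserved."""
    sd = block.matrix.std(axis=0, ddof=0)
    keep = sd >= threshold if threshold > 0 else np.ones(len(sd), dtype=bool)
    if not keep.any():
        raise ValueError(
            f"column filter at {threshold} would drop every column; lower the threshold"
        )
    dropped = [m for m, k in zip(block.column_meta, keep) if not k]
    kept_meta = [m for m, k in zip(block.column_meta, keep) if k]
    return FieldBlock(
        block.matrix[:, keep], kept_meta, list(block.molecule_ids),
        grid=block.grid, dropped_columns=list(block.dropped_columns) + dropped,
    )


BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


def write_cube(path, grid: GridSpec, values: np.ndarray, comment: str = "field grid") -> None:
    """Write one scalar field as a Gaussian cube file (no atoms block)."""
    values = np.asarray(values, dtype=float)
    if values.size != grid.n_points:
        raise ValueError("value count does not match grid")
    nx, ny, nz = grid.dims
    o = grid.origin * BOHR_PER_ANGSTROM
    step = grid.spacing * BOHR_PER_ANGSTROM
    lines = [comment, "generated by aconiqstr",
             f"{0:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}",
             f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}",
             f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}",
             f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}"]
    flat = values.reshape(nx, ny, nz)
    for ix in range(nx):
        for iy in range(ny):
            row = flat[ix, iy]
            for start in range(0, nz, 6):
                lines.append("".join(f"{v:13.5E}" for v in row[start:start + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
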