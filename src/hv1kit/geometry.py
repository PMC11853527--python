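"""Trajectory geometry statistics: superposition RMSD/RMSF, salt-bridge
occupancy with strong/weak classification, axial shifts relative to the
hydrophobic-gasket plane, and water-number profiles along the pore axis.

The hydrophobic gasket (VAL109, PHE150, VAL178, VAL179) defines the z = 0
reference plane; the membrane normal is assumed to be the z axis of the
input coordinates, the convention of membrane-builder outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "StructureEnsemble",
    "SaltBridgeOccupancy",
    "SaltBridgeTable",
    "AxialProfile",
    "superpose",
    "rmsd_series",
    "rmsf",
    "salt_bridge_occupancy",
    "build_salt_bridge_table",
    "parse_salt_bridge_table",
    "hg_reference",
    "axial_shift",
    "water_axial_profile",
    "dewetted_width",
]

#: Hydrophobic-gasket residues defining the z = 0 plane.
GASKET_RESIDS = (109, 150, 178, 179)

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP"}

#: Side-chain nitrogen donors of basic residues and carboxylate-oxygen
#: acceptors of acidic residues.  His counts both ring nitrogens regardless
#: of protonation state.
BASIC_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

SIDECHAIN_TIP = {"ARG": "CZ", "LYS": "NZ"}

STRONG_GLYPH, WEAK_GLYPH = "✓", "∨"  # ✓ and ∨


@dataclass
class StructureEnsemble:
    """Coordinate frames with constant topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``names``,
    ``resnames`` and ``resids`` are per-atom and identical across frames.
    """

    names: list[str]
    resnames: list[str]
    resids: list[int]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        n = self.coords.shape[1]
        if not (len(self.names) == len(self.resnames) == len(self.resids) == n):
            raise ValueError("atom annotation lengths do not match coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self._names = np.asarray(self.names)
        self._resnames = np.asarray(self.resnames)
        self._resids = np.asarray(self.resids)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, resids: Iterable[int] | None = None,
               resnames: Iterable[str] | None = None,
               names: Iterable[str] | None = None) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resids is not None:
            mask &= np.isin(self._resids, list(resids))
        if resnames is not None:
            mask &= np.isin(self._resnames, list(resnames))
        if names is not None:
            mask &= np.isin(self._names, list(names))
        return np.nonzero(mask)[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass
class SaltBridgeOccupancy:
    pair: tuple[str, str]     # (basic residue id, acidic residue id), e.g. ("R205", "D112")
    occupancy: float
    klass: str                # strong | weak | none


@dataclass
class SaltBridgeTable:
    """Pair-by-column interaction matrix with per-column (strong, weak) sums."""

    pairs: list[str]
    columns: list[tuple[str, str]]            # (channel, configuration)
    cells: dict[tuple[str, tuple[str, str]], str]  # -> strong|weak|none
    printed_sums: dict[tuple[str, str], tuple[int, int]] | None = None

    def recompute_sums(self) -> dict[tuple[str, str], tuple[int, int]]:
        sums = {}
        for col in self.columns:
            strong = sum(1 for p in self.pairs if self.cells.get((p, col)) == "strong")
            weak = sum(1 for p in self.pairs if self.cells.get((p, col)) == "weak")
            sums[col] = (strong, weak)
        return sums


@dataclass
class AxialProfile:
    """Mean water count per axial bin, z relative to the gasket plane."""

    z_bins: np.ndarray        # bin centers, A
    values: np.ndarray        # mean count per frame
    bin_width: float
    radius: float
    no_waters: bool = False


# ---------------------------------------------------------------- superposition

def _kabsch(mobile: np.ndarray, reference: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation (SVD form) of mobile onto reference."""
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - mc, reference - rc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mc, rc


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None
              ) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body superposition of one frame onto another.

    The fit uses ``selection`` (all atoms by default); the returned frame is
    the fully transformed mobile and the RMSD is the minimized value over
    the selection.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have matching shapes")
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    R, mc, rc = _kabsch(mobile[sel], reference[sel])
    transformed = (mobile - mc) @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[sel] - reference[sel]) ** 2,
                                        axis=1))))
    return transformed, rmsd


def rmsd_series(ensemble: StructureEnsemble, reference: np.ndarray,
                selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame minimized RMSD against a reference frame."""
    return np.array([superpose(ensemble.frame(i), reference, selection)[1]
                     for i in range(ensemble.n_frames)])


def rmsf(ensemble: StructureEnsemble, selection: np.ndarray | None = None
         ) -> pd.Series:
    """Per-residue root-mean-square fluctuation about the ensemble mean.

    Frames are iteratively superposed onto the mean structure of the
    selection; RMSF_i = sqrt(<|r_i - <r_i>|^2>) averaged over the atoms of
    each residue.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = (np.arange(ensemble.n_atoms) if selection is None
           else np.asarray(selection))
    frames = ensemble.coords.copy()
    mean = frames.mean(axis=0)
    for _ in range(3):
        frames = np.array([superpose(f, mean, sel)[0] for f in frames])
        new_mean = frames.mean(axis=0)
        if np.allclose(new_mean, mean, atol=1e-10):
            break
        mean = new_mean
    dev2 = np.sum((frames - mean) ** 2, axis=2).mean(axis=0)  # per atom
    resids = ensemble._resids[sel]
    per_atom = pd.Series(dev2[sel], index=resids)
    return per_atom.groupby(level=0).mean().pow(0.5)


# ---------------------------------------------------------------- salt bridges

def _residue_atoms(ens: StructureEnsemble, resid: int,
                   atom_map: dict[str, tuple[str, ...]]) -> np.ndarray:
    idx = ens.select(resids=[resid])
    if idx.size == 0:
        return idx
    resname = ens._resnames[idx[0]]
    wanted = atom_map.get(resname)
    if wanted is None:
        return np.array([], dtype=int)
    return idx[np.isin(ens._names[idx], wanted)]


def _default_pairs(ens: StructureEnsemble) -> list[tuple[int, int]]:
    basic = sorted({int(r) for r, n in zip(ens._resids, ens._resnames)
                    if n in BASIC_ATOMS})
    acidic = sorted({int(r) for r, n in zip(ens._resids, ens._resnames)
                     if n in ACIDIC_ATOMS})
    return [(b, a) for b in basic for a in acidic]


def _pair_label(ens: StructureEnsemble, resid: int) -> str:
    idx = ens.select(resids=[resid])
    one = {"ARG": "R", "LYS": "K", "HIS": "H", "ASP": "D", "GLU": "E"}.get(
        str(ens._resnames[idx[0]]), "X")
    return f"{one}{resid}"


def salt_bridge_occupancy(ensemble: StructureEnsemble,
                          pairs: Sequence[tuple[int, int]] | None = None,
                          d_on: float = 4.0, s_hi: float = 0.65,
                          s_lo: float = 0.25) -> list[SaltBridgeOccupancy]:
    """Salt-bridge occupancies over the trajectory.

    A frame is "in contact" when the minimum distance between any basic
    side-chain nitrogen and any acidic carboxylate oxygen is at most
    ``d_on``.  Occupancy >= ``s_hi`` classifies as strong, >= ``s_lo`` as
    weak, below as none.  Pairs with missing side-chain atoms are skipped
    with a log record.
    """
    if pairs is None:
        pairs = _default_pairs(ensemble)
    out = []
    for b_resid, a_resid in pairs:
        b_idx = _residue_atoms(ensemble, b_resid, BASIC_ATOMS)
        a_idx = _residue_atoms(ensemble, a_resid, ACIDIC_ATOMS)
        if b_idx.size == 0 or a_idx.size == 0:
            log.warning("pair (%s, %s) skipped: missing side-chain atoms",
                        b_resid, a_resid)
            continue
        bc = ensemble.coords[:, b_idx]        # (F, nb, 3)
        ac = ensemble.coords[:, a_idx]        # (F, na, 3)
        d = np.linalg.norm(bc[:, :, None] - ac[:, None, :], axis=-1)
        dmin = d.reshape(ensemble.n_frames, -1).min(axis=1)
        occ = float(np.mean(dmin <= d_on))
        klass = "strong" if occ >= s_hi else ("weak" if occ >= s_lo else "none")
        out.append(SaltBridgeOccupancy(
            pair=(_pair_label(ensemble, b_resid), _pair_label(ensemble, a_resid)),
            occupancy=occ, klass=klass))
    return out


def build_salt_bridge_table(
        occupancies: dict[tuple[str, str], list[SaltBridgeOccupancy]]
        ) -> SaltBridgeTable:
    """Assemble the pair-by-(channel, configuration) classification matrix
    from per-channel occupancy lists."""
    columns = list(occupancies)
    pairs: list[str] = []
    cells: dict[tuple[str, tuple[str, str]], str] = {}
    for col, occs in occupancies.items():
        for o in occs:
            name = f"{o.pair[0]}-{o.pair[1]}"
            if name not in pairs:
                pairs.append(name)
            cells[(name, col)] = o.klass
    for p in pairs:
        for col in columns:
            cells.setdefault((p, col), "none")
    return SaltBridgeTable(pairs=pairs, columns=columns, cells=cells)


def parse_salt_bridge_table(path) -> SaltBridgeTable:
    """Read a glyph-matrix TSV (✓ strong, ∨ weak, blank none).

    Layout: row 1 channel names over paired d/a columns, row 2 the d/a
    configuration labels, then one row per interaction pair, and optionally
    a final ``Sum`` row of the printed per-column sums (``7✓5∨`` style),
    which is parsed into ``printed_sums`` for cross-checking.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str).fillna("")
    channels = [c for c in df.iloc[0, 1:] if c]
    configs = list(df.iloc[1, 1:])
    columns: list[tuple[str, str]] = []
    chan = None
    ci = -1
    for cfg in configs:
        if cfg == "d":
            ci += 1
        columns.append((channels[ci], cfg))
    pairs = []
    cells = {}
    printed = None
    glyph_map = {STRONG_GLYPH: "strong", WEAK_GLYPH: "weak", "": "none"}
    for _, row in df.iloc[2:].iterrows():
        name = row.iloc[0]
        if name == "Sum":
            printed = {}
            for col, cell in zip(columns, row.iloc[1:]):
                s, rest = cell.split(STRONG_GLYPH)
                w = rest.rstrip(WEAK_GLYPH)
                printed[col] = (int(s), int(w))
            continue
        pairs.append(name)
        for col, cell in zip(columns, row.iloc[1:]):
            cell = cell.strip()
            if cell not in glyph_map:
                raise ValueError(f"unknown cell glyph {cell!r} in pair {name}")
            cells[(name, col)] = glyph_map[cell]
    return SaltBridgeTable(pairs=pairs, columns=columns, cells=cells,
                           printed_sums=printed)


# ---------------------------------------------------------------- axial geometry

def hg_reference(ensemble: StructureEnsemble, frame: int | None = None
                 ) -> tuple[float, tuple[float, float]]:
    """Gasket reference: z0 and (x, y) axis from the four gasket C-alphas.

    Averaged over all frames unless ``frame`` selects one.
    """
    idx = ensemble.select(resids=GASKET_RESIDS, names=["CA"])
    found = set(ensemble._resids[idx])
    missing = set(GASKET_RESIDS) - found
    if missing:
        raise ValueError(f"gasket residues missing: {sorted(missing)}")
    coords = ensemble.coords[:, idx] if frame is None else ensemble.coords[[frame]][:, idx]
    mean = coords.mean(axis=(0, 1))
    return float(mean[2]), (float(mean[0]), float(mean[1]))


def _selection_z(ens: StructureEnsemble, resids: Sequence[int],
                 atom_mode: str) -> float:
    """Mean z (over frames and atoms) of a residue selection, gasket-relative."""
    z0, _ = hg_reference(ens)
    if atom_mode == "CA":
        idx = ens.select(resids=resids, names=["CA"])
    elif atom_mode == "sidechain_tip":
        idx_list = []
        for r in resids:
            ridx = ens.select(resids=[r])
            if ridx.size == 0:
                continue
            tip = SIDECHAIN_TIP.get(str(ens._resnames[ridx[0]]), "CA")
            idx_list.extend(ens.select(resids=[r], names=[tip]))
        idx = np.asarray(idx_list, dtype=int)
    else:
        raise ValueError("atom_mode must be 'CA' or 'sidechain_tip'")
    if idx.size == 0:
        raise ValueError(f"selection {list(resids)} absent from ensemble")
    return float(ens.coords[:, idx, 2].mean()) - z0


def axial_shift(ensemble_a: StructureEnsemble, ensemble_b: StructureEnsemble,
                resids: Sequence[int], atom_mode: str = "CA") -> float:
    """Axial displacement (A) of a residue or helix range between two
    ensembles, measured relative to each ensemble's own gasket plane.

    Positive values mean the selection sits higher (more extracellular) in
    ``ensemble_b``; helix ranges average over the C-alphas of the range.
    """
    return (_selection_z(ensemble_b, resids, atom_mode)
            - _selection_z(ensemble_a, resids, atom_mode))


def water_axial_profile(ensemble: StructureEnsemble, radius: float = 8.0,
                        bin_width: float = 0.5,
                        z_range: tuple[float, float] = (-12.0, 12.0)
                        ) -> AxialProfile:
    """Mean number of water oxygens per axial bin within a cylinder about
    the pore axis, z relative to the gasket plane."""
    z0, (x0, y0) = hg_reference(ensemble)
    widx = ensemble.select(resnames=sorted(WATER_RESNAMES))
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if widx.size == 0:
        return AxialProfile(z_bins=centers, values=np.zeros(centers.size),
                            bin_width=bin_width, radius=radius, no_waters=True)
    w = ensemble.coords[:, widx]  # (F, n, 3)
    r_xy = np.hypot(w[..., 0] - x0, w[..., 1] - y0)
    z = w[..., 2] - z0
    counts = np.zeros(centers.size)
    for f in range(ensemble.n_frames):
        inside = r_xy[f] <= radius
        counts += np.histogram(z[f][inside], bins=edges)[0]
    return AxialProfile(z_bins=centers, values=counts / ensemble.n_frames,
                        bin_width=bin_width, radius=radius)


def dewetted_width(profile: AxialProfile, level: float = 1.0) -> float:
    """Axial extent of the contiguous region around the profile's lowest
    minimum where the mean water number falls below ``level``; endpoints by
    linear interpolation at the level crossings.

    Returns 0 when the profile never dips below the level; the full z range
    when it never rises above it (flagged by a log record).
    """
    z, v = profile.z_bins, profile.values
    if profile.no_waters or np.all(v < level):
        log.warning("profile never reaches the level: dewetted width is the "
                    "full range")
        return float(z[-1] - z[0])
    below = v < level
    if not below.any():
        return 0.0
    imin = int(np.argmin(v))
    if not below[imin]:
        imin = int(np.nonzero(below)[0][np.argmin(v[below])])
    lo = hi = imin
    while lo > 0 and below[lo - 1]:
        lo -= 1
    while hi < v.size - 1 and below[hi + 1]:
        hi += 1
    if lo == 0:
        z_lo = z[0]
    else:
        z_lo = z[lo] - profile.bin_width * (level - v[lo]) / (v[lo - 1] - v[lo])
    if hi == v.size - 1:
        z_hi = z[-1]
    else:
        z_hi = z[hi] + profile.bin_width * (level - v[hi]) / (v[hi + 1] - v[hi])
    return float(z_hi - z_lo)
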