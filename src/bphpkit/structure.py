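"""Rigid-body comparison of Pr and Pfr coordinate models.

The photoconversion cascade of a phytochrome is quantified here with a
small set of geometric descriptors computed between two atomic models of
the same protein in different photostates:

* **domain rotation** — align both states on a reference domain (the
  GAF frame), then measure the residual rigid-body rotation of a second
  domain (e.g. the ~35 deg PHY-domain rotation on Pr -> Pfr).
* **ring flip** — angle between oriented least-squares planes of the
  chromophore D pyrrole ring in the two states (~161 deg on Pr -> Pfr).
* **pair distance** — Euclidean distance between two named atoms (e.g.
  Calpha Gly177-Ile483: 15.5 A as Pr vs 9.5 A as Pfr).
* **helix scissoring** — acute angle between the principal axes of the
  paired signalling helices within one state.

Superpositions use the Kabsch algorithm (SVD with determinant correction,
so reflections are never returned).  Residue numbering follows the
deposition (author numbering); ranges are inclusive and never renumbered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "Selection",
    "SuperpositionResult",
    "read_structure",
    "superpose",
    "rotation_angle",
    "domain_rotation",
    "plane_flip_angle",
    "pair_distance",
    "helix_scissor_angle",
]

_ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "element",
                 "x", "y", "z", "occupancy", "altloc", "hetero"]


@dataclass
class StructureModel:
    """Atom records of one coordinate model.

    ``atoms`` is a DataFrame with columns chain, resnum (author
    numbering), resname, atom, element, x/y/z (A), occupancy, altloc,
    hetero.  (chain, resnum, atom, altloc) must be unique.
    """

    id: str
    atoms: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(_ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        key = self.atoms[["chain", "resnum", "atom", "altloc"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chain, resnum, atom, altloc) records")

    @property
    def chains(self) -> set:
        return set(self.atoms["chain"].unique())

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, df: Optional[pd.DataFrame] = None) -> np.ndarray:
        d = self.atoms if df is None else df
        return d[["x", "y", "z"]].to_numpy(dtype=float)

    def atom(self, chain: str, resnum: int, name: str) -> np.ndarray:
        """Coordinates of one atom; raises naming the missing spec."""
        d = self.atoms
        hit = d[(d["chain"] == chain) & (d["resnum"] == resnum) & (d["atom"] == name)]
        if hit.empty:
            raise KeyError(f"atom {chain}/{resnum}/{name} not found in {self.id}")
        return hit[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with every coordinate mapped through x -> R x + t."""
        out = self.atoms.copy()
        xyz = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        out[["x", "y", "z"]] = xyz
        return StructureModel(id=self.id, atoms=out)


@dataclass(frozen=True)
class Selection:
    """A chain / inclusive residue-range / atom-name filter.

    ``atom_names=None`` with ``ligand`` set selects heteroatoms of that
    residue name instead of the default Calpha trace.
    """

    chain: str
    residue_range: Optional[Tuple[int, int]] = None
    atom_names: Optional[Tuple[str, ...]] = ("CA",)
    ligand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.residue_range is not None and self.residue_range[0] > self.residue_range[1]:
            raise ValueError("residue_range start must be <= end")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``chain:start-end[:atom]`` CLI syntax."""
        parts = text.split(":")
        if len(parts) < 2:
            raise ValueError(f"cannot parse selection {text!r}; "
                             "expected chain:start-end[:atom]")
        chain = parts[0]
        lo, hi = (int(v) for v in parts[1].split("-"))
        atoms = (parts[2],) if len(parts) > 2 else ("CA",)
        return cls(chain=chain, residue_range=(lo, hi), atom_names=atoms)

    def resolve(self, model: StructureModel) -> pd.DataFrame:
        d = model.atoms
        mask = d["chain"] == self.chain
        if self.ligand is not None:
            mask &= d["resname"] == self.ligand
        if self.residue_range is not None:
            mask &= (d["resnum"] >= self.residue_range[0]) & (d["resnum"] <= self.residue_range[1])
        if self.atom_names is not None:
            mask &= d["atom"].isin(self.atom_names)
        return d[mask].sort_values(["chain", "resnum", "atom"], kind="stable")


@dataclass
class SuperpositionResult:
    """Optimal proper rotation/translation mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def read_structure(path, format: Optional[str] = None) -> StructureModel:
    """Load the first model of a PDB or mmCIF file.

    Alternate locations other than blank/'A' are dropped (count logged).
    ``format`` may force ``"pdb"`` or ``"mmcif"``; by default the dialect
    is detected from the file.
    """
    import gemmi

    path = str(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(path)
        elif format == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    rows = []
    dropped = 0
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    dropped += 1
                    continue
                rows.append((chain.name, res.seqid.num, res.name, atom.name,
                             atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z,
                             atom.occ, "" if atom.altloc in ("", "\x00") else atom.altloc,
                             res.het_flag == "H"))
    if dropped:
        logger.info("%s: dropped %d alternate-location atoms", path, dropped)
    atoms = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    if atoms.empty:
        raise ValueError(f"{path}: no atoms in first model")
    return StructureModel(id=st.name or path, atoms=atoms)


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain_name, chain_df in model.atoms.groupby("chain", sort=True):
        ch = gemmi.Chain(str(chain_name))
        for (resnum, resname), res_df in chain_df.groupby(["resnum", "resname"], sort=True):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), " ")
            het = bool(res_df["hetero"].iloc[0])
            res.het_flag = "H" if het else "A"
            for _, row in res_df.iterrows():
                at = gemmi.Atom()
                at.name = str(row["atom"])
                at.element = gemmi.Element(str(row["element"]))
                at.pos = gemmi.Position(float(row["x"]), float(row["y"]), float(row["z"]))
                at.occ = float(row["occupancy"])
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of paired coordinate sets.

    Returns the proper rotation R and translation t minimising
    ``|| R mobile + t - reference ||``; reflections are excluded by
    determinant correction of the SVD solution.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) geometry: superposition ill-posed")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def rotation_angle(rotation: np.ndarray) -> Tuple[float, np.ndarray]:
    """Angle (deg, in [0, 180]) and unit axis of a proper rotation matrix.

    The axis sign is fixed to a nonnegative z component (ties broken by
    nonnegative y, then x).  Inputs more than 1e-6 from orthogonal are
    rejected.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
        raise ValueError("matrix is not orthogonal within 1e-6")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (det < 0)")
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    # axis from the antisymmetric part; near 180 deg use the symmetric part
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(w) > 1e-8:
        axis = w / np.linalg.norm(w)
    else:
        if theta < 1e-6:
            axis = np.array([0.0, 0.0, 1.0])
        else:
            M = (R + np.eye(3)) / 2.0
            axis = np.sqrt(np.clip(np.diag(M), 0.0, None))
            # recover relative signs from off-diagonals
            if M[0, 1] < 0:
                axis[1] *= -1
            if M[0, 2] < 0:
                axis[2] *= -1
            if axis[0] == 0 and M[1, 2] < 0:
                axis[2] *= -1
            axis /= np.linalg.norm(axis)
    for i in (2, 1, 0):
        if abs(axis[i]) > 1e-12:
            if axis[i] < 0:
                axis = -axis
            break
    return theta, axis


def _paired_coords(state_a: StructureModel, state_b: StructureModel,
                   sel: Selection) -> Tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms present in both states under ``sel``,
    paired by (chain, resnum, atom)."""
    da = sel.resolve(state_a).set_index(["chain", "resnum", "atom"])
    db = sel.resolve(state_b).set_index(["chain", "resnum", "atom"])
    common = da.index.intersection(db.index)
    if len(common) == 0:
        raise ValueError(f"selection {sel} matches no common atoms")
    if len(common) < len(da) or len(common) < len(db):
        logger.info("selection %s: %d common atoms (of %d / %d)",
                    sel, len(common), len(da), len(db))
    A = da.loc[common][["x", "y", "z"]].to_numpy(dtype=float)
    B = db.loc[common][["x", "y", "z"]].to_numpy(dtype=float)
    return A, B


def domain_rotation(state_a: StructureModel, state_b: StructureModel,
                    align_sel: Selection, measure_sel: Selection) -> float:
    """Rotation (deg) of ``measure_sel`` between states after aligning
    both on ``align_sel``.

    Both states are first put into the same reference frame by
    superposing state B's alignment selection onto state A's; the
    residual Kabsch rotation between the measurement selections is then
    reported as an angle.
    """
    A_align, B_align = _paired_coords(state_a, state_b, align_sel)
    if A_align.shape[0] < 3:
        raise ValueError("alignment selection resolves to fewer than 3 common atoms")
    frame = superpose(B_align, A_align)
    A_meas, B_meas = _paired_coords(state_a, state_b, measure_sel)
    if A_meas.shape[0] < 3:
        raise ValueError("measurement selection resolves to fewer than 3 common atoms")
    B_in_frame = frame.apply(B_meas)
    res = superpose(A_meas, B_in_frame)
    angle, _ = rotation_angle(res.rotation)
    return angle


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Oriented unit normal of the least-squares plane through ordered
    points; orientation follows the right-hand rule around the given
    atom order (Newell's method fixes the sign)."""
    X = np.asarray(coords, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 atoms to fit a plane")
    C = X - X.mean(axis=0)
    _, S, Vt = np.linalg.svd(C)
    if S[1] < 1e-9:
        raise ValueError("collinear atoms: plane ill-posed")
    normal = Vt[2]
    newell = np.zeros(3)
    for i in range(X.shape[0]):
        a, b = X[i], X[(i + 1) % X.shape[0]]
        newell += np.cross(a, b)
    if np.dot(normal, newell) < 0:
        normal = -normal
    return normal


def plane_flip_angle(state_a: StructureModel, state_b: StructureModel,
                     ring_sel: Selection, align_sel: Selection) -> float:
    """Angle (deg, [0, 180]) between the oriented ring planes of the two
    states after aligning on ``align_sel``; a flip exceeds 90 deg."""
    A_align, B_align = _paired_coords(state_a, state_b, align_sel)
    frame = superpose(B_align, A_align)
    ra = ring_sel.resolve(state_a)
    rb = ring_sel.resolve(state_b)
    if len(ra) < 3 or len(rb) < 3:
        raise ValueError("ring selection resolves to fewer than 3 atoms")
    # keep deposition atom order consistent between states
    order = [n for n in ra["atom"] if n in set(rb["atom"])]
    ca = ra.set_index("atom").loc[order][["x", "y", "z"]].to_numpy(dtype=float)
    cb = rb.set_index("atom").loc[order][["x", "y", "z"]].to_numpy(dtype=float)
    na = _plane_normal(ca)
    nb = _plane_normal(frame.apply(cb))
    cosang = np.clip(np.dot(na, nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pair_distance(structure: StructureModel,
                  atom_a: Tuple[str, int, str],
                  atom_b: Tuple[str, int, str]) -> float:
    """Euclidean distance (A) between two atoms given as
    (chain, resnum, atom_name)."""
    pa = structure.atom(*atom_a)
    pb = structure.atom(*atom_b)
    return float(np.linalg.norm(pa - pb))


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant principal direction of a Calpha trace, oriented N -> C."""
    X = np.asarray(coords, dtype=float)
    C = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(C)
    axis = Vt[0]
    if np.dot(axis, X[-1] - X[0]) < 0:
        axis = -axis
    return axis


def helix_scissor_angle(state: StructureModel, sel_a: Selection,
                        sel_b: Selection) -> float:
    """Acute angle (deg, [0, 90]) between the principal axes of two
    helical Calpha selections within one state."""
    ca = sel_a.resolve(state)
    cb = sel_b.resolve(state)
    if len(ca) < 5 or len(cb) < 5:
        raise ValueError("each helix selection needs at least 5 Calpha atoms")
    ax_a = _helix_axis(state.coords(ca))
    ax_b = _helix_axis(state.coords(cb))
    cosang = np.clip(abs(np.dot(ax_a, ax_b)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
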