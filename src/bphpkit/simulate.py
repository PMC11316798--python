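"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of a :class:`GeneratorSpec`: the same
spec yields byte-identical output (one :class:`numpy.random.Generator`
per call, no global state), and every generated artifact carries its
ground-truth parameters so recovery tests never re-enter them by hand.

Default grids mirror the experiments the package analyses: analytical
SEC chromatograms over 8-24 mL at 0.02-mL steps, thermal-reversion
scans over 650-785 nm, and kinase time courses over 0-7200 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from bphpkit.association import yfrac_equilibrium
from bphpkit.chromatography import Chromatogram, EMGComponent, EMGMixture, mixture_value
from bphpkit.kinase import KineticsTrace, saturation_model
from bphpkit.photokinetics import SpectralSeries, reversion_model
from bphpkit.structure import StructureModel, _ATOM_COLUMNS

__all__ = [
    "GeneratorSpec",
    "Grid",
    "NoiseModel",
    "default_sec_truth",
    "default_reversion_truth",
    "default_kinetics_truth",
    "make_chromatogram",
    "make_equilibrium_series",
    "make_reversion_series",
    "make_kinetics_trace",
    "make_phosphotransfer_pair",
    "make_rotated_pair",
    "make_ideal_helix",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian ("gaussian", scale = sigma), multiplicative
    ("multiplicative", scale = fractional sigma) or no noise ("none")."""

    kind: str = "none"
    scale: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.scale == 0.0:
            return clean.copy()
        if self.kind == "gaussian":
            return clean + rng.normal(0.0, self.scale, size=clean.shape)
        return clean * (1.0 + rng.normal(0.0, self.scale, size=clean.shape))


@dataclass(frozen=True)
class Grid:
    """A uniform axis: ``count`` points from ``start`` to ``stop``."""

    start: float
    stop: float
    count: int

    def axis(self) -> np.ndarray:
        if self.count < 2:
            raise ValueError("grid needs at least 2 points")
        return np.linspace(self.start, self.stop, self.count)


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed + noise model + grid + stage-specific truth parameters."""

    seed: int
    noise: NoiseModel = NoiseModel()
    grid: Optional[Grid] = None
    truth: Any = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# chromatograms

#: typical Superdex-200-like elution parameters for a 165-kDa dimer and
#: its 330-kDa tetramer (tetramer elutes earlier)
def default_sec_truth(amp_t: float = 0.6, amp_d: float = 0.6,
                      b: float = 0.01, c: float = 5e-4) -> EMGMixture:
    return EMGMixture(
        tetramer=EMGComponent(amp=amp_t, lam=4.0, mu=10.6, sigma=0.22),
        dimer=EMGComponent(amp=amp_d, lam=4.0, mu=12.1, sigma=0.25),
        b=b, c=c,
    )


DEFAULT_SEC_GRID = Grid(8.0, 24.0, 801)


def make_chromatogram(spec: GeneratorSpec) -> Chromatogram:
    """Two-peak EMG chromatogram with embedded ground truth."""
    truth = spec.truth if spec.truth is not None else default_sec_truth()
    if not isinstance(truth, EMGMixture):
        raise TypeError("chromatogram truth must be an EMGMixture")
    grid = spec.grid if spec.grid is not None else DEFAULT_SEC_GRID
    if grid.count < 20:
        raise ValueError("chromatogram grid too coarse: need >= 20 points")
    v = grid.axis()
    clean = mixture_value(truth, v)
    y = spec.noise.apply(np.asarray(clean), spec.rng())
    return Chromatogram(v, y, label=f"synthetic seed={spec.seed}", truth=truth)


def make_equilibrium_series(k2: float, concentrations: Sequence[float],
                            template: GeneratorSpec,
                            area_per_molar: float = 2e5) -> List[Chromatogram]:
    """Chromatograms of a concentration titration on the dimer-tetramer
    isotherm.

    Component area fractions at each total dimer concentration C (M)
    are ``yfrac_equilibrium(k2, C)`` and its complement; the total area
    scales linearly with C (``area_per_molar`` in absorbance·mL/M).
    Each chromatogram's ``truth`` records the mixture and the tetramer
    fraction used.
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    base = template.truth if template.truth is not None else default_sec_truth()
    out = []
    for i, c in enumerate(concentrations):
        y = yfrac_equilibrium(k2, c)
        total = area_per_molar * c
        truth = EMGMixture(
            tetramer=replace(base.tetramer, amp=total * y),
            dimer=replace(base.dimer, amp=total * (1.0 - y)),
            b=base.b, c=base.c)
        sub = replace(template, seed=template.seed + i, truth=truth)
        chrom = make_chromatogram(sub)
        chrom.label = f"equilibrium c={c:.3e} M seed={sub.seed}"
        out.append(chrom)
    return out


# ---------------------------------------------------------------------------
# thermal reversion

def _gauss_band(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


def default_reversion_truth(wavelengths: np.ndarray,
                            k1: float = 3e-3, k2: float = 3e-4) -> dict:
    """Two spectral bands of opposite sign: decay of the far-red Pfr band
    paired with recovery of the red Pr band, split across the two
    kinetic components."""
    amp1 = 0.12 * _gauss_band(wavelengths, 750.0, 28.0) \
        - 0.07 * _gauss_band(wavelengths, 700.0, 22.0)
    amp2 = 0.08 * _gauss_band(wavelengths, 755.0, 30.0) \
        - 0.04 * _gauss_band(wavelengths, 698.0, 20.0)
    abs0 = 0.05 + 0.25 * _gauss_band(wavelengths, 700.0, 24.0)
    return {"k1": k1, "k2": k2, "amp1": amp1, "amp2": amp2, "abs0": abs0}


DEFAULT_REVERSION_WAVELENGTHS = Grid(650.0, 785.0, 28)
DEFAULT_REVERSION_TIMES = Grid(0.0, 7200.0, 200)


def make_reversion_series(spec: GeneratorSpec,
                          time_grid: Optional[Grid] = None) -> SpectralSeries:
    """Multi-wavelength biexponential decay with embedded truth.

    ``spec.grid`` is the wavelength axis; ``time_grid`` the time axis.
    ``spec.truth`` may carry ``k1``/``k2`` (and optionally full amplitude
    arrays); band shapes default to opposite-sign Gaussians.
    """
    wgrid = spec.grid if spec.grid is not None else DEFAULT_REVERSION_WAVELENGTHS
    tgrid = time_grid if time_grid is not None else DEFAULT_REVERSION_TIMES
    w = wgrid.axis()
    t = tgrid.axis()
    if not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    truth = dict(spec.truth) if spec.truth is not None else {}
    base = default_reversion_truth(w, k1=truth.get("k1", 3e-3),
                                   k2=truth.get("k2", 3e-4))
    for key in ("amp1", "amp2", "abs0"):
        if key in truth:
            base[key] = np.asarray(truth[key], dtype=float)
    if not base["k1"] > base["k2"] > 0:
        raise ValueError("truth must satisfy k1 > k2 > 0")
    clean = reversion_model(base["k1"], base["k2"], base["amp1"], base["amp2"],
                            base["abs0"], t)
    absorbance = spec.noise.apply(np.asarray(clean), spec.rng())
    return SpectralSeries(w, t, absorbance, truth=base)


# ---------------------------------------------------------------------------
# kinase kinetics

def default_kinetics_truth(delta_s: float = 100.0, k: float = 4.7e-3,
                           s0: float = 5.0) -> dict:
    return {"delta_s": delta_s, "k": k, "s0": s0}


DEFAULT_KINETICS_TIMES = Grid(0.0, 7200.0, 25)


def make_kinetics_trace(spec: GeneratorSpec, replicate_id: str = "r1",
                        species: str = "kinase") -> KineticsTrace:
    """One saturating-exponential densitometry trace with embedded truth."""
    truth = dict(spec.truth) if spec.truth is not None else default_kinetics_truth()
    grid = spec.grid if spec.grid is not None else DEFAULT_KINETICS_TIMES
    t = grid.axis()
    clean = saturation_model(truth["delta_s"], truth["k"], truth["s0"], t)
    if "delta_s2" in truth:
        clean = clean + truth["delta_s2"] * (1.0 - np.exp(-truth["k2"] * t))
    y = spec.noise.apply(np.asarray(clean), spec.rng())
    return KineticsTrace(t, y, replicate_id=replicate_id, species=species,
                         truth=truth)


def make_phosphotransfer_pair(spec: GeneratorSpec,
                              total_label: float = 120.0) -> Tuple[KineticsTrace, KineticsTrace]:
    """Donor/acceptor trace pair with conserved total label.

    The donor kinase loses label (negative amplitude) with the same rate
    at which the acceptor regulator gains it; donor(t) + acceptor(t) is
    constant by construction before noise.
    """
    truth = dict(spec.truth) if spec.truth is not None else default_kinetics_truth()
    amp = abs(truth["delta_s"])
    k = truth["k"]
    grid = spec.grid if spec.grid is not None else DEFAULT_KINETICS_TIMES
    t = grid.axis()
    donor_clean = saturation_model(-amp, k, total_label, t)
    acceptor_clean = saturation_model(amp, k, 0.0, t)
    rng = spec.rng()
    donor = KineticsTrace(t, spec.noise.apply(np.asarray(donor_clean), rng),
                          replicate_id="donor", species="donor kinase",
                          truth={"delta_s": -amp, "k": k, "s0": total_label})
    acceptor = KineticsTrace(t, spec.noise.apply(np.asarray(acceptor_clean), rng),
                             replicate_id="acceptor", species="acceptor regulator",
                             truth={"delta_s": amp, "k": k, "s0": 0.0})
    return donor, acceptor


# ---------------------------------------------------------------------------
# coordinate fixtures

def make_ideal_helix(n_res: int, chain: str = "A", start_res: int = 1,
                     origin=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
                     resname: str = "ALA") -> pd.DataFrame:
    """Calpha trace of an ideal alpha helix (rise 1.5 A, 100 deg/residue,
    radius 2.3 A) along ``direction`` starting at ``origin``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # build an orthonormal frame around the helix axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    rows = []
    for i in range(n_res):
        ang = np.radians(100.0 * i)
        pos = (np.asarray(origin) + 1.5 * i * d
               + 2.3 * (np.cos(ang) * u + np.sin(ang) * v))
        rows.append((chain, start_res + i, resname, "CA", "C",
                     pos[0], pos[1], pos[2], 1.0, "", False))
    return pd.DataFrame(rows, columns=_ATOM_COLUMNS)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


@dataclass(frozen=True)
class RigidTransformTruth:
    """Ground truth of a generated two-state coordinate pair."""

    angle_deg: float
    axis: Tuple[float, float, float]
    pivot: Tuple[float, float, float]
    mobile_range: Tuple[int, int]


def make_rotated_pair(spec: GeneratorSpec, angle_deg: float = 35.0,
                      axis=(0.0, 1.0, 0.0), pivot=(0.0, 0.0, 45.0),
                      with_ring: bool = False,
                      ring_flip_deg: Optional[float] = None
                      ) -> Tuple[StructureModel, StructureModel, RigidTransformTruth]:
    """Two-domain Calpha scaffold and its copy with the mobile domain
    rotated by a known rigid-body transform.

    Domain 1 (residues 1-30, the alignment frame) stays fixed; domain 2
    (residues 101-130) rotates ``angle_deg`` about ``axis`` through
    ``pivot``.  With ``with_ring`` a planar 5-atom pyrrole-like ligand
    (residue RNG 999) is attached to the fixed frame and flipped by
    ``ring_flip_deg`` about an in-plane axis in state B.  Gaussian
    coordinate noise follows ``spec.noise``.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    fixed = make_ideal_helix(30, chain="A", start_res=1,
                             origin=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0))
    mobile = make_ideal_helix(30, chain="A", start_res=101,
                              origin=(8.0, 3.0, 48.0), direction=(0.3, 0.1, 1.0))
    frames = [fixed, mobile]
    if with_ring:
        ring_atoms = []
        names = ["ND", "C1D", "C2D", "C3D", "C4D"]
        for i, name in enumerate(names):
            ang = 2 * np.pi * i / 5
            ring_atoms.append(("A", 999, "RNG", name, "N" if name == "ND" else "C",
                               4.0 + 1.4 * np.cos(ang), 2.0 + 1.4 * np.sin(ang), 20.0,
                               1.0, "", True))
        frames.append(pd.DataFrame(ring_atoms, columns=_ATOM_COLUMNS))
    atoms_a = pd.concat(frames, ignore_index=True)
    state_a = StructureModel(id="synthetic-Pr", atoms=atoms_a)

    R = _rotation_matrix(np.asarray(axis), angle_deg)
    p = np.asarray(pivot, dtype=float)
    atoms_b = atoms_a.copy()
    mob_mask = (atoms_b["resnum"] >= 101) & (atoms_b["resnum"] <= 130)
    xyz = atoms_b.loc[mob_mask, ["x", "y", "z"]].to_numpy(dtype=float)
    atoms_b.loc[mob_mask, ["x", "y", "z"]] = (xyz - p) @ R.T + p

    if with_ring and ring_flip_deg is not None:
        ring_mask = atoms_b["resname"] == "RNG"
        ring_xyz = atoms_b.loc[ring_mask, ["x", "y", "z"]].to_numpy(dtype=float)
        centre = ring_xyz.mean(axis=0)
        Rf = _rotation_matrix(np.array([1.0, 0.0, 0.0]), ring_flip_deg)
        atoms_b.loc[ring_mask, ["x", "y", "z"]] = (ring_xyz - centre) @ Rf.T + centre

    if spec.noise.kind == "gaussian" and spec.noise.scale > 0:
        rng = spec.rng()
        noisy = atoms_b[["x", "y", "z"]].to_numpy(dtype=float)
        atoms_b[["x", "y", "z"]] = noisy + rng.normal(0, spec.noise.scale, noisy.shape)

    state_b = StructureModel(id="synthetic-Pfr", atoms=atoms_b)
    truth = RigidTransformTruth(angle_deg=float(angle_deg),
                                axis=tuple(float(x) for x in axis),
                                pivot=tuple(float(x) for x in pivot),
                                mobile_range=(101, 130))
    return state_a, state_b, truth
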