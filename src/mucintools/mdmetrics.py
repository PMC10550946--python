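"""Mucin-domain polymer metrics on coordinate trajectories.

Given multi-frame coordinates of a glycoprotein, this module computes
the quantities used to characterise mucin-domain stiffness and
extension:

* normalized end-to-end distance (Å per mucin residue),
* bending angle at the domain midpoint (degrees),
* persistence length from the bond-vector autocorrelation
  ``C(n) = <cos theta(i, i+n)> = exp(-n*lb/lp)`` of the N/CA/C backbone
  chain, fitted per replica over the last frames of each trajectory,
* height per glycan (backbone end-to-end length divided by glycan
  count) in the outstretched (first frame) and equilibrated (final
  window) states — the "total" vs "effective" glycosylation measures.

Trajectories can be built from numpy arrays (e.g. by the worm-like-chain
generator) or read from multi-model PDB / DCD files via MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PolymerTrajectory",
    "MucinSelection",
    "ReplicaFit",
    "PersistenceResult",
    "end_to_end_series",
    "bending_angle_series",
    "bond_autocorrelation",
    "persistence_length",
    "height_per_glycan",
]

#: Fallback atomic masses by element symbol inferred from the atom name.
_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

_BACKBONE_ORDER = {"N": 0, "CA": 1, "C": 2}

DEFAULT_FRAME_WINDOW = 1000


def _mass_from_name(name: str) -> float:
    # PDB-style names start with the element for standard protein atoms
    element = name.strip()[0].upper()
    return _ELEMENT_MASSES.get(element, 12.011)


@dataclass
class PolymerTrajectory:
    """Frames of coordinates (Å) for a fixed atom set.

    ``coordinates`` has shape (n_frames, n_atoms, 3); ``resids`` are
    1-based residue indices per atom.
    """

    coordinates: np.ndarray
    resids: np.ndarray
    atom_names: Sequence[str]
    masses: np.ndarray | None = None
    replica_id: str = "rep1"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("at least one frame required")
        self.resids = np.asarray(self.resids, dtype=int)
        self.atom_names = list(self.atom_names)
        if len(self.atom_names) != self.coordinates.shape[1] or self.resids.size != len(self.atom_names):
            raise ValueError("atom metadata does not match coordinate array")
        if self.masses is None:
            self.masses = np.array([_mass_from_name(n) for n in self.atom_names])
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[1])

    def residue_com(self, resid: int) -> np.ndarray:
        """Per-frame mass-weighted centre of mass of one residue, (F, 3)."""
        mask = self.resids == resid
        if not mask.any():
            raise ValueError(f"residue {resid} not present in trajectory")
        m = self.masses[mask]
        return (self.coordinates[:, mask, :] * m[None, :, None]).sum(axis=1) / m.sum()

    def backbone_chain(
        self, first: int, last: int, atom_names: Sequence[str] = ("N", "CA", "C")
    ) -> np.ndarray:
        """Ordered polymer-chain coordinates (F, n_chain_atoms, 3).

        Atoms with the given names in residues ``first..last`` ordered by
        residue then by backbone position (N, CA, C).
        """
        wanted = {n: i for i, n in enumerate(atom_names)}
        keys = []
        for idx, (resid, name) in enumerate(zip(self.resids, self.atom_names)):
            if first <= resid <= last and name in wanted:
                keys.append((resid, wanted[name], idx))
        if not keys:
            raise ValueError(f"no chain atoms {atom_names} in residues {first}..{last}")
        keys.sort()
        order = [idx for _, _, idx in keys]
        return self.coordinates[:, order, :]

    def tail(self, n_frames: int) -> "PolymerTrajectory":
        """The last ``n_frames`` frames (all frames, with a warning, if fewer)."""
        if n_frames >= self.n_frames:
            if n_frames > self.n_frames:
                warnings.warn(
                    f"requested window of {n_frames} frames exceeds trajectory "
                    f"length {self.n_frames}; using all frames",
                    stacklevel=2,
                )
            return self
        return PolymerTrajectory(
            self.coordinates[-n_frames:], self.resids, self.atom_names, self.masses, self.replica_id
        )

    # -- MDAnalysis-backed readers ------------------------------------
    @classmethod
    def from_universe(cls, universe, selection: str = "protein", replica_id: str = "rep1"):
        atoms = universe.select_atoms(selection)
        if len(atoms) == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        frames = [atoms.positions.copy() for _ in universe.trajectory]
        try:
            masses = atoms.masses.copy()
            if not np.all(np.isfinite(masses)) or masses.sum() <= 0:
                masses = None
        except Exception:
            masses = None
        return cls(
            np.stack(frames), atoms.resids.copy(), [a.name for a in atoms], masses, replica_id
        )

    @classmethod
    def from_files(
        cls, topology, trajectory=None, selection: str = "protein", replica_id: str = "rep1"
    ):
        """Read a multi-model PDB, or a DCD with a PDB topology."""
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(
                str(topology), str(trajectory)
            )
        return cls.from_universe(u, selection, replica_id)


@dataclass(frozen=True)
class MucinSelection:
    """Residue anchors defining a mucin-domain polymer.

    ``first_residue..last_residue`` is the polymer (persistence-length)
    range; ``bend_anchors`` are the (first, middle, last) residues for the
    bending angle; ``e2e_anchors`` the (first, last) residues for the
    end-to-end distance; ``n_mucin_residues`` normalizes the end-to-end
    distance and ``n_glycans`` the height-per-glycan.
    """

    first_residue: int
    last_residue: int
    n_glycans: int
    n_mucin_residues: int
    bend_anchors: tuple[int, int, int] | None = None
    e2e_anchors: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.first_residue >= self.last_residue:
            raise ValueError("first_residue must precede last_residue")
        if self.n_glycans < 1:
            raise ValueError("n_glycans must be >= 1")
        if self.bend_anchors is not None:
            a, b, c = self.bend_anchors
            if not a < b < c:
                raise ValueError("bend anchors must be ordered first < middle < last")

    @property
    def e2e_pair(self) -> tuple[int, int]:
        return self.e2e_anchors or (self.first_residue, self.last_residue)


#: Anchor sets used in the TIM receptor analyses (UniProt residue numbering).
TIM3_SELECTION = MucinSelection(
    first_residue=133, last_residue=198, n_glycans=14, n_mucin_residues=71,
    bend_anchors=(131, 166, 202), e2e_anchors=(133, 198),
)
TIM4_SELECTION = MucinSelection(
    first_residue=137, last_residue=310, n_glycans=51, n_mucin_residues=179,
    bend_anchors=(135, 225, 314), e2e_anchors=(137, 310),
)


def end_to_end_series(traj: PolymerTrajectory, sel: MucinSelection) -> np.ndarray:
    """Per-frame anchor-to-anchor distance normalized by mucin residue count."""
    first, last = sel.e2e_pair
    d = np.linalg.norm(traj.residue_com(first) - traj.residue_com(last), axis=1)
    return d / sel.n_mucin_residues


def bending_angle_series(traj: PolymerTrajectory, sel: MucinSelection) -> np.ndarray:
    """Per-frame angle (degrees, in [0, 180]) at the middle anchor.

    Vectors run from the middle anchor to the first and to the last anchor;
    frames with a zero-length vector yield NaN.
    """
    if sel.bend_anchors is None:
        raise ValueError("selection has no bending anchors")
    a, b, c = sel.bend_anchors
    v1 = traj.residue_com(a) - traj.residue_com(b)
    v2 = traj.residue_com(c) - traj.residue_com(b)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (v1 * v2).sum(axis=1) / (n1 * n2)
    cosang = np.where((n1 == 0) | (n2 == 0), np.nan, np.clip(cosang, -1.0, 1.0))
    return np.degrees(np.arccos(cosang))


def bond_autocorrelation(chain: np.ndarray, n_max: int | None = None) -> np.ndarray:
    """C(n): average cosine between bond vectors ``n`` bonds apart.

    ``chain`` has shape (frames, atoms, 3).  C(0) = 1 exactly; averaging
    runs over frames and positions.
    """
    bonds = np.diff(chain, axis=1)
    norms = np.linalg.norm(bonds, axis=2, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length bond in chain")
    u = bonds / norms
    n_bonds = u.shape[1]
    if n_bonds < 2:
        raise ValueError("need at least 2 bonds")
    if n_max is None:
        n_max = n_bonds // 2
    n_max = min(n_max, n_bonds - 1)
    c = np.empty(n_max + 1)
    c[0] = 1.0
    for n in range(1, n_max + 1):
        c[n] = float(np.mean(np.sum(u[:, :-n, :] * u[:, n:, :], axis=2)))
    return c


@dataclass(frozen=True)
class ReplicaFit:
    replica_id: str
    lp: float                 # Å; inf when no decorrelation is observed
    lb: float                 # mean bond length, Å
    n_fit: int                # number of C(n) points in the fit
    n_frames: int
    autocorrelation: np.ndarray = field(repr=False, default=None)

    @property
    def finite(self) -> bool:
        return np.isfinite(self.lp)


@dataclass
class PersistenceResult:
    """Persistence-length estimates per replica with their mean ± SD."""

    replicas: list[ReplicaFit]

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def per_replica_lp(self) -> np.ndarray:
        return np.array([r.lp for r in self.replicas])

    @property
    def lp(self) -> float:
        """Mean persistence length over replicas (Å)."""
        return float(np.mean(self.per_replica_lp))

    @property
    def lp_sd(self) -> float:
        vals = self.per_replica_lp
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def lb(self) -> float:
        return float(np.mean([r.lb for r in self.replicas]))

    def summary(self) -> str:
        lines = [
            "Persistence length (bond-autocorrelation fit)",
            "=" * 46,
            f"replicas: {self.n_replicas}",
            f"mean bond length lb: {self.lb:.3f} A",
            f"lp mean +/- SD: {self.lp:.1f} +/- {self.lp_sd:.1f} A",
            "-" * 46,
        ]
        for r in self.replicas:
            lp = f"{r.lp:.1f}" if r.finite else "inf (no decorrelation)"
            lines.append(f"  {r.replica_id}: lp = {lp} A  (fit over {r.n_fit} lags, {r.n_frames} frames)")
        return "\n".join(lines)


def _fit_replica(
    traj: PolymerTrajectory, sel: MucinSelection, frame_window: int
) -> ReplicaFit:
    window = traj.tail(frame_window)
    chain = window.backbone_chain(sel.first_residue, sel.last_residue)
    bonds = np.diff(chain, axis=1)
    lb = float(np.mean(np.linalg.norm(bonds, axis=2)))
    c = bond_autocorrelation(chain)
    # fit range: n = 1 .. first n with C(n) < e^-2 (or half the chain), C(n) > 0 only
    cut = len(c) - 1
    for n in range(1, len(c)):
        if c[n] < np.exp(-2.0):
            cut = n
            break
    ns = np.arange(1, cut + 1)
    mask = c[1 : cut + 1] > 0
    ns, cs = ns[mask], c[1 : cut + 1][mask]
    if len(ns) == 0:
        return ReplicaFit(traj.replica_id, 0.0, lb, 0, window.n_frames, c)
    logc = np.log(cs)
    slope = float(ns @ logc / (ns @ ns))        # least squares through origin
    if slope >= 0.0:
        lp = float("inf")
    else:
        lp = -lb / slope
    return ReplicaFit(traj.replica_id, lp, lb, len(ns), window.n_frames, c)


def persistence_length(
    trajectories: Sequence[PolymerTrajectory] | PolymerTrajectory,
    sel: MucinSelection,
    frame_window: int = DEFAULT_FRAME_WINDOW,
) -> PersistenceResult:
    """Fit ``C(n) = exp(-n*lb/lp)`` per replica over the last frames.

    Each replica trajectory contributes an independent estimate; the
    result reports all of them together with their mean and SD.  A rigid
    rod (no decorrelation) is flagged with ``lp = inf``.
    """
    if isinstance(trajectories, PolymerTrajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("no trajectories supplied")
    return PersistenceResult([_fit_replica(t, sel, frame_window) for t in trajectories])


def height_per_glycan(
    trajectories: Sequence[PolymerTrajectory] | PolymerTrajectory,
    sel: MucinSelection,
    mode: str = "equilibrated",
    frame_window: int = DEFAULT_FRAME_WINDOW,
) -> tuple[float, float]:
    """Backbone end-to-end length of the mucin range divided by glycan count.

    ``mode='outstretched'`` uses frame 0 of each replica (the unequilibrated
    starting structure — "total glycosylation"); ``mode='equilibrated'``
    averages over the final ``frame_window`` frames of each replica
    ("effective glycosylation").  Returns (mean, SD) across replicas in Å
    per glycan.
    """
    if isinstance(trajectories, PolymerTrajectory):
        trajectories = [trajectories]
    if mode not in ("outstretched", "equilibrated"):
        raise ValueError("mode must be 'outstretched' or 'equilibrated'")
    values = []
    for traj in trajectories:
        d = np.linalg.norm(
            traj.residue_com(sel.first_residue) - traj.residue_com(sel.last_residue), axis=1
        )
        if mode == "outstretched":
            values.append(d[0] / sel.n_glycans)
        else:
            tail = d[-min(frame_window, len(d)):]
            values.append(float(np.mean(tail)) / sel.n_glycans)
    values = np.array(values)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return float(np.mean(values)), sd
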