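"""Coarse-grained helical bundle models of YG-box dimers and tetramers.

Helices are ideal alpha helices (rise 1.5 A, twist 100 deg, C-alpha radius
2.3 A) carrying one C-alpha and one radially displaced C-beta pseudo-atom
per residue.  Dimers are built with the glycine-zipper face of each helix
toward its partner, staggered by a small azimuthal offset so the facing
glycines interdigitate instead of colliding.  Tetramers are dimer-of-dimers
assemblies in one of two docking modes:

* ``parallel`` -- co-oriented dimers related by an exact 2-fold parallel to
  the helix axes, crossed right-handed, docked so the stripe flanking the
  small-residue face near the C-terminal end of the zipper (the 273..277
  region in human numbering) points at the partner dimer;
* ``antiparallel`` -- head-to-tail stacked dimers related by a 2-fold
  perpendicular to the helix axes, crossed left-handed, overlapping around
  the core of the small-residue face.

Crosslink feasibility between the two dimers of a tetramer is scored from
the minimum C-beta--C-beta distance at a given residue position through a
logistic band (midpoint 6 A): engineered cysteines at positions whose
C-betas approach across the dimer--dimer interface can form disulfides
under oxidation, so the score ranks candidate positions the way a
crosslinking gel would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .seqmotif import OrthologSequence, scan_motifs

DEFAULT_RISE = 1.5
DEFAULT_TWIST = 100.0
DEFAULT_CA_RADIUS = 2.3
DEFAULT_CB_OFFSET = 1.5
DEFAULT_INTER_AXIS = 7.5
DEFAULT_FACING_OFFSET = 10.0
DEFAULT_CLASH_FLOOR = 3.0

DEFAULT_CROSSING_ANGLE = {"parallel": 35.0, "antiparallel": 20.0}
DEFAULT_HANDEDNESS = {"parallel": "right", "antiparallel": "left"}
DEFAULT_INTERFACE_SEPARATION = {"parallel": 7.0, "antiparallel": 7.5}  # A2-B1 axis distance (A)
DEFAULT_DOCK_AZIMUTH = {"parallel": -50.0, "antiparallel": 0.0}  # deg off the anti-zipper face

DEFAULT_XLINK_MIDPOINT = 6.0  # A, C-beta--C-beta logistic midpoint
DEFAULT_XLINK_WIDTH = 1.0


class AssemblyError(ValueError):
    """Raised when an assembly violates the steric clash floor."""

    def __init__(self, msg: str, offending_pair: Optional[Tuple[int, int]] = None):
        super().__init__(msg)
        self.offending_pair = offending_pair


# ---------------------------------------------------------------------------
# elementary rotations

def _rx(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _frame_from_direction(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is ``direction`` (deterministic)."""
    w = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("zero direction vector")
    w = w / norm
    seed = np.array([1.0, 0.0, 0.0])
    if abs(w @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ w) * w
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


@dataclass(frozen=True)
class HelixModel:
    """An ideal helix: per-residue C-alpha/C-beta coordinates plus its axis."""

    sequence: str
    first_residue_number: int
    ca: np.ndarray  # (n, 3)
    cb: np.ndarray  # (n, 3)
    axis_point: np.ndarray
    axis_direction: np.ndarray  # unit vector

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_index(self, residue_number: int) -> int:
        i = residue_number - self.first_residue_number
        if not 0 <= i < len(self.sequence):
            raise KeyError(f"residue {residue_number} not in helix")
        return i

    def ca_of(self, residue_number: int) -> np.ndarray:
        return self.ca[self.residue_index(residue_number)]

    def cb_of(self, residue_number: int) -> np.ndarray:
        return self.cb[self.residue_index(residue_number)]

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "HelixModel":
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return replace(
            self,
            ca=self.ca @ r.T + t,
            cb=self.cb @ r.T + t,
            axis_point=r @ self.axis_point + t,
            axis_direction=r @ self.axis_direction,
        )


def build_ideal_helix(
    sequence: str,
    *,
    rise: float = DEFAULT_RISE,
    twist_deg: float = DEFAULT_TWIST,
    radius: float = DEFAULT_CA_RADIUS,
    origin=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    phase_deg: float = 0.0,
    first_residue_number: int = 1,
    cb_offset: float = DEFAULT_CB_OFFSET,
    center_axially: bool = False,
) -> HelixModel:
    """Place C-alpha atoms on an ideal helical lattice.

    Residue ``i`` (0-based) sits at cylindrical coordinates
    ``(radius, phase + i * twist, i * rise)`` in the frame defined by
    ``origin``/``direction``; the C-beta pseudo-atom is displaced a further
    ``cb_offset`` radially outward.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if rise <= 0 or radius <= 0:
        raise ValueError("rise and radius must be positive")
    n = len(sequence)
    i = np.arange(n)
    theta = np.radians(phase_deg + i * twist_deg)
    z = i * rise
    if center_axially:
        z = z - z.mean()
    ca_local = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    rb = radius + cb_offset
    cb_local = np.column_stack([rb * np.cos(theta), rb * np.sin(theta), z])
    frame = _frame_from_direction(np.asarray(direction, dtype=float))
    origin = np.asarray(origin, dtype=float)
    return HelixModel(
        sequence=sequence,
        first_residue_number=first_residue_number,
        ca=ca_local @ frame.T + origin,
        cb=cb_local @ frame.T + origin,
        axis_point=origin + (frame @ np.array([0.0, 0.0, float(z[0])])),
        axis_direction=frame @ np.array([0.0, 0.0, 1.0]),
    )


@dataclass
class BundleModel:
    """A dimer or dimer-of-dimers bundle with its assembly metadata."""

    helices: List[HelixModel]
    level: str  # "dimer" | "tetramer"
    mode: str  # dimer: helix polarity; tetramer: docking mode
    handedness: Optional[str] = None  # crossing handedness for tetramers
    crossing_angle_deg: float = 0.0
    inter_axis_distance: float = DEFAULT_INTER_AXIS
    inter_dimer_distance: Optional[float] = None  # centre-of-mass separation
    register_offset: float = 0.0  # axial offset of dimer B (residues)
    facing_positions: Tuple[int, ...] = ()
    symmetry: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (R, t): first half -> second half

    def __post_init__(self) -> None:
        if len(self.helices) not in (2, 4):
            raise ValueError("bundle must contain 2 or 4 helices")

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    def coords(self) -> np.ndarray:
        return np.vstack([h.ca for h in self.helices])

    def cb_coords(self) -> np.ndarray:
        return np.vstack([h.cb for h in self.helices])

    def dimer_halves(self) -> Tuple[List[HelixModel], List[HelixModel]]:
        k = len(self.helices) // 2
        return self.helices[:k], self.helices[k:]

    def com(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def rg(self) -> float:
        return compute_rg(self.coords())

    def dmax(self) -> float:
        return compute_dmax(self.coords())

    def symmetry_rmsd(self) -> float:
        """RMSD of the first half mapped through the declared 2-fold onto
        the second half (atom-wise, C-alpha)."""
        if self.symmetry is None:
            raise ValueError("no symmetry declared for this bundle")
        rot, t = self.symmetry
        first, second = self.dimer_halves()
        a = np.vstack([h.ca for h in first]) @ rot.T + t
        b = np.vstack([h.ca for h in second])
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_clashes(
    groups_a: Sequence[HelixModel], groups_b: Sequence[HelixModel], clash_floor: float
) -> None:
    for ha in groups_a:
        for hb in groups_b:
            d = cdist(ha.ca, hb.ca)
            dmin = d.min()
            if dmin < clash_floor:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                pair = (
                    ha.first_residue_number + int(i),
                    hb.first_residue_number + int(j),
                )
                raise AssemblyError(
                    f"clash: CA-CA {dmin:.2f} A < floor {clash_floor:.2f} A "
                    f"between residues {pair[0]} and {pair[1]}",
                    offending_pair=pair,
                )


def _facing_phase(
    facing_positions: Sequence[int],
    first_residue_number: int,
    twist_deg: float,
    offset_deg: float,
) -> float:
    """Phase putting the circular mean of the facing positions at azimuth 0
    (+x, toward the partner), staggered by ``offset_deg``."""
    angles = np.radians(
        [(p - first_residue_number) * twist_deg for p in facing_positions]
    )
    mean = math.degrees(math.atan2(np.sin(angles).mean(), np.cos(angles).mean()))
    return -mean + offset_deg


def assemble_dimer(
    sequence,
    *,
    first_residue_number: int = 1,
    rise: float = DEFAULT_RISE,
    twist_deg: float = DEFAULT_TWIST,
    radius: float = DEFAULT_CA_RADIUS,
    inter_axis_distance: float = DEFAULT_INTER_AXIS,
    polarity: str = "parallel",
    facing_positions: Optional[Sequence[int]] = None,
    facing_offset_deg: float = DEFAULT_FACING_OFFSET,
    clash_floor: float = DEFAULT_CLASH_FLOOR,
) -> BundleModel:
    """Build a two-helix zipper dimer.

    The azimuthal phase is chosen so that the configured facing positions
    (by default the glycine-zipper motif found by the motif scanner) point
    toward the partner helix, offset by ``facing_offset_deg`` so that the
    facing residues of the two helices interdigitate rather than collide.
    The two helices are related by an exact 2-fold: about the bundle axis
    for ``parallel`` polarity, perpendicular to it for ``antiparallel``.
    """
    if isinstance(sequence, OrthologSequence):
        seq = sequence.ungapped()
        sequence_str = seq.residues
        first_residue_number = seq.first_residue_number
    else:
        sequence_str = str(sequence)
    if polarity not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if facing_positions is None:
        hits = scan_motifs(
            OrthologSequence("x", sequence_str, first_residue_number), "G"
        )
        if not hits:
            raise ValueError(
                "no glycine-zipper motif found; supply facing_positions explicitly"
            )
        facing_positions = max(hits, key=lambda h: len(h.positions)).positions
    phase = _facing_phase(facing_positions, first_residue_number, twist_deg, facing_offset_deg)
    helix_a = build_ideal_helix(
        sequence_str,
        rise=rise,
        twist_deg=twist_deg,
        radius=radius,
        origin=(-inter_axis_distance / 2.0, 0.0, 0.0),
        phase_deg=phase,
        first_residue_number=first_residue_number,
        center_axially=True,
    )
    if polarity == "parallel":
        rot = _rz(180.0)
    else:
        rot = _ry(180.0)
    helix_b = helix_a.transformed(rot)
    _check_clashes([helix_a], [helix_b], clash_floor)
    return BundleModel(
        helices=[helix_a, helix_b],
        level="dimer",
        mode=polarity,
        inter_axis_distance=inter_axis_distance,
        facing_positions=tuple(facing_positions),
        symmetry=(rot, np.zeros(3)),
    )


def _dimer_geometry(dimer: BundleModel) -> Tuple[float, float, int]:
    helix = dimer.helices[0]
    n = len(helix)
    zs = helix.ca[:, 2]
    rise = float((zs[-1] - zs[0]) / (n - 1))
    center_res = helix.first_residue_number + (n - 1) / 2.0
    return rise, center_res, n


def assemble_tetramer(
    dimer: BundleModel,
    mode: str = "parallel",
    *,
    crossing_angle_deg: Optional[float] = None,
    handedness: Optional[str] = None,
    inter_dimer_distance: Optional[float] = None,
    interface_separation: Optional[float] = None,
    dock_azimuth_deg: Optional[float] = None,
    contact_residue: Optional[float] = None,
    register: Optional[float] = None,
    clash_floor: float = DEFAULT_CLASH_FLOOR,
) -> BundleModel:
    """Dock two copies of a zipper dimer into a dimer-of-dimers tetramer.

    ``parallel``: the dimers are co-oriented, related by an exact 2-fold
    about the bundle axis, and crossed (default right-handed, 30 deg).
    The closest approach between the two interface helices is placed at
    ``contact_residue`` (default: one residue before the C-terminal facing
    glycine, where the small-residue face and its flanking positions
    cluster), so the juxtaposed surface is the face opposite the
    dimerization glycines.

    ``antiparallel``: the dimers stack head-to-tail (exact 2-fold
    perpendicular to the helix axes, default left-handed cross), axially
    offset so the overlap is centred on ``contact_residue`` (default: four
    residues before the N-terminal facing glycine, the core of the
    small-residue face).

    ``inter_dimer_distance`` is the requested centre-of-mass separation of
    the two dimers; when omitted it is derived from ``interface_separation``
    (the lateral offset between the two dimer frames).  ``register`` (in
    residues) overrides the mode's default axial offset of dimer B.
    """
    if dimer.level != "dimer":
        raise ValueError("assemble_tetramer expects a dimer")
    if mode not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown mode {mode!r}")
    if handedness is None:
        handedness = DEFAULT_HANDEDNESS[mode]
    if crossing_angle_deg is None:
        crossing_angle_deg = DEFAULT_CROSSING_ANGLE[mode]
    if interface_separation is None:
        interface_separation = DEFAULT_INTERFACE_SEPARATION[mode]
    if dock_azimuth_deg is None:
        dock_azimuth_deg = DEFAULT_DOCK_AZIMUTH[mode]
    sigma = +1.0 if handedness == "right" else -1.0
    rise, center_res, n = _dimer_geometry(dimer)
    facing = dimer.facing_positions
    if contact_residue is None:
        if not facing:
            contact_residue = center_res
        elif mode == "parallel":
            contact_residue = max(facing) - 1.0
        else:
            contact_residue = min(facing) - 4.0
    z_c = (contact_residue - center_res) * rise

    # 1) roll the dimer about its interface-helix axis so the requested
    #    docking face points along +x (toward the partner dimer)
    iface_helix = dimer.helices[1]
    pivot = np.array([iface_helix.axis_point[0], iface_helix.axis_point[1], 0.0])
    roll = _rz(dock_azimuth_deg)
    placed = [h.transformed(roll, pivot - roll @ pivot) for h in dimer.helices]
    # 2) tilt by half the crossing angle about the docking (x) axis
    half_tilt = _rx(-sigma * crossing_angle_deg / 2.0)
    placed = [h.transformed(half_tilt) for h in placed]
    # 3) put the interface-helix axis at (-interface_separation/2, 0) at the
    #    contact height, so the closest approach sits on the 2-fold axis
    axis_p = placed[1].axis_point
    axis_d = placed[1].axis_direction
    t_axis = (z_c - axis_p[2]) / axis_d[2]
    at_contact = axis_p + t_axis * axis_d
    shift = np.array([-interface_separation / 2.0 - at_contact[0], -at_contact[1], 0.0])
    if mode == "antiparallel":
        dz_b = (2.0 * z_c) if register is None else register * rise
        shift = shift + np.array([0.0, 0.0, -dz_b / 2.0 - 0.0])
        register_res = dz_b / rise
    else:
        dz_b = (register or 0.0) * rise
        register_res = register or 0.0
    placed = [h.transformed(np.eye(3), shift) for h in placed]

    # optional extra lateral offset to honour a requested COM separation
    if inter_dimer_distance is not None:
        com = np.vstack([h.ca for h in placed]).mean(axis=0)
        if mode == "parallel":
            transverse = math.hypot(com[1], dz_b / 2.0)
        else:
            transverse = abs(com[2])
        half = inter_dimer_distance / 2.0
        if half <= transverse:
            raise ValueError(
                f"requested inter-dimer distance {inter_dimer_distance} A is "
                f"smaller than the construction's transverse offset "
                f"{2 * transverse:.2f} A"
            )
        delta = com[0] + math.sqrt(half**2 - transverse**2)
        placed = [h.transformed(np.eye(3), np.array([-delta, 0.0, 0.0])) for h in placed]

    if mode == "parallel":
        rot_b, t_b = _rz(180.0), np.array([0.0, 0.0, dz_b])
        symmetry = (rot_b, t_b) if dz_b == 0.0 else None
    else:
        rot_b, t_b = _ry(180.0), np.zeros(3)
        symmetry = (rot_b, t_b)
    dimer_a = placed
    dimer_b = [h.transformed(rot_b, t_b) for h in placed]

    _check_clashes(dimer_a, dimer_b, clash_floor)
    bundle = BundleModel(
        helices=dimer_a + dimer_b,
        level="tetramer",
        mode=mode,
        handedness=handedness,
        crossing_angle_deg=crossing_angle_deg,
        inter_axis_distance=dimer.inter_axis_distance,
        register_offset=register_res,
        facing_positions=facing,
        symmetry=symmetry,
    )
    com_a = np.vstack([h.ca for h in dimer_a]).mean(axis=0)
    com_b = np.vstack([h.ca for h in dimer_b]).mean(axis=0)
    bundle.inter_dimer_distance = float(np.linalg.norm(com_a - com_b))
    return bundle


# ---------------------------------------------------------------------------
# size measures

def compute_rg(coords: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Mass-weighted radius of gyration, sqrt(sum w |r - rbar|^2 / sum w)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if weights is None:
        weights = np.ones(coords.shape[0])
    weights = np.asarray(weights, dtype=float)
    center = (weights[:, None] * coords).sum(axis=0) / weights.sum()
    d2 = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt((weights * d2).sum() / weights.sum()))


def compute_dmax(coords: np.ndarray) -> float:
    """Maximum pairwise distance."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    return float(pdist(coords).max())


# ---------------------------------------------------------------------------
# crosslink feasibility

@dataclass(frozen=True)
class CrosslinkPrediction:
    """Cross-dimer disulfide feasibility at one residue position."""

    position: int
    distance: Optional[float]  # min C-beta--C-beta across the interface (A)
    score: Optional[float]  # logistic propensity in [0, 1]
    error: Optional[str] = None


def logistic_score(distance: float, midpoint: float = DEFAULT_XLINK_MIDPOINT,
                   width: float = DEFAULT_XLINK_WIDTH) -> float:
    return 1.0 / (1.0 + math.exp((distance - midpoint) / width))


def predict_crosslinks(
    tetramer: BundleModel,
    positions: Iterable[int],
    *,
    midpoint: float = DEFAULT_XLINK_MIDPOINT,
    width: float = DEFAULT_XLINK_WIDTH,
) -> List[CrosslinkPrediction]:
    """Minimum cross-dimer C-beta--C-beta distance and logistic propensity
    for each candidate position, ranked by descending propensity.

    Positions absent from the model yield an error record instead of a
    number.  The score is monotone non-increasing in distance.
    """
    if tetramer.level != "tetramer":
        raise ValueError("crosslink prediction requires a tetramer")
    half_a, half_b = tetramer.dimer_halves()
    out: List[CrosslinkPrediction] = []
    for pos in positions:
        try:
            cbs_a = [h.cb_of(pos) for h in half_a]
            cbs_b = [h.cb_of(pos) for h in half_b]
        except KeyError:
            out.append(
                CrosslinkPrediction(pos, None, None, error=f"position {pos} not in model")
            )
            continue
        d = float(cdist(np.asarray(cbs_a), np.asarray(cbs_b)).min())
        out.append(CrosslinkPrediction(pos, d, logistic_score(d, midpoint, width)))
    out.sort(key=lambda p: (-(p.score if p.score is not None else -1.0)))
    return out


# ---------------------------------------------------------------------------
# optional template superposition

def superpose(mobile: np.ndarray, target: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch): returns (R, t, rmsd) with
    ``mobile @ R.T + t`` approximating ``target``."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must have identical (n, 3) shapes")
    mu_m, mu_t = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_t - rot @ mu_m
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, t, rmsd
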