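"""Sequence-motif analysis for YG-box self-interaction domains.

The C-terminal self-interaction domain of SMN-family proteins ("YG box")
carries three overlapping, regularly spaced motifs on a single alpha helix:

* the **Y-motif** ``YxxxYxxxY`` of stacked tyrosines,
* the **G-motif** ``GxxxGxxxG`` of the glycine-zipper family, and
* the **s-motif** of small residues (Ser/Ala/Thr and relatives) on the
  helix face opposite the dimer interface.

Because the spacing of all three motifs is 4 residues (~40 degrees of
helical twist per step at 100 degrees/residue), each motif decorates one
face of the helix.  This module scans sequences for such step-4 motif
runs, maps equivalent residue numbers between orthologs via an alignment,
and provides the helix-face geometry used to reason about which residues
can share an interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: residue alphabets defining each motif class
MOTIF_ALPHABETS: Dict[str, frozenset] = {
    "Y": frozenset("Y"),
    "G": frozenset("G"),
    "s": frozenset("GASTC"),
}

#: motif spacing along the helix (residues); step-4 keeps a motif on one face
MOTIF_STEP = 4
MIN_RUN = 3

#: residue classes for conservation profiles; overlapping membership is
#: resolved by priority glycine > small > hydrophobic > polar
CONSERVATION_CLASSES: Tuple[str, ...] = ("glycine", "small", "hydrophobic", "polar")
_SMALL = frozenset("GASTC")
_HYDROPHOBIC = frozenset("AVLIMFWYC")

DEFAULT_TWIST_DEG = 100.0  # ideal alpha helix, 3.6 residues/turn
DEFAULT_FACE_HALF_WIDTH = 50.0


class NoEquivalentError(KeyError):
    """Raised when a residue has no aligned equivalent in the target species."""


@dataclass(frozen=True)
class OrthologSequence:
    """A (possibly aligned) protein sequence fragment with residue numbering.

    ``first_residue_number`` is the number of the first *residue* (gaps in an
    aligned sequence do not consume numbers), following the 1-based numbering
    of each species' full-length protein.
    """

    species_id: str
    residues: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues.upper()) - AA_ALPHABET - {GAP}
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
        if self.first_residue_number < 1:
            raise ValueError("first_residue_number must be >= 1")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_aligned(self) -> bool:
        return GAP in self.residues

    def ungapped(self) -> "OrthologSequence":
        return OrthologSequence(
            self.species_id, self.residues.replace(GAP, ""), self.first_residue_number
        )

    def numbering(self) -> List[Optional[int]]:
        """Residue number of every column (``None`` for gap columns)."""
        out: List[Optional[int]] = []
        n = self.first_residue_number
        for ch in self.residues:
            if ch == GAP:
                out.append(None)
            else:
                out.append(n)
                n += 1
        return out


@dataclass(frozen=True)
class MotifHit:
    """A maximal run of >=3 same-class residues spaced 4 apart."""

    motif_class: str
    positions: Tuple[int, ...]
    matched_residues: str

    def __post_init__(self) -> None:
        steps = {b - a for a, b in zip(self.positions, self.positions[1:])}
        if steps != {MOTIF_STEP}:
            raise ValueError("motif positions must step by 4")

    @property
    def start(self) -> int:
        return self.positions[0]


def scan_motifs(
    seq: OrthologSequence,
    motif_class: str,
    alphabets: Mapping[str, frozenset] = MOTIF_ALPHABETS,
) -> List[MotifHit]:
    """Find every maximal step-4 run of >=3 motif-class residues.

    Runs in different step-4 phases may overlap; each is reported
    separately.  Hits are sorted by start position.
    """
    if motif_class not in alphabets:
        raise ValueError(f"unknown motif class {motif_class!r}; know {sorted(alphabets)}")
    if seq.is_aligned:
        seq = seq.ungapped()
    if len(seq) < MIN_RUN * MOTIF_STEP - 3:
        raise ValueError("sequence shorter than one motif span (9 residues)")
    alpha = alphabets[motif_class]
    res = seq.residues
    hits: List[MotifHit] = []
    for i, ch in enumerate(res):
        if ch not in alpha:
            continue
        if i >= MOTIF_STEP and res[i - MOTIF_STEP] in alpha:
            continue  # not the start of a maximal run
        j = i
        while j + MOTIF_STEP < len(res) and res[j + MOTIF_STEP] in alpha:
            j += MOTIF_STEP
        count = (j - i) // MOTIF_STEP + 1
        if count >= MIN_RUN:
            idx = list(range(i, j + 1, MOTIF_STEP))
            hits.append(
                MotifHit(
                    motif_class,
                    tuple(seq.first_residue_number + k for k in idx),
                    "".join(res[k] for k in idx),
                )
            )
    hits.sort(key=lambda h: h.start)
    return hits


class PositionMap:
    """Cross-species residue-number mapping derived from an alignment.

    Columns in which both species carry a residue define a bijection
    between their residue numbers; gapped columns have no equivalent.
    """

    def __init__(self, aligned: Iterable[OrthologSequence]):
        seqs = list(aligned)
        if not seqs:
            raise ValueError("no sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
        self.species: List[str] = [s.species_id for s in seqs]
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids")
        self._seqs: Dict[str, OrthologSequence] = {s.species_id: s for s in seqs}
        self._numbering: Dict[str, List[Optional[int]]] = {
            s.species_id: s.numbering() for s in seqs
        }
        self._col_of: Dict[str, Dict[int, int]] = {
            sp: {num: col for col, num in enumerate(nums) if num is not None}
            for sp, nums in self._numbering.items()
        }

    @property
    def n_columns(self) -> int:
        return len(next(iter(self._seqs.values())))

    def sequences(self) -> Dict[str, OrthologSequence]:
        return dict(self._seqs)

    def column_of(self, species: str, residue_number: int) -> int:
        try:
            return self._col_of[species][residue_number]
        except KeyError:
            raise KeyError(
                f"residue {residue_number} not present in {species!r}"
            ) from None

    def map_position(self, from_species: str, residue_number: int, to_species: str) -> int:
        """Return the equivalent residue number in ``to_species``.

        Raises :class:`NoEquivalentError` when the aligned column is a gap in
        the target species (an explicit no-equivalent outcome, never a number).
        """
        col = self.column_of(from_species, residue_number)
        if to_species not in self._numbering:
            raise KeyError(f"unknown species {to_species!r}")
        num = self._numbering[to_species][col]
        if num is None:
            raise NoEquivalentError(
                f"{from_species}:{residue_number} aligns to a gap in {to_species}"
            )
        return num

    def get(
        self, from_species: str, residue_number: int, to_species: str
    ) -> Optional[int]:
        """Like :meth:`map_position` but returns ``None`` for gapped columns."""
        try:
            return self.map_position(from_species, residue_number, to_species)
        except NoEquivalentError:
            return None


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle into the interval (-180, 180]."""
    a = math.fmod(angle_deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def helix_face_angle(
    pos_a: int, pos_b: int, twist_per_residue: float = DEFAULT_TWIST_DEG
) -> float:
    """Azimuthal angle (degrees, wrapped to (-180, 180]) between two residues
    of one helix, accumulated at ``twist_per_residue`` degrees per residue."""
    return wrap_angle((pos_b - pos_a) * twist_per_residue)


def same_face(
    pos_a: int,
    pos_b: int,
    twist_per_residue: float = DEFAULT_TWIST_DEG,
    face_half_width: float = DEFAULT_FACE_HALF_WIDTH,
) -> bool:
    return abs(helix_face_angle(pos_a, pos_b, twist_per_residue)) <= face_half_width


def classify_residue(ch: str) -> str:
    """Assign a residue to a conservation class.

    Priority for overlapping membership: glycine > small > hydrophobic > polar.
    """
    if ch == "G":
        return "glycine"
    if ch in _SMALL:
        return "small"
    if ch in _HYDROPHOBIC:
        return "hydrophobic"
    return "polar"


@dataclass
class ConservationProfile:
    """Per-column frequency of residue classes over the non-gap residues."""

    classes: Tuple[str, ...]
    frequencies: np.ndarray  # (n_columns, n_classes)
    n_observed: np.ndarray = field(default_factory=lambda: np.array([]))

    def frequency(self, column: int, cls: str) -> float:
        return float(self.frequencies[column, self.classes.index(cls)])


def conservation_profile(aligned_seqs: Iterable[OrthologSequence]) -> ConservationProfile:
    seqs = list(aligned_seqs)
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
    n_col = lengths.pop()
    counts = np.zeros((n_col, len(CONSERVATION_CLASSES)), dtype=float)
    observed = np.zeros(n_col, dtype=int)
    idx = {c: k for k, c in enumerate(CONSERVATION_CLASSES)}
    for s in seqs:
        for col, ch in enumerate(s.residues):
            if ch == GAP:
                continue
            counts[col, idx[classify_residue(ch)]] += 1.0
            observed[col] += 1
    freqs = np.zeros_like(counts)
    nz = observed > 0
    freqs[nz] = counts[nz] / observed[nz, None]
    return ConservationProfile(CONSERVATION_CLASSES, freqs, observed)


def load_reference_alignment() -> PositionMap:
    """Load the bundled synthetic YG-box alignment.

    The shipped alignment is a synthetic stand-in (real ortholog sequences are
    user inputs): it encodes the cross-species residue correspondences used
    throughout the human (hs), fruit-fly (dm) and fission-yeast (sp) SMN
    literature -- e.g. hs273/dm204/sp137 and hs277/dm208/sp141 -- together
    with the step-4 motif registers (hs s-motif 262/266/270/274, Y-motif
    268/272/276, G-motif 271/275/279).
    """
    from . import io as _io

    with resources.as_file(
        resources.files("oligostate.data") / "synthetic_yg_alignment.fasta"
    ) as path:
        seqs = _io.read_fasta(path)
    return PositionMap(seqs)
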