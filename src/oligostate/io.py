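"""File formats: FASTA, 3-column SAXS ``.dat``, CSV frame stacks and
chromatograms, P(r) tables and coarse-grained PDB models.

FASTA headers may carry ``key=value`` tokens after the identifier; the
``first_residue=N`` token sets the residue numbering of the fragment
(defaults to 1).  All tabular formats are plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqmotif import OrthologSequence

if TYPE_CHECKING:  # pragma: no cover
    from .helixmodel import BundleModel, HelixModel

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(record: SeqRecord) -> Dict[str, str]:
    tokens = record.description.split()[1:]
    return dict(t.split("=", 1) for t in tokens if "=" in t)


def read_fasta(path: PathLike) -> List[OrthologSequence]:
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(rec)
        seqs.append(
            OrthologSequence(
                species_id=rec.id,
                residues=str(rec.seq),
                first_residue_number=int(meta.get("first_residue", 1)),
            )
        )
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(path: PathLike, seqs: Iterable[OrthologSequence]) -> None:
    records = [
        SeqRecord(
            Seq(s.residues),
            id=s.species_id,
            description=f"first_residue={s.first_residue_number}",
        )
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAXS profiles (q, I, sigma) and P(r) tables

def read_saxs_profile(path: PathLike):
    """Read a whitespace- or comma-delimited ``q I [sigma]`` profile."""
    from .saxs import SAXSProfile

    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip().replace(",", " ")
        if not line or line[0] in "#%;":
            continue
        parts = line.split()
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError:
            continue  # header line
        if len(vals) >= 2:
            rows.append(vals + [np.nan] * (3 - len(vals)))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows, dtype=float)
    sigma = arr[:, 2] if arr.shape[1] > 2 and np.isfinite(arr[:, 2]).all() else None
    return SAXSProfile(q=arr[:, 0], intensity=arr[:, 1], sigma=sigma)


def write_saxs_profile(path: PathLike, profile) -> None:
    cols = [profile.q, profile.intensity]
    header = "q I"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(str(path), np.column_stack(cols), header=header)


def write_pofr(path: PathLike, pofr) -> None:
    np.savetxt(
        str(path),
        np.column_stack([pofr.r, pofr.p]),
        header=f"Dmax={pofr.dmax:.6g} Rg={pofr.rg:.6g}\nr p(r)",
    )


# ---------------------------------------------------------------------------
# SEC-SAXS frame matrices (CSV: one row per frame, columns = q grid)

def read_frame_matrix(path: PathLike):
    from .saxs import FrameMatrix

    df = pd.read_csv(path, index_col=0)
    q = np.array([float(c) for c in df.columns])
    return FrameMatrix(
        intensities=df.to_numpy(dtype=float),
        q=q,
        frame_index=df.index.to_numpy(),
    )


def write_frame_matrix(path: PathLike, frames) -> None:
    df = pd.DataFrame(
        frames.intensities,
        index=frames.frame_index,
        columns=[f"{qi:.6g}" for qi in frames.q],
    )
    df.index.name = "frame"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# MALS chromatograms (CSV: time, C, R@<angle_deg> ...)

def read_chromatogram(path: PathLike, optical_constant: Optional[float] = None):
    from .mals import Chromatogram

    df = pd.read_csv(path)
    angle_cols = [c for c in df.columns if c.startswith("R@")]
    if not angle_cols:
        raise ValueError("no light-scattering columns (expected headers like 'R@90')")
    angles = np.array([float(c[2:]) for c in angle_cols])
    meta_k = None
    if "K" in df.columns:
        meta_k = float(df["K"].iloc[0])
    k = optical_constant if optical_constant is not None else meta_k
    if k is None:
        raise ValueError("optical constant K not given and not stored in file")
    return Chromatogram(
        time=df["time"].to_numpy(dtype=float),
        concentration=df["C"].to_numpy(dtype=float),
        angles_deg=angles,
        rayleigh=df[angle_cols].to_numpy(dtype=float),
        optical_constant=k,
        buffer_region=_parse_buffer_region(df),
    )


def _parse_buffer_region(df: pd.DataFrame):
    if "buffer" in df.columns:
        mask = df["buffer"].to_numpy()
        return np.asarray(mask, dtype=bool)
    return None


def write_chromatogram(path: PathLike, chrom) -> None:
    data = {"time": chrom.time, "C": chrom.concentration}
    for j, ang in enumerate(chrom.angles_deg):
        data[f"R@{ang:g}"] = chrom.rayleigh[:, j]
    data["K"] = np.full(len(chrom.time), chrom.optical_constant)
    if chrom.buffer_region is not None:
        data["buffer"] = chrom.buffer_region.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PDB coordinate models (CA/CB pseudo-atoms, one chain per helix)

_CHAIN_IDS = "ABCDEFGHIJKLMNOP"


def write_bundle_pdb(path: PathLike, bundle: "BundleModel") -> None:
    import gemmi

    structure = gemmi.Structure()
    structure.name = "oligostate-model"
    model = gemmi.Model("1")
    for h_idx, helix in enumerate(bundle.helices):
        chain = gemmi.Chain(_CHAIN_IDS[h_idx])
        for i, aa in enumerate(helix.sequence):
            res = gemmi.Residue()
            res.name = _one_to_three(aa)
            res.seqid = gemmi.SeqId(helix.first_residue_number + i, " ")
            for name, xyz in (("CA", helix.ca[i]), ("CB", helix.cb[i])):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_coords_pdb(path: PathLike, atom_names: Sequence[str] = ("CA",)) -> np.ndarray:
    """Read selected atom coordinates (Angstrom) from a PDB file."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    wanted = set(atom_names)
    coords = []
    for model in structure:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.name in wanted:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break
    if not coords:
        raise ValueError(f"no {sorted(wanted)} atoms in {path}")
    return np.asarray(coords, dtype=float)


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _one_to_three(aa: str) -> str:
    return _THREE.get(aa.upper(), "UNK")
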