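"""Read/write conformer ensembles and convert between dihedrals and Cartesians.

Supported on-disk forms:

* multi-model PDB (one MODEL per conformer; relative energies carried as
  ``REMARK 250 ENERGY`` lines next to each MODEL record — a dialect of this
  package, ignored by other readers);
* multi-frame XYZ with atom-name labels (N, CA, C, O, CB, OXT) and a
  ``key=value`` comment line carrying ``peptide=`` and ``energy=``;
* CSV dihedral tables, one conformer per row, columns
  ``phi1,psi1,...,phiK,psiK[,energy]`` in degrees / kcal/mol.

Backbones are rebuilt from phi-psi strings by sequential internal-coordinate
placement (the natural extension reference frame, NeRF) with fixed ideal bond
lengths and angles and all peptide bonds trans (omega = 180).  The rebuilt
structures are *starting points* for external optimization, not final
geometries: termini are neutral (N-terminal NH2 implicit, C-terminal COOH as
O + OXT), no hydrogens are placed, and psi of residue 1 — which is pure gauge
for the unit string — is fixed at 180.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.SeqUtils import seq1, seq3

from .core import ConformerRecord, Ensemble, PhiPsiUnit, circular_diff, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneGeometry",
    "BackboneCoords",
    "build_backbone",
    "extract_units",
    "read_ensemble",
    "write_ensemble",
    "load_table1_fixture",
]


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal backbone geometry used by the NeRF builder.

    Lengths in Angstrom, angles in degrees.  Values are Engh–Huber-like
    protein backbone constants.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_ca_c_oxt: float = 117.0
    ca_cb: float = 1.530
    ang_c_ca_cb: float = 110.1
    improper_n_c_ca_cb: float = 122.6
    omega: float = 180.0

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n", "c_o", "ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be > 0")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca", "ang_ca_c_o",
                     "ang_ca_c_oxt", "ang_c_ca_cb"):
            if not 0 < getattr(self, name) < 180:
                raise ValueError(f"bond angle {name} must be in (0, 180)")


@dataclass
class BackboneCoords:
    """Cartesian backbone of one conformer.

    ``atoms`` maps ``(residue_index, atom_name)`` (1-based residues, PDB
    atom names) to xyz arrays in Angstrom, in build/file order.
    """

    sequence: str
    atoms: dict = field(default_factory=dict)

    def get(self, resi: int, name: str) -> np.ndarray:
        return self.atoms[(resi, name)]

    def has(self, resi: int, name: str) -> bool:
        return (resi, name) in self.atoms

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def _dihedral_deg(p1, p2, p3, p4) -> float:
    # float64 throughout: Bio.PDB's calc_dihedral stores vectors as float32,
    # which costs ~1e-6 degrees and breaks the round-trip tolerance
    b1 = np.subtract(p2, p1, dtype=float)
    b2 = np.subtract(p3, p2, dtype=float)
    b3 = np.subtract(p4, p3, dtype=float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    rad = -math.atan2(np.dot(m1, n2), np.dot(n1, n2))
    return wrap_angle(math.degrees(rad))


def _nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A, B, C so that |CD| = bond, angle(B,C,D) = angle
    and dihedral(A,B,C,D) = torsion (IUPAC sign convention)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    units,
    sequence: str,
    geometry: BackboneGeometry = BackboneGeometry(),
) -> BackboneCoords:
    """Build Cartesian backbone coordinates from a phi-psi unit string.

    ``units`` holds the (phi, psi) pair of residues 2..n, i.e.
    ``len(units) == len(sequence) - 1``.  CB atoms are placed with ideal
    tetrahedral geometry for non-glycine residues, and the C-terminus gets
    O and OXT, with psi of the last residue defined through OXT.
    """
    sequence = sequence.upper()
    units = [u if isinstance(u, PhiPsiUnit) else PhiPsiUnit(*u) for u in units]
    n = len(sequence)
    if len(units) != n - 1:
        raise ValueError(
            f"need {n - 1} units for {n} residues, got {len(units)}"
        )
    if n < 2:
        raise ValueError("at least 2 residues required")
    g = geometry

    phi = {i + 2: u.phi for i, u in enumerate(units)}  # residues 2..n
    psi = {i + 2: u.psi for i, u in enumerate(units)}
    psi[1] = 180.0  # gauge choice: does not enter any unit

    bb = BackboneCoords(sequence=sequence)
    # residue 1 seed triad in the xy-plane
    N1 = np.array([0.0, 0.0, 0.0])
    CA1 = np.array([g.n_ca, 0.0, 0.0])
    ang = math.radians(g.ang_n_ca_c)
    C1 = CA1 + g.ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])
    bb.atoms[(1, "N")] = N1
    bb.atoms[(1, "CA")] = CA1
    bb.atoms[(1, "C")] = C1
    for r in range(2, n + 1):
        Np = bb.get(r - 1, "N")
        CAp = bb.get(r - 1, "CA")
        Cp = bb.get(r - 1, "C")
        Nr = _nerf_place(Np, CAp, Cp, g.c_n, g.ang_ca_c_n, psi[r - 1])
        CAr = _nerf_place(CAp, Cp, Nr, g.n_ca, g.ang_c_n_ca, g.omega)
        Cr = _nerf_place(Cp, Nr, CAr, g.ca_c, g.ang_n_ca_c, phi[r])
        bb.atoms[(r, "N")] = Nr
        bb.atoms[(r, "CA")] = CAr
        bb.atoms[(r, "C")] = Cr
    # decorate: carbonyl O (trans to the downstream N), CB, terminal OXT
    for r in range(1, n + 1):
        Nr, CAr, Cr = bb.get(r, "N"), bb.get(r, "CA"), bb.get(r, "C")
        if r < n:
            bb.atoms[(r, "O")] = _nerf_place(
                Nr, CAr, Cr, g.c_o, g.ang_ca_c_o, wrap_angle(psi[r] + 180.0)
            )
        else:
            bb.atoms[(r, "O")] = _nerf_place(
                Nr, CAr, Cr, g.c_o, g.ang_ca_c_o, wrap_angle(psi[r] + 180.0)
            )
            bb.atoms[(r, "OXT")] = _nerf_place(
                Nr, CAr, Cr, g.c_o, g.ang_ca_c_oxt, psi[r]
            )
        if sequence[r - 1] != "G":
            bb.atoms[(r, "CB")] = _nerf_place(
                Nr, Cr, CAr, g.ca_cb, g.ang_c_ca_cb, g.improper_n_c_ca_cb
            )
    return bb


def extract_units(coords: BackboneCoords) -> list[PhiPsiUnit]:
    """Extract the phi-psi unit string (residues 2..n) from coordinates.

    phi(r) = dihedral C(r-1)-N(r)-CA(r)-C(r); psi(r) closes on N(r+1) for
    interior residues and on the terminal carboxyl oxygen for the last one
    (OXT directly if present, else O shifted by 180).
    """
    n = coords.n_residues
    if n < 2:
        raise ValueError("at least 2 residues required to define a unit")
    for r in range(1, n + 1):
        for name in ("N", "CA", "C"):
            if not coords.has(r, name):
                raise ValueError(f"missing backbone atom {name} of residue {r}")
    if not (coords.has(n, "OXT") or coords.has(n, "O")):
        raise ValueError(f"missing carbonyl oxygen of terminal residue {n}")
    units = []
    for r in range(2, n + 1):
        phi = _dihedral_deg(
            coords.get(r - 1, "C"), coords.get(r, "N"), coords.get(r, "CA"), coords.get(r, "C")
        )
        if r < n:
            x = coords.get(r + 1, "N")
            psi = _dihedral_deg(coords.get(r, "N"), coords.get(r, "CA"), coords.get(r, "C"), x)
        elif coords.has(n, "OXT"):
            psi = _dihedral_deg(
                coords.get(r, "N"), coords.get(r, "CA"), coords.get(r, "C"), coords.get(n, "OXT")
            )
        else:
            psi = wrap_angle(
                _dihedral_deg(
                    coords.get(r, "N"), coords.get(r, "CA"), coords.get(r, "C"), coords.get(n, "O")
                )
                + 180.0
            )
        units.append(PhiPsiUnit(phi, psi))
    return units


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_ENERGY_REMARK = "REMARK 250 ENERGY"


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix in ("xyz", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def _normalize_energies(records: list[ConformerRecord]) -> None:
    energies = [c.energy_rel for c in records if c.energy_rel is not None]
    if not energies:
        return
    e0 = min(energies)
    for c in records:
        if c.energy_rel is not None:
            c.energy_rel = c.energy_rel - e0


def read_ensemble(path, format: Optional[str] = None, peptide: Optional[str] = None,
                  energy_window: float = 10.0) -> Ensemble:
    """Read a conformer ensemble from PDB, XYZ or CSV.

    Energies are shifted so the ensemble minimum is 0 (they are consumed as
    relative kcal/mol everywhere downstream).  PDB models missing backbone
    atoms are rejected with a logged reason.  For CSV (which carries no
    sequence) ``peptide`` defaults to poly-glycine of the right length.
    """
    fmt = _infer_format(path, format)
    if fmt not in ("pdb", "xyz", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty file: {path}")
    if fmt == "pdb":
        ens = _read_pdb(path, text, peptide)
    elif fmt == "xyz":
        ens = _read_xyz(text, peptide)
    elif fmt == "csv":
        ens = _read_csv(path, peptide)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _normalize_energies(ens.conformers)
    ens.energy_window = energy_window
    if not ens.conformers:
        raise ValueError(f"no usable conformers in {path}")
    return ens


def _structure_to_backbone(model) -> BackboneCoords:
    residues = [r for r in next(iter(model)) if "CA" in r]
    seq = "".join(seq1(r.get_resname()) for r in residues)
    bb = BackboneCoords(sequence=seq)
    for i, res in enumerate(residues, start=1):
        for atom in res:
            name = atom.get_name()
            if name in ("N", "CA", "C", "O", "CB", "OXT"):
                bb.atoms[(i, name)] = np.asarray(atom.get_coord(), dtype=float)
    return bb


def _read_pdb(path, text: str, peptide: Optional[str]) -> Ensemble:
    # our dialect stores the per-model energy on a REMARK 250 line following
    # each MODEL record
    energies: dict[int, float] = {}
    order: list[int] = []
    current = None
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = int(line.split()[1])
            order.append(current)
        elif line.startswith(_ENERGY_REMARK) and current is not None:
            energies[current] = float(line.split()[-1])
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", _stdio.StringIO(text))
    records = []
    seq = None
    for model in structure:
        try:
            bb = _structure_to_backbone(model)
            units = extract_units(bb)
        except (ValueError, KeyError) as exc:
            logger.warning("rejecting model %s of %s: %s", model.id, path, exc)
            continue
        serial = model.serial_num if model.serial_num else model.id + 1
        records.append(
            ConformerRecord(
                units=units,
                energy_rel=energies.get(serial),
                coords=bb,
                id=f"model-{serial}",
            )
        )
        seq = bb.sequence
    if seq is None:
        raise ValueError(f"no model with a complete backbone in {path}")
    return Ensemble(peptide=peptide or seq, conformers=records)


def _read_xyz(text: str, peptide: Optional[str]) -> Ensemble:
    lines = text.splitlines()
    records = []
    seq_from_comment = None
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        natoms = int(lines[pos].strip())
        comment = lines[pos + 1]
        meta = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        energy = float(meta["energy"]) if "energy" in meta else None
        if "peptide" in meta:
            seq_from_comment = meta["peptide"].upper()
        atom_lines = lines[pos + 2 : pos + 2 + natoms]
        pos += 2 + natoms
        frame += 1
        bb = BackboneCoords(sequence="")
        resi = 0
        names = []
        for al in atom_lines:
            parts = al.split()
            name = parts[0].upper()
            xyz = np.array([float(p) for p in parts[1:4]])
            if name == "N":
                resi += 1
            bb.atoms[(resi, name)] = xyz
            names.append(name)
        seq = seq_from_comment or peptide
        if seq is None:
            # fall back: glycine unless a CB was seen for that residue
            seq = "".join(
                "A" if (i, "CB") in bb.atoms else "G" for i in range(1, resi + 1)
            )
        bb.sequence = seq.upper()
        units = extract_units(bb)
        records.append(
            ConformerRecord(units=units, energy_rel=energy, coords=bb, id=meta.get("id", f"frame-{frame}"))
        )
    if not records:
        raise ValueError("no frames found in XYZ input")
    return Ensemble(peptide=peptide or records[0].coords.sequence, conformers=records)


def _read_csv(path, peptide: Optional[str]) -> Ensemble:
    df = pd.read_csv(path)
    phis = sorted((c for c in df.columns if c.startswith("phi")), key=lambda c: int(c[3:]))
    psis = sorted((c for c in df.columns if c.startswith("psi")), key=lambda c: int(c[3:]))
    if not phis or len(phis) != len(psis):
        raise ValueError(f"CSV {path} must have matching phiK/psiK columns")
    records = []
    for i, row in df.iterrows():
        units = [PhiPsiUnit(row[p], row[s]) for p, s in zip(phis, psis)]
        energy = float(row["energy"]) if "energy" in df.columns and pd.notna(row["energy"]) else None
        rid = str(row["id"]) if "id" in df.columns else f"row-{i + 1}"
        records.append(ConformerRecord(units=units, energy_rel=energy, id=rid))
    if peptide is None:
        # a CSV carries no sequence; a file named after one (gfgg.csv) names it
        stem = Path(path).stem
        if len(stem) == len(phis) + 1 and all(c in "ACDEFGHIKLMNPQRSTVWY" for c in stem.upper()):
            peptide = stem.upper()
    pep = peptide or "G" * (len(phis) + 1)
    return Ensemble(peptide=pep, conformers=records)


def write_ensemble(ensemble: Ensemble, path, format: Optional[str] = None,
                   geometry: BackboneGeometry = BackboneGeometry()) -> None:
    """Write an ensemble as multi-model PDB, multi-frame XYZ or CSV.

    PDB/XYZ conformers lacking coordinates are rebuilt with
    :func:`build_backbone`.  Round trip preserves unit tables and relative
    energies.
    """
    if not ensemble.conformers:
        raise ValueError("refusing to write an empty ensemble")
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "csv":
        _write_csv(ensemble, path)
    elif fmt == "xyz":
        _write_xyz(ensemble, path, geometry)
    elif fmt == "pdb":
        _write_pdb(ensemble, path, geometry)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _conformer_coords(ensemble: Ensemble, c: ConformerRecord,
                      geometry: BackboneGeometry) -> BackboneCoords:
    if isinstance(c.coords, BackboneCoords):
        return c.coords
    return build_backbone(c.units, ensemble.peptide, geometry)


def _write_csv(ensemble: Ensemble, path: Path) -> None:
    k = ensemble.n_units
    cols = []
    for i in range(1, k + 1):
        cols += [f"phi{i}", f"psi{i}"]
    rows = []
    for c in ensemble.conformers:
        row = list(np.round(c.unit_array().ravel(), 6))
        row.append("" if c.energy_rel is None else round(c.energy_rel, 6))
        rows.append(row)
    pd.DataFrame(rows, columns=cols + ["energy"]).to_csv(path, index=False)


def _write_xyz(ensemble: Ensemble, path: Path, geometry: BackboneGeometry) -> None:
    out = []
    for c in ensemble.conformers:
        bb = _conformer_coords(ensemble, c, geometry)
        keys = sorted(bb.atoms, key=lambda k: (k[0],
                      ["N", "CA", "C", "O", "OXT", "CB"].index(k[1])))
        out.append(str(len(keys)))
        comment = f"peptide={bb.sequence}"
        if c.energy_rel is not None:
            comment += f" energy={c.energy_rel:.6f}"
        if c.id:
            comment += f" id={c.id}"
        out.append(comment)
        for key in keys:
            x, y, z = bb.atoms[key]
            out.append(f"{key[1]:<4s} {x:12.6f} {y:12.6f} {z:12.6f}")
    path.write_text("\n".join(out) + "\n")


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "OXT": "O", "CB": "C"}


def _write_pdb(ensemble: Ensemble, path: Path, geometry: BackboneGeometry) -> None:
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("ens")
    energies = []
    for m, c in enumerate(ensemble.conformers):
        bb = _conformer_coords(ensemble, c, geometry)
        builder.init_model(m, m + 1)
        builder.init_chain("A")
        builder.init_seg("    ")
        for resi in range(1, bb.n_residues + 1):
            resname = seq3(bb.sequence[resi - 1]).upper()
            builder.init_residue(resname, " ", resi, " ")
            for name in ("N", "CA", "C", "O", "OXT", "CB"):
                if bb.has(resi, name):
                    builder.init_atom(
                        name, bb.get(resi, name), 0.0, 1.0, " ",
                        name.center(4) if len(name) < 4 else name,
                        element=_ELEMENTS[name],
                    )
        energies.append(c.energy_rel)
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    buf = _stdio.StringIO()
    pdbio.save(buf)
    raw = buf.getvalue().splitlines()
    if not any(l.startswith("MODEL") for l in raw):
        # Biopython omits MODEL/ENDMDL for a single model; restore them so
        # every ensemble file is uniformly multi-model
        body = [l for l in raw if not l.startswith("END")]
        raw = ["MODEL        1"] + body + ["ENDMDL", "END"]
    lines = []
    model_idx = 0
    for line in raw:
        lines.append(line)
        if line.startswith("MODEL"):
            e = energies[model_idx]
            if e is not None:
                lines.append(f"{_ENERGY_REMARK} {e:12.6f}")
            model_idx += 1
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# packaged pairwise error-rate table
# ---------------------------------------------------------------------------

_TABLE1_SHA256 = "7115ef1fde632f2cd9334240f22e6d3243414e1855d0c57958718f6938c99def"


def load_table1_fixture():
    """Load the packaged 19x19 pairwise error-rate matrix.

    The matrix holds the published pairwise random-forest misclassification
    rates between the phi-psi units of the tri-/tetrapeptide learning set
    (gvgg1..3, gtgg1..3, gfgg1..3, gtg1..2, gvg1..2, vgg1..2, mgg1..2,
    fgg1..2).  It is symmetric with an undefined (NaN) diagonal.  The file
    content is checksummed to guard against accidental edits.
    """
    from .words import ErrorRateMatrix

    ref = resources.files("pepgram").joinpath("data/table1_error_rates.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError(
            "packaged error-rate table failed its checksum "
            f"(got {digest[:12]}...); refusing to use a modified fixture"
        )
    df = pd.read_csv(_stdio.BytesIO(raw), index_col=0)
    values = df.to_numpy(dtype=float)
    return ErrorRateMatrix(labels=list(df.columns), values=values)
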