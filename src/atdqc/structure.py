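"""Macromolecular structure handling and geometric analysis.

Covers everything the cross-subunit Gly-Pro comparison needs: reading
PDB/mmCIF coordinates, backbone torsions (phi/psi/omega), cis/trans
peptide-bond calls, locating the Gly-Pro motif and the active-site pocket
it inserts into, carbonyl-orientation labels, iterative Calpha
superposition, B-factor rigidity, and side-chain/main-chain contacts.

The scientific background: D-aminoacyl-tRNA deacylase (DTD) is a homodimer
whose active sites sit at the dimer interface; each site receives a
Gly-cisPro dipeptide from the *other* protomer, and the cis conformation
points both carbonyl oxygens into the pocket ("outward parallel"),
sterically rejecting L-amino acids. Its Animalia-specific paralog ATD
carries the same cross-subunit dipeptide in *trans*, flipping psi by
~180 degrees and the carbonyls toward the protein core ("inward
parallel"), which relaxes the chiral filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .family import DEFAULT_PATTERNS, MotifPattern, _mismatches
from .geometry import (
    SuperpositionReport,
    dihedral,
    kabsch_superpose,
)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueRef",
    "TorsionRecord",
    "PeptideBondCall",
    "MotifSite",
    "OrientationReport",
    "RigidityReport",
    "ContactRecord",
    "FormatError",
    "EmptyStructureError",
    "AlignmentFailureError",
    "OrientationUndefinedError",
    "read_structure",
    "write_pdb",
    "chain_sequence",
    "backbone_torsions",
    "classify_peptide_bond",
    "find_glypro_motifs",
    "carbonyl_orientation",
    "align_and_superpose",
    "motif_rigidity",
    "motif_contacts",
    "torsion_table",
]

PEPTIDE_BOND_MAX = 2.5  # Angstrom C(i-1)-N(i) distance beyond which the chain is broken
BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class FormatError(ValueError):
    """Unreadable or wrongly declared coordinate file."""


class EmptyStructureError(ValueError):
    """A coordinate file with no polymer (amino-acid) content."""


class AlignmentFailureError(ValueError):
    """No alignable residues between two structures."""


class OrientationUndefinedError(ValueError):
    """Carbonyl orientation requested with missing C or O atoms."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")


@dataclass
class Residue:
    name: str
    seq_id: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False  # waters and non-polymer heteroatoms

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def polymer(self) -> list[Residue]:
        return [r for r in self.residues if not r.het]


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer]

    @property
    def n_polymer_residues(self) -> int:
        return sum(len(c.polymer) for c in self.chains)


@dataclass(frozen=True)
class ResidueRef:
    chain: str
    seq_id: int
    icode: str
    name: str


def _ref(chain_id: str, res: Residue) -> ResidueRef:
    return ResidueRef(chain_id, res.seq_id, res.icode, res.name)


@dataclass(frozen=True)
class TorsionRecord:
    chain: str
    residue: ResidueRef
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float]


@dataclass(frozen=True)
class PeptideBondCall:
    preceding_residue: ResidueRef
    following_residue: ResidueRef
    omega: float
    conformation: str  # "cis" | "trans"


@dataclass
class MotifSite:
    donor_chain: str
    acceptor_chain: str
    gly_ref: ResidueRef
    pro_ref: ResidueRef
    cross_subunit: bool
    bond_call: Optional[PeptideBondCall]
    pocket_centroid: Optional[np.ndarray] = None


@dataclass(frozen=True)
class OrientationReport:
    parallelism_angle: float
    mean_projection: float
    label: str  # "outward-parallel" | "inward-parallel" | "non-parallel"


@dataclass(frozen=True)
class RigidityReport:
    motif_mean_b: float
    chain_mean_b: float
    chain_sd_b: float
    motif_z: float


@dataclass(frozen=True)
class ContactRecord:
    donor: tuple[ResidueRef, str]  # side-chain atom of the probe residue
    acceptor: tuple[ResidueRef, str]  # backbone atom of the motif
    distance: float
    same_chain: bool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Waters and heteroatoms are kept but flagged (``Residue.het``); for
    alternate conformations only the highest-occupancy altloc of each atom
    is retained (ties broken by altloc letter). Only the first model of a
    multi-model file is used.
    """
    import gemmi

    path = str(path)
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise ValueError(f"format must be one of {sorted(fmt_map)}")
    try:
        st = gemmi.read_structure(path, format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read {path!r} as {format}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path!r} contains no models")
    st.setup_entities()
    model = st[0]
    out = Structure(id=st.name or Path(path).stem)
    for ch in model:
        chain = Chain(id=ch.name)
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = bool(info and info.is_amino_acid())
            r = Residue(
                name=res.name,
                seq_id=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                het=not is_aa,
            )
            best: dict[str, "gemmi.Atom"] = {}
            for at in res:
                prev = best.get(at.name)
                key = (at.occ, -ord(at.altloc or "A"))
                if prev is None or key > (prev.occ, -ord(prev.altloc or "A")):
                    best[at.name] = at
            for at in best.values():
                r.atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        bfactor=at.b_iso,
                        occupancy=at.occ,
                        altloc=(at.altloc or "").strip(),
                    )
                )
            chain.residues.append(r)
        if chain.residues:
            out.chains.append(chain)
    if out.n_polymer_residues == 0:
        raise EmptyStructureError(f"{path!r} has no polymer (amino-acid) residues")
    return out


def write_pdb(structure: Structure) -> str:
    """Serialize a structure to minimal PDB format text."""
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            record = "HETATM" if res.het else "ATOM  "
            for at in res.atoms:
                name = at.name if len(at.name) == 4 else f" {at.name:<3s}"
                x, y, z = at.coords
                lines.append(
                    f"{record}{serial:5d} {name}{'':1s}{res.name:>3s} "
                    f"{chain.id[:1]}{res.seq_id:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{at.occupancy:6.2f}{at.bfactor:6.2f}"
                    f"          {at.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence of the polymer residues of a chain."""
    return "".join(THREE_TO_ONE.get(r.name, "X") for r in chain.polymer)


# ---------------------------------------------------------------------------
# Torsions and cis/trans calls
# ---------------------------------------------------------------------------

def _connected(prev: Residue, res: Residue) -> bool:
    c, n = prev.atom("C"), res.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.coords - n.coords)) <= PEPTIDE_BOND_MAX


def _safe_dihedral(*atoms) -> Optional[float]:
    if any(a is None for a in atoms):
        return None
    try:
        return dihedral(*(a.coords for a in atoms))
    except ValueError:
        return None


def backbone_torsions(structure: Structure, chain_id: str) -> list[TorsionRecord]:
    """Phi/psi/omega for every polymer residue of a chain.

    omega(i) is the torsion of the peptide bond *preceding* residue i,
    computed from CA(i-1), C(i-1), N(i), CA(i). Chain breaks (C-N distance
    above 2.5 A) and missing backbone atoms yield None for the affected
    angles rather than an error.
    """
    chain = structure.chain(chain_id)
    residues = chain.polymer
    out = []
    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        prev_ok = prev is not None and _connected(prev, res)
        next_ok = nxt is not None and _connected(res, nxt)
        phi = (
            _safe_dihedral(prev.atom("C"), res.atom("N"), res.atom("CA"), res.atom("C"))
            if prev_ok
            else None
        )
        psi = (
            _safe_dihedral(res.atom("N"), res.atom("CA"), res.atom("C"), nxt.atom("N"))
            if next_ok
            else None
        )
        omega = (
            _safe_dihedral(prev.atom("CA"), prev.atom("C"), res.atom("N"), res.atom("CA"))
            if prev_ok
            else None
        )
        out.append(TorsionRecord(chain_id, _ref(chain_id, res), phi, psi, omega))
    return out


def classify_peptide_bond(omega: Optional[float]) -> str:
    """cis/trans call from the omega torsion: cis iff omega in (-90, +90]."""
    if omega is None or not math.isfinite(omega):
        raise ValueError("omega undefined: cannot classify peptide bond")
    return "cis" if -90.0 < omega <= 90.0 else "trans"


# ---------------------------------------------------------------------------
# Gly-Pro motif location and orientation
# ---------------------------------------------------------------------------

def _motif1_patterns(patterns: Sequence[MotifPattern]) -> list[MotifPattern]:
    m1 = [p for p in patterns if p.motif_index == 1]
    return m1 or list(patterns)


def _pocket_match(chain: Chain, patterns: Sequence[MotifPattern]):
    """Best motif match on a chain -> (residues, mismatches) or None."""
    seq = chain_sequence(chain)
    poly = chain.polymer
    best = None
    for pat in patterns:
        m = len(pat.pattern)
        for i in range(len(seq) - m + 1):
            mm = _mismatches(pat.pattern, seq[i : i + m])
            if mm <= pat.max_mismatch and (best is None or mm < best[1]):
                best = (poly[i : i + m], mm)
    return best


def _pocket_centroid(chain: Chain, patterns: Sequence[MotifPattern]) -> Optional[np.ndarray]:
    match = _pocket_match(chain, patterns)
    if match is None:
        return None
    cas = [r.atom("CA").coords for r in match[0] if r.atom("CA") is not None]
    if not cas:
        return None
    return np.mean(cas, axis=0)


def find_glypro_motifs(
    structure: Structure,
    pocket_patterns: Sequence[MotifPattern] | None = None,
) -> list[MotifSite]:
    """Locate every Gly-Pro dipeptide and assign it to an active-site pocket.

    The pocket of each chain is the best match of the family motif-1
    signature (PQATL for ATD, SQFTL for DTD) on that chain; a Gly-Pro is
    assigned to the chain whose pocket Calpha centroid is nearest its own
    backbone centroid. ``cross_subunit`` is true when donor and acceptor
    chains differ — the hallmark of the DTD-fold dimeric active site.
    """
    if not structure.chains:
        raise ValueError("structure has no chains")
    patterns = _motif1_patterns(pocket_patterns or DEFAULT_PATTERNS)
    pockets = {
        c.id: cen
        for c in structure.polymer_chains
        if (cen := _pocket_centroid(c, patterns)) is not None
    }
    sites: list[MotifSite] = []
    for chain in structure.polymer_chains:
        poly = chain.polymer
        for i in range(len(poly) - 1):
            gly, pro = poly[i], poly[i + 1]
            if gly.name != "GLY" or pro.name != "PRO":
                continue
            bb = [
                a.coords
                for r in (gly, pro)
                for a in r.atoms
                if a.name in BACKBONE_ATOMS
            ]
            centroid = np.mean(bb, axis=0) if bb else None
            acceptor = chain.id
            pocket_cen = None
            if pockets and centroid is not None:
                acceptor = min(
                    pockets, key=lambda cid: float(np.linalg.norm(pockets[cid] - centroid))
                )
                pocket_cen = pockets[acceptor]
            omega = (
                _safe_dihedral(gly.atom("CA"), gly.atom("C"), pro.atom("N"), pro.atom("CA"))
                if _connected(gly, pro)
                else None
            )
            call = None
            if omega is not None:
                call = PeptideBondCall(
                    _ref(chain.id, gly),
                    _ref(chain.id, pro),
                    omega,
                    classify_peptide_bond(omega),
                )
            sites.append(
                MotifSite(
                    donor_chain=chain.id,
                    acceptor_chain=acceptor,
                    gly_ref=_ref(chain.id, gly),
                    pro_ref=_ref(chain.id, pro),
                    cross_subunit=acceptor != chain.id,
                    bond_call=call,
                    pocket_centroid=pocket_cen,
                )
            )
    return sites


def _find_residue(structure: Structure, ref: ResidueRef) -> Residue:
    for res in structure.chain(ref.chain).residues:
        if res.seq_id == ref.seq_id and res.icode == ref.icode:
            return res
    raise KeyError(f"residue {ref} not found")


def carbonyl_orientation(
    site: MotifSite,
    structure: Structure,
    parallel_threshold: float = 45.0,
) -> OrientationReport:
    """Label the Gly-Pro carbonyl orientation relative to the pocket.

    The pocket axis runs from the midpoint of the two carbonyl carbons to
    the Calpha centroid of the acceptor chain's motif-1 match. Both C=O
    unit vectors are projected on it; "outward-parallel" means the oxygens
    point into the pocket (mean projection > 0, the DTD chiral filter),
    "inward-parallel" means they point away (the ATD arrangement), and
    angles above ``parallel_threshold`` between the two C=O vectors are
    "non-parallel".
    """
    gly = _find_residue(structure, site.gly_ref)
    pro = _find_residue(structure, site.pro_ref)
    atoms = [gly.atom("C"), gly.atom("O"), pro.atom("C"), pro.atom("O")]
    if any(a is None for a in atoms):
        raise OrientationUndefinedError("missing carbonyl C/O atoms on the motif")
    cg, og, cp, op = (a.coords for a in atoms)
    pocket = site.pocket_centroid
    if pocket is None:
        pocket = _pocket_centroid(
            structure.chain(site.acceptor_chain), _motif1_patterns(DEFAULT_PATTERNS)
        )
    if pocket is None:
        raise OrientationUndefinedError("acceptor pocket unresolvable")
    v1 = (og - cg) / np.linalg.norm(og - cg)
    v2 = (op - cp) / np.linalg.norm(op - cp)
    mid = 0.5 * (cg + cp)
    axis = pocket - mid
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise OrientationUndefinedError("pocket centroid coincides with the motif")
    axis = axis / norm
    ang = float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))
    proj = float(0.5 * (np.dot(v1, axis) + np.dot(v2, axis)))
    if ang > parallel_threshold:
        label = "non-parallel"
    else:
        label = "outward-parallel" if proj > 0 else "inward-parallel"
    return OrientationReport(parallelism_angle=ang, mean_projection=proj, label=label)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _chain_pairing(a: Structure, b: Structure):
    """Greedy optimal chain matching by global alignment score."""
    from .family import _global_aligner

    aligner = _global_aligner()
    scored = []
    for ca in a.polymer_chains:
        sa = chain_sequence(ca).replace("X", "A")
        for cb in b.polymer_chains:
            sb = chain_sequence(cb).replace("X", "A")
            if not sa or not sb:
                continue
            scored.append((float(aligner.score(sa, sb)), ca.id, cb.id))
    scored.sort(reverse=True)
    used_a, used_b, pairs = set(), set(), []
    for _, ia, ib in scored:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib))
    return pairs


def _aligned_ca_pairs(a: Structure, b: Structure):
    from .family import _global_aligner

    aligner = _global_aligner()
    xs, ys = [], []
    for ca_id, cb_id in _chain_pairing(a, b):
        ra = a.chain(ca_id).polymer
        rb = b.chain(cb_id).polymer
        sa = chain_sequence(a.chain(ca_id)).replace("X", "A")
        sb = chain_sequence(b.chain(cb_id)).replace("X", "A")
        aln = aligner.align(sa, sb)[0]
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            for i, j in zip(range(a0, a1), range(b0, b1)):
                atom_a, atom_b = ra[i].atom("CA"), rb[j].atom("CA")
                if atom_a is not None and atom_b is not None:
                    xs.append(atom_a.coords)
                    ys.append(atom_b.coords)
    return np.array(xs), np.array(ys)


def align_and_superpose(
    a: Structure,
    b: Structure,
    prune_cutoff: Optional[float] = 3.5,
) -> SuperpositionReport:
    """Sequence-guided iterative Calpha superposition of ``b`` onto ``a``.

    Calpha pairs come from global sequence alignment (chains matched by
    best alignment score first); the superposition is then iterated,
    discarding pairs deviating by more than ``prune_cutoff`` A, until the
    pair set is stable. ``prune_cutoff=None`` disables pruning. The final
    r.m.s.d. and retained pair count mirror how distant homologs such as
    the ATD/DTD pair are compared (reported values in the literature are
    around 1.7 A over ~140 Calpha for that pair).
    """
    A, B = _aligned_ca_pairs(a, b)
    if len(A) == 0:
        raise AlignmentFailureError("no alignable residues with Calpha atoms")
    n_iter = 0
    while True:
        rep = kabsch_superpose(A, B)
        n_iter += 1
        if prune_cutoff is None:
            break
        dev = np.linalg.norm(A - rep.apply(B), axis=1)
        keep = dev <= prune_cutoff
        if keep.all() or keep.sum() < 3:
            break
        A, B = A[keep], B[keep]
    return SuperpositionReport(
        rotation=rep.rotation,
        translation=rep.translation,
        rmsd=rep.rmsd,
        n_pairs=rep.n_pairs,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Rigidity and contacts
# ---------------------------------------------------------------------------

def motif_rigidity(structure: Structure, site: MotifSite) -> RigidityReport:
    """B-factor z-score of the Gly-Pro motif against its donor chain.

    Negative ``motif_z`` means the motif backbone is more ordered (rigid)
    than the chain average — the case for the Gly-Pro motif in both
    deacylase families.
    """
    gly = _find_residue(structure, site.gly_ref)
    pro = _find_residue(structure, site.pro_ref)
    motif_b = [
        a.bfactor for r in (gly, pro) for a in r.atoms if a.name in BACKBONE_ATOMS
    ]
    chain_b = [
        a.bfactor
        for r in structure.chain(site.donor_chain).polymer
        for a in r.atoms
        if a.name in BACKBONE_ATOMS
    ]
    if not motif_b or not chain_b:
        raise ValueError("no backbone B-factors available")
    if max(chain_b) == 0.0:
        raise ValueError("all-zero B-factors: rigidity undefined")
    motif_mean = float(np.mean(motif_b))
    chain_mean = float(np.mean(chain_b))
    chain_sd = float(np.std(chain_b))
    if chain_sd > 0:
        z = (motif_mean - chain_mean) / chain_sd
    elif motif_mean == chain_mean:
        z = 0.0
    else:
        raise ValueError("zero chain B-factor variance with differing motif mean")
    return RigidityReport(motif_mean, chain_mean, chain_sd, float(z))


def motif_contacts(
    structure: Structure,
    probe_residue: ResidueRef,
    site: MotifSite,
    cutoff: float = 3.5,
) -> list[ContactRecord]:
    """Side-chain atoms of ``probe_residue`` within ``cutoff`` of the motif
    backbone (N/CA/C/O of the Gly and Pro).

    Used for the conserved-arginine interaction: in DTD an Arg of the same
    monomer clamps the Gly-cisPro backbone; in ATD the migrated Arg acts
    from the dimeric counterpart.
    """
    probe = _find_residue(structure, probe_residue)
    gly = _find_residue(structure, site.gly_ref)
    pro = _find_residue(structure, site.pro_ref)
    side = [
        a
        for a in probe.atoms
        if a.name not in BACKBONE_ATOMS + ("OXT",) and a.element != "H"
    ]
    out = []
    same = probe_residue.chain == site.donor_chain
    for r, rref in ((gly, site.gly_ref), (pro, site.pro_ref)):
        for bb in r.atoms:
            if bb.name not in BACKBONE_ATOMS:
                continue
            for sc in side:
                d = float(np.linalg.norm(sc.coords - bb.coords))
                if d <= cutoff:
                    out.append(
                        ContactRecord(
                            donor=(probe_residue, sc.name),
                            acceptor=(rref, bb.name),
                            distance=d,
                            same_chain=same,
                        )
                    )
    return sorted(out, key=lambda c: c.distance)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def torsion_table(structure: Structure):
    """Per-residue torsion table (one row per polymer residue) as a
    pandas DataFrame: chain, seq_id, name, phi, psi, omega, conformation
    of the preceding peptide bond."""
    import pandas as pd

    rows = []
    for chain in structure.polymer_chains:
        for rec in backbone_torsions(structure, chain.id):
            conf = None
            if rec.omega is not None:
                conf = classify_peptide_bond(rec.omega)
            rows.append(
                {
                    "chain": rec.chain,
                    "seq_id": rec.residue.seq_id,
                    "name": rec.residue.name,
                    "phi": rec.phi,
                    "psi": rec.psi,
                    "omega": rec.omega,
                    "conformation": conf,
                }
            )
    return pd.DataFrame(rows)
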