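"""Synthetic-data generators for every analysis stage.

Each generator is deterministic given its seed and draws from its own
independent random stream, so adding a generator (or reordering calls)
never perturbs the output of another. The generated objects satisfy the
invariants of the types they feed:

* :func:`build_peptide` — internal-coordinate (NeRF) chain building from
  ideal bond lengths/angles; recomputing torsions returns the requested
  values to well below 1e-6 degrees.
* :func:`build_deacylase_dimer` — a C2-symmetric homodimer whose Gly-Pro
  dipeptide from one protomer sits in the partner's signature-motif
  pocket, with the cis (DTD-like) or trans (ATD-like) conformation and
  the ~180-degree psi flip between the two families.
* :func:`gen_family_sequences` — random-background sequences with family
  signature motifs embedded at fixed offsets.
* :func:`gen_trna_set` — canonical acceptor-stem tRNA genes with a
  controlled per-isotype G4:U69 probability and Gaussian scores.
* :func:`gen_decay_series` / :func:`gen_dose_ladder` — exponential decay
  time courses with Gaussian noise; the dose ladder scales k linearly
  with enzyme concentration, optionally attenuated by an EF-Tu
  protection factor.
* :func:`gen_presence_table` — per-organism enrichment rows plus an ATD
  presence map with a controlled concordance.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .family import AMINO_ACIDS, ATD_REFERENCE, DTD_REFERENCE, ProteinRecord
from .kinetics import TimeCourse
from .structure import (
    Atom,
    Chain,
    Residue,
    Structure,
    find_glypro_motifs,
)
from .wobble import EnrichmentRow, TRNAGene

__all__ = [
    "IDEAL_GEOMETRY",
    "nerf_place",
    "build_peptide",
    "build_deacylase_dimer",
    "gen_family_sequences",
    "gen_trna_set",
    "gen_decay_series",
    "gen_dose_ladder",
    "gen_presence_table",
]

# Per-generator stream ids keep the random streams independent.
_STREAMS = {
    "peptide": 101,
    "sequences": 102,
    "trnas": 103,
    "decay": 104,
    "presence": 105,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# Peptide builder (internal coordinates)
# ---------------------------------------------------------------------------

#: Ideal backbone geometry (Engh-Huber-like standard values). Exact values
#: only matter for round-trip stability, not for any biological claim.
IDEAL_GEOMETRY = {
    ("bond", "N-CA"): 1.458,
    ("bond", "CA-C"): 1.525,
    ("bond", "C-N"): 1.329,
    ("bond", "C-O"): 1.231,
    ("bond", "CA-CB"): 1.521,
    ("angle", "C-N-CA"): 121.7,
    ("angle", "N-CA-C"): 111.2,
    ("angle", "CA-C-N"): 116.2,
    ("angle", "CA-C-O"): 120.8,
    ("angle", "C-CA-CB"): 110.6,
    ("torsion", "N-C-CA-CB"): -122.6,  # L-chirality improper
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three reference atoms by internal coordinates.

    d is bonded to c with the given bond length, forms angle b-c-d, and
    torsion a-b-c-d (natural extension reference frame).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    sequence: str,
    dihedrals: Sequence[tuple[float, float, float]],
    chain_id: str = "A",
    bfactors: Optional[Sequence[float]] = None,
    start_seq_id: int = 1,
) -> Structure:
    """Build a peptide chain from a per-residue (phi, psi, omega) spec.

    ``sequence`` is one-letter; residue i's omega is the torsion of the
    peptide bond preceding it (the first residue's omega is unused, as is
    the first phi and the last psi — matching where those angles are
    defined). Backbone atoms N, CA, C, O are built; non-Gly residues also
    get a CB. Recomputing torsions from the built coordinates returns the
    spec to well below 1e-6 degrees.
    """
    if len(sequence) != len(dihedrals):
        raise ValueError("dihedral spec length must equal sequence length")
    if bfactors is None:
        bfactors = [20.0] * len(sequence)
    g = IDEAL_GEOMETRY
    chain = Chain(id=chain_id)
    # seed frame for residue 1
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([g[("bond", "N-CA")], 0.0, 0.0])
    ang = math.radians(g[("angle", "N-CA-C")])
    c = ca + g[("bond", "CA-C")] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    prev = None  # (N, CA, C) of previous residue
    for i, (aa, (phi, psi, omega)) in enumerate(zip(sequence, dihedrals)):
        if prev is not None:
            pn, pca, pc = prev
            n = nerf_place(pn, pca, pc, g[("bond", "C-N")], g[("angle", "CA-C-N")], prev_psi)
            ca = nerf_place(pca, pc, n, g[("bond", "N-CA")], g[("angle", "C-N-CA")], omega)
            c = nerf_place(pc, n, ca, g[("bond", "CA-C")], g[("angle", "N-CA-C")], phi)
        o = nerf_place(n, ca, c, g[("bond", "C-O")], g[("angle", "CA-C-O")], psi + 180.0)
        res = Residue(name=ONE_TO_THREE.get(aa, "ALA"), seq_id=start_seq_id + i)
        b = float(bfactors[i])
        res.atoms.append(Atom("N", "N", n, bfactor=b))
        res.atoms.append(Atom("CA", "C", ca, bfactor=b))
        res.atoms.append(Atom("C", "C", c, bfactor=b))
        res.atoms.append(Atom("O", "O", o, bfactor=b))
        if aa != "G":
            cb = nerf_place(
                n, c, ca,
                g[("bond", "CA-CB")],
                g[("angle", "C-CA-CB")],
                g[("torsion", "N-C-CA-CB")],
            )
            res.atoms.append(Atom("CB", "C", cb, bfactor=b))
        chain.residues.append(res)
        prev = (n, ca, c)
        prev_psi = psi
    return Structure(id=f"synthetic_{chain_id}", chains=[chain])


_HELIX = (-57.0, -47.0, 180.0)

# Gly-Pro motif torsions of the two synthetic folds: psi flips by
# ~180 degrees at both residues between families and the Pro omega
# switches between trans (ATD) and cis (DTD). phi_pro is chosen per
# family to keep the two carbonyls as parallel as ideal geometry allows
# (a cis peptide with ideal bond angles cannot bring them below ~51
# degrees, so the cis pair sits just above the 45-degree default
# parallel threshold; see docs/methods.md).
_MOTIF_TORSIONS = {
    "ATD": {"psi_gly": -30.0, "phi_pro": -75.0, "psi_pro": -35.0, "omega_pro": 180.0},
    "DTD": {"psi_gly": 150.0, "phi_pro": 16.0, "psi_pro": 165.0, "omega_pro": 0.0},
}

# 0-based Gly index within each family's reference sequence (inside motif 2)
_GLY_INDEX = {"ATD": 102, "DTD": 82}


def _c2_transform(p: np.ndarray, q: np.ndarray):
    """A two-fold rotation exchanging points p and q."""
    v = q - p
    w = np.array([0.0, 0.0, 1.0])
    if np.linalg.norm(np.cross(v, w)) < 1e-6:
        w = np.array([0.0, 1.0, 0.0])
    axis = np.cross(v, w)
    axis /= np.linalg.norm(axis)
    origin = 0.5 * (p + q)
    rot = 2.0 * np.outer(axis, axis) - np.eye(3)  # 180-degree rotation
    return rot, origin


def build_deacylase_dimer(
    family: str = "ATD",
    seed: int = 0,
    noise_sd: float = 0.0,
    sequence: Optional[str] = None,
    motif_bfactor: float = 12.0,
    baseline_bfactor: float = 30.0,
) -> Structure:
    """A synthetic C2 homodimer with a cross-subunit Gly-Pro motif.

    Each protomer is the family's synthetic reference sequence built as a
    regular helix, with the motif-2 Gly-Pro torsions set to the family
    conformation (trans with "inward"-flipped psi for ATD, cis for DTD).
    The second protomer is the two-fold image chosen so each chain's
    Gly-Pro centroid coincides with the partner's motif-1 pocket centroid
    — the geometry :func:`atdqc.structure.find_glypro_motifs` resolves as
    cross-subunit. Gaussian coordinate noise (``noise_sd``, A) is applied
    per chain; the motif backbone gets a low B-factor against a modulated
    chain baseline so rigidity z-scores are negative, as observed for the
    real motif.
    """
    family = family.upper()
    if family not in _MOTIF_TORSIONS:
        raise ValueError("family must be 'ATD' or 'DTD'")
    if sequence is None:
        sequence = (ATD_REFERENCE if family == "ATD" else DTD_REFERENCE).sequence
    gi = sequence.find("GP", max(0, _GLY_INDEX[family] - 2))
    if gi < 0:
        gi = sequence.find("GP")
    if gi < 0:
        raise ValueError("sequence has no Gly-Pro dipeptide")
    tor = _MOTIF_TORSIONS[family]
    dihedrals = [list(_HELIX) for _ in sequence]
    dihedrals[gi][1] = tor["psi_gly"]
    dihedrals[gi + 1][0] = tor["phi_pro"]
    dihedrals[gi + 1][1] = tor["psi_pro"]
    dihedrals[gi + 1][2] = tor["omega_pro"]
    rng = _rng(seed, "peptide")
    bf = baseline_bfactor + 6.0 * np.sin(np.arange(len(sequence)) / 7.0)
    bf[gi] = bf[gi + 1] = motif_bfactor
    mono = build_peptide(sequence, [tuple(d) for d in dihedrals], chain_id="A", bfactors=bf)
    chain_a = mono.chains[0]

    from .family import DEFAULT_PATTERNS
    from .structure import _motif1_patterns, _pocket_centroid

    pocket = _pocket_centroid(chain_a, _motif1_patterns(DEFAULT_PATTERNS))
    gly, pro = chain_a.polymer[gi], chain_a.polymer[gi + 1]
    bb = [a.coords for r in (gly, pro) for a in r.atoms if a.name in ("N", "CA", "C", "O")]
    gp_centroid = np.mean(bb, axis=0)
    # The partner pocket sits a few A off the motif, on the side the
    # carbonyls face in the cis (DTD) fold and opposite it in the trans
    # (ATD) fold — carbonyls into the pocket vs away from it.
    vs = []
    for r in (gly, pro):
        v = r.atom("O").coords - r.atom("C").coords
        vs.append(v / np.linalg.norm(v))
    vmean = np.mean(vs, axis=0)
    vmean /= np.linalg.norm(vmean)
    pocket_target = gp_centroid + (7.0 if family == "DTD" else -7.0) * vmean
    rot, origin = _c2_transform(pocket, pocket_target)

    chain_b = Chain(id="B")
    for res in chain_a.residues:
        r2 = Residue(name=res.name, seq_id=res.seq_id)
        for at in res.atoms:
            r2.atoms.append(
                Atom(
                    at.name,
                    at.element,
                    rot @ (at.coords - origin) + origin,
                    bfactor=at.bfactor,
                )
            )
        chain_b.residues.append(r2)
    st = Structure(id=f"synthetic_{family}_dimer", chains=[chain_a, chain_b])
    if noise_sd > 0:
        for ch in st.chains:
            for res in ch.residues:
                for at in res.atoms:
                    at.coords = at.coords + rng.normal(0.0, noise_sd, size=3)
    return st


# ---------------------------------------------------------------------------
# Family sequences
# ---------------------------------------------------------------------------

_FAMILY_MOTIFS = {
    "ATD": (("PQATL", 30), ("TNGPYTH", 100)),
    "DTD": (("SQFTL", 30), ("NAGPVT", 100)),
}


def gen_family_sequences(
    n: int,
    family: str = "ATD",
    mutation_rate: float = 0.0,
    seed: int = 0,
    length: int = 160,
    max_motif_mismatch: int = 1,
) -> list[ProteinRecord]:
    """Random-background protein sequences with family motifs embedded.

    Motif 1 starts at offset 30 and motif 2 at offset 100 (0-based).
    Point mutations hit background sites at ``mutation_rate``; within each
    motif at most ``max_motif_mismatch`` mutations are allowed so the
    signature stays detectable by design.
    """
    family = family.upper()
    if family not in _FAMILY_MOTIFS:
        raise ValueError("family must be 'ATD' or 'DTD'")
    if not 0.0 <= mutation_rate <= 0.3:
        raise ValueError("mutation_rate must be in [0, 0.3]")
    rng = _rng(seed, "sequences")
    aa = np.array(list(AMINO_ACIDS))
    motifs = _FAMILY_MOTIFS[family]
    records = []
    for idx in range(n):
        s = rng.choice(aa, size=length)
        motif_sites = set()
        for motif, off in motifs:
            s[off : off + len(motif)] = list(motif)
            motif_sites.update(range(off, off + len(motif)))
        if mutation_rate > 0:
            hit = rng.random(length) < mutation_rate
            budget = {off: max_motif_mismatch for _, off in motifs}
            for i in np.flatnonzero(hit):
                if i in motif_sites:
                    off = max(o for _, o in motifs if o <= i)
                    if budget[off] == 0:
                        continue
                    budget[off] -= 1
                s[i] = rng.choice(aa)
        records.append(
            ProteinRecord(
                id=f"{family.lower()}_synth_{idx}",
                sequence="".join(s),
                organism="synthetic",
            )
        )
    return records


# ---------------------------------------------------------------------------
# tRNA genes
# ---------------------------------------------------------------------------

_RNA = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def gen_trna_set(
    n_per_isotype: Mapping[str, int],
    wobble_prob: Mapping[str, float],
    score_dist: tuple[float, float] = (70.0, 10.0),
    seed: int = 0,
    organism: str = "synthetic_org",
) -> list[TRNAGene]:
    """Canonical 73-nt mature tRNA genes with controlled G4:U69 frequency.

    The acceptor stem (positions 1-7 vs 66-72) is Watson-Crick except that
    pair 4 is replaced by G4:U69 with the isotype's stated probability;
    position 73 is the discriminator. The body between the stem halves is
    random filler (no attempt at D/T/anticodon arm realism). Scores are
    Gaussian with the given mean and sd.
    """
    rng = _rng(seed, "trnas")
    mean, sd = score_dist
    genes = []
    for isotype in sorted(n_per_isotype):
        p = float(wobble_prob.get(isotype, 0.0))
        if not 0.0 <= p <= 1.0:
            raise ValueError("wobble probabilities must be in [0, 1]")
        for k in range(int(n_per_isotype[isotype])):
            stem5 = rng.choice(list(_RNA), size=7)
            # position 1 is G and position 2 non-G, so the 3' stem half can
            # never end in CC and spell an accidental CCA with the
            # discriminator (which CCA-stripping would then remove)
            stem5[0] = "G"
            if stem5[1] == "G":
                stem5[1] = "C"
            wobble = bool(rng.random() < p)
            if wobble:
                stem5[3] = "G"
            body = rng.choice(list(_RNA), size=58)
            seq = list(stem5) + list(body)
            # 3' stem half: complement of 5' half, pair i <-> position 73-i
            stem3 = [_WC[b] for b in stem5[::-1]]
            if wobble:
                stem3[-4] = "U"  # position 69 pairs position 4
            seq += stem3 + ["A"]  # discriminator 73
            genes.append(
                TRNAGene(
                    organism=organism,
                    isotype=isotype,
                    anticodon="".join(rng.choice(list(_RNA), size=3)),
                    score=float(rng.normal(mean, sd)),
                    sequence="".join(seq),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def gen_decay_series(
    k: float,
    s0: float = 1.0,
    timepoints: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0),
    noise_sd: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
    substrate: str = "substrate",
    enzyme_conc: float = 50.0,
    eftu: str = "none",
) -> list[TimeCourse]:
    """Replicated first-order decay time courses with Gaussian noise.

    Fractions are s0 * exp(-k t) + N(0, noise_sd), clipped to [0, 1.2].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "decay")
    t = np.asarray(timepoints, dtype=float)
    out = []
    for _ in range(n_rep):
        y = s0 * np.exp(-k * t)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=t.shape)
        y = np.clip(y, 0.0, 1.2)
        out.append(
            TimeCourse(
                substrate=substrate,
                enzyme_conc=enzyme_conc,
                points=tuple(zip(t.tolist(), y.tolist())),
                eftu=eftu,
            )
        )
    return out


def gen_dose_ladder(
    k_eff: float,
    concentrations: Sequence[float],
    timepoints: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    substrate: str = "substrate",
    eftu: str = "none",
    protection: float = 1.0,
) -> list[TimeCourse]:
    """Dose-response series with k(c) = k_eff * c / protection.

    ``k_eff`` is the observed rate per nM of enzyme (min^-1 nM^-1);
    ``protection`` > 1 models EF-Tu occupancy shielding the substrate by
    scaling the accessible substrate pool's decay rate down uniformly.
    """
    if protection <= 0:
        raise ValueError("protection must be positive")
    out = []
    for i, c in enumerate(concentrations):
        out.extend(
            gen_decay_series(
                k=k_eff * c / protection,
                timepoints=timepoints,
                noise_sd=noise_sd,
                n_rep=1,
                seed=seed + 7919 * i,
                substrate=substrate,
                enzyme_conc=float(c),
                eftu=eftu,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Presence/absence
# ---------------------------------------------------------------------------

def gen_presence_table(
    n_organisms: int,
    concordance: float = 1.0,
    seed: int = 0,
    n_genes: int = 20,
    enriched_fraction: float = 0.30,
    background_prob: float = 0.01,
    enriched_prob: float = 0.5,
    enrich_threshold: float = 10.0,
) -> tuple[list[EnrichmentRow], dict[str, bool]]:
    """Per-organism tRNA-Thr enrichment rows plus an ATD presence map.

    Each organism is enriched with probability ``enriched_prob``; enriched
    organisms draw their G4:U69 gene count as Binomial(n_genes,
    enriched_fraction), others as Binomial(n_genes, background_prob). ATD
    presence then agrees with the *realized* enrichment state (fraction >=
    ``enrich_threshold`` %) with probability ``concordance``.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    rng = _rng(seed, "presence")
    rows, presence = [], {}
    for i in range(n_organisms):
        org = f"org_{i:04d}"
        enriched = bool(rng.random() < enriched_prob)
        p = enriched_fraction if enriched else background_prob
        n_wob = int(rng.binomial(n_genes, p))
        row = EnrichmentRow(org, "Thr", n_genes, n_wob)
        realized = row.fraction >= enrich_threshold
        agree = bool(rng.random() < concordance)
        presence[org] = realized if agree else not realized
        rows.append(row)
    return rows, presence
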