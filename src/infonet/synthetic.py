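"""Synthetic datasets with known family structure.

The sequence generator emulates families of homologous proteins: one
uniform-random ancestor per family, diversified per member by i.i.d.
point substitutions and geometric-length single-site indels.  Indels
change member lengths, which exercises the sliding-window maximum in the
pairwise comparison.  The structure generator builds backbone
coordinates from ideal peptide geometry at prescribed (phi, psi)
targets, so the torsion computation can be validated by round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .seqio import AA_ALPHABET, ProteinRecord

#: Ideal backbone bond lengths (Angstrom) and angles (degrees).
BOND_N_CA, BOND_CA_C, BOND_C_N = 1.458, 1.525, 1.329
ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_C_N_CA = 111.2, 116.2, 121.7
OMEGA_TRANS = 180.0

#: Canonical (phi, psi) targets per secondary-structure motif.
MOTIF_ANGLES = {"alpha": (-60.0, -45.0), "beta": (-120.0, 120.0)}

#: Continuation probability of the geometric indel-length model.
INDEL_GEOM_P = 0.5


@dataclass
class FamilySpec:
    """Parameters of a synthetic family dataset.

    Defaults are the reference fixture: 3 families of 6 members, ancestor
    length 200, substitution rate 0.05 per site, indel rate 0.01 per
    site, seed 7 — rates at which within-family similarity cleanly
    exceeds between-family similarity.
    """

    n_families: int = 3
    members_per_family: int = 6
    ancestor_length: int = 200
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    seed: int = 7

    def __post_init__(self):
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member per family")
        if self.ancestor_length < 10:
            raise ValueError("ancestor length must be >= 10")
        for rate in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")


def _mutate(ancestor: np.ndarray, spec: FamilySpec, rng: np.random.Generator) -> str:
    """One descendant: per-site substitutions plus geometric indels."""
    out: list[int] = []
    i = 0
    while i < len(ancestor):
        if spec.indel_rate > 0.0 and rng.random() < spec.indel_rate:
            length = rng.geometric(1.0 - INDEL_GEOM_P)
            if rng.random() < 0.5:  # insertion before the current site
                out.extend(rng.integers(0, 20, size=length).tolist())
                continue  # current site still to be emitted
            i += length  # deletion of `length` sites from here
            continue
        aa = int(ancestor[i])
        if spec.substitution_rate > 0.0 and rng.random() < spec.substitution_rate:
            aa = (aa + int(rng.integers(1, 20))) % 20  # uniform over other 19
        out.append(aa)
        i += 1
    if len(out) < 2:  # only reachable at extreme rates
        out = ancestor[:2].tolist()
    return "".join(AA_ALPHABET[v] for v in out)


def generate_families(spec: FamilySpec) -> tuple[list[ProteinRecord], list[int]]:
    """Generate a family dataset and its ground-truth family labels.

    Fully reproducible from ``spec.seed``; record ids are
    ``fam{f}_m{m}`` and labels name the family.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    truth: list[int] = []
    for f in range(spec.n_families):
        ancestor = rng.integers(0, 20, size=spec.ancestor_length)
        for m in range(spec.members_per_family):
            residues = _mutate(ancestor, spec, rng)
            records.append(
                ProteinRecord(
                    id=f"fam{f}_m{m}",
                    label=f"family{f}",
                    residues=residues,
                    meta={"family": f, "seed": spec.seed},
                )
            )
            truth.append(f)
    return records, truth


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write sequence records as plain FASTA (id + label headers)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.label}".rstrip()
            fh.write(f"{header}\n{rec.residues}\n")


# --------------------------------------------------------------------------
# structure generator
# --------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position atom d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (standard internal-coordinate step)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_from_torsions(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone N/CA/C coordinates realizing the given torsions.

    ``phi`` covers residues 2..n and ``psi`` residues 1..n-1 (the
    terminal angles are undefined); omega is fixed trans.  Returns an
    array of shape (n, 3, 3).
    """
    n_res = len(phi) + 1
    if len(psi) != n_res - 1:
        raise ValueError("phi and psi length mismatch (need len(psi) == len(phi))")
    coords = np.zeros((n_res, 3, 3))
    # residue 1 in an arbitrary frame
    coords[0, 0] = np.array([0.0, 0.0, 0.0])  # N
    coords[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])  # CA
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )  # C
    for i in range(1, n_res):
        prev_n, prev_ca, prev_c = coords[i - 1]
        n_i = _place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = _place_atom(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i - 1])
        coords[i] = np.stack([n_i, ca_i, c_i])
    return coords


def generate_torsion_structure(
    n_residues: int,
    motif: str = "alpha",
    noise_deg: float = 0.0,
    seed: int = 0,
) -> ProteinRecord:
    """Synthesize a backbone whose torsions sit near a canonical motif.

    ``motif`` is ``alpha`` (helix, phi/psi -60/-45), ``beta`` (sheet,
    -120/+120) or ``mixed`` (first half helix, second half sheet);
    Gaussian noise of ``noise_deg`` degrees is added per angle.  The
    generating target angles are logged in ``meta`` so round-trip tests
    can compare against them.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    if motif in MOTIF_ANGLES:
        phi0, psi0 = MOTIF_ANGLES[motif]
        phi = np.full(n_residues - 1, phi0)
        psi = np.full(n_residues - 1, psi0)
    elif motif == "mixed":
        half = n_residues // 2
        phi = np.where(np.arange(2, n_residues + 1) <= half,
                       MOTIF_ANGLES["alpha"][0], MOTIF_ANGLES["beta"][0])
        psi = np.where(np.arange(1, n_residues) <= half,
                       MOTIF_ANGLES["alpha"][1], MOTIF_ANGLES["beta"][1])
        phi = phi.astype(float)
        psi = psi.astype(float)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    if noise_deg > 0.0:
        phi = phi + rng.normal(0.0, noise_deg, size=len(phi))
        psi = psi + rng.normal(0.0, noise_deg, size=len(psi))
    phi = (phi + 180.0) % 360.0 - 180.0
    psi = (psi + 180.0) % 360.0 - 180.0
    coords = backbone_from_torsions(phi, psi)
    return ProteinRecord(
        id=f"{motif}_{n_residues}_{seed}",
        label=f"synthetic {motif} backbone",
        backbone=coords,
        chain_index=np.zeros(n_residues, dtype=np.int64),
        meta={"target_phi": phi, "target_psi": psi, "motif": motif,
              "noise_deg": noise_deg, "seed": seed},
    )


def write_pdb(record: ProteinRecord, path: str | Path) -> None:
    """Write a backbone-only record as a standard PDB file (poly-ALA)."""
    if record.backbone is None:
        raise ValueError("record has no backbone coordinates")
    builder = StructureBuilder()
    builder.init_structure(record.id[:4] or "SYNT")
    builder.init_model(0)
    builder.init_seg("    ")
    chain_ids = (
        record.chain_index
        if record.chain_index is not None
        else np.zeros(len(record.backbone), dtype=np.int64)
    )
    current_chain = None
    serial = 1
    for i, triple in enumerate(record.backbone):
        cid = chr(ord("A") + int(chain_ids[i]) % 26)
        if cid != current_chain:
            builder.init_chain(cid)
            current_chain = cid
        builder.init_residue("ALA", " ", i + 1, " ")
        for name, coord in zip(("N", "CA", "C"), triple):
            builder.init_atom(
                name, np.asarray(coord, dtype=float), 0.0, 1.0, " ",
                name.center(4), serial, name[0],
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
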