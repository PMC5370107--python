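"""Input records and integer-state encoding.

Protein sequences are read from FASTA and mapped to discrete 20-state
series; protein structures are read from PDB, converted to backbone
(phi, psi) torsion angles and discretised into the same kind of
integer-state series, so both branches feed one information engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

logger = logging.getLogger("infonet")

#: The 20 standard amino acids in alphabetical one-letter order; residue
#: ``AA_ALPHABET[k]`` encodes to integer state ``k + 1``.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INT = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET)}
INT_TO_AA = {i + 1: aa for i, aa in enumerate(AA_ALPHABET)}

#: Nearest-standard-residue mapping for ambiguity codes under the
#: ``map-to-nearest`` policy.  X and gap characters have no nearest
#: residue and are always dropped.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

ALPHABET_POLICIES = ("drop", "error", "map-to-nearest")


class SequenceError(ValueError):
    """Raised for malformed or degenerate sequence/structure input."""


@dataclass
class ProteinRecord:
    """One input protein: a sequence or a backbone-coordinate chain.

    Exactly one of ``residues`` (sequence branch) or ``backbone``
    (structure branch) is set.  ``backbone`` has shape (n_residues, 3, 3):
    per residue the N, CA, C coordinates in Angstroms.  ``chain_index``
    marks which chain each residue came from so that torsion angles are
    never computed across a chain boundary.
    """

    id: str
    label: str = ""
    residues: str | None = None
    backbone: np.ndarray | None = None
    chain_index: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise SequenceError("record id must be nonempty")


@dataclass
class DiscreteSeries:
    """An integer-state series with states in 1..k."""

    values: np.ndarray
    k: int
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise SequenceError(f"series {self.source_id!r}: need a 1-d series")
        if len(self.values) and (self.values.min() < 1 or self.values.max() > self.k):
            raise SequenceError(
                f"series {self.source_id!r}: states must lie in 1..{self.k}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TorsionSeries:
    """Backbone torsion angles in degrees, each in [-180, 180).

    ``kinds`` runs parallel to ``angles`` and marks each entry as
    ``"phi"`` or ``"psi"``; the default layout interleaves the two in
    residue order (psi_1, phi_2, psi_2, ..., phi_n).
    """

    angles: np.ndarray
    kinds: list[str]
    source_id: str = ""

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) != len(self.kinds):
            raise SequenceError("angles and kinds must have equal length")
        if len(self.angles) and (
            self.angles.min() < -180.0 or self.angles.max() >= 180.0
        ):
            raise SequenceError("torsion angles must lie in [-180, 180)")

    def __len__(self) -> int:
        return len(self.angles)

    def select(self, kind: str) -> "TorsionSeries":
        """Return the phi-only or psi-only sub-series."""
        mask = [k == kind for k in self.kinds]
        return TorsionSeries(
            angles=self.angles[np.asarray(mask, bool)],
            kinds=[k for k in self.kinds if k == kind],
            source_id=self.source_id,
        )


# --------------------------------------------------------------------------
# FASTA input and sequence encoding
# --------------------------------------------------------------------------

def sanitize_residues(raw: str, policy: str = "drop") -> tuple[str, int]:
    """Uppercase ``raw`` and resolve non-standard characters.

    Returns the cleaned sequence and the number of characters that were
    dropped or remapped.  ``policy`` is one of ``drop`` (default),
    ``error``, or ``map-to-nearest`` (ambiguity codes remapped via
    :data:`AMBIGUITY_MAP`; X and gaps still dropped).
    """
    if policy not in ALPHABET_POLICIES:
        raise ValueError(f"unknown alphabet policy {policy!r}")
    out = []
    touched = 0
    for ch in raw.upper():
        if ch in AA_TO_INT:
            out.append(ch)
        elif ch.isspace():
            continue
        elif policy == "error":
            raise SequenceError(f"non-standard residue {ch!r}")
        elif policy == "map-to-nearest" and ch in AMBIGUITY_MAP:
            out.append(AMBIGUITY_MAP[ch])
            touched += 1
        else:
            touched += 1
    return "".join(out), touched


def parse_fasta(path: str | Path, alphabet_policy: str = "drop") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header's first token becomes the id, the remainder the label.
    Residues outside the 20-letter alphabet are handled per
    ``alphabet_policy``; dropped/remapped counts are logged and stored in
    each record's ``meta["sanitized"]``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise SequenceError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        label = entry.description[len(entry.id):].strip()
        residues, touched = sanitize_residues(str(entry.seq), alphabet_policy)
        if touched:
            logger.warning(
                "record %s: %d non-standard character(s) handled by policy %r",
                rid, touched, alphabet_policy,
            )
        if len(residues) < 2:
            raise SequenceError(
                f"record {rid!r}: fewer than 2 standard residues after sanitization"
            )
        records.append(
            ProteinRecord(id=rid, label=label, residues=residues,
                          meta={"sanitized": touched})
        )
    if not records:
        raise SequenceError(f"no records found in {path}")
    return records


def encode_sequence(record: ProteinRecord) -> DiscreteSeries:
    """Map a sequence record to its 20-state integer series.

    Uses the fixed bijection A->1 ... Y->20 (alphabetical order).  Any
    fixed bijection gives identical mutual-information values — the
    quantity depends only on state frequencies, not labels — so the
    choice is frozen purely for reproducibility.
    """
    if record.residues is None:
        raise SequenceError(f"record {record.id!r} has no residues")
    try:
        values = np.fromiter(
            (AA_TO_INT[ch] for ch in record.residues), dtype=np.int64,
            count=len(record.residues),
        )
    except KeyError as exc:
        raise SequenceError(
            f"record {record.id!r}: cannot encode residue {exc.args[0]!r}"
        ) from None
    return DiscreteSeries(values=values, k=20, source_id=record.id)


def decode_sequence(series: DiscreteSeries) -> str:
    """Inverse of :func:`encode_sequence` (k must be 20)."""
    if series.k != 20:
        raise SequenceError("decode is defined for the 20-letter alphabet only")
    return "".join(INT_TO_AA[int(v)] for v in series.values)


# --------------------------------------------------------------------------
# PDB input and torsion angles
# --------------------------------------------------------------------------

def parse_pdb_backbone(
    path: str | Path,
    model_policy: str = "first",
    chain_policy: str = "concat",
) -> ProteinRecord:
    """Extract per-residue backbone N/CA/C coordinates from a PDB file.

    Only the first model is used (``model_policy="first"``); chains are
    concatenated in file order (``chain_policy="concat"``).  Residues
    missing any of the three backbone atoms are excluded with a warning.
    """
    if model_policy != "first":
        raise ValueError(f"unsupported model policy {model_policy!r}")
    if chain_policy != "concat":
        raise ValueError(f"unsupported chain policy {chain_policy!r}")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # malformed records surface with file context
        raise SequenceError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise SequenceError(f"{path}: no model found")
    model = models[0]

    coords: list[np.ndarray] = []
    chain_idx: list[int] = []
    skipped = 0
    for ci, chain in enumerate(model):
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / water
                continue
            if all(name in residue for name in ("N", "CA", "C")):
                triple = np.stack(
                    [residue["N"].coord, residue["CA"].coord, residue["C"].coord]
                ).astype(float)
                coords.append(triple)
                chain_idx.append(ci)
            else:
                skipped += 1
                logger.warning(
                    "%s: residue %s%s missing backbone atom(s); excluded",
                    path.name, chain.id, residue.id[1],
                )
    if not coords:
        raise SequenceError(f"{path}: no complete backbone residue")
    return ProteinRecord(
        id=path.stem,
        backbone=np.stack(coords),
        chain_index=np.asarray(chain_idx, dtype=np.int64),
        meta={"skipped_residues": skipped},
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points, degrees in [-180, 180).

    IUPAC sign convention via the atan2 formulation: looking from p1 to
    p2, a clockwise rotation of p3 relative to p0 is positive.  Exactly
    planar-trans arrangements are reported as -180 (half-open range).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise ValueError("degenerate dihedral: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang >= 180.0:
        ang -= 360.0
    return ang


def compute_torsions(record: ProteinRecord) -> TorsionSeries:
    """Backbone (phi, psi) torsions of a structure record.

    phi(i) = dihedral(C(i-1), N(i), CA(i), C(i)) for i >= 2 and
    psi(i) = dihedral(N(i), CA(i), C(i), N(i+1)) for i <= n-1; the
    undefined terminal angles (phi_1, psi_n) are omitted.  Output is
    interleaved in residue order, psi_1, phi_2, psi_2, ..., phi_n, so a
    single complete chain of n residues yields 2n - 2 angles.  Angle
    pairs whose atoms span a chain boundary are excluded.
    """
    if record.backbone is None:
        raise SequenceError(f"record {record.id!r} has no backbone coordinates")
    bb = record.backbone
    n = len(bb)
    if n < 2:
        raise SequenceError(f"record {record.id!r}: need at least 2 residues")
    chain = (
        record.chain_index
        if record.chain_index is not None
        else np.zeros(n, dtype=np.int64)
    )
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]

    angles: list[float] = []
    kinds: list[str] = []
    for i in range(n):
        if i >= 1 and chain[i] == chain[i - 1]:
            phi = dihedral(C[i - 1], N[i], CA[i], C[i])
            angles.append(phi)
            kinds.append("phi")
        if i <= n - 2 and chain[i] == chain[i + 1]:
            psi = dihedral(N[i], CA[i], C[i], N[i + 1])
            angles.append(psi)
            kinds.append("psi")
    if not angles:
        raise SequenceError(f"record {record.id!r}: no defined torsion angle")
    return TorsionSeries(
        angles=np.asarray(angles), kinds=kinds, source_id=record.id
    )


def discretize_torsions(series: TorsionSeries, bins: int = 20) -> DiscreteSeries:
    """Uniformly bin [-180, 180) into ``bins`` states 1..bins.

    Angle a maps to floor((a + 180) / (360 / bins)) + 1; each bin is
    left-closed/right-open, so -180 always lands in state 1.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    width = 360.0 / bins
    values = np.floor((series.angles + 180.0) / width).astype(np.int64) + 1
    # guard against floating rounding at the upper edge
    np.clip(values, 1, bins, out=values)
    return DiscreteSeries(values=values, k=bins, source_id=series.source_id)
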