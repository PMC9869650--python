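"""Readers and writers for the external input formats.

The evaluation pipeline consumes four kinds of files:

* protein backbone structures in PDB format (N, CA, C, O atoms; header
  resolution),
* per-residue prediction matrices in CSV format (20 probability columns
  over the canonical amino-acid alphabet),
* a plain-text dataset map assigning each chain a CATH architecture code
  and a structure file,
* optional precomputed DSSP output files (classic fixed-column format).

Everything is validated on the way in and converted to the small set of
dataclasses defined here; downstream modules never touch raw files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet, fixed order.
ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: Marker for residues whose identity could not be canonicalized.
UNKNOWN_AA = "X"

_STANDARD_3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

# Common non-canonical residues mapped to the standard parent they are
# derived from (chemical modification, selenium substitution, alternative
# protonation-state naming).  Unmapped codes become UNKNOWN_AA.
NONCANONICAL_3TO1 = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine, scored as cysteine
    "PYL": "K",  # pyrrolysine
    "HSD": "H", "HSE": "H", "HSP": "H", "HIE": "H", "HID": "H", "HIP": "H",
    "CSO": "C", "CSS": "C", "CME": "C", "OCS": "C",  # oxidised cysteines
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "KCX": "K", "MLY": "K", "M3L": "K", "LLP": "K",  # modified lysines
    "HYP": "P",  # hydroxyproline
    "MLE": "L",
    "FME": "M",
    "PCA": "Q",  # pyroglutamate
    "DAL": "A", "DSN": "S",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """Input file violates the expected format."""


class ValidationError(ValueError):
    """Input parsed but failed a semantic validation rule."""


class ChainNotFoundError(KeyError):
    """Requested chain is absent from a structure file."""


def canonicalize_residue(aa3: str) -> str:
    """Map a three-letter residue code to a one-letter canonical code.

    Standard residues map to their letter; a shipped substitution table
    maps common non-canonical residues to their canonical parent (e.g.
    MSE -> M).  Anything else returns the unknown marker ``X``.  Total
    function: never raises.
    """
    aa3 = aa3.strip().upper()
    if aa3 in _STANDARD_3TO1:
        return _STANDARD_3TO1[aa3]
    if aa3 in NONCANONICAL_3TO1:
        return NONCANONICAL_3TO1[aa3]
    return UNKNOWN_AA


@dataclass
class Residue:
    """One residue of a backbone chain.

    ``seq_id`` is the author residue number plus insertion code (e.g.
    ``"42"`` or ``"42A"``).  ``coords`` maps atom name to a 3-vector in
    Angstroms; any of N, CA, C, O may be missing.
    """

    seq_id: str
    aa_true: str
    coords: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(a in self.coords for a in BACKBONE_ATOMS)


@dataclass
class BackboneStructure:
    """An ordered protein chain with backbone coordinates."""

    chain_key: str
    residues: list[Residue]
    resolution: float | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_true for r in self.residues)


@dataclass
class PredictionSet:
    """Per-residue probability rows for one design method.

    ``rows[chain_key]`` is an (n, 20) array aligned to :data:`ALPHABET`;
    row order follows structure order of the scored residues.
    """

    model_name: str
    chain_keys: list[str]
    rows: dict[str, np.ndarray]


@dataclass
class MapEntry:
    chain_key: str
    architecture_code: str
    fold_class: str
    structure_path: str


@dataclass
class DatasetMap:
    entries: list[MapEntry]

    def __iter__(self):
        return iter(self.entries)

    def by_chain(self) -> dict[str, MapEntry]:
        return {e.chain_key: e for e in self.entries}


FOLD_CLASSES = ("mainly-alpha", "mainly-beta", "alpha-beta", "special")

_ARCH_RE = re.compile(r"^\d\.\d+$")


def fold_class_of(architecture_code: str) -> str:
    """CATH class digit -> coarse fold class (1/2/3 -> named, else special)."""
    digit = architecture_code.split(".", 1)[0]
    return {"1": "mainly-alpha", "2": "mainly-beta", "3": "alpha-beta"}.get(
        digit, "special")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _best_altloc_atoms(res: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Resolve altlocs: per atom name keep the highest occupancy, ties ->
    first encountered."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return best


def read_pdb_backbone(path: str | Path, chain_id: str) -> BackboneStructure:
    """Read one chain's backbone from a PDB file.

    Only the first model is used.  Water and HETATM-only ligands are
    excluded; HETATM residues whose code is in the non-canonical
    substitution table (e.g. MSE) are kept.  Residues with unparseable
    identity are retained with the unknown marker so exclusion counts can
    be reported downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse PDB: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models in file")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found in {path} "
            f"(available: {[c.name for c in model]})")

    residues: list[Residue] = []
    n_excluded = 0
    for res in chain:
        if res.name in ("HOH", "DOD", "WAT"):
            n_excluded += 1
            continue
        is_atom_record = res.het_flag == "A"
        aa = canonicalize_residue(res.name)
        if not is_atom_record and aa == UNKNOWN_AA:
            # HETATM-only ligand with no amino-acid mapping
            n_excluded += 1
            continue
        atoms = _best_altloc_atoms(res)
        coords = {}
        for name in BACKBONE_ATOMS:
            if name in atoms:
                pos = atoms[name].pos
                vec = np.array([pos.x, pos.y, pos.z], dtype=float)
                if not np.all(np.isfinite(vec)):
                    raise FormatError(
                        f"{path}: non-finite coordinates for atom {name} "
                        f"of residue {res.seqid}")
                coords[name] = vec
        seq_id = f"{res.seqid.num}{res.seqid.icode}".strip()
        residues.append(Residue(seq_id=seq_id, aa_true=aa, coords=coords))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    pdb_id = path.stem
    structure = BackboneStructure(
        chain_key=f"{pdb_id}_{chain_id}", residues=residues,
        resolution=resolution)
    logger.info("read %s chain %s: %d residues, %d records excluded",
                path.name, chain_id, len(residues), n_excluded)
    return structure


def write_pdb(structure: BackboneStructure, path: str | Path,
              chain_id: str | None = None) -> None:
    """Write a backbone structure as PDB text (fixture support).

    Coordinates are emitted at standard fixed-width precision (3 decimal
    places); a REMARK 2 resolution record is written when resolution is
    set.
    """
    if chain_id is None:
        chain_id = structure.chain_key.rsplit("_", 1)[-1] or "A"
    one_to_three = {v: k for k, v in _STANDARD_3TO1.items()}
    st = gemmi.Structure()
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for res in structure.residues:
        g = gemmi.Residue()
        g.name = one_to_three.get(res.aa_true, "UNK")
        m = re.match(r"^(-?\d+)([A-Za-z]?)$", res.seq_id)
        if not m:
            raise ValueError(f"bad seq_id {res.seq_id!r}")
        g.seqid = gemmi.SeqId(int(m.group(1)), m.group(2) or " ")
        for name in BACKBONE_ATOMS:
            if name not in res.coords:
                continue
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(name[0])
            a.pos = gemmi.Position(*res.coords[name])
            a.occ = 1.0
            a.b_iso = 20.0
            g.add_atom(a)
        chain.add_residue(g)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# Prediction CSV
# ---------------------------------------------------------------------------

def read_prediction_csv(path: str | Path,
                        model_name: str | None = None) -> PredictionSet:
    """Read a prediction matrix CSV into a :class:`PredictionSet`.

    Expected header: ``chain_key,position,A,C,...,Y`` (20 alphabet
    columns).  Rows for a chain must be contiguous; alignment to the
    structure is by row order.  Each probability vector must be
    non-negative and sum to 1 within +/-0.01; vectors inside the
    tolerance are renormalized exactly to 1.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["chain_key", "position", *ALPHABET]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no prediction rows")

    probs = df[list(ALPHABET)].to_numpy(dtype=float)
    if not np.all(np.isfinite(probs)):
        bad = int(np.argwhere(~np.isfinite(probs).all(axis=1))[0][0])
        raise ValidationError(f"{path}: non-finite probability in row {bad}")
    neg = probs < 0
    if neg.any():
        bad = int(np.argwhere(neg.any(axis=1))[0][0])
        raise ValidationError(f"{path}: negative probability in row {bad}")
    sums = probs.sum(axis=1)
    off = (sums < 0.99) | (sums > 1.01)
    if off.any():
        bad = int(np.argwhere(off)[0][0])
        raise ValidationError(
            f"{path}: row {bad} probabilities sum to {sums[bad]:.4f}, "
            "outside [0.99, 1.01]")
    probs = probs / sums[:, None]

    chain_col = df["chain_key"].astype(str).to_numpy()
    chain_keys: list[str] = []
    rows: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    start = 0
    for i in range(1, len(chain_col) + 1):
        if i == len(chain_col) or chain_col[i] != chain_col[start]:
            key = chain_col[start]
            if key in seen:
                raise ValidationError(
                    f"{path}: rows for chain {key!r} are not contiguous")
            seen.add(key)
            chain_keys.append(key)
            rows[key] = probs[start:i]
            start = i
    logger.info("read %s: %d rows over %d chains", path.name,
                len(df), len(chain_keys))
    return PredictionSet(model_name=model_name or path.stem,
                         chain_keys=chain_keys, rows=rows)


def write_prediction_csv(preds: PredictionSet, path: str | Path) -> None:
    """Write a prediction set in the CSV dialect ``read_prediction_csv``
    consumes."""
    frames = []
    for key in preds.chain_keys:
        mat = preds.rows[key]
        frame = pd.DataFrame(mat, columns=list(ALPHABET))
        frame.insert(0, "chain_key", key)
        frame.insert(1, "position", np.arange(1, len(mat) + 1))
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


# ---------------------------------------------------------------------------
# Dataset map
# ---------------------------------------------------------------------------

def read_dataset_map(path: str | Path) -> DatasetMap:
    """Read the whitespace-separated dataset map.

    Line format: ``chain_key architecture_code structure_path``; ``#``
    starts a comment.  The fold class is derived from the leading CATH
    class digit of the architecture code.
    """
    path = Path(path)
    entries: list[MapEntry] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 fields "
                f"(chain_key architecture_code structure_path), got {len(parts)}")
        chain_key, arch, struct_path = parts
        if chain_key in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate chain_key {chain_key!r}")
        seen.add(chain_key)
        if not _ARCH_RE.match(arch):
            raise FormatError(
                f"{path}:{lineno}: malformed architecture code {arch!r} "
                "(expected digit.digits, e.g. 1.10)")
        entries.append(MapEntry(chain_key=chain_key, architecture_code=arch,
                                fold_class=fold_class_of(arch),
                                structure_path=struct_path))
    logger.info("read %s: %d entries", path.name, len(entries))
    return DatasetMap(entries=entries)


# ---------------------------------------------------------------------------
# DSSP classic output
# ---------------------------------------------------------------------------

_DSSP_HEADER = "  #  RESIDUE"


def read_dssp_file(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse classic DSSP output into (chain, residue-number, 8-state code)
    triples.

    Data lines follow the ``  #  RESIDUE`` header; chain-break ``!``
    lines are skipped; a blank structure code means coil (``C``).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith(_DSSP_HEADER):
            start = i + 1
            break
    if start is None:
        raise FormatError(f"{path}: DSSP data header '  #  RESIDUE' not found")
    out: list[tuple[str, str, str]] = []
    for line in lines[start:]:
        if len(line) < 17 or line[13] == "!":
            continue
        resnum = line[5:11].strip()
        chain = line[11].strip()
        code = line[16].strip() or "C"
        out.append((chain, resnum, code))
    return out


def write_dssp_file(labels: Iterable[tuple[str, str, str, str]],
                    path: str | Path) -> None:
    """Write (chain, resnum, aa, state8) records in classic DSSP data-line
    layout (fixture support; header is minimal but column-accurate)."""
    rows = list(labels)
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition, synthetic fixture ====\n")
        fh.write(f"{len(rows):5d} residues\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")
        for i, (chain, resnum, aa, code) in enumerate(rows, start=1):
            ss = " " if code == "C" else code
            # cols: 0-4 index, 5-9 resnum, 10 icode, 11 chain, 13 aa, 16 ss
            fh.write(f"{i:5d}{int(resnum):5d} {chain} {aa}  {ss}\n")
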