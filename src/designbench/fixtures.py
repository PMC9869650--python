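"""Synthetic structures, predictors and manifests with planted properties.

Everything here is generated from ideal peptide geometry and seeded RNGs,
so the whole evaluation pipeline can be exercised — and its outputs
predicted analytically — without downloading a single real structure.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import dihedral, place_atom
from .io_formats import (ALPHABET, AA_INDEX, BackboneStructure, DatasetMap,
                         MapEntry, PredictionSet, Residue, write_dssp_file,
                         write_pdb, write_prediction_csv)

# Ideal peptide-bond geometry: bond lengths (A) and angles (deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def build_chain_from_torsions(phi_psi_list, sequence: str | None = None,
                              chain_key: str = "synt_A",
                              resolution: float | None = None,
                              start_seq_num: int = 1) -> BackboneStructure:
    """Build an all-atom backbone from a list of (phi, psi) torsions.

    Uses fixed ideal bond lengths and angles with a trans peptide bond
    (omega = 180 deg), so recomputing phi/psi from the built coordinates
    returns the inputs (up to floating-point error).  phi of the first
    residue and psi of the last are accepted but only psi of the last
    residue still shapes the terminal carbonyl.
    """
    phi_psi = [(float(p), float(s)) for p, s in phi_psi_list]
    n = len(phi_psi)
    if n == 0:
        raise ValueError("empty torsion list")
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length != torsion list length")

    coords: list[dict[str, np.ndarray]] = []
    # first residue in the xy-plane
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    theta = np.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        psi_prev = phi_psi[i - 1][1]
        prev = coords[-1]
        N = place_atom(prev["N"], prev["CA"], prev["C"],
                       BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA = place_atom(prev["CA"], prev["C"], N,
                        BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C = place_atom(prev["C"], N, CA,
                       BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        coords.append({"N": N, "CA": CA, "C": C})
    # carbonyl oxygens: O trans to the next amide nitrogen
    for i in range(n):
        psi = phi_psi[i][1]
        o_torsion = psi + 180.0
        if o_torsion > 180.0:
            o_torsion -= 360.0
        coords[i]["O"] = place_atom(coords[i]["N"], coords[i]["CA"],
                                    coords[i]["C"], BOND_C_O, ANGLE_CA_C_O,
                                    o_torsion)

    residues = [Residue(seq_id=str(start_seq_num + i), aa_true=sequence[i],
                        coords=coords[i])
                for i in range(n)]
    return BackboneStructure(chain_key=chain_key, residues=residues,
                             resolution=resolution)


def make_ideal_helix(n: int, sequence: str | None = None,
                     chain_key: str = "helx_A",
                     resolution: float | None = None) -> BackboneStructure:
    """Ideal alpha-helix built from (phi, psi) = (-57, -47) torsions."""
    if n < 6:
        raise ValueError(f"helix needs >= 6 residues, got {n}")
    return build_chain_from_torsions([HELIX_PHI_PSI] * n, sequence=sequence,
                                     chain_key=chain_key,
                                     resolution=resolution)


def _transform(structure: BackboneStructure, R: np.ndarray,
               t: np.ndarray) -> None:
    for res in structure.residues:
        for name in list(res.coords):
            res.coords[name] = R @ res.coords[name] + t


def make_extended_strand(n: int, sequence: str | None = None,
                         chain_key: str = "strd_A",
                         resolution: float | None = None) -> BackboneStructure:
    """A single extended beta-strand with no hydrogen-bonding partner."""
    if n < 2:
        raise ValueError(f"strand needs >= 2 residues, got {n}")
    return build_chain_from_torsions([STRAND_PHI_PSI] * n, sequence=sequence,
                                     chain_key=chain_key,
                                     resolution=resolution)


def make_antiparallel_sheet(strand_len: int, separation: float = 4.8,
                            sequence: str | None = None,
                            chain_key: str = "shet_A",
                            resolution: float | None = None
                            ) -> BackboneStructure:
    """Two antiparallel extended strands with registered carbonyls.

    The second strand is the first rotated 180 degrees about the strand
    axis normal and translated by ``separation`` across the sheet plane,
    then shifted along the strand axis so amide N-H groups face the
    partner strand's carbonyls.  Residue numbering jumps between strands
    (seq gap 10) to mark the segment break.
    """
    if strand_len < 4:
        raise ValueError(f"strands need >= 4 residues, got {strand_len}")
    n = 2 * strand_len
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length != 2 * strand_len")

    a = build_chain_from_torsions([STRAND_PHI_PSI] * strand_len,
                                  sequence=sequence[:strand_len],
                                  chain_key=chain_key)
    b = build_chain_from_torsions([STRAND_PHI_PSI] * strand_len,
                                  sequence=sequence[strand_len:],
                                  chain_key=chain_key,
                                  start_seq_num=strand_len + 11)
    # the two-residue pleat means the C2 registration depends on strand
    # length parity; odd strands need half a residue rise extra
    register = _SHEET_REGISTER_SHIFT + (1.0 if strand_len % 2 else 0.0)
    axis, offset = _sheet_placement(a, separation, register)
    _transform(b, axis, offset)
    residues = a.residues + b.residues
    return BackboneStructure(chain_key=chain_key, residues=residues,
                             resolution=resolution)


def _sheet_placement(strand: BackboneStructure, separation: float,
                     register: float) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform placing an antiparallel partner next to ``strand``.

    Rotation: 180 degrees about the axis perpendicular to the strand
    direction within the sheet plane, which reverses the chain direction
    while keeping backbones roughly coplanar.  Translation: ``separation``
    along the sheet normal plus a registration shift along the strand
    axis (calibrated once against ideal-strand geometry; see the repo's
    methods note).
    """
    ca = np.array([r.coords["CA"] for r in strand.residues])
    # strand direction = first principal axis of CA positions
    centred = ca - ca.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0] / np.linalg.norm(vt[0])
    # sheet plane spanned by d and the CA pleat direction; normal from SVD
    normal = vt[2] / np.linalg.norm(vt[2])
    within = np.cross(normal, d)
    R = _rotation_about(within, 180.0)
    centre = ca.mean(axis=0)
    t = centre - R @ centre + separation * normal + register * d
    return R, t


#: Shift (A) of the partner strand along the strand axis that registers
#: carbonyls with amide protons for ideal (-139, 135) strands.
_SHEET_REGISTER_SHIFT = -2.8


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


# ---------------------------------------------------------------------------
# Synthetic predictors
# ---------------------------------------------------------------------------

@dataclass
class PredictorSpec:
    """Recipe for a synthetic design method.

    kinds:
      perfect            one-hot at the native residue
      uniform            0.05 everywhere
      constant           one-hot at ``letter`` regardless of the native
      biased             per residue: one-hot at ``letter`` with
                         probability ``strength``, else one-hot at the
                         native (expected accuracy 1 - s + s * f_letter)
      softmax_noise      softmax of Gaussian logits centred on the native
                         (logit gap 1/temperature, unit noise)
    """

    kind: str
    letter: str | None = None
    strength: float = 0.5
    temperature: float = 1.0
    seed: int = 0


def make_predictions(truth: str, spec: PredictorSpec,
                     chain_key: str = "synt_A",
                     model_name: str | None = None) -> PredictionSet:
    """Generate a probability matrix for one chain from a predictor spec."""
    for aa in truth:
        if aa not in AA_INDEX:
            raise ValueError(f"invalid letter {aa!r} in truth sequence")
    n = len(truth)
    idx = np.array([AA_INDEX[a] for a in truth])
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "perfect":
        mat = np.zeros((n, 20))
        mat[np.arange(n), idx] = 1.0
    elif spec.kind == "uniform":
        mat = np.full((n, 20), 0.05)
    elif spec.kind == "constant":
        if spec.letter not in AA_INDEX:
            raise ValueError(f"invalid constant letter {spec.letter!r}")
        mat = np.zeros((n, 20))
        mat[:, AA_INDEX[spec.letter]] = 1.0
    elif spec.kind == "biased":
        if spec.letter not in AA_INDEX:
            raise ValueError(f"invalid bias letter {spec.letter!r}")
        if not 0.0 <= spec.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        mat = np.zeros((n, 20))
        flip = rng.random(n) < spec.strength
        target = np.where(flip, AA_INDEX[spec.letter], idx)
        mat[np.arange(n), target] = 1.0
    elif spec.kind == "softmax_noise":
        if spec.temperature <= 0:
            raise ValueError("temperature must be > 0")
        logits = rng.standard_normal((n, 20))
        logits[np.arange(n), idx] += 1.0 / spec.temperature
        logits -= logits.max(axis=1, keepdims=True)
        mat = np.exp(logits)
        mat /= mat.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown predictor kind {spec.kind!r}")
    return PredictionSet(model_name=model_name or spec.kind,
                         chain_keys=[chain_key], rows={chain_key: mat})


def concat_predictions(model_name: str,
                       parts: list[PredictionSet]) -> PredictionSet:
    """Merge single-chain prediction sets into one multi-chain set."""
    chain_keys: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for p in parts:
        for key in p.chain_keys:
            if key in rows:
                raise ValueError(f"duplicate chain {key!r}")
            chain_keys.append(key)
            rows[key] = p.rows[key]
    return PredictionSet(model_name=model_name, chain_keys=chain_keys,
                         rows=rows)


# ---------------------------------------------------------------------------
# Toy benchmark on disk
# ---------------------------------------------------------------------------

#: (chain_key template, architecture code, builder) per fold class.
_TOY_RECIPES = [
    ("mainly-alpha", "1.10", "helix"),
    ("mainly-beta", "2.40", "sheet"),
    ("alpha-beta", "3.30", "mixed"),
    ("special", "6.10", "strand"),
]


def _toy_chain(kind: str, n: int, sequence: str, chain_key: str,
               resolution: float) -> BackboneStructure:
    if kind == "helix":
        return make_ideal_helix(n, sequence=sequence, chain_key=chain_key,
                                resolution=resolution)
    if kind == "sheet":
        half = n // 2
        return make_antiparallel_sheet(half, sequence=sequence[:2 * half],
                                       chain_key=chain_key,
                                       resolution=resolution)
    if kind == "mixed":
        half = n // 2
        torsions = [HELIX_PHI_PSI] * half + [STRAND_PHI_PSI] * (n - half)
        return build_chain_from_torsions(torsions, sequence=sequence,
                                         chain_key=chain_key,
                                         resolution=resolution)
    if kind == "strand":
        return make_extended_strand(n, sequence=sequence,
                                    chain_key=chain_key,
                                    resolution=resolution)
    raise ValueError(kind)


def published_composition_path() -> Path:
    """Path to the packaged published benchmark composition table."""
    return Path(resources.files("designbench") / "data" /
                "published_composition.csv")


def make_toy_benchmark(out_dir: str | Path, seed: int = 7,
                       chains_per_class: int = 2,
                       chain_len: int = 18) -> dict:
    """Write a miniature benchmark: structures, dataset map, truth
    sequences, DSSP-style label files and a sidecar manifest of planted
    per-fold-class counts.

    Emulates, at toy scale, a fold-balanced benchmark spanning all four
    CATH fold classes.  Returns the sidecar manifest as a dict.
    """
    from . import secstruct  # deferred: secstruct imports this module's types

    out_dir = Path(out_dir)
    structs_dir = out_dir / "structures"
    dssp_dir = out_dir / "dssp"
    try:
        structs_dir.mkdir(parents=True, exist_ok=True)
        dssp_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}")

    rng = np.random.default_rng(seed)
    entries = []
    truths = {}
    planted = {}
    for ci, (fold_class, arch, kind) in enumerate(_TOY_RECIPES):
        planted[fold_class] = chains_per_class
        for k in range(chains_per_class):
            pdb_id = f"tc{ci}{k}"
            chain_key = f"{pdb_id}_A"
            seq = "".join(rng.choice(list(ALPHABET), size=chain_len))
            resolution = float(np.round(1.0 + 2.0 * rng.random(), 2))
            st = _toy_chain(kind, chain_len, seq, chain_key, resolution)
            pdb_path = structs_dir / f"{pdb_id}.pdb"
            write_pdb(st, pdb_path, chain_id="A")
            labels = secstruct.assign_secondary_structure(st)
            write_dssp_file(
                [("A", r.seq_id, r.aa_true, lab.state8 or lab.state)
                 for r, lab in zip(st.residues, labels)],
                dssp_dir / f"{pdb_id}.dssp")
            truths[chain_key] = st.sequence
            entries.append((chain_key, arch,
                            str(Path("structures") / f"{pdb_id}.pdb")))

    with open(out_dir / "dataset_map.txt", "w") as fh:
        fh.write("# chain_key architecture_code structure_path\n")
        for chain_key, arch, rel in entries:
            fh.write(f"{chain_key} {arch} {rel}\n")
    with open(out_dir / "truth_sequences.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    shutil.copy(published_composition_path(),
                out_dir / "published_composition.csv")
    manifest = {"seed": seed, "chains_per_class": chains_per_class,
                "chain_len": chain_len,
                "planted_fold_class_counts": planted,
                "n_chains": sum(planted.values())}
    with open(out_dir / "planted_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
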