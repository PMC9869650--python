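"""Backbone torsion geometry and true-vs-predicted Ramachandran tables.

Torsion angles follow the IUPAC convention: phi(i) is the dihedral
C(i-1)-N(i)-CA(i)-C(i), psi(i) is N(i)-CA(i)-C(i)-N(i+1), signed,
right-handed, reported in degrees in (-180, 180].  Chain termini and
residues with missing neighbour atoms get absent angles (None) rather
than errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ALPHABET, BackboneStructure


class UndefinedTorsionError(ValueError):
    """Dihedral undefined: three consecutive points are colinear."""


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180].

    Right-handed convention: looking down the p2->p3 axis, a clockwise
    rotation of p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise UndefinedTorsionError("central points p2, p3 coincide")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedTorsionError("colinear points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond_length: float, bond_angle: float,
               torsion: float) -> np.ndarray:
    """Place a fourth point given three reference points and internal
    coordinates (NeRF construction).

    ``bond_angle`` is the angle b-c-new and ``torsion`` the dihedral
    a-b-c-new, both in degrees.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond_length * np.cos(theta),
                  bond_length * np.sin(theta) * np.cos(chi),
                  bond_length * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class TorsionPair:
    phi: float | None
    psi: float | None


def phi_psi(chain: BackboneStructure) -> list[TorsionPair]:
    """Backbone phi/psi for every residue; absent at termini and wherever
    a needed neighbour atom is missing."""
    out: list[TorsionPair] = []
    res = chain.residues
    for i, r in enumerate(res):
        phi = psi = None
        if i > 0 and "C" in res[i - 1].coords and all(
                a in r.coords for a in ("N", "CA", "C")):
            try:
                phi = dihedral(res[i - 1].coords["C"], r.coords["N"],
                               r.coords["CA"], r.coords["C"])
            except UndefinedTorsionError:
                phi = None
        if i + 1 < len(res) and "N" in res[i + 1].coords and all(
                a in r.coords for a in ("N", "CA", "C")):
            try:
                psi = dihedral(r.coords["N"], r.coords["CA"], r.coords["C"],
                               res[i + 1].coords["N"])
            except UndefinedTorsionError:
                psi = None
        out.append(TorsionPair(phi=phi, psi=psi))
    return out


#: Ramachandran histogram bin width in degrees (36x36 grid).
BIN_WIDTH = 10.0
N_BINS = int(360.0 / BIN_WIDTH)


def _bin_index(angle: float) -> int:
    """Bin an angle from (-180, 180] onto 0..35; each bin is (lo, hi]."""
    idx = int(np.ceil((angle + 180.0) / BIN_WIDTH)) - 1
    return min(max(idx, 0), N_BINS - 1)


@dataclass
class RamachandranTable:
    """Per-amino-acid (phi, psi) histograms under two labelings.

    ``bins[(aa, mode)]`` is a 36x36 count array; ``mode`` is ``"true"``
    (positions where the native residue is ``aa``) or ``"predicted"``
    (positions where the design method's argmax is ``aa``).
    """

    bins: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: aa, mode, phi_bin, psi_bin, count
        (zero-count cells omitted)."""
        records = []
        for (aa, mode), hist in sorted(self.bins.items()):
            for i, j in zip(*np.nonzero(hist)):
                records.append((aa, mode,
                                -180.0 + BIN_WIDTH * i, -180.0 + BIN_WIDTH * j,
                                int(hist[i, j])))
        return pd.DataFrame(records,
                            columns=["aa", "mode", "phi_bin", "psi_bin",
                                     "count"])


def ramachandran_comparison(torsions: list[TorsionPair], true_seq: str,
                            predicted_seq: str) -> RamachandranTable:
    """Histogram backbone torsions at positions where each amino acid is
    the native residue versus where it is the predicted one.

    Contrasting the two distributions for one residue type reveals
    overprediction into conformational regions the type does not
    naturally occupy.  Positions with an absent phi or psi contribute to
    neither histogram.
    """
    if not (len(torsions) == len(true_seq) == len(predicted_seq)):
        raise ValueError(
            f"length mismatch: {len(torsions)} torsions, "
            f"{len(true_seq)} true, {len(predicted_seq)} predicted")
    table = RamachandranTable()
    for aa in ALPHABET:
        table.bins[(aa, "true")] = np.zeros((N_BINS, N_BINS), dtype=int)
        table.bins[(aa, "predicted")] = np.zeros((N_BINS, N_BINS), dtype=int)
    for tp, t, p in zip(torsions, true_seq, predicted_seq):
        if tp.phi is None or tp.psi is None:
            continue
        i, j = _bin_index(tp.phi), _bin_index(tp.psi)
        if (t, "true") in table.bins:
            table.bins[(t, "true")][i, j] += 1
        if (p, "predicted") in table.bins:
            table.bins[(p, "predicted")][i, j] += 1
    return table
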