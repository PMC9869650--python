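"""Secondary-structure assignment from backbone hydrogen bonds.

Two routes produce per-residue labels:

* a built-in simplified Kabsch–Sander assigner — place amide hydrogens,
  score N-H...O=C hydrogen bonds with the classic electrostatic model,
  then detect alpha-helix turns and beta-bridge ladders; emits the
  3-state alphabet {H, E, C} only,
* import of precomputed DSSP output files, whose 8-state codes are kept
  and reduced to the same 3-state alphabet.

The built-in assigner deliberately skips 3-10/pi helix classes, bends
and beta-bulges; it exists so the pipeline is testable without an
external binary and agrees with DSSP on regular elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BackboneStructure

#: Hydrogen-bond energy threshold (kcal/mol): bonds must be below this.
HBOND_ENERGY_CUTOFF = -0.5
#: Minimum |donor - acceptor| sequence separation for a bond.
MIN_SEQ_SEPARATION = 2
#: Coupling constant of the Kabsch-Sander electrostatic model:
#: q1*q2*332 with partial charges 0.42 and 0.20.
KS_COUPLING = 0.084 * 332
#: Amide N-H bond length used when reconstructing hydrogens (A).
NH_BOND_LENGTH = 1.01

EIGHT_TO_THREE = {"H": "H", "G": "H", "I": "H",
                  "E": "E", "B": "E",
                  "T": "C", "S": "C", "C": "C"}


class ClashError(ValueError):
    """Atoms closer than the clash guard: energy model invalid."""


@dataclass
class HBond:
    """Backbone hydrogen bond: C=O of ``acceptor_index`` to N-H of
    ``donor_index``."""

    donor_index: int
    acceptor_index: int
    energy: float


@dataclass
class SSLabel:
    state: str            # 3-state: H, E or C
    state8: str | None = None  # 8-state code when known (DSSP import)
    excluded: bool = False     # residue incomplete; label defaulted to C


def reduce_8_to_3(state8: str) -> str:
    """Collapse the 8-state alphabet: helices (H,G,I) -> H, strands
    (E,B) -> E, everything else -> C."""
    try:
        return EIGHT_TO_THREE[state8]
    except KeyError:
        raise ValueError(f"unknown 8-state code {state8!r}") from None


def place_amide_hydrogens(chain: BackboneStructure) -> list[np.ndarray | None]:
    """Reconstruct backbone amide hydrogen positions.

    H sits ``NH_BOND_LENGTH`` from N along the normalized sum of the unit
    vectors N - C(prev) and N - CA, an approximation of the DSSP
    convention.  The first residue (no preceding carbonyl) and prolines
    (no amide proton) get None, as does any residue missing the needed
    atoms.
    """
    out: list[np.ndarray | None] = []
    res = chain.residues
    for i, r in enumerate(res):
        if i == 0 or r.aa_true == "P":
            out.append(None)
            continue
        prev = res[i - 1]
        if "C" not in prev.coords or "N" not in r.coords or "CA" not in r.coords:
            out.append(None)
            continue
        n = r.coords["N"]
        v1 = n - prev.coords["C"]
        v2 = n - r.coords["CA"]
        v1 = v1 / np.linalg.norm(v1)
        v2 = v2 / np.linalg.norm(v2)
        u = v1 + v2
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            out.append(None)
            continue
        out.append(n + NH_BOND_LENGTH * u / norm)
    return out


def kabsch_sander_energy(n: np.ndarray, h: np.ndarray, c: np.ndarray,
                         o: np.ndarray) -> float:
    """Electrostatic hydrogen-bond energy (kcal/mol) of an N-H donor and
    a C=O acceptor:

        E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332

    Strongly negative for short, linear N-H...O=C geometry; vanishes as
    the groups separate.  Distances below 0.5 A raise :class:`ClashError`.
    """
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    for name, r in (("ON", r_on), ("CH", r_ch), ("OH", r_oh), ("CN", r_cn)):
        if r <= 0.5:
            raise ClashError(f"distance {name} = {r:.3f} A <= 0.5 A")
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def find_hbonds(chain: BackboneStructure) -> list[HBond]:
    """All backbone hydrogen bonds with energy below the cutoff and
    sequence separation >= ``MIN_SEQ_SEPARATION``."""
    hydrogens = place_amide_hydrogens(chain)
    res = chain.residues
    bonds: list[HBond] = []
    for j, r_don in enumerate(res):  # donor N-H
        h = hydrogens[j]
        if h is None or "N" not in r_don.coords:
            continue
        n = r_don.coords["N"]
        for i, r_acc in enumerate(res):  # acceptor C=O
            if abs(i - j) < MIN_SEQ_SEPARATION:
                continue
            if "C" not in r_acc.coords or "O" not in r_acc.coords:
                continue
            c, o = r_acc.coords["C"], r_acc.coords["O"]
            # cheap distance gate before the 4-distance energy
            if np.linalg.norm(o - n) > 5.0:
                continue
            e = kabsch_sander_energy(n, h, c, o)
            if e < HBOND_ENERGY_CUTOFF:
                bonds.append(HBond(donor_index=j, acceptor_index=i, energy=e))
    return bonds


def assign_secondary_structure(chain: BackboneStructure) -> list[SSLabel]:
    """Built-in 3-state assignment from reconstructed hydrogen bonds.

    Alpha-helix: residues i..i+3 wherever 4-turns start at both i-1 and
    i (i.e. C=O(i-1)->N-H(i+3) and C=O(i)->N-H(i+4) bonds exist).
    Strand: any residue in a parallel or antiparallel bridge, detected
    by the classic two-bond patterns.  Helix takes precedence over
    strand; everything else, including incomplete residues, is coil.
    """
    n = len(chain.residues)
    if n == 0:
        return []
    # co_nh[(i, j)]: carbonyl of residue i accepts from amide of residue j
    co_nh = {(b.acceptor_index, b.donor_index)
             for b in find_hbonds(chain)}

    def hb(i: int, j: int) -> bool:
        return (i, j) in co_nh

    states = ["C"] * n
    # bridges first, helix overwrites
    for i in range(1, n - 1):
        for j in range(i + MIN_SEQ_SEPARATION + 1, n - 1):
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or \
                       (hb(j - 1, i) and hb(i, j + 1))
            antiparallel = (hb(i, j) and hb(j, i)) or \
                           (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if parallel or antiparallel:
                states[i] = "E"
                states[j] = "E"
    for i in range(1, n - 4):
        if hb(i - 1, i + 3) and hb(i, i + 4):
            for k in range(i, i + 4):
                states[k] = "H"

    labels = []
    for i, r in enumerate(chain.residues):
        if not r.complete:
            labels.append(SSLabel(state="C", state8=None, excluded=True))
        else:
            labels.append(SSLabel(state=states[i], state8=None))
    return labels


def labels_from_dssp(triples: list[tuple[str, str, str]],
                     chain: BackboneStructure) -> list[SSLabel]:
    """Align imported DSSP triples to a chain by residue order.

    The DSSP file may cover several chains; only records for the chain's
    identifier (last ``_`` component of the chain key) are used, and
    their count must match the chain length.
    """
    chain_id = chain.chain_key.rsplit("_", 1)[-1]
    codes = [code for (c, _num, code) in triples if c == chain_id]
    if len(codes) != len(chain.residues):
        raise ValueError(
            f"DSSP records for chain {chain_id!r}: {len(codes)}, "
            f"structure has {len(chain.residues)} residues")
    return [SSLabel(state=reduce_8_to_3(code), state8=code)
            for code in codes]
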