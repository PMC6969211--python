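"""Rigid superposition, salt-bridge detection, phosphomimetic mutation,
and trajectory post-processing.

The structural question behind this module: the phosphate of a
phosphorylated activation-loop serine (SEP) donates salt bridges to three
basic side chains (in RSK2: Arg114 on the αC-helix, Arg192 in the catalytic
loop, Lys216 after the DFG motif).  An aspartate substituted at the same
position carries its carboxylate oxygens roughly 2 Å closer to the backbone
and cannot reach the full network.  The operations here measure exactly
that: minimum acidic-O to basic-N distances, optimal-superposition RMSD
between conformations, and per-residue fluctuations over a trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .pdbio import AtomRecord, StructureModel, Trajectory

#: Acidic oxygen atoms able to accept/donate the salt bridge, per residue type.
ACIDIC_O = {
    "SEP": ("O1P", "O2P", "O3P", "OG"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
#: Basic nitrogen atoms of the positively charged side chains.
BASIC_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}

#: Default charged-group heavy-atom cutoff (Å).  Chosen to split an
#: interacting carboxylate-guanidinium pair (~3.9 Å) from a non-interacting
#: one (~5.2 Å); direct phosphate bridges sit near 2.2-3.2 Å.
SALT_BRIDGE_CUTOFF = 4.0


@dataclass(frozen=True)
class ContactRecord:
    """One acidic-oxygen / basic-nitrogen contact, at its minimum distance."""

    acidic_residue: tuple[str, int, str]  # (chain, number, residue_name)
    basic_residue: tuple[str, int, str]
    min_distance: float
    atom_pair: tuple[str, str]  # (acidic O name, basic N name)

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("non-positive contact distance")


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid transform mapping X onto Y.

    Returns (R, t, rmsd) with R a proper rotation (SVD with determinant
    sign correction, reflections excluded) and
    rmsd = sqrt(mean |R x + t - y|^2).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"size mismatch: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xc, Y - yc
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff**2).sum() / len(X)))
    return R, t, rmsd


def matched_ca_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    pairing: Sequence[tuple[int, int]],
    chain_a: str = "A",
    chain_b: str = "A",
) -> float:
    """Kabsch RMSD over paired CA atoms of two structures.

    *pairing* lists (residue_number_in_a, residue_number_in_b) pairs,
    typically derived from a sequence alignment of the two chains.  A paired
    residue missing its CA atom is an error naming the residue.
    """
    xa, xb = [], []
    for na, nb in pairing:
        try:
            a = model_a.atom(chain_a, na, "CA")
        except KeyError:
            raise KeyError(f"residue {chain_a}:{na} has no CA atom") from None
        try:
            b = model_b.atom(chain_b, nb, "CA")
        except KeyError:
            raise KeyError(f"residue {chain_b}:{nb} has no CA atom") from None
        xa.append(a.coords)
        xb.append(b.coords)
    return kabsch_superpose(np.array(xa), np.array(xb))[2]


def saltbridge_network(
    model: StructureModel,
    center: tuple[str, int],
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> list[ContactRecord]:
    """Basic residues whose side-chain N comes within *cutoff* of the
    center residue's acidic oxygens.

    *center* is (chain, residue_number) of a SEP, ASP or GLU residue.  One
    ContactRecord per contacting basic residue, carrying the minimum O-N
    distance and the atom pair achieving it; sorted by distance.
    """
    chain, number = center
    center_atoms = model.residue(chain, number)
    if not center_atoms:
        raise KeyError(f"center residue {chain}:{number} not found")
    resname = center_atoms[0].residue_name
    if resname not in ACIDIC_O:
        raise ValueError(
            f"center residue {chain}:{number} is {resname}, expected SEP/ASP/GLU"
        )
    o_atoms = [a for a in center_atoms if a.name in ACIDIC_O[resname]]
    contacts: list[ContactRecord] = []
    for ckey in model.residues():
        cchain, cnum, cname = ckey
        if cname not in BASIC_N or (cchain, cnum) == (chain, number):
            continue
        n_atoms = [
            a
            for a in model.residue(cchain, cnum)
            if a.name in BASIC_N[cname]
        ]
        best: tuple[float, str, str] | None = None
        for oa in o_atoms:
            for na in n_atoms:
                dist = math.dist(oa.coords, na.coords)
                if best is None or dist < best[0]:
                    best = (dist, oa.name, na.name)
        if best is not None and best[0] <= cutoff:
            contacts.append(
                ContactRecord(
                    acidic_residue=(chain, number, resname),
                    basic_residue=ckey,
                    min_distance=best[0],
                    atom_pair=(best[1], best[2]),
                )
            )
    return sorted(contacts, key=lambda c: c.min_distance)


# --- Ser -> Asp side-chain rebuild -----------------------------------------

# Ideal internal coordinates for the aspartate side chain (Engh-Huber-like).
_BOND_CB_CG = 1.516
_BOND_CG_OD = 1.249
_ANGLE_CA_CB_CG = 113.4
_ANGLE_CB_CG_OD = 118.4

#: Candidate rotamers: chi1 x chi2 grid, scanned in this order.
CHI1_CANDIDATES = (-60.0, 60.0, 180.0)
CHI2_CANDIDATES = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)

CLASH_DISTANCE = 2.8  # heavy-atom clash threshold (Å)
CLASH_WEIGHT = -10.0
SALT_BRIDGE_REWARD_CUTOFF = 4.0
SALT_BRIDGE_WEIGHT = 1.0


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom d from three reference atoms and internal coordinates
    (standard natural-extension/NeRF construction): |c-d| = bond,
    angle(b,c,d) = angle, dihedral(a,b,c,d) = dihedral."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            -bond * math.sin(angle) * math.cos(dihedral),
            -bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def mutate_ser_to_asp(
    model: StructureModel,
    residue: tuple[str, int],
    chi1_candidates: Sequence[float] = CHI1_CANDIDATES,
    chi2_candidates: Sequence[float] = CHI2_CANDIDATES,
) -> StructureModel:
    """Replace a Ser (or phospho-Ser) side chain with an ideal-geometry Asp.

    The backbone (N, CA, C, O) and CB are kept in place; OG and any
    phosphate atoms are removed; CG, OD1, OD2 are built from ideal internal
    coordinates over a chi1 x chi2 rotamer grid.  Each candidate is scored
    by -10 per heavy-atom clash (< 2.8 Å to any atom outside the mutated
    residue) plus +1 per carboxylate oxygen within 4.0 Å of a basic
    side-chain nitrogen; the best-scoring candidate wins, ties broken by
    candidate order.  No atom outside the mutated residue moves.
    """
    chain, number = residue
    res_atoms = model.residue(chain, number)
    if not res_atoms:
        raise KeyError(f"residue {chain}:{number} not found")
    resname = res_atoms[0].residue_name
    if resname not in ("SER", "SEP"):
        raise ValueError(
            f"residue {chain}:{number} is {resname}, expected SER or SEP"
        )
    by_name = {a.name: a for a in res_atoms}
    for needed in ("N", "CA", "C", "CB"):
        if needed not in by_name:
            raise ValueError(
                f"residue {chain}:{number} missing backbone atom {needed}"
            )
    n = np.array(by_name["N"].coords)
    ca = np.array(by_name["CA"].coords)
    cb = np.array(by_name["CB"].coords)

    environment = [
        np.array(a.coords)
        for a in model.atoms
        if not (a.chain == chain and a.residue_number == number)
    ]
    env = np.array(environment) if environment else np.empty((0, 3))
    basic_n = [
        np.array(a.coords)
        for a in model.atoms
        if a.residue_name in BASIC_N
        and a.name in BASIC_N.get(a.residue_name, ())
        and not (a.chain == chain and a.residue_number == number)
    ]
    basic = np.array(basic_n) if basic_n else np.empty((0, 3))

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for chi1 in chi1_candidates:
        cg = place_atom(n, ca, cb, _BOND_CB_CG, _ANGLE_CA_CB_CG, chi1)
        for chi2 in chi2_candidates:
            od1 = place_atom(ca, cb, cg, _BOND_CG_OD, _ANGLE_CB_CG_OD, chi2)
            od2 = place_atom(
                ca, cb, cg, _BOND_CG_OD, _ANGLE_CB_CG_OD, chi2 + 180.0
            )
            score = 0.0
            for atom in (cg, od1, od2):
                if len(env) and (
                    np.linalg.norm(env - atom, axis=1) < CLASH_DISTANCE
                ).any():
                    score += CLASH_WEIGHT
            for atom in (od1, od2):
                if len(basic) and (
                    np.linalg.norm(basic - atom, axis=1)
                    <= SALT_BRIDGE_REWARD_CUTOFF
                ).any():
                    score += SALT_BRIDGE_WEIGHT
            if best is None or score > best[0]:
                best = (score, cg, od1, od2)
    assert best is not None
    _, cg, od1, od2 = best

    keep_names = ("N", "CA", "C", "O", "CB", "OXT")
    new_atoms: list[AtomRecord] = []
    serial = 0
    placed = False
    for a in model.atoms:
        if a.chain == chain and a.residue_number == number:
            if a.name not in keep_names:
                continue
            serial += 1
            new_atoms.append(
                replace(a, serial=serial, residue_name="ASP", het=False)
            )
            if a.name == "CB" and not placed:
                for nm, xyz in (("CG", cg), ("OD1", od1), ("OD2", od2)):
                    serial += 1
                    new_atoms.append(
                        AtomRecord(
                            serial=serial,
                            name=nm,
                            residue_name="ASP",
                            chain=chain,
                            residue_number=number,
                            coords=tuple(float(v) for v in xyz),
                            element=nm[0],
                        )
                    )
                placed = True
        else:
            serial += 1
            new_atoms.append(replace(a, serial=serial))
    return StructureModel(atoms=new_atoms, model_id=model.model_id)


# --- Trajectory post-processing --------------------------------------------

def rmsd_trace(
    traj: Trajectory,
    reference: StructureModel,
    selection: Callable[[AtomRecord], bool] | None = None,
) -> list[tuple[int, float]]:
    """Per-frame RMSD to *reference* after Kabsch superposition on the
    selected atoms (default: CA atoms)."""
    selection = selection or (lambda a: a.name == "CA")
    ref_idx = [i for i, a in enumerate(reference.atoms) if selection(a)]
    if not ref_idx:
        raise ValueError("empty atom selection in reference")
    roster = [
        (reference.atoms[i].chain, reference.atoms[i].residue_number,
         reference.atoms[i].name)
        for i in ref_idx
    ]
    out: list[tuple[int, float]] = []
    for frame, m in enumerate(traj.models):
        idx = [i for i, a in enumerate(m.atoms) if selection(a)]
        r = [(m.atoms[i].chain, m.atoms[i].residue_number, m.atoms[i].name)
             for i in idx]
        if r != roster:
            raise ValueError(f"frame {frame}: selection roster mismatch")
        X = m.coords()[idx]
        Y = reference.coords()[ref_idx]
        out.append((frame, kabsch_superpose(X, Y)[2]))
    return out


def rmsf(
    traj: Trajectory,
    selection: Callable[[AtomRecord], bool] | None = None,
    refinement_passes: int = 2,
) -> list[tuple[tuple[str, int], float]]:
    """Per-residue root-mean-square fluctuation (Å) over the trajectory.

    Frames are superposed (on the selected atoms, default CA) to the mean
    structure, the mean is recomputed, and the superposition repeated for
    *refinement_passes* rounds; RMSF_i = sqrt(mean_t |r_i(t) - r_mean_i|^2).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    selection = selection or (lambda a: a.name == "CA")
    m0 = traj.models[0]
    idx = [i for i, a in enumerate(m0.atoms) if selection(a)]
    if not idx:
        raise ValueError("empty atom selection")
    keys = [(m0.atoms[i].chain, m0.atoms[i].residue_number) for i in idx]
    frames = traj.coords()[:, idx, :]  # (T, n, 3)

    aligned = frames.copy()
    mean = aligned.mean(axis=0)
    for _ in range(refinement_passes):
        for t in range(aligned.shape[0]):
            R, tr, _ = kabsch_superpose(frames[t], mean)
            aligned[t] = frames[t] @ R.T + tr
        mean = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    return list(zip(keys, fluct.tolist()))
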