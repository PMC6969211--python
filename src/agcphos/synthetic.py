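"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real analysis —
a kinome whose activation-loop (AL) and hydrophobic-motif (HM) sites occupy
known states with known co-occurrence between a phosphorylatable AL and
basic phosphate-coordination residues; structure pairs related by a known
rigid motion; phospho-site neighbourhoods with planted minimum O-N contact
distances; trajectories with known per-residue fluctuation.  They do not
emulate indel evolution, force-field energetics or real kinase sequences:
every label is verifiable by re-measuring the emitted output.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pdbio import AtomRecord, StructureModel, Trajectory
from .seqio import Alignment, KinaseSeq

# ---------------------------------------------------------------------------
# Kinome generator
# ---------------------------------------------------------------------------

#: Default AL/HM state mixes: the observed composition of the 61-member human
#: AGC kinome (43 phosphorylatable AL, 17 substituted, 1 without a conserved
#: activation segment; 32 phosphorylatable HM, 5 phosphomimetic, 16 other or
#: truncated, 8 absent).
AL_STATE_PROBS_DEFAULT = {
    "phosphorylatable": 43 / 61,
    "phosphomimetic": 0.0,
    "other": 17 / 61,
    "absent": 1 / 61,
}
HM_STATE_PROBS_DEFAULT = {
    "phosphorylatable": 32 / 61,
    "phosphomimetic": 5 / 61,
    "other": 16 / 61,
    "absent": 8 / 61,
}
#: P(basic residue at the triad site | AL phosphorylatable) and
#: P(basic | AL not phosphorylatable).  The αC-helix site (R114) is basic in
#: 25 of the 43 phospho-AL kinases and never otherwise; the catalytic-loop
#: site (R192) is universally conserved; the post-DFG site (K216) tracks the
#: phosphorylatable AL.
TRIAD_GIVEN_AL_DEFAULT = {
    "R114_site": (25 / 43, 0.0),
    "R192_site": (1.0, 1.0),
    "K216_site": (1.0, 0.0),
}

# Template layout (0-based positions in the 290-residue synthetic domain).
SEQ_LEN = 290
POS_R114 = 85
POS_R192 = 160
POS_DFG = 170  # D F G at 170..172
POS_K216 = 175
POS_AL = 190  # AL phospho-site; G at 193, T at 194 complete the consensus
POS_APE = 196  # A P E at 196..198 -> segment length 29
POS_HM = 284  # z of F-x-x-F-z-F at 280..285

#: Residues used for non-motif fill and substitution noise.  D, E, F, G, P,
#: S, T, Y are excluded so random positions can never assemble a spurious
#: DFG, APE-like terminator, S/T-x-x-G-T consensus or F-x-x-F/Y motif; the
#: planted truth therefore stays unambiguous under any noise level.
FILL_ALPHABET = "ACHIKLMNQRVW"
#: Non-basic, non-phospho, non-mimetic letters for negative triad/site draws.
NEUTRAL = "ACILMNQVW"

MOTIF_COLUMNS = frozenset(
    [POS_R114, POS_R192, POS_K216, POS_AL, 193, 194, POS_HM]
    + list(range(POS_DFG, POS_DFG + 3))
    + list(range(POS_APE, POS_APE + 3))
    + [280, 283, 285]
)


@dataclass
class KinomeTruth:
    """Ground-truth labels for one generated kinase family."""

    ids: list[str]
    al_state: dict[str, str]
    al_position: dict[str, int | None]
    hm_state: dict[str, str]
    hm_position: dict[str, int | None]
    triad: dict[str, dict[str, str]]  # id -> site -> residue
    params: dict = field(default_factory=dict)

    def triad_basic(self, kid: str, site: str) -> bool:
        return self.triad[kid][site] in "RKH"


def _allocate(n: int, probs: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of n items to states (deterministic)."""
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    raw = {k: n * p for k, p in probs.items()}
    base = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))[:short]:
        base[k] += 1
    out: list[str] = []
    for k in probs:  # insertion order: deterministic
        out.extend([k] * base[k])
    return out


def gen_kinase_family(
    n: int = 61,
    al_state_probs: dict[str, float] | None = None,
    hm_state_probs: dict[str, float] | None = None,
    triad_given_al: dict[str, tuple[float, float]] | None = None,
    mutation_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[KinaseSeq], Alignment, KinomeTruth]:
    """Generate a kinase family with planted AL/HM/triad truth.

    State counts — and the number of basic triad residues within the
    phospho-AL and non-phospho-AL groups — are allocated deterministically
    from the probabilities (largest-remainder rounding, assignment shuffled
    by seed) so that the default parameters reproduce the real kinome's
    composition exactly at n = 61 (43 phospho-AL, 25 of them with a basic
    alpha-C site, and so on).  Substitution noise at rate *mutation_rate*
    hits non-motif
    columns only, from an alphabet that cannot create spurious motifs.  The
    alignment is indel-free, so it equals the sequences themselves.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    al_state_probs = al_state_probs or AL_STATE_PROBS_DEFAULT
    hm_state_probs = hm_state_probs or HM_STATE_PROBS_DEFAULT
    triad_given_al = triad_given_al or TRIAD_GIVEN_AL_DEFAULT
    rng = np.random.default_rng(seed)

    template = _template(rng)
    ids = [f"KIN{i:03d}" for i in range(n)]

    al_states = _allocate(n, al_state_probs)
    hm_states = _allocate(n, hm_state_probs)
    rng.shuffle(al_states)
    rng.shuffle(hm_states)

    # triad sites: exact-count allocation of basic residues within the
    # phospho-AL and non-phospho-AL groups, so the planted co-occurrence
    # (e.g. basic alpha-C residue in 25 of 43 phospho-AL kinases) is the
    # stated condition, not a binomial draw around it
    phospho_idx = [i for i, s in enumerate(al_states) if s == "phosphorylatable"]
    other_idx = [i for i, s in enumerate(al_states) if s != "phosphorylatable"]
    triad_basic_flags: dict[str, np.ndarray] = {}
    for site, (p_if, p_else) in triad_given_al.items():
        flags = np.zeros(n, dtype=bool)
        for group, p in ((phospho_idx, p_if), (other_idx, p_else)):
            if not group:
                continue
            k = int(round(p * len(group)))
            chosen = rng.choice(len(group), size=k, replace=False)
            for c in chosen:
                flags[group[int(c)]] = True
        triad_basic_flags[site] = flags

    canonical_basic = {"R114_site": "R", "R192_site": "R", "K216_site": "K"}
    site_pos = {"R114_site": POS_R114, "R192_site": POS_R192, "K216_site": POS_K216}

    truth = KinomeTruth(
        ids=ids,
        al_state={},
        al_position={},
        hm_state={},
        hm_position={},
        triad={},
        params={
            "n": n,
            "al_state_probs": dict(al_state_probs),
            "hm_state_probs": dict(hm_state_probs),
            "triad_given_al": {k: list(v) for k, v in triad_given_al.items()},
            "mutation_rate": mutation_rate,
            "seed": seed,
        },
    )

    seqs: list[KinaseSeq] = []
    for idx, (kid, al_state, hm_state) in enumerate(zip(ids, al_states, hm_states)):
        s = list(template)
        # AL site
        if al_state == "phosphorylatable":
            s[POS_AL] = rng.choice(list("ST"))
            truth.al_position[kid] = POS_AL
        elif al_state == "phosphomimetic":
            s[POS_AL] = rng.choice(list("DE"))
            truth.al_position[kid] = POS_AL
        elif al_state == "other":
            s[POS_AL] = rng.choice(list(NEUTRAL))
            truth.al_position[kid] = POS_AL
        else:  # absent: no conserved activation segment
            for p in range(POS_DFG, POS_DFG + 3):
                s[p] = rng.choice(list(NEUTRAL))
            s[POS_AL] = rng.choice(list(NEUTRAL))
            truth.al_position[kid] = None
        truth.al_state[kid] = al_state
        # HM site
        if hm_state == "phosphorylatable":
            s[POS_HM] = rng.choice(list("ST"))
            truth.hm_position[kid] = POS_HM
        elif hm_state == "phosphomimetic":
            s[POS_HM] = rng.choice(list("DE"))
            truth.hm_position[kid] = POS_HM
        elif hm_state == "other":
            s[POS_HM] = rng.choice(list(NEUTRAL))
            truth.hm_position[kid] = POS_HM
        else:  # absent: destroy the aromatic anchors
            for p in (280, 283, 285):
                s[p] = rng.choice(list(NEUTRAL))
            s[POS_HM] = rng.choice(list(NEUTRAL))
            truth.hm_position[kid] = None
        truth.hm_state[kid] = hm_state
        # triad columns, conditional on AL phosphorylatability
        triad_res: dict[str, str] = {}
        for site in triad_given_al:
            if triad_basic_flags[site][idx]:
                triad_res[site] = canonical_basic[site]
            else:
                triad_res[site] = str(rng.choice(list(NEUTRAL)))
            s[site_pos[site]] = triad_res[site]
        truth.triad[kid] = triad_res
        # substitution noise at non-motif columns only
        if mutation_rate > 0:
            hits = np.nonzero(rng.random(SEQ_LEN) < mutation_rate)[0]
            for p in hits:
                if int(p) in MOTIF_COLUMNS:
                    continue
                choices = [c for c in FILL_ALPHABET if c != s[p]]
                s[p] = str(rng.choice(choices))
        seqs.append(KinaseSeq(id=kid, residues="".join(s)))

    msa = Alignment(rows=[(q.id, q.residues) for q in seqs])
    return seqs, msa, truth


def _template(rng: np.random.Generator) -> str:
    s = [str(c) for c in rng.choice(list(FILL_ALPHABET), size=SEQ_LEN)]
    s[POS_DFG : POS_DFG + 3] = list("DFG")
    s[POS_APE : POS_APE + 3] = list("APE")
    s[193], s[194] = "G", "T"  # consensus anchor S/T-x-x-G-T
    s[280], s[283], s[285] = "F", "F", "F"  # HM anchors F-x-x-F-z-F
    return "".join(s)


# ---------------------------------------------------------------------------
# Geometry generators
# ---------------------------------------------------------------------------


@dataclass
class GeometryTruth:
    """What was planted: transforms, distances, fluctuations."""

    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    noise_sigma: float | None = None
    contact_distances: list[tuple[str, float]] = field(default_factory=list)
    per_residue_sigma: np.ndarray | None = None
    seed: int = 0


def _ca_model(xyz: np.ndarray, model_id: int = 1) -> StructureModel:
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            residue_name="ALA",
            chain="A",
            residue_number=i + 1,
            coords=tuple(float(v) for v in row),
            element="C",
        )
        for i, row in enumerate(xyz)
    ]
    return StructureModel(atoms=atoms, model_id=model_id)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def gen_structure_pair(
    n_atoms: int = 100,
    rotation_angle_deg: float = 30.0,
    translation: tuple[float, float, float] = (5.0, -3.0, 2.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, GeometryTruth]:
    """A random CA cloud and its rigidly moved (optionally jittered) copy.

    B = R·A + t + N(0, σ²) per coordinate; with σ = 0 the optimal
    superposition RMSD is exactly 0, otherwise it approaches σ√3 for large
    n (three coordinates each contributing σ²).
    """
    if n_atoms < 3:
        raise ValueError("need n_atoms >= 3")
    rng = np.random.default_rng(seed)
    A = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    axis = rng.normal(size=3)
    R = rotation_matrix(axis, rotation_angle_deg)
    t = np.asarray(translation, dtype=float)
    B = A @ R.T + t
    if noise_sigma > 0:
        B = B + rng.normal(scale=noise_sigma, size=B.shape)
    truth = GeometryTruth(
        rotation=R, translation=t, noise_sigma=noise_sigma, seed=seed
    )
    return _ca_model(A, 1), _ca_model(B, 2), truth


# fragment atom layouts: (atom name, offset along the outward axis beyond the
# contact nitrogen); the first listed nitrogen is the contact atom.
_FRAGMENTS = {
    "ARG": [("NH1", 0.0), ("CZ", 1.33), ("NH2", 2.2), ("NE", 2.4), ("CD", 3.6)],
    "LYS": [("NZ", 0.0), ("CE", 1.49), ("CD", 2.9)],
    "HIS": [("NE2", 0.0), ("CE1", 1.32), ("ND1", 2.15), ("CG", 2.3)],
}


def gen_phospho_site_structure(
    contact_spec: list[tuple[str, float]],
    center_type: str = "SEP",
    seed: int = 0,
) -> tuple[StructureModel, GeometryTruth]:
    """A phospho-Ser (or Asp) residue surrounded by basic side-chain
    fragments at planted minimum O-N distances.

    Each (residue_type, distance) entry places an ARG/LYS/HIS fragment on
    its own outward direction so that the minimum distance from any acidic
    oxygen of the centre to any basic nitrogen of that fragment equals the
    requested value to within 1e-6 Å.  Distances below 1.5 Å are rejected
    as physically impossible packing.
    """
    for rtype, dist in contact_spec:
        if rtype not in _FRAGMENTS:
            raise ValueError(f"unsupported basic residue type {rtype!r}")
        if dist <= 1.5:
            raise ValueError(f"infeasible contact distance {dist} Å")
    rng = np.random.default_rng(seed)

    atoms: list[AtomRecord] = []
    serial = 0

    def add(name, resname, resnum, xyz, element=None, het=False):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                residue_name=resname,
                chain="A",
                residue_number=resnum,
                coords=tuple(float(v) for v in xyz),
                element=element or name[0],
                het=het,
            )
        )

    # centre residue around the origin: backbone + side chain
    resnum = 227  # author-style numbering of the planted phospho-site
    add("N", center_type, resnum, (-1.46, 1.05, 0.0))
    add("CA", center_type, resnum, (0.0, 1.1, 0.0))
    add("C", center_type, resnum, (0.74, 2.4, 0.0))
    add("O", center_type, resnum, (0.2, 3.5, 0.0))
    add("CB", center_type, resnum, (0.55, 0.0, 0.95))
    if center_type == "SEP":
        og = np.array([0.3, -1.3, 0.4])
        add("OG", center_type, resnum, og, het=True)
        p = og + np.array([0.0, -1.4, 0.6])
        add("P", center_type, resnum, p, element="P", het=True)
        for i, off in enumerate(
            [(1.35, -0.5, 0.0), (-1.2, -0.8, 0.2), (0.0, -0.6, -1.4)]
        ):
            add(f"O{i + 1}P", center_type, resnum, p + np.array(off), het=True)
    elif center_type == "ASP":
        cg = np.array([0.2, -1.35, 0.6])
        add("CG", center_type, resnum, cg)
        add("OD1", center_type, resnum, cg + np.array([1.15, -0.5, 0.0]))
        add("OD2", center_type, resnum, cg + np.array([-1.0, -0.7, 0.3]))
    else:
        raise ValueError(f"unsupported centre type {center_type!r}")

    from .geometry import ACIDIC_O  # local import avoids a cycle

    o_xyz = np.array(
        [a.coords for a in atoms if a.name in ACIDIC_O[center_type]]
    )

    m = len(contact_spec)
    truth = GeometryTruth(seed=seed)
    for k, (rtype, dist) in enumerate(contact_spec):
        # well-separated outward directions, mildly randomised in z
        az = 2 * math.pi * k / max(m, 1)
        u = np.array(
            [math.cos(az), math.sin(az) * 0.2 - 0.6, math.sin(az)]
        ) + rng.normal(scale=0.05, size=3)
        u /= np.linalg.norm(u)
        # the oxygen most extremal along u is the guaranteed closest approach
        o_ref = o_xyz[np.argmax(o_xyz @ u)]
        base = o_ref + dist * u
        for name, off in _FRAGMENTS[rtype]:
            add(name, rtype, 201 + k, base + off * u, element=name[0])
        truth.contact_distances.append((rtype, dist))
    return StructureModel(atoms=atoms), truth


def gen_trajectory(
    n_frames: int,
    per_residue_sigma: np.ndarray | list[float],
    scaffold: StructureModel | None = None,
    global_wobble: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, GeometryTruth]:
    """Frames = scaffold (+ optional rigid wobble) + per-residue isotropic
    Gaussian jitter.

    With per-axis standard deviation σ_i, the expected RMSF of residue i is
    σ_i·√3.  A rigid global wobble adds no fluctuation after superposition.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    sigma = np.asarray(per_residue_sigma, dtype=float)
    rng = np.random.default_rng(seed)
    if scaffold is None:
        # extended CA chain with a gentle helical twist
        t = np.arange(len(sigma))
        xyz = np.stack(
            [1.5 * np.cos(t * 1.66), 1.5 * np.sin(t * 1.66), 1.5 * t], axis=1
        )
        scaffold = _ca_model(xyz)
    base = scaffold.coords()
    if len(base) != len(sigma):
        raise ValueError("sigma vector length must match scaffold residues")
    models = []
    for f in range(n_frames):
        xyz = base.copy()
        if global_wobble:
            R = rotation_matrix(rng.normal(size=3), rng.uniform(-15, 15))
            xyz = (xyz - xyz.mean(0)) @ R.T + xyz.mean(0) + rng.normal(
                scale=2.0, size=3
            )
        xyz = xyz + rng.normal(size=xyz.shape) * sigma[:, None]
        m = scaffold.with_coords(xyz)
        m.model_id = f + 1
        models.append(m)
    truth = GeometryTruth(per_residue_sigma=sigma, seed=seed)
    return Trajectory(models=models), truth
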