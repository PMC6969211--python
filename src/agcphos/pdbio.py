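"""Fixed-width PDB reading and writing for structures and trajectories.

Parses ATOM and HETATM records (phospho-serine, residue name SEP, is usually
deposited as HETATM), splits MODEL/ENDMDL blocks into separate models, and
resolves alternate locations by keeping the highest-occupancy conformer
(ties: altloc 'A', then first seen).  A multi-model file doubles as the
trajectory format.  Hydrogens are dropped: the analysis works on heavy atoms
only, as crystal structures rarely resolve hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    coords: tuple[float, float, float]
    element: str
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("empty atom name")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class StructureModel:
    """One coordinate set (a MODEL block, or the whole single-model file)."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __post_init__(self) -> None:
        keys = [(a.chain, a.residue_number, a.name) for a in self.atoms]
        if len(keys) != len(set(keys)):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k}")
                seen.add(k)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, coords=tuple(float(v) for v in row))
            for a, row in zip(self.atoms, xyz)
        ]
        return StructureModel(atoms=atoms, model_id=self.model_id)

    def residue(self, chain: str, number: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == number
        ]

    def atom(self, chain: str, number: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if (
                a.chain == chain
                and a.residue_number == number
                and a.name == name
            ):
                return a
        raise KeyError(f"atom {chain}:{number}:{name} not found")

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, number, residue_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen: set = set()
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.residue_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


@dataclass
class Trajectory:
    """Ordered models with identical atom rosters (a multi-model PDB)."""

    models: list[StructureModel]
    timestep_ns: float | None = None

    def __post_init__(self) -> None:
        if self.models:
            roster = [(a.chain, a.residue_number, a.name) for a in self.models[0].atoms]
            for m in self.models[1:]:
                r = [(a.chain, a.residue_number, a.name) for a in m.atoms]
                if r != roster:
                    raise ValueError(
                        f"model {m.model_id} atom roster differs from model "
                        f"{self.models[0].model_id}"
                    )

    def __len__(self) -> int:
        return len(self.models)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.array([m.coords() for m in self.models])


def parse_pdb(text: str) -> list[StructureModel]:
    """Parse PDB text into one StructureModel per MODEL block.

    Malformed fixed-width ATOM/HETATM lines raise with their line number.
    Hydrogens (element H or D) are skipped; alternate locations are reduced
    to a single conformer per atom.
    """
    models: list[StructureModel] = []
    current: list[AtomRecord] = []
    model_id = 1
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(_finish_model(current, model_id))
                current = []
            try:
                model_id = int(line[6:].split()[0])
            except (IndexError, ValueError):
                model_id = len(models) + 1
            in_model = True
        elif rec == "ENDMDL":
            models.append(_finish_model(current, model_id))
            current = []
            in_model = False
            model_id += 1
        elif rec in ("ATOM", "HETATM"):
            try:
                atom = _parse_atom_line(line)
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed {rec} record at line {lineno}: {exc}"
                ) from exc
            if atom.element not in ("H", "D"):
                current.append(atom)
    if current or not models:
        if not current and not models:
            raise ValueError("no ATOM/HETATM records found")
        models.append(_finish_model(current, model_id if in_model else len(models) + 1))
    return models


def _parse_atom_line(line: str) -> AtomRecord:
    if len(line) < 54:
        raise ValueError("line shorter than the coordinate fields")
    name = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # standard PDB right-justifies one-letter elements in the name field
        element = name.lstrip("0123456789")[:1]
    return AtomRecord(
        serial=int(line[6:11]),
        name=name,
        residue_name=line[17:20].strip(),
        chain=line[21].strip() or "A",
        residue_number=int(line[22:26]),
        coords=(
            float(line[30:38]),
            float(line[38:46]),
            float(line[46:54]),
        ),
        element=element,
        occupancy=float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0,
        altloc=line[16].strip(),
        het=line[:6].strip() == "HETATM",
    )


def _finish_model(atoms: list[AtomRecord], model_id: int) -> StructureModel:
    # altloc resolution: highest occupancy, ties to 'A', then first seen
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if a.occupancy > b.occupancy + 1e-9 or (
                abs(a.occupancy - b.occupancy) <= 1e-9
                and a.altloc == "A"
                and b.altloc != "A"
            ):
                best[key] = a
    resolved = [replace(best[k], altloc="") for k in order]
    return StructureModel(atoms=resolved, model_id=model_id)


def write_pdb(target, path: str) -> None:
    """Write a StructureModel or Trajectory as fixed-width PDB text."""
    models = target.models if isinstance(target, Trajectory) else [target]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m in models:
            if multi:
                fh.write(f"MODEL     {m.model_id:4d}\n")
            for a in m.atoms:
                fh.write(format_atom_line(a) + "\n")
            fh.write("ENDMDL\n" if multi else "END\n")


def format_atom_line(a: AtomRecord) -> str:
    rec = "HETATM" if a.het else "ATOM  "
    # 4-char name field: 1/2-letter elements with short names are offset by one
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.coords
    return (
        f"{rec}{a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
        f"{a.chain:1s}{a.residue_number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )
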