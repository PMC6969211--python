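"""End-to-end pipeline runs with a reproducibility manifest.

Two drivers: the sequence pipeline (FASTA + MSA -> per-kinase records,
state proportions, Euler overlaps, NJ tree) and the structure pipeline
(PDB -> salt-bridge table, Ser->Asp mutant, side-by-side distance report).
All interchange is TSV with a header row and 1-based residue numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cooccur import (
    al_phosphorylatable,
    euler_overlap,
    fisher_exact,
    state_proportions,
    triad_basic,
)
from .geometry import mutate_ser_to_asp, saltbridge_network
from .motifs import KinaseRecord, SiteKind, classify_kinome
from .pdbio import parse_pdb, write_pdb
from .phylo import msa_distance, neighbor_joining, to_newick
from .seqio import read_alignment, read_sequences


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    seqs: str | None = None
    msa: str | None = None
    pdb: str | None = None
    ref_id: str | None = None
    ref_sites: tuple[int, int, int] = (114, 192, 216)  # 1-based
    al_ref_site: int | None = None  # 1-based reference AL position (e.g. 227)
    distance_method: str = "pdist"
    cutoff: float = 4.0
    center: tuple[str, int] | None = None  # (chain, residue_number)
    tail_window: int = 60
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.ref_sites, list):
            cfg.ref_sites = tuple(cfg.ref_sites)
        if isinstance(cfg.center, list):
            cfg.center = (cfg.center[0], int(cfg.center[1]))
        return cfg

    def validate_files(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"config field {name!r}: {path!r}")


def records_to_frame(records: list[KinaseRecord]) -> pd.DataFrame:
    """Per-kinase table; positions are printed 1-based."""
    rows = []
    for r in records:
        triad = {t.site: t for t in r.triad}
        rows.append(
            {
                "id": r.id,
                "segment_start": None if r.segment is None else r.segment.dfg_start + 1,
                "segment_length": None if r.segment is None else r.segment.length,
                "AL_pos": None if r.al_call.position is None else r.al_call.position + 1,
                "AL_res": r.al_call.residue or "-",
                "AL_state": r.al_call.state.value,
                "HM_pos": None if r.hm_call.position is None else r.hm_call.position + 1,
                "HM_res": r.hm_call.residue or "-",
                "HM_state": r.hm_call.state.value
                + ("(truncated)" if r.hm_call.truncated else ""),
                "R114": triad.get("R114_site").mapped_residue if "R114_site" in triad else "",
                "R192": triad.get("R192_site").mapped_residue if "R192_site" in triad else "",
                "K216": triad.get("K216_site").mapped_residue if "K216_site" in triad else "",
            }
        )
    return pd.DataFrame(rows)


def run_sequence_pipeline(config: RunConfig) -> dict:
    """FASTA + MSA -> records.tsv, proportions.tsv, overlaps.tsv, tree.nwk."""
    t0 = time.time()
    config.validate_files("seqs", "msa")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    seqs = read_sequences(config.seqs)
    msa = read_alignment(config.msa)
    log.append(f"read {len(seqs)} sequences, alignment {msa.length} columns")

    ref_positions = [p - 1 for p in config.ref_sites] if config.ref_id else None
    al_hint = None
    if config.ref_id and config.al_ref_site:
        al_hint = msa.column_of(config.ref_id, config.al_ref_site - 1)
    records = classify_kinome(
        seqs,
        msa=msa,
        ref_id=config.ref_id,
        ref_positions=ref_positions,
        al_column_hint=al_hint,
        tail_window=config.tail_window,
    )
    frame = records_to_frame(records)
    frame.to_csv(out / "records.tsv", sep="\t", index=False)
    log.append(f"classified {len(records)} kinases -> records.tsv")

    props = []
    for kind in (SiteKind.AL, SiteKind.HM):
        sc = state_proportions(records, kind)
        for state, count in sorted(sc.counts.items(), key=lambda kv: kv[0].value):
            props.append(
                {
                    "site": kind.value,
                    "state": state.value,
                    "count": count,
                    "proportion": count / sc.total,
                }
            )
    pd.DataFrame(props).to_csv(out / "proportions.tsv", sep="\t", index=False)

    overlaps = []
    for site, label in (
        ("R114_site", "r114_basic"),
        ("R192_site", "r192_basic"),
        ("K216_site", "k216_basic"),
    ):
        ov = euler_overlap(
            records, al_phosphorylatable, triad_basic(site), "al_phospho", label
        )
        overlaps.append(
            {
                "set_a": ov.set_a_name,
                "set_b": ov.set_b_name,
                "n_a": ov.n_a,
                "n_b": ov.n_b,
                "n_both": ov.n_both,
                "n_neither": ov.n_neither,
                "universe": ov.universe,
                "fisher_p": fisher_exact(ov.contingency()),
            }
        )
    pd.DataFrame(overlaps).to_csv(out / "overlaps.tsv", sep="\t", index=False)
    log.append("overlaps + Fisher tests -> overlaps.tsv")

    dm = msa_distance(msa, method=config.distance_method)
    tree = neighbor_joining(dm)
    (out / "tree.nwk").write_text(to_newick(tree) + "\n")
    log.append(f"NJ tree ({config.distance_method}) -> tree.nwk")

    manifest = _manifest(config, ["seqs", "msa"], t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return {
        "records": frame,
        "overlaps": pd.DataFrame(overlaps),
        "tree": tree,
        "manifest": manifest,
    }


def run_structure_pipeline(config: RunConfig) -> dict:
    """PDB -> bridges.tsv, mutant PDB, side-by-side distance report.

    The report lists, per basic residue near the phospho-site, the minimum
    acidic-O to basic-N distance in the input (phospho) structure and in
    the in-silico Ser->Asp mutant — the comparison that shows which
    contacts the carboxylate can and cannot reach.
    """
    t0 = time.time()
    config.validate_files("pdb")
    if config.center is None:
        raise ValueError("structure pipeline requires a center residue")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    models = parse_pdb(Path(config.pdb).read_text())
    model = models[0]
    log.append(f"parsed {len(models)} model(s), {len(model.atoms)} atoms")

    contacts = saltbridge_network(model, config.center, cutoff=config.cutoff)
    bridges = pd.DataFrame(
        [
            {
                "acidic": f"{c.acidic_residue[2]}{c.acidic_residue[1]}",
                "basic": f"{c.basic_residue[2]}{c.basic_residue[1]}",
                "chain": c.basic_residue[0],
                "min_distance_A": round(c.min_distance, 3),
                "atom_pair": "-".join(c.atom_pair),
            }
            for c in contacts
        ]
    )
    bridges.to_csv(out / "bridges.tsv", sep="\t", index=False)
    log.append(f"{len(contacts)} salt bridges at cutoff {config.cutoff} Å")

    report_rows = []
    mutant = None
    center_res = model.residue(*config.center)
    if center_res and center_res[0].residue_name in ("SER", "SEP"):
        mutant = mutate_ser_to_asp(model, config.center)
        write_pdb(mutant, str(out / "mutant_asp.pdb"))
        # compare distances at a permissive cutoff so lost contacts show up
        wide = {c.basic_residue: c for c in saltbridge_network(model, config.center, cutoff=8.0)}
        wide_mut = {
            c.basic_residue: c
            for c in saltbridge_network(mutant, config.center, cutoff=8.0)
        }
        for key in sorted(set(wide) | set(wide_mut), key=lambda k: (k[0], k[1])):
            phos = wide.get(key)
            mut = wide_mut.get(key)
            report_rows.append(
                {
                    "basic": f"{key[2]}{key[1]}",
                    "phospho_min_distance_A": None if phos is None else round(phos.min_distance, 3),
                    "asp_min_distance_A": None if mut is None else round(mut.min_distance, 3),
                    "phospho_bridged": phos is not None and phos.min_distance <= config.cutoff,
                    "asp_bridged": mut is not None and mut.min_distance <= config.cutoff,
                }
            )
        log.append("Ser->Asp mutant built -> mutant_asp.pdb, distance report")
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "distance_report.tsv", sep="\t", index=False)

    manifest = _manifest(config, ["pdb"], t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return {"bridges": bridges, "report": report, "mutant": mutant, "manifest": manifest}


def _manifest(config: RunConfig, input_fields: list[str], t0: float) -> dict:
    inputs = {}
    for name in input_fields:
        path = getattr(config, name)
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        inputs[name] = {"path": str(path), "sha256": digest}
    params = {
        k: v
        for k, v in vars(config).items()
        if k not in ("seqs", "msa", "pdb")
    }
    params["ref_sites"] = list(config.ref_sites)
    if config.center is not None:
        params["center"] = list(config.center)
    return {
        "package": "agcphos",
        "version": __version__,
        "inputs": inputs,
        "params": params,
        "elapsed_s": round(time.time() - t0, 3),
    }
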