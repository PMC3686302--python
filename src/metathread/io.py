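"""Readers and writers for the formats the toolkit touches.

PDB-subset reading (CA traces plus HETATM partners) is delegated to gemmi
after a fixed-width pre-validation pass that reports malformed lines by line
number; score tables and site tables are TSV via pandas; trained models and
metrics are JSON. All writers are deterministic: identical inputs produce
byte-identical files (stable ordering, fixed float formatting).

Coordinates are stored in angstrom as in PDB. Residue numbering is 1-based
externally (as in the source files and all written output) and 0-based
ordinal internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .classifier import THREADING_METHODS, GaussianNBCModel, TemplateRecord
from .geometry import (
    SUPPORTED_METALS,
    BindingAspect,
    BoundPartner,
    Structure,
)
from .sites import RankedSite

__all__ = [
    "MODEL_SCHEMA_VERSION",
    "RunConfig",
    "read_pdb_subset",
    "write_pdb_fixture",
    "read_score_table",
    "write_score_table",
    "save_model",
    "load_model",
    "read_fingerprints",
    "write_fingerprints",
    "read_alignment",
    "write_sites_table",
]

MODEL_SCHEMA_VERSION = 1

#: Residue names that imply a metal ion when the element column is absent.
_METAL_RESNAMES = {m.upper(): m for m in SUPPORTED_METALS}
_FES_RESNAMES = {"SF4", "FES", "F3S", "FS4"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_DNA_RESNAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "A": "A", "C": "C", "G": "G", "T": "T"}


@dataclass
class RunConfig:
    """All tunable thresholds and seeds, pre-loaded with the published defaults.

    Serialized alongside every result for provenance: TM-score significance
    0.4; partner-distance thresholds 4/2/3/6/6 angstrom for
    ligand/metal/Fe-S/protein/DNA; ligand Tanimoto 0.5; interface IS-score
    0.191; BEDROC alpha 20; site cluster cutoff 8 angstrom.
    """

    aspect: str = "ligand"
    flavor: str = "LOCATION"
    tm_threshold: float = 0.4
    distance_thresholds: dict[str, float] = field(
        default_factory=lambda: {"ligand": 4.0, "metal": 2.0, "fe_s": 3.0, "protein": 6.0, "dna": 6.0}
    )
    tanimoto_threshold: float = 0.5
    interface_score_threshold: float = 0.191
    bedroc_alpha: float = 20.0
    cluster_cutoff: float = 8.0
    min_posterior: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path) -> None:
    """Reject malformed fixed-width coordinate lines, naming the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            stripped = line.rstrip("\n")
            if len(stripped) < 54:
                raise ValueError(f"{path}:{lineno}: coordinate line shorter than 54 columns")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(stripped[lo:hi])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unparseable coordinate field in fixed columns 31-54"
                ) from None


def read_pdb_subset(path: str | Path) -> Structure:
    """Read a PDB-format file into a CA-trace Structure with bound partners.

    The longest protein chain becomes the Structure (CA atoms only, source
    residue numbering kept); every other entity becomes a BoundPartner:
    additional protein chains (CA atoms, PROTEIN aspect), nucleic chains
    (heavy atoms plus sequence, DNA aspect), and HETATM groups split into
    metal ions (single atom, supported element), iron-sulfur clusters
    (by component name), and ligands. Waters are skipped; alternate
    locations keep the highest-occupancy conformer.
    """
    path = Path(path)
    _prevalidate_pdb(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model = st[0]

    protein_chains: list[tuple[str, list[tuple[int, str]], list[np.ndarray]]] = []
    partners: list[BoundPartner] = []

    for chain in model:
        residues_ca: list[tuple[int, str]] = []
        coords_ca: list[np.ndarray] = []
        dna_seq: list[str] = []
        dna_atoms: list[np.ndarray] = []
        for res in chain:
            name = res.name.strip().upper()
            if name == "HOH":
                continue
            if name in _THREE_TO_ONE:
                ca = _best_altloc(res, "CA")
                if ca is not None:
                    residues_ca.append((res.seqid.num, _THREE_TO_ONE[name]))
                    coords_ca.append(np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
                continue
            if name in _DNA_RESNAMES:
                dna_seq.append(_DNA_RESNAMES[name])
                dna_atoms.extend(_heavy_atoms(res))
                continue
            # HETATM group -> metal / Fe-S cluster / ligand
            atoms = _heavy_atoms(res)
            if not atoms:
                continue
            element = _metal_element(res)
            if element is not None and len(atoms) == 1:
                partners.append(
                    BoundPartner(
                        aspect=BindingAspect.METAL, atoms=np.array(atoms),
                        element=element, name=name,
                    )
                )
            elif name in _FES_RESNAMES:
                partners.append(
                    BoundPartner(aspect=BindingAspect.FE_S, atoms=np.array(atoms), name=name)
                )
            else:
                partners.append(
                    BoundPartner(aspect=BindingAspect.LIGAND, atoms=np.array(atoms), name=name)
                )
        if residues_ca:
            protein_chains.append((chain.name, residues_ca, coords_ca))
        if dna_seq:
            partners.append(
                BoundPartner(
                    aspect=BindingAspect.DNA,
                    atoms=np.array(dna_atoms),
                    sequence="".join(dna_seq),
                    name=chain.name,
                )
            )

    if not protein_chains:
        raise ValueError(f"{path}: no CA atoms found")
    protein_chains.sort(key=lambda c: (-len(c[1]), c[0]))
    main_name, main_res, main_xyz = protein_chains[0]
    for name, res, xyz in protein_chains[1:]:
        partners.append(
            BoundPartner(aspect=BindingAspect.PROTEIN, atoms=np.array(xyz), name=name)
        )
    return Structure(
        id=f"{path.stem}_{main_name}",
        residues=main_res,
        ca_coords=np.array(main_xyz),
        het_groups=partners,
    )


def _best_altloc(res: "gemmi.Residue", atom_name: str):
    best, best_occ = None, -1.0
    for atom in res:
        if atom.name == atom_name and atom.occ > best_occ:
            best, best_occ = atom, atom.occ
    return best


def _heavy_atoms(res: "gemmi.Residue") -> list[np.ndarray]:
    out = []
    seen: dict[str, float] = {}
    coords: dict[str, np.ndarray] = {}
    for atom in res:
        if atom.element.name == "H":
            continue
        if atom.name not in seen or atom.occ > seen[atom.name]:
            seen[atom.name] = atom.occ
            coords[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return [coords[k] for k in coords]


def _metal_element(res: "gemmi.Residue") -> str | None:
    name = res.name.strip().upper()
    for atom in res:
        el = atom.element.name
        if el.capitalize() in SUPPORTED_METALS:
            return el.capitalize()
    if name in _METAL_RESNAMES:
        return _METAL_RESNAMES[name]
    return None


def write_pdb_fixture(structure: Structure, path: str | Path) -> None:
    """Write a Structure (CA trace + partners) as a minimal PDB fixture file."""
    lines = []
    serial = 1
    for (resnum, aa), xyz in zip(structure.residues, structure.ca_coords):
        lines.append(_pdb_line("ATOM", serial, "CA", _ONE_TO_THREE[aa], "A", resnum, xyz, "C"))
        serial += 1
    het_chain = "B"
    for gi, p in enumerate(structure.het_groups):
        if p.aspect is BindingAspect.METAL:
            resname = (p.element or "ZN").upper()
            lines.append(_pdb_line("HETATM", serial, resname, resname, het_chain, gi + 1,
                                   p.atoms[0], p.element or "Zn"))
            serial += 1
        elif p.aspect is BindingAspect.PROTEIN:
            chain = chr(ord("C") + gi)
            for ri, xyz in enumerate(p.atoms, start=1):
                lines.append(_pdb_line("ATOM", serial, "CA", "GLY", chain, ri, xyz, "C"))
                serial += 1
        elif p.aspect is BindingAspect.DNA and p.sequence:
            chain = chr(ord("C") + gi)
            n_per = max(1, len(p.atoms) // len(p.sequence))
            for ri, base in enumerate(p.sequence, start=1):
                for ai in range(n_per):
                    idx = (ri - 1) * n_per + ai
                    if idx >= len(p.atoms):
                        break
                    lines.append(_pdb_line("HETATM", serial, f"C{ai+1}", f"D{base}",
                                           chain, ri, p.atoms[idx], "C"))
                    serial += 1
        else:
            resname = (p.name or "LIG")[:3] or "LIG"
            for ai, xyz in enumerate(p.atoms):
                lines.append(_pdb_line("HETATM", serial, f"C{ai+1}", resname, het_chain,
                                       gi + 1, xyz, "C"))
                serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_line(record, serial, atom_name, resname, chain, resnum, xyz, element) -> str:
    name = atom_name if len(atom_name) >= 4 else f" {atom_name}"
    return (
        f"{record:<6}{serial:>5} {name:<4} {resname:<3} {chain}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element[:2]:>2}"
    )


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

_KEY_COLS = ["target_id", "template_id", "aspect"]
_LABEL_COLS = ["label_location", "label_features"]
_POSTERIOR_COLS = ["posterior_location", "posterior_features"]


def write_score_table(records: Sequence[TemplateRecord], path: str | Path) -> None:
    """Write template records as a TSV score table (lossless round-trip).

    Columns: the three key columns, the ten method columns, then any label
    or posterior columns that are set on at least one record. Missing scores
    and unset labels are empty cells.
    """
    rows = []
    for r in records:
        row = {
            "target_id": r.target_id,
            "template_id": r.template_id,
            "aspect": r.aspect.value,
        }
        for m in THREADING_METHODS:
            row[m] = r.scores.get(m, np.nan)
        row["label_location"] = _bool_cell(r.label_location)
        row["label_features"] = _bool_cell(r.label_features)
        row["posterior_location"] = r.posterior_location
        row["posterior_features"] = r.posterior_features
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in _LABEL_COLS + _POSTERIOR_COLS:
        if df[col].isna().all() or (df[col] == "").all():
            df = df.drop(columns=[col])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _bool_cell(v: bool | None) -> str:
    return "" if v is None else ("1" if v else "0")


def read_score_table(path: str | Path) -> list[TemplateRecord]:
    """Read a TSV score table into template records.

    Empty cells are missing scores (never zero); unknown columns and
    duplicate (target, template, aspect) rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "template_id": str})
    allowed = set(_KEY_COLS) | set(THREADING_METHODS) | set(_LABEL_COLS) | set(_POSTERIOR_COLS)
    unknown = set(df.columns) - allowed
    if unknown:
        raise ValueError(f"unknown columns in score table: {sorted(unknown)}")
    missing_keys = [c for c in _KEY_COLS if c not in df.columns]
    if missing_keys:
        raise ValueError(f"score table lacks key columns: {missing_keys}")
    dup = df.duplicated(subset=_KEY_COLS)
    if dup.any():
        first = df.loc[dup, _KEY_COLS].iloc[0].tolist()
        raise ValueError(f"duplicate score-table row for {tuple(first)}")
    records = []
    for _, row in df.iterrows():
        scores = {
            m: float(row[m])
            for m in THREADING_METHODS
            if m in df.columns and not pd.isna(row[m])
        }
        records.append(
            TemplateRecord(
                target_id=row["target_id"],
                template_id=row["template_id"],
                aspect=BindingAspect(row["aspect"]),
                scores=scores,
                label_location=_cell_bool(row.get("label_location")),
                label_features=_cell_bool(row.get("label_features")),
                posterior_location=_cell_float(row.get("posterior_location")),
                posterior_features=_cell_float(row.get("posterior_features")),
            )
        )
    return records


def _cell_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return bool(int(v))


def _cell_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: GaussianNBCModel, path: str | Path) -> None:
    """Serialize a trained model to JSON (bit-exact round-trip)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "aspect": model.aspect.value,
        "flavor": model.flavor,
        "class_priors": list(model.class_priors),
        "sd_floor": model.sd_floor,
        "per_feature": {
            m: list(v) for m, v in sorted(model.per_feature.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> GaussianNBCModel:
    """Load a model JSON, checking the schema version."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: model schema version {version!r} != {MODEL_SCHEMA_VERSION}; retrain the model"
        )
    return GaussianNBCModel(
        aspect=BindingAspect(payload["aspect"]),
        flavor=payload["flavor"],
        class_priors=tuple(payload["class_priors"]),
        per_feature={m: tuple(v) for m, v in payload["per_feature"].items()},
        sd_floor=payload["sd_floor"],
    )


# ---------------------------------------------------------------------------
# Fingerprints, alignments, site tables
# ---------------------------------------------------------------------------

def write_fingerprints(fps: dict[str, np.ndarray], path: str | Path) -> None:
    """Write ligand fingerprints as TSV: id, then n_bits characters of {0,1}."""
    lines = [
        f"{lid}\t{''.join('1' if b else '0' for b in np.asarray(bits, dtype=bool))}"
        for lid, bits in sorted(fps.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fingerprints(path: str | Path, n_bits: int = 1024) -> dict[str, np.ndarray]:
    """Read a fingerprint file: one ``id<TAB>bits`` record per line.

    ``bits`` is either ``n_bits`` characters of {0,1} or ``n_bits/4`` hex
    digits (most-significant bit first).
    """
    out: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            lid, bits = line.split("\t")
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated fields") from None
        if len(bits) == n_bits and set(bits) <= {"0", "1"}:
            out[lid] = np.array([c == "1" for c in bits])
        elif len(bits) == n_bits // 4:
            value = int(bits, 16)
            out[lid] = np.array(
                [(value >> (n_bits - 1 - i)) & 1 == 1 for i in range(n_bits)]
            )
        else:
            raise ValueError(
                f"{path}:{lineno}: fingerprint must be {n_bits} binary or {n_bits // 4} hex characters"
            )
    return out


def read_alignment(path: str | Path) -> list[tuple[int, int]]:
    """Read residue correspondences: two-column TSV (template, target), 1-based.

    Returned pairs are 0-based ordinals. Lines starting with '#' are skipped.
    """
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        a, b = int(parts[0]), int(parts[1])
        if a < 1 or b < 1:
            raise ValueError(f"{path}:{lineno}: residue indices are 1-based")
        pairs.append((a - 1, b - 1))
    return pairs


def write_sites_table(sites: Sequence[RankedSite], path: str | Path) -> None:
    """Write ranked binding-site predictions as TSV."""
    rows = [
        {
            "rank": s.rank,
            "x": round(float(s.center[0]), 3),
            "y": round(float(s.center[1]), 3),
            "z": round(float(s.center[2]), 3),
            "weight": round(float(s.weight), 6),
            "n_members": len(s.members),
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["rank", "x", "y", "z", "weight", "n_members"]).to_csv(
        path, sep="\t", index=False
    )
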