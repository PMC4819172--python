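"""Readers and writers for the formats the tool touches.

PDB models, single-record FASTA targets, DSSP output files, per-residue
3-state/2-state prediction strings and tab-separated raw-score tables.
Parsing of PDB/FASTA/DSSP is delegated to Biopython; this module adapts
the results into the package's lightweight domain types and enforces the
dialect rules the scorer relies on (first MODEL block, one CA per
residue, single chain).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .config import THREE_TO_ONE

logger = logging.getLogger(__name__)

RAW_SCORE_COLUMNS = ("dfire2", "rwplus", "rf_cb_srs_od", "dope", "modeleval")

#: DSSP 8-state -> 3-state collapse (total over the 8 codes; blank/other -> C).
DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
                 "T": "C", "S": "C", "-": "C", " ": "C", "P": "C"}


@dataclass
class Residue:
    name: str                      # 3-letter code
    index: int                     # author residue number
    icode: str = " "
    atoms: dict = field(default_factory=dict)   # atom name -> np.ndarray (3,)

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructuralModel:
    """A single-chain protein model: ordered residues with coordinates in Angstrom."""

    model_id: str
    residues: list[Residue]

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def residue_indices(self) -> list[int]:
        return [r.index for r in self.residues]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.model_id}: model has no residues")
        for r in self.residues:
            if "CA" not in r.atoms:
                raise ValueError(f"{self.model_id}: residue {r.index} lacks CA")


@dataclass(frozen=True)
class SequenceRecord:
    target_id: str
    sequence: str

    @property
    def n(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PerResidueAnnotation:
    """A per-residue character string aligned to the target sequence.

    ``kind`` is one of predicted_ss / model_ss / predicted_sa / model_sa;
    3-state codes are {H, E, C}, 2-state accessibility codes {e, b}.
    Positions without an assignment (unresolved residues, chain breaks)
    carry '-' and are excluded from similarity numerators and denominators.
    """

    kind: str
    states: str

    _ALPHABETS = {
        "predicted_ss": set("HEC-"),
        "model_ss": set("HEC-"),
        "predicted_sa": set("eb-"),
        "model_sa": set("eb-"),
    }

    def __post_init__(self):
        allowed = self._ALPHABETS.get(self.kind)
        if allowed is None:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        bad = set(self.states) - allowed
        if bad:
            raise ValueError(f"{self.kind}: invalid state characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


def read_pdb(path, model_id: str | None = None) -> StructuralModel:
    """Parse the first MODEL block of a PDB file into a StructuralModel.

    Altloc conflicts resolve to the highest-occupancy conformer (Biopython's
    convention).  Residues without a CA atom are dropped with a warning;
    a file yielding zero CA residues is an error, as is multi-chain input.
    """
    path = Path(path)
    if model_id is None:
        model_id = path.stem
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(model_id, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no ATOM records parsed")
    first = models[0]
    chains = [c for c in first if any(res.id[0] == " " for res in c)]
    if len(chains) > 1:
        raise ValueError(
            f"{path}: {len(chains)} chains present; only single-chain models are scored"
        )
    if not chains:
        raise ValueError(f"{path}: no residues (ATOM records) found")
    residues: list[Residue] = []
    for res in chains[0]:
        if res.id[0] != " ":      # skip HETATM / water
            continue
        atoms = {}
        for atom in res:
            # disordered atoms expose the highest-occupancy conformer
            atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        if "CA" not in atoms:
            logger.warning("%s: residue %s%s has no CA, dropped", model_id,
                           res.get_resname(), res.id[1])
            continue
        residues.append(Residue(name=res.get_resname(), index=res.id[1],
                                icode=res.id[2], atoms=atoms))
    if not residues:
        raise ValueError(f"{path}: no residues with CA atoms")
    residues.sort(key=lambda r: (r.index, r.icode))
    return StructuralModel(model_id=model_id, residues=residues)


def write_pdb(model: StructuralModel, path) -> None:
    """Write a minimal single-chain PDB (ATOM records, chain A)."""
    lines = []
    serial = 1
    for res in model.residues:
        for name, xyz in res.atoms.items():
            el = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {res.name:<3s} A{res.index:4d}"
                f"{res.icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> SequenceRecord:
    """Read a single-record FASTA; multi-record files are an error."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(f"{path}: expected 1 FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX")
    if bad:
        raise ValueError(f"{path}: non-amino-acid letters {sorted(bad)}")
    return SequenceRecord(target_id=rec.id, sequence=seq)


def read_dssp(path) -> tuple[dict[int, str], dict[int, float]]:
    """Parse a DSSP output file.

    Returns two dicts keyed by author residue number: the 3-state secondary
    structure code (8-state DSSP collapsed as H,G,I->H; E,B->E; else C) and
    the absolute exposed area in A^2.  Chain-break records ('!') are absent
    from the output, leaving annotation gaps.
    """
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:  # malformed header or truncated file
        raise ValueError(f"{path}: not a parsable DSSP file ({exc})") from exc
    ss: dict[int, str] = {}
    acc: dict[int, float] = {}
    for key in keys:
        aa, code, accessibility = dssp_dict[key][0], dssp_dict[key][1], dssp_dict[key][2]
        if aa == "!":
            continue
        resnum = key[1][1]
        ss[resnum] = DSSP_COLLAPSE.get(code, "C")
        acc[resnum] = float(accessibility)
    if not ss:
        raise ValueError(f"{path}: DSSP file contains no residues")
    return ss, acc


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV of raw external scores, indexed by model_id.

    Header must name ``model_id`` plus any of dfire2 / rwplus /
    rf_cb_srs_od / dope / modeleval; unknown columns are dropped with a
    warning and empty cells become missing values (NaN), never zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str})
    if "model_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'model_id'")
    if df["model_id"].duplicated().any():
        dups = df.loc[df["model_id"].duplicated(), "model_id"].tolist()
        raise ValueError(f"{path}: duplicate model_id values: {dups}")
    unknown = [c for c in df.columns if c not in RAW_SCORE_COLUMNS + ("model_id",)]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)
        df = df.drop(columns=unknown)
    df = df.set_index("model_id")
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    me = df.get("modeleval")
    if me is not None:
        present = me.dropna()
        if ((present < 0) | (present > 1)).any():
            raise ValueError(f"{path}: modeleval scores must already lie in [0, 1]")
    return df


def read_truths(path) -> pd.DataFrame:
    """Read a truths TSV with columns target_id, model_id, gdtts."""
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})
    required = {"target_id", "model_id", "gdtts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if ((df["gdtts"] < 0) | (df["gdtts"] > 1)).any():
        raise ValueError(f"{path}: gdtts values must lie in [0, 1]")
    return df
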