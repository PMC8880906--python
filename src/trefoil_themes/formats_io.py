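"""Readers and writers for the formats the pipeline touches.

Sequences travel as plain FASTA, alignments as aligned FASTA, structures as
legacy PDB (including water ``HETATM`` records), and domain listings as TSV
with ECOD-style dotted group labels (``X.T.F``).  Hit tables are written as
TSV with a fixed, documented column set.

Residue ranges everywhere are 1-based, inclusive, in author numbering.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "DomainRecord",
    "MSA",
    "Residue",
    "Water",
    "Structure",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_structure",
    "write_pdb",
    "read_domain_table",
    "parse_range",
    "parse_group",
    "HIT_TABLE_COLUMNS",
    "write_hit_table",
    "read_hit_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclasses.dataclass
class Residue:
    """One residue: author number, optional insertion code, heavy atoms."""

    number: int
    name: str = "ALA"
    icode: str = ""
    atoms: dict = dataclasses.field(default_factory=dict)

    @property
    def rid(self) -> str:
        return f"{self.number}{self.icode}"

    @property
    def complete_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclasses.dataclass
class Water:
    """A water oxygen with its PDB identifier."""

    water_id: str
    coord: np.ndarray


@dataclasses.dataclass
class Structure:
    """Backbone atoms of one chain plus its water oxygens."""

    chain: str
    residues: list
    waters: list = dataclasses.field(default_factory=list)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues if "CA" in r.atoms])

    def residue_by_number(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {number}{icode} not in chain {self.chain}")

    def subset(self, segments: Sequence[tuple]) -> "Structure":
        """Residues whose author number falls in any (start, end) segment."""
        keep = [
            r
            for r in self.residues
            if any(lo <= r.number <= hi for lo, hi in segments)
        ]
        return Structure(self.chain, keep, list(self.waters))


@dataclasses.dataclass
class MSA:
    """An alignment whose first row (by default) is the master sequence."""

    master_id: str
    rows: list  # ordered (id, aligned sequence) pairs

    def __post_init__(self):
        if not self.rows:
            raise FormatError("empty alignment")
        width = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != width:
                raise FormatError(
                    f"alignment row {rid!r} has length {len(seq)}, expected {width}"
                )
        if self.master_id not in {rid for rid, _ in self.rows}:
            raise FormatError(f"master {self.master_id!r} not among rows")
        if not self.master.replace("-", ""):
            raise FormatError("master row is entirely gaps")

    @property
    def master(self) -> str:
        for rid, seq in self.rows:
            if rid == self.master_id:
                return seq
        raise KeyError(self.master_id)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])


@dataclasses.dataclass
class DomainRecord:
    """One classified domain: sequence, lineage label, optional annotation.

    ``group`` is a dotted ``X.T.F`` label; only the X-group (first field) is
    required.  ``segments`` are author-numbered (start, end) ranges on the
    chain; ``ss`` is a per-residue string over ``{H, E, C}``.
    """

    domain_id: str
    sequence: str = ""
    group: str = ""
    pdb_id: str = ""
    chain: str = ""
    segments: list = dataclasses.field(default_factory=list)
    residue_numbers: list | None = None
    ss: str | None = None
    structure: Structure | None = None

    def __post_init__(self):
        if self.ss is not None and self.sequence and len(self.ss) != len(self.sequence):
            raise ValueError(
                f"{self.domain_id}: ss length {len(self.ss)} != sequence length"
                f" {len(self.sequence)}"
            )
        if (
            self.residue_numbers is not None
            and self.sequence
            and len(self.residue_numbers) != len(self.sequence)
        ):
            raise ValueError(f"{self.domain_id}: residue_numbers/sequence mismatch")
        if self.group:
            parse_group(self.group)

    @property
    def xgroup(self) -> int:
        return parse_group(self.group)[0]


def parse_group(group: str) -> tuple:
    """Split a dotted lineage label into 1–3 integer fields (X, T, F)."""
    parts = group.split(".")
    if not 1 <= len(parts) <= 4:
        raise FormatError(f"bad group label {group!r}")
    try:
        fields = tuple(int(p) for p in parts[:3])
    except ValueError as exc:
        raise FormatError(f"bad group label {group!r}") from exc
    return fields + (None,) * (3 - len(fields))


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read FASTA into ordered (id, sequence) pairs.

    Sequences are uppercased and stop characters (``*``) stripped.
    """
    records = []
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not FASTA (no leading '>')")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("*", "")))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: Iterable) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_alignment(path, master_id: str | None = None) -> MSA:
    """Read an aligned FASTA; the first record is the master unless named.

    ``.`` gaps are normalized to ``-``; ragged rows raise :class:`FormatError`
    naming the offending row.
    """
    records = read_fasta(path)
    rows = [(rid, seq.replace(".", "-")) for rid, seq in records]
    width = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != width:
            raise FormatError(f"{path}: row {rid!r} has ragged length {len(seq)}")
    return MSA(master_id=master_id or rows[0][0], rows=rows)


def write_alignment(path, msa: MSA) -> None:
    write_fasta(path, msa.rows)


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_structure(path, chain: str) -> Structure:
    """Read one chain of a PDB file: backbone/heavy atoms plus waters.

    Alternate locations keep the first encountered; HOH/WAT residues are
    returned as :class:`Water` records; insertion codes are preserved in
    residue identifiers.  Residues missing backbone atoms are retained with
    the atoms present.
    """
    residues: dict = {}
    order: list = []
    waters: list = []
    chains_seen = set()
    with open(path) as fh:
        for line in fh:
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            ch = line[21]
            chains_seen.add(ch)
            resname = line[17:20].strip()
            if resname in _WATER_NAMES:
                # waters are kept regardless of chain: crystallographic
                # solvent is often deposited on its own chain id
                atom = line[12:16].strip()
                if atom not in ("O", "OW"):
                    continue
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                wid = f"{resname}_{ch}_{line[22:26].strip()}{line[26].strip()}"
                waters.append(Water(wid, xyz))
                continue
            if ch != chain:
                continue
            altloc = line[16]
            number = int(line[22:26])
            icode = line[26].strip()
            key = (number, icode)
            if key not in residues:
                residues[key] = Residue(number=number, name=resname, icode=icode)
                order.append(key)
            atom = line[12:16].strip()
            if atom in residues[key].atoms:
                continue  # keep first altloc
            if altloc not in (" ", "A", "1"):
                continue
            residues[key].atoms[atom] = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if not order:
        raise KeyError(
            f"{path}: chain {chain!r} not found (chains present: "
            f"{sorted(chains_seen)})"
        )
    return Structure(chain, [residues[k] for k in order], waters)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
AA1 = {v: k for k, v in _AA3.items()}
AA1["MSE"] = "M"


def write_pdb(path, structure: Structure) -> None:
    """Write a minimal PDB file (fixed columns, Å to 3 decimals)."""
    serial = 1
    lines = []
    for res in structure.residues:
        for atom, xyz in res.atoms.items():
            lines.append(
                "ATOM  %5d %-4s %3s %1s%4d%1s   %8.3f%8.3f%8.3f  1.00  0.00"
                % (
                    serial,
                    f" {atom}" if len(atom) < 4 else atom,
                    res.name,
                    structure.chain,
                    res.number,
                    res.icode or " ",
                    xyz[0],
                    xyz[1],
                    xyz[2],
                )
            )
            serial += 1
    for i, w in enumerate(structure.waters, start=1):
        lines.append(
            "HETATM%5d  O   HOH %1s%4d    %8.3f%8.3f%8.3f  1.00  0.00"
            % (serial, structure.chain, 9000 + i, w.coord[0], w.coord[1], w.coord[2])
        )
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# domain table
# --------------------------------------------------------------------------

def parse_range(text: str) -> list:
    """Parse ``"52-69,77-87"`` into [(52, 69), (77, 87)] (1-based inclusive)."""
    segments = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            lo_s, hi_s = part.rsplit("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        except ValueError as exc:
            raise FormatError(f"unparseable range segment {part!r}") from exc
        if lo > hi:
            raise FormatError(f"range segment {part!r} has start > end")
        segments.append((lo, hi))
    if not segments:
        raise FormatError(f"empty range {text!r}")
    return segments


DOMAIN_TABLE_COLUMNS = ["domain_id", "pdb", "chain", "range", "group"]


def read_domain_table(path) -> list:
    """Read a TSV of domains (domain_id, pdb, chain, range, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in DOMAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            segments = parse_range(row["range"])
        except FormatError as exc:
            raise FormatError(f"{path} line {i + 2}: {exc}") from exc
        out.append(
            DomainRecord(
                domain_id=row["domain_id"],
                pdb_id=row["pdb"],
                chain=row["chain"],
                segments=segments,
                group=row["group"],
            )
        )
    return out


# --------------------------------------------------------------------------
# hit tables
# --------------------------------------------------------------------------

HIT_TABLE_COLUMNS = [
    "profile_id",
    "master_domain",
    "window_strands",
    "target_domain",
    "target_group",
    "bit_score",
    "evalue",
    "shuffle_pvalue",
    "aln_master_range",
    "aln_target_range",
    "segment_rmsd",
]


def write_hit_table(path, rows: Iterable[dict], header_comment: str = "") -> None:
    df = pd.DataFrame(list(rows), columns=HIT_TABLE_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_hit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
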