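"""Structure, confidence-score and mutation-table I/O.

Reads protein–protein complexes from PDB/mmCIF (via gemmi), AF3-server-style
confidence summaries (JSON with ``iptm``/``ptm``), and SKEMPI-style mutation
tables, and converts dissociation constants to binding free energy changes.

Structures are reduced to heavy-atom point clouds with one position per atom:
waters and (by default) other heteroatoms are dropped, hydrogens are dropped,
and for alternate conformations the highest-occupancy conformer is kept.
Residues are addressed by author numbering with insertion codes (the SKEMPI
convention), carried as strings such as ``"52"`` or ``"52A"``.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "MutationSpec",
    "ConfidenceScores",
    "DDGRecord",
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "parse_structure",
    "write_structure",
    "parse_confidence",
    "parse_mutation_code",
    "ddg_from_affinities",
    "parse_skempi",
]

#: Gas constant in kcal/(mol K), the unit system of SKEMPI affinities.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Fallback temperature (K) when a mutation table omits or garbles it.
DEFAULT_TEMPERATURE = 298.0

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_AA = frozenset(AA3_TO_1.values())


class StructureParseError(ValueError):
    """Raised when a structure or table file cannot be interpreted."""


@dataclass(frozen=True, eq=False)
class Atom:
    """One heavy atom of a complex.

    Coordinates are in Å, ``b_factor`` in Å². ``res_seq`` is the author
    residue number as a string, with any insertion code appended. Equality
    and hashing are by object identity: an atom belongs to one structure,
    and subsets are subsets of that structure's atom list.
    """

    element: str
    coords: np.ndarray
    chain: str
    res_seq: str
    res_name: str
    name: str
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element symbol must be non-empty")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor {self.b_factor}")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain, self.res_seq)


@dataclass
class Structure:
    """An ordered heavy-atom collection with a two-group partner partition.

    ``partition`` maps each chain id to ``"P1"`` or ``"P2"``. A complex must
    have both sides populated before interface subsets can be formed; a
    partition may be attached after parsing via :meth:`with_partition`.
    """

    id: str
    atoms: list[Atom]
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain, group in self.partition.items():
            if group not in ("P1", "P2"):
                raise ValueError(f"partition group for chain {chain} must be P1 or P2")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)

    def with_partition(self, partition: dict[str, str]) -> "Structure":
        missing = [c for c in self.chains if c not in partition]
        if missing:
            raise ValueError(f"partition missing chains: {missing}")
        return Structure(self.id, list(self.atoms), dict(partition))

    def partner_of(self, atom: Atom) -> str:
        try:
            return self.partition[atom.chain]
        except KeyError:
            raise KeyError(f"chain {atom.chain} has no partner label") from None

    def residues(self) -> dict[tuple[str, str], list[Atom]]:
        """Atoms grouped by (chain, res_seq), in file order."""
        out: dict[tuple[str, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def residue_atoms(self, chain: str, res_seq: str) -> list[Atom]:
        got = [a for a in self.atoms if a.chain == chain and a.res_seq == res_seq]
        if not got:
            raise KeyError(f"no residue {res_seq} on chain {chain} in {self.id}")
        return got


@dataclass(frozen=True)
class MutationSpec:
    """A single point mutation in SKEMPI notation, e.g. ``TI38F``."""

    wt_aa: str
    chain: str
    res_seq: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in CANONICAL_AA or self.mut_aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical amino acid in {self.wt_aa}->{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wild-type and mutant residue coincide: {self.code}")

    @property
    def code(self) -> str:
        return f"{self.wt_aa}{self.chain}{self.res_seq}{self.mut_aa}"


@dataclass(frozen=True)
class ConfidenceScores:
    """AF3-style interface (ipTM) and global (pTM) predicted TM-scores."""

    iptm: float
    ptm: float

    def __post_init__(self) -> None:
        for label, v in (("iptm", self.iptm), ("ptm", self.ptm)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label}={v} outside [0, 1]")


@dataclass(frozen=True)
class DDGRecord:
    """One mutation with its binding free energy change (kcal/mol)."""

    complex_id: str
    mutation: MutationSpec
    ddg: float
    temperature: float = DEFAULT_TEMPERATURE
    source_affinities: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if not math.isfinite(self.ddg):
            raise ValueError("ddG must be finite")
        if self.source_affinities is not None:
            kw, km = self.source_affinities
            if kw <= 0 or km <= 0:
                raise ValueError("dissociation constants must be positive")


# ---------------------------------------------------------------------------
# structure parsing


def _element_symbol(gatom: gemmi.Atom) -> str:
    el = gatom.element.name.strip()
    if el and el != "X":
        return el
    guess = re.sub(r"[^A-Za-z]", "", gatom.name)[:1].upper()
    warnings.warn(f"atom {gatom.name}: element inferred as {guess} from atom name")
    return guess


def _res_seq_string(res: gemmi.Residue) -> str:
    icode = res.seqid.icode.strip()
    return f"{res.seqid.num}{icode}"


def parse_structure(
    path: str | Path,
    fmt: str | None = None,
    *,
    keep_hetero: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a heavy-atom :class:`Structure`.

    Waters and hydrogens are always removed; other HETATM records are removed
    unless ``keep_hetero``. Alternate conformations keep the highest-occupancy
    conformer so that every atom has a single position. ``fmt`` may be
    ``"pdb"`` or ``"mmcif"``; by default it is inferred from the suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    st.setup_entities()
    st.remove_waters()
    st.remove_hydrogens()
    if not keep_hetero:
        st.remove_ligands_and_waters()

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            res_seq = _res_seq_string(res)
            best: dict[str, gemmi.Atom] = {}
            for ga in res:
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            for ga in best.values():
                atoms.append(
                    Atom(
                        element=_element_symbol(ga),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        chain=chain.name,
                        res_seq=res_seq,
                        res_name=res.name,
                        name=ga.name,
                        b_factor=max(ga.b_iso, 0.0),
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path}: no polymer heavy atoms found")
    sid = structure_id or st.name or path.stem
    return Structure(id=sid.upper() if len(sid) == 4 else sid, atoms=atoms)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a minimal PDB file (ATOM records + TER/END)."""
    path = Path(path)
    lines = []
    serial = 0
    prev_chain: str | None = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain != prev_chain:
            lines.append("TER")
        prev_chain = a.chain
        serial += 1
        m = re.match(r"^(-?\d+)([A-Za-z]?)$", a.res_seq)
        if not m:
            raise ValueError(f"unserializable residue id {a.res_seq!r}")
        num, icode = int(m.group(1)), (m.group(2) or " ")
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {a.res_name:<3s} {a.chain[:1]}{num:4d}{icode}"
            f"   {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
        )
    lines += ["TER", "END", ""]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# confidence summaries


def parse_confidence(path: str | Path) -> ConfidenceScores:
    """Read ipTM and pTM from an AF3-server-style JSON summary file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise StructureParseError(f"{path}: not valid JSON ({exc})") from exc
    scores = {}
    for key in ("iptm", "ptm"):
        if key not in payload:
            raise KeyError(f"{path}: confidence summary missing key {key!r}")
        scores[key] = float(payload[key])
    return ConfidenceScores(**scores)


# ---------------------------------------------------------------------------
# mutation codes and free energies

_MUTCODE = re.compile(
    r"^(?P<wt>[A-Z])(?P<chain>[A-Za-z0-9])(?P<num>-?\d+)(?P<icode>[A-Za-z]?)(?P<mut>[A-Z])$"
)


def parse_mutation_code(code: str) -> MutationSpec:
    """Parse a SKEMPI mutation code such as ``TI38F``.

    Format: wild-type letter, chain id, residue number (optionally followed
    by an insertion code letter), mutant letter. Round-trips via
    :attr:`MutationSpec.code`.
    """
    m = _MUTCODE.match(code.strip())
    if not m:
        raise ValueError(f"unrecognized mutation code {code!r}")
    return MutationSpec(
        wt_aa=m.group("wt"),
        chain=m.group("chain"),
        res_seq=m.group("num") + m.group("icode"),
        mut_aa=m.group("mut"),
    )


def ddg_from_affinities(kd_wt: float, kd_mut: float, temperature: float) -> float:
    """Binding free energy change from dissociation constants.

    ΔG = RT ln Kd per complex, so ΔΔG = RT ln(Kd_mut / Kd_wt) in kcal/mol
    (positive = the mutation weakens binding). Kd in molar, T in Kelvin.
    """
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    # difference of logs keeps the forward/reverse antisymmetry bitwise exact
    return GAS_CONSTANT_KCAL * temperature * (math.log(kd_mut) - math.log(kd_wt))


# ---------------------------------------------------------------------------
# SKEMPI-style tables

_DEFAULT_COLUMNS = {
    "pdb": "#Pdb",
    "mutation": "Mutation(s)_cleaned",
    "kd_wt": "Affinity_wt_parsed",
    "kd_mut": "Affinity_mut_parsed",
    "temperature": "Temperature",
}


def _parse_temperature(raw: object) -> float:
    """SKEMPI temperature fields may carry annotations like ``298(assumed)``."""
    m = re.search(r"\d+(\.\d+)?", str(raw))
    if not m:
        warnings.warn(f"unparseable temperature {raw!r}; assuming {DEFAULT_TEMPERATURE} K")
        return DEFAULT_TEMPERATURE
    return float(m.group())


def parse_skempi(
    path: str | Path,
    *,
    sep: str = ";",
    columns: dict[str, str] | None = None,
    average_duplicates: bool = True,
) -> tuple[list[DDGRecord], int]:
    """Read a SKEMPI-2.0-style table into single-mutation ΔΔG records.

    The first column is expected in the ``PDB_CH1_CH2`` form naming the two
    partner sides. Multi-mutation rows and rows missing either affinity are
    dropped; the second return value counts dropped rows. Duplicate
    (complex, mutation) measurements are averaged by default.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for logical, name in colmap.items():
        if name not in df.columns:
            raise StructureParseError(f"{path}: missing column {name!r} ({logical})")

    records: list[DDGRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        mut_field = str(row[colmap["mutation"]]).strip()
        if "," in mut_field:  # multi-point mutation
            dropped += 1
            continue
        kd_wt_raw, kd_mut_raw = row[colmap["kd_wt"]], row[colmap["kd_mut"]]
        try:
            kd_wt, kd_mut = float(kd_wt_raw), float(kd_mut_raw)
        except (TypeError, ValueError):
            dropped += 1
            continue
        if not (math.isfinite(kd_wt) and math.isfinite(kd_mut)) or kd_wt <= 0 or kd_mut <= 0:
            dropped += 1
            continue
        temperature = _parse_temperature(row[colmap["temperature"]])
        pdb_id = str(row[colmap["pdb"]]).split("_")[0].upper()
        try:
            mut = parse_mutation_code(mut_field)
        except ValueError:
            dropped += 1
            continue
        records.append(
            DDGRecord(
                complex_id=pdb_id,
                mutation=mut,
                ddg=ddg_from_affinities(kd_wt, kd_mut, temperature),
                temperature=temperature,
                source_affinities=(kd_wt, kd_mut),
            )
        )

    if average_duplicates:
        grouped: dict[tuple[str, str], list[DDGRecord]] = {}
        for rec in records:
            grouped.setdefault((rec.complex_id, rec.mutation.code), []).append(rec)
        records = [
            replace(rs[0], ddg=float(np.mean([r.ddg for r in rs])),
                    source_affinities=None if len(rs) > 1 else rs[0].source_affinities)
            for rs in grouped.values()
        ]
    return records, dropped


def partition_from_skempi_id(pdb_field: str) -> dict[str, str]:
    """Chain partition from a SKEMPI ``PDB_CH1_CH2`` identifier.

    ``"1CSE_E_I"`` maps chain E to P1 and chain I to P2; multi-letter groups
    like ``"1A4Y_AB_C"`` put every listed chain on its side.
    """
    parts = pdb_field.strip().split("_")
    if len(parts) != 3:
        raise ValueError(f"expected PDB_CH1_CH2, got {pdb_field!r}")
    out: dict[str, str] = {}
    for group, label in ((parts[1], "P1"), (parts[2], "P2")):
        for ch in group:
            out[ch] = label
    return out
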