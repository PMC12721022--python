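"""Reading, writing and partitioning atomic models.

Coordinate files (mmCIF / PDB) are parsed with gemmi; this module flattens
them into plain per-atom records carrying chain, residue and atom identity,
and assigns chains to the analysis roles (reference subunit, mobile
subunit, excluded). Author-style identifiers are the default because the
literature on these assemblies cites author residue numbers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

from .errors import ConfigError, DegenerateGeometryError, StructureParseError

# Standard residue-name vocabularies used to classify entity kind.
_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_RNA = {"A", "U", "G", "C", "I", "N"}
_DNA = {"DA", "DT", "DG", "DC", "DU", "DI", "DN"}


def entity_kind_of(residue_name: str) -> str:
    """Classify a residue name as protein / rna / dna / other.

    Deterministic lookup on the standard residue-name vocabularies; anything
    unrecognized (ligands, ions, waters, modified residues) is 'other'.
    """
    name = residue_name.strip().upper()
    if name in _AMINO3:
        return "protein"
    if name in _RNA:
        return "rna"
    if name in _DNA:
        return "dna"
    return "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its full identity.

    residue_number uses the requested id scheme (author by default);
    insertion_code is "" when absent; position is in Å.
    """

    model_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""

    @property
    def entity_kind(self) -> str:
        return entity_kind_of(self.residue_name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.atom_name)


@dataclass
class StructureModel:
    """A flat, ordered atomic model with a chain index."""

    atoms: list[AtomRecord]
    source_path: str = ""
    source_dialect: str = ""
    model_id: str = ""
    chain_index: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chain_index:
            self.rebuild_chain_index()

    def rebuild_chain_index(self) -> None:
        index: dict[str, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            index.setdefault(atom.chain_id, []).append(i)
        self.chain_index = index

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chain_index)

    def positions(self, indices: Sequence[int] | None = None) -> np.ndarray:
        if indices is None:
            return np.array([a.position for a in self.atoms], dtype=float)
        return np.array([self.atoms[i].position for i in indices], dtype=float)

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.chain_index.get(chain_id, [])]

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)


@dataclass
class SubunitPartition:
    """Assignment of chains to reference ('LSU'), mobile ('SSU') and
    excluded (tRNA/mRNA/ligand) roles, with an optional residue-range
    restriction of the mobile body."""

    reference_chains: set[str]
    mobile_chains: set[str]
    excluded_chains: set[str] = field(default_factory=set)
    mobile_body_ranges: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.reference_chains = set(self.reference_chains)
        self.mobile_chains = set(self.mobile_chains)
        self.excluded_chains = set(self.excluded_chains)
        roles = [self.reference_chains, self.mobile_chains,
                 self.excluded_chains]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = roles[i] & roles[j]
                if overlap:
                    raise ConfigError(
                        f"chains assigned to more than one role: {sorted(overlap)}")
        for chain, ranges in self.mobile_body_ranges.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ConfigError(
                        f"mobile_body_ranges[{chain!r}]: interval start {lo} > end {hi}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubunitPartition":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read partition config {path}: {exc}")
        if not isinstance(data, dict):
            raise ConfigError(f"partition config {path} is not a mapping")
        ranges = {
            str(chain): [(int(lo), int(hi)) for lo, hi in intervals]
            for chain, intervals in (data.get("mobile_body_ranges") or {}).items()
        }
        return cls(
            reference_chains=set(map(str, data.get("reference_chains") or [])),
            mobile_chains=set(map(str, data.get("mobile_chains") or [])),
            excluded_chains=set(map(str, data.get("excluded_chains") or [])),
            mobile_body_ranges=ranges,
        )


@dataclass
class ChainNameMap:
    """Canonical entity names for chain labels, per model.

    Chain labels differ between depositions of the same assembly, so
    composition comparisons run on canonical names (e.g. 'mS47',
    '21S rRNA'), not on labels.
    """

    entries: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        per_model: dict[str, dict[str, str]] = {}
        for (model_id, chain_id), name in self.entries.items():
            if not name:
                raise ConfigError(
                    f"empty canonical name for ({model_id}, {chain_id})")
            per_model.setdefault(model_id, {})[chain_id] = name

    def name_for(self, model_id: str, chain_id: str) -> str | None:
        return self.entries.get((model_id, chain_id))

    def chains_of(self, model_id: str) -> dict[str, str]:
        return {c: n for (m, c), n in self.entries.items() if m == model_id}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChainNameMap":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read name map {path}: {exc}")
        if not isinstance(data, dict):
            raise ConfigError(f"name map {path} is not a mapping")
        entries: dict[tuple[str, str], str] = {}
        for model_id, chains in data.items():
            if not isinstance(chains, dict):
                raise ConfigError(
                    f"name map entry for model {model_id!r} is not a mapping")
            for chain_id, name in chains.items():
                entries[(str(model_id), str(chain_id))] = str(name)
        return cls(entries)


_DIALECT_FORMATS = {
    "mmcif": gemmi.CoorFormat.Mmcif,
    "pdb": gemmi.CoorFormat.Pdb,
}


def _detect_dialect(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".cif", ".mmcif") for s in suffixes):
        return "mmcif"
    if any(s in (".pdb", ".ent") for s in suffixes):
        return "pdb"
    # fall back on content sniffing: mmCIF starts with 'data_'
    try:
        head = path.open("rb").read(64)
    except OSError as exc:
        raise StructureParseError(f"cannot open {path}: {exc}")
    return "mmcif" if head.lstrip().startswith(b"data_") else "pdb"


def read_structure(path: str | Path, dialect: str = "auto",
                   id_scheme: str = "auth") -> StructureModel:
    """Read the first model block of a coordinate file.

    Alt-loc duplicates collapse to the highest-occupancy record (ties break
    to the lexicographically smallest alt_loc label). ``id_scheme`` selects
    author ('auth', default) or label chain/residue identifiers; label
    identifiers fall back to author values where a file carries none.
    """
    path = Path(path)
    if id_scheme not in ("auth", "label"):
        raise ConfigError(f"unknown id_scheme {id_scheme!r}")
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in _DIALECT_FORMATS:
        raise ConfigError(f"unknown dialect {dialect!r}")
    try:
        structure = gemmi.read_structure(str(path),
                                         format=_DIALECT_FORMATS[dialect])
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path} as {dialect}: {exc}")
    structure.setup_entities()
    if len(structure) == 0:
        raise StructureParseError(f"{path}: no model blocks")
    model = structure[0]
    model_id = structure.name or path.stem

    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for chain in model:
        for residue in chain:
            if id_scheme == "label":
                chain_id = residue.subchain or chain.name
                seq = residue.label_seq
                resnum = int(seq) if seq is not None else residue.seqid.num
                icode = ""
            else:
                chain_id = chain.name
                resnum = residue.seqid.num
                icode = (residue.seqid.icode or "").strip()
            for atom in residue:
                rec = AtomRecord(
                    model_id=model_id,
                    chain_id=chain_id,
                    residue_number=resnum,
                    insertion_code=icode,
                    residue_name=residue.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(atom.occ),
                    alt_loc=(atom.altloc or "").strip(),
                )
                key = rec.atom_key
                held = best.get(key)
                if held is None:
                    best[key] = rec
                    order.append(key)
                elif (rec.occupancy, _altloc_rank(rec.alt_loc)) > (
                        held.occupancy, _altloc_rank(held.alt_loc)):
                    best[key] = rec
    atoms = [best[k] for k in order]
    if not atoms:
        raise StructureParseError(f"{path}: no atoms")
    return StructureModel(atoms=atoms, source_path=str(path),
                          source_dialect=dialect, model_id=model_id)


def _altloc_rank(alt_loc: str) -> tuple:
    # higher rank wins; smaller altloc label preferred on occupancy ties
    return tuple(-ord(c) for c in alt_loc) if alt_loc else (1,)


_PDB_MAX_CHAIN = 2  # hybrid-36 style wwPDB files carry two-character chains


def write_structure(model: StructureModel, path: str | Path,
                    dialect: str = "mmcif") -> Path:
    """Write a model as mmCIF or PDB; the file re-reads to the same atoms
    (coordinates at format precision, 1e-3 Å)."""
    path = Path(path)
    if dialect not in _DIALECT_FORMATS:
        raise ConfigError(f"unknown dialect {dialect!r}")
    if not model.atoms:
        raise StructureParseError("refusing to write an empty model")
    if dialect == "pdb":
        for cid in model.chain_index:
            if len(cid) > _PDB_MAX_CHAIN:
                raise ConfigError(
                    f"chain id {cid!r} exceeds {_PDB_MAX_CHAIN} characters; "
                    "the PDB dialect cannot represent it (use mmcif)")

    # Group into chain -> residue -> atoms up front: gemmi's add_chain /
    # add_residue copy their argument, so the tree is built leaf-first.
    chain_order: list[str] = []
    residue_order: dict[str, list[tuple[str, int, str]]] = {}
    grouped: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for atom in model.atoms:
        if atom.chain_id not in residue_order:
            chain_order.append(atom.chain_id)
            residue_order[atom.chain_id] = []
        rkey = atom.residue_key
        if rkey not in grouped:
            residue_order[atom.chain_id].append(rkey)
            grouped[rkey] = []
        grouped[rkey].append(atom)

    structure = gemmi.Structure()
    structure.name = model.model_id or "model"
    gmodel = gemmi.Model("1")
    for chain_id in chain_order:
        chain = gemmi.Chain(chain_id)
        for rkey in residue_order[chain_id]:
            atoms = grouped[rkey]
            residue = gemmi.Residue()
            residue.name = atoms[0].residue_name
            residue.seqid = gemmi.SeqId(atoms[0].residue_number,
                                        atoms[0].insertion_code or " ")
            for atom in atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.atom_name
                gatom.element = gemmi.Element(atom.element or "X")
                gatom.pos = gemmi.Position(*atom.position)
                gatom.occ = atom.occupancy
                gatom.altloc = atom.alt_loc[:1] if atom.alt_loc else "\0"
                residue.add_atom(gatom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    if dialect == "pdb":
        structure.write_pdb(str(path))
    else:
        structure.make_mmcif_document().write_file(str(path))
    return path


def partition_chains(model: StructureModel,
                     config: SubunitPartition) -> SubunitPartition:
    """Validate a partition against a model.

    Unknown chain ids are an error; chains the config does not mention are
    added to the excluded role. Idempotent.
    """
    present = set(model.chain_index)
    configured = (config.reference_chains | config.mobile_chains
                  | config.excluded_chains)
    missing = configured - present
    if missing:
        raise ConfigError(
            f"partition names chains absent from {model.model_id or 'model'}: "
            f"{sorted(missing)}")
    reference = config.reference_chains & present
    mobile = config.mobile_chains & present
    excluded = (config.excluded_chains | (present - configured))
    if not reference or not mobile:
        raise ConfigError(
            "degenerate partition: reference and mobile roles must each "
            f"contain at least one chain (got {len(reference)} reference, "
            f"{len(mobile)} mobile)")
    return SubunitPartition(
        reference_chains=reference,
        mobile_chains=mobile,
        excluded_chains=excluded,
        mobile_body_ranges=dict(config.mobile_body_ranges),
    )


_BACKBONE_NAMES = {"P": {"P"}, "CA": {"CA"}, "both": {"P", "CA"}}


def select_backbone(model: StructureModel, chains: Iterable[str],
                    atom_class: str = "both",
                    body_ranges: Mapping[str, Sequence[tuple[int, int]]]
                    | None = None) -> list[AtomRecord]:
    """Backbone atoms (nucleotide P, amino-acid CA, or both) of the given
    chains, ordered by (chain_id, residue_number, atom_name).

    ``body_ranges`` restricts listed chains to inclusive residue intervals;
    chains without an entry are kept whole.
    """
    chains = set(chains)
    if not chains:
        raise ConfigError("select_backbone: empty chain set")
    try:
        wanted = _BACKBONE_NAMES[atom_class]
    except KeyError:
        raise ConfigError(f"unknown atom_class {atom_class!r}")
    selected: list[AtomRecord] = []
    for atom in model.atoms:
        if atom.chain_id not in chains or atom.atom_name not in wanted:
            continue
        if body_ranges and atom.chain_id in body_ranges:
            if not any(lo <= atom.residue_number <= hi
                       for lo, hi in body_ranges[atom.chain_id]):
                continue
        selected.append(atom)
    if not selected:
        raise DegenerateGeometryError(
            f"no backbone atoms selected (chains={sorted(chains)}, "
            f"atom_class={atom_class})")
    selected.sort(key=lambda a: (a.chain_id, a.residue_number,
                                 a.insertion_code, a.atom_name))
    return selected
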