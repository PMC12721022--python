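"""Non-rotational model comparisons.

Per-residue displacement profiles (how far each residue moved between two
superposed models), threshold-based difference-region calling, single
residue lookups, and chain-composition diffs on canonical entity names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correspondence import MatchedPairs
from .errors import ConfigError, DegenerateGeometryError
from .structure_io import ChainNameMap, StructureModel

log = logging.getLogger(__name__)

# representative-atom conventions: auto = P for nucleotides, CA for proteins
_REPRESENTATIVES = ("auto", "P", "CA", "max_backbone")
_BACKBONE = {"P", "CA"}


@dataclass
class DisplacementProfile:
    """Per-residue displacement table (one entry per residue)."""

    entries: pd.DataFrame  # chain_id, residue_number, representative_atom, displacement

    def value_at(self, chain_id: str, residue_number: int) -> float:
        rows = self.entries[(self.entries.chain_id == chain_id)
                            & (self.entries.residue_number == residue_number)]
        if rows.empty:
            raise KeyError(f"no profile entry for {chain_id}/{residue_number}")
        return float(rows.displacement.iloc[0])


@dataclass
class DifferenceRegion:
    chain_id: str
    start_residue: int
    end_residue: int
    max_displacement: float
    mean_displacement: float
    n_residues: int


@dataclass
class CompositionDiff:
    shared: set[str]
    only_a: set[str]
    only_b: set[str]


def _representative_displacements(pairs: MatchedPairs, chains: set[str],
                                  representative: str
                                  ) -> dict[tuple[str, int], tuple[str, float]]:
    if representative not in _REPRESENTATIVES:
        raise ConfigError(f"unknown representative {representative!r}")
    disp = np.linalg.norm(pairs.pos_b - pairs.pos_a, axis=1)
    per_residue: dict[tuple[str, int], dict[str, float]] = {}
    for key, d in zip(pairs.keys, disp):
        chain_id, resnum, _icode, atom_name = key
        if chain_id not in chains or atom_name not in _BACKBONE:
            continue
        per_residue.setdefault((chain_id, resnum), {})[atom_name] = float(d)
    out: dict[tuple[str, int], tuple[str, float]] = {}
    skipped = 0
    for rkey, atoms in per_residue.items():
        if representative == "max_backbone":
            name = max(atoms, key=lambda a: atoms[a])
        elif representative == "auto":
            # nucleotide backbone carries P; protein backbone carries CA
            name = "P" if "P" in atoms else "CA"
        else:
            name = representative
        if name not in atoms:
            skipped += 1
            continue
        out[rkey] = (name, atoms[name])
    if skipped:
        log.info("%d residue(s) lacked the requested representative atom",
                 skipped)
    return out


def residue_displacement_profile(pairs: MatchedPairs, chains: set[str],
                                 representative: str = "auto"
                                 ) -> DisplacementProfile:
    """One displacement per residue of the requested chains.

    The displacement is |pos_b − pos_a| of the representative atom (P for
    nucleotides, CA for amino acids by default), or the maximum over the
    residue's matched backbone atoms for representative='max_backbone'.
    """
    chains = set(chains)
    values = _representative_displacements(pairs, chains, representative)
    if not values:
        raise DegenerateGeometryError(
            f"no matched residues in chains {sorted(chains)}")
    rows = [(c, r, name, d) for (c, r), (name, d) in sorted(values.items())]
    frame = pd.DataFrame(rows, columns=["chain_id", "residue_number",
                                        "representative_atom", "displacement"])
    return DisplacementProfile(entries=frame)


def measure_residue_displacement(pairs: MatchedPairs, chain_id: str,
                                 residue_number: int,
                                 representative: str = "auto") -> float:
    """Representative-atom displacement of one residue (same convention as
    the profile)."""
    values = _representative_displacements(pairs, {chain_id}, representative)
    entry = values.get((chain_id, residue_number))
    if entry is None:
        present_a = any(k[0] == chain_id and k[1] == residue_number
                        for k in pairs.keys)
        side = ("its representative atom is unmatched" if present_a
                else "it is absent from the matched pairs (missing in one model)")
        raise KeyError(
            f"residue {chain_id}/{residue_number}: {side}")
    return entry[1]


def call_difference_regions(profile: DisplacementProfile, threshold: float = 2.0,
                            max_gap: int = 1) -> list[DifferenceRegion]:
    """Merge above-threshold residues into maximal runs.

    Residues with displacement > threshold seed regions; up to ``max_gap``
    consecutive profiled sub-threshold residues are absorbed inside a run.
    Regions are sorted by (chain, start). Idempotent and order-invariant.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    if max_gap < 0:
        raise ConfigError("max_gap must be >= 0")
    regions: list[DifferenceRegion] = []
    frame = profile.entries.sort_values(["chain_id", "residue_number"])
    for chain_id, group in frame.groupby("chain_id", sort=True):
        resnums = group.residue_number.to_numpy()
        disps = group.displacement.to_numpy()
        hot = disps > threshold
        run: list[int] | None = None  # indices into group
        gap = 0

        def close(run_idx: list[int]) -> None:
            sel = disps[run_idx]
            regions.append(DifferenceRegion(
                chain_id=str(chain_id),
                start_residue=int(resnums[run_idx[0]]),
                end_residue=int(resnums[run_idx[-1]]),
                max_displacement=float(sel.max()),
                mean_displacement=float(sel.mean()),
                n_residues=len(run_idx)))

        for i in range(len(resnums)):
            if hot[i]:
                if run is None:
                    run = [i]
                else:
                    run.extend(range(run[-1] + 1, i + 1))
                gap = 0
            elif run is not None:
                gap += 1
                if gap > max_gap:
                    close(run)
                    run, gap = None, 0
        if run is not None:
            close(run)
    regions.sort(key=lambda r: (r.chain_id, r.start_residue))
    return regions


def _canonical_names(model: StructureModel, name_map: ChainNameMap,
                     kind_filter: str) -> set[str]:
    if kind_filter not in ("protein", "rna", "all"):
        raise ConfigError(f"unknown kind_filter {kind_filter!r}")
    names: set[str] = set()
    unmapped: list[str] = []
    for chain_id, indices in model.chain_index.items():
        name = name_map.name_for(model.model_id, chain_id)
        if name is None:
            unmapped.append(chain_id)
            continue
        if kind_filter != "all":
            kinds = [model.atoms[i].entity_kind for i in indices]
            majority = max(set(kinds), key=kinds.count)
            if majority != kind_filter:
                continue
        names.add(name)
    if unmapped:
        raise ConfigError(
            f"name map does not cover chains {sorted(unmapped)} of model "
            f"{model.model_id!r}")
    return names


def compare_chain_composition(model_a: StructureModel, model_b: StructureModel,
                              name_map: ChainNameMap,
                              kind_filter: str = "all") -> CompositionDiff:
    """Entity-level composition diff on canonical names."""
    names_a = _canonical_names(model_a, name_map, kind_filter)
    names_b = _canonical_names(model_b, name_map, kind_filter)
    diff = CompositionDiff(shared=names_a & names_b,
                           only_a=names_a - names_b,
                           only_b=names_b - names_a)
    log.info("composition: %d shared, %d only in A, %d only in B",
             len(diff.shared), len(diff.only_a), len(diff.only_b))
    return diff


def count_protein_chains(model: StructureModel, name_map: ChainNameMap) -> int:
    """Distinct canonical protein-entity names in a model (copies of one
    named protein count once)."""
    return len(_canonical_names(model, name_map, "protein"))
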