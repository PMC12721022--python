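"""Per-atom correspondence between two models and rigid superposition.

Atoms are matched by identity — (chain_id, residue_number, insertion_code,
atom_name) after any chain renaming — never by sequence alignment; numbering
mismatches surface as low match counts. The common frame is set by a
least-squares proper rigid superposition (Kabsch) of model B onto model A,
by default on the reference-subunit backbone, because the analysis treats
the reference subunit as the fixed body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError
from .structure_io import StructureModel, SubunitPartition, select_backbone

log = logging.getLogger(__name__)


@dataclass
class MatchedPairs:
    """Paired coordinates of identically named backbone atoms.

    pos_a holds the start-state positions, pos_b the end-state positions;
    role marks each key as reference- or mobile-subunit.
    """

    keys: list[tuple[str, int, str, str]]
    pos_a: np.ndarray  # (n, 3) Å
    pos_b: np.ndarray  # (n, 3) Å
    role: np.ndarray   # (n,) of {"reference", "mobile"}

    def __post_init__(self) -> None:
        self.pos_a = np.asarray(self.pos_a, dtype=float).reshape(-1, 3)
        self.pos_b = np.asarray(self.pos_b, dtype=float).reshape(-1, 3)
        self.role = np.asarray(self.role, dtype=object)
        n = len(self.keys)
        if not (self.pos_a.shape[0] == self.pos_b.shape[0]
                == self.role.shape[0] == n):
            raise ValueError("keys, pos_a, pos_b, role lengths differ")
        if len(set(self.keys)) != n:
            raise ValueError("duplicate keys in MatchedPairs")

    def mask(self, role: str) -> np.ndarray:
        return self.role == role

    def subset(self, mask: np.ndarray) -> "MatchedPairs":
        idx = np.flatnonzero(mask)
        return MatchedPairs(
            keys=[self.keys[i] for i in idx],
            pos_a=self.pos_a[idx],
            pos_b=self.pos_b[idx],
            role=self.role[idx],
        )

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class SuperpositionResult:
    """Proper rigid transform (rotation then translation) mapping model B
    onto model A, with fit diagnostics."""

    rotation: np.ndarray     # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd_before: float
    rmsd_after: float
    n_atoms_fit: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def match_backbone(model_a: StructureModel, model_b: StructureModel,
                   partition: SubunitPartition,
                   atom_class: str = "both") -> MatchedPairs:
    """Match backbone atoms by identity across the two models.

    Only keys present in both models are kept; the mobile role honours the
    partition's mobile_body_ranges, the reference role never does. Ordering
    follows select_backbone (reference block first, then mobile).
    """
    keys: list[tuple[str, int, str, str]] = []
    pos_a: list[tuple[float, float, float]] = []
    pos_b: list[tuple[float, float, float]] = []
    roles: list[str] = []
    counts = {}
    for role, chains, ranges in (
            ("reference", partition.reference_chains, None),
            ("mobile", partition.mobile_chains,
             partition.mobile_body_ranges or None)):
        sel_a = select_backbone(model_a, chains, atom_class, ranges)
        sel_b = select_backbone(model_b, chains, atom_class, ranges)
        index_b = {a.atom_key: a for a in sel_b}
        matched = 0
        for atom in sel_a:
            other = index_b.get(atom.atom_key)
            if other is None:
                continue
            keys.append(atom.atom_key)
            pos_a.append(atom.position)
            pos_b.append(other.position)
            roles.append(role)
            matched += 1
        counts[role] = (matched, len(sel_a) - matched, len(sel_b) - matched)
        if matched == 0:
            raise DegenerateGeometryError(
                f"no matched {role} atoms between "
                f"{model_a.model_id or 'A'} and {model_b.model_id or 'B'}")
    for role, (m, ua, ub) in counts.items():
        log.info("match_backbone[%s]: %d matched, %d only in A, %d only in B",
                 role, m, ua, ub)
    return MatchedPairs(keys=keys, pos_a=np.array(pos_a),
                        pos_b=np.array(pos_b), role=np.array(roles, dtype=object))


def rmsd(pos_x: np.ndarray, pos_y: np.ndarray) -> float:
    """Root-mean-square per-atom Euclidean distance between paired lists."""
    pos_x = np.asarray(pos_x, dtype=float).reshape(-1, 3)
    pos_y = np.asarray(pos_y, dtype=float).reshape(-1, 3)
    if pos_x.shape != pos_y.shape or pos_x.shape[0] == 0:
        raise ValueError(
            f"rmsd needs equal nonempty lists, got {pos_x.shape} vs {pos_y.shape}")
    return float(np.sqrt(np.mean(np.sum((pos_x - pos_y) ** 2, axis=1))))


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s.shape[0] < 2 or s[1] <= tol * max(s[0], 1.0)


def kabsch_superpose(pairs: MatchedPairs,
                     fit_on: str = "reference") -> SuperpositionResult:
    """Least-squares proper rigid transform of model B onto model A.

    Reflections are never returned; mirror-image inputs yield the best
    proper rotation (with nonzero residual) instead.
    """
    if fit_on == "all":
        fit_mask = np.ones(len(pairs), dtype=bool)
    elif fit_on in ("reference", "mobile"):
        fit_mask = pairs.mask(fit_on)
    else:
        raise ValueError(f"unknown fit_on {fit_on!r}")
    a = pairs.pos_a[fit_mask]
    b = pairs.pos_b[fit_mask]
    if a.shape[0] < 3 or _collinear(a) or _collinear(b):
        raise DegenerateGeometryError(
            f"degenerate fit: need >=3 non-collinear atoms in the "
            f"{fit_on} fit set (got {a.shape[0]})")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - cen_a, b - cen_b)
    matrix = rot.as_matrix()
    translation = cen_a - matrix @ cen_b
    fitted = b @ matrix.T + translation
    return SuperpositionResult(
        rotation=matrix,
        translation=translation,
        rmsd_before=rmsd(a, b),
        rmsd_after=rmsd(a, fitted),
        n_atoms_fit=int(a.shape[0]),
    )


def apply_transform(pairs: MatchedPairs,
                    transform: SuperpositionResult) -> MatchedPairs:
    """Return pairs with pos_b mapped through the transform; pos_a fixed."""
    return replace(pairs, pos_b=transform.apply(pairs.pos_b),
                   keys=list(pairs.keys), pos_a=pairs.pos_a.copy(),
                   role=pairs.role.copy())
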