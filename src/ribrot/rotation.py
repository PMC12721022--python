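"""Planar inter-subunit rotation analysis.

The procedure quantifies how one subunit of a two-subunit assembly rotates
relative to the other between two conformational states:

1. a plane maximally separating the reference- and mobile-subunit atom
   clouds is fitted (Fisher linear discriminant by default);
2. mobile-subunit backbone start positions and displacement vectors are
   projected onto that plane;
3. atoms whose 3D displacement does not exceed a threshold (3 Å default)
   are dropped so coordinate noise does not masquerade as motion;
4. a 2D rotation center is found by maximizing the tangentiality of the
   displacement field — equivalently, minimizing the mean squared cosine
   between each atom's radial direction and its displacement direction;
5. each retained atom gets a chord angle θ = 2·arcsin(chord / 2r), exact
   for circular motion, and the field is summarized by the median (or
   mean) angle.

Everything is deterministic: plane and center come from closed forms and a
grid + Nelder–Mead refinement with fixed tolerances, so repeated runs are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .correspondence import MatchedPairs
from .errors import DegenerateGeometryError

log = logging.getLogger(__name__)


@dataclass
class RotationConfig:
    """Tunable knobs of the rotation analysis.

    min_displacement: retain only atoms moving farther than this in 3D (Å);
    the default 3.0 suppresses spurious shifts from coordinate error.
    center_grid_step: coarse-grid spacing of the center search (Å).
    """

    min_displacement: float = 3.0
    atom_class: str = "both"
    plane_method: str = "fisher"
    center_grid_step: float = 2.0
    center_refine_tol: float = 1e-6
    angle_summary: str = "median"

    def __post_init__(self) -> None:
        if self.min_displacement < 0:
            raise ValueError("min_displacement must be >= 0")
        if self.center_grid_step <= 0:
            raise ValueError("center_grid_step must be > 0")
        if self.angle_summary not in ("median", "mean"):
            raise ValueError(f"unknown angle_summary {self.angle_summary!r}")
        if self.plane_method not in ("fisher", "pca_gap"):
            raise ValueError(f"unknown plane_method {self.plane_method!r}")


@dataclass
class SeparatingPlane:
    """Oriented plane with an in-plane orthonormal basis.

    normal points from the reference toward the mobile cloud; (basis_u,
    basis_v, normal) is right-handed. separation_score is the distance of
    the projected cloud means in pooled-standard-deviation units.
    """

    normal: np.ndarray
    origin: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    separation_score: float

    def __post_init__(self) -> None:
        for name in ("normal", "origin", "basis_u", "basis_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for v in (self.normal, self.basis_u, self.basis_v):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("plane basis vectors must be unit length")
        gram = np.abs([self.normal @ self.basis_u, self.normal @ self.basis_v,
                       self.basis_u @ self.basis_v])
        if gram.max() > 1e-9:
            raise ValueError("plane basis must be orthogonal")
        if np.cross(self.basis_u, self.basis_v) @ self.normal < 0:
            raise ValueError("(basis_u, basis_v, normal) must be right-handed")

    def project_point(self, xyz: np.ndarray) -> np.ndarray:
        """In-plane (u, v) coordinates of 3D point(s)."""
        rel = np.asarray(xyz, dtype=float) - self.origin
        return np.stack([rel @ self.basis_u, rel @ self.basis_v], axis=-1)

    def project_vector(self, vec: np.ndarray) -> np.ndarray:
        vec = np.asarray(vec, dtype=float)
        return np.stack([vec @ self.basis_u, vec @ self.basis_v], axis=-1)

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """3D point of in-plane coordinates (u, v)."""
        u, v = np.asarray(uv, dtype=float)
        return self.origin + u * self.basis_u + v * self.basis_v


@dataclass
class RotationField:
    """Projected mobile-subunit displacement field with retention mask."""

    keys: list[tuple[str, int, str, str]]
    start_2d: np.ndarray   # (n, 2) projected start positions, Å
    disp_2d: np.ndarray    # (n, 2) in-plane displacement, Å
    disp_3d: np.ndarray    # (n,) 3D displacement magnitude, Å
    retained: np.ndarray   # (n,) bool, disp_3d > min_displacement
    min_displacement: float

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class RotationSummary:
    """Fitted center, per-atom geometry, and summary angle statistics."""

    center_2d: np.ndarray
    objective_at_optimum: float
    n_retained: int
    per_atom_keys: list[tuple[str, int, str, str]] = field(default_factory=list)
    per_atom_radius: np.ndarray | None = None
    per_atom_angle_deg: np.ndarray | None = None
    summary_angle_deg: float = float("nan")
    mean_angle_deg: float = float("nan")
    angle_dispersion: float = float("nan")
    sign: str = "mixed"


def _orthonormal_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis: unit projection of the x-axis (y-axis when the
    normal is within 1e-6 of x), then v = normal × u (right-handed)."""
    for axis in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
        proj = axis - (axis @ normal) * normal
        norm = np.linalg.norm(proj)
        if norm > 1e-6:
            u = proj / norm
            break
    else:  # pragma: no cover - normal cannot align with both axes
        raise DegenerateGeometryError("cannot build in-plane basis")
    v = np.cross(normal, u)
    return u, v / np.linalg.norm(v)


def fit_separating_plane(reference_atoms: np.ndarray, mobile_atoms: np.ndarray,
                         config: RotationConfig | None = None) -> SeparatingPlane:
    """Fit the plane maximally separating the two subunit point clouds.

    fisher (default): the normal is the Fisher linear-discriminant
    direction (between-set separation over pooled within-set variance,
    closed form w ∝ S_w⁻¹ (μ_mobile − μ_ref)). pca_gap: the candidate
    direction (pooled principal axes + mean difference) with the largest
    gap between the projected cloud extents.
    """
    config = config or RotationConfig()
    ref = np.asarray(reference_atoms, dtype=float).reshape(-1, 3)
    mob = np.asarray(mobile_atoms, dtype=float).reshape(-1, 3)
    if ref.shape[0] < 3 or mob.shape[0] < 3:
        raise DegenerateGeometryError(
            "plane fit needs >=3 atoms in each subunit")
    mu_r = ref.mean(axis=0)
    mu_m = mob.mean(axis=0)
    delta = mu_m - mu_r
    if np.linalg.norm(delta) < 1e-12:
        raise DegenerateGeometryError(
            "inseparable clouds: subunit means coincide")

    if config.plane_method == "fisher":
        sw = np.cov(ref.T, bias=False) * (ref.shape[0] - 1)
        sw = sw + np.cov(mob.T, bias=False) * (mob.shape[0] - 1)
        sw = sw / (ref.shape[0] + mob.shape[0] - 2)
        # ridge keeps the solve well-posed for degenerate (planar) clouds
        sw = sw + 1e-9 * np.trace(sw) / 3.0 * np.eye(3) + 1e-12 * np.eye(3)
        direction = np.linalg.solve(sw, delta)
    else:  # pca_gap
        pooled = np.vstack([ref - mu_r, mob - mu_m])
        _, _, vt = np.linalg.svd(pooled, full_matrices=False)
        candidates = list(vt) + [delta / np.linalg.norm(delta)]
        direction, best_gap = None, -np.inf
        for cand in candidates:
            s = 1.0 if cand @ delta >= 0 else -1.0
            cand = s * cand
            gap = (mob @ cand).min() - (ref @ cand).max()
            if gap > best_gap:
                best_gap, direction = gap, cand
    normal = np.asarray(direction, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if normal @ delta < 0:
        normal = -normal

    proj_r = ref @ normal
    proj_m = mob @ normal
    pooled_sd = np.sqrt(0.5 * (proj_r.var(ddof=1) + proj_m.var(ddof=1)))
    score = (float("inf") if pooled_sd < 1e-12
             else float((proj_m.mean() - proj_r.mean()) / pooled_sd))
    origin = 0.5 * (mu_r + mu_m)
    u, v = _orthonormal_basis(normal)
    return SeparatingPlane(normal=normal, origin=origin, basis_u=u,
                           basis_v=v, separation_score=score)


def build_rotation_field(pairs: MatchedPairs, plane: SeparatingPlane,
                         config: RotationConfig | None = None) -> RotationField:
    """Project mobile-atom displacements into the plane and flag the atoms
    moving farther than the threshold (strict >) in 3D."""
    config = config or RotationConfig()
    mobile = pairs.subset(pairs.mask("mobile"))
    if len(mobile) == 0:
        raise DegenerateGeometryError("no mobile atoms in pairs")
    disp3 = mobile.pos_b - mobile.pos_a
    disp_3d = np.linalg.norm(disp3, axis=1)
    return RotationField(
        keys=list(mobile.keys),
        start_2d=plane.project_point(mobile.pos_a),
        disp_2d=plane.project_vector(disp3),
        disp_3d=disp_3d,
        retained=disp_3d > config.min_displacement,
        min_displacement=config.min_displacement,
    )


def tangentiality_objective(center: np.ndarray, chord_mid: np.ndarray,
                            unit_disp: np.ndarray) -> float:
    """Mean squared cosine between radial and displacement directions.

    The radial direction is taken from the candidate center to the chord
    midpoint: for circular motion the chord is exactly perpendicular to
    that radius (the perpendicular-bisector property), so the objective is
    zero at the true center for any rotation magnitude — whereas the
    radius to the chord start is off-perpendicular by θ/2 even at the true
    center. Ranges over [0, 1]; 1 means a purely radial field. Atoms
    closer than 1e-9 Å to the candidate center are skipped (their radial
    direction is undefined).
    """
    radial = chord_mid - np.asarray(center, dtype=float)
    norms = np.linalg.norm(radial, axis=1)
    ok = norms > 1e-9
    if not np.any(ok):
        return 1.0
    cosines = np.einsum("ij,ij->i", radial[ok], unit_disp[ok]) / norms[ok]
    return float(np.mean(cosines ** 2))


def _direction_spread_ok(unit_disp: np.ndarray, tol_deg: float = 1.0) -> bool:
    """False when all displacement directions lie within tol of one line
    (sign-blind), i.e. the field is translation-dominated."""
    second_moment = unit_disp.T @ unit_disp / unit_disp.shape[0]
    eigvals = np.linalg.eigvalsh(second_moment)
    return bool(np.sqrt(max(eigvals[0], 0.0)) > np.sin(np.radians(tol_deg)))


def fit_rotation_center(fld: RotationField,
                        config: RotationConfig | None = None) -> RotationSummary:
    """Locate the 2D rotation center by maximizing tangentiality.

    Deterministic two-stage search: a coarse grid over the retained atoms'
    bounding box expanded by 50% on each side, then Nelder–Mead from the
    best grid point down to the configured tolerance.
    """
    config = config or RotationConfig()
    start = fld.start_2d[fld.retained]
    disp = fld.disp_2d[fld.retained]
    if start.shape[0] < 3:
        raise DegenerateGeometryError(
            f"insufficient retained atoms: {start.shape[0]} after the "
            f"{fld.min_displacement} Å displacement filter (need >=3)")
    norms = np.linalg.norm(disp, axis=1)
    moving = norms > 1e-12
    if moving.sum() < 3:
        raise DegenerateGeometryError(
            "insufficient retained atoms with in-plane motion")
    start = start[moving]
    disp = disp[moving]
    unit_disp = disp / norms[moving, None]
    chord_mid = start + 0.5 * disp
    if not _direction_spread_ok(unit_disp):
        raise DegenerateGeometryError(
            "no rotation center: displacement directions are within 1° of a "
            "common line (translation-dominated field)")

    lo = start.min(axis=0)
    hi = start.max(axis=0)
    span = np.maximum(hi - lo, config.center_grid_step)
    lo = lo - 0.5 * span
    hi = hi + 0.5 * span
    gu = np.arange(lo[0], hi[0] + config.center_grid_step,
                   config.center_grid_step)
    gv = np.arange(lo[1], hi[1] + config.center_grid_step,
                   config.center_grid_step)
    uu, vv = np.meshgrid(gu, gv, indexing="ij")
    centers = np.stack([uu.ravel(), vv.ravel()], axis=1)
    # vectorized objective over the whole grid (chunked to bound memory)
    best_val, best_center = np.inf, centers[0]
    for block in np.array_split(centers, max(1, centers.shape[0] // 4096)):
        radial = chord_mid[None, :, :] - block[:, None, :]
        norms_r = np.linalg.norm(radial, axis=2)
        safe = np.where(norms_r > 1e-9, norms_r, np.inf)
        cos = np.einsum("cij,ij->ci", radial, unit_disp) / safe
        vals = np.mean(cos ** 2, axis=1)
        i = int(np.argmin(vals))
        if vals[i] < best_val:
            best_val, best_center = float(vals[i]), block[i]

    result = minimize(
        tangentiality_objective, best_center, args=(chord_mid, unit_disp),
        method="Nelder-Mead",
        options={"xatol": config.center_refine_tol,
                 "fatol": config.center_refine_tol ** 2,
                 "maxiter": 2000},
    )
    center = result.x if result.fun <= best_val else best_center
    value = min(float(result.fun), best_val)
    log.info("rotation center (%.3f, %.3f) Å, objective %.3e, %d atoms",
             center[0], center[1], value, chord_mid.shape[0])
    return RotationSummary(center_2d=np.asarray(center, dtype=float),
                           objective_at_optimum=value,
                           n_retained=int(fld.retained.sum()))


def per_atom_angles(fld: RotationField, center_2d: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chord angles (degrees) of the retained atoms about a center.

    θ = 2·arcsin(clamp(|chord| / 2r, 0, 1)): exact for circular motion in
    the plane. Returns (retained-index array, radii, angles); retained
    atoms sitting at the center (r ≤ 1e-6 Å) are excluded with a warning.
    """
    idx = np.flatnonzero(fld.retained)
    if idx.size == 0:
        raise DegenerateGeometryError("no retained atoms for angle computation")
    center = np.asarray(center_2d, dtype=float)
    radial = fld.start_2d[idx] - center
    radii = np.linalg.norm(radial, axis=1)
    ok = radii > 1e-6
    if not np.all(ok):
        log.warning("%d retained atom(s) at the rotation center excluded "
                    "from angles", int((~ok).sum()))
    idx, radii = idx[ok], radii[ok]
    chords = np.linalg.norm(fld.disp_2d[idx], axis=1)
    ratio = np.clip(chords / (2.0 * radii), 0.0, 1.0)
    return idx, radii, np.degrees(2.0 * np.arcsin(ratio))


def summarize_rotation(fld: RotationField, center_fit: RotationSummary,
                       config: RotationConfig | None = None) -> RotationSummary:
    """Complete the summary: per-atom radii/angles, median (or mean) angle,
    IQR dispersion, and the majority rotation sense."""
    config = config or RotationConfig()
    idx, radii, angles = per_atom_angles(fld, center_fit.center_2d)
    q25, q75 = np.percentile(angles, [25, 75])
    radial = fld.start_2d[idx] - center_fit.center_2d
    cross = radial[:, 0] * fld.disp_2d[idx, 1] - radial[:, 1] * fld.disp_2d[idx, 0]
    n_pos = int((cross > 0).sum())
    n_neg = int((cross < 0).sum())
    if n_pos > len(cross) / 2:
        sign = "ccw"
    elif n_neg > len(cross) / 2:
        sign = "cw"
    else:
        sign = "mixed"
    summary = float(np.median(angles) if config.angle_summary == "median"
                    else np.mean(angles))
    return RotationSummary(
        center_2d=center_fit.center_2d,
        objective_at_optimum=center_fit.objective_at_optimum,
        n_retained=center_fit.n_retained,
        per_atom_keys=[fld.keys[i] for i in idx],
        per_atom_radius=radii,
        per_atom_angle_deg=angles,
        summary_angle_deg=summary,
        mean_angle_deg=float(np.mean(angles)),
        angle_dispersion=float(q75 - q25),
        sign=sign,
    )


def analyze_rotation(pairs: MatchedPairs, config: RotationConfig | None = None,
                     plane: SeparatingPlane | None = None,
                     ) -> tuple[SeparatingPlane, RotationField, RotationSummary]:
    """Plane → field → center → angles on superposed matched pairs.

    ``plane`` overrides the fitted separating plane; the chord relation is
    exact only when the true rotation axis is normal to the analysis plane,
    so callers with an externally known axis can supply it.
    """
    config = config or RotationConfig()
    if plane is None:
        plane = fit_separating_plane(pairs.pos_a[pairs.mask("reference")],
                                     pairs.pos_a[pairs.mask("mobile")], config)
    fld = build_rotation_field(pairs, plane, config)
    center = fit_rotation_center(fld, config)
    return plane, fld, summarize_rotation(fld, center, config)
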