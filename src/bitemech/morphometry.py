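"""Fibre morphometry by rank matching on segmented CT data.

Mandible closer muscle fibres originate on the head capsule and run as
approximately straight lines to the central apodeme, either inserting
directly or via thin cuticular filaments.  Given the fibre origin points
("seeds"), a point cloud on the apodeme surface, and (optionally) a binary
muscle-tissue mask, the algorithm

1. pairs each seed with an apodeme surface point of the same relative
   anterior-posterior rank (fibres rarely cross, and attachment density on
   the apodeme is roughly uniform), choosing within a rank bin the surface
   point nearest in Euclidean distance;
2. measures the filament length by marching from the insertion point along
   the fibre direction until the ray has crossed a cumulative
   ``threshold_px`` muscle voxels (approximately one fibre diameter): the
   filament length is the arc length at the *first* muscle voxel of that
   run, the threshold acting as confirmation of genuine muscle entry
   (cumulative rather than consecutive counting; configurable);
3. classifies fibres with filament length below ``threshold_px`` voxels as
   directly attached (their fibre length is the full seed-insertion
   distance), computes fibre length and pennation angle for the rest, and
   excludes fibres shorter than twice the fibre diameter.

Coordinates are 0-based voxel units; physical positions are
``(index + 0.5) * voxel_size`` (voxel-centre convention).  Masks are
indexed ``[z, y, x]`` as read from a one-page-per-slice TIFF stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FibreField",
    "FibreRecord",
    "rank_match",
    "grow_filament",
    "classify_and_measure",
    "measure_fibres",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FibreField:
    """Inputs of the rank-matching morphometry for one muscle.

    ``seeds`` and ``apodeme_surface`` are (n, 3) arrays in voxel units
    (x, y, z); ``voxel_size`` is mm per voxel.  ``muscle_mask`` is an
    optional boolean raster indexed [z, y, x]; non-binary masks should be
    thresholded upstream (the loader warns and thresholds at > 0).
    ``anterior_axis`` is the unit anterior-posterior direction in the
    field's frame used for rank sorting.
    """

    seeds: np.ndarray
    apodeme_surface: np.ndarray
    apodeme_axis: np.ndarray
    voxel_size: float
    muscle_mask: np.ndarray | None = None
    fibre_diameter_px: float = 5.0
    anterior_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        seeds = np.atleast_2d(np.asarray(self.seeds, dtype=float))
        surf = np.atleast_2d(np.asarray(self.apodeme_surface, dtype=float))
        if seeds.size == 0 or surf.size == 0:
            raise ValueError("seeds and apodeme_surface must be non-empty")
        if seeds.shape[1] != 3 or surf.shape[1] != 3:
            raise ValueError("point sets must be (n, 3) arrays")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        ax = np.asarray(self.apodeme_axis, dtype=float)
        ant = np.asarray(self.anterior_axis, dtype=float)
        for v, name in ((ax, "apodeme_axis"), (ant, "anterior_axis")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a unit vector")
        object.__setattr__(self, "seeds", seeds)
        object.__setattr__(self, "apodeme_surface", surf)
        object.__setattr__(self, "apodeme_axis", ax)
        object.__setattr__(self, "anterior_axis", ant)
        if self.muscle_mask is not None:
            mask = np.asarray(self.muscle_mask)
            if mask.dtype != bool:
                log.warning("non-binary muscle mask thresholded at > 0")
                mask = mask > 0
            object.__setattr__(self, "muscle_mask", mask)
            # [z, y, x] extents must cover all points (x, y, z)
            extents = np.array(mask.shape[::-1], dtype=float)
            pts = np.vstack([seeds, surf])
            if np.any(pts < -0.5) or np.any(pts + 0.5 > extents):
                raise ValueError("mask does not cover all seed/surface points")


@dataclass(frozen=True)
class FibreRecord:
    """Per-fibre morphometry output (lengths in mm, pennation in degrees)."""

    seed: np.ndarray
    insertion: np.ndarray
    total_length: float
    filament_length: float
    fibre_length: float
    pennation: float
    attachment: Literal["direct", "filament"]
    excluded: bool = False
    reason: str = ""
    filament_reliable: bool = True


def _ap_rank_order(points: np.ndarray, anterior_axis: np.ndarray,
                   secondary_axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Sort order along the anterior-posterior axis; ties broken dorso-ventrally."""
    primary = points @ anterior_axis
    secondary = points @ np.asarray(secondary_axis, dtype=float)
    return np.lexsort((secondary, primary))


def rank_match(field: FibreField) -> list[tuple[int, int]]:
    """Pair each fibre seed with an apodeme surface point by relative rank.

    Seeds and surface points are sorted by anterior-posterior position;
    surface rank ``j`` (of ``N_a``) is assigned to the seed-rank bin
    ``floor(j * N_s / N_a)``, and the seed of rank ``i`` picks, from bin
    ``i``, the surface point nearest in Euclidean distance (preventing
    fibres from crossing the apodeme).  An empty bin falls back to the
    nearest non-empty bin (logged).  Returns (seed_index, surface_index)
    pairs in the original array order.

    The pairing is a bijection onto its image whenever surface points are
    at least as numerous as seeds; otherwise shared insertions are logged.
    """
    seeds, surf = field.seeds, field.apodeme_surface
    n_s, n_a = len(seeds), len(surf)
    seed_order = _ap_rank_order(seeds, field.anterior_axis)
    surf_order = _ap_rank_order(surf, field.anterior_axis)

    bins: list[list[int]] = [[] for _ in range(n_s)]
    for j, surf_idx in enumerate(surf_order):
        b = min(int(j * n_s / n_a), n_s - 1)
        bins[b].append(surf_idx)

    pairs: list[tuple[int, int]] = []
    for i, seed_idx in enumerate(seed_order):
        candidates = bins[i]
        if not candidates:
            # nearest non-empty bin in rank distance
            offsets = sorted(range(n_s), key=lambda b: abs(b - i))
            for b in offsets:
                if bins[b]:
                    candidates = bins[b]
                    log.info("empty rank bin %d: fell back to bin %d", i, b)
                    break
        d = np.linalg.norm(surf[candidates] - seeds[seed_idx], axis=1)
        pairs.append((int(seed_idx), int(candidates[int(np.argmin(d))])))

    used = [s for _, s in pairs]
    if n_a >= n_s and len(set(used)) < len(used):
        log.info("surface points shared between seeds despite n_a >= n_s")
    elif n_a < n_s:
        log.info(
            "fewer surface points (%d) than seeds (%d): insertions shared "
            "with multiplicity", n_a, n_s,
        )
    pairs.sort()
    return pairs


def _voxel_of(point: np.ndarray) -> tuple[int, int, int]:
    # point (x, y, z) in voxel-centre coordinates -> integer voxel index;
    # the 1e-9 snap makes points sitting on a voxel boundary (within float
    # rounding) resolve consistently regardless of how they were computed
    ix, iy, iz = np.floor(point + 0.5 + 1e-9).astype(int)
    return int(iz), int(iy), int(ix)


def grow_filament(
    insertion,
    direction,
    mask: np.ndarray,
    threshold_px: float = 5.0,
    voxel_size: float = 1.0,
    step: float = 0.5,
    max_steps: int = 100_000,
):
    """Filament length (mm) by ray marching from the insertion point.

    The ray starts at ``insertion`` (voxel units) and advances in
    ``step``-voxel increments along the unit ``direction`` (pointing from
    insertion towards the seed).  Each newly entered voxel that is
    muscle-labelled increments a cumulative counter; once the counter
    reaches ``threshold_px`` the growth terminates and the arc length at
    the *first* muscle voxel encountered is returned as the filament
    length (the threshold confirms genuine muscle entry rather than a
    stray labelled voxel).

    Returns ``(length_mm, reliable)``; if the ray exits the mask before
    the threshold is reached, ``(nan, False)`` is returned and the caller
    should substitute the full seed-insertion distance.
    """
    p = np.asarray(insertion, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    nz, ny, nx = mask.shape
    count = 0
    first_muscle_arc = np.nan
    visited: set[tuple[int, int, int]] = set()
    for k in range(max_steps):
        arc = k * step
        pos = p + arc * d
        vz, vy, vx = _voxel_of(pos)
        if not (0 <= vz < nz and 0 <= vy < ny and 0 <= vx < nx):
            return np.nan, False
        vox = (vz, vy, vx)
        if vox not in visited:
            visited.add(vox)
            if mask[vox]:
                if count == 0:
                    first_muscle_arc = arc
                count += 1
                if count >= threshold_px:
                    return first_muscle_arc * voxel_size, True
    return np.nan, False


def classify_and_measure(
    pairs: list[tuple[int, int]],
    filaments: list[tuple[float, bool]],
    field: FibreField,
) -> list[FibreRecord]:
    """Assemble per-fibre records from pairings and filament lengths.

    ``filaments`` holds one ``(length_mm, reliable)`` tuple per pair (use
    ``(0.0, True)`` throughout when no mask is available and all fibres
    are to be treated as directly attached, or the precomputed outputs of
    :func:`grow_filament`).  Attachment is classified by the
    ``threshold_px``-voxel rule; fibre length is total length minus
    filament length; pennation is the angle between the seed-insertion
    line and the apodeme main axis, folded into [0, 90] degrees.  Records
    with fibre length below twice the fibre diameter are flagged excluded.
    """
    if len(filaments) != len(pairs):
        raise ValueError("one filament length per pair is required")
    vox = field.voxel_size
    direct_cut = field.fibre_diameter_px * vox  # threshold_px == fibre diameter
    exclusion_cut = 2.0 * field.fibre_diameter_px * vox
    records = []
    for (si, ai), (l_fil, reliable) in zip(pairs, filaments):
        seed = field.seeds[si]
        ins = field.apodeme_surface[ai]
        conn = seed - ins
        l_t = float(np.linalg.norm(conn) * vox)
        if not reliable or np.isnan(l_fil):
            # ray left the mask before confirming muscle: fall back to the
            # full connection length, flagged unreliable
            l_fil, reliable = l_t, False
        cosang = abs(float(conn @ field.apodeme_axis)) / max(
            np.linalg.norm(conn), 1e-12
        )
        pennation = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
        if l_fil < direct_cut:
            attachment, l_fil_out, l_f = "direct", 0.0, l_t
        else:
            attachment, l_fil_out = "filament", float(min(l_fil, l_t))
            l_f = l_t - l_fil_out
        excluded, reason = False, ""
        if l_f < exclusion_cut:
            excluded = True
            reason = (
                f"fibre length {l_f:.3g} mm < 2 x fibre diameter "
                f"({exclusion_cut:.3g} mm)"
            )
        records.append(
            FibreRecord(
                seed=seed,
                insertion=ins,
                total_length=l_t,
                filament_length=l_fil_out,
                fibre_length=l_f,
                pennation=pennation,
                attachment=attachment,
                excluded=excluded,
                reason=reason,
                filament_reliable=reliable,
            )
        )
    return records


def measure_fibres(field: FibreField) -> list[FibreRecord]:
    """End-to-end morphometry: rank-match, grow filaments, classify."""
    pairs = rank_match(field)
    filaments = []
    for si, ai in pairs:
        if field.muscle_mask is None:
            filaments.append((0.0, True))
            continue
        direction = field.seeds[si] - field.apodeme_surface[ai]
        filaments.append(
            grow_filament(
                field.apodeme_surface[ai],
                direction,
                field.muscle_mask,
                threshold_px=field.fibre_diameter_px,
                voxel_size=field.voxel_size,
            )
        )
    return classify_and_measure(pairs, filaments, field)
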