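"""Scoring of reconstructed spectra against reference libraries.

Reconstructed (pseudo-individual) spectra are aligned to the reference
spectrum of the same compound at the same collision energy within a 3 mDa
mass-error window, recalibrated against the reference's theoretical m/z,
and scored with three intensity-weighted metrics:

* similarity — cosine of the two intensity vectors on a merged m/z axis
  (0.2 mDa matching window);
* precision — fraction of reconstructed intensity that matches the
  reference (penalises wrongly assigned peaks only; unaffected by peaks
  missing from the reconstruction);
* recall — fraction of reference intensity recovered in the reconstruction
  (penalises missing peaks only; unaffected by wrong extra peaks).

Also here: NCE50 (collision energy at which the precursor ion carries half
of the total MS2 intensity) and the scan-distance between two modulated
intensity profiles at the half-maximum level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .deconvolve import IntensityMatrix
from .spectra import Peak, ReconstructedSpectrum, ReferenceSpectrum

__all__ = [
    "AlignedPair",
    "EvalResult",
    "ModulationProfile",
    "align",
    "recalibrate",
    "similarity",
    "precision",
    "recall",
    "evaluate_pair",
    "nce50",
    "profile_distance",
    "assignment_accuracy",
    "DEFAULT_ALIGN_TOL",
    "DEFAULT_SIM_TOL",
]

logger = logging.getLogger(__name__)

#: reference-alignment mass-error window, Th (3 mDa)
DEFAULT_ALIGN_TOL = 0.003
#: similarity m/z matching window, Th (0.2 mDa)
DEFAULT_SIM_TOL = 0.0002


@dataclass(frozen=True)
class AlignedPair:
    """One-to-one matching between a reconstruction and a reference.

    ``matched`` holds (reference peak index, reconstructed peak index)
    pairs; every peak of either spectrum lands in exactly one bucket.
    """

    matched: tuple[tuple[int, int], ...]
    unmatched_ref: tuple[int, ...]
    unmatched_recon: tuple[int, ...]
    tolerance: float


@dataclass(frozen=True)
class EvalResult:
    similarity: float
    precision: float
    recall: float
    n_correct: int
    n_incorrect: int
    n_missing: int


@dataclass(frozen=True)
class ModulationProfile:
    """Max-normalised intensity of one peak across the scan series."""

    peak_id: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or v.max() <= 0:
            raise ValueError("profile must contain a positive intensity")
        object.__setattr__(self, "values", v / v.max())

    @classmethod
    def from_matrix(cls, m: IntensityMatrix, peak_id: int) -> "ModulationProfile":
        return cls(peak_id=peak_id, values=m.values[peak_id])


def _greedy_match(
    ref_mzs: np.ndarray, recon_mzs: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """One-to-one greedy matching by ascending |Δm/z| within ``tol``."""
    cands = []
    for i, rm in enumerate(ref_mzs):
        for j, qm in enumerate(recon_mzs):
            d = abs(rm - qm)
            if d <= tol:
                cands.append((d, i, j))
    cands.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    return pairs


def align(
    recon: ReconstructedSpectrum,
    ref: ReferenceSpectrum,
    tol: float = DEFAULT_ALIGN_TOL,
) -> AlignedPair:
    """Match reconstructed peaks to reference peaks within ``tol`` (Th).

    Matching is greedy one-to-one by ascending mass error against the
    reference's theoretical m/z values.
    """
    if not recon.peaks or not ref.peaks:
        raise ValueError("both spectra must be nonempty")
    ref_mzs = np.asarray(ref.theoretical_mz, dtype=float)
    rec_mzs = np.array([p.mz for p in recon.peaks])
    pairs = _greedy_match(ref_mzs, rec_mzs, tol)
    mi = {i for i, _ in pairs}
    mj = {j for _, j in pairs}
    return AlignedPair(
        matched=tuple(sorted(pairs)),
        unmatched_ref=tuple(i for i in range(len(ref.peaks)) if i not in mi),
        unmatched_recon=tuple(j for j in range(len(recon.peaks)) if j not in mj),
        tolerance=tol,
    )


def recalibrate(
    recon: ReconstructedSpectrum, aligned: AlignedPair, ref: ReferenceSpectrum
) -> ReconstructedSpectrum:
    """Recalibrate reconstructed m/z against the reference's theoretical m/z.

    The median relative (ppm) offset of all matched pairs is removed from
    every peak of the reconstruction.
    """
    if not aligned.matched:
        raise ValueError("recalibration needs at least one matched pair")
    offsets = [
        (recon.peaks[j].mz - ref.theoretical_mz[i]) / ref.theoretical_mz[i]
        for i, j in aligned.matched
    ]
    shift = float(np.median(offsets))
    new_peaks = tuple(
        Peak(p.mz / (1.0 + shift), p.intensity) for p in recon.peaks
    )
    return ReconstructedSpectrum(
        precursor_id=recon.precursor_id,
        peaks=new_peaks,
        precursor_mz=recon.precursor_mz / (1.0 + shift),
        recalibrated=True,
        is_substitute=recon.is_substitute,
        nce=recon.nce,
    )


def _cosine_on_merged_axis(
    u_mzs: np.ndarray, u_int: np.ndarray,
    v_mzs: np.ndarray, v_int: np.ndarray,
    tol: float,
) -> float:
    pairs = _greedy_match(u_mzs, v_mzs, tol)
    ui = {i for i, _ in pairs}
    vj = {j for _, j in pairs}
    u_vec = [u_int[i] for i, _ in pairs] + [
        u_int[i] for i in range(len(u_mzs)) if i not in ui
    ] + [0.0] * sum(1 for j in range(len(v_mzs)) if j not in vj)
    v_vec = [v_int[j] for _, j in pairs] + [
        0.0 for i in range(len(u_mzs)) if i not in ui
    ] + [v_int[j] for j in range(len(v_mzs)) if j not in vj]
    u_vec = np.asarray(u_vec)
    v_vec = np.asarray(v_vec)
    nu = np.linalg.norm(u_vec)
    nv = np.linalg.norm(v_vec)
    if nu == 0 or nv == 0:
        logger.warning("zero-norm intensity vector in similarity; score 0")
        return 0.0
    return float(u_vec @ v_vec / (nu * nv))


def similarity(
    u: ReconstructedSpectrum | ReferenceSpectrum,
    v: ReferenceSpectrum | ReconstructedSpectrum,
    tol: float = DEFAULT_SIM_TOL,
) -> float:
    """Cosine similarity of two spectra on a merged m/z axis.

    Peaks are aligned one-to-one within ``tol`` (default 0.2 mDa); an
    unmatched peak contributes zero to the other spectrum's vector. For
    nonnegative intensities the score lies in [0, 1].
    """
    if not u.peaks or not v.peaks:
        raise ValueError("both spectra must be nonempty")
    return _cosine_on_merged_axis(
        np.array([p.mz for p in u.peaks]),
        np.array([p.intensity for p in u.peaks]),
        np.array([p.mz for p in v.peaks]),
        np.array([p.intensity for p in v.peaks]),
        tol,
    )


def precision(
    recon: ReconstructedSpectrum,
    ref: ReferenceSpectrum,
    tol: float = DEFAULT_ALIGN_TOL,
) -> float:
    """Intensity fraction of the reconstruction that is correctly assigned.

    A reconstructed peak is correct when it matches a reference peak within
    ``tol``. Weighted by reconstructed intensities: high even when most
    reference peaks are missing; decreased only by wrongly assigned peaks.
    """
    if not recon.peaks:
        raise ValueError("reconstructed spectrum is empty")
    a = align(recon, ref, tol)
    total = sum(p.intensity for p in recon.peaks)
    if total == 0:
        return 0.0
    correct = sum(recon.peaks[j].intensity for _, j in a.matched)
    return correct / total


def recall(
    recon: ReconstructedSpectrum,
    ref: ReferenceSpectrum,
    tol: float = DEFAULT_ALIGN_TOL,
) -> float:
    """Intensity fraction of the reference recovered in the reconstruction.

    Weighted by reference intensities: wrong extra peaks in the
    reconstruction do not lower it; only reference peaks absent from the
    reconstruction do.
    """
    if not ref.peaks:
        raise ValueError("reference spectrum is empty")
    a = align(recon, ref, tol)
    total = sum(p.intensity for p in ref.peaks)
    if total == 0:
        return 0.0
    found = sum(ref.peaks[i].intensity for i, _ in a.matched)
    return found / total


def evaluate_pair(
    recon: ReconstructedSpectrum,
    ref: ReferenceSpectrum,
    align_tol: float = DEFAULT_ALIGN_TOL,
    sim_tol: float = DEFAULT_SIM_TOL,
    do_recalibrate: bool = True,
) -> EvalResult:
    """Align, optionally recalibrate, and score one compound.

    Similarity is computed on the recalibrated spectrum (matching the
    processing order of the method); precision and recall use the 3 mDa
    alignment window.
    """
    a = align(recon, ref, align_tol)
    scored = recon
    if do_recalibrate and a.matched:
        scored = recalibrate(recon, a, ref)
    return EvalResult(
        similarity=similarity(scored, ref, sim_tol),
        precision=precision(recon, ref, align_tol),
        recall=recall(recon, ref, align_tol),
        n_correct=len(a.matched),
        n_incorrect=len(a.unmatched_recon),
        n_missing=len(a.unmatched_ref),
    )


# ---------------------------------------------------------------------------
# Auxiliary statistics
# ---------------------------------------------------------------------------

def nce50(points: list[tuple[float, float]]) -> float:
    """Collision energy at which the precursor carries 50% of MS2 intensity.

    ``points`` are (NCE, precursor intensity fraction) pairs; the first
    downward crossing of 0.5 in ascending-NCE order is linearly
    interpolated. A point exactly at 0.5 returns its NCE.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 (nce, fraction) points")
    pts = sorted(points)
    for nce, frac in pts:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} outside [0, 1]")
    for (n0, f0), (n1, f1) in zip(pts, pts[1:]):
        if f0 == 0.5:
            return float(n0)
        if f0 > 0.5 >= f1:
            return float(n0 + (f0 - 0.5) / (f0 - f1) * (n1 - n0))
    if pts[-1][1] == 0.5:
        return float(pts[-1][0])
    raise ValueError("precursor fraction never crosses 0.5 downward")


def _crossings(values: np.ndarray, level: float, interpolate: bool) -> tuple[float, float]:
    """First (rising) and last (falling) positions where profile reaches level."""
    v = np.asarray(values, dtype=float)
    above = v >= level
    if not above.any():
        raise ValueError(f"profile never reaches level {level}")
    first = int(np.argmax(above))
    last = int(len(v) - 1 - np.argmax(above[::-1]))
    rise: float = float(first)
    fall: float = float(last)
    if first > 0:
        lo, hi = v[first - 1], v[first]
        frac = (level - lo) / (hi - lo) if hi != lo else 1.0
        rise = first - 1 + frac
    if last < len(v) - 1:
        hi, lo = v[last], v[last + 1]
        frac = (hi - level) / (hi - lo) if hi != lo else 0.0
        fall = last + frac
    if not interpolate:
        # nearest scan, half-up (avoids banker's-rounding ties)
        rise = float(np.floor(rise + 0.5))
        fall = float(np.floor(fall + 0.5))
    return rise, fall


def profile_distance(
    a: ModulationProfile,
    b: ModulationProfile,
    level: float = 0.5,
    interpolate: bool = False,
) -> float:
    """Scan-count distance between two modulated intensity profiles.

    Each max-normalised profile crosses ``level`` once on its rising and
    once on its falling flank; the distance is
    |rise_a - rise_b| + |fall_a - fall_b| in scans. Crossings are rounded
    to the nearest scan unless ``interpolate`` is set.
    """
    ra, fa = _crossings(a.values, level, interpolate)
    rb, fb = _crossings(b.values, level, interpolate)
    return float(abs(ra - rb) + abs(fa - fb))


def assignment_accuracy(
    assignments: dict[int, str | None],
    peak_mzs: np.ndarray,
    truth_owner: dict[float, str],
    tol: float = 0.002,
) -> float:
    """Fraction of ground-truth unshared fragments assigned to their owner.

    Peaks without a ground-truth owner within ``tol`` (blank or merged
    artefacts) and shared fragments are excluded from the denominator.
    """
    n_ok = 0
    n_tot = 0
    tmz = np.array(sorted(truth_owner))
    for pid, assigned in assignments.items():
        mz = peak_mzs[pid]
        i = int(np.argmin(np.abs(tmz - mz)))
        if abs(tmz[i] - mz) > tol:
            continue
        owner = truth_owner[float(tmz[i])]
        if owner == "shared":
            continue
        n_tot += 1
        if assigned == owner:
            n_ok += 1
    if n_tot == 0:
        raise ValueError("no ground-truth fragments among the assignments")
    return n_ok / n_tot
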