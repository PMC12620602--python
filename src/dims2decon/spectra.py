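"""Core spectral domain types and peak-list primitives.

All tolerances in this package are absolute m/z tolerances in Thomson (Th),
because the processing parameters of the method are stated in mDa, not ppm.
Every spectrum is assumed centroided; profile-mode data must be centroided
upstream (e.g. with msConvert) and is rejected on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Peak",
    "Ms2Scan",
    "ScanSeries",
    "ReferenceSpectrum",
    "ReconstructedSpectrum",
    "merge_peaklists",
    "base_peak",
    "EmptyPeakListError",
    "REFERENCE_CLEANUP_FRAC",
]

#: Relative-intensity cutoff applied to reference spectra on load: peaks with
#: intensity strictly below this fraction of the base peak are discarded.
REFERENCE_CLEANUP_FRAC = 0.003


class EmptyPeakListError(ValueError):
    """Raised when an operation requires at least one peak."""


class Peak(NamedTuple):
    """A centroided peak: m/z in Th, nonnegative intensity (arbitrary units)."""

    mz: float
    intensity: float


def _validate_peaks(peaks: Sequence[Peak]) -> tuple[Peak, ...]:
    out = tuple(Peak(float(p[0]), float(p[1])) for p in peaks)
    for p in out:
        if p.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {p.mz}")
        if p.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {p.intensity}")
    mzs = [p.mz for p in out]
    if any(b < a for a, b in zip(mzs, mzs[1:])):
        raise ValueError("peaks must be sorted by ascending m/z")
    return out


@dataclass(frozen=True)
class Ms2Scan:
    """One centroided fragmentation spectrum with its isolation-window metadata.

    Parameters
    ----------
    peaks:
        Peaks sorted by ascending m/z.
    isolation_center, isolation_width:
        Centre and full width of the isolation window in Th.
    nce:
        Normalised collision energy (vendor-scaled, unitless %).
    scan_index:
        0-based position of the scan in the acquisition series.
    """

    peaks: tuple[Peak, ...]
    isolation_center: float
    isolation_width: float
    nce: float = 0.0
    scan_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", _validate_peaks(self.peaks))
        if self.isolation_width <= 0:
            raise ValueError("isolation_width must be > 0")
        if self.scan_index < 0:
            raise ValueError("scan_index must be >= 0")

    @property
    def tic(self) -> float:
        """Total ion intensity of the scan."""
        return float(sum(p.intensity for p in self.peaks))

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class ScanSeries:
    """An ordered stepped-isolation-window MS2 scan series.

    Scan indices are strictly increasing and isolation centers strictly
    increase across the series (the window is swept from low to high m/z).
    The ``plan`` attribute, when present, records the acquisition schedule
    the series was recorded (or simulated) with.
    """

    scans: tuple[Ms2Scan, ...]
    plan: "object | None" = None  # ScanPlan; untyped to avoid a module cycle

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans", tuple(self.scans))
        idx = [s.scan_index for s in self.scans]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("scan_index must be strictly increasing")
        centers = [s.isolation_center for s in self.scans]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("isolation_center must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    def __getitem__(self, i):
        return self.scans[i]

    def centers(self) -> np.ndarray:
        return np.array([s.isolation_center for s in self.scans], dtype=float)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """A library fragmentation spectrum of a single pure compound.

    ``theoretical_mz`` carries the formula-derived exact m/z for each peak
    (parallel to ``peaks``); where no annotation exists the observed m/z is
    used in its place. The 0.3% base-peak cleanup rule is applied on load by
    :func:`dims2decon.io.read_reference_library`, so instances built from a
    library file never contain sub-threshold peaks.
    """

    compound_id: str
    precursor_mz_theoretical: float
    peaks: tuple[Peak, ...]
    theoretical_mz: tuple[float, ...] = ()
    nce: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", _validate_peaks(self.peaks))
        if not self.theoretical_mz:
            object.__setattr__(
                self, "theoretical_mz", tuple(p.mz for p in self.peaks)
            )
        if len(self.theoretical_mz) != len(self.peaks):
            raise ValueError("theoretical_mz must parallel peaks")

    def cleaned(self, frac: float = REFERENCE_CLEANUP_FRAC) -> "ReferenceSpectrum":
        """Drop peaks with intensity strictly below ``frac`` of the base peak."""
        if not self.peaks:
            return self
        cut = frac * base_peak(self.peaks).intensity
        kept = [
            (p, t)
            for p, t in zip(self.peaks, self.theoretical_mz)
            if p.intensity >= cut
        ]
        return ReferenceSpectrum(
            compound_id=self.compound_id,
            precursor_mz_theoretical=self.precursor_mz_theoretical,
            peaks=tuple(p for p, _ in kept),
            theoretical_mz=tuple(t for _, t in kept),
            nce=self.nce,
        )


@dataclass(frozen=True)
class ReconstructedSpectrum:
    """A per-precursor pseudo-individual MS2 spectrum after deconvolution.

    ``precursor_id`` labels the precursor (or, when the precursor ion was
    absent and a fragment substituted for it, the substitute's label).
    """

    precursor_id: str
    peaks: tuple[Peak, ...]
    precursor_mz: float = 0.0
    recalibrated: bool = False
    is_substitute: bool = False
    nce: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", _validate_peaks(self.peaks))


# ---------------------------------------------------------------------------
# Peak-list primitives
# ---------------------------------------------------------------------------

_COMBINE = ("mean", "sum", "max")


def base_peak(peaks: Sequence[Peak]) -> Peak:
    """Return the maximal-intensity peak; ties broken by lower m/z.

    Raises
    ------
    EmptyPeakListError
        If ``peaks`` is empty.
    """
    if not peaks:
        raise EmptyPeakListError("base_peak of an empty peak list")
    return max(peaks, key=lambda p: (p.intensity, -p.mz))


def merge_peaklists(
    lists: Iterable[Sequence[Peak]],
    tol: float,
    combine: str = "mean",
) -> tuple[Peak, ...]:
    """Merge several sorted peak lists into one consensus list.

    Peaks closer than ``tol`` (absolute Th) across the pooled input are
    clustered greedily in ascending-m/z order; each cluster becomes one
    consensus peak at the intensity-weighted mean m/z, with intensity
    combined per ``combine`` ({"mean", "sum", "max"}). The output contains
    no two peaks closer than ``tol`` and merging a merged list with itself
    (combine="mean") is a no-op.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if combine not in _COMBINE:
        raise ValueError(f"combine must be one of {_COMBINE}, got {combine!r}")
    pooled = sorted((p for lst in lists for p in lst), key=lambda p: p.mz)
    if not pooled:
        return ()

    clusters: list[list[Peak]] = [[pooled[0]]]
    for p in pooled[1:]:
        cur = clusters[-1]
        # consensus of the open cluster so far (intensity-weighted mean m/z)
        w = sum(q.intensity for q in cur)
        cmz = (
            sum(q.mz * q.intensity for q in cur) / w
            if w > 0
            else sum(q.mz for q in cur) / len(cur)
        )
        if p.mz - cmz <= tol:
            cur.append(p)
        else:
            clusters.append([p])

    out: list[Peak] = []
    for cl in clusters:
        w = sum(q.intensity for q in cl)
        mz = (
            sum(q.mz * q.intensity for q in cl) / w
            if w > 0
            else sum(q.mz for q in cl) / len(cl)
        )
        if combine == "mean":
            inten = w / len(cl)
        elif combine == "sum":
            inten = w
        else:
            inten = max(q.intensity for q in cl)
        out.append(Peak(mz, inten))
    return tuple(out)
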