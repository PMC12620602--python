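"""Correlation-based deconvolution of chimeric stepped-isolation MS2 series.

Processing chain: (1) build a template peak list from the most intense scan
merged with its neighbours, ground-noise filtered and blank-subtracted;
(2) fill a peaks x scans intensity matrix from the template; (3) compute
the all-pairs Pearson correlation of the modulated intensity profiles;
(4) assign every fragment peak to the precursor it correlates with best
(hard assignment). A precursor ion absent from the spectra can be replaced
by its most intense known fragment from a reference spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    Ms2Scan,
    Peak,
    ReconstructedSpectrum,
    ReferenceSpectrum,
    ScanSeries,
    base_peak,
    merge_peaklists,
)

__all__ = [
    "TemplateSpectrum",
    "IntensityMatrix",
    "CorrelationMatrix",
    "PrecursorSet",
    "DeconvolutionResult",
    "DeconvolutionError",
    "build_template",
    "build_intensity_matrix",
    "correlation_matrix",
    "assign_fragments",
    "substitute_precursor",
    "deconvolute",
    "DEFAULT_NOISE_FRAC",
    "DEFAULT_BLANK_FRAC",
    "DEFAULT_N_NEIGHBORS",
    "DEFAULT_MATCH_TOL",
]

logger = logging.getLogger(__name__)

# processing defaults: ground-noise threshold 0.3% of the base peak, blank
# threshold 1% of the blank base peak, template from the seed scan plus 10
# neighbours (5 before, 5 after)
DEFAULT_NOISE_FRAC = 0.003
DEFAULT_BLANK_FRAC = 0.01
DEFAULT_N_NEIGHBORS = 10
#: cross-scan m/z matching tolerance in Th
DEFAULT_MATCH_TOL = 0.002

#: minimum number of scans with nonzero intensity for a defined correlation
MIN_NONZERO_SUPPORT = 3


class DeconvolutionError(RuntimeError):
    """A processing stage could not produce a usable result."""


@dataclass(frozen=True)
class TemplateSpectrum:
    """Blank-subtracted master peak list defining the peak universe.

    Peak IDs are the row indices into the template's peak tuple (and into
    the intensity/correlation matrices built from it).
    """

    peaks: tuple[Peak, ...]
    source_scan_index: int
    noise_floor: float

    def __len__(self) -> int:
        return len(self.peaks)

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    def find_peak(self, mz: float, tol: float) -> int | None:
        """ID of the template peak nearest ``mz`` within ``tol``, or None."""
        mzs = self.mz_array()
        if mzs.size == 0:
            return None
        i = int(np.argmin(np.abs(mzs - mz)))
        return i if abs(mzs[i] - mz) <= tol else None


@dataclass(frozen=True)
class IntensityMatrix:
    """Template peaks x scans intensity matrix.

    ``values[p, s]`` is the summed intensity of the scan-s peaks within the
    matching tolerance of template peak p, 0 when the peak is absent from
    the scan. ``scan_centers`` records each column's isolation center so
    that profile centroids can be expressed on the m/z axis.
    """

    values: np.ndarray
    peak_mzs: np.ndarray
    scan_centers: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.peak_mzs), len(self.scan_centers)):
            raise ValueError("matrix dimensions do not match peak/scan axes")
        if (self.values < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_scans(self) -> int:
        return self.values.shape[1]

    def profile_centroid_mz(self, peak_id: int) -> float:
        """Intensity-weighted mean isolation center of one peak's profile.

        For a symmetric transmission curve this estimates the m/z of the
        precursor whose modulation the peak follows.
        """
        row = self.values[peak_id]
        tot = row.sum()
        if tot <= 0:
            return float("nan")
        return float((row * self.scan_centers).sum() / tot)


@dataclass(frozen=True)
class CorrelationMatrix:
    """All-pairs Pearson correlation of peak intensity profiles.

    Undefined entries (zero-variance profiles or fewer than
    ``MIN_NONZERO_SUPPORT`` nonzero scans) are NaN, never silently 0.
    """

    values: np.ndarray
    peak_mzs: np.ndarray
    profile_centroids: np.ndarray

    def is_defined(self, i: int, j: int) -> bool:
        return not np.isnan(self.values[i, j])


@dataclass(frozen=True)
class PrecursorSet:
    """Template peak IDs acting as precursor anchors for assignment."""

    entries: tuple[tuple[str, int, bool], ...]  # (precursor_id, peak_id, is_substitute)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("precursor set must be nonempty")
        ids = [pid for _, pid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("precursor peak IDs must be distinct")

    @property
    def peak_ids(self) -> tuple[int, ...]:
        return tuple(pid for _, pid, _ in self.entries)


# ---------------------------------------------------------------------------
# Stage 1: template
# ---------------------------------------------------------------------------

def build_template(
    series: ScanSeries,
    blank: tuple[Peak, ...] | list[Peak] = (),
    noise_frac: float = DEFAULT_NOISE_FRAC,
    blank_frac: float = DEFAULT_BLANK_FRAC,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    match_tol: float = DEFAULT_MATCH_TOL,
    seed_mode: str = "tic",
) -> TemplateSpectrum:
    """Build the master peak list from the most intense scan and neighbours.

    The seed scan is the one with maximal total ion intensity (or maximal
    base-peak intensity with ``seed_mode="base_peak"``); it is merged with
    floor(n_neighbors/2) scans before and after (truncated at the series
    boundaries) using mean combination. Each scan is ground-noise filtered
    at ``noise_frac`` of its base peak before merging, the merged template
    again at ``noise_frac`` of the template base peak. Template peaks
    matching (within ``match_tol``) a blank peak whose intensity exceeds
    ``blank_frac`` of the blank base peak are removed.
    """
    if len(series) == 0:
        raise DeconvolutionError("cannot build a template from an empty series")
    if seed_mode not in ("tic", "base_peak"):
        raise ValueError(f"unknown seed_mode {seed_mode!r}")

    def scan_weight(s: Ms2Scan) -> float:
        if not s.peaks:
            return 0.0
        return s.tic if seed_mode == "tic" else base_peak(s.peaks).intensity

    weights = [scan_weight(s) for s in series]
    seed = int(np.argmax(weights))
    before = n_neighbors // 2
    after = n_neighbors - before
    lo = max(0, seed - before)
    hi = min(len(series), seed + after + 1)

    filtered = []
    for s in series.scans[lo:hi]:
        if not s.peaks:
            continue
        cut = noise_frac * base_peak(s.peaks).intensity
        filtered.append([p for p in s.peaks if p.intensity >= cut])
    merged = merge_peaklists(filtered, tol=match_tol, combine="mean")
    if not merged:
        raise DeconvolutionError("template empty after merging")

    floor = noise_frac * base_peak(merged).intensity
    kept = [p for p in merged if p.intensity >= floor]

    if blank:
        blank_base = base_peak(tuple(blank)).intensity
        strong_blank = [b.mz for b in blank if b.intensity > blank_frac * blank_base]
        if strong_blank:
            bmz = np.array(strong_blank)
            kept = [
                p for p in kept if np.abs(bmz - p.mz).min() > match_tol
            ]
    if not kept:
        raise DeconvolutionError("all template peaks were filtered out")
    return TemplateSpectrum(
        peaks=tuple(kept), source_scan_index=seed, noise_floor=floor
    )


# ---------------------------------------------------------------------------
# Stage 2: intensity matrix
# ---------------------------------------------------------------------------

def build_intensity_matrix(
    template: TemplateSpectrum,
    series: ScanSeries,
    match_tol: float = DEFAULT_MATCH_TOL,
) -> IntensityMatrix:
    """Per-scan intensities of every template peak.

    A peak absent from a scan contributes 0 (absence is informative of
    transmission, not missing-at-random).
    """
    tmz = template.mz_array()
    values = np.zeros((len(tmz), len(series)))
    for s, scan in enumerate(series):
        if not scan.peaks:
            continue
        smz = scan.mz_array()
        sint = scan.intensity_array()
        lo = np.searchsorted(smz, tmz - match_tol, side="left")
        hi = np.searchsorted(smz, tmz + match_tol, side="right")
        for p in range(len(tmz)):
            if hi[p] > lo[p]:
                values[p, s] = sint[lo[p]:hi[p]].sum()
    return IntensityMatrix(
        values=values, peak_mzs=tmz, scan_centers=series.centers()
    )


# ---------------------------------------------------------------------------
# Stage 3: correlation matrix
# ---------------------------------------------------------------------------

def correlation_matrix(m: IntensityMatrix) -> CorrelationMatrix:
    """Pearson correlation across scans for every pair of template peaks.

    Rows with zero variance or with fewer than ``MIN_NONZERO_SUPPORT``
    nonzero scans get NaN (undefined) against every other row; the
    diagonal of defined rows is exactly 1.
    """
    if m.n_scans < 3:
        raise DeconvolutionError(
            f"need at least 3 scans for correlation, got {m.n_scans}"
        )
    x = m.values.astype(float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    support = (x > 0).sum(axis=1)
    defined = (norms > 0) & (support >= MIN_NONZERO_SUPPORT)

    vals = np.full((m.n_peaks, m.n_peaks), np.nan)
    if defined.any():
        c = centered[defined]
        nrm = norms[defined]
        block = (c @ c.T) / np.outer(nrm, nrm)
        np.clip(block, -1.0, 1.0, out=block)
        idx = np.where(defined)[0]
        vals[np.ix_(idx, idx)] = block
        vals[idx, idx] = 1.0

    centroids = np.array(
        [m.profile_centroid_mz(i) for i in range(m.n_peaks)]
    )
    return CorrelationMatrix(
        values=vals, peak_mzs=m.peak_mzs.copy(), profile_centroids=centroids
    )


# ---------------------------------------------------------------------------
# Stage 4: assignment
# ---------------------------------------------------------------------------

def assign_fragments(
    corr: CorrelationMatrix,
    precursors: PrecursorSet,
) -> dict[int, str | None]:
    """Assign every non-precursor template peak to one precursor.

    Each fragment goes to the precursor with the highest correlation (hard
    assignment — a shared fragment is given only to its top precursor).
    Undefined correlations are excluded from the argmax; exact ties are
    broken towards the precursor whose anchor-peak m/z is nearest the
    fragment's profile centroid on the m/z axis, and logged. A fragment
    with no defined correlation to any precursor maps to ``None``
    (unassigned pool) and is logged.
    """
    pid_by_peak = {pid: name for name, pid, _ in precursors.entries}
    out: dict[int, str | None] = {}
    for f in range(len(corr.peak_mzs)):
        if f in pid_by_peak:
            continue
        scores = [(corr.values[f, pid], name, pid) for name, pid, _ in precursors.entries]
        defined = [t for t in scores if not np.isnan(t[0])]
        if not defined:
            logger.warning(
                "peak %d (m/z %.4f): correlation undefined for every "
                "precursor; left unassigned", f, corr.peak_mzs[f],
            )
            out[f] = None
            continue
        best = max(s for s, _, _ in defined)
        top = [t for t in defined if t[0] == best]
        if len(top) > 1:
            centroid = corr.profile_centroids[f]
            top.sort(key=lambda t: abs(corr.peak_mzs[t[2]] - centroid))
            logger.info(
                "peak %d (m/z %.4f): correlation tie at %.6f between %s; "
                "broke towards %s (profile centroid %.4f)",
                f, corr.peak_mzs[f], best,
                "/".join(t[1] for t in top), top[0][1], centroid,
            )
        out[f] = top[0][1]
    return out


def substitute_precursor(
    template: TemplateSpectrum,
    reference: ReferenceSpectrum,
    match_tol: float = DEFAULT_MATCH_TOL,
) -> int:
    """Template peak ID of the most intense known fragment of ``reference``.

    Used when a precursor ion is missing from the MS2 spectra (fully
    fragmented, or unresolved at low mass resolution): its most intense
    library fragment present in the template anchors the correlation
    instead. Reference peaks are tried in descending intensity; the
    precursor ion itself is skipped.
    """
    if not reference.peaks:
        raise ValueError("reference spectrum is empty")
    candidates = sorted(
        (
            p
            for p in reference.peaks
            if abs(p.mz - reference.precursor_mz_theoretical) > match_tol
        ),
        key=lambda p: -p.intensity,
    )
    for p in candidates:
        pid = template.find_peak(p.mz, match_tol)
        if pid is not None:
            return pid
    raise DeconvolutionError(
        f"no fragment of {reference.compound_id} found in the template; "
        "precursor cannot be resolved"
    )


# ---------------------------------------------------------------------------
# Stage 5: end-to-end
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeconvolutionResult:
    """Everything the pipeline produced, for inspection and evaluation."""

    spectra: tuple[ReconstructedSpectrum, ...]
    template: TemplateSpectrum
    intensity_matrix: IntensityMatrix
    correlation: CorrelationMatrix
    precursors: PrecursorSet
    assignments: dict[int, str | None]

    @property
    def unassigned_peak_ids(self) -> tuple[int, ...]:
        return tuple(k for k, v in self.assignments.items() if v is None)


def deconvolute(
    series: ScanSeries,
    blank: tuple[Peak, ...] | list[Peak] = (),
    precursor_mzs: dict[str, float] | list[float] | None = None,
    references: dict[str, ReferenceSpectrum] | None = None,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    blank_frac: float = DEFAULT_BLANK_FRAC,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    match_tol: float = DEFAULT_MATCH_TOL,
    seed_mode: str = "tic",
) -> DeconvolutionResult:
    """Reconstruct per-precursor MS2 spectra from a chimeric scan series.

    ``precursor_mzs`` maps labels to expected precursor m/z (a bare list
    gets labels "P1", "P2", ...). A precursor ion missing from the template
    is replaced by its most intense known fragment when a reference
    spectrum for its label is supplied in ``references``; otherwise it is
    an error. Each reconstructed spectrum carries its precursor (or
    substitute) peak plus all fragments assigned to it, with template
    intensities.
    """
    if not precursor_mzs:
        raise ValueError("at least one precursor m/z is required")
    if isinstance(precursor_mzs, (list, tuple)):
        precursor_mzs = {f"P{i + 1}": mz for i, mz in enumerate(precursor_mzs)}

    template = build_template(
        series, blank, noise_frac=noise_frac, blank_frac=blank_frac,
        n_neighbors=n_neighbors, match_tol=match_tol, seed_mode=seed_mode,
    )

    entries = []
    for name, mz in precursor_mzs.items():
        pid = template.find_peak(mz, match_tol)
        is_sub = False
        if pid is None:
            if references and name in references:
                pid = substitute_precursor(template, references[name], match_tol)
                is_sub = True
                logger.info(
                    "precursor %s (m/z %.4f) absent from template; using "
                    "fragment peak %d (m/z %.4f) as substitute",
                    name, mz, pid, template.peaks[pid].mz,
                )
            else:
                raise DeconvolutionError(
                    f"precursor {name} (m/z {mz:.4f}) not found in template "
                    "and no reference spectrum available for substitution"
                )
        entries.append((name, pid, is_sub))
    pset = PrecursorSet(entries=tuple(entries))

    m = build_intensity_matrix(template, series, match_tol=match_tol)
    corr = correlation_matrix(m)
    assignments = assign_fragments(corr, pset)

    nce = series.scans[0].nce if series.scans else 0.0
    spectra = []
    for name, pid, is_sub in pset.entries:
        ids = [pid] + [f for f, owner in assignments.items() if owner == name]
        ids.sort(key=lambda i: template.peaks[i].mz)
        spectra.append(
            ReconstructedSpectrum(
                precursor_id=name,
                peaks=tuple(template.peaks[i] for i in ids),
                precursor_mz=template.peaks[pid].mz,
                is_substitute=is_sub,
                nce=nce,
            )
        )
    return DeconvolutionResult(
        spectra=tuple(spectra),
        template=template,
        intensity_matrix=m,
        correlation=corr,
        precursors=pset,
        assignments=assignments,
    )
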