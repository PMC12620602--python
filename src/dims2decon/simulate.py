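"""Synthetic stepped-isolation DI-MS2 scan series with known ground truth.

The simulator emulates the phenomenology that makes correlation-based
deconvolution possible: as the isolation window steps from low to high m/z,
each co-isolated precursor is transmitted with an efficiency that depends on
its position inside the window, so its precursor ion and all of its
fragments share one modulated intensity profile. Two isobars a few mTh
apart therefore produce profiles that are translated (quadrupole-like
behaviour, ``shifted_bandpass``) or differently widened (ion-trap-like
behaviour, ``widened_bandpass``) relative to each other.

Also modelled: fragments shared between precursors, contamination by the
first carbon isotopologue (which enters the window near the end of the
sweep and produces the same fragments), multiplicative lognormal intensity
noise, a detection floor below which peaks are missing from a scan, and
constant solvent/blank background peaks.

The transmission curve is a trapezoid — flat top over the central half of
the window, linear edges — the simplest shape with imperfect band-pass
edges; a Gaussian alternative is available via ``model="gaussian"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plan import ScanPlan, build_plan
from .spectra import Ms2Scan, Peak, ReferenceSpectrum, ScanSeries

__all__ = [
    "PrecursorModel",
    "SimConfig",
    "GroundTruth",
    "transmission",
    "simulate_series",
    "two_isobar_preset",
    "reference_spectra",
    "ISOTOPOLOGUE_OFFSET",
]

#: 13C-12C spacing in Th (singly charged).
ISOTOPOLOGUE_OFFSET = 1.00336

_MODELS = ("shifted_bandpass", "widened_bandpass", "gaussian")


def transmission(
    mz: float,
    center: float,
    width: float,
    model: str = "shifted_bandpass",
    width_scale: float | tuple[float, float] = 1.0,
) -> float:
    """Transmission efficiency in [0, 1] of an ion through the window.

    ``shifted_bandpass`` / ``widened_bandpass``: trapezoid with efficiency 1
    for |mz - center| <= 0.25*width, falling linearly to 0 at
    0.5*width*width_scale. ``width_scale`` may be a (left, right) pair for
    an asymmetric stretch; ``widened_bandpass`` is the same shape used with
    width_scale > 1 (the profile support widens on both flanks).
    ``gaussian``: exp(-d^2 / (2 sigma^2)) with sigma = width*width_scale/4.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if model not in _MODELS:
        raise ValueError(f"unknown transmission model {model!r}")
    d = mz - center
    if isinstance(width_scale, tuple):
        ws = width_scale[0] if d < 0 else width_scale[1]
    else:
        ws = float(width_scale)
    if ws <= 0:
        raise ValueError("width_scale must be > 0")

    if model == "gaussian":
        sigma = width * ws / 4.0
        return math.exp(-0.5 * (d / sigma) ** 2)

    flat = 0.25 * width
    edge = 0.5 * width * ws
    ad = abs(d)
    if ad <= flat:
        return 1.0
    if ad >= edge:
        return 0.0
    return (edge - ad) / (edge - flat)


@dataclass(frozen=True)
class PrecursorModel:
    """One co-isolated precursor and its fragmentation pattern.

    ``fragments`` is a list of (fragment m/z, branching fraction); branching
    fractions sum to at most 1, the remainder staying on the surviving
    precursor ion. ``profile_width_scale`` > 1 widens the modulation profile
    (the ion-trap 'appeared first, disappeared last' pattern).
    """

    precursor_id: str
    mz: float
    base_intensity: float
    fragments: tuple[tuple[float, float], ...]
    profile_model: str = "shifted_bandpass"
    profile_width_scale: float | tuple[float, float] = 1.0

    def __post_init__(self) -> None:
        s = sum(bf for _, bf in self.fragments)
        if s > 1.0 + 1e-12:
            raise ValueError(f"branching fractions sum to {s} > 1")
        for fmz, bf in self.fragments:
            if fmz >= self.mz:
                raise ValueError("fragment m/z must be below precursor m/z")
            if bf < 0:
                raise ValueError("branching fraction must be >= 0")

    @property
    def survival_fraction(self) -> float:
        return 1.0 - sum(bf for _, bf in self.fragments)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated measurement cycle."""

    plan: ScanPlan
    precursors: tuple[PrecursorModel, ...]
    isotopologue_offset: float = ISOTOPOLOGUE_OFFSET
    isotopologue_rel_abundance: float = 0.19
    noise_sd_rel: float = 0.0
    noise_floor_rel: float = 1e-4
    blank_peaks: tuple[Peak, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0 or self.noise_floor_rel < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.isotopologue_rel_abundance < 0:
            raise ValueError("isotopologue abundance must be >= 0")

    @property
    def shared_fragment_mzs(self) -> tuple[float, ...]:
        """Fragment m/z values produced by two or more precursors."""
        seen: dict[float, int] = {}
        for p in self.precursors:
            for fmz, _ in p.fragments:
                seen[fmz] = seen.get(fmz, 0) + 1
        return tuple(sorted(mz for mz, n in seen.items() if n > 1))


@dataclass(frozen=True)
class GroundTruth:
    """Known provenance of every simulated (non-blank) peak.

    ``owner`` maps each simulated m/z to the precursor_id that produced it,
    or ``"shared"`` for fragments produced by more than one precursor.
    ``noiseless`` holds the per-scan noise-free intensity of each m/z;
    ``per_precursor`` the per-scan total contribution (precursor ion plus
    fragments, isotopologues excluded) of each precursor; and
    ``transmission_profiles`` each precursor's raw transmission efficiency
    per scan.
    """

    owner: dict[float, str]
    noiseless: dict[float, np.ndarray]
    per_precursor: dict[str, np.ndarray]
    transmission_profiles: dict[str, np.ndarray]
    precursor_mzs: dict[str, float]

    def owner_of(self, mz: float, tol: float = 1e-6) -> str | None:
        for k, v in self.owner.items():
            if abs(k - mz) <= tol:
                return v
        return None


def simulate_series(config: SimConfig) -> tuple[ScanSeries, GroundTruth]:
    """Run one measurement cycle of ``config.plan`` and return the scans.

    For every isolation center, each precursor contributes
    ``base_intensity * transmission`` split between its surviving precursor
    ion and its fragments according to the branching fractions; its first
    isotopologue (at ``isotopologue_offset``) contributes the same fragment
    pattern scaled by ``isotopologue_rel_abundance``. Shared fragments
    accumulate contributions from every producer. Multiplicative lognormal
    noise is then applied, peaks below the detection floor
    (``noise_floor_rel`` of the global noiseless maximum) are dropped, and
    blank peaks are added at constant intensity. All randomness derives
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    plan = config.plan
    cs = plan.centers()
    n = len(cs)

    # --- noiseless contributions ------------------------------------------
    noiseless: dict[float, np.ndarray] = {}
    per_precursor: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    owner: dict[float, str] = {}

    def _add(mz: float, s: int, val: float) -> None:
        arr = noiseless.setdefault(mz, np.zeros(n))
        arr[s] += val

    shared = set(config.shared_fragment_mzs)
    for p in config.precursors:
        eff = np.array(
            [
                transmission(
                    p.mz, c, plan.isolation_width, p.profile_model,
                    p.profile_width_scale,
                )
                for c in cs
            ]
        )
        iso_mz = p.mz + config.isotopologue_offset
        eff_iso = np.array(
            [
                transmission(
                    iso_mz, c, plan.isolation_width, p.profile_model,
                    p.profile_width_scale,
                )
                for c in cs
            ]
        )
        profiles[p.precursor_id] = eff
        per_precursor[p.precursor_id] = p.base_intensity * eff
        ab = config.isotopologue_rel_abundance
        rem = p.survival_fraction
        for s in range(n):
            _add(p.mz, s, p.base_intensity * eff[s] * rem)
            for fmz, bf in p.fragments:
                _add(fmz, s, p.base_intensity * eff[s] * bf)
            if ab > 0:
                _add(iso_mz, s, p.base_intensity * ab * eff_iso[s] * rem)
                for fmz, bf in p.fragments:
                    _add(fmz, s, p.base_intensity * ab * eff_iso[s] * bf)
        owner[p.mz] = p.precursor_id
        if ab > 0:
            owner[iso_mz] = p.precursor_id
        for fmz, _ in p.fragments:
            owner[fmz] = "shared" if fmz in shared else p.precursor_id

    truth = GroundTruth(
        owner=owner,
        noiseless={k: v.copy() for k, v in noiseless.items()},
        per_precursor=per_precursor,
        transmission_profiles=profiles,
        precursor_mzs={p.precursor_id: p.mz for p in config.precursors},
    )

    # --- noise, detection floor, blank ------------------------------------
    global_max = max((v.max() for v in noiseless.values()), default=0.0)
    floor = config.noise_floor_rel * global_max
    mzs = sorted(noiseless)
    scans = []
    for s in range(n):
        peaks = []
        for mz in mzs:
            val = noiseless[mz][s]
            if val <= 0:
                continue
            if config.noise_sd_rel > 0:
                val *= math.exp(rng.normal(0.0, config.noise_sd_rel))
            if val < floor:
                continue
            peaks.append(Peak(mz, val))
        for bp in config.blank_peaks:
            peaks.append(bp)
        peaks.sort(key=lambda q: q.mz)
        scans.append(
            Ms2Scan(
                peaks=tuple(peaks),
                isolation_center=float(cs[s]),
                isolation_width=plan.isolation_width,
                nce=plan.nce,
                scan_index=s,
            )
        )
    return ScanSeries(scans=tuple(scans), plan=plan), truth


# ---------------------------------------------------------------------------
# Ready-made two-isobar mixtures
# ---------------------------------------------------------------------------

# fragment patterns loosely shaped after small aromatic metabolites around
# nominal mass 342; branching fractions leave 30-35% on the precursor ion
_FRAGS_A = ((84.0444, 0.25), (121.0648, 0.20), (158.0812, 0.15), (212.1040, 0.10))
_FRAGS_B = ((95.0491, 0.25), (139.0542, 0.20), (185.0866, 0.12), (241.1190, 0.08))
_SHARED_FRAG_MZ = 163.0754
_BLANK = (Peak(149.0233, 5.0e4), Peak(279.1591, 1.0e4))


def two_isobar_preset(
    delta_mz: float,
    intensity_ratio: float = 1.0,
    model_pair: tuple[str, str] = ("shifted_bandpass", "shifted_bandpass"),
    nominal_mass: float = 342.0,
    base_intensity: float = 1.0e6,
    n_shared: int = 1,
    width_scales: tuple[float, float] = (1.0, 1.0),
    noise_sd_rel: float = 0.0,
    seed: int = 0,
    plan: ScanPlan | None = None,
) -> SimConfig:
    """A ready config mimicking one of the study's isobaric mixtures.

    Two precursors at ``nominal_mass -/+ delta_mz/2`` with
    ``base_intensity * intensity_ratio`` and ``base_intensity`` respectively
    (``intensity_ratio`` 20 reproduces the ~20:1 precursor imbalance of the
    hardest mixture), four unshared fragments each plus ``n_shared`` common
    fragments, and the default 81-event acquisition plan unless ``plan``
    is given. Δm/z of 0.006-0.048 spans the mixtures studied.
    """
    if delta_mz <= 0:
        raise ValueError("delta_mz must be > 0")
    if plan is None:
        plan = build_plan(nominal_mass)
    shared = tuple((_SHARED_FRAG_MZ + 2.0 * k, 0.10) for k in range(n_shared))
    pa = PrecursorModel(
        precursor_id="P1",
        mz=nominal_mass - delta_mz / 2.0,
        base_intensity=base_intensity * intensity_ratio,
        fragments=_FRAGS_A + shared,
        profile_model=model_pair[0],
        profile_width_scale=width_scales[0],
    )
    pb = PrecursorModel(
        precursor_id="P2",
        mz=nominal_mass + delta_mz / 2.0,
        base_intensity=base_intensity,
        fragments=_FRAGS_B + shared,
        profile_model=model_pair[1],
        profile_width_scale=width_scales[1],
    )
    return SimConfig(
        plan=plan,
        precursors=(pa, pb),
        noise_sd_rel=noise_sd_rel,
        blank_peaks=_BLANK,
        seed=seed,
    )


def reference_spectra(config: SimConfig) -> list[ReferenceSpectrum]:
    """Ideal per-precursor reference spectra implied by ``config``.

    Each precursor's reference holds its surviving precursor ion and all of
    its fragments at the branching-fraction intensities — the spectrum a
    clean single-compound measurement would give at full transmission.
    """
    out = []
    for p in config.precursors:
        entries = [(p.mz, p.base_intensity * p.survival_fraction)] + [
            (fmz, p.base_intensity * bf) for fmz, bf in p.fragments
        ]
        entries.sort()
        out.append(
            ReferenceSpectrum(
                compound_id=p.precursor_id,
                precursor_mz_theoretical=p.mz,
                peaks=tuple(Peak(mz, i) for mz, i in entries if i > 0),
                nce=config.plan.nce,
            )
        )
    return out
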