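"""Reading and writing the formats the pipeline touches.

Scan series come in as centroided mzML (read with pyteomics) or as a plain
TSV scan table for desk-scale fixtures; spectral libraries move as MGF
(pyteomics) or MSP (matchms). The simulator's mzML output is written with a
minimal built-in mzML 1.1.0 serializer (64-bit float, uncompressed,
base64-encoded arrays) that round-trips through the pyteomics reader.

MSP entries carry theoretical m/z annotations in the ``Comment:`` field as
space-separated ``mz|annotation`` pairs, where the annotation is either a
theoretical m/z (float) or a molecular formula of the ion (its monoisotopic
mass, minus one electron for positive ions, is then used). MGF entries use
an equivalent ``ANNOTATIONS=`` parameter.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matchms import Spectrum as MatchmsSpectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_msp
from pyteomics import mgf as pyt_mgf
from pyteomics import mass as pyt_mass

from .spectra import (
    Ms2Scan,
    Peak,
    ReconstructedSpectrum,
    ReferenceSpectrum,
    ScanSeries,
    REFERENCE_CLEANUP_FRAC,
)

__all__ = [
    "RunMetadata",
    "read_scan_series",
    "write_scan_series_mzml",
    "read_scan_series_tsv",
    "write_scan_series_tsv",
    "write_spectrum_library",
    "read_reference_library",
    "FormatError",
]

logger = logging.getLogger(__name__)

_ELECTRON_MASS = 0.000548579909

_DIALECTS = ("MGF", "MSP")


class FormatError(ValueError):
    """Malformed or unsupported file content."""


@dataclass(frozen=True)
class RunMetadata:
    """Provenance of one acquisition run."""

    source_file: str
    instrument_label: str = ""
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    """Element tag without its XML namespace."""
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem: ET.Element) -> dict[str, str]:
    """accession -> value for the direct cvParam children of ``elem``."""
    return {
        c.get("accession", ""): c.get("value", "")
        for c in elem
        if _local(c.tag) == "cvParam"
    }


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    params = _cv_params(bda)
    text = ""
    for c in bda.iter():
        if _local(c.tag) == "binary":
            text = c.text or ""
            break
    raw = base64.b64decode(text)
    if "MS:1000574" in params:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_scan_series(path: str | Path) -> ScanSeries:
    """Read a centroided MS2 scan series from mzML.

    Scans are ordered by acquisition; isolation center and width come from
    the isolation-window elements and NCE from the activation element.
    Profile spectra and MS2 scans without isolation metadata are errors.

    This is a purpose-built reader for centroided MS2 mzML (64/32-bit
    float, uncompressed or zlib-compressed arrays) as produced by msConvert
    or by :func:`write_scan_series_mzml`; it is namespace-tolerant and
    ignores chromatograms and MS1 content.
    """
    path = Path(path)
    scans = []
    for _, spectrum in ET.iterparse(str(path)):
        if _local(spectrum.tag) != "spectrum":
            continue
        params = _cv_params(spectrum)
        if params.get("MS:1000511") != "2":  # ms level
            spectrum.clear()
            continue
        sid = spectrum.get("id", f"index {spectrum.get('index', '?')}")
        if "MS:1000128" in params:  # profile spectrum
            raise FormatError(
                f"scan {sid!r} is profile mode; centroid upstream (msConvert)"
            )
        center = width = None
        nce = 0.0
        mzs = ints = None
        for elem in spectrum.iter():
            tag = _local(elem.tag)
            if tag == "isolationWindow":
                p = _cv_params(elem)
                try:
                    center = float(p["MS:1000827"])  # target m/z
                    width = float(p["MS:1000828"]) + float(p["MS:1000829"])
                except KeyError:
                    pass
            elif tag == "activation":
                p = _cv_params(elem)
                if "MS:1000045" in p:  # collision energy
                    nce = float(p["MS:1000045"])
            elif tag == "binaryDataArray":
                p = _cv_params(elem)
                if "MS:1000514" in p:  # m/z array
                    mzs = _decode_binary_array(elem)
                elif "MS:1000515" in p:  # intensity array
                    ints = _decode_binary_array(elem)
        if center is None or width is None:
            raise FormatError(f"scan {sid!r} lacks isolation-window metadata")
        if mzs is None or ints is None:
            raise FormatError(f"scan {sid!r} lacks peak data arrays")
        order = np.argsort(mzs, kind="stable")
        peaks = tuple(
            Peak(float(m), float(i)) for m, i in zip(mzs[order], ints[order])
        )
        scans.append(
            Ms2Scan(
                peaks=peaks,
                isolation_center=center,
                isolation_width=width,
                nce=nce,
                scan_index=len(scans),
            )
        )
        spectrum.clear()
    if not scans:
        raise FormatError(f"{path} contains no MS2 scans")
    return ScanSeries(scans=tuple(scans))


def _cv(parent: ET.Element, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value
    )


def write_scan_series_mzml(series: ScanSeries, path: str | Path) -> None:
    """Write a scan series as minimal centroided mzML 1.1.0."""
    ns = "http://psi.hupo.org/ms/mzml"
    root = ET.Element("mzML", xmlns=ns, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, "run", id="simulated")
    slist = ET.SubElement(run, "spectrumList", count=str(len(series)))
    for k, scan in enumerate(series):
        mzs = scan.mz_array()
        ints = scan.intensity_array()
        sp = ET.SubElement(
            slist, "spectrum", index=str(k), id=f"scan={k + 1}",
            defaultArrayLength=str(len(mzs)),
        )
        _cv(sp, "MS:1000511", "ms level", "2")
        _cv(sp, "MS:1000127", "centroid spectrum")
        plist = ET.SubElement(sp, "precursorList", count="1")
        prec = ET.SubElement(plist, "precursor")
        iso = ET.SubElement(prec, "isolationWindow")
        _cv(iso, "MS:1000827", "isolation window target m/z", repr(scan.isolation_center))
        _cv(iso, "MS:1000828", "isolation window lower offset", repr(scan.isolation_width / 2.0))
        _cv(iso, "MS:1000829", "isolation window upper offset", repr(scan.isolation_width / 2.0))
        act = ET.SubElement(prec, "activation")
        _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        _cv(act, "MS:1000045", "collision energy", repr(scan.nce))
        blist = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (mzs, "MS:1000514", "m/z array"),
            (ints, "MS:1000515", "intensity array"),
        ):
            enc = base64.b64encode(
                struct.pack(f"<{len(arr)}d", *arr)
            ).decode("ascii")
            bda = ET.SubElement(blist, "binaryDataArray", encodedLength=str(len(enc)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = enc
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV fixture dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["scan_index", "isolation_center", "isolation_width", "nce", "mz", "intensity"]


def write_scan_series_tsv(series: ScanSeries, path: str | Path) -> None:
    """Write the fixture TSV dialect: one row per peak, columns
    scan_index, isolation_center, isolation_width, nce, mz, intensity."""
    rows = [
        (s.scan_index, s.isolation_center, s.isolation_width, s.nce, p.mz, p.intensity)
        for s in series
        for p in s.peaks
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scan_series_tsv(path: str | Path) -> ScanSeries:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"TSV scan table lacks columns: {sorted(missing)}")
    scans = []
    for idx, grp in df.groupby("scan_index", sort=True):
        grp = grp.sort_values("mz")
        peaks = tuple(Peak(m, i) for m, i in zip(grp["mz"], grp["intensity"]))
        scans.append(
            Ms2Scan(
                peaks=peaks,
                isolation_center=float(grp["isolation_center"].iloc[0]),
                isolation_width=float(grp["isolation_width"].iloc[0]),
                nce=float(grp["nce"].iloc[0]),
                scan_index=int(idx),
            )
        )
    if not scans:
        raise FormatError(f"{path} contains no scans")
    return ScanSeries(scans=tuple(scans))


# ---------------------------------------------------------------------------
# Spectral libraries (MGF / MSP)
# ---------------------------------------------------------------------------

def _spectrum_fields(spec: ReconstructedSpectrum | ReferenceSpectrum):
    if isinstance(spec, ReferenceSpectrum):
        name = spec.compound_id
        pmz = spec.precursor_mz_theoretical
        annotations = " ".join(
            f"{p.mz:.6f}|{t:.6f}" for p, t in zip(spec.peaks, spec.theoretical_mz)
        )
    else:
        name = spec.precursor_id
        pmz = spec.precursor_mz
        annotations = ""
    return name, pmz, spec.nce, annotations


def write_spectrum_library(
    spectra: Sequence[ReconstructedSpectrum | ReferenceSpectrum],
    path: str | Path,
    dialect: str = "MGF",
) -> None:
    """Write spectra as an MGF or MSP library, one entry per spectrum."""
    if not spectra:
        raise ValueError("no spectra to write")
    dialect = dialect.upper()
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown library dialect {dialect!r}")
    for spec in spectra:
        if not spec.peaks:
            logger.warning(
                "spectrum %s has no peaks; writing an empty entry",
                _spectrum_fields(spec)[0],
            )
    if dialect == "MGF":
        entries = []
        for spec in spectra:
            name, pmz, nce, ann = _spectrum_fields(spec)
            params = {"title": name, "pepmass": pmz, "nce": nce}
            if ann:
                params["annotations"] = ann
            entries.append(
                {
                    "m/z array": np.array([p.mz for p in spec.peaks]),
                    "intensity array": np.array([p.intensity for p in spec.peaks]),
                    "params": params,
                }
            )
        pyt_mgf.write(entries, str(path), file_mode="w")
    else:
        ms_spectra = []
        for spec in spectra:
            name, pmz, nce, ann = _spectrum_fields(spec)
            meta = {"compound_name": name, "precursor_mz": pmz, "nce": str(nce)}
            if ann:
                meta["comment"] = ann
            ms_spectra.append(
                MatchmsSpectrum(
                    mz=np.array([p.mz for p in spec.peaks], dtype=float),
                    intensities=np.array([p.intensity for p in spec.peaks], dtype=float),
                    metadata=meta,
                    metadata_harmonization=False,
                )
            )
        save_as_msp(ms_spectra, str(path))


def _theoretical_from_annotation(token: str) -> float:
    """An annotation is either a theoretical m/z or an ion formula."""
    try:
        return float(token)
    except ValueError:
        return float(pyt_mass.calculate_mass(formula=token)) - _ELECTRON_MASS


def _parse_annotations(ann: str, entry_no: int) -> dict[float, float]:
    out = {}
    for pair in ann.split():
        try:
            obs, token = pair.split("|", 1)
            out[float(obs)] = _theoretical_from_annotation(token)
        except Exception as exc:
            raise FormatError(
                f"library entry {entry_no}: bad annotation token {pair!r}"
            ) from exc
    return out


def _build_reference(
    name: str,
    pmz: float,
    nce: float,
    mzs: np.ndarray,
    ints: np.ndarray,
    annotations: str,
    entry_no: int,
) -> ReferenceSpectrum:
    ann = _parse_annotations(annotations, entry_no) if annotations else {}
    order = np.argsort(mzs, kind="stable")
    mzs, ints = mzs[order], ints[order]
    theo = []
    n_missing = 0
    for m in mzs:
        if ann:
            key = min(ann, key=lambda k: abs(k - m), default=None)
            if key is not None and abs(key - m) <= 1e-4:
                theo.append(ann[key])
                continue
        theo.append(float(m))
        n_missing += 1
    if n_missing:
        logger.warning(
            "library entry %d (%s): %d peak(s) without theoretical m/z; "
            "using observed m/z", entry_no, name, n_missing,
        )
    ref = ReferenceSpectrum(
        compound_id=name,
        precursor_mz_theoretical=pmz,
        peaks=tuple(Peak(float(m), float(i)) for m, i in zip(mzs, ints)),
        theoretical_mz=tuple(theo),
        nce=nce,
    )
    return ref.cleaned(REFERENCE_CLEANUP_FRAC)


def read_reference_library(
    path: str | Path, dialect: str | None = None
) -> list[ReferenceSpectrum]:
    """Read an MGF or MSP reference library.

    The 0.3% base-peak cleanup is applied per entry on load (peaks strictly
    below the threshold are discarded; peaks exactly at it are retained).
    ``dialect`` defaults to the file extension.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").upper()
    dialect = dialect.upper()
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown library dialect {dialect!r}")

    out = []
    if dialect == "MGF":
        with pyt_mgf.read(str(path)) as reader:
            for k, entry in enumerate(reader):
                try:
                    params = entry["params"]
                    pep = params.get("pepmass", (0.0,))
                    pmz = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
                    out.append(
                        _build_reference(
                            name=str(params.get("title", f"entry_{k}")),
                            pmz=pmz,
                            nce=float(params.get("nce", 0.0)),
                            mzs=np.asarray(entry["m/z array"], dtype=float),
                            ints=np.asarray(entry["intensity array"], dtype=float),
                            annotations=str(params.get("annotations", "")),
                            entry_no=k,
                        )
                    )
                except FormatError:
                    raise
                except Exception as exc:
                    raise FormatError(f"malformed MGF entry {k}: {exc}") from exc
    else:
        for k, spec in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
            try:
                meta = spec.metadata
                out.append(
                    _build_reference(
                        name=str(meta.get("compound_name", f"entry_{k}")),
                        pmz=float(meta.get("precursor_mz", 0.0)),
                        nce=float(meta.get("nce", 0.0)),
                        mzs=np.asarray(spec.peaks.mz, dtype=float),
                        ints=np.asarray(spec.peaks.intensities, dtype=float),
                        annotations=str(meta.get("comment", "")),
                        entry_no=k,
                    )
                )
            except FormatError:
                raise
            except Exception as exc:
                raise FormatError(f"malformed MSP entry {k}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no library entries found")
    return out
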