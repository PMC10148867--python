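"""MS2 peak-list ingestion (MGF, optional mzML), preprocessing, ppm arithmetic."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mgf as _pmgf

logger = logging.getLogger(__name__)

# TPP-style titles, e.g. "run01.1234.1234.2" or 'File:"x.raw", scan=1234'
_TPP_TITLE = re.compile(r"^(?P<file>.+?)\.(?P<scan>\d+)\.(?P<scan2>\d+)\.(?P<z>\d+)")


@dataclass
class Spectrum:
    """One MS2 scan with parallel, m/z-ascending peak arrays."""

    source: str
    scan: str
    title: str
    precursor_mz: float
    precursor_charge: int
    rt_seconds: float
    mz: np.ndarray
    intensity: np.ndarray
    retained_n: int | None = None  # set by preprocess()

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def precursor_neutral_mass(self) -> float:
        from .constants import PROTON

        return (self.precursor_mz - PROTON) * self.precursor_charge

    def __len__(self) -> int:
        return len(self.mz)


def _parse_title(title: str, default_file: str) -> tuple[str, str]:
    m = _TPP_TITLE.match(title.strip())
    if m:
        return m.group("file"), m.group("scan")
    return default_file, ""


def read_peaklist(path: str | Path, fmt: str | None = None) -> list[Spectrum]:
    """Read an MGF (or mzML) peak list into :class:`Spectrum` objects.

    MS1 scans in mzML input are skipped.  MGF entries without a CHARGE
    line default to 2+ with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mgf":
        spectra = _read_mgf(path)
    elif fmt == "mzml":
        spectra = _read_mzml(path)
    else:
        raise ValueError(f"unsupported peak-list format {fmt!r}")
    logger.info("%s: read %d MS2 spectra", path.name, len(spectra))
    return spectra


def _read_mgf(path: Path) -> list[Spectrum]:
    out: list[Spectrum] = []
    with _pmgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={i}"))
            pepmass = params.get("pepmass", (0.0,))
            charge_field = params.get("charge")
            if charge_field:
                charge = int(charge_field[0])
            else:
                charge = 2
                logger.warning(
                    "%s: spectrum %r has no CHARGE; assuming 2+", path.name, title
                )
            src, scan = _parse_title(title, path.stem)
            rt = float(params.get("rtinseconds", 0.0))
            out.append(
                Spectrum(
                    source=src,
                    scan=scan or str(i + 1),
                    title=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=abs(charge),
                    rt_seconds=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def _read_mzml(path: Path) -> list[Spectrum]:
    from pyteomics import mzml as _pmzml

    out: list[Spectrum] = []
    with _pmzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            sid = entry.get("id", "")
            scan_m = re.search(r"scan=(\d+)", sid)
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            charge = int(ion.get("charge state", 2))
            rt = 0.0
            scan_list = entry.get("scanList", {}).get("scan", [])
            if scan_list:
                rt = float(scan_list[0].get("scan start time", 0.0)) * 60.0
            out.append(
                Spectrum(
                    source=path.stem,
                    scan=scan_m.group(1) if scan_m else sid,
                    title=sid,
                    precursor_mz=float(ion["selected ion m/z"]),
                    precursor_charge=charge,
                    rt_seconds=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Serialize spectra to Mascot generic format."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.title,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                    "rtinseconds": s.rt_seconds,
                },
            }
        )
    _pmgf.write(entries, str(path), file_mode="w")


def preprocess(spectrum: Spectrum, top_n: int = 100) -> Spectrum:
    """Retain the ``top_n`` most intense peaks, m/z order restored.

    Intensity ties at the cutoff keep the lower-m/z peak.  The retained
    count is recorded on the spectrum for enrichment scoring.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    n = len(spectrum)
    if n <= top_n:
        keep_mz, keep_int = spectrum.mz, spectrum.intensity
    else:
        # sort by (-intensity, m/z): stable preference for lower m/z on ties
        order = np.lexsort((spectrum.mz, -spectrum.intensity))
        keep = np.sort(order[:top_n])
        keep_mz, keep_int = spectrum.mz[keep], spectrum.intensity[keep]
    out = Spectrum(
        source=spectrum.source,
        scan=spectrum.scan,
        title=spectrum.title,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        rt_seconds=spectrum.rt_seconds,
        mz=keep_mz.copy(),
        intensity=keep_int.copy(),
    )
    out.retained_n = len(out)
    return out


def ppm_error(observed: float | np.ndarray, theoretical: float | np.ndarray):
    """Signed relative error in ppm, denominator = theoretical."""
    return (observed - theoretical) / theoretical * 1e6


def ppm_match(
    observed: float, theoretical: float, tol: float
) -> tuple[bool, float]:
    """Inclusive ±tol ppm match decision plus the signed error."""
    err = ppm_error(observed, theoretical)
    return bool(abs(err) <= tol), float(err)
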