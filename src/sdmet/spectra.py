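"""Domain types and I/O for nominal-mass electron-ionization spectra.

Spectra are stored as ordered peak lists of (integer nominal m/z, relative
intensity in % of the base peak).  Silylated metabolites measured by GC-EI-MS
are reported at unit mass resolution, so integer m/z with a 0.5 Da matching
tolerance is the native representation.  Two text formats are supported: a
NIST-style MSP dialect and a flat CSV peak table (columns: name, mz, ri).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "SpectrumLibrary",
    "IonKey",
    "MatchedIonTable",
    "MetaboliteRecord",
    "MspFormatError",
    "IonCollisionError",
    "read_msp",
    "write_msp",
    "read_peak_csv",
    "match_ions",
    "parse_metabolite_table",
    "METABOLITE_CLASSES",
]

#: Closed vocabulary of metabolite classes used by the inventory table.
METABOLITE_CLASSES = (
    "organic acid",
    "phenolic",
    "fatty acid",
    "carbohydrate",
    "aminosugar",
    "amino acid/derivative",
    "other",
)

# Section headings of the inventory table mapped onto the class vocabulary.
_SECTION_TO_CLASS = {
    "organic acids": "organic acid",
    "phenolic compounds": "phenolic",
    "fatty acids": "fatty acid",
    "carbohydrates (cbs)": "carbohydrate",
    "carbohydrates": "carbohydrate",
    "aminosugars": "aminosugar",
    "amino acids and their derivatives": "amino acid/derivative",
    "other connections": "other",
}


class MspFormatError(ValueError):
    """Raised when a spectral library file cannot be parsed."""


class IonCollisionError(ValueError):
    """Raised when two peaks of one spectrum match the same ion slot."""


@dataclass(frozen=True)
class MassSpectrum:
    """A named nominal-mass peak list with relative intensities.

    Parameters
    ----------
    name : str
        Label of the analyte (e.g. ``"CB_B"`` or a library entry name).
    peaks : tuple of (int, float)
        ``(mz, ri)`` pairs, strictly increasing in m/z; ``ri`` is the
        relative intensity in % of the base peak.
    rt_min : float, optional
        Chromatographic retention time in minutes.
    derivatization : str, optional
        Chemical derivatization tag (``"TMS"`` for trimethylsilylation).
    metadata : dict
        Free key/value map; may carry treatment descriptors such as the
        magnetic-pulse frequency (Hz) and exposure time (s).
    """

    name: str
    peaks: tuple[tuple[int, float], ...]
    rt_min: float | None = None
    derivatization: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(mz <= 0 for mz in mzs):
            raise ValueError(f"spectrum {self.name!r}: all m/z must be > 0")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(
                f"spectrum {self.name!r}: m/z values must be strictly "
                "increasing (duplicates are forbidden)"
            )
        if any(ri < 0 for _, ri in self.peaks):
            raise ValueError(f"spectrum {self.name!r}: intensities must be >= 0")

    @property
    def mz(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks], dtype=float)

    @property
    def ri(self) -> np.ndarray:
        return np.array([ri for _, ri in self.peaks], dtype=float)

    @property
    def base_peak(self) -> tuple[int, float] | None:
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p[1])

    def normalized(self) -> "MassSpectrum":
        """Rescale intensities so the base peak is exactly 100 %.

        Idempotent; an empty or all-zero spectrum is returned unchanged.
        """
        if not self.peaks:
            return self
        top = max(ri for _, ri in self.peaks)
        if top <= 0:
            return self
        scale = 100.0 / top
        peaks = tuple((mz, ri * scale) for mz, ri in self.peaks)
        return MassSpectrum(
            name=self.name,
            peaks=peaks,
            rt_min=self.rt_min,
            derivatization=self.derivatization,
            metadata=dict(self.metadata),
        )

    def intensity_at(self, mz: float, tolerance: float = 0.5) -> float | None:
        """Intensity of the first peak within ``tolerance`` of ``mz``."""
        for pmz, ri in self.peaks:
            if abs(pmz - mz) <= tolerance:
                return ri
        return None


@dataclass
class SpectrumLibrary:
    """A named collection of spectra (entry names are unique)."""

    entries: dict[str, MassSpectrum]
    source: str = ""

    def __post_init__(self) -> None:
        for name, spec in self.entries.items():
            if name != spec.name:
                raise ValueError(f"library key {name!r} != spectrum name {spec.name!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> MassSpectrum:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries.values())

    def names(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True)
class IonKey:
    """One comparison channel: a primary nominal mass plus alternates.

    Ions printed as slashed pairs (129/133, 205/204, 361/359, ...) are one
    slot: the primary mass wins when both are present in a spectrum.
    Alternates must lie within 4 Da of the primary mass.
    """

    primary_mz: int
    alternates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.primary_mz <= 0:
            raise ValueError("primary_mz must be positive")
        for alt in self.alternates:
            if abs(alt - self.primary_mz) > 4:
                raise ValueError(
                    f"alternate m/z {alt} more than 4 Da from primary "
                    f"{self.primary_mz}"
                )

    @property
    def label(self) -> str:
        if not self.alternates:
            return str(self.primary_mz)
        return "/".join(str(m) for m in (self.primary_mz, *self.alternates))

    @classmethod
    def parse(cls, text: str | int) -> "IonKey":
        """Parse ``"205"`` or ``"361/359"`` into an ion key."""
        if isinstance(text, int):
            return cls(text)
        parts = [int(p) for p in str(text).split("/")]
        return cls(parts[0], tuple(parts[1:]))


@dataclass
class MatchedIonTable:
    """Spectra aligned on a shared ion set; NaN marks a missing ion.

    ``columns`` maps spectrum name to an intensity vector with one value per
    entry of ``ions``.  This is the substrate for pairwise correlation
    scoring of spectra.
    """

    ions: list[IonKey]
    columns: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.ions)
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            self.columns[name] = col
            if col.shape != (n,):
                raise ValueError(
                    f"column {name!r} has {col.shape} values for {n} ions"
                )
            if np.all(np.isnan(col)):
                raise ValueError(f"column {name!r} is all-missing")

    def column(self, name: str) -> np.ndarray:
        return self.columns[name]

    def to_json(self) -> str:
        payload = {
            "ions": [k.label for k in self.ions],
            "columns": {
                name: [None if math.isnan(v) else v for v in col]
                for name, col in self.columns.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MatchedIonTable":
        payload = json.loads(text)
        ions = [IonKey.parse(s) for s in payload["ions"]]
        columns = {
            name: np.array(
                [math.nan if v is None else float(v) for v in col], dtype=float
            )
            for name, col in payload["columns"].items()
        }
        return cls(ions=ions, columns=columns)


@dataclass(frozen=True)
class MetaboliteRecord:
    """One row of the metabolite inventory table."""

    index: int
    rt_min: float
    name: str
    met_class: str

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ValueError(f"record {self.index}: rt_min must be > 0")
        if self.met_class not in METABOLITE_CLASSES:
            raise ValueError(
                f"record {self.index}: unknown class {self.met_class!r}"
            )


# ---------------------------------------------------------------------------
# MSP / CSV spectral library I/O
# ---------------------------------------------------------------------------

def _finalize_record(
    name: str | None,
    peaks: list[tuple[int, float]],
    num_declared: int | None,
    meta: dict,
    lineno: int,
    normalize: bool,
) -> MassSpectrum:
    if name is None:
        raise MspFormatError(f"line {lineno}: record without a Name: field")
    if num_declared is not None and num_declared != len(peaks):
        raise MspFormatError(
            f"record {name!r} (near line {lineno}): declared {num_declared} "
            f"peaks but found {len(peaks)}"
        )
    peaks.sort(key=lambda p: p[0])
    for (a, _), (b, _) in zip(peaks, peaks[1:]):
        if a == b:
            raise MspFormatError(
                f"record {name!r}: duplicate m/z {a} within one spectrum"
            )
    rt = meta.pop("rt", None)
    deriv = meta.pop("derivatization", None)
    spec = MassSpectrum(
        name=name,
        peaks=tuple(peaks),
        rt_min=float(rt) if rt is not None else None,
        derivatization=deriv,
        metadata=meta,
    )
    return spec.normalized() if normalize else spec


def read_msp(path: str | Path, normalize: bool = True) -> SpectrumLibrary:
    """Read a NIST-style MSP library (or the CSV dialect, by extension).

    The MSP dialect: ``Name:`` opens a record, ``Num Peaks:`` declares the
    peak count, subsequent lines are whitespace-separated ``mz intensity``
    pairs, ``;`` starts a comment.  Other ``Key: value`` headers (``RT:``,
    ``Derivatization:``) are kept as metadata.  All spectra are normalized
    to base peak = 100 % unless ``normalize=False``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_peak_csv(path, normalize=normalize)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise MspFormatError(f"{path}: empty library file")

    entries: dict[str, MassSpectrum] = {}
    name: str | None = None
    peaks: list[tuple[int, float]] = []
    num_declared: int | None = None
    meta: dict = {}
    started = False

    def close(lineno: int) -> None:
        nonlocal name, peaks, num_declared, meta
        spec = _finalize_record(name, peaks, num_declared, meta, lineno, normalize)
        if spec.name in entries:
            raise MspFormatError(f"duplicate record name {spec.name!r}")
        entries[spec.name] = spec
        name, peaks, num_declared, meta = None, [], None, {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("name:"):
            if started:
                close(lineno)
            name = line.split(":", 1)[1].strip()
            started = True
            continue
        if low.startswith("num peaks:"):
            try:
                num_declared = int(line.split(":", 1)[1])
            except ValueError as exc:
                raise MspFormatError(
                    f"line {lineno}: unparseable Num Peaks in record {name!r}"
                ) from exc
            continue
        if ":" in line and not line[0].isdigit():
            key, value = (s.strip() for s in line.split(":", 1))
            meta[key.lower()] = value
            continue
        parts = line.replace(",", " ").split()
        if len(parts) % 2 != 0:
            raise MspFormatError(
                f"line {lineno}: malformed peak line {line!r} in record {name!r}"
            )
        for mz_s, ri_s in zip(parts[::2], parts[1::2]):
            try:
                mz = int(round(float(mz_s)))
                ri = float(ri_s)
            except ValueError as exc:
                raise MspFormatError(
                    f"line {lineno}: malformed peak pair ({mz_s!r}, {ri_s!r}) "
                    f"in record {name!r}"
                ) from exc
            peaks.append((mz, ri))
    if started:
        close(lineno)
    if not entries:
        raise MspFormatError(f"{path}: no records found")
    return SpectrumLibrary(entries=entries, source=str(path))


def read_peak_csv(path: str | Path, normalize: bool = True) -> SpectrumLibrary:
    """Read the CSV peak-table dialect (columns: name, mz, ri)."""
    path = Path(path)
    groups: dict[str, list[tuple[int, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "mz", "ri"} <= set(
            reader.fieldnames
        ):
            raise MspFormatError(f"{path}: CSV must have columns name, mz, ri")
        for i, row in enumerate(reader, start=2):
            try:
                mz = int(round(float(row["mz"])))
                ri = float(row["ri"])
            except (TypeError, ValueError) as exc:
                raise MspFormatError(
                    f"{path} line {i}: malformed peak row {row!r}"
                ) from exc
            groups.setdefault(row["name"], []).append((mz, ri))
    if not groups:
        raise MspFormatError(f"{path}: empty peak table")
    entries = {}
    for name, peaks in groups.items():
        spec = _finalize_record(name, peaks, None, {}, 0, normalize)
        entries[name] = spec
    return SpectrumLibrary(entries=entries, source=str(path))


def write_msp(lib: SpectrumLibrary, path: str | Path) -> Path:
    """Write a library in the MSP dialect; round-trips m/z and ri exactly
    to 4 decimal places."""
    if len(lib) == 0:
        raise ValueError("refusing to write an empty library")
    path = Path(path)
    lines: list[str] = []
    for spec in lib:
        lines.append(f"Name: {spec.name}")
        if spec.rt_min is not None:
            lines.append(f"RT: {spec.rt_min:.4f}")
        if spec.derivatization:
            lines.append(f"Derivatization: {spec.derivatization}")
        for key, value in spec.metadata.items():
            lines.append(f"{key}: {value}")
        lines.append(f"Num Peaks: {len(spec.peaks)}")
        for mz, ri in spec.peaks:
            lines.append(f"{mz} {ri:.4f}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Ion matching
# ---------------------------------------------------------------------------

def match_ions(
    spectra: Sequence[MassSpectrum],
    ion_keys: Sequence[IonKey],
    tolerance: float = 0.5,
) -> MatchedIonTable:
    """Align spectra on a shared ion-key set.

    For each spectrum and key the intensity of the first peak matching the
    primary mass (or, failing that, any alternate) within ``tolerance`` is
    taken; a NaN marks a missing ion.  Intensities are never altered.  Two
    peaks of one spectrum matching the same key raise
    :class:`IonCollisionError` so the caller can refine the key set.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not ion_keys:
        raise ValueError("ion_keys must be nonempty")
    columns: dict[str, np.ndarray] = {}
    for spec in spectra:
        col = np.full(len(ion_keys), np.nan)
        for j, key in enumerate(ion_keys):
            candidates = (key.primary_mz, *key.alternates)
            hits: list[tuple[int, float]] = []
            for target in candidates:
                for pmz, ri in spec.peaks:
                    if abs(pmz - target) <= tolerance:
                        hits.append((pmz, ri))
            # distinct peaks hitting one slot is a key-definition problem
            distinct = {mz for mz, _ in hits}
            if len(distinct) > 1:
                raise IonCollisionError(
                    f"spectrum {spec.name!r}: peaks at m/z {sorted(distinct)} "
                    f"all match ion slot {key.label} (tolerance {tolerance})"
                )
            if hits:
                col[j] = hits[0][1]
        columns[spec.name] = col
    return MatchedIonTable(ions=list(ion_keys), columns=columns)


# ---------------------------------------------------------------------------
# Metabolite inventory table
# ---------------------------------------------------------------------------

def _parse_rt(text: str, row: int) -> float:
    """Parse a retention time printed as ``min:sec`` (or decimal minutes)."""
    text = text.strip()
    try:
        if ":" in text:
            mins, secs = text.split(":")
            return int(mins) + int(secs) / 60.0
        return float(text)
    except ValueError as exc:
        raise ValueError(f"row {row}: unparseable retention time {text!r}") from exc


def parse_metabolite_table(path: str | Path) -> list[MetaboliteRecord]:
    """Parse the metabolite inventory CSV into records.

    Rows with an empty index cell are section headers; every following row
    is assigned the class of the most recent section.  An empty file yields
    an empty list.
    """
    path = Path(path)
    records: list[MetaboliteRecord] = []
    current_class: str | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for rowno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if rowno == 1 and row[0].strip().lower() == "index":
                continue
            if not row[0].strip():
                header = row[-1].strip().lower()
                if header not in _SECTION_TO_CLASS:
                    raise ValueError(
                        f"row {rowno}: unknown section header {row[-1]!r}"
                    )
                current_class = _SECTION_TO_CLASS[header]
                continue
            if current_class is None:
                raise ValueError(f"row {rowno}: data row before any section header")
            index = int(row[0])
            rt = _parse_rt(row[1], rowno)
            name = row[2]
            records.append(
                MetaboliteRecord(
                    index=index, rt_min=rt, name=name, met_class=current_class
                )
            )
    return records


def class_counts(records: Iterable[MetaboliteRecord]) -> dict[str, int]:
    """Count inventory records per metabolite class."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.met_class] = counts.get(rec.met_class, 0) + 1
    return counts
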