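"""MS² spectra and activity labels: reading, cleaning, averaging, filtering.

A :class:`Spectrum` is a peak list (m/z, intensity) with the precursor m/z
and light metadata. Spectra enter from MSP or MGF library files, are
normalized to the base peak, optionally averaged across collision energies,
and quality-filtered before similarity scoring. Activity labels are ternary
(active / inactive / inconclusive) per assay endpoint and attach to a
compound identifier — the first 14-character block of an InChIKey, which
collapses stereoisomers and salt forms to one record.
"""

from __future__ import annotations

import random
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "LabeledCompound",
    "read_spectra",
    "write_spectra",
    "normalize_peaks",
    "clean_peaks",
    "average_spectra",
    "quality_filter",
    "clean_labels",
    "read_label_table",
    "stratified_split",
]

LABELS = ("active", "inactive", "inconclusive")


@dataclass(frozen=True)
class Spectrum:
    """A single MS² spectrum.

    Peaks are kept sorted by ascending m/z. ``precursor_mz`` may be absent
    (``None``); operations that need it (the modified cosine's shifted
    matching) raise in that case rather than guessing.
    """

    compound_id: str
    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float | None = None
    collision_energy: float | None = None
    adduct: str | None = None
    ionization_mode: str = "positive"

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        object.__setattr__(self, "peaks", pk)
        if self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        for mz, inten in pk:
            if mz <= 0 or inten < 0:
                raise ValueError(f"invalid peak ({mz}, {inten})")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class LabeledCompound:
    """A compound: id, optional spectrum and fingerprint, per-assay labels."""

    compound_id: str
    spectrum: Spectrum | None = None
    fingerprint: np.ndarray | None = None
    labels: dict[str, str] = field(default_factory=dict)

    def label_binary(self, assay: str) -> int | None:
        """1 for active, 0 for inactive, None for inconclusive/absent."""
        lab = self.labels.get(assay)
        if lab == "active":
            return 1
        if lab == "inactive":
            return 0
        return None


# ---------------------------------------------------------------------------
# File I/O — MSP (NIST text) and MGF dialects
# ---------------------------------------------------------------------------

def _parse_float(text: str) -> float | None:
    try:
        return float(text)
    except ValueError:
        return None


def _make_spectrum(meta: dict, peaks: list, index: int) -> Spectrum:
    if not peaks:
        raise ValueError(f"record {index}: no peaks")
    return Spectrum(
        compound_id=meta.get("name", f"record_{index}"),
        peaks=tuple(peaks),
        precursor_mz=meta.get("precursor_mz"),
        collision_energy=meta.get("collision_energy"),
        adduct=meta.get("adduct"),
        ionization_mode=meta.get("ionization_mode", "positive"),
    )


def _read_msp(lines: Iterable[str]) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    n_expected: int | None = None
    index = 0

    def flush() -> None:
        nonlocal meta, peaks, n_expected, index
        if meta or peaks:
            if n_expected is not None and len(peaks) != n_expected:
                raise ValueError(
                    f"record {index}: declared {n_expected} peaks, found {len(peaks)}"
                )
            spectra.append(_make_spectrum(meta, peaks, index))
            index += 1
        meta, peaks, n_expected = {}, [], None

    for raw in lines:
        line = raw.strip()
        if not line:
            flush()
            continue
        if ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key == "name":
                meta["name"] = value
            elif key in ("precursormz", "precursor_mz", "pepmass"):
                meta["precursor_mz"] = _parse_float(value)
            elif key in ("collisionenergy", "collision_energy"):
                meta["collision_energy"] = _parse_float(value)
            elif key in ("precursortype", "adduct"):
                meta["adduct"] = value
            elif key in ("ionmode", "ionization_mode"):
                meta["ionization_mode"] = value.lower()
            elif key in ("num peaks", "numpeaks"):
                n_expected = int(value)
        else:
            parts = line.replace(";", " ").split()
            if len(parts) < 2:
                raise ValueError(f"record {index}: malformed peak line {line!r}")
            mz, inten = _parse_float(parts[0]), _parse_float(parts[1])
            if mz is None or inten is None:
                raise ValueError(f"record {index}: malformed peak line {line!r}")
            peaks.append((mz, inten))
    flush()
    return spectra


def _read_mgf(lines: Iterable[str]) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    in_block = False
    index = 0
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "BEGIN IONS":
            in_block, meta, peaks = True, {}, []
        elif line.upper() == "END IONS":
            if not in_block:
                raise ValueError(f"record {index}: END IONS without BEGIN IONS")
            spectra.append(_make_spectrum(meta, peaks, index))
            index += 1
            in_block = False
        elif in_block:
            if "=" in line:
                key, _, value = line.partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "TITLE":
                    meta["name"] = value
                elif key == "PEPMASS":
                    meta["precursor_mz"] = _parse_float(value.split()[0])
                elif key == "CHARGE":
                    meta["ionization_mode"] = (
                        "negative" if value.endswith("-") else "positive"
                    )
                elif key == "COLLISION_ENERGY":
                    meta["collision_energy"] = _parse_float(value)
                elif key == "ADDUCT":
                    meta["adduct"] = value
            else:
                parts = line.split()
                mz, inten = _parse_float(parts[0]), (
                    _parse_float(parts[1]) if len(parts) > 1 else None
                )
                if mz is None or inten is None:
                    raise ValueError(f"record {index}: malformed peak line {line!r}")
                peaks.append((mz, inten))
    if in_block:
        raise ValueError(f"record {index}: unterminated BEGIN IONS block")
    return spectra


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from an MSP or MGF file.

    ``format`` is inferred from the suffix when not given. An empty file
    yields an empty list with a warning; a malformed record raises a
    ``ValueError`` naming the record index.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("msp", "mgf"):
        raise ValueError(f"unknown spectrum format {format!r}")
    lines = path.read_text().splitlines()
    out = _read_msp(lines) if format == "msp" else _read_mgf(lines)
    if not out:
        warnings.warn(f"{path}: no spectra found", stacklevel=2)
    return out


def write_spectra(spectra: Sequence[Spectrum], path: str | Path,
                  format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    blocks: list[str] = []
    for s in spectra:
        if format == "msp":
            lines = [f"NAME: {s.compound_id}"]
            if s.precursor_mz is not None:
                lines.append(f"PRECURSORMZ: {s.precursor_mz:.6f}")
            if s.collision_energy is not None:
                lines.append(f"COLLISIONENERGY: {s.collision_energy:g}")
            if s.adduct:
                lines.append(f"PRECURSORTYPE: {s.adduct}")
            lines.append(f"IONMODE: {s.ionization_mode}")
            lines.append(f"Num Peaks: {len(s)}")
            lines += [f"{mz:.6f} {i:.6g}" for mz, i in s.peaks]
            blocks.append("\n".join(lines))
        elif format == "mgf":
            lines = ["BEGIN IONS", f"TITLE={s.compound_id}"]
            if s.precursor_mz is not None:
                lines.append(f"PEPMASS={s.precursor_mz:.6f}")
            lines += [f"{mz:.6f} {i:.6g}" for mz, i in s.peaks]
            lines.append("END IONS")
            blocks.append("\n".join(lines))
        else:
            raise ValueError(f"unknown spectrum format {format!r}")
    path.write_text("\n\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# Cleaning, normalization, averaging, quality filtering
# ---------------------------------------------------------------------------

def normalize_peaks(s: Spectrum) -> Spectrum:
    """Scale intensities so the base peak equals 1.0."""
    if len(s) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = max(i for _, i in s.peaks)
    if top <= 0:
        raise ValueError("all intensities are zero")
    return replace(s, peaks=tuple((mz, i / top) for mz, i in s.peaks))


def clean_peaks(s: Spectrum, precursor_window: float = 0.5) -> Spectrum:
    """Standard peak hygiene: drop zero-intensity peaks and peaks beyond the
    precursor (mz > precursor + ``precursor_window`` Da, when the precursor is
    known), then normalize to the base peak."""
    peaks = [(mz, i) for mz, i in s.peaks if i > 0]
    if s.precursor_mz is not None:
        peaks = [(mz, i) for mz, i in peaks if mz <= s.precursor_mz + precursor_window]
    if not peaks:
        raise ValueError(f"{s.compound_id}: no peaks survive cleaning")
    return normalize_peaks(replace(s, peaks=tuple(peaks)))


def average_spectra(group: Sequence[Spectrum], mz_tolerance: float = 0.01) -> Spectrum:
    """Average a group of spectra of one compound (e.g. across collision
    energies).

    Each spectrum is normalized first. Peaks are merged by single-linkage in
    ascending m/z within ``mz_tolerance``; a merged peak's m/z is the
    intensity-weighted mean and its intensity the arithmetic mean over all
    input spectra, counting a spectrum without the peak as 0. The result is
    re-normalized.
    """
    if not group:
        raise ValueError("empty spectrum group")
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be positive")
    ids = {s.compound_id for s in group}
    if len(ids) > 1:
        raise ValueError(f"mixed compound ids in group: {sorted(ids)}")
    normed = [normalize_peaks(s) for s in group]
    # pool all peaks, sorted ascending by m/z; single-linkage clustering
    pooled = sorted(
        (mz, inten, k) for k, s in enumerate(normed) for mz, inten in s.peaks
    )
    clusters: list[list[tuple[float, float, int]]] = []
    for p in pooled:
        if clusters and p[0] - clusters[-1][-1][0] <= mz_tolerance:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    n = len(normed)
    merged = []
    for cl in clusters:
        w = sum(i for _, i, _ in cl)
        mz = sum(m * i for m, i, _ in cl) / w if w > 0 else cl[0][0]
        merged.append((mz, sum(i for _, i, _ in cl) / n))
    base = normed[0]
    prec = [s.precursor_mz for s in normed if s.precursor_mz is not None]
    out = replace(
        base,
        peaks=tuple(merged),
        precursor_mz=float(np.mean(prec)) if prec else None,
        collision_energy=None,
    )
    return normalize_peaks(out)


def quality_filter(s: Spectrum, min_peaks: int = 5,
                   min_rel_intensity: float = 0.05) -> bool:
    """True iff the spectrum has >= ``min_peaks`` peaks with relative
    intensity strictly above ``min_rel_intensity``. Expects a normalized
    spectrum (base peak 1.0)."""
    return sum(1 for _, i in s.peaks if i > min_rel_intensity) >= min_peaks


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def clean_labels(records: Iterable[tuple[str, str, str]]) -> list[LabeledCompound]:
    """Aggregate raw label rows (compound_id, assay, label) per compound.

    Rows are grouped by the 14-character id block. Per assay, a compound is
    active if any report is active (precautionary principle), else inactive
    if any report is inactive, else inconclusive.
    """
    by_id: dict[str, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    order: list[str] = []
    for cid, assay, label in records:
        cid = str(cid).strip()[:14]
        label = str(label).strip().lower()
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r} for {cid}/{assay}")
        if cid not in by_id:
            order.append(cid)
        by_id[cid][assay].add(label)
    out = []
    for cid in order:
        labels = {}
        for assay, seen in by_id[cid].items():
            if "active" in seen:
                labels[assay] = "active"
            elif "inactive" in seen:
                labels[assay] = "inactive"
            else:
                labels[assay] = "inconclusive"
        out.append(LabeledCompound(compound_id=cid, labels=labels))
    return out


def read_label_table(path: str | Path, sep: str = "\t") -> list[LabeledCompound]:
    """Read a delimited label table with columns compound_id, assay, label."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    required = {"compound_id", "assay", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table needs columns {sorted(required)}")
    return clean_labels(df[["compound_id", "assay", "label"]].itertuples(index=False))


def stratified_split(
    compounds: Sequence[LabeledCompound],
    test_fraction: float,
    assay: str,
    seed: int,
    exclude_ids: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[LabeledCompound], list[LabeledCompound]]:
    """Deterministic stratified train/test split on one assay's binary label.

    Class proportions are preserved within +-1 compound per class and ids in
    ``exclude_ids`` never land in the test set. Compounds without a binary
    label for the assay are stratified as their own group.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    strata: dict[object, list[LabeledCompound]] = defaultdict(list)
    for c in sorted(compounds, key=lambda c: c.compound_id):
        strata[c.label_binary(assay)].append(c)
    rng = random.Random(seed)
    train: list[LabeledCompound] = []
    test: list[LabeledCompound] = []
    for key in sorted(strata, key=str):
        members = strata[key]
        if key is not None and len(members) < 2:
            raise ValueError(f"class {key} for assay {assay!r} has < 2 members")
        eligible = [c for c in members if c.compound_id not in exclude_ids]
        excluded = [c for c in members if c.compound_id in exclude_ids]
        n_test = min(round(len(members) * test_fraction), len(eligible))
        rng.shuffle(eligible)
        test.extend(eligible[:n_test])
        train.extend(eligible[n_test:])
        train.extend(excluded)
    return train, test
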