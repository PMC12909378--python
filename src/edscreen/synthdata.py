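"""Seeded synthetic data with the statistical structure the methods assume.

The generator emulates a screening-library world in miniature: compounds
are sparse binary fingerprints; activity is an OR over a few hidden
"toxicophore" bits, flipped with a small label-noise probability; each set
bit emits a fixed table of characteristic fragment peaks, so compounds
sharing substructure bits produce similar MS² spectra — the
spectrum-structure correlation that molecular networking relies on.
Influent/effluent feature tables are built directly in the intensity-ratio
bands that the fate classifier reads back out.

Class imbalance defaults to 16% active, the upper end of what nuclear
receptor panels show (3%-16% across assays); label noise defaults to 5%.
Everything is deterministic under the config seed: per-bit peak tables come
from per-bit seeded generators, and per-compound jitter is seeded from
(seed, compound index), so no draw depends on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fpmodel import FingerprintMatrix
from .prioritize import FeatureRecord
from .spectra import LabeledCompound, Spectrum

__all__ = [
    "SynthConfig",
    "generate_compounds",
    "generate_spectrum",
    "generate_dataset",
    "generate_feature_table",
    "generate_exchangeable_features",
    "PRESETS",
    "preset",
]

_BIT_TABLE_SEED = 9173  # namespace for per-bit peak tables; never varied


@dataclass(frozen=True)
class SynthConfig:
    """Stated world for the generator; defaults are the tested conditions."""

    n_compounds: int = 150
    n_bits: int = 64
    toxicophore_bits: tuple[int, ...] = (0, 1)
    label_noise: float = 0.05
    bit_prevalence: float = 0.03
    spectrum_peaks_per_bit: int = 4
    mz_jitter_sd: float = 0.01
    spectrum_noise_peaks: int = 1
    active_fraction_target: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if any(b < 0 or b >= self.n_bits for b in self.toxicophore_bits):
            raise ValueError("toxicophore_bits out of range")
        if not 0 < self.active_fraction_target < 1:
            raise ValueError("active_fraction_target must be in (0, 1)")


# ---------------------------------------------------------------------------
# Compounds: fingerprints + labels
# ---------------------------------------------------------------------------

def _toxicophore_prevalence(cfg: SynthConfig) -> float:
    """Per-toxicophore-bit prevalence q with 1 - (1-q)^k = target (pre-noise)."""
    k = len(cfg.toxicophore_bits)
    return 1.0 - (1.0 - cfg.active_fraction_target) ** (1.0 / k)


def generate_compounds(cfg: SynthConfig) -> tuple[FingerprintMatrix, np.ndarray]:
    """Draw fingerprints and activity labels.

    Background bits are Bernoulli(``bit_prevalence``); toxicophore bits use
    the prevalence that makes the OR hit ``active_fraction_target``. The
    label is the OR over toxicophore bits, flipped with probability
    ``label_noise``. If the realized active fraction falls outside the
    target +-5 percentage points, prevalences are resampled (bounded
    retries, deterministic sub-seeds).
    """
    if not cfg.toxicophore_bits:
        raise ValueError("need at least one toxicophore bit")
    q0 = _toxicophore_prevalence(cfg)
    tox = set(cfg.toxicophore_bits)
    for attempt in range(30):
        rng = np.random.default_rng([cfg.seed, attempt, 101])
        q = q0
        prev = np.full(cfg.n_bits, cfg.bit_prevalence)
        for b in tox:
            prev[b] = q
        bits = (rng.random((cfg.n_compounds, cfg.n_bits)) < prev).astype(np.uint8)
        # no compound may be bit-less: give it one random background bit
        empty = np.flatnonzero(bits.sum(axis=1) == 0)
        if empty.size:
            background = [b for b in range(cfg.n_bits) if b not in tox]
            bits[empty, rng.choice(background, size=empty.size)] = 1
        clean = bits[:, sorted(tox)].any(axis=1).astype(int)
        flips = rng.random(cfg.n_compounds) < cfg.label_noise
        labels = np.where(flips, 1 - clean, clean)
        frac = labels.mean()
        if abs(frac - cfg.active_fraction_target) <= 0.05:
            ids = [f"CMP{i:05d}" for i in range(cfg.n_compounds)]
            return FingerprintMatrix(ids, bits), labels
    raise ValueError(
        f"active fraction target {cfg.active_fraction_target} unattainable")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _bit_peak_table(bit: int, peaks_per_bit: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed characteristic fragments of one bit: m/z in [50, 500] Da and
    intensities in [0.3, 1.0], from a per-bit seeded generator."""
    rng = np.random.default_rng([_BIT_TABLE_SEED, bit])
    mz = rng.uniform(50.0, 500.0, size=peaks_per_bit)
    inten = rng.uniform(0.3, 1.0, size=peaks_per_bit)
    return mz, inten


def generate_spectrum(fp_row: np.ndarray, cfg: SynthConfig,
                      compound_id: str = "synthetic",
                      compound_index: int = 0) -> Spectrum:
    """Emit the spectrum of one fingerprint row.

    Each set bit contributes its characteristic peaks with Gaussian m/z
    jitter; ``spectrum_noise_peaks`` uniform-random low peaks are added.
    The precursor m/z is a deterministic function of the bit pattern.
    """
    fp_row = np.asarray(fp_row).astype(bool)
    set_bits = np.flatnonzero(fp_row)
    if set_bits.size == 0:
        raise ValueError("empty fingerprint: no bits set")
    rng = np.random.default_rng([cfg.seed, 7, compound_index])
    mzs, intens = [], []
    for b in set_bits:
        mz, inten = _bit_peak_table(int(b), cfg.spectrum_peaks_per_bit)
        mzs.append(mz + rng.normal(0.0, cfg.mz_jitter_sd, size=mz.size)
                   if cfg.mz_jitter_sd > 0 else mz)
        intens.append(inten)
    for _ in range(cfg.spectrum_noise_peaks):
        mzs.append(np.array([rng.uniform(50.0, 500.0)]))
        intens.append(np.array([rng.uniform(0.05, 0.3)]))
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    # precursor: base mass plus fixed per-bit contributions, above every peak
    contrib = sum(float(np.random.default_rng([_BIT_TABLE_SEED, 2, int(b)])
                        .uniform(1.0, 20.0)) for b in set_bits)
    precursor = 520.0 + contrib
    top = inten.max()
    peaks = tuple((float(m), float(i / top)) for m, i in zip(mz, inten))
    return Spectrum(compound_id=compound_id, peaks=peaks,
                    precursor_mz=precursor, ionization_mode="positive")


def generate_dataset(cfg: SynthConfig) -> tuple[list[LabeledCompound], np.ndarray]:
    """Compounds with fingerprints, spectra, and one-assay labels."""
    fp, labels = generate_compounds(cfg)
    compounds = []
    for i, cid in enumerate(fp.ids):
        spec = generate_spectrum(fp.bits[i], cfg, compound_id=cid,
                                 compound_index=i)
        compounds.append(LabeledCompound(
            compound_id=cid,
            spectrum=spec,
            fingerprint=fp.bits[i].copy(),
            labels={"synthetic_assay": "active" if labels[i] else "inactive"},
        ))
    return compounds, labels


# ---------------------------------------------------------------------------
# Feature tables (wastewater world)
# ---------------------------------------------------------------------------

_FATE_BANDS = {  # interiors of the fate bands, clear of the boundaries
    "persistent": (0.85, 1.15),
    "transformation_product": (1.6, 2.5),
    "other": (0.3, 0.7),
}


def generate_feature_table(
    n_features: int,
    fraction_persistent: float,
    fraction_tp: float,
    cfg: SynthConfig,
) -> list[FeatureRecord]:
    """Influent/effluent feature records with exact fate-band counts.

    Exactly round(n * fraction) features fall in the persistent and
    transformation-product bands; the remainder are 'other'. Intensity
    ratios are drawn from the interiors of the bands so reclassification is
    exact.
    """
    if fraction_persistent + fraction_tp > 1:
        raise ValueError("fate fractions sum beyond 1")
    rng = np.random.default_rng([cfg.seed, 31])
    n_pers = round(n_features * fraction_persistent)
    n_tp = round(n_features * fraction_tp)
    fates = (["persistent"] * n_pers + ["transformation_product"] * n_tp
             + ["other"] * (n_features - n_pers - n_tp))
    order = rng.permutation(n_features)
    records = []
    for k in range(n_features):
        fate = fates[order[k]]
        lo, hi = _FATE_BANDS[fate]
        influent = float(rng.uniform(1e4, 1e6))
        ratio = float(rng.uniform(lo, hi))
        records.append(FeatureRecord(
            feature_id=f"FT{k:05d}",
            precursor_mz=float(rng.uniform(100.0, 600.0)),
            rt=float(rng.uniform(0.5, 15.0)),
            intensity_influent=influent,
            intensity_effluent=influent * ratio,
        ))
    return records


# ---------------------------------------------------------------------------
# Exchangeable feature vectors (conformal-validity world)
# ---------------------------------------------------------------------------

def generate_exchangeable_features(
    n: int, n_features: int = 10, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """IID class-conditional feature vectors in [0, 1]^d.

    Labels are balanced Bernoulli(0.5); features are Beta-distributed with
    class-dependent shape (moderate overlap), mimicking similarity-to-
    training-set feature vectors. Rows are iid, hence exchangeable across
    any train/calibration/test split.
    """
    rng = np.random.default_rng([seed, 53])
    y = (rng.random(n) < 0.5).astype(int)
    X = np.where(
        y[:, None] == 1,
        rng.beta(4.0, 3.0, size=(n, n_features)),
        rng.beta(3.0, 4.0, size=(n, n_features)),
    )
    return X, y


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0) -> dict:
    """Named data bundles used by the demos and the evaluation suites."""
    if name == "mn-demo":
        cfg = SynthConfig(n_compounds=150, seed=seed)
        compounds, labels = generate_dataset(cfg)
        return {"config": cfg, "compounds": compounds, "labels": labels}
    if name == "cp-validity":
        X_fit, y_fit = generate_exchangeable_features(1200, seed=seed)
        X_test, y_test = generate_exchangeable_features(2000, seed=seed + 2**20)
        return {"X_fit": X_fit, "y_fit": y_fit,
                "X_test": X_test, "y_test": y_test,
                "calibration_fraction": 200 / 1200}
    if name == "fp-recovery":
        cfg = SynthConfig(n_compounds=600, seed=seed)
        fp, labels = generate_compounds(cfg)
        return {"config": cfg, "fingerprints": fp, "labels": labels}
    if name == "wastewater":
        # strata of the case-study world: 40/968 persistent, 153/968 TPs
        cfg = SynthConfig(seed=seed)
        features = generate_feature_table(968, 40 / 968, 153 / 968, cfg)
        return {"config": cfg, "features": features}
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("mn-demo", "cp-validity", "fp-recovery", "wastewater")
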