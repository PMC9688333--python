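"""Synthetic SERS mapping datasets with known ground truth.

The generator emulates the statistical structure of label-free SERS mapping
of pleural fluid: per subject, hundreds of mapping spectra over a few
substrate locations; Lorentzian vibrational bands in the 700-1800 cm^-1
fingerprint region; a broad autofluorescence baseline that dominates the
SERS signal; iid detector noise; occasional single-bin cosmic-ray spikes;
and a multiplicative per-subject enhancement gain (SERS enhancement varies
with substrate spot, so subject variation is multiplicative, not additive).

Class differences are injected as multiplicative intensity effects on
selected bands, and the generator returns those band intervals as ground
truth so downstream discrimination (PLS-DA VIP scores) can be tested for
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CANONICAL_GRID, CLASS_LABELS, SpectralDataset

__all__ = [
    "PeakSpec",
    "SimConfig",
    "EffectBand",
    "generate_dataset",
    "study_roster",
    "case1_peaks",
    "case2_peaks",
    "lorentzian",
]


def lorentzian(x: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Lorentzian line with unit peak height scaled by *amplitude*."""
    hw = fwhm / 2.0
    return amplitude * hw**2 / ((x - center) ** 2 + hw**2)


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band: position, width, strength, class effect.

    ``class_effect`` maps a class label to a multiplicative intensity
    factor (1.0 = no effect).  Classes not listed get factor 1.
    """

    center: float
    fwhm: float = 12.0
    base_amplitude: float = 300.0
    class_effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (4.0 <= self.fwhm <= 60.0):
            raise ValueError(f"fwhm {self.fwhm} outside [4, 60] cm^-1")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        bad = set(self.class_effect) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown classes in class_effect: {sorted(bad)}")

    def amplitude_for(self, class_label: str) -> float:
        return self.base_amplitude * float(self.class_effect.get(class_label, 1.0))


@dataclass(frozen=True)
class EffectBand:
    """Ground-truth interval where a class effect was injected."""

    start_cm1: float
    end_cm1: float
    effect: float


# Vibrational bands of the lung-vs-control scenario.  Centers are the
# assigned discriminative fingerprint bands of that comparison
# (phenylalanine ring stretch at 1002, lipid C-C skeletal at 1068, nucleic
# acid/lipid modes at 1168/1198, CH2 twisting near 1310, C=O/CH2 at 1398,
# CH2 scissoring at 1432, olefinic C=C near 1558/1590), all carrying
# lung-cancer intensity effects of 1.3-1.6 so recovery tests can place
# truth where discrimination is expected.  Note that per-spectrum mean
# normalization closes the data (row means are forced to 1), so a
# class-neutral band would still pick up an anti-correlated closure
# effect and be flagged by VIP; the default scenario therefore carries
# effects on every band, matching the band table of that comparison.
def case1_peaks() -> list[PeakSpec]:
    eff = lambda f: {"lung_cancer": f}
    return [
        PeakSpec(1002.0, 10.0, 600.0, eff(1.5)),
        PeakSpec(1068.0, 12.0, 320.0, eff(1.4)),
        PeakSpec(1168.0, 14.0, 260.0, eff(1.35)),
        PeakSpec(1198.0, 14.0, 240.0, eff(1.3)),
        PeakSpec(1310.0, 18.0, 300.0, eff(1.45)),
        PeakSpec(1398.0, 14.0, 260.0, eff(1.35)),
        PeakSpec(1432.0, 14.0, 340.0, eff(1.5)),
        PeakSpec(1558.0, 12.0, 240.0, eff(1.3)),
        PeakSpec(1590.0, 14.0, 380.0, eff(1.6)),
    ]


# All-cancer-vs-control scenario: effects on the bands assigned in that
# comparison (protein modes at 887, amide III at 1222, purine wagging at
# 1325, amide I at 1655, ...), applied to both cancer classes.
def case2_peaks() -> list[PeakSpec]:
    eff = lambda f: {"lung_cancer": f, "other_cancer": f}
    return [
        PeakSpec(760.0, 14.0, 180.0),
        PeakSpec(887.0, 14.0, 240.0, eff(1.4)),
        PeakSpec(959.0, 14.0, 220.0, eff(1.35)),
        PeakSpec(1008.0, 10.0, 600.0, eff(1.5)),
        PeakSpec(1078.0, 12.0, 320.0, eff(1.4)),
        PeakSpec(1145.0, 25.0, 260.0, eff(1.3)),
        PeakSpec(1222.0, 16.0, 260.0, eff(1.35)),
        PeakSpec(1325.0, 16.0, 300.0, eff(1.45)),
        PeakSpec(1432.0, 14.0, 340.0),
        PeakSpec(1590.0, 14.0, 380.0),
        PeakSpec(1655.0, 20.0, 320.0, eff(1.4)),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``n_subjects_per_class`` is either an integer (same count for
    lung_cancer and control) or a mapping class label -> subject count;
    classes absent from the mapping get no subjects.  Defaults follow the
    mapping protocol the analysis assumes: 500 spectra per subject over 3
    substrate locations.
    """

    n_subjects_per_class: int | Mapping[str, int] = 10
    spectra_per_subject: int = 500
    n_locations: int = 3
    peaks: Sequence[PeakSpec] = field(default_factory=case1_peaks)
    baseline_amplitude: float = 2000.0
    noise_sd: float = 20.0
    spike_rate: float = 0.05
    subject_sd: float = 0.15
    seed: int = 0
    grid: np.ndarray = field(default_factory=lambda: CANONICAL_GRID.copy())

    def subject_counts(self) -> dict[str, int]:
        if isinstance(self.n_subjects_per_class, Mapping):
            counts = {k: int(v) for k, v in self.n_subjects_per_class.items() if v}
        else:
            n = int(self.n_subjects_per_class)
            counts = {"lung_cancer": n, "control": n}
        bad = set(counts) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown classes: {sorted(bad)}")
        return counts

    def __post_init__(self) -> None:
        for name in ("baseline_amplitude", "noise_sd", "spike_rate", "subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spectra_per_subject < 1 or self.n_locations < 1:
            raise ValueError("spectra_per_subject and n_locations must be >= 1")


def _baseline_curve(grid: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Broad autofluorescence background: sum of 3 wide Gaussians.

    Centers and widths are jittered per subject; widths stay >= 300 cm^-1
    fwhm so the background is always much broader than any Raman band.
    """
    if amplitude == 0:
        return np.zeros_like(grid)
    span = grid[-1] - grid[0]
    base = np.zeros_like(grid)
    centers = grid[0] + span * np.array([0.2, 0.55, 0.9])
    rel_amp = np.array([0.8, 1.0, 0.6])
    for c0, a0 in zip(centers, rel_amp):
        c = c0 + rng.normal(0.0, 40.0)
        fwhm = max(300.0, rng.normal(600.0, 80.0))
        sigma = fwhm / 2.3548200450309493
        a = amplitude * a0 * rng.uniform(0.8, 1.2)
        base += a * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return base


def _pure_signal(grid: np.ndarray, peaks: Sequence[PeakSpec], class_label: str) -> np.ndarray:
    sig = np.zeros_like(grid)
    for pk in peaks:
        sig += lorentzian(grid, pk.center, pk.fwhm, pk.amplitude_for(class_label))
    return sig


def effect_bands(peaks: Sequence[PeakSpec], classes: Sequence[str]) -> list[EffectBand]:
    """Ground-truth intervals (center +/- fwhm/2) where any class effect != 1."""
    bands = []
    for pk in peaks:
        effs = [pk.class_effect.get(c, 1.0) for c in classes]
        if any(e != 1.0 for e in effs):
            strongest = max(effs, key=lambda e: abs(e - 1.0))
            bands.append(EffectBand(pk.center - pk.fwhm / 2.0,
                                    pk.center + pk.fwhm / 2.0, strongest))
    return sorted(bands, key=lambda b: b.start_cm1)


def generate_dataset(config: SimConfig) -> tuple[SpectralDataset, list[EffectBand]]:
    """Generate a synthetic mapping dataset plus its ground-truth effect bands.

    For subject ``s`` of class ``c`` a log-normal gain ``g_s`` (log-sd
    ``subject_sd``) scales the Lorentzian mixture; each spectrum then adds a
    subject-jittered autofluorescence baseline, iid Gaussian noise and
    Poisson-distributed single-bin cosmic spikes of 10-50x the noise sd.
    Identical configs (including seed) give bit-identical output.
    """
    counts = config.subject_counts()
    if any(v < 2 for v in counts.values()):
        raise ValueError(
            "need >= 2 subjects per simulated class (cross-validation impossible otherwise)"
        )
    grid = np.asarray(config.grid, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(int(config.seed) % (2**31)))

    rows, subs, labels, locs, sids = [], [], [], [], []
    nspec = config.spectra_per_subject
    classes = sorted(counts)
    pure = {c: _pure_signal(grid, config.peaks, c) for c in classes}
    k = 0
    for c in classes:
        for j in range(counts[c]):
            subject = f"{c}_{j:02d}"
            gain = float(np.exp(rng.normal(0.0, config.subject_sd))) if config.subject_sd > 0 else 1.0
            base = _baseline_curve(grid, config.baseline_amplitude, rng)
            signal = gain * pure[c] + base
            block = np.tile(signal, (nspec, 1))
            if config.noise_sd > 0:
                block += rng.normal(0.0, config.noise_sd, size=(nspec, grid.size))
            if config.spike_rate > 0:
                nspk = rng.poisson(config.spike_rate, size=nspec)
                for i in np.nonzero(nspk)[0]:
                    pos = rng.integers(0, grid.size, size=nspk[i])
                    amp = rng.uniform(10.0, 50.0, size=nspk[i]) * max(config.noise_sd, 1.0)
                    block[i, pos] += amp
            rows.append(block)
            subs += [subject] * nspec
            labels += [c] * nspec
            # spectra are dealt across mapping locations round-robin
            locs += [1 + (i % config.n_locations) for i in range(nspec)]
            sids += [f"{subject}_m{i:04d}" for i in range(nspec)]
            k += 1

    dataset = SpectralDataset(
        grid=grid.copy(),
        X=np.vstack(rows),
        subject_ids=np.array(subs),
        class_labels=np.array(labels),
        location_index=np.array(locs, dtype=int),
        spectrum_ids=np.array(sids),
    )
    return dataset, effect_bands(config.peaks, classes)


# ---------------------------------------------------------------------------
# study roster fixture


def study_roster() -> pd.DataFrame:
    """Subject roster of the study cohort: 34 subjects.

    15 lung cancer; 7 other cancers (1 breast, 1 ovarian, 1 peritoneal,
    2 malignant mesothelioma, 1 multiple myeloma, 1 lymphoma); 12 controls
    (8 exudate, 4 transudate).  Columns: subject_id, class_label, condition.
    """
    path = Path(__file__).parent / "data" / "study_roster.csv"
    return pd.read_csv(path)
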