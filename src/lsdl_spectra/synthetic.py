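"""Synthetic FTIR-like cohort generator.

Spectra are sums of Gaussian absorbance peaks plus a small random linear
baseline and additive noise. The class effect is an amplitude shift applied
to the peaks whose base amplitude lies inside ``affected_band``, which plants
a recoverable amplitude-threshold boundary at the band's lower edge: below it
the spectra are dominated by common-mode clutter whose per-subject width
jitter makes features highly variable, above it only the class-shifted peak
survives. Subject-level randomness (amplitudes, widths, baseline, point
noise) defines the subject's "true" spectrum; acquisitions add independent
replicate jitter on top, so replicate averaging reduces exactly that jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .spectra_io import SpectraDataset, Spectrum

__all__ = [
    "default_grid",
    "CohortSpec",
    "EffectSpec",
    "generate_spectrum",
    "generate_cohort",
    "generate_grade_cohort",
    "null_effect",
]

POSITIVE_LABELS = {"cancer", "high_grade"}

# Study cohort structure: 31 noncancer + 22 cancer; Gleason 4/5/13.
DEFAULT_GLEASON_COUNTS = {"GS<7": 4, "GS=7": 5, "GS>7": 13}
_GLEASON_VALUE = {"GS<7": 6, "GS=7": 7, "GS>7": 9}


def default_grid(start: float = 4000.0, stop: float = 650.0, step: float = 8.0) -> np.ndarray:
    """Descending wavenumber axis. The 8 cm^-1 default keeps runs desk-scale;
    pass step=2 for instrument-like resolution."""
    if step <= 0 or start <= stop:
        raise ValidationError("need start > stop and step > 0")
    return np.arange(start, stop, -step)


@dataclass
class CohortSpec:
    """Cohort sizes mirroring the study: 31 noncancer + 22 cancer subjects."""

    n_noncancer: int = 31
    n_cancer: int = 22
    gleason_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GLEASON_COUNTS)
    )
    grid: np.ndarray = field(default_factory=default_grid)
    seed: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.n_noncancer < 0 or self.n_cancer < 0:
            raise ValidationError("cohort sizes must be nonnegative")
        if self.gleason_counts and sum(self.gleason_counts.values()) != self.n_cancer:
            raise ValidationError(
                "gleason_counts must sum to n_cancer "
                f"({sum(self.gleason_counts.values())} != {self.n_cancer})"
            )

    def gleason_values(self) -> list[int]:
        vals: list[int] = []
        for group, cnt in self.gleason_counts.items():
            if group not in _GLEASON_VALUE:
                raise ValidationError(f"unknown Gleason group {group!r}")
            vals.extend([_GLEASON_VALUE[group]] * cnt)
        return vals


@dataclass
class EffectSpec:
    """Shape of the synthetic spectra and of the planted class effect.

    Peak positions are plausible biofluid bands (lipid ~2925, amide I ~1650,
    amide II ~1540, carbohydrate ~1080 cm^-1) — configuration, not science.
    Peaks with base amplitude strictly inside ``affected_band`` receive
    ``class_shift`` for positive-class subjects; the clutter peak at exactly
    the band's lower edge gets per-subject width jitter instead, making the
    edge the recoverable threshold.
    """

    peak_centers: tuple[float, ...] = (2925.0, 1650.0, 1400.0, 1080.0)
    base_amplitudes: tuple[float, ...] = (1.9, 2.09, 1.6, 1.75)
    peak_widths: tuple[float, ...] = (150.0, 120.0, 50.0, 50.0)
    class_shift: float = 0.5
    affected_band: tuple[float, float] = (2.0, 3.5)
    noise_sd: float = 0.005
    baseline: tuple[tuple[float, float], tuple[float, float]] = (
        (-2e-5, 2e-5),  # slope range (a.u. per cm^-1)
        (0.0, 0.01),  # intercept range (a.u.)
    )
    replicate_jitter_sd: float = 0.01
    amplitude_jitter_sd: float = 0.2  # unaffected peaks only
    width_jitter_frac: float = 0.4  # unaffected peaks only
    # band substructure on the affected peaks: keeps their sub-signals
    # textured enough for template-match features to stay defined
    ripple_frac: float = 0.12
    ripple_period: float = 64.0  # cm^-1
    clutter_margin: float = 0.05  # clutter saturates this far below the floor

    def __post_init__(self):
        k = len(self.peak_centers)
        if not (len(self.base_amplitudes) == len(self.peak_widths) == k):
            raise ValidationError("peak parameter tuples must share length")
        if any(w <= 0 for w in self.peak_widths):
            raise ValidationError("peak widths must be positive")
        if self.noise_sd < 0 or self.replicate_jitter_sd < 0:
            raise ValidationError("noise levels must be nonnegative")
        lo, hi = self.affected_band
        if not lo < hi:
            raise ValidationError("affected_band must satisfy lo < hi")

    def affected_mask(self) -> np.ndarray:
        lo, hi = self.affected_band
        amps = np.asarray(self.base_amplitudes)
        return (amps > lo) & (amps <= hi)


def null_effect(**overrides) -> EffectSpec:
    """EffectSpec with the class effect removed (both classes one distribution)."""
    return EffectSpec(class_shift=0.0, **overrides)


def _subject_truth(
    effect: EffectSpec, label: str | None, grid: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    amps = np.asarray(effect.base_amplitudes, dtype=float).copy()
    widths = np.asarray(effect.peak_widths, dtype=float).copy()
    affected = effect.affected_mask()
    if label in POSITIVE_LABELS:
        amps[affected] += effect.class_shift
    # clutter variability on unaffected peaks only; their profiles saturate
    # at the band floor (below) so the class effect stays confined to the band
    clip_level = effect.affected_band[0] - effect.clutter_margin
    amps[~affected] = amps[~affected] * (
        1 + rng.normal(0, effect.amplitude_jitter_sd, size=int((~affected).sum()))
    )
    widths[~affected] = widths[~affected] * (
        1 + rng.uniform(
            -effect.width_jitter_frac, effect.width_jitter_frac,
            size=int((~affected).sum()),
        )
    )
    widths = np.clip(widths, 1e-3, None)
    y = np.zeros_like(grid)
    for c, a, w, is_affected in zip(effect.peak_centers, amps, widths, affected):
        peak = a * np.exp(-0.5 * ((grid - c) / w) ** 2)
        if is_affected:
            if effect.ripple_frac > 0:
                peak = peak * (
                    1
                    + effect.ripple_frac
                    * np.cos(2 * np.pi * (grid - c) / effect.ripple_period)
                )
        else:
            peak = np.minimum(peak, clip_level)  # common-mode saturates below the floor
        y += peak
    (slope_lo, slope_hi), (int_lo, int_hi) = effect.baseline
    slope = rng.uniform(slope_lo, slope_hi)
    intercept = rng.uniform(int_lo, int_hi)
    y += slope * (grid - grid.mean()) + intercept
    y += rng.normal(0, effect.noise_sd, size=grid.size) if effect.noise_sd > 0 else 0.0
    return np.clip(y, 0.0, None)


def generate_spectrum(
    effect: EffectSpec,
    label: str | None,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    sample_id: str = "synthetic",
) -> Spectrum:
    """One subject-level spectrum (no acquisition jitter)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    y = _subject_truth(effect, label, grid, rng)
    return Spectrum(
        sample_id=sample_id,
        wavenumbers=grid,
        intensities=y,
        label=label,
        acquisition_mode="synthetic",
    )


def _build_pair(
    labels: list[str],
    gleason: list[int | None],
    effect: EffectSpec,
    grid: np.ndarray,
    rng: np.random.Generator,
    replicates: int,
    name_prefix: str,
) -> tuple[SpectraDataset, SpectraDataset]:
    averaged, single = [], []
    for i, (label, gs) in enumerate(zip(labels, gleason)):
        sid = f"subj-{i:03d}"
        truth = _subject_truth(effect, label, grid, rng)
        acqs = [
            np.clip(
                truth + rng.normal(0, effect.replicate_jitter_sd, size=grid.size)
                if effect.replicate_jitter_sd > 0
                else truth.copy(),
                0.0,
                None,
            )
            for _ in range(replicates)
        ]
        mean = np.mean(acqs, axis=0)
        averaged.append(
            Spectrum(sid, grid, mean, label=label, acquisition_mode="averaged",
                     gleason=gs, source=f"{name_prefix}1")
        )
        single.append(
            Spectrum(sid, grid, acqs[0], label=label, acquisition_mode="single",
                     gleason=gs, source=f"{name_prefix}2")
        )
    return (
        SpectraDataset(averaged, name=f"{name_prefix}1"),
        SpectraDataset(single, name=f"{name_prefix}2"),
    )


def generate_cohort(
    cohort: CohortSpec,
    effect: EffectSpec | None = None,
    replicates: int = 3,
) -> tuple[SpectraDataset, SpectraDataset]:
    """Cancer/noncancer cohort as two acquisition variants of the same subjects.

    Returns ``(dataset1, dataset2)``: per-subject replicate average and the
    first single acquisition, both carrying the same labels.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(cohort.seed)
    labels = ["noncancer"] * cohort.n_noncancer + ["cancer"] * cohort.n_cancer
    gleason: list[int | None] = [None] * cohort.n_noncancer + list(
        cohort.gleason_values()
    )
    return _build_pair(labels, gleason, effect, cohort.grid, rng, replicates, "dataset")


def grade_label(gleason: int) -> str:
    """Grouping rule: GS <= 7 is low grade, GS > 7 is high grade."""
    return "low_grade" if gleason <= 7 else "high_grade"


def generate_grade_cohort(
    cohort: CohortSpec,
    effect_low: EffectSpec | None = None,
    effect_high: EffectSpec | None = None,
    replicates: int = 3,
) -> tuple[SpectraDataset, SpectraDataset]:
    """Cancer-only cohort relabeled by Gleason grouping (GS<=7 vs GS>7).

    Returns the (averaged, single-acquisition) dataset pair, mirroring
    :func:`generate_cohort`.
    """
    if not cohort.gleason_counts:
        raise ValidationError("grade cohort requires gleason_counts")
    effect_low = effect_low or null_effect()
    effect_high = effect_high or EffectSpec()
    rng = np.random.default_rng(cohort.seed + 1)
    gleason = cohort.gleason_values()
    labels = [grade_label(g) for g in gleason]
    # one subject stream; the per-subject effect spec depends on the grade
    averaged, single = [], []
    grid = cohort.grid
    for i, (label, gs) in enumerate(zip(labels, gleason)):
        eff = effect_high if label == "high_grade" else effect_low
        sid = f"grade-subj-{i:03d}"
        truth = _subject_truth(eff, label, grid, rng)
        acqs = [
            np.clip(
                truth + rng.normal(0, eff.replicate_jitter_sd, size=grid.size)
                if eff.replicate_jitter_sd > 0
                else truth.copy(),
                0.0,
                None,
            )
            for _ in range(replicates)
        ]
        mean = np.mean(acqs, axis=0)
        averaged.append(
            Spectrum(sid, grid, mean, label=label, acquisition_mode="averaged",
                     gleason=gs, source="grade_dataset1")
        )
        single.append(
            Spectrum(sid, grid, acqs[0], label=label, acquisition_mode="single",
                     gleason=gs, source="grade_dataset2")
        )
    return (
        SpectraDataset(averaged, name="grade_dataset1"),
        SpectraDataset(single, name="grade_dataset2"),
    )
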