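"""Synthetic data generators with known ground truth.

Three generators emulate the study's data modalities so every analysis
stage can be validated without the original recordings or repository
downloads:

* :func:`generate_cilia_video` — video stacks in which masked regions
  beat as additive sinusoids of known frequency (phase jitter models
  imperfect metachrony across pixels) on a noisy background;
* :func:`generate_longitudinal` — tidy endpoint tables from a paired
  smoke/air design with compound-symmetry residual covariance across
  days (equal variance, equal pairwise correlation within a culture);
* :func:`generate_two_cohort_expression` — an in vitro cohort (paired
  air/smoke donors) and an in vivo cohort (smokers vs non-smokers)
  sharing a deregulated signature, separated by a per-transcript additive
  platform offset, with a configurable fraction of signature transcripts
  whose in vivo direction is flipped.

All generators take an explicit integer seed and are bit-reproducible;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cilia import FrequencyMap, VideoStack
from .expression import ExpressionMatrix

__all__ = [
    "CiliaRegion",
    "CiliaVideoSpec",
    "LongitudinalSpec",
    "TwoCohortExpressionSpec",
    "generate_cilia_video",
    "generate_longitudinal",
    "generate_two_cohort_expression",
]


@dataclass(frozen=True)
class CiliaRegion:
    """A contiguous patch of beating cilia: boolean mask + signal parameters."""

    mask: np.ndarray  # (H, W) bool
    frequency: float  # Hz
    amplitude: float  # intensity units
    phase_jitter_sd: float = 0.0  # radians, per-pixel phase spread


@dataclass(frozen=True)
class CiliaVideoSpec:
    height: int = 100
    width: int = 100
    n_frames: int = 512
    fps: float = 30.0
    regions: tuple[CiliaRegion, ...] = ()
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ValueError(f"n_frames must be >= 64, got {self.n_frames}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "regions", tuple(self.regions))
        for i, region in enumerate(self.regions):
            if region.frequency >= self.fps / 2:
                raise ValueError(
                    f"region {i}: frequency {region.frequency} Hz is at or above the "
                    f"Nyquist limit {self.fps / 2} Hz for {self.fps} fps"
                )
            mask = np.asarray(region.mask, dtype=bool)
            if mask.shape != (self.height, self.width):
                raise ValueError(
                    f"region {i}: mask shape {mask.shape} does not fit the "
                    f"{self.height}x{self.width} field of view"
                )


def generate_cilia_video(spec: CiliaVideoSpec) -> tuple[VideoStack, FrequencyMap]:
    """Render a video stack and its ground-truth frequency map.

    Every pixel inside a region follows ``background + amplitude *
    sin(2*pi*f*t/fps + phase)`` with a per-pixel phase drawn from
    ``N(0, phase_jitter_sd)``; pixels outside all regions carry no
    periodic component.  Gaussian noise of sd ``noise_sd`` is added to
    every sample.  Overlapping regions are applied in order, later
    regions replacing earlier ones.  The ground truth records each
    pixel's true frequency (NaN = inactive).
    """
    rng = np.random.default_rng(spec.seed)
    T, H, W = spec.n_frames, spec.height, spec.width
    t = np.arange(T) / spec.fps
    frames = np.full((T, H, W), float(spec.background_level))
    truth = np.full((H, W), np.nan)
    for region in spec.regions:
        mask = np.asarray(region.mask, dtype=bool)
        ys, xs = np.nonzero(mask)
        phases = rng.normal(0.0, region.phase_jitter_sd, size=ys.size)
        signal = region.amplitude * np.sin(
            2 * np.pi * region.frequency * t[:, None] + phases[None, :]
        )
        frames[:, ys, xs] = spec.background_level + signal
        truth[ys, xs] = region.frequency
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    return VideoStack(frames=frames, fps=spec.fps), FrequencyMap(values=truth, fps=spec.fps)


@dataclass(frozen=True)
class LongitudinalSpec:
    """Paired smoke/air longitudinal design with compound symmetry.

    ``mean_curves`` maps (group, treatment) to the per-day mean values;
    each subject receives both treatments (paired design).  The residual
    vector of each series is equicorrelated across days with correlation
    ``within_subject_correlation`` and marginal sd ``residual_sd``, on top
    of a subject-level random intercept of sd ``subject_sd`` shared by
    both of the subject's series.
    """

    n_subjects_per_group: int = 3
    groups: tuple[str, ...] = ("HC", "COPD")
    treatments: tuple[str, str] = ("CS", "Air")
    days: tuple[float, ...] = (7.0, 14.0, 21.0, 28.0)
    subject_sd: float = 1.0
    residual_sd: float = 1.0
    within_subject_correlation: float = 0.5
    mean_curves: dict = field(default_factory=dict)  # (group, treatment) -> per-day means
    endpoint: str = "endpoint"
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if len(days) == 0:
            raise ValueError("days must be non-empty")
        if not all(b > a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if not 0 <= self.within_subject_correlation < 1:
            raise ValueError("within_subject_correlation must lie in [0, 1)")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        object.__setattr__(self, "days", days)
        for g in self.groups:
            for tr in self.treatments:
                curve = np.asarray(self.mean_curves.get((g, tr), np.zeros(len(days))), float)
                if curve.shape != (len(days),):
                    raise ValueError(f"mean curve for {(g, tr)} must have {len(days)} entries")


def generate_longitudinal(spec: LongitudinalSpec) -> pd.DataFrame:
    """Tidy table (subject, group, treatment, endpoint, day, value).

    Residual draws use the equicorrelated decomposition ``residual_sd *
    (sqrt(rho) * z_shared + sqrt(1 - rho) * z_day)``, giving marginal
    variance ``residual_sd**2`` and between-day correlation ``rho``.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days)
    n_days = days.size
    rho = spec.within_subject_correlation
    records = []
    for group in spec.groups:
        for s in range(spec.n_subjects_per_group):
            subject = f"{group}_{s + 1}"
            b = rng.normal(0.0, spec.subject_sd)
            for treatment in spec.treatments:
                means = np.asarray(spec.mean_curves.get((group, treatment), np.zeros(n_days)), float)
                z_shared = rng.normal()
                z_day = rng.normal(size=n_days)
                resid = spec.residual_sd * (np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_day)
                values = means + b + resid
                for d, v in zip(days, values):
                    records.append((subject, group, treatment, spec.endpoint, d, v))
    return pd.DataFrame(
        records, columns=["subject", "group", "treatment", "endpoint", "day", "value"]
    )


@dataclass(frozen=True)
class TwoCohortExpressionSpec:
    """Two expression cohorts sharing a deregulated signature.

    The in vitro cohort is paired (each donor contributes one air and one
    smoke sample); the in vivo cohort is unpaired (smokers vs
    non-smokers).  Signature transcripts are shifted by ``effect_size``
    (sign drawn per transcript) in exposed samples of both cohorts, with
    ``discordant_fraction`` of them flipped in the in vivo cohort.  A
    per-transcript constant offset of sd ``platform_shift_sd`` separates
    the cohorts; per-dataset min-max normalization removes it exactly.
    """

    n_transcripts: int = 500
    n_signature: int = 50
    effect_size: float = 2.0  # log2-fold-change units
    invitro_donors: int = 3
    invivo_smokers: int = 20
    invivo_nonsmokers: int = 20
    platform_shift_sd: float = 2.0
    donor_effect_sd: float = 1.0
    noise_sd: float = 0.5
    discordant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature > self.n_transcripts:
            raise ValueError("n_signature cannot exceed n_transcripts")
        if not 0 <= self.discordant_fraction <= 1:
            raise ValueError("discordant_fraction must lie in [0, 1]")
        if min(self.invitro_donors, self.invivo_smokers, self.invivo_nonsmokers) < 2:
            raise ValueError("need at least two donors/subjects per cohort arm")


def generate_two_cohort_expression(
    spec: TwoCohortExpressionSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Generate (in vitro matrix, in vivo matrix, truth table).

    The truth table is indexed by transcript id with columns
    ``is_signature``, ``direction_invitro`` and ``direction_invivo``
    (+1 / -1 for signature transcripts, 0 otherwise).
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_transcripts
    ids = [f"TX{i + 1:05d}" for i in range(m)]
    baseline = rng.normal(8.0, 2.0, size=m)
    sig_idx = np.sort(rng.choice(m, size=spec.n_signature, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_signature)
    n_flip = int(round(spec.discordant_fraction * spec.n_signature))
    flip_idx = rng.choice(spec.n_signature, size=n_flip, replace=False)
    flip = np.ones(spec.n_signature)
    flip[flip_idx] = -1.0

    direction_invitro = np.zeros(m)
    direction_invitro[sig_idx] = signs
    direction_invivo = np.zeros(m)
    direction_invivo[sig_idx] = signs * flip

    # --- in vitro: paired air/smoke per donor -----------------------------
    samples_iv = []
    columns_iv = {}
    meta_iv = []
    for d in range(spec.invitro_donors):
        donor = f"donor{d + 1}"
        donor_effect = rng.normal(0.0, spec.donor_effect_sd, size=m)
        for condition in ("air", "smoke"):
            name = f"IV_{donor}_{condition}"
            x = baseline + donor_effect + rng.normal(0.0, spec.noise_sd, size=m)
            if condition == "smoke":
                x = x + direction_invitro * spec.effect_size
            columns_iv[name] = x
            meta_iv.append((name, "invitro", condition, donor))
    invitro = ExpressionMatrix(
        values=pd.DataFrame(columns_iv, index=ids),
        metadata=pd.DataFrame(
            meta_iv, columns=["sample", "cohort", "condition", "donor"]
        ).set_index("sample"),
    )

    # --- in vivo: unpaired smokers vs non-smokers, platform-shifted -------
    platform = rng.normal(0.0, spec.platform_shift_sd, size=m)
    columns_vv = {}
    meta_vv = []
    for condition, count in (("nonsmoker", spec.invivo_nonsmokers), ("smoker", spec.invivo_smokers)):
        for s in range(count):
            name = f"VV_{condition}{s + 1}"
            x = baseline + platform + rng.normal(0.0, spec.noise_sd, size=m)
            if condition == "smoker":
                x = x + direction_invivo * spec.effect_size
            columns_vv[name] = x
            meta_vv.append((name, "invivo", condition, name))
    invivo = ExpressionMatrix(
        values=pd.DataFrame(columns_vv, index=ids),
        metadata=pd.DataFrame(
            meta_vv, columns=["sample", "cohort", "condition", "donor"]
        ).set_index("sample"),
    )

    truth = pd.DataFrame(
        {
            "is_signature": direction_invitro != 0,
            "direction_invitro": direction_invitro.astype(int),
            "direction_invivo": direction_invivo.astype(int),
        },
        index=pd.Index(ids, name="transcript"),
    )
    return invitro, invivo, truth
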