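"""Synthetic signals and cohorts with known fractal structure.

Two layers of ground truth make every pipeline stage testable without any
recorded EEG:

* **Signals.**  Fractional Brownian motion (fBm) with Hurst exponent H has
  a graph of fractal dimension exactly ``2 - H``, so fBm paths provide an
  analytic target for the Higuchi estimator.  Paths are synthesised by
  circulant embedding (Davies–Harte): fractional Gaussian noise with the
  exact autocovariance, cumulated to fBm.  Ramps, constants, sines and
  white noise cover the degenerate and limiting cases.

* **Cohorts.**  ``make_cohort`` draws a three-group cohort — young
  controls (YC), elderly controls (EC) and Alzheimer's patients (AD) —
  whose per-channel fractal dimensions follow a known generative model:
  an inverted-U dependence of whole-brain FD on age peaking near 60,
  an extra ageing decline in central/parietal channels with a steeper
  right-parietal slope, a temporo-occipital deficit in AD, MMSE coupled
  positively and non-ceruloplasmin copper (NCC) negatively to FD.  The
  fast path emits per-channel FD values directly; the slow path renders
  each channel as an fBm recording with ``H = 2 - FD`` and exercises the
  full signal pipeline.  All draws are deterministic given the seed, and
  the generating parameters are returned so recovery tests can check the
  analysis against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .preprocessing import EEGRecording, MONTAGE_19
from .regions import GENERATOR_REGION_OF_CHANNEL

__all__ = [
    "SignalSpec",
    "CohortSpec",
    "SyntheticCohort",
    "fractional_gaussian_noise",
    "fractional_brownian_motion",
    "make_signal",
    "make_recording",
    "make_cohort",
]


def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-covariance fGn of length ``n`` via circulant embedding.

    The autocovariance ``g(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})``
    is embedded in a circulant matrix of order 2n whose eigenvalues are the
    FFT of its first row; these are non-negative for all H in (0, 1), so a
    complex-Gaussian draw in the eigenbasis yields two independent exact
    samples, of which one is returned.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst={hurst} must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    # pad the embedding until the circulant eigenvalues are non-negative
    half = max(n, 2)
    for _ in range(12):
        k = np.arange(half + 1, dtype=float)
        g = 0.5 * (
            (k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst)
        )
        row = np.concatenate([g, g[-2:0:-1]])  # length 2*half
        lam = np.fft.fft(row).real
        if lam.min() > -1e-9 * lam.max():
            break
        half *= 2
    lam = np.clip(lam, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(z * np.sqrt(lam / m))
    return w.real[:n]


def fractional_brownian_motion(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """fBm path of ``n`` samples starting at 0: cumulated exact fGn."""
    return np.cumsum(fractional_gaussian_noise(n, hurst, rng))


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one test signal.

    ``kind`` is one of ``fbm`` (requires ``hurst``), ``white_noise``,
    ``ramp``, ``constant``, ``sine``; ``seed`` is mandatory for the
    stochastic kinds.
    """

    kind: Literal["fbm", "white_noise", "ramp", "constant", "sine"]
    n_samples: int
    fs: float = 128.0
    hurst: float | None = None
    seed: int | None = None
    frequency_hz: float = 10.0  # sine only
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.kind == "fbm":
            if self.hurst is None:
                raise ValueError("fbm requires a hurst exponent")
            if not 0.0 < self.hurst < 1.0:
                raise ValueError(f"hurst={self.hurst} must lie in (0, 1)")
        if self.kind in ("fbm", "white_noise") and self.seed is None:
            raise ValueError(f"kind={self.kind!r} requires a seed")


def make_signal(spec: SignalSpec) -> np.ndarray:
    """Render a :class:`SignalSpec` to a sample array (deterministic)."""
    n = spec.n_samples
    if spec.kind == "ramp":
        return spec.amplitude * np.arange(n, dtype=float)
    if spec.kind == "constant":
        return np.full(n, spec.amplitude, dtype=float)
    if spec.kind == "sine":
        t = np.arange(n) / spec.fs
        return spec.amplitude * np.sin(2 * np.pi * spec.frequency_hz * t)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white_noise":
        return spec.amplitude * rng.standard_normal(n)
    if spec.kind == "fbm":
        return spec.amplitude * fractional_brownian_motion(n, spec.hurst, rng)
    raise ValueError(f"unknown signal kind {spec.kind!r}")


FD_TARGET_RANGE = (1.05, 1.95)


def make_recording(
    per_channel_fd: dict[str, float],
    duration_s: float,
    fs: float = 128.0,
    seed: int | None = 0,
    subject_id: str = "synthetic",
) -> EEGRecording:
    """19-channel synthetic recording with per-channel target FD.

    Each channel is an independent fBm path with ``hurst = 2 - target``;
    targets must lie in [1.05, 1.95] so the Hurst exponent stays away from
    the estimator's saturation boundaries.  Channel labels must belong to
    the standard 19-channel montage.
    """
    lo, hi = FD_TARGET_RANGE
    for ch, fd in per_channel_fd.items():
        if ch not in MONTAGE_19:
            raise ValueError(f"unknown channel label {ch!r}")
        if not lo <= fd <= hi:
            raise ValueError(f"target FD {fd} for {ch} outside [{lo}, {hi}]")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    labels = [ch for ch in MONTAGE_19 if ch in per_channel_fd]
    data = np.stack(
        [
            fractional_brownian_motion(n, 2.0 - per_channel_fd[ch], rng)
            for ch in labels
        ]
    )
    return EEGRecording(data=data, fs=fs, channel_labels=labels, subject_id=subject_id)


# --- cohort generation -----------------------------------------------------

#: Table-style group descriptives used as simulation defaults:
#: (size, mean age, age SD, age range, M/F counts)
_GROUP_AGE = {
    "YC": (24, 30.3, 7.52, (20.0, 50.0), (10, 14)),
    "EC": (17, 69.5, 9.46, (51.0, 85.0), (6, 11)),
    "AD": (67, 73.0, 8.58, (50.0, 88.0), (21, 46)),
}


@dataclass
class CohortSpec:
    """Generative model for a synthetic three-group cohort.

    The defaults encode the study conditions the analysis is meant to
    recover: an inverted-U whole-brain FD-age curve with vertex at 60
    years, an ageing decline confined to central/parietal channels that is
    steeper over the right parietal scalp, a temporo-occipital FD deficit
    plus a small global deficit in AD, MMSE coupled positively and NCC
    coupled negatively to the subject's FD.  Units: FD is dimensionless,
    age in years, MMSE in points, copper in umol/L, ceruloplasmin in mg/dL.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: v[0] for g, v in _GROUP_AGE.items()}
    )
    # whole-brain FD vs age: fd = peak_fd - curvature * (age - vertex_age)^2
    peak_fd: float = 1.945
    curvature: float = 2.0e-5
    vertex_age: float = 60.0
    subject_noise_sd: float = 0.008
    channel_noise_sd: float = 0.006
    # ageing decline on central+parietal channels, per year past vertex age
    central_parietal_ageing_slope: float = 4.0e-4
    # extra right-parietal decline per year of age past 20 (drives HArS-age)
    right_parietal_ageing_slope: float = 2.5e-4
    # AD deficits (FD units)
    ad_global_delta: float = -0.015
    ad_temporo_occipital_delta: float = -0.030
    # MMSE model: group mean/SD plus positive coupling to whole-brain FD
    mmse_mean: dict[str, float] = field(default_factory=lambda: {"EC": 27.6, "AD": 20.6})
    mmse_sd: dict[str, float] = field(default_factory=lambda: {"EC": 1.3, "AD": 4.0})
    mmse_fd_coupling: float = 160.0  # MMSE points per FD unit
    # copper model: ceruloplasmin mg/dL, NCC umol/L with negative coupling
    # to parietal FD; serum copper is emitted as CB + NCC so the pipeline's
    # own biochemistry reproduces NCC.
    ceruloplasmin_mean: dict[str, float] = field(
        default_factory=lambda: {"EC": 28.0, "AD": 26.0}
    )
    ceruloplasmin_sd: float = 4.0
    ncc_mean: dict[str, float] = field(default_factory=lambda: {"EC": 1.7, "AD": 3.2})
    ncc_sd: dict[str, float] = field(default_factory=lambda: {"EC": 0.9, "AD": 1.4})
    ncc_fd_coupling: float = -45.0  # umol/L per FD unit of parietal deviation
    seed: int = 0

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """A spec with every systematic effect zeroed (type-I error runs)."""
        return cls(
            curvature=0.0,
            central_parietal_ageing_slope=0.0,
            right_parietal_ageing_slope=0.0,
            ad_global_delta=0.0,
            ad_temporo_occipital_delta=0.0,
            mmse_fd_coupling=0.0,
            ncc_fd_coupling=0.0,
            seed=seed,
            **overrides,
        )


@dataclass
class SyntheticCohort:
    """Output bundle of :func:`make_cohort` — self-describing fixtures."""

    covariates: pd.DataFrame  # one row per subject
    channel_hfd: pd.DataFrame  # subjects x channels (fast-path FD values)
    true_targets: pd.DataFrame  # generating per-channel FD targets
    spec: CohortSpec
    recordings: dict[str, EEGRecording] | None = None

    def generating_parameters(self) -> dict:
        return asdict(self.spec)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                out[i] = v
                break
        else:
            out[i] = float(np.clip(mean, lo, hi))
    return out


def _channel_targets(
    spec: CohortSpec, age: float, group: str, rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-channel FD targets: (noisy draw, deterministic prediction)."""
    subject_shift = rng.normal(0.0, spec.subject_noise_sd)
    targets: dict[str, float] = {}
    expected: dict[str, float] = {}
    for ch in MONTAGE_19:
        fd = spec.peak_fd - spec.curvature * (age - spec.vertex_age) ** 2
        region, hemi = GENERATOR_REGION_OF_CHANNEL[ch]
        if region in ("central", "parietal"):
            fd -= spec.central_parietal_ageing_slope * max(0.0, age - spec.vertex_age)
        if region == "parietal" and hemi == "right":
            fd -= spec.right_parietal_ageing_slope * max(0.0, age - 20.0)
        if group == "AD":
            fd += spec.ad_global_delta
            if region in ("temporal", "occipital"):
                fd += spec.ad_temporo_occipital_delta
        expected[ch] = float(fd)
        targets[ch] = float(fd + subject_shift + rng.normal(0.0, spec.channel_noise_sd))
    return targets, expected


def make_cohort(
    spec: CohortSpec | None = None,
    *,
    emit_recordings: bool = False,
    duration_s: float = 60.0,
    fs: float = 128.0,
) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``spec`` (deterministic per seed).

    The fast path stores the generated per-channel FD values directly in
    ``channel_hfd`` (these are the analysis inputs for every statistics
    test).  With ``emit_recordings=True`` each subject is also rendered as
    a multichannel fBm recording whose per-channel Hurst exponents encode
    the same targets (clipped to the invertible range), so the estimator
    stage can be exercised end to end; ``duration_s`` keeps that path
    affordable.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = FD_TARGET_RANGE
    cov_rows, fd_rows, tgt_rows = [], [], []
    recordings: dict[str, EEGRecording] = {}
    for group, n_g in spec.group_sizes.items():
        if group not in _GROUP_AGE:
            raise ValueError(f"unknown group {group!r}")
        _, age_mu, age_sd, (age_lo, age_hi), (n_m, n_f) = _GROUP_AGE[group]
        ages = _truncated_normal(rng, age_mu, age_sd, age_lo, age_hi, n_g)
        p_male = n_m / (n_m + n_f)
        for j in range(n_g):
            sid = f"{group}{j + 1:03d}"
            age = float(ages[j])
            targets, expected = _channel_targets(spec, age, group, rng)
            fd_obs = dict(targets)
            parietal_chs = [
                ch for ch, (r, _) in GENERATOR_REGION_OF_CHANNEL.items()
                if r == "parietal"
            ]
            # subject deviations from the deterministic prediction drive the
            # MMSE / NCC couplings, keeping the group means on target
            wb_dev = float(np.mean(list(fd_obs.values()))) - float(
                np.mean(list(expected.values()))
            )
            parietal_dev = float(np.mean([fd_obs[c] for c in parietal_chs])) - float(
                np.mean([expected[c] for c in parietal_chs])
            )
            row: dict = {
                "subject_id": sid,
                "group": group,
                "age": round(age, 1),
                "sex": "M" if rng.random() < p_male else "F",
                "education_years": float(
                    np.clip(rng.normal(13.0 if group == "YC" else 9.2, 4.5), 3, 22)
                ),
            }
            if group in spec.mmse_mean:
                mmse = (
                    spec.mmse_mean[group]
                    + spec.mmse_fd_coupling * wb_dev
                    + rng.normal(0.0, spec.mmse_sd[group])
                )
                bounds = (24, 30) if group == "EC" else (5, 24)
                row["mmse"] = int(np.clip(round(mmse), *bounds))
                cp = max(5.0, rng.normal(spec.ceruloplasmin_mean[group], spec.ceruloplasmin_sd))
                ncc = (
                    spec.ncc_mean[group]
                    + spec.ncc_fd_coupling * parietal_dev
                    + rng.normal(0.0, spec.ncc_sd[group])
                )
                cb = cp * 10.0 * 0.0472
                row["ceruloplasmin_mg_dl"] = round(cp, 2)
                row["serum_copper_umol_l"] = round(cb + ncc, 3)
            else:
                row["mmse"] = np.nan
                row["ceruloplasmin_mg_dl"] = np.nan
                row["serum_copper_umol_l"] = np.nan
            cov_rows.append(row)
            fd_rows.append({"subject_id": sid, **fd_obs})
            tgt_rows.append({"subject_id": sid, **targets})
            if emit_recordings:
                clipped = {ch: float(np.clip(v, lo, hi)) for ch, v in targets.items()}
                recordings[sid] = make_recording(
                    clipped,
                    duration_s=duration_s,
                    fs=fs,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject_id=sid,
                )
    covariates = pd.DataFrame(cov_rows).set_index("subject_id")
    channel_hfd = pd.DataFrame(fd_rows).set_index("subject_id")
    true_targets = pd.DataFrame(tgt_rows).set_index("subject_id")
    return SyntheticCohort(
        covariates=covariates,
        channel_hfd=channel_hfd,
        true_targets=true_targets,
        spec=spec,
        recordings=recordings or None,
    )
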