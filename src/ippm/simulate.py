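"""Synthetic-data generation and ground-truth recovery experiments.

Two tiers of synthesis are provided:

*Expression level* — :func:`simulate_expression` emits significant
expression points directly: for every ground-truth transform, a cloud
of per-source points with Gaussian latency jitter (σ = 10 ms by
default), surprisals decaying with jitter so the focus tends to the
true latency, plus optional spurious points.  Cheap, and exact control
over noise.

*Signal level* — :func:`simulate_recordings` synthesizes band-passed
(5–100 Hz) white-noise computational signals, inserts them into generic
recording channels at jittered latencies together with competing
signals (500 insertions = 10 each of 50 random signals, uniform 0–500 ms
latencies) and additive measurement noise, and
:func:`detect_expression` recovers expression points by lagged
correlation against each candidate signal with a spectrum-aware null.
The anatomical forward model of a real M/EEG simulation is deliberately
replaced by a one-hot source-to-channel assignment: channels are
generic sensors, and absolute source amplitudes become a dimensionless
``relative_strength`` in [0, 1] of the competing sources' unit
amplitude.

:func:`strength_sweep` runs the full recover-and-evaluate pipeline over
a grid of relative signal strengths with fresh re-randomization of
source assignment and jitter per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .denoise import denoise_expression
from .expression import (
    CandidateTransformList,
    ExpressionPoint,
    ExpressionSet,
    ParameterError,
    corrected_threshold_logp,
)
from .graph import build_ippm
from .metrics import causality_violation, transform_recall

__all__ = [
    "GroundTruthTransform",
    "GroundTruthIPPM",
    "three_stream_preset",
    "SimConfig",
    "simulate_expression",
    "generate_bandpassed_signal",
    "simulate_recordings",
    "detect_expression",
    "strength_sweep",
]


@dataclass(frozen=True)
class GroundTruthTransform:
    name: str
    parents: tuple[str, ...]
    true_latency_ms: float
    n_sources: int = 10


@dataclass
class GroundTruthIPPM:
    """A known pathway map used to generate synthetic data."""

    transforms: list[GroundTruthTransform]
    input_streams: set[str]

    def to_ctl(self) -> CandidateTransformList:
        return CandidateTransformList(
            parents={t.name: list(t.parents) for t in self.transforms},
            input_streams=set(self.input_streams),
        )

    @property
    def true_latencies(self) -> dict[str, float]:
        return {t.name: t.true_latency_ms for t in self.transforms}

    def expected_edges(self) -> set[tuple[str, str]]:
        """Transform-level edge set (parent label -> child name)."""
        return {(p, t.name) for t in self.transforms for p in t.parents}


def three_stream_preset(n_sources: int = 10) -> GroundTruthIPPM:
    """Default ground truth: three parallel streams with a late merge.

    Three input streams each feed an initial transform expressed at
    60 ms (``step_1..3``); each of those feeds an identity-like null
    transform at 100 ms (``null_1..3``) and all three combine into a
    single node at 70 ms (``step_4``), from which two parallel
    transforms (``step_5``, ``step_6``) output at 125 ms.  The early
    merge node (70 ms, before the 100 ms nulls) makes causality errors
    easy to trigger under noise.
    """
    streams = {"stream_1", "stream_2", "stream_3"}
    transforms = []
    for i in (1, 2, 3):
        transforms.append(
            GroundTruthTransform(f"step_{i}", (f"stream_{i}",), 60.0, n_sources)
        )
        transforms.append(
            GroundTruthTransform(f"null_{i}", (f"step_{i}",), 100.0, n_sources)
        )
    transforms.append(
        GroundTruthTransform("step_4", ("step_1", "step_2", "step_3"), 70.0, n_sources)
    )
    transforms.append(GroundTruthTransform("step_5", ("step_4",), 125.0, n_sources))
    transforms.append(GroundTruthTransform("step_6", ("step_4",), 125.0, n_sources))
    return GroundTruthIPPM(transforms=transforms, input_streams=streams)


@dataclass
class SimConfig:
    """Simulation conditions.

    ``relative_strength`` scales the ground-truth sources relative to
    the competing sources, whose peak amplitude is normalized to 1.
    ``n_competing_signals`` counts insertions: each of
    ``n_competing_signals / insertions_per_competing`` distinct
    band-passed signals is inserted ``insertions_per_competing`` times
    at independent uniform latencies.
    """

    jitter_sd_ms: float = 10.0
    n_competing_signals: int = 500
    insertions_per_competing: int = 10
    competing_latency_range_ms: tuple[float, float] = (0.0, 500.0)
    relative_strength: float = 1.0
    duration_s: float = 30.0
    sample_rate_hz: float = 1000.0
    band_hz: tuple[float, float] = (5.0, 100.0)
    n_channels: int = 64
    noise_sd: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not (0 < low < high < self.sample_rate_hz / 2):
            raise ParameterError("band must satisfy 0 < low < high < Nyquist")
        if not (0.0 <= self.relative_strength <= 1.0):
            raise ParameterError("relative_strength must be in [0, 1]")
        if self.jitter_sd_ms < 0:
            raise ParameterError("jitter_sd_ms must be >= 0")


def _child_seed(*key) -> int:
    """Deterministic sub-seed (< 2^31) derived from a key tuple."""
    clean = tuple(0 if k is None else int(k) for k in key)
    return int(np.random.SeedSequence(clean).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Expression-level synthesis
# ---------------------------------------------------------------------------

def simulate_expression(
    gt: GroundTruthIPPM,
    cfg: SimConfig,
    spurious_rate: float = 0.0,
    surprisal_scale: float = 5.0,
    threshold_logp: float = 3.0,
    n_hexels: int = 10242,
    bilateral: bool = False,
    seed: int | None = None,
) -> tuple[dict[str, ExpressionSet], dict[str, float]]:
    """Generate significant expression points directly from a ground truth.

    For each transform, each of its ``n_sources`` sources is detected
    with probability ``cfg.relative_strength``, at latency
    ``true + N(0, jitter_sd^2)`` and surprisal ``threshold +
    Exp(surprisal_scale)`` damped by the jitter magnitude (so the most
    significant point tends to sit at the true latency).
    ``spurious_rate`` adds Poisson-many spurious significant points per
    transform at uniform random latencies.  Returns one hemisphere by
    default (``{"left": set}``), or both with independent jitter when
    ``bilateral`` is set, plus the true latencies.
    """
    if seed is None:
        seed = cfg.seed
    hemispheres = ("left", "right") if bilateral else ("left",)
    sets: dict[str, ExpressionSet] = {}
    sigma = cfg.jitter_sd_ms
    for h_idx, hemi in enumerate(hemispheres):
        rng = np.random.default_rng(_child_seed(seed, h_idx))
        points: list[ExpressionPoint] = []
        for t in gt.transforms:
            n_spurious = rng.poisson(spurious_rate) if spurious_rate > 0 else 0
            hexels = rng.choice(n_hexels, size=t.n_sources + n_spurious, replace=False)
            for i in range(t.n_sources):
                detected = rng.random() < cfg.relative_strength
                jitter = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                excess = rng.exponential(surprisal_scale)
                if not detected:
                    continue
                damp = np.exp(-0.5 * (jitter / sigma) ** 2) if sigma > 0 else 1.0
                points.append(
                    ExpressionPoint(
                        hexel_id=int(hexels[i]),
                        transform=t.name,
                        hemisphere=hemi,
                        latency_ms=t.true_latency_ms + jitter,
                        surprisal=threshold_logp + excess * damp,
                    )
                )
            lo, hi = cfg.competing_latency_range_ms
            for j in range(n_spurious):
                points.append(
                    ExpressionPoint(
                        hexel_id=int(hexels[t.n_sources + j]),
                        transform=t.name,
                        hemisphere=hemi,
                        latency_ms=rng.uniform(lo, hi),
                        surprisal=threshold_logp + rng.exponential(surprisal_scale),
                    )
                )
        sets[hemi] = ExpressionSet(
            points, n_hexels_per_hemisphere=n_hexels, alpha_threshold_logp=threshold_logp
        )
    return sets, gt.true_latencies


# ---------------------------------------------------------------------------
# Signal-level synthesis
# ---------------------------------------------------------------------------

def generate_bandpassed_signal(
    duration_s: float,
    sample_rate_hz: float,
    band_hz: tuple[float, float] = (5.0, 100.0),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Band-passed white noise, zero-mean, peak-normalized to 1."""
    low, high = band_hz
    if not (0 < low < high < sample_rate_hz / 2):
        raise ParameterError("band must satisfy 0 < low < high < Nyquist")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    white = rng.standard_normal(n)
    sos = sps.butter(4, band_hz, btype="bandpass", fs=sample_rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x = x - x.mean()
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _insert_delayed(channel: np.ndarray, sig: np.ndarray, delay_samples: int, amp: float) -> None:
    n = channel.shape[0]
    d = delay_samples
    if d >= 0:
        m = max(0, n - d)
        if m:
            channel[d : d + m] += amp * sig[:m]
    else:
        m = max(0, n + d)
        if m:
            channel[:m] += amp * sig[-d : -d + m]


def simulate_recordings(
    gt: GroundTruthIPPM, cfg: SimConfig, seed: int | None = None
) -> tuple[np.ndarray, dict]:
    """Synthesize recording channels mixing ground-truth and competing sources.

    Every source (ground truth or competing) is a delayed copy of its
    band-passed signal inserted into one uniformly chosen channel;
    white measurement noise of sd ``cfg.noise_sd`` is added to every
    channel.  Ground-truth sources have amplitude
    ``cfg.relative_strength``; competing sources amplitude 1.

    Returns ``(channels, info)`` where ``channels`` has shape
    ``(n_channels, n_samples)`` and ``info`` carries the transform
    signals and a per-source record table.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(_child_seed(seed, 1))
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    fs = cfg.sample_rate_hz
    channels = np.zeros((cfg.n_channels, n))

    transform_signals = {
        t.name: generate_bandpassed_signal(cfg.duration_s, fs, cfg.band_hz, rng=rng)
        for t in gt.transforms
    }
    sources = []
    for t in gt.transforms:
        for _ in range(t.n_sources):
            ch = int(rng.integers(cfg.n_channels))
            jitter = rng.normal(0.0, cfg.jitter_sd_ms) if cfg.jitter_sd_ms > 0 else 0.0
            lat = t.true_latency_ms + jitter
            if cfg.relative_strength > 0:
                _insert_delayed(
                    channels[ch],
                    transform_signals[t.name],
                    int(round(lat * fs / 1000.0)),
                    cfg.relative_strength,
                )
            sources.append({"kind": "ground_truth", "transform": t.name, "channel": ch, "latency_ms": lat})

    n_base = max(1, int(np.ceil(cfg.n_competing_signals / cfg.insertions_per_competing)))
    lo, hi = cfg.competing_latency_range_ms
    inserted = 0
    for b in range(n_base):
        base = generate_bandpassed_signal(cfg.duration_s, fs, cfg.band_hz, rng=rng)
        for _ in range(cfg.insertions_per_competing):
            if inserted >= cfg.n_competing_signals:
                break
            ch = int(rng.integers(cfg.n_channels))
            lat = rng.uniform(lo, hi)
            if cfg.jitter_sd_ms > 0:
                lat += rng.normal(0.0, cfg.jitter_sd_ms)
            _insert_delayed(channels[ch], base, int(round(lat * fs / 1000.0)), 1.0)
            sources.append({"kind": "competing", "transform": f"competing_{b}", "channel": ch, "latency_ms": lat})
            inserted += 1

    if cfg.noise_sd > 0:
        channels += rng.normal(0.0, cfg.noise_sd, size=channels.shape)
    info = {"transform_signals": transform_signals, "sources": pd.DataFrame(sources)}
    return channels, info


# ---------------------------------------------------------------------------
# Surrogate detector
# ---------------------------------------------------------------------------

def _max_corr_stats(sig: np.ndarray, ch: np.ndarray, lag_lo: int, lag_hi: int):
    """Observed max lagged correlation plus spectral quantities for the null.

    Returns (obs, best_lag, lam0, omega2, cross_fft_mag, n) where lam0
    is the null variance of the correlation at a single lag and omega2
    the normalized second spectral moment (rad^2/sample) of the
    correlation process over lags.
    """
    n = sig.shape[0]
    fs_ = np.fft.rfft(sig)
    fc_ = np.fft.rfft(ch)
    cross = np.conj(fs_) * fc_
    # full circular cross-correlation x(l) = sum_t s(t) c(t+l)
    x = np.fft.irfft(cross, n)
    denom = n * sig.std() * ch.std()
    r = x / denom
    window = r[lag_lo : lag_hi + 1]
    best = int(np.argmax(window))
    obs = float(window[best])

    # Spectral weights: double interior rfft bins to cover the full spectrum.
    q = np.abs(cross) ** 2
    w = np.ones_like(q)
    w[1:] = 2.0
    if n % 2 == 0:
        w[-1] = 1.0
    ps = np.abs(fs_) ** 2
    pc = np.abs(fc_) ** 2
    sum_q = float(np.sum(w * q))
    lam0 = sum_q / (float(np.sum(w * ps)) * float(np.sum(w * pc)))
    freqs = np.arange(q.shape[0]) / n  # cycles/sample
    omega = 2 * np.pi * freqs
    omega2 = float(np.sum(w * q * omega**2) / sum_q) if sum_q > 0 else 0.0
    return obs, best + lag_lo, lam0, omega2, cross, n


def _analytic_pvalue(obs: float, lam0: float, omega2: float, n_lags: int) -> float:
    """Upcrossing (Rice) bound for the max of a stationary Gaussian process.

    P(max over L+1 lags > u) <= P(r(0) > u) + L * rate of upcrossings,
    with rate (1/2pi) sqrt(lam2/lam0) exp(-u^2 / (2 lam0)).
    """
    if lam0 <= 0:
        return 1.0
    z = obs / np.sqrt(lam0)
    rate = (1.0 / (2 * np.pi)) * np.sqrt(omega2) * np.exp(-0.5 * z * z)
    p = norm.sf(z) + max(0, n_lags - 1) * rate
    return float(min(1.0, p))


def _permutation_pvalue(
    obs: float,
    cross: np.ndarray,
    n: int,
    denom: float,
    lag_lo: int,
    lag_hi: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Phase-randomization surrogate null for the max lagged correlation.

    Randomizing the phases of the cross-spectrum preserves both
    autocorrelation structures while destroying any phase alignment
    between channel and signal (a spectrum-preserving permutation).
    """
    mag = np.abs(cross)
    m = mag.shape[0]
    phases = rng.uniform(0, 2 * np.pi, size=(n_perm, m))
    surro = mag[None, :] * np.exp(1j * phases)
    surro[:, 0] = mag[0] * np.where(rng.random(n_perm) < 0.5, 1.0, -1.0)
    if n % 2 == 0:
        surro[:, -1] = mag[-1] * np.where(rng.random(n_perm) < 0.5, 1.0, -1.0)
    x = np.fft.irfft(surro, n, axis=1) / denom
    null_max = x[:, lag_lo : lag_hi + 1].max(axis=1)
    return float((1 + np.sum(null_max >= obs)) / (1 + n_perm))


def detect_expression(
    channels: np.ndarray,
    transform_signals: Mapping[str, np.ndarray],
    sample_rate_hz: float,
    latency_range_ms: tuple[float, float] = (0.0, 500.0),
    alpha: float = 0.05,
    correction: str = "bonferroni",
    null: str = "analytic",
    n_perm: int = 200,
    seed: int | None = None,
    hemisphere: str = "left",
    max_surprisal: float = 350.0,
) -> ExpressionSet:
    """Detect transform expression in recording channels by lagged correlation.

    For every (channel, transform) pair the correlation with the
    candidate signal is computed at every lag on the sample grid within
    ``latency_range_ms``; the maximum is converted to a p-value under a
    no-association null (``"analytic"``: Rice/extreme-value bound from
    the cross-spectrum; ``"permutation"``: phase-randomization
    surrogates, ``n_perm`` of them).  Significance is corrected over the
    channel x transform family, and each significant pair yields one
    expression point at its best lag with surprisal -log10(p).
    """
    if null not in ("analytic", "permutation"):
        raise ParameterError(f"unknown null method {null!r}")
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    names = sorted(transform_signals)
    n_channels = channels.shape[0]
    m = n_channels * len(names)
    threshold = corrected_threshold_logp(alpha, correction, m)
    lag_lo = int(round(latency_range_ms[0] * sample_rate_hz / 1000.0))
    lag_hi = int(round(latency_range_ms[1] * sample_rate_hz / 1000.0))
    points: list[ExpressionPoint] = []
    for ch_idx in range(n_channels):
        ch = channels[ch_idx]
        if ch.std() == 0:
            warnings.warn(f"channel {ch_idx} is constant; skipped")
            continue
        ch = ch - ch.mean()
        for name in names:
            sig = transform_signals[name]
            sig = sig - sig.mean()
            obs, best_lag, lam0, omega2, cross, n = _max_corr_stats(sig, ch, lag_lo, lag_hi)
            if null == "analytic":
                p = _analytic_pvalue(obs, lam0, omega2, lag_hi - lag_lo + 1)
            else:
                denom = n * sig.std() * ch.std()
                p = _permutation_pvalue(
                    obs, cross, n, denom, lag_lo, lag_hi, n_perm, rng
                )
            surprisal = max_surprisal if p <= 0 else min(-np.log10(p), max_surprisal)
            if surprisal >= threshold:
                points.append(
                    ExpressionPoint(
                        hexel_id=ch_idx,
                        transform=name,
                        hemisphere=hemisphere,
                        latency_ms=best_lag * 1000.0 / sample_rate_hz,
                        surprisal=float(surprisal),
                    )
                )
    return ExpressionSet(
        points, n_hexels_per_hemisphere=n_channels, alpha_threshold_logp=threshold
    )


# ---------------------------------------------------------------------------
# Strength sweep
# ---------------------------------------------------------------------------

def strength_sweep(
    gt: GroundTruthIPPM,
    cfg: SimConfig,
    strengths: Sequence[float],
    n_replicates: int = 20,
    strategy: str = "mp",
    strategy_cfg=None,
    seed: int | None = None,
    tr_variant: str = "ctl_total",
    alpha: float = 0.05,
    correction: str = "bonferroni",
    null: str = "analytic",
    missing_policy: str = "bypass",
) -> pd.DataFrame:
    """Full-pipeline ground-truth recovery across relative signal strengths.

    Every (strength, replicate) cell re-randomizes source-to-channel
    assignment, jitter, competing signals and noise, then runs
    simulate → detect → denoise → build → evaluate.  TR uses the full
    CTL as denominator by default (the ground truth is known to contain
    every transform).  Returns a tidy table with columns
    ``strength, replicate, tr, cv, n_points, n_detected_transforms``.
    """
    if any(s < 0 or s > 1 for s in strengths):
        raise ParameterError("strengths must lie in [0, 1]")
    ctl = gt.to_ctl()
    rows = []
    for si, s in enumerate(strengths):
        for rep in range(n_replicates):
            run_seed = _child_seed(seed, si, rep)
            run_cfg = replace(cfg, relative_strength=float(s), seed=run_seed)
            channels, info = simulate_recordings(gt, run_cfg, seed=run_seed)
            raw = detect_expression(
                channels,
                info["transform_signals"],
                sample_rate_hz=cfg.sample_rate_hz,
                latency_range_ms=cfg.competing_latency_range_ms,
                alpha=alpha,
                correction=correction,
                null=null,
                seed=run_seed,
            )
            if len(raw) == 0:
                tr, cv = 0.0, 0.0
                n_detected = 0
            else:
                foci = denoise_expression(
                    raw, strategy=strategy, cfg=strategy_cfg, seed=run_seed
                )
                g = build_ippm(foci, ctl, missing_policy=missing_policy)
                cv, _, _ = causality_violation(g)
                tr, _, recalled = transform_recall(g, raw, ctl, variant=tr_variant)
                n_detected = len(recalled)
            rows.append(
                {
                    "strength": float(s),
                    "replicate": rep,
                    "seed": run_seed,
                    "tr": tr,
                    "cv": cv,
                    "n_points": len(raw),
                    "n_detected_transforms": n_detected,
                }
            )
    return pd.DataFrame(rows)
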