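"""Synthetic dichotomous kinematic data with known planted ground truth.

No motion-capture recordings ship with the package, so every pipeline stage
is exercised on simulated running-stance data that emulate the study shape:
11 subjects x 2 shoe conditions x 20 trials x 13 markers x 3 axes x 101
normalized time points (a 440 x 3939 matrix).

Model per trial (height-normalized units): a smooth base movement waveform
per marker/axis (sums of low-frequency sinusoids drawn once from a fixed
design generator, so the movement itself is identical across seeds), a
multiplicative per-subject amplitude random effect, a multiplicative
per-trial amplitude jitter, additive i.i.d. measurement noise, and a
condition-signed localized effect component — by default a Gaussian bump on
marker 3's vertical trajectory around 39% of stance, the kind of heel-region
footwear effect the method is meant to isolate.  The planted effect
directions, expressed in whitened space via the generator's expected
within-subject SDs, are returned as :class:`SyntheticTruth` so recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import subspace_angles

from .basis import OrthonormalBasis
from .layout import IndexMap, TrialKey, TrialRecord

__all__ = ["EffectComponent", "SyntheticConfig", "SyntheticTruth", "generate", "generate_raw", "truth_alignment"]

_DESIGN_SEED = 987654321  # fixed: the base movement is part of the design, not the noise


@dataclass(frozen=True)
class EffectComponent:
    """One planted condition-effect: a localized bump on one marker/axis.

    ``center``/``width`` are in 1-based normalized time points.

    shape "shift" (default): the conditions differ by a mean shift of
    +/- amplitude/2 along the unit bump direction (amplitude = full
    between-condition separation, height-normalized units).  A mean shift is
    one-dimensional, so alone it yields a 1-D classifying subspace.

    shape "timing": both conditions receive the bump (of ``amplitude``) but
    its center is offset by +/- timing_delta/2 between conditions, with
    per-trial timing noise of SD ``timing_sd`` (time points).  The condition
    difference is then nonlinear in time, which is what makes the
    classifying subspace multi-dimensional (redundant) like real gait
    effects.
    """

    marker: int = 3
    axis: int = 3
    center: float = 39.0
    width: float = 8.0
    amplitude: float = 0.1
    window: tuple[int, int] | None = None  # 1-based inclusive; None = full range
    shape: str = "shift"  # or "timing"
    timing_delta: float = 6.0
    timing_sd: float = 1.5


@dataclass
class SyntheticConfig:
    """Study-shaped simulation parameters.

    Defaults emulate the study conditions: 11 subjects, 2 conditions,
    20 trials per condition, 13 markers, 101 time points; noise of 0.01
    height units (~2 cm on a 1.8 m subject: optical noise plus soft-tissue /
    placement variability), 10% between-subject amplitude variation, 3%
    trial-to-trial amplitude jitter, and one planted effect.

    ``effect_snr`` expresses effect strength where the decomposition
    operates: the between-condition separation along the planted direction
    in whitened space, in units of the (unit) within-subject SD.  When set
    (default 10), each effect's raw amplitude is calibrated to reach it in
    closed form; set it to None to use the raw ``EffectComponent.amplitude``
    values directly.  An amplitude of 0 always means "no effect".

    ``effect_timing_jitter_sd`` (time points) shifts each effect's bump
    center per subject: subjects then express the condition effect at
    slightly different stance times, which is the between-subject
    heterogeneity that makes the classifying subspace multi-dimensional
    (redundant) rather than a single direction.  0 (default) keeps the
    planted effect identical across subjects.
    """

    subjects: int = 11
    trials_per_condition: int = 20
    markers: int = 13
    timepoints: int = 101
    sample_rate: float = 240.0
    condition_names: tuple[str, str] = ("shoe_A", "shoe_B")
    base_amplitude: float = 0.25
    subject_effect_sd: float = 0.1
    trial_jitter_sd: float = 0.03
    trial_noise_sd: float = 0.01
    noise_dist: str = "gaussian"  # or "laplace" (heavier tails, ICA stress)
    effects: tuple[EffectComponent, ...] = (EffectComponent(),)
    effect_snr: float | None = 10.0
    effect_timing_jitter_sd: float = 0.0
    seed: int = 0

    @property
    def layout(self) -> IndexMap:
        return IndexMap(markers=self.markers, axes=3, timepoints=self.timepoints)


@dataclass
class SyntheticTruth:
    """Planted effect directions and amplitudes.

    ``raw_directions`` are the unit bump vectors in raw variable space;
    ``directions`` are their whitened-space counterparts (scaled by the
    expected within-subject SD per variable, then renormalized) — the
    directions a decomposition of the whitened matrix should recover.
    """

    directions: np.ndarray  # (k, p), whitened space, unit rows
    raw_directions: np.ndarray  # (k, p), raw space, unit rows
    amplitudes: np.ndarray  # (k,)
    layout: IndexMap = field(default_factory=IndexMap)


def _base_curves(config: SyntheticConfig) -> np.ndarray:
    """Smooth per-(marker, axis) base waveforms, (markers, 3, T).

    Drawn from a fixed design generator: identical for every seed.
    """
    rng = np.random.default_rng(_DESIGN_SEED)
    T = config.timepoints
    tau = np.linspace(0.0, 1.0, T)
    curves = np.empty((config.markers, 3, T))
    for m in range(config.markers):
        for a in range(3):
            offset = rng.uniform(0.1, 0.9) if a == 2 else rng.uniform(-0.3, 0.3)
            c = offset * np.ones(T)
            for h in (1, 2, 3):
                amp = rng.normal(0.0, config.base_amplitude / h)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                c = c + amp * np.sin(2.0 * np.pi * h * tau + phase)
            curves[m, a] = c
    return curves


def _bump_curve(timepoints: int, center: float, width: float, window=None) -> np.ndarray:
    """Unit-norm Gaussian bump over the normalized time grid (length T)."""
    t = np.arange(1, timepoints + 1, dtype=float)
    bump = np.exp(-0.5 * ((t - center) / width) ** 2)
    lo, hi = window or (1, timepoints)
    if not (1 <= lo <= hi <= timepoints):
        raise ValueError(f"window {window} outside 1..{timepoints}")
    bump = np.where((t >= lo) & (t <= hi), bump, 0.0)
    norm = np.linalg.norm(bump)
    if norm == 0.0:
        raise ValueError("bump vanishes inside its window")
    return bump / norm


def _validate_effect(config: SyntheticConfig, i: int, e: EffectComponent) -> None:
    if not (1 <= e.marker <= config.markers and 1 <= e.axis <= 3):
        raise ValueError(f"effect {i}: marker/axis out of range")
    if e.amplitude < 0 or e.width <= 0:
        raise ValueError(f"effect {i}: amplitude must be >= 0 and width > 0")
    if e.shape not in ("shift", "timing"):
        raise ValueError(f"effect {i}: unknown shape {e.shape!r}")


def _effect_vectors(config: SyntheticConfig, centers=None) -> np.ndarray:
    """Unit bump vectors in raw variable space, one row per effect.

    ``centers`` optionally overrides each effect's bump center (used for
    per-subject timing jitter).
    """
    lay = config.layout
    out = np.zeros((len(config.effects), lay.num_variables))
    for i, e in enumerate(config.effects):
        _validate_effect(config, i, e)
        center = e.center if centers is None else centers[i]
        out[i, lay.block_slice(e.marker, e.axis)] = _bump_curve(
            lay.timepoints, center, e.width, e.window
        )
    return out


def _timing_moments(config: SyntheticConfig, e: EffectComponent) -> tuple[np.ndarray, np.ndarray]:
    """(mean-difference, pooled variance) per variable of a unit-amplitude timing effect.

    Computed by quadrature over the per-trial timing noise and the 50/50
    condition mixture; deterministic given the config.
    """
    lay = config.layout
    eps = np.linspace(-4.0 * e.timing_sd, 4.0 * e.timing_sd, 81) if e.timing_sd > 0 else np.zeros(1)
    w = np.exp(-0.5 * (eps / e.timing_sd) ** 2) if e.timing_sd > 0 else np.ones(1)
    w = w / w.sum()
    means = {}
    ex2 = np.zeros(lay.timepoints)
    for sgn in (1.0, -1.0):
        acc = np.zeros(lay.timepoints)
        for wk, ek in zip(w, eps):
            g = _bump_curve(lay.timepoints, e.center + sgn * e.timing_delta / 2.0 + ek, e.width, e.window)
            acc += wk * g
            ex2 += 0.5 * wk * g**2
        means[sgn] = acc
    ex = 0.5 * (means[1.0] + means[-1.0])
    var_t = np.maximum(ex2 - ex**2, 0.0)
    diff = np.zeros(lay.num_variables)
    var = np.zeros(lay.num_variables)
    sl = lay.block_slice(e.marker, e.axis)
    diff[sl] = means[1.0] - means[-1.0]
    var[sl] = var_t
    return diff, var


def _background_variance(config: SyntheticConfig, base_flat: np.ndarray) -> np.ndarray:
    """Expected within-subject variance per variable, excluding effect shifts."""
    return (
        base_flat**2 * (1.0 + config.subject_effect_sd**2) * config.trial_jitter_sd**2
        + config.trial_noise_sd**2
    )


def _calibrate_amplitude(u: np.ndarray, background: np.ndarray, snr: float) -> float:
    """Raw amplitude whose whitened-space separation along ``u`` equals ``snr``.

    The separation ||A u_k / sigma_k(A)|| grows monotonically in A but
    saturates at 2 sqrt(nnz(u)) because the effect inflates its own whitening
    SDs; unreachable targets raise.
    """
    if snr == 0.0:
        return 0.0
    nz = u != 0.0
    ceiling = 2.0 * np.sqrt(int(nz.sum()))

    def sep(A: float) -> float:
        s2 = background + (A * u / 2.0) ** 2
        return float(np.sqrt(((A * u) ** 2 / s2).sum()))

    if snr >= 0.98 * ceiling:
        raise ValueError(
            f"target whitened SNR {snr} unreachable (ceiling ~{ceiling:.1f}); "
            "spread the effect over a wider window"
        )
    lo, hi = 0.0, 1.0
    while sep(hi) < snr:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if sep(mid) < snr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _amplitudes(config: SyntheticConfig, base_flat: np.ndarray, u_raw: np.ndarray) -> np.ndarray:
    """Planted raw amplitudes per effect.

    Shift effects are calibrated to ``effect_snr`` when it is set (effects
    are assumed to occupy disjoint variable blocks); timing effects always
    use their raw amplitude, since their strength is governed jointly by
    amplitude, timing offset and timing noise.
    """
    background = _background_variance(config, base_flat)
    out = np.empty(len(config.effects))
    for i, (e, u) in enumerate(zip(config.effects, u_raw)):
        if e.shape == "timing" or config.effect_snr is None or e.amplitude == 0.0:
            out[i] = e.amplitude
        else:
            out[i] = _calibrate_amplitude(u, background, config.effect_snr)
    return out


def _truth(
    config: SyntheticConfig, base_flat: np.ndarray, u_raw: np.ndarray, amps: np.ndarray
) -> SyntheticTruth:
    # expected within-subject variance per variable (over trials and
    # conditions pooled): amplitude jitter + noise + condition-effect spread
    var = _background_variance(config, base_flat)
    raw_dirs = np.zeros_like(u_raw)
    for i, e in enumerate(config.effects):
        if e.shape == "timing":
            diff, v = _timing_moments(config, e)
            var = var + amps[i] ** 2 * v
            n = np.linalg.norm(diff)
            raw_dirs[i] = diff / n if n > 0 else diff
        else:
            var = var + (amps[i] * u_raw[i] / 2.0) ** 2
            raw_dirs[i] = u_raw[i]
    sd = np.sqrt(var)
    directions = raw_dirs / sd
    norms = np.linalg.norm(directions, axis=1)
    norms[norms == 0.0] = 1.0
    return SyntheticTruth(
        directions=directions / norms[:, None],
        raw_directions=raw_dirs,
        amplitudes=amps,
        layout=config.layout,
    )


def generate(config: SyntheticConfig | None = None) -> tuple[list[TrialRecord], SyntheticTruth]:
    """Generate time-normalized trials (matrix mode) plus the planted truth.

    Deterministic given ``config.seed``; the seed drives subject effects,
    trial jitter and noise only — base movement and truth directions are
    identical across seeds.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    lay = config.layout
    base = _base_curves(config)
    base_flat = base.transpose(0, 1, 2).reshape(-1)  # marker-major, matches IndexMap
    u_raw = _effect_vectors(config)
    amps = _amplitudes(config, base_flat, u_raw)
    truth = _truth(config, base_flat, u_raw, amps)
    trials: list[TrialRecord] = []
    for s in range(config.subjects):
        subj = f"S{s + 1:02d}"
        a_s = rng.normal(0.0, config.subject_effect_sd)
        centers = [e.center for e in config.effects]
        if config.effect_timing_jitter_sd > 0 and len(config.effects):
            centers = [
                float(np.clip(c + rng.normal(0.0, config.effect_timing_jitter_sd), 1, lay.timepoints))
                for c in centers
            ]
        u_s = _effect_vectors(config, centers) if len(config.effects) else u_raw
        for ci, cond in enumerate(config.condition_names):
            sign = 1.0 if ci == 0 else -1.0
            for j in range(config.trials_per_condition):
                jitter = rng.normal(0.0, config.trial_jitter_sd)
                if config.noise_dist == "laplace":
                    noise = rng.laplace(0.0, config.trial_noise_sd / np.sqrt(2.0), lay.num_variables)
                else:
                    noise = rng.normal(0.0, config.trial_noise_sd, lay.num_variables)
                effect = np.zeros(lay.num_variables)
                for i, e in enumerate(config.effects):
                    if amps[i] == 0.0:
                        continue
                    if e.shape == "timing":
                        center = np.clip(
                            centers[i]
                            + sign * e.timing_delta / 2.0
                            + rng.normal(0.0, e.timing_sd),
                            1,
                            lay.timepoints,
                        )
                        g = np.zeros(lay.num_variables)
                        g[lay.block_slice(e.marker, e.axis)] = _bump_curve(
                            lay.timepoints, float(center), e.width, e.window
                        )
                        effect += amps[i] * g
                    else:
                        effect += sign * amps[i] / 2.0 * u_s[i]
                row = base_flat * (1.0 + a_s) * (1.0 + jitter) + effect + noise
                positions = row.reshape(lay.markers, 3, lay.timepoints).transpose(2, 0, 1)
                trials.append(
                    TrialRecord(
                        key=TrialKey(subject=subj, condition=cond, trial=j + 1),
                        positions=positions,
                        sample_rate=config.sample_rate,
                    )
                )
    return trials, truth


def generate_raw(
    config: SyntheticConfig | None = None,
    stance_duration_s: float = 0.27,
    padding_frames: int = 30,
    peak_force_n: float = 1500.0,
) -> tuple[list[TrialRecord], SyntheticTruth, dict[str, float]]:
    """Frame-rate trials with synthetic force traces (raw mode).

    Emits meter-scale trajectories on the camera clock with a half-sine
    vertical force over stance, so the preprocessing pipeline (filter, 15 N
    stance crop, 101-point resampling, centering, height scaling) is
    exercisable end to end.  Returns (trials, truth, per-subject heights).
    """
    config = config or SyntheticConfig()
    mat_trials, truth = generate(config)
    rng = np.random.default_rng(config.seed + 1)
    n_stance = max(int(round(stance_duration_s * config.sample_rate)), 8)
    heights: dict[str, float] = {}
    raw: list[TrialRecord] = []
    T = config.timepoints
    grid = np.arange(T, dtype=float)
    for t in mat_trials:
        subj = t.key.subject
        if subj not in heights:
            heights[subj] = float(rng.normal(1.76, 0.05))
        h = heights[subj]
        # resample the normalized trial onto the frame clock of stance
        spline = CubicSpline(grid, t.positions, axis=0)
        stance = spline(np.linspace(0.0, T - 1.0, n_stance)) * h
        pad_pre = np.repeat(stance[:1], padding_frames, axis=0)
        pad_post = np.repeat(stance[-1:], padding_frames, axis=0)
        positions = np.concatenate([pad_pre, stance, pad_post], axis=0)
        force = np.zeros(positions.shape[0])
        tau = np.linspace(0.0, 1.0, n_stance)
        force[padding_frames : padding_frames + n_stance] = peak_force_n * np.sin(np.pi * tau)
        raw.append(
            TrialRecord(
                key=t.key, positions=positions, sample_rate=config.sample_rate, force=force
            )
        )
    return raw, truth, heights


def truth_alignment(
    recovered: np.ndarray | OrthonormalBasis, truth: SyntheticTruth
) -> dict:
    """Score how well a recovered subspace captures the planted directions.

    Returns per-direction |cosine| between each planted (whitened-space)
    direction and its orthogonal projection onto the recovered span, plus the
    principal angles (radians) between the planted and recovered subspaces.
    """
    V = recovered.vectors if isinstance(recovered, OrthonormalBasis) else np.atleast_2d(recovered)
    V = np.asarray(V, dtype=float)
    if V.shape[1] != truth.directions.shape[1]:
        raise ValueError(
            f"recovered vectors have dimension {V.shape[1]}, truth {truth.directions.shape[1]}"
        )
    # orthonormalize the span (recovered sets like an ICA base need not be orthogonal)
    Q, R = np.linalg.qr(V.T)
    keep = np.abs(np.diag(R)) > 1e-12
    Q = Q[:, keep]
    cosines = np.linalg.norm(truth.directions @ Q, axis=1)
    angles = (
        subspace_angles(Q, truth.directions.T) if Q.size and truth.directions.size else np.array([])
    )
    return {"cosines": cosines, "principal_angles": angles}
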