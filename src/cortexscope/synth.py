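"""Ground-truthed synthetic widefield studies.

Emulates the study design the downstream analyses assume: 7 subjects imaged on
3 consecutive days (drug order a random permutation per subject), a 10-min
session before and after administration of saline, thioperamide or pitolisant,
two-channel acquisition at 11.7 fps per channel.

Generative model per region trace (frame rate ``fps``):

* calcium events: Poisson-timed causal exponential transients (amplitude
  drawn from a lognormal truncated below 2 SD, decay ``decay_tau``).  Event
  times come from a global candidate train that each region joins with
  probability ``shared_event_participation`` (global cortical events, with
  amplitudes drawn independently per region) plus region-private events
  topping the rate up to ``event_rate``.  The shared drive dominates the
  trace variance, as it does in widefield recordings, and is what carries
  the inter-regional correlations seen at 1-s resolution.
* a correlated slow Gaussian latent (AR(1), timescale ``latent_tau_s``) with
  inter-regional correlation ``shared_latent_corr``, filling whatever
  variance the events do not account for;
* white Gaussian noise.

Amplitudes are expressed in the units the detector measures: the session
z-score of the median-filtered trace.  Two calibrations make this hold.
First, the generator computes the expected event-train variance analytically
(Campbell's theorem, under the saline parameter set) and sizes the baseline
(latent + noise) so total trace variance is 1; the session z-score is then
approximately the identity.  Second, a 5-point median filter attenuates the
peak of an isolated exponential transient by exactly exp(-2 / (fps * tau)),
so event kernels are rendered with their peaks pre-scaled by the inverse of
that factor.  Without these two calibrations no planted amplitude is
recoverable from the z-scored, filtered trace and the generator could not
serve as ground truth for the detector.

Drug conditions (post-administration sessions only) modify two things,
mirroring the effects the analyses are meant to recover.  First, the left
somatosensory event rate in the 2.0-2.5 SD amplitude class is multiplied by
``low_amp_scale_leftS`` (the variance this removes returns as uncorrelated
noise, so the session z-score stays neutral across conditions).  Second,
right somatosensory coupling to the global event drive is increased:
``rightS_coupling_gain`` adds to right-S's participation probability in
global events, raising its correlation with every other region while leaving
its event rate, amplitude law and prominence statistics untouched -- the
drug re-times right-S activity rather than re-scaling it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm

from .preprocess import REFERENCE_TAG, SIGNAL_TAG, RegionTraces, TwoChannelMovie
from .regions import REGIONS, HEMISPHERES, RegionAtlas, homotopic_pairs

CONDITIONS: tuple[str, ...] = ("saline", "thioperamide", "pitolisant")
PHASES: tuple[str, ...] = ("pre", "post")

#: amplitude class whose rate the drug suppresses (SD units)
LOW_AMP_CLASS: tuple[float, float] = (2.0, 2.5)


# ----------------------------------------------------------------- amplitude law


@dataclass(frozen=True)
class TruncatedLognormal:
    """Lognormal event-amplitude law truncated below ``lower`` (SD units).

    The truncation guarantees every planted event clears the detector's 2 SD
    height criterion in the noise-free limit.
    """

    median: float = 2.0
    sigma: float = 0.15
    lower: float = 2.0

    @property
    def mu(self) -> float:
        return math.log(self.median)

    def _z(self, x: float) -> float:
        return (math.log(x) - self.mu) / self.sigma

    @property
    def _tail(self) -> float:
        return norm.sf(self._z(self.lower))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        lo = norm.cdf(self._z(self.lower))
        u = rng.uniform(lo, 1.0, size=n)
        return np.exp(self.mu + self.sigma * norm.ppf(u))

    def class_prob(self, lo: float, hi: float) -> float:
        """P(amplitude in [lo, hi)) under the truncated law."""
        a = max(lo, self.lower)
        if hi <= a:
            return 0.0
        return (norm.cdf(self._z(hi)) - norm.cdf(self._z(a))) / self._tail

    def partial_moment(self, k: int, lo: float, hi: float = math.inf) -> float:
        """E[a^k ; a in [lo, hi)) under the truncated law."""
        a = max(lo, self.lower)
        if hi <= a:
            return 0.0
        shift = k * self.sigma
        hi_z = norm.cdf(self._z(hi) - shift) if math.isfinite(hi) else 1.0
        mass = hi_z - norm.cdf(self._z(a) - shift)
        return math.exp(k * self.mu + 0.5 * k**2 * self.sigma**2) * mass / self._tail

    def moment(self, k: int) -> float:
        return self.partial_moment(k, self.lower)


# ----------------------------------------------------------------- configuration


@dataclass(frozen=True)
class DrugEffect:
    """Condition-specific perturbations applied to post-administration sessions."""

    low_amp_scale_leftS: float = 1.0
    rightS_coupling_gain: float = 0.0


@dataclass(frozen=True)
class ArtifactConfig:
    """Shared slow artifact rendered into both movie channels (hemodynamic-like)."""

    amplitude: float = 0.02  # SD of the artifact trace, in ΔF/F units
    timescale_s: float = 10.0
    gain_signal: float = 2.0
    gain_reference: float = 1.0


def default_latent_corr() -> np.ndarray:
    """Baseline inter-regional latent correlation: 0.80 globally, 0.85 homotopic."""
    c = np.full((12, 12), 0.80)
    np.fill_diagonal(c, 1.0)
    for i, j in homotopic_pairs():
        c[i, j] = c[j, i] = 0.85
    return c


def default_drug_effects() -> dict[str, DrugEffect]:
    return {
        "saline": DrugEffect(),
        "thioperamide": DrugEffect(low_amp_scale_leftS=0.5, rightS_coupling_gain=0.13),
        "pitolisant": DrugEffect(low_amp_scale_leftS=0.5, rightS_coupling_gain=0.13),
    }


@dataclass
class SynthConfig:
    """Study design constants and generative parameters (defaults = study conditions)."""

    n_subjects: int = 7
    n_days: int = 3
    session_s: float = 600.0
    fps_per_channel: float = 11.7
    regions: tuple[str, ...] = REGIONS
    event_rate: float = 16.5  # planted events/min per region
    shared_event_frac: float = 0.84  # fraction of a region's events drawn from the global train
    shared_event_participation: float = 0.87  # baseline probability of joining a global event
    amplitude_law: TruncatedLognormal = field(default_factory=TruncatedLognormal)
    decay_tau: float = 0.3  # s, transient decay
    latent_tau_s: float = 16.0  # s, timescale of the residual Gaussian latent
    shared_latent_corr: np.ndarray = field(default_factory=default_latent_corr)
    drug_effects: dict[str, DrugEffect] = field(default_factory=default_drug_effects)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    noise_sd: float = 0.10  # per-region white noise, SD units
    noise_sd_px: float = 0.5  # per-pixel noise in raw intensity units
    dff_scale: float = 0.02  # ΔF/F per SD unit when rendering movies
    baseline_value: float = 100.0  # raw intensity baseline for rendering
    movie_shape: tuple[int, int] = (128, 128)
    render_hires: bool = False  # render at 512x512 to exercise the downsampler
    day_effect_sd: float = 0.0  # optional per-day baseline shift, default off
    fill_variance: bool = True  # scale baseline so total frame variance is 1
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.shared_latent_corr, dtype=float)
        if c.shape != (len(self.regions),) * 2:
            raise ValueError("shared_latent_corr must be square over the regions")
        if not np.allclose(c, c.T):
            raise ValueError("shared_latent_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("shared_latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-9:
            raise ValueError("shared_latent_corr must be positive semidefinite")
        self.shared_latent_corr = c
        if len(self.regions) != 12:
            raise ValueError("exactly 12 regions required")
        for h in HEMISPHERES:
            if sum(r.startswith(f"{h}_") for r in self.regions) != 6:
                raise ValueError("regions must have 6 entries per hemisphere")
        for name, val in [
            ("event_rate", self.event_rate),
            ("decay_tau", self.decay_tau),
            ("noise_sd", self.noise_sd),
            ("session_s", self.session_s),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.shared_event_frac <= 1:
            raise ValueError("shared_event_frac must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps_per_channel * self.session_s))


@dataclass
class GroundTruth:
    """Planted events, model-implied correlations, and the session label."""

    events: pd.DataFrame  # columns: region, frame, time_s, amplitude
    true_corr: np.ndarray  # (12, 12) frame-level trace correlation
    labels: dict  # subject, day, condition, phase


# ----------------------------------------------------------------- event trains


def _decay_coef(decay_tau: float, fps: float) -> float:
    return math.exp(-1.0 / (fps * decay_tau)) if decay_tau > 0 else 0.0


def _render_train(frames: np.ndarray, amps: np.ndarray, n_frames: int, r: float) -> np.ndarray:
    x = np.zeros(n_frames)
    np.add.at(x, frames, amps)
    if r > 0:
        x = lfilter([1.0], [1.0, -r], x)
    return x


def sample_event_train(
    rate: float,
    amplitude_law: TruncatedLognormal,
    duration_s: float,
    fps: float,
    seed: int | np.random.Generator,
    decay_tau: float = 1.0,
    forced_events: list[tuple[int, float]] | None = None,
) -> tuple[list[tuple[int, float]], np.ndarray]:
    """Homogeneous-Poisson transient train on a zero baseline.

    Returns ``(events, trace)`` where events are (frame, amplitude) pairs and
    the trace is the superposition of one causal exponential-decay kernel per
    event (peak = amplitude, time constant ``decay_tau``).  ``forced_events``
    bypasses sampling for deterministic tests.
    """
    if rate < 0 or duration_s <= 0:
        raise ValueError("rate must be >= 0 and duration positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    if forced_events is not None:
        frames = np.array([f for f, _ in forced_events], dtype=int)
        amps = np.array([a for _, a in forced_events], dtype=float)
    else:
        n = rng.poisson(rate / 60.0 * duration_s)
        frames = rng.integers(0, n_frames, size=n)
        amps = amplitude_law.sample(rng, n)
    order = np.argsort(frames, kind="stable")
    frames, amps = frames[order], amps[order]
    trace = _render_train(frames, amps, n_frames, _decay_coef(decay_tau, fps))
    return list(zip(frames.tolist(), amps.tolist())), trace


# ------------------------------------------------------- analytic variance budget


def filter_compensation(cfg: SynthConfig) -> float:
    """Inverse of the 5-point median filter's peak attenuation of an isolated
    causal exponential transient (the filtered peak is the second sample of
    the decay, exp(-2 / (fps * tau)) of the raw peak)."""
    if cfg.decay_tau <= 0:
        return 1.0
    return math.exp(2.0 / (cfg.fps_per_channel * cfg.decay_tau))


def _event_moment_rates(cfg: SynthConfig, low_scale: float) -> tuple[float, float]:
    """Per-event kept first and second amplitude moments after class thinning."""
    law = cfg.amplitude_law
    lo, hi = LOW_AMP_CLASS
    m1 = law.moment(1) - (1 - low_scale) * law.partial_moment(1, lo, hi)
    m2 = law.moment(2) - (1 - low_scale) * law.partial_moment(2, lo, hi)
    return m1, m2


def _participation(cfg: SynthConfig, effect: DrugEffect) -> np.ndarray:
    """Per-region probability of joining a global event.

    The right-S coupling raises right-S participation by the planted gain:
    its event times become more shared while its event rate, amplitude law
    and prominence statistics are untouched.
    """
    p = np.full(len(cfg.regions), cfg.shared_event_participation)
    if effect.rightS_coupling_gain != 0:
        j = cfg.regions.index("R_S")
        p[j] = min(1.0, p[j] + effect.rightS_coupling_gain)
    return p


def _event_second_moments(cfg: SynthConfig, effect: DrugEffect) -> dict:
    """Campbell-theorem variances/covariances of the rendered event trains."""
    fps = cfg.fps_per_channel
    r = _decay_coef(cfg.decay_tau, fps)
    s2 = 1.0 / (1.0 - r * r) if r > 0 else 1.0
    comp = filter_compensation(cfg)
    lam_f = cfg.event_rate / 60.0 / fps  # events per frame per region
    lam_sh = lam_f * cfg.shared_event_frac
    n = len(cfg.regions)
    left_s = cfg.regions.index("L_S")
    m1 = np.empty(n)
    m2 = np.empty(n)
    for i in range(n):
        scale = effect.low_amp_scale_leftS if i == left_s else 1.0
        m1[i], m2[i] = _event_moment_rates(cfg, scale)
    m1 = m1 * comp
    m2 = m2 * comp**2
    v_ev = lam_f * m2 * s2
    # pairwise shared-event rate: global candidate train at rate f*lam/p0, each
    # region joining an event with its participation probability
    part = _participation(cfg, effect)
    lam_global = lam_sh / cfg.shared_event_participation
    cross_ev = lam_global * (np.outer(part, part) * np.outer(m1, m1)) * s2
    np.fill_diagonal(cross_ev, 0.0)
    return {"v_ev": v_ev, "cross_ev": cross_ev, "m1": m1, "s2": s2}


def _baseline_budget(cfg: SynthConfig, effect: DrugEffect | None = None) -> dict:
    """Variance-preserving baseline budget.

    The latent variance is sized once, from the saline parameter set, so every
    region of every condition shares the same correlated latent.  Per-region
    white-noise variance is then topped up so that total frame variance is 1
    in every condition: when drug thinning removes event variance from left S,
    the shortfall returns as (uncorrelated) noise, keeping the session z-score
    neutral with respect to condition.
    """
    effect = effect or DrugEffect()
    n = len(cfg.regions)
    if not cfg.fill_variance:
        return {"v_lat": 0.0, "v_noise": np.full(n, cfg.noise_sd**2)}
    v_ev_sal = _event_second_moments(cfg, DrugEffect())["v_ev"]
    v_lat = float(np.clip(1.0 - v_ev_sal.max() - cfg.noise_sd**2, 0.0, None))
    v_ev = _event_second_moments(cfg, effect)["v_ev"]
    v_noise = np.clip(1.0 - v_ev - v_lat, 0.0, None)
    return {"v_lat": v_lat, "v_noise": v_noise}


def true_trace_corr(cfg: SynthConfig, effect: DrugEffect) -> np.ndarray:
    """Model-implied frame-level correlation of the generated traces."""
    mom = _event_second_moments(cfg, effect)
    budget = _baseline_budget(cfg, effect)
    cov = budget["v_lat"] * cfg.shared_latent_corr + mom["cross_ev"]
    var = budget["v_lat"] + mom["v_ev"] + budget["v_noise"]
    np.fill_diagonal(cov, var)
    d = 1.0 / np.sqrt(var)
    corr = cov * np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


# ----------------------------------------------------------------- trace synthesis


def _sample_latent(cfg: SynthConfig, c_lat: np.ndarray, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) latent (unit marginal variance, correlation ``c_lat``)."""
    phi = math.exp(-1.0 / (cfg.fps_per_channel * cfg.latent_tau_s)) if cfg.latent_tau_s > 0 else 0.0
    chol = np.linalg.cholesky(c_lat + 1e-12 * np.eye(c_lat.shape[0]))
    innov = rng.standard_normal((n_frames, c_lat.shape[0])) @ chol.T
    innov[1:] *= math.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], innov, axis=0)


def generate_region_traces(
    config: SynthConfig,
    condition: str,
    seed: int | np.random.Generator,
    phase: str = "post",
    labels: dict | None = None,
) -> tuple[RegionTraces, GroundTruth]:
    """One session of region traces plus its ground truth.

    Pre-administration sessions use the saline parameter set for every
    condition; drug effects apply to post sessions only.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effect = config.drug_effects.get(condition, DrugEffect()) if phase == "post" else DrugEffect()

    n = len(config.regions)
    n_frames = config.n_frames
    fps = config.fps_per_channel
    r = _decay_coef(config.decay_tau, fps)
    left_s = config.regions.index("L_S")
    lo, hi = LOW_AMP_CLASS

    # --- event trains: a global candidate train that each region joins with its
    # participation probability, plus region-private events; kernels are
    # rendered with peaks pre-scaled for the median filter's attenuation
    comp = filter_compensation(config)
    rate_f = config.event_rate / 60.0 / fps
    part = _participation(config, effect)
    lam_global = rate_f * config.shared_event_frac / config.shared_event_participation
    n_global = rng.poisson(lam_global * n_frames)
    global_frames = rng.integers(0, n_frames, size=n_global)
    event_rows = []
    event_traces = np.zeros((n, n_frames))
    for i, region in enumerate(config.regions):
        joined = global_frames[rng.random(n_global) < part[i]]
        # private rate keeps the region's total event rate at event_rate
        private_rate = rate_f - lam_global * part[i]
        if private_rate < -1e-12:
            raise ValueError("participation exceeds the region event rate")
        n_priv = rng.poisson(max(private_rate, 0.0) * n_frames)
        frames = np.concatenate([joined, rng.integers(0, n_frames, size=n_priv)])
        amps = config.amplitude_law.sample(rng, len(frames))
        if i == left_s and effect.low_amp_scale_leftS < 1.0:
            in_class = (amps >= lo) & (amps < hi)
            drop = in_class & (rng.random(len(amps)) >= effect.low_amp_scale_leftS)
            frames, amps = frames[~drop], amps[~drop]
        order = np.argsort(frames, kind="stable")
        frames, amps = frames[order], amps[order]
        event_traces[i] = _render_train(frames, comp * amps, n_frames, r)
        event_rows.append(
            pd.DataFrame(
                {"region": region, "frame": frames, "time_s": frames / fps, "amplitude": amps}
            )
        )

    # --- residual correlated latent + per-region noise (variance-preserving
    # budget); couplings to the global drive substitute noise variance
    budget = _baseline_budget(config, effect)
    latent = _sample_latent(config, config.shared_latent_corr, n_frames, rng)
    values = (
        event_traces
        + math.sqrt(budget["v_lat"]) * latent.T
        + np.sqrt(budget["v_noise"])[:, None] * rng.standard_normal((n, n_frames))
    )
    if config.day_effect_sd > 0 and labels and "day" in labels:
        day_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(7001, int(labels["day"])))
        )
        values += config.day_effect_sd * day_rng.standard_normal((n, 1))

    labels = dict(labels or {})
    labels.update({"condition": condition, "phase": phase})
    traces = RegionTraces(
        values=values, region_names=config.regions, fps=fps, units="sd", meta=dict(labels)
    )
    truth = GroundTruth(
        events=pd.concat(event_rows, ignore_index=True),
        true_corr=true_trace_corr(config, effect),
        labels=labels,
    )
    return traces, truth


# ----------------------------------------------------------------- study assembly


def condition_orders(config: SynthConfig, seed: int | None = None) -> dict[int, tuple[str, ...]]:
    """Random drug order per subject (a permutation of the three conditions)."""
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=(9001,)))
    return {
        s: tuple(np.array(CONDITIONS)[rng.permutation(len(CONDITIONS))])
        for s in range(config.n_subjects)
    }


def study_manifest(config: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Session manifest: subject x day x {pre, post} with per-subject drug orders."""
    orders = condition_orders(config, seed)
    rows = [
        {"subject": s, "day": d, "condition": orders[s][d], "phase": phase}
        for s in range(config.n_subjects)
        for d in range(config.n_days)
        for phase in PHASES
    ]
    return pd.DataFrame(rows)


def session_rng(master_seed: int, subject: int, day: int, phase: str) -> np.random.Generator:
    """Counter-based per-session stream: any session is reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(subject, day, PHASES.index(phase)))
    )


def generate_study(
    config: SynthConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[tuple[int, int, str], tuple[RegionTraces, GroundTruth]]]:
    """Generate every session of the study; keyed by (subject, day, phase)."""
    master = config.seed if seed is None else seed
    manifest = study_manifest(config, master)
    sessions = {}
    for row in manifest.itertuples(index=False):
        rng = session_rng(master, row.subject, row.day, row.phase)
        sessions[(row.subject, row.day, row.phase)] = generate_region_traces(
            config,
            row.condition,
            rng,
            phase=row.phase,
            labels={"subject": row.subject, "day": row.day},
        )
    return manifest, sessions


# ----------------------------------------------------------------- movie rendering


def _sample_artifact(cfg: SynthConfig, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Slow shared artifact trace (AR(1), SD = artifact.amplitude, ΔF/F units)."""
    art = cfg.artifact
    if art.amplitude == 0:
        return np.zeros(n_frames)
    phi = math.exp(-1.0 / (cfg.fps_per_channel * art.timescale_s)) if art.timescale_s > 0 else 0.0
    innov = rng.standard_normal(n_frames)
    innov[1:] *= math.sqrt(1.0 - phi * phi)
    return art.amplitude * lfilter([1.0], [1.0, -phi], innov)


def render_movie(
    traces: RegionTraces,
    atlas: RegionAtlas,
    config: SynthConfig,
    seed: int | np.random.Generator,
) -> tuple[TwoChannelMovie, np.ndarray]:
    """Render region traces into an interleaved two-channel raw-intensity movie.

    Signal channel pixel = baseline * (1 + dff_scale*trace + gain_signal*artifact);
    reference channel   = baseline * (1 + gain_reference*artifact); both get
    white pixel noise.  Returns the movie and the planted artifact trace.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (512, 512) if config.render_hires else config.movie_shape
    if atlas.label_image.shape != shape:
        raise ValueError(f"atlas shape {atlas.label_image.shape} does not match render shape {shape}")
    missing = [r for r in traces.region_names if not atlas.labels_for_region(r)]
    if missing:
        raise ValueError(f"regions missing from atlas: {missing}")

    n_frames = traces.n_frames
    artifact = _sample_artifact(config, n_frames, rng)
    region_dff = config.dff_scale * traces.values  # (12, T)

    # per-pixel map of region index (-1 outside brain)
    region_idx = np.full(atlas.label_image.shape, -1, dtype=int)
    for i, region in enumerate(traces.region_names):
        for lbl in atlas.labels_for_region(region):
            region_idx[atlas.label_image == lbl] = i

    art = config.artifact
    base = config.baseline_value
    inside = region_idx >= 0
    sig = np.empty((n_frames,) + shape, dtype=np.float32)
    ref = np.empty_like(sig)
    dff_field = np.zeros(shape)
    for t in range(n_frames):
        dff_field[inside] = region_dff[region_idx[inside], t]
        sig[t] = base * (1.0 + dff_field + art.gain_signal * artifact[t])
        ref[t] = base * (1.0 + art.gain_reference * artifact[t])
    if config.noise_sd_px > 0:
        sig += config.noise_sd_px * rng.standard_normal(sig.shape).astype(np.float32)
        ref += config.noise_sd_px * rng.standard_normal(ref.shape).astype(np.float32)

    frames = np.empty((2 * n_frames,) + shape, dtype=np.float32)
    frames[0::2] = sig
    frames[1::2] = ref
    tags = np.empty(2 * n_frames, dtype=object)
    tags[0::2] = SIGNAL_TAG
    tags[1::2] = REFERENCE_TAG
    movie = TwoChannelMovie(
        frames=frames, channel_tags=np.asarray(tags, dtype=str), fps_per_channel=config.fps_per_channel
    )
    return movie, artifact
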