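"""Seeded synthetic infant-sleep cohorts for end-to-end testing.

The study population this emulates: ~10 short laboratory recordings
(about 70 +/- 26 min each) of healthy term infants, scored in 30-s epochs
with roughly 28% wake, 0.7% unable-to-score, and sleep split between REM
and NREM.  The generator produces, per subject:

* a **hypnogram** -- alternating wake/sleep bouts with lognormal
  durations; sleep epochs sub-labelled REM/NREM by a two-state Markov
  chain; a small fraction of epochs relabelled 'U' uniformly at random;
* a **10 Hz actigraphy trace** conditional on the hypnogram -- wake
  epochs emit a burst/quiet Markov-modulated Poisson count process
  (vigorous, clustered movement), with occasional *motionless-wake* runs
  adjacent to bursts (the hard case the pSLP feature exists for); sleep
  epochs emit rare short movement events, more frequent in REM than NREM;
* optionally, **rendered grayscale frames** -- a textured ellipse on a
  noisy background that translates by logged integer steps whenever the
  activity count is positive, giving ground-truth displacements for the
  motion estimator.

Movement is modelled at the activity-count level (blocks per frame), not
biomechanically.  All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidConfigError
from .motion import ActigraphySignal, FrameSequence

__all__ = [
    "SimulationConfig",
    "SyntheticRecording",
    "simulate_hypnogram",
    "simulate_actigraphy",
    "render_frames",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator, with study-scale defaults."""

    n_subjects: int = 10
    recording_minutes_mean: float = 70.0
    recording_minutes_sd: float = 26.0
    recording_minutes_min: float = 20.0
    epoch_length_s: float = 30.0
    frame_rate: float = 10.0

    # bout structure; the wake-bout mean is derived from wake_fraction so
    # the stationary wake share matches the target
    wake_fraction: float = 0.28
    sleep_bout_mean_min: float = 18.0
    sleep_bout_sd_min: float = 12.0
    wake_bout_sd_min: float = 5.0

    # REM/NREM sub-labelling of sleep epochs
    rem_share: float = 0.4
    rem_run_mean_epochs: float = 10.0

    # wake movement: burst/quiet Markov modulation at frame level
    burst_intensity: float = 6.0
    p_quiet_to_burst: float = 0.02
    p_burst_to_quiet: float = 0.03

    # motionless-wake runs adjacent to bursts
    motionless_bout_prob: float = 0.35
    motionless_run_min: int = 2
    motionless_run_max: int = 6

    # sleep movement events
    rem_event_rate: float = 0.6   # events per epoch
    nrem_event_rate: float = 0.2
    event_len_min: int = 3        # frames
    event_len_max: int = 10
    event_intensity: float = 3.0  # blocks/frame during an event

    unscored_fraction: float = 0.007

    # frame rendering (small-format by default; full-scale is 376x480)
    image_height: int = 48
    image_width: int = 64
    blob_height: int = 20
    blob_width: int = 28
    noise_sd: float = 2.0
    max_step: int = 3

    def __post_init__(self) -> None:
        for name in ("wake_fraction", "rem_share", "motionless_bout_prob",
                     "unscored_fraction", "p_quiet_to_burst", "p_burst_to_quiet"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} must lie in [0, 1]")
        for name in ("burst_intensity", "rem_event_rate", "nrem_event_rate",
                     "event_intensity"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0.0 < self.wake_fraction < 1.0:
            raise InvalidConfigError("wake_fraction must lie strictly in (0, 1)")
        if min(self.wake_bout_mean_min, self.sleep_bout_mean_min) * 60 < self.epoch_length_s:
            raise InvalidConfigError("mean bout duration below one epoch is infeasible")
        if self.blob_height > self.image_height or self.blob_width > self.image_width:
            raise InvalidConfigError("blob must fit inside the image")

    @property
    def wake_bout_mean_min(self) -> float:
        wf = self.wake_fraction
        return self.sleep_bout_mean_min * wf / (1.0 - wf)

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.epoch_length_s * self.frame_rate))


@dataclass
class SyntheticRecording:
    """One simulated subject: labels, trace, truth metadata, frames."""

    subject_id: str
    hypnogram: np.ndarray          # per-epoch labels from {W,N1,N2,N3,R,U}
    actigraphy: ActigraphySignal   # n_epochs * frames_per_epoch samples
    bouts: list = field(default_factory=list)  # (state, start_epoch, n_epochs)
    frames: FrameSequence | None = None
    displacements: np.ndarray | None = None  # logged (dy, dx) per transition

    @property
    def n_epochs(self) -> int:
        return len(self.hypnogram)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _lognormal_minutes(rng, mean: float, sd: float) -> float:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_hypnogram(config: SimulationConfig, seed) -> tuple[np.ndarray, list]:
    """Simulate one recording's per-epoch stage labels.

    Returns (labels, bouts) where bouts is a list of
    ``(state, start_epoch, n_epochs)`` with state in {'W', 'S'} describing
    the underlying alternating-renewal structure before sub-labelling.
    """
    rng = _rng(seed)
    epm = 60.0 / config.epoch_length_s  # epochs per minute
    minutes = max(
        config.recording_minutes_min,
        rng.normal(config.recording_minutes_mean, config.recording_minutes_sd),
    )
    n_epochs = max(1, int(round(minutes * epm)))

    # alternating wake/sleep bouts with lognormal durations
    state = "W" if rng.random() < config.wake_fraction else "S"
    labels = np.empty(n_epochs, dtype=object)
    bouts = []
    pos = 0
    while pos < n_epochs:
        mean, sd = (
            (config.wake_bout_mean_min, config.wake_bout_sd_min)
            if state == "W"
            else (config.sleep_bout_mean_min, config.sleep_bout_sd_min)
        )
        dur = max(1, int(round(_lognormal_minutes(rng, mean, sd) * epm)))
        dur = min(dur, n_epochs - pos)
        labels[pos : pos + dur] = state
        bouts.append((state, pos, dur))
        pos += dur
        state = "S" if state == "W" else "W"

    # REM/NREM chain over sleep epochs: stationary REM share, geometric runs
    p_rn = 1.0 / config.rem_run_mean_epochs
    p_nr = p_rn * config.rem_share / max(1e-12, 1.0 - config.rem_share)
    rem_state = rng.random() < config.rem_share
    nrem_stage = "N2"
    sleep_idx = np.flatnonzero(labels == "S")
    for i in sleep_idx:
        if rem_state:
            labels[i] = "R"
            if rng.random() < p_rn:
                rem_state = False
                nrem_stage = rng.choice(["N1", "N2", "N3"], p=[0.2, 0.5, 0.3])
        else:
            labels[i] = nrem_stage
            if rng.random() < p_nr:
                rem_state = True

    # unable-to-score epochs, uniformly placed
    u_mask = rng.random(n_epochs) < config.unscored_fraction
    labels[u_mask] = "U"
    return labels.astype(str), bouts


def simulate_actigraphy(hypnogram: np.ndarray, bouts: list,
                        config: SimulationConfig, seed) -> ActigraphySignal:
    """Simulate the 10 Hz activity-count trace conditional on a hypnogram.

    Wake: two-state (burst/quiet) Markov modulation at frame resolution
    with Poisson counts during bursts; per wake bout, with probability
    ``motionless_bout_prob`` a short interior run of epochs is forced to
    zero ("motionless wake" adjacent to bursts).  Sleep: Poisson-many
    short movement events per epoch, at a higher rate in REM than NREM.
    """
    rng = _rng(seed)
    fpe = config.frames_per_epoch
    n_epochs = len(hypnogram)
    activity = np.zeros(n_epochs * fpe, dtype=np.int64)

    # choose motionless runs per wake bout (hypnogram-level decision)
    motionless = np.zeros(n_epochs, dtype=bool)
    for state, start, dur in bouts:
        if state != "W" or dur < config.motionless_run_min + 2:
            continue
        if rng.random() < config.motionless_bout_prob:
            max_run = min(config.motionless_run_max, dur - 2)
            run = int(rng.integers(config.motionless_run_min, max_run + 1))
            offset = int(rng.integers(1, dur - run))  # keep bursty epochs on both sides
            motionless[start + offset : start + offset + run] = True

    burst = rng.random() < 0.4  # modulation state carries across wake epochs
    for i, lab in enumerate(hypnogram):
        sl = slice(i * fpe, (i + 1) * fpe)
        # U epochs still carry whatever the body does; use the bout state
        underlying = "W" if any(
            s == "W" and start <= i < start + dur for s, start, dur in bouts
        ) else "S"
        if underlying == "W":
            if motionless[i]:
                continue
            states = np.empty(fpe, dtype=bool)
            for t in range(fpe):
                p = config.p_burst_to_quiet if burst else config.p_quiet_to_burst
                if rng.random() < p:
                    burst = not burst
                states[t] = burst
            counts = np.zeros(fpe, dtype=np.int64)
            if states.any():
                counts[states] = rng.poisson(config.burst_intensity, states.sum())
            activity[sl] = counts
        else:
            rate = config.rem_event_rate if lab == "R" else config.nrem_event_rate
            n_events = rng.poisson(rate)
            seg = np.zeros(fpe, dtype=np.int64)
            for _ in range(n_events):
                length = int(rng.integers(config.event_len_min, config.event_len_max + 1))
                start_f = int(rng.integers(0, max(1, fpe - length)))
                seg[start_f : start_f + length] += rng.poisson(
                    config.event_intensity, length
                ).astype(np.int64) + 1
            activity[sl] = seg

    return ActigraphySignal(activity.astype(float), frame_rate=config.frame_rate)


def render_frames(actigraphy: ActigraphySignal, config: SimulationConfig,
                  seed) -> tuple[FrameSequence, np.ndarray]:
    """Render grayscale frames realizing an activity trace.

    A textured ellipse on a dark noisy background translates by a logged
    integer step whenever the activity count at that transition is
    positive, and stays put otherwise.  Returns the frames (one more than
    the number of transitions) and the (n_transitions, 2) array of logged
    (dy, dx) ground-truth displacements.
    """
    rng = _rng(seed)
    h, w = config.image_height, config.image_width
    bh, bw = config.blob_height, config.blob_width
    if bh > h or bw > w:
        raise InvalidConfigError("blob must fit inside the image")

    yy, xx = np.mgrid[0:bh, 0:bw]
    mask = ((yy - (bh - 1) / 2) / (bh / 2)) ** 2 + ((xx - (bw - 1) / 2) / (bw / 2)) ** 2 <= 1.0
    # smooth the blob texture so block matching sees spatial gradients,
    # as real fabric/skin does, rather than per-pixel white noise
    from scipy.ndimage import gaussian_filter

    raw = gaussian_filter(rng.normal(size=(bh, bw)), sigma=1.5)
    raw = (raw - raw.min()) / max(1e-12, raw.max() - raw.min())
    texture = (60 + 140 * raw).astype(np.uint8)

    n_trans = len(actigraphy)
    disp = np.zeros((n_trans, 2), dtype=np.int64)
    pos = np.array([(h - bh) // 2, (w - bw) // 2], dtype=np.int64)
    positions = [pos.copy()]
    for t in range(n_trans):
        if actigraphy.activity[t] > 0:
            step = np.zeros(2, dtype=np.int64)
            while not step.any():
                step = rng.integers(-config.max_step, config.max_step + 1, size=2)
            new = np.clip(pos + step, [0, 0], [h - bh, w - bw])
            disp[t] = new - pos
            pos = new
        positions.append(pos.copy())

    frames = np.empty((n_trans + 1, h, w), dtype=np.uint8)
    for k, p in enumerate(positions):
        bg = np.clip(rng.normal(20.0, config.noise_sd, size=(h, w)), 0, 255)
        y0, x0 = int(p[0]), int(p[1])
        patch = bg[y0 : y0 + bh, x0 : x0 + bw]
        patch[mask] = texture[mask]
        frames[k] = bg.astype(np.uint8)
    return FrameSequence(frames, frame_rate=actigraphy.frame_rate), disp


def simulate_recording(config: SimulationConfig, seed,
                       subject_id: str = "S01",
                       render: bool = False) -> SyntheticRecording:
    """Simulate one subject: hypnogram, actigraphy, optional frames."""
    rng = _rng(seed)
    hyp_rng, act_rng, render_rng = rng.spawn(3)
    hypnogram, bouts = simulate_hypnogram(config, hyp_rng)
    actigraphy = simulate_actigraphy(hypnogram, bouts, config, act_rng)
    rec = SyntheticRecording(
        subject_id=subject_id, hypnogram=hypnogram,
        actigraphy=actigraphy, bouts=bouts,
    )
    if render:
        rec.frames, rec.displacements = render_frames(actigraphy, config, render_rng)
    return rec


def simulate_cohort(config: SimulationConfig | None = None, seed: int = 0,
                    render: bool = False) -> dict[str, SyntheticRecording]:
    """Simulate the full cohort: ``n_subjects`` independent recordings."""
    config = config or SimulationConfig()
    streams = np.random.SeedSequence(seed).spawn(config.n_subjects)
    cohort = {}
    for k, ss in enumerate(streams):
        sid = f"S{k + 1:02d}"
        cohort[sid] = simulate_recording(
            config, np.random.default_rng(ss), subject_id=sid, render=render
        )
    return cohort
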