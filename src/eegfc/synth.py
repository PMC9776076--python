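"""Synthetic multichannel EEG with known, band-specific, stage-dependent
coupling structure.

Each channel is independent 1/f^alpha (pink) background noise plus a sum of
shared band-limited sources. A shared source is white noise restricted to
one frequency band by the same zero-phase Butterworth band-pass used in
preprocessing (so the injected coupling lives exactly in the intended
band), rescaled to unit variance, and added to every channel of its target
set with a per-stage gain. Two channels that share a source are therefore
correlated within that band, with strength controlled by the gain, and the
expected pairwise coupling is known exactly (`ground_truth_coupling`).

Randomness is fully reproducible: every (stage, channel) and
(stage, source) pair draws from its own substream derived from the single
configuration seed, so regenerating any stage in isolation yields
bit-identical data.

The five recording stages emulate a pre/task/post design: 1 open eyes
(baseline), 2 closed eyes, 3 task (e.g., immersive VR), 4 open eyes post,
5 closed eyes post. The ``vr_effect_config`` preset raises the
fronto-posterior block couplings in the beta/low-gamma/high-gamma bands
with stage 1 < stage 4 < stage 3 (and stage 2 < stage 5), on top of a
stage-constant strong neighbor-pair "anchor" coupling that pins the
max-normalization of the connectivity matrices (emulating the near-ceiling
entries that volume conduction produces between adjacent electrodes) and a
stage-constant weak global background coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, default_montage
from .preprocess import BAND_BY_NAME, BandDefinition, Recording, bandpass_array

STAGES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Default analysis bands for the presets (where the emulated effects live).
PRESET_BANDS: tuple[str, ...] = ("beta", "low_gamma", "high_gamma")


@dataclass(frozen=True)
class CouplingSpec:
    """One shared band-limited source projected onto a channel subset."""

    source_id: str
    band: BandDefinition
    target_channels: tuple[str, ...]
    gain_by_stage: dict[int, float]

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gain_by_stage.values()):
            raise ValueError(f"coupling {self.source_id!r} has negative gain")

    def gain(self, stage: int) -> float:
        return float(self.gain_by_stage.get(stage, 0.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic five-stage experiment."""

    montage: Montage = field(default_factory=default_montage)
    sampling_rate: float = 500.0
    stage_duration: float = 60.0
    couplings: tuple[CouplingSpec, ...] = ()
    noise_sd: float = 1.0
    pink_noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.stage_duration <= 0:
            raise ValueError("sampling_rate and stage_duration must be positive")
        labels = set(self.montage.labels)
        for c in self.couplings:
            unknown = set(c.target_channels) - labels
            if unknown:
                raise ValueError(
                    f"coupling {c.source_id!r} targets unknown channels "
                    f"{sorted(unknown)}")
            if c.band.high >= self.sampling_rate / 2:
                raise ValueError(
                    f"coupling {c.source_id!r} band edge {c.band.high} Hz "
                    f">= Nyquist {self.sampling_rate / 2} Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.stage_duration * self.sampling_rate))


def _pink_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_source(rng: np.random.Generator, n: int, band: BandDefinition,
                 fs: float) -> np.ndarray:
    """Unit-variance white noise band-limited to ``band``."""
    src = bandpass_array(rng.standard_normal(n), band, fs)
    sd = src.std()
    return src / sd if sd > 0 else src


def generate_stage(config: SyntheticConfig, stage: int) -> Recording:
    """Generate one stage of the experiment; deterministic in (config, stage)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage}; expected one of {STAGES}")
    n = config.n_samples
    labels = config.montage.labels
    stage_root = np.random.SeedSequence(entropy=config.seed,
                                        spawn_key=(stage,))
    streams = stage_root.spawn(len(labels) + len(config.couplings))
    data = np.empty((len(labels), n))
    for i, ss in enumerate(streams[:len(labels)]):
        rng = np.random.default_rng(ss)
        data[i] = config.noise_sd * _pink_noise(rng, n,
                                                config.pink_noise_exponent)
    for c, ss in zip(config.couplings, streams[len(labels):]):
        gain = c.gain(stage)
        source = _band_source(np.random.default_rng(ss), n, c.band,
                              config.sampling_rate)
        if gain == 0.0:
            continue
        idx = config.montage.indices(c.target_channels)
        data[idx] += gain * source
    return Recording(labels=labels, sampling_rate=config.sampling_rate,
                     data=data, stage=stage)


def generate_experiment(config: SyntheticConfig) -> list[Recording]:
    """All five stages, with independent noise streams per stage."""
    return [generate_stage(config, s) for s in STAGES]


def ground_truth_coupling(config: SyntheticConfig, stage: int,
                          band: str | BandDefinition):
    """The known expected coupling matrix for one stage and band.

    Entry (i, j) sums, over the sources of that band, the product of the
    gains applied to channels i and j; it is a test oracle for the ranking
    of estimated connectivity, not an MI value.
    """
    from .connectivity import ConnectivityMatrix

    band_name = band if isinstance(band, str) else band.name
    labels = config.montage.labels
    values = np.zeros((len(labels), len(labels)))
    for c in config.couplings:
        if c.band.name != band_name:
            continue
        g = c.gain(stage)
        if g == 0.0:
            continue
        idx = config.montage.indices(c.target_channels)
        for a in idx:
            for b in idx:
                if a != b:
                    values[a, b] += g * g
    return ConnectivityMatrix(labels=labels, values=values, band=band_name,
                              stage=stage, normalized=False)


# ---------------------------------------------------------------------------
# presets

#: Stage-dependent block gains emulating a task effect that partially
#: persists post-task: baseline < post < task, and closed-eyes post >
#: closed-eyes pre.
EFFECT_GAINS: dict[int, float] = {1: 0.2, 2: 0.2, 3: 0.65, 4: 0.35, 5: 0.35}
NULL_GAINS: dict[int, float] = {s: 0.4 for s in STAGES}
ANCHOR_GAIN: float = 1.5
BACKGROUND_GAIN: float = 0.1

#: The coupled channel blocks: within-posterior, within-right-frontal, and
#: the two fronto-posterior interaction blocks (left and right frontal
#: groups joined with the extended posterior group).
def _block_sets(montage: Montage) -> dict[str, tuple[str, ...]]:
    g = montage.groups
    return {
        "posterior": g["posterior"],
        "frontal_right": g["frontal_right"],
        "left_fronto_posterior": tuple(g["frontal_left"]) + tuple(
            g["posterior_extended"]),
        "right_fronto_posterior": tuple(g["frontal_right"][:4]) + tuple(
            g["posterior"]),
    }


def _preset(gains: dict[int, float], seed: int, stage_duration: float,
            bands: tuple[str, ...]) -> SyntheticConfig:
    montage = default_montage()
    couplings: list[CouplingSpec] = []
    for band_name in bands:
        band = BAND_BY_NAME[band_name]
        for block_name, channels in _block_sets(montage).items():
            couplings.append(CouplingSpec(
                source_id=f"{block_name}:{band_name}", band=band,
                target_channels=tuple(channels),
                gain_by_stage=dict(gains)))
        couplings.append(CouplingSpec(
            source_id=f"anchor:{band_name}", band=band,
            target_channels=("Cz", "C3"),
            gain_by_stage={s: ANCHOR_GAIN for s in STAGES}))
        couplings.append(CouplingSpec(
            source_id=f"background:{band_name}", band=band,
            target_channels=montage.labels,
            gain_by_stage={s: BACKGROUND_GAIN for s in STAGES}))
    return SyntheticConfig(montage=montage, couplings=tuple(couplings),
                           seed=seed, stage_duration=stage_duration)


def vr_effect_config(seed: int = 0, stage_duration: float = 60.0,
                     bands: tuple[str, ...] = PRESET_BANDS) -> SyntheticConfig:
    """Task-effect preset: block couplings with stage 1 < stage 4 < stage 3."""
    return _preset(EFFECT_GAINS, seed, stage_duration, bands)


def null_config(seed: int = 0, stage_duration: float = 60.0,
                bands: tuple[str, ...] = PRESET_BANDS) -> SyntheticConfig:
    """Null preset: identical coupling gains in every stage."""
    return _preset(NULL_GAINS, seed, stage_duration, bands)


def occipital_lateralized_config(seed: int = 0, stage_duration: float = 60.0,
                                 channel: str = "O2",
                                 bands: tuple[str, ...] = ("high_gamma",),
                                 ) -> SyntheticConfig:
    """Preset that turns one occipital channel into a stage-3 hub.

    Star-like pairwise couplings from ``channel`` to distant channels make
    it an intermediary on many shortest paths during the task stage only,
    so its betweenness rises from stage 1 to stage 3.
    """
    montage = default_montage()
    # two distant spokes only: every extra spoke source inflates the hub
    # channel's variance and dilutes its pairwise correlations below the
    # level where two-hop routes beat the histogram-bias floor edges
    spokes = {"F3": {1: 0.3, 2: 0.3, 3: 3.0, 4: 1.5, 5: 1.0},
              "CP5": {1: 0.3, 2: 0.3, 3: 3.0, 4: 1.5, 5: 1.0}}
    # a random stage-constant pair connectome (seed-dependent, so each
    # subject gets their own) keeps betweenness continuous-valued across
    # subjects; without it the hub's boost is a quantized path count and
    # the group t-test degenerates on zero-variance differences
    rng = np.random.default_rng([seed, 0x0CC1])
    others = [l for l in montage.labels if l not in (channel, "O1")]
    couplings: list[CouplingSpec] = []
    for band_name in bands:
        band = BAND_BY_NAME[band_name]
        for spoke, gains in spokes.items():
            couplings.append(CouplingSpec(
                source_id=f"star:{channel}-{spoke}:{band_name}", band=band,
                target_channels=(channel, spoke),
                gain_by_stage=dict(gains)))
        for k in range(60):
            a, b = rng.choice(len(others), size=2, replace=False)
            gain = float(rng.uniform(0.25, 0.4))
            couplings.append(CouplingSpec(
                source_id=f"random-pair-{k}:{band_name}", band=band,
                target_channels=(others[a], others[b]),
                gain_by_stage={s: gain for s in STAGES}))
        # per-subject jitter on one spoke's variance moves the hub's
        # routing margin smoothly across subjects
        jitter = float(rng.uniform(0.0, 0.8))
        couplings.append(CouplingSpec(
            source_id=f"spoke-jitter:{band_name}", band=band,
            target_channels=("F3", "T8"),
            gain_by_stage={s: jitter for s in STAGES}))
        # weak stage-constant edges at the occipital pair give both
        # candidate channels a small continuous baseline betweenness, so
        # the group contrast never has literally zero-variance differences
        for occ in (channel, "O1"):
            for k in range(3):
                a = int(rng.integers(len(others)))
                g_occ = float(rng.uniform(0.15, 0.3))
                couplings.append(CouplingSpec(
                    source_id=f"occ-baseline-{occ}-{k}:{band_name}",
                    band=band, target_channels=(occ, others[a]),
                    gain_by_stage={s: g_occ for s in STAGES}))
        couplings.append(CouplingSpec(
            source_id=f"background:{band_name}", band=band,
            target_channels=montage.labels,
            gain_by_stage={s: 0.15 for s in STAGES}))
    return SyntheticConfig(montage=montage, couplings=tuple(couplings),
                           seed=seed, stage_duration=stage_duration)


def subject_seed(base_seed: int, subject: int) -> int:
    """Derive a per-subject seed below 2**31 from a base seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(subject,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
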