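"""Synthetic dual-sensor movie generator with known ground truth.

The forward model composes three stages that mirror the physics the analysis
assumes:

1. **Release**: dopamine concentration is a uniform background plus a sum of
   spatially Gaussian hotspots, each driven at every stimulus frame by the
   rise–decay kernel (1 − e^(−t/τON))·e^(−t/τOFF), normalized to peak 1.
   Events superpose linearly.
2. **Binding**: each sensor converts concentration to ΔF/F through a Hill
   transform ΔF/F = dff_max · Cⁿ / (Cⁿ + Kdⁿ).  The two bundled sensor
   presets differ in affinity by three orders of magnitude (Kd tens of nM
   for the GRAB-like channel, tens of µM for the nIRCat-like channel), so at
   sub-saturating dopamine the low-affinity response is ~10³-fold smaller.
3. **Rendering**: counts F = f0·(1 + ΔF/F)·B(t) + ε with a double-exponential
   photobleach curve B (normalized so B(0) = 1), i.i.d. Gaussian (or Poisson)
   noise, clipping to the unsigned 16-bit range.

All randomness flows from the single seed in :class:`SyntheticConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import MovieStack, write_movie
from .kinetics import peak_factor

logger = logging.getLogger(__name__)

__all__ = [
    "SensorModel",
    "HotspotField",
    "StimulusProtocol",
    "SyntheticConfig",
    "GRAB_LIKE",
    "NIRCAT_LIKE",
    "CAL520_LIKE",
    "simulate_concentration",
    "sensor_response",
    "render_movie",
    "generate_wave_fixture",
    "generate_hotspot_fixture",
]


@dataclass(frozen=True)
class SensorModel:
    """Hill binding parameters plus response kinetics for one indicator.

    kd is the dissociation constant in µM (concentration of half-maximal
    response); dff_max the saturating ΔF/F; tau_on/tau_off the rise and
    decay time constants in seconds.
    """

    name: str
    kd: float
    dff_max: float
    tau_on: float
    tau_off: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("kd", "hill_n", "dff_max", "tau_on", "tau_off"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


# Bundled presets.  Affinities reflect the contrast between a high-affinity
# genetically encoded dopamine indicator (tens of nM) and a low-affinity
# nanotube catecholamine sensor (tens of µM); with equal dff_max and n = 1
# the linear-regime response ratio is kd_g/kd_n = 1e-3.
GRAB_LIKE = SensorModel("grab_da_like", kd=0.02, dff_max=1.0, tau_on=0.5, tau_off=2.0)
NIRCAT_LIKE = SensorModel("nircat_like", kd=20.0, dff_max=1.0, tau_on=1.5, tau_off=6.0)
# Calcium channel stand-in for wave imaging: high SNR, fast kinetics so
# sparse waves stand far above the full-trace SD used for z-scoring.
CAL520_LIKE = SensorModel("cal520_like", kd=0.3, dff_max=1.0, tau_on=0.5, tau_off=1.5)


@dataclass(frozen=True)
class HotspotField:
    """Localized release sites: Gaussian concentration bumps on a background.

    centers are (y, x) positions in µm; sigma the common Gaussian width in
    µm; amplitudes the peak added concentration per hotspot in µM.
    """

    centers: tuple[tuple[float, float], ...]
    sigma: float
    amplitudes: tuple[float, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.centers) != len(self.amplitudes):
            raise ValueError("centers and amplitudes must have equal length")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be nonnegative")
        if self.background < 0:
            raise ValueError("background must be nonnegative")


@dataclass(frozen=True)
class StimulusProtocol:
    """Event timing: frame indices at which release (or a wave) occurs."""

    event_frames: tuple[int, ...]
    kind: str = "electrical"  # electrical | k_puff | wave
    per_event_scale: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        ef = self.event_frames
        if any(b <= a for a, b in zip(ef, ef[1:])):
            raise ValueError("event_frames must be strictly increasing")
        if self.kind not in ("electrical", "k_puff", "wave"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.per_event_scale is not None and len(self.per_event_scale) != len(ef):
            raise ValueError("per_event_scale must match event_frames length")

    def scales(self) -> np.ndarray:
        if self.per_event_scale is None:
            return np.ones(len(self.event_frames))
        return np.asarray(self.per_event_scale, dtype=float)


@dataclass(frozen=True)
class SyntheticConfig:
    """Acquisition and rendering parameters for a synthetic movie.

    Defaults mirror a scanned-slice acquisition (1.47 frames/s) at a
    test-friendly 64×64 frame; pixel size is free metadata because the grid
    analysis works in pixels.  ``bleach`` is (a1, tau1, a2, tau2) of the
    double-exponential photobleach curve, normalized internally so B(0) = 1.
    """

    n_frames: int = 120
    height: int = 64
    width: int = 64
    frame_rate: float = 1.47
    pixel_size: float = 0.75
    f0_mean: float = 2000.0
    noise_sd: float = 10.0
    bleach: tuple[float, float, float, float] = (0.02, 40.0, 0.98, 4000.0)
    seed: int = 0
    noise_mode: str = "gaussian"  # gaussian | poisson

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.height < 1 or self.width < 1:
            raise ValueError("movie dimensions too small")
        if self.frame_rate <= 0 or self.pixel_size <= 0 or self.f0_mean <= 0:
            raise ValueError("frame_rate, pixel_size and f0_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        a1, t1, a2, t2 = self.bleach
        if t1 <= 0 or t2 <= 0 or a1 < 0 or a2 < 0 or a1 + a2 <= 0:
            raise ValueError("invalid bleach parameters")
        if self.noise_mode not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def bleach_curve(self) -> np.ndarray:
        """B(t) = (a1·e^(−t/τ1) + a2·e^(−t/τ2)) / (a1 + a2); B(0) = 1."""
        a1, t1, a2, t2 = self.bleach
        t = self.times
        return (a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)) / (a1 + a2)


def _event_kernel(t: np.ndarray, model: SensorModel) -> np.ndarray:
    """Rise–decay kernel normalized to peak 1; zero for t < 0."""
    k = np.where(
        t >= 0,
        (1.0 - np.exp(-np.clip(t, 0, None) / model.tau_on))
        * np.exp(-np.clip(t, 0, None) / model.tau_off),
        0.0,
    )
    return k / peak_factor(model.tau_on, model.tau_off)


def hotspot_map(field: HotspotField, config: SyntheticConfig) -> np.ndarray:
    """Spatial sum of hotspot Gaussians (Y×X, µM), excluding the background."""
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    y_um = yy * config.pixel_size
    x_um = xx * config.pixel_size
    spatial = np.zeros((config.height, config.width))
    for (cy, cx), amp in zip(field.centers, field.amplitudes):
        if not (0 <= cy <= (config.height - 1) * config.pixel_size):
            raise ValueError(f"hotspot center y={cy} outside field of view")
        if not (0 <= cx <= (config.width - 1) * config.pixel_size):
            raise ValueError(f"hotspot center x={cx} outside field of view")
        spatial += amp * np.exp(
            -((y_um - cy) ** 2 + (x_um - cx) ** 2) / (2.0 * field.sigma**2)
        )
    return spatial


def simulate_concentration(
    field: HotspotField,
    protocol: StimulusProtocol,
    model: SensorModel,
    config: SyntheticConfig,
) -> np.ndarray:
    """Dopamine concentration movie (T×Y×X, µM) from hotspots and events.

    Concentration at pixel p and time t is

        background + Σ_events Σ_hotspots amp·scale·G(p)·K(t − t_event)

    with the spatial Gaussian G normalized to 1 at its center and the
    temporal kernel K normalized to peak 1 (the model's τON/τOFF set its
    shape).  Event fields superpose linearly; before the first event only
    the background is present.
    """
    if protocol.event_frames and (
        protocol.event_frames[0] < 0 or protocol.event_frames[-1] >= config.n_frames
    ):
        raise ValueError(
            f"event frames {protocol.event_frames} outside movie of "
            f"{config.n_frames} frames"
        )
    t = config.times
    drive = np.zeros(config.n_frames)
    for f, s in zip(protocol.event_frames, protocol.scales()):
        drive += s * _event_kernel(t - t[f], model)
    spatial = hotspot_map(field, config)
    return field.background + spatial[None, :, :] * drive[:, None, None]


def sensor_response(conc: np.ndarray, model: SensorModel) -> np.ndarray:
    """Pointwise Hill transform: ΔF/F = dff_max·Cⁿ/(Cⁿ + Kdⁿ).

    Monotone nondecreasing in C and bounded by dff_max.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    cn = conc**model.hill_n
    return model.dff_max * cn / (cn + model.kd**model.hill_n)


def render_movie(
    dff: np.ndarray,
    config: SyntheticConfig,
    channel: str = "",
    stim_frames: tuple[int, ...] = (),
) -> MovieStack:
    """Render a ΔF/F movie to unsigned 16-bit counts.

    F(p, t) = f0_mean·(1 + ΔF/F)·B(t) + ε with the normalized bleach curve B
    and i.i.d. noise ε of scale noise_sd (Gaussian by default; in Poisson
    mode counts are Poisson-distributed around the noiseless mean and
    noise_sd is ignored).  Values are clipped to [0, 65535] with a logged
    warning; identical config (including seed) gives bit-identical output.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.shape != (config.n_frames, config.height, config.width):
        raise ValueError(
            f"dff shape {dff.shape} does not match config "
            f"{(config.n_frames, config.height, config.width)}"
        )
    b = config.bleach_curve()[:, None, None]
    clean = config.f0_mean * (1.0 + dff) * b
    rng = np.random.default_rng(config.seed)
    if config.noise_mode == "poisson":
        noisy = rng.poisson(np.clip(clean, 0, None)).astype(float)
    else:
        noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else clean
    n_clip = int(np.sum((noisy < 0) | (noisy > 65535)))
    if n_clip:
        logger.warning("render_movie: clipped %d samples to [0, 65535]", n_clip)
    counts = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    return MovieStack(
        data=counts,
        frame_rate=config.frame_rate,
        pixel_size=config.pixel_size,
        channel=channel,
        stim_frames=stim_frames,
    )


def generate_wave_fixture(
    config: SyntheticConfig,
    wave_frames: tuple[int, ...],
    ca_model: SensorModel = CAL520_LIKE,
    da_model: SensorModel = NIRCAT_LIKE,
    ca_amp_um: float = 0.3,
    da_amp_um: float = 0.2,
    min_separation_s: float = 10.0,
    outdir: str | Path | None = None,
) -> tuple[MovieStack, MovieStack, dict]:
    """Dual-channel retinal-wave fixture: global transients in both channels.

    Each wave frame drives a spatially uniform release transient seen by a
    high-SNR calcium-like channel (drive ``ca_amp_um`` µM against its Kd)
    and, through the low-affinity dopamine channel, a much weaker response
    (``da_amp_um`` µM against a tens-of-µM Kd).  Wave amplitudes vary ±20%
    event to event (seeded).  Waves must be separated by more than
    ``min_separation_s`` so downstream detection is unambiguous.

    Returns (calcium movie, nIR movie, ground truth).  The ground truth
    records the wave frames, the per-event scales, the seeds, and the
    noiseless calcium-trace peak frame per wave (what an ideal detector
    should report).  If ``outdir`` is given, both channels are written as
    TIFF + sidecar along with ``ground_truth.json``.
    """
    wf = tuple(int(f) for f in wave_frames)
    min_gap = min_separation_s * config.frame_rate
    if any(b - a <= min_gap for a, b in zip(wf, wf[1:])):
        raise ValueError(
            f"wave frames must be separated by more than {min_separation_s} s "
            f"({min_gap:.1f} frames)"
        )
    rng = np.random.default_rng(config.seed)
    scales = tuple(rng.uniform(0.8, 1.2, size=len(wf)))

    t = config.times
    movies = {}
    for label, model, amp in (
        ("ca", ca_model, ca_amp_um),
        ("nir", da_model, da_amp_um),
    ):
        drive = np.zeros(config.n_frames)
        for f, s in zip(wf, scales):
            drive += s * _event_kernel(t - t[f], model)
        conc = amp * drive
        dff_trace = sensor_response(conc, model)
        dff = np.broadcast_to(
            dff_trace[:, None, None], (config.n_frames, config.height, config.width)
        )
        cfg = config.replace(seed=int(rng.integers(0, 2**31 - 1)))
        movies[label] = render_movie(dff, cfg, channel=label, stim_frames=wf)

    # ideal detector answer: per-wave argmax of the noiseless calcium trace
    peak_offset = int(np.argmax(_event_kernel(t - t[0], ca_model)))
    peak_frames = [min(f + peak_offset, config.n_frames - 1) for f in wf]
    truth = {
        "wave_frames": list(wf),
        "peak_frames": peak_frames,
        "per_event_scale": list(map(float, scales)),
        "ca_amp_um": ca_amp_um,
        "da_amp_um": da_amp_um,
        "ca_model": dataclasses.asdict(ca_model),
        "da_model": dataclasses.asdict(da_model),
        "seed": config.seed,
        "frame_rate_hz": config.frame_rate,
    }
    if outdir is not None:
        outdir = Path(outdir)
        write_movie(movies["ca"], outdir / "calcium.tif", seed=config.seed)
        write_movie(movies["nir"], outdir / "nir.tif", seed=config.seed)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return movies["ca"], movies["nir"], truth


def generate_hotspot_fixture(
    config: SyntheticConfig | None = None,
    model: SensorModel = NIRCAT_LIKE,
    n_trials: int = 3,
    stim_frame: int = 30,
    square_px: int = 8,
    hotspot_squares: tuple[tuple[int, int], ...] = ((1, 1), (2, 5), (4, 3), (5, 6), (6, 2)),
    amplitudes_um: tuple[float, ...] = (60.0, 45.0, 60.0, 4.0, 3.6),
    sigma_um: float = 1.0,
    amp_scale: float = 1.0,
    outdir: str | Path | None = None,
) -> tuple[list[MovieStack], dict]:
    """Striatal-style fixture: repeated stimulation of Gaussian hotspots.

    Hotspots sit at the centers of the named grid squares so the expected
    active-ROI set is unambiguous by construction (neighbor-square leakage
    is orders of magnitude below the 2-SD criterion at the default noise).
    Each trial is an independent movie with one stimulus at ``stim_frame``;
    trial noise seeds derive from the config seed.  ``amp_scale`` scales all
    amplitudes (e.g. 0.4 for a release-suppressed pharmacological condition).

    Returns (trial movies, ground truth); the ground truth lists hotspot
    squares/centers/amplitudes, the stimulus frame and the kinetic
    constants.  With ``outdir`` the trials and ground truth are written out.
    """
    if config is None:
        config = SyntheticConfig()
    if len(hotspot_squares) != len(amplitudes_um):
        raise ValueError("hotspot_squares and amplitudes_um must match")
    half = (square_px - 1) / 2.0
    centers = tuple(
        ((r * square_px + half) * config.pixel_size, (c * square_px + half) * config.pixel_size)
        for r, c in hotspot_squares
    )
    amps = tuple(a * amp_scale for a in amplitudes_um)
    field = HotspotField(centers=centers, sigma=sigma_um, amplitudes=amps)
    protocol = StimulusProtocol((stim_frame,), kind="electrical")
    conc = simulate_concentration(field, protocol, model, config)
    dff = sensor_response(conc, model)

    rng = np.random.default_rng(config.seed)
    movies = []
    for _ in range(n_trials):
        cfg = config.replace(seed=int(rng.integers(0, 2**31 - 1)))
        movies.append(render_movie(dff, cfg, channel=model.name, stim_frames=(stim_frame,)))
    truth = {
        "hotspot_squares": [list(s) for s in hotspot_squares],
        "centers_um": [list(c) for c in centers],
        "amplitudes_um": list(amps),
        "sigma_um": sigma_um,
        "square_px": square_px,
        "stim_frame": stim_frame,
        "model": dataclasses.asdict(model),
        "seed": config.seed,
        "n_trials": n_trials,
        "frame_rate_hz": config.frame_rate,
    }
    if outdir is not None:
        outdir = Path(outdir)
        for i, mov in enumerate(movies):
            write_movie(mov, outdir / f"trial_{i}.tif", seed=config.seed)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return movies, truth
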