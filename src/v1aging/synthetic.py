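"""Seeded synthetic-data generator for the whole analysis pipeline.

Everything the pipeline consumes can be generated here with a fixed seed:

* populations of double-Gaussian-tuned Poisson-spiking neurons whose
  analytic selectivity indices follow a group preset (young / old) built
  from the published group statistics;
* per-trial stimulus and pre-stimulus spike trains, and optional raw
  voltage traces with planted spike templates;
* spatial point-process cell maps emulating NeuN/GABA double labelling,
  and rendered two-channel images of them;
* western-blot lanes as lognormal optical densities.

Ground truth is always returned alongside the data so recovery can be
tested; every generator is a pure function of (spec, seed).

Index-targeted neuron generation: rather than sampling tuning amplitudes
freely, each neuron's target OSI, DSI, peak evoked rate and spontaneous
rate are drawn from the preset distributions, and the two Gaussian
amplitudes plus the shared width are solved so the noiseless tuning curve
reproduces those targets exactly.  This makes parameter- and
index-recovery tests well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from . import reference
from .spikes import SpikeTrain, StimulusProtocol, Trial, TrialSet, VoltageTrace
from .tuning import double_gaussian

MAX_DEPTH_UM = 1500.0


# ---------------------------------------------------------------------------
# presets and distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPreset:
    """Configuration surface of the simulator for one age group."""

    name: str
    osi_mean: float
    osi_sd: float
    dsi_mean: float
    dsi_sd: float
    or_mean: float
    or_sd: float
    sa_mean: float
    sa_sd: float
    simple_fraction: float
    n_neurons: int
    sa_family: str = "truncnorm"  # "truncnorm" | "lognormal"

    def __post_init__(self) -> None:
        for sd in (self.osi_sd, self.dsi_sd, self.or_sd, self.sa_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        for m in (self.osi_mean, self.dsi_mean, self.simple_fraction):
            if not 0.0 <= m <= 1.0:
                raise ValueError("index means and simple_fraction must be in [0,1]")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be nonnegative")
        if self.sa_family not in ("truncnorm", "lognormal"):
            raise ValueError("sa_family must be 'truncnorm' or 'lognormal'")


def young_preset(n_neurons: int | None = None) -> GroupPreset:
    g = reference.GROUP_STATS
    return GroupPreset(
        name="young",
        osi_mean=g["osi"]["young"][0], osi_sd=g["osi"]["young"][1],
        dsi_mean=g["dsi"]["young"][0], dsi_sd=g["dsi"]["young"][1],
        or_mean=g["or"]["young"][0], or_sd=g["or"]["young"][1],
        sa_mean=g["sa"]["young"][0], sa_sd=g["sa"]["young"][1],
        simple_fraction=reference.SIMPLE_COMPLEX["young"][0]
        / sum(reference.SIMPLE_COMPLEX["young"]),
        n_neurons=n_neurons if n_neurons is not None else reference.N_NEURONS["young"],
        sa_family="truncnorm",
    )


def old_preset(n_neurons: int | None = None) -> GroupPreset:
    g = reference.GROUP_STATS
    return GroupPreset(
        name="old",
        osi_mean=g["osi"]["old"][0], osi_sd=g["osi"]["old"][1],
        dsi_mean=g["dsi"]["old"][0], dsi_sd=g["dsi"]["old"][1],
        or_mean=g["or"]["old"][0], or_sd=g["or"]["old"][1],
        sa_mean=g["sa"]["old"][0], sa_sd=g["sa"]["old"][1],
        simple_fraction=reference.SIMPLE_COMPLEX["old"][0]
        / sum(reference.SIMPLE_COMPLEX["old"]),
        n_neurons=n_neurons if n_neurons is not None else reference.N_NEURONS["old"],
        sa_family="lognormal",  # large mean/SD: lognormal matched by moments
    )


def index_truncnorm(mean: float, sd: float):
    """Truncated normal on [0, 1] located at (mean, sd) before truncation.

    This is the distribution the selectivity-index targets are drawn from;
    its moments are the reference against which generator calibration is
    checked (the post-truncation mean is slightly below ``mean``).
    """
    if sd == 0:
        return sps.norm(loc=mean, scale=0)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return sps.truncnorm(a, b, loc=mean, scale=sd)


def matched_truncnorm_at_zero(mean: float, sd: float):
    """Truncated-at-zero normal whose post-truncation moments match (mean, sd).

    Solved by 1-D root finding on the standardized location; feasible for
    coefficients of variation below ~1 (the half-normal-to-exponential
    range of the family).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd == 0:
        return sps.norm(loc=mean, scale=0)
    cv_target = sd / mean

    # cv depends only on the standardized location a = mu/s:
    def cv(a: float) -> float:
        m, v = sps.truncnorm.stats(-a, np.inf, loc=a, scale=1.0, moments="mv")
        return float(np.sqrt(v) / m)

    lo, hi = -40.0, 60.0
    if not (cv(hi) <= cv_target <= cv(lo)):
        raise ValueError(
            f"cv {cv_target:.3f} unreachable by a truncated normal; use lognormal"
        )
    a = optimize.brentq(lambda x: cv(x) - cv_target, lo, hi, xtol=1e-10)
    m_std = float(sps.truncnorm.stats(-a, np.inf, loc=a, scale=1.0, moments="m"))
    sd_std = float(
        np.sqrt(sps.truncnorm.stats(-a, np.inf, loc=a, scale=1.0, moments="v"))
    )
    s = sd / sd_std
    mu = s * a
    # shift so the mean is matched exactly
    assert abs(s * m_std - mean) < 1e-6 * max(1.0, mean)
    return sps.truncnorm((0.0 - mu) / s, np.inf, loc=mu, scale=s)


def matched_lognormal(mean: float, sd: float):
    """Lognormal with the given first two moments."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd == 0:
        return sps.norm(loc=mean, scale=0)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return sps.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))


def sa_distribution(preset: GroupPreset):
    if preset.sa_family == "lognormal":
        return matched_lognormal(preset.sa_mean, preset.sa_sd)
    return matched_truncnorm_at_zero(preset.sa_mean, preset.sa_sd)


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronGroundTruth:
    """True tuning parameters of one simulated neuron (baseline a0 = 0)."""

    a1_true: float  # spikes/s, preferred-direction lobe amplitude
    a2_true: float  # spikes/s, null-direction lobe amplitude
    theta0_true: float  # degrees in [0, 360)
    sigma_true: float  # degrees
    sa_true: float  # spikes/s
    modulation_depth: float  # in [0, 1]
    depth_um: float
    osi_true: float  # analytic index of the noiseless curve
    dsi_true: float
    or_true: float  # peak evoked rate, spikes/s
    is_simple_true: bool = False

    def __post_init__(self) -> None:
        if not (self.a1_true >= self.a2_true >= 0):
            raise ValueError("amplitudes must satisfy a1 >= a2 >= 0")
        if self.sigma_true <= 0:
            raise ValueError("sigma must be positive")
        if self.sa_true < 0:
            raise ValueError("spontaneous rate must be nonnegative")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")

    def evoked(self, theta_deg: np.ndarray | float) -> np.ndarray:
        """Noiseless evoked rate (spikes/s) at motion direction theta."""
        return double_gaussian(
            theta_deg, 0.0, self.a1_true, self.a2_true,
            self.theta0_true, self.sigma_true,
        )


def analytic_indices(
    a1: float, a2: float, sigma: float, sa: float
) -> tuple[float, float]:
    """OSI and DSI of the noiseless double-Gaussian evoked curve.

    Uses the fitted-curve definition: optimal response at theta0, null at
    theta0+180 (DSI) or the mean of theta0 +/- 90 (OSI), spontaneous rate
    in the denominator.
    """
    k90 = math.exp(-(90.0**2) / (2.0 * sigma**2))
    k180 = math.exp(-(180.0**2) / (2.0 * sigma**2))
    r_opt = a1 + a2 * k180
    r_null_dir = a2 + a1 * k180
    r_null_orth = (a1 + a2) * k90
    denom = r_opt - sa
    if denom <= 0:
        raise ValueError("peak evoked rate does not exceed spontaneous rate")
    return (r_opt - r_null_orth) / denom, (r_opt - r_null_dir) / denom


def solve_tuning_shape(
    osi: float, dsi: float, peak: float, sa: float,
    sigma_lo: float = 5.0, sigma_hi: float = 150.0,
) -> tuple[float, float, float] | None:
    """Solve (a1, a2, sigma) so the noiseless curve hits the index targets.

    Closed-form inversion of the analytic index expressions given sigma,
    with sigma found by 1-D root bracketing; returns None when no
    admissible solution (a1 >= a2 >= 0) exists.
    """
    D = peak - sa
    if D <= 0 or not (0 <= osi <= 1) or not (0 <= dsi <= 1):
        return None

    def implied_peak_gap(sigma: float) -> float:
        k90 = math.exp(-(90.0**2) / (2.0 * sigma**2))
        k180 = math.exp(-(180.0**2) / (2.0 * sigma**2))
        M = dsi * D / (1.0 - k180)  # a1 - a2
        S = (peak - osi * D) / k90  # a1 + a2
        return (S * (1.0 + k180) + M * (1.0 - k180)) / 2.0 - peak

    grid = np.geomspace(sigma_lo, sigma_hi, 80)
    vals = np.array([implied_peak_gap(s) for s in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    sigma = optimize.brentq(implied_peak_gap, grid[i], grid[i + 1], xtol=1e-10)
    k90 = math.exp(-(90.0**2) / (2.0 * sigma**2))
    k180 = math.exp(-(180.0**2) / (2.0 * sigma**2))
    M = dsi * D / (1.0 - k180)
    S = (peak - osi * D) / k90
    a1, a2 = (S + M) / 2.0, (S - M) / 2.0
    if a2 < 0 or a1 < a2:
        return None
    return a1, a2, sigma


def make_population(
    preset: GroupPreset, seed: int, max_retries: int = 200
) -> list[NeuronGroundTruth]:
    """Draw a population of ground-truth neurons under a group preset.

    Per neuron, (OSI, DSI, peak rate, SA) targets are drawn from the preset
    distributions — indices from [0,1]-truncated normals, peak rate and SA
    from nonnegative distributions moment-matched to the preset — and the
    tuning shape is solved to hit them.  Infeasible target draws are
    redrawn up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    osi_dist = index_truncnorm(preset.osi_mean, preset.osi_sd)
    dsi_dist = index_truncnorm(preset.dsi_mean, preset.dsi_sd)
    or_dist = matched_truncnorm_at_zero(preset.or_mean, preset.or_sd)
    sa_dist = sa_distribution(preset)

    neurons: list[NeuronGroundTruth] = []
    for _ in range(preset.n_neurons):
        solution = None
        for _attempt in range(max_retries):
            osi = float(osi_dist.rvs(random_state=rng))
            dsi = float(dsi_dist.rvs(random_state=rng))
            peak = float(or_dist.rvs(random_state=rng))
            sa = float(sa_dist.rvs(random_state=rng))
            if peak <= sa + 1.0:
                continue
            solution = solve_tuning_shape(osi, dsi, peak, sa)
            if solution is not None:
                break
        if solution is None:
            raise RuntimeError(
                f"no feasible tuning shape after {max_retries} target draws "
                f"(preset {preset.name!r})"
            )
        a1, a2, sigma = solution
        is_simple = bool(rng.random() < preset.simple_fraction)
        mod = float(rng.uniform(0.7, 1.0) if is_simple else rng.uniform(0.0, 0.3))
        neurons.append(
            NeuronGroundTruth(
                a1_true=a1,
                a2_true=a2,
                theta0_true=float(rng.uniform(0.0, 360.0)),
                sigma_true=sigma,
                sa_true=sa,
                modulation_depth=mod,
                depth_um=float(rng.uniform(0.0, MAX_DEPTH_UM)),
                osi_true=osi,
                dsi_true=dsi,
                or_true=peak,
                is_simple_true=is_simple,
            )
        )
    return neurons


# ---------------------------------------------------------------------------
# spike trains and voltage traces
# ---------------------------------------------------------------------------

def _inhomogeneous_poisson(
    rate_fn, rate_max: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Thinning sampler for an inhomogeneous Poisson process."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n))
    keep = rng.uniform(0.0, 1.0, n) * rate_max < rate_fn(t)
    return np.unique(t[keep])


def simulate_trials(
    neuron: NeuronGroundTruth,
    protocol: StimulusProtocol,
    seed: int,
    neuron_id: str = "n0",
) -> TrialSet:
    """Simulate all direction x repetition trials for one neuron.

    Stimulus-epoch spikes follow an inhomogeneous Poisson process with

        r(t; theta) = max(0, sa + evoked(theta) * (1 + m cos(2 pi f t)))

    and pre-stimulus spikes a homogeneous Poisson process at the
    spontaneous rate.
    """
    rng = np.random.default_rng(seed)
    f = protocol.temporal_freq_hz
    m = neuron.modulation_depth
    trials: list[Trial] = []
    for direction in protocol.directions_deg:
        ev = float(neuron.evoked(direction))
        rate_max = neuron.sa_true + max(ev, 0.0) * (1.0 + m)
        for rep in range(protocol.n_reps):
            pre = _inhomogeneous_poisson(
                lambda t: np.full_like(t, neuron.sa_true),
                neuron.sa_true,
                protocol.prestim_duration_s,
                rng,
            )
            def rate(t: np.ndarray) -> np.ndarray:
                return np.maximum(
                    0.0,
                    neuron.sa_true + ev * (1.0 + m * np.cos(2 * np.pi * f * t)),
                )
            stim = _inhomogeneous_poisson(
                rate, rate_max, protocol.stim_duration_s, rng
            )
            trials.append(
                Trial(
                    direction_deg=float(direction),
                    rep=rep,
                    stim=SpikeTrain(stim, "stim", protocol.stim_duration_s),
                    prestim=SpikeTrain(pre, "prestim", protocol.prestim_duration_s),
                )
            )
    return TrialSet(neuron_id=neuron_id, protocol=protocol, trials=trials)


@dataclass(frozen=True)
class SpikeTemplate:
    """Biphasic extracellular spike waveform parameters."""

    amplitude_v: float = 200e-6
    rise_ms: float = 0.25
    decay_ms: float = 0.6
    undershoot: float = 0.4

    def waveform(self, rate_hz: float) -> np.ndarray:
        support_ms = self.rise_ms + 3.0 * self.decay_ms
        n = max(int(round(support_ms / 1000.0 * rate_hz)), 1)
        t = np.arange(n) / rate_hz * 1000.0  # ms
        pos = np.exp(-((t - self.rise_ms) ** 2) / (2 * (self.rise_ms / 2) ** 2))
        neg = np.exp(
            -((t - self.rise_ms - self.decay_ms) ** 2) / (2 * (self.decay_ms / 2) ** 2)
        )
        return self.amplitude_v * (pos - self.undershoot * neg)


def synthesize_voltage(
    spike_times_s: np.ndarray,
    duration_s: float,
    template: SpikeTemplate | None = None,
    noise_sd: float = 20e-6,
    rate_hz: float = 20000.0,
    seed: int = 0,
) -> tuple[VoltageTrace, np.ndarray]:
    """Gaussian noise plus a spike template inserted at each planted time.

    Returns (trace, planted times).  Templates of spikes closer together
    than the waveform support simply sum.
    """
    times = np.sort(np.asarray(spike_times_s, dtype=float))
    if times.size and (times[0] < 0 or times[-1] >= duration_s):
        raise ValueError("spike times must lie within the trace duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    wave = (template or SpikeTemplate()).waveform(rate_hz)
    for t in times:
        i = int(round(t * rate_hz))
        j = min(i + len(wave), n)
        x[i:j] += wave[: j - i]
    return VoltageTrace(samples=x, rate_hz=rate_hz), times


# ---------------------------------------------------------------------------
# cell maps, images, blots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellMapSpec:
    """Spatial point-process specification for one cortical layer."""

    layer: str
    neun_density: float  # cells/mm^2
    gaba_fraction: float
    aoi_area_mm2: float = 0.05
    n_aois: int = 61

    def __post_init__(self) -> None:
        if self.neun_density < 0:
            raise ValueError("density must be nonnegative")
        if not 0.0 <= self.gaba_fraction <= 1.0:
            raise ValueError("gaba_fraction must be in [0, 1]")
        if self.aoi_area_mm2 <= 0 or self.n_aois < 1:
            raise ValueError("AOI area must be positive and n_aois >= 1")

    @property
    def aoi_side_um(self) -> float:
        return math.sqrt(self.aoi_area_mm2) * 1000.0


@dataclass
class AoiPoints:
    """Planted cell centroids (um) within one square AOI."""

    layer: str
    index: int
    side_um: float
    xy_um: np.ndarray  # (n, 2)
    gaba: np.ndarray  # (n,) bool

    @property
    def area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2


@dataclass
class CellMap:
    spec: CellMapSpec
    aois: list[AoiPoints]


def make_cell_map(spec: CellMapSpec, seed: int) -> CellMap:
    """Homogeneous spatial Poisson process per AOI with Bernoulli GABA marks."""
    rng = np.random.default_rng(seed)
    side = spec.aoi_side_um
    aois = []
    for i in range(spec.n_aois):
        n = rng.poisson(spec.neun_density * spec.aoi_area_mm2)
        xy = rng.uniform(0.0, side, size=(n, 2))
        gaba = rng.random(n) < spec.gaba_fraction
        aois.append(AoiPoints(spec.layer, i, side, xy, gaba))
    return CellMap(spec=spec, aois=aois)


def render_image(
    aoi: AoiPoints,
    blob_sigma_um: float = 3.0,
    intensity: tuple[float, float] = (0.8, 0.8),
    background: float = 0.05,
    noise_sd: float = 0.01,
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Render one AOI as a co-registered two-channel raster image.

    Channel 0 carries every cell (NeuN analogue), channel 1 only the
    GABA-marked subset; each cell is a Gaussian blob (an impulse if the
    blob is smaller than one pixel) on a constant background plus Gaussian
    noise.  Returns an array of shape (2, H, W) in [0, ~1].
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = np.random.default_rng(seed)
    npx = max(int(round(aoi.side_um / pixel_size_um)), 1)
    img = np.full((2, npx, npx), background, dtype=float)
    sigma_px = blob_sigma_um / pixel_size_um
    half = max(int(math.ceil(3 * sigma_px)), 1)
    ax = np.arange(-half, half + 1)
    if sigma_px >= 0.5:
        kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma_px**2))
    else:  # sub-pixel blob: single-pixel impulse
        kernel = np.zeros((2 * half + 1, 2 * half + 1))
        kernel[half, half] = 1.0
    for (x, y), is_gaba in zip(aoi.xy_um, aoi.gaba):
        cx, cy = int(round(x / pixel_size_um)), int(round(y / pixel_size_um))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, npx)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, npx)
        kx0, ky0 = x0 - (cx - half), y0 - (cy - half)
        patch = kernel[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)]
        channels = (0, 1) if is_gaba else (0,)
        for ch in channels:
            img[ch, y0:y1, x0:x1] += intensity[ch] * patch
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return img


@dataclass(frozen=True)
class BlotGroupSpec:
    """Per-group lognormal parameters for one blot target protein."""

    group: str
    protein: str
    target_mean: float
    target_sd: float
    gapdh_mean: float = 1.0
    gapdh_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.target_mean <= 0 or self.gapdh_mean <= 0:
            raise ValueError("band OD means must be positive")


@dataclass(frozen=True)
class BlotLane:
    subject_id: str
    group: str
    protein: str
    target_od: float
    gapdh_od: float

    @property
    def normalized(self) -> float:
        return self.target_od / self.gapdh_od


def make_blot_lanes(spec: BlotGroupSpec, n_per_group: int, seed: int) -> list[BlotLane]:
    """Lognormal band optical densities, one lane per subject."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    t_dist = matched_lognormal(spec.target_mean, spec.target_sd)
    g_dist = matched_lognormal(spec.gapdh_mean, spec.gapdh_sd)
    lanes = []
    for i in range(n_per_group):
        t = float(t_dist.rvs(random_state=rng)) if spec.target_sd > 0 else spec.target_mean
        g = float(g_dist.rvs(random_state=rng)) if spec.gapdh_sd > 0 else spec.gapdh_mean
        lanes.append(
            BlotLane(
                subject_id=f"{spec.group}-{i + 1}",
                group=spec.group,
                protein=spec.protein,
                target_od=t,
                gapdh_od=g,
            )
        )
    return lanes
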