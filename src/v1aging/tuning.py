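"""Direction tuning analysis: double-Gaussian fits and selectivity indices.

A neuron's response to a drifting grating moving in direction theta is
modelled as a baseline plus two Gaussian lobes sharing a width sigma, one
at the preferred direction theta0 and one at the null direction
theta1 = theta0 + 180:

    R(theta) = a0 + a1 exp(-d(theta, theta0)^2 / 2 sigma^2)
                  + a2 exp(-d(theta, theta1)^2 / 2 sigma^2)

with d(.,.) the angular difference wrapped to (-180, 180].  Responses are
normalized by the curve maximum before fitting, a0 is fixed to the mean of
the four lowest normalized points, and fits with mean squared error >= 0.5
are rejected from selectivity analysis.

Selectivity indices follow

    OSI or DSI = (R_opt - R_null) / (R_opt - R_spon)

where R_opt is the fitted response at theta0, R_null the fitted response at
the orthogonal orientations (OSI, mean of theta0 +/- 90) or the opposite
direction (DSI, theta0 + 180), and R_spon the spontaneous rate.  Indices
are clipped to [0, 1].

Response summaries: OR (peak response over the 24 directions), AR (mean
response across directions), SA (spontaneous rate), and SNR = OR / max(SA, 1)
— spontaneous activity below 1 spike/s is floored at 1 so low-SA cells do
not produce inflated ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .groupstats import assign_layer
from .spikes import TrialResponse, TrialSet, modulation_ratio, trial_rates

MSE_ACCEPT_THRESHOLD = 0.5  # on the max-normalized response scale


def wrap_angle_deg(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angular difference in degrees to (-180, 180]."""
    return -(np.mod(-np.asarray(delta, dtype=float) + 180.0, 360.0) - 180.0)


def double_gaussian(
    theta_deg: np.ndarray | float,
    a0: float,
    a1: float,
    a2: float,
    theta0_deg: float,
    sigma_deg: float,
    theta1_deg: float | None = None,
) -> np.ndarray:
    """Evaluate the wrapped double-Gaussian tuning model."""
    if theta1_deg is None:
        theta1_deg = theta0_deg + 180.0
    d0 = wrap_angle_deg(np.asarray(theta_deg, dtype=float) - theta0_deg)
    d1 = wrap_angle_deg(np.asarray(theta_deg, dtype=float) - theta1_deg)
    s2 = 2.0 * sigma_deg**2
    return a0 + a1 * np.exp(-(d0**2) / s2) + a2 * np.exp(-(d1**2) / s2)


@dataclass
class TuningCurve:
    """Per-direction mean evoked responses plus the spontaneous rate."""

    directions_deg: np.ndarray
    mean_response: np.ndarray  # spikes/s, spontaneous-subtracted
    sd_response: np.ndarray
    sa: float  # spikes/s, mean pre-stimulus rate
    n_reps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.directions_deg) != len(self.mean_response):
            raise ValueError("one mean response per direction required")
        if self.sa < 0:
            raise ValueError("spontaneous rate must be nonnegative")


@dataclass
class TuningFit:
    a0: float
    a1: float
    a2: float
    theta0_deg: float
    theta1_deg: float
    sigma_deg: float
    mse: float
    accepted: bool
    scale: float = 1.0  # normalization factor (curve maximum, spikes/s)

    def predict_normalized(self, theta_deg: np.ndarray | float) -> np.ndarray:
        return double_gaussian(
            theta_deg,
            self.a0,
            self.a1,
            self.a2,
            self.theta0_deg,
            self.sigma_deg,
            theta1_deg=self.theta1_deg,
        )

    def predict(self, theta_deg: np.ndarray | float) -> np.ndarray:
        """Fitted curve on the original spikes/s scale."""
        return self.scale * self.predict_normalized(theta_deg)


@dataclass
class NeuronRecord:
    """Per-neuron analysis output; undefined metrics are None with a flag."""

    neuron_id: str
    osi: float | None
    dsi: float | None
    or_: float
    ar: float
    sa: float
    snr: float
    cell_class: str | None
    modulation: float | None
    depth_um: float | None
    layer: str | None
    fit: TuningFit | None
    flags: list[str] = field(default_factory=list)


def build_tuning_curve(
    responses: list[TrialResponse],
    expected_directions: tuple[float, ...] | None = None,
) -> TuningCurve:
    """Average per-trial evoked rates into a 24-point tuning curve.

    The spontaneous rate is the mean pre-stimulus rate across all trials.
    Duplicate (direction, rep) rows and absent directions are integrity
    errors, and repetition counts outside the expected 4-6 range warn.
    """
    import warnings

    if not responses:
        raise ValueError("no trial responses supplied")
    seen = set()
    for r in responses:
        key = (r.direction_deg, r.rep)
        if key in seen:
            raise ValueError(f"duplicate trial row for direction/rep {key}")
        seen.add(key)
    directions = np.array(sorted({r.direction_deg for r in responses}))
    if expected_directions is not None:
        absent = sorted(set(expected_directions) - set(directions))
        if absent:
            raise ValueError(f"no trials for direction(s): {absent}")
    means, sds, n_reps = [], [], []
    for d in directions:
        ev = np.array([r.evoked_rate for r in responses if r.direction_deg == d])
        means.append(ev.mean())
        sds.append(ev.std(ddof=1) if ev.size > 1 else 0.0)
        n_reps.append(ev.size)
    n_reps = np.array(n_reps)
    if np.any(n_reps < 4) or np.any(n_reps > 6):
        warnings.warn("repetitions per direction outside the expected 4-6 range",
                      stacklevel=2)
    sa = float(np.mean([r.prestim_rate for r in responses]))
    return TuningCurve(
        directions_deg=directions,
        mean_response=np.array(means),
        sd_response=np.array(sds),
        sa=sa,
        n_reps=n_reps,
    )


def _candidate_peaks(directions: np.ndarray, y: np.ndarray) -> list[float]:
    """Primary peak direction plus the best secondary peak (> 90 deg away)."""
    primary = float(directions[int(np.argmax(y))])
    far = np.abs(wrap_angle_deg(directions - primary)) > 90.0
    if np.any(far):
        idx = np.flatnonzero(far)
        secondary = float(directions[idx[np.argmax(y[idx])]])
    else:
        secondary = primary + 180.0
    return [primary, secondary]


def fit_double_gaussian(
    curve: TuningCurve,
    constrain_null: bool = True,
    sigma_starts: tuple[float, ...] = (15.0, 30.0, 60.0),
) -> TuningFit:
    """Fit the double-Gaussian model to a measured tuning curve.

    Responses are normalized by their maximum; a0 is fixed to the mean of
    the four lowest normalized points; the remaining parameters are fit by
    bounded nonlinear least squares with the angular difference wrapped.
    With ``constrain_null`` (default) theta1 is tied to theta0 + 180;
    otherwise it is a free parameter.  Multi-start initialization covers
    the two highest response peaks and three widths; the lowest mean
    squared error wins, ties going to the smaller sigma.  Degenerate
    (flat or nonpositive) curves are flagged rather than raised.
    """
    directions = np.asarray(curve.directions_deg, dtype=float)
    resp = np.asarray(curve.mean_response, dtype=float)
    peak = float(np.max(resp))
    if peak <= 0 or np.allclose(resp, resp[0]):
        return TuningFit(0.0, 0.0, 0.0, 0.0, 180.0, 30.0, np.inf, False, scale=1.0)
    y = resp / peak
    a0 = float(np.mean(np.sort(y)[:4]))

    def residuals(params: np.ndarray) -> np.ndarray:
        if constrain_null:
            a1, a2, th0, sig = params
            th1 = None
        else:
            a1, a2, th0, th1, sig = params
        return double_gaussian(directions, a0, a1, a2, th0, sig, theta1_deg=th1) - y

    best: TuningFit | None = None
    amp0 = max(1.0 - a0, 1e-3)
    for th_start in _candidate_peaks(directions, y):
        opp = wrap_angle_deg(directions - (th_start + 180.0))
        amp2 = max(float(y[np.argmin(np.abs(opp))]) - a0, 1e-3)
        for sig_start in sigma_starts:
            if constrain_null:
                x0 = [amp0, amp2, th_start, sig_start]
                lb = [0.0, 0.0, th_start - 180.0, 3.0]
                ub = [3.0, 3.0, th_start + 180.0, 180.0]
            else:
                x0 = [amp0, amp2, th_start, th_start + 180.0, sig_start]
                lb = [0.0, 0.0, th_start - 180.0, th_start - 180.0, 3.0]
                ub = [3.0, 3.0, th_start + 180.0, th_start + 540.0, 180.0]
            try:
                sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
            except Exception:
                continue
            mse = float(np.mean(sol.fun**2))
            if constrain_null:
                a1, a2, th0, sig = sol.x
                th1 = th0 + 180.0
            else:
                a1, a2, th0, th1, sig = sol.x
            if a2 > a1:  # canonicalize: the preferred lobe is the larger one
                a1, a2, th0, th1 = a2, a1, th1, th0
            cand = TuningFit(
                a0=a0,
                a1=float(a1),
                a2=float(a2),
                theta0_deg=float(np.mod(th0, 360.0)),
                theta1_deg=float(np.mod(th1, 360.0)),
                sigma_deg=float(sig),
                mse=mse,
                accepted=mse < MSE_ACCEPT_THRESHOLD,
                scale=peak,
            )
            if (
                best is None
                or cand.mse < best.mse - 1e-12
                or (abs(cand.mse - best.mse) <= 1e-12 and cand.sigma_deg < best.sigma_deg)
            ):
                best = cand
    if best is None:  # every start failed to converge
        return TuningFit(a0, 0.0, 0.0, 0.0, 180.0, 30.0, np.inf, False, scale=peak)
    return best


def selectivity_indices(
    fit: TuningFit,
    curve: TuningCurve,
    use_fitted: bool = True,
    clip: bool = True,
) -> tuple[float, float]:
    """Orientation and direction selectivity indices from a fitted curve.

    Raises ValueError when the fit was rejected or the optimal response
    does not exceed the spontaneous rate (indices undefined).  With
    ``use_fitted=False`` the raw tuning-curve bins nearest the relevant
    angles are used instead of the fitted curve.
    """
    if not fit.accepted:
        raise ValueError("selectivity undefined: tuning fit rejected")
    th0 = fit.theta0_deg
    if use_fitted:
        r_opt = float(fit.predict(th0))
        r_null_dir = float(fit.predict(th0 + 180.0))
        r_null_orth = float(
            np.mean(fit.predict(np.array([th0 + 90.0, th0 - 90.0])))
        )
    else:
        dirs = np.asarray(curve.directions_deg, dtype=float)

        def nearest(angle: float) -> float:
            return float(
                curve.mean_response[np.argmin(np.abs(wrap_angle_deg(dirs - angle)))]
            )

        r_opt = nearest(th0)
        r_null_dir = nearest(th0 + 180.0)
        r_null_orth = 0.5 * (nearest(th0 + 90.0) + nearest(th0 - 90.0))
    r_spon = curve.sa
    denom = r_opt - r_spon
    if denom <= 0:
        raise ValueError("selectivity undefined: optimal response <= spontaneous")
    osi = (r_opt - r_null_orth) / denom
    dsi = (r_opt - r_null_dir) / denom
    if clip:
        osi = float(np.clip(osi, 0.0, 1.0))
        dsi = float(np.clip(dsi, 0.0, 1.0))
    return osi, dsi


def response_metrics(
    curve: TuningCurve, subtract_spontaneous: bool = True
) -> tuple[float, float, float, float]:
    """(OR, AR, SA, SNR) response summaries for one tuning curve.

    OR and AR are taken from the spontaneous-subtracted curve by default;
    ``subtract_spontaneous=False`` reports them on the raw-rate scale.
    SNR floors spontaneous activity at 1 spike/s.
    """
    resp = np.asarray(curve.mean_response, dtype=float)
    offset = 0.0 if subtract_spontaneous else curve.sa
    or_ = float(np.max(resp) + offset)
    ar = float(np.mean(resp) + offset)
    sa = float(curve.sa)
    snr = or_ / max(sa, 1.0)
    return or_, ar, sa, snr


def analyze_neuron(
    trial_set: TrialSet,
    depth_um: float | None = None,
    layer_boundaries: dict[str, tuple[float, float]] | None = None,
    constrain_null: bool = True,
) -> NeuronRecord:
    """Run the full per-neuron analysis chain on one trial set.

    trial rates -> tuning curve -> double-Gaussian fit -> OSI/DSI ->
    OR/AR/SA/SNR -> F1/F0 classification -> layer assignment.  Neurons
    whose fit fails the error filter, or whose optimal response does not
    exceed the spontaneous rate, keep their response metrics but carry
    ``osi``/``dsi`` of None and an explanatory flag.
    """
    flags: list[str] = []
    responses = trial_rates(trial_set)
    curve = build_tuning_curve(
        responses, expected_directions=trial_set.protocol.directions_deg
    )
    or_, ar, sa, snr = response_metrics(curve)

    fit = fit_double_gaussian(curve, constrain_null=constrain_null)
    osi = dsi = None
    if not fit.accepted:
        flags.append("fit_rejected")
    else:
        try:
            osi, dsi = selectivity_indices(fit, curve)
        except ValueError:
            flags.append("indices_undefined")

    pref_dir = float(curve.directions_deg[int(np.argmax(curve.mean_response))])
    stim_trains = [t.stim for t in trial_set.by_direction(pref_dir)]
    mod = modulation_ratio(
        stim_trains, trial_set.protocol.temporal_freq_hz, prestim_rate=sa
    )
    if mod.cell_class is None:
        flags.append("class_undefined")

    layer = None
    if depth_um is not None:
        layer = assign_layer(depth_um, layer_boundaries)

    return NeuronRecord(
        neuron_id=trial_set.neuron_id,
        osi=osi,
        dsi=dsi,
        or_=or_,
        ar=ar,
        sa=sa,
        snr=snr,
        cell_class=mod.cell_class,
        modulation=mod.ratio if np.isfinite(mod.ratio) else None,
        depth_um=depth_um,
        layer=layer,
        fit=fit,
        flags=flags,
    )
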