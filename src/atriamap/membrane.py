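"""Atrial membrane kinetics: detailed ionic model and fast surrogate.

Two interchangeable models drive the monodomain solver:

* ``crn`` (alias ``ramirez``): the Courtemanche-Ramirez-Nattel atrial
  ionic formulation (21 state variables) augmented with the
  acetylcholine-activated K+ current of Kneller et al.  Elevated ACh
  shortens the action potential locally, creating repolarization
  gradients.  Requires explicit time steps of <= 20 us.
* ``surrogate``: a 2-variable phenomenological model of the
  Mitchell-Schaeffer type whose action potential duration is a direct
  parameter, so that whole-chamber studies run in minutes.  ACh enters as
  a saturating dose-response that scales the APD down.

State vectors always carry the transmembrane potential Vm (mV) in slot 0 so
the diffusion operator is model-agnostic.  Stimulus current is expressed as
a dVm/dt contribution in mV/ms.
"""

from __future__ import annotations

import typing
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "MembraneModel",
    "SurrogateModel",
    "CRNModel",
    "get_model",
    "step_cell",
    "measure_apd",
    "NoCaptureError",
    "ApdConvergenceError",
]


class NoCaptureError(RuntimeError):
    """Stimulus failed to elicit an action potential."""


class ApdConvergenceError(RuntimeError):
    """Beat-to-beat APD did not converge (e.g. alternans)."""


# ---------------------------------------------------------------------------
# surrogate (Mitchell-Schaeffer type)
# ---------------------------------------------------------------------------

_V_REST = -80.0     # mV
_V_AMP = 105.0      # mV, so the peak sits near +25 mV

# ACh dose-response on APD: apd_eff = apd * (1 - SMAX * ach / (ach + K50))
_ACH_SMAX = 0.45
_ACH_K50 = 0.01     # uM


@njit(cache=True)
def _surrogate_step(state, ach, istim, dt, tau_in, tau_out, tau_open,
                    apd0, cal_a, cal_b, v_gate):
    n = state.shape[0]
    for i in range(n):
        v = (state[i, 0] - _V_REST) / _V_AMP
        w = state[i, 1]
        apd_eff = apd0 * (1.0 - _ACH_SMAX * ach[i] / (ach[i] + _ACH_K50))
        tau_close = (apd_eff - cal_b) / cal_a
        if tau_close < 5.0:
            tau_close = 5.0
        dv = w * v * v * (1.0 - v) / tau_in - v / tau_out + istim[i] / _V_AMP
        if v < v_gate:
            dw = (1.0 - w) / tau_open
        else:
            dw = -w / tau_close
        v += dt * dv
        w += dt * dw
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        state[i, 0] = _V_REST + _V_AMP * v
        state[i, 1] = w


@dataclass
class SurrogateModel:
    """Two-variable excitable model with directly parameterized APD.

    ``apd`` (ms) sets the 90%-repolarization action potential duration at
    ACh = 0 through the closed-form plateau duration of the
    Mitchell-Schaeffer model: the recovery gate decays as exp(-t/tau_close)
    while excited and the plateau collapses once it reaches
    w* = 4 tau_in / tau_out, so tau_close = (apd - t_tail) / ln(1/w*),
    with a repolarization tail t_tail ~ 2 tau_out after the plateau ends.
    """

    apd: float = 180.0       # ms at ACh = 0
    tau_in: float = 0.3      # ms
    tau_out: float = 6.0     # ms
    tau_open: float = 120.0  # ms
    v_gate: float = 0.13
    name: str = "surrogate"
    n_state: int = 2
    max_dt: float = 0.05     # ms, documented explicit stability bound

    # cached APD(tau_close) affine calibrations keyed by shape parameters
    _calibrations: typing.ClassVar[dict | None] = None

    def resting_state(self, ach: float = 0.0) -> np.ndarray:
        return np.array([_V_REST, 1.0])

    def _apd_at_tau(self, tau_close: float) -> float:
        """Single-cell APD90 with a pinned tau_close (used for calibration)."""
        state = np.array([[_V_REST, 1.0]])
        zero = np.zeros(1)
        dt = self.max_dt
        vs = []
        n_steps = int(round(2 * 600.0 / dt))
        stride = int(round(0.5 / dt))
        for s in range(n_steps):
            in_beat = s % int(round(600.0 / dt))
            stim = np.full(1, 40.0) if in_beat < int(round(2.0 / dt)) else zero
            _surrogate_step(state, zero, stim, dt, self.tau_in, self.tau_out,
                            self.tau_open, tau_close, 1.0, 0.0, self.v_gate)
            if s % stride == 0:
                vs.append(state[0, 0])
        second = np.asarray(vs)[len(vs) // 2:]
        return _apd_from_trace(second, 0.5, 0.9)

    @property
    def calibration(self) -> tuple[float, float]:
        """Affine map APD90 ~ a * tau_close + b, measured once per shape.

        The asymptotic slope is ln(tau_out / (4 tau_in)) from the
        closed-form plateau duration; the measured affine fit also absorbs
        the slow-passage and repolarization-tail contributions.
        """
        key = (self.tau_in, self.tau_out, self.tau_open, self.v_gate,
               self.max_dt)
        if SurrogateModel._calibrations is None:
            SurrogateModel._calibrations = {}
        if key not in SurrogateModel._calibrations:
            t1, t2 = 55.0, 110.0
            a1, a2 = self._apd_at_tau(t1), self._apd_at_tau(t2)
            a = (a2 - a1) / (t2 - t1)
            b = a1 - a * t1
            SurrogateModel._calibrations[key] = (a, b)
        return SurrogateModel._calibrations[key]

    @property
    def tau_close(self) -> float:
        a, b = self.calibration
        return max((self.apd - b) / a, 5.0)

    def step(self, state: np.ndarray, ach: np.ndarray, istim: np.ndarray,
             dt: float) -> None:
        a, b = self.calibration
        _surrogate_step(state, ach, istim, dt, self.tau_in, self.tau_out,
                        self.tau_open, self.apd, a, b, self.v_gate)

    def apd_of_ach(self, ach: float) -> float:
        """Closed-form APD under the ACh dose-response (ms)."""
        return self.apd * (1.0 - _ACH_SMAX * ach / (ach + _ACH_K50))


# ---------------------------------------------------------------------------
# detailed ionic model (CRN + Kneller ACh current)
# ---------------------------------------------------------------------------

# state layout: 0 V, 1 m, 2 h, 3 j, 4 oa, 5 oi, 6 ua, 7 ui, 8 xr, 9 xs,
# 10 d, 11 f, 12 fca, 13 u, 14 v, 15 w, 16 Nai, 17 Ki, 18 Cai, 19 Caup,
# 20 Carel
_CRN_REST = np.array([
    -81.18, 2.908e-3, 0.9649, 0.9775, 3.043e-2, 0.9992, 4.966e-3, 0.9986,
    3.29e-5, 1.869e-2, 1.367e-4, 0.9996, 0.7755, 0.0, 1.0, 0.9992,
    11.17, 139.0, 1.013e-4, 1.488, 1.488,
])


@njit(cache=True)
def _crn_step(state, ach, istim, dt):
    R = 8.3143; T = 310.0; F = 96.4867
    Cm = 100.0
    Nao = 140.0; Ko = 5.4; Cao = 1.8
    Vi = 13668.0; Vup = 1109.52; Vrel = 96.48
    KQ10 = 3.0
    rtf = R * T / F

    for i in range(state.shape[0]):
        V = state[i, 0]
        m = state[i, 1]; h = state[i, 2]; jg = state[i, 3]
        oa = state[i, 4]; oi = state[i, 5]; ua = state[i, 6]; ui = state[i, 7]
        xr = state[i, 8]; xs = state[i, 9]
        d = state[i, 10]; f = state[i, 11]; fca = state[i, 12]
        u = state[i, 13]; vg = state[i, 14]; w = state[i, 15]
        Nai = state[i, 16]; Ki = state[i, 17]; Cai = state[i, 18]
        Caup = state[i, 19]; Carel = state[i, 20]

        ENa = rtf * np.log(Nao / Nai)
        EK = rtf * np.log(Ko / Ki)
        ECa = 0.5 * rtf * np.log(Cao / Cai)

        INa = Cm * 7.8 * m ** 3 * h * jg * (V - ENa)
        IK1 = Cm * 0.09 * (V - EK) / (1.0 + np.exp(0.07 * (V + 80.0)))
        Ito = Cm * 0.1652 * oa ** 3 * oi * (V - EK)
        gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
        IKur = Cm * gkur * ua ** 3 * ui * (V - EK)
        IKr = Cm * 0.0294 * xr * (V - EK) / (1.0 + np.exp((V + 15.0) / 22.4))
        IKs = Cm * 0.129 * xs * xs * (V - EK)
        ICaL = Cm * 0.1238 * d * f * fca * (V - 65.0)
        IpCa = Cm * 0.275 * Cai / (0.0005 + Cai)
        sigma = (np.exp(Nao / 67.3) - 1.0) / 7.0
        fNaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / rtf)
                      + 0.0365 * sigma * np.exp(-V / rtf))
        INaK = (Cm * 0.59933874 * fNaK * Ko / (Ko + 1.5)
                / (1.0 + (10.0 / Nai) ** 1.5))
        expg = np.exp(0.35 * V / rtf)
        expg1 = np.exp((0.35 - 1.0) * V / rtf)
        INaCa = (Cm * 1600.0 * (expg * Nai ** 3 * Cao - expg1 * Nao ** 3 * Cai)
                 / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao)
                    * (1.0 + 0.1 * expg1)))
        IbNa = Cm * 0.0006744375 * (V - ENa)
        IbCa = Cm * 0.001131 * (V - ECa)
        # Kneller et al. ACh-activated K+ current ([ACh] in uM)
        a = ach[i]
        if a > 0.0:
            gkach = 10.0 / (1.0 + 9.13652 / a ** 0.477811)
        else:
            gkach = 0.0
        IKACh = (Cm * gkach
                 * (0.0517 + 0.4516 / (1.0 + np.exp((V + 59.53) / 17.18)))
                 * (V - EK))

        Itot = (INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa + INaK
                + INaCa + IbNa + IbCa + IKACh)

        # --- gating kinetics ------------------------------------------------
        if abs(V + 47.13) < 1e-6:
            am = 3.2
        else:
            am = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
        bm = 0.08 * np.exp(-V / 11.0)
        if V >= -40.0:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
            aj = 0.0
            bj = (0.3 * np.exp(-2.535e-7 * V)
                  / (1.0 + np.exp(-0.1 * (V + 32.0))))
        else:
            ah = 0.135 * np.exp(-(V + 80.0) / 6.8)
            bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
            aj = ((-1.2714e5 * np.exp(0.2444 * V)
                   - 3.474e-5 * np.exp(-0.04391 * V)) * (V + 37.78)
                  / (1.0 + np.exp(0.311 * (V + 79.23))))
            bj = (0.1212 * np.exp(-0.01052 * V)
                  / (1.0 + np.exp(-0.1378 * (V + 40.14))))

        aoa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
        boa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
        tau_oa = 1.0 / ((aoa + boa) * KQ10)
        oa_inf = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
        aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
        boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
        tau_oi = 1.0 / ((aoi + boi) * KQ10)
        oi_inf = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
        aua = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
        bua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
        tau_ua = 1.0 / ((aua + bua) * KQ10)
        ua_inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
        aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
        bui = np.exp((V - 158.0) / 16.0)
        tau_ui = 1.0 / ((aui + bui) * KQ10)
        ui_inf = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
        if abs(V + 14.1) < 1e-6:
            axr = 0.0015
        else:
            axr = 0.0003 * (V + 14.1) / (1.0 - np.exp(-(V + 14.1) / 5.0))
        if abs(V - 3.3328) < 1e-6:
            bxr = 3.7836118e-4
        else:
            bxr = (7.3898e-5 * (V - 3.3328)
                   / (np.exp((V - 3.3328) / 5.1237) - 1.0))
        tau_xr = 1.0 / (axr + bxr)
        xr_inf = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
        if abs(V - 19.9) < 1e-6:
            axs = 0.00068
            bxs = 0.000315
        else:
            axs = 4e-5 * (V - 19.9) / (1.0 - np.exp(-(V - 19.9) / 17.0))
            bxs = 3.5e-5 * (V - 19.9) / (np.exp((V - 19.9) / 9.0) - 1.0)
        tau_xs = 0.5 / (axs + bxs)
        xs_inf = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
        if abs(V + 10.0) < 1e-6:
            tau_d = 4.579 / (1.0 + np.exp(-(V + 10.0) / 6.24))
        else:
            tau_d = ((1.0 - np.exp(-(V + 10.0) / 6.24))
                     / (0.035 * (V + 10.0)
                        * (1.0 + np.exp(-(V + 10.0) / 6.24))))
        d_inf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
        tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
        f_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
        fca_inf = 1.0 / (1.0 + Cai / 0.00035)
        tau_fca = 2.0

        Irel = 30.0 * u * u * vg * w * (Carel - Cai)
        Fn = 1e-12 * Vrel * Irel - (5e-13 / F) * (0.5 * ICaL - 0.2 * INaCa)
        u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
        tau_u = 8.0
        v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
        tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
        w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
        if abs(V - 7.9) < 1e-6:
            tau_w = 6.0 * 0.2 / 1.3
        else:
            tau_w = (6.0 * (1.0 - np.exp(-(V - 7.9) / 5.0))
                     / ((1.0 + 0.3 * np.exp(-(V - 7.9) / 5.0)) * (V - 7.9)))

        Iup = 0.005 / (1.0 + 0.00092 / Cai)
        Iup_leak = 0.005 * Caup / 15.0
        Itr = (Caup - Carel) / 180.0

        # --- integrate: forward Euler for V and concentrations,
        # Rush-Larsen exponential steps for the Hodgkin-Huxley gates
        # (the m gate has tau ~ 8 us at rest, far below the 20 us step)
        state[i, 0] = V + dt * (-Itot / Cm + istim[i])
        m_inf = am / (am + bm); tau_m = 1.0 / (am + bm)
        h_inf = ah / (ah + bh); tau_h = 1.0 / (ah + bh)
        j_inf = aj / (aj + bj); tau_j = 1.0 / (aj + bj)
        state[i, 1] = m_inf + (m - m_inf) * np.exp(-dt / tau_m)
        state[i, 2] = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
        state[i, 3] = j_inf + (jg - j_inf) * np.exp(-dt / tau_j)
        state[i, 4] = oa_inf + (oa - oa_inf) * np.exp(-dt / tau_oa)
        state[i, 5] = oi_inf + (oi - oi_inf) * np.exp(-dt / tau_oi)
        state[i, 6] = ua_inf + (ua - ua_inf) * np.exp(-dt / tau_ua)
        state[i, 7] = ui_inf + (ui - ui_inf) * np.exp(-dt / tau_ui)
        state[i, 8] = xr_inf + (xr - xr_inf) * np.exp(-dt / tau_xr)
        state[i, 9] = xs_inf + (xs - xs_inf) * np.exp(-dt / tau_xs)
        state[i, 10] = d_inf + (d - d_inf) * np.exp(-dt / tau_d)
        state[i, 11] = f_inf + (f - f_inf) * np.exp(-dt / tau_f)
        state[i, 12] = fca_inf + (fca - fca_inf) * np.exp(-dt / tau_fca)
        state[i, 13] = u_inf + (u - u_inf) * np.exp(-dt / tau_u)
        state[i, 14] = v_inf + (vg - v_inf) * np.exp(-dt / tau_v)
        state[i, 15] = w_inf + (w - w_inf) * np.exp(-dt / tau_w)

        B1 = ((2.0 * INaCa - IpCa - ICaL - IbCa) / (2.0 * F * Vi)
              + (Vup * (Iup_leak - Iup) + Irel * Vrel) / Vi)
        B2 = (1.0 + 0.070 * 0.0005 / (Cai + 0.0005) ** 2
              + 0.050 * 0.00238 / (Cai + 0.00238) ** 2)
        state[i, 16] = Nai + dt * (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) / (F * Vi)
        state[i, 17] = Ki + dt * (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs
                                  - IKACh) / (F * Vi)
        state[i, 18] = Cai + dt * B1 / B2
        state[i, 19] = Caup + dt * (Iup - Iup_leak - Itr * Vrel / Vup)
        state[i, 20] = Carel + dt * ((Itr - Irel)
                                     / (1.0 + 10.0 * 0.8 / (Carel + 0.8) ** 2))


@dataclass
class CRNModel:
    """Courtemanche-Ramirez-Nattel atrial kinetics + Kneller ACh K+ current.

    Stands in for the canine-specific variant of the same model family; the
    parameter set is the published human atrial one, which preserves the
    properties this package relies on (wave shape, ACh-graded APD
    shortening, APD < 300 ms).
    """

    name: str = "crn"
    n_state: int = 21
    max_dt: float = 0.02  # ms (20 us explicit step)

    def resting_state(self, ach: float = 0.0) -> np.ndarray:
        return _CRN_REST.copy()

    def step(self, state: np.ndarray, ach: np.ndarray, istim: np.ndarray,
             dt: float) -> None:
        _crn_step(state, ach, istim, dt)


MembraneModel = SurrogateModel | CRNModel


def get_model(name: str, **kwargs) -> MembraneModel:
    """Look up a membrane model by configuration name."""
    key = name.lower()
    if key in ("crn", "ramirez"):
        return CRNModel(**kwargs)
    if key == "surrogate":
        return SurrogateModel(**kwargs)
    raise ValueError(f"unknown membrane model: {name!r}")


def model_to_json(model: MembraneModel, path) -> None:
    """Persist a model's name and parameter set as JSON."""
    import dataclasses
    import json

    d = {k: v for k, v in dataclasses.asdict(model).items()
         if not k.startswith("_")}
    with open(path, "w") as f:
        json.dump(d, f)


def model_from_json(path) -> MembraneModel:
    import json

    with open(path) as f:
        d = json.load(f)
    name = d.pop("name")
    d.pop("n_state", None)
    d.pop("max_dt", None)
    return get_model(name, **d)


# ---------------------------------------------------------------------------
# single-cell utilities
# ---------------------------------------------------------------------------

def step_cell(model: MembraneModel, state: np.ndarray, istim: float,
              dt: float, ach: float = 0.0) -> np.ndarray:
    """Advance a single cell one explicit step; returns the new state."""
    if dt > model.max_dt + 1e-12:
        raise ValueError(
            f"dt={dt} ms exceeds the stability bound {model.max_dt} ms "
            f"for model {model.name}"
        )
    s = np.atleast_2d(np.asarray(state, dtype=float)).copy()
    model.step(s, np.full(len(s), ach), np.full(len(s), istim), dt)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite state after membrane step")
    return s[0]


def _run_paced(model, cl, ach, dt, n_beats, stim_amp, stim_dur, sample_every):
    state = np.atleast_2d(model.resting_state(ach)).copy()
    ach_arr = np.full(1, ach)
    zero = np.zeros(1)
    stim = np.full(1, stim_amp)
    steps_per_beat = int(round(cl / dt))
    stim_steps = int(round(stim_dur / dt))
    stride = max(1, int(round(sample_every / dt)))
    traces = []
    for _ in range(n_beats):
        vs = []
        for s in range(steps_per_beat):
            cur = stim if s < stim_steps else zero
            model.step(state, ach_arr, cur, dt)
            if s % stride == 0:
                vs.append(state[0, 0])
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("non-finite state during pacing")
        traces.append(np.asarray(vs))
    return traces, sample_every * 1.0


def _apd_from_trace(v: np.ndarray, dt_samp: float, level: float) -> float:
    v_rest = v[0]
    v_peak = v.max()
    if v_peak < 0.0:
        raise NoCaptureError("no action potential elicited")
    upstroke = int(np.argmax(np.diff(v)))
    thr = v_peak - level * (v_peak - v_rest)
    below = np.where(v[upstroke:] <= thr)[0]
    if below.size == 0:
        raise ApdConvergenceError("repolarization did not reach threshold")
    k = upstroke + below[0]
    # linear interpolation of the crossing
    if k > 0 and v[k - 1] != v[k]:
        frac = (v[k - 1] - thr) / (v[k - 1] - v[k])
    else:
        frac = 0.0
    return (k - 1 + frac - upstroke) * dt_samp


def measure_apd(
    model: MembraneModel,
    cycle_length: float = 600.0,
    ach: float = 0.0,
    level: float = 0.9,
    dt: float | None = None,
    stim_amp: float = 40.0,
    stim_dur: float = 2.0,
    max_beats: int = 10,
    tol: float = 0.01,
) -> float:
    """APD at the given repolarization level after pacing to steady state.

    Beats are delivered at ``cycle_length`` until the beat-to-beat APD
    change is below ``tol`` (1%, the steady-state criterion used throughout
    the package); raises :class:`ApdConvergenceError` otherwise.
    """
    dt = dt if dt is not None else model.max_dt
    traces, dt_samp = _run_paced(model, cycle_length, ach, dt, max_beats,
                                 stim_amp, stim_dur, sample_every=0.5)
    prev = None
    for trace in traces:
        apd = _apd_from_trace(trace, dt_samp, level)
        if prev is not None and abs(apd - prev) <= tol * prev:
            return apd
        prev = apd
    raise ApdConvergenceError(
        f"APD did not converge within {max_beats} beats (last {prev:.1f} ms)"
    )
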