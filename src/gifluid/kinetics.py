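"""One-compartment kinetic model of luminal fluid in a ligated intestinal loop.

The luminal fluid volume ``V_GI`` in a closed loop evolves under first-order
absorption into the body and a constant-rate secretion input driven by the
body fluid pool::

    dV_GI/dt = -k_abs * V_GI + k_sec * V_body * s_ratio

where ``k_abs`` (min^-1) is the real fluid absorption rate constant,
``k_sec`` (min^-1) the fluid secretion rate constant, ``V_body`` (mL) the
total body fluid volume and ``s_ratio`` the fraction of total intestinal
surface area enclosed in the loop.  With ``V_body`` held constant the model
is linear with the closed-form solution

    V_GI(t) = V_ss + (V0 - V_ss) * exp(-k_abs * t),
    V_ss    = k_sec * V_body * s_ratio / k_abs.

The module also provides the decomposition of ``V_GI`` into ingested water
remaining (``V0 * exp(-k_abs t)``) and secreted fluid currently in the lumen,
both absorbed at the same ``k_abs`` (single well-mixed lumen), and a
mass-conserving variant in which the body pool depletes as it secretes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import EstimationError, ValidationError

__all__ = [
    "DEFAULT_V_BODY_ML",
    "DEFAULT_S_RATIO",
    "ModelParams",
    "Trajectory",
    "secretion_input_rate",
    "steady_state_volume",
    "closed_form_vgi",
    "simulate",
]

#: Total body fluid volume of a ~230 g rat (mL), used as the initial body pool.
DEFAULT_V_BODY_ML = 167.0

#: Loop-to-total intestinal length fraction: 10 cm loop / 142 cm total.
DEFAULT_S_RATIO = 10.0 / 142.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the luminal fluid kinetic model.

    Parameters
    ----------
    k_abs : float
        Real fluid absorption rate constant (min^-1), > 0.
    k_sec : float
        Fluid secretion rate constant (min^-1), >= 0.
    v_body : float
        Total body fluid volume (mL), default 167.
    s_ratio : float
        Loop surface area as a fraction of total intestinal surface area,
        in (0, 1]; default 10/142.
    v0 : float
        Administered (initial) luminal volume (mL), default 1.
    """

    k_abs: float
    k_sec: float = 0.0
    v_body: float = DEFAULT_V_BODY_ML
    s_ratio: float = DEFAULT_S_RATIO
    v0: float = 1.0

    def __post_init__(self) -> None:
        if not self.k_abs > 0:
            raise ValidationError(f"k_abs must be > 0, got {self.k_abs}")
        if self.k_sec < 0:
            raise ValidationError(f"k_sec must be >= 0, got {self.k_sec}")
        if not self.v_body > 0:
            raise ValidationError(f"v_body must be > 0, got {self.v_body}")
        if not 0 < self.s_ratio <= 1:
            raise ValidationError(f"s_ratio must be in (0, 1], got {self.s_ratio}")
        if self.v0 < 0:
            raise ValidationError(f"v0 must be >= 0, got {self.v0}")


def secretion_input_rate(p: ModelParams) -> float:
    """Zero-order secretion input into the loop, ``k_sec * v_body * s_ratio`` (mL/min)."""
    return p.k_sec * p.v_body * p.s_ratio


def steady_state_volume(p: ModelParams) -> float:
    """Steady-state luminal volume ``k_sec * v_body * s_ratio / k_abs`` (mL)."""
    return secretion_input_rate(p) / p.k_abs


def closed_form_vgi(p: ModelParams, t):
    """Closed-form luminal volume ``V_ss + (V0 - V_ss) exp(-k_abs t)`` (mL).

    ``t`` may be a scalar or array of times (min, >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    v_ss = steady_state_volume(p)
    out = v_ss + (p.v0 - v_ss) * np.exp(-p.k_abs * t)
    return out if out.ndim else float(out)


@dataclass
class Trajectory:
    """Simulated time courses of luminal fluid in a closed loop.

    ``v_gi = v_ingested + v_secreted`` at every time point; ``absorbed_cum``
    and ``secreted_cum`` are the cumulative volumes absorbed from, and
    secreted into, the lumen since t = 0.  ``v_body`` is tracked only in
    the mass-conserving mode (None otherwise).
    """

    times: np.ndarray
    v_gi: np.ndarray
    v_ingested: np.ndarray
    v_secreted: np.ndarray
    absorbed_cum: np.ndarray
    secreted_cum: np.ndarray
    params: ModelParams
    mode: str
    v_body: np.ndarray | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_min": self.times,
                "v_gi_ml": self.v_gi,
                "v_ingested_ml": self.v_ingested,
                "v_secreted_ml": self.v_secreted,
                "absorbed_cum_ml": self.absorbed_cum,
                "secreted_cum_ml": self.secreted_cum,
            }
        )
        if self.v_body is not None:
            df["v_body_ml"] = self.v_body
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    return t


def simulate(p: ModelParams, times, mode: str = "constant_body") -> Trajectory:
    """Simulate the loop fluid time course.

    Parameters
    ----------
    p : ModelParams
    times : array-like
        Strictly increasing, non-negative output times (min).
    mode : {"constant_body", "conserving_body"}
        ``constant_body`` holds the body fluid pool fixed (the default; the
        closed form is then exact).  ``conserving_body`` integrates the
        coupled lumen/body pair numerically so that total water
        ``v_gi + v_body`` is conserved.
    """
    t = _validate_times(times)
    if mode == "constant_body":
        rate = secretion_input_rate(p)
        v_ss = steady_state_volume(p)
        decay = np.exp(-p.k_abs * t)
        v_ing = p.v0 * decay
        v_sec = v_ss * (1.0 - decay)
        v_gi = v_ing + v_sec
        sec_cum = rate * t
        abs_cum = p.v0 + sec_cum - v_gi
        return Trajectory(t, v_gi, v_ing, v_sec, abs_cum, sec_cum, p, mode)
    if mode == "conserving_body":
        return _simulate_conserving(p, t)
    raise ValidationError(f"unknown mode {mode!r}")


def _simulate_conserving(p: ModelParams, t: np.ndarray) -> Trajectory:
    # state: [v_ingested, v_secreted, v_body, absorbed_cum, secreted_cum]
    def rhs(_t, y):
        v_ing, v_sec, v_body = y[0], y[1], y[2]
        sec_rate = p.k_sec * v_body * p.s_ratio
        abs_rate = p.k_abs * (v_ing + v_sec)
        return [
            -p.k_abs * v_ing,
            -p.k_abs * v_sec + sec_rate,
            abs_rate - sec_rate,
            abs_rate,
            sec_rate,
        ]

    y0 = [p.v0, 0.0, p.v_body, 0.0, 0.0]
    if t[-1] == 0.0:  # only t = 0 requested
        cols = np.array(y0, dtype=float)[:, None]
        return Trajectory(
            t, cols[0] + cols[1], cols[0], cols[1], cols[3], cols[4], p,
            "conserving_body", cols[2],
        )
    t_eval = t if t[0] == 0.0 else np.concatenate([[0.0], t])
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA on a linear system
        raise EstimationError(f"ODE integration failed: {sol.message}")
    y = sol.y if t[0] == 0.0 else sol.y[:, 1:]
    v_ing, v_sec, v_body, abs_cum, sec_cum = y
    return Trajectory(
        t, v_ing + v_sec, v_ing, v_sec, abs_cum, sec_cum, p, "conserving_body", v_body
    )
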