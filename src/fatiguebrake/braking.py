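"""Ship emergency-braking distance, decomposed into three strokes.

An emergency stop from initial speed ``u`` is modelled as three phases:

1. reaction stroke ``S1 = u * t1`` - constant-speed travel while the driver
   reacts (t1 grows with fatigue);
2. reversing stroke ``S2 = u * (t2 - t1)`` - constant-speed travel while the
   engine spins down and reverses (the simplifying assumption: speed is held
   at ``u`` during reversing, which over-predicts distance and is therefore
   the safe standard);
3. braking stroke ``S3 = integral_0^u m V^2 / (R V + P) dV`` - deceleration
   to rest under maximum reverse thrust ``P`` (W) and linear-in-speed water
   resistance with coefficient ``R`` (N s/m), for a ship of full-load
   displacement ``m`` (kg).

The braking integral has the closed form

    S3 = m [ u^2/(2R) - P u / R^2 + (P^2 / R^3) ln(1 + R u / P) ]

with limit ``m u^3 / (3P)`` as R -> 0. The implementation evaluates the
equivalent cancellation-free form ``(m u^3 / P) g(x)`` with ``x = R u / P``
and ``g(x) = (x^2/2 - x + log1p(x)) / x^3`` (series for small x), and an
adaptive-quadrature route is provided as an independent check.

All quantities are SI internally; the CLI accepts km/h with explicit
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import integrate

__all__ = [
    "BrakingScenario",
    "BrakingResult",
    "ReactionTimeMap",
    "reaction_stroke",
    "reversing_stroke",
    "braking_stroke",
    "total_braking_distance",
    "fatigue_to_reaction_time",
    "load_scenario",
    "KMH_TO_MS",
]

KMH_TO_MS = 1000.0 / 3600.0


@dataclass(frozen=True)
class BrakingScenario:
    """Ship and driver parameters for one emergency stop.

    u: initial speed (m/s); t1: driver reaction time (s); t2: time from the
    danger signal to the end of engine reversing (s); m: full-load
    displacement (kg); R: water-resistance coefficient (N s/m, force = R*V);
    P: maximum reverse propeller power (W).
    """

    u: float
    t1: float
    t2: float
    m: float
    R: float
    P: float

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError("initial speed u must be >= 0")
        if self.t1 < 0:
            raise ValueError("reaction time t1 must be >= 0")
        if self.t2 < self.t1:
            raise ValueError(
                f"reversing must end after the reaction: t2={self.t2} < t1={self.t1}"
            )
        if self.m <= 0:
            raise ValueError("displacement m must be positive")
        if self.R < 0:
            raise ValueError("resistance coefficient R must be >= 0")
        if self.P <= 0:
            raise ValueError("reverse power P must be positive")


@dataclass(frozen=True)
class BrakingResult:
    """The three stroke lengths and their exact sum (meters)."""

    s1: float
    s2: float
    s3: float

    @property
    def s_total(self) -> float:
        return self.s1 + self.s2 + self.s3


@dataclass(frozen=True)
class ReactionTimeMap:
    """Affine, capped map from a fatigue score to driver reaction time.

    ``t1 = min(t_base + slope * fss, t_max)``. The linear form encodes only
    the direction reported for fatigue (longer reaction times); its slope is
    a tunable, not an estimate from data.
    """

    t_base: float = 1.0
    slope: float = 0.5
    t_max: float = 10.0

    def __post_init__(self) -> None:
        if self.t_base <= 0:
            raise ValueError("t_base must be positive")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.t_max < self.t_base:
            raise ValueError("t_max must be >= t_base")


def reaction_stroke(sc: BrakingScenario) -> float:
    """S1 = u * t1 (m)."""
    return sc.u * sc.t1


def reversing_stroke(sc: BrakingScenario) -> float:
    """S2 = u * (t2 - t1) (m), constant-speed simplification."""
    return sc.u * (sc.t2 - sc.t1)


def _g(x: float) -> float:
    """(x^2/2 - x + log1p(x)) / x^3, series-expanded near 0 for stability."""
    if x < 1e-3:
        # log1p expansion: numerator = x^3/3 - x^4/4 + x^5/5 - x^6/6 + ...
        return 1.0 / 3.0 - x / 4.0 + x**2 / 5.0 - x**3 / 6.0 + x**4 / 7.0
    return (0.5 * x * x - x + np.log1p(x)) / x**3


def braking_stroke(sc: BrakingScenario, method: str = "closed_form") -> float:
    """S3: distance to stop under reverse thrust and water resistance (m).

    ``closed_form`` evaluates the analytic antiderivative (stable for all
    R >= 0 including the R -> 0 limit m u^3/(3P)); ``quadrature`` integrates
    m V^2/(R V + P) adaptively and exists as an independent cross-check.
    """
    if sc.u == 0:
        return 0.0
    if method == "closed_form":
        x = sc.R * sc.u / sc.P
        return sc.m * sc.u**3 / sc.P * _g(x)
    if method == "quadrature":
        val, _ = integrate.quad(
            lambda v: sc.m * v * v / (sc.R * v + sc.P), 0.0, sc.u,
            epsabs=0.0, epsrel=1e-12,
        )
        return float(val)
    raise ValueError(f"method must be 'closed_form' or 'quadrature', got {method!r}")


def total_braking_distance(sc: BrakingScenario, method: str = "closed_form") -> BrakingResult:
    """All three strokes; ``s_total`` is exactly their sum."""
    return BrakingResult(
        s1=reaction_stroke(sc),
        s2=reversing_stroke(sc),
        s3=braking_stroke(sc, method=method),
    )


def fatigue_to_reaction_time(fss: float, rmap: ReactionTimeMap | None = None) -> float:
    """Driver reaction time (s) implied by a predicted fatigue score."""
    if fss < 0:
        raise ValueError(f"fatigue score must be >= 0, got {fss}")
    rmap = rmap or ReactionTimeMap()
    return min(rmap.t_base + rmap.slope * fss, rmap.t_max)


def load_scenario(path: str | Path, fss: float | None = None) -> BrakingScenario:
    """Build a scenario from a YAML config file.

    Keys: ``speed`` (+ optional ``speed_units``: ``m/s`` default or
    ``km/h``), ``reaction_time`` or a ``fatigue``/``reaction_map`` pair,
    ``reversing_time`` (t2 - t1, s), ``displacement`` (kg), ``resistance``
    (N s/m), ``reverse_power`` (W). A ``fss`` argument overrides the file's
    fatigue value.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    u = float(cfg["speed"])
    if str(cfg.get("speed_units", "m/s")).lower() in ("km/h", "kmh", "kph"):
        u *= KMH_TO_MS
    if fss is None:
        fss = cfg.get("fatigue")
    if "reaction_time" in cfg and fss is None:
        t1 = float(cfg["reaction_time"])
    else:
        if fss is None:
            raise ValueError("config needs either reaction_time or fatigue (or --fss)")
        rm = cfg.get("reaction_map", {})
        t1 = fatigue_to_reaction_time(float(fss), ReactionTimeMap(
            t_base=float(rm.get("t_base", 1.0)),
            slope=float(rm.get("slope", 0.5)),
            t_max=float(rm.get("t_max", 10.0)),
        ))
    return BrakingScenario(
        u=u,
        t1=t1,
        t2=t1 + float(cfg["reversing_time"]),
        m=float(cfg["displacement"]),
        R=float(cfg["resistance"]),
        P=float(cfg["reverse_power"]),
    )


def speed_time_curve(sc: BrakingScenario, n: int = 200) -> np.ndarray:
    """(t, v) samples of the simplified trajectory for plotting.

    Constant speed until t2, then deceleration under dV/dt = -(R V + P)/(m V)
    integrated numerically until rest.
    """
    ts = [0.0, sc.t2]
    vs = [sc.u, sc.u]
    if sc.u > 0:
        v = sc.u
        # dt = -m v / (R v + P) dv over a fine speed grid
        grid = np.linspace(sc.u, 0.0, n)
        t = sc.t2
        for v_next in grid[1:]:
            vm = 0.5 * (v + v_next)
            dt = sc.m * vm / (sc.R * vm + sc.P) * (v - v_next)
            t += dt
            ts.append(t)
            vs.append(v_next)
            v = v_next
    return np.column_stack([ts, vs])
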