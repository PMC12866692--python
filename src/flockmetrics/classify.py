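"""Four-state mechanical classification of a monolayer.

The observed states are defined comparatively: a jammed solid has
V_RMS ≈ 0, low L_CORR and minimal rearrangement; an unjammed disordered
fluid has elevated V_RMS but short-ranged correlation; a flocking fluid
combines high V_RMS with extended L_CORR; a flocking solid keeps the
alignment (high L_CORR) but shows little neighbor exchange.

The rule table makes those comparisons explicit with configurable
numeric thresholds (artifact constants calibrated once against the
simulator presets — the underlying biology only fixes the orderings):

    V_RMS < v_rms_low                                  → jammed_solid
    V_RMS ≥ v_rms_low, L_CORR < l_corr_low             → disordered fluid
    V_RMS ≥ v_rms_low, L_CORR ≥ l_corr_low,
        exchange slope ≥ exchange_slope_high           → flocking_fluid
        exchange slope < exchange_slope_high           → flocking_solid

ψ and the shape-index SD are recorded as supporting evidence but do not
split states (the state definitions split on V_RMS, L_CORR and neighbor
exchange; shape data may be absent entirely). Every call carries the
metrics and thresholds that produced it, so it is exactly re-derivable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np


@dataclass(frozen=True)
class StateThresholds:
    """Artifact constants, calibrated once against the simulator presets
    (the biology fixes only the orderings): arrested below 5 µm/h;
    correlated beyond one 50-µm PIV window; rearranging above an
    exchange-slope of 0.08 µm/h, with slopes below 0.02 reported as ≈ 0."""

    v_rms_low: float = 5.0              # µm/h
    l_corr_low: float = 50.0            # µm (one 50-µm PIV window)
    exchange_slope_low: float = 0.02    # µm/h, "≈ 0" band (reported only)
    exchange_slope_high: float = 0.08   # µm/h, fluid vs solid split
    si_sd_low: float | None = None      # optional supporting criterion

    def __post_init__(self) -> None:
        if not self.exchange_slope_low < self.exchange_slope_high:
            raise ValueError("exchange_slope_low must be below exchange_slope_high")


@dataclass
class TissueStateCall:
    state: str
    metrics: dict
    thresholds: dict
    rationale: str = ""
    reasons_unclassifiable: list = field(default_factory=list)


REQUIRED_METRICS = ("v_rms", "l_corr", "exchange_slope")

STATES = (
    "jammed_solid",
    "unjammed_disordered_fluid",
    "flocking_fluid",
    "flocking_solid",
)


def classify_state(metrics: dict, thresholds: StateThresholds | None = None) -> TissueStateCall:
    """Apply the rule table to a metric bundle.

    ``metrics`` must carry ``v_rms`` (µm/h, framecut mean), ``l_corr``
    (µm, fitted) and ``exchange_slope`` (µm/h); ``psi`` and ``si_sd`` are
    recorded when present. Missing metrics raise; a not-converged or NaN
    L_CORR makes the call explicitly "unclassifiable" (with reasons)
    unless V_RMS already places the tissue in the jammed branch.
    """
    th = thresholds or StateThresholds()
    missing = [k for k in REQUIRED_METRICS if k not in metrics]
    if missing:
        raise ValueError(f"missing metrics for classification: {', '.join(missing)}")
    v_rms = float(metrics["v_rms"])
    l_corr = float(metrics["l_corr"]) if metrics["l_corr"] is not None else np.nan
    slope = float(metrics["exchange_slope"])

    def call(state: str, why: str) -> TissueStateCall:
        return TissueStateCall(
            state=state, metrics=dict(metrics), thresholds=asdict(th), rationale=why
        )

    if not np.isfinite(v_rms):
        return TissueStateCall(
            "unclassifiable", dict(metrics), asdict(th),
            reasons_unclassifiable=["V_RMS undefined"],
        )
    if v_rms < th.v_rms_low:
        return call(
            "jammed_solid",
            f"V_RMS {v_rms:.2f} < {th.v_rms_low} µm/h: arrested monolayer",
        )
    if not np.isfinite(l_corr):
        return TissueStateCall(
            "unclassifiable", dict(metrics), asdict(th),
            reasons_unclassifiable=["L_CORR not converged"],
        )
    if l_corr < th.l_corr_low:
        return call(
            "unjammed_disordered_fluid",
            f"V_RMS {v_rms:.2f} ≥ {th.v_rms_low} with short-ranged correlation "
            f"(L_CORR {l_corr:.1f} < {th.l_corr_low} µm)",
        )
    if not np.isfinite(slope):
        return TissueStateCall(
            "unclassifiable", dict(metrics), asdict(th),
            reasons_unclassifiable=["exchange slope undefined"],
        )
    if slope >= th.exchange_slope_high:
        return call(
            "flocking_fluid",
            f"aligned (L_CORR {l_corr:.1f} µm) and rearranging "
            f"(Δd slope {slope:.2f} ≥ {th.exchange_slope_high} µm/h)",
        )
    return call(
        "flocking_solid",
        f"aligned (L_CORR {l_corr:.1f} µm) with suppressed neighbor exchange "
        f"(Δd slope {slope:.2f} < {th.exchange_slope_high} µm/h)",
    )


__all__ = ["STATES", "StateThresholds", "TissueStateCall", "classify_state"]
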