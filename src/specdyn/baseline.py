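"""Baseline correction of time-frequency power.

Four correction variants are compared against the raw decomposition:
decibel ``10*log10(data/B)``, relative change ``(data-B)/B``, normalised
change ``(data-B)/(data+B)`` and absolute change ``data-B``, where ``B`` is
the time-mean of power in a pre-stimulus window, computed per subject,
condition, channel and frequency after trial averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tfr import TimeFrequencyRepresentation

__all__ = ["BaselineSpec", "BASELINE_METHODS", "BASELINE_WINDOWS", "apply_baseline"]

BASELINE_METHODS = ("decibel", "relative_change", "normalized_change",
                    "absolute_change")
BASELINE_WINDOWS = ((-0.5, -0.2), (-0.3, 0.0), (-0.5, 0.0))


@dataclass(frozen=True)
class BaselineSpec:
    """Correction method plus pre-stimulus window (seconds, end <= 0)."""

    method: str = "decibel"
    window: tuple = (-0.5, -0.2)

    def __post_init__(self):
        if self.method not in BASELINE_METHODS:
            raise ValueError(
                f"unknown baseline method {self.method!r}; "
                f"choose one of {BASELINE_METHODS}"
            )
        start, end = self.window
        if not (start < end <= 0):
            raise ValueError("baseline window must satisfy start < end <= 0")


def _correct(data: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    if method == "decibel":
        return 10.0 * np.log10(data / b)
    if method == "relative_change":
        return (data - b) / b
    if method == "normalized_change":
        return (data - b) / (data + b)
    if method == "absolute_change":
        return data - b
    raise ValueError(f"unknown baseline method {method!r}")


def apply_baseline(tfr: TimeFrequencyRepresentation,
                   spec: BaselineSpec) -> TimeFrequencyRepresentation:
    """Return a baseline-corrected copy of ``tfr``.

    The baseline ``B`` is the arithmetic time-mean of power inside the
    window, per subject x condition x channel x frequency.  Ratio-based
    methods require a strictly positive baseline; a violation raises with
    the offending channel/frequency indices.  Note the corrected values are
    no longer non-negative raw power.
    """
    start, end = spec.window
    times = tfr.times
    if start < times[0] or end > times[-1]:
        raise ValueError(
            f"baseline window {spec.window} outside epoch "
            f"({times[0]:.3f}, {times[-1]:.3f}) s"
        )
    mask = (times >= start) & (times <= end)
    if tfr.valid is not None:
        mask = mask & np.all(tfr.valid, axis=0)
    if not np.any(mask):
        raise ValueError("baseline window contains no valid timepoints")

    b = tfr.power[..., mask].mean(axis=-1, keepdims=True)
    if spec.method != "absolute_change":
        bad = ~(b > 0) & np.isfinite(b)
        if np.any(bad):
            locs = np.argwhere(bad[..., 0])
            s, c, ch, f = locs[0]
            raise ValueError(
                f"non-positive baseline under {spec.method!r}: first at "
                f"subject {s}, condition {c}, channel {ch}, "
                f"frequency {tfr.frequencies[f]:g} Hz "
                f"({len(locs)} cells total)"
            )
    corrected = _correct(tfr.power, b, spec.method)
    return replace(tfr, power=corrected,
                   params={**tfr.params, "baseline": (spec.method, spec.window)})
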