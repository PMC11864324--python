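"""Response-shape classification and critical loads.

The realized shape of a fitted deposition response over a unit's observed
deposition range defines an ordered vulnerability scale:

    increase (0) < flat (1) < unimodal/sigmoid (2) < decrease (3)

A unimodal N response whose peak lies beyond the observed maximum is, over
the window actually sampled, monotone increasing; a peak below the observed
minimum leaves only the decreasing limb.  Critical loads follow from the
fitted parameters: the N critical load is the lognormal peak ``n1`` (the
deposition above which the response begins to decline), the lognormal-S
critical load is ``s1``, and the sigmoid-S critical load is found by
inverting the sigmoid at a chosen fractional reduction ``f``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .core import DomainError, sulfur_sigmoid
from .fitting import SelectionOutcome

__all__ = [
    "Shape",
    "ResponseShape",
    "CriticalLoad",
    "classify_n_shape",
    "classify_s_shape",
    "critical_load_direct",
    "critical_load_sigmoid",
]


class Shape(enum.IntEnum):
    """Ordered vulnerability categories (ascending vulnerability)."""

    INCREASE = 0
    FLAT = 1
    UNIMODAL_SIGMOID = 2
    DECREASE = 3

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Shape.INCREASE: "increase",
    Shape.FLAT: "flat",
    Shape.UNIMODAL_SIGMOID: "unimodal_or_sigmoid",
    Shape.DECREASE: "decrease",
}
_FROM_LABEL = {v: k for k, v in _LABELS.items()}


def shape_from_label(label: str) -> Optional[Shape]:
    if label == "not_applicable":
        return None
    return _FROM_LABEL[label]


@dataclass
class ResponseShape:
    pollutant: str  # "N" | "S"
    shape: Optional[Shape]  # None == not_applicable (excluded unit)

    @property
    def label(self) -> str:
        return "not_applicable" if self.shape is None else self.shape.label


@dataclass
class CriticalLoad:
    """A deposition threshold in kg ha^-1 yr^-1, or undefined.

    ``basis`` records how the value was obtained: the N lognormal peak
    (``n1``), the lognormal S location (``s1_lognormal``), or inversion of
    the S sigmoid at reduction fraction ``f`` (``sigmoid_inversion``).
    """

    pollutant: str
    endpoint: str
    value: Optional[float]
    basis: str
    f: Optional[float] = None
    note: str = ""


def classify_n_shape(selected: SelectionOutcome,
                     n_range: tuple[float, float]) -> ResponseShape:
    """Classify the N response over the unit's observed deposition range.

    The lognormal N term peaks at ``n1``: a peak at or above the observed
    maximum leaves a monotone increasing realized curve, at or below the
    minimum a monotone decreasing one, and a strictly interior peak is
    unimodal.  Units without an N term are flat; excluded units are
    not_applicable.
    """
    if selected.status != "selected":
        return ResponseShape("N", None)
    n_min, n_max = n_range
    if not (n_min < n_max):
        raise DomainError("degenerate N range: N_min must be < N_max")
    spec = selected.selected_fit.spec
    if not spec.has_N:
        return ResponseShape("N", Shape.FLAT)
    n1 = selected.selected_fit.params.n1
    if n1 >= n_max:
        return ResponseShape("N", Shape.INCREASE)
    if n1 <= n_min:
        return ResponseShape("N", Shape.DECREASE)
    return ResponseShape("N", Shape.UNIMODAL_SIGMOID)


def classify_s_shape(selected: SelectionOutcome) -> ResponseShape:
    """Classify the S response from the selected model's S form.

    The sigmoid form is flat at low deposition then declines (category 2);
    the lognormal form is constrained to its decreasing limb over the data
    (category 3); no S term is flat.
    """
    if selected.status != "selected":
        return ResponseShape("S", None)
    s_form = selected.selected_fit.spec.s_form
    if s_form == "none":
        return ResponseShape("S", Shape.FLAT)
    if s_form == "lognormal":
        return ResponseShape("S", Shape.DECREASE)
    return ResponseShape("S", Shape.UNIMODAL_SIGMOID)


def critical_load_direct(params, pollutant: str, s_form: str = "none",
                         endpoint: str = "") -> CriticalLoad:
    """Critical load read directly off the fitted parameters.

    N: the lognormal peak ``n1``.  Lognormal S: the location ``s1``.  Returns
    an undefined load (value None) when the term is absent from the selected
    model, with the reason in ``note``.
    """
    if pollutant == "N":
        n1 = getattr(params, "n1", None)
        if n1 is None:
            return CriticalLoad("N", endpoint, None, "n1",
                                note="selected model has no N term")
        return CriticalLoad("N", endpoint, float(n1), "n1")
    if pollutant == "S":
        if s_form != "lognormal":
            return CriticalLoad("S", endpoint, None, "s1_lognormal",
                                note="selected model has no lognormal S term")
        s1 = getattr(params, "s1", None)
        if s1 is None:
            return CriticalLoad("S", endpoint, None, "s1_lognormal",
                                note="selected model has no S term")
        return CriticalLoad("S", endpoint, float(s1), "s1_lognormal")
    raise DomainError(f"unknown pollutant {pollutant!r}")


def critical_load_sigmoid(s1: float, s2: float, s3: float, f: float,
                          endpoint: str = "") -> CriticalLoad:
    """Invert the S sigmoid at fractional reduction ``f``.

    Solves ``s3 + (1-s3)/(1+(S/s1)**s2) = 1 - f`` for S, giving

        CL = s1 * (f / (1 - f - s3)) ** (1/s2)

    ``f`` must satisfy ``0 < f < 1 - s3``: a reduction deeper than the
    curve's plateau never occurs, and that case is reported as undefined
    rather than clipped.
    """
    if s1 <= 0 or s2 <= 0:
        raise DomainError("s1 and s2 must be positive")
    if not (0 <= s3 < 1):
        raise DomainError("s3 must lie in [0, 1)")
    if not (0 < f < 1):
        raise DomainError("f must lie in (0, 1)")
    denom = 1.0 - f - s3
    if f >= 1.0 - s3 or denom <= 0.0:
        return CriticalLoad(
            "S", endpoint, None, "sigmoid_inversion", f=f,
            note=f"f={f} reaches the plateau (1-s3={1 - s3:.4g}); "
                 "the response never declines that far")
    value = s1 * (f / denom) ** (1.0 / s2)
    # invariant: the sigmoid at the computed load returns exactly 1 - f
    assert abs(sulfur_sigmoid(value, s1, s2, s3) - (1.0 - f)) < 1e-6 * max(1.0, 1.0 - f)
    return CriticalLoad("S", endpoint, float(value), "sigmoid_inversion", f=f)
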