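"""Discrete force-time descriptors of the trial-averaged handgrip curve.

The scalar summaries conventionally reported alongside the functional
analysis: peak force and its time, the 63.2 %-of-peak point, force at test
end, rates of force development over the early (0-250 ms), rise-to-63.2 %,
63.2 %-to-peak and decay windows, and the static fatigability index

    FI = 100 * (Area1 - Area2) / Area1,

where Area1 = F_max * (t_final - t_max) is the area of a hypothetical
perfectly sustained peak and Area2 is the actual area under the curve from
the peak to the end of the test (trapezoidal rule).

All descriptors are computed on the filtered, onset-aligned mean curve (the
same curve the statistical mapping uses), with off-grid instants evaluated
by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DescriptorError
from .preprocess import ForceTrace
from .segmentation import KeyInstants

#: Canonical descriptor order for reports and group comparisons.
DESCRIPTOR_NAMES = (
    "F_max", "t_max", "F_63", "t_63", "F_final",
    "RFD250", "RFD1", "RFD2", "RFD3", "FI",
)


@dataclass
class DescriptorRow:
    """All scalar descriptors of one participant's mean curve."""

    participant: str
    group: str
    F_max: float
    t_max: float
    F_63: float
    t_63: float
    F_final: float
    RFD250: float
    RFD1: float
    RFD2: float
    RFD3: float
    FI: float
    area1: float
    area2: float
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"participant": self.participant, "group": self.group}
        d.update({k: getattr(self, k) for k in DESCRIPTOR_NAMES})
        d.update({"area1": self.area1, "area2": self.area2})
        return d


def fatigability_index(
    trace: ForceTrace, ki: KeyInstants
) -> tuple[float, float, float]:
    """Static fatigability index and its two areas (kgf·s).

    Raises
    ------
    DescriptorError
        If the curve peaks at the very end (no decay window exists).
    """
    if not ki.t_max < ki.t_final:
        raise DescriptorError("no post-peak window: t_max == t_final")
    t, f = trace.t, trace.f
    i0 = int(np.searchsorted(t, ki.t_max - 1e-12))
    # t_max is the first-maximum sample, hence on the grid
    area2 = float(np.trapezoid(f[i0:], t[i0:]))
    area1 = ki.F_max * (ki.t_final - ki.t_max)
    return 100.0 * (area1 - area2) / area1, area1, area2


def compute_descriptors(
    trace: ForceTrace, ki: KeyInstants, participant: str = "", group: str = ""
) -> DescriptorRow:
    """All discrete descriptors of one mean curve.

    Undefined quantities (coincident key instants) are reported as NaN with a
    note rather than aborting the cohort; timing descriptors are reported
    relative to onset, so they do not depend on where the curve sits on the
    clock.
    """
    notes: list[str] = []
    t, f = trace.t, trace.f
    F_250 = float(np.interp(ki.t_250, t, f))
    RFD250 = (F_250 - ki.F_onset) / 0.250
    dt63 = ki.t_63 - ki.t_onset
    RFD1 = (ki.F_63 - ki.F_onset) / dt63
    if ki.t_max - ki.t_63 <= 0:
        RFD2 = float("nan")
        notes.append("RFD2 undefined: t_max == t_63")
    else:
        RFD2 = (ki.F_max - ki.F_63) / (ki.t_max - ki.t_63)
    if ki.t_final - ki.t_max <= 0:
        RFD3 = 0.0  # peak sustained to the very end: no decay by convention
    else:
        RFD3 = (ki.F_final - ki.F_max) / (ki.t_final - ki.t_max)
    try:
        FI, area1, area2 = fatigability_index(trace, ki)
    except DescriptorError as exc:
        FI, area1, area2 = float("nan"), float("nan"), float("nan")
        notes.append(str(exc))
    return DescriptorRow(
        participant=participant,
        group=group,
        F_max=ki.F_max,
        t_max=ki.t_max - ki.t_onset,
        F_63=ki.F_63,
        t_63=dt63,
        F_final=ki.F_final,
        RFD250=RFD250,
        RFD1=RFD1,
        RFD2=RFD2,
        RFD3=RFD3,
        FI=FI,
        area1=area1,
        area2=area2,
        notes=notes,
    )


def descriptor_table(rows: list[DescriptorRow]) -> pd.DataFrame:
    """One row per participant, columns in canonical order."""
    return pd.DataFrame([r.as_dict() for r in rows])
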