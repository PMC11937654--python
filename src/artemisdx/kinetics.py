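"""Plate-reader kinetics: parsing, baseline removal, endpoint ratios.

The detection readout is collateral (trans) cleavage of a quenched
fluorescent reporter: target-activated Cas12a cuts the reporter and
fluorescence grows over time.  Plate readers export the kinetic run as a
delimited matrix with time in the first column and one column per well.
Analysis here mirrors the usual baseline-and-ratio treatment: subtract a
baseline (each trace's first timepoint, or the timepoint-wise mean of a
negative-control group), then compare replicate groups by the ratio of
their mean endpoint fluorescence, with the standard deviation of the
ratio from first-order (quotient) error propagation.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticTrace",
    "RatioResult",
    "parse_kinetic_table",
    "traces_to_frame",
    "write_kinetic_table",
    "baseline_subtract",
    "endpoint_ratio",
]


@dataclass(frozen=True)
class KineticTrace:
    """One well's fluorescence time course (times in minutes, values in A.U.)."""

    well_id: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    group: str = "ungrouped"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError(f"{self.well_id}: times and values differ in length")
        if len(self.times) == 0:
            raise ValueError(f"{self.well_id}: empty trace")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError(f"{self.well_id}: times must be strictly increasing")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"{self.well_id}: non-finite fluorescence value")

    def value_at(self, timepoint: float) -> float:
        try:
            return self.values[self.times.index(timepoint)]
        except ValueError:
            raise ValueError(
                f"{self.well_id}: no sample at t={timepoint} min "
                f"(trace covers {self.times[0]}-{self.times[-1]} min)"
            ) from None


@dataclass(frozen=True)
class RatioResult:
    """Replicate-aggregated endpoint fluorescence ratio between two groups."""

    numerator_group: str
    denominator_group: str
    ratio: float
    sd: float
    n_numerator: int
    n_denominator: int

    def __post_init__(self) -> None:
        if self.n_numerator < 1 or self.n_denominator < 1:
            raise ValueError("each group needs at least one replicate")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def parse_kinetic_table(
    path: str | Path, layout: Mapping[str, str] | None = None
) -> list[KineticTrace]:
    """Parse a wells-as-columns × timepoints-as-rows delimited matrix.

    The first column is time in minutes; every remaining column is one
    well, named in the header.  Wells absent from ``layout`` get the
    group ``"ungrouped"``.  Ragged rows, non-numeric cells and duplicate
    well headers are errors.
    """
    text = Path(path).read_text()
    delimiter = _sniff_delimiter(text[:4096])
    header = next(csv.reader(io.StringIO(text), delimiter=delimiter))
    wells = [h.strip() for h in header[1:]]
    dupes = {w for w in wells if wells.count(w) > 1}
    if dupes:
        raise ValueError(f"duplicate well column header(s): {sorted(dupes)}")
    df = pd.read_csv(io.StringIO(text), sep=delimiter)
    if df.isna().any().any():
        raise ValueError("kinetic table has ragged rows or empty cells")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in kinetic table: {exc}") from exc
    times = tuple(float(t) for t in df.iloc[:, 0])
    layout = layout or {}
    return [
        KineticTrace(
            well_id=well,
            times=times,
            values=tuple(float(v) for v in df[col]),
            group=layout.get(well, "ungrouped"),
        )
        for well, col in zip(wells, df.columns[1:])
    ]


def traces_to_frame(traces: Sequence[KineticTrace]) -> pd.DataFrame:
    """Tidy (well, group, time, value) frame for export."""
    rows = [
        {"well": t.well_id, "group": t.group, "time_min": tm, "value": v}
        for t in traces
        for tm, v in zip(t.times, t.values)
    ]
    return pd.DataFrame(rows, columns=["well", "group", "time_min", "value"])


def write_kinetic_table(traces: Sequence[KineticTrace], path: str | Path) -> None:
    """Serialize traces back to the wells-as-columns matrix (lossless for
    numeric cells)."""
    times = traces[0].times
    for t in traces:
        if t.times != times:
            raise ValueError("all traces must share the same time axis")
    df = pd.DataFrame({"time_min": list(times)})
    for t in traces:
        df[t.well_id] = list(t.values)
    df.to_csv(path, index=False)


def baseline_subtract(
    trace: KineticTrace,
    mode: Literal["first_timepoint", "control_group_mean"] = "first_timepoint",
    controls: Sequence[KineticTrace] = (),
) -> KineticTrace:
    """Remove baseline fluorescence from one trace.

    ``first_timepoint`` subtracts the trace's own t0 value, so every
    corrected trace starts at exactly 0; ``control_group_mean`` subtracts,
    timepoint-wise, the mean of the negative-control traces (which must
    share the time axis).
    """
    if mode == "first_timepoint":
        base = np.full(len(trace.values), trace.values[0])
    elif mode == "control_group_mean":
        if not controls:
            raise ValueError("control_group_mean requires a non-empty control group")
        for c in controls:
            if c.times != trace.times:
                raise ValueError("control traces must share the trace's time axis")
        base = np.mean([c.values for c in controls], axis=0)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    corrected = tuple(float(v) for v in np.asarray(trace.values) - base)
    return replace(trace, values=corrected)


def endpoint_ratio(
    traces: Sequence[KineticTrace],
    numerator: str,
    denominator: str,
    timepoint: Literal["last"] | float = "last",
) -> RatioResult:
    """Ratio of mean endpoint fluorescence between two replicate groups.

    ``timepoint`` is the last common timepoint by default, or an explicit
    time in minutes (which must be sampled in every trace).  The ratio's
    standard deviation comes from first-order propagation of the two
    group standard deviations (sample sd, ddof=1; 0 for n=1):
    ``sd = |r| * sqrt((s_n/m_n)^2 + (s_d/m_d)^2)``.
    """
    groups: dict[str, list[KineticTrace]] = {}
    for t in traces:
        groups.setdefault(t.group, []).append(t)
    for label in (numerator, denominator):
        if not groups.get(label):
            raise ValueError(f"group {label!r} is empty or absent")
    if timepoint == "last":
        tp = min(t.times[-1] for t in groups[numerator] + groups[denominator])
    else:
        tp = float(timepoint)
    num = np.array([t.value_at(tp) for t in groups[numerator]], dtype=float)
    den = np.array([t.value_at(tp) for t in groups[denominator]], dtype=float)
    mean_n, mean_d = float(num.mean()), float(den.mean())
    if mean_d == 0:
        raise ZeroDivisionError(
            f"denominator group {denominator!r} has zero mean at t={tp} min"
        )
    sd_n = float(num.std(ddof=1)) if len(num) > 1 else 0.0
    sd_d = float(den.std(ddof=1)) if len(den) > 1 else 0.0
    ratio = mean_n / mean_d
    # general quotient form; equals |r|*sqrt((s_n/m_n)^2+(s_d/m_d)^2) for m_n != 0
    sd = math.sqrt((sd_n / mean_d) ** 2 + (ratio * sd_d / mean_d) ** 2)
    return RatioResult(
        numerator_group=numerator,
        denominator_group=denominator,
        ratio=ratio,
        sd=sd,
        n_numerator=len(num),
        n_denominator=len(den),
    )
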