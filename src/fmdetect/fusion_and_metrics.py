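"""Six-axis mask fusion and event-level TDR/PPV evaluation.

Each window yields a 6-bit mask Mk(1:6) — one bit per accelerometer axis,
1 meaning that axis's detector called FM. The fused window label is the
logical OR of the bits: if one or more axes of either sensor sees fetal
movement, the window is FM. Windows vetoed by the artifact gate carry an
all-zero mask.

Runs of consecutive FM windows are merged into detected events and scored
against the maternally perceived intervals:

    TDR = 100 * DME / TMF,     PPV = 100 * DME / (DME + FD),

where TMF is the number of annotated (perceived) events, DME the number of
annotated events that at least one detected event overlaps (each annotated
event counted once, however many detections overlap it), and FD the number
of detected events overlapping no annotation. Any nonzero temporal overlap
matches. Percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .artifact_gate import AxisState, GateFlag, GateOutcome
from .detectors import AxisDecision, Label
from .errors import ContractError, MetricsUndefinedError
from .signal_model import DEFAULT_WINDOW_SECONDS, EventInterval


@dataclass
class WindowDecision:
    """Fused decision for one window: mask bits, label, and the gate flag."""

    window_index: int
    mask: tuple[int, ...]  # 6 bits, 1 = FM on that axis
    fused_label: Label
    gate_flag: GateFlag
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mask) != 6 or any(b not in (0, 1) for b in self.mask):
            raise ContractError(f"mask must be 6 binary values, got {self.mask}")
        if (self.fused_label is Label.FM) != (sum(self.mask) >= 1):
            raise ContractError("fused label must be FM iff any mask bit is 1")
        if self.gate_flag is GateFlag.ARTIFACT and sum(self.mask) != 0:
            raise ContractError("an ARTIFACT window must carry an all-zero mask")


@dataclass
class MetricsReport:
    """Event counts and the derived TDR/PPV percentages."""

    TMF: int
    DME: int
    FD: int
    TDR: float
    PPV: float

    def as_row(self, subject: str = "all") -> str:
        return f"{subject}\t{self.TMF}\t{self.DME}\t{self.FD}\t{self.TDR:.2f}\t{self.PPV:.2f}"


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (table formatting convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fuse_masks(axis_decisions, gate: GateOutcome,
               start_s: float = 0.0) -> WindowDecision:
    """Fuse six per-axis outcomes into one window decision.

    ``axis_decisions`` holds exactly six entries, one per axis: an
    :class:`AxisDecision` for axes the gate passed to a detector, or None
    for suppressed axes (which contribute a 0 bit).
    """
    decisions = list(axis_decisions)
    if len(decisions) != 6:
        raise ContractError(f"expected exactly 6 axis entries, got {len(decisions)}")
    bits = []
    for i, (dec, state) in enumerate(zip(decisions, gate.per_axis)):
        is_fm = (
            dec is not None
            and state is AxisState.CANDIDATE
            and dec.label is Label.FM
        )
        bits.append(1 if is_fm else 0)
    mask = tuple(bits)
    fused = Label.FM if sum(mask) >= 1 else Label.NON_FM
    return WindowDecision(
        window_index=gate.window_index,
        mask=mask,
        fused_label=fused,
        gate_flag=gate.window_flag,
        start_s=start_s,
    )


def decisions_to_events(decisions, window_seconds: float = DEFAULT_WINDOW_SECONDS):
    """Merge maximal runs of consecutive FM windows into detected intervals.

    ``decisions`` must be ordered by window index; each run of consecutive
    FM windows becomes one interval [first_start, last_start + window_seconds).
    """
    events: list[EventInterval] = []
    run_start: float | None = None
    prev_index: int | None = None
    prev_start = 0.0
    for dec in decisions:
        if dec.fused_label is Label.FM:
            if run_start is None or (prev_index is not None and dec.window_index != prev_index + 1):
                if run_start is not None:
                    events.append(EventInterval(run_start, prev_start + window_seconds, "FM_detected"))
                run_start = dec.start_s
            prev_index = dec.window_index
            prev_start = dec.start_s
        else:
            if run_start is not None:
                events.append(EventInterval(run_start, prev_start + window_seconds, "FM_detected"))
                run_start = None
            prev_index = dec.window_index
    if run_start is not None:
        events.append(EventInterval(run_start, prev_start + window_seconds, "FM_detected"))
    return events


def metrics_from_counts(TMF: int, DME: int, FD: int) -> MetricsReport:
    """Build a report from raw event counts (TDR/PPV per the definitions)."""
    if TMF == 0:
        raise MetricsUndefinedError("TDR is undefined when no events are annotated (TMF == 0)")
    if not 0 <= DME <= TMF:
        raise ContractError(f"DME must satisfy 0 <= DME <= TMF, got DME={DME}, TMF={TMF}")
    if FD < 0:
        raise ContractError("FD must be non-negative")
    tdr = round_half_up(100.0 * DME / TMF)
    ppv = 0.0 if DME + FD == 0 else round_half_up(100.0 * DME / (DME + FD))
    return MetricsReport(TMF=TMF, DME=DME, FD=FD, TDR=tdr, PPV=ppv)


def compute_metrics(detected, truth) -> MetricsReport:
    """Score detected event intervals against annotated ground truth.

    A truth event counts as detected (DME) if at least one detected interval
    overlaps it; a detected interval overlapping no truth event is one false
    detection (FD). Multiple detections overlapping one truth event count as
    a single DME with no extra FD.
    """
    detected = list(detected)
    truth = list(truth)
    if len(truth) == 0:
        raise MetricsUndefinedError("TDR is undefined when no events are annotated (TMF == 0)")
    dme = sum(1 for t in truth if any(t.overlaps(d) for d in detected))
    fd = sum(1 for d in detected if not any(d.overlaps(t) for t in truth))
    return metrics_from_counts(TMF=len(truth), DME=dme, FD=fd)
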