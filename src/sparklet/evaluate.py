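"""Recovery scoring of detections against simulator ground truth.

A detected event matches a true channel opening when it lies within a
small radius of the opening's site and their time spans overlap (the
opening span is padded by a few decay half-lives, since fluorescence
outlasts the open state).  One detected event may match several true
openings: openings that overlap in time at one site merge into a single
multi-level episode in the trace, which the detector correctly reports
as one event.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detect import CandidateEvent
from .simulate import GroundTruth

__all__ = ["MatchResult", "match_events"]


@dataclass
class MatchResult:
    n_truth: int
    n_detected: int
    n_truth_matched: int
    n_detected_matched: int
    pairs: list[tuple[int, int]]  # (opening index, event index)

    @property
    def recall(self) -> float:
        return 1.0 if self.n_truth == 0 else self.n_truth_matched / self.n_truth

    @property
    def precision(self) -> float:
        return 1.0 if self.n_detected == 0 else self.n_detected_matched / self.n_detected


def match_events(
    truth: GroundTruth,
    events: list[CandidateEvent],
    max_dist_um: float = 3.0,
    pad_s: float | None = None,
) -> MatchResult:
    """Score detected events against true openings.

    ``pad_s`` extends each opening's interval to cover the fluorescence
    tail; the default is three decay half-lives of the configured
    kinetics.
    """
    if pad_s is None:
        pad_s = 3.0 * truth.config.decay_half_ms / 1000.0
    pairs: list[tuple[int, int]] = []
    matched_truth: set[int] = set()
    matched_det: set[int] = set()
    for oi, op in enumerate(truth.openings):
        site = truth.sites[op.site]
        for ei, ev in enumerate(events):
            d2 = (ev.x_um - site.x_um) ** 2 + (ev.y_um - site.y_um) ** 2
            if d2 > max_dist_um**2:
                continue
            if ev.t_start <= op.t_close + pad_s and op.t_open - pad_s <= ev.t_end:
                pairs.append((oi, ei))
                matched_truth.add(oi)
                matched_det.add(ei)
    return MatchResult(
        n_truth=len(truth.openings),
        n_detected=len(events),
        n_truth_matched=len(matched_truth),
        n_detected_matched=len(matched_det),
        pairs=pairs,
    )
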