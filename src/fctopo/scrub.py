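"""Motion scrubbing: frame censoring and the minimum-duration inclusion rule.

Frames are censored when framewise displacement (FD, mm) or the temporal
derivative of the signal variance (DVARS, %) strictly exceeds its
threshold; subjects are retained only if enough uncensored data remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FrameMask:
    """Boolean keep-mask over the original frames."""

    keep: np.ndarray

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def __len__(self) -> int:
        return len(self.keep)


@dataclass
class SubjectTimeSeries:
    """Regional BOLD time courses with per-frame motion summaries."""

    subject_id: str
    data: np.ndarray  # frames x nodes
    tr_seconds: float
    fd: np.ndarray  # mm
    dvars: np.ndarray  # percent

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        n = self.data.shape[0]
        if len(self.fd) != n or len(self.dvars) != n:
            raise ValueError(
                f"subject {self.subject_id}: fd/dvars length must equal frame count {n}"
            )
        if np.isnan(self.data).any() or np.isnan(self.fd).any() or np.isnan(self.dvars).any():
            raise ValueError(f"subject {self.subject_id}: missing values not allowed")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def scrub_frames(
    ts: SubjectTimeSeries,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 0.5,
    drop_initial: int = 0,
) -> tuple[SubjectTimeSeries, FrameMask]:
    """Censor high-motion frames.

    A frame is removed iff it is among the first ``drop_initial`` frames, or
    FD > ``fd_thresh``, or DVARS > ``dvars_thresh`` (strict inequalities:
    frames exactly at threshold are kept). Retained frames keep their
    original order.
    """
    if fd_thresh <= 0 or dvars_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if drop_initial >= ts.n_frames:
        raise ValueError("drop_initial must be smaller than the frame count")
    keep = (ts.fd <= fd_thresh) & (ts.dvars <= dvars_thresh)
    keep[:drop_initial] = False
    if not keep.any():
        raise ValueError(f"all frames removed for subject {ts.subject_id}")
    mask = FrameMask(keep=keep)
    scrubbed = SubjectTimeSeries(
        subject_id=ts.subject_id,
        data=ts.data[keep],
        tr_seconds=ts.tr_seconds,
        fd=ts.fd[keep],
        dvars=ts.dvars[keep],
    )
    return scrubbed, mask


def check_inclusion(mask: FrameMask, tr_seconds: float, min_minutes: float = 4.0) -> bool:
    """True iff the retained data span at least ``min_minutes`` (inclusive)."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return mask.n_kept * tr_seconds >= min_minutes * 60.0
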