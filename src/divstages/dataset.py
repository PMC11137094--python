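"""Container for per-cycle (birth size, division size) observations.

All analyses work on normalized lengths: every size is divided by the mean
size at birth of the retained records, so that ``<s_b> = 1`` and conclusions
are scale-free.  Records with ``s_d <= s_b`` (segmentation artifacts in real
data; the model assigns them zero density) or non-positive sizes are dropped
and counted, never silently ignored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulator import CellCycleRecord

__all__ = ["Dataset"]

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Normalized single-cell cycle data for one growth condition."""

    s_b: np.ndarray
    s_d: np.ndarray
    tau: np.ndarray | None = None
    label: str = ""
    normalization: float = 1.0  # original <s_b> before rescaling
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_b = np.asarray(self.s_b, dtype=float)
        self.s_d = np.asarray(self.s_d, dtype=float)
        if self.s_b.shape != self.s_d.shape or self.s_b.ndim != 1:
            raise ValueError("s_b and s_d must be 1-D arrays of equal length")
        if self.N == 0:
            raise ValueError("dataset contains no valid records")
        if np.any(self.s_b <= 0) or np.any(self.s_d <= self.s_b):
            raise ValueError("dataset invariant violated: require 0 < s_b < s_d; use from_raw()")

    # ------------------------------------------------------------------ accessors
    @property
    def N(self) -> int:
        return self.s_b.size

    @property
    def delta(self) -> np.ndarray:
        """Added size per cycle, ``Delta = s_d - s_b``."""
        return self.s_d - self.s_b

    @property
    def mean_sd(self) -> float:
        return float(self.s_d.mean())

    # ------------------------------------------------------------------ construction
    @classmethod
    def from_raw(
        cls,
        s_b,
        s_d,
        tau=None,
        label: str = "",
        normalize: bool = True,
        meta: dict | None = None,
    ) -> "Dataset":
        """Filter invalid records, normalize by ``<s_b>`` and build a Dataset."""
        s_b = np.asarray(s_b, dtype=float)
        s_d = np.asarray(s_d, dtype=float)
        valid = np.isfinite(s_b) & np.isfinite(s_d) & (s_b > 0) & (s_d > s_b)
        n_dropped = int((~valid).sum())
        if n_dropped:
            logger.info("dropped %d of %d records with s_d <= s_b or non-positive sizes", n_dropped, s_b.size)
        s_b, s_d = s_b[valid], s_d[valid]
        if s_b.size == 0:
            raise ValueError("no valid records remain after filtering")
        if tau is not None:
            tau = np.asarray(tau, dtype=float)[valid]
        norm = float(s_b.mean()) if normalize else 1.0
        return cls(
            s_b=s_b / norm,
            s_d=s_d / norm,
            tau=tau,
            label=label,
            normalization=norm,
            n_dropped=n_dropped,
            meta=dict(meta or {}),
        )

    @classmethod
    def from_records(
        cls,
        records: Sequence[CellCycleRecord],
        label: str = "",
        normalize: bool = True,
        meta: dict | None = None,
    ) -> "Dataset":
        s_b = np.array([r.s_b for r in records])
        s_d = np.array([r.s_d for r in records])
        tau = np.array([r.tau for r in records])
        return cls.from_raw(s_b, s_d, tau=tau, label=label, normalize=normalize, meta=meta)

    # ------------------------------------------------------------------ export
    def to_frame(self) -> pd.DataFrame:
        cols = {"size_at_birth": self.s_b, "size_at_division": self.s_d, "added_size": self.delta}
        if self.tau is not None:
            cols["division_time"] = self.tau
        frame = pd.DataFrame(cols)
        if self.label:
            frame["condition"] = self.label
        return frame
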