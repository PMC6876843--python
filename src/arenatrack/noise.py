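"""Imaging-noise monitor: skip corrupt frames, trigger reacquisition.

The count of above-threshold pixels in the difference image is a cheap,
sensitive summary of segmentation quality: a nudged arena, flickering
light or codec glitch all inflate it far beyond what the animals
themselves produce.  The monitor samples that count's distribution under
known-clean imaging as a baseline, then flags a frame as noisy when the
rolling mean of recent counts exceeds ``baseline_mean + k_flag *
max(baseline_std, 1)``.  Flagged frames contribute no positions; a run of
``m_reacquire`` consecutive noisy frames forces background reacquisition.
"""

from __future__ import annotations

from collections import deque

import numpy as np

__all__ = ["NoiseState", "sample_baseline"]


class NoiseState:
    """Baseline plus rolling statistics of above-threshold pixel counts."""

    def __init__(
        self,
        baseline_mean: float,
        baseline_std: float,
        window: int = 10,
        k_flag: float = 5.0,
        m_reacquire: int = 10,
    ):
        if baseline_std < 0:
            raise ValueError("baseline_std must be >= 0")
        self.baseline_mean = float(baseline_mean)
        self.baseline_std = float(baseline_std)
        self.window = int(window)
        self.k_flag = float(k_flag)
        self.m_reacquire = int(m_reacquire)
        self.rolling: deque[float] = deque(maxlen=self.window)
        self.consecutive_noisy = 0

    def evaluate(self, count: float) -> str:
        """Push one frame's count; return ``"clean"`` or ``"noisy"``."""
        self.rolling.append(float(count))
        rolling_mean = sum(self.rolling) / len(self.rolling)
        limit = self.baseline_mean + self.k_flag * max(self.baseline_std, 1.0)
        if rolling_mean > limit:
            self.consecutive_noisy += 1
            return "noisy"
        self.consecutive_noisy = 0
        return "clean"

    def should_reacquire(self) -> bool:
        return self.consecutive_noisy >= self.m_reacquire

    def reset_after_reacquire(self) -> None:
        """Clear the rolling buffer and the consecutive-noisy counter."""
        self.rolling.clear()
        self.consecutive_noisy = 0

    def rebaseline(self, counts) -> None:
        """Update the baseline in place after reacquisition settles.

        The update ratchets: a freshly reacquired reference absorbs the
        animals, so counts right after reacquisition underestimate the
        clean steady state, and adopting them wholesale would make the
        animals' reappearance look like noise (a reacquisition feedback
        loop).  Mean and spread therefore only ever move up.
        """
        counts = np.asarray(list(counts), dtype=float)
        self.baseline_mean = max(self.baseline_mean, float(counts.mean()))
        self.baseline_std = max(self.baseline_std, float(counts.std()))


def sample_baseline(
    counts,
    window: int = 10,
    k_flag: float = 5.0,
    m_reacquire: int = 10,
) -> NoiseState:
    """Baseline statistics from clean-imaging counts (at least 30)."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size < 30:
        raise ValueError("baseline sampling needs at least 30 counts")
    return NoiseState(
        baseline_mean=float(counts.mean()),
        baseline_std=float(counts.std()),
        window=window,
        k_flag=k_flag,
        m_reacquire=m_reacquire,
    )
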