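"""Block-design visual sustained-attention task (VSAT) timing and regressors.

The task alternates task and rest blocks. Within a task block a cue is
shown, then a three-digit target sequence, a short break, and nine probe
sequences each followed by a response period. Durations are held as exact
rationals so the design arithmetic (block length, run length) is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ParadigmSpec",
    "block_duration",
    "total_duration",
    "double_gamma_hrf",
    "task_boxcar",
    "task_regressor",
]


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x).limit_denominator(10**9)


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing of one run of the block-design attention task.

    Defaults give 30 s blocks and a 5 min run: a 0.8 s cue, three digits at
    0.4 s each, a 1.0 s break, then nine 3-digit probe sequences each
    followed by a 1.8 s response window, with five task and five rest blocks.
    """

    cue_s: float = 0.8
    digit_s: float = 0.4
    target_len: int = 3
    break_s: float = 1.0
    n_sequences: int = 9
    response_s: float = 1.8
    n_task_blocks: int = 5
    n_rest_blocks: int = 5
    rest_first: bool = True

    def __post_init__(self) -> None:
        for name in ("cue_s", "digit_s", "break_s", "response_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.target_len < 1 or self.n_task_blocks < 1 or self.n_rest_blocks < 0:
            raise ValueError("counts must be positive")

    @property
    def block_s(self) -> float:
        return float(self.block_duration())

    @property
    def total_s(self) -> float:
        return float(self.total_duration() * 60)

    def block_duration(self) -> Fraction:
        """Exact block length in seconds."""
        cue, digit, brk, resp = map(
            _frac, (self.cue_s, self.digit_s, self.break_s, self.response_s)
        )
        seq = self.target_len * digit
        return cue + seq + brk + self.n_sequences * (seq + resp)

    def total_duration(self) -> Fraction:
        """Exact run length in minutes."""
        return (self.n_task_blocks + self.n_rest_blocks) * self.block_duration() / 60


def block_duration(p: ParadigmSpec) -> float:
    """Length of one block in seconds (exact arithmetic, returned as float)."""
    return float(p.block_duration())


def total_duration(p: ParadigmSpec) -> float:
    """Length of the whole run in minutes."""
    return float(p.total_duration())


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t``.

    Positive gamma with mode at ``peak_delay`` s minus a ``ratio``-scaled
    undershoot with mode at ``undershoot_delay`` s (gamma shape = delay + 1
    at unit rate, so the mode falls exactly on the stated delay);
    peak-normalized to 1.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / dispersion

    def gpdf(x, shape):
        # gamma pdf with rate 1, via log for stability
        return np.exp((shape - 1) * np.log(x) - x - gammaln(shape))

    h = gpdf(tp, peak_delay + 1) - ratio * gpdf(tp, undershoot_delay + 1)
    out[pos] = h
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out


def task_boxcar(p: ParadigmSpec, dt: float) -> np.ndarray:
    """0/1 indicator of task blocks sampled every ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    block = float(p.block_duration())
    total = float(p.total_duration() * 60)
    t = np.arange(0.0, total, dt)
    block_idx = np.floor(t / block).astype(int)
    on = (block_idx % 2 == 1) if p.rest_first else (block_idx % 2 == 0)
    # trailing blocks beyond the alternating span are rest
    on &= block_idx < (p.n_task_blocks + p.n_rest_blocks)
    return on.astype(float)


def task_regressor(
    p: ParadigmSpec,
    sampling_interval: float,
    hrf_params: dict | None = None,
    oversample: int = 10,
) -> np.ndarray:
    """Boxcar convolved with the HRF, unit-peak-normalized.

    ``hrf_params`` may override :func:`double_gamma_hrf` keywords, or map
    ``{"kind": "delta"}`` to an identity HRF (regressor equals the boxcar).
    The convolution runs on a grid ``oversample`` times finer than the
    sampling interval and is then decimated back.
    """
    hrf_params = dict(hrf_params or {})
    dt = sampling_interval / oversample
    box = task_boxcar(p, dt)
    if hrf_params.pop("kind", "double_gamma") == "delta":
        reg_fine = box
    else:
        t_hrf = np.arange(0.0, 32.0 + dt, dt)
        hrf = double_gamma_hrf(t_hrf, **hrf_params)
        reg_fine = np.convolve(box, hrf)[: len(box)] * dt
    reg = reg_fine[::oversample]
    n = int(round(float(p.total_duration() * 60) / sampling_interval))
    reg = reg[:n]
    peak = np.abs(reg).max()
    if peak > 0:
        reg = reg / peak
    return reg
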