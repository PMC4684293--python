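import math

import numpy as np
import pytest

from wiggleindex import FrameStack


def naive_sigma_fw(frames: np.ndarray, F: int) -> np.ndarray:
    """Triple-loop reference: per-pixel population SD in each rolling window."""
    N, H, W = frames.shape
    n_win = N - F + 1
    out = np.zeros((n_win, H, W))
    for w in range(n_win):
        for i in range(H):
            for j in range(W):
                seg = frames[w : w + F, i, j]
                mu = seg.mean()
                out[w, i, j] = math.sqrt(((seg - mu) ** 2).mean())
    return out


def naive_sigma_s(sfw: np.ndarray) -> np.ndarray:
    """Triple-loop reference: per-pixel population SD of the sigma_FW series."""
    n_win, H, W = sfw.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            seg = sfw[:, i, j]
            mu = seg.mean()
            out[i, j] = math.sqrt(((seg - mu) ** 2).mean())
    return out


def naive_wi(sigma_s_map: np.ndarray, T: float, denominator: str = "all") -> tuple[float, int]:
    vals = [v for row in sigma_s_map for v in row if v >= T]
    if not vals:
        return 0.0, 0
    if denominator == "above":
        return sum(vals) / len(vals), len(vals)
    return sum(vals) / sigma_s_map.size, len(vals)


@pytest.fixture
def random_stack():
    """Factory for small random 8-bit integer stacks."""

    def make(shape=(12, 8, 8), seed=0, frame_rate=25.0):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 200, size=shape).astype(float)
        return FrameStack(frames=frames, frame_rate=frame_rate, source_id=f"rand{seed}")

    return make
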