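import numpy as np
import pandas as pd
import pytest

from stimchar import RatingMatrix, SyntheticVideoSpec, make_motion_video


@pytest.fixture
def quiet_clip():
    """60-frame 200x200 clip, 30x30 patch of step 120 appearing at frame 10."""
    spec = SyntheticVideoSpec(onset_frame=10, seed=7)
    seq, truth = make_motion_video(spec)
    return seq, truth


@pytest.fixture
def hand_ratings():
    """2 items, 3 raters: votes (A, A, B) and (B, B, B); kappa = 0.25."""
    ratings = pd.DataFrame(
        {"r1": ["A", "B"], "r2": ["A", "B"], "r3": ["B", "B"]},
        index=["item1", "item2"],
    )
    return RatingMatrix(ratings=ratings, labels=("A", "B"))


@pytest.fixture
def small_truth_ratings():
    """3 items x 2 raters with truth, small enough to count by hand."""
    ratings = pd.DataFrame(
        {
            "r1": ["Normal", "How", "What"],
            "r2": ["How", "How", "What"],
        },
        index=["v1", "v2", "v3"],
    )
    truth = pd.Series(["Normal", "How", "What"], index=ratings.index)
    return RatingMatrix(ratings=ratings, truth=truth)


def flood_fill_boxes(mask: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Brute-force 8-connected component bounding boxes: (x, y, w, h), 1-based.

    Independent of the implementation under test; plain stack-based fill.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask, dtype=bool)
    H, W = mask.shape
    boxes = []
    for i in range(H):
        for j in range(W):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            rmin = rmax = i
            cmin = cmax = j
            while stack:
                r, c = stack.pop()
                rmin, rmax = min(rmin, r), max(rmax, r)
                cmin, cmax = min(cmin, c), max(cmax, c)
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            boxes.append((cmin + 1, rmin + 1, cmax - cmin + 1, rmax - rmin + 1))
    boxes.sort(key=lambda b: (b[1], b[0]))
    return boxes
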